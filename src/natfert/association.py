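"""Relatedness-corrected association of genotype with a quantitative trait.

The measured-genotype model: y ~ N(X beta, Sigma) with
Sigma = sigma2_a * 2*Phi + sigma2_e * I, where Phi is the pedigree kinship
matrix.  Variance components are estimated once by maximum likelihood under
the null (covariates-only) model and the resulting Sigma is reused for
every genotype coding at a locus.  Significance is an F-statistic comparing
null and alternative generalized-least-squares fits on the whitened scale;
the Amish-style variant reports a Wald t on the additive coefficient.

Genotype codings at a biallelic locus (g = count of the derived allele):

* ``general``        g and a heterozygosity indicator (2 df);
* ``recessive_met``  carrier indicator 1[g >= 1]: homozygotes for the
  ancestral allele against everyone else (1 df);
* ``additive``       g alone (1 df).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

__all__ = [
    "CODING_SCHEMES",
    "coding_columns",
    "VarianceComponents",
    "estimate_variance_components",
    "AssocResult",
    "gls_association",
    "wald_t_additive",
    "percent_variance",
    "bonferroni",
    "effect_summary",
]

CODING_SCHEMES = ("general", "recessive_met", "additive")


def coding_columns(g: np.ndarray, scheme: str) -> tuple[np.ndarray, list[str]]:
    """Design columns for a coding scheme from derived-allele counts g."""
    g = np.asarray(g, dtype=float)
    if not np.isin(g, (0.0, 1.0, 2.0)).all():
        raise ValueError("genotype counts must be 0, 1 or 2")
    if scheme == "general":
        return np.column_stack([g, (g == 1).astype(float)]), ["additive", "dominance"]
    if scheme == "recessive_met":
        return (g >= 1).astype(float)[:, None], ["carrier"]
    if scheme == "additive":
        return g[:, None], ["additive"]
    raise ValueError(f"unknown coding scheme {scheme!r}; use one of {CODING_SCHEMES}")


@dataclass(frozen=True)
class VarianceComponents:
    sigma2_a: float
    sigma2_e: float
    h2: float
    loglik: float
    converged: bool
    sigma2_d: float = 0.0

    def covariance(self, A: np.ndarray) -> np.ndarray:
        """Sigma = sigma2_a * A + sigma2_e * I with A = 2*Phi."""
        return self.sigma2_a * A + self.sigma2_e * np.eye(A.shape[0])


def estimate_variance_components(
    y: np.ndarray,
    X: np.ndarray | None,
    Phi: np.ndarray,
    n_grid: int = 101,
) -> VarianceComponents:
    """ML variance components of y ~ N(X a, sigma2_a*2Phi + sigma2_e*I).

    The likelihood is profiled over the heritability ratio
    h = sigma2_a / (sigma2_a + sigma2_e) using the eigendecomposition of
    A = 2*Phi, then refined by bounded scalar optimization.  Ties (a flat
    likelihood, e.g. unrelated samples where sigma2_a is unidentifiable)
    resolve to the smaller h, so the additive component hits the 0 boundary.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if np.ptp(y) == 0:
        raise ValueError("phenotype has zero variance; components undefined")
    if X is None:
        X = np.ones((n, 1))
    else:
        X = np.asarray(X, dtype=float).reshape(n, -1)
        has_const = any(np.ptp(X[:, j]) == 0 and X[0, j] != 0
                        for j in range(X.shape[1]))
        if not has_const:
            X = np.column_stack([np.ones(n), X])
    A = 2.0 * np.asarray(Phi, dtype=float)
    w_eig, U = linalg.eigh(A)
    if w_eig.min() < -1e-8 * max(1.0, w_eig.max()):
        raise ValueError("2*Phi is not positive semidefinite")
    w_eig = np.clip(w_eig, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    def neg_profile_ll(h: float) -> float:
        wv = h * w_eig + (1.0 - h)
        if wv.min() <= 0:
            return np.inf
        sw = 1.0 / np.sqrt(wv)
        Xw = Xt * sw[:, None]
        yw = yt * sw
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        rss = float(np.sum((yw - Xw @ beta) ** 2))
        if rss <= 0:
            return np.inf
        return 0.5 * (n * np.log(rss / n) + np.sum(np.log(wv)))

    hs = np.linspace(0.0, 0.999, n_grid)
    vals = np.array([neg_profile_ll(h) for h in hs])
    k = int(np.argmin(vals))
    lo = hs[max(k - 1, 0)]
    hi = hs[min(k + 1, n_grid - 1)]
    res = optimize.minimize_scalar(neg_profile_ll, bounds=(lo, hi),
                                   method="bounded",
                                   options={"xatol": 1e-6})
    h_hat, f_hat = (float(res.x), float(res.fun)) if res.fun <= vals[k] \
        else (float(hs[k]), float(vals[k]))
    # flat likelihood -> boundary at 0 (parsimony tie-break)
    if neg_profile_ll(0.0) <= f_hat + 1e-9:
        h_hat, f_hat = 0.0, float(neg_profile_ll(0.0))
    wv = h_hat * w_eig + (1.0 - h_hat)
    sw = 1.0 / np.sqrt(wv)
    Xw, yw = Xt * sw[:, None], yt * sw
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    sigma2 = float(np.sum((yw - Xw @ beta) ** 2)) / n
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + np.sum(np.log(wv)) + n)
    return VarianceComponents(
        sigma2_a=h_hat * sigma2,
        sigma2_e=(1.0 - h_hat) * sigma2,
        h2=h_hat,
        loglik=ll,
        converged=bool(getattr(res, "success", True)),
    )


@dataclass
class AssocResult:
    """Outcome of one genotype-coding test at one locus."""

    scheme: str
    beta: dict[str, float]
    se: dict[str, float]
    statistic: float
    stat_name: str  # "F" or "t"
    df: tuple
    p_value: float
    p_bonferroni: float
    pct_variance_explained: float
    rss_null: float
    rss_alt: float
    n: int
    lower_fertility_allele: str | None = None
    dropped_columns: list[str] = field(default_factory=list)

    def apply_bonferroni(self, n_tests: int) -> "AssocResult":
        self.p_bonferroni = bonferroni(self.p_value, n_tests)
        return self


def _whiten(Sigma: np.ndarray) -> np.ndarray:
    try:
        L = linalg.cholesky(Sigma, lower=True)
    except linalg.LinAlgError as e:
        raise ValueError("covariance matrix is singular or not PD") from e
    return L


def _drop_degenerate(cols: np.ndarray, names: list[str], base: np.ndarray):
    """Remove genotype columns that are constant or collinear with the base
    design (e.g. no homozygote class present); warn rather than fail."""
    keep, dropped = [], []
    for j, name in enumerate(names):
        c = cols[:, j]
        trial = np.column_stack([base] + [cols[:, k] for k in keep] + [c])
        if np.ptp(c) == 0 or np.linalg.matrix_rank(trial) < trial.shape[1]:
            dropped.append(name)
        else:
            keep.append(j)
    if dropped:
        warnings.warn(
            f"dropping degenerate genotype column(s) {dropped}", stacklevel=3
        )
    return cols[:, keep], [names[j] for j in keep], dropped


def gls_association(
    y: np.ndarray,
    X_cov: np.ndarray | None,
    g: np.ndarray,
    scheme: str,
    Sigma: np.ndarray,
    n_tests: int = 1,
    ancestral: str = "Met",
    derived: str = "Val",
) -> AssocResult:
    """GLS F-test of genotype coding columns over a covariate-only null.

    Both models are whitened by the Cholesky factor of Sigma and fit by
    least squares; F = [(RSS0 - RSS1)/q] / [RSS1/(n - p1)].  With
    Sigma = sigma^2 * I this reproduces ordinary least squares exactly.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    base = np.ones((n, 1)) if X_cov is None else np.column_stack(
        [np.ones(n), np.atleast_2d(np.asarray(X_cov, dtype=float)).reshape(n, -1)]
    )
    cols, names, dropped = _drop_degenerate(
        *coding_columns(np.asarray(g), scheme), base=base
    )
    if cols.shape[1] == 0:
        raise ValueError(
            f"no informative genotype column left under coding {scheme!r}"
        )
    L = _whiten(np.asarray(Sigma, dtype=float))
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw0 = linalg.solve_triangular(L, base, lower=True)
    Xw1 = linalg.solve_triangular(L, np.column_stack([base, cols]), lower=True)

    beta0, *_ = np.linalg.lstsq(Xw0, yw, rcond=None)
    rss0 = float(np.sum((yw - Xw0 @ beta0) ** 2))
    beta1, *_ = np.linalg.lstsq(Xw1, yw, rcond=None)
    resid1 = yw - Xw1 @ beta1
    rss1 = float(np.sum(resid1 ** 2))
    q = cols.shape[1]
    p1 = Xw1.shape[1]
    df2 = n - p1
    F = ((rss0 - rss1) / q) / (rss1 / df2)
    p = float(stats.f.sf(F, q, df2))

    s2 = rss1 / df2
    XtX_inv = np.linalg.pinv(Xw1.T @ Xw1)
    ses = np.sqrt(np.diag(XtX_inv) * s2)
    geno_beta = {nm: float(b) for nm, b in zip(names, beta1[base.shape[1]:])}
    geno_se = {nm: float(s) for nm, s in zip(names, ses[base.shape[1]:])}

    key = "carrier" if "carrier" in geno_beta else "additive"
    direction = None
    if key in geno_beta:
        # positive derived-allele/carrier effect => ancestral allele lowers it
        direction = ancestral if geno_beta[key] > 0 else derived
    return AssocResult(
        scheme=scheme,
        beta=geno_beta,
        se=geno_se,
        statistic=float(F),
        stat_name="F",
        df=(q, df2),
        p_value=p,
        p_bonferroni=bonferroni(p, n_tests),
        pct_variance_explained=percent_variance(rss0, rss1),
        rss_null=rss0,
        rss_alt=rss1,
        n=n,
        lower_fertility_allele=direction,
        dropped_columns=dropped,
    )


def wald_t_additive(
    y: np.ndarray,
    X_cov: np.ndarray | None,
    g: np.ndarray,
    Phi: np.ndarray,
    n_tests: int = 1,
    vc: VarianceComponents | None = None,
    ancestral: str = "Met",
    derived: str = "Val",
) -> AssocResult:
    """Measured-genotype Wald t-test of the additive SNP coefficient.

    The polygenic component enters through Sigma from the ML variance
    components estimated under the covariates-only null; the test is
    t = beta_hat / SE(beta_hat) from the GLS fit, two-sided.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if vc is None:
        vc = estimate_variance_components(y, X_cov, Phi)
    Sigma = vc.covariance(2.0 * np.asarray(Phi, dtype=float))
    res = gls_association(y, X_cov, g, "additive", Sigma,
                          n_tests=n_tests, ancestral=ancestral, derived=derived)
    beta = res.beta["additive"]
    se = res.se["additive"]
    t = beta / se
    df = res.df[1]
    p = float(2.0 * stats.t.sf(abs(t), df))
    res.statistic = float(t)
    res.stat_name = "t"
    res.df = (df,)
    res.p_value = p
    res.p_bonferroni = bonferroni(p, n_tests)
    return res


def percent_variance(rss_null: float, rss_alt: float) -> float:
    """Percent phenotypic variance explained: (RSS0 - RSS1)/RSS0 * 100."""
    if rss_alt > rss_null * (1 + 1e-12):
        raise ValueError("alternative RSS exceeds null RSS")
    if rss_null <= 0:
        raise ValueError("null RSS must be positive")
    return float(max(0.0, (rss_null - rss_alt) / rss_null) * 100.0)


def bonferroni(p: float, n_tests: int) -> float:
    """Conservative multiple-testing correction: min(1, p * n_tests)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0,1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return float(min(1.0, p * n_tests))


def effect_summary(per_year_effect: float, mean_reproductive_years: float) -> float:
    """Births deficit over an average reproductive span, 2-decimal report.

    E.g. a 0.049 births/yr deficit over an 11.5-yr span is 0.56 fewer births.
    """
    return round(abs(per_year_effect) * mean_reproductive_years, 2)
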