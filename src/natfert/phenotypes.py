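"""Birth-rate phenotype construction from reproductive histories.

The phenotype is the birth rate of a married man with at least two
children: (number of births - 1) / (sum of interbirth intervals).  Because
the intervals telescope, the denominator equals the span from first to last
birth; both are computed and must agree.  Rates are residualized on two
covariates — wife's birth year and years from marriage to last birth — by
ordinary least squares, and the residuals feed the relatedness-corrected
association tests.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ReproductiveHistory",
    "BirthRatePhenotype",
    "ExcludedRecord",
    "birth_rate",
    "build_phenotypes",
    "covariate_table",
    "residualize",
    "NormalityReport",
    "normality_check",
    "read_histories",
    "write_histories",
]


class ExcludedRecord(Exception):
    """A history that does not qualify for the phenotype (not an error).

    Raised with a reason; pipeline code catches it and reports exclusions.
    """


@dataclass(frozen=True)
class ReproductiveHistory:
    """Marriage and ordered birth timeline of one man, in decimal years."""

    individual_id: str
    marriage_year: float
    wife_birth_year: float
    birth_years: tuple[float, ...]
    observation_end: float

    def __post_init__(self):
        ys = self.birth_years
        if any(b > a for a, b in zip(ys[1:], ys)):
            raise ValueError(f"{self.individual_id}: birth years not sorted")
        if ys and not (self.marriage_year <= ys[0] <= self.observation_end):
            raise ValueError(
                f"{self.individual_id}: first birth outside "
                "[marriage_year, observation_end]"
            )

    @property
    def n_births(self) -> int:
        return len(self.birth_years)

    @property
    def marriage_to_last_birth(self) -> float:
        if not self.birth_years:
            raise ExcludedRecord(f"{self.individual_id}: no births")
        return self.birth_years[-1] - self.marriage_year


@dataclass(frozen=True)
class BirthRatePhenotype:
    individual_id: str
    n_births: int
    rate: float  # births per year


def birth_rate(history: ReproductiveHistory) -> BirthRatePhenotype:
    """Births per year over the reproductive span.

    rate = (n_births - 1) / sum(interbirth intervals); requires >= 2 births
    and a positive span.  Twin births contribute a zero-length interval.
    Raises :class:`ExcludedRecord` for non-qualifying histories.
    """
    ys = history.birth_years
    if len(ys) < 2:
        raise ExcludedRecord(f"{history.individual_id}: fewer than two births")
    gaps = np.diff(ys)
    total = float(gaps.sum())
    span = ys[-1] - ys[0]
    assert abs(total - span) < 1e-9, "interval sum must telescope to the span"
    if total <= 0:
        raise ExcludedRecord(f"{history.individual_id}: zero reproductive span")
    return BirthRatePhenotype(history.individual_id, len(ys), (len(ys) - 1) / total)


def build_phenotypes(
    histories: Iterable[ReproductiveHistory],
) -> tuple[list[BirthRatePhenotype], dict[str, str]]:
    """Phenotype every qualifying history; return (phenotypes, exclusions)."""
    phenos, excluded = [], {}
    for h in histories:
        try:
            phenos.append(birth_rate(h))
        except ExcludedRecord as e:
            excluded[h.individual_id] = str(e)
    return phenos, excluded


def covariate_table(histories: Sequence[ReproductiveHistory]) -> pd.DataFrame:
    """The two covariates of the fertility model, indexed by individual."""
    return pd.DataFrame(
        {
            "wife_birth_year": [h.wife_birth_year for h in histories],
            "marriage_to_last_birth": [
                h.marriage_to_last_birth if h.birth_years else float("nan")
                for h in histories
            ],
        },
        index=[h.individual_id for h in histories],
    )


def residualize(
    phenos: Sequence[BirthRatePhenotype], covariates: pd.DataFrame
) -> pd.Series:
    """OLS residuals of birth rate on the covariates (with intercept).

    Complete cases only; residuals have mean 0 and are orthogonal to every
    covariate column.  Raises on a rank-deficient design.
    """
    ids = [p.individual_id for p in phenos]
    X = covariates.loc[ids].astype(float)
    y = pd.Series([p.rate for p in phenos], index=ids, name="birth_rate")
    mask = X.notna().all(axis=1) & y.notna()
    X, y = X[mask], y[mask]
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    fit = sm.OLS(y, design).fit()
    return fit.resid.rename("birth_rate_residual")


@dataclass(frozen=True)
class NormalityReport:
    n: int
    skewness: float
    kurtosis: float  # excess kurtosis
    shapiro_p: float
    degenerate: bool

    @property
    def rejected_at(self):
        return lambda alpha: (not self.degenerate) and self.shapiro_p < alpha


def normality_check(residuals: Sequence[float]) -> NormalityReport:
    """Advisory normality diagnostics (Shapiro–Wilk); never blocks a run."""
    x = np.asarray(residuals, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        return NormalityReport(int(x.size), float("nan"), float("nan"),
                               float("nan"), degenerate=True)
    _, p = stats.shapiro(x)
    return NormalityReport(
        int(x.size),
        float(stats.skew(x)),
        float(stats.kurtosis(x)),
        float(p),
        degenerate=False,
    )


# ---------------------------------------------------------------------------
# CSV interface: individual_id, marriage_year, wife_birth_year,
# birth_years (semicolon-separated), observation_end.

def read_histories(path: str | Path) -> list[ReproductiveHistory]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(filter(lambda l: not l.startswith("#"), fh)):
            births = tuple(
                float(b) for b in row["birth_years"].split(";") if b.strip()
            )
            out.append(
                ReproductiveHistory(
                    row["individual_id"],
                    float(row["marriage_year"]),
                    float(row["wife_birth_year"]),
                    births,
                    float(row["observation_end"]),
                )
            )
    return out


def write_histories(histories: Iterable[ReproductiveHistory],
                    path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["individual_id", "marriage_year", "wife_birth_year",
                    "birth_years", "observation_end"])
        for h in histories:
            w.writerow([h.individual_id, f"{h.marriage_year:.3f}",
                        f"{h.wife_birth_year:.3f}",
                        ";".join(f"{b:.3f}" for b in h.birth_years),
                        f"{h.observation_end:.3f}"])
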