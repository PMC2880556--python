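"""Selection-signature statistics on haplotype panels and allele counts.

* Weir–Cockerham theta (Fst) for two populations from allele counts, in the
  allele-frequency (haploid ANOVA) formulation, with a genotype-level,
  heterozygosity-aware variant available for diploid genotype counts.
* Extended haplotype homozygosity (EHH): the probability that two randomly
  chosen chromosomes carrying the core allele are identical at every SNP
  from the core out to distance x.
* iHH: trapezoidal area under the EHH curve, truncated where EHH first
  drops below a cutoff (0.05 by default), summed over both directions.
* Unstandardized iHS = ln(iHH_ancestral / iHH_derived); negative values
  mean the derived-allele haplotypes are longer.  Standardization is a
  z-score within bins of derived-allele frequency.
* Empirical marginal and joint tail fractions against a genome-wide
  (fst, ihs) distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "FstResult",
    "weir_cockerham_theta",
    "weir_cockerham_theta_genotypic",
    "HaplotypePanel",
    "EHHCurve",
    "ehh",
    "ihh",
    "IHSResult",
    "ihs_unstandardized",
    "standardize_ihs",
    "empirical_percentile",
    "read_hap_legend",
    "read_phased_vcf",
]


# ---------------------------------------------------------------------------
# Weir–Cockerham theta

@dataclass(frozen=True)
class FstResult:
    n1: int
    n2: int
    p1: float
    p2: float
    msp: float  # mean square among populations
    msg: float  # mean square within (among alleles/genes)
    theta: float
    undefined: bool = False
    method: str = "allele"


def weir_cockerham_theta(n1: int, x1: int, n2: int, x2: int) -> FstResult:
    """Weir–Cockerham theta from allele counts of two populations.

    ``n_i`` sampled alleles, ``x_i`` derived-allele counts.  Haploid ANOVA
    form: with MSP the among-population and MSG the within-population mean
    square of allele indicators,

        theta = (MSP - MSG) / (MSP + (n_c - 1) * MSG),

    n_c the usual sample-size correction.  The estimator is unbiased, so it
    is slightly negative at zero differentiation and exactly 1 when the
    populations are fixed for opposite alleles.  Symmetric in population
    order and invariant to swapping allele labels.
    """
    for n, x in ((n1, x1), (n2, x2)):
        if n < 2:
            raise ValueError("need at least 2 sampled alleles per population")
        if not 0 <= x <= n:
            raise ValueError("derived count outside [0, n]")
    p1, p2 = x1 / n1, x2 / n2
    if (x1 == 0 and x2 == 0) or (x1 == n1 and x2 == n2):
        return FstResult(n1, n2, p1, p2, 0.0, 0.0, float("nan"), undefined=True)
    ns = np.array([n1, n2], dtype=float)
    ps = np.array([p1, p2], dtype=float)
    n_tot = ns.sum()
    p_bar = float((ns * ps).sum() / n_tot)
    r = 2
    msp = float((ns * (ps - p_bar) ** 2).sum() / (r - 1))
    msg = float((ns * ps * (1 - ps)).sum() / (ns - 1).sum())
    n_c = float((n_tot - (ns ** 2).sum() / n_tot) / (r - 1))
    theta = (msp - msg) / (msp + (n_c - 1) * msg)
    return FstResult(n1, n2, p1, p2, msp, msg, float(theta))


def weir_cockerham_theta_genotypic(
    n1: int, geno1: Sequence[int], n2: int, geno2: Sequence[int]
) -> FstResult:
    """Heterozygosity-aware Weir–Cockerham theta from diploid genotype counts.

    ``geno_i = (n_AA, n_Aa, n_aa)`` for n_i individuals.  Implements the
    two-population a/b/c variance components with the observed
    heterozygote frequencies (the full diploid estimator, labelled
    ``method="genotypic"``).
    """
    g1 = np.asarray(geno1, float)
    g2 = np.asarray(geno2, float)
    if g1.sum() != n1 or g2.sum() != n2:
        raise ValueError("genotype counts must sum to the sample size")
    ns = np.array([n1, n2], dtype=float)
    ps = np.array(
        [(2 * g1[0] + g1[1]) / (2 * n1), (2 * g2[0] + g2[1]) / (2 * n2)]
    )
    hs = np.array([g1[1] / n1, g2[1] / n2])  # observed het frequencies
    if ps.min() == ps.max() and ps[0] in (0.0, 1.0):
        return FstResult(int(n1), int(n2), ps[0], ps[1], 0.0, 0.0,
                         float("nan"), undefined=True, method="genotypic")
    r = 2
    n_bar = ns.mean()
    n_c = (ns.sum() - (ns ** 2).sum() / ns.sum()) / (r - 1)
    p_bar = float((ns * ps).sum() / ns.sum())
    s2 = float((ns * (ps - p_bar) ** 2).sum() / ((r - 1) * n_bar))
    h_bar = float((ns * hs).sum() / ns.sum())
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    denom = a + b + c
    theta = a / denom if denom != 0 else float("nan")
    return FstResult(int(n1), int(n2), float(ps[0]), float(ps[1]),
                     a, b + c, float(theta),
                     undefined=not np.isfinite(theta), method="genotypic")


# ---------------------------------------------------------------------------
# EHH / iHH / iHS

@dataclass
class HaplotypePanel:
    """Phased binary haplotypes (0 = ancestral, 1 = derived) around a core SNP."""

    haplotypes: np.ndarray  # (n_hap, n_snp) in {0,1}
    positions: np.ndarray  # physical bp, strictly increasing
    core_index: int
    genetic_map: np.ndarray | None = None  # cM, optional

    def __post_init__(self):
        H = np.asarray(self.haplotypes)
        if not np.isin(H, (0, 1)).all():
            raise ValueError("panel entries must be 0/1; missing data unsupported")
        self.haplotypes = H.astype(np.int8)
        self.positions = np.asarray(self.positions, dtype=float)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not 0 <= self.core_index < H.shape[1]:
            raise ValueError("core_index out of range")

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    def derived_freq(self, j: int | None = None) -> float:
        j = self.core_index if j is None else j
        return float(self.haplotypes[:, j].mean())


@dataclass
class EHHCurve:
    direction: str  # "upstream" (decreasing position) or "downstream"
    distances: np.ndarray  # bp (or cM) from the core, starting at 0
    ehh: np.ndarray  # values in [0,1], EHH(0) = 1


def _pairs(counts: np.ndarray) -> float:
    return float((counts * (counts - 1) // 2).sum())


def ehh(panel: HaplotypePanel, core_allele: int, direction: str) -> EHHCurve:
    """Homozygosity decay away from the core among core-allele carriers.

    At marker distance x, EHH = sum_h C(n_h, 2) / C(n_c, 2) over the sizes
    n_h of identical-haplotype classes spanning core..x among the n_c
    carriers.  Non-increasing by construction (classes only split).
    """
    H = panel.haplotypes
    carriers = np.flatnonzero(H[:, panel.core_index] == core_allele)
    if carriers.size < 2:
        raise ValueError("need >= 2 carriers of the core allele")
    coords = panel.genetic_map if panel.genetic_map is not None else panel.positions
    if direction == "downstream":
        cols = range(panel.core_index + 1, H.shape[1])
    elif direction == "upstream":
        cols = range(panel.core_index - 1, -1, -1)
    else:
        raise ValueError("direction must be 'upstream' or 'downstream'")
    n_c = carriers.size
    denom = n_c * (n_c - 1) / 2
    classes = np.zeros(n_c, dtype=np.int64)  # identical-prefix class ids
    dists = [0.0]
    vals = [1.0]
    core_coord = coords[panel.core_index]
    for j in cols:
        alleles = H[carriers, j].astype(np.int64)
        key = classes * 2 + alleles
        _, classes = np.unique(key, return_inverse=True)
        counts = np.bincount(classes)
        dists.append(abs(coords[j] - core_coord))
        vals.append(_pairs(counts) / denom)
    return EHHCurve(direction, np.asarray(dists), np.asarray(vals))


def ihh(curve_up: EHHCurve, curve_down: EHHCurve,
        cutoff: float = 0.05) -> tuple[float, bool]:
    """Integrated EHH: trapezoids over distance, both directions summed.

    Integration runs outward until (and including) the first segment whose
    far end falls below ``cutoff``.  Returns (area, edge_truncated); the
    flag is True when either curve never drops below the cutoff inside the
    panel, i.e. the integral is truncated by the panel edge instead.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must be in (0,1)")
    total = 0.0
    edge = False
    for curve in (curve_up, curve_down):
        d, v = curve.distances, curve.ehh
        side = 0.0
        hit = False
        for k in range(1, d.size):
            side += 0.5 * (v[k - 1] + v[k]) * (d[k] - d[k - 1])
            if v[k] < cutoff:
                hit = True
                break
        if not hit:
            edge = True
        total += side
    return total, edge


@dataclass
class IHSResult:
    ihh_ancestral: float
    ihh_derived: float
    uihs: float
    derived_freq: float
    edge_truncated: bool
    ihs: float | None = None  # filled by standardize_ihs
    bin_id: int | None = None


def ihs_unstandardized(panel: HaplotypePanel, cutoff: float = 0.05) -> IHSResult:
    """ln(iHH_ancestral / iHH_derived) at the panel's core SNP."""
    areas = {}
    edge = False
    for allele, name in ((0, "ancestral"), (1, "derived")):
        up = ehh(panel, allele, "upstream")
        down = ehh(panel, allele, "downstream")
        area, e = ihh(up, down, cutoff)
        edge = edge or e
        if area <= 0:
            raise ValueError(f"zero integrated EHH on the {name} background")
        areas[name] = area
    return IHSResult(
        ihh_ancestral=areas["ancestral"],
        ihh_derived=areas["derived"],
        uihs=float(np.log(areas["ancestral"] / areas["derived"])),
        derived_freq=panel.derived_freq(),
        edge_truncated=edge,
    )


def standardize_ihs(
    uihs_values: Sequence[float],
    derived_freqs: Sequence[float],
    bins: int | Sequence[float] = 20,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Within-frequency-bin z-scores of unstandardized iHS.

    ``bins`` is a count of equal-width bins on (0,1) or explicit edges.
    Bins with fewer than 2 values (or zero spread) are merged into their
    nearest occupied neighbor; merges are reported as (from_bin, into_bin).
    Returns (ihs, bin_id_per_value, merges).
    """
    u = np.asarray(uihs_values, dtype=float)
    f = np.asarray(derived_freqs, dtype=float)
    if u.shape != f.shape:
        raise ValueError("uihs and frequency vectors must align")
    edges = np.linspace(0.0, 1.0, bins + 1) if np.isscalar(bins) \
        else np.asarray(bins, float)
    bin_id = np.clip(np.digitize(f, edges) - 1, 0, len(edges) - 2)
    merges: list[tuple[int, int]] = []
    # merge undersized/degenerate bins into the nearest occupied neighbor
    def usable(b):
        vals = u[bin_id == b]
        return vals.size >= 2 and np.ptp(vals) > 0

    occupied = sorted(set(bin_id.tolist()))
    for b in occupied:
        if usable(b):
            continue
        others = [o for o in sorted(set(bin_id.tolist())) if o != b and usable(o)]
        if not others:
            raise ValueError("no bin with >= 2 distinct values to standardize on")
        target = min(others, key=lambda o: abs(o - b))
        bin_id[bin_id == b] = target
        merges.append((b, target))
    z = np.empty_like(u)
    for b in set(bin_id.tolist()):
        sel = bin_id == b
        z[sel] = (u[sel] - u[sel].mean()) / u[sel].std(ddof=0)
    return z, bin_id, merges


def empirical_percentile(
    fst_dist: Sequence[float],
    ihs_dist: Sequence[float],
    fst_value: float,
    ihs_value: float,
) -> dict[str, float]:
    """Empirical tail fractions against a genome-wide distribution.

    Marginal fractions P(Fst >= fst_value) and P(iHS <= ihs_value), and —
    when the two vectors are paired per SNP — the joint fraction of SNPs at
    least as extreme in both.  A fraction of 0 is reported as < 1/N via the
    ``*_lt_one_over_n`` flags.
    """
    fst = np.asarray(fst_dist, float)
    ihs = np.asarray(ihs_dist, float)
    if fst.size == 0 or ihs.size == 0:
        raise ValueError("empty distribution")
    out = {
        "fst_tail": float((fst >= fst_value).mean()),
        "ihs_tail": float((ihs <= ihs_value).mean()),
    }
    if fst.shape == ihs.shape:
        out["joint_tail"] = float(((fst >= fst_value) & (ihs <= ihs_value)).mean())
        out["n_joint"] = float(fst.size)
    out["fst_tail_lt_one_over_n"] = out["fst_tail"] == 0.0
    out["ihs_tail_lt_one_over_n"] = out["ihs_tail"] == 0.0
    return out


# ---------------------------------------------------------------------------
# Panel readers

def read_hap_legend(hap_path: str | Path, legend_path: str | Path,
                    core_position: int | None = None,
                    core_index: int | None = None) -> HaplotypePanel:
    """IMPUTE-style panel: legend `id position allele0 allele1 [ancestral]`,
    hap file one row per SNP with space-separated 0/1 per haplotype.

    Hap entries are recoded so 1 = derived whenever the legend carries an
    ``ancestral`` column naming the ancestral base.
    """
    legend = []
    lines = Path(legend_path).read_text().splitlines()
    header = lines[0].split()
    for line in lines[1:]:
        if line.strip():
            legend.append(dict(zip(header, line.split())))
    positions = np.array([float(r["position"]) for r in legend])
    rows = [np.array(l.split(), dtype=int)
            for l in Path(hap_path).read_text().splitlines() if l.strip()]
    H = np.vstack(rows).T  # (n_hap, n_snp)
    if "ancestral" in header:
        for j, rec in enumerate(legend):
            if rec["ancestral"] == rec["allele1"]:
                H[:, j] = 1 - H[:, j]  # flip so 1 = derived
    if core_index is None:
        if core_position is None:
            raise ValueError("give core_position or core_index")
        core_index = int(np.flatnonzero(positions == core_position)[0])
    return HaplotypePanel(H, positions, core_index)


def read_phased_vcf(path: str | Path, core_position: int,
                    ancestral: dict[int, str] | None = None) -> HaplotypePanel:
    """Fully phased biallelic VCF subset -> HaplotypePanel (needs cyvcf2).

    ``ancestral`` maps position -> ancestral base; sites where the ALT
    allele is ancestral are flipped so 1 = derived.
    """
    from cyvcf2 import VCF  # optional dependency

    cols, positions = [], []
    for var in VCF(str(path)):
        if len(var.ALT) != 1:
            raise ValueError(f"site {var.POS} is not biallelic")
        gts = np.array(var.genotype.array())[:, :2]
        if (gts < 0).any():
            raise ValueError(f"missing genotype at {var.POS}")
        col = gts.reshape(-1)
        if ancestral and ancestral.get(var.POS) == var.ALT[0]:
            col = 1 - col
        cols.append(col)
        positions.append(var.POS)
    H = np.column_stack(cols)
    positions = np.asarray(positions, float)
    core_index = int(np.flatnonzero(positions == core_position)[0])
    return HaplotypePanel(H, positions, core_index)
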