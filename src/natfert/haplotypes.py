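"""Rule-based phasing of the CFTR (TG)m–polyT–Met470Val three-locus system.

Intron 8 diplotypes ((TG)m with polyT) come pre-phased from single-amplicon
sequencing; the phasing problem is attaching the exon-10 Met/Val alleles to
the two intron-8 haplotypes.  Phase is assigned only by direct observation
— homozygosity forces it, otherwise alleles segregating in the families
(Mendelian transmission between parents and children) may determine it.
No statistical (EM) phasing is used: individuals whose phase cannot be
deduced are reported as ambiguous, never guessed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

from .pedigree import Pedigree

__all__ = [
    "TG_ALLELES",
    "POLYT_ALLELES",
    "M470V_ALLELES",
    "Haplotype",
    "ThreeLocusGenotype",
    "HaplotypeAssignment",
    "InvalidAlleleError",
    "MendelianInconsistencyError",
    "phase_intron8",
    "candidate_pairs",
    "phase_by_pedigree",
    "haplotype_frequencies",
    "LDResult",
    "d_prime",
    "read_genotypes",
]

TG_ALLELES = frozenset({10, 11, 12, 13})
POLYT_ALLELES = frozenset({5, 7, 9})
M470V_ALLELES = frozenset({"Met", "Val"})


class InvalidAlleleError(ValueError):
    """An allele outside the locus domain."""


class MendelianInconsistencyError(ValueError):
    """A trio's genotypes admit no consistent transmission."""


class Haplotype(NamedTuple):
    tg: int
    polyt: int
    m470v: str

    def __str__(self) -> str:
        return f"TG{self.tg}-{self.polyt}T-{self.m470v}470"


def _check(alleles, domain, locus):
    for a in alleles:
        if a not in domain:
            raise InvalidAlleleError(f"{locus} allele {a!r} not in {sorted(map(str, domain))}")


@dataclass(frozen=True)
class ThreeLocusGenotype:
    """Unphased genotype; ``intron8_phased`` means (tg[i], polyt[i]) are cis."""

    individual_id: str
    tg: tuple[int, int]
    polyt: tuple[int, int]
    m470v: tuple[str, str]
    intron8_phased: bool = True

    def __post_init__(self):
        _check(self.tg, TG_ALLELES, "(TG)m")
        _check(self.polyt, POLYT_ALLELES, "polyT")
        _check(self.m470v, M470V_ALLELES, "Met470Val")


def phase_intron8(genotype: ThreeLocusGenotype) -> tuple[tuple[int, int], tuple[int, int]]:
    """The two (TG, polyT) cis combinations, taken as observed.

    Amplicon sequencing yields the intron-8 diplotype directly, so this is
    a pass-through, not an inference.  Raises ``ValueError`` when the
    amplicon phase is missing (the unphased-intron8 case).
    """
    if not genotype.intron8_phased:
        raise ValueError(
            f"{genotype.individual_id}: intron 8 amplicon phase unavailable"
        )
    return ((genotype.tg[0], genotype.polyt[0]), (genotype.tg[1], genotype.polyt[1]))


def _pair(a: Haplotype, b: Haplotype) -> tuple[Haplotype, Haplotype]:
    return (a, b) if a <= b else (b, a)


def candidate_pairs(genotype: ThreeLocusGenotype) -> set[tuple[Haplotype, Haplotype]]:
    """All unordered haplotype pairs consistent with the unphased genotype."""
    pairs: set[tuple[Haplotype, Haplotype]] = set()
    mv = genotype.m470v
    if genotype.intron8_phased:
        cis1, cis2 = phase_intron8(genotype)
        for m1, m2 in {(mv[0], mv[1]), (mv[1], mv[0])}:
            pairs.add(_pair(Haplotype(*cis1, m1), Haplotype(*cis2, m2)))
    else:
        tg, pt = genotype.tg, genotype.polyt
        for ti, pi, mi in product(range(2), repeat=3):
            h1 = Haplotype(tg[ti], pt[pi], mv[mi])
            h2 = Haplotype(tg[1 - ti], pt[1 - pi], mv[1 - mi])
            pairs.add(_pair(h1, h2))
    return pairs


@dataclass
class HaplotypeAssignment:
    individual_id: str
    pair: tuple[Haplotype, Haplotype] | None  # None when ambiguous
    consistent_pairs: set = field(default_factory=set)

    @property
    def ambiguous(self) -> bool:
        return self.pair is None


def _transmittable(cand: set | None) -> set | None:
    """Haplotypes an individual could pass on; None = unconstrained."""
    if cand is None:
        return None
    return {h for pair in cand for h in pair}


def _child_pair_ok(pair, pat: set | None, mat: set | None) -> bool:
    a, b = pair
    ok1 = (pat is None or a in pat) and (mat is None or b in mat)
    ok2 = (pat is None or b in pat) and (mat is None or a in mat)
    return ok1 or ok2


def phase_by_pedigree(
    genotypes: Mapping[str, ThreeLocusGenotype],
    ped: Pedigree,
) -> dict[str, HaplotypeAssignment]:
    """Phase every genotyped individual by observation and transmission.

    Deterministic constraint propagation to a fixed point: an individual's
    candidate set starts from its own genotype (homozygosity leaves one
    candidate) and is pruned against what each genotyped parent could
    transmit; parents are in turn pruned against what their genotyped
    children must have received.  Newly phased individuals keep phasing
    their relatives until nothing changes, so the result is independent of
    processing order.  Candidates are never guessed: individuals with more
    than one surviving pair are reported as ambiguous.

    Raises :class:`MendelianInconsistencyError` naming the trio whose
    genotypes admit no transmission-consistent assignment.
    """
    cand: dict[str, set] = {
        iid: candidate_pairs(g) for iid, g in genotypes.items() if iid in ped
    }
    trios = [
        (ind.id, ind.father, ind.mother)
        for ind in ped
        if not ind.is_founder and ind.id in cand
    ]
    changed = True
    while changed:
        changed = False
        for child, fa, mo in trios:
            pat = _transmittable(cand.get(fa))
            mat = _transmittable(cand.get(mo))
            kept = {p for p in cand[child] if _child_pair_ok(p, pat, mat)}
            if not kept:
                raise MendelianInconsistencyError(
                    f"trio (child={child}, father={fa}, mother={mo}): "
                    "no transmission-consistent phase"
                )
            if kept != cand[child]:
                cand[child] = kept
                changed = True
            # prune each genotyped parent against this child's needs
            for parent, other in ((fa, mo), (mo, fa)):
                if parent not in cand:
                    continue
                other_t = _transmittable(cand.get(other))
                kept_p = set()
                for px in cand[parent]:
                    trans_p = set(px)
                    ok = any(
                        _child_pair_ok(cp, trans_p, other_t)
                        or _child_pair_ok(cp, other_t, trans_p)
                        for cp in cand[child]
                    )
                    if ok:
                        kept_p.add(px)
                if not kept_p:
                    raise MendelianInconsistencyError(
                        f"trio (child={child}, father={fa}, mother={mo}): "
                        f"parent {parent} has no phase consistent with children"
                    )
                if kept_p != cand[parent]:
                    cand[parent] = kept_p
                    changed = True
    out = {}
    for iid, pairs in cand.items():
        if len(pairs) == 1:
            out[iid] = HaplotypeAssignment(iid, next(iter(pairs)), pairs)
        else:
            out[iid] = HaplotypeAssignment(iid, None, pairs)
    return out


def haplotype_frequencies(
    assignments: Iterable[HaplotypeAssignment],
) -> tuple[dict[Haplotype, float], int]:
    """Counting-based frequencies over resolved individuals.

    Returns (haplotype -> frequency, number of ambiguous individuals
    excluded).  Frequencies are counts / (2 * n_resolved) and sum to 1.
    """
    counts: dict[Haplotype, int] = {}
    n_res = n_amb = 0
    for a in assignments:
        if a.ambiguous:
            n_amb += 1
            continue
        n_res += 1
        for h in a.pair:
            counts[h] = counts.get(h, 0) + 1
    if n_res == 0:
        raise ValueError("no resolved haplotype assignments")
    total = 2 * n_res
    return {h: c / total for h, c in sorted(counts.items())}, n_amb


@dataclass(frozen=True)
class LDResult:
    locus_a: str
    locus_b: str
    p_a: float
    p_b: float
    p_ab: float
    D: float
    D_prime: float
    r2: float


def d_prime(
    freqs: Mapping[Haplotype, float],
    locus_a: tuple[str, set],
    locus_b: tuple[str, set],
) -> LDResult:
    """Pairwise LD between two dichotomized loci of the haplotype system.

    ``locus_a = ("polyt", {7})`` means allele A is "polyT in {7}".  D is
    p_AB - p_A p_B; D' normalizes by the maximum |D| attainable at the
    marginals, so D' = 1 whenever one of the four haplotype classes is
    absent; r^2 = D^2 / (p_A q_A p_B q_B).
    """
    name_a, set_a = locus_a
    name_b, set_b = locus_b
    p_a = sum(f for h, f in freqs.items() if getattr(h, name_a) in set_a)
    p_b = sum(f for h, f in freqs.items() if getattr(h, name_b) in set_b)
    p_ab = sum(
        f for h, f in freqs.items()
        if getattr(h, name_a) in set_a and getattr(h, name_b) in set_b
    )
    if not (0 < p_a < 1) or not (0 < p_b < 1):
        raise ValueError("monomorphic locus under the given dichotomization")
    D = p_ab - p_a * p_b
    if D > 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    elif D < 0:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    else:
        dmax = 1.0
    dp = D / dmax if dmax > 0 else 0.0
    r2 = D * D / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LDResult(name_a, name_b, p_a, p_b, p_ab, float(D), float(dp), float(r2))


def read_genotypes(path: str | Path) -> dict[str, ThreeLocusGenotype]:
    """Genotype CSV: individual_id, tg1, tg2, polyt1, polyt2, m470v1,
    m470v2, intron8_phased.  When intron8_phased, (tg_i, polyt_i) are cis."""
    out = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(filter(lambda l: not l.startswith("#"), fh)):
            g = ThreeLocusGenotype(
                row["individual_id"],
                (int(row["tg1"]), int(row["tg2"])),
                (int(row["polyt1"]), int(row["polyt2"])),
                (row["m470v1"], row["m470v2"]),
                str(row.get("intron8_phased", "1")).strip().lower()
                in {"1", "true", "yes"},
            )
            out[g.individual_id] = g
    return out
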