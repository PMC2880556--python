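"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study setting: a deep founder pedigree with
consanguineous loops (defaults shaped like a 13-generation, 62-founder
isolate), Mendelian genotypes dropped through it, a birth-rate phenotype
with covariate + SNP + polygenic + environmental structure, right-censored
birth histories, two-population allele counts, and haplotype panels in
which derived-allele carriers share a long identical tract (a sweep
signature).  Every generator is deterministic given (config, seed) and
returns a truth record alongside its outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .pedigree import (
    Individual,
    KinshipMatrix,
    Pedigree,
    gene_drop,
    kinship_matrix,
)
from .phenotypes import ReproductiveHistory
from .selection import HaplotypePanel

__all__ = [
    "PedigreeSimConfig",
    "SimulatedPedigree",
    "simulate_pedigree",
    "PedigreeExtinctionError",
    "FertilitySimConfig",
    "FertilitySim",
    "simulate_fertility",
    "haplotype_drop",
    "simulate_two_pop_counts",
    "SweepPanelConfig",
    "simulate_sweep_panel",
]


class PedigreeExtinctionError(RuntimeError):
    """The simulated population ran out of mateable pairs; raise sibship."""


@dataclass(frozen=True)
class PedigreeSimConfig:
    """Shape of the simulated isolate.

    Defaults mirror the study pedigree: 13 generations descending from 62
    founders, large sibships, and a nonzero rate of cousin marriages so
    that inbreeding loops exist.
    """

    n_generations: int = 13
    n_founders: int = 62
    mean_sibship: float = 4.0
    cousin_mating_prob: float = 0.15
    max_couples_per_generation: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_generations < 2:
            raise ValueError("need at least 2 generations")
        if not 0.0 <= self.cousin_mating_prob <= 1.0:
            raise ValueError("cousin_mating_prob must be in [0,1]")
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")


@dataclass
class SimulatedPedigree:
    pedigree: Pedigree
    couples: list[tuple[str, str, int]]  # (husband, wife, generation of children)
    config: PedigreeSimConfig

    def husbands(self) -> list[str]:
        return [h for h, _, _ in self.couples]


def simulate_pedigree(cfg: PedigreeSimConfig) -> SimulatedPedigree:
    """Forward-in-time pedigree: founder couples, Poisson sibships, mating
    within each generation with a preference for first cousins at rate
    ``cousin_mating_prob``.  Sib matings never occur.  With
    ``cousin_mating_prob = 0`` the population is kept fully outbred: every
    mate pair must share no ancestry, and when no such partner exists an
    unrelated immigrant founder marries in (so founder count can exceed
    ``n_founders`` in that mode)."""
    rng = np.random.default_rng(cfg.seed)
    cap = cfg.max_couples_per_generation or max(cfg.n_founders // 2, 1)
    inds: list[Individual] = []
    parents: dict[str, tuple[str, str]] = {}
    ancestry: dict[str, frozenset] = {}  # id -> all ancestors incl. self

    founders = []
    for k in range(cfg.n_founders):
        sex = "M" if k % 2 == 0 else "F"
        iid = f"G00-{k:04d}{sex}"
        inds.append(Individual(iid, None, None, sex))
        ancestry[iid] = frozenset({iid})
        founders.append((iid, sex))
    males = [i for i, s in founders if s == "M"]
    females = [i for i, s in founders if s == "F"]
    couples_prev = list(zip(males, females))
    all_couples: list[tuple[str, str, int]] = []
    n_immigrants = 0

    for g in range(1, cfg.n_generations):
        all_couples.extend((h, w, g) for h, w in couples_prev)
        kids: list[tuple[str, str]] = []
        counter = 0
        for h, w in couples_prev:
            n_kids = rng.poisson(cfg.mean_sibship)
            for _ in range(n_kids):
                sex = "M" if rng.random() < 0.5 else "F"
                iid = f"G{g:02d}-{counter:04d}{sex}"
                counter += 1
                inds.append(Individual(iid, h, w, sex))
                parents[iid] = (h, w)
                ancestry[iid] = ancestry[h] | ancestry[w] | {iid}
                kids.append((iid, sex))
        if g == cfg.n_generations - 1:
            break  # terminal generation reproduces no further

        def grandparents(iid: str) -> set:
            out = set()
            for p in parents.get(iid, ()):
                out.update(parents.get(p, ()))
            return out

        sons = [i for i, s in kids if s == "M"]
        daughters = [i for i, s in kids if s == "F"]
        rng.shuffle(sons)
        rng.shuffle(daughters)
        new_couples = []
        pool = list(daughters)
        for son in sons:
            if len(new_couples) >= cap:
                break
            if cfg.cousin_mating_prob == 0.0:
                unrelated = [d for d in pool
                             if not (ancestry[son] & ancestry[d])]
                if unrelated:
                    wife = unrelated[rng.integers(len(unrelated))]
                    pool.remove(wife)
                else:  # marry in an unrelated immigrant founder
                    wife = f"G{g:02d}-IMM{n_immigrants:04d}F"
                    n_immigrants += 1
                    inds.append(Individual(wife, None, None, "F"))
                    ancestry[wife] = frozenset({wife})
                new_couples.append((son, wife))
                continue
            if not pool:
                break
            non_sib = [d for d in pool if parents[d] != parents[son]]
            if not non_sib:
                continue
            gp = grandparents(son)
            cousins = [d for d in non_sib if gp & grandparents(d)]
            if cousins and rng.random() < cfg.cousin_mating_prob:
                wife = cousins[rng.integers(len(cousins))]
            else:
                wife = non_sib[rng.integers(len(non_sib))]
            pool.remove(wife)
            new_couples.append((son, wife))
        if not new_couples:
            raise PedigreeExtinctionError(
                f"no mateable pairs at generation {g}; "
                "increase mean_sibship or n_founders"
            )
        couples_prev = new_couples
    return SimulatedPedigree(Pedigree(inds), all_couples, cfg)


@dataclass(frozen=True)
class FertilitySimConfig:
    """Generative model of the birth-rate phenotype.

    The latent rate (births/yr) of married man i is

        mu + effect(g_i) + b_wife*(wife_year - mean) + b_span*(span - mean)
           + a_i + e_i,

    a ~ N(0, sigma2_a * 2Phi) polygenic, e ~ N(0, residual_sd^2).  Birth
    years follow Gamma interbirth intervals with mean 1/rate until the
    marriage duration is exhausted.  SNP defaults are the study values: a
    recessive 0.049 births/yr deficit for ancestral homozygotes at derived
    allele frequency 0.29, mean reproductive span 11.5 +/- 5.0 yr.
    """

    snp_allele_freq: float = 0.29  # derived (Val) frequency
    effect_model: str = "recessive"  # recessive | additive | general
    effect_size: float = 0.049  # recessive: Met/Met deficit (births/yr)
    genotype_means: tuple[float, float, float] | None = None  # general model
    mu: float = 0.49
    h2: float = 0.2  # polygenic fraction of (polygenic + residual) variance
    residual_sd: float = 0.11
    wife_year_slope: float = -0.002
    span_slope: float = -0.004
    mean_duration: float = 11.5
    sd_duration: float = 5.0
    gamma_shape: float = 4.0
    n_men: int | None = None  # subsample husbands (latest generations first)
    freq_tolerance: float = 0.03  # cohort-frequency window for the gene drop
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.h2 < 1.0:
            raise ValueError("h2 must be in [0,1)")
        if not 0.0 <= self.snp_allele_freq <= 1.0:
            raise ValueError("snp_allele_freq must be in [0,1]")

    def genotype_effect(self, dosage: np.ndarray) -> np.ndarray:
        g = np.asarray(dosage)
        if self.effect_model == "recessive":
            return np.where(g == 0, -self.effect_size, 0.0)
        if self.effect_model == "additive":
            return self.effect_size * g
        if self.effect_model == "general":
            means = self.genotype_means or (0.0, 0.0, 0.0)
            return np.asarray(means, float)[g]
        raise ValueError(f"unknown effect model {self.effect_model!r}")


@dataclass
class FertilitySim:
    histories: list[ReproductiveHistory]
    dosages: dict[str, int]  # derived-allele count per phenotyped man
    truth: dict


def simulate_fertility(
    simped: SimulatedPedigree,
    cfg: FertilitySimConfig,
    kin: KinshipMatrix | None = None,
    dosages: dict[str, int] | None = None,
) -> FertilitySim:
    """Histories (and truth) for the husbands of the simulated pedigree."""
    rng = np.random.default_rng(cfg.seed)
    ped = simped.pedigree
    couples = sorted(simped.couples, key=lambda c: (-c[2], c[0]))
    if cfg.n_men is not None:
        couples = couples[: cfg.n_men]
    men = [h for h, _, _ in couples]
    gens = {h: g for h, _, g in couples}
    n = len(men)

    if dosages is None:
        # conditional gene drop: drift through the deep pedigree scatters
        # the cohort frequency widely around the founder frequency, so
        # redraw transmission until the sampled men's allele frequency
        # lands in the configured window around the target
        best, best_gap = None, np.inf
        for _ in range(500):
            drop = gene_drop(ped, cfg.snp_allele_freq,
                             int(rng.integers(2**31)))
            d = {m: drop.dosage(m) for m in men}
            gap = abs(sum(d.values()) / (2 * n) - cfg.snp_allele_freq)
            if gap < best_gap:
                best, best_gap = d, gap
            if gap <= cfg.freq_tolerance:
                break
        dosages = best
    g = np.array([dosages[m] for m in men])

    if kin is None:
        kin = kinship_matrix(ped)
    A = kin.subset(men).additive()

    sigma2_e = cfg.residual_sd**2
    sigma2_a = cfg.h2 / (1.0 - cfg.h2) * sigma2_e if cfg.h2 > 0 else 0.0
    if sigma2_a > 0:
        L = np.linalg.cholesky(A + 1e-10 * np.eye(n))
        poly = np.sqrt(sigma2_a) * (L @ rng.standard_normal(n))
    else:
        poly = np.zeros(n)
    env = cfg.residual_sd * rng.standard_normal(n)

    husband_birth = np.array(
        [1900.0 + 25.0 * gens[m] for m in men]
    ) + rng.normal(0, 3, n)
    wife_birth = husband_birth + rng.normal(0, 2, n)
    marriage = np.maximum(husband_birth, wife_birth) + 23.0 + rng.normal(0, 2, n)
    duration = np.clip(
        rng.normal(cfg.mean_duration, cfg.sd_duration, n), 2.0, 30.0
    )

    rate = (
        cfg.mu
        + cfg.genotype_effect(g)
        + cfg.wife_year_slope * (wife_birth - wife_birth.mean())
        + cfg.span_slope * (duration - cfg.mean_duration)
        + poly
        + env
    )
    rate = np.clip(rate, 0.05, None)

    histories = []
    for i, m in enumerate(men):
        births = []
        shape = cfg.gamma_shape
        t = marriage[i] + rng.gamma(shape, 1.0 / (rate[i] * shape))
        end = marriage[i] + duration[i]
        while t <= end:
            births.append(round(t, 3))
            t += rng.gamma(shape, 1.0 / (rate[i] * shape))
        histories.append(
            ReproductiveHistory(
                m,
                round(marriage[i], 3),
                round(wife_birth[i], 3),
                tuple(births),
                round(end, 3),
            )
        )
    truth = {
        "config": asdict(cfg),
        "men": men,
        "latent_rate": rate.tolist(),
        "polygenic": poly.tolist(),
        "sigma2_a": sigma2_a,
        "sigma2_e": sigma2_e,
    }
    return FertilitySim(histories, {m: int(dosages[m]) for m in men}, truth)


def haplotype_drop(
    ped: Pedigree,
    freqs: dict,
    seed: int,
) -> dict[str, tuple]:
    """Drop whole haplotypes (arbitrary labels) through a pedigree.

    Founders draw two haplotypes i.i.d. from ``freqs`` (label -> relative
    frequency); each non-founder inherits a uniformly chosen haplotype of
    each parent.  Returns id -> (paternal, maternal) labels, i.e. genotypes
    with known true phase — the generative counterpart of the observational
    phasing rules.
    """
    labels = list(freqs)
    probs = np.array([freqs[h] for h in labels], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    out: dict[str, tuple] = {}
    for ind in ped:
        if ind.is_founder:
            i, j = rng.choice(len(labels), size=2, p=probs)
            out[ind.id] = (labels[i], labels[j])
        else:
            pat = out[ind.father][rng.integers(2)]
            mat = out[ind.mother][rng.integers(2)]
            out[ind.id] = (pat, mat)
    return out


def simulate_two_pop_counts(
    p1: float, p2: float, n1: int, n2: int, seed: int
) -> dict:
    """Binomial allele counts for two populations (feeds the Fst estimator)."""
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError("allele frequency must be in [0,1]")
    rng = np.random.default_rng(seed)
    return {
        "n1": n1,
        "x1": int(rng.binomial(n1, p1)),
        "n2": n2,
        "x2": int(rng.binomial(n2, p2)),
        "truth": {"p1": p1, "p2": p2, "seed": seed},
    }


@dataclass(frozen=True)
class SweepPanelConfig:
    """Haplotype panel with a planted sweep signature at the core SNP.

    Derived-core haplotypes are copies of one template across a tract of
    ``sweep_tract_bp`` centred on the core, perturbed by per-site mutation
    noise; ancestral haplotypes (and all sites outside the tract) are drawn
    site-independently at matched frequencies.  Positions default to 1 kb
    spacing over 1 Mb — a +/- 500 kb window around the core.
    """

    n_hap: int = 120
    n_snp: int = 1001
    derived_core_freq: float = 0.5
    sweep_tract_bp: float = 600_000.0
    mutation_noise_per_site: float = 0.02
    spacing_bp: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.derived_core_freq < 1.0:
            raise ValueError("derived_core_freq must be in (0,1)")
        if self.sweep_tract_bp > (self.n_snp - 1) * self.spacing_bp:
            raise ValueError("sweep tract exceeds the panel span")


def simulate_sweep_panel(cfg: SweepPanelConfig) -> tuple[HaplotypePanel, dict]:
    rng = np.random.default_rng(cfg.seed)
    positions = cfg.spacing_bp * np.arange(cfg.n_snp)
    core = cfg.n_snp // 2
    n_derived = int(np.clip(round(cfg.derived_core_freq * cfg.n_hap),
                            2, cfg.n_hap - 2))
    site_freq = rng.uniform(0.05, 0.95, cfg.n_snp)
    H = (rng.random((cfg.n_hap, cfg.n_snp)) < site_freq).astype(np.int8)
    template = (rng.random(cfg.n_snp) < site_freq).astype(np.int8)
    in_tract = np.abs(positions - positions[core]) <= cfg.sweep_tract_bp / 2.0
    derived_rows = np.arange(n_derived)
    if cfg.sweep_tract_bp > 0 and in_tract.any():
        block = np.tile(template[in_tract], (n_derived, 1))
        flips = rng.random(block.shape) < cfg.mutation_noise_per_site
        H[np.ix_(derived_rows, np.flatnonzero(in_tract))] = np.where(
            flips, 1 - block, block
        )
    H[:, core] = 0
    H[derived_rows, core] = 1
    panel = HaplotypePanel(H, positions, core)
    truth = {
        "config": asdict(cfg),
        "core_index": core,
        "swept_rows": derived_rows.tolist(),
        "in_tract_snps": int(in_tract.sum()),
    }
    return panel, truth
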