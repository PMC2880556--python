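"""Reproducible multi-stage pipeline tying the analysis modules together.

Stages: phenotype construction -> relatedness-corrected association ->
survival comparison -> haplotype phasing (-> LD) -> selection statistics.
Every output table is TSV with a ``#``-prefixed provenance header (package
version, seed, config hash); reruns with the same config and seed are
byte-identical.  No stage mutates its inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    estimate_variance_components,
    gls_association,
)
from .haplotypes import (
    d_prime,
    haplotype_frequencies,
    phase_by_pedigree,
    read_genotypes,
)
from .pedigree import kinship_matrix, read_ped
from .phenotypes import build_phenotypes, covariate_table, read_histories
from .selection import ihs_unstandardized, read_hap_legend, weir_cockerham_theta
from .survival import kaplan_meier, log_rank, time_to_kth_birth

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

ALL_STAGES = ("phenotype", "assoc", "survival", "phase", "selection")


class PipelineError(RuntimeError):
    """Stage-level failure carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    pedigree: str | None = None
    histories: str | None = None
    genotypes: str | None = None  # three-locus CSV
    panel_hap: str | None = None
    panel_legend: str | None = None
    counts: dict | None = None  # {n1, x1, n2, x2}
    codings: tuple[str, ...] = ("general", "recessive_met")
    n_tests: int = 4
    kth_birth: int = 6
    ehh_cutoff: float = 0.05
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        kwargs["extras"] = {k: v for k, v in raw.items() if k not in known}
        for key in ("stages", "codings"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def config_hash(self) -> str:
        # outdir excluded: the hash identifies the analysis, not where it lands
        blob = json.dumps(
            {k: getattr(self, k) for k in self.__dataclass_fields__
             if k != "outdir"},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def validate(self) -> None:
        for name in ("pedigree", "histories", "genotypes",
                     "panel_hap", "panel_legend"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError(
                    "preflight", f"input file for {name!r} not found: {p}"
                )
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise PipelineError("preflight", f"unknown stages {sorted(unknown)}")


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    header = (
        f"# natfert {__version__}\n"
        f"# seed {cfg.seed}\n"
        f"# config {cfg.config_hash()}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _dosages(genotypes: dict) -> dict[str, int]:
    return {iid: sum(a == "Val" for a in g.m470v)
            for iid, g in genotypes.items()}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the requested stages; returns {stage: output paths/objects}."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    histories = read_histories(cfg.histories) if cfg.histories else None
    genotypes = read_genotypes(cfg.genotypes) if cfg.genotypes else None
    ped = read_ped(cfg.pedigree) if cfg.pedigree else None

    if "phenotype" in cfg.stages:
        if histories is None:
            raise PipelineError("phenotype", "histories input required")
        phenos, excluded = build_phenotypes(histories)
        from .phenotypes import residualize

        resid = residualize(phenos, covariate_table(histories))
        df = pd.DataFrame(
            {
                "individual_id": [p.individual_id for p in phenos],
                "n_births": [p.n_births for p in phenos],
                "birth_rate": [p.rate for p in phenos],
            }
        )
        df["residual"] = resid.reindex(df["individual_id"]).to_numpy()
        path = outdir / "phenotypes.tsv"
        _write_tsv(df, path, cfg)
        results["phenotype"] = {"table": path, "excluded": excluded,
                                "phenotypes": phenos, "residuals": resid}

    if "assoc" in cfg.stages:
        if ped is None or histories is None or genotypes is None:
            raise PipelineError(
                "assoc", "pedigree, histories and genotypes inputs required"
            )
        phenos, _ = build_phenotypes(histories)
        dos = _dosages(genotypes)
        keep = [p for p in phenos if p.individual_id in dos
                and p.individual_id in ped]
        if not keep:
            raise PipelineError("assoc", "no phenotyped, genotyped individuals")
        ids = [p.individual_id for p in keep]
        y = np.array([p.rate for p in keep])
        hist_by_id = {h.individual_id: h for h in histories}
        X = np.column_stack(
            [
                [hist_by_id[i].wife_birth_year for i in ids],
                [hist_by_id[i].marriage_to_last_birth for i in ids],
            ]
        )
        g = np.array([dos[i] for i in ids])
        kin = kinship_matrix(ped).subset(ids)
        vc = estimate_variance_components(y, X, kin.phi)
        Sigma = vc.covariance(kin.additive())
        rows = []
        for scheme in cfg.codings:
            r = gls_association(y, X, g, scheme, Sigma, n_tests=cfg.n_tests)
            rows.append(
                {
                    "locus": "Met470Val",
                    "scheme": scheme,
                    "lower_fertility_allele": r.lower_fertility_allele,
                    "statistic": r.statistic,
                    "df1": r.df[0],
                    "df2": r.df[1],
                    "p_value": r.p_value,
                    "p_bonferroni": r.p_bonferroni,
                    "pct_variance_explained": r.pct_variance_explained,
                    "n": r.n,
                    "h2_null": vc.h2,
                }
            )
        path = outdir / "association.tsv"
        _write_tsv(pd.DataFrame(rows), path, cfg)
        results["assoc"] = {"table": path, "vc": vc, "rows": rows}

    if "survival" in cfg.stages:
        if histories is None or genotypes is None:
            raise PipelineError("survival", "histories and genotypes required")
        dos = _dosages(genotypes)
        records = []
        for h in histories:
            if h.individual_id not in dos or not h.birth_years:
                continue
            rec = time_to_kth_birth(h, cfg.kth_birth)
            group = "Met/Met" if dos[h.individual_id] == 0 else "Val carrier"
            records.append(type(rec)(rec.individual_id, rec.time,
                                     rec.event, group))
        curves = {}
        frames = []
        for grp in sorted({r.group for r in records}):
            c = kaplan_meier([r for r in records if r.group == grp])
            curves[grp] = c
            frames.append(
                pd.DataFrame(
                    {
                        "group": grp,
                        "time": c.times,
                        "n_risk": c.n_risk,
                        "n_event": c.n_event,
                        "survival": c.survival,
                    }
                )
            )
        lr = log_rank(records) if len(curves) > 1 else None
        path = outdir / "survival_km.tsv"
        _write_tsv(pd.concat(frames, ignore_index=True), path, cfg)
        if lr is not None:
            _write_tsv(
                pd.DataFrame(
                    [{"chi_square": lr.chi_square, "df": lr.df,
                      "p_value": lr.p_value}]
                ),
                outdir / "survival_logrank.tsv",
                cfg,
            )
        results["survival"] = {"table": path, "log_rank": lr, "curves": curves}

    if "phase" in cfg.stages:
        if ped is None or genotypes is None:
            raise PipelineError("phase", "pedigree and genotypes required")
        assignments = phase_by_pedigree(genotypes, ped)
        freqs, n_amb = haplotype_frequencies(assignments.values())
        df = pd.DataFrame(
            [{"haplotype": str(h), "frequency": f} for h, f in freqs.items()]
        )
        path = outdir / "haplotypes.tsv"
        _write_tsv(df, path, cfg)
        ld = None
        try:
            ld = d_prime(freqs, ("polyt", {7}), ("m470v", {"Val"}))
        except ValueError:
            pass
        results["phase"] = {"table": path, "frequencies": freqs,
                            "n_ambiguous": n_amb, "ld_7t_val": ld}

    if "selection" in cfg.stages:
        sel: dict = {}
        if cfg.panel_hap and cfg.panel_legend:
            panel = read_hap_legend(cfg.panel_hap, cfg.panel_legend,
                                    core_index=cfg.extras.get("core_index"))
            r = ihs_unstandardized(panel, cutoff=cfg.ehh_cutoff)
            df = pd.DataFrame(
                [
                    {
                        "core_index": panel.core_index,
                        "derived_freq": r.derived_freq,
                        "ihh_ancestral": r.ihh_ancestral,
                        "ihh_derived": r.ihh_derived,
                        "uihs": r.uihs,
                        "edge_truncated": r.edge_truncated,
                    }
                ]
            )
            path = outdir / "ihs.tsv"
            _write_tsv(df, path, cfg)
            sel["ihs"] = r
            sel["ihs_table"] = path
        if cfg.counts:
            c = cfg.counts
            fst = weir_cockerham_theta(c["n1"], c["x1"], c["n2"], c["x2"])
            _write_tsv(
                pd.DataFrame([{"p1": fst.p1, "p2": fst.p2,
                               "theta": fst.theta}]),
                outdir / "fst.tsv",
                cfg,
            )
            sel["fst"] = fst
        if sel:
            results["selection"] = sel

    return results
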