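"""End-to-end orchestration: simulate/load -> QC -> adjust -> rank ->
select -> GRM -> REML -> CV -> report tables.

Stages write plain-text outputs into the run directory and are resumable:
a stage is skipped when all of its outputs already exist.  A single
global seed deterministically derives per-stage seeds, so a stage can be
recomputed in isolation and reproduce its original results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_io, simulate, subset_selection, vim_ranking
from .cv_evaluation import CvConfig, cv_accuracy, make_folds, panel_comparison
from .grm import DEFAULT_RIDGE, build_vanraden, grm_diagnostics
from .reml_gblup import fit_reml, make_spec, variance_share
from .subset_selection import SnpPanel

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("data", "qc", "adjust", "rank", "select", "variance", "cv")


@dataclasses.dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 42
    # data source: simulation parameters, or explicit input paths
    sim: dict = dataclasses.field(default_factory=dict)
    genotypes: str | None = None
    snp_map: str | None = None
    phenotypes: str | None = None
    n_discovery: int | None = None  # first animals form the discovery cohort
    maf_min: float = 0.01
    methods: list = dataclasses.field(default_factory=lambda: ["rf", "gbm", "xgb"])
    rf: dict = dataclasses.field(default_factory=dict)
    boost: dict = dataclasses.field(default_factory=dict)
    panel_sizes: list = dataclasses.field(default_factory=lambda: [400, 1000, 3000])
    include_positive: bool = True
    include_even: bool = True
    include_all: bool = True
    ridge: float = DEFAULT_RIDGE
    cv_folds: int = 5
    cv_scheme: str = "random"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
        return Path(path)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")  # the science is invariant to the run directory
        canon = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "little")


class _Run:
    """Disk-backed pipeline state for one run directory."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.out = Path(cfg.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        (self.out / "panels").mkdir(exist_ok=True)
        self.stamp = f"config_hash={cfg.config_hash()} seed={cfg.seed}"
        self.log_path = self.out / "pipeline.log"

    def path(self, name: str) -> Path:
        return self.out / name

    def write_table(self, df: pd.DataFrame, name: str) -> Path:
        p = self.path(name)
        with open(p, "w") as fh:
            fh.write(f"# {self.stamp}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        return p

    def read_table(self, name: str) -> pd.DataFrame:
        return pd.read_csv(self.path(name), sep="\t", comment="#")

    def log(self, stage: str, seconds: float, **info) -> None:
        rec = {"stage": stage, "wall_s": round(seconds, 3), **info}
        with open(self.log_path, "a") as fh:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


_STAGE_OUTPUTS = {
    "data": ["genotypes.tsv", "snp_map.tsv", "phenotypes.tsv", "cohorts.tsv"],
    "qc": ["genotypes_qc.tsv", "qc_removed.tsv"],
    "adjust": ["phenotypes_adjusted.tsv"],
    "rank": [],      # filled per configured method
    "select": [],    # panels + overlap + top snps
    "variance": ["variance_table.tsv", "grm_diagnostics.tsv"],
    "cv": ["accuracy_table.tsv", "panel_comparison.tsv"],
}

_METHOD_FULL = {"rf": "rf_permutation", "gbm": "gbm_influence", "xgb": "xgb_gain"}


def _panel_names(cfg: PipelineConfig) -> list[str]:
    names = []
    for meth in cfg.methods:
        for k in cfg.panel_sizes:
            names.append(f"{meth.upper()}{k}")
        if cfg.include_positive:
            names.append(f"{meth.upper()}pos")
    if cfg.include_even:
        names += [f"Even{k}" for k in cfg.panel_sizes]
    if cfg.include_all:
        names.append("ALL")
    return names


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Execute all stages in order, skipping stages whose outputs exist.

    Returns a mapping of output names to paths.  Any stage error halts
    the run with the stage name; completed stages stay on disk.
    """
    run = _Run(cfg)
    outputs: dict[str, Path] = {}
    for stage in STAGES:
        expected = _stage_files(cfg, stage)
        paths = [run.path(f) for f in expected]
        if expected and all(p.exists() for p in paths):
            outputs.update({f: p for f, p in zip(expected, paths)})
            continue
        t0 = time.perf_counter()
        try:
            _STAGE_FN[stage](run)
        except Exception as e:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
        run.log(stage, time.perf_counter() - t0, seed=cfg.stage_seed(stage))
        outputs.update({f: run.path(f) for f in expected})
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {s: _stage_files(cfg, s) for s in STAGES},
    }
    with open(run.path("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    outputs["manifest.json"] = run.path("manifest.json")
    return outputs


def _stage_files(cfg: PipelineConfig, stage: str) -> list[str]:
    if stage == "rank":
        return [f"vim_{m}.tsv" for m in cfg.methods]
    if stage == "select":
        files = [f"panels/{n}.tsv" for n in _panel_names(cfg)]
        files.append("top_snps.tsv")
        if cfg.include_positive and len(cfg.methods) >= 2:
            files.append("overlap_counts.tsv")
        return files
    return list(_STAGE_OUTPUTS[stage])


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_data(run: _Run) -> None:
    cfg = run.cfg
    if cfg.genotypes:
        snps = data_io.read_snp_map(cfg.snp_map) if cfg.snp_map else None
        g = data_io.read_genotypes(cfg.genotypes, snp_map=snps)
        pheno = data_io.read_phenotypes(cfg.phenotypes)
    else:
        sim_cfg = simulate.SimConfig(**{"seed": cfg.stage_seed("data"), **cfg.sim})
        g, pheno, truth = simulate.simulate_cohort(sim_cfg)
        with open(run.path("truth.json"), "w") as fh:
            json.dump({"qtl_ids": truth.qtl_ids,
                       "h2_realized": truth.h2_realized,
                       "qtl_effects": truth.qtl_effects.tolist()}, fh, indent=1)
    n_disc = cfg.n_discovery if cfg.n_discovery is not None else g.n_animals // 2
    if not 0 < n_disc < g.n_animals:
        raise ValueError(f"n_discovery={n_disc} outside (0, {g.n_animals})")
    cohorts = pd.DataFrame({
        "animal_id": g.animal_ids,
        "cohort": ["discovery"] * n_disc + ["validation"] * (g.n_animals - n_disc),
    })
    data_io.write_genotypes(g, run.path("genotypes.tsv"), "tsv")
    data_io.write_snp_map(g.snps, run.path("snp_map.tsv"))
    data_io.write_phenotypes(pheno, run.path("phenotypes.tsv"))
    run.write_table(cohorts, "cohorts.tsv")


def _load_geno(run: _Run, name: str = "genotypes_qc.tsv") -> data_io.GenotypeMatrix:
    snps = data_io.read_snp_map(run.path("snp_map.tsv"))
    return data_io.read_genotypes(run.path(name), "tsv", snp_map=snps)


def _cohort_ids(run: _Run, cohort: str) -> list[str]:
    df = run.read_table("cohorts.tsv")
    return df.loc[df["cohort"] == cohort, "animal_id"].astype(str).tolist()


def _stage_qc(run: _Run) -> None:
    g = _load_geno(run, "genotypes.tsv")
    g2, reasons = data_io.qc_filter(g, run.cfg.maf_min, return_reasons=True)
    data_io.write_genotypes(g2, run.path("genotypes_qc.tsv"), "tsv")
    run.write_table(pd.DataFrame({"snp_id": list(reasons),
                                  "reason": list(reasons.values())}),
                    "qc_removed.tsv")


def _stage_adjust(run: _Run) -> None:
    pheno = data_io.read_phenotypes(run.path("phenotypes.tsv"))
    parts = []
    for cohort in ("discovery", "validation"):
        ids = set(_cohort_ids(run, cohort))
        sub = data_io.PhenotypeTable(
            pheno.data[pheno.data["animal_id"].isin(ids)].reset_index(drop=True))
        adj = data_io.adjust_phenotypes(sub)
        part = adj.data.copy()
        part["cohort"] = cohort
        parts.append(part)
    data_io.write_phenotypes(
        data_io.PhenotypeTable(pd.concat(parts, ignore_index=True)),
        run.path("phenotypes_adjusted.tsv"))


def _stage_rank(run: _Run) -> None:
    cfg = run.cfg
    g = _load_geno(run)
    pheno = data_io.read_phenotypes(run.path("phenotypes_adjusted.tsv"))
    disc = _cohort_ids(run, "discovery")
    gd = g.subset_animals(disc)
    y = pheno.data.set_index("animal_id").loc[disc, "y_adjusted"].to_numpy(float)
    for meth in cfg.methods:
        seed = cfg.stage_seed(f"rank:{meth}")
        if meth == "rf":
            params = vim_ranking.RfParams(**{"seed": seed, **cfg.rf})
            tbl = vim_ranking.rf_importance(gd, y, params)
        elif meth == "gbm":
            params = vim_ranking.BoostParams(**{"seed": seed, **cfg.boost})
            tbl = vim_ranking.gbm_importance(gd, y, params)
        elif meth == "xgb":
            params = vim_ranking.BoostParams(**{"seed": seed, **cfg.boost})
            tbl = vim_ranking.xgb_importance(gd, y, params)
        else:
            raise ValueError(f"unknown ranking method {meth!r}")
        tbl.to_tsv(run.path(f"vim_{meth}.tsv"), gd.snps)


def _stage_select(run: _Run) -> None:
    cfg = run.cfg
    g = _load_geno(run)
    tops = []
    positives = []
    for meth in cfg.methods:
        tbl = vim_ranking.VimTable.from_tsv(run.path(f"vim_{meth}.tsv"),
                                            _METHOD_FULL[meth])
        for k in cfg.panel_sizes:
            subset_selection.top_k(tbl, min(k, len(tbl.snp_ids)),
                                   name=f"{meth.upper()}{k}") \
                .to_tsv(run.path(f"panels/{meth.upper()}{k}.tsv"))
        if cfg.include_positive:
            pos = subset_selection.positive_set(tbl, name=f"{meth.upper()}pos")
            pos.to_tsv(run.path(f"panels/{meth.upper()}pos.tsv"))
            positives.append(pos)
        top = tbl.to_frame(g.snps).head(20)
        top.insert(0, "method", meth)
        tops.append(top)
    if cfg.include_even:
        for k in cfg.panel_sizes:
            subset_selection.evenly_spaced(g.snps, min(k, g.m_snps), name=f"Even{k}") \
                .to_tsv(run.path(f"panels/Even{k}.tsv"))
    if cfg.include_all:
        subset_selection.all_snps(g.snps).to_tsv(run.path("panels/ALL.tsv"))
    run.write_table(pd.concat(tops, ignore_index=True), "top_snps.tsv")
    if cfg.include_positive and len(positives) >= 2:
        counts = subset_selection.overlap_counts(positives[:3])
        run.write_table(pd.DataFrame({"region": list(counts),
                                      "count": list(counts.values())}),
                        "overlap_counts.tsv")


def _validation_data(run: _Run):
    g = _load_geno(run)
    val = _cohort_ids(run, "validation")
    gv = g.subset_animals(val)
    pheno = data_io.read_phenotypes(run.path("phenotypes_adjusted.tsv"))
    pv = data_io.PhenotypeTable(
        pheno.data[pheno.data["animal_id"].isin(set(val))]
        .drop(columns=["cohort"]).reset_index(drop=True))
    return gv, pv


def _stage_variance(run: _Run) -> None:
    cfg = run.cfg
    gv, pv = _validation_data(run)
    vcs = {}
    diag_rows, var_rows = [], []
    names = _panel_names(cfg)
    for name in names:
        panel = SnpPanel.from_tsv(run.path(f"panels/{name}.tsv"))
        G = build_vanraden(gv, panel)
        ridge = cfg.ridge if G.m_snps < gv.n_animals else 0.0
        d = grm_diagnostics(G, ridge=cfg.ridge)
        diag_rows.append(pd.concat([pd.Series({"panel": name, "m_snps": G.m_snps}),
                                    d.to_series()]))
        vc = fit_reml(make_spec(G, pv, ridge=ridge))
        vcs[name] = vc
        var_rows.append(pd.Series({
            "panel": name, "m_snps": G.m_snps,
            "sigma2_a": vc.sigma2_a, "se_sigma2_a": vc.se_sigma2_a,
            "sigma2_e": vc.sigma2_e, "se_sigma2_e": vc.se_sigma2_e,
            "sigma2_p": vc.sigma2_p, "h2": vc.h2, "se_h2": vc.se_h2,
            "loglik": vc.loglik_reml, "ridge": ridge,
        }))
    all_name = "ALL" if cfg.include_all else names[-1]
    for row in var_rows:
        row["pct_sigma2_a_of_all"] = variance_share(vcs[row["panel"]], vcs[all_name])
    run.write_table(pd.DataFrame(var_rows), "variance_table.tsv")
    run.write_table(pd.DataFrame(diag_rows), "grm_diagnostics.tsv")


def _stage_cv(run: _Run) -> None:
    cfg = run.cfg
    gv, pv = _validation_data(run)
    cv_cfg = CvConfig(n_folds=cfg.cv_folds, seed=cfg.stage_seed("cv"),
                      scheme=cfg.cv_scheme)
    folds = make_folds(gv.animal_ids, cv_cfg)
    results = []
    rows = []
    for name in _panel_names(cfg):
        panel = SnpPanel.from_tsv(run.path(f"panels/{name}.tsv"))
        try:
            res = cv_accuracy(gv, pv, panel, cv_cfg, ridge=cfg.ridge, folds=folds)
        except ValueError as e:
            # e.g. a panel whose full-cohort heritability hits the zero
            # boundary: record the panel, leave its accuracies unset
            warnings.warn(f"CV skipped for panel {name}: {e}", UserWarning)
            rows.append(pd.Series({"panel": name, "mean_accuracy": np.nan,
                                   "sd_accuracy": np.nan, "h2_used": np.nan}))
            continue
        results.append(res)
        rows.append(res.to_series())
    run.write_table(pd.DataFrame(rows), "accuracy_table.tsv")
    if len(results) >= 2:
        run.write_table(panel_comparison(results), "panel_comparison.tsv")
    else:  # still emit the file so the stage output contract holds
        run.write_table(pd.DataFrame(rows), "panel_comparison.tsv")


_STAGE_FN = {
    "data": _stage_data,
    "qc": _stage_qc,
    "adjust": _stage_adjust,
    "rank": _stage_rank,
    "select": _stage_select,
    "variance": _stage_variance,
    "cv": _stage_cv,
}
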