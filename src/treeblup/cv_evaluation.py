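"""k-fold cross-validated accuracy of genomic prediction per SNP panel.

Per fold the fold's phenotypes are masked, REML+GBLUP is fitted on the
remaining records, and fold accuracy is
``corr(GEBV_masked, y_corrected_masked) / sqrt(h2_used)``.  By default
``h2_used`` is the REML heritability of the same panel fitted once on
the full cohort; a per-fold-training mode is available.
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import GenotypeMatrix, PhenotypeTable
from .grm import DEFAULT_RIDGE, build_vanraden
from .reml_gblup import VarianceComponents, fit_reml, make_spec, predict_gebv
from .subset_selection import SnpPanel

__all__ = ["CvConfig", "CvResult", "make_folds", "fold_accuracy",
           "cv_accuracy", "panel_comparison"]


@dataclasses.dataclass
class CvConfig:
    n_folds: int = 5
    seed: int = 0
    scheme: str = "random"  # or "family_based"
    h2_mode: str = "full_cohort"  # or "fold_training"
    h2_override: float | None = None  # fixed denominator h2 (skips estimation)

    def validate(self, n_animals: int) -> None:
        if not 2 <= self.n_folds <= n_animals:
            raise ValueError(f"n_folds must be in [2, {n_animals}]")
        if self.scheme not in ("random", "family_based"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.h2_mode not in ("full_cohort", "fold_training"):
            raise ValueError(f"unknown h2_mode {self.h2_mode!r}")


@dataclasses.dataclass
class CvResult:
    panel_name: str
    fold_accuracies: list[float]
    mean_accuracy: float
    sd_accuracy: float
    h2_used: float
    fold_hash: str  # fingerprint of the fold assignment, for pairing checks

    def __post_init__(self) -> None:
        if not np.isclose(self.mean_accuracy, np.mean(self.fold_accuracies)):
            raise ValueError("mean_accuracy does not match fold_accuracies")

    def to_series(self) -> pd.Series:
        s = pd.Series({"panel": self.panel_name,
                       "mean_accuracy": self.mean_accuracy,
                       "sd_accuracy": self.sd_accuracy,
                       "h2_used": self.h2_used})
        for i, a in enumerate(self.fold_accuracies, 1):
            s[f"fold{i}"] = a
        return s


def make_folds(animal_ids: Sequence[str], cfg: CvConfig,
               families: Sequence | None = None) -> np.ndarray:
    """Fold assignment (0..n_folds-1) per animal.

    ``random``: seeded permutation split into near-equal parts (sizes
    differ by at most one, larger folds first).  ``family_based``: whole
    families are placed greedily (largest first) into the currently
    smallest fold.
    """
    n = len(animal_ids)
    cfg.validate(n)
    assign = np.empty(n, dtype=int)
    if cfg.scheme == "random":
        perm = np.random.default_rng(cfg.seed).permutation(n)
        base, extra = divmod(n, cfg.n_folds)
        start = 0
        for f in range(cfg.n_folds):
            size = base + (1 if f < extra else 0)
            assign[perm[start:start + size]] = f
            start += size
    else:
        if families is None:
            raise ValueError("family_based scheme requires family labels")
        fam = np.asarray(families)
        if len(fam) != n:
            raise ValueError("family labels length mismatch")
        sizes = np.zeros(cfg.n_folds, dtype=int)
        labels, counts = np.unique(fam, return_counts=True)
        order = np.argsort(-counts, kind="stable")
        for li in order:
            f = int(np.argmin(sizes))
            members = fam == labels[li]
            assign[members] = f
            sizes[f] += int(counts[li])
    return assign


def _fold_hash(assign: np.ndarray, animal_ids: Sequence[str]) -> str:
    h = hashlib.sha256()
    for a, f in zip(animal_ids, assign):
        h.update(f"{a}:{f};".encode())
    return h.hexdigest()[:16]


def fold_accuracy(gebv: np.ndarray, y_corrected: np.ndarray, h2_used: float) -> float:
    """corr(GEBV, corrected phenotype) / sqrt(h2)."""
    if h2_used <= 0:
        raise ValueError("h2_used must be positive")
    gebv = np.asarray(gebv, float)
    y = np.asarray(y_corrected, float)
    if gebv.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(gebv, y)[0, 1] / np.sqrt(h2_used))


def cv_accuracy(g: GenotypeMatrix, p: PhenotypeTable, panel: SnpPanel,
                cfg: CvConfig | None = None, ridge: float = DEFAULT_RIDGE,
                families: Sequence | None = None,
                folds: np.ndarray | None = None) -> CvResult:
    """Cross-validated prediction accuracy of one SNP panel.

    Requires corrected phenotypes (``adjust_phenotypes``).  The REML fits
    use the raw phenotype with contemporary group and age in the model.
    A precomputed ``folds`` assignment may be passed to share folds
    across panels.
    """
    cfg = cfg or CvConfig()
    p = p.aligned_to(g)
    if "y_corrected" not in p.data.columns:
        raise ValueError("phenotypes lack y_corrected; run adjust_phenotypes")
    known = set(g.snp_ids)
    missing = [s for s in panel.snp_ids if s not in known]
    if missing:
        raise ValueError(f"panel SNPs absent from genotypes: {missing[:5]}...")
    if folds is None:
        folds = make_folds(g.animal_ids, cfg, families)
    else:
        cfg.validate(g.n_animals)
        if len(folds) != g.n_animals:
            raise ValueError("fold assignment length mismatch")

    G = build_vanraden(g, panel)
    # ridge only for rank-deficient (m < n) panel GRMs, and always recorded
    use_ridge = ridge if G.m_snps < g.n_animals else 0.0

    h2_full = np.nan
    if cfg.h2_override is not None:
        if cfg.h2_override <= 0:
            raise ValueError("h2_override must be positive")
        h2_full = cfg.h2_override
    elif cfg.h2_mode == "full_cohort":
        vc_full = fit_reml(make_spec(G, p, ridge=use_ridge))
        h2_full = vc_full.h2
        if not np.isfinite(h2_full) or h2_full <= 0:
            raise ValueError(
                f"full-cohort heritability {h2_full} unusable as accuracy denominator")

    y_corr = p.data.set_index("animal_id")["y_corrected"]
    accs: list[float] = []
    h2s: list[float] = []
    for f in range(cfg.n_folds):
        mask_ids = {a for a, ff in zip(g.animal_ids, folds) if ff == f}
        spec = make_spec(G, p, mask_ids=mask_ids, ridge=use_ridge)
        vc = fit_reml(spec)
        if cfg.h2_override is None and cfg.h2_mode == "fold_training":
            if not np.isfinite(vc.h2) or vc.h2 <= 0:
                warnings.warn(f"fold {f}: non-positive training h2, skipped",
                              UserWarning)
                continue
            h2_used = vc.h2
        else:
            h2_used = h2_full
        gt = predict_gebv(spec, vc)
        gmap = gt.gebv_of()
        ids = sorted(mask_ids)
        accs.append(fold_accuracy([gmap[a] for a in ids], y_corr.loc[ids].to_numpy(),
                                  h2_used))
        h2s.append(h2_used)
    if len(accs) < 2:
        raise ValueError("fewer than 2 usable folds")
    return CvResult(
        panel_name=panel.name,
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        sd_accuracy=float(np.std(accs, ddof=1)),
        h2_used=float(np.mean(h2s)),
        fold_hash=_fold_hash(folds, g.animal_ids),
    )


def panel_comparison(results: Sequence[CvResult]) -> pd.DataFrame:
    """Rank panels by mean accuracy with paired-fold differences.

    All results must come from the same fold assignment (checked via the
    fold fingerprint).  The returned table is sorted by mean accuracy and
    reports each panel's difference from the best panel across the shared
    folds, with its SD.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 results to compare")
    hashes = {r.fold_hash for r in results}
    if len(hashes) != 1:
        raise ValueError("results use different fold assignments; pairing invalid")
    n_folds = {len(r.fold_accuracies) for r in results}
    if len(n_folds) != 1:
        raise ValueError("results have different usable fold counts")
    ordered = sorted(results, key=lambda r: -r.mean_accuracy)
    best = np.asarray(ordered[0].fold_accuracies)
    rows = []
    for r in ordered:
        diff = np.asarray(r.fold_accuracies) - best
        rows.append({
            "panel": r.panel_name,
            "mean_accuracy": r.mean_accuracy,
            "sd_accuracy": r.sd_accuracy,
            "h2_used": r.h2_used,
            "diff_vs_best": float(diff.mean()),
            "sd_diff_vs_best": float(diff.std(ddof=1)),
        })
    return pd.DataFrame(rows)
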