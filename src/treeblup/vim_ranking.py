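"""Per-SNP variable importance from three tree-ensemble methods.

* ``rf_importance``  -- random forest out-of-bag permutation importance
  (%IncMSE: percentage increase in OOB MSE after permuting a SNP,
  averaged over the trees containing it; negative values preserved);
* ``gbm_importance`` -- least-squares gradient boosting relative
  influence (sum of squared-error split improvements over all trees);
* ``xgb_importance`` -- second-order boosting gain with L2/split
  penalties, normalised to sum to one.

All methods are deterministic given their seed.  RNG discipline (relied
on by the test oracles): tree ``t`` uses ``default_rng([seed, t])`` and
draws, in order, (1) the in-bag rows, (2) ``mtry`` candidate columns at
each split attempt in pre-order (left child first), (3) one OOB
permutation per used feature in ascending feature order.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from . import _tree
from .data_io import MISSING, GenotypeMatrix, SnpRecord

__all__ = ["RfParams", "BoostParams", "VimTable", "TuningCurve",
           "rf_importance", "gbm_importance", "xgb_importance",
           "tuning_curve", "find_plateau"]


@dataclasses.dataclass
class RfParams:
    ntree: int = 500
    mtry: int | None = None          # default sqrt(m) at fit time
    sample_fraction: float = 2.0 / 3.0
    min_node_size: int = 5
    seed: int = 0
    bootstrap: bool = False          # True: classical bootstrap with replacement
    mtry_per_tree: bool = False      # draw candidates once per tree, not per split
    scale_by_se: bool = False        # divide mean %IncMSE by its between-tree SE

    def resolve_mtry(self, m: int) -> int:
        mtry = self.mtry if self.mtry is not None else max(1, round(math.sqrt(m)))
        if not 1 <= mtry <= m:
            raise ValueError(f"mtry must be in [1, {m}], got {mtry}")
        return mtry

    def validate(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")


@dataclasses.dataclass
class BoostParams:
    ntree: int = 500
    learning_rate: float = 0.1
    max_depth: int = 3
    min_samples_leaf: int = 10
    subsample: float = 1.0
    reg_lambda: float = 1.0   # second-order method only
    reg_gamma: float = 0.0    # second-order method only
    seed: int = 0

    def validate(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if not 0 < self.learning_rate <= 1:
            raise ValueError(f"learning_rate must be in (0, 1], got {self.learning_rate}")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.reg_lambda < 0 or self.reg_gamma < 0:
            raise ValueError("reg_lambda and reg_gamma must be >= 0")
        if not 0 < self.subsample <= 1:
            raise ValueError("subsample must be in (0, 1]")


_METHODS = ("rf_permutation", "gbm_influence", "xgb_gain")


def _genome_order_keys(snps: Sequence[SnpRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Numeric (chrom, pos) sort keys; chromosome names sort naturally."""
    def chrom_key(c: str):
        return (0, int(c), "") if c.isdigit() else (1, 0, c)

    levels = sorted({s.chrom for s in snps}, key=chrom_key)
    code = {c: i for i, c in enumerate(levels)}
    return (np.array([code[s.chrom] for s in snps]),
            np.array([s.pos_bp for s in snps]))


@dataclasses.dataclass
class VimTable:
    """Scores and 1-based ranks for one importance method."""

    method: str
    snp_ids: list[str]
    scores: np.ndarray
    ranks: np.ndarray
    flags: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        m = len(self.snp_ids)
        if len(self.scores) != m or len(self.ranks) != m:
            raise ValueError("scores/ranks length mismatch")
        if sorted(self.ranks) != list(range(1, m + 1)):
            raise ValueError("ranks must be a permutation of 1..m")

    @classmethod
    def from_scores(cls, method: str, snps: Sequence[SnpRecord],
                    scores: np.ndarray, flags: dict | None = None) -> "VimTable":
        scores = np.asarray(scores, dtype=float)
        chrom_key, pos_key = _genome_order_keys(snps)
        order = np.lexsort((pos_key, chrom_key, -scores))
        ranks = np.empty(len(scores), dtype=int)
        ranks[order] = np.arange(1, len(scores) + 1)
        return cls(method, [s.snp_id for s in snps], scores, ranks, flags or {})

    def score_of(self) -> dict[str, float]:
        return dict(zip(self.snp_ids, self.scores.tolist()))

    def rank_of(self) -> dict[str, int]:
        return dict(zip(self.snp_ids, self.ranks.tolist()))

    def top_ids(self, k: int) -> list[str]:
        order = np.argsort(self.ranks)
        return [self.snp_ids[i] for i in order[:k]]

    def to_frame(self, snps: Sequence[SnpRecord] | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"snp_id": self.snp_ids, "score": self.scores,
                           "rank": self.ranks})
        if snps is not None:
            by_id = {s.snp_id: s for s in snps}
            df.insert(1, "chrom", [by_id[s].chrom for s in self.snp_ids])
            df.insert(2, "pos_bp", [by_id[s].pos_bp for s in self.snp_ids])
        return df.sort_values("rank").reset_index(drop=True)

    def to_tsv(self, path, snps: Sequence[SnpRecord] | None = None) -> None:
        self.to_frame(snps).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, method: str) -> "VimTable":
        df = pd.read_csv(path, sep="\t", dtype={"snp_id": str}).sort_index()
        tbl = cls(method, df["snp_id"].tolist(),
                  df["score"].to_numpy(float), df["rank"].to_numpy(int))
        return tbl


def _check_inputs(g: GenotypeMatrix, y: np.ndarray) -> np.ndarray:
    if (g.dosage == MISSING).any():
        raise ValueError("genotypes contain missing calls; run qc_filter first")
    y = np.asarray(y, dtype=float)
    if len(y) != g.n_animals:
        raise ValueError(f"phenotype length {len(y)} != {g.n_animals} animals")
    return y


def rf_importance(g: GenotypeMatrix, y_adjusted: np.ndarray,
                  params: RfParams | None = None) -> VimTable:
    """Random-forest %IncMSE importance.

    Per tree: subsample rows (without replacement at ``sample_fraction``
    by default), grow an unpruned CART with ``mtry`` candidate columns
    per split, compute the out-of-bag MSE, then for every SNP used in the
    tree permute its OOB column and record
    ``(MSE_permuted - MSE_oob) / MSE_oob * 100``.  A SNP's score is the
    average of its per-tree increases over all ``ntree`` trees (trees not
    containing the SNP contribute 0, as in the classical forest
    implementation), so never-used SNPs score 0 and rarely-used SNPs are
    shrunk toward 0.
    """
    params = params or RfParams()
    params.validate()
    y = _check_inputs(g, y_adjusted)
    n, m = g.n_animals, g.m_snps
    mtry = params.resolve_mtry(m)
    X = np.ascontiguousarray(g.dosage, dtype=np.float32)
    yc = (y - y.mean())  # centring is float32-safe and leaves MSE ratios unchanged

    score_sum = np.zeros(m)
    score_sq = np.zeros(m)
    n_used = np.zeros(m, dtype=int)
    ever_used = np.zeros(m, dtype=bool)
    no_oob_trees = 0
    n_in = max(1, int(np.floor(params.sample_fraction * n)))

    for t in range(params.ntree):
        rng = np.random.default_rng([params.seed, t])
        if params.bootstrap:
            inbag = rng.integers(0, n, size=n)
        else:
            inbag = rng.permutation(n)[:n_in]
        oob = np.setdiff1d(np.arange(n), inbag)
        tree = _tree.grow_tree(X, yc, inbag, min_leaf=params.min_node_size,
                               mtry=mtry, rng=rng,
                               mtry_per_tree=params.mtry_per_tree)
        used = tree.used_features()
        ever_used[used] = True
        if len(oob) == 0 or len(used) == 0:
            no_oob_trees += 1
            continue
        X_oob = X[oob]
        pred = _tree.predict(tree, X_oob)
        mse_oob = float(np.mean((yc[oob] - pred) ** 2))
        for f in used:
            perm = rng.permutation(len(oob))
            saved = X_oob[:, f].copy()
            X_oob[:, f] = saved[perm]
            pred_p = _tree.predict(tree, X_oob)
            X_oob[:, f] = saved
            mse_p = float(np.mean((yc[oob] - pred_p) ** 2))
            if mse_oob > 0:
                contrib = (mse_p - mse_oob) / mse_oob * 100.0
            else:
                contrib = 0.0
            score_sum[f] += contrib
            score_sq[f] += contrib * contrib
            n_used[f] += 1

    scores = score_sum / params.ntree
    flags = {"trees_without_oob": no_oob_trees,
             "snps_used_without_oob_eval": int((ever_used & (n_used == 0)).sum())}
    if params.scale_by_se:
        var = score_sq / params.ntree - scores**2
        se = np.sqrt(np.maximum(var, 0.0) / params.ntree)
        scores = np.where(se > 0, scores / np.where(se > 0, se, 1.0), scores)
    return VimTable.from_scores("rf_permutation", g.snps, scores, flags)


def _boost_importance(g: GenotypeMatrix, y: np.ndarray, params: BoostParams,
                      criterion: str) -> np.ndarray:
    n, m = g.n_animals, g.m_snps
    X = np.ascontiguousarray(g.dosage, dtype=np.float32)
    lam = params.reg_lambda if criterion == "gain" else 0.0
    gamma = params.reg_gamma if criterion == "gain" else 0.0
    yc = y - y.mean()  # f0 = mean(y); boosting proceeds on the centred scale
    f = np.zeros(n)
    importance = np.zeros(m)
    full_idx = np.arange(n)
    n_sub = max(1, int(np.floor(params.subsample * n)))
    for t in range(params.ntree):
        r = yc - f
        if params.subsample < 1.0:
            rng = np.random.default_rng([params.seed, t])
            idx = rng.permutation(n)[:n_sub]
        else:
            idx = full_idx
        tree = _tree.grow_tree(X, r, idx, max_depth=params.max_depth,
                               min_leaf=params.min_samples_leaf,
                               criterion=criterion, lam=lam, gamma=gamma)
        internal = tree.feature != -1
        np.add.at(importance, tree.feature[internal], tree.improvement[internal])
        f = f + params.learning_rate * _tree.predict(tree, X)
    return importance


def gbm_importance(g: GenotypeMatrix, y_adjusted: np.ndarray,
                   params: BoostParams | None = None,
                   backend: str = "reference") -> VimTable:
    """Gradient-boosting relative influence: per SNP, the summed
    squared-error improvement over all split points of all trees."""
    params = params or BoostParams()
    params.validate()
    y = _check_inputs(g, y_adjusted)
    if backend == "sklearn":
        from sklearn.ensemble import GradientBoostingRegressor

        est = GradientBoostingRegressor(
            n_estimators=params.ntree, learning_rate=params.learning_rate,
            max_depth=params.max_depth, min_samples_leaf=params.min_samples_leaf,
            subsample=params.subsample, random_state=params.seed)
        est.fit(g.dosage, y)
        scores = est.feature_importances_
    elif backend == "reference":
        scores = _boost_importance(g, y, params, criterion="sse")
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return VimTable.from_scores("gbm_influence", g.snps, scores)


def xgb_importance(g: GenotypeMatrix, y_adjusted: np.ndarray,
                   params: BoostParams | None = None) -> VimTable:
    """Second-order boosting gain importance (squared loss, unit
    hessians), normalised so positive scores sum to 1."""
    params = params or BoostParams()
    params.validate()
    y = _check_inputs(g, y_adjusted)
    scores = _boost_importance(g, y, params, criterion="gain")
    total = scores[scores > 0].sum()
    if total > 0:
        scores = scores / total
    return VimTable.from_scores("xgb_gain", g.snps, scores)


@dataclasses.dataclass
class TuningCurve:
    """Held-out MSE across a parameter grid, plus the detected plateau."""

    method: str
    grid: list[tuple[dict, float]]
    plateau_index: int

    @property
    def plateau_setting(self) -> dict:
        return self.grid[self.plateau_index][0]

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(setting, mean_mse=mse) for setting, mse in self.grid]
        return pd.DataFrame(rows)


def find_plateau(mses: Sequence[float], rtol: float = 0.05) -> int:
    """Index of the first grid point whose MSE is within ``rtol`` of the
    minimum (the smallest adequate setting for a grid ordered small to
    large)."""
    mses = np.asarray(mses, dtype=float)
    if len(mses) == 0:
        raise ValueError("empty tuning grid")
    lo = mses.min()
    return int(np.argmax(mses <= lo * (1.0 + rtol)))


def _forest_oob_mse(g: GenotypeMatrix, y: np.ndarray, params: RfParams) -> float:
    n, m = g.n_animals, g.m_snps
    X = np.ascontiguousarray(g.dosage, dtype=np.float32)
    mtry = params.resolve_mtry(m)
    pred_sum = np.zeros(n)
    pred_cnt = np.zeros(n)
    n_in = max(1, int(np.floor(params.sample_fraction * n)))
    for t in range(params.ntree):
        rng = np.random.default_rng([params.seed, t])
        inbag = rng.integers(0, n, size=n) if params.bootstrap else rng.permutation(n)[:n_in]
        oob = np.setdiff1d(np.arange(n), inbag)
        if len(oob) == 0:
            continue
        tree = _tree.grow_tree(X, y, inbag, min_leaf=params.min_node_size,
                               mtry=mtry, rng=rng, mtry_per_tree=params.mtry_per_tree)
        pred_sum[oob] += _tree.predict(tree, X[oob])
        pred_cnt[oob] += 1
    have = pred_cnt > 0
    if not have.any():
        raise ValueError("no OOB predictions; increase ntree or lower sample_fraction")
    return float(np.mean((y[have] - pred_sum[have] / pred_cnt[have]) ** 2))


def tuning_curve(g: GenotypeMatrix, y_adjusted: np.ndarray, method: str,
                 grid: Sequence[dict], base_params=None, seed: int = 0,
                 holdout_fraction: float = 0.2, rtol: float = 0.05) -> TuningCurve:
    """Held-out MSE for each grid setting (OOB MSE for the forest,
    validation-split MSE for the boosters) with a plateau detector."""
    if len(grid) == 0:
        raise ValueError("tuning grid must be non-empty")
    y = _check_inputs(g, y_adjusted)
    kind = {"rf": "rf", "rf_permutation": "rf",
            "gbm": "gbm", "gbm_influence": "gbm",
            "xgb": "xgb", "xgb_gain": "xgb"}.get(method)
    if kind is None:
        raise ValueError(f"unknown method {method!r}")

    results: list[tuple[dict, float]] = []
    if kind == "rf":
        base = base_params or RfParams(seed=seed)
        for setting in grid:
            params = dataclasses.replace(base, **setting)
            results.append((dict(setting), _forest_oob_mse(g, y, params)))
    else:
        rng = np.random.default_rng([seed, 9])
        n = g.n_animals
        perm = rng.permutation(n)
        n_val = max(1, int(np.floor(holdout_fraction * n)))
        val, train = perm[:n_val], perm[n_val:]
        g_train = GenotypeMatrix([g.animal_ids[i] for i in train], list(g.snps),
                                 g.dosage[train])
        base = base_params or BoostParams(seed=seed)
        for setting in grid:
            params = dataclasses.replace(base, **setting)
            params.validate()
            pred = _boost_predict(g_train, y[train], params, kind, g.dosage[val])
            results.append((dict(setting), float(np.mean((y[val] - pred) ** 2))))
    mses = [mse for _, mse in results]
    if len({tuple(sorted(s.items())) for s, _ in results}) != len(results):
        warnings.warn("duplicate settings in tuning grid", UserWarning)
    return TuningCurve(method, results, find_plateau(mses, rtol))


def _boost_predict(g: GenotypeMatrix, y: np.ndarray, params: BoostParams,
                   kind: str, X_new: np.ndarray) -> np.ndarray:
    criterion = "gain" if kind == "xgb" else "sse"
    n = g.n_animals
    X = np.ascontiguousarray(g.dosage, dtype=np.float32)
    Xn = np.asarray(X_new, dtype=np.float32)
    lam = params.reg_lambda if criterion == "gain" else 0.0
    gamma = params.reg_gamma if criterion == "gain" else 0.0
    yc = y - y.mean()
    f = np.zeros(n)
    out = np.full(Xn.shape[0], y.mean())
    full_idx = np.arange(n)
    n_sub = max(1, int(np.floor(params.subsample * n)))
    for t in range(params.ntree):
        r = yc - f
        if params.subsample < 1.0:
            rng = np.random.default_rng([params.seed, t])
            idx = rng.permutation(n)[:n_sub]
        else:
            idx = full_idx
        tree = _tree.grow_tree(X, r, idx, max_depth=params.max_depth,
                               min_leaf=params.min_samples_leaf,
                               criterion=criterion, lam=lam, gamma=gamma)
        f = f + params.learning_rate * _tree.predict(tree, X)
        out = out + params.learning_rate * _tree.predict(tree, Xn)
    return out
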