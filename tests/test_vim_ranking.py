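import numpy as np
import pytest

from treeblup.simulate import SimConfig, simulate_cohort
from treeblup.data_io import adjust_phenotypes
from treeblup.vim_ranking import (BoostParams, RfParams, VimTable, find_plateau,
                                  gbm_importance, rf_importance, tuning_curve,
                                  xgb_importance)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# straight-line oracles, written against the documented procedures only
# ---------------------------------------------------------------------------

def _oracle_tree(X, y, idx, min_leaf, mtry, rng):
    """Recursive CART following the documented RNG discipline: candidates
    drawn per split attempt, pre-order, left child first; ties to the
    lowest column index; leaf when best reduction is (near) zero."""
    n, m = X.shape

    def node(idx, depth):
        r = y[idx]
        rec = {"value": float(r.mean()), "feature": -1, "threshold": 0.0,
               "left": None, "right": None}
        if len(idx) < 2 * min_leaf or np.ptp(r) == 0.0:
            return rec
        cand = np.sort(rng.choice(m, size=mtry, replace=False)) if mtry < m \
            else np.arange(m)
        best = (-np.inf, None, None)
        sse = lambda v: float(((v - v.mean()) ** 2).sum()) if len(v) else 0.0
        for j in cand:
            for thr in (0.5, 1.5):
                mask = X[idx, j] < thr
                if mask.sum() < min_leaf or (~mask).sum() < min_leaf:
                    continue
                red = sse(r) - sse(r[mask]) - sse(r[~mask])
                if red > best[0] + 1e-12:
                    best = (red, int(j), thr)
        if best[1] is None or best[0] <= 1e-12 * max(1.0, float(r @ r)):
            return rec
        _, j, thr = best
        rec.update(feature=j, threshold=thr)
        mask = X[idx, j] < thr
        rec["left"] = node(idx[mask], depth + 1)
        rec["right"] = node(idx[~mask], depth + 1)
        return rec

    return node(np.asarray(idx), 0)


def _oracle_predict(tree, x):
    while tree["feature"] != -1:
        tree = tree["left"] if x[tree["feature"]] < tree["threshold"] else tree["right"]
    return tree["value"]


def _oracle_used(tree, acc):
    if tree["feature"] != -1:
        acc.add(tree["feature"])
        _oracle_used(tree["left"], acc)
        _oracle_used(tree["right"], acc)
    return acc


def oracle_rf_scores(X, y, ntree, mtry, sample_fraction, min_leaf, seed):
    """Steps (1)-(6) of the forest permutation-importance procedure,
    implemented independently of the package's engine."""
    n, m = X.shape
    score_sum = np.zeros(m)
    yc = y - y.mean()
    n_in = int(np.floor(sample_fraction * n))
    for t in range(ntree):
        rng = np.random.default_rng([seed, t])
        inbag = rng.permutation(n)[:n_in]
        oob = np.setdiff1d(np.arange(n), inbag)
        tree = _oracle_tree(X, yc, inbag, min_leaf, mtry, rng)
        used = sorted(_oracle_used(tree, set()))
        if len(oob) == 0 or not used:
            continue
        preds = np.array([_oracle_predict(tree, X[i]) for i in oob])
        mse = np.mean((yc[oob] - preds) ** 2)
        for f in used:
            perm = rng.permutation(len(oob))
            Xp = X[oob].copy()
            Xp[:, f] = Xp[perm, f]
            pp = np.array([_oracle_predict(tree, row) for row in Xp])
            msep = np.mean((yc[oob] - pp) ** 2)
            if mse > 0:
                score_sum[f] += (msep - mse) / mse * 100.0
    return score_sum / ntree


def oracle_gbm(X, y, n_stages, lr, max_depth, min_leaf):
    """Stage-wise least-squares boosting with exhaustive stump/tree search."""
    n, m = X.shape
    f = np.full(n, y.mean())
    importance = np.zeros(m)
    rng = np.random.default_rng(0)  # unused: no subsampling
    for _ in range(n_stages):
        r = y - f
        tree = _oracle_tree(X, r, np.arange(n), min_leaf, m, rng)
        # depth-1 restriction: chop children of children
        if max_depth == 1 and tree["feature"] != -1:
            for side in ("left", "right"):
                tree[side]["feature"] = -1

        def collect_imp(t, idx):
            if t["feature"] == -1:
                return
            rr = r[idx]
            mask = X[idx, t["feature"]] < t["threshold"]
            sse = lambda v: float(((v - v.mean()) ** 2).sum()) if len(v) else 0.0
            importance[t["feature"]] += sse(rr) - sse(rr[mask]) - sse(rr[~mask])
            collect_imp(t["left"], idx[mask])
            collect_imp(t["right"], idx[~mask])

        collect_imp(tree, np.arange(n))
        f = f + lr * np.array([_oracle_predict(tree, X[i]) for i in range(n)])
    return importance


# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def qtl_cohort():
    cfg = SimConfig(n_animals=250, m_snps=60, n_qtl=5, h2_true=0.5, n_groups=4,
                    seed=88, qtl_maf_min=0.1)
    g, p, truth = simulate_cohort(cfg)
    y = adjust_phenotypes(p).data["y_adjusted"].to_numpy()
    return g, y, truth


class TestRfImportance:
    def test_matches_straight_line_oracle(self, rng):
        X = rng.integers(0, 3, size=(20, 5)).astype(np.int8)
        y = X[:, 0] * 2.0 + rng.normal(size=20)
        g = make_matrix(X)
        params = RfParams(ntree=2, mtry=3, min_node_size=2, seed=42)
        tbl = rf_importance(g, y, params)
        expected = oracle_rf_scores(X.astype(float), y, ntree=2, mtry=3,
                                    sample_fraction=2 / 3, min_leaf=2, seed=42)
        np.testing.assert_allclose(tbl.scores, expected, rtol=1e-4, atol=1e-6)

    def test_null_snp_scores_near_zero(self, rng):
        g = make_matrix(rng.integers(0, 3, size=(150, 10)).astype(np.int8))
        y = rng.normal(size=150)  # independent of every SNP
        tbl = rf_importance(g, y, RfParams(ntree=300, mtry=3, seed=1))
        assert np.abs(tbl.scores.mean()) < 2.0
        assert np.abs(tbl.scores).max() < 15.0

    def test_single_qtl_ranks_first(self):
        wins = 0
        for seed in range(10):
            cfg = SimConfig(n_animals=150, m_snps=30, n_qtl=1, h2_true=0.5,
                            n_groups=1, seed=seed, qtl_maf_min=0.2)
            g, p, truth = simulate_cohort(cfg)
            y = adjust_phenotypes(p).data["y_adjusted"].to_numpy()
            tbl = rf_importance(g, y, RfParams(ntree=120, seed=seed))
            wins += tbl.top_ids(1)[0] == truth.qtl_ids[0]
        assert wins >= 9

    def test_deterministic(self, qtl_cohort):
        g, y, _ = qtl_cohort
        p = RfParams(ntree=10, seed=7)
        t1 = rf_importance(g, y, p)
        t2 = rf_importance(g, y, p)
        np.testing.assert_array_equal(t1.scores, t2.scores)
        t3 = rf_importance(g, y, RfParams(ntree=10, seed=8))
        assert not np.array_equal(t1.scores, t3.scores)

    def test_negative_scores_occur_on_noise(self, rng):
        g = make_matrix(rng.integers(0, 3, size=(120, 20)).astype(np.int8))
        y = rng.normal(size=120)
        tbl = rf_importance(g, y, RfParams(ntree=150, mtry=5, seed=2))
        assert (tbl.scores < 0).any()

    def test_no_oob_flag(self, qtl_cohort):
        g, y, _ = qtl_cohort
        tbl = rf_importance(g, y, RfParams(ntree=2, sample_fraction=1.0, seed=1))
        assert tbl.flags["trees_without_oob"] == 2
        np.testing.assert_array_equal(tbl.scores, 0.0)

    def test_missing_genotypes_rejected(self, rng):
        from treeblup.data_io import MISSING

        X = rng.integers(0, 3, size=(30, 4)).astype(np.int8)
        X[0, 0] = MISSING
        with pytest.raises(ValueError, match="missing"):
            rf_importance(make_matrix(X), np.zeros(30))


class TestGbmImportance:
    def test_single_predictor_carries_influence(self, rng):
        X = rng.integers(0, 3, size=(200, 8)).astype(np.int8)
        y = 3.0 * X[:, 2] + rng.normal(0, 0.01, 200)
        tbl = gbm_importance(make_matrix(X), y,
                             BoostParams(ntree=30, max_depth=1, min_samples_leaf=5))
        assert tbl.scores[2] / tbl.scores.sum() > 0.99
        assert tbl.ranks[2] == 1

    def test_matches_stagewise_oracle(self, rng):
        X = rng.integers(0, 3, size=(10, 3)).astype(np.int8)
        y = rng.normal(size=10)
        params = BoostParams(ntree=3, learning_rate=0.1, max_depth=1,
                             min_samples_leaf=1, seed=0)
        tbl = gbm_importance(make_matrix(X), y, params)
        expected = oracle_gbm(X.astype(float), y, n_stages=3, lr=0.1,
                              max_depth=1, min_leaf=1)
        np.testing.assert_allclose(tbl.scores, expected, rtol=1e-4, atol=1e-7)

    def test_scores_nonnegative(self, qtl_cohort):
        g, y, _ = qtl_cohort
        tbl = gbm_importance(g, y, BoostParams(ntree=25, seed=3))
        assert (tbl.scores >= 0).all()

    def test_all_noise_spreads_influence(self, rng):
        X = rng.integers(0, 3, size=(100, 20)).astype(np.int8)
        y_tr = rng.normal(size=100)
        tbl = gbm_importance(make_matrix(X), y_tr, BoostParams(ntree=40, seed=5))
        assert tbl.scores.max() / tbl.scores.sum() < 0.5

    def test_invalid_learning_rate(self, qtl_cohort):
        g, y, _ = qtl_cohort
        with pytest.raises(ValueError, match="learning_rate"):
            gbm_importance(g, y, BoostParams(learning_rate=0.0))

    def test_sklearn_backend_agrees_on_top_snps(self, qtl_cohort):
        g, y, truth = qtl_cohort
        params = BoostParams(ntree=60, max_depth=3, min_samples_leaf=5, seed=1)
        ours = gbm_importance(g, y, params)
        theirs = gbm_importance(g, y, params, backend="sklearn")
        # different tie-breaking/implementations: compare top-10 overlap
        assert len(set(ours.top_ids(10)) & set(theirs.top_ids(10))) >= 6


class TestXgbImportance:
    def test_scores_sum_to_one(self, qtl_cohort):
        g, y, _ = qtl_cohort
        tbl = xgb_importance(g, y, BoostParams(ntree=25, seed=1))
        assert (tbl.scores >= 0).all()
        assert tbl.scores.sum() == pytest.approx(1.0)

    def test_reduces_to_first_order_split(self, rng):
        # lam=0, gamma=0, depth 1, one stage: same root split as plain CART
        from treeblup._tree import fit_regression_tree

        X = rng.integers(0, 3, size=(60, 10)).astype(np.int8)
        y = X[:, 4] * 1.5 + rng.normal(size=60)
        params = BoostParams(ntree=1, max_depth=1, min_samples_leaf=1,
                             reg_lambda=0.0, reg_gamma=0.0, seed=0)
        tbl = xgb_importance(make_matrix(X), y, params)
        cart = fit_regression_tree(X.astype(float), y - y.mean(), max_depth=1)
        assert tbl.ranks[cart.feature[0]] == 1

    def test_invalid_lambda(self, qtl_cohort):
        g, y, _ = qtl_cohort
        with pytest.raises(ValueError, match="reg_lambda"):
            xgb_importance(g, y, BoostParams(reg_lambda=-1.0))

    def test_deterministic(self, qtl_cohort):
        g, y, _ = qtl_cohort
        p = BoostParams(ntree=10, seed=4)
        np.testing.assert_array_equal(xgb_importance(g, y, p).scores,
                                      xgb_importance(g, y, p).scores)


class TestVimTable:
    def test_ranks_are_permutation(self, qtl_cohort):
        g, y, _ = qtl_cohort
        tbl = gbm_importance(g, y, BoostParams(ntree=5))
        assert sorted(tbl.ranks) == list(range(1, g.m_snps + 1))

    def test_tie_break_by_genome_order(self):
        g = make_matrix(np.zeros((4, 3), dtype=np.int8),
                        chroms=[2, 1, 1], positions=[50, 900, 100])
        tbl = VimTable.from_scores("gbm_influence", g.snps,
                                   np.array([5.0, 5.0, 3.0]))
        # tie between s1 (chr2) and s2 (chr1:900): s2 wins on chromosome
        assert tbl.rank_of() == {"s2": 1, "s1": 2, "s3": 3}

    def test_round_trip_tsv(self, tmp_path, qtl_cohort):
        g, y, _ = qtl_cohort
        tbl = gbm_importance(g, y, BoostParams(ntree=5))
        tbl.to_tsv(tmp_path / "vim.tsv", g.snps)
        back = VimTable.from_tsv(tmp_path / "vim.tsv", "gbm_influence")
        assert back.rank_of() == tbl.rank_of()
        assert back.score_of() == pytest.approx(tbl.score_of())


class TestTuningCurve:
    def test_single_setting_is_plateau(self, qtl_cohort):
        g, y, _ = qtl_cohort
        curve = tuning_curve(g, y, "gbm", [{"ntree": 5}], seed=1)
        assert curve.plateau_index == 0
        assert len(curve.grid) == 1

    def test_plateau_detector_on_constructed_curve(self):
        mses = [10.0, 6.0, 3.0, 1.01, 1.0, 1.0]
        assert find_plateau(mses, rtol=0.05) == 3
        assert find_plateau([5.0], rtol=0.05) == 0
        with pytest.raises(ValueError):
            find_plateau([])

    def test_mtry_one_dominates_tuned_mtry(self):
        # single-marker trees cannot capture a multi-QTL signal: higher MSE
        cfg = SimConfig(n_animals=250, m_snps=50, n_qtl=10, h2_true=0.6,
                        n_groups=1, seed=17, qtl_maf_min=0.2)
        g, p, _ = simulate_cohort(cfg)
        y = adjust_phenotypes(p).data["y_adjusted"].to_numpy()
        curve = tuning_curve(g, y, "rf",
                             [{"mtry": 1, "ntree": 60}, {"mtry": 5, "ntree": 60}],
                             seed=2)
        assert curve.grid[0][1] > curve.grid[1][1]

    def test_empty_grid_rejected(self, qtl_cohort):
        g, y, _ = qtl_cohort
        with pytest.raises(ValueError, match="non-empty"):
            tuning_curve(g, y, "rf", [])


def test_power_rf_gbm_recover_qtls_small_scale():
    """Desk-scale screening power: most QTLs inside the top 3*n_qtl."""
    cfg = SimConfig(n_animals=400, m_snps=800, n_qtl=10, h2_true=0.4,
                    n_groups=4, seed=5, qtl_effect_dist="equal_var",
                    qtl_maf_min=0.15)
    g, p, truth = simulate_cohort(cfg)
    y = adjust_phenotypes(p).data["y_adjusted"].to_numpy()
    qtl = set(truth.qtl_ids)
    k = 3 * len(qtl)
    rf = rf_importance(g, y, RfParams(ntree=300, mtry=80, min_node_size=20, seed=1))
    gbm = gbm_importance(g, y, BoostParams(ntree=150, seed=1))
    assert len(set(rf.top_ids(k)) & qtl) >= 7
    assert len(set(gbm.top_ids(k)) & qtl) >= 7
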