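"""RF regression, permutation null, selection, refit and layer combination."""

import numpy as np
import pandas as pd
import pytest

import omicsforest as of
from omicsforest.datasets import AlignmentError, DegenerateInputError


def _matrix(seed, n, p, prefix="Gene"):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n, p)),
        index=[f"s{i:03d}" for i in range(n)],
        columns=[f"{prefix}_{j + 1}" for j in range(p)],
    )


FAST = of.RFParams(n_trees=60, seed=0)


def test_perfect_predictor_dominates():
    X = _matrix(0, 80, 30)
    rng = np.random.default_rng(1)
    y = pd.Series(X["Gene_7"].to_numpy() + 0.01 * rng.normal(size=80),
                  index=X.index, name="t")
    fit = of.fit_random_forest(X, y, FAST)
    assert fit.importance.idxmax() == "Gene_7"
    assert fit.importance["Gene_7"] > 3 * fit.importance.drop("Gene_7").max()
    assert fit.oob_r2 > 0.5


def test_importance_nonnegative_and_complete():
    X = _matrix(2, 60, 40)
    y = pd.Series(np.random.default_rng(3).normal(size=60), index=X.index)
    fit = of.fit_random_forest(X, y, FAST)
    assert list(fit.importance.index) == list(X.columns)
    assert np.isfinite(fit.importance).all()
    assert (fit.importance >= 0).all()
    assert fit.oob_r2 <= 1


def test_seeded_determinism():
    X = _matrix(4, 60, 25)
    y = pd.Series(X["Gene_1"].to_numpy() + np.random.default_rng(5).normal(size=60),
                  index=X.index)
    f1 = of.fit_random_forest(X, y, of.RFParams(n_trees=40, seed=99))
    f2 = of.fit_random_forest(X, y, of.RFParams(n_trees=40, seed=99))
    assert f1.oob_r2 == f2.oob_r2
    pd.testing.assert_series_equal(f1.importance, f2.importance)


def test_null_oob_r2_is_low():
    """With y independent of X the predictive OOB R^2 hovers at or below
    zero; demand <= 0.1 in at least 95 of 100 seeded runs."""
    X = _matrix(6, 100, 200)
    rng = np.random.default_rng(7)
    params = of.RFParams(n_trees=30, max_features=30, seed=0)
    low = 0
    for k in range(100):
        y = pd.Series(rng.normal(size=100), index=X.index)
        fit = of.fit_random_forest(
            X, y, of.RFParams(n_trees=30, max_features=30, seed=k)
        )
        low += fit.oob_r2 <= 0.1
    assert low >= 95


def test_input_validation():
    X = _matrix(8, 30, 10)
    y_bad = pd.Series(np.zeros(30), index=[f"z{i}" for i in range(30)])
    with pytest.raises(AlignmentError):
        of.fit_random_forest(X, y_bad, FAST)
    y_const = pd.Series(np.ones(30), index=X.index)
    with pytest.raises(DegenerateInputError):
        of.fit_random_forest(X, y_const, FAST)


def test_missing_values_imputed():
    X = _matrix(9, 50, 12)
    X.iloc[::7, 3] = np.nan
    y = pd.Series(np.random.default_rng(10).normal(size=50), index=X.index)
    fit = of.fit_random_forest(X, y, FAST)
    assert np.isfinite(fit.importance).all()


def test_permutation_null_thresholds_monotone():
    X = _matrix(11, 40, 8)
    y = pd.Series(np.random.default_rng(12).normal(size=40), index=X.index)
    null = of.permutation_null(X, y, of.RFParams(n_trees=25, seed=1), n_perm=120, seed=2)
    assert null.importance_threshold(0.95) <= null.importance_threshold(0.999)
    assert null.r2_threshold(0.9) <= null.r2_threshold(0.99)
    assert null.null_r2.shape == (120,)
    assert null.null_importance_pool.shape == (120 * 8,)
    per_feat = null.importance_threshold(0.95, per_feature=True)
    assert len(per_feat) == 8


def test_small_n_perm_warns():
    X = _matrix(13, 40, 5)
    y = pd.Series(np.random.default_rng(14).normal(size=40), index=X.index)
    with pytest.warns(UserWarning, match="quantile resolution"):
        of.permutation_null(X, y, of.RFParams(n_trees=10, seed=0), n_perm=20, seed=0)


def _fake_null(feature_ids, r2s, imps):
    return of.PermutationNull(
        n_perm=len(r2s),
        null_r2=np.asarray(r2s, dtype=float),
        null_importance=np.asarray(imps, dtype=np.float32),
        feature_ids=list(feature_ids),
        params=of.RFParams(n_trees=1),
    )


def test_selection_gate_behaviour():
    """A model below its null R^2 threshold yields an empty set; above it,
    features are ranked by importance in strictly descending order."""
    ids = ["Gene_1", "Gene_2", "Gene_3"]
    imp = pd.Series([5.0, 0.1, 3.0], index=ids)
    null = _fake_null(ids, np.linspace(0, 0.6, 100), np.full((100, 3), 0.5))
    gated = of.select_significant(
        of.RFResult(0.1, imp, of.RFParams(n_trees=1)), null, 0.05, 0.05
    )
    assert not gated.model_significant
    assert len(gated) == 0

    passed = of.select_significant(
        of.RFResult(0.95, imp, of.RFParams(n_trees=1)), null, 0.05, 0.05
    )
    assert passed.model_significant
    assert passed.feature_ids == ["Gene_1", "Gene_3"]
    assert list(passed.features["rank"]) == [1, 2]
    assert passed.features["importance"].is_monotonic_decreasing


def test_refit_all_features_equals_full_fit():
    X = _matrix(15, 60, 20)
    y = pd.Series(X["Gene_2"].to_numpy() + np.random.default_rng(16).normal(size=60),
                  index=X.index)
    full = of.fit_random_forest(X, y, FAST)
    refit = of.refit_on_selection(X, list(X.columns), y, FAST)
    assert refit.oob_r2 == full.oob_r2
    assert np.allclose(refit.importance, full.importance)


def test_refit_empty_selection_rejected():
    X = _matrix(17, 40, 6)
    y = pd.Series(np.random.default_rng(18).normal(size=40), index=X.index)
    with pytest.raises(ValueError, match="empty"):
        of.refit_on_selection(X, [], y, FAST)


def _sig_set(layer, ids):
    feats = pd.DataFrame(
        {"feature_id": ids, "importance": np.arange(len(ids), 0, -1, dtype=float),
         "rank": np.arange(1, len(ids) + 1)}
    )
    return of.SignificantSet(layer, feats, True, 0.05, 0.05)


def test_combine_layers_concatenates_namespaces():
    samples = [f"s{i:03d}" for i in range(30)]
    rng = np.random.default_rng(19)
    gene = of.OmicsDataset("gene", pd.DataFrame(
        rng.normal(size=(4, 30)), index=[f"Gene_{i}" for i in range(4)], columns=samples))
    lc = of.OmicsDataset("lc", pd.DataFrame(
        rng.normal(size=(3, 30)), index=[f"LC_{i}" for i in range(3)], columns=samples))
    sets = [_sig_set("gene", ["Gene_0", "Gene_2"]), _sig_set("lc", ["LC_1"])]
    combined = of.combine_layers(sets, [gene, lc])
    assert combined.n_features == 3
    assert set(combined.feature_ids) == {"Gene_0", "Gene_2", "LC_1"}
    # single non-empty set: that layer's restriction, unchanged values
    solo = of.combine_layers([_sig_set("gene", ["Gene_1"])], [gene, lc])
    assert np.allclose(
        solo.values.loc["Gene_1", samples], gene.values.loc["Gene_1", samples]
    )


def test_combine_layers_rejects_disjoint_samples():
    rng = np.random.default_rng(20)
    gene = of.OmicsDataset("gene", pd.DataFrame(
        rng.normal(size=(2, 5)), index=["Gene_0", "Gene_1"],
        columns=[f"a{i}" for i in range(5)]))
    lc = of.OmicsDataset("lc", pd.DataFrame(
        rng.normal(size=(2, 5)), index=["LC_0", "LC_1"],
        columns=[f"b{i}" for i in range(5)]))
    with pytest.raises(AlignmentError):
        of.combine_layers(
            [_sig_set("gene", ["Gene_0"]), _sig_set("lc", ["LC_0"])], [gene, lc]
        )
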