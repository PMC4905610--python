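"""Marker-regression scans, thresholds, calls, cis/trans, representatives."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import omicsforest as of
from omicsforest.qtl import LOD_CEILING, QTLCall


def _trait_on(geno, marker, effect, sd, seed):
    rng = np.random.default_rng(seed)
    g = geno.values[marker].to_numpy()
    return pd.Series(effect * g + rng.normal(0, sd, len(g)),
                     index=geno.samples, name="y")


def test_pvalues_match_ttest_oracle(small_map, small_geno):
    """Single-marker regression p-values equal the equal-variance
    two-sample t-test on the genotype split, to 1e-10."""
    rng = np.random.default_rng(0)
    for rep in range(10):
        y = pd.Series(rng.normal(size=120), index=small_geno.samples, name="y")
        scan = of.marker_scan(y, small_geno, small_map)
        for _, row in scan.table.iloc[::7].iterrows():
            g = small_geno.values[row["marker_id"]].to_numpy()
            t = stats.ttest_ind(y[g == 0], y[g == 1], equal_var=True)
            assert abs(row["p"] - t.pvalue) < 1e-10


def test_toy_split_matches_ttest():
    table = pd.DataFrame(
        {"marker_id": ["m1"], "linkage_group": [1], "position_cM": [0.0]}
    )
    gmap = of.GeneticMap(table)
    geno = of.GenotypeMatrix(pd.DataFrame(
        {"m1": [0, 0, 0, 0, 1, 1, 1, 1]}, index=[f"s{i}" for i in range(8)],
        dtype=float))
    y = pd.Series([1, 2, 1, 2, 4, 5, 4, 5], index=geno.samples, dtype=float, name="y")
    scan = of.marker_scan(y, geno, gmap)
    t = stats.ttest_ind([1, 2, 1, 2], [4, 5, 4, 5], equal_var=True)
    assert abs(scan.table["p"].iloc[0] - t.pvalue) < 1e-10


def test_perfect_cosegregation_capped(small_map, small_geno):
    y = pd.Series(small_geno.values["M3_4"].to_numpy(), index=small_geno.samples,
                  name="y")
    scan = of.marker_scan(y, small_geno, small_map)
    row = scan.table[scan.table["marker_id"] == "M3_4"].iloc[0]
    assert row["lod"] == LOD_CEILING
    assert row["p"] <= 1e-300
    assert scan.table.loc[scan.table["lod"].idxmax(), "marker_id"] == "M3_4"


def test_affine_invariance(small_map, small_geno):
    y = _trait_on(small_geno, "M2_3", 1.0, 1.0, seed=1)
    s1 = of.marker_scan(y, small_geno, small_map)
    s2 = of.marker_scan(-2.5 * y + 7.0, small_geno, small_map)
    assert np.allclose(s1.table["lod"], s2.table["lod"], atol=1e-9)


def test_constant_trait_warns_zero_scan(small_map, small_geno):
    y = pd.Series(np.ones(120), index=small_geno.samples, name="flat")
    with pytest.warns(UserWarning, match="constant"):
        scan = of.marker_scan(y, small_geno, small_map)
    assert (scan.table["lod"] == 0).all()
    assert (scan.table["p"] == 1).all()


def test_undersized_genotype_class_skipped(small_map):
    values = pd.DataFrame(
        0.0, index=[f"s{i}" for i in range(20)], columns=small_map.marker_ids
    )
    values.iloc[0, 0] = 1.0  # first marker: class 1 has a single individual
    geno = of.GenotypeMatrix(values)
    y = pd.Series(np.random.default_rng(2).normal(size=20), index=geno.samples,
                  name="y")
    scan = of.marker_scan(y, geno, small_map)
    assert bool(scan.table["skipped"].iloc[0])
    assert np.isnan(scan.table["lod"].iloc[0])


def test_missing_genotypes_dropped_markerwise(small_map, small_geno):
    values = small_geno.values.copy()
    values.iloc[:30, 5] = np.nan
    geno = of.GenotypeMatrix(values)
    y = _trait_on(small_geno, "M1_2", 1.0, 1.0, seed=3)
    scan = of.marker_scan(y, geno, small_map)
    assert scan.table["n_used"].iloc[5] == 90
    assert scan.table["n_used"].iloc[0] == 120


def test_threshold_monotone_in_alpha(small_map, small_geno):
    y = pd.Series(np.random.default_rng(4).normal(size=120),
                  index=small_geno.samples, name="y")
    t05 = of.genomewide_threshold(y, small_geno, small_map, 200, 0.05, seed=5)
    t01 = of.genomewide_threshold(y, small_geno, small_map, 200, 0.01, seed=5)
    assert t05 <= t01


def test_single_marker_threshold_is_marker_quantile():
    table = pd.DataFrame(
        {"marker_id": ["m1"], "linkage_group": [1], "position_cM": [0.0]}
    )
    gmap = of.GeneticMap(table)
    rng = np.random.default_rng(6)
    geno = of.GenotypeMatrix(pd.DataFrame(
        {"m1": rng.integers(0, 2, 40).astype(float)},
        index=[f"s{i}" for i in range(40)]))
    y = pd.Series(rng.normal(size=40), index=geno.samples, name="y")
    thr = of.genomewide_threshold(y, geno, gmap, 300, 0.05, seed=7)
    # max over one marker == that marker's LOD, so the threshold is just the
    # permutation quantile of a single-marker LOD: small and non-negative
    assert 0 <= thr < 3


def _scan_from(gmap, lods):
    tab = gmap.table.copy()
    tab["lod"] = lods
    tab["p"] = 0.5
    tab["n_used"] = 100.0
    tab["skipped"] = False
    return of.QTLScan("f", tab)


def test_calls_one_per_group_above_threshold(small_map):
    lods = np.zeros(small_map.n_markers)
    lods[2] = 5.0   # group 1
    lods[9] = 4.0   # group 2
    scan = _scan_from(small_map, lods)
    calls = of.call_qtls(scan, 3.0, small_map)
    assert [(c.linkage_group, c.peak_marker) for c in calls] == [(1, "M1_3"), (2, "M2_2")]
    for c in calls:
        lo, hi = c.support_interval
        assert lo <= small_map.position_of(c.peak_marker) <= hi
    assert of.call_qtls(_scan_from(small_map, np.zeros(small_map.n_markers)),
                        3.0, small_map) == []


def test_call_tie_breaks_to_smallest_position(small_map):
    lods = np.zeros(small_map.n_markers)
    lods[3] = 6.0
    lods[5] = 6.0  # same group, larger cM
    calls = of.call_qtls(_scan_from(small_map, lods), 3.0, small_map)
    assert calls[0].peak_marker == "M1_4"


def test_support_interval_is_lod_drop(small_map):
    lods = np.zeros(small_map.n_markers)
    lods[1:6] = [2.0, 5.0, 6.0, 4.9, 2.0]  # group 1, peak at M1_4 (30 cM)
    calls = of.call_qtls(_scan_from(small_map, lods), 3.0, small_map)
    assert calls[0].support_interval == (20.0, 40.0)


@pytest.mark.parametrize(
    "annotation,expected",
    [({"f": 3}, "cis"), ({"f": 10}, "trans"), ({"f": "unknown"}, "unknown"),
     ({}, "unknown")],
)
def test_classify_cis_trans(annotation, expected):
    call = QTLCall("f", 3, "M3_1", 8.0, 2.0, (0.0, 10.0))
    assert of.classify_cis_trans(call, annotation) == expected


def _sigset(layer, ids_imps):
    feats = pd.DataFrame(
        {"feature_id": [i for i, _ in ids_imps],
         "importance": [v for _, v in ids_imps]}
    ).sort_values("importance", ascending=False)
    feats["rank"] = np.arange(1, len(feats) + 1)
    return of.SignificantSet(layer, feats.reset_index(drop=True), True, 0.05, 0.05)


def _call(fid, group, lod=5.0):
    return QTLCall(fid, group, f"M{group}_1", lod, 2.0, (0.0, 10.0))


def test_representatives_pick_highest_importance():
    sets = [_sigset("gene", [("Gene_a", 5.0), ("Gene_b", 3.0)])]
    calls = {"Gene_a": [_call("Gene_a", 2)], "Gene_b": [_call("Gene_b", 2)]}
    reps = of.select_representatives(sets, calls, [_call("trait", 2)])
    assert reps.feature_ids == ["Gene_a"]


def test_representatives_tie_breaks():
    sets = [_sigset("gene", [("Gene_b", 5.0), ("Gene_a", 5.0)])]
    calls = {
        "Gene_a": [_call("Gene_a", 2, lod=9.0)],
        "Gene_b": [_call("Gene_b", 2, lod=4.0)],
    }
    reps = of.select_representatives(sets, calls, [_call("trait", 2)])
    assert reps.feature_ids == ["Gene_a"]  # equal importance -> higher LOD
    calls_eq = {
        "Gene_a": [_call("Gene_a", 2, lod=5.0)],
        "Gene_b": [_call("Gene_b", 2, lod=5.0)],
    }
    reps = of.select_representatives(sets, calls_eq, [_call("trait", 2)])
    assert reps.feature_ids == ["Gene_a"]  # full tie -> lexicographic


def test_representatives_one_per_layer_group():
    sets = [
        _sigset("gene", [("Gene_a", 5.0), ("Gene_b", 4.0), ("Gene_c", 3.0)]),
        _sigset("lc", [("LC_a", 2.0)]),
    ]
    calls = {
        "Gene_a": [_call("Gene_a", 2)],
        "Gene_b": [_call("Gene_b", 4)],
        "Gene_c": [_call("Gene_c", 2)],
        "LC_a": [_call("LC_a", 4)],
    }
    trait_calls = [_call("trait", 2), _call("trait", 4)]
    reps = of.select_representatives(sets, calls, trait_calls)
    key = reps.entries.set_index(["layer", "linkage_group"])["feature_id"]
    assert key.to_dict() == {("gene", 2): "Gene_a", ("gene", 4): "Gene_b",
                             ("lc", 4): "LC_a"}
    assert not reps.entries.duplicated(["layer", "linkage_group"]).any()


def test_no_trait_qtl_warns_empty():
    sets = [_sigset("gene", [("Gene_a", 5.0)])]
    with pytest.warns(UserWarning, match="no trait QTL"):
        reps = of.select_representatives(sets, {"Gene_a": [_call("Gene_a", 1)]}, [])
    assert len(reps) == 0
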