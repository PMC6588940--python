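import math

import numpy as np
import pandas as pd
import pytest

from srnabench import metrics as M


def _df(cols: dict) -> pd.DataFrame:
    return pd.DataFrame(cols)


# --- size factors -----------------------------------------------------------

def test_identical_samples_have_unit_factors(rng):
    a = pd.Series(rng.integers(1, 100, size=30).astype(float))
    f = M.size_factors(_df({"A": a, "B": a}))
    np.testing.assert_allclose(f.to_numpy(), [1.0, 1.0])


def test_doubled_sample_splits_sqrt2():
    a = pd.Series([10.0, 20.0, 30.0, 40.0, 55.0])
    f = M.size_factors(_df({"A": a, "B": 2 * a}))
    assert f["A"] == pytest.approx(1 / math.sqrt(2))
    assert f["B"] == pytest.approx(math.sqrt(2))


def test_zero_features_excluded_from_median():
    a = pd.Series([10.0, 20.0, 30.0, 40.0, 55.0, 0.0])
    b = pd.Series([20.0, 40.0, 60.0, 80.0, 110.0, 7.0])
    f = M.size_factors(_df({"A": a, "B": b}))
    assert f["A"] == pytest.approx(1 / math.sqrt(2))


def test_no_all_positive_feature_raises():
    with pytest.raises(ValueError, match="all-positive"):
        M.size_factors(_df({"A": [0.0, 1.0], "B": [1.0, 0.0]}))
    with pytest.raises(ValueError, match="2 samples"):
        M.size_factors(pd.DataFrame({"A": [1.0, 2.0]}))


def test_scaling_invariance_of_normalized_matrix(rng):
    # scaling one sample by k scales its factor by k relative to the others
    # (the per-feature geometric means absorb k^(1/m)), and the normalized
    # matrix changes only by the global constant k^(1/m)
    raw = pd.DataFrame(rng.integers(1, 500, size=(60, 3)).astype(float),
                       columns=["A", "B", "C"])
    f0 = M.size_factors(raw)
    scaled = raw.copy()
    scaled["B"] *= 7.0
    f1 = M.size_factors(scaled)
    assert (f1["B"] / f1["A"]) / (f0["B"] / f0["A"]) == pytest.approx(7.0)
    assert f1["B"] / f0["B"] == pytest.approx(7.0 ** (2 / 3))
    pd.testing.assert_frame_equal(
        M.normalize_counts(raw) * 7.0 ** (1 / 3), M.normalize_counts(scaled),
        atol=1e-9, rtol=1e-9,
    )


# --- accuracy error ---------------------------------------------------------

def test_accuracy_error_closed_form():
    err = M.accuracy_error(pd.Series([120.0, 80.0, 100.0, 100.0]))
    np.testing.assert_allclose(
        err.to_numpy(), [math.log2(21), math.log2(21), 0.0, 0.0]
    )
    assert err.iloc[0] == pytest.approx(4.392, abs=1e-3)


def test_accuracy_error_zero_at_equality():
    assert (M.accuracy_error(pd.Series([5.0] * 10)) == 0).all()
    with pytest.raises(ValueError):
        M.accuracy_error(pd.Series([1.0]))


def test_accuracy_error_monotone_in_deviation():
    base = M.accuracy_error(pd.Series([100.0, 100.0, 100.0, 104.0]))
    wide = M.accuracy_error(pd.Series([100.0, 100.0, 100.0, 108.0]))
    assert wide.iloc[3] > base.iloc[3]


# --- detection & inconsistency ---------------------------------------------

def test_detection_threshold_is_strict():
    norm = _df({"rep1": [10.0, 10.5], "rep2": [10.0, 10.5], "rep3": [10.0, 10.5]})
    norm.index = ["at_threshold", "above"]
    ds = M.detect(norm, 10.0)
    assert ds.replicate_sets["rep1"] == {"above"}
    assert ds.consensus == {"above"}


def test_detection_consensus_requires_all_replicates():
    norm = _df({"rep1": [11.0], "rep2": [11.0], "rep3": [9.0]})
    norm.index = ["f"]
    ds = M.detect(norm, 10.0)
    assert ds.replicate_sets["rep1"] == {"f"} and ds.replicate_sets["rep3"] == set()
    assert ds.consensus == set()


def test_inconsistency_formula_example():
    ds = M.DetectionSet(
        {"r1": {"a", "b", "c"}, "r2": {"a", "b"}, "r3": {"a", "b"}}, threshold=10
    )
    out = M.detection_inconsistency(ds)
    assert out["r1"] == pytest.approx(100.0 / 3.0)
    assert out["r2"] == 0.0 and out["r3"] == 0.0


def test_inconsistency_identical_and_disjoint_triplicates():
    same = M.DetectionSet({"r1": {"a"}, "r2": {"a"}, "r3": {"a"}}, 10)
    assert (M.detection_inconsistency(same) == 0).all()
    disjoint = M.DetectionSet({"r1": {"a"}, "r2": {"b"}, "r3": {"c"}}, 10)
    assert (M.detection_inconsistency(disjoint) == 100.0).all()


def test_inconsistency_empty_replicate_is_missing():
    ds = M.DetectionSet({"r1": set(), "r2": {"a"}}, 10)
    assert np.isnan(M.detection_inconsistency(ds)["r1"])


def test_inconsistency_scale_invariant():
    norm = _df({"r1": [20.0, 15.0], "r2": [20.0, 9.0], "r3": [20.0, 15.0]})
    norm.index = ["a", "b"]
    out1 = M.detection_inconsistency(M.detect(norm, 10.0))
    # rescaling everything well above threshold keeps the percentages
    out2 = M.detection_inconsistency(M.detect(norm * 3.0, 30.0))
    pd.testing.assert_series_equal(out1, out2)


# --- false isomiRs ----------------------------------------------------------

def _iso_df(values, cols=("s1",)):
    idx = pd.MultiIndex.from_tuples(
        [(f"p{i}", f"SEQ{i}") for i in range(len(values))],
        names=["parent_id", "isomir_seq"],
    )
    return pd.DataFrame({c: values for c in cols}, index=idx)


def test_false_isomir_threshold_strict():
    out = M.false_isomirs(_iso_df([100.0]))
    assert out["total_unique"] == 0
    out = M.false_isomirs(_iso_df([100.5]))
    assert out["total_unique"] == 1


def test_false_isomir_empty_table():
    empty = pd.DataFrame(
        index=pd.MultiIndex.from_arrays([[], []], names=["parent_id", "isomir_seq"]),
        columns=["s1"], dtype=float,
    )
    assert M.false_isomirs(empty)["total_unique"] == 0


def test_false_isomir_per_parent_counts():
    idx = pd.MultiIndex.from_tuples(
        [("pA", "S1"), ("pA", "S2"), ("pB", "S3")], names=["parent_id", "isomir_seq"]
    )
    df = pd.DataFrame({"s1": [150.0, 200.0, 50.0]}, index=idx)
    out = M.false_isomirs(df)
    assert out["total_unique"] == 2
    assert out["per_parent"].to_dict() == {"pA": 2}
    assert out["expression"].loc[("pA", "S1")] == 150.0


# --- similarity -------------------------------------------------------------

def test_ma_identical_methods_all_zero():
    a = pd.Series([10.0, 20.0], index=["x", "y"])
    ma = M.ma_statistics(a, a)
    assert (ma["M"] == 0).all()


def test_ma_doubling_gives_minus_one():
    a = pd.Series([10.0], index=["x"])
    ma = M.ma_statistics(a, 2 * a)
    assert ma["M"].iloc[0] == pytest.approx(-1.0)


def test_similarity_filter_excludes_any_low_sample():
    norm = _df({"s1": [5.0, 0.5], "s2": [5.0, 5.0]})
    norm.index = ["keep", "drop"]
    assert list(M.similarity_filter(norm)) == ["keep"]


def test_topn_overlap_fractions():
    feats = [f"f{i:02d}" for i in range(40)]
    a = pd.Series(np.arange(40, 0, -1, dtype=float), index=feats)
    same = M.topn_overlap({"m1": a, "m2": a.copy()}, n=20)
    assert same["global"] == 1.0
    b = pd.Series(np.arange(1, 41, dtype=float), index=feats)  # reversed ranking
    disjoint = M.topn_overlap({"m1": a, "m2": b}, n=20)
    assert disjoint["global"] == 0.0
    # 6 shared of 20 -> 30%
    c = a.copy()
    c.iloc[6:20] = 0.0  # demote 14 of A's top features
    partial = M.topn_overlap({"m1": a, "m2": c}, n=20)
    assert partial["global"] == pytest.approx(0.30)
    with pytest.raises(ValueError):
        M.topn_overlap({"m1": a.iloc[:10]}, n=20)


# --- consistency ------------------------------------------------------------

def test_batch_error_closed_forms():
    b1 = _df({"r1": [100.0, 100.0], "r2": [100.0, 100.0], "r3": [100.0, 100.0]})
    b1.index = ["zero", "gap"]
    b2 = pd.Series([100.0, 132.0], index=["zero", "gap"])
    err = M.batch_error(b1, b2)
    assert err["zero"] == 0.0
    assert err["gap"] == pytest.approx(math.log2(33), abs=1e-9)
    assert err["gap"] == pytest.approx(5.044, abs=1e-3)


def test_batch_error_filter_excludes_low_features():
    b1 = _df({"r1": [100.0, 8.0], "r2": [100.0, 100.0], "r3": [100.0, 100.0]})
    b1.index = ["keep", "drop"]
    b2 = pd.Series([100.0, 100.0], index=["keep", "drop"])
    assert list(M.batch_error(b1, b2).index) == ["keep"]


def test_triplicate_error_closed_forms():
    df = _df({"r1": [100.0, 90.0], "r2": [100.0, 100.0], "r3": [100.0, 110.0]})
    df.index = ["flat", "spread"]
    err = M.triplicate_error(df)
    assert err["flat"] == 0.0
    assert err["spread"] == pytest.approx(2 * math.log2(11) / 3, abs=1e-9)
    assert err["spread"] == pytest.approx(2.306, abs=1e-3)


# --- starting-molecule estimation -------------------------------------------

def test_starting_molecule_estimate_closed_form():
    n0, sat = M.estimate_starting_molecules(10**6, efficiency=0.625, cycles=18)
    assert n0 == pytest.approx(10**6 / 1.625**18)
    assert n0 == pytest.approx(160.2, abs=0.1)
    assert not sat


def test_starting_molecule_zero_cycles_identity():
    n0, _ = M.estimate_starting_molecules(1234, cycles=0)
    assert n0 == 1234


def test_starting_molecule_saturation_flag():
    _n0, sat = M.estimate_starting_molecules(20000 * 1.625**18, cycles=18)
    assert sat  # 20,000 estimated molecules > 20% of the 65,536 UMI space


def test_starting_molecule_round_trip_recovery():
    # simulate PCR families and invert the expected-growth formula
    from srnabench.bias import BiasModel
    from srnabench.simulate import amplify, sample_molecules
    from srnabench.pool import ReferencePool

    pool = ReferencePool(["m1"], ["ACGTACGTACGTACGTACGT"], np.array([1.0]))
    model = BiasModel(pcr_efficiency_base=0.625, pcr_cycles=18)
    rng = np.random.default_rng(21)
    mols = sample_molecules(pool, np.ones(1), 200, 4, rng)
    out = amplify(mols, model, rng)
    n0, _ = M.estimate_starting_molecules(len(out), efficiency=0.625, cycles=18)
    # Monte-Carlo error of the mean family size is ~3.4% at 200 molecules
    assert n0 == pytest.approx(200, rel=0.12)
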