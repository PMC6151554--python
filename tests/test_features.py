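import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from critres._mdlp import information_gain, mdlp_cut_points
from critres.features import (
    ConstantFeatureFilter,
    FeatureTable,
    InfoGainFilter,
    SpearmanRedundancyFilter,
    information_gain_filter,
    read_feature_table,
    remove_useless,
    spearman_redundancy_filter,
    write_feature_table,
)
from critres.synthetic import make_feature_table


def small_table():
    X = pd.DataFrame(
        {"a": [1.0, 2.0, 3.0, 4.0], "b": [0.5, 0.5, 0.5, 0.5], "c": [4.0, 3.0, 2.0, 1.0]}
    )
    y = pd.Series(["critical", "non-critical", "critical", "non-critical"], name="class")
    return FeatureTable(X, y)


# --- I/O ---------------------------------------------------------------------

def test_csv_round_trip(tmp_path):
    t = small_table()
    p = tmp_path / "t.csv"
    write_feature_table(t, p)
    t2 = read_feature_table(p)
    pd.testing.assert_frame_equal(t.X, t2.X)
    assert list(t.y) == list(t2.y)
    assert t2.target_type == "nominal"


def test_arff_round_trip_with_nominal_class(tmp_path):
    t = small_table()
    p = tmp_path / "t.arff"
    write_feature_table(t, p)
    t2 = read_feature_table(p)
    assert np.allclose(t.X.to_numpy(), t2.X.to_numpy(), atol=1e-12)
    assert list(t.y) == list(t2.y)
    assert t2.target_type == "nominal"


def test_csv_arff_conversion_preserves_values(tmp_path):
    table, _ = make_feature_table(n_instances=30, n_informative=2, n_noise=3, seed=1)
    write_feature_table(table, tmp_path / "t.csv")
    write_feature_table(table, tmp_path / "t.arff")
    from_csv = read_feature_table(tmp_path / "t.csv")
    from_arff = read_feature_table(tmp_path / "t.arff")
    assert np.allclose(from_csv.X.to_numpy(), from_arff.X.to_numpy(), atol=1e-12)


def test_malformed_arff_rejected(tmp_path):
    p = tmp_path / "bad.arff"
    p.write_text("@RELATION x\n@DATA\n1,2\n")
    with pytest.raises(ValueError, match="malformed ARFF"):
        read_feature_table(p)


def test_missing_values_rejected():
    X = pd.DataFrame({"a": [1.0, np.nan]})
    with pytest.raises(ValueError, match="missing values"):
        FeatureTable(X, pd.Series(["x", "y"]))


def test_duplicate_descriptor_names_rejected():
    X = pd.DataFrame([[1.0, 2.0]], columns=["a", "a"])
    with pytest.raises(ValueError, match="duplicate"):
        FeatureTable(X, pd.Series(["x"]))


# --- constant filter ---------------------------------------------------------

def test_constant_columns_dropped_varying_kept():
    t, report = remove_useless(small_table())
    assert report["dropped"] == ["b"]
    assert t.descriptor_names == ["a", "c"]
    t2, report2 = remove_useless(t)  # idempotent
    assert report2["dropped"] == []


def test_constant_filter_scan_oracle():
    table, truth = make_feature_table(
        n_instances=50, n_informative=5, n_noise=45, n_constant=10, seed=2
    )
    t, report = remove_useless(table)
    expected = {
        name for name in table.descriptor_names
        if table.X[name].nunique() == 1
    }
    assert set(report["dropped"]) == expected and len(expected) == 10


# --- Spearman redundancy filter ----------------------------------------------

def test_duplicate_and_monotone_transform_columns_dropped():
    rng = np.random.default_rng(3)
    x = rng.normal(size=40)
    X = pd.DataFrame({"x": x, "x_copy": x.copy(), "x_mono": np.exp(2 * x + 1)})
    t = FeatureTable(X, pd.Series(["a"] * 40))
    flt = SpearmanRedundancyFilter(threshold=0.95).fit(t.X)
    assert flt.dropped_names_ == ["x_copy", "x_mono"]


def test_spearman_filter_drops_exactly_the_later_twins():
    table, truth = make_feature_table(
        n_instances=100, n_informative=5, n_noise=12, n_twins=3, seed=4
    )
    t, report = spearman_redundancy_filter(table)
    # oracle: pairwise |rho| matrix over the original columns
    rho = table.X.corr(method="spearman").abs().to_numpy()
    names = table.descriptor_names
    expected = set()
    kept = []
    for j, name in enumerate(names):
        if any(rho[j, k] >= 0.95 for k in kept):
            expected.add(name)
        else:
            kept.append(j)
    assert set(report["dropped"]) == expected == set(truth.twins)


def test_spearman_filter_invariant_to_row_order():
    table, _ = make_feature_table(n_instances=60, n_informative=3, n_noise=5,
                                  n_twins=2, seed=5)
    _, r1 = spearman_redundancy_filter(table)
    perm = np.random.default_rng(0).permutation(table.n_instances)
    shuffled = FeatureTable(
        table.X.iloc[perm].reset_index(drop=True),
        table.y.iloc[perm].reset_index(drop=True),
    )
    _, r2 = spearman_redundancy_filter(shuffled)
    assert r1["dropped"] == r2["dropped"]


def test_spearman_matches_scipy_on_random_pairs():
    rng = np.random.default_rng(6)
    x, z = rng.normal(size=50), rng.normal(size=50)
    y = 0.9 * x + 0.1 * z
    rho = abs(spearmanr(x, y).statistic)
    X = pd.DataFrame({"x": x, "y": y})
    flt = SpearmanRedundancyFilter(threshold=rho + 1e-9).fit(X)
    assert flt.dropped_names_ == []
    flt2 = SpearmanRedundancyFilter(threshold=rho - 1e-9).fit(X)
    assert flt2.dropped_names_ == ["y"]


# --- information-gain filter -------------------------------------------------

def test_class_identical_descriptor_kept_noise_dropped():
    rng = np.random.default_rng(7)
    y = np.array(["a"] * 50 + ["b"] * 50)
    X = pd.DataFrame({"copy": (y == "a").astype(float), "noise": rng.normal(size=100)})
    flt = InfoGainFilter().fit(X, y)
    assert flt.dropped_names_ == ["noise"]
    assert flt.gains_[0] == pytest.approx(1.0)  # class entropy of a 50/50 split


def test_mdlp_finds_no_cut_in_pure_noise():
    rng = np.random.default_rng(8)
    y = rng.choice(["a", "b"], size=100)
    assert mdlp_cut_points(rng.normal(size=100), y) == []


def test_mdlp_cut_near_true_boundary():
    x = np.concatenate([np.zeros(30), np.ones(30) * 10])
    y = np.array(["a"] * 30 + ["b"] * 30)
    cuts = mdlp_cut_points(x, y)
    assert len(cuts) == 1 and 0 < cuts[0] < 10
    assert information_gain(x, y) == pytest.approx(1.0)


def test_planted_informative_kept_noise_mostly_dropped():
    table, truth = make_feature_table(
        n_instances=200, n_informative=5, n_noise=40, seed=9
    )
    t, report = information_gain_filter(table)
    kept = set(t.descriptor_names)
    assert all(name in kept for name in truth.informative)
    dropped_noise = sum(1 for n in truth.noise if n not in kept)
    assert dropped_noise >= 0.9 * len(truth.noise)


def test_numeric_target_rejected():
    X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
    t = FeatureTable(X, pd.Series([0.1, 0.9, 0.4]), target_type="numeric")
    with pytest.raises(ValueError, match="binary class"):
        information_gain_filter(t)


def test_filters_are_idempotent():
    table, _ = make_feature_table(
        n_instances=120, n_informative=4, n_noise=20, n_twins=2, n_constant=2, seed=10
    )
    t1, _ = remove_useless(table)
    t1b, r = remove_useless(t1)
    assert r["dropped"] == []
    t2, _ = spearman_redundancy_filter(t1)
    t2b, r = spearman_redundancy_filter(t2)
    assert r["dropped"] == []
    t3, _ = information_gain_filter(t2)
    t3b, r = information_gain_filter(t3)
    assert r["dropped"] == []
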