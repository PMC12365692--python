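import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcreliab.connectivity import devectorize_upper
from fcreliab.icc import (
    SplitHalfDataset,
    bin_icc,
    bin_icc_matrix,
    edgewise_icc,
    icc_2_1,
    network_icc_by_duration,
    network_icc_post_average,
    network_icc_pre_average,
    parcelwise_mean_icc,
    parcelwise_trc,
)


def brute_force_icc_2_1(table):
    """Independent oracle: explicit two-way ANOVA decomposition, loops only."""
    x = np.asarray(table, dtype=float)
    n, k = x.shape
    grand = x.mean()
    ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_total = sum(
        (x[i, j] - grand) ** 2 for i in range(n) for j in range(k)
    )
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


def _dataset(half_a, half_b, groups=None, labels=None):
    half_a = np.asarray(half_a, float)
    n_sub, n = half_a.shape[0], half_a.shape[1]
    node_ids = tuple(f"node{i:04d}" for i in range(n))
    return SplitHalfDataset(
        half_a,
        np.asarray(half_b, float),
        t_minutes=10.0,
        subject_ids=tuple(f"s{i}" for i in range(n_sub)),
        groups=tuple(groups) if groups else ("g",) * n_sub,
        node_ids=node_ids,
        network_labels=labels,
    )


def _symmetric_stack(rng, n_sub, n):
    out = np.empty((n_sub, n, n))
    for s in range(n_sub):
        m = rng.normal(size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, np.nan)
        out[s] = m
    return out


class TestICC21:
    def test_identical_measurements_give_one(self):
        table = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        assert icc_2_1(table) == pytest.approx(1.0)

    def test_toy_table_matches_anova_oracle(self):
        table = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        assert icc_2_1(table) == pytest.approx(brute_force_icc_2_1(table), abs=1e-12)

    def test_random_tables_match_anova_oracle(self, rng):
        for _ in range(100):
            table = rng.normal(size=(5, 2))
            assert icc_2_1(table) == pytest.approx(
                brute_force_icc_2_1(table), abs=1e-10
            )

    def test_matches_pingouin_icc2(self, rng):
        pingouin = pytest.importorskip("pingouin")
        table = rng.normal(size=(12, 3))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "score": table.ravel(),
            }
        )
        res = pingouin.intraclass_corr(
            df, targets="subject", raters="rater", ratings="score"
        )
        expected = float(res.loc[res.Type == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_2_1(table) == pytest.approx(expected, abs=1e-10)

    def test_variance_ratio_recovery(self):
        # subject variance 3, residual 1 => ICC = 3/4
        rng = np.random.default_rng(2024)
        subj = rng.normal(0, np.sqrt(3), size=(200, 1))
        table = subj + rng.normal(0, 1, size=(200, 2))
        assert icc_2_1(table) == pytest.approx(0.75, abs=0.05)

    @given(st.floats(-5, 5), st.floats(0.1, 10))
    @settings(deadline=None, max_examples=25)
    def test_affine_invariance(self, shift, scale):
        rng = np.random.default_rng(8)
        table = rng.normal(size=(10, 2))
        base = icc_2_1(table)
        assert icc_2_1(table * scale + shift) == pytest.approx(base, abs=1e-8)

    def test_degenerate_table_is_nan(self):
        assert np.isnan(icc_2_1(np.full((4, 2), 3.0)))

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            icc_2_1(np.ones((1, 2)))
        with pytest.raises(ValueError):
            icc_2_1(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestEdgewiseICC:
    def test_identical_halves_give_unit_icc(self, rng):
        half = _symmetric_stack(rng, 5, 6)
        edge = edgewise_icc(_dataset(half, half.copy()))
        off = ~np.eye(6, dtype=bool)
        np.testing.assert_allclose(edge[off], 1.0, atol=1e-9)

    def test_no_between_subject_variance_drives_icc_to_zero(self, rng):
        common = _symmetric_stack(rng, 1, 8)[0]
        noise = lambda: _symmetric_stack(rng, 40, 8) * 0.3
        a = common[None] + noise()
        b = common[None] + noise()
        edge = edgewise_icc(_dataset(a, b))
        assert abs(np.nanmean(edge)) < 0.1

    def test_matches_scalar_icc_per_edge(self, rng):
        a = _symmetric_stack(rng, 6, 4)
        b = _symmetric_stack(rng, 6, 4)
        edge = edgewise_icc(_dataset(a, b))
        i, j = 0, 2
        table = np.stack([a[:, i, j], b[:, i, j]], axis=1)
        assert edge[i, j] == pytest.approx(icc_2_1(table), abs=1e-12)


LABELS2 = {f"node{i:04d}": ("A" if i < 3 else "B") for i in range(6)}


class TestNetworkAveraging:
    def test_single_network_reduces_to_mean_edge_icc(self, rng):
        labels = {f"node{i:04d}": "A" for i in range(5)}
        a, b = _symmetric_stack(rng, 8, 5), _symmetric_stack(rng, 8, 5)
        ds = _dataset(a, b, labels=labels)
        pre = network_icc_pre_average(ds)
        iu = np.triu_indices(5, k=1)
        table = np.stack(
            [a[:, iu[0], iu[1]].mean(axis=1), b[:, iu[0], iu[1]].mean(axis=1)],
            axis=1,
        )
        assert pre.loc["A", "A"] == pytest.approx(icc_2_1(table), abs=1e-12)

    def test_post_average_block_means_by_hand(self):
        edge_vals = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])  # nodes 0<1<2<3
        labels = {f"node{i:04d}": ("A" if i < 2 else "B") for i in range(4)}
        m = devectorize_upper(edge_vals, 4)
        post = network_icc_post_average(m, tuple(labels), labels)
        # edges: (0,1)=.1 AA; (0,2)=.2,(0,3)=.3,(1,2)=.4,(1,3)=.5 AB; (2,3)=.6 BB
        assert post.loc["A", "A"] == pytest.approx(0.1)
        assert post.loc["A", "B"] == pytest.approx(0.35)
        assert post.loc["B", "B"] == pytest.approx(0.6)

    def test_uniform_edges_give_uniform_blocks(self):
        m = devectorize_upper(np.full(15, 0.42), 6)
        post = network_icc_post_average(m, tuple(LABELS2), LABELS2)
        np.testing.assert_allclose(post.to_numpy(), 0.42)

    def test_node_permutation_invariance(self, rng):
        a, b = _symmetric_stack(rng, 6, 6), _symmetric_stack(rng, 6, 6)
        ds = _dataset(a, b, labels=LABELS2)
        pre = network_icc_pre_average(ds)
        perm = rng.permutation(6)
        labels_p = {f"node{i:04d}": LABELS2[f"node{perm[i]:04d}"] for i in range(6)}
        a_p = a[:, perm][:, :, perm]
        b_p = b[:, perm][:, :, perm]
        node_ids = tuple(f"node{i:04d}" for i in range(6))
        ds_p = SplitHalfDataset(a_p, b_p, 10.0, ds.subject_ids, ds.groups,
                                node_ids, labels_p)
        pre_p = network_icc_pre_average(ds_p)
        np.testing.assert_allclose(
            pre.loc[["A", "B"], ["A", "B"]].to_numpy(),
            pre_p.loc[["A", "B"], ["A", "B"]].to_numpy(),
            atol=1e-10,
        )

    def test_undersized_network_excluded_with_warning(self, rng):
        labels = dict(LABELS2)
        labels["node0005"] = "C"  # singleton network
        a, b = _symmetric_stack(rng, 6, 6), _symmetric_stack(rng, 6, 6)
        with pytest.warns(UserWarning, match="excluded"):
            pre = network_icc_pre_average(_dataset(a, b, labels=labels))
        assert "C" not in pre.index


class TestParcelwise:
    def test_three_node_mean_by_hand(self):
        m = devectorize_upper(np.array([0.2, 0.4, 0.6]), 3)
        np.testing.assert_allclose(parcelwise_mean_icc(m), [0.3, 0.4, 0.5])

    def test_uniform_and_bounds(self, rng):
        vals = rng.uniform(0, 1, 10)
        m = devectorize_upper(vals, 5)
        node_means = parcelwise_mean_icc(m)
        assert node_means.min() >= vals.min() - 1e-12
        assert node_means.max() <= vals.max() + 1e-12
        uniform = parcelwise_mean_icc(devectorize_upper(np.full(10, 0.7), 5))
        np.testing.assert_allclose(uniform, 0.7)

    def test_identical_halves_unit_trc_and_zero_group_difference(self, rng):
        half = _symmetric_stack(rng, 4, 7)
        ds = _dataset(half, half.copy(), groups=["a", "a", "b", "b"])
        table = parcelwise_trc(ds)
        np.testing.assert_allclose(table["a"], 1.0, atol=1e-9)
        np.testing.assert_allclose(table["a"] - table["b"], 0.0, atol=1e-9)


class TestBinning:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.3, "poor"), (0.5, "fair"), (0.7, "good"), (0.8, "excellent"),
         (0.4, "poor"), (-0.1, "poor"), (0.6, "good"), (0.75, "excellent")],
    )
    def test_category_examples(self, value, expected):
        assert bin_icc(value) == expected

    @given(st.floats(-1, 1))
    @settings(deadline=None, max_examples=200)
    def test_bins_cover_the_whole_range(self, v):
        assert bin_icc(v) in ("poor", "fair", "good", "excellent")

    def test_matrix_binning_preserves_nan_diagonal(self):
        m = devectorize_upper(np.array([0.2, 0.5, 0.9]), 3)
        out = bin_icc_matrix(m)
        assert out[0, 0] == ""
        assert out[0, 1] == "poor" and out[1, 2] == "excellent"


class TestDurationSweep:
    def test_noise_free_cohort_is_fully_reliable(self, rng):
        half = _symmetric_stack(rng, 6, 6)
        labels = LABELS2
        datasets = {
            ("g", t): _dataset(half, half.copy(), labels=labels) for t in (5, 10)
        }
        out = network_icc_by_duration(datasets, ["A", "B"], durations=(5, 10),
                                      labels=labels)
        np.testing.assert_allclose(out["mean_icc"], 1.0, atol=1e-9)

    def test_missing_group_duration_skipped_with_warning(self, rng):
        half = _symmetric_stack(rng, 6, 6)
        datasets = {("g", 5): _dataset(half, half.copy(), labels=LABELS2)}
        with pytest.warns(UserWarning, match="skipped"):
            out = network_icc_by_duration(
                datasets, ["A"], durations=(5, 54), labels=LABELS2
            )
        assert set(out["duration_min"]) == {5}
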