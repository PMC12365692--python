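import math

import numpy as np
import pytest

from fcreliab.connectivity import (
    ParcellatedTimeseries,
    concat_censored,
    fisher_z,
    pearson_fc,
    vectorize_upper,
)
from fcreliab.motion import FDTrace
from fcreliab.synthetic import (
    AcquisitionSpec,
    MotionModel,
    block_template,
    default_network_labels,
    generate_latent_connectome,
    generate_run,
)
from fcreliab.trc import (
    UNREACHABLE,
    ReliabilityCurve,
    SplitScheme,
    cohens_d,
    condition_trc,
    default_split_scheme,
    duration_grid,
    incremental_benefit,
    iterative_trc,
    split_session_trc,
    time_to_threshold,
)

QUIET = MotionModel(burst_prob=0.0, signal_spike_scale=0.0)
ACQ = AcquisitionSpec()


def _ts(signal, session, condition="narrative", run=1, subject="s1"):
    signal = np.asarray(signal, dtype=float)
    return ParcellatedTimeseries(
        subject_id=subject,
        session=session,
        condition=condition,
        run=run,
        signal=signal,
        node_ids=tuple(f"n{i}" for i in range(signal.shape[0])),
        tr_seconds=2.0,
        fd=FDTrace(np.zeros(signal.shape[1]), 2.0),
    )


def _curve(grid, values):
    return ReliabilityCurve("s", "split_session", grid, np.asarray(values, float))


class TestSplitScheme:
    def test_default_three_way_partition(self):
        scheme = default_split_scheme(4)
        assert len(scheme.pairs) == 3
        for a, b in scheme.pairs:
            assert a | b == {1, 2, 3, 4} and not a & b

    def test_overlapping_halves_rejected(self):
        with pytest.raises(ValueError):
            SplitScheme((((1, 2), (2, 3)),))


class TestSplitSessionTRC:
    def test_identical_halves_give_unit_trc(self, rng):
        sig = rng.normal(size=(10, 400))
        runs = [_ts(sig, session=1), _ts(sig, session=2)]
        curve = split_session_trc(
            runs, default_split_scheme(2), grid=(5.0, 10.0)
        )
        np.testing.assert_allclose(curve.trc, [1.0, 1.0], atol=1e-12)

    def test_long_duration_trc_matches_latent_similarity(self):
        # halves drawn from two different latent connectomes: TRC converges to
        # the correlation of the ground-truth edge vectors
        labels = default_network_labels(50)
        t = block_template(labels)
        la = generate_latent_connectome(t, 0.25, 101)
        lb = generate_latent_connectome(t, 0.25, 202)
        runs = [
            generate_run(la, ACQ, 0.0, 1.0, QUIET, 1, session=1, n_volumes=6000),
            generate_run(lb, ACQ, 0.0, 1.0, QUIET, 2, session=2, n_volumes=6000),
        ]
        curve = split_session_trc(runs, default_split_scheme(2), grid=(200.0,))
        za = fisher_z(vectorize_upper(la.matrix))
        zb = fisher_z(vectorize_upper(lb.matrix))
        expected = np.corrcoef(za, zb)[0, 1]
        assert curve.trc[0] == pytest.approx(expected, abs=0.05)

    def test_infeasible_durations_are_missing(self, rng):
        runs = [_ts(rng.normal(size=(5, 150)), 1), _ts(rng.normal(size=(5, 150)), 2)]
        curve = split_session_trc(
            runs, default_split_scheme(2), grid=(2.0, 60.0)
        )
        assert not math.isnan(curve.trc[0])
        assert math.isnan(curve.trc[1])

    def test_group_mean_nondecreasing_on_stationary_data(self):
        labels = default_network_labels(40)
        t = block_template(labels)
        grid = duration_grid(5, 20, 5)
        stacks = []
        for s in range(8):
            lat = generate_latent_connectome(t, 0.15, 50 + s)
            runs = [
                generate_run(lat, ACQ, 0.5, 1.0, QUIET, 900 + 10 * s + ses,
                             session=ses, n_volumes=1230)
                for ses in (1, 2, 3, 4)
            ]
            stacks.append(split_session_trc(runs, default_split_scheme(4), grid).trc)
        gm = np.vstack(stacks).mean(axis=0)
        assert np.all(np.diff(gm) > -0.02)


class TestIterativeTRC:
    def test_noise_free_data_gives_unit_trc(self, rng):
        sig = np.asarray(rng.normal(size=(8, 1500)))
        # reference and residual sample the same stationary series; with a
        # latent-free check we use literally identical chunk statistics
        curve = iterative_trc(
            np.tile(sig[:, :30], 50), 2.0, grid=(2.0,),
            reference_minutes=4, n_iterations=5, seed=1,
        )
        assert curve.trc[0] == pytest.approx(1.0, abs=1e-9)

    def test_seed_robustness(self):
        labels = default_network_labels(30)
        lat = generate_latent_connectome(block_template(labels), 0.2, 77)
        ts = generate_run(lat, ACQ, 0.3, 1.0, QUIET, 5, n_volumes=1200)
        kwargs = dict(reference_minutes=10, n_iterations=50)
        a = iterative_trc(ts.signal, 2.0, (2.0, 4.0, 6.0), seed=1, **kwargs)
        b = iterative_trc(ts.signal, 2.0, (2.0, 4.0, 6.0), seed=2, **kwargs)
        np.testing.assert_allclose(a.trc, b.trc, atol=0.05)

    def test_determinism_under_seed(self, rng):
        sig = np.asarray(rng.normal(size=(6, 900)))
        a = iterative_trc(sig, 2.0, (2.0,), reference_minutes=5,
                          n_iterations=10, seed=3)
        b = iterative_trc(sig, 2.0, (2.0,), reference_minutes=5,
                          n_iterations=10, seed=3)
        np.testing.assert_array_equal(a.trc, b.trc)

    def test_infeasible_reference_flags_curve(self, rng):
        sig = np.asarray(rng.normal(size=(5, 100)))
        curve = iterative_trc(sig, 2.0, (2.0,), reference_minutes=60,
                              n_iterations=5, seed=0)
        assert np.isnan(curve.trc).all()


class TestConditionTRC:
    def test_single_condition_matches_whole_data_curve(self, rng):
        sigs = {ses: rng.normal(size=(8, 300)) for ses in (1, 2)}
        runs = [_ts(sigs[1], 1), _ts(sigs[2], 2)]
        scheme = default_split_scheme(2)
        grid = (2.0, 4.0)
        whole = split_session_trc(runs, scheme, grid)
        cond = condition_trc(runs, scheme, "narrative", grid=grid)
        np.testing.assert_allclose(cond.trc, whole.trc)
        assert cond.condition_scope == "narrative"

    def test_noisier_condition_is_less_reliable(self):
        labels = default_network_labels(30)
        t = block_template(labels)
        diffs = []
        for s in range(6):
            lat = generate_latent_connectome(t, 0.15, 300 + s)
            runs = []
            for ses in (1, 2):
                for cond, noise in (("narrative", 0.3), ("lowdemand", 1.2)):
                    runs.append(
                        generate_run(
                            lat, ACQ, noise, 1.0, QUIET, 40 * s + 10 * ses +
                            (1 if cond == "narrative" else 2),
                            session=ses, condition=cond, n_volumes=600,
                        )
                    )
            scheme = default_split_scheme(2)
            clean = condition_trc(runs, scheme, "narrative", grid=(5.0, 10.0))
            noisy = condition_trc(runs, scheme, "lowdemand", grid=(5.0, 10.0))
            diffs.append(np.mean(clean.trc - noisy.trc))
        assert np.mean(diffs) > 0

    def test_unavailable_duration_missing(self, rng):
        runs = [_ts(rng.normal(size=(5, 200)), 1), _ts(rng.normal(size=(5, 200)), 2)]
        curve = condition_trc(runs, default_split_scheme(2), "narrative",
                              grid=(2.0, 50.0))
        assert math.isnan(curve.trc[1])


class TestTimeToThreshold:
    def test_linear_interpolation_between_grid_points(self):
        assert time_to_threshold(
            _curve((20.0, 25.0), [0.78, 0.82]), 0.8
        ) == pytest.approx(22.5)

    def test_first_point_already_above(self):
        assert time_to_threshold(_curve((5.0, 10.0), [0.85, 0.9]), 0.8) == 5.0

    def test_unreachable_curve(self):
        assert time_to_threshold(_curve((5.0, 10.0), [0.5, 0.79]), 0.8) is UNREACHABLE

    def test_skips_missing_entries(self):
        t = time_to_threshold(
            _curve((5.0, 10.0, 15.0), [0.7, np.nan, 0.9]), 0.8
        )
        assert t == pytest.approx(10.0)  # interpolates 5 -> 15


class TestEffectSizes:
    def test_identical_groups_give_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_computed_value(self):
        assert cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(-2.0)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=20), rng.normal(1.0, 1.0, size=20)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_degenerate_pooled_sd(self):
        assert math.isnan(cohens_d([1, 1], [2, 2]))


class TestIncrementalBenefit:
    def test_constant_curve_gives_zeros(self):
        inc = incremental_benefit(_curve((5.0, 10.0, 15.0), [0.6, 0.6, 0.6]))
        assert all(v == 0 for v in inc.values())

    def test_first_differences_aligned_to_later_duration(self):
        inc = incremental_benefit(_curve((5.0, 10.0, 15.0), [0.5, 0.7, 0.75]))
        assert inc == {10.0: pytest.approx(0.2), 15.0: pytest.approx(0.05)}

    def test_telescoping_sum(self, rng):
        vals = np.sort(rng.uniform(0, 1, 6))
        inc = incremental_benefit(_curve(tuple(range(5, 35, 5)), vals))
        assert sum(inc.values()) == pytest.approx(vals[-1] - vals[0])
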