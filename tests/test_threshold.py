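import numpy as np
import pytest
from hypothesis import given, strategies as st

from _oracles import exhaustive_stringent
from seacr.threshold import (
    ThresholdCurve,
    compute_f_curve,
    empirical_fdr,
    global_threshold,
    normalize_control,
    select_relaxed,
)


class TestNormalizeControl:
    def test_point_masses(self):
        res = normalize_control([20.0] * 1000, [10.0] * 1000)
        assert (res.target_mode, res.control_mode, res.scaling_factor) == (20.0, 10.0, 2.0)

    def test_identical_vectors_factor_one(self, rng):
        x = rng.lognormal(5, 0.5, size=500)
        res = normalize_control(x, x)
        assert res.scaling_factor == pytest.approx(1.0)

    def test_prescaled_control_recovers_inverse_factor(self, rng):
        x = rng.lognormal(5, 0.5, size=500)
        for c in (0.25, 3.0):
            res = normalize_control(x, c * x)
            assert res.scaling_factor == pytest.approx(1.0 / c, rel=1e-12)

    def test_empty_vector_errors(self):
        with pytest.raises(ValueError, match="both datasets"):
            normalize_control([], [1.0])


class TestFCurve:
    def test_worked_example(self):
        c = compute_f_curve([10, 10, 50, 60], [10, 12])
        assert c.candidates.tolist() == [0, 10, 12, 50]  # t=60 excluded (0/0)
        assert c.f_values.tolist() == [0.5, 0.5, 1.0, 1.0]
        assert (c.f_max, c.t_stringent, c.T) == (1.0, 12.0, 60.0)

    def test_control_dominates_target(self):
        c = compute_f_curve([5], [10])
        assert c.f_values.tolist() == [0.5, 0.0]
        assert (c.f_max, c.t_stringent) == (0.5, 0.0)

    def test_identical_sets_flat_half(self, rng):
        x = rng.integers(1, 50, size=30).astype(float)
        c = compute_f_curve(x, x)
        assert np.allclose(c.f_values, 0.5)
        assert c.t_stringent == 0.0  # smallest maximizer

    def test_remaining_fractions_monotone_from_one(self, rng):
        c = compute_f_curve(rng.integers(1, 100, 40), rng.integers(1, 100, 40))
        assert c.frac_target_remaining[0] == 1.0
        assert c.frac_control_remaining[0] == 1.0
        assert np.all(np.diff(c.frac_target_remaining) <= 0)
        assert np.all(np.diff(c.frac_control_remaining) <= 0)
        assert np.all((c.f_values >= 0) & (c.f_values <= 1))

    def test_empty_inputs_error(self):
        with pytest.raises(ValueError, match="empty"):
            compute_f_curve([], [1.0])
        with pytest.raises(ValueError, match="global-threshold"):
            compute_f_curve([1.0], [])

    def test_removed_variant_worked_example(self):
        # hand enumeration of the removed-count ratio on the pooled set
        c = compute_f_curve([10, 10, 50, 60], [10, 12], variant="removed")
        assert c.candidates.tolist() == [10, 12, 50, 60]  # t=0 excluded (0/0)
        np.testing.assert_allclose(c.f_values, [2 / 3, 1 / 2, 3 / 5, 2 / 3])
        assert (c.f_max, c.t_stringent) == (2 / 3, 10.0)

    @given(seed=st.integers(0, 200))
    def test_matches_exhaustive_enumeration(self, seed):
        """(f_max, t_stringent) equal an exhaustive scan over all distinct totals."""
        r = np.random.default_rng(seed)
        target = r.integers(1, 30, size=int(r.integers(1, 51))).astype(float)
        control = r.integers(1, 30, size=int(r.integers(1, 51))).astype(float)
        c = compute_f_curve(target, control)
        f_max, t_str = exhaustive_stringent(target, control)
        assert c.f_max == pytest.approx(f_max)
        assert c.t_stringent == t_str


def curve(t, f):
    t = np.asarray(t, dtype=float)
    f = np.asarray(f, dtype=float)
    i = int(np.argmax(f))
    return ThresholdCurve(
        candidates=t,
        f_values=f,
        frac_target_remaining=f,
        frac_control_remaining=f,
        f_max=float(f[i]),
        t_stringent=float(t[i]),
        T=float(t[-1]),
    )


class TestSelectRelaxed:
    def test_worked_knee_example(self):
        c = select_relaxed(curve([0, 1, 2, 3, 4], [0.2, 0.6, 0.8, 0.9, 0.95]))
        assert c.knee_f == pytest.approx(0.9)
        # F_relaxed = 0.95 - (0.95-0.9)/2 = 0.925, interpolated between t=3 and 4
        assert c.t_relaxed == pytest.approx(3.5)

    def test_no_qualifying_knee_falls_back_to_stringent(self):
        c = select_relaxed(curve([0, 10, 12, 50], [0.5, 0.5, 1.0, 1.0]))
        assert c.knee_f is None and c.t_relaxed == 12.0

    def test_flat_curve_falls_back(self):
        c = select_relaxed(curve([0, 1, 2, 3], [0.5, 0.5, 0.5, 0.5]))
        assert c.knee_f is None and c.t_relaxed == c.t_stringent

    def test_fewer_than_three_candidates_falls_back(self):
        c = select_relaxed(curve([0, 5], [0.5, 1.0]))
        assert c.t_relaxed == c.t_stringent

    @given(seed=st.integers(0, 100))
    def test_relaxed_never_exceeds_stringent(self, seed):
        r = np.random.default_rng(seed)
        target = r.integers(1, 40, size=30).astype(float)
        control = r.integers(1, 40, size=30).astype(float)
        c = select_relaxed(compute_f_curve(target, control))
        assert c.t_relaxed <= c.t_stringent
        # retained-count monotonicity follows from strict-> retention
        assert (target > c.t_relaxed).sum() >= (target > c.t_stringent).sum()


class TestGlobalThreshold:
    def test_top_fraction_quantile(self):
        totals = list(range(1, 11))
        t = global_threshold(totals, 0.2)
        assert t == 8.0
        assert sorted(x for x in totals if x > t) == [9, 10]

    def test_tiny_q_keeps_single_largest(self):
        totals = list(range(1, 11))
        t = global_threshold(totals, 0.05)
        assert [x for x in totals if x > t] == [10]

    def test_all_equal_warns_empty(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            t = global_threshold([7.0] * 5, 0.1)
        assert t == 7.0 and any("empty" in r.message for r in caplog.records)

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.5, 2.0])
    def test_q_out_of_range(self, q):
        with pytest.raises(ValueError):
            global_threshold([1.0, 2.0], q)


class TestEmpiricalFDR:
    @pytest.mark.parametrize(
        "target,control,t,expected",
        [
            ([50, 60], [10, 12], 12, 0.0),
            ([5], [10, 20], 7, 1.0),
            ([1, 2], [1, 2], 0, 0.5),
            ([1], [1], 5, 0.0),  # nothing above threshold
        ],
    )
    def test_fdr_values(self, target, control, t, expected):
        assert empirical_fdr(target, control, t).value == expected

    def test_counts_reported(self):
        res = empirical_fdr([50, 60], [10, 12], 12)
        assert (res.n_target_above, res.n_control_above) == (2, 0)


class TestScalingEquivariance:
    @given(
        seed=st.integers(0, 50),
        c=st.floats(min_value=1e-3, max_value=1e3, allow_nan=False),
    )
    def test_thresholds_scale_and_selection_invariant(self, seed, c):
        """Multiplying all totals by c scales thresholds by c and leaves
        F values, retained identities and empirical FDR unchanged."""
        r = np.random.default_rng(seed)
        target = r.integers(1, 100, size=40).astype(float)
        control = r.integers(1, 100, size=40).astype(float)
        base = select_relaxed(compute_f_curve(target, control))
        scaled = select_relaxed(compute_f_curve(c * target, c * control))
        assert scaled.f_max == pytest.approx(base.f_max)
        assert scaled.t_stringent == pytest.approx(c * base.t_stringent, rel=1e-9)
        assert scaled.t_relaxed == pytest.approx(c * base.t_relaxed, rel=1e-9)
        kept_base = target > base.t_stringent
        kept_scaled = c * target > scaled.t_stringent
        assert np.array_equal(kept_base, kept_scaled)
        f_base = empirical_fdr(target, control, base.t_stringent)
        f_scaled = empirical_fdr(c * target, c * control, scaled.t_stringent)
        assert f_base.value == pytest.approx(f_scaled.value)


class TestNullSpecificity:
    def test_mean_retained_fraction_small_under_null(self):
        """With target and control totals i.i.d. from the same distribution,
        the expected fraction of target blocks retained in stringent mode
        stays small (mean over 20 seeded replicates <= 5%)."""
        fractions = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            target = r.lognormal(5.0, 0.6, size=400)
            control = r.lognormal(5.0, 0.6, size=400)
            c = compute_f_curve(target, control)
            fractions.append((target > c.t_stringent).mean())
        assert np.mean(fractions) <= 0.05
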