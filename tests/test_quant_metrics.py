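"""Bias, linearity, repeatability (wSD/wCV/RC) and reproducibility."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cisubquant.quant_metrics import (RC_FACTOR, ReplicateSet,
                                      assess_linearity, compute_bias,
                                      compute_repeatability,
                                      compute_reproducibility)


def make_replicates(measured_fn, levels=(0.0, 0.5, 1.0, 3.0), n_rep=3,
                    n_session=2, scenario="FBP", seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_session):
        for r in range(n_rep):
            for lvl in levels:
                rows.append({"scenario": scenario, "nominal_ci": lvl,
                             "replicate": r, "session": s,
                             "measured_ci": measured_fn(lvl, rng)})
    return ReplicateSet(pd.DataFrame(rows))


class TestBias:
    def test_single_measurement(self):
        per, mean = compute_bias([3.2], 3.0)
        assert per[0] == pytest.approx(0.2)
        assert mean == pytest.approx(0.2)

    def test_exact_measurement_has_zero_bias(self):
        _, mean = compute_bias([1.0, 1.0], 1.0)
        assert mean == 0.0

    def test_symmetric_errors_cancel(self):
        _, mean = compute_bias([0.9, 1.1], 1.0)
        assert mean == pytest.approx(0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_bias([], 1.0)


class TestLinearity:
    def test_identity_data_passes(self):
        reps = make_replicates(lambda lvl, rng: lvl)
        rep = assess_linearity(reps, "FBP")
        assert rep.beta1 == pytest.approx(1.0)
        assert rep.beta2 == pytest.approx(0.0, abs=1e-12)
        assert rep.r_squared == pytest.approx(1.0)
        assert rep.passes

    def test_quadratic_data_fails_with_oracle_checked_beta2(self):
        reps = make_replicates(lambda lvl, rng: lvl ** 2)
        rep = assess_linearity(reps, "FBP")
        # independent oracle: dense Vandermonde least squares
        df = reps.scenario("FBP")
        x = df["nominal_ci"].to_numpy()
        y = df["measured_ci"].to_numpy()
        V = np.vander(x, 3)
        beta2_oracle = np.linalg.lstsq(V, y, rcond=None)[0][0]
        assert rep.beta2 == pytest.approx(beta2_oracle, rel=1e-9)
        assert rep.beta2 >= 0.5
        assert not rep.passes

    def test_threshold_boundaries(self):
        # slope outside (0.95, 1.05) must fail even with perfect R^2
        reps = make_replicates(lambda lvl, rng: 1.10 * lvl)
        assert not assess_linearity(reps, "FBP").passes
        reps = make_replicates(lambda lvl, rng: 0.96 * lvl + 0.01)
        assert assess_linearity(reps, "FBP").passes

    def test_unbiased_affine_process_with_small_noise_passes(self):
        reps = make_replicates(
            lambda lvl, rng: 1.02 * lvl + rng.normal(0, 0.02), seed=1)
        assert assess_linearity(reps, "FBP").passes

    def test_too_few_levels_rejected(self):
        reps = make_replicates(lambda lvl, rng: lvl, levels=(0.0, 1.0, 2.0))
        df = reps.df[reps.df["nominal_ci"] < 1.5]
        with pytest.raises(ValueError):
            assess_linearity(ReplicateSet(df), "FBP")


class TestRepeatability:
    def test_worked_example(self):
        """Replicates (2.9, 3.0, 3.1) at level 3: wSD = 0.1,
        wCV = 0.0333, RC = 0.277."""
        rows = [{"scenario": "FBP", "nominal_ci": 3.0, "replicate": i,
                 "session": 0, "measured_ci": v}
                for i, v in enumerate([2.9, 3.0, 3.1])]
        rep = compute_repeatability(ReplicateSet(pd.DataFrame(rows)), "FBP")
        lvl = rep.per_level.iloc[0]
        assert lvl["wsd"] == pytest.approx(0.1)
        assert lvl["wcv"] == pytest.approx(0.1 / 3.0)
        assert lvl["rc"] == pytest.approx(0.277)

    def test_identical_replicates_have_zero_spread(self):
        reps = make_replicates(lambda lvl, rng: lvl + 0.1)
        rep = compute_repeatability(reps, "FBP")
        assert np.allclose(rep.per_level["wsd"], 0.0)
        assert np.allclose(rep.per_level["rc"], 0.0)

    def test_rc_to_wsd_ratio_is_exact(self):
        reps = make_replicates(
            lambda lvl, rng: lvl + rng.normal(0, 0.05), seed=2)
        rep = compute_repeatability(reps, "FBP")
        wsd = rep.per_level["wsd"].to_numpy()
        rc = rep.per_level["rc"].to_numpy()
        assert np.all(wsd > 0)
        np.testing.assert_allclose(rc / wsd, RC_FACTOR, rtol=0, atol=0)

    def test_zero_mean_level_flags_wcv(self):
        reps = make_replicates(lambda lvl, rng: lvl - 0.0 + (0.01 if rng.random() > 0.5 else -0.01))
        rep = compute_repeatability(reps, "FBP")
        row0 = rep.per_level[rep.per_level["nominal_ci"] == 0.0].iloc[0]
        # mean is close to 0 but not exactly; construct exact-zero case
        rows = [{"scenario": "X", "nominal_ci": 0.0, "replicate": i,
                 "session": 0, "measured_ci": v}
                for i, v in enumerate([-0.1, 0.1])]
        rep2 = compute_repeatability(ReplicateSet(pd.DataFrame(rows)), "X")
        assert np.isnan(rep2.per_level.iloc[0]["wcv"])
        assert row0["wsd"] >= 0

    def test_pooled_wsd_is_rms_of_levels(self):
        reps = make_replicates(
            lambda lvl, rng: lvl + rng.normal(0, 0.1), seed=3)
        rep = compute_repeatability(reps, "FBP")
        rms = np.sqrt(np.mean(rep.per_level["wsd"] ** 2))
        assert rep.pooled_wsd == pytest.approx(rms)
        assert rep.pooled_rc == pytest.approx(RC_FACTOR * rms)


class TestRecoveryProperties:
    def test_wsd_recovers_injected_noise(self):
        """measured = nominal + N(0, sigma^2), 20 replicates per level:
        pooled wSD within 15% of sigma, mean bias within 2 sigma/sqrt(n)."""
        sigma = 0.12
        reps = make_replicates(
            lambda lvl, rng: lvl + rng.normal(0, sigma),
            n_rep=10, n_session=2, seed=7)
        rep = compute_repeatability(reps, "FBP")
        assert rep.pooled_wsd == pytest.approx(sigma, rel=0.15)
        df = reps.scenario("FBP")
        n = len(df)
        all_bias = (df["measured_ci"] - df["nominal_ci"]).mean()
        assert abs(all_bias) < 2 * sigma / np.sqrt(n / 4)

    def test_rc_scales_linearly_with_noise(self):
        rcs = []
        sigmas = [0.05, 0.10, 0.20]
        for sigma in sigmas:
            reps = make_replicates(
                lambda lvl, rng: lvl + rng.normal(0, sigma),
                n_rep=25, n_session=2, seed=11)
            rcs.append(compute_repeatability(reps, "FBP").pooled_rc)
        slope = np.polyfit(sigmas, rcs, 1)[0]
        assert slope == pytest.approx(RC_FACTOR, rel=0.15)


class TestReproducibility:
    @pytest.mark.parametrize("transform,expected_r", [
        (lambda x: x, 1.0),
        (lambda x: 2 * x + 1, 1.0),
        (lambda x: -x, -1.0)])
    def test_affine_relations(self, transform, expected_r):
        x = np.array([0.1, 0.5, 1.0, 2.9, 3.2])
        r, p = compute_reproducibility(x, transform(x))
        assert r == pytest.approx(expected_r)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_reproducibility([1, 2, 3], [1, 2])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            compute_reproducibility([1, 1, 1], [1, 2, 3])


class TestReplicateSetValidation:
    def test_missing_column_rejected(self):
        with pytest.raises(ValueError):
            ReplicateSet(pd.DataFrame({"scenario": ["A"],
                                       "measured_ci": [1.0]}))

    def test_single_replicate_rejected(self):
        df = pd.DataFrame([{"scenario": "A", "nominal_ci": 1.0,
                            "replicate": 0, "session": 0,
                            "measured_ci": 1.0}])
        with pytest.raises(ValueError):
            ReplicateSet(df)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=-10, max_value=10), min_size=2,
                max_size=12).filter(lambda v: np.std(v, ddof=0) > 1e-6))
def test_rc_is_always_277_times_wsd(values):
    """Property: for any replicate set with wSD > 0, RC/wSD = 2.77."""
    rows = [{"scenario": "S", "nominal_ci": 1.0, "replicate": i,
             "session": 0, "measured_ci": float(v)}
            for i, v in enumerate(values)]
    rep = compute_repeatability(ReplicateSet(pd.DataFrame(rows)), "S")
    wsd = rep.per_level.iloc[0]["wsd"]
    rc = rep.per_level.iloc[0]["rc"]
    assert rc == wsd * RC_FACTOR
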