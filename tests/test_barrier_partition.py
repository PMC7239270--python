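"""Inversion of the six-treatment system, residuals, bootstrap, consistency."""

import numpy as np
import pytest

from cutipart import (
    PartitionInputs,
    RateSeries,
    bootstrap_uncertainty,
    build_partition_inputs,
    cuticular_abaxial,
    estimate_k,
    estimate_residual_stomatal,
    intracuticular_rates,
    partition_table,
    scan_table_consistency,
    simulate_experiment,
    solve_surface_rates,
)
from cutipart.barrier_partition import GROUP_ORDER, partition_hour
from cutipart.dataio import load_reference_partition
from cutipart.errors import GapError, PartitionWarning, SingularPartitionError
from cutipart.pipeline import rates_by_group
from cutipart.synthetic_leaf import SimulationParams


def forward_inputs(hour, k, t_ad, t_ab, t_ad_intra, t_ab_intra):
    """Generate the six observable group means from the true components."""
    return PartitionInputs(
        hour=hour,
        t_control=t_ad + t_ab,
        t_ad_vas=k * t_ad + t_ab,
        t_ab_vas=t_ad + k * t_ab,
        t_both_vas=k * (t_ad + t_ab),
        t_minus_ew_ad=t_ad_intra + k * t_ab,
        t_minus_ew_ab=t_ab_intra + k * t_ad,
    )


# printed first-hour component values for mature tea leaves
ROW1 = dict(k=0.206, t_ad=0.094, t_ab=0.199, t_ab_c=0.142,
            t_ad_intra=0.104, t_ab_intra=0.452, t_ab_intra_c=0.413)


class TestEstimateK:
    def test_perfect_seal(self):
        # boundary value: returned exactly, flagged as outside (0, 1)
        with pytest.warns(PartitionWarning):
            assert estimate_k(0.3, 0.0) == 0.0

    def test_inert_coating_flagged(self):
        with pytest.warns(PartitionWarning):
            assert estimate_k(0.3, 0.3) == 1.0

    def test_division_oracle(self):
        t = ROW1["t_ad"] + ROW1["t_ab"]
        assert estimate_k(t, ROW1["k"] * t) == pytest.approx(0.206, abs=1e-12)

    def test_zero_control_rejected(self):
        with pytest.raises(SingularPartitionError):
            estimate_k(0.0, 0.1)


class TestSolveSurfaceRates:
    def test_perfect_seal_reduces_to_subtraction(self):
        t_ad, t_ab, resid = solve_surface_rates(0.3, 0.2, 0.1, k=0.0)
        assert (t_ad, t_ab) == pytest.approx((0.1, 0.2))
        assert resid == pytest.approx(0.0, abs=1e-15)

    def test_round_trip_printed_row(self):
        inp = forward_inputs(1.0, **{k: ROW1[k] for k in
                                     ("k", "t_ad", "t_ab", "t_ad_intra", "t_ab_intra")})
        t_ad, t_ab, resid = solve_surface_rates(
            inp.t_control, inp.t_ad_vas, inp.t_ab_vas, ROW1["k"]
        )
        assert t_ad == pytest.approx(0.094, abs=5e-4)
        assert t_ab == pytest.approx(0.199, abs=5e-4)
        assert resid == pytest.approx(0.0, abs=1e-12)

    def test_consistent_inputs_zero_residual(self):
        # T_Ad/Vas + T_Ab/Vas = (1 + k) T  <=>  residual 0
        k, t = 0.3, 0.5
        t_ad_vas = 0.31
        t_ab_vas = (1 + k) * t - t_ad_vas
        _, _, resid = solve_surface_rates(t, t_ad_vas, t_ab_vas, k)
        assert resid == pytest.approx(0.0, abs=1e-12)

    def test_singular_for_k_one(self):
        with pytest.raises(SingularPartitionError):
            solve_surface_rates(0.3, 0.2, 0.1, k=1.0)


class TestIntracuticularAndAbaxial:
    def test_intra_forward_oracles(self):
        t_ad_intra, t_ab_intra = intracuticular_rates(
            t_minus_ew_ad=0.104 + 0.206 * 0.199,
            t_minus_ew_ab=0.452 + 0.206 * 0.094,
            k=0.206, t_ad=0.094, t_ab=0.199,
        )
        assert t_ad_intra == pytest.approx(0.104, abs=1e-12)
        assert t_ab_intra == pytest.approx(0.452, abs=1e-12)

    def test_zero_k_identity(self):
        t_ad_intra, t_ab_intra = intracuticular_rates(0.104, 0.452, 0.0, 0.094, 0.199)
        assert (t_ad_intra, t_ab_intra) == (0.104, 0.452)

    def test_cuticular_abaxial_subtraction(self):
        t_ab_c, _ = cuticular_abaxial(0.199, 0.057)
        assert t_ab_c == pytest.approx(0.142)

    def test_zero_residual_identity(self):
        assert cuticular_abaxial(0.199, 0.0)[0] == 0.199

    def test_printed_rounding_stays_close(self):
        # using the rounded printed residual 0.06 stays within 0.005 of 0.142
        t_ab_c, _ = cuticular_abaxial(0.199, 0.06)
        assert t_ab_c == pytest.approx(0.142, abs=5e-3)

    def test_negative_flagged(self):
        with pytest.warns(PartitionWarning):
            cuticular_abaxial(0.05, 0.06)


def step_rate_group(code, profile, n_leaves=4, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    times = np.arange(1.0, len(profile) + 1)
    return [
        RateSeries(leaf_id=f"{code}{i}", treatment=code, times=times,
                   rates=np.asarray(profile) + rng.normal(0, jitter, len(profile)),
                   rwd=np.linspace(0.01, 0.1, len(profile)))
        for i in range(n_leaves)
    ]


class TestResidualStomatal:
    def test_constant_rates_zero(self):
        group = step_rate_group("CONTROL", [0.27] * 6)
        est = estimate_residual_stomatal(group, closure_hour=5.0)
        assert est.value == pytest.approx(0.0, abs=1e-12)

    def test_control_drop_oracle(self):
        group = step_rate_group("CONTROL", [0.270, 0.270, 0.270, 0.270, 0.210, 0.210])
        est = estimate_residual_stomatal(group, closure_hour=5.0, mode="single_hour")
        assert est.value == pytest.approx(0.060, abs=1e-12)
        # the settled plateau gives the same answer on truly flat data
        est_p = estimate_residual_stomatal(group, closure_hour=5.0, mode="plateau")
        assert est_p.value == pytest.approx(0.060, abs=1e-12)

    def test_stripped_group_drop_oracle(self):
        group = step_rate_group(
            "MINUS_EW_AB_AD_VAS", [0.494, 0.494, 0.494, 0.452, 0.452, 0.452]
        )
        est = estimate_residual_stomatal(group, closure_hour=4.0, mode="single_hour")
        assert est.value == pytest.approx(0.042, abs=1e-12)

    def test_negative_estimate_flagged(self):
        group = step_rate_group("CONTROL", [0.20, 0.20, 0.20, 0.20, 0.25, 0.25])
        with pytest.warns(PartitionWarning):
            est = estimate_residual_stomatal(group, closure_hour=5.0)
        assert "negative_residual" in est.flags


class TestPartitionTable:
    def test_round_trip_printed_row(self):
        """Forward-generated group means reproduce every printed first-hour value."""
        inp = forward_inputs(1.0, **{k: ROW1[k] for k in
                                     ("k", "t_ad", "t_ab", "t_ad_intra", "t_ab_intra")})
        res = partition_table([inp], t_ab_s=0.057, intra_residual=0.039)[0]
        assert res.k == pytest.approx(0.206, abs=5e-4)
        assert res.t_ad == pytest.approx(0.094, abs=5e-4)
        assert res.t_ab == pytest.approx(0.199, abs=5e-4)
        assert res.t_ab_c == pytest.approx(0.142, abs=5e-4)
        assert res.t_ad_intra == pytest.approx(0.104, abs=5e-4)
        assert res.t_ab_intra == pytest.approx(0.452, abs=5e-4)
        assert res.t_ab_intra_c == pytest.approx(0.413, abs=5e-4)

    def test_least_squares_agrees_on_consistent_inputs(self):
        inp = forward_inputs(1.0, 0.2, 0.1, 0.2, 0.11, 0.45)
        a = partition_hour(inp, t_ab_s=0.05)
        b = partition_hour(inp, t_ab_s=0.05, least_squares=True)
        assert a.t_ad == pytest.approx(b.t_ad, abs=1e-10)
        assert a.t_ab == pytest.approx(b.t_ab, abs=1e-10)

    def test_per_hour_k_rises_when_control_declines(self):
        """Sealed groups constant + declining control => apparent k increases."""
        inputs = []
        for h, t_control in enumerate([0.293, 0.270, 0.250, 0.230], start=1):
            inputs.append(
                PartitionInputs(hour=float(h), t_control=t_control,
                                t_ad_vas=0.218, t_ab_vas=0.135, t_both_vas=0.0604,
                                t_minus_ew_ad=0.145, t_minus_ew_ab=0.471)
            )
        res = partition_table(inputs, t_ab_s=0.057)
        ks = [r.k for r in res]
        assert np.all(np.diff(ks) > 0)
        # first-hour mode pins k at its first value instead
        res_fixed = partition_table(inputs, t_ab_s=0.057, k_mode="first_hour")
        assert len({r.k for r in res_fixed}) == 1

    def test_missing_group_raises_gap_error(self):
        groups = {g: step_rate_group(g, [0.3] * 4) for g in GROUP_ORDER[:-1]}
        with pytest.raises(GapError):
            build_partition_inputs(groups)

    def test_exact_inversion_of_noise_free_generator(self, ideal_experiment):
        """Zero noise + shut stomata: the closed forms recover the truth exactly."""
        groups = rates_by_group(ideal_experiment.leaves)
        inputs = [i for i in build_partition_inputs(groups) if i.hour > 0]
        res = partition_table(inputs, t_ab_s=0.0)
        truth = ideal_experiment.truth
        for r in res:
            assert r.k == pytest.approx(truth.k, abs=1e-9)
            assert r.t_ad == pytest.approx(truth.t_ad, abs=1e-9)
            assert r.t_ab == pytest.approx(truth.t_ab, abs=1e-9)
            assert r.t_ad_intra == pytest.approx(truth.t_ad_intra, abs=1e-9)
            assert r.t_ab_intra == pytest.approx(truth.t_ab_intra, abs=1e-9)
            assert r.consistency_residual == pytest.approx(0.0, abs=1e-9)


class TestSensitivityToUnequalK:
    def test_t_ad_bias_grows_with_k_asymmetry(self):
        """The equal-k assumption: bias in T_Ad rises with |k_ad - k_ab|."""
        biases = []
        for delta in (0.0, 0.04, 0.08):
            params = SimulationParams(
                g_s0=0.0, noise_sd=0.0, k_ad=0.206 + delta, k_ab=0.206 - delta, seed=3
            )
            exp = simulate_experiment(params)
            groups = rates_by_group(exp.leaves)
            inputs = [i for i in build_partition_inputs(groups) if i.hour == 1.0]
            res = partition_table(inputs, t_ab_s=0.0)[0]
            biases.append(abs(res.t_ad - exp.truth.t_ad))
        assert biases[0] == pytest.approx(0.0, abs=1e-9)
        assert biases[0] < biases[1] < biases[2]


class TestBootstrap:
    LEVELS = {
        "CONTROL": 0.30,
        "AD_VAS": 0.22,
        "AB_VAS": 0.14,
        "BOTH_VAS": 0.06,
        "MINUS_EW_AD_AB_VAS": 0.15,
        "MINUS_EW_AB_AD_VAS": 0.47,
    }

    @classmethod
    def identical_groups(cls):
        """Within-group identical leaves at distinct, invertible group levels."""
        return {g: step_rate_group(g, [cls.LEVELS[g]] * 4) for g in GROUP_ORDER}

    def test_identical_leaves_zero_se(self):
        groups = self.identical_groups()
        boot = bootstrap_uncertainty(groups, B=200, seed=1, closure_hour=3.0)
        for name, arr in boot["ses"].items():
            assert np.allclose(arr, 0.0), name

    def test_seed_stability(self, default_experiment):
        groups = rates_by_group(default_experiment.leaves)
        b1 = bootstrap_uncertainty(groups, B=1000, seed=1, closure_hour=5.0)
        b2 = bootstrap_uncertainty(groups, B=1000, seed=2, closure_hour=5.0)
        for name in ("k", "t_ad", "t_ab", "t_ab_c"):
            s1, s2 = b1["ses"][name][0], b2["ses"][name][0]
            assert abs(s1 - s2) / s1 < 0.15, name

    def test_deterministic_given_seed(self):
        groups = self.identical_groups()
        b1 = bootstrap_uncertainty(groups, B=150, seed=9, closure_hour=3.0)
        b2 = bootstrap_uncertainty(groups, B=150, seed=9, closure_hour=3.0)
        for name in b1["ses"]:
            assert np.array_equal(b1["ses"][name], b2["ses"][name])

    def test_doubling_spread_doubles_t_ad_se(self):
        """Leaf-to-leaf spread in the adaxial-sealed group scales T_Ad's SE."""
        offsets = np.array([-0.02, -0.01, 0.01, 0.02])

        def groups_with_spread(scale):
            groups = self.identical_groups()
            times = np.arange(1.0, 5.0)
            groups["AD_VAS"] = [
                RateSeries(leaf_id=f"A{i}", treatment="AD_VAS", times=times,
                           rates=np.full(4, self.LEVELS["AD_VAS"]) + scale * off,
                           rwd=np.linspace(0.01, 0.05, 4))
                for i, off in enumerate(offsets)
            ]
            return groups

        se1 = bootstrap_uncertainty(groups_with_spread(1.0), B=500, seed=4,
                                    closure_hour=3.0)["ses"]["t_ad"][0]
        se2 = bootstrap_uncertainty(groups_with_spread(2.0), B=500, seed=4,
                                    closure_hour=3.0)["ses"]["t_ad"][0]
        assert se2 == pytest.approx(2.0 * se1, rel=1e-9)


class TestReferenceTableConsistency:
    def test_constant_residuals_within_tolerance(self):
        scan = scan_table_consistency(load_reference_partition())
        assert scan["consistent"]
        assert scan["c_abaxial"] == pytest.approx(0.057, abs=0.002)
        assert scan["c_intra"] == pytest.approx(0.039, abs=0.002)
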