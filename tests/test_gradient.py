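"""Gradient profile fitting and power-law coupling recovery."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from axonmt import gradient, synth
from axonmt.gradient import (
    FitError,
    GradientFit,
    fit_exponential,
    fit_power_law,
    normalize_profiles,
    predict_dg,
)

TRUE = dict(b=1.0, s=0.05, x0=-20.0)


def make_binned_dg(fit: GradientFit, noise_sigma: float = 0.0, seed: int = 0,
                   n_bins: int = 12) -> pd.DataFrame:
    """Observed per-bin d_g tables from a known coupling (generator truth)."""
    rng = np.random.default_rng(seed)
    rows = []
    for direction in (1, -1):
        sign = -1 if direction == 1 else 1
        for b0 in range(0, 10 * n_bins, 10):
            val = gradient._bin_mean_prediction(fit, b0, b0 + 10, sign)
            if np.isfinite(val) and noise_sigma > 0:
                val *= np.exp(noise_sigma * rng.standard_normal())
            rows.append({"bin_start_um": b0, "bin_end_um": b0 + 10,
                         "value": val, "direction": direction})
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def profile_fit():
    prof, _ = synth.gen_p150_profiles(**TRUE, noise_sigma=0.0, n_axons=3, seed=0)
    return fit_exponential(prof)


class TestNormalizeProfiles:
    @staticmethod
    def raw(scale=1.0, n=3):
        rng = np.random.default_rng(5)
        rows = []
        for a in range(n):
            x = np.arange(0.0, 120.0, 1.0)
            p150 = scale * (1 + np.exp(-0.05 * (x + 20)) + 0.01 * rng.standard_normal(x.size))
            rows.append(pd.DataFrame({"axon_id": f"a{a}", "x_um": x, "p150": p150,
                                      "tubulin": scale * np.full(x.size, 2.0),
                                      "celltracker": scale * np.full(x.size, 3.0)}))
        return pd.concat(rows, ignore_index=True)

    def test_constant_channels_give_unit_ratio(self):
        x = np.arange(0.0, 50.0, 1.0)
        raw = pd.DataFrame({"axon_id": "a", "x_um": x, "p150": 7.0,
                            "tubulin": 2.0, "celltracker": 3.0})
        prof = normalize_profiles(raw)
        assert prof["value"].to_numpy() == pytest.approx(np.ones(len(prof)))

    def test_scale_invariance(self):
        a = normalize_profiles(self.raw(scale=1.0))
        b = normalize_profiles(self.raw(scale=2.0))
        assert b["value"].to_numpy() == pytest.approx(a["value"].to_numpy())

    def test_zero_median_channel_rejected(self):
        raw = self.raw().assign(celltracker=0.0)
        with pytest.raises(ValueError, match="zero median"):
            normalize_profiles(raw)

    def test_treatment_normalized_by_control_mean(self):
        control = normalize_profiles(self.raw())
        treated = normalize_profiles(self.raw(), control_reference=control)
        ref = control["value"].mean()
        assert treated["value"].to_numpy() == pytest.approx(
            control["value"].to_numpy() / ref
        )
        assert (treated["condition"] == "treatment").all()


class TestFitExponential:
    def test_noiseless_recovery_within_1pct(self, profile_fit):
        assert profile_fit.b == pytest.approx(TRUE["b"], rel=0.01)
        assert profile_fit.s == pytest.approx(TRUE["s"], rel=0.01)
        assert profile_fit.x0 == pytest.approx(TRUE["x0"], rel=0.01)
        assert not profile_fit.degenerate

    def test_flat_profile_flagged_degenerate(self):
        prof, _ = synth.gen_p150_profiles(**TRUE, noise_sigma=0.0, n_axons=3,
                                          seed=1, treatment=True)
        fit = fit_exponential(prof)
        assert fit.degenerate

    def test_offset_shifts_b_only(self, profile_fit):
        prof, _ = synth.gen_p150_profiles(**TRUE, noise_sigma=0.0, n_axons=3, seed=0)
        shifted = prof.assign(value=prof["value"] + 0.7)
        fit2 = fit_exponential(shifted)
        assert fit2.b == pytest.approx(profile_fit.b + 0.7, abs=1e-4)
        assert fit2.s == pytest.approx(profile_fit.s, rel=1e-3)

    def test_requires_12_bins(self):
        prof, _ = synth.gen_p150_profiles(**TRUE, n_bins=8, n_axons=2, seed=0)
        with pytest.raises(FitError, match="12 bins"):
            fit_exponential(prof)

    def test_uses_only_first_12_bins(self, profile_fit):
        """Perturbing bins beyond 120 µm leaves the fit unchanged."""
        prof, _ = synth.gen_p150_profiles(**TRUE, noise_sigma=0.0, n_axons=3,
                                          n_bins=15, seed=0)
        prof.loc[prof["bin_start_um"] >= 120, "value"] *= 5.0
        fit = fit_exponential(prof)
        assert fit.s == pytest.approx(profile_fit.s, rel=1e-6)


class TestPredictDg:
    def test_power_zero_is_constant(self, profile_fit):
        f = replace(profile_fit, A=1.7, alpha=0.0)
        xs = np.array([0.0, 5.0, 40.0, 90.0])
        assert predict_dg(xs, -1, f) == pytest.approx(np.full(4, 1.7))
        assert predict_dg(xs, 1, f) == pytest.approx(np.full(4, 1.7))

    def test_tipward_exceeds_awayward_on_decaying_gradient(self, profile_fit):
        f = replace(profile_fit, A=0.6, alpha=4.0)
        for x in (5.0, 10.0, 30.0):
            assert predict_dg(x, -1, f) >= predict_dg(x, 1, f)

    def test_hand_evaluation_spot_check(self):
        f = GradientFit(b=1.0, s=0.1, x0=0.0, A=2.0, alpha=4.0)

        def p150(x):
            return 1 + np.exp(-0.1 * x)

        def dg(x):
            return 2 * p150(x) ** 4

        x = 5.0
        end_tip = max(x - dg(x), -2.0)
        assert predict_dg(x, -1, f) == pytest.approx(0.5 * (dg(end_tip) + dg(x)))
        end_away = x + dg(x)
        assert predict_dg(x, 1, f) == pytest.approx(0.5 * (dg(end_away) + dg(x)))

    def test_away_growth_starts_at_least_4um_from_tip(self, profile_fit):
        f = replace(profile_fit, A=0.6, alpha=4.0)
        assert predict_dg(1.0, 1, f) == pytest.approx(predict_dg(4.0, 1, f))

    def test_requires_coupling(self, profile_fit):
        with pytest.raises(FitError, match="no power-law"):
            predict_dg(5.0, 1, profile_fit)

    def test_invalid_sign(self, profile_fit):
        f = replace(profile_fit, A=1.0, alpha=1.0)
        with pytest.raises(ValueError, match="sign"):
            predict_dg(5.0, 0, f)


class TestFitPowerLaw:
    def test_noiseless_recovery_within_5pct(self, profile_fit):
        truth = replace(profile_fit, A=0.6, alpha=4.0)
        obs = make_binned_dg(truth)
        fit = fit_power_law(obs, profile_fit)
        assert fit.alpha == pytest.approx(4.0, rel=0.05)
        assert fit.A == pytest.approx(0.6, rel=0.05)

    def test_no_coupling_gives_alpha_zero(self, profile_fit):
        obs = make_binned_dg(replace(profile_fit, A=1.7, alpha=0.0))
        fit = fit_power_law(obs, profile_fit)
        assert abs(fit.alpha) < 0.05
        assert fit.A == pytest.approx(1.7, rel=0.05)

    def test_noisy_recovery_median_within_10pct(self, profile_fit):
        """Median recovered alpha over 20 replicates at 10% noise."""
        truth = replace(profile_fit, A=0.6, alpha=4.0)
        alphas = []
        for rep in range(20):
            obs = make_binned_dg(truth, noise_sigma=0.10, seed=100 + rep)
            alphas.append(fit_power_law(obs, profile_fit).alpha)
        assert np.median(alphas) == pytest.approx(4.0, rel=0.10)

    def test_scale_covariance(self, profile_fit):
        """p150 -> c*p150 rescales A by c**(-alpha), alpha unchanged."""
        c = 2.0
        truth = replace(profile_fit, A=0.6, alpha=4.0)
        obs = make_binned_dg(truth)
        prof_scaled, _ = synth.gen_p150_profiles(**TRUE, noise_sigma=0.0,
                                                 n_axons=3, seed=0)
        prof_scaled["value"] *= c
        pfit_scaled = gradient.fit_exponential(prof_scaled)
        fit = fit_power_law(obs, pfit_scaled)
        assert fit.alpha == pytest.approx(4.0, rel=0.02)
        assert fit.A == pytest.approx(0.6 * c**-4.0, rel=0.05)

    def test_joint_fit_beats_either_single_direction_solution(self, profile_fit):
        truth = replace(profile_fit, A=0.6, alpha=4.0)
        obs = make_binned_dg(truth, noise_sigma=0.15, seed=9)
        joint = fit_power_law(obs, profile_fit)

        def joint_sse(f):
            sse = 0.0
            for _, row in obs.iterrows():
                sign = -1 if row["direction"] == 1 else 1
                pred = gradient._bin_mean_prediction(
                    f, row["bin_start_um"], row["bin_end_um"], sign)
                if np.isfinite(pred):
                    sse += (pred - row["value"]) ** 2
            return sse

        for direction in (1, -1):
            single = fit_power_law(obs[obs["direction"] == direction], profile_fit)
            assert joint_sse(joint) <= joint_sse(single) + 1e-9

    def test_underdetermined(self, profile_fit):
        obs = make_binned_dg(replace(profile_fit, A=0.6, alpha=4.0)).iloc[:1]
        with pytest.raises(FitError, match="2 informative bins"):
            fit_power_law(obs, profile_fit)
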