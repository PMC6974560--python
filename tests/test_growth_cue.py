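import numpy as np
import pandas as pd
import pytest

from cuephylo import growth_cue as gc
from cuephylo import synthetic_data as sd


def oracle_window(t, y, min_pts=3, max_pts=10):
    """Exhaustive enumeration with numpy.polyfit, independent tie-break scan."""
    best = None
    n = len(t)
    for length in range(min_pts, min(max_pts, n) + 1):
        for start in range(n - length + 1):
            slope = np.polyfit(t[start:start + length], y[start:start + length], 1)[0]
            cand = (start, start + length - 1, slope, length)
            if (
                best is None
                or slope > best[2] + 1e-11
                or (abs(slope - best[2]) <= 1e-11
                    and (length, -start) > (best[3], -best[0]))
            ):
                best = cand
    return best[0], best[1]


class TestWindow:
    def test_piecewise_series_selects_exponential_stretch(self):
        t = np.arange(14.0)
        y = np.concatenate([
            np.zeros(4), 0.3 * (np.arange(1, 7)), 1.8 + np.zeros(4)])
        w = gc.find_exponential_window(t, y)
        assert w == oracle_window(t, y)
        assert w[0] >= 3 and w[1] <= 10  # the rising stretch, give or take ties

    def test_collinear_points_pick_longest_window(self):
        t = np.arange(8.0)
        y = 0.25 * t + 1.0
        assert gc.find_exponential_window(t, y) == (0, 7)

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            gc.find_exponential_window(np.array([0.0, 1.0]), np.array([0.0, 1.0]))

    def test_matches_enumeration_oracle_on_random_series(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 21))
            t = np.sort(rng.uniform(0, 30, n))
            t += np.arange(n) * 1e-3
            y = rng.normal(size=n).cumsum()
            assert gc.find_exponential_window(t, y) == oracle_window(t, y)


class TestConversions:
    def test_od_to_biomass(self, constants):
        assert gc.od_to_biomass_c(0.0, constants) == 0.0
        assert gc.od_to_biomass_c(0.1, constants) == pytest.approx(130.0)
        one_ml = gc.AssayConstants(culture_ml=1.0)
        assert gc.od_to_biomass_c(1.0, one_ml) == pytest.approx(130.0)
        with pytest.raises(ValueError):
            gc.od_to_biomass_c(-0.1, constants)

    def test_co2_baseline_and_linearity(self, constants):
        ppm = np.array([420.0, 420.0, 430.0, 440.0])
        c = gc.co2_to_carbon(ppm, constants, 25.0)
        assert c[0] == 0.0 and c[1] == 0.0
        assert c[3] == pytest.approx(2 * c[2])

    def test_molar_volume_identity(self):
        # 22.414 L headspace at 0 C holds one mole: 1 ppm above baseline is
        # 1 umol CO2 = 12.011 ug C.
        consts = gc.AssayConstants(headspace_ml=22414.0)
        c = gc.co2_to_carbon(np.array([400.0, 401.0]), consts, 0.0)
        assert c[1] == pytest.approx(12.011, rel=1e-4)

    def test_energy_per_carbon(self, constants):
        consts = gc.AssayConstants(substrate_table={"x": (600.0, 2), "y": (600.0, 1)})
        assert gc.energy_per_carbon("x", consts) == pytest.approx(300.0)
        assert gc.energy_per_carbon("y", consts) == pytest.approx(600.0)
        with pytest.raises(KeyError):
            gc.energy_per_carbon("unknown", constants)


class TestRates:
    def test_noiseless_recovery_to_four_decimals(self, constants):
        p = sd.GrowthSimParams(mu_true=0.3, cue_true=0.6,
                               od_noise_sd=0.0, co2_noise_sd=0.0, seed=1)
        curves, _ = sd.simulate_growth_experiment(p, 1)
        fit = gc.fit_exponential_rates(gc.GrowthCurve.from_frame(curves), constants)
        assert fit.mu == pytest.approx(0.3, abs=1e-6)
        assert fit.r_mass_specific == pytest.approx(0.2, abs=1e-6)
        assert fit.cue == pytest.approx(0.6, abs=1e-6)

    def test_constant_co2_flagged_nonrespiring(self, constants):
        p = sd.GrowthSimParams(mu_true=0.3, cue_true=1.0,
                               od_noise_sd=0.0, co2_noise_sd=0.0, seed=1)
        curves, _ = sd.simulate_growth_experiment(p, 1)
        fit = gc.fit_exponential_rates(gc.GrowthCurve.from_frame(curves), constants)
        assert fit.r_mass_specific == pytest.approx(0.0, abs=1e-12)
        assert fit.r_p > 0.05
        assert fit.cue == pytest.approx(1.0)

    def test_estimation_methods_agree_on_noiseless_input(self, constants):
        p = sd.GrowthSimParams(mu_true=0.25, cue_true=0.5,
                               od_noise_sd=0.0, co2_noise_sd=0.0, seed=2)
        curves, _ = sd.simulate_growth_experiment(p, 1)
        curve = gc.GrowthCurve.from_frame(curves)
        r_cum = gc.fit_exponential_rates(curve, constants).r_mass_specific
        r_int = gc.fit_exponential_rates(
            curve, constants, respiration_method="interval").r_mass_specific
        assert r_int == pytest.approx(r_cum, rel=0.01)

    def test_cue_invariant_to_joint_mass_rescaling(self, constants):
        p = sd.GrowthSimParams(mu_true=0.3, cue_true=0.55, seed=5)
        curves, _ = sd.simulate_growth_experiment(p, 1)
        curve = gc.GrowthCurve.from_frame(curves)
        base = gc.fit_exponential_rates(curve, constants).cue
        # scaling biomass conversion and headspace volume together scales
        # biomass-C and CO2-C by the same factor
        scaled = gc.AssayConstants(biomass_per_od=constants.biomass_per_od * 3.7,
                                   culture_ml=constants.culture_ml,
                                   headspace_ml=constants.headspace_ml * 3.7)
        assert gc.fit_exponential_rates(curve, scaled).cue == pytest.approx(base)


class TestCueAndQC:
    @pytest.mark.parametrize("mu,r,expected", [(0.2, 0.2, 0.5), (0.3, 0.1, 0.75),
                                               (0.4, 0.0, 1.0)])
    def test_compute_cue(self, mu, r, expected):
        assert gc.compute_cue(mu, r) == pytest.approx(expected)

    def test_compute_cue_domain(self):
        with pytest.raises(ValueError):
            gc.compute_cue(0.0, 0.1)
        with pytest.raises(ValueError):
            gc.compute_cue(0.3, -0.1)

    def _records(self, rows):
        base = {"isolate": "i", "substrate": "glc", "temperature_c": 25.0,
                "cue": 0.5, "mu": 0.3, "r": 0.3}
        return pd.DataFrame([{**base, **r} for r in rows])

    def test_failing_replicate_dropped_condition_kept(self):
        recs = self._records([
            {"replicate": "r1", "mu_p": 0.01, "r_p": 0.01},
            {"replicate": "r2", "mu_p": 0.01, "r_p": 0.2},
            {"replicate": "r3", "mu_p": 0.01, "r_p": 0.01},
        ])
        out = gc.qc_filter(recs)
        assert list(out["replicate"]) == ["r1", "r3"]

    def test_condition_dropped_below_min_replicates(self):
        recs = self._records([
            {"replicate": "r1", "mu_p": 0.01, "r_p": 0.01},
            {"replicate": "r2", "mu_p": 0.2, "r_p": 0.01},
        ])
        assert gc.qc_filter(recs).empty

    def test_all_passing_is_identity(self):
        recs = self._records([
            {"replicate": f"r{i}", "mu_p": 0.01, "r_p": 0.01} for i in range(3)
        ])
        assert len(gc.qc_filter(recs)) == 3
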