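import math

import numpy as np
import pandas as pd
import pytest

from okrsphere.geometry import GeoCoord, geo_to_unit, great_circle_angle
from okrsphere.simulate import default_cohort, default_truth, generate_dataset
from okrsphere.spatial import (
    BimodalVmfModel,
    FrequencyTuningModel,
    SizeTuningModel,
    VmfModel,
    correct_arena_rotation,
    direct_visibility,
    vmf_kernel_smooth,
    vmf_sum_eval,
)


def single_component(kappa=1.0, C1=1.0, C3=0.0, mu=(0, 0, 1)):
    return VmfModel(mu1=np.array(mu, float), mu2=np.array([0.0, 1.0, 0.0]),
                    kappa1=kappa, kappa2=1.0, C1=C1, C2=0.0, C3=C3)


def fibonacci_sphere(n=20000):
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(1.0 - z * z)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


class TestVmfEvaluation:
    def test_closed_form_at_centre_and_antipode(self):
        # kappa*e^kappa / (4*pi*sinh(kappa)) and kappa*e^-kappa / (...)
        m = single_component(kappa=1.0)
        assert vmf_sum_eval(m, np.array([0.0, 0.0, 1.0])) == pytest.approx(
            0.18407, abs=1e-5
        )
        assert vmf_sum_eval(m, np.array([0.0, 0.0, -1.0])) == pytest.approx(
            0.02492, abs=1e-5
        )

    def test_zero_masses_give_offset(self):
        m = VmfModel(mu1=np.array([0.0, 0, 1]), mu2=np.array([0.0, 1, 0]),
                     kappa1=2.0, kappa2=3.0, C1=0.0, C2=0.0, C3=0.7)
        pts = fibonacci_sphere(50)
        assert np.allclose(vmf_sum_eval(m, pts), 0.7)

    def test_log_domain_matches_naive_for_moderate_kappa(self):
        pts = fibonacci_sphere(200)
        for kappa in (0.5, 5.0, 50.0, 100.0):
            m = single_component(kappa=kappa)
            naive = (
                kappa
                * np.exp(kappa * (pts @ m.mu1))
                / (2 * math.pi * (math.exp(kappa) - math.exp(-kappa)))
            )
            ours = vmf_sum_eval(m, pts)
            assert np.allclose(ours, naive, rtol=1e-10)

    def test_finite_at_high_concentration(self):
        m = single_component(kappa=700.0)
        assert np.isfinite(vmf_sum_eval(m, np.array([0.0, 0.0, 1.0])))

    def test_rejects_nonpositive_kappa(self):
        with pytest.raises(ValueError):
            single_component(kappa=0.0)

    def test_normalisation_each_component_integrates_to_its_mass(self):
        # quadrature over a Fibonacci point set: mean(F - C3) * 4*pi = C1 + C2
        m = VmfModel(
            mu1=geo_to_unit(GeoCoord(-82.5, 5.1)),
            mu2=geo_to_unit(GeoCoord(81.7, 1.6)),
            kappa1=8.0, kappa2=4.0, C1=0.23, C2=0.31, C3=0.05,
        )
        pts = fibonacci_sphere(40000)
        integral = float(np.mean(vmf_sum_eval(m, pts) - m.C3) * 4 * math.pi)
        assert integral == pytest.approx(m.C1 + m.C2, abs=1e-4)


class TestBimodalVmfFit:
    def test_zero_noise_recovery_on_38_centres(self, centres):
        truth = default_truth(kappa=8.0)
        rows = [
            dict(azimuth=c.azimuth, elevation=c.elevation,
                 gain=float(vmf_sum_eval(truth.vmf, c)))
            for c in centres
        ]
        res = BimodalVmfModel(pd.DataFrame(rows)).fit()
        c1, c2 = res.centres
        assert great_circle_angle(c1, GeoCoord(-82.5, 5.1)) < 0.5
        assert great_circle_angle(c2, GeoCoord(81.7, 1.6)) < 0.5
        assert res.r_squared > 0.999

    def test_mirror_symmetric_data_gives_mirror_symmetric_centres(self, centres):
        truth = default_truth(kappa=8.0, centres=((-80.0, 10.0), (80.0, 10.0)))
        rows = [
            dict(azimuth=c.azimuth, elevation=c.elevation,
                 gain=float(vmf_sum_eval(truth.vmf, c)))
            for c in centres
        ]
        res = BimodalVmfModel(pd.DataFrame(rows)).fit()
        c1, c2 = res.centres
        assert c1.azimuth == pytest.approx(-c2.azimuth, abs=0.5)
        assert c1.elevation == pytest.approx(c2.elevation, abs=0.5)

    def test_noisy_recovery_median_error(self, centres):
        # 20% of peak as gain noise, several seeded replicates
        errs = []
        for seed in range(10):
            truth = default_truth(gain_noise_sd=0.06)
            cohort = default_cohort(n_fish=7, truth=truth, centres=centres,
                                    rng_seed=seed)
            table, _ = generate_dataset(cohort, truth, with_traces=False)
            res = BimodalVmfModel(table[table.stimulated == "direct"]).fit(n_starts=3)
            c1, c2 = res.centres
            if c1.azimuth > c2.azimuth:  # order by hemisphere
                c1, c2 = c2, c1
            errs.append(great_circle_angle(c1, GeoCoord(-82.5, 5.1)))
            errs.append(great_circle_angle(c2, GeoCoord(81.7, 1.6)))
        assert np.median(errs) < 5.0

    def test_requires_enough_positions(self):
        df = pd.DataFrame(
            dict(azimuth=np.arange(10.0), elevation=np.zeros(10), gain=np.ones(10))
        )
        with pytest.raises(ValueError):
            BimodalVmfModel(df)

    def test_flat_gains_flagged_degenerate(self, centres):
        df = pd.DataFrame(
            [dict(azimuth=c.azimuth, elevation=c.elevation, gain=0.2) for c in centres]
        )
        res = BimodalVmfModel(df).fit(n_starts=2)
        assert res.degenerate

    def test_summary_mentions_centres(self, centres):
        truth = default_truth()
        df = pd.DataFrame(
            [dict(azimuth=c.azimuth, elevation=c.elevation,
                  gain=float(vmf_sum_eval(truth.vmf, c))) for c in centres]
        )
        s = BimodalVmfModel(df).fit(n_starts=2).summary()
        assert "centre 1" in s and "kappa" in s


class TestKernelSmoothing:
    def test_single_record_constant_map(self):
        df = pd.DataFrame([dict(azimuth=10.0, elevation=5.0, gain=0.3)])
        out = vmf_kernel_smooth(df, kappa_smooth=4.0, grid_step=30.0)
        assert np.allclose(out["gain"], 0.3)

    def test_high_concentration_reproduces_sample(self):
        df = pd.DataFrame(
            [
                dict(azimuth=0.0, elevation=0.0, gain=0.1),
                dict(azimuth=90.0, elevation=0.0, gain=0.9),
            ]
        )
        out = vmf_kernel_smooth(
            df, kappa_smooth=500.0, grid=np.array([[0.0, 0.0]])
        )
        assert out["gain"].iloc[0] == pytest.approx(0.1, abs=1e-6)

    def test_antipodal_midpoint_average(self):
        df = pd.DataFrame(
            [
                dict(azimuth=90.0, elevation=0.0, gain=0.2),
                dict(azimuth=-90.0, elevation=0.0, gain=0.4),
            ]
        )
        out = vmf_kernel_smooth(df, kappa_smooth=2.0, grid=np.array([[0.0, 0.0]]))
        assert out["gain"].iloc[0] == pytest.approx(0.3)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            vmf_kernel_smooth(pd.DataFrame(columns=["azimuth", "elevation", "gain"]))


class TestArenaRotationCorrection:
    def test_mean_of_medians(self):
        o = pd.DataFrame([dict(azimuth=90.0, elevation=0.0, gain=g) for g in (0.1, 0.2, 0.3)])
        r = pd.DataFrame([dict(azimuth=-90.0, elevation=0.0, gain=g) for g in (0.3, 0.4, 0.5)])
        out = correct_arena_rotation(o, r)
        assert len(out) == 1
        assert out["gain"].iloc[0] == pytest.approx((0.2 + 0.4) / 2)

    def test_identical_tables_give_medians(self, centres):
        truth = default_truth()
        df = pd.DataFrame(
            [dict(azimuth=c.azimuth, elevation=c.elevation,
                  gain=float(vmf_sum_eval(truth.vmf, c))) for c in centres]
        )
        mirrored = df.copy()
        mirrored["azimuth"] = -mirrored["azimuth"]
        mirrored["elevation"] = -mirrored["elevation"]
        out = correct_arena_rotation(df, mirrored)
        assert out["matched"].all()
        merged = out.merge(df, on=["azimuth", "elevation"], suffixes=("", "_orig"))
        assert np.allclose(merged["gain"], merged["gain_orig"])

    def test_odd_bias_cancels(self, centres):
        truth = default_truth()
        base = {c.as_tuple(): float(vmf_sum_eval(truth.vmf, c)) for c in centres}
        bias = 0.07
        o = pd.DataFrame(
            [dict(azimuth=a, elevation=e, gain=g + bias) for (a, e), g in base.items()]
        )
        r = pd.DataFrame(
            [dict(azimuth=-a, elevation=-e, gain=base[(a, e)] - bias)
             for (a, e) in base]
        )
        out = correct_arena_rotation(o, r)
        for _, row in out.iterrows():
            assert row["gain"] == pytest.approx(base[(row.azimuth, row.elevation)], abs=1e-12)

    def test_unmatched_position_flagged(self):
        o = pd.DataFrame([dict(azimuth=10.0, elevation=0.0, gain=0.2)])
        r = pd.DataFrame([dict(azimuth=-20.0, elevation=0.0, gain=0.2)])
        out = correct_arena_rotation(o, r)
        assert not out["matched"].any()
        assert out["gain"].isna().all()


def _tuning_table(values_by_key, key):
    rows = []
    for (az, el) in [(-85.0, 0.0), (85.0, 0.0)]:
        for k, g in values_by_key.items():
            rows.append({"azimuth": az, "elevation": el, key: k, "gain": g})
    return pd.DataFrame(rows)


class TestFrequencyTuning:
    def test_log_gaussian_peak_recovered(self):
        freqs = np.array([0.005, 0.01, 0.02, 0.04, 0.08, 0.16, 0.32])
        gains = 0.3 * np.exp(-((np.log(freqs) - np.log(0.04)) ** 2) / (2 * 0.8**2))
        fit = FrequencyTuningModel(_tuning_table(dict(zip(freqs, gains)), "frequency")).fit()
        for peak, raw, flag in fit.per_location.values():
            assert 0.02 <= peak <= 0.08
            assert raw == pytest.approx(0.04)
            assert flag == ""

    def test_flat_gains_flagged(self):
        fit = FrequencyTuningModel(
            _tuning_table({0.01: 0.2, 0.04: 0.2, 0.16: 0.2}, "frequency")
        ).fit()
        for peak, _, flag in fit.per_location.values():
            assert flag == "flat" and math.isnan(peak)

    def test_monotone_gains_flagged_boundary(self):
        fit = FrequencyTuningModel(
            _tuning_table({0.01: 0.1, 0.04: 0.2, 0.16: 0.3}, "frequency")
        ).fit()
        for _, raw, flag in fit.per_location.values():
            assert flag == "boundary"
            assert raw == pytest.approx(0.16)

    def test_too_few_frequencies_rejected(self):
        with pytest.raises(ValueError):
            FrequencyTuningModel(_tuning_table({0.01: 0.1, 0.04: 0.2}, "frequency"))


class TestSizeTuning:
    sizes = np.array([0.008, 0.02, 0.05, 0.12, 0.25, 0.5, 1.0])

    @staticmethod
    def sigmoid(s, g_max=0.3, s50=0.25, w=0.5):
        return g_max / (1.0 + np.exp(-(np.log(s) - np.log(s50)) / w))

    def test_exact_s50_recovery(self):
        table = _tuning_table(dict(zip(self.sizes, self.sigmoid(self.sizes))), "size")
        fit = SizeTuningModel(table).fit()
        for g_max, s50, w, flag in fit.per_location.values():
            assert s50 == pytest.approx(0.25, abs=1e-3)
            assert g_max == pytest.approx(0.3, abs=1e-3)
            assert flag == ""

    def test_noisy_s50_recovery(self):
        # cohort design: 7 fish x 2 repetitions per size point, 20%-of-peak
        # gain noise; the fit averages within each (location, size) cell
        rng = np.random.default_rng(0)
        errs = []
        for _ in range(50):
            rows = []
            for s in self.sizes:
                for _f in range(14):
                    g = self.sigmoid(s) + rng.normal(0, 0.06)
                    rows.append(dict(azimuth=85.0, elevation=0.0, size=s,
                                     gain=max(g, 0.0)))
            fit = SizeTuningModel(pd.DataFrame(rows)).fit()
            for _, s50, _, _ in fit.per_location.values():
                errs.append(abs(math.log(s50) - math.log(0.25)))
        assert np.median(errs) < 0.2

    def test_flat_flagged(self):
        table = _tuning_table({s: 0.0 for s in self.sizes}, "size")
        fit = SizeTuningModel(table).fit()
        for g_max, s50, _, flag in fit.per_location.values():
            assert flag == "flat" and math.isnan(s50)

    def test_nonspanning_sizes_rejected(self):
        with pytest.raises(ValueError):
            SizeTuningModel(_tuning_table({0.2: 0.1, 0.3: 0.2, 0.4: 0.25, 0.5: 0.28}, "size"))


class TestDirectVisibility:
    def test_lateral_stimulus_direct_for_near_eye(self):
        assert direct_visibility(GeoCoord(90, 0), 20.0, "right") == "direct"

    def test_contralateral_stimulus_indirect(self):
        # angle from (-90, 0) to the right eye axis is ~170 deg > 163/2 + 20
        assert direct_visibility(GeoCoord(-90, 0), 20.0, "right") == "indirect"

    def test_full_surround_fov_always_direct(self):
        assert direct_visibility(GeoCoord(180, -80), 1.0, "left", fov=360.0) == "direct"

    def test_fov_validation(self):
        with pytest.raises(ValueError):
            direct_visibility(GeoCoord(0, 0), 10.0, "left", fov=0.0)


def test_vmf_model_json_round_trip():
    m = VmfModel(
        mu1=geo_to_unit(GeoCoord(-82.5, 5.1)),
        mu2=geo_to_unit(GeoCoord(81.7, 1.6)),
        kappa1=8.0, kappa2=4.0, C1=0.2, C2=0.3, C3=0.05,
    )
    back = VmfModel.from_dict(m.to_dict())
    pts = fibonacci_sphere(100)
    assert np.allclose(vmf_sum_eval(back, pts), vmf_sum_eval(m, pts), atol=1e-12)
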