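"""Projection, attenuation factors, MLEM reconstruction, dynamic simulation."""

import numpy as np
import pytest

import petacbias as pb
from petacbias import emission
from petacbias.acmaps import MuMap

from conftest import disk_image

PX_MM = 4.0  # tests use a 64-grid, 4 mm scale unless stated


class TestForwardProject:
    def test_zero_image(self):
        sino = pb.forward_project(np.zeros((64, 64)), PX_MM)
        assert np.all(sino.values == 0)
        assert sino.values.shape == (64, 180)

    def test_disk_central_chord(self):
        radius_px, value, px_mm = 40.0, 0.7, 2.0
        img = disk_image(128, radius_px, value)
        sino = pb.forward_project(img, px_mm)
        expected = 2 * radius_px * (px_mm / 10.0) * value  # 2 r v in cm
        central = sino.values[sino.values.shape[0] // 2]
        assert np.allclose(central, expected, rtol=0.02)
        assert central.mean() == pytest.approx(expected, rel=0.005)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a = disk_image(64, 15, 1.0) * rng.uniform(0.5, 1.5, (64, 64))
        b = disk_image(64, 10, 2.0)
        pa = pb.forward_project(a, PX_MM).values
        pb_ = pb.forward_project(b, PX_MM).values
        pab = pb.forward_project(a + b, PX_MM).values
        assert np.allclose(pab, pa + pb_, atol=1e-9)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            pb.forward_project(np.zeros((32, 64)), PX_MM)


class TestAttenuationFactors:
    def test_air_path_is_one(self):
        acf = pb.attenuation_factors(np.zeros((64, 64)), PX_MM)
        assert np.allclose(acf.values, 1.0)

    def test_water_disk_closed_form(self):
        # 10 cm water path: ACF = exp(0.96) ≈ 2.61
        px_mm = 2.0
        mu = disk_image(128, radius_px=50.0 / px_mm, value=0.096)
        acf = pb.attenuation_factors(mu, px_mm)
        central = acf.values[acf.values.shape[0] // 2]
        assert central.mean() == pytest.approx(np.exp(0.96), rel=0.02)
        assert np.allclose(central, np.exp(0.96), rtol=0.04)

    def test_acf_at_least_one_and_bone_monotone(self):
        mu = disk_image(64, 12, 0.096)
        acf0 = pb.attenuation_factors(mu, PX_MM)
        assert np.all(acf0.values >= 1.0)
        mu_bone = mu.copy()
        mu_bone[30:34, 20:24] = 0.17
        acf1 = pb.attenuation_factors(mu_bone, PX_MM)
        assert np.all(acf1.values >= acf0.values - 1e-12)


class TestEmissionSimulation:
    def test_no_attenuation_matches_projection(self):
        act = disk_image(64, 15, 3.0)
        sino = pb.simulate_emission_sinogram(act, np.zeros((64, 64)), PX_MM)
        proj = pb.forward_project(act, PX_MM)
        assert np.allclose(sino.values, proj.values)

    def test_noise_free_deterministic(self):
        act = disk_image(64, 15, 3.0)
        mu = disk_image(64, 18, 0.096)
        a = pb.simulate_emission_sinogram(act, mu, PX_MM, seed=1)
        b = pb.simulate_emission_sinogram(act, mu, PX_MM, seed=2)
        assert np.array_equal(a.values, b.values)

    def test_poisson_mean_matches_noise_free(self):
        act = disk_image(64, 15, 3.0)
        mu = disk_image(64, 18, 0.096)
        clean = pb.simulate_emission_sinogram(act, mu, PX_MM)
        total_counts = 2e4
        reps = 200
        totals = np.empty(reps)
        for i in range(reps):
            noisy = pb.simulate_emission_sinogram(
                act, mu, PX_MM, total_counts=total_counts, seed=i
            )
            totals[i] = noisy.values.sum()
        # aggregate totals: Poisson SE of the summed counts, back in data units
        scale = total_counts / clean.values.sum()
        se_total = np.sqrt(total_counts) / scale / np.sqrt(reps)
        assert abs(totals.mean() - clean.values.sum()) < 3 * se_total


class TestMlem:
    def test_matched_disk_recovers_interior(self):
        act = disk_image(64, 16, 2.5)
        mu = disk_image(64, 20, 0.096)
        acf = pb.attenuation_factors(mu, PX_MM)
        sino = pb.simulate_emission_sinogram(act, mu, PX_MM, acf_true=acf)
        rec = pb.mlem_reconstruct(sino, acf, pb.ReconSettings(), PX_MM)
        interior = disk_image(64, 10, 1.0) > 0  # away from the edge
        assert rec[interior].mean() == pytest.approx(2.5, rel=0.03)

    def test_zero_data_zero_image(self):
        acf = pb.attenuation_factors(disk_image(64, 20, 0.096), PX_MM)
        zero = emission.Sinogram(
            values=np.zeros((64, 180)), angles_deg=emission.projection_angles(), bin_mm=PX_MM
        )
        rec = pb.mlem_reconstruct(zero, acf, pb.ReconSettings(), PX_MM)
        assert np.all(rec == 0)

    def test_bone_free_acf_underestimates(self):
        # reconstructing with attenuation factors that ignore the bone ring
        # must underestimate interior activity
        act = disk_image(64, 14, 2.0)
        mu_true = disk_image(64, 20, 0.096)
        ring = disk_image(64, 20, 1.0) - disk_image(64, 17, 1.0)
        mu_true = mu_true + ring * (0.17 - 0.096)
        mu_nobone = disk_image(64, 20, 0.096)
        sino = pb.simulate_emission_sinogram(act, mu_true, PX_MM)
        acf_nobone = pb.attenuation_factors(mu_nobone, PX_MM)
        rec = pb.mlem_reconstruct(sino, acf_nobone, pb.ReconSettings(), PX_MM)
        interior = disk_image(64, 9, 1.0) > 0
        assert rec[interior].mean() < 2.0 * 0.97

    def test_nonnegativity(self):
        act = disk_image(64, 14, 2.0)
        mu = disk_image(64, 20, 0.096)
        acf = pb.attenuation_factors(mu, PX_MM)
        sino = pb.simulate_emission_sinogram(act, mu, PX_MM, total_counts=5e3, seed=0)
        for init in ("fbp", "uniform"):
            rec = pb.mlem_reconstruct(sino, acf, pb.ReconSettings(), PX_MM, init=init)
            assert np.all(rec >= 0)


@pytest.fixture(scope="module")
def short_schedule():
    return pb.FrameSchedule(
        start_min=np.array([0.0, 0.5, 1.0, 3.0, 6.0, 10.0]),
        end_min=np.array([0.5, 1.0, 3.0, 6.0, 10.0, 15.0]),
    )


class TestDynamicStudy:
    def test_matched_ac_small_bias(self, small_phantom, inputs, short_schedule):
        from scipy.ndimage import gaussian_filter

        truth_map = MuMap(mu=small_phantom.mu_true, method="truth")
        frames = pb.simulate_dynamic_study(
            small_phantom, inputs, short_schedule, truth_map, total_counts=None
        )
        act = pb.synth_dynamic_activity(small_phantom, inputs, short_schedule)
        sigma = 6.0 / 2.355 / small_phantom.spec.pixel_mm
        wb = small_phantom.voi_masks["WBGM"]
        for f in range(2, short_schedule.n_frames):
            ref = gaussian_filter(act[f], sigma)[wb].mean()
            assert frames[f][wb].mean() == pytest.approx(ref, rel=0.03)

    def test_bone_free_ac_cortical_gradient(self, small_phantom, inputs, short_schedule):
        pair = pb.synth_dixon_pair(small_phantom, noise_sd=0.0)
        mu_dixon = pb.dixon_standard_mu(pair)
        frames = pb.simulate_dynamic_study(
            small_phantom, inputs, short_schedule, mu_dixon, total_counts=None
        )
        truth_map = MuMap(mu=small_phantom.mu_true, method="truth")
        ref = pb.simulate_dynamic_study(
            small_phantom, inputs, short_schedule, truth_map, total_counts=None
        )
        f = short_schedule.n_frames - 1
        rel = {
            r: frames[f][m].mean() / ref[f][m].mean() - 1
            for r, m in small_phantom.voi_masks.items()
        }
        assert rel["SPL"] < rel["INS"] < 0  # cortical worse than deep, both low

    def test_frame_count_matches_schedule(self, small_phantom, inputs):
        sched = pb.default_frame_schedule()
        truth_map = MuMap(mu=small_phantom.mu_true, method="truth")
        frames = pb.simulate_dynamic_study(
            small_phantom, inputs, sched, truth_map,
            pb.ReconSettings(iterations=1, subsets=7, n_angles=28),
            total_counts=None,
        )
        assert frames.shape[0] == 18
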