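"""Phantom geometry, Dixon synthesis, input functions, dynamic activity."""

import numpy as np
import pytest
from scipy.ndimage import distance_transform_edt
from scipy.optimize import minimize_scalar

import petacbias as pb
from petacbias.phantom import InputFunctionParams, PhantomConfigError, Tissue


class TestGeometry:
    def test_border_is_air(self, head_phantom):
        lab = head_phantom.label_map
        for border in (lab[0], lab[-1], lab[:, 0], lab[:, -1]):
            assert np.all(border == Tissue.AIR)

    def test_skull_encloses_brain(self, head_phantom):
        # walking outward from any brain voxel along a row must cross bone
        lab = head_phantom.label_map
        brain_rows = np.unique(np.nonzero(head_phantom.brain_mask)[0])
        for r in brain_rows[:: max(1, brain_rows.size // 8)]:
            cols = np.nonzero(head_phantom.brain_mask[r])[0]
            assert Tissue.BONE in lab[r, cols[-1]: ]
            assert Tissue.BONE in lab[r, : cols[0] + 1]

    def test_voi_bone_distances(self, head_phantom, default_spec):
        # independent oracle: recompute the distance transform on the label map
        bone = head_phantom.label_map == Tissue.BONE
        dist_mm = distance_transform_edt(~bone, sampling=default_spec.pixel_mm)
        assert np.all(dist_mm[head_phantom.voi_masks["SPL"]] <= 6.0)
        assert np.all(dist_mm[head_phantom.voi_masks["INS"]] >= 20.0)

    def test_vois_inside_brain(self, head_phantom):
        for mask in head_phantom.voi_masks.values():
            assert np.all(head_phantom.brain_mask[mask])

    def test_mu_and_hu_values(self, head_phantom, default_spec):
        lab = head_phantom.label_map
        assert np.all(head_phantom.mu_true >= 0)
        assert np.all(head_phantom.mu_true[lab == Tissue.AIR] == 0)
        assert np.all(head_phantom.hu_map[lab == Tissue.AIR] == -1000)
        assert np.all(head_phantom.hu_map[lab == Tissue.BONE] == default_spec.skull_hu)

    def test_custom_skull_hu_assignment(self):
        subj = pb.build_head_phantom(pb.PhantomSpec(skull_hu=1500.0))
        assert np.all(subj.hu_map[subj.label_map == Tissue.BONE] == 1500.0)

    def test_ill_ordered_ellipses_rejected(self):
        with pytest.raises(PhantomConfigError):
            pb.PhantomSpec(skull_outer=(90.0, 70.0))  # inside skull_inner
        with pytest.raises(PhantomConfigError):
            pb.PhantomSpec(grid_size=63)

    def test_geometry_deterministic(self, default_spec, head_phantom):
        again = pb.build_head_phantom(default_spec)
        assert np.array_equal(again.label_map, head_phantom.label_map)
        assert np.array_equal(again.mu_true, head_phantom.mu_true)


class TestDixonSynthesis:
    def test_pure_voxel_algebra(self, head_phantom):
        pair = pb.synth_dixon_pair(head_phantom, noise_sd=0.0)
        fat, water = pair.fat_water()
        gray = head_phantom.label_map == Tissue.GRAY
        # in = W + F and opp = F - W by construction
        assert np.allclose(pair.in_phase[gray], water[gray] + fat[gray])
        assert np.allclose(pair.opp_phase[gray], fat[gray] - water[gray])
        fat_ring = head_phantom.label_map == Tissue.FAT
        assert np.all(pair.opp_phase[fat_ring] > 0)  # fat-dominant
        assert np.all(pair.opp_phase[gray] < 0)  # water-dominant

    def test_inversion_changes_only_labels(self, head_phantom):
        a = pb.synth_dixon_pair(head_phantom, inverted=False, noise_sd=0.0)
        b = pb.synth_dixon_pair(head_phantom, inverted=True, noise_sd=0.0)
        assert np.array_equal(a.in_phase, b.in_phase)
        assert np.array_equal(a.opp_phase, b.opp_phase)
        assert a.vendor_inverted != b.vendor_inverted

    def test_noise_seed_reproducible(self, head_phantom):
        a = pb.synth_dixon_pair(head_phantom, noise_sd=0.02, seed=3)
        b = pb.synth_dixon_pair(head_phantom, noise_sd=0.02, seed=3)
        c = pb.synth_dixon_pair(head_phantom, noise_sd=0.02, seed=4)
        assert np.array_equal(a.in_phase, b.in_phase)
        assert not np.array_equal(a.in_phase, c.in_phase)

    def test_negative_noise_rejected(self, head_phantom):
        with pytest.raises(ValueError):
            pb.synth_dixon_pair(head_phantom, noise_sd=-0.1)


class TestInputFunctions:
    def test_zero_before_bolus(self, inputs):
        pre = inputs.t_min <= InputFunctionParams().tau_min
        assert np.all(inputs.c_plasma_total[pre] == 0)
        assert np.all(inputs.c_wholeblood[inputs.t_min == 0] == 0)

    def test_parent_fraction_monotone_from_one(self, inputs):
        assert inputs.parent_fraction[0] == pytest.approx(1.0)
        assert np.all(np.diff(inputs.parent_fraction) <= 0)
        assert np.all(inputs.c_plasma_parent <= inputs.c_plasma_total + 1e-12)

    def test_parent_is_total_times_fraction(self, inputs):
        assert np.allclose(
            inputs.c_plasma_parent, inputs.c_plasma_total * inputs.parent_fraction
        )

    def test_peak_time_matches_closed_form(self, inputs):
        # oracle: maximize the continuous tri-exponential directly
        p = InputFunctionParams()

        def neg_cp(u):
            return -(
                (p.A1 * u - p.A2 - p.A3) * np.exp(p.lam1 * u)
                + p.A2 * np.exp(p.lam2 * u)
                + p.A3 * np.exp(p.lam3 * u)
            )

        res = minimize_scalar(neg_cp, bounds=(0.01, 5.0), method="bounded")
        t_peak_grid = inputs.t_min[np.argmax(inputs.c_plasma_total)] - p.tau_min
        assert t_peak_grid == pytest.approx(res.x, abs=2.0 / 60.0)
        assert 0.3 <= t_peak_grid <= 2.0

    def test_positive_decay_rates_rejected(self):
        with pytest.raises(PhantomConfigError):
            InputFunctionParams(lam1=0.5)

    def test_coarse_grid_rejected(self):
        with pytest.raises(PhantomConfigError):
            InputFunctionParams(dt_s=5.0)


class TestDynamicActivity:
    def test_zero_kinetics_region_is_zero(self, head_phantom, inputs, schedule):
        act = pb.synth_dynamic_activity(head_phantom, inputs, schedule)
        bone = head_phantom.label_map == Tissue.BONE
        air = head_phantom.label_map == Tissue.AIR
        assert np.all(act[:, bone] == 0)
        assert np.all(act[:, air] == 0)
        assert np.all(np.isfinite(act)) and np.all(act >= 0)

    def test_frames_match_model_tac(self, head_phantom, inputs, schedule):
        act = pb.synth_dynamic_activity(head_phantom, inputs, schedule)
        gray_params = head_phantom.kinetics_by_tissue[Tissue.GRAY]
        expected = pb.model_tac(gray_params, inputs, schedule)
        gray = head_phantom.label_map == Tissue.GRAY
        assert np.allclose(act[:, gray], expected[:, None])

    def test_constant_input_equilibrium(self, head_phantom):
        # closed-form limit: value -> VT*c*(1-Vb) + Vb*c_wb for constant input
        t = np.arange(0, 300.0 + 1e-9, 1.0 / 60.0)
        c = 5.0
        const = pb.InputFunctionSet(
            t_min=t,
            c_plasma_total=np.full_like(t, c),
            parent_fraction=np.ones_like(t),
            c_wholeblood=np.full_like(t, c),
        )
        sched = pb.FrameSchedule(start_min=np.array([0.0, 290.0]), end_min=np.array([290.0, 300.0]))
        act = pb.synth_dynamic_activity(head_phantom, const, sched)
        p = head_phantom.kinetics_by_tissue[Tissue.GRAY]
        expected = p.VT * c * (1 - p.Vb) + p.Vb * c
        gray_val = act[-1][head_phantom.label_map == Tissue.GRAY][0]
        assert gray_val == pytest.approx(expected, rel=1e-3)

    def test_missing_region_parameters_error(self, head_phantom, inputs, schedule):
        broken = pb.SubjectPhantom(
            spec=head_phantom.spec,
            label_map=head_phantom.label_map,
            mu_true=head_phantom.mu_true,
            hu_map=head_phantom.hu_map,
            voi_masks=head_phantom.voi_masks,
            kinetics_by_tissue={},
        )
        with pytest.raises(KeyError):
            pb.synth_dynamic_activity(broken, inputs, schedule)
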