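"""Phantom construction, forward signal model, and study assembly."""

import numpy as np
import pytest

from oemri import (
    AcquisitionProtocol,
    StudySpec,
    challenged_phantom_spec,
    control_phantom_spec,
    make_phantom,
    make_study,
    simulate_signal,
)
from oemri.synthetic import ir_magnitude_signal, make_lung_mask

from .conftest import small_study_spec


class TestPhantom:
    def test_control_moments_match_template(self):
        """In-mask mean/SD reproduce the group values (within-animal moments
        are exact by construction)."""
        gt = make_phantom(control_phantom_spec(seed=1))
        m = gt.mask
        assert abs(gt.s0_air[m].mean() - 3.29) < 1e-9
        assert abs(gt.s0_air[m].std() - 0.62) < 1e-9
        assert abs(gt.r1_air[m].mean() - 0.557) < 1e-9
        assert abs(gt.delta_r1[m].mean() - 0.024) < 1e-9
        # within 20% of the challenged/control heterogeneity target
        assert abs(gt.delta_r1[m].std() - 0.094) < 0.2 * 0.094
        assert abs(gt.delta_r2star[m].std() - 0.205) < 1e-9

    def test_degenerate_constant_phantom(self):
        spec = control_phantom_spec(
            seed=2,
            sd_s0_air=0.0,
            sd_r1_air=0.0,
            sd_delta_r1=0.0,
            sd_delta_r2star=0.0,
            density_uptake_slope=0.0,
            uptake_delivery_slope=0.0,
        )
        gt = make_phantom(spec)
        m = gt.mask
        assert np.all(gt.s0_air[m] == 3.29)
        assert np.all(gt.r1_air[m] == 0.557)
        assert np.all(gt.delta_r1[m] == 0.024)
        assert np.all(gt.delta_r2star[m] == 0.071)

    def test_r1_air_independent_of_density(self):
        """Baseline R1 carries no density dependence (flat across densities)."""
        gt = make_phantom(control_phantom_spec(seed=3))
        m = gt.mask
        r = np.corrcoef(gt.s0_air[m], gt.r1_air[m])[0, 1]
        assert abs(r) < 0.2

    def test_challenged_has_wider_density_and_uptake_range(self):
        c = make_phantom(control_phantom_spec(seed=4))
        p = make_phantom(challenged_phantom_spec(seed=4))
        assert p.s0_air[p.mask].std() > c.s0_air[c.mask].std()
        assert np.ptp(p.delta_r1[p.mask]) > np.ptp(c.delta_r1[c.mask])

    def test_mask_size_near_target(self):
        mask = make_lung_mask((64, 64), 1200)
        assert abs(int(mask.sum()) - 1200) < 0.15 * 1200

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            make_lung_mask((8, 8), 1200)

    def test_infeasible_variance_budget_rejected(self):
        with pytest.raises(ValueError, match="density_uptake_slope"):
            control_phantom_spec(density_uptake_slope=1.0)  # 1.0*0.62 > 0.094


class TestSignalModel:
    def test_no_inversion_gives_flat_signal(self, noiseless_protocol):
        ti = np.array(noiseless_protocol.inversion_times)
        s = ir_magnitude_signal(ti, 3.29, 0.0, 0.557)
        np.testing.assert_allclose(s, 3.29)

    def test_null_point(self):
        # TI = ln(2)/R1 nulls the perfect-inversion signal
        s = ir_magnitude_signal(np.array([1386.0]), 1.0, 2.0, 0.5)
        assert abs(s[0]) < 1e-3

    def test_no_full_relaxation_at_last_ti(self):
        """At TI = 6 s the control-lung curve reaches only ~93% of S0, so
        S0 must be estimated, never read off the last image."""
        s = ir_magnitude_signal(np.array([6000.0]), 1.0, 2.0, 0.557)
        expected = 1.0 - 2.0 * np.exp(-0.557 * 6.0)
        assert abs(s[0] - expected) < 1e-12
        assert s[0] < 0.95

    def test_oxygen_attenuation_and_inverse(self, noiseless_protocol):
        """The simulator's S0 attenuation is exactly inverted by the dR2*
        formula ln(S0_air/S0_O2)/TE."""
        from oemri import delta_r2star

        dr2s_true = 0.090  # ms^-1, challenged-group delivery level
        te = noiseless_protocol.echo_time
        s0_air = 2.90
        s0_o2 = s0_air * np.exp(-dr2s_true * te)
        assert abs(s0_o2 / s0_air - np.exp(-0.045)) < 1e-15
        recovered = delta_r2star(np.array([s0_air]), np.array([s0_o2]), te)
        assert abs(recovered[0] - dr2s_true) < 1e-12

    def test_simulated_images_nonnegative_and_background_is_noise(self, default_protocol):
        gt = make_phantom(control_phantom_spec(seed=6, grid_shape=(24, 24), n_pixels_target=120))
        series = simulate_signal(gt, default_protocol, seed=7)
        for stack in series.images.values():
            assert np.all(stack >= 0)
            bg = stack[:, ~gt.mask]
            assert 0 < bg.mean() < 3 * default_protocol.noise_sigma

    def test_rician_noise_model(self, default_protocol):
        gt = make_phantom(control_phantom_spec(seed=6, grid_shape=(24, 24), n_pixels_target=120))
        series = simulate_signal(gt, default_protocol, seed=7, noise_model="rician")
        assert all(np.all(s >= 0) for s in series.images.values())

    def test_unknown_noise_model_rejected(self, default_protocol):
        gt = make_phantom(control_phantom_spec(seed=6, grid_shape=(24, 24), n_pixels_target=120))
        with pytest.raises(ValueError):
            simulate_signal(gt, default_protocol, seed=1, noise_model="uniform")


class TestStudy:
    def test_default_study_design(self):
        study = make_study(StudySpec(master_seed=1), simulate=False)
        groups = [gt.group for gt, _ in study]
        assert len(study) == 17
        assert groups.count("control") == 9
        assert groups.count("challenged") == 8
        assert len({gt.animal_id for gt, _ in study}) == 17

    def test_determinism(self):
        spec = small_study_spec(seed=42, n_pixels=80, grid=24)
        s1 = make_study(spec)
        s2 = make_study(spec)
        for (gt1, se1), (gt2, se2) in zip(s1, s2):
            np.testing.assert_array_equal(gt1.s0_air, gt2.s0_air)
            np.testing.assert_array_equal(gt1.delta_r2star, gt2.delta_r2star)
            for state in se1.images:
                np.testing.assert_array_equal(se1.images[state], se2.images[state])

    def test_single_group_study_allowed(self):
        study = make_study(StudySpec(n_challenged=0, master_seed=1), simulate=False)
        assert len(study) == 9
        assert all(gt.group == "control" for gt, _ in study)

    def test_uptake_delivery_correlation_per_group(self):
        """Pooled (dR2*, dR1) scatter is linear with positive slope in both
        groups on noiseless ground truth."""
        study = make_study(small_study_spec(seed=9), simulate=False)
        for group in ("control", "challenged"):
            dr1 = np.concatenate(
                [gt.delta_r1[gt.mask] for gt, _ in study if gt.group == group]
            )
            dr2s = np.concatenate(
                [gt.delta_r2star[gt.mask] for gt, _ in study if gt.group == group]
            )
            r = np.corrcoef(dr2s, dr1)[0, 1]
            assert r > 0.9
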