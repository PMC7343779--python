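"""Laplace potential, streamline profiles, and the profile metrics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cortexdti import cortical_profiles as cp
from cortexdti import synthetic_data as sd
from cortexdti.errors import ContractError, ParameterError, TopologyError
from cortexdti.regions import LABEL_PIAL, LABEL_WHITE


class TestPotential:
    def test_slab_potential_is_linear(self, slab_phantom):
        ribbon, _, _ = slab_phantom
        pot = cp.solve_ribbon_potential(ribbon)
        z = np.indices(ribbon.labels.shape)[2]
        gm = ribbon.gm_mask
        # ribbon occupies z in [2, 8); 1-D Laplace solution is linear with
        # Dirichlet values attained at the boundary voxel layers
        for zz in range(2, 8):
            expected = (zz - 1) / 7.0
            vals = pot[gm & (z == zz)]
            assert np.abs(vals - expected).max() < 1e-4

    def test_shell_potential_matches_spherical_closed_form(self, shell_phantom):
        ribbon, _, _ = shell_phantom
        pot = cp.solve_ribbon_potential(ribbon)
        centre = (np.array(ribbon.labels.shape) - 1) / 2.0
        idx = np.argwhere(np.isfinite(pot) & ribbon.gm_mask)
        r = np.linalg.norm(idx - centre, axis=1)
        r0, r1 = 10.0, 16.0
        analytic = (1 / r0 - 1 / r) / (1 / r0 - 1 / r1)
        mid = np.abs(r - (r0 + r1) / 2) < 0.5
        err = np.abs(pot[tuple(idx[mid].T)] - analytic[mid])
        assert err.max() < 0.02

    def test_potential_bounded_no_interior_extrema(self, shell_phantom):
        ribbon, _, _ = shell_phantom
        pot = cp.solve_ribbon_potential(ribbon)
        vals = pot[np.isfinite(pot) & ribbon.gm_mask]
        assert vals.min() > -1e-9 and vals.max() < 1 + 1e-9

    def test_missing_boundaries_is_topology_error(self):
        labels = np.full((8, 8, 8), 11)  # all GM, no white/pial labels
        ribbon = cp.RibbonLabels(labels=labels, affine=np.eye(4),
                                 region_map={11: "phantom_left"})
        with pytest.raises(TopologyError):
            cp.solve_ribbon_potential(ribbon)


class TestTraceProfiles:
    def test_slab_profiles_are_straight_normal_segments(self, slab_phantom):
        ribbon, _, _ = slab_phantom
        pot = cp.solve_ribbon_potential(ribbon)
        profiles, drops = cp.trace_profiles(pot, ribbon, step_h=0.5)
        assert len(profiles) > 500
        assert sum(drops.values()) == 0
        for p in profiles[::25]:
            assert np.allclose(p.tangents, [0, 0, 1], atol=1e-6)
            assert abs(p.length - 6.0) <= 1.0  # ribbon spans ~6 voxels of 1 mm

    def test_shell_tangents_are_radial(self, shell_phantom):
        ribbon, _, _ = shell_phantom
        pot = cp.solve_ribbon_potential(ribbon)
        profiles, _ = cp.trace_profiles(pot, ribbon, step_h=0.5)
        centre = (np.array(ribbon.labels.shape) - 1) / 2.0
        for p in profiles:
            rvec = p.points - centre
            rhat = rvec / np.linalg.norm(rvec, axis=1, keepdims=True)
            assert np.abs((p.tangents * rhat).sum(axis=1)).min() > 0.99

    def test_unreachable_seed_is_dropped_and_logged(self):
        # a slab plus an isolated white+GM pair with no pial connection
        labels = np.zeros((20, 8, 12), dtype=int)
        labels[:10, :, 0:2] = LABEL_WHITE
        labels[:10, :, 2:6] = 11
        labels[:10, :, 6:8] = LABEL_PIAL
        labels[15, 4, 2] = LABEL_WHITE
        labels[15, 4, 3] = 11
        ribbon = cp.RibbonLabels(labels=labels, affine=np.eye(4),
                                 region_map={11: "phantom_left"})
        pot = cp.solve_ribbon_potential(ribbon)
        assert np.isnan(pot[15, 4, 3])
        profiles, drops = cp.trace_profiles(pot, ribbon)
        assert drops["unreachable_seed"] == 1
        seeds = {tuple(np.round(p.points[0]).astype(int)) for p in profiles}
        assert (15, 4, 3) not in seeds

    def test_invalid_step_rejected(self, slab_phantom):
        ribbon, _, _ = slab_phantom
        pot = cp.solve_ribbon_potential(ribbon)
        with pytest.raises(ParameterError):
            cp.trace_profiles(pot, ribbon, step_h=0.0)


class TestAngleOps:
    def test_angle_parallel_orthogonal_antiparallel(self):
        z = np.array([0.0, 0.0, 1.0])
        x = np.array([1.0, 0.0, 0.0])
        assert cp.angle_r(z, z) == 0.0
        assert np.isclose(cp.angle_r(x, z), np.pi / 2)
        assert cp.angle_r(-z, z) == 0.0

    def test_zero_vector_rejected(self):
        with pytest.raises(ContractError):
            cp.angle_r(np.zeros(3), np.array([0.0, 0.0, 1.0]))

    def test_angle_invariant_to_joint_rotation_and_sign(self, rng):
        """AngleR depends only on the relative orientation of e1 and the
        tangent, so a rigid rotation applied to both leaves it unchanged,
        as does flipping the eigenvector sign."""
        for _ in range(50):
            v = rng.standard_normal(3)
            w = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            w /= np.linalg.norm(w)
            R = Rotation.random(rng=rng).as_matrix()
            a = cp.angle_r(v, w)
            assert abs(cp.angle_r(R @ v, R @ w) - a) < 1e-6
            assert abs(cp.angle_r(-v, w) - a) < 1e-12

    @pytest.mark.parametrize(
        "angle, perp, parl",
        [(0.0, 0.0, 1.0), (np.pi / 2, 1.0, 0.0),
         (np.pi / 4, np.sqrt(0.5), np.sqrt(0.5))],
    )
    def test_perp_parl_projections(self, angle, perp, parl):
        got_perp, got_parl = cp.perp_parl(1.0e-3, angle)
        assert np.isclose(got_perp, perp, atol=1e-12)
        assert np.isclose(got_parl, parl, atol=1e-12)

    def test_perp_parl_conserves_principal_magnitude(self, rng):
        """PerpPD^2 + ParlPD^2 equals the (scaled) squared principal
        eigenvalue at every sample."""
        for _ in range(200):
            lam = rng.uniform(1e-4, 3e-3)
            ang = rng.uniform(0, np.pi / 2)
            perp, parl = cp.perp_parl(lam, ang)
            assert np.isclose(perp**2 + parl**2, (1e3 * lam) ** 2, rtol=1e-10)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ContractError):
            cp.perp_parl(-1e-3, 0.1)


class TestSampleMetrics:
    def test_tilted_slab_recovers_exact_angle(self, slab_phantom):
        ribbon, tensors, truth = slab_phantom
        pot = cp.solve_ribbon_potential(ribbon)
        profiles, _ = cp.trace_profiles(pot, ribbon)
        metrics = [cp.sample_profile_metrics(p, tensors) for p in profiles]
        angles = np.array([m.angle_r for m in metrics])
        assert np.abs(angles - np.pi / 6).max() < 1e-3

    def test_radial_shell_profiles_have_small_angle(self, shell_phantom):
        ribbon, tensors, _ = shell_phantom
        pot = cp.solve_ribbon_potential(ribbon)
        profiles, _ = cp.trace_profiles(pot, ribbon)
        metrics = [cp.sample_profile_metrics(p, tensors) for p in profiles]
        assert np.mean([m.angle_r for m in metrics]) < 0.05

    def test_isotropic_field_excludes_angle_keeps_md_fa(self, slab_phantom):
        ribbon, tensors, _ = slab_phantom
        iso = np.zeros_like(tensors.D)
        iso[..., [0, 2, 5]] = 1e-3  # Dxx = Dyy = Dzz
        tensors_iso = type(tensors)(D=iso, S0=tensors.S0, affine=tensors.affine,
                                    mask=tensors.mask, degenerate=tensors.degenerate)
        pot = cp.solve_ribbon_potential(ribbon)
        profiles, _ = cp.trace_profiles(pot, ribbon)
        m = cp.sample_profile_metrics(profiles[0], tensors_iso)
        assert m.n_angle_excluded == m.n_samples
        assert np.isnan(m.angle_r)
        assert np.isclose(m.fa, 0.0, atol=1e-12)
        assert np.isclose(m.md, 1.0, rtol=1e-12)  # 1e-3 mm^2/s in report units

    def test_all_degenerate_marks_profile_missing(self, slab_phantom):
        ribbon, tensors, _ = slab_phantom
        bad = type(tensors)(D=tensors.D, S0=tensors.S0, affine=tensors.affine,
                            mask=tensors.mask,
                            degenerate=np.ones_like(tensors.degenerate))
        pot = cp.solve_ribbon_potential(ribbon)
        profiles, _ = cp.trace_profiles(pot, ribbon)
        m = cp.sample_profile_metrics(profiles[0], bad)
        assert m.missing and m.n_samples == 0


class TestAggregate:
    @staticmethod
    def _pm(angle, region):
        return cp.ProfileMetrics(angle_r=angle, perp_pd=0.5, parl_pd=0.5,
                                 md=0.7, fa=0.2, n_samples=5,
                                 n_angle_excluded=0, region_code=region)

    def test_region_mean_of_two_profiles(self):
        table = cp.aggregate_regions([self._pm(0.4, 11), self._pm(0.6, 11)],
                                     {11: "phantom_left"})
        assert np.isclose(table.loc["phantom_left", "AngleR"], 0.5)

    def test_whole_brain_is_profile_level_mean(self):
        ms = [self._pm(0.4, 11), self._pm(0.6, 12), self._pm(0.8, 12)]
        table = cp.aggregate_regions(ms, {11: "A", 12: "B"})
        assert np.isclose(table.loc["A", "AngleR"], 0.4)
        assert np.isclose(table.loc["B", "AngleR"], 0.7)
        assert np.isclose(table.loc["whole_brain", "AngleR"], 0.6)
        # region-level averaging mode
        table_r = cp.aggregate_regions(ms, {11: "A", 12: "B"}, whole_brain="regions")
        assert np.isclose(table_r.loc["whole_brain", "AngleR"], 0.55)

    def test_empty_region_carries_missing_marker(self):
        table = cp.aggregate_regions([self._pm(0.4, 11)], {11: "A", 12: "B"})
        assert np.isnan(table.loc["B", "AngleR"])
        assert table.loc["B", "n_profiles"] == 0

    def test_empty_input_is_an_error(self):
        with pytest.raises(ContractError):
            cp.aggregate_regions([], {11: "A"})

    def test_whole_brain_matches_brute_force_recomputation(self, slab_phantom):
        ribbon, tensors, _ = slab_phantom
        pot = cp.solve_ribbon_potential(ribbon)
        profiles, _ = cp.trace_profiles(pot, ribbon)
        metrics = [cp.sample_profile_metrics(p, tensors) for p in profiles]
        table = cp.aggregate_regions(metrics, ribbon.region_map)
        brute = np.mean([m.angle_r for m in metrics if not m.missing])
        assert np.isclose(table.loc["whole_brain", "AngleR"], brute, rtol=1e-12)
        lo = min(m.angle_r for m in metrics)
        hi = max(m.angle_r for m in metrics)
        assert lo - 1e-12 <= table.loc["whole_brain", "AngleR"] <= hi + 1e-12


class TestPhantomRecovery:
    def test_angle_and_projection_monotonicity_in_true_tilt(self):
        """Increasing the true tilt strictly increases whole-brain AngleR
        and PerpPD and decreases ParlPD on matched-seed phantoms."""
        wb = []
        for theta in (0.0, 15.0, 30.0, 45.0):
            spec = sd.PhantomSpec(geometry="slab", shape=(20, 20, 16),
                                  theta_deg=theta, sigma_deg=5.0, seed=99)
            ribbon, tensors, _ = sd.make_phantom(spec)
            pot = cp.solve_ribbon_potential(ribbon)
            profiles, _ = cp.trace_profiles(pot, ribbon)
            metrics = [cp.sample_profile_metrics(p, tensors) for p in profiles]
            table = cp.aggregate_regions(metrics, ribbon.region_map)
            wb.append(table.loc["whole_brain"])
        angles = [row["AngleR"] for row in wb]
        perps = [row["PerpPD"] for row in wb]
        parls = [row["ParlPD"] for row in wb]
        assert all(a < b for a, b in zip(angles, angles[1:]))
        assert all(a < b for a, b in zip(perps, perps[1:]))
        assert all(a > b for a, b in zip(parls, parls[1:]))
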