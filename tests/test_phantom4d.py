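"""Phantom geometry, motion model and attenuation evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coromct.errors import InvalidParameterError
from coromct.grids import GridSpec, Volume
from coromct.phantom4d import (PhantomSpec, PhantomState, attenuation_at,
                               cardiac_phase, default_coronary_tree,
                               instantiate, instantiate_phases, static_spec,
                               voxelize)
from coromct.units import MU_WATER, hu_to_mu, mu_to_hu


class TestCardiacPhase:
    @pytest.mark.parametrize("t, rate, expected", [
        (0.0, 600.0, 0.0),
        (0.1, 600.0, 0.0),       # exactly one 100 ms cycle
        (0.025, 600.0, 0.25),
    ])
    def test_examples(self, t, rate, expected):
        assert cardiac_phase(t, rate) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            cardiac_phase(1.0, 0.0)

    @given(t=st.floats(0, 100), k=st.integers(1, 50),
           rate=st.floats(100, 1000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_periodicity(self, t, k, rate):
        p0 = cardiac_phase(t, rate)
        p1 = cardiac_phase(t + k * 60.0 / rate, rate)
        d = abs(p1 - p0)
        assert min(d, 1 - d) < 1e-6 * k


class TestSpecValidation:
    def test_axes_ordering_enforced(self):
        with pytest.raises(InvalidParameterError):
            PhantomSpec(heart_long_axis=3.0, heart_short_axis=4.0)

    def test_yaml_round_trip(self, tmp_path):
        spec = PhantomSpec(heart_rate=587.0, blood_enhancement=550.0)
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        back = PhantomSpec.from_yaml(path)
        assert back == spec


class TestMotionModel:
    def test_static_spec_time_invariant(self):
        spec = static_spec()
        rng = np.random.default_rng(0)
        pts = rng.uniform(-5, 5, (3000, 3))
        a = attenuation_at(instantiate(spec, 0.0), pts)
        b = attenuation_at(instantiate(spec, 0.123), pts)
        np.testing.assert_array_equal(a, b)

    def test_cardiac_periodicity_without_respiration(self):
        spec = PhantomSpec(resp_amplitude=0.0, resp_ap_expansion=0.0)
        rng = np.random.default_rng(1)
        pts = rng.uniform(-5, 5, (3000, 3))
        t = 0.0137
        period = 60.0 / spec.heart_rate
        a = attenuation_at(instantiate(spec, t), pts)
        for k in (1, 3):
            b = attenuation_at(instantiate(spec, t + k * period), pts)
            np.testing.assert_allclose(a, b, atol=1e-9)

    def test_myocardial_volume_conserved_over_cycle(self):
        """Wall thickening in systole conserves the shell volume within 2%
        (dense-grid integration oracle)."""
        spec = PhantomSpec()
        mu_myo = hu_to_mu(spec.myocardium_hu)

        def shell_volume(c):
            state = instantiate_phases(spec, c, 0.7)
            g = np.linspace(-2.5, 2.5, 120)
            z = np.linspace(-5, 5, 240)
            X, Y, Z = np.meshgrid(g, g, z, indexing="ij")
            mu = attenuation_at(state, np.stack([X, Y, Z], -1).reshape(-1, 3))
            dv = (g[1] - g[0]) ** 2 * (z[1] - z[0])
            return np.isclose(mu, mu_myo).sum() * dv

        v0 = shell_volume(0.0)
        v1 = shell_volume(0.4 * spec.waveform_duty)  # near peak systole
        assert abs(v1 - v0) / v0 < 0.02

    def test_coronary_diameters_rigid_over_time(self):
        """Coronary diameters are rigid properties of the tree: the ostium
        is defined at 400 um and every capsule-segment radius is identical
        at all time points even though the centerline moves."""
        spec = PhantomSpec()
        assert default_coronary_tree(spec)[0].diameter[0] * 1000 \
            == pytest.approx(spec.coronary_ostium_diameter)
        radii_per_t = []
        for t in (0.0, 0.02, 0.05, 0.09):
            state = instantiate(spec, t)
            chain = next(p for p in state.primitives
                         if p.label == "coronary-tree")
            radii_per_t.append([s[2] for s in chain.segments])
        for radii in radii_per_t[1:]:
            np.testing.assert_allclose(radii, radii_per_t[0], rtol=1e-12)

    def test_nesting_consistency_over_cycle(self):
        """Primitives are nested/disjoint by construction: the priority
        evaluation and the additive host-contrast evaluation agree, which is
        what makes the analytic line integrals exact."""
        spec = PhantomSpec()
        rng = np.random.default_rng(2)
        pts = rng.uniform(-7, 7, (40000, 3))
        for t in np.linspace(0, 0.102, 7):
            state = instantiate(spec, t)
            mu_prio = attenuation_at(state, pts)
            mu_add = np.zeros(len(pts))
            for p in state.primitives:
                mu_add += (p.mu - p.host_mu) * p.contains(pts)
            np.testing.assert_allclose(mu_prio, mu_add, atol=1e-9)


class TestCoronaryTree:
    def test_taper_monotone_and_span(self):
        spec = PhantomSpec()
        tree = default_coronary_tree(spec)
        trunk_to_apex = np.concatenate([tree[0].diameter, tree[1].diameter])
        assert np.all(np.diff(trunk_to_apex) <= 1e-12)
        d_um = trunk_to_apex * 1000
        assert d_um.max() == pytest.approx(spec.coronary_ostium_diameter)
        assert d_um.min() == pytest.approx(0.5 * spec.coronary_mean_diameter)


class TestAttenuation:
    def test_priority_and_background(self):
        spec = PhantomSpec()
        state = instantiate_phases(spec, 0.0, 0.7)
        pts = np.array([
            [-0.55, 0.0, -0.25],     # LV blood-pool center
            [4.0, 3.0, 0.0],         # inside body, outside heart
            [20.0, 0.0, 0.0],        # outside everything (air)
        ])
        mu = attenuation_at(state, pts)
        assert mu[0] == pytest.approx(hu_to_mu(spec.blood_enhancement))
        assert mu[1] == pytest.approx(hu_to_mu(spec.background_hu))
        assert mu[2] == 0.0

    def test_rejects_non_finite_points(self):
        state = instantiate(PhantomSpec(), 0.0)
        with pytest.raises(InvalidParameterError):
            attenuation_at(state, np.array([[np.nan, 0, 0]]))

    @given(hu=st.floats(-1000, 3000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_hu_mu_round_trip(self, hu):
        assert mu_to_hu(hu_to_mu(hu)) == pytest.approx(hu, abs=1e-9)

    def test_chords_match_dense_sampling(self):
        """Analytic ray-primitive intersection lengths agree with a dense
        point-sampling oracle for every primitive kind."""
        state = instantiate(PhantomSpec(), 0.033)
        rng = np.random.default_rng(3)
        n = 40
        o = np.tile(np.array([-25.0, 0, 0]), (n, 1))
        o[:, 1] = rng.uniform(-2, 2, n)
        o[:, 2] = rng.uniform(-4, 4, n)
        d = rng.normal(0, 0.08, (n, 3))
        d[:, 0] = 1.0
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        ts = np.arange(0, 60, 0.001)
        for prim in state.primitives:
            ana = prim.chords(o, d)
            for i in range(0, n, 7):
                num = prim.contains(o[i] + ts[:, None] * d[i]).sum() * 0.001
                assert abs(num - ana[i]) < 5e-3


class TestVoxelize:
    def test_nifti_round_trip(self, tmp_path):
        state = instantiate_phases(PhantomSpec(), 0.5, 0.7)
        grid = GridSpec((24, 24, 24), 0.4)
        vol = voxelize(state, grid)
        path = tmp_path / "phantom.nii.gz"
        vol.save_nifti(path)
        back = Volume.load_nifti(path)
        np.testing.assert_allclose(back.data, vol.data, rtol=1e-6)
        assert back.grid.voxel == pytest.approx(grid.voxel)

    def test_from_primitives_state(self):
        from coromct.phantom4d import Capsule

        state = PhantomState.from_primitives(
            [Capsule((0, 0, -1), (0, 0, 1), 0.5, 0.02, 0.0, 1)])
        mu = attenuation_at(state, np.array([[0, 0, 0], [2, 0, 0]]))
        assert mu[0] == 0.02 and mu[1] == 0.0
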