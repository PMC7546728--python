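"""Shared fixtures.

The expensive simulations (dynamic desk scan, static scan, gated series,
motion fields, dose sweep) are session-scoped and shared between the module
tests and the acceptance suite.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from coromct.gating import GatingSpec, PhaseTrack, end_expiration_bin, \
    extract_gating_signals
from coromct.grids import GridSpec
from coromct.metrics import dose_resolution_experiment, dose_sweep
from coromct.moco import DemonsParams, estimate_cycle_fields, motion_compensate
from coromct.phantom4d import Capsule, PhantomSpec, PhantomState, static_spec
from coromct.recon import fdk, reconstruct_phase_series
from coromct.scanner import (ProjectionSet, ScanGeometry, apply_noise,
                             desk_geometry, make_timeline, project_state,
                             simulate_scan)

DESK_VOXEL = 0.15


@pytest.fixture(scope="session")
def desk_spec() -> PhantomSpec:
    # simulation default: incommensurate rates (587 bpm vs 300 rpm) so the
    # cardiac fundamental clears the respiratory harmonic comb
    return PhantomSpec(heart_rate=587.0, resp_rate=300.0)


@pytest.fixture(scope="session")
def desk_geo() -> ScanGeometry:
    return desk_geometry()


@pytest.fixture(scope="session")
def desk_grid() -> GridSpec:
    return GridSpec((72, 72, 72), DESK_VOXEL)


@pytest.fixture(scope="session")
def desk_demons() -> DemonsParams:
    return DemonsParams(iterations=(30, 20, 10, 5), presmooth_sigma=2.0,
                        fluid_sigma=2.5, diffusion_sigma=1.5)


@pytest.fixture(scope="session")
def dyn_projections(desk_spec, desk_geo) -> ProjectionSet:
    """Full dynamic desk scan (2580 frames, 30 s) with photon noise."""
    ps = simulate_scan(desk_spec, desk_geo)
    return apply_noise(ps, 1.0, seed=7)


@pytest.fixture(scope="session")
def track(dyn_projections) -> PhaseTrack:
    return extract_gating_signals(dyn_projections)


@pytest.fixture(scope="session")
def phase_series(dyn_projections, track, desk_grid):
    gspec = GatingSpec()
    rb = end_expiration_bin(track, gspec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return reconstruct_phase_series(dyn_projections, track, gspec, rb,
                                        desk_grid)


@pytest.fixture(scope="session")
def cycle_fields(phase_series, desk_demons):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return estimate_cycle_fields(phase_series, desk_demons)


@pytest.fixture(scope="session")
def moco_volume(phase_series, cycle_fields):
    return motion_compensate(phase_series, cycle_fields,
                             len(phase_series) - 1)


@pytest.fixture(scope="session")
def sweep_result(dyn_projections, track, desk_spec, desk_grid, desk_demons):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return dose_sweep(dyn_projections, track, GatingSpec(),
                          [2000, 1500, 1000, 500], desk_spec, desk_grid,
                          moco_params=desk_demons, seed=1)


# -- static scans ----------------------------------------------------------

@pytest.fixture(scope="session")
def cyl_geo() -> ScanGeometry:
    """Single-revolution calibration geometry (258 frames)."""
    return desk_geometry(framerate=258.0, scan_duration=1.0)


@pytest.fixture(scope="session")
def cyl_projections(cyl_geo) -> ProjectionSet:
    """Noiseless scan of a uniform water cylinder (mu = 0.02/mm, r = 3 mm)."""
    tl = make_timeline(cyl_geo)
    state = PhantomState.from_primitives(
        [Capsule((0, 0, -8.0), (0, 0, 8.0), 3.0, 0.02, 0.0, 1, "cylinder")])
    frames = np.stack([project_state(state, cyl_geo, a) for a in tl.angles])
    return ProjectionSet(frames, tl, cyl_geo)


@pytest.fixture(scope="session")
def cyl_grid() -> GridSpec:
    return GridSpec((48, 64, 64), DESK_VOXEL)


@pytest.fixture(scope="session")
def cyl_recon(cyl_projections, cyl_grid):
    return fdk(cyl_projections, cyl_grid)


@pytest.fixture(scope="session")
def cyl_roi(cyl_grid):
    pts = cyl_grid.points()
    return ((pts[..., 0] ** 2 + pts[..., 1] ** 2 <= 1.5**2)
            & (np.abs(pts[..., 2]) < 1.0))


@pytest.fixture(scope="session")
def static_heart_case(desk_spec, desk_geo, desk_grid, desk_demons):
    """Static-anatomy pipeline for the noise-equivalence laws: Std, PC
    (cardiac gating only) and MoCo reconstructions of the same noisy scan,
    plus the noiseless reference."""
    spec = static_spec(desk_spec)
    clean = simulate_scan(spec, desk_geo)
    noisy = apply_noise(clean, 1.0, seed=11)
    ref = fdk(clean, desk_grid)
    std = fdk(noisy, desk_grid)
    track = PhaseTrack.from_true_phases(noisy)
    gspec = GatingSpec(n_resp_bins=1, resp_width=100.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        series = reconstruct_phase_series(noisy, track, gspec, 0, desk_grid)
        fields = estimate_cycle_fields(series, desk_demons)
    moco = motion_compensate(series, fields, len(series) - 1)
    return {"ref": ref, "std": std, "series": series, "moco": moco,
            "fields": fields, "grid": desk_grid}


@pytest.fixture(scope="session")
def uniform_roi(desk_grid):
    """Uniform thorax-background region away from the heart."""
    from coromct.metrics import sphere_mask

    return sphere_mask(desk_grid, (-2.0, 1.5, -1.0), 1.2)


@pytest.fixture(scope="session")
def dose_resolution_result():
    return dose_resolution_experiment(seed=1)


def circular_rms(est: np.ndarray, true: np.ndarray) -> float:
    """Circular RMS phase error in cycles, after removing the constant
    circular offset between the two phase origins."""
    d = np.mod(np.asarray(est) - np.asarray(true) + 0.5, 1.0) - 0.5
    off = np.angle(np.exp(2j * np.pi * d).mean()) / (2 * np.pi)
    d2 = np.mod(d - off + 0.5, 1.0) - 0.5
    return float(np.sqrt((d2**2).mean()))
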