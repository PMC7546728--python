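"""Cone-beam acquisition simulator.

Circular trajectory, flat detector, monochromatic effective energy.  The
source rotates in the z = 0 plane: at gantry angle ``theta`` the source sits
at ``R_F * (cos t, sin t, 0)`` and the detector center at
``(R_F - R_FD) * (cos t, sin t, 0)``, with detector columns along
``(-sin t, cos t, 0)`` and rows along +z.

Projections are line integrals of mu (dimensionless).  The forward model is
an exact analytic primitive projector: each phantom primitive contributes
``chord_length * (mu - host_mu)``, which is exact because the phantom's
primitives are nested or disjoint by construction.  A slower voxelized
ray-sampling projector (`project_voxelized`) serves as an independent
cross-check.

Photon noise follows a Poisson model on transmitted counts at a dose-scaled
photon budget; dose reduction can alternatively be realized by uniform frame
thinning (`thin_frames`), matching the acquisition protocol's use of
fractions of the acquired data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
from scipy.ndimage import map_coordinates

from .errors import InvalidParameterError
from .grids import GridSpec
from .phantom4d import PhantomSpec, PhantomState, instantiate, voxelize

__all__ = [
    "ScanGeometry",
    "AcquisitionTimeline",
    "ProjectionSet",
    "make_timeline",
    "forward_project",
    "simulate_scan",
    "apply_noise",
    "thin_frames",
    "project_voxelized",
    "desk_geometry",
]


@dataclass(frozen=True)
class ScanGeometry:
    """Cone-beam system constants (full-protocol defaults)."""

    source_isocenter: float = 90.0       # R_F, mm
    source_detector: float = 590.0       # R_FD, mm
    detector_pixel: float = 0.0748 * 4   # mm (4x4-binned pitch)
    n_rows: int = 768
    n_cols: int = 972
    framerate: float = 86.0              # frames / s
    rotation_time: float = 10.0          # s / revolution
    scan_duration: float = 300.0         # s
    nominal_full_dose: float = 5000.0    # mGy
    photons_per_frame: float = 5.0e4     # I0 per detector pixel at full dose

    def __post_init__(self):
        if not (self.source_detector > self.source_isocenter > 0):
            raise InvalidParameterError("require R_FD > R_F > 0")
        if self.detector_pixel <= 0:
            raise InvalidParameterError("detector pixel must be positive")
        if self.framerate <= 0 or self.rotation_time <= 0:
            raise InvalidParameterError("framerate and rotation time must be positive")
        if self.framerate * self.rotation_time < 8:
            raise InvalidParameterError("angular sampling below minimum (8 frames/rev)")

    @property
    def magnification(self) -> float:
        return self.source_detector / self.source_isocenter

    @property
    def iso_pixel(self) -> float:
        """Detector pixel pitch rescaled to the isocenter plane, mm."""
        return self.detector_pixel / self.magnification

    def iso_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Isocenter-plane coordinates (u of columns, v of rows), mm."""
        du = self.iso_pixel
        u = (np.arange(self.n_cols) - (self.n_cols - 1) / 2.0) * du
        v = (np.arange(self.n_rows) - (self.n_rows - 1) / 2.0) * du
        return u, v


def desk_geometry(**overrides) -> ScanGeometry:
    """Desk-scale profile: 128x96 detector, 86 fps, 1 s/rev, 30 s scan
    (2580 frames over 30 revolutions, same angle formula as the full
    protocol)."""
    kw = dict(detector_pixel=0.8, n_rows=96, n_cols=128, rotation_time=1.0,
              scan_duration=30.0)
    kw.update(overrides)
    return ScanGeometry(**kw)


@dataclass(frozen=True)
class AcquisitionTimeline:
    """Per-frame acquisition schedule."""

    timestamps: np.ndarray    # s, strictly increasing at 1/framerate
    angles: np.ndarray        # rad, 2*pi*t/rotation_time mod 2*pi

    def __post_init__(self):
        object.__setattr__(self, "timestamps", np.asarray(self.timestamps, dtype=float))
        object.__setattr__(self, "angles", np.asarray(self.angles, dtype=float))
        if len(self.timestamps) != len(self.angles):
            raise InvalidParameterError("timestamps/angles length mismatch")
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise InvalidParameterError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)

    def subset(self, idx) -> "AcquisitionTimeline":
        return AcquisitionTimeline(self.timestamps[idx], self.angles[idx])


def make_timeline(geometry: ScanGeometry) -> AcquisitionTimeline:
    """Continuous-rotation schedule: floor(framerate * duration) frames."""
    n = int(np.floor(geometry.framerate * geometry.scan_duration))
    if n < 1:
        raise InvalidParameterError("zero-duration scan")
    t = np.arange(n) / geometry.framerate
    angles = np.mod(2.0 * np.pi * t / geometry.rotation_time, 2.0 * np.pi)
    return AcquisitionTimeline(t, angles)


@dataclass
class ProjectionSet:
    """Stack of line-integral frames with their schedule and geometry."""

    frames: np.ndarray                    # (n_frames, n_rows, n_cols), float32
    timeline: AcquisitionTimeline
    geometry: ScanGeometry
    dose_fraction: float = 1.0
    noise_seed: int | None = None
    true_cardiac_phase: np.ndarray | None = None   # simulation ground truth
    true_resp_phase: np.ndarray | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.shape[0] != len(self.timeline):
            raise InvalidParameterError("frame count != timeline length")
        if not (0 < self.dose_fraction <= 1):
            raise InvalidParameterError("dose_fraction must be in (0, 1]")
        if not np.all(np.isfinite(self.frames)):
            raise InvalidParameterError("non-finite line integrals")

    def __len__(self) -> int:
        return self.frames.shape[0]

    # -- persistence -------------------------------------------------------
    def save_h5(self, path: str | Path) -> None:
        with h5py.File(str(path), "w") as f:
            f.create_dataset("frames", data=self.frames, dtype="f4")
            f.create_dataset("timestamps", data=self.timeline.timestamps)
            f.create_dataset("angles", data=self.timeline.angles)
            if self.true_cardiac_phase is not None:
                f.create_dataset("true_cardiac_phase", data=self.true_cardiac_phase)
            if self.true_resp_phase is not None:
                f.create_dataset("true_resp_phase", data=self.true_resp_phase)
            g = f.create_group("geometry")
            for k, v in vars(self.geometry).items():
                g.attrs[k] = v
            f.attrs["dose_fraction"] = self.dose_fraction
            f.attrs["noise_seed"] = -1 if self.noise_seed is None else self.noise_seed

    @classmethod
    def load_h5(cls, path: str | Path) -> "ProjectionSet":
        with h5py.File(str(path), "r") as f:
            geo = ScanGeometry(**{k: v.item() if hasattr(v, "item") else v
                                  for k, v in f["geometry"].attrs.items()})
            tl = AcquisitionTimeline(f["timestamps"][:], f["angles"][:])
            seed = int(f.attrs["noise_seed"])
            return cls(
                frames=f["frames"][:],
                timeline=tl,
                geometry=geo,
                dose_fraction=float(f.attrs["dose_fraction"]),
                noise_seed=None if seed < 0 else seed,
                true_cardiac_phase=(f["true_cardiac_phase"][:]
                                    if "true_cardiac_phase" in f else None),
                true_resp_phase=(f["true_resp_phase"][:]
                                 if "true_resp_phase" in f else None),
            )


# --------------------------------------------------------------------------
# forward projection
# --------------------------------------------------------------------------

def _rays(geometry: ScanGeometry, angle: float) -> tuple[np.ndarray, np.ndarray]:
    """Source origin and unit directions of all detector pixels for one frame."""
    ct, st = np.cos(angle), np.sin(angle)
    src = np.array([geometry.source_isocenter * ct,
                    geometry.source_isocenter * st, 0.0])
    eu = np.array([-st, ct, 0.0])
    ez = np.array([0.0, 0.0, 1.0])
    du = geometry.detector_pixel
    u = (np.arange(geometry.n_cols) - (geometry.n_cols - 1) / 2.0) * du
    v = (np.arange(geometry.n_rows) - (geometry.n_rows - 1) / 2.0) * du
    det_center = np.array([(geometry.source_isocenter - geometry.source_detector) * ct,
                           (geometry.source_isocenter - geometry.source_detector) * st,
                           0.0])
    pix = (det_center[None, None, :]
           + v[:, None, None] * ez[None, None, :]
           + u[None, :, None] * eu[None, None, :])
    d = pix.reshape(-1, 3) - src
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return src, d


def project_state(state: PhantomState, geometry: ScanGeometry,
                  angle: float) -> np.ndarray:
    """Analytic line integrals of one frozen phantom state at one angle."""
    src, dirs = _rays(geometry, angle)
    origins = np.broadcast_to(src, dirs.shape)
    total = np.zeros(len(dirs))
    for prim in state.primitives:
        dmu = prim.mu - prim.host_mu
        if dmu == 0.0:
            continue
        total += dmu * prim.chords(origins, dirs)
    return total.reshape(geometry.n_rows, geometry.n_cols)


def forward_project(spec: PhantomSpec, geometry: ScanGeometry,
                    timeline: AcquisitionTimeline, frame_index: int) -> np.ndarray:
    """One line-integral frame of the dynamic phantom (motion frozen at the
    frame timestamp)."""
    if not (0 <= frame_index < len(timeline)):
        raise InvalidParameterError(f"frame_index {frame_index} out of range")
    state = instantiate(spec, timeline.timestamps[frame_index])
    return project_state(state, geometry, timeline.angles[frame_index])


def simulate_scan(spec: PhantomSpec, geometry: ScanGeometry,
                  timeline: AcquisitionTimeline | None = None,
                  progress: bool = False) -> ProjectionSet:
    """Project every frame of the timeline.

    For a static spec (all motion amplitudes zero) frames are computed once
    per unique gantry angle and replicated, which makes multi-revolution
    static scans cheap.
    """
    from .phantom4d import cardiac_phase, respiratory_phase

    tl = timeline if timeline is not None else make_timeline(geometry)
    n = len(tl)
    static = (spec.ejection_amplitude == 0 and spec.resp_amplitude == 0
              and spec.resp_ap_expansion == 0)
    frames = np.empty((n, geometry.n_rows, geometry.n_cols), dtype=np.float32)
    if static:
        ang = np.round(tl.angles, 9)
        uniq, inv = np.unique(ang, return_inverse=True)
        state = instantiate(spec, 0.0)
        cache = np.empty((len(uniq), geometry.n_rows, geometry.n_cols), dtype=np.float32)
        for k, a in enumerate(uniq):
            cache[k] = project_state(state, geometry, float(a))
        frames[:] = cache[inv]
    else:
        for i in range(n):
            state = instantiate(spec, tl.timestamps[i])
            frames[i] = project_state(state, geometry, tl.angles[i])
    return ProjectionSet(
        frames=frames, timeline=tl, geometry=geometry,
        true_cardiac_phase=np.asarray(cardiac_phase(tl.timestamps, spec.heart_rate)),
        true_resp_phase=np.asarray(respiratory_phase(tl.timestamps, spec.resp_rate)),
    )


def project_voxelized(state: PhantomState, geometry: ScanGeometry, angle: float,
                      grid: GridSpec, step: float | None = None) -> np.ndarray:
    """Voxelized ray-sampling projector (independent cross-check oracle).

    The state is voxelized on `grid` and each ray is integrated by trilinear
    sampling at `step` mm spacing (default: half a voxel).
    """
    vol = voxelize(state, grid).data
    step = step if step is not None else grid.voxel / 2.0
    src, dirs = _rays(geometry, angle)
    # clip sampling to the grid's bounding sphere around the isocenter
    half = grid.voxel * (max(grid.shape)) / 2.0
    radius = np.sqrt(3.0) * half + np.linalg.norm(grid.center)
    t0 = geometry.source_isocenter - radius
    t1 = geometry.source_isocenter + radius
    ts = np.arange(t0, t1, step)
    out = np.zeros(len(dirs), dtype=float)
    for i, d in enumerate(dirs):
        pts = src[None, :] + ts[:, None] * d[None, :]
        idx = GridSpec.world_to_index(grid, pts)      # (n, 3) as (z, y, x)
        vals = map_coordinates(vol, idx.T, order=1, mode="constant", cval=0.0)
        out[i] = vals.sum() * step
    return out.reshape(geometry.n_rows, geometry.n_cols)


# --------------------------------------------------------------------------
# noise and dose
# --------------------------------------------------------------------------

def apply_noise(projections: ProjectionSet, dose_fraction: float = 1.0,
                seed: int | None = 0) -> ProjectionSet:
    """Poisson photon noise at a dose-scaled photon budget.

    Transmitted counts are Poisson with mean ``I0 * dose_fraction *
    exp(-q)``; the returned frames are the re-log-transformed noisy line
    integrals.  Reproducible for equal seeds.
    """
    if not (0 < dose_fraction <= 1):
        raise InvalidParameterError("dose_fraction must be in (0, 1]")
    i0 = projections.geometry.photons_per_frame * dose_fraction
    if i0 < 10:
        warnings.warn("air photon budget below 10 counts: log-transform bias regime",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    mean = i0 * np.exp(-projections.frames.astype(np.float64))
    counts = rng.poisson(mean).astype(np.float64)
    counts = np.maximum(counts, 0.5)          # avoid log(0) at very low budgets
    noisy = np.log(i0 / counts)
    return replace(projections, frames=noisy.astype(np.float32),
                   dose_fraction=projections.dose_fraction * dose_fraction,
                   noise_seed=seed)


def thin_frames(projections: ProjectionSet, fraction: float,
                seed: int | None = None) -> ProjectionSet:
    """Uniform frame thinning to a dose fraction.

    With `seed=None` frames are kept on a deterministic uniform stride; with
    a seed, one frame is drawn per stride block (stratified random), which
    avoids resonances between the thinning stride and periodic phase/angle
    patterns while keeping the kept frames uniformly spread in time.
    """
    if not (0 < fraction <= 1):
        raise InvalidParameterError("fraction must be in (0, 1]")
    n = len(projections)
    n_keep = int(round(n * fraction))
    if seed is None:
        keep = np.unique(np.round(np.linspace(0, n - 1, n_keep)).astype(int))
    else:
        rng = np.random.default_rng(seed)
        edges = np.round(np.linspace(0, n, n_keep + 1)).astype(int)
        keep = np.array(sorted(
            int(rng.integers(lo, hi)) for lo, hi in zip(edges[:-1], edges[1:])
            if hi > lo))
    return thin_to_indices(projections, keep, fraction)


def thin_to_indices(projections: ProjectionSet, idx: np.ndarray,
                    fraction: float | None = None) -> ProjectionSet:
    """Subset a projection set to explicit frame indices."""
    idx = np.asarray(idx)
    frac = fraction if fraction is not None else len(idx) / len(projections)
    return ProjectionSet(
        frames=projections.frames[idx],
        timeline=projections.timeline.subset(idx),
        geometry=projections.geometry,
        dose_fraction=projections.dose_fraction * frac if frac <= 1 else 1.0,
        noise_seed=projections.noise_seed,
        true_cardiac_phase=(None if projections.true_cardiac_phase is None
                            else projections.true_cardiac_phase[idx]),
        true_resp_phase=(None if projections.true_resp_phase is None
                         else projections.true_resp_phase[idx]),
    )
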