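"""Cyclic motion estimation and motion-compensated superposition.

The cardiac phase series (one gated volume per cardiac bin) is registered
pairwise between adjacent phases with a symmetric-force Demons algorithm
(multi-resolution, Gaussian fluid/diffusion regularization — delegated to
SimpleITK behind this module's surface).  The resulting displacement fields
wrap around the cycle; because cardiac motion returns to the same state
after one cycle, the composition of all fields around the loop must be the
identity.  `enforce_cyclicity` distributes any loop residual equally over
the fields.  `motion_compensate` then warps every phase volume to a
reference phase along the shorter arc of the cycle and averages, so all
acquired data contribute to a single motion-frozen volume whose noise level
approaches that of an ungated reconstruction.

Field convention: ``field[k, j, i] = (dz, dy, dx)`` in mm on the volume
grid; the field of pair ``i`` maps phase-i coordinates to phase-(i+1)
sampling positions (``x_{i+1} = x_i + u_i(x_i)``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dfield

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import gaussian_filter, map_coordinates

from .errors import CoromctError, InvalidParameterError
from .grids import GridSpec, Volume, Volume4D

__all__ = [
    "DemonsParams",
    "MotionVectorField",
    "demons_register",
    "enforce_cyclicity",
    "motion_compensate",
    "compose_fields",
    "invert_field",
    "warp_volume",
    "estimate_cycle_fields",
]


@dataclass(frozen=True)
class DemonsParams:
    """Demons hyperparameters (sigmas in voxels)."""

    fluid_sigma: float = 1.5        # update-field (fluid) regularization
    diffusion_sigma: float = 1.0    # displacement-field (diffusion) regularization
    iterations: tuple[int, ...] = (60, 40, 20, 10)  # per pyramid level, coarse->fine
    shrinks: tuple[int, ...] = (8, 4, 2, 1)
    presmooth_sigma: float = 1.0    # voxels; force computation only
    max_step: float = 1.25          # voxels, per-iteration update cap


@dataclass
class MotionVectorField:
    """Dense displacement field on a volume grid, mm, (dz, dy, dx) last axis."""

    data: np.ndarray
    grid: GridSpec
    meta: dict = dfield(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.shape != (*self.grid.shape, 3):
            raise InvalidParameterError("field shape does not match grid")
        if not np.all(np.isfinite(self.data)):
            raise InvalidParameterError("non-finite displacements")

    def max_voxels(self) -> float:
        return float(np.abs(self.data).max() / self.grid.voxel)

    @classmethod
    def zero(cls, grid: GridSpec) -> "MotionVectorField":
        return cls(np.zeros((*grid.shape, 3), dtype=np.float32), grid)

    def save_nifti(self, path) -> None:
        import nibabel as nib

        vox = self.grid.voxel
        aff = np.diag([vox] * 3 + [1.0])
        aff[:3, 3] = self.grid.origin
        # store as (x, y, z, component) with components (dx, dy, dz)
        arr = np.transpose(self.data[..., ::-1], (2, 1, 0, 3)).astype(np.float32)
        nib.save(nib.Nifti1Image(arr, aff), str(path))


# --------------------------------------------------------------------------
# registration
# --------------------------------------------------------------------------

def _to_sitk(arr: np.ndarray, voxel: float) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr, dtype=np.float32))
    img.SetSpacing((voxel,) * 3)
    return img


def demons_register(fixed: Volume, moving: Volume,
                    params: DemonsParams | None = None) -> MotionVectorField:
    """Symmetric-force Thirion Demons over a 3-level pyramid.

    Returns the displacement field mapping fixed-volume coordinates to the
    corresponding moving-volume sampling positions (SSD-minimizing).
    """
    params = params or DemonsParams()
    if fixed.grid != moving.grid:
        raise InvalidParameterError("volumes must share one grid")
    f_arr, m_arr = fixed.data, moving.data
    lo = max(f_arr.min(), m_arr.min())
    hi = min(f_arr.max(), m_arr.max())
    if hi <= lo:
        warnings.warn("non-overlapping intensity ranges: registration may stall",
                      stacklevel=2)
    voxel = fixed.grid.voxel
    if params.presmooth_sigma > 0:
        f_arr = gaussian_filter(f_arr, params.presmooth_sigma)
        m_arr = gaussian_filter(m_arr, params.presmooth_sigma)
    # normalize to a robust [0, 1] range shared by both volumes
    p1, p99 = np.percentile(np.concatenate([f_arr.ravel(), m_arr.ravel()]),
                            [1.0, 99.0])
    scale = 1.0 / max(p99 - p1, 1e-12)
    f_arr = (f_arr - p1) * scale
    m_arr = (m_arr - p1) * scale
    f_img = _to_sitk(f_arr, voxel)
    m_img = _to_sitk(m_arr, voxel)

    disp = None
    metadata = {"levels": []}
    for shrink, iters in zip(params.shrinks, params.iterations):
        if shrink > 1:
            f_l = sitk.SmoothingRecursiveGaussian(f_img, 0.5 * shrink * voxel)
            m_l = sitk.SmoothingRecursiveGaussian(m_img, 0.5 * shrink * voxel)
            f_l = sitk.Shrink(f_l, [shrink] * 3)
            m_l = sitk.Shrink(m_l, [shrink] * 3)
        else:
            f_l, m_l = f_img, m_img
        dem = sitk.FastSymmetricForcesDemonsRegistrationFilter()
        dem.SetNumberOfIterations(int(iters))
        dem.SetMaximumRMSError(1e-5)
        if params.diffusion_sigma > 0:
            dem.SetSmoothDisplacementField(True)
            dem.SetStandardDeviations(params.diffusion_sigma * voxel * shrink)
        else:
            dem.SetSmoothDisplacementField(False)
        dem.SetSmoothUpdateField(True)
        dem.SetUpdateFieldStandardDeviations(params.fluid_sigma * voxel * shrink)
        # physical units: cap at `max_step` level-voxels per iteration
        dem.SetMaximumUpdateStepLength(params.max_step * voxel * shrink)
        if disp is None:
            disp = dem.Execute(f_l, m_l)
        else:
            init = sitk.Resample(disp, f_l, sitk.Transform(),
                                 sitk.sitkLinear, 0.0,
                                 sitk.sitkVectorFloat64)
            disp = dem.Execute(f_l, m_l, init)
        metadata["levels"].append({"shrink": shrink, "iterations": int(iters),
                                   "rms_change": dem.GetRMSChange()})
    disp_full = sitk.Resample(disp, f_img, sitk.Transform(), sitk.sitkLinear,
                              0.0, sitk.sitkVectorFloat64)
    arr = sitk.GetArrayFromImage(disp_full)       # (z, y, x, [dx, dy, dz]) physical mm
    data = arr[..., ::-1].astype(np.float32)      # -> (dz, dy, dx)
    meta = {"fluid_sigma": params.fluid_sigma,
            "diffusion_sigma": params.diffusion_sigma, **metadata}
    return MotionVectorField(data, fixed.grid, meta)


def clamp_displacements(field: MotionVectorField,
                        cap_mm: float) -> MotionVectorField:
    """Soft magnitude cap: displacements above `cap_mm` are rescaled to it
    (streak-chasing in low-contrast regions produces non-physiological
    outliers on noisy gated volumes)."""
    mag = np.linalg.norm(field.data, axis=-1, keepdims=True)
    scale = np.minimum(1.0, cap_mm / np.maximum(mag, 1e-12))
    return MotionVectorField((field.data * scale).astype(np.float32),
                             field.grid, dict(field.meta))


def temporal_harmonic_filter(fields: list[MotionVectorField],
                             n_harmonics: int = 3,
                             scale: float = 1.0) -> list[MotionVectorField]:
    """Project the cyclic field sequence onto its first `n_harmonics`
    temporal Fourier modes (per voxel and component), dropping the DC term.

    Physiological cyclic motion is smooth over the cycle, while
    registration noise is independent between phase pairs, so this keeps
    the motion and suppresses the noise; removing the DC term removes the
    inconsistent drift component that breaks loop closure.  `scale`
    additionally shrinks all displacements (noise-adaptive motion trust).
    """
    import scipy.fft

    grid = fields[0].grid
    arr = np.stack([f.data for f in fields])
    spec = scipy.fft.rfft(arr, axis=0)
    spec[0] = 0
    spec[n_harmonics + 1:] = 0
    out = (scale * scipy.fft.irfft(spec, n=arr.shape[0], axis=0)).astype(np.float32)
    return [MotionVectorField(out[i], grid, dict(fields[i].meta))
            for i in range(arr.shape[0])]


def estimate_cycle_fields(phases: Volume4D,
                          params: DemonsParams | None = None,
                          cyclic_tol: float = 0.1,
                          max_displacement_mm: float | None = 0.5,
                          mask_air_hu: float | None = -600.0,
                          n_harmonics: int | None = 3,
                          noise_shrinkage_hu: float | None = 150.0
                          ) -> list[MotionVectorField]:
    """Adjacent-phase Demons fields around the full cardiac cycle (phase
    N-1 -> 0 included), regularized and cyclicity-corrected.

    Post-registration regularization, in order: displacements capped at
    `max_displacement_mm` (streak-chasing on sparse gated volumes produces
    non-physiological outliers); zeroed in air (below `mask_air_hu`);
    projected onto the first `n_harmonics` cyclic temporal Fourier modes
    (cyclic motion is smooth over the cycle, registration noise is not);
    and shrunk by 1 / (1 + (sigma/sigma0)^2) with `sigma0 =
    noise_shrinkage_hu` and sigma the per-phase image noise — registration
    accuracy degrades with SNR, so on very noisy series the compensation
    approaches a plain phase average rather than applying unreliable warps.
    Finally the loop residual is distributed over the fields; on measured
    volumes it converges to the level set by registration inconsistency,
    and a warning rather than an error is raised if the strict tolerance is
    not reached.
    """
    n = len(phases)
    fields = [demons_register(phases[i], phases[(i + 1) % n], params)
              for i in range(n)]
    if max_displacement_mm is not None:
        fields = [clamp_displacements(f, max_displacement_mm) for f in fields]
    if mask_air_hu is not None:
        from .units import hu_to_mu

        body = (phases.stack().mean(axis=0) > hu_to_mu(mask_air_hu)).astype(float)
        body = gaussian_filter(body, 2.0)
        for f in fields:
            f.data = (f.data * body[..., None]).astype(np.float32)
    scale = 1.0
    if noise_shrinkage_hu is not None:
        from .tbaf import local_noise_sigma
        from .units import MU_WATER

        sigma_phase = float(np.median(local_noise_sigma(phases.stack().mean(0)))
                            / MU_WATER * 1000.0) * np.sqrt(n)
        scale = 1.0 / (1.0 + (sigma_phase / noise_shrinkage_hu) ** 2)
        for f in fields:
            f.meta["noise_sigma_hu"] = sigma_phase
            f.meta["motion_trust"] = scale
    if n_harmonics is not None:
        fields = temporal_harmonic_filter(fields, n_harmonics, scale)
    elif scale != 1.0:
        for f in fields:
            f.data = (f.data * scale).astype(np.float32)
    return enforce_cyclicity(fields, tol_voxels=cyclic_tol, on_fail="warn")


# --------------------------------------------------------------------------
# field algebra
# --------------------------------------------------------------------------

def _sample_field(field: np.ndarray, idx: np.ndarray, voxel: float) -> np.ndarray:
    """Trilinear sample of a (z, y, x, 3) displacement field at fractional
    (z, y, x) voxel indices."""
    out = np.empty_like(idx, dtype=np.float64)
    for c in range(3):
        out[..., c] = map_coordinates(field[..., c], idx.reshape(-1, 3).T,
                                      order=1, mode="nearest").reshape(idx.shape[:-1])
    return out


def compose_fields(first: MotionVectorField,
                   second: MotionVectorField) -> MotionVectorField:
    """Displacement of applying `first` then `second`:
    ``u(x) = u1(x) + u2(x + u1(x))``."""
    if first.grid != second.grid:
        raise InvalidParameterError("fields must share one grid")
    grid = first.grid
    base = np.indices(grid.shape).transpose(1, 2, 3, 0).astype(np.float64)
    idx1 = base + first.data / grid.voxel
    u2 = _sample_field(second.data, idx1, grid.voxel)
    return MotionVectorField((first.data + u2).astype(np.float32), grid)


def invert_field(field: MotionVectorField, iterations: int = 8) -> MotionVectorField:
    """Fixed-point inverse: v(x) = -u(x + v(x))."""
    grid = field.grid
    base = np.indices(grid.shape).transpose(1, 2, 3, 0).astype(np.float64)
    v = np.zeros_like(field.data, dtype=np.float64)
    for _ in range(iterations):
        v = -_sample_field(field.data, base + v / grid.voxel, grid.voxel)
    return MotionVectorField(v.astype(np.float32), grid)


def warp_volume(volume: Volume, field: MotionVectorField) -> Volume:
    """Resample `volume` at ``x + u(x)`` (pull-back warp, trilinear)."""
    if volume.grid != field.grid:
        raise InvalidParameterError("volume and field must share one grid")
    grid = volume.grid
    base = np.indices(grid.shape).transpose(1, 2, 3, 0).astype(np.float64)
    idx = base + field.data / grid.voxel
    data = map_coordinates(volume.data, idx.reshape(-1, 3).T, order=1,
                           mode="nearest").reshape(grid.shape)
    return Volume(data.astype(np.float32), grid,
                  {**volume.provenance, "warped": True})


def loop_residual(fields: list[MotionVectorField]) -> np.ndarray:
    """Displacement residual (mm) of composing all fields around the cycle."""
    total = fields[0]
    for f in fields[1:]:
        total = compose_fields(total, f)
    return total.data


def enforce_cyclicity(fields: list[MotionVectorField], tol_voxels: float = 0.1,
                      max_iter: int = 50, damping: float = 1.0,
                      on_fail: str = "raise") -> list[MotionVectorField]:
    """Iteratively distribute the loop-closure residual equally over the N
    fields until the composed cycle is the identity to `tol_voxels`.

    `damping` scales each correction step (values < 1 stabilize the fixed
    point for large or inconsistent fields).  If the tolerance is not
    reached within `max_iter` iterations the best iterate is either
    rejected (`on_fail='raise'`) or returned with a warning
    (`on_fail='warn'`).
    """
    if not fields:
        raise InvalidParameterError("no fields")
    grid = fields[0].grid
    n = len(fields)
    out = [MotionVectorField(f.data.copy(), grid, dict(f.meta)) for f in fields]
    best: tuple[float, list[np.ndarray]] | None = None
    for _ in range(max_iter):
        res = loop_residual(out)
        max_res = float(np.abs(res).max() / grid.voxel)
        if best is None or max_res < best[0]:
            best = (max_res, [f.data.copy() for f in out])
        if max_res < tol_voxels:
            for f in out:
                f.meta["cyclic_residual_voxels"] = max_res
            return out
        corr = (damping * res / n).astype(np.float32)
        for f in out:
            f.data = f.data - corr
    max_res, datas = best
    for f, d in zip(out, datas):
        f.data = d
        f.meta["cyclic_residual_voxels"] = max_res
    msg = (f"cyclicity enforcement did not converge: residual {max_res:.3f} "
           f"voxels after {max_iter} iterations (tolerance {tol_voxels})")
    if on_fail == "warn":
        warnings.warn(msg, stacklevel=2)
        return out
    raise CoromctError(msg)


# --------------------------------------------------------------------------
# motion-compensated superposition
# --------------------------------------------------------------------------

def _chain_to(fields: list[MotionVectorField], reference: int, target: int,
              inverses: dict[int, MotionVectorField]) -> MotionVectorField | None:
    """Field mapping reference-phase coordinates to target-phase positions,
    composed along the shorter arc of the cyclic phase graph."""
    n = len(fields)
    if target == reference:
        return None
    fwd = (target - reference) % n
    bwd = n - fwd
    grid = fields[0].grid
    if fwd <= bwd:
        total: MotionVectorField | None = None
        for s in range(fwd):
            f = fields[(reference + s) % n]
            total = f if total is None else compose_fields(total, f)
        return total
    total = None
    for s in range(bwd):
        f = inverses[(reference - 1 - s) % n]
        total = f if total is None else compose_fields(total, f)
    return total


def motion_compensate(phases: Volume4D, fields: list[MotionVectorField],
                      reference_bin: int) -> Volume:
    """Warp every phase volume to `reference_bin` and average (intensity-only
    superposition, no Jacobian density compensation)."""
    n = len(phases)
    if len(fields) != n:
        raise InvalidParameterError(
            f"need one field per phase pair ({n}), got {len(fields)}"
        )
    if not (0 <= reference_bin < n):
        raise InvalidParameterError("reference_bin out of range")
    grid = phases.grid
    need_inv = {(reference_bin - 1 - s) % n
                for s in range(max(0, n - 1 - n // 2))}
    inverses = {i: invert_field(fields[i]) for i in need_inv}
    acc = np.zeros(grid.shape, dtype=np.float64)
    for j in range(n):
        chain = _chain_to(fields, reference_bin, j, inverses)
        vol = phases[j] if chain is None else warp_volume(phases[j], chain)
        acc += vol.data
    out = (acc / n).astype(np.float32)
    return Volume(out, grid,
                  {"tag": "MoCo", "reference_bin": reference_bin, "n_phases": n})
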