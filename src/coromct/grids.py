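"""Reconstruction grids and volume containers.

Conventions used throughout the package:

* world coordinates are (x, y, z) in mm, isocenter at the origin, z along the
  rotation axis (craniocaudal);
* volume arrays are indexed ``(slice, row, col) == (z, y, x)``, 0-based;
* voxels are isotropic; the grid is described by its shape, voxel size and the
  world position of its center.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import InvalidParameterError


@dataclass(frozen=True)
class GridSpec:
    """Isotropic 3D sampling grid.

    Parameters
    ----------
    shape : tuple of int
        Array shape ``(nz, ny, nx)``.
    voxel : float
        Isotropic voxel size in mm.
    center : tuple of float
        World coordinates (x, y, z) of the grid center in mm.
    """

    shape: tuple[int, int, int]
    voxel: float
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.voxel <= 0:
            raise InvalidParameterError("voxel size must be positive")
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise InvalidParameterError(f"invalid grid shape {self.shape}")

    @property
    def origin(self) -> np.ndarray:
        """World (x, y, z) of voxel index (0, 0, 0)."""
        nz, ny, nx = self.shape
        c = np.asarray(self.center, dtype=float)
        return c - self.voxel * (np.array([nx, ny, nz], dtype=float) - 1) / 2.0

    def axis_coords(self, axis: str) -> np.ndarray:
        """World coordinates along one axis ('x', 'y' or 'z')."""
        nz, ny, nx = self.shape
        n = {"x": nx, "y": ny, "z": nz}[axis]
        o = self.origin[{"x": 0, "y": 1, "z": 2}[axis]]
        return o + self.voxel * np.arange(n)

    def points(self) -> np.ndarray:
        """All voxel centers as an array of shape ``(nz, ny, nx, 3)`` (x, y, z)."""
        zz, yy, xx = np.meshgrid(
            self.axis_coords("z"), self.axis_coords("y"), self.axis_coords("x"),
            indexing="ij",
        )
        return np.stack([xx, yy, zz], axis=-1)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world (x, y, z) points to fractional (z, y, x) array indices."""
        p = np.asarray(points, dtype=float)
        o = self.origin
        return (p[..., ::-1] - o[::-1]) / self.voxel


@dataclass
class Volume:
    """A reconstructed (or voxelized) scalar volume of mu values in 1/mm."""

    data: np.ndarray
    grid: GridSpec
    provenance: dict = field(default_factory=dict)
    coverage: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.shape != tuple(self.grid.shape):
            raise InvalidParameterError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )

    def to_hu(self, mu_water: float | None = None) -> np.ndarray:
        from .units import MU_WATER, mu_to_hu

        return mu_to_hu(self.data, MU_WATER if mu_water is None else mu_water)

    # -- I/O ---------------------------------------------------------------
    def affine(self) -> np.ndarray:
        """RAS affine mapping (i, j, k) = (x, y, z) voxel indices to world mm."""
        a = np.diag([self.grid.voxel] * 3 + [1.0])
        a[:3, 3] = self.grid.origin
        return a

    def save_nifti(self, path: str | Path) -> None:
        # nibabel expects the fastest-varying array axis first -> transpose to (x, y, z)
        img = nib.Nifti1Image(np.asarray(self.data.T, dtype=np.float32), self.affine())
        img.header.set_zooms((self.grid.voxel,) * 3)
        nib.save(img, str(path))
        side = Path(str(path)).with_suffix("").with_suffix("")
        Path(str(side) + ".provenance.json").write_text(
            json.dumps(_jsonable(self.provenance), indent=1)
        )

    @classmethod
    def load_nifti(cls, path: str | Path) -> "Volume":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float32).T
        voxel = float(img.header.get_zooms()[0])
        aff = img.affine
        origin = aff[:3, 3]
        nz, ny, nx = data.shape
        center = origin + voxel * (np.array([nx, ny, nz]) - 1) / 2.0
        grid = GridSpec((nz, ny, nx), voxel, tuple(center))
        prov = {}
        side = Path(str(path)).with_suffix("").with_suffix("")
        pfile = Path(str(side) + ".provenance.json")
        if pfile.exists():
            prov = json.loads(pfile.read_text())
        return cls(data, grid, prov)


@dataclass
class Volume4D:
    """Ordered cardiac-phase series of volumes on a shared grid."""

    volumes: list[Volume]

    def __post_init__(self):
        if not self.volumes:
            raise InvalidParameterError("empty phase series")
        g0 = self.volumes[0].grid
        if any(v.grid != g0 for v in self.volumes):
            raise InvalidParameterError("phase volumes must share one grid")

    @property
    def grid(self) -> GridSpec:
        return self.volumes[0].grid

    def __len__(self) -> int:
        return len(self.volumes)

    def __getitem__(self, i: int) -> Volume:
        return self.volumes[i]

    def stack(self) -> np.ndarray:
        return np.stack([v.data for v in self.volumes])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj
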