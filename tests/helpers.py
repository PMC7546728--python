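"""Independent oracles used by the tests (kept deliberately separate from
the package's implementation paths)."""

from __future__ import annotations

import numpy as np


def fan_beam_fbp(sinogram: np.ndarray, angles: np.ndarray, r_f: float,
                 du_iso: float, grid_n: int, voxel: float) -> np.ndarray:
    """Plain 2D equal-spaced (flat detector) fan-beam filtered backprojection.

    Spatial-domain Shepp-Logan kernel, direct convolution, linear detector
    interpolation, voxel loop over a centered square grid.  Independent of
    the package's FFT/numba chain.
    """
    n_ang, n_det = sinogram.shape
    u = (np.arange(n_det) - (n_det - 1) / 2.0) * du_iso
    cosw = r_f / np.sqrt(r_f**2 + u**2)
    # discrete Shepp-Logan kernel
    n = np.arange(-n_det + 1, n_det)
    h = -2.0 / (np.pi**2 * du_iso**2 * (4.0 * n**2 - 1.0))
    out = np.zeros((grid_n, grid_n))
    xs = (np.arange(grid_n) - (grid_n - 1) / 2.0) * voxel
    d_beta = 2.0 * np.pi / n_ang
    for a, beta in enumerate(angles):
        q = sinogram[a] * cosw
        qf = np.convolve(q, h)[n_det - 1:2 * n_det - 1] * du_iso
        ct, st = np.cos(beta), np.sin(beta)
        X, Y = np.meshgrid(xs, xs, indexing="xy")
        d = r_f - (X * ct + Y * st)
        up = (-X * st + Y * ct) * r_f / d
        vals = np.interp(up, u, qf, left=0.0, right=0.0)
        out += 0.5 * d_beta * (r_f / d) ** 2 * vals
    return out


def brute_force_bin_labels(phases: np.ndarray, n_bins: int,
                           width_pct: float) -> np.ndarray:
    """Exhaustive circular-interval membership check per frame and bin."""
    w = width_pct / 100.0
    labels = np.full(len(phases), -1, dtype=int)
    for i, p in enumerate(phases):
        for k in range(n_bins):
            c = (k + 0.5) / n_bins
            lo = (c - w / 2.0) % 1.0
            hi = (c + w / 2.0) % 1.0
            if lo < hi:
                inside = lo <= p < hi
            else:                       # wrapped window
                inside = p >= lo or p < hi
            if inside:
                labels[i] = k
                break
    return labels
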