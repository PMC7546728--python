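"""Parametric 4D digital mouse thorax/heart phantom.

The phantom stands in for the study animal: a beating heart of murine size
(~9 mm long axis, ~4 mm short axis, heart rates up to 600 bpm) with
respiratory motion (rates up to 300 rpm), a contrast-enhanced blood pool
with temporally constant enhancement (blood-pool-agent model) and a left
coronary tree tapering from ~400 um diameter at the ostium to below 100 um
at the distal tips.

The anatomy is a compound of analytic primitives (ellipsoids and capsule
chains).  Every primitive carries its absolute attenuation ``mu`` together
with the attenuation of its *host* region, and primitives are nested or
disjoint by construction.  Point-wise evaluation resolves overlaps by
priority (coronary > chamber blood > myocardium > great vessels > thorax
background); line integrals can equivalently be accumulated additively as
``sum(chord * (mu - host_mu))``, which is what the analytic projector in
:mod:`coromct.scanner` does.

Motion model
------------
* Cardiac: ventricular inner semi-axes contract by a raised-cosine waveform
  with a systolic duty factor; the myocardial wall thickens such that the
  shell volume is conserved exactly; atria are modulated in anti-phase; the
  pulmonary trunk dilates in systole.
* Respiratory: craniocaudal translation plus a fractional anteroposterior
  expansion of the thorax, again a raised-cosine gasp with a quiet
  end-expiratory plateau.
* The coronary centerline is defined in epicardial surface coordinates and
  therefore rides the moving surface; its diameters are rigid.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .errors import InvalidParameterError
from .grids import GridSpec, Volume
from .units import MU_WATER, hu_to_mu

__all__ = [
    "PhantomSpec",
    "PhantomState",
    "Ellipsoid",
    "Capsule",
    "CoronaryBranch",
    "CapsuleChain",
    "cardiac_phase",
    "respiratory_phase",
    "raised_cosine",
    "instantiate",
    "instantiate_phases",
    "attenuation_at",
    "voxelize",
    "coronary_centerline",
    "default_coronary_tree",
    "static_spec",
]


# --------------------------------------------------------------------------
# primitives
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid with absolute and host attenuation (1/mm)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    mu: float
    host_mu: float
    priority: int
    label: str = ""

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = (np.asarray(points, dtype=float) - np.asarray(self.center)) / np.asarray(
            self.semi_axes
        )
        return np.einsum("...i,...i->...", p, p) <= 1.0

    def chords(self, origins: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        """Length of each ray's intersection with the ellipsoid.

        ``origins``/``dirs`` have shape (N, 3); directions must be unit.
        """
        s = np.asarray(self.semi_axes)
        e = (origins - np.asarray(self.center)) / s
        f = dirs / s
        a = np.einsum("ij,ij->i", f, f)
        b = np.einsum("ij,ij->i", e, f)
        c = np.einsum("ij,ij->i", e, e) - 1.0
        disc = b * b - a * c
        out = np.zeros(len(origins))
        hit = disc > 0
        out[hit] = 2.0 * np.sqrt(disc[hit]) / a[hit]
        return out


_BIG = 1.0e30


def _capsule_interval(p0: np.ndarray, p1: np.ndarray, radius: float,
                      origins: np.ndarray, dirs: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Entry/exit ray parameters of one capsule (single interval: capsules
    are convex, the union of the slab-clipped cylinder and the two cap
    spheres).  Empty intersections are encoded as (+_BIG, -_BIG)."""
    r2 = radius**2
    a = np.asarray(p0, dtype=float)
    axis = np.asarray(p1, dtype=float) - a
    L = float(np.linalg.norm(axis))
    ah = axis / L if L > 0 else np.array([0.0, 0.0, 1.0])

    m = origins - a
    md = m @ ah
    dd = dirs @ ah

    lo = np.full(len(origins), _BIG)
    hi = np.full(len(origins), -_BIG)

    def merge(t1, t2, valid):
        np.minimum(lo, np.where(valid, t1, _BIG), out=lo)
        np.maximum(hi, np.where(valid, t2, -_BIG), out=hi)

    # infinite cylinder clipped to the axial slab [0, L]
    mp = m - np.outer(md, ah)
    dp = dirs - np.outer(dd, ah)
    A = np.einsum("ij,ij->i", dp, dp)
    B = np.einsum("ij,ij->i", mp, dp)
    C = np.einsum("ij,ij->i", mp, mp) - r2
    with np.errstate(divide="ignore", invalid="ignore"):
        disc = B * B - A * C
        sq = np.sqrt(np.maximum(disc, 0.0))
        t1 = np.where(A > 1e-14, (-B - sq) / A, -_BIG)
        t2 = np.where(A > 1e-14, (-B + sq) / A, _BIG)
        # slab interval along t
        s1 = np.where(np.abs(dd) > 1e-14, (0.0 - md) / dd, -_BIG)
        s2 = np.where(np.abs(dd) > 1e-14, (L - md) / dd, _BIG)
    slo = np.minimum(s1, s2)
    shi = np.maximum(s1, s2)
    # rays parallel to axis outside the slab never cross it
    par_out = (np.abs(dd) <= 1e-14) & ((md < 0) | (md > L))
    cyl_hit = (disc > 0) | (A <= 1e-14)
    cyl_hit &= ~((A <= 1e-14) & (C > 0))
    c1 = np.maximum(t1, slo)
    c2 = np.minimum(t2, shi)
    merge(c1, c2, cyl_hit & ~par_out & (c2 > c1))

    # cap spheres
    for cen in (a, a + axis):
        mm = origins - cen
        Bs = np.einsum("ij,ij->i", mm, dirs)
        Cs = np.einsum("ij,ij->i", mm, mm) - r2
        disc_s = Bs * Bs - Cs
        sqs = np.sqrt(np.maximum(disc_s, 0.0))
        merge(-Bs - sqs, -Bs + sqs, disc_s > 0)
    return lo, hi


def _capsule_intervals_batch(segments, origins: np.ndarray, dirs: np.ndarray
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Entry/exit parameters of many capsules at once, shape (n_seg, n_rays);
    empty intersections encoded as (+_BIG, -_BIG)."""
    p0 = np.array([s[0] for s in segments], dtype=float)      # (S, 3)
    p1 = np.array([s[1] for s in segments], dtype=float)
    rad = np.array([s[2] for s in segments], dtype=float)     # (S,)
    axis = p1 - p0
    length = np.linalg.norm(axis, axis=1)
    ah = np.where(length[:, None] > 0, axis / np.maximum(length, 1e-300)[:, None],
                  np.array([0.0, 0.0, 1.0]))
    r2 = (rad**2)[:, None]

    m = origins[None, :, :] - p0[:, None, :]                  # (S, N, 3)
    md = np.einsum("snk,sk->sn", m, ah)
    dd = np.einsum("nk,sk->sn", dirs, ah)
    mp = m - md[..., None] * ah[:, None, :]
    dp = dirs[None, :, :] - dd[..., None] * ah[:, None, :]
    A = np.einsum("snk,snk->sn", dp, dp)
    B = np.einsum("snk,snk->sn", mp, dp)
    C = np.einsum("snk,snk->sn", mp, mp) - r2
    with np.errstate(divide="ignore", invalid="ignore"):
        disc = B * B - A * C
        sq = np.sqrt(np.maximum(disc, 0.0))
        ok_a = A > 1e-14
        t1 = np.where(ok_a, (-B - sq) / A, -_BIG)
        t2 = np.where(ok_a, (-B + sq) / A, _BIG)
        ok_d = np.abs(dd) > 1e-14
        s1 = np.where(ok_d, (0.0 - md) / dd, -_BIG)
        s2 = np.where(ok_d, (length[:, None] - md) / dd, _BIG)
    slo = np.minimum(s1, s2)
    shi = np.maximum(s1, s2)
    par_out = ~ok_d & ((md < 0) | (md > length[:, None]))
    cyl_hit = ((disc > 0) | ~ok_a) & ~(~ok_a & (C > 0)) & ~par_out
    c1 = np.maximum(t1, slo)
    c2 = np.minimum(t2, shi)
    valid = cyl_hit & (c2 > c1)
    lo = np.where(valid, c1, _BIG)
    hi = np.where(valid, c2, -_BIG)

    for cen in (p0, p1):
        mm = origins[None, :, :] - cen[:, None, :]
        Bs = np.einsum("snk,nk->sn", mm, dirs)
        Cs = np.einsum("snk,snk->sn", mm, mm) - r2
        disc_s = Bs * Bs - Cs
        sqs = np.sqrt(np.maximum(disc_s, 0.0))
        hit = disc_s > 0
        np.minimum(lo, np.where(hit, -Bs - sqs, _BIG), out=lo)
        np.maximum(hi, np.where(hit, -Bs + sqs, -_BIG), out=hi)
    return lo, hi


def _capsule_intervals_pairs(p0: np.ndarray, p1: np.ndarray, rad: np.ndarray,
                             src: np.ndarray, dirs: np.ndarray
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Exact intervals for paired (capsule, ray) arrays of equal length P,
    all rays sharing the origin `src`."""
    axis = p1 - p0
    length = np.linalg.norm(axis, axis=1)
    ah = axis / np.maximum(length, 1e-300)[:, None]
    r2 = rad**2

    m = src[None, :] - p0                          # (P, 3)
    md = np.einsum("pk,pk->p", m, ah)
    dd = np.einsum("pk,pk->p", dirs, ah)
    mp = m - md[:, None] * ah
    dp = dirs - dd[:, None] * ah
    A = np.einsum("pk,pk->p", dp, dp)
    B = np.einsum("pk,pk->p", mp, dp)
    C = np.einsum("pk,pk->p", mp, mp) - r2
    with np.errstate(divide="ignore", invalid="ignore"):
        disc = B * B - A * C
        sq = np.sqrt(np.maximum(disc, 0.0))
        ok_a = A > 1e-14
        t1 = np.where(ok_a, (-B - sq) / A, -_BIG)
        t2 = np.where(ok_a, (-B + sq) / A, _BIG)
        ok_d = np.abs(dd) > 1e-14
        s1 = np.where(ok_d, (0.0 - md) / dd, -_BIG)
        s2 = np.where(ok_d, (length - md) / dd, _BIG)
    slo = np.minimum(s1, s2)
    shi = np.maximum(s1, s2)
    par_out = ~ok_d & ((md < 0) | (md > length))
    cyl_hit = ((disc > 0) | ~ok_a) & ~(~ok_a & (C > 0)) & ~par_out
    c1 = np.maximum(t1, slo)
    c2 = np.minimum(t2, shi)
    valid = cyl_hit & (c2 > c1)
    lo = np.where(valid, c1, _BIG)
    hi = np.where(valid, c2, -_BIG)
    for cen in (p0, p1):
        mm = src[None, :] - cen
        Bs = np.einsum("pk,pk->p", mm, dirs)
        Cs = np.einsum("pk,pk->p", mm, mm) - r2
        disc_s = Bs * Bs - Cs
        sqs = np.sqrt(np.maximum(disc_s, 0.0))
        hit = disc_s > 0
        np.minimum(lo, np.where(hit, -Bs - sqs, _BIG), out=lo)
        np.maximum(hi, np.where(hit, -Bs + sqs, -_BIG), out=hi)
    return lo, hi


def _point_in_capsule(p0, p1, radius, points: np.ndarray) -> np.ndarray:
    p = np.asarray(points, dtype=float)
    a = np.asarray(p0, dtype=float)
    d = np.asarray(p1, dtype=float) - a
    L2 = float(d @ d)
    if L2 == 0.0:
        t = np.zeros(p.shape[:-1])
    else:
        t = np.clip(np.einsum("...i,i->...", p - a, d) / L2, 0.0, 1.0)
    closest = a + t[..., None] * d
    dist2 = np.einsum("...i,...i->...", p - closest, p - closest)
    return dist2 <= radius**2


@dataclass(frozen=True)
class Capsule:
    """Capsule (cylinder with spherical caps) between two points."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float
    mu: float
    host_mu: float
    priority: int
    label: str = ""

    def contains(self, points: np.ndarray) -> np.ndarray:
        return _point_in_capsule(self.p0, self.p1, self.radius, points)

    def chords(self, origins: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        lo, hi = _capsule_interval(self.p0, self.p1, self.radius, origins, dirs)
        return np.maximum(hi - lo, 0.0)


@dataclass(frozen=True)
class CapsuleChain:
    """Union of capsule segments with per-segment radii (a vessel tree).

    Line integrals use the exact union of the per-segment intervals so that
    overlapping joints and crossing branches are never double counted.
    """

    segments: tuple[tuple[tuple, tuple, float], ...]   # (p0, p1, radius)
    mu: float
    host_mu: float
    priority: int
    label: str = ""

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        out = np.zeros(p.shape[:-1], dtype=bool)
        for p0, p1, r in self.segments:
            out |= _point_in_capsule(p0, p1, r, p)
        return out

    def contains_min_radius(self, points: np.ndarray,
                            min_radius: float) -> np.ndarray:
        """Membership restricted to segments at/above a radius (proximal
        portions of the tree)."""
        p = np.asarray(points, dtype=float)
        out = np.zeros(p.shape[:-1], dtype=bool)
        for p0, p1, r in self.segments:
            if r >= min_radius:
                out |= _point_in_capsule(p0, p1, r, p)
        return out

    def chords(self, origins: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        if len(origins) > 64 and np.ptp(origins, axis=0).max() < 1e-12:
            return self._chords_shared_origin(origins[0], dirs)
        lo, hi = _capsule_intervals_batch(self.segments, origins, dirs)
        order = np.argsort(lo, axis=0)
        lo = np.take_along_axis(lo, order, axis=0)
        hi = np.take_along_axis(hi, order, axis=0)
        run = np.maximum.accumulate(hi, axis=0)
        prev = np.vstack([np.full((1, lo.shape[1]), -_BIG), run[:-1]])
        contrib = np.clip(hi - np.maximum(lo, prev), 0.0, None)
        return contrib.sum(axis=0)

    def _chords_shared_origin(self, src: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        """Fast path for cone-beam frames (one source, many rays): a cheap
        ray-to-segment-midpoint bound selects the few (segment, ray) pairs
        that can intersect; exact intervals are evaluated pairwise and
        unioned per ray."""
        p0 = np.array([s[0] for s in self.segments], dtype=float)
        p1 = np.array([s[1] for s in self.segments], dtype=float)
        rad = np.array([s[2] for s in self.segments], dtype=float)
        mid = 0.5 * (p0 + p1)
        reach = 0.5 * np.linalg.norm(p1 - p0, axis=1) + rad

        w = mid - src                                    # (S, 3)
        proj = w @ dirs.T                                # (S, N)
        d2 = np.einsum("sk,sk->s", w, w)[:, None] - proj**2
        seg_i, ray_i = np.nonzero(d2 <= (reach**2)[:, None] * 1.000001)
        total = np.zeros(len(dirs))
        if len(seg_i) == 0:
            return total
        lo, hi = _capsule_intervals_pairs(p0[seg_i], p1[seg_i], rad[seg_i],
                                          src, dirs[ray_i])
        valid = hi > lo
        seg_i, ray_i, lo, hi = seg_i[valid], ray_i[valid], lo[valid], hi[valid]
        if len(ray_i) == 0:
            return total
        # grouped union: sort by (ray, lo); running max of hi within each
        # ray group via a per-group additive offset
        order = np.lexsort((lo, ray_i))
        ray_s, lo_s, hi_s = ray_i[order], lo[order], hi[order]
        big = 4.0 * (np.abs(hi_s).max() + np.abs(lo_s).max() + 1.0)
        run = np.maximum.accumulate(ray_s * big + hi_s)
        prev = np.concatenate([[-_BIG], run[:-1]]) - ray_s * big
        prev[prev < -0.5 * big] = -_BIG           # previous entry was another ray
        contrib = np.clip(hi_s - np.maximum(lo_s, prev), 0.0, None)
        np.add.at(total, ray_s, contrib)
        return total


Primitive = Ellipsoid | Capsule | CapsuleChain


# --------------------------------------------------------------------------
# specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CoronaryBranch:
    """A coronary branch in epicardial surface coordinates.

    ``phi`` is the azimuth (rad), ``zeta`` the normalized long-axis position
    (z / outer long semi-axis, +1 base ... -1 apex) and ``diameter`` the local
    vessel diameter in mm, non-increasing away from the ostium.
    """

    phi: tuple[float, ...]
    zeta: tuple[float, ...]
    diameter: tuple[float, ...]
    name: str = ""


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of the dynamic mouse thorax/heart.

    Lengths are mm except coronary diameters (um, as usually quoted);
    tissue values are HU; rates are per minute.
    """

    heart_long_axis: float = 9.0          # mm
    heart_short_axis: float = 4.0         # mm
    lv_wall_thickness: float = 0.55       # mm
    coronary_ostium_diameter: float = 400.0   # um
    coronary_mean_diameter: float = 160.0     # um
    blood_enhancement: float = 600.0      # HU
    myocardium_hu: float = 50.0
    background_hu: float = -200.0
    heart_rate: float = 600.0             # bpm
    resp_rate: float = 300.0              # rpm
    ejection_amplitude: float = 0.25      # fractional inner-radius contraction
    resp_amplitude: float = 0.8           # mm craniocaudal translation
    resp_ap_expansion: float = 0.03       # fractional AP expansion
    waveform_duty: float = 0.35           # fraction of cardiac cycle in systole
    resp_duty: float = 0.45               # fraction of resp cycle in the gasp
    body_semi_axes: tuple[float, float, float] = (5.5, 5.0, 7.0)
    mu_water: float = MU_WATER
    include_rca: bool = False
    phase_jitter: float = 0.0             # cycles, Gaussian sigma
    jitter_seed: int = 0
    coronary_tree: tuple[CoronaryBranch, ...] | None = None

    def __post_init__(self):
        if self.heart_long_axis <= 0 or self.heart_short_axis <= 0:
            raise InvalidParameterError("heart axes must be positive")
        if self.heart_long_axis <= self.heart_short_axis:
            raise InvalidParameterError("long axis must exceed short axis")
        if self.heart_rate <= 0 or self.resp_rate <= 0:
            raise InvalidParameterError("rates must be positive")
        if min(self.coronary_ostium_diameter, self.coronary_mean_diameter) <= 0:
            raise InvalidParameterError("coronary diameters must be positive")
        if not (0 < self.waveform_duty < 1) or not (0 < self.resp_duty < 1):
            raise InvalidParameterError("duty factors must be in (0, 1)")
        if self.lv_wall_thickness <= 0:
            raise InvalidParameterError("wall thickness must be positive")

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path: str | Path | None = None) -> str:
        d = _spec_to_dict(self)
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, src: str | Path) -> "PhantomSpec":
        if isinstance(src, Path) or (isinstance(src, str) and "\n" not in src and Path(src).exists()):
            text = Path(src).read_text()
        else:
            text = src
        d = yaml.safe_load(io.StringIO(text))
        tree = d.pop("coronary_tree", None)
        if tree is not None:
            tree = tuple(
                CoronaryBranch(
                    tuple(b["phi"]), tuple(b["zeta"]), tuple(b["diameter"]),
                    b.get("name", ""),
                )
                for b in tree
            )
        d["body_semi_axes"] = tuple(d["body_semi_axes"])
        return cls(coronary_tree=tree, **d)


def _spec_to_dict(spec: PhantomSpec) -> dict:
    d = {
        k: getattr(spec, k)
        for k in PhantomSpec.__dataclass_fields__
        if k != "coronary_tree"
    }
    d["body_semi_axes"] = list(spec.body_semi_axes)
    if spec.coronary_tree is not None:
        d["coronary_tree"] = [
            {"phi": list(b.phi), "zeta": list(b.zeta),
             "diameter": list(b.diameter), "name": b.name}
            for b in spec.coronary_tree
        ]
    return d


def default_coronary_tree(spec: PhantomSpec) -> tuple[CoronaryBranch, ...]:
    """Left coronary tree: trunk -> bifurcation into OMA/LCX analogues with
    small sub-branches; an optional RCA analogue on the right side.

    Diameters taper linearly from the ostium value to the bifurcation
    (~0.65x ostium, matching the reported 400/260 um pair) and on to
    half the quoted mean diameter at the distal tips.
    """
    d_ost = spec.coronary_ostium_diameter / 1000.0   # -> mm
    d_bif = 0.65 * d_ost
    d_tip = 0.5 * spec.coronary_mean_diameter / 1000.0

    def lin(a, b, n):
        return tuple(np.linspace(a, b, n))

    n_tr, n_br = 8, 14
    trunk = CoronaryBranch(
        phi=lin(0.30 * np.pi, 0.45 * np.pi, n_tr),
        zeta=lin(0.93, 0.50, n_tr),
        diameter=lin(d_ost, d_bif, n_tr),
        name="trunk",
    )
    oma = CoronaryBranch(   # oblique course to the apex
        phi=lin(0.45 * np.pi, 0.85 * np.pi, n_br),
        zeta=lin(0.50, -0.92, n_br),
        diameter=lin(d_bif, d_tip, n_br),
        name="OMA",
    )
    lcx = CoronaryBranch(   # circumflex along the atrioventricular groove
        phi=lin(0.45 * np.pi, 1.25 * np.pi, n_br),
        zeta=lin(0.48, 0.30, n_br),
        diameter=lin(d_bif, d_tip, n_br),
        name="LCX",
    )
    sub1 = CoronaryBranch(
        phi=lin(0.62 * np.pi, 0.45 * np.pi, 6),
        zeta=lin(-0.10, -0.55, 6),
        diameter=lin(0.45 * d_ost * 0.65, d_tip, 6),
        name="OMA-sub",
    )
    sub2 = CoronaryBranch(
        phi=lin(0.85 * np.pi, 1.05 * np.pi, 6),
        zeta=lin(0.40, -0.05, 6),
        diameter=lin(0.45 * d_ost * 0.65, d_tip, 6),
        name="LCX-sub",
    )
    tree = [trunk, oma, lcx, sub1, sub2]
    if spec.include_rca:
        tree.append(
            CoronaryBranch(
                phi=lin(-0.25 * np.pi, -0.85 * np.pi, n_br),
                zeta=lin(0.90, 0.25, n_br),
                diameter=lin(0.65 * d_ost, d_tip, n_br),
                name="RCA",
            )
        )
    return tuple(tree)


# --------------------------------------------------------------------------
# waveforms and phases
# --------------------------------------------------------------------------

def cardiac_phase(time, heart_rate: float):
    """Fractional cardiac phase in [0, 1) at `time` (s) for `heart_rate` (bpm)."""
    if heart_rate <= 0:
        raise InvalidParameterError("heart_rate must be positive")
    return np.mod(np.asarray(time, dtype=float) * heart_rate / 60.0, 1.0)


def respiratory_phase(time, resp_rate: float):
    """Fractional respiratory phase in [0, 1) at `time` (s) for `resp_rate` (rpm)."""
    if resp_rate <= 0:
        raise InvalidParameterError("resp_rate must be positive")
    return np.mod(np.asarray(time, dtype=float) * resp_rate / 60.0, 1.0)


def raised_cosine(phase, duty: float):
    """Raised-cosine activity waveform: 0 at phase 0, a single smooth bump of
    unit peak within [0, duty), and exactly 0 on the plateau [duty, 1)."""
    p = np.mod(np.asarray(phase, dtype=float), 1.0)
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * p / duty))
    return np.where(p < duty, w, 0.0)


# --------------------------------------------------------------------------
# state instantiation
# --------------------------------------------------------------------------

@dataclass
class PhantomState:
    """Phantom anatomy frozen at one time point, evaluable as mu(x) (1/mm)."""

    spec: PhantomSpec | None
    time: float
    cardiac_phase: float
    resp_phase: float
    primitives: list[Primitive] = field(default_factory=list)

    @classmethod
    def from_primitives(cls, primitives, time: float = 0.0) -> "PhantomState":
        """Build a bare state from an explicit primitive list (for tests and
        calibration objects such as uniform cylinders)."""
        return cls(spec=None, time=time, cardiac_phase=0.0, resp_phase=0.0,
                   primitives=list(primitives))


# priorities: higher wins at a point
PRIO_BODY, PRIO_VESSEL, PRIO_MYO, PRIO_CHAMBER, PRIO_CORONARY = 0, 1, 2, 3, 4


def instantiate(spec: PhantomSpec, time: float) -> PhantomState:
    """Evaluate the motion model and build the primitive set at `time` (s)."""
    c = float(cardiac_phase(time, spec.heart_rate))
    r = float(respiratory_phase(time, spec.resp_rate))
    if spec.phase_jitter > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.jitter_seed, int(round(time * 1e7)) & 0x7FFFFFFF])
        )
        c = float(np.mod(c + rng.normal(0.0, spec.phase_jitter), 1.0))
    return instantiate_phases(spec, c, r, time=time)


def instantiate_phases(spec: PhantomSpec, c: float, r: float,
                       time: float = 0.0) -> PhantomState:
    """Build the primitive set directly at cardiac phase `c` and respiratory
    phase `r` (both in [0, 1))."""

    wc = float(raised_cosine(c, spec.waveform_duty)) * (spec.ejection_amplitude > 0)
    wr = float(raised_cosine(r, spec.resp_duty)) * (
        spec.resp_amplitude > 0 or spec.resp_ap_expansion > 0
    )

    mu_bg = hu_to_mu(spec.background_hu, spec.mu_water)
    mu_myo = hu_to_mu(spec.myocardium_hu, spec.mu_water)
    mu_blood = hu_to_mu(spec.blood_enhancement, spec.mu_water)

    # respiratory transform: craniocaudal shift of the heart and vessels,
    # AP (y) expansion of the thorax body
    dz = spec.resp_amplitude * wr
    ap = 1.0 + spec.resp_ap_expansion * wr

    b = spec.heart_short_axis / 2.0          # outer transverse semi-axis at rest
    c_out = spec.heart_long_axis / 2.0       # outer long semi-axis (fixed)
    u = b / 2.0                              # anatomy length unit

    # resting chamber geometry (disjoint by construction; the containment/
    # disjointness invariant is asserted by the test suite over the cycle)
    lv_semi0 = spec.heart_short_axis / 2.0 - spec.lv_wall_thickness - 0.40
    lv_center = np.array([-0.55, 0.0, -0.25]) * u
    lv_semi = np.array([0.90 * lv_semi0, lv_semi0])
    lv_z = 0.72 * c_out
    rv_center = np.array([1.05, 0.0, 0.0]) * u
    rv_semi = np.array([0.50, 0.85]) * u
    rv_z = 0.53 * c_out

    s_in = 1.0 - spec.ejection_amplitude * wc    # transverse contraction factor
    lv_ab = lv_semi * s_in
    rv_ab = rv_semi * s_in

    # conserve myocardial shell volume: adjust outer transverse semi-axes
    def ell_vol(a_, b_, c_):
        return 4.0 / 3.0 * np.pi * a_ * b_ * c_

    v_shell0 = (ell_vol(b, b, c_out)
                - ell_vol(lv_semi[0], lv_semi[1], lv_z)
                - ell_vol(rv_semi[0], rv_semi[1], rv_z))
    v_in = ell_vol(lv_ab[0], lv_ab[1], lv_z) + ell_vol(rv_ab[0], rv_ab[1], rv_z)
    ab_out2 = (v_shell0 + v_in) * 3.0 / (4.0 * np.pi * c_out)
    g = np.sqrt(ab_out2) / b                      # common outer transverse scale
    a_out = b_out = b * g

    prims: list[Primitive] = []

    # thorax body (host: air)
    body = np.asarray(spec.body_semi_axes, dtype=float)
    prims.append(Ellipsoid((0.0, 0.0, 0.0), (body[0], body[1] * ap, body[2]),
                           mu_bg, 0.0, PRIO_BODY, "body"))

    shift = np.array([0.0, 0.0, dz])

    prims.append(Ellipsoid(tuple(shift), (a_out, b_out, c_out),
                           mu_myo, mu_bg, PRIO_MYO, "myocardium"))
    prims.append(Ellipsoid(tuple(lv_center + shift), (lv_ab[0], lv_ab[1], lv_z),
                           mu_blood, mu_myo, PRIO_CHAMBER, "lv-blood"))
    prims.append(Ellipsoid(tuple(rv_center + shift), (rv_ab[0], rv_ab[1], rv_z),
                           mu_blood, mu_myo, PRIO_CHAMBER, "rv-blood"))

    # atria: anti-phase (filled in systole), small spheres near the base
    r_at = 0.30 * u * (1.0 + 0.15 * wc)
    for sx, name in ((-1.0, "left-atrium"), (1.0, "right-atrium")):
        cen = np.array([sx * 0.75, 0.28, 0.0]) * u + np.array([0, 0, 0.72 * c_out])
        prims.append(Ellipsoid(tuple(cen + shift), (r_at, r_at, r_at),
                               mu_blood, mu_myo, PRIO_CHAMBER, name))

    # great vessels above the heart base (host: body background)
    z_top = c_out + 0.55
    aorta_r = 0.60 * u
    prims.append(Capsule(tuple(np.array([0.3, -0.3, z_top]) + shift),
                         tuple(np.array([0.6, -0.1, z_top + 0.3]) + shift),
                         aorta_r, mu_blood, mu_bg, PRIO_VESSEL, "aorta"))
    pt_r = 0.50 * u * (1.0 + 0.15 * wc)   # dilates in systole
    prims.append(Capsule(tuple(np.array([-0.9, 0.6, z_top - 0.45]) + shift),
                         tuple(np.array([-1.3, 1.1, z_top - 0.05]) + shift),
                         pt_r, mu_blood, mu_bg, PRIO_VESSEL, "pulmonary-trunk"))

    # coronary tree riding the epicardial surface (host: body background);
    # one chain primitive so joints and crossings are never double counted
    tree = spec.coronary_tree or default_coronary_tree(spec)
    segments = []
    for branch in tree:
        pts = _branch_points(branch, a_out, b_out, c_out) + shift
        radii = 0.5 * np.asarray(branch.diameter)
        for i in range(len(pts) - 1):
            rad = 0.5 * (radii[i] + radii[i + 1])
            segments.append((tuple(pts[i]), tuple(pts[i + 1]), float(rad)))
    prims.append(CapsuleChain(tuple(segments), mu_blood, mu_bg,
                              PRIO_CORONARY, "coronary-tree"))

    return PhantomState(spec=spec, time=float(time), cardiac_phase=c,
                        resp_phase=r, primitives=prims)


def _branch_points(branch: CoronaryBranch, a_out: float, b_out: float,
                   c_out: float) -> np.ndarray:
    """World points of a branch: epicardial surface position pushed outward
    (radially) by 1.3 local radii so the capsules clear the moving surface."""
    phi = np.asarray(branch.phi)
    zeta = np.asarray(branch.zeta)
    rad = 0.5 * np.asarray(branch.diameter)
    off = 1.3 * rad
    rho = np.sqrt(np.clip(1.0 - zeta**2, 0.0, None))
    x = (a_out + off) * rho * np.cos(phi)
    y = (b_out + off) * rho * np.sin(phi)
    z = (c_out + off) * zeta
    return np.stack([x, y, z], axis=-1)


def coronary_centerline(state: PhantomState) -> list[np.ndarray]:
    """World-coordinate polylines of each coronary branch of a state."""
    spec = state.spec
    if spec is None:
        return []
    myo = next(p for p in state.primitives
               if isinstance(p, Ellipsoid) and p.label == "myocardium")
    a_out, b_out, c_out = myo.semi_axes
    shift = np.asarray(myo.center)
    tree = spec.coronary_tree or default_coronary_tree(spec)
    return [_branch_points(b, a_out, b_out, c_out) + shift for b in tree]


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

def attenuation_at(state: PhantomState, points: np.ndarray) -> np.ndarray:
    """Piecewise-constant mu(x) in 1/mm; the highest-priority primitive wins."""
    p = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(p)):
        raise InvalidParameterError("points must be finite")
    mu = np.zeros(p.shape[:-1])
    for prim in sorted(state.primitives, key=lambda q: q.priority):
        inside = prim.contains(p)
        mu[inside] = prim.mu
    return mu


def voxelize(state: PhantomState, grid: GridSpec, supersample: int = 1) -> Volume:
    """Sample mu(x) on a grid (optionally with sub-voxel supersampling)."""
    pts = grid.points()
    if supersample <= 1:
        data = attenuation_at(state, pts.reshape(-1, 3)).reshape(grid.shape)
    else:
        acc = np.zeros(grid.shape)
        offs = (np.arange(supersample) + 0.5) / supersample - 0.5
        for oz in offs:
            for oy in offs:
                for ox in offs:
                    q = pts + grid.voxel * np.array([ox, oy, oz])
                    acc += attenuation_at(state, q.reshape(-1, 3)).reshape(grid.shape)
        data = acc / supersample**3
    return Volume(data.astype(np.float32), grid,
                  provenance={"kind": "phantom", "time": state.time,
                              "cardiac_phase": state.cardiac_phase,
                              "resp_phase": state.resp_phase})


def static_spec(spec: PhantomSpec | None = None) -> PhantomSpec:
    """Copy of a spec with all motion amplitudes set to zero."""
    spec = spec or PhantomSpec()
    return replace(spec, ejection_amplitude=0.0, resp_amplitude=0.0,
                   resp_ap_expansion=0.0)
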