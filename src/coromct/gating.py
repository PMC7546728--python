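"""Intrinsic cardiorespiratory gating from projection rawdata.

Both gating signals are derived from the projections themselves, without
ECG electrodes or a pneumatic pillow:

* respiratory surrogate: the row-wise (craniocaudal) center of mass of the
  detector intensity of each frame, which follows the breathing translation
  of the thorax;
* cardiac surrogate: the mean intensity inside an automatically selected
  detector region whose temporal spectrum carries the most energy in the
  cardiac frequency band (the beating heart's projection footprint).

Each surrogate is band-pass filtered (zero-phase Butterworth, order 4)
around the dominant spectral peak found inside its physiological search
band; signal peaks are then detected with sub-frame (parabolic) refinement
and the phase is a linear 0 -> 1 ramp between consecutive peaks.  Phase 0
therefore sits at the surrogate peak; the convention is arbitrary but
consistent, which is all retrospective binning requires.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.fft
from scipy import signal

from .errors import GatingError, InvalidParameterError
from .scanner import ProjectionSet

__all__ = [
    "PhaseTrack",
    "GatingSpec",
    "GatingParams",
    "extract_gating_signals",
    "assign_bins",
    "BinAssignment",
    "max_integration_time_ms",
]


@dataclass(frozen=True)
class GatingParams:
    """Tunables of the surrogate extraction (Hz bands fit the default rates:
    ~10 Hz cardiac at 600 bpm, ~5 Hz respiratory at 300 rpm)."""

    resp_band: tuple[float, float] = (1.0, 8.0)
    cardiac_band: tuple[float, float] = (6.0, 15.0)
    bandpass_halfwidth: float = 0.35      # relative to the detected peak frequency
    roi_fraction: float = 0.05            # detector fraction used for the cardiac ROI
    min_peak_snr: float = 3.0             # spectral peak vs band median power


@dataclass
class PhaseTrack:
    """Per-frame cardiac/respiratory phases plus audit signals."""

    cardiac_phase: np.ndarray
    resp_phase: np.ndarray
    cardiac_rate_bpm: float
    resp_rate_rpm: float
    surrogates: dict = field(default_factory=dict)

    def __post_init__(self):
        self.cardiac_phase = np.asarray(self.cardiac_phase, dtype=float)
        self.resp_phase = np.asarray(self.resp_phase, dtype=float)
        for p in (self.cardiac_phase, self.resp_phase):
            if np.any((p < 0) | (p >= 1)):
                raise InvalidParameterError("phases must lie in [0, 1)")
        if len(self.cardiac_phase) != len(self.resp_phase):
            raise InvalidParameterError("phase track length mismatch")

    def __len__(self) -> int:
        return len(self.cardiac_phase)

    def export_csv(self, path: str | Path, timestamps=None, bins=None) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            header = ["frame", "time_s", "cardiac_phase", "resp_phase"]
            if bins is not None:
                header += ["cardiac_bin", "resp_bin"]
            w.writerow(header)
            for i in range(len(self)):
                row = [i,
                       "" if timestamps is None else f"{timestamps[i]:.6f}",
                       f"{self.cardiac_phase[i]:.6f}", f"{self.resp_phase[i]:.6f}"]
                if bins is not None:
                    row += [int(bins.cardiac_bin[i]), int(bins.resp_bin[i])]
                w.writerow(row)

    @classmethod
    def from_true_phases(cls, projections: ProjectionSet) -> "PhaseTrack":
        """Ground-truth track recorded by the simulator (simulation privilege)."""
        if projections.true_cardiac_phase is None:
            raise InvalidParameterError("projection set carries no ground-truth phases")
        t = projections.timeline.timestamps
        dur = t[-1] - t[0]
        c = projections.true_cardiac_phase
        r = projections.true_resp_phase
        return cls(c, r,
                   cardiac_rate_bpm=60.0 * _cycles(c) / dur,
                   resp_rate_rpm=60.0 * _cycles(r) / dur)


def _cycles(phase: np.ndarray) -> float:
    return float(np.sum(np.diff(phase) < -0.5) + (phase[-1] - phase[0]))


@dataclass(frozen=True)
class GatingSpec:
    """Gating window definitions (defaults: 4 x 25 % respiratory and
    10 x 10 % cardiac non-overlapping windows, centers equispaced)."""

    n_resp_bins: int = 4
    resp_width: float = 25.0        # percent of the cycle
    n_cardiac_bins: int = 10
    cardiac_width: float = 10.0     # percent

    def __post_init__(self):
        for w in (self.resp_width, self.cardiac_width):
            if not (0 < w <= 100):
                raise InvalidParameterError("window widths must be in (0, 100] percent")
        if self.n_resp_bins < 1 or self.n_cardiac_bins < 1:
            raise InvalidParameterError("bin counts must be >= 1")

    def centers(self, which: str) -> np.ndarray:
        n = self.n_cardiac_bins if which == "cardiac" else self.n_resp_bins
        return (np.arange(n) + 0.5) / n

    def expected_joint_fraction(self) -> float:
        """Expected per-joint-bin frame fraction for uniform phases."""
        return (self.cardiac_width / 100.0) * (self.resp_width / 100.0)


# --------------------------------------------------------------------------
# surrogate extraction
# --------------------------------------------------------------------------

def _harmonic_notch(freqs: np.ndarray, f0: float, halfwidth: float = 0.15,
                    k_max: int = 12) -> np.ndarray:
    """Boolean mask that is False within `halfwidth` Hz of any harmonic of
    f0 (used to keep respiratory harmonics out of the cardiac analysis)."""
    keep = np.ones(len(freqs), dtype=bool)
    for k in range(1, k_max + 1):
        keep &= np.abs(freqs - k * f0) > halfwidth
    return keep


def _regress_out_harmonics(x: np.ndarray, t: np.ndarray, fundamentals,
                           k_max: int = 10, f_max: float = 20.0) -> np.ndarray:
    """Least-squares removal of the harmonic series of each fundamental."""
    cols = [np.ones_like(t)]
    for f0 in fundamentals:
        for k in range(1, k_max + 1):
            f = k * f0
            if f > f_max:
                break
            cols += [np.cos(2 * np.pi * f * t), np.sin(2 * np.pi * f * t)]
    X = np.stack(cols, axis=1)
    beta, *_ = np.linalg.lstsq(X, x, rcond=None)
    return x - X @ beta


def _dominant_frequency(x: np.ndarray, fs: float, band: tuple[float, float],
                        name: str, min_snr: float,
                        notch: np.ndarray | None = None) -> float:
    x = x - x.mean()
    freqs = scipy.fft.rfftfreq(len(x), 1.0 / fs)
    power = np.abs(scipy.fft.rfft(x)) ** 2
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if notch is not None:
        sel &= notch
    if not np.any(sel):
        raise GatingError(f"{name}: search band {band} outside spectrum")
    p_band = power[sel]
    # exponential (chi^2_2) noise floor: the expected maximum over n bins is
    # ~mean*ln(n), so require the peak to clear that by `min_snr`
    mean_floor = np.median(p_band) / np.log(2.0) + 1e-30
    k = int(np.argmax(p_band))
    if p_band[k] < min_snr * mean_floor * np.log(len(p_band) + 1.0):
        raise GatingError(
            f"{name}: no spectral peak above the noise floor in band {band} Hz"
        )
    # parabolic refinement on log power
    ks = np.flatnonzero(sel)
    kk = ks[k]
    if 0 < kk < len(power) - 1:
        lp = np.log(power[kk - 1:kk + 2] + 1e-30)
        denom = lp[0] - 2 * lp[1] + lp[2]
        delta = 0.5 * (lp[0] - lp[2]) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return float(freqs[kk] + delta * (freqs[1] - freqs[0]))


def _bandpass(x: np.ndarray, fs: float, f0: float, halfwidth: float) -> np.ndarray:
    lo = max(f0 * (1 - halfwidth), 0.05)
    hi = min(f0 * (1 + halfwidth), 0.49 * fs)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x - x.mean())


def _peak_phases(x: np.ndarray, fs: float, f0: float) -> tuple[np.ndarray, float]:
    """Phase ramp from sub-frame-refined peaks of a band-passed surrogate."""
    dist = max(2, int(round(0.7 * fs / f0)))
    peaks, _ = signal.find_peaks(x, distance=dist)
    if len(peaks) < 3:
        raise GatingError("fewer than 3 surrogate peaks detected")
    # parabolic sub-sample refinement
    t_pk = []
    for p in peaks:
        if 0 < p < len(x) - 1:
            denom = x[p - 1] - 2 * x[p] + x[p + 1]
            d = 0.5 * (x[p - 1] - x[p + 1]) / denom if denom != 0 else 0.0
            t_pk.append((p + float(np.clip(d, -0.5, 0.5))) / fs)
        else:
            t_pk.append(p / fs)
    t_pk = np.asarray(t_pk)
    period = float(np.median(np.diff(t_pk)))
    t = np.arange(len(x)) / fs
    # cycle index as a function of time: linear 0->1 between consecutive peaks,
    # extrapolated with the median period outside the first/last peak
    cyc = np.interp(t, t_pk, np.arange(len(t_pk), dtype=float))
    before = t < t_pk[0]
    after = t > t_pk[-1]
    cyc[before] = (t[before] - t_pk[0]) / period
    cyc[after] = len(t_pk) - 1 + (t[after] - t_pk[-1]) / period
    return np.mod(cyc, 1.0), 60.0 / period


def extract_gating_signals(projections: ProjectionSet,
                           params: GatingParams | None = None) -> PhaseTrack:
    """Derive per-frame cardiac and respiratory phases intrinsically."""
    params = params or GatingParams()
    t = projections.timeline.timestamps
    fs = 1.0 / float(np.median(np.diff(t)))
    if len(t) / fs < 30.0 - 1e-6:
        raise InvalidParameterError(
            "need >= 30 s of frames for spectral separation of the gating bands"
        )
    frames = projections.frames

    # respiratory surrogate: row-wise center of mass of detector intensity
    row_mass = frames.mean(axis=2).astype(np.float64)        # (n, n_rows)
    rows = np.arange(frames.shape[1], dtype=float)
    resp_raw = (row_mass * rows).sum(axis=1) / (row_mass.sum(axis=1) + 1e-12)
    f_resp = _dominant_frequency(resp_raw, fs, params.resp_band,
                                 "respiratory", params.min_peak_snr)
    resp_bp = _bandpass(resp_raw, fs, f_resp, params.bandpass_halfwidth)
    resp_phase, resp_rate = _peak_phases(resp_bp, fs, f_resp)

    # cardiac surrogate: mean intensity over the detector region with the
    # highest temporal spectral energy inside the cardiac band, with
    # respiratory harmonics notched out (breathing moves the whole heart,
    # so its harmonic series leaks into the cardiac band)
    f_resp_ref = resp_rate / 60.0
    f_rot = 1.0 / projections.geometry.rotation_time   # gantry harmonics of the
    n = frames.shape[0]                                # rotating anatomy view
    flat = frames.reshape(n, -1)
    spec = scipy.fft.rfft(flat - flat.mean(axis=0, keepdims=True), axis=0,
                          workers=1)
    freqs = scipy.fft.rfftfreq(n, 1.0 / fs)
    notch = (_harmonic_notch(freqs, f_resp_ref)
             & _harmonic_notch(freqs, f_rot,
                               k_max=int(params.cardiac_band[1] / f_rot) + 1))
    band = (freqs >= params.cardiac_band[0]) & (freqs <= params.cardiac_band[1])
    band &= notch
    energy = (np.abs(spec[band]) ** 2).sum(axis=0)
    n_roi = max(16, int(params.roi_fraction * flat.shape[1]))
    roi = np.argsort(energy)[-n_roi:]
    # sign-align pixels with the dominant band component before averaging
    kmax = int(np.argmax((np.abs(spec[band][:, roi]) ** 2).sum(axis=1)))
    ref = spec[band][kmax, roi]
    sgn = np.sign(np.real(ref * np.conj(ref[np.argmax(np.abs(ref))])))
    sgn[sgn == 0] = 1.0
    card_raw = (flat[:, roi] * sgn[None, :]).mean(axis=1).astype(np.float64)
    card_raw = _regress_out_harmonics(
        card_raw, t, [f_resp_ref, f_rot],
        k_max=int(params.cardiac_band[1] / min(f_resp_ref, f_rot)) + 1,
        f_max=params.cardiac_band[1] + 2.0)
    f_card = _dominant_frequency(card_raw, fs, params.cardiac_band,
                                 "cardiac", params.min_peak_snr, notch=notch)
    card_bp = _bandpass(card_raw, fs, f_card, params.bandpass_halfwidth)
    card_phase, card_rate = _peak_phases(card_bp, fs, f_card)

    return PhaseTrack(
        cardiac_phase=card_phase,
        resp_phase=resp_phase,
        cardiac_rate_bpm=card_rate,
        resp_rate_rpm=resp_rate,
        surrogates={
            "resp_raw": resp_raw, "resp_bandpassed": resp_bp,
            "cardiac_raw": card_raw, "cardiac_bandpassed": card_bp,
            "resp_peak_hz": f_resp, "cardiac_peak_hz": f_card,
            "sample_rate_hz": fs, "cardiac_roi": roi,
        },
    )


# --------------------------------------------------------------------------
# bin assignment
# --------------------------------------------------------------------------

@dataclass
class BinAssignment:
    """Per-frame bin labels; -1 where a phase falls in no window."""

    cardiac_bin: np.ndarray
    resp_bin: np.ndarray
    spec: GatingSpec

    def mask(self, cardiac_bin: int, resp_bin: int) -> np.ndarray:
        return (self.cardiac_bin == cardiac_bin) & (self.resp_bin == resp_bin)

    def joint_fraction(self, cardiac_bin: int, resp_bin: int) -> float:
        return float(self.mask(cardiac_bin, resp_bin).mean())


def _window_label(phase: np.ndarray, n_bins: int, width_pct: float) -> np.ndarray:
    """Half-open windows [center - w/2, center + w/2) around (k + 0.5)/n,
    with wrap-around at 1.0."""
    centers = (np.arange(n_bins) + 0.5) / n_bins
    w = width_pct / 100.0
    label = np.full(len(phase), -1, dtype=int)
    for k, c in enumerate(centers):
        d = np.mod(phase - c + 0.5, 1.0) - 0.5       # circular distance in [-0.5, 0.5)
        label[(d >= -w / 2) & (d < w / 2)] = k
    return label


def assign_bins(track: PhaseTrack, spec: GatingSpec) -> BinAssignment:
    """Label every frame with its (cardiac, respiratory) gating window."""
    cb = _window_label(track.cardiac_phase, spec.n_cardiac_bins, spec.cardiac_width)
    rb = _window_label(track.resp_phase, spec.n_resp_bins, spec.resp_width)
    out = BinAssignment(cb, rb, spec)
    for c in range(spec.n_cardiac_bins):
        for r in range(spec.n_resp_bins):
            if not np.any(out.mask(c, r)):
                warnings.warn(f"empty joint gating bin (cardiac={c}, resp={r})",
                              stacklevel=2)
    return out


def end_expiration_bin(track: PhaseTrack, spec: GatingSpec) -> int:
    """Respiratory bin covering quiet end-expiration.

    Phase 0 sits at the surrogate peak (end-inspiration), so the quiet
    plateau of the gasp-like murine breathing pattern is found where the
    band-passed respiratory surrogate is most negative; without surrogate
    signals (e.g. a ground-truth track whose phase 0 is the gasp onset) the
    late-phase bin is used.
    """
    rb = _window_label(track.resp_phase, spec.n_resp_bins, spec.resp_width)
    sur = track.surrogates.get("resp_bandpassed") if track.surrogates else None
    if sur is None:
        return spec.n_resp_bins - 1
    means = np.array([sur[rb == k].mean() if np.any(rb == k) else np.inf
                      for k in range(spec.n_resp_bins)])
    return int(np.argmin(means))


def max_integration_time_ms(resp_rate_rpm: float, n_phases: int) -> float:
    """Maximum detector integration time (ms) that still samples `n_phases`
    non-overlapping respiratory phases equidistantly at `resp_rate_rpm`."""
    if resp_rate_rpm <= 0 or n_phases < 1:
        raise InvalidParameterError("rate and phase count must be positive")
    return 60.0 / resp_rate_rpm / n_phases * 1000.0
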