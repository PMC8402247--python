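"""Beat-level feature extraction from multi-channel cuff-inflation recordings.

A :class:`Recording` carries time-aligned channels (cuff pressure, distal
arterial pressure, a PPG-like finger pulse, ECG) at their native sampling
rates (ECG at 500 Hz, pressure/PPG channels at 125 Hz in the emulated
operating-room setup).  From it the module extracts R-peaks, waveform feet
(intersecting-tangent method), per-beat PAT / PTT series referenced to the
pre-inflation baseline, per-beat diastolic/systolic/mean pressures, the lower
envelope of the distal pressure used by the circuit-parameter estimator, and
an inflation-level quality-control decision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

__all__ = [
    "Recording",
    "BeatSeries",
    "Envelope",
    "detect_r_peaks",
    "detect_foot",
    "beat_features",
    "lower_envelope",
    "qc_reject",
]


@dataclass
class Recording:
    """Named channels with per-channel sample rates and a common clock."""

    channels: dict  # name -> np.ndarray
    rates: dict  # name -> Hz
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, fs in self.rates.items():
            if fs <= 0:
                raise ValueError(f"Recording: non-positive rate for channel {name!r}")
        if "cuff" in self.channels and np.any(self.channels["cuff"] < -1e-9):
            raise ValueError("Recording: cuff channel must be non-negative")

    def time(self, name: str) -> np.ndarray:
        return self.t0 + np.arange(len(self.channels[name])) / self.rates[name]

    def duration(self) -> float:
        name = next(iter(self.channels))
        return len(self.channels[name]) / self.rates[name]


@dataclass
class BeatSeries:
    """Per-beat timing and pressure features, plus baseline-referenced deltas."""

    beat_time: np.ndarray
    r_peak_time: np.ndarray
    abp_foot_time: np.ndarray
    ppg_foot_time: np.ndarray
    pat: np.ndarray
    ptt_abp_ppg: np.ndarray
    p_dia: np.ndarray
    p_sys: np.ndarray
    map: np.ndarray
    cuff_at_beat: np.ndarray
    dpat: np.ndarray = None  # type: ignore[assignment]
    dptt_abp_ppg: np.ndarray = None  # type: ignore[assignment]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "beat_time": self.beat_time, "r_peak_time": self.r_peak_time,
            "abp_foot_time": self.abp_foot_time, "ppg_foot_time": self.ppg_foot_time,
            "pat": self.pat, "ptt_abp_ppg": self.ptt_abp_ppg,
            "p_dia": self.p_dia, "p_sys": self.p_sys, "map": self.map,
            "cuff_at_beat": self.cuff_at_beat,
            "dpat": self.dpat, "dptt_abp_ppg": self.dptt_abp_ppg,
        })


@dataclass
class Envelope:
    """Lower envelope of the distal pressure: per-beat diastolic minima.

    ``cuff_grid`` holds the cuff pressure at each envelope point (monotone
    non-decreasing over an inflation; repeated at the plateau value while the
    cuff holds).  ``beat_time`` keeps the time coordinate of each point.
    """

    cuff_grid: np.ndarray
    bp_env: np.ndarray
    beat_time: np.ndarray = None  # type: ignore[assignment]

    def on_grid(self, step: float = 1.0) -> "Envelope":
        """Resample onto a uniform cuff-pressure grid from 0 to max (ramp part)."""
        # restrict to the strictly increasing ramp portion for inversion
        keep = np.concatenate([[True], np.diff(self.cuff_grid) > 0])
        cg, ev = self.cuff_grid[keep], self.bp_env[keep]
        grid = np.arange(0.0, cg.max() + step / 2, step)
        return Envelope(cuff_grid=grid, bp_env=np.interp(grid, cg, ev))


def detect_r_peaks(ecg: np.ndarray, sample_rate: float,
                   min_rr: float = 0.4) -> np.ndarray:
    """R-peak times from an ECG channel.

    A threshold-and-refractory peak search: adequate for clean to moderately
    noisy signals whose QRS complexes dominate the amplitude distribution.
    Returns an empty array (with a warning) on a flat signal.
    """
    if sample_rate < 250:
        raise ValueError("detect_r_peaks: sample rate must be >= 250 Hz")
    ecg = np.asarray(ecg, dtype=float)
    amp = np.percentile(np.abs(ecg), 99.9)
    if amp <= 0 or np.ptp(ecg) < 1e-12:
        warnings.warn("detect_r_peaks: flat ECG, no peaks found")
        return np.array([])
    idx, _ = find_peaks(ecg, height=0.4 * amp, distance=int(min_rr * sample_rate))
    return idx / sample_rate


def detect_foot(pulse: np.ndarray, sample_rate: float,
                beat_windows) -> np.ndarray:
    """Per-beat pulse-foot times by the intersecting-tangent method.

    For each ``(t_lo, t_hi)`` window the foot is the intersection of the
    horizontal tangent through the pre-upstroke diastolic minimum with the
    tangent through the point of maximum upslope.  Robust to baseline drift
    and amplitude scaling.  Beats with no detectable upslope yield ``nan``.
    """
    pulse = np.asarray(pulse, dtype=float)
    out = np.full(len(beat_windows), np.nan)
    for k, (t_lo, t_hi) in enumerate(beat_windows):
        i_lo = max(0, int(np.floor(t_lo * sample_rate)))
        i_hi = min(len(pulse), int(np.ceil(t_hi * sample_rate)))
        if i_hi - i_lo < 8:
            continue
        seg = pulse[i_lo:i_hi]
        # polynomial smoothing keeps single-sample noise out of the tangents
        win = min(9, 2 * ((len(seg) - 1) // 2) + 1)
        xs = savgol_filter(seg, win, 2)
        ds = savgol_filter(seg, win, 2, deriv=1) * sample_rate
        i_up = int(np.argmax(ds))
        slope = ds[i_up]
        if slope <= 0:
            continue  # no upslope in window: beat skipped
        i_min = int(np.argmin(xs[: i_up + 1]))
        y_min = xs[i_min]
        t_up = (i_lo + i_up) / sample_rate
        out[k] = t_up - (xs[i_up] - y_min) / slope
    return out


def _inflation_start(cuff: np.ndarray, fs: float, thresh: float = 2.0) -> int:
    idx = np.flatnonzero(cuff > thresh)
    return int(idx[0]) if idx.size else len(cuff)


def beat_features(rec: Recording, *, ppg_min_amp_frac: float = 0.15,
                  baseline_beats: int = 5) -> BeatSeries:
    """Extract the per-beat feature table from a recording.

    PAT is PPG foot minus R-peak; PTT is PPG foot minus ABP foot; per-beat
    diastolic/systolic/mean pressures come from the ABP channel between
    consecutive R-peaks; delta series subtract the median of the last
    ``baseline_beats`` beats preceding inflation onset.  Beats whose distal
    pulse is too small to carry a foot (cuff at or above systolic) get
    ``nan`` timing entries rather than extrapolated values.
    """
    ecg = rec.channels["ecg"]
    abp = rec.channels["abp"]
    ppg = rec.channels["ppg"]
    cuff = rec.channels["cuff"]
    fs_e, fs_a = rec.rates["ecg"], rec.rates["abp"]
    fs_p, fs_c = rec.rates["ppg"], rec.rates["cuff"]

    r_times = detect_r_peaks(ecg, fs_e)
    if len(r_times) < 3:
        raise ValueError("beat_features: too few R-peaks detected")
    rr = float(np.median(np.diff(r_times)))

    windows = [(r, r + 0.95 * rr) for r in r_times]
    # pulse feet searched in a window shifted by a nominal arrival delay
    foot_windows = [(r + 0.02, r + 0.95 * rr) for r in r_times]
    ppg_feet = detect_foot(ppg, fs_p, foot_windows)
    abp_feet = detect_foot(abp, fs_a, foot_windows)

    nb = len(r_times)
    p_dia = np.full(nb, np.nan)
    p_sys = np.full(nb, np.nan)
    p_map = np.full(nb, np.nan)
    cuff_at = np.full(nb, np.nan)
    ppg_amp = np.full(nb, np.nan)
    for k, r in enumerate(r_times):
        i0 = int(r * fs_a)
        i1 = int((r + rr) * fs_a)
        seg = abp[i0:min(i1, len(abp))]
        if seg.size:
            p_dia[k], p_sys[k], p_map[k] = seg.min(), seg.max(), seg.mean()
        j0, j1 = int(r * fs_p), int((r + rr) * fs_p)
        pseg = ppg[j0:min(j1, len(ppg))]
        if pseg.size:
            ppg_amp[k] = np.ptp(pseg)
        ic = min(int(r * fs_c), len(cuff) - 1)
        cuff_at[k] = cuff[ic]

    # invalidate feet where the pulse has effectively vanished
    ref_amp = np.nanmedian(ppg_amp[:max(baseline_beats, 1)])
    if np.isfinite(ref_amp) and ref_amp > 0:
        dead = ppg_amp < ppg_min_amp_frac * ref_amp
        ppg_feet[dead] = np.nan
        abp_feet[dead] = np.nan

    pat = ppg_feet - r_times
    ptt = ppg_feet - abp_feet

    i_inf = _inflation_start(cuff, fs_c)
    t_inf = i_inf / fs_c
    pre = np.flatnonzero(r_times < t_inf - 0.5 * rr)[-baseline_beats:]
    if pre.size == 0:
        pre = np.arange(min(baseline_beats, nb))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pat_ref = np.nanmedian(pat[pre])
        ptt_ref = np.nanmedian(ptt[pre])

    bs = BeatSeries(beat_time=r_times, r_peak_time=r_times,
                    abp_foot_time=abp_feet, ppg_foot_time=ppg_feet,
                    pat=pat, ptt_abp_ppg=ptt, p_dia=p_dia, p_sys=p_sys,
                    map=p_map, cuff_at_beat=cuff_at)
    bs.dpat = pat - pat_ref
    bs.dptt_abp_ppg = ptt - ptt_ref
    return bs


def lower_envelope(abp: np.ndarray, cuff: np.ndarray, sample_rate: float,
                   heart_rate: float, *, include_hold: bool = True) -> Envelope:
    """Lower envelope of the distal pressure over an inflation.

    Per-beat diastolic minima from inflation onset until the cuff pressure
    leaves its plateau (or the record ends), indexed by the cuff pressure at
    each beat.  Requires at least 5 beats.
    """
    abp = np.asarray(abp, dtype=float)
    cuff = np.asarray(cuff, dtype=float)
    period = int(round(sample_rate / heart_rate))
    i_inf = _inflation_start(cuff, sample_rate)
    # end of inflation: last sample where cuff is still within 1% of running max
    after = cuff[i_inf:]
    if after.size == 0:
        raise ValueError("lower_envelope: no inflation segment in record")
    peak = after.max()
    i_rel = np.flatnonzero(after >= 0.99 * peak)
    i_end = i_inf + (int(i_rel[-1]) + 1 if include_hold else int(i_rel[0]) + 1)
    nb = (i_end - i_inf) // period
    if nb < 5:
        raise ValueError("lower_envelope: fewer than 5 beats in inflation segment")
    blocks = abp[i_inf:i_inf + nb * period].reshape(nb, period)
    env = blocks.min(axis=1)
    cuff_at = cuff[i_inf:i_inf + nb * period].reshape(nb, period)[:, 0]
    times = (i_inf + np.arange(nb) * period) / sample_rate
    return Envelope(cuff_grid=cuff_at, bp_env=env, beat_time=times)


def qc_reject(rec: Recording, *, pp_thresh: float = 20.0,
              gap_thresh: float = 2.0, flush_level: float = 250.0) -> tuple[bool, str | None]:
    """Inflation-level quality control; returns ``(keep, reason)``.

    Rejection reasons:

    * ``"dropout"`` — the pulse is undetectable for more than 2 s in a part
      of the record where it should be present (before the cuff passes 70%
      of its maximum);
    * ``"flush"`` — an arterial-line flush signature (saturation plateau
      above ``flush_level`` mmHg);
    * ``"pulse_step"`` — the cuff-free pulse pressure after the inflation
      differs from the pre-inflation pulse pressure by more than 20 mmHg,
      indicating a major hemodynamic event during the 20 s of inflation.

    Deterministic: no randomness is involved.
    """
    abp = rec.channels["abp"]
    ppg = rec.channels["ppg"]
    cuff = rec.channels["cuff"]
    fs = rec.rates["abp"]
    fs_c = rec.rates["cuff"]

    # (b) flush: saturation plateau
    high = abp > flush_level
    if high.any():
        # sustained for >= 0.5 s
        run = np.diff(np.flatnonzero(np.diff(np.concatenate([[0], high.view(np.int8), [0]]))).reshape(-1, 2), axis=1)
        if run.size and run.max() >= 0.5 * fs:
            return False, "flush"

    # (a) dropout: gap between pulse events where pulse should exist
    i_inf = _inflation_start(cuff, fs_c)
    peak = cuff.max() if cuff.max() > 0 else np.inf
    limit = np.flatnonzero(cuff > 0.7 * peak)
    i_lim = int(limit[0]) if limit.size else len(cuff)
    t_lim = i_lim / fs_c
    seg = ppg[: int(t_lim * rec.rates["ppg"])]
    if seg.size:
        amp = np.percentile(np.abs(seg - np.median(seg)), 99)
        idx, _ = find_peaks(seg, prominence=0.3 * amp if amp > 0 else None,
                            distance=int(0.4 * rec.rates["ppg"]))
        times = idx / rec.rates["ppg"]
        times = np.concatenate([[0.0], times, [t_lim]])
        if np.diff(times).max() > gap_thresh:
            return False, "dropout"

    # (c) pulse-pressure step across the inflation, measured cuff-free
    t_abp = np.arange(len(abp)) / fs
    cuff_on_abp = np.interp(t_abp, np.arange(len(cuff)) / fs_c, cuff)
    free = cuff_on_abp <= 2.0
    pre = free & (t_abp < i_inf / fs_c)
    post = free & (t_abp > i_inf / fs_c + 20.0)
    if pre.sum() > fs and post.sum() > fs:
        pp_pre = _pulse_pressure(abp[pre], fs)
        pp_post = _pulse_pressure(abp[post], fs)
        if abs(pp_post - pp_pre) > pp_thresh:
            return False, "pulse_step"

    return True, None


def _pulse_pressure(seg: np.ndarray, fs: float) -> float:
    """Median per-beat peak-to-peak amplitude over ~1 s blocks."""
    n = int(fs)
    nb = len(seg) // n
    if nb == 0:
        return float(np.ptp(seg))
    return float(np.median(np.ptp(seg[: nb * n].reshape(nb, n), axis=1)))
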