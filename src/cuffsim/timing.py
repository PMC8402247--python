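"""Forward models of cuff-induced pulse-timing changes.

Two transit segments change during a brachial cuff inflation:

* the segment **under the cuff**, where the transmural pressure drops by the
  cuff pressure and the Bramwell-Hill PWV falls with it — transit time over
  the cuff length increases (Delta-PTT_brachial > 0);
* the **distal** arm, where the cuff-induced rise in distal mean pressure
  stiffens the artery through an approximately linear PWV-MAP relationship —
  distal transit time shortens (Delta-PTT_distal < 0).

The pulse arrival time (ECG R-peak to finger pulse foot) changes by the sum
of the two, the pre-ejection period being assumed constant.  With a radial
arterial line placed halfway between the distal cuff edge and the fingertip,
the brachial share can be recovered from measured series as

    dPTT_brachial = dPAT(ECG-PPG) - 2 * dPTT(ABP-PPG).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .collapse import CollapseParams, pwv
from .simulate import SystemicWave

__all__ = [
    "TimingModel",
    "calibrate_pwv_map",
    "brachial_dptt",
    "distal_dptt",
    "total_dpat",
    "brachial_from_measured",
    "simulated_timing_table",
]


@dataclass(frozen=True)
class TimingModel:
    """Linear distal PWV-MAP law plus path geometry and the reference PAT.

    ``distal_length`` is the cuff-edge-to-fingertip path (m), twice the
    radial-line-to-fingertip distance.  ``path_length_total`` is the full
    heart-to-finger path used by the PAT-BP calibration (1 m).
    """

    pwv_map_slope: float  # (m/s)/mmHg
    pwv_map_intercept: float  # m/s
    map_ref: float  # mmHg, pre-inflation distal MAP
    distal_length: float = 0.4  # m
    path_length_total: float = 1.0  # m
    ref_pat: float = 0.22  # s

    def pwv_of_map(self, map_mmhg):
        return self.pwv_map_intercept + self.pwv_map_slope * np.asarray(map_mmhg, dtype=float)


def calibrate_pwv_map(map_ref: float, *, pwv_ref: float = 5.0,
                      target_dptt: float = -0.020, dmap: float = 20.0,
                      distal_length: float = 0.4, **kwargs) -> TimingModel:
    """Fit the linear PWV-MAP law to a target distal transit-time drop.

    The slope is solved so that a MAP rise of ``dmap`` mmHg above
    ``map_ref`` changes the distal transit time by ``target_dptt`` seconds
    (default -20 ms at +20 mmHg, the amplitude observed invasively), with
    ``pwv_ref`` the distal PWV at the reference MAP.
    """
    inv_target = distal_length / (distal_length / pwv_ref + target_dptt)
    slope = (inv_target - pwv_ref) / dmap
    intercept = pwv_ref - slope * map_ref
    return TimingModel(pwv_map_slope=slope, pwv_map_intercept=intercept,
                       map_ref=map_ref, distal_length=distal_length, **kwargs)


def brachial_dptt(pcuff, wave: SystemicWave, col: CollapseParams,
                  p_beat=None):
    """Transit-time change over the cuffed segment at cuff pressure ``pcuff`` (s).

    ``L_cuff * (1/PWV(p_beat - pcuff) - 1/PWV(p_beat))``: transit at the
    reduced transmural pressure minus the transit the same beat would have
    at zero cuff pressure.  ``p_beat`` is the arterial pressure under the
    cuff at the moment the wave foot passes — the foot rides at diastolic
    level, and with the cuff above systemic diastolic the under-cuff artery
    communicates with the (elevated) distal side, so per-beat distal
    diastolic pressure is the faithful choice; the default falls back to
    the systemic diastolic value.  Positive and increasing while the artery
    is open; ``nan`` once the segment is fully collapsed (pulse blocked).
    """
    pcuff_arr = np.atleast_1d(np.asarray(pcuff, dtype=float))
    if p_beat is None:
        p_beat = wave.p_dia
    pb = np.broadcast_to(np.asarray(p_beat, dtype=float), pcuff_arr.shape)
    ptm = pb - pcuff_arr
    blocked = ptm <= col.ptm_collapse
    out = np.full(pcuff_arr.shape, np.nan)
    if np.any(~blocked):
        l_m = col.cuff_length / 100.0
        v = np.asarray(pwv(ptm[~blocked], col))
        v0 = np.asarray(pwv(pb[~blocked], col))
        out[~blocked] = l_m * (1.0 / v - 1.0 / v0)
    return out if np.ndim(pcuff) else float(out[0])


def distal_dptt(map_series, tm: TimingModel):
    """Distal transit-time change for a distal-MAP series (s); negative when MAP rises."""
    v = np.asarray(tm.pwv_of_map(map_series), dtype=float)
    v_ref = float(tm.pwv_of_map(tm.map_ref))
    if np.any(v <= 0.0) or v_ref <= 0.0:
        raise ValueError("distal_dptt: PWV-MAP law non-positive over the series")
    out = tm.distal_length * (1.0 / v - 1.0 / v_ref)
    return out if np.ndim(map_series) else float(out)


def total_dpat(brachial, distal):
    """Total pulse-arrival-time change: elementwise sum (PEP assumed constant)."""
    b = np.asarray(brachial, dtype=float)
    d = np.asarray(distal, dtype=float)
    if b.shape != d.shape:
        raise ValueError(f"total_dpat: shape mismatch {b.shape} vs {d.shape}")
    out = b + d
    return out if out.ndim else float(out)


def simulated_timing_table(res, wave: SystemicWave, col: CollapseParams,
                           tm: TimingModel | None = None):
    """Beat-indexed timing observables from a simulation result.

    Returns a pandas DataFrame with one row per beat of the simulation:
    beat time, cuff pressure, distal diastolic/mean pressure, the brachial
    and distal transit-time changes and their sum (the total dPAT).  Beats
    whose distal pulse is blocked (cuff at or above the systemic systolic
    pressure) carry ``nan`` timing values — no pulse arrives to be timed.
    ``tm`` defaults to the PWV-MAP law calibrated against the pre-inflation
    mean pressure of this very simulation.
    """
    import pandas as pd

    period = 1.0 / wave.heart_rate
    n_per = int(round(period / res.dt))
    nb = len(res.t) // n_per
    blocks = res.p_art_distal[: nb * n_per].reshape(nb, n_per)
    p_map = blocks.mean(axis=1)
    p_dia = blocks.min(axis=1)
    cuff_b = res.p_cuff[: nb * n_per].reshape(nb, n_per)[:, 0]
    if tm is None:
        free = cuff_b == 0
        tm = calibrate_pwv_map(float(p_map[free][:5].mean()))
    bra = brachial_dptt(cuff_b, wave, col, p_beat=p_dia)
    dis = distal_dptt(p_map, tm)
    blocked = cuff_b >= wave.p_sys
    bra[blocked] = np.nan
    dpat = bra + dis
    return pd.DataFrame({
        "beat_time": np.arange(nb) * period,
        "cuff_at_beat": cuff_b,
        "p_dia": p_dia,
        "map": p_map,
        "dptt_brachial": bra,
        "dptt_distal": dis,
        "dpat": dpat,
    })


def brachial_from_measured(dpat_ecg_ppg, dptt_abp_ppg):
    """Recover the brachial transit change from measured series.

    ``dPAT - 2*dPTT(ABP-PPG)``: the factor 2 encodes the arterial line
    sitting halfway between the distal cuff edge and the fingertip.
    """
    a = np.asarray(dpat_ecg_ppg, dtype=float)
    b = np.asarray(dptt_abp_ppg, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"brachial_from_measured: shape mismatch {a.shape} vs {b.shape}")
    out = a - 2.0 * b
    return out if out.ndim else float(out)
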