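"""Seeded generator of patient-like multi-channel cuff-inflation recordings.

Stands in for operating-room recordings (which are restricted): the
two-compartment simulator provides the distal arterial pressure, the timing
model provides per-beat transit delays, and the generator assembles the four
channels of the clinical setup —

* ``cuff``  cuff pressure, 125 Hz;
* ``abp``   radial arterial-line pressure, 125 Hz: the simulated distal
  pressure warped in time by the per-beat arrival delay (brachial plus half
  the distal transit change, the line sitting halfway between cuff edge and
  fingertip), plus Gaussian transducer noise and a slow respiratory drift;
* ``ppg``   finger pulse surrogate, 125 Hz: one raised-cosine pulse per
  beat at the model arrival time, amplitude tracking the distal pulse
  pressure (the analysis uses only foot times, so morphology is schematic);
* ``ecg``   500 Hz impulse train at the R-peak times.

Everything is reproducible from the scenario seed; distinct seeds share the
noiseless core and differ only in noise/artifact realisations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .collapse import CollapseParams
from .features import Recording
from .presets import literature_preset
from .simulate import (CircuitParams, CuffProfile, SystemicWave,
                       generate_cuff_ramp, generate_systemic_wave, simulate)
from .timing import TimingModel, simulated_timing_table

__all__ = ["Scenario", "generate_recording", "inject_artifact"]

_SIM_DT = 1e-3
_FS_WAVE = 125.0
_FS_ECG = 500.0


@dataclass(frozen=True)
class Scenario:
    """Full description of one synthetic acquisition."""

    wave: SystemicWave = field(default_factory=SystemicWave)
    cuff: CuffProfile = field(default_factory=CuffProfile)
    circuit: CircuitParams = field(default_factory=CircuitParams)
    collapse: CollapseParams = field(default_factory=CollapseParams)
    timing: TimingModel | None = None  # None -> calibrated per recording
    noise_sd: float = 2.0  # mmHg, matches the transducer noise assumption
    drift_amp: float = 1.0  # mmHg, sinusoidal respiratory drift
    drift_freq: float = 0.2  # Hz
    artifacts: tuple = ()
    seed: int = 0
    pep: float = 0.08  # s, pre-ejection period (constant)
    transit_base: float = 0.14  # s, heart-to-finger transit at baseline

    def __post_init__(self) -> None:
        errors = []
        if self.noise_sd < 0:
            errors.append("noise_sd must be >= 0")
        if self.drift_amp < 0:
            errors.append("drift_amp must be >= 0")
        for art in self.artifacts:
            if len(art) != 3:
                errors.append(f"artifact {art!r} must be (type, t, magnitude)")
        if errors:
            raise ValueError("Scenario: " + "; ".join(errors))

    @classmethod
    def from_preset(cls, **overrides) -> "Scenario":
        pre = literature_preset()
        kw = dict(wave=pre.wave, cuff=pre.cuff, circuit=pre.circuit,
                  collapse=pre.collapse)
        kw.update(overrides)
        return cls(**kw)


def _raised_cosine(t_rel: np.ndarray, width: float) -> np.ndarray:
    """Single pulse: 0.5*(1 - cos(2 pi t/width)) on [0, width)."""
    out = np.zeros_like(t_rel)
    inside = (t_rel >= 0) & (t_rel < width)
    out[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * t_rel[inside] / width))
    return out


def generate_recording(s: Scenario, duration: float | None = None) -> Recording:
    """Render a scenario into a four-channel :class:`Recording`.

    The noiseless core (simulation, beat delays, pulse placement) depends
    only on the scenario parameters; the RNG seeded by ``s.seed`` adds
    measurement noise and drift, so the same seed gives identical output.
    """
    if duration is None:
        duration = s.cuff.t_end + 5.0
    if duration < s.cuff.t_end:
        raise ValueError("generate_recording: duration does not cover the cuff profile")
    rng = np.random.default_rng(s.seed)

    wave_s = generate_systemic_wave(s.wave, duration, sample_rate=1.0 / _SIM_DT)
    cuff_s = generate_cuff_ramp(s.cuff, duration, sample_rate=1.0 / _SIM_DT)
    res = simulate(s.circuit, s.collapse, wave_s, cuff_s, _SIM_DT)
    tab = simulated_timing_table(res, s.wave, s.collapse, s.timing)

    beat_t = tab["beat_time"].to_numpy()
    bra = tab["dptt_brachial"].to_numpy()  # nan where the pulse is blocked
    dis = tab["dptt_distal"].to_numpy()
    dpat = bra + dis

    t_sim = res.t
    n125 = int(duration * _FS_WAVE)
    t125 = np.arange(n125) / _FS_WAVE
    cuff = np.interp(t125, t_sim, res.p_cuff)

    # per-beat envelope of the simulated distal pressure
    period = 1.0 / s.wave.heart_rate
    n_per = int(round(period / _SIM_DT))
    nb = len(beat_t)
    blocks = res.p_art_distal[: nb * n_per].reshape(nb, n_per)
    dia = blocks.min(axis=1)
    pulse_pp = blocks.max(axis=1) - blocks.min(axis=1)
    amp = pulse_pp / max(pulse_pp[0], 1e-9)

    # ABP: per-beat diastolic baseline (carries the build-up and the
    # post-collapse decay) plus raised-cosine pulses whose feet sit at the
    # model arrival time for the radial site — brachial change plus half the
    # distal change, the line being halfway to the fingertip.  Intra-beat
    # morphology is schematic; foot times and the pressure envelope are what
    # the analysis consumes.
    width = 0.45 * period
    abp = np.interp(t125, beat_t, dia)
    feet_abp = beat_t + s.pep + 0.5 * s.transit_base + bra + 0.5 * dis
    for k in range(nb):
        if not np.isfinite(feet_abp[k]) or pulse_pp[k] < 0.5:
            continue
        abp += pulse_pp[k] * _raised_cosine(t125 - feet_abp[k], width)
    abp = abp + rng.normal(0.0, s.noise_sd, n125)
    abp = abp + s.drift_amp * np.sin(2.0 * np.pi * s.drift_freq * t125)

    ppg = np.zeros(n125)
    foot_times = beat_t + s.pep + s.transit_base + dpat
    for k in range(nb):
        if not np.isfinite(foot_times[k]) or amp[k] <= 1e-2:
            continue
        ppg += amp[k] * _raised_cosine(t125 - foot_times[k], width)
    ppg += rng.normal(0.0, 0.0025 * s.noise_sd, n125)

    n500 = int(duration * _FS_ECG)
    t500 = np.arange(n500) / _FS_ECG
    ecg = np.zeros(n500)
    for bt in beat_t:
        ecg += np.exp(-0.5 * ((t500 - bt) / 0.004) ** 2)
    ecg += rng.normal(0.0, 0.01 * s.noise_sd, n500)

    rec = Recording(
        channels={"cuff": cuff, "abp": abp, "ppg": ppg, "ecg": ecg},
        rates={"cuff": _FS_WAVE, "abp": _FS_WAVE, "ppg": _FS_WAVE, "ecg": _FS_ECG},
        meta={"seed": s.seed, "scenario": "synthetic",
              "p_dia": s.wave.p_dia, "p_sys": s.wave.p_sys,
              "heart_rate": s.wave.heart_rate,
              "cuff_t_start": s.cuff.t_start,
              "cuff_t_end": s.cuff.t_end},
    )
    for art in s.artifacts:
        rec = inject_artifact(rec, art)
    return rec


def inject_artifact(rec: Recording, artifact) -> Recording:
    """Return a copy of ``rec`` with one artifact applied.

    * ``("dropout", t, dur)``   — pulse amplitude zeroed on PPG and ABP for
      ``dur`` seconds from ``t`` (motion making the pulse indistinguishable);
    * ``("flush", t, dur)``     — ABP saturates at the flush-bag plateau
      (300 mmHg) for ``dur`` seconds;
    * ``("pulse_step", t, mag)`` — pulse-pressure change of ``mag`` mmHg from
      ``t`` onward (an abrupt hemodynamic event), applied to the AC component
      of ABP and scaled onto PPG.
    """
    kind, t0, mag = artifact
    channels = {k: v.copy() for k, v in rec.channels.items()}
    fs = rec.rates["abp"]
    abp = channels["abp"]
    ppg = channels["ppg"]

    def _ac_dc(x, win):
        import pandas as pd

        dc = pd.Series(x).rolling(win, center=True, min_periods=1).median().to_numpy()
        return x - dc, dc

    if kind == "dropout":
        i0, i1 = int(t0 * fs), int((t0 + mag) * fs)
        ac, dc = _ac_dc(abp, int(2 * fs))
        abp[i0:i1] = dc[i0:i1]
        ppg[i0:i1] = 0.0
    elif kind == "flush":
        i0, i1 = int(t0 * fs), int((t0 + mag) * fs)
        abp[i0:i1] = 300.0
    elif kind == "pulse_step":
        i0 = int(t0 * fs)
        ac, dc = _ac_dc(abp, int(2 * fs))
        # reference pulse pressure from the undisturbed opening seconds
        head = abp[: int(4 * fs)]
        nb = len(head) // int(fs)
        base_pp = float(np.median(np.ptp(head[: nb * int(fs)].reshape(nb, int(fs)), axis=1)))
        factor = 1.0 + mag / max(base_pp, 1e-9)
        abp[i0:] = dc[i0:] + ac[i0:] * factor
        ppg[i0:] = ppg[i0:] * factor
    else:
        raise ValueError(f"inject_artifact: unknown artifact type {kind!r}")

    return Recording(channels=channels, rates=dict(rec.rates), t0=rec.t0,
                     meta={**rec.meta, "artifact": kind})
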