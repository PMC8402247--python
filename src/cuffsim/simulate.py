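"""Two-compartment time-domain simulation of the distal arm during cuff inflation.

The distal arm is modelled as an arterial capacitance Ca fed from the systemic
pressure wave through the state-dependent brachial resistance Ra(Ptm), draining
through the arm peripheral resistance Rs into a venous capacitance Cv, which
empties through the brachial venous resistance Rv into the systemic venous
pool.  The vein acts as a switch: outflow stops once its transmural pressure
(Pv - Pcuff) falls below the collapse threshold (default -10 mmHg).

    Ca dPa/dt = Qin - Qs,     Qin = (Psystemic - Pa) / Ra(Psystemic - Pcuff)
    Cv dPv/dt = Qs - Qout,    Qs  = (Pa - Pv) / Rs
                              Qout = (Pv - Pven) / Rv   while the vein is open

The transmural pressure driving Ra uses the proximal (systemic) pressure, so
inflow is gated beat-by-beat like a diode: pulses enter only while the
systemic pressure exceeds the cuff pressure, which reproduces the observed
diastolic build-up and systolic attenuation stages.

Integration is fixed-step implicit (backward) Euler on the 2x2 linear system,
which is unconditionally stable against the stiffness introduced when Ra
approaches the occlusion cap, and conserves stored volume against integrated
flows to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .collapse import CollapseParams, brachial_resistance

__all__ = [
    "CircuitParams",
    "SystemicWave",
    "CuffProfile",
    "SimulationResult",
    "generate_systemic_wave",
    "generate_cuff_ramp",
    "simulate",
    "classify_stages",
    "stage5_onset",
    "STAGE_NAMES",
]

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@dataclass(frozen=True)
class CircuitParams:
    """Lumped distal-arm circuit parameters.

    Ca, Cv in mL/mmHg; Rs, Rv in mmHg*s/mL; p_ven_sys in mmHg.
    ``vein_collapse_ptm`` is the venous transmural pressure below which the
    vein collapses and outflow stops (default -10 mmHg).
    """

    Ca: float = 0.03
    Cv: float = 0.9
    Rs: float = 106.0
    Rv: float = 10.0
    p_ven_sys: float = 10.0
    vein_collapse_ptm: float = -10.0

    def __post_init__(self) -> None:
        for name in ("Ca", "Cv", "Rs", "Rv"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"CircuitParams.{name} must be finite and > 0, got {v!r}")


@dataclass(frozen=True)
class SystemicWave:
    """Periodic systemic arterial pressure wave.

    Half-sinusoid systolic upstroke over ``systole_frac`` of the period,
    followed by an exponential diastolic decay back to p_dia.
    """

    p_dia: float = 50.0
    p_sys: float = 100.0
    heart_rate: float = 1.0
    systole_frac: float = 0.35
    sample_rate: float = 1000.0
    shape: str = "halfsine-expdecay"

    def __post_init__(self) -> None:
        if not (self.p_sys >= self.p_dia > 0):
            raise ValueError("SystemicWave requires p_sys >= p_dia > 0")
        if self.heart_rate <= 0:
            raise ValueError("SystemicWave requires heart_rate > 0")


@dataclass(frozen=True)
class CuffProfile:
    """Trapezoidal cuff inflation: linear ramp, hold, instantaneous release."""

    t_start: float = 5.0
    ramp_duration: float = 25.0
    p_max: float = 150.0
    hold_duration: float = 20.0
    shape: str = "linear"

    def __post_init__(self) -> None:
        if self.p_max < 0:
            raise ValueError("CuffProfile.p_max must be >= 0")
        if self.ramp_duration <= 0:
            raise ValueError("CuffProfile.ramp_duration must be > 0")

    @property
    def t_end(self) -> float:
        return self.t_start + self.ramp_duration + self.hold_duration


@dataclass
class SimulationResult:
    """Time-aligned simulation traces (all mmHg / mL/s on grid ``t``)."""

    t: np.ndarray
    p_art_distal: np.ndarray
    p_ven_distal: np.ndarray
    p_cuff: np.ndarray
    p_systemic: np.ndarray
    flow_in: np.ndarray
    flow_s: np.ndarray
    flow_out: np.ndarray
    stage_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


def generate_systemic_wave(w: SystemicWave, duration: float,
                           sample_rate: float | None = None) -> np.ndarray:
    """Sample the periodic systemic wave over ``duration`` seconds.

    Each beat starts at its diastolic foot (value exactly p_dia): a quarter-
    sine upstroke to the systolic peak over the systolic fraction of the
    period, then an exponential relaxation whose rate is set so the wave is
    back within 1% of the pulse pressure of p_dia at the end of the beat.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    fs = float(sample_rate or w.sample_rate)
    t = np.arange(0.0, duration, 1.0 / fs)
    period = 1.0 / w.heart_rate
    phase = np.mod(t, period) / period
    pp = w.p_sys - w.p_dia
    sf = w.systole_frac
    wave = np.empty_like(t)
    up = phase < sf
    wave[up] = w.p_dia + pp * np.sin(0.5 * np.pi * phase[up] / sf)
    k = -np.log(0.01) / (1.0 - sf)  # 1% of pulse pressure left at beat end
    wave[~up] = w.p_dia + pp * np.exp(-k * (phase[~up] - sf))
    return wave


def generate_cuff_ramp(c: CuffProfile, duration: float,
                       sample_rate: float = 1000.0) -> np.ndarray:
    """Sample the cuff pressure profile: 0 / linear ramp / hold / 0."""
    t = np.arange(0.0, duration, 1.0 / sample_rate)
    p = np.zeros_like(t)
    rising = (t >= c.t_start) & (t < c.t_start + c.ramp_duration)
    p[rising] = c.p_max * (t[rising] - c.t_start) / c.ramp_duration
    holding = (t >= c.t_start + c.ramp_duration) & (t < c.t_end)
    p[holding] = c.p_max
    return p


@njit(cache=False)
def _step_loop(ps, pcuff, ra, dt, ca, cv, rs, rv, pven, collapse_ptm, hyst,
               pa0, pv0):  # pragma: no cover - numba-compiled
    n = ps.shape[0]
    pa = np.empty(n)
    pv = np.empty(n)
    qin = np.empty(n)
    qs = np.empty(n)
    qout = np.empty(n)
    gate = np.empty(n, dtype=np.uint8)
    pa_c = pa0
    pv_c = pv0
    vein_open = True
    for i in range(n):
        if vein_open:
            if pv_c - pcuff[i] < collapse_ptm:
                vein_open = False
        else:
            if pv_c - pcuff[i] > collapse_ptm + hyst:
                vein_open = True
        g = 1.0 if vein_open else 0.0
        # implicit Euler on the 2x2 linear system
        a11 = ca / dt + 1.0 / ra[i] + 1.0 / rs
        a12 = -1.0 / rs
        a21 = -1.0 / rs
        a22 = cv / dt + 1.0 / rs + g / rv
        b1 = ca / dt * pa_c + ps[i] / ra[i]
        b2 = cv / dt * pv_c + g * pven / rv
        det = a11 * a22 - a12 * a21
        pa_n = (b1 * a22 - a12 * b2) / det
        pv_n = (a11 * b2 - a21 * b1) / det
        pa[i] = pa_n
        pv[i] = pv_n
        qin[i] = (ps[i] - pa_n) / ra[i]
        qs[i] = (pa_n - pv_n) / rs
        qout[i] = g * (pv_n - pven) / rv
        gate[i] = 1 if vein_open else 0
        pa_c = pa_n
        pv_c = pv_n
    return pa, pv, qin, qs, qout, gate


def simulate(cp: CircuitParams, col: CollapseParams, wave: np.ndarray,
             cuff: np.ndarray, dt: float, *, pa0: float | None = None,
             pv0: float | None = None) -> SimulationResult:
    """Integrate the two-compartment model over the supplied input series.

    ``wave`` and ``cuff`` must share the same uniform grid with spacing
    ``dt`` (required <= 2 ms).  Initial conditions default to the systemic
    wave at t=0 for the artery and the systemic venous pressure for the vein.
    """
    wave = np.ascontiguousarray(wave, dtype=float)
    cuff = np.ascontiguousarray(cuff, dtype=float)
    if wave.shape != cuff.shape:
        raise ValueError("simulate: wave and cuff must share one grid")
    if dt > 2e-3:
        raise ValueError("simulate: dt must be <= 2 ms")
    ptm = wave - cuff
    ra = np.ascontiguousarray(brachial_resistance(ptm, col))
    pa0 = float(wave[0]) if pa0 is None else float(pa0)
    pv0 = cp.p_ven_sys if pv0 is None else float(pv0)
    pa, pv, qin, qs, qout, gate = _step_loop(
        wave, cuff, ra, dt, cp.Ca, cp.Cv, cp.Rs, cp.Rv, cp.p_ven_sys,
        cp.vein_collapse_ptm, 1.0, pa0, pv0,
    )
    if not (np.isfinite(pa[-1]) and np.isfinite(pv[-1])):
        bad = int(np.flatnonzero(~np.isfinite(pa))[0])
        raise FloatingPointError(f"simulate: non-finite state at step {bad} (t={bad * dt:.4f} s)")
    t = np.arange(wave.shape[0]) * dt
    res = SimulationResult(t=t, p_art_distal=pa, p_ven_distal=pv, p_cuff=cuff,
                           p_systemic=wave, flow_in=qin, flow_s=qs, flow_out=qout)
    res.stage_labels = None
    return res


STAGE_NAMES = {
    1: "cuff below venous pressure",
    2: "vein collapsed, artery unaffected",
    3: "diastolic build-up",
    4: "systolic attenuation",
    5: "no inflow, exponential equilibration",
}


def classify_stages(res: SimulationResult, wave: SystemicWave, cp: CircuitParams,
                    *, sys_margin: float = 10.0,
                    inflow_eps: float = 1e-3) -> np.ndarray:
    """Label each sample with its cuff-inflation stage (1..5).

    1. cuff pressure below the systemic venous pressure;
    2. vein collapsed (outflow stopped) while the artery is unaffected;
    3. cuff above diastolic pressure: distal diastolic pressure builds up;
    4. cuff within ``sys_margin`` of systolic pressure: distal systolic falls;
    5. no arterial inflow over a full beat: exponential equilibration.

    Stores the labels on ``res.stage_labels`` and returns them.  If the ramp
    never reaches the systolic range, stages 4-5 are simply absent.
    """
    pcuff = res.p_cuff
    n = pcuff.shape[0]
    stages = np.ones(n, dtype=np.int8)
    vein_closed = res.flow_out == 0.0
    # stage 2 from the first sustained vein closure during inflation
    stages[vein_closed & (pcuff > 0)] = 2
    stages[(pcuff > wave.p_dia)] = 3
    stages[(pcuff > wave.p_sys - sys_margin)] = 4
    # stage 5: no inflow for a whole beat period
    period = 1.0 / wave.heart_rate
    win = max(1, int(round(period / res.dt)))
    inflow = res.flow_in > inflow_eps
    # rolling "any inflow in the past beat"
    csum = np.concatenate([[0], np.cumsum(inflow)])
    recent = csum[win:] - csum[:-win]  # inflow samples in trailing window
    quiet = np.zeros(n, dtype=bool)
    quiet[win - 1:] = recent == 0
    stages[quiet & (pcuff > wave.p_dia)] = 5
    # outside the inflation keep stage 1
    stages[pcuff <= 0] = 1
    # enforce monotone non-decreasing stage during the ramp-up portion
    ramp = pcuff > 0
    idx = np.flatnonzero(ramp)
    if idx.size:
        stages[idx] = np.maximum.accumulate(stages[idx])
    res.stage_labels = stages
    return stages


def stage5_onset(res: SimulationResult, wave: SystemicWave, cp: CircuitParams,
                 **kwargs) -> float | None:
    """Time at which arterial inflow has been absent for one full beat."""
    stages = res.stage_labels
    if stages is None:
        stages = classify_stages(res, wave, cp, **kwargs)
    idx = np.flatnonzero(stages == 5)
    if idx.size == 0:
        return None
    return float(res.t[idx[0]])
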