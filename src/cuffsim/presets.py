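"""Reference parameter presets.

``literature_preset`` bundles the simulation conditions used throughout the
package's validation experiments: systemic 50/100 mmHg at 1 Hz, a 25 s linear
cuff ramp, venous pressure 10 mmHg, arm peripheral resistance 106 mmHg*s/mL,
arterial compliance 0.03 mL/mmHg and venous compliance 0.9 mL/mmHg (all
literature values for the adult upper arm), with brachial collapse parameters
a = 0.03, c = 0.1 and the area scale fixed by a 0.22 cm open radius from
ultrasound ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

from .collapse import CollapseParams
from .simulate import CircuitParams, CuffProfile, SystemicWave

__all__ = ["Preset", "literature_preset"]


@dataclass(frozen=True)
class Preset:
    wave: SystemicWave
    cuff: CuffProfile
    circuit: CircuitParams
    collapse: CollapseParams
    dt: float = 1e-3
    duration: float = 55.0


def literature_preset(*, p_max: float = 150.0, hold_duration: float = 20.0,
                      t_start: float = 5.0) -> Preset:
    """The standard simulation scenario used for validation experiments."""
    wave = SystemicWave(p_dia=50.0, p_sys=100.0, heart_rate=1.0)
    cuff = CuffProfile(t_start=t_start, ramp_duration=25.0, p_max=p_max,
                       hold_duration=hold_duration)
    circuit = CircuitParams(Ca=0.03, Cv=0.9, Rs=106.0, Rv=10.0, p_ven_sys=10.0)
    collapse = CollapseParams.with_open_radius(0.22, 100.0, a=0.03, c=0.1,
                                               cuff_length=10.0)
    duration = cuff.t_end + 5.0
    return Preset(wave=wave, cuff=cuff, circuit=circuit, collapse=collapse,
                  duration=duration)
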