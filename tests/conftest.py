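import numpy as np
import pytest

from cuffsim import (Scenario, generate_cuff_ramp, generate_recording,
                     generate_systemic_wave, simulate, simulated_timing_table)
from cuffsim.presets import literature_preset


@pytest.fixture(scope="session")
def preset():
    return literature_preset()


@pytest.fixture(scope="session")
def preset_sim(preset):
    """The standard inflation simulation shared across the suite."""
    wave = generate_systemic_wave(preset.wave, preset.duration)
    cuff = generate_cuff_ramp(preset.cuff, preset.duration)
    res = simulate(preset.circuit, preset.collapse, wave, cuff, preset.dt)
    return res


@pytest.fixture(scope="session")
def preset_inputs(preset):
    wave = generate_systemic_wave(preset.wave, preset.duration)
    cuff = generate_cuff_ramp(preset.cuff, preset.duration)
    return wave, cuff


@pytest.fixture(scope="session")
def timing_table(preset, preset_sim):
    return simulated_timing_table(preset_sim, preset.wave, preset.collapse)


@pytest.fixture(scope="session")
def ramp_beats(preset, timing_table):
    """Inflation-ramp beats with a measurable pulse (the dPAT dataset)."""
    tab = timing_table
    on_ramp = ((tab.beat_time >= preset.cuff.t_start)
               & (tab.beat_time < preset.cuff.t_start + preset.cuff.ramp_duration))
    return tab[on_ramp & np.isfinite(tab.dpat)]


@pytest.fixture(scope="session")
def clean_recording():
    """Noiseless synthetic recording of the standard scenario."""
    s = Scenario.from_preset(seed=11, noise_sd=0.0, drift_amp=0.0)
    return s, generate_recording(s)


@pytest.fixture(scope="session")
def noisy_recording():
    s = Scenario.from_preset(seed=11)
    return s, generate_recording(s)
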