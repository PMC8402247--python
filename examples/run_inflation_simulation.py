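"""Simulate one cuff inflation and report the distal pressure response.

Builds the standard scenario (systemic 50/100 mmHg at 1 Hz, 25 s linear ramp
to 150 mmHg, literature circuit values), integrates the two-compartment arm
model and prints the distal mean-pressure rise and the five inflation stages.
"""

import numpy as np

from cuffsim import (classify_stages, generate_cuff_ramp,
                     generate_systemic_wave, literature_preset, simulate)
from cuffsim.simulate import STAGE_NAMES

pre = literature_preset()
wave = generate_systemic_wave(pre.wave, pre.duration)
cuff = generate_cuff_ramp(pre.cuff, pre.duration)
res = simulate(pre.circuit, pre.collapse, wave, cuff, pre.dt)
stages = classify_stages(res, pre.wave, pre.circuit)

n_per = int(round(1.0 / pre.wave.heart_rate / pre.dt))
nb = len(res.t) // n_per
beats = res.p_art_distal[: nb * n_per].reshape(nb, n_per)
maps = beats.mean(axis=1)
cuff_b = res.p_cuff[: nb * n_per].reshape(nb, n_per)[:, 0]
ref = maps[cuff_b == 0][:5].mean()

print(f"reference distal MAP      : {ref:6.1f} mmHg")
print(f"peak distal MAP           : {maps.max():6.1f} mmHg")
print(f"MAP rise during inflation : {maps.max() - ref:6.1f} mmHg "
      "(outflow is blocked while blood keeps entering)")
print()
print("inflation stages (cuff pressure at onset):")
for s in range(1, 6):
    idx = np.flatnonzero((stages == s) & (res.p_cuff > 0))
    if idx.size:
        print(f"  stage {s}: t = {res.t[idx[0]]:5.1f} s, "
              f"cuff = {res.p_cuff[idx[0]]:5.1f} mmHg - {STAGE_NAMES[s]}")
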