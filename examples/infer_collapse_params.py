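"""Bayesian inference of the brachial collapse parameters (a, c) from dPAT.

The simulated total pulse-arrival-time change contains both the brachial
collapse effect (truth a=0.03, c=0.1) and the distal stiffening effect from
the cuff-induced pressure rise.  Fitting the full cuff-pressure range with a
brachial-only forward model therefore biases the estimate; restricting to
points below diastolic cuff pressure recovers the truth at the price of a
wider posterior.
"""

import numpy as np

from cuffsim import (generate_cuff_ramp, generate_systemic_wave,
                     literature_preset, simulate, simulated_timing_table)
from cuffsim.inference import infer_collapse

pre = literature_preset()
wave = generate_systemic_wave(pre.wave, pre.duration)
cuff = generate_cuff_ramp(pre.cuff, pre.duration)
res = simulate(pre.circuit, pre.collapse, wave, cuff, pre.dt)

tab = simulated_timing_table(res, pre.wave, pre.collapse)
ramp = ((tab.beat_time >= pre.cuff.t_start)
        & (tab.beat_time < pre.cuff.t_start + pre.cuff.ramp_duration))
sub = tab[ramp & np.isfinite(tab.dpat)]

print(f"true parameters: a = {pre.collapse.a}, c = {pre.collapse.c}")
for mode in ("full", "truncate_at_pdia"):
    post = infer_collapse(sub.cuff_at_beat.to_numpy(), sub.dpat.to_numpy(),
                          pre.wave, pre.collapse,
                          p_beat=sub.p_dia.to_numpy(), mode=mode, seed=1)
    (a_lo, a_hi), (c_lo, c_hi) = post.hdi95
    print(f"{mode:>16}: a = {post['a']:.4f} [{a_lo:.4f}, {a_hi:.4f}], "
          f"c = {post['c']:.4f} [{c_lo:.4f}, {c_hi:.4f}]")
print("full-range fitting mistakes the distal slowdown for a softer artery;")
print("truncation removes the bias but widens the 95% interval.")
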