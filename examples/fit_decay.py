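"""Fit the post-collapse exponential decay for tau and the equilibrium pressure.

After the cuff stops all arterial inflow, the distal arterial and venous
pressures relax toward a common value as a two-capacitor RC discharge.  The
fitted time constant and asymptote are compared with their closed forms
tau = Rs*Ca*Cv/(Ca+Cv) and P_eq = (Ca*Pa0 + Cv*Pv0)/(Ca+Cv); a short fit
window reads slightly high in tau because the first seconds of the segment
still carry a trace of inflow from the final attenuated beats.
"""

from cuffsim import (generate_cuff_ramp, generate_systemic_wave,
                     literature_preset, simulate)
from cuffsim.inference import (analytic_tau, detect_decay_onset,
                               equilibrium_pressure, fit_exponential)

pre = literature_preset()
wave = generate_systemic_wave(pre.wave, pre.duration)
cuff = generate_cuff_ramp(pre.cuff, pre.duration)
res = simulate(pre.circuit, pre.collapse, wave, cuff, pre.dt)

t_on = detect_decay_onset(res, pre.wave)
i0 = int(t_on / pre.dt)
peq = equilibrium_pressure(res.p_art_distal[i0], res.p_ven_distal[i0], pre.circuit)

print(f"decay segment starts at t = {t_on:.1f} s")
print(f"analytic tau   : {analytic_tau(pre.circuit):.2f} s")
print(f"analytic P_eq  : {peq:.1f} mmHg (charge-sharing value at collapse)")
for wlen in (15.0, 4.0):
    i1 = i0 + int(wlen / pre.dt)
    fit = fit_exponential(res.p_art_distal[i0:i1], res.t[i0:i1])
    print(f"{wlen:4.0f} s window : tau = {fit.tau:.2f} s, "
          f"P_eq = {fit.p_equilibrium:.1f} mmHg "
          f"(rms residual {fit.residual_rms:.2f} mmHg)")
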