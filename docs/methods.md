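# Methods

## Model

The arm distal to an inflating brachial cuff is represented as a
two-compartment lumped circuit: arterial capacitance `Ca` charged from the
systemic pressure wave through the collapse-dependent brachial resistance
`Ra(Ptm)`, draining through the arm peripheral resistance `Rs` into venous
capacitance `Cv`, which empties through the venous resistance `Rv` into the
systemic venous pool.  The vein is a hard switch: outflow is zero whenever
its transmural pressure `Pv − Pcuff` is below the collapse threshold
(−10 mmHg, with 1 mmHg of reopening hysteresis to prevent chattering).
Assumptions: no autoregulation of `Rs` during the ~30 s of an inflation, no
wave propagation (lumped pressures), rigid cuff coupling (cuff pressure acts
directly as external pressure on artery and vein), instantaneous cuff
release, and a systemic wave unaffected by the inflation.

The brachial lumen follows the arterial collapse law
`A(Ptm) = d·ln(a·Ptm + 3.3)/(1 + e^(−c·Ptm))` (area in cm², pressures in
mmHg; the literal constant 3.3 together with `a` fixes the collapse point).
The formula yields a non-physical negative area once the log argument drops
below 1; the implementation clamps that regime to zero area ("fully
collapsed") where a caller opts in, and otherwise raises.  Poiseuille
resistance over the cuff length is capped at 10⁶ mmHg·s/mL — at physiologic
gradients this passes < 10⁻⁴ mL/s, numerically indistinguishable from full
occlusion, while keeping the ODE well-conditioned.

**Which pressure drives `Ra`.**  Inflow gating uses the proximal (systemic)
pressure: `Ptm = Ps(t) − Pcuff(t)`.  This reproduces the diode-like beat
entry observed distally (beats enter while the systemic wave tops the cuff
pressure) and makes `Ra(t)` an exogenous series, which keeps the integration
linear per step and makes the circuit-MCMC forward model cheap.

**Pulse timing.**  The transit change over the cuffed segment is
`ΔPTT_brachial = L_cuff·(1/PWV(p_beat − Pcuff) − 1/PWV(p_beat))`, with
Bramwell–Hill `PWV = sqrt(V/(ρC))` (the area scale `d` cancels).  The
intra-beat evaluation pressure `p_beat` is the per-beat **under-cuff
diastolic** pressure: the wave foot — the feature all PAT/PTT measurements
lock onto — rides at diastolic level, and once the cuff exceeds systemic
diastolic the under-cuff segment communicates with the distal compartment,
whose diastolic pressure is elevated.  Evaluating at systolic pressure
instead makes the simulated total ΔPAT monotone in cuff pressure and moves
the full-range fit optimum to a qualitatively different ridge; the
diastolic-side choice yields the observed rise-then-dip ΔPAT shape.  The
distal segment uses a linear PWV–MAP law calibrated once per scenario so
that a +20 mmHg MAP rise gives a −20 ms transit change (the amplitude seen
invasively), with 5 m/s distal PWV at the reference MAP and a 0.4 m
cuff-to-finger path; the radial line sits halfway along it, hence measured
`ΔPTT(ABP−PPG)` is half the distal change, and
`ΔPAT − 2·ΔPTT(ABP−PPG)` recovers the brachial share exactly.

## Parameters and defaults

| parameter | default | unit | note |
|---|---|---|---|
| Ca, Cv | 0.03, 0.9 | mL/mmHg | literature values for the adult arm; Cv ≈ 30·Ca |
| Rs | 106 | mmHg·s/mL | direct in-vivo measurements of arm resistance |
| Rv | 10 | mmHg·s/mL | weakly identified during fast inflations |
| Pven | 10 | mmHg | physiologic range 5–15 |
| a, c | 0.03, 0.1 | 1/mmHg | brachial collapse shape |
| d | 0.0826 | cm² | sets open radius 0.22 cm at Ptm = 100 (ultrasound range) |
| η | 3.2×10⁻⁵ | mmHg·s | ≈ 4.3 mPa·s blood viscosity |
| ρ | 1.06 | g/cm³ | blood density |
| cuff length | 10 | cm | occluded segment |
| ramp | 0→150 mmHg in 25 s, hold 20 s | | systolic + 50, standard rapid NIBP inflation; the hold leaves a 15 s collapsed segment |
| σ (envelope likelihood) | 2 | mmHg | pressure transducer noise |
| σ (dPAT likelihood) | 1 | ms | simulated beat series are numerically clean; use ~4 ms (one 125 Hz sample per foot) for real recordings |

## Numerics

Integration is fixed-step backward Euler at `dt = 1 ms` on the 2×2 linear
system per step (stiffness-safe against the `Ra` cap); the flows recorded at
the updated state make stored volume match integrated flux to machine
precision, and halving `dt` moves the pressure trace by < 0.5 mmHg.
Exponential fits use Levenberg–Marquardt least squares with slope-based
initialisation; they are exact (rel. error < 10⁻⁶) on noiseless
exponentials.  The PWV(Ptm) calibration is tabulated on a 1 mmHg grid over
the monotone branch (≥ 50 mmHg, where PWV is near-linear in Ptm) and
inverted by linear interpolation; beats whose implied PWV leaves the table
are marked unestimable rather than extrapolated.

**Decay-window start.**  The "fully collapsed" segment begins at the first
beat whose distal pulse pressure falls below 15% of the pre-inflation pulse
pressure — the point where the pulse has visually vanished from the trace.
The first second or two beyond this point still admit a trace of inflow
from the final attenuated beats while the ramp finishes; this contamination
is deliberate and is what makes the short (4 s) fit read ~10% high in τ and
~1 mmHg low in the asymptote relative to the closed forms, mirroring what
segment-by-eye analysis of real inflations produces.  A stricter rule (no
inflow for a full beat) yields the analytic constants from either window.

**Samplers.**  Both Bayesian estimators use a single-chain random-walk
Metropolis sampler in log-parameter space (positivity by construction) with
scale adaptation to a 20–50% acceptance rate and covariance-shape adaptation
(classic adaptive Metropolis) during the 20% burn-in; the shape adaptation
matters on the ridge-shaped `(a, c)` posterior.  Priors are flat on the
natural scale over broad physiologic boxes (`a ∈ [0.003, 0.3]`,
`c ∈ [0.01, 1]`; `Ca ∈ [0.003, 0.3]`, `Rs ∈ [10, 1000]`,
`Cv ∈ [0.05, 9]`), the circuit prior additionally rejecting parameter sets
whose RC decay constant exceeds 10 s.  Central tendency is the posterior
median; intervals are 95% highest-density intervals (narrowest window over
sorted samples).  Defaults: 40 000 iterations for the cheap analytic dPAT
likelihood, 6 000 for the simulation-backed envelope likelihood.  The
envelope likelihood sums per beat (each beat contributes its diastolic
minimum at its cuff pressure), covering ramp and hold; data and model
envelopes share one beat grid, so no cuff-pressure interpolation enters the
likelihood.

## Synthetic recordings

The generator emulates an operating-room acquisition: cuff, radial ABP and
finger PPG at 125 Hz, ECG at 500 Hz, one inflation per record.  ABP is the
simulated per-beat diastolic baseline plus raised-cosine pulses whose feet
sit at the model arrival times, with Gaussian transducer noise (2 mmHg) and
sinusoidal respiratory drift; the PPG surrogate is an amplitude-tracking
raised-cosine pulse train (the analysis uses only foot times); the ECG is a
narrow-impulse train.  Artifacts (pulse dropout, arterial-line flush
plateau, abrupt pulse-pressure steps) can be injected for QC testing.  All
noise flows from one seed; a zero-noise scenario is bit-identical across
seeds.

What the generator does **not** emulate: real PQRST and PPG morphology,
heart-rate variability, respiration-locked stroke-volume modulation,
probe-contact-pressure effects, or intra-beat waveform changes under the
cuff (ABP morphology is schematic between its foot and its envelope).
Passing round-trip tests therefore demonstrates the internal consistency of
the pipeline — detector bias cancels in Δ-features to within one 125 Hz
sample — not robustness to clinical morphology; QC thresholds (2 s pulse
gaps, 250 mmHg flush plateau, 20 mmHg pulse-pressure change across an
inflation) are exercised on these schematic artifacts only.  The
pulse-pressure QC criterion compares cuff-free segments before and ≥ 20 s
after inflation onset, since during the ramp the cuff itself changes the
distal pulse pressure by far more than the threshold in every clean
recording.

## Known limitations

* The model holds `Rs` fixed through an inflation; real arm resistance
  likely adapts, so inferred values are indicators rather than measurements.
* `d` (absolute collapse amplitude) is not identifiable from timing data and
  is held fixed during `(a, c)` inference; applying the circuit estimator to
  real data requires an independent handle on `d` via cuff/tissue mechanics.
* The equilibrium pressure equals the mean systemic filling pressure only if
  artery and vein collapse simultaneously; under a standard ramp the vein
  closes ~20 s earlier, so `P_eq` sits above venous pressure by the trapped
  charge.
* The homogeneous-segment assumption for the distal path (and the halfway
  placement of the arterial line) makes the factor-2 recombination exact in
  the generator but only approximate in vivo.
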