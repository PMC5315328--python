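# Methods

## The plant: a lumped-parameter mock-circulation-loop surrogate

The physical apparatus being emulated is a dual-circuit mock circulation
loop (MCL): pneumatically driven silicone ventricles with an automatic
beat controller and a built-in per-beat Starling response, passively
filling atria, four air-chamber Windkessel compliances (systemic and
pulmonary, arterial and venous), socket-valve vascular resistances and
mechanical check valves, with a centrifugal LVAD cannulated from the
left ventricle to the aorta. `slcsim` replaces that hardware with a
deterministic ODE model of eight fluid compartments plus pump flow:

    LA → MV → LV → AoV → SA → SVR → SV → RA → TV → RV → PuV
       → PA → PVR → PV → LA,     pump: LV → SA

Passive chambers are linear compliances, P = (V − V0)/C. Ventricles are
time-varying elastance chambers,

    P(V, t) = e(t)·E_es·(V − V0) + (1 − e(t))·P_ed(V)

with a sin² activation e(t) over the systolic interval (smooth, single
peak of 1 at mid-systole, zero in diastole). Valves are ideal diodes
with series resistance; vascular resistances are configured in
dyne·s·cm⁻⁵ as on the bench and converted internally by 1/1333.22 to
mmHg·s/mL. Flows are mL/s internally and L/min in all reported
quantities.

### Passive ventricular pressure–volume relations

The two end-diastolic P–V relations carry most of the scenario
phenomenology and are deliberately different in shape:

* **Left ventricle — concave-logarithmic.**
  `P_ed = c·ln(1 + (V − V0)/s)` with c = 6 mmHg, s = 25 mL, V0 = 10 mL.
  The sac is stiff when under-filled (pressure falls steeply toward
  negative values below V0, which is what a preload sampler reads
  during suction) and increasingly compliant once distended. The
  concavity is essential: a convex exponential EDPVR either makes the
  exercise preload rise implausibly large or the blood-loss preload
  drop implausibly small — with one curvature it cannot do both. Below
  10 % of the volume scale the logarithm is continued linearly (slope
  matched) so any transient volume the integrator visits has a defined
  pressure.
* **Right ventricle — saturating.**
  `P_ed = a·(1 − exp(−b·(V − V0)))` with a = 15 mmHg, b = 0.0015 /mL,
  V0 = 20 mL. The passive pressure approaches a ceiling: a weakened
  right ventricle cannot push flow through a raised pulmonary
  resistance simply by dilating without bound, so when its contraction
  collapses (blood loss) the left-side supply genuinely starves —
  which is what produces suction under the constant-speed pump.

### Ventricular Starling mechanism and contractility index

At each beat onset the end-diastolic pressure of each ventricle is
sampled and its end-systolic elastance for the coming beat is scaled by
`clamp(1 + gain·(EDP − ref), lo, hi)`. The left ventricle uses gain
0.15 /mmHg around ref 7.5 mmHg on [0.2, 2.2]; the right uses a much
steeper gain 0.8 /mmHg around ref 5.5 mmHg on [0.02, 1.25]. The
asymmetry is intentional: the RV's upward response saturates early
(limiting how hard exercise volume loading is transmitted into the left
heart) while its downward response collapses quickly (so hemorrhage
shuts the right-side supply down). The bench reports left-ventricular
contractility as an index C_lv in mmHg/s (a dP/dt-like quantity); it is
mapped affinely to end-systolic elastance,
`E_es = max(7.7e-4·C_lv − 0.35, 0.02)` mmHg/mL, so that the baseline
setting (1040) gives a failing ventricle, the exercise setting (1880) a
near-normal one, and the "contractility eliminated" setting (25) an
essentially passive chamber with no pulsatility.

### Suction guard

Below a residual volume (7.5 mL, just under the LV unstressed volume)
the pump inlet resistance rises steeply (logistic in volume, width
0.4 mL, up to +300 mmHg/(L/min)). An over-drained ventricle therefore
rides a volume floor where the EDPVR reads ≈ −0.1 mmHg — the
end-diastolic-pressure signature of suction — instead of integrating to
negative volumes.

### Pump and actuator

Head: `H = a0·ω² + a1·ω·Q + a2·Q·|Q|` (a0 = 2.66e-5 mmHg/rpm², a1 = 0,
a2 = −1.05 mmHg·min²/L²). The droop term is odd in Q: with a literal
a2·Q² a transiently reversed flow would see a head *gain* and run away.
Cannula momentum balance `L·dQ/dt = H − (P_ao − P_lv) − R·Q` with
R = 1.2 mmHg/(L/min) and L = 0.35 mmHg·s/(L/min); the speed actuator is
a first-order lag (τ = 0.2 s, small against the ~2 s closed-loop
dynamics) toward the clamped command, never below 1800 rpm while a
controller is engaged.

### Integration

Fixed-step RK4 at dt = 0.5 ms, the controller sample period; the
controller is invoked once per step. Determinism was a design
requirement (regression tests, bit-identical reruns), which rules out
adaptive steppers. Mass balance is exact by construction: every flow
enters one compartment's derivative positively and one negatively, the
shift reservoir included, so total fluid is conserved to floating-point
accuracy over a full 240 s run (tested < 1 mL). The passive-equilibrium
oracle (no beats, no pump) relaxes to the closed-form mean circulatory
filling pressure obtained by a bracketed root find on the total-volume
balance; the slowest redistribution time constant is ≈ C_total·SVR ≈
95 s, so the oracle run relaxes for 600 s at a coarser 5 ms step (no
controller is present there).

## Controllers

The Starling-like controller follows the bench implementation exactly:
PLVED sampled once per beat at the instant preceding activation onset
(the beat clock is owned by the loop, so end-diastole is known); a
first-order 0.25 Hz low-pass (exact unit DC gain,
α = 1 − exp(−dt/τ)) yields PLVED_m; the cubic control line with scaling
K maps it to a flow reference, floored at 0 (the cubic is negative below
≈0.1 mmHg; the 1800 rpm clamp is the real lower bound); a 1 s moving
average smooths the reference; and a PID with the published gains tracks
it against the 0.25 Hz-filtered pump flow. The PID output is a
correction added to the measured (filtered) mean speed — the incremental
form of the printed transfer function; an absolute-position variant is
available behind `mode="absolute"`. Discretisation: trapezoidal
integrator, derivative on the error after an extra 0.25 Hz low-pass
(all feedback signals on the bench are filtered at 0.25 Hz; an
unfiltered derivative at 2 kHz would amplify beat ripple), integrator
hold while the speed clamp is active. The constant-speed controller
returns its set speed (2100 rpm in the protocol), clamped at 1800.

### Step-response assessment

The tuning experiment steps the flow set point from 1.80 L/min (idle at
minimum speed) to 5.2 L/min. Settling time (5 % band, last exit) and
overshoot are measured on a 1 s trailing average of pump flow, which
cancels the beat-frequency component exactly at 60 bpm. The
controller's own 0.25 Hz first-order filter attenuates 1 Hz ripple only
4×, leaving a small beat-synchronous limit cycle that grazes the 5 %
band indefinitely and makes a last-exit settling time on that signal
ill-defined; the beat average is the standard mean-flow estimator for
assessment and does not enter the control loop. On the shipped plant
the step settles in ≈1.2 s with ≈4.7 % overshoot (bounds: ≤10 s, ≤10 %).

## Scenarios

Each experiment is 120 s of baseline heart failure (HR 60 bpm, SVR 1300,
PVR 110 dyne·s·cm⁻⁵, C_lv 1040 mmHg/s), an instantaneous parameter step,
and 120 s post-transition. Exercise: HR 90, SVR 600, PVR 40, C_lv 1880,
+700 mL shifted from the venous reservoir into the circulation over
20 s (linear ramp). Blood loss: HR 65, SVR 1635, PVR 210, −300 mL over
20 s. Contractility elimination: C_lv 25, all else unchanged. The 20 s
shift duration is the upper bound the bench could achieve; the exact
hardware value is not published. The atria fill passively throughout
(no atrial contraction is modelled); during exercise only C_lv is
stepped — the right ventricle responds through its own Starling law.

## Evaluation

NSD/SHD/RMSHD exactly as defined: per-sample excursion outside
[LL, UL], normalised by the band midpoint, squared; integrated by
trapezoid over the scoring epoch Td; RMSHD = 100·√(ΣSHD/Td). The
scoring epoch is the 120 s post-transition window (baseline epochs score
0 by construction when in bounds). Limits: MAP [80, 120] mmHg, PLVED
[2, 15] mmHg, CO [4, 6] L/min at rest and hemorrhage, [6, 11] L/min
during exercise — selected automatically from the scenario. Mean
signals for scoring reuse the controller's 0.25 Hz filter (initialised
at the first sample, so constant fixtures score exactly); PLVED_m is
the beat-wise sample held between beats and filtered identically.
Summary statistics (mean ± sd of speed, MAP, PLA, PLVED_m, CO, Q̄P) use
the final 30 s of each epoch. Suction is flagged when the 5-beat mean
of PLVED drops below 0 mmHg or the LV volume touches the collapse floor.

## Tuning and what the shipped defaults reproduce

The loop ODEs and several parameters (compliances, unstressed volumes,
Starling gains, pump coefficients, total volume) are not published for
the bench; they were calibrated, by scripted parameter sweeps, so that
the constant-speed controller at 2100 rpm under the baseline condition
settles near the bench's baseline operating point (mean pump flow
5.16 L/min, MAP 92 mmHg, PLVED_m 7.2 mmHg, left atrial pressure
9.2 mmHg here), and the three transitions reproduce the bench's
qualitative and approximate quantitative outcomes: exercise raises SLC
flow ≈42 % (to ≈7.4 L/min, against ≈5.8 L/min at constant speed);
blood loss drives the constant-speed run into suction (PLVED_m ≈ 0,
flagged) while the SLC backs off to minimum speed and holds PLVED_m ≈
2.4 mmHg; contractility elimination leaves both controllers inside all
clinical limits (RMSHD 0.0 %) with the SLC holding ≈5.2 L/min and the
CSC drifting to ≈5.1 L/min. Baseline MAP sits ~0.5 mmHg above the
90-mmHg-centred bench value: MAP, venous pressure and pump head are
linearly coupled at fixed SVR, and pushing MAP lower removed the
blood-loss suction margin, so the flow and preload anchors were given
priority.

The surrogate's speed excursions are larger than the bench's (the
fitted pump curve is under-determined: only a handful of printed
speed/flow pairs constrain a0, a1, a2), and the SLC settles *exactly*
on the printed control line — its steady state satisfies
Q̄P = cubic(PLVED_m) to within 2 % — whereas the bench's reported
exercise operating point lies about 1 L/min below that line,
presumably reflecting sensor scaling or reference offsets in the
physical rig. Agreement with bench numbers is therefore expected at
the 10–20 % level for flows and pressures, not at printed precision.

## Synthetic fixtures

Unit tests for the controllers and the metric run without the plant on
seeded synthetic traces: mean + half-sinusoid systolic pulse at the
configured heart rate + Gaussian noise per channel, with optional
injected per-beat PLVED staircases (recovered exactly by the preload
sampler) and scripted limit excursions (hand-checkable RMSHD values).
The default noise (0.5 mmHg pressures, 0.05 L/min flows) matches the
±0.1-scale run-to-run variability of the bench tables. These fixtures
emulate sensor streams, not physiology — no dicrotic notch, no
respiratory modulation, no sensor drift — so tests that pass on them
validate signal handling and scoring, not hemodynamic realism; the
plant runs carry that burden.

## Known limitations

* No baroreflex (deliberate: the bench has none either) and no
  long-term adaptation of the scaling factor K.
* The plant is a tuned surrogate: absolute agreement with the bench is
  approximate by construction, and conclusions transfer only at the
  level of controller-to-controller contrasts.
* The blood-loss suction margin under the constant-speed controller is
  a genuinely delicate balance (≈0.2 L/min between supply and demand),
  as it is physically; moderate parameter changes can tip the run
  either side of the suction threshold.
* Pump coefficients, cannula inertance and the actuator time constant
  are plausible but unverifiable against the bench hardware.
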