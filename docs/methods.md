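# Methods

## Model structure

The circulation is a closed loop of lumped elements: left atrium (LA) →
mitral valve → left ventricle (LV) → aortic valve → resistive aortic tree →
three-element Windkessel (RCR) terminals → a common venous node → a single
venous resistance → back into the LA. There is no right heart, pulmonary
circulation, baroreflex or coronary autoregulation; the coronary bed is one
of the six RCR terminals, branching at the aortic root.

State variables are the two chamber volumes, the two valve opening states,
the two transvalvular flows, one capacitor pressure per terminal and — when
the device is coupled — the device pocket volume (13 states). The aortic
segments are rigid and store no volume, so all node pressures and branch
flows follow algebraically from the state through a nodal analysis of the
resistive tree that is reduced once per parameter set to an affine map
`[p_root, p_device, p_outlets] = A·p_cap + b_av·Q_AV + b_dev·q_dev`. The
aortic-valve flow is a state (see Valves), so no nonlinear solve is needed
inside the right-hand side. Total stored blood volume is conserved exactly
by construction (the observed drift is ~1e-9 % per 10 cycles, pure
round-off).

### Chambers

`P(V,t) = A_pas·(exp(B_pas·(V−V0)) − 1) + e(t)·E_max·(V−V0)`. The
activation `e(t)` is a C¹ cosine bump that is zero outside
`[t_onset, t_onset+t_sys]`, rises to exactly 1 at `peak_frac·t_sys` into the
window and returns to 0 at the window end; the rising limb may additionally
be raised to a power `rise_power ≤ 1`. The defaults `peak_frac = 0.5`,
`rise_power = 1` give the symmetric half-cosine
`0.5·(1 − cos(2π·rel/t_sys))`. The LV defaults used for the patient are
`t_sys = 0.60·T`, `peak_frac = 0.95`, `rise_power = 0.5`: a fast upstroke
(pre-ejection period ≈ 60 ms), a slow late build-up of elastance, and a
rapid relaxation. This shape was chosen because the patient's CMR flow
waveform is broad (peak 266 mL/s at a stroke volume of 86 mL implies an
ejection lasting ≈0.5 s with a nearly flat profile); a symmetric bump
compresses ejection into ~0.2 s and overshoots the peak flow threefold. The
near-end-systolic elastance peak matches the physiological behaviour of
measured elastance curves. LA activation sits in late diastole
(onset 0.86·T, duration 0.13·T — an atrial kick ending 10 ms before
ventricular onset), placed so that the kick does not leave a diastasis gap
in which the LA pressure falls below LV end-diastolic pressure (which would
cause pre-systolic mitral back-leak).

### Valves

The opening state obeys `ds/dt = (1−s)·K_open·Δp` for forward gradients and
`ds/dt = s·K_close·Δp` for reverse gradients; both boundary factors vanish
at 0 and 1, so `s` cannot leave the unit interval (the RK4 step clips pure
round-off). The module-level flow law is the gated Bernoulli orifice
`Q = sign(Δp)·s·sqrt(|Δp|/b)` with `b = (ρ/2)/A_eff²` and a 1e-6 floor on
`s` inside the division only.

In the assembled loop, flow instead carries the blood-column inertance of
the orifice: `L·dQ/dt = Δp − (b/s²)·Q·|Q|`. The quasi-steady law lets the
reverse flow pin the transvalvular gradient near zero during closure, which
stalls the closing dynamics and produces ~30 mL/cycle of regurgitation; with
inertance the deceleration head drives closure and back-leak falls below 1%
of forward volume, matching healthy valve physiology. Below an opening gate
of `s = 0.05` the valve passes no orifice flow and the remaining flow decays
with a 2 ms time constant (this also bounds the stiffness of the `b/s²`
term; 0.05 is the same threshold the metrics use to mark valve closure).
Defaults: `K_open = 30`, `K_close = 60 /(mmHg·s)` (20–50 ms transitions at
physiological gradients), MV area 4.0 cm², AV effective area 1.0 cm² with a
10 cm blood-column inertance. The small AV area and long inertance stand in
for the full LVOT-plus-ascending-aorta impedance in an 87-year-old; they
shave the early-systolic flow spike without affecting mean gradients by more
than a few mmHg.

### Arterial tree and terminals

Segment resistances come from Poiseuille flow through the arithmetic mean of
10–20 sampled lumen areas (`R = 8πμL/Ā²`, μ = 0.04 poise, converted
dyn·s/cm⁵ → mmHg·s/mL by 1/1333.22), split into three equal series
sub-resistors. The packaged geometry is a plausible adult aortic arch
(synthetic — the source CT is not available): two ascending-aorta segments
(the device couples between them), brachiocephalic trunk, arch, the four
supra-aortic branches, a coronary trunk at the root and a 20 cm descending
aorta. Segment resistances are 10³–10⁴ times smaller than the calibrated
terminal resistances, so the fixture's exact dimensions are immaterial to
the calibrated hemodynamics.

Each terminal is `R_prox — C — R_dist`. The proximal share is 0.22 of the
branch resistance — an effective characteristic impedance of ≈0.24 mmHg·s/mL
at the root, typical of a stiff elderly aorta. It matters: pulse pressure
generated resistively (Zc·Q) does not have to be stored in the compliance,
which is what allows a 150/68 mmHg pulse together with a 266 mL/s peak flow.
Total terminal capacitance defaults to 0.9 mL/mmHg (uniformly rescaled by
calibration), distributed across terminals in proportion to their flow
fractions. All distal resistances drain into a single venous node (no
storage) connected to the LA through `R_ven = 0.03 mmHg·s/mL`.

### Device

Per actuation cycle, in time normalized to the delay
(`t_norm = t − ⌊(t−δt)/T⌋·T − δt`):

```
p_sr = g_act·p_aorta·(1 − exp(−k1·t_norm))          0 ≤ t_norm ≤ t_on
     = c·exp(−k2·(t_norm − t_on)) + d               t_on < t_norm ≤ t_off
     = 0                                            otherwise
```

with `k1 = 13.04 s⁻¹`, `k2 = 34.66 s⁻¹` and `(c, d)` fixed by continuity at
`t_on` and a zero at `t_off`. The gain is the quadratic surface
`g_act(p_aorta, p_act)` fitted by linear least squares to bench data and
clamped to [0, 1) before use (the capacitive analog cannot exceed its source
pressure). `p_aorta` during coupled simulation is the mean aortic-root
pressure of the previous completed cycle, refreshed at each cycle boundary —
the bench characterization used a static loop pressure, so the gain should
not see the instantaneous waveform. `p_act` stays in psi throughout,
matching the bench protocol.

The coupling is a capacitance `C_sr = 0.05 mL/mmHg` whose external plate is
driven at `λ·p_sr`, with a small series resistance `R_sr = 0.01 mmHg·s/mL`
that regularizes the algebraic loop into an ODE (coupling time constant
0.5 ms, well resolved at the 0.1 ms step). The pocket volume `x` references
the *deviation* of node pressure from the baseline mean, so an unpressurized
device exchanges no net volume with the circulation; at equilibrium
`x = C_sr·(p_node − p_ref − λ·p_sr)` and the injected flow is `−dx/dt`,
volume-neutral over every periodic cycle. A device block whose gain
coefficients are all zero is treated as absent, and `p_act = 0` runs the
identical code path as no device at all (bit-for-bit).

The correction factor λ absorbs the compliance/resistance difference between
the silicone bench loop and the patient aorta: it is found by bracketing so
that the peak pocket displacement at a 100 mmHg mean aortic pressure matches
the bench displacement. The synthetic bench target is 10 mL, chosen so the
coupled device produces diastolic augmentation of a few to ~10 mmHg — the
same order as the published device-on effects; λ ≈ 3.8 on the calibrated
patient.

### Synthetic bench data

The generator emulates the silicone-loop experiment: the full
8 × 7 protocol grid (loop pressure 50, 60, 70, 80, 90, 100, 125, 150 mmHg ×
actuation pressure 6–12 psi), gains drawn from a hidden surface of the
fitted quadratic form (chosen to lie in (0, 1), strictly increasing in
`p_act` and strictly decreasing in `p_aorta` over the grid), optional
Gaussian noise, and `t_on ≈ 0.3 s` / `t_off ≈ 0.5 s` with a mild `p_act`
dependence. What it does *not* emulate: actuator hysteresis, pneumatic line
delays, vessel-wall kinking, or any temperature/fatigue drift of the real
McKibben actuator — so tests passing on it show the fitting and coupling
machinery is correct, not that the real device behaves quadratically.

## Calibration

Stages, each owning its dominant knob:

1. **Total resistance** — `R_total = (MAP − p_ven)/CO` with the cuff
   estimate `MAP = DBP + (SBP − DBP)/3` and `p_ven ≈ EDP − 3 mmHg`; the
   total stressed blood volume is then trimmed by a secant until simulated
   CO is within 2%.
2. **Flow splits** — branch resistances `R_i = R_total/f_i` from the target
   fractions (the packaged defaults follow in-vivo splits, rescaled so the
   upper-body total matches the patient's measured upper/lower split), with
   multiplicative trims to within 0.5 percentage points at preserved total.
3. **Compliance** — uniform capacitance scaling until pulse pressure is
   within 5%.
4. **Heart** — the passive curve is pinned so
   `A_pas·(exp(B_pas·(EDV_target − V0)) − 1) = EDP_target`, then peak
   elastance (→ ESV) and systolic duration (→ peak flow) are tuned by
   damped secants.

Up to five outer refinement loops then update all knobs simultaneously
(volume → EDV with a stroke-volume assist, elastance → ESV, systolic
duration → peak flow, resistance → SBP, compliance → pulse pressure,
fractions → splits) and re-pin the passive curve at the *measured* EDV so
the realized end-diastolic pressure equals the target — the printed patient
table is internally inconsistent (CO ≠ HR·(EDV−ESV) by ~1.5%), so the
converged EDV is necessarily a few mL above the target and pinning at the
target value would overshoot EDP by >10%.

That same inconsistency is resolved up front by a minimax reconciliation:
internal setpoints `(EDV*, ESV*)` minimize the largest of the three
deviations `|EDV*−EDV|/(EDV·2.8%)`, `|ESV*−ESV|/(ESV·7.5%)`,
`|EDV*−ESV*−SV|/(SV·0.3%)`, the tolerances mirroring the fidelity of the
published model column. For self-consistent targets the reconciliation is
the identity, which is what makes forward-simulate-then-recalibrate round
trips recover all nine summary quantities to <1%.

All updates are deterministic (damped multiplicative secants plus
Nelder-Mead for the 2-variable reconciliation); the `seed` argument exists
for interface stability and feeds only synthetic-data generation. Two runs
with the same inputs produce identical reports.

## Measurement conventions

End-diastole is the LV activation onset (the R-wave, cycle origin): EDV and
EDP are read at the cycle boundary, where activation is exactly zero. ESV is
the cycle minimum of LV volume. CO is the cycle mean of aortic-root flow
× 0.06 (mL/s → L/min). Stroke work is `−∮P_LV dV_LV` over the time-ordered
cycle (positive for an ejecting loop), reported in mmHg·mL and J
(×1.33322e-4). Arterial elastance is ESP/CO with ESP the LV pressure when
the aortic-valve state first falls below 0.05 after ejection; with CO in
mL/s its unit is mmHg/(mL/s). Branch pressures and flows are recorded at the
junction between a branch's last vessel sub-resistor and its terminal's
proximal resistor. Diastolic augmentation is detected as a second local
maximum (prominence ≥ 2 mmHg) of a branch pressure waveform within one
cycle.

## Numerics

Fixed-step explicit RK4, default `dt = 0.1 ms`, 10 cycles; halving the step
changes CO, peak pressure and EDV by <0.001%. The stiffest time scale is the
device coupling (0.5 ms) followed by valve closure at large gradients
(`K_close·Δp ≈ 5·10³ s⁻¹`), both comfortably inside the RK4 stability region
at 0.1 ms. Initial conditions start from a literature guess (LV 120 mL,
LA 60 mL, terminals 80 mmHg) and are refined by a fixed-point iteration on
single cycles (next guess = cycle end) until the normalized mean-squared
cycle mismatch is below 1e-4, typically within 2–5 cycles; non-convergence
warns and returns the best state. Periodicity is declared at the first cycle
whose start values all repeat to 1% relative (denominator floored at 1e-9
for near-zero states). Calibration runs its ~50 settle-and-measure
evaluations at the full 0.1 ms step (a few seconds with the numba-compiled
kernel); sweeps settle 8 cycles per point from a warm start and measure on
the following cycles.

## Known limitations

No right heart, pulmonary loop, baroreflex, coronary flow regulation or
heart-rate variability; rigid named vessels (all arterial storage lives in
the terminals); the systolic activation window is long (0.6·T) because it
spans contraction build-up plus relaxation — its effective ejection time
(~0.5 s) is what matches the patient's broad flow waveform, but mean left
atrial pressure comes out ~13 mmHg against the ~11 mmHg a shorter systole
would give. Published device-on absolute numbers depend on the real bench
surface, timing tables and correction factor, none of which are public; the
coupled experiments are therefore validated through directional and
structural properties (timing of best/worst actuation, monotonicity in
actuation pressure, second diastolic peak in every branch, per-cycle volume
neutrality), never through absolute device-on values.
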