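# Methods

## Model

The model is a two-compartment conductance-based neuron: an isopotential
soma and a single lumped dendrite coupled by one conductance G_C, with
coupling currents weighted by the morphological factor p (somatic fraction
of total membrane area):

    C_m,S dV_S/dt = -G_m,S (V_S - E_L) - (G_C/p)     (V_S - V_D) - ΣI_A,S + I_S
    C_m,D dV_D/dt = -G_m,D (V_D - E_L) - (G_C/(1-p)) (V_D - V_S) - ΣI_A,D + I_D

All quantities are in normalized (dimensionless) units: conductances and
capacitances are specific (per-area) values, injected currents are
normalized by the area of their compartment, voltages are scaled so that
rest sits near V_S = −0.5 and spikes peak near +0.3. Time is ms-scaled, so
a frequency f in Hz enters as ω = 2πf/1000 rad per time unit; the
characteristic AC frequency defaults to 250 Hz (ω = π/2), the dominant
component of a ~2 ms action potential treated as half a sine period.

### Inverse solve (five properties → five parameters)

The order of solution is forced by the structure of the equations:

1. **Conductances.** The steady-state circuit gives
   VA_SD^DC = (G_C/(1−p))/(G_m,D + G_C/(1−p)),
   VA_DS^DC = (G_C/p)/(G_m,S + G_C/p), and
   r_N = 1/(G_m,S + (G_C/p)(1 − VA_SD^DC)). These invert in closed form;
   G_m,S is independent of p, while G_m,D and G_C scale with it.
2. **Dendritic capacitance.** The soma→dendrite transfer is first order, so
   its magnitude at ω determines C_m,D:
   C_m,D = sqrt((G_C/(1−p))²/VA_SD^AC² − (G_m,D + G_C/(1−p))²)/ω.
   A real solution exists only while VA_SD^AC < VA_SD^DC — the AC signal
   must have decayed below the DC level, the defining property of a passive
   low-pass tree. Violations are classified, not raised blindly
   (`ac_exceeds_dc`, `nonpositive_conductance`,
   `no_valid_somatic_capacitance`, `slow_eigenvalue_mismatch`).
3. **Somatic capacitance, last.** −1/τ_m is imposed as a root of the
   characteristic polynomial of the system matrix, which is linear in
   C_m,S once C_m,D is known. The solution is accepted only if −1/τ_m is
   the *slow* eigenvalue of the assembled matrix; the other root of any
   quadratic that arises (e.g. in the uniform-capacitance variant) would
   make it the fast, equalizing mode and is rejected.

The morphological factor p = 0.168 is the package default; it is the value
back-solved from the reference conductance set (G_C/p is fixed by the
VA_DS^DC constraint) and is exposed in `SystemProperties`.

The uniform-capacitance variant (C_m,S = C_m,D = C, constrained only by
τ_m) exists as an explicit contrast model: with the default conductances it
yields C ≈ 3.18 and |VA_SD(2π·0.25)| ≈ 0.07, versus 0.49 for the
split-capacitance model — the quantitative argument for fitting reduced
models on AC as well as DC signaling.

Useful derived identity (used as a test): the dendritic input resistance of
the solved circuit satisfies r_N,D = r_N · ((1−p)/p) · VA_SD^DC/VA_DS^DC,
where the (1−p)/p factor carries the per-area normalization of the two
compartments.

## Dendritic-tree frequency response

`freqresp` solves the complex nodal system (G + jωC)V = I on a compartment
tree for a unit point current, giving amplitude ratio and phase lag between
the source and every node. Numerical scheme:

- Each child node owns the frustum segment to its parent; half of each
  frustum's lateral area is lumped onto each endpoint (centered scheme,
  second-order accurate). A type-1 root additionally carries its spherical
  surface. Axial conductance of a frustum is πr₁r₂/(R_a L).
- Defaults R_a = 70 Ω·cm, C_m = 1 µF/cm², uniform R_m = 10 kΩ·cm²
  (configurable; an optional soma/dendrite step can be set by constructing
  trees with different constants — non-uniform profiles beyond that are out
  of scope).
- Dendrite→soma profiles place the point source at each node in turn; all
  solves reuse one sparse LU factorization.
- Phase is unwrapped by accumulating wrapped increments along root-to-tip
  paths, reproducing the continuous 0 → −2π lag of long dendrites.
- Against the sealed-end finite-cable closed form
  cosh((L−x)/λ_c)/cosh(L/λ_c), λ_c = λ/√(1+jωτ_m), the solver agrees to
  better than 10⁻³ relative at 5 µm discretization; discretization
  interpolates radii linearly, which conserves frustum area exactly.

Profiles are condensed by unweighted least squares on the linear VA scale
into a single-exponential decay constant η (VA = e^(−D_path/η)) and a cubic
through the origin for phase. The decay-constant triple
(η_SD^DC, η_DS^DC, η_SD^AC) defines a parametric "physiological trajectory"
through attenuation space, exp(−D_path/η) per axis, used by the sweep
intersection.

The direction asymmetry VA_SD ≥ VA_DS holds on fixtures whose somatic
impedance is low relative to dendritic point impedances — true of motor
neurons, whose soma anchors many thick dendrites, and emulated in tests by
a large equivalent soma. It is asserted exactly at DC; at 250 Hz the
proximal ~100 µm is excluded, where complex-impedance phase can invert the
pointwise comparison by <1e-3.

## Active dynamics

Somatic spiking uses the Morris-Lecar mechanism: instantaneous inward
activation m_S∞(V_S) (tanh form, half −0.01, slope 0.15) against a
delayed-rectifier gate n_S (half 0.0, slope 0.15, rate 0.5). Repetitive
firing starts at a subcritical-flavored Hopf bifurcation near I_S ≈ 0.45.
The n_S rate was set high enough that spikes are a few time units wide:
back-propagated spikes then carry energy near the characteristic frequency
band where C_m,D filters the three AC-attenuation variants differently.
This matters — with wide spikes the VA_SD^AC = 0.49 and 0.88 models receive
nearly identical dendritic ripple and the plateau threshold loses its
dependence on AC attenuation.

The dendritic PIC is an L-type-Ca-like current G_Ca·m_D·(V_D − E_Ca) whose
gate is *not* instantaneous: dm_D/dt = (m_D∞ − m_D)/τ_mD(V_D). The
activation time constant is bell-shaped in voltage,

    τ_mD(V) = τ_min + (τ_max − τ_min) · exp(−((V − V_half)/w)²),

slowest (300 time units) near half-activation and fast (40) far from it.
The slow near-threshold kinetics produce the delayed plateau onset (TTP > 0)
and the gradual build-up of net inward current before the bifurcation; the
fast kinetics at hyperpolarized potentials let a strong hyperpolarizing
pulse actually deactivate the PIC. A monotone (sigmoid) τ profile that stays
slow at rest was tried first and rejected: residual activation then decays
more slowly than spikes re-pump it, the plateau re-ignites after every
switch-off pulse, and bidirectional pulse switching is impossible.
A delayed-rectifier K⁺ gate n_D (half 0.0, slope 0.08, rate 0.1) shapes the
plateau amplitude and the deactivation fold.

**The default active set is a calibrated stand-in, not a published
parameter set.** It was produced by a three-stage constrained search
(documented and re-checked by `scripts/calibrate_active.py`): somatic grid
search for robust repetitive firing; closed-form placement of the dendritic
S-curve folds (the spikes-blocked equilibrium branch I_S(V_D) is analytic,
so fold currents are design variables); kinetic tuning of τ_mD. The
constraints it satisfies: rest at V_S ≈ −0.5; Hopf rheobase invariant
(<0.01) across the VA_SD^AC ∈ {0.08, 0.49, 0.88} variants; blocked plateau
threshold capacitance-invariant; onset fold between rheobase and ramp peak,
deactivation fold below rheobase; fully bistable (all CIs positive) firing
at all three variants under the standard ramp; plateau threshold
monotonically decreasing in VA_SD^AC; pulse-latched rest↔firing switching.
Quantitative magnitudes that depend on the exact channel parameters — CI
sizes, the precise threshold ratios, region boundary coordinates — are
model-specific here and are asserted only as orderings and signs.

Integration uses LSODA with rtol 10⁻⁶, atol 10⁻⁸, max step 0.5, dense
output on a uniform grid (Δt = 0.05 default; 0.1 for the long ramps in the
test battery, 0.2 inside sweeps). Gates are clipped to [0,1] on output as
numerical hygiene only. Simulations are deterministic; halving the
tolerances changes no spike count and moves spike times by <0.1 time units.

## Firing analysis

- **Spikes**: upward crossings of V_S through 0 (rest −0.5, peaks ≈ +0.3)
  with a 2-time-unit refractory, crossing instants linearly interpolated.
- **Plateau**: detected on the *lower envelope* of V_D (rolling minimum
  over 60 time units, longer than one interspike interval). Back-propagated
  spikes ride on V_D as large brief transients; the envelope tracks the
  inter-spike troughs, which is what actually distinguishes a plateau from
  ripple. Onset is the first sustained (≥10 units) crossing of the midpoint
  between the envelope's baseline and its high level; a lift of <0.15 is no
  plateau.
- **Characteristic indexes** under the symmetric triangular ramp
  (0→2.5→0 over 2700 time units): TTP = plateau onset − first spike;
  TES = last spike − the instant the descending ramp re-crosses the
  ascending rheobase; DSF = descending − ascending instantaneous rate
  (1/ISI assigned to the second spike of each pair), both linearly
  interpolated at the rheobase current. DSF is measured at the rheobase
  current, the threshold current of the first ascending spike.
- **Classification**: fully bistable (Type IV) ⇔ TTP, TES, DSF all
  positive, with deadbands |TTP| < 5 and |DSF| < 0.002 for "≈ 0" decisions
  (interpolation noise floor measured during calibration). Type III =
  plateau with TTP ≈ 0, sustained firing, DSF ≈ 0; partial bistable =
  plateau deactivating on descent above rheobase; I/II = no plateau,
  overlapping vs clockwise F–I.
- **Structural gates.** When a trace carries its model parameters, two
  capacitance-free facts about the spikes-blocked equilibrium branch are
  folded into classification: a cell is plateau-capable only if the branch
  is S-shaped with its onset fold reachable within the stimulus, and fully
  bistable only if its deactivation fold lies below the measured rheobase.
  Without this gate, tightly coupled cells (VA_SD^DC ≈ VA_DS^DC, large G_C)
  exhibit smooth dendritic depolarization whose slow-gate lag mimics
  counter-clockwise hysteresis and would be misread as bistable; their
  label is partial (synchronized) instead.

Two properties of the calibrated stand-in deviate from idealized
expectations and are tested at honest tolerances: the full model's
subthreshold V_S–I_S slope is ~10% above r_N (the Na window conductance at
rest; the passive model recovers r_N to <2%), and with the PIC ablated
(G_Ca = 0) TES remains slightly positive (~75 vs ~300 intact) because slow
passage through the Hopf point under a ramp delays the ascending first
spike and thereby shifts the rheobase-recross reference; DSF ≈ 0 and the
label correctly collapses to Type I/II.

## Bifurcation analysis

Equilibria have gates at steady state, reducing the search to (V_S, V_D):
multi-start Newton (hybr) from a 16×16 grid over [−0.9, 1.1]², deduplicated
at 10⁻⁵, residual tolerance 10⁻¹¹. Stability comes from the eigenvalues of
the full 5-D Jacobian (forward differences, step 10⁻⁷·max(1,|x|)). Hopf
points are sign changes of the leading complex-pair real part along the
resting branch, refined by bisection; folds are changes in equilibrium
count, bisected to 10⁻⁵. Fixed points are capacitance-independent (checked
numerically); stability is not.

The plateau-threshold current has two regimes. With somatic spiking blocked
(G_Na = G_K,S = 0) it is the saddle-node at which the hyperpolarized branch
disappears — found by tracking the lowest equilibrium along a current grid
and bisecting the disappearance — and is exactly invariant to the
capacitances, hence to VA_SD^AC. With spiking active, back-propagated
spikes tip the dendrite over the fold early, so the threshold is measured
from the standard ramp as the current at plateau onset; this is the
quantity that decreases monotonically as VA_SD^AC grows. A fixed-point fold
cannot carry that dependence (folds do not involve capacitances), so the
simulation-based definition is the only self-consistent one.

Limit-cycle envelopes come from post-transient simulation (first 30% of the
window discarded) started slightly depolarized off the lowest equilibrium.

## Attenuation-space sweep

Each grid cell of the (VA_DS^DC, VA_SD^DC, VA_SD^AC) cube is solved for its
passive parameters (r_N, τ_m, p held at defaults), simulated under the
standard ramp, and labeled; infeasible cells (mostly ac_exceeds_dc, i.e.
VA_SD^DC below the slice's AC level) are labeled without simulation, and
per-cell failures are recorded as "error" without aborting. Cross-section
"area" is the bistable fraction of feasible-grid cells in one AC slice.
The test battery uses a 4×4×3 smoke grid whose axes contain the default
triple (0.26, 0.89, 0.49) — about 30 s on one CPU; the default grid (step
0.04 on the DC axes, ~0.08 on the AC axis, ~8k cells) completes in under
an hour on one CPU. On the default active
set the bistable volume sits strictly above the VA_SD^DC = VA_DS^DC
diagonal, its area peaks at intermediate VA_SD^AC, and the physiological
trajectory built from measured decay constants (2678.7, 225, 420.1 µm)
enters the volume in a contiguous D_path interval containing 300 µm — the
hypothesized PIC location.

## Known limitations

- The active parameter set is a calibrated stand-in satisfying stated
  qualitative constraints; quantitative CI magnitudes and region boundary
  coordinates are not transferable to other channel parameterizations.
- Dendrite→soma attenuation uses single-point sources; synchronous
  distributed sources (which would decay more slowly with distance) are an
  extension, not implemented.
- Trees are passive: no resonant or regenerative dendritic conductances in
  the frequency-response engine, where the AC-below-DC feasibility
  condition could fail.
- Phase lag is not fit by the reduction (only AC amplitude); the
  first-order transfer form shows the model's phase saturates at −π/2,
  while long dendrites reach −2π.
- The synthetic morphologies are stylized (cylinders, symmetric binaries,
  random tapers); they reproduce the qualitative attenuation structure of
  reconstructed motor neurons, not any individual cell, so passing tests
  demonstrate correctness of the machinery, not anatomical fidelity.
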