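# Methods

This note documents the models and estimators in `ltccmicro`, the
parameter choices that matter, what the synthetic data do and do not
emulate, and the known limitations. Nothing here states an empirical
result that the test-suite or `scripts/acceptance.py` does not itself
compute.

## 1. Single-channel analysis pipeline (`ltccmicro.patch`)

**Potentials.** All stored potentials are liquid-junction corrected:
the K-gluconate bath / Ba²⁺-pipette solution pair carries a −16.7 mV
offset, so the protocols are hold −96.7 mV, I-V steps −36.7…+23.3 mV in
10 mV increments, and the open-probability step −6.7 mV (1 s, 50
consecutive pulses).

**Idealization.** Baseline (median of the pre-pulse window) is
subtracted, the trace is normalized by the unitary amplitude, and
per-sample integer open counts come from half-amplitude thresholds at
k − ½ level boundaries. Events shorter than 0.3 ms — about the rise
time of the 2 kHz acquisition filter — are merged into their longer
neighbour, shortest first. A sweep whose baseline drifts by more than
half a unitary amplitude is excluded with a reason code, mirroring
manual sweep rejection. On noiseless synthetic sweeps idealization
reproduces the generator's truth path exactly; at signal-to-noise 6 the
per-sweep open fraction is recovered within ±0.02, and the end-to-end
Po estimator is unbiased within 0.005 across Po ∈ {0.057, 0.102, 0.113}
(50 sweeps × 100 replicates, computed in the suite).

**Channel count and Po.** The channel count is the maximum simultaneous
open level across sweeps — a lower bound that reaches the true count
for sufficiently long recordings (property-tested). Po = NPo/N over the
depolarizing step, excluding 5 ms after the capacitive edge, and is
refused below the 20-analyzable-sweep protocol floor.

**Seal area.** `area = C / R²` with C = 110.6 µm²·MΩ², an inverse-square
tip-geometry law calibrated so the stated mean pipette resistance
(27.78 MΩ) maps to the tabulated grand-mean area per seal
(43.56 µm² / 304 seals ≈ 0.143 µm²). The original calibration constants
of the pipette-geometry method are not published, so this single-point
anchoring is the package's own choice.

**Aggregation.** Occurrence = active/total seals; density = total
channels / total sealed area; pooled strata sum counts and areas before
taking ratios (never means of ratios; pooling is order-invariant and
associative by construction). Internal arithmetic is unrounded;
presentation uses half-up rounding (one decimal for occurrence, two for
density). Four density cells and two occurrence cells of the published
table disagree with the packaged counts in the last digit; these are
pre-rounding/truncation artifacts of the source table, are flagged by
`ltccmicro patch table1 --verify`, and the printed densities are used as
inputs wherever the original comparison used them (the agonist-group
density ratio of 2.0).

## 2. Stochastic LTCC gating (`ltccmicro.markov`)

**State space.** The channel is a product of five independent binary
gates — activation d, fast/slow voltage inactivation ff/fs, fast/slow
Ca-dependent inactivation fcaf/fcas — the Hodgkin–Huxley decomposition
of the human ventricular I_CaL formulation. 2⁵ = 32 joint states; the
single all-permissive state conducts. A phosphorylated twin of every
state (no interconversion on gating time scales) gives 64 states.
Because the gates are independent and conduction requires all of them
permissive, the ensemble open fraction equals the product of gate open
probabilities; the deterministic generator-matrix integration of the
same chain is the oracle in the tests (row sums zero, occupancy
normalized, stochastic-vs-deterministic agreement within 3 Monte-Carlo
SEs at 1000 channels).

**Rates.** Gate steady states and time constants follow the
O'Hara–Rudy I_CaL laws. The prior single-channel study's exact rates
are not published, so the reconstruction carries two declared free
elements, both fixed in closed form before any simulation:

- the two voltage-inactivation gates share a non-inactivating pedestal,
  solved analytically so the **unphosphorylated stationary Po at
  −6.7 mV equals the measured control TT value, 0.057**;
- the Ca-dependent gates see a fixed representative microdomain Ca
  (TT 1.0 µM dyadic, crest 0.1 µM bulk) with half-inhibition 2 µM.

**Phosphorylation variants.**

- *PKA*: 2.5× unitary current; −8 mV hyperpolarizing shift of both the
  activation and voltage-inactivation half-voltages; 30% slowed
  inactivation time constants (voltage- and Ca-dependent). The shifts
  and slowing are stand-ins patterned on published β-adrenergic I_CaL
  modules, whose phosphorylated gate sets shift both curves
  hyperpolarized and slow both inactivation pathways.
- *CaMKII*: no current change; 2.5× slowed fast inactivation (the
  baseline model's own CaMK-phosphorylated gate set) plus a −6 mV
  activation shift anchored so the phosphorylated stationary Po at
  −6.7 mV is about twice the unphosphorylated one — the increase
  measured for DCM crest channels (0.113 vs 0.057). Slowed kinetics
  alone leave stationary Po unchanged, so without the shift
  phosphorylation could not raise Po at all.

**Ensemble simulation.** Each channel is an exact event-driven
continuous-time path (per-event exponential waiting time, switching
gate chosen proportionally to its rate) — no time-step bias in dwell
statistics. Initial gate states are stationary at the clamp voltage
with per-gate stratification: gate g is open in exactly
round(p·N) channels, scrambled across channels by coprime strides.
This removes the dominant between-channel variance — the slow
voltage-inactivation gate dwells ~13 s at −6.7 mV, far beyond any
affordable simulated duration — while leaving the ensemble mean
unbiased. Open time is accumulated after a 100 ms equilibration
discard.

**Calibration.** Every channel is simulated once unphosphorylated and
once phosphorylated with common random numbers; a channel is
phosphorylated with probability f, and the mixed-ensemble Po uses each
channel's expectation over that assignment (the f-weighted average of
its two paths — the Rao-Blackwellized mixture, which removes assignment
noise). Bisection on f to |Po − target| ≤ 2.5×10⁻⁴ over 120 s paths is
deterministic given the seed; targets outside the achievable range
clamp to 0 or 1 with a flag. With the defaults above, the fraction
matching the ICM TT Po of 0.102 at 1000 channels is ≈ 0.66–0.70
depending on seed (the suite asserts 0.7 ± 0.1, the tolerance chosen
because the prior model's rates are reconstructions).

## 3. Myocyte model (`ltccmicro.myocyte`, `ltccmicro.ord_model`)

**Baseline.** The O'Hara–Rudy human ventricular formulation,
re-implemented from its public description (endo/epi native scalings;
the endo/epi treatment of the cited transmural-remodeling study is not
reprinted, so the native celltype scalings stand in). Fixed-step
integration with Rush-Larsen exponential updates for gates and forward
Euler for voltage and concentrations, dt = 0.01 ms (single cell).
Validation in the suite: resting potential ≈ −88 mV, control endo APD90
≈ 285–296 ms at 1 Hz, deterministic traces.

**Microdomain partition.** I_CaL (and its Na/K components) is split
into a TT population (fraction `f_tt`, drives and senses the dyadic
subspace: strong Ca-dependent inactivation, feeds SR release) and a
crest population (fraction `1 − f_tt`, senses and feeds bulk cytosolic
Ca through its own Ca-binding gate: weak CDI, voltage inactivation
dominates). Control `f_tt` ≈ 0.71 comes from applying the
occurrence-ratio equation to the control strata — the same equation the
disease variants use — since the healthy split is not directly
measured. TTD multiplies the TT-population conductance (an interpretive
coupling; the integrity parameter is defined without an explicit rule).
The total current is always the sum of the two components (machine
tolerance), and rebuilding a disease variant with healthy knobs
(TTD = 1, control `f_tt`, no phosphorylation, no remodeling) reproduces
the control trace exactly.

**Variants.** ICM: TTD 0.65, `f_tt` 4/9, PKA on 70% of TT channels.
DCM: `f_tt` 0.45 (from the DCM occurrences), all crest channels
CaMKII-phosphorylated (dedicated shifted-activation + slowed-gate
states). Kinase block (H-89 / KN-93 analogues) resets the respective
phospho population to base gating. The correction factor iteratively
rescales the whole-cell LTCC current until the −96.7 → −6.7 mV clamp
peak matches control within 1% (applied to the summed current, per the
stated adjustment of the whole-cell current).

**Heart-failure remodeling.** Non-LTCC changes in both diseases are a
named, editable scaling set: SERCA 0.5, NCX 1.75, IK1 0.68, Ito 0.6,
INaL 2.0, IKr 0.25, IKs 0.8, SR release 0.8. These are phenomenological
calibrations, not literature measurements: the set was chosen so the
model family reproduces the qualitative disease surface — APD
prolongation, EADs in ICM and DCM but not in control, EAD disappearance
under the matching kinase block, and the tissue-level separation below.
IKr is the decisive lever; 0.25 sits midway between the value at which
the kinase-blocked variants begin to EAD (≤ 0.2) and the value at which
ICM stops (≥ 0.35). A consequence of this severity is that the DCM
cell at 1 Hz shows dome-collapse alternans: alternate beats lose the
plateau (very short APD90) while the others are EAD-laden and fail to
repolarize within their cycle; the APD tests treat
non-repolarizing-within-window as prolonged and require only one of the
first two DCM responses to show prolongation directly.

**Protocols and measures.** Voltage clamp: 2 s hold at −96.7 mV, 500 ms
step to −6.7 mV; decay metric = time from peak to 50% of peak per
component. Pacing: 100 pre-pacing beats at 1 Hz (cached per parameter
vector), then the skipped-beat protocol — two stimuli at 1 s intervals,
two skipped beats, 1 Hz resumed at 4 s; stimulus −80 µA/µF × 0.5 ms.
APD90 runs from maximum upstroke velocity to the interpolated crossing
of peak − 90% of amplitude. An EAD is a negative-to-positive dV/dt sign
change after the AP peak, before repolarization to −40 mV, followed by
≥ 2 mV of secondary depolarization (the source experiments report EADs
without an operational definition; this one is the package's).

## 4. Structure metrics (`ltccmicro.structure`)

Density: Otsu threshold inside the cell mask, reported as foreground
fraction of the masked area (bounded by 1; the literal black:white odds
ratio is a secondary output); a class-separation guard keeps pure-noise
images at density 0. Regularity: mean over 40 × 5 µm rectangles of the
normalized 1D power-spectrum peak within the physiological sarcomere
band (1/2.2–1/1.6 µm⁻¹) of the long-axis projection; 1 for a pure
sinusoid at the sarcomere period; because the original macro's
normalization is unpublished, only relative comparisons are meaningful.
Z-groove index: detected valley length per groove line over the
expected length inferred from the dominant transverse period; flat or
aperiodic maps return 0 with a low-confidence flag. TT openings:
difference-of-Gaussians band-pass at the 0.3–1.2 µm scale, local
depressions kept at circularity ≥ 0.6. All four metrics are invariant
to constant offsets. Recovery against generator truth: density within
0.03, groove completeness within 0.07, opening counts within ±1.

## 5. Tissue cable (`ltccmicro.cable`)

Monodomain reaction-diffusion with operator splitting: each cell steps
the ionic model, then an explicit finite-difference diffusion step
couples voltages with no-flux ends; the CFL bound is checked before
integration. Defaults: 100 µm pitch (one myocyte per node),
D = 0.0017 cm²/ms — about 50 cm/s control conduction — dt = 0.005 ms,
a 20-cell central disease patch, 5 stimulated edge cells × 2 ms (at
tissue load the single-cell stimulus fails to excite). The 100 µm
pitch is a deliberate cell-scale discretization: it carries a few
percent discrete-cable conduction offset, and grid convergence (< 2%
activation-time change under dx/dt halving) is verified on the
continuum-resolved 50 → 25 µm pair with the stimulus width fixed in
physical units.

Classification: `none` (activations only at stimuli),
`local_ead` (patch EADs without distal non-stimulated activation),
`triggered_propagation` (a distal activation with no stimulus in the
preceding 200 ms). Under the defaults the surface is: control `none`,
ICM `none` (its cellular EADs are electrotonically clamped), DCM
`triggered_propagation` after the skipped beats — the ordinal severity
ranking control ≤ ICM ≤ DCM that stands in for the whole-heart
experiment.

**Limitation.** In 1D the transition is effectively binary: sweeping
patch size or coupling moves an ICM patch straight from fully clamped
to fully propagating (at ≈ 47 of 60 cells), without an organic
intermediate confined-EAD regime. The "EAD island" of the whole-heart
simulations needs a 2D/3D source-sink ratio that a cable cannot
provide; the `local_ead` classification logic is therefore exercised
with constructed traces in the tests, and the cable's claim is the
ordinal ranking, not reentry.

## 6. Synthetic data (`ltccmicro.synth`)

Sweep sets: continuous-time gating (exponential dwells, exact
event-driven) sampled onto the 10 kHz grid; openings only during the
depolarizing step; current = open count × unitary amplitude
(−1.2 pA default at −6.7 mV, consistent with ~18 pS and reversal near
+60 mV — the recordings' own amplitude and noise levels are not
published) plus Gaussian noise shaped by a 4-pole Bessel low-pass at
2 kHz; the true path is stored in a parallel array, never mixed into
the signal. Images: stripe lattices at the sarcomere spacing with
jitter controlled by the regularity parameter, trimmed/topped-up to the
exact requested tubule fraction. Topography: groove lines at the
sarcomere spacing, segment-wise removal to the requested completeness,
Gaussian-bowl openings centred on kept grooves. I-V: amplitudes on
`i = g(V − V_rev)` plus noise.

What the generators do **not** emulate: amplifier/seal artifacts,
baseline wander and flicker noise, modal (mode-2) gating, optical
point-spread functions, scanning physics, nuclei or cell-boundary
irregularity. Passing recovery tests therefore demonstrates estimator
correctness under the stated acquisition model, not robustness to every
pathology of real recordings.

## 7. Problem sizes

Chosen to keep the default suite and the reproduction script
desk-scale: calibration 1000 channels × 120 s paths; recovery tests
50 sweeps × 100 replicates per Po; pacing 100 pre-beats + 8 s protocol
per variant; cables 60 cells × 9.5 s (convergence check 80/160 cells ×
0.35 s). The acceptance script runs the counts-table arithmetic and one
full calibration.
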