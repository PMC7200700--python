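# Methods

`thetalock` models how CA1 pyramidal cells in the deep and superficial
portions of stratum pyramidale lock their firing to different phases of the
hippocampal theta rhythm, and provides the analysis stack used to measure
that phase locking in simulated or recorded data. This note documents the
model, its parameters, the numerical choices, what the synthetic-data
generators do and do not emulate, and the known limitations.

## The biophysical cell model

Cells are trees of cylindrical compartments. Each compartment integrates 18
coupled state equations: the membrane potential, an intracellular calcium
pool, and 16 gating variables distributed over eight active conductances —
Na (fast activation m, inactivation h, and a slow attenuation gate s),
delayed-rectifier K (n plus a slow inactivation gate), A-type K (a, b),
BK-like Ca-and-voltage-dependent K (voltage gate x calcium gate), slow AHP
K (calcium gate), M-type K (two activation time scales), L-type Ca (two
gates) and HCN (fast and slow components) — plus the passive leak. Every
current is ohmic, I = g(V,t) (V − V_rev), and every effective conductance
is the product of a maximal conductance and a dimensionless scaling factor
(the quantity tuned by the genetic-algorithm fit).

Passive properties follow the conventions of scaled-down CA1 models:

- axial resistivity Ra = 100 Ohm·cm (times its scaling factor);
- somatic capacitance 5 uF/cm²; dendritic capacitance 1.8 x 5 x SS, where
  SS is the spine surface-area correction (1 at the soma, 2.51 on basal
  dendrites, and a diameter/distance decision table on apical dendrites:
  1.69 / 1.60 / 1.86 for thick / intermediate / thin apical segments within
  350 um of the soma, 2.10 / 0.35-um-threshold / 1.71 beyond). Diameter
  thresholds are half-open intervals closed on the lower bound, and
  z = 350 um exactly falls under the proximal rule; the source material
  leaves both boundaries unspecified, so these are conventions chosen for
  determinism.
- leak conductance rising sigmoidally with somatodendritic distance z:
  g_pas(z) = 0.001 / (80 + (0.4 − 80)/(1 + exp((225 − z)/30))) S/cm²,
  scaled by SS outside the soma. The profile runs from ~1.25e-5 S/cm²
  perisomatically to 2.5e-3 S/cm² distally, which makes distal dendrites
  two orders of magnitude leakier than the soma and strongly attenuates
  distal synaptic drive.

Somatodendritic distance z is measured along the tree from the soma centre
(path distance), since no other definition is workable on an abstract
compartment tree.

### Gating kinetics and channel distributions

The rate functions are generic CA1 pyramidal kinetics in the
Migliore/Poirazi tradition, parameterized as sigmoidal steady states with
constant or bell-shaped time constants, and exposed as a plain dictionary
(`DEFAULT_KINETICS`) so that an external kinetics set can be dropped in
wholesale. The exact allocation of the 16 gating variables across channels
is a documented convention — the constraint honored is the total of 18
state equations per compartment.

Maximal conductances follow linear-in-z profiles with floors and caps
(`DEFAULT_GMAX_PROFILES`): Na and the delayed rectifier are strongest
perisomatically (120 and 40 mS/cm² at the soma, falling to 80 and
22 mS/cm² distally), the A-type and HCN currents grow with distance, and
the remaining channels are uniform. The dendritic Na floor matters
scientifically: with passive dendrites the distal entorhinal input cannot
drive somatic firing at all, while with soma-level dendritic Na the
dendrites escape perisomatic inhibitory control. The shipped value
(80 mS/cm²) keeps dendrites regeneratively boosting distal input while the
perisomatic compartments still gate action-potential output, which is the
regime the sublayer experiments probe. These profiles were calibrated once,
together with the input table below, so that the default cell fires at
realistic rates (0.01–8 Hz) under the full theta-modulated input
collection, and were not revisited afterwards.

### Numerics

Gating variables advance by exponential Euler (exact for frozen rates; the
step factor is precomputed for constant-tau gates). The voltage of the
whole tree is solved implicitly each step by Hines-style elimination
(children eliminated into parents, then back-substitution), which keeps the
stiff axial coupling stable. The default step is dt = 0.05 ms for the
long theta simulations and the convergence contract — halving dt changes
the endpoint voltage by well under 0.1 mV — is part of the test suite
rather than a property of the scheme. Any compartment leaving ±200 mV
aborts the run with a diagnostic naming the compartment and time. Spike
detection mirrors the analysis of experimental traces: the somatic voltage
is high-pass filtered above 300 Hz (zero-phase Butterworth) and
suprathreshold excursions are reduced to one event per excursion with a
2 ms refractory period; the threshold on the high-passed trace defaults to
10 mV, which cleanly separates action potentials (tens of mV after
filtering) from synaptic noise (~1 mV).

## Synaptic input model

Twelve afferent populations are modeled as inhomogeneous point processes:
four glutamatergic (CA3, CA2, entorhinal layer III and layer II) and eight
GABAergic (axo-axonic, bistratified, CCK and PV basket, Ivy, neurogliaform,
OLM, Schaffer-associated). Each pathway has a bouton count, a target band
on a signed somatodendritic coordinate (apical positive, basal negative;
the perisomatic band is −50 to +150 um), double-exponential conductance
kinetics normalized so one event of weight w peaks at w, a per-bouton event
rate, and a theta phase tuning: event phases follow a Beta(b1, b2)
distribution mapped onto the full cycle centred on the preferred phase and
wrapped circularly. Boutons are placed with probability proportional to
compartment membrane area within the band.

Phase preferences use the trough = 0°, peak = 180° convention and follow
the juxtacellular literature for identified interneurons: CA3/CA2/ECII
drive near the trough, ECIII at the peak, CCK baskets on the ascending
phase (~155°), axo-axonic cells just after the peak, PV baskets on the
descending phase (~280°), and OLM/bistratified cells near the trough. The
"falling phase" therefore refers to the physically descending quadrant
(270°–360°) of the cycle. Bouton counts are sized for desk-scale
morphologies (tens of compartments); conductances were calibrated once so
that the inhibitory pathways tile the cycle — trough-side dendritic
inhibition, ascending-phase CCK, post-peak axo-axonic, descending-phase PV
— and the excitation/inhibition balance leaves the default cell firing
sparsely. All values are overridable and serializable as JSON.

This tiling is what makes the sublayer manipulations informative: removing
most CCK input (the deep profile) opens the ascending/peak window, so deep
cells fire there (trough–peak index < 0), while removing most PV input
(the superficial profile) opens the descending/trough window (index > 0).
Fully removing PV input shifts the population's preferred phase into the
descending quadrant — the model's testable prediction.

## Genetic-algorithm fit

An individual is a vector of conductance scaling factors; its error is the
integer count of measured features outside their acceptance intervals
(boundaries count as inside), so error 0 means all targets matched. Each
generation, target-hitting values survive with probability 0.40, failing
ones with probability 0.20 (preserving variability), vacancies are refilled
uniformly within bounds, and 40% of individuals are mutated at exactly one
randomly chosen factor. Survival is interpreted per individual; a
per-value variant sits behind a flag, since the original description is
ambiguous on this point. Fitness is binary valid/invalid — no graded
ranking — and the run collects every error-0 individual encountered.
Default runs last 100 generations with a population of 64 (tests and the
recovery experiments use 24 to bound runtime).

Measured intrinsic features are resting potential, input resistance, sag
ratio, step-evoked spike count and spike amplitude, from somatic current
steps whose amplitudes adapt to the cell's input conductance (a ~10 mV
hyperpolarization and ~2.5x that depolarizing drive) so the same protocol
works from few-compartment reductions to full trees. A synaptic protocol
measures the somatic PSP to a synchronous CA3 bouton volley. Acceptance
intervals are configuration values; the recovery experiments build them
around the measured features of a known factor vector (±15% relative,
with absolute widths for resting potential, sag and spike count), so the
planted vector has error 0 by construction. Cross-morphology validation
draws individuals from a reference pool and replaces any that fail on any
morphology until the requested number validate, with an explicit failure
reporting the count achieved if the pool runs dry.

## Analysis stack

Circular statistics operate in degrees on the trough-0 convention. The
trough–peak index is TP = (n_trough − n_peak)/n with the trough window
[270°, 360°) ∪ [0°, 90°); it is +1 for pure trough firing
(superficial-like), −1 for pure peak firing (deep-like), and antisymmetric
under half-cycle shifts. The Rayleigh test uses the standard series
approximation; Watson–Williams and Harrison–Kanji use the classical
F-approximations and flag low-concentration samples where their assumption
fails (a single-level factor degenerates Harrison–Kanji to the one-way
test). The surrogate modulation test permutes the cell's per-cycle spike
counts across cycles and redraws phases uniformly within the assigned
cycles (1000 surrogates by default), yielding a rate-matched,
phase-unlocked null; a conservative counts-only variant that bootstraps the
cell's own marginal phase distribution sits behind a flag.

Theta cycles are detected on the 4–12 Hz band with a zero-phase FIR
filter; troughs are validated by flanking peaks of at least half the trough
magnitude at lags within 0.6 of the spectral period, an in-band implied
cycle frequency, and band dominance (band-limited RMS at least 0.4 of the
raw RMS) so broadband noise produces almost no validated cycles. Cycles
are peak-to-peak windows resampled to 64 samples, embedded by PCA
retaining >90% variance, organized by an in-package self-organizing map
(8x8 grid, Gaussian neighborhood, exponentially decaying learning rate and
radius), whose unit weights are grouped by Ward agglomeration; the cluster
count minimizes the Davies–Bouldin index over 2–6, with a single-class
guard at DB > 1.8 (calibrated so an unstructured Gaussian cloud, DB >= 2,
collapses to one class while planted structure, DB <= 1.3, does not).
Clusters are labeled by the dominant theta-nested spectral component of
their members' averaged Morlet-wavelet power (averaging power rather than
waveforms keeps bursts with variable carrier phase visible): tSC1 (<20 Hz),
tSC2 (30–40 Hz on the falling phase), tSC3 (50–60 Hz at the peak), tSC4
(70–90 Hz at the peak). The wavelet profile is compensated by a factor f
to offset the 1/f background. Because a sub-20 Hz component rides at twice
the theta frequency, its within-cycle position is not resolvable and the
band alone identifies tSC1; components matching no signature stay
unlabeled.

The rank-order test ranks the first spike of each unit within a cycle
(ties broken by unit id), normalizes ranks to [0, 1], and excludes cycles
with fewer than four participants. A cycle is significant when its count
of high-correlation partners (Pearson r > 0.8 over >= 4 shared units)
exceeds the 95th percentile of that count under 500 within-cycle rank
shuffles; a mean-correlation statistic is available behind a flag.

The determinants regression bins preferred phases into twelve 30° classes
and fits a multinomial logit (L-BFGS, standardized features, so the
coefficient map is invariant to affine rescaling of inputs). Feature
significance is the resultant of the positive coefficient mass over
bin-centre phases, calibrated against refits on phase-permuted responses
with null statistics pooled across features — the coefficients of a joint
multinomial fit are mutually dependent, so the analytic Rayleigh null would
be miscalibrated, and pooling gives p-value resolution of about
1/(permutations x features). "Variance explained" per bin is permutation
importance on the per-bin deviance, (D_perm − D_full)/D_perm; a
feature-direction is selected when the share reaches 0.20 in three
consecutive bins with circular adjacency, the direction given by the sign
of the coefficients over the qualifying bins.

## Synthetic data

The LFP generator produces a theta sinusoid (trough at phase 0) plus
per-cycle Gaussian-windowed oscillatory bursts for each cycle's planted
tSC class and 1/f background noise. Burst width is ~1.5 carrier periods,
capped at 2/7 of the theta period so a burst stays confined within its
cycle. Spike-train units have Poisson per-cycle counts and von Mises
phases (kappa = 0 giving uniform). Feature tables carry the canonical
95-column feature list (per-pathway factor, conductances, boutons,
frequency, phase; per-channel factor and mean conductance; branch counts)
with independent noise on loosely realistic scales, and planted effects add
a phase shift per standard deviation of the chosen features before von
Mises jitter. Planted-recovery experiments use shifts of roughly 40–50°
per SD with kappa = 14: large enough to dominate the noise, small enough
that the combined shift stays within half a cycle — beyond that the
wrapped response defeats any linear-in-features classifier, which is a
genuine limitation of the binned-multinomial design, not of the
implementation.

What the generators do not emulate: spike waveforms and sorting artifacts,
sharp-wave ripples, behavioral state changes, electrode drift, cross-
frequency coupling beyond the planted bursts, and correlated noise across
features. Tests passing on these data therefore demonstrate the internal
consistency and calibration of the pipeline, not its robustness to the
full messiness of in vivo recordings.

## Problem sizes

The shipped experiments run at desk scale by choice: synthetic
morphologies of ~40–60 compartments (configurable to the 200–300 range of
full reconstructions), 200 theta cycles per simulated condition against
the 1000-cycle default of the full protocol, GA populations of 24 with
early stopping for recovery runs, 2000 null simulations per calibration
check, and 50 replicates for the regression-recovery experiment. The
qualitative results — the deep/superficial trough–peak dissociation, the
PV-removal phase shift, planted-class and planted-feature recovery — are
stable at these sizes.

## Known limitations

- Gating kinetics and maximal conductances are literature-style defaults
  rather than fits to any single published parameter set; the 18-equation
  structure and every scaling-factor pathway are exact, the rate constants
  are replaceable approximations (the kinetics dictionary accepts external
  values wholesale).
- Sustained somatic drive beyond roughly twice rheobase produces
  depolarization block; spike-count monotonicity holds below that regime.
- The deep/superficial contrast is a property of the calibrated input
  tiling; with a different phase table the same machinery can produce
  different population behavior.
- tSC1 labeling is frequency-only (see above), so a sub-20 Hz burst at a
  non-peak phase would still be called tSC1.
- The multinomial determinants analysis assumes feature effects on phase
  stay within about half a cycle in aggregate.
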