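# Methods

## The measurement problem

The transretinal ERG of an isolated, superfused retina sums field
potentials from three cellular generators: a fast negative
photoreceptor component (the a-wave, with an early hyperpolarisation
"nose" followed by a slower recovery plateau), a positive ON-bipolar
component (the b-wave), and a slow negative Müller glial cell (MGC)
potential carried by inwardly rectifying potassium currents.  Because
the pigment epithelium is removed, there is no c-wave.  Perfusing the
retina sequentially with

1. normal Locke's solution,
2. Locke's + BaCl₂ (100 µM) — blocks the MGC potassium currents,
3. Locke's + BaCl₂ + L-AP4 (14 µM) + aspartic acid (100 µM) — silences
   the ON- and OFF-bipolar pathways,

lets each generator be recovered from intensity-matched flash families:

* MGC = (Locke's) − (BaCl₂),
* ON-bipolar = (BaCl₂) − (BaCl₂ + L-AP4 + AA),
* photoreceptor = the final condition itself.

Both subtractions are oriented so the derived MGC wave is negative-going
and the derived ON-bipolar wave positive-going, matching the polarity of
the underlying generators.  The ON-bipolar subtraction also contains any
OFF-bipolar residual; it is accepted, not modelled, since OFF-bipolar
cells contribute little to the dark-adapted mouse ERG.

## Amplitude measurement

Each sweep triplet is averaged point-wise with equal weights (no outlier
rejection).  Amplitudes are measured from the pre-stimulus baseline (the
mean over the 100 ms immediately before flash onset) to the component's
extremum inside a per-component search window after the flash:

| component      | statistic                | default window (s) |
|----------------|--------------------------|--------------------|
| photoreceptor, NOSE     | minimum         | [0, 0.30]  |
| photoreceptor, RECOVERY | mean (plateau)  | [0.40, 0.60] |
| ON-bipolar     | maximum                  | [0, 1.0]   |
| MGC            | minimum                  | [0, 2.0]   |

The windows follow the kinetic ordering of the components and are
configuration-exposed; they are clamped to the record end so shorter
scaled-down records remain usable, and an entirely empty window is an
error.  Amplitudes are reported as non-negative magnitudes with the
polarity carried separately.  The NOSE (baseline-to-trough) measure is
the default photoreceptor amplitude used downstream; the RECOVERY
plateau is additionally recorded.  Intensity matching across conditions
is strict after rounding to 4 significant figures; a relative-tolerance
mode exists behind a flag.

## Intensity–response model

Amplitude versus flash intensity follows a Hill (Naka–Rushton) law

    R(I) = R_max · Iⁿ / (Iⁿ + Kⁿ)

with R_max the saturated amplitude (µV), K the half-maximal intensity
(photons/µm², reported as log₁₀ K for group statistics), and n the Hill
slope.  The denominator uses Kⁿ so that K keeps intensity units and
R(K) = R_max/2 exactly; simulator and fitter share the identical form.

Fitting is unweighted nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective) in the
parameter vector (R_max, log₁₀ K, n), which keeps the problem well
scaled across the four-decade intensity range.  Initialisation is
data-driven: R_max₀ = max amplitude, K₀ = log-linear interpolation of
the intensity at half of R_max₀, n₀ = 1.  Bounds — R_max ∈ (0, 10 × max
amplitude], K ∈ [min I/10, max I × 10], n ∈ (0, 10] — prevent divergence
on flat data.  Tolerances are set to 1e-15 so noise-free model-class
data is recovered to machine precision.  Degenerate inputs are flagged
rather than fitted: an all-zero amplitude series returns a null fit with
NaN parameters, and a series whose amplitude spread is below 5% of its
maximum (fully saturated or flat) is marked non-identifiable for K and
excluded from K comparisons.  The slope n is fitted freely by default
(it can be fixed by configuration); at least four distinct intensities
are required.  A pooled fit over all retinas of a group is provided as a
display statistic only.

## Group statistics

Genotype comparisons use Welch's unequal-variance t-test with
Welch–Satterthwaite degrees of freedom and two-sided p-values, computed
from the closed-form statistic.  Stars follow * (0.01 < p < 0.05),
** (0.001 < p < 0.01), *** (p < 0.001); exact boundary values fall into
the less-significant bin.  If both sample variances are zero, p = 1 when
the means are equal, 0 otherwise.  Groups with fewer than two retinas
are skipped with a logged warning.

No multiplicity correction is applied by default, reproducing the
convention of raw per-intensity stars; Holm step-down adjustment is
available by flag.  The package's own acceptance scenarios use the Holm
flag when asserting a *joint* null claim ("no K difference anywhere",
"nothing differs before eye opening"): with 9–18 simultaneous tests a
raw-α joint assertion would be falsely rejected 37–60% of the time even
when the null is exactly true, so familywise control is the appropriate
test of the joint pattern.  Positive claims (reduced R_max) are asserted
on raw per-comparison p-values, which is the stricter direction.

Proportionality analysis divides each retina's fitted R_max by the
wildtype mean R_max of the same component and summarises, per genotype,
the signed perpendicular deviation (y − x)/√2 of the paired points from
the identity diagonal, with a seeded 2,000-resample bootstrap percentile
interval.  Uniform scaling of both components gives deviation exactly 0;
a disproportionate loss of the y-component is negative.  Developmental
trajectories report mean ± SEM (n ≥ 2; NaN otherwise) of R_max per
genotype × age class × component.

## Synthetic data generator

No public recordings exist for this preparation, so the generator is a
first-class, tested module.  It emulates:

* **Acquisition**: triplicate sweeps, 10 kHz digitisation, 2 ms flashes,
  nine log-spaced intensities spanning 5–50,000 photons/µm², 0.2 s
  pre-stimulus baseline in a 2.2 s record.  An 8-pole Bessel low-pass at
  300 Hz is available as an explicit operation (`acquisition_filter`,
  applied causally with steady-state initial conditions so DC gain is
  exactly 1); it is not applied inside the generator by default so that
  noise-free additivity and ground-truth amplitude equality hold
  sample-wise.
* **Component kinetics**: sums of alpha kernels (t/τ)·e^(1−t/τ).  The
  photoreceptor is a fast nose trough (τ = 30 ms, 30% of trough depth)
  relaxing onto a sustained plateau (rise 20 ms, decay 1.5 s); the
  ON-bipolar peak is an alpha function (τ = 120 ms) delayed 15 ms
  synaptically; the MGC trough is a slow alpha (τ = 500 ms).  Constants
  are free configuration; the defaults reproduce the canonical ordering
  photoreceptor trough < ON-bipolar peak < MGC trough.  Shapes are
  normalised on the simulation grid so the sampled extremum equals the
  Hill amplitude exactly, making noise-free parameter recovery exact by
  construction.
* **Condition logic**: Locke's = P + B + M, BaCl₂ = P + B, cocktail = P
  (a configurable residual MGC fraction exists, default 0 — complete
  barium blockade is assumed).
* **Noise**: additive i.i.d. Gaussian per sample (default 2 µV SD) plus
  optional linear drift.  No 1/f component is modelled.
* **Biological scatter**: per-retina lognormal factors on each
  component's R_max (σ = 0.15) and K (σ = 0.10).  Without retina-level
  variability every group comparison would be trivially significant at
  machine-level p; the chosen CVs give the realistic regime in which
  low-intensity comparisons are not significant while mid-to-high
  intensity comparisons mostly are.
* **Disease presets** (multiplicative effects on wildtype parameters):
  adult — R_max × 0.5 for all components in all three mutants, K
  unchanged; eye opening — photoreceptor R_max × 0.6 in all mutants,
  ON-bipolar × 0.65 in R141C only, MGC × 1.5 in C59S only;
  pre-eye-opening — no effect.  Wildtype base parameters per age class
  encode the developmental pattern (photoreceptor R_max 120 → 280 → 300
  µV across pre-eye-opening → eye-opening → adult; ON-bipolar 110 → 260
  → 420 µV; MGC 60 → 150 → 260 µV), with half-maximal intensities in the
  70–1,500 photons/µm² range.  These absolute values are package
  defaults chosen to be representative of the preparation; no published
  table fixes them.

What passing tests on this generator do **not** show about real data:
real recordings have correlated (filtered, 1/f) noise, perfusion-order
and rundown effects, possibly incomplete barium blockade, and
inter-animal kinetic differences, none of which are modelled.  The
pipeline's correctness claims are about the analysis operations; the
presets establish that it detects the qualitative disease pattern under
realistic effect sizes, not that the simulated retina is biophysically
faithful (no Lamb–Pugh phototransduction cascade, no schisis structure).

## Determinism and problem sizes

All randomness flows from one top-level seed through
`numpy.random.SeedSequence` spawning, one child per retina in
(genotype, retina-index) order; identical configuration and seed give
byte-identical output tables (floats are serialised with %.17g and read
back with round-trip parsing).

Simulation studies use a scaled-down acquisition preset (500 Hz
sampling, 1.1 s records, 0.1 s pre-stimulus) that keeps every
measurement window usable at a fraction of the full 10 kHz cost; the
full-rate configuration remains the default for single-family work.
Benchmark sizes: Hill recovery — 200 replicates at 5 µV noise, 9
intensities, 3 sweeps, checked against an exhaustive grid search with K
and n gridded at 1% multiplicative resolution and R_max profiled in
closed form; test calibration — 500 replicates of an 8-vs-8 null cohort
(13,500 per-intensity Welch tests); disease-pattern scenarios — 8
retinas per genotype per age class.

## Known limitations

* The Welch test's finite-sample level on the skewed low-intensity
  amplitude distribution is slightly conservative for very small groups
  (n ≈ 4); at the standard n = 8 it is within sampling error of nominal.
* Oscillatory potentials, cone/rod pathway separation, c-wave analysis
  and kinetic (waveform-shape) inference are out of scope.
* Hierarchical/mixed-effects modelling across development is not
  implemented; the design is treated as cross-sectional.
* Axon ABF ingestion is an extension point; the supported interchange is
  the CSV + JSON sidecar format (optionally HDF5-free by design).
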