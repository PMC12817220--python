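# ergdissect

Pharmacological component dissection and intensity–response analysis of
*ex vivo* electroretinograms (ERGs).

The transretinal ERG of an isolated, superfused retina sums field
potentials from photoreceptors (fast negative a-wave), ON-bipolar cells
(positive b-wave) and Müller glial cells (slow negative potential).
Perfusing sequentially with normal Locke's, Locke's + BaCl₂ (blocks the
glial potassium currents) and Locke's + BaCl₂ + L-AP4 + aspartic acid
(silences the bipolar pathways) lets each generator be isolated by
subtracting intensity-matched flash responses.  `ergdissect` implements
that workflow end to end for flash-family recordings — of the kind used
to characterise *Rs1*-mutant mouse models of X-linked retinoschisis
across development — together with a tested synthetic-ERG generator so
every stage can be validated against exact ground truth:

* **simulate** — additive three-component flash families with known Hill
  parameters, perfusion-condition logic, triplicate sweeps, noise and
  retina-to-retina variability;
* **isolate** — triplicate averaging, strict intensity-matched
  condition subtraction, baseline-to-extremum amplitude measurement
  (including the a-wave nose/recovery phases);
* **fit** — per-retina Hill (Naka–Rushton) fits
  R(I) = R_max·Iⁿ/(Iⁿ + Kⁿ) giving the saturated amplitude R_max, the
  half-maximal intensity K (reported as log₁₀ K) and slope n;
* **compare** — Welch unequal-variance tests of each mutant genotype
  against wildtype, per intensity and per fitted parameter, with the
  */**/*** star convention, plus wildtype-normalised R_max
  proportionality analysis against the identity diagonal;
* **trajectory** — mean ± SEM of R_max per genotype × age class ×
  component across pre-eye-opening, eye-opening and adult stages.

See `docs/methods.md` for the model, the measurement conventions and the
generator's assumptions.

## Worked example

```python
from ergdissect import Genotype, derive_components, simulate_family
from ergdissect.core import AgeClass
from ergdissect.presets import FAST_CONFIG, base_models, genotype_effect

result = simulate_family(
    FAST_CONFIG, base_models(AgeClass.ADULT),
    genotype_effect(Genotype.WT, AgeClass.ADULT),
    retina_id="demo_wt", age_days=35, rng=42,
)
components = derive_components(result.family)
print(components.amplitude_table().head())
```

Running `python examples/01_simulate_and_isolate.py` prints the measured
amplitude of each derived component at each flash intensity:

```
   intensity  photoreceptor  ON-bipolar      MGC   (uV)
           5            4.7        17.2      9.0
       15.81            5.9        57.4     18.0
          50           11.4       173.1     39.8
       158.1           34.4       341.1     85.3
         500           95.8       434.4    138.0
        1581          190.0       462.9    173.2
        5000          266.8       470.3    189.7
       15810          299.4       471.5    194.7
       50000          310.6       471.7    196.6
```

Each column saturates with intensity following the Hill law the retina
was generated with (this retina's true saturated amplitudes were 314,
470 and 194 µV); fitting these series with
`examples/02_fit_intensity_response.py` recovers R_max, log₁₀ K and n to
within a few percent under 2 µV recording noise.  The remaining examples
run a full genotype comparison (halved R_max with unchanged K in the
adult disease presets, proportional photoreceptor/ON-bipolar loss on the
diagonal) and the developmental R_max trajectory.

A thin CLI wraps the same stages for shell use:

```sh
ergdissect simulate --out families/ --seed 1 --age-classes ADULT --retinas 3
ergdissect isolate --input families/ --out amplitudes.csv
ergdissect fit --amplitudes amplitudes.csv --out fits.csv
ergdissect compare --fits fits.csv --amplitudes amplitudes.csv --out results/
ergdissect run --out results/          # full pipeline from a TOML config
```

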