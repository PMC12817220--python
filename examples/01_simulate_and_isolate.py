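"""Simulate one retina's flash family and isolate its cellular components.

A flash family is recorded three times under sequential perfusion:
normal Locke's (all components), + BaCl2 (Müller glial potassium
currents blocked), + L-AP4 + aspartic acid (bipolar pathways silenced).
Intensity-matched subtraction then recovers the Müller glial (MGC) and
ON-bipolar waves; the final condition is the photoreceptor response.
"""

from ergdissect import ComponentKind, Genotype, derive_components, simulate_family
from ergdissect.core import AgeClass
from ergdissect.presets import FAST_CONFIG, base_models, genotype_effect

result = simulate_family(
    FAST_CONFIG,
    base_models(AgeClass.ADULT),
    genotype_effect(Genotype.WT, AgeClass.ADULT),
    retina_id="demo_wt",
    age_days=35,
    rng=42,
)
components = derive_components(result.family)

print(f"retina {components.retina_id}: {len(result.family)} sweeps, "
      f"{len(result.family.intensities)} flash intensities\n")
print(f"{'intensity':>12} {'photoreceptor':>14} {'ON-bipolar':>11} {'MGC':>8}   (uV)")
table = components.amplitude_table()
nose = table[(table["component"] != "PHOTORECEPTOR") | (table["phase"] == "NOSE")]
wide = nose.pivot_table(index="intensity", columns="component", values="amplitude")
for intensity, row in wide.iterrows():
    print(f"{intensity:>12g} {row['PHOTORECEPTOR']:>14.1f} "
          f"{row['ON_BIPOLAR']:>11.1f} {row['MGC']:>8.1f}")
truth = result.truth
print("\nGround-truth saturated amplitudes this retina was generated with:")
for kind in ComponentKind:
    m = truth.models[kind]
    print(f"  {kind.value:<14} R_max = {m.r_max:6.1f} uV, K = {m.k:7.1f} photons/um^2")
print("\nEach measured amplitude is baseline-to-extremum of the derived wave;")
print("they saturate with intensity following the Hill law the generator used.")
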