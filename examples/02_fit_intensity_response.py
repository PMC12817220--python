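"""Fit the Hill intensity-response function to measured amplitudes.

Component amplitude R grows with flash intensity I as
R = R_max * I^n / (I^n + K^n): R_max is the saturated response, K the
half-maximal ("sensitivity") intensity, n the slope.  Here we measure a
noisy simulated retina and recover the generating parameters.
"""

import numpy as np

from ergdissect import (
    ComponentKind,
    Genotype,
    IntensityResponse,
    derive_components,
    fit_hill,
    simulate_family,
)
from ergdissect.core import AgeClass, Phase
from ergdissect.presets import FAST_CONFIG, base_models, genotype_effect

result = simulate_family(
    FAST_CONFIG,
    base_models(AgeClass.ADULT),
    genotype_effect(Genotype.WT, AgeClass.ADULT),
    retina_id="fit_demo",
    age_days=35,
    rng=3,
)
components = derive_components(result.family)
intensities = np.array(FAST_CONFIG.intensities)

print(f"{'component':<14} {'R_max fit':>10} {'true':>7}  {'log10 K fit':>11} "
      f"{'true':>6}  {'n fit':>6} {'true':>5}")
for kind in ComponentKind:
    amps = {
        rec.intensity: rec.amplitude for rec in components.amplitudes
        if rec.component is kind and rec.phase is not Phase.RECOVERY
    }
    fit = fit_hill(IntensityResponse(
        "fit_demo", kind, intensities,
        np.array([amps[i] for i in sorted(amps)]),
    ))
    truth = result.truth.models[kind]
    print(f"{kind.value:<14} {fit.r_max:>10.1f} {truth.r_max:>7.1f}  "
          f"{fit.log10_k:>11.2f} {np.log10(truth.k):>6.2f}  "
          f"{fit.n:>6.2f} {truth.n:>5.2f}")
print("\nWith 2 uV recording noise on hundreds-of-uV responses, the fitted")
print("parameters land within a few percent of this retina's true values.")
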