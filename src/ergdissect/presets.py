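"""Shipped study presets: base component models, genotype effects, cohorts.

The base Hill parameters per age class encode the developmental pattern
of the wildtype ex vivo ERG: the photoreceptor R_max rises from before
eye opening to eye opening and then stabilises, while the ON-bipolar and
MGC amplitudes keep growing into adulthood.  Absolute values are
representative of transretinal recordings (hundreds of microvolts at
saturation); no published table fixes them, so they are package defaults
documented in docs/methods.md.

Genotype-effect presets encode the qualitative disease pattern of the
three Rs1 mutant models relative to wildtype:

* adult: R_max of all three components halved in every mutant, K unchanged;
* eye opening: photoreceptor R_max reduced in all mutants, ON-bipolar
  R_max reduced only in R141C, MGC R_max increased only in C59S;
* pre eye opening: no effect (all factors 1).
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping, Sequence

import numpy as np

from .core import AgeClass, ComponentKind, Genotype
from .synthetic import ComponentModel, GenotypeEffect, SimConfig, SimResult, simulate_family

__all__ = [
    "BASE_MODELS",
    "AGE_DAYS",
    "FAST_CONFIG",
    "NOISE_FREE_CONFIG",
    "base_models",
    "genotype_effect",
    "null_effect",
    "simulate_cohort",
]

_K = ComponentKind

#: Ground-truth Hill parameters (r_max uV, k photons/um^2, n) per age class.
BASE_MODELS: dict[AgeClass, dict[ComponentKind, ComponentModel]] = {
    AgeClass.PRE_EYE_OPENING: {
        _K.PHOTORECEPTOR: ComponentModel(_K.PHOTORECEPTOR, r_max=120.0, k=1500.0, n=1.0),
        _K.ON_BIPOLAR: ComponentModel(_K.ON_BIPOLAR, r_max=110.0, k=200.0, n=1.1),
        _K.MGC: ComponentModel(_K.MGC, r_max=60.0, k=350.0, n=1.0),
    },
    AgeClass.EYE_OPENING: {
        _K.PHOTORECEPTOR: ComponentModel(_K.PHOTORECEPTOR, r_max=280.0, k=1200.0, n=1.1),
        _K.ON_BIPOLAR: ComponentModel(_K.ON_BIPOLAR, r_max=260.0, k=120.0, n=1.2),
        _K.MGC: ComponentModel(_K.MGC, r_max=150.0, k=300.0, n=1.0),
    },
    AgeClass.ADULT: {
        _K.PHOTORECEPTOR: ComponentModel(_K.PHOTORECEPTOR, r_max=300.0, k=1200.0, n=1.1),
        _K.ON_BIPOLAR: ComponentModel(_K.ON_BIPOLAR, r_max=420.0, k=70.0, n=1.3),
        _K.MGC: ComponentModel(_K.MGC, r_max=260.0, k=250.0, n=1.0),
    },
}

#: Nominal postnatal age (days) attached to simulated retinas.
AGE_DAYS = {
    AgeClass.PRE_EYE_OPENING: 11,
    AgeClass.EYE_OPENING: 13,
    AgeClass.ADULT: 35,
}

_EFFECT_TABLE: dict[AgeClass, dict[Genotype, dict[ComponentKind, tuple[float, float]]]] = {
    AgeClass.ADULT: {
        g: {kind: (0.5, 1.0) for kind in ComponentKind}
        for g in (Genotype.KO, Genotype.R141C, Genotype.C59S)
    },
    AgeClass.EYE_OPENING: {
        Genotype.KO: {_K.PHOTORECEPTOR: (0.6, 1.0)},
        Genotype.R141C: {_K.PHOTORECEPTOR: (0.6, 1.0), _K.ON_BIPOLAR: (0.65, 1.0)},
        Genotype.C59S: {_K.PHOTORECEPTOR: (0.6, 1.0), _K.MGC: (1.5, 1.0)},
    },
    AgeClass.PRE_EYE_OPENING: {
        Genotype.KO: {}, Genotype.R141C: {}, Genotype.C59S: {},
    },
}

#: Scaled-down acquisition settings for simulation studies: 500 Hz sampling
#: over a 1.1 s record (0.1 s pre-stimulus) keeps every default measurement
#: window usable at a fraction of the full 10 kHz / 2.2 s cost.
FAST_CONFIG = SimConfig(sample_rate=500.0, pre_flash=0.1, record_duration=1.1)

#: Fully deterministic generator settings (no noise, no drift, no
#: retina-to-retina variability) for exact oracle checks.
NOISE_FREE_CONFIG = replace(
    FAST_CONFIG, noise_sd=0.0, drift_sd=0.0, retina_cv_r_max=0.0, retina_cv_k=0.0
)


def base_models(age_class: AgeClass) -> dict[ComponentKind, ComponentModel]:
    return dict(BASE_MODELS[age_class])


def genotype_effect(genotype: Genotype, age_class: AgeClass) -> GenotypeEffect:
    """Shipped qualitative effect preset for one genotype x age class."""
    if genotype is Genotype.WT:
        return GenotypeEffect.null(genotype, age_class)
    return GenotypeEffect(genotype, age_class, _EFFECT_TABLE[age_class][genotype])


def null_effect(genotype: Genotype, age_class: AgeClass) -> GenotypeEffect:
    """Identity effect for any genotype (null-hypothesis simulations)."""
    return GenotypeEffect(genotype, age_class, {}) if genotype is Genotype.WT \
        else GenotypeEffect(genotype, age_class, {k: (1.0, 1.0) for k in ComponentKind})


def simulate_cohort(
    age_class: AgeClass,
    *,
    n_retinas: int = 8,
    seed: int = 0,
    config: SimConfig = FAST_CONFIG,
    genotypes: Sequence[Genotype] = tuple(Genotype),
    effects: Mapping[Genotype, GenotypeEffect] | None = None,
) -> list[SimResult]:
    """Simulate ``n_retinas`` per genotype at one age class.

    Randomness is fanned out deterministically: one child seed sequence
    per retina, spawned in (genotype order, retina index) order from the
    top-level seed.
    """
    if effects is None:
        effects = {g: genotype_effect(g, age_class) for g in genotypes}
    root = np.random.SeedSequence(seed)
    children = iter(root.spawn(len(genotypes) * n_retinas))
    results: list[SimResult] = []
    for genotype in genotypes:
        for idx in range(n_retinas):
            child = next(children)
            retina_id = f"{genotype.value}_{age_class.value}_{idx:02d}"
            results.append(
                simulate_family(
                    config,
                    BASE_MODELS[age_class],
                    effects[genotype],
                    retina_id=retina_id,
                    age_days=AGE_DAYS[age_class],
                    rng=np.random.default_rng(child),
                )
            )
    return results
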