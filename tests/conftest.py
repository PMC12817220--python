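import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ergdissect.core import (
    AgeClass,
    Genotype,
    PerfusionCondition,
    Trace,
)
from ergdissect.presets import (
    FAST_CONFIG,
    NOISE_FREE_CONFIG,
    base_models,
    genotype_effect,
    simulate_cohort,
)
from ergdissect.synthetic import simulate_family

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_trace(
    samples,
    *,
    sample_rate=1000.0,
    t0_flash=0.1,
    intensity=50.0,
    condition=PerfusionCondition.LOCKES,
    retina_id="r0",
    sweep_index=0,
):
    """Trace factory with convenient defaults for unit tests."""
    return Trace(
        samples=np.asarray(samples, dtype=float),
        sample_rate=sample_rate,
        t0_flash=t0_flash,
        flash_duration=0.002,
        intensity=intensity,
        condition=condition,
        retina_id=retina_id,
        sweep_index=sweep_index,
    )


@pytest.fixture(scope="session")
def noise_free_wt():
    """One deterministic wildtype adult retina (no noise, no retina scatter)."""
    return simulate_family(
        NOISE_FREE_CONFIG,
        base_models(AgeClass.ADULT),
        genotype_effect(Genotype.WT, AgeClass.ADULT),
        retina_id="wt_nf",
        age_days=35,
        rng=11,
    )


@pytest.fixture(scope="session")
def noise_free_adult_cohort():
    """Noise-free adult cohort, 3 retinas per genotype, all four genotypes."""
    return simulate_cohort(
        AgeClass.ADULT, n_retinas=3, seed=5, config=NOISE_FREE_CONFIG
    )


@pytest.fixture(scope="session")
def noisy_adult_cohort():
    """Default-noise adult cohort, 8 retinas per genotype (disease preset)."""
    return simulate_cohort(AgeClass.ADULT, n_retinas=8, seed=21, config=FAST_CONFIG)
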