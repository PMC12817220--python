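"""Synthetic ex vivo ERG generator with ground-truth components.

Builds flash families whose three additive cellular components
(photoreceptor, ON-bipolar, Müller glial cell) follow known kinetics and
a Hill-type amplitude law R(I) = R_max * I^n / (I^n + K^n), and whose
perfusion conditions implement the pharmacological blockade logic:

* normal Locke's          -> photoreceptor + ON-bipolar + MGC
* Locke's + BaCl2         -> photoreceptor + ON-bipolar (MGC blocked)
* + L-AP4 + aspartic acid -> photoreceptor only

so that downstream subtraction can be checked against exact ground
truth.  With ``noise_sd = 0`` the additivity is exact at every sample.

Component shapes are built from alpha-type kernels (t/tau)*exp(1 - t/tau)
and normalised on the simulation grid so the sampled extremum equals the
Hill amplitude exactly.  The photoreceptor waveform is a fast trough
("nose") relaxing onto a slower sustained plateau; the ON-bipolar peak is
synaptically delayed; the MGC trough is slowest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import signal

from .core import (
    AgeClass,
    ComponentKind,
    ErgError,
    FlashFamily,
    Genotype,
    PerfusionCondition,
    StructuralError,
    Trace,
    canonical_intensity,
    make_flash_family,
)

__all__ = [
    "DEFAULT_KINETICS",
    "ComponentModel",
    "GenotypeEffect",
    "SimConfig",
    "GroundTruth",
    "SimResult",
    "hill_amplitude",
    "component_shape",
    "component_waveform",
    "simulate_family",
    "acquisition_filter",
    "default_intensities",
]

#: Default kinetic constants (seconds, dimensionless fractions).  Chosen so
#: the default waveforms reproduce the canonical component ordering: fast
#: photoreceptor nose, delayed positive ON-bipolar peak, slow MGC trough.
DEFAULT_KINETICS: dict[ComponentKind, dict[str, float]] = {
    ComponentKind.PHOTORECEPTOR: {
        "tau_nose": 0.030,       # alpha-function time-to-trough of the nose
        "nose_fraction": 0.3,    # fraction of trough depth carried by the nose
        "tau_on": 0.020,         # rise of the sustained plateau
        "tau_off": 1.5,          # slow decay of the sustained plateau
    },
    ComponentKind.ON_BIPOLAR: {
        "delay": 0.015,          # synaptic delay after flash
        "tau": 0.120,            # alpha-function time-to-peak
    },
    ComponentKind.MGC: {
        "tau": 0.500,            # alpha-function time-to-trough
    },
}


def hill_amplitude(
    intensity: float | np.ndarray, r_max: float, k: float, n: float
) -> float | np.ndarray:
    """Saturating amplitude law R(I) = R_max * I^n / (I^n + K^n).

    K is the intensity eliciting a half-maximal response; n the Hill
    slope.  R(0) = 0 and R -> R_max as I -> infinity.
    """
    i = np.asarray(intensity, dtype=float)
    if np.any(i < 0):
        raise ErgError("intensity must be non-negative")
    with np.errstate(divide="ignore"):
        # 1 / (1 + (K/I)^n) is stable across the full intensity range
        ratio = np.where(i > 0, (k / np.where(i > 0, i, 1.0)) ** n, np.inf)
    out = r_max / (1.0 + ratio)
    return float(out) if np.isscalar(intensity) else out


def _alpha(t: np.ndarray, tau: float) -> np.ndarray:
    """Alpha kernel (t/tau)*exp(1 - t/tau); unit peak at t = tau, zero for t < 0."""
    x = np.clip(t / tau, 0.0, None)
    return x * np.exp(1.0 - x)


@dataclass(frozen=True)
class ComponentModel:
    """Ground-truth description of one cellular component.

    ``r_max`` (uV), ``k`` (photons/um^2) and ``n`` set the Hill amplitude
    law; ``kinetics`` holds the shape constants (see
    :data:`DEFAULT_KINETICS`).
    """

    kind: ComponentKind
    r_max: float
    k: float
    n: float
    kinetics: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.r_max < 0:
            raise StructuralError("r_max must be non-negative")
        if not self.k > 0:
            raise StructuralError("k must be positive")
        if not self.n > 0:
            raise StructuralError("Hill slope n must be positive")
        kin = dict(DEFAULT_KINETICS[self.kind])
        if self.kinetics is not None:
            unknown = set(self.kinetics) - set(kin)
            if unknown:
                raise StructuralError(f"unknown kinetic parameters: {sorted(unknown)}")
            kin.update(self.kinetics)
        for key, val in kin.items():
            if key == "delay":
                if val < 0:
                    raise StructuralError("synaptic delay must be non-negative")
            elif key == "nose_fraction":
                if not 0 <= val <= 1:
                    raise StructuralError("nose_fraction must lie in [0, 1]")
            elif not val > 0:
                raise StructuralError(f"kinetic constant {key} must be positive")
        object.__setattr__(self, "kinetics", kin)

    def scaled(self, r_max_factor: float = 1.0, k_factor: float = 1.0) -> "ComponentModel":
        return replace(self, r_max=self.r_max * r_max_factor, k=self.k * k_factor)


def component_shape(
    kind: ComponentKind, kinetics: Mapping[str, float], t: np.ndarray
) -> np.ndarray:
    """Unit-extremum waveform shape on the grid ``t`` (s from flash onset).

    The returned array carries the component's polarity and has sampled
    extremum magnitude exactly 1 (so scaling by the Hill amplitude yields
    a waveform whose measured peak equals the amplitude law exactly).
    """
    t = np.asarray(t, dtype=float)
    if kind is ComponentKind.PHOTORECEPTOR:
        nose = _alpha(t, kinetics["tau_nose"])
        plateau = (1.0 - np.exp(-np.clip(t, 0.0, None) / kinetics["tau_on"])) * np.exp(
            -np.clip(t, 0.0, None) / kinetics["tau_off"]
        )
        plateau[t < 0] = 0.0
        pmax = plateau.max()
        if pmax > 0:
            plateau = plateau / pmax
        f = kinetics["nose_fraction"]
        raw = -(f * nose + (1.0 - f) * plateau)
    elif kind is ComponentKind.ON_BIPOLAR:
        raw = _alpha(t - kinetics["delay"], kinetics["tau"])
    elif kind is ComponentKind.MGC:
        raw = -_alpha(t, kinetics["tau"])
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(kind)
    peak = np.max(np.abs(raw))
    return raw / peak if peak > 0 else raw


def component_waveform(
    model: ComponentModel, intensity: float, t: np.ndarray
) -> np.ndarray:
    """Noise-free component voltage (uV) on grid ``t`` (s from flash onset)."""
    if intensity < 0:
        raise ErgError("intensity must be non-negative")
    amp = hill_amplitude(intensity, model.r_max, model.k, model.n)
    return amp * component_shape(model.kind, model.kinetics, t)


@dataclass(frozen=True)
class GenotypeEffect:
    """Multiplicative per-component scaling of R_max and K for one genotype.

    ``factors`` maps each component to ``(r_max_factor, k_factor)``.
    Wildtype effects are the identity by definition.
    """

    genotype: Genotype
    age_class: AgeClass
    factors: Mapping[ComponentKind, tuple[float, float]]

    def __post_init__(self) -> None:
        fac = {kind: tuple(map(float, self.factors.get(kind, (1.0, 1.0))))
               for kind in ComponentKind}
        for kind, (fr, fk) in fac.items():
            if not (fr > 0 and fk > 0):
                raise StructuralError(f"scaling factors for {kind.name} must be positive")
        if self.genotype is Genotype.WT and any(
            f != (1.0, 1.0) for f in fac.values()
        ):
            raise StructuralError("wildtype scaling factors must all be 1")
        object.__setattr__(self, "factors", fac)

    @classmethod
    def null(cls, genotype: Genotype, age_class: AgeClass) -> "GenotypeEffect":
        return cls(genotype, age_class, {})


def default_intensities(n: int = 9) -> tuple[float, ...]:
    """Log-spaced flash series over the 5-50,000 photons/um^2 protocol range."""
    return tuple(canonical_intensity(i) for i in np.geomspace(5.0, 50_000.0, n))


@dataclass(frozen=True)
class SimConfig:
    """Acquisition and noise settings for the generator.

    Defaults mirror the recording protocol: triplicate sweeps, 10 kHz
    digitisation, 2 ms flashes, nine log-spaced intensities spanning
    5-50,000 photons/um^2, and 2 uV additive Gaussian noise per sample.
    ``retina_cv_r_max`` / ``retina_cv_k`` add lognormal retina-to-retina
    variability in the component parameters (biological scatter).
    """

    intensities: tuple[float, ...] = field(default_factory=default_intensities)
    sweeps: int = 3
    sample_rate: float = 10_000.0
    pre_flash: float = 0.2
    record_duration: float = 2.2
    flash_duration: float = 0.002
    noise_sd: float = 2.0
    drift_sd: float = 0.0
    retina_cv_r_max: float = 0.15
    retina_cv_k: float = 0.10
    mgc_residual_fraction: float = 0.0
    intensity_range: tuple[float, float] = (5.0, 50_000.0)

    def __post_init__(self) -> None:
        if not self.intensities:
            raise StructuralError("intensity series is empty")
        object.__setattr__(
            self, "intensities", tuple(canonical_intensity(i) for i in self.intensities)
        )
        lo, hi = self.intensity_range
        if any(not lo <= i <= hi for i in self.intensities):
            raise StructuralError("intensities outside the configured range")
        if self.sweeps < 1:
            raise StructuralError("sweeps must be >= 1")
        for name in ("sample_rate", "pre_flash", "record_duration", "flash_duration"):
            if not getattr(self, name) > 0:
                raise StructuralError(f"{name} must be positive")
        if self.record_duration <= self.pre_flash:
            raise StructuralError("record_duration must exceed pre_flash")
        for name in ("noise_sd", "drift_sd", "retina_cv_r_max", "retina_cv_k",
                     "mgc_residual_fraction"):
            if getattr(self, name) < 0:
                raise StructuralError(f"{name} must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.record_duration * self.sample_rate))

    def time_from_flash(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate - self.pre_flash


@dataclass
class GroundTruth:
    """Generating truth stored alongside a simulated family."""

    models: dict[ComponentKind, ComponentModel]
    component_traces: dict[tuple[ComponentKind, float], np.ndarray]
    amplitudes: dict[tuple[ComponentKind, float], float]
    seed_entropy: str

    def amplitude(self, kind: ComponentKind, intensity: float) -> float:
        return self.amplitudes[(kind, canonical_intensity(intensity))]


@dataclass
class SimResult:
    family: FlashFamily
    truth: GroundTruth


def _effective_models(
    base: Mapping[ComponentKind, ComponentModel],
    effect: GenotypeEffect,
    config: SimConfig,
    rng: np.random.Generator,
) -> dict[ComponentKind, ComponentModel]:
    """Genotype scaling plus lognormal retina-level variability."""
    out: dict[ComponentKind, ComponentModel] = {}
    for kind in ComponentKind:
        fr, fk = effect.factors[kind]
        # lognormal with unit median; CV parameters interpreted as sigma of log
        vr = math.exp(rng.normal(0.0, config.retina_cv_r_max)) if config.retina_cv_r_max else 1.0
        vk = math.exp(rng.normal(0.0, config.retina_cv_k)) if config.retina_cv_k else 1.0
        out[kind] = base[kind].scaled(fr * vr, fk * vk)
    return out


def simulate_family(
    config: SimConfig,
    base_models: Mapping[ComponentKind, ComponentModel],
    effect: GenotypeEffect,
    *,
    retina_id: str,
    age_days: int,
    rng: np.random.Generator | int,
) -> SimResult:
    """Simulate one retina's flash family under all three perfusion conditions.

    Returns the noisy :class:`FlashFamily` together with the exact
    per-retina :class:`GroundTruth` (scaled component models, noise-free
    component traces, and Hill amplitudes).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    models = _effective_models(base_models, effect, config, rng)
    t = config.time_from_flash()

    truth_traces: dict[tuple[ComponentKind, float], np.ndarray] = {}
    truth_amps: dict[tuple[ComponentKind, float], float] = {}
    condition_base: dict[tuple[PerfusionCondition, float], np.ndarray] = {}
    for intensity in config.intensities:
        comps = {
            kind: component_waveform(models[kind], intensity, t) for kind in ComponentKind
        }
        for kind in ComponentKind:
            truth_traces[(kind, intensity)] = comps[kind]
            truth_amps[(kind, intensity)] = hill_amplitude(
                intensity, models[kind].r_max, models[kind].k, models[kind].n
            )
        p = comps[ComponentKind.PHOTORECEPTOR]
        b = comps[ComponentKind.ON_BIPOLAR]
        m = comps[ComponentKind.MGC]
        residual = config.mgc_residual_fraction * m
        condition_base[(PerfusionCondition.LOCKES, intensity)] = p + b + m
        condition_base[(PerfusionCondition.BACL2, intensity)] = p + b + residual
        condition_base[(PerfusionCondition.BACL2_LAP4_AA, intensity)] = p + residual

    traces: list[Trace] = []
    times = np.arange(config.n_samples) / config.sample_rate
    for condition in PerfusionCondition:
        for intensity in config.intensities:
            base = condition_base[(condition, intensity)]
            for sweep in range(config.sweeps):
                samples = base
                if config.noise_sd > 0:
                    samples = samples + rng.normal(0.0, config.noise_sd, config.n_samples)
                if config.drift_sd > 0:
                    samples = samples + rng.normal(0.0, config.drift_sd) * times
                if samples is base:
                    samples = base.copy()
                traces.append(
                    Trace(
                        samples=samples,
                        sample_rate=config.sample_rate,
                        t0_flash=config.pre_flash,
                        flash_duration=config.flash_duration,
                        intensity=intensity,
                        condition=condition,
                        retina_id=retina_id,
                        sweep_index=sweep,
                    )
                )

    family = make_flash_family(
        traces,
        genotype=effect.genotype,
        age_days=age_days,
        age_class=effect.age_class,
        retina_id=retina_id,
        intensity_range=config.intensity_range,
    )
    truth = GroundTruth(
        models=models,
        component_traces=truth_traces,
        amplitudes=truth_amps,
        seed_entropy=str(rng.bit_generator.seed_seq),
    )
    return SimResult(family=family, truth=truth)


def acquisition_filter(trace: Trace, cutoff_hz: float = 300.0, poles: int = 8) -> Trace:
    """Emulate the acquisition chain's low-pass Bessel filter.

    A ``poles``-pole Bessel low-pass at ``cutoff_hz`` applied causally
    with steady-state initial conditions (DC gain 1, so a constant trace
    passes through unchanged).
    """
    nyquist = trace.sample_rate / 2.0
    if cutoff_hz >= nyquist:
        raise ErgError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist frequency {nyquist} Hz"
        )
    sos = signal.bessel(poles, cutoff_hz, btype="low", fs=trace.sample_rate, output="sos")
    zi = signal.sosfilt_zi(sos) * trace.samples[0]
    filtered, _ = signal.sosfilt(sos, trace.samples, zi=zi)
    return trace.with_samples(filtered)
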