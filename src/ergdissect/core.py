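"""Core domain types for ex vivo electroretinogram (ERG) analysis.

The transretinal ERG of an isolated, superfused retina is a sum of
cell-class-specific field potentials: a fast negative photoreceptor
component (the a-wave, with an early "nose" trough and a slower recovery
plateau), a positive ON-bipolar component (the b-wave), and a slow
negative Müller glial cell (MGC) component carried by glial potassium
currents.  Sequential perfusion with barium chloride (which blocks the
MGC potassium currents) and L-AP4 + aspartic acid (which silence the
bipolar pathways) lets each component be recovered by subtracting
intensity-matched flash responses across perfusion conditions.

This module holds the validated containers shared by every pipeline
stage: single sweeps (:class:`Trace`), per-retina flash families
(:class:`FlashFamily`), and baseline-referenced amplitude measurements
(:class:`AmplitudeRecord`).  Voltages are microvolts and times seconds
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DEFAULT_BASELINE_WINDOW",
    "DEFAULT_INTENSITY_RANGE",
    "ErgError",
    "StructuralError",
    "EmptyInputError",
    "WindowError",
    "MissingConditionError",
    "IntensityMismatchError",
    "SchemaError",
    "DegenerateFitError",
    "PerfusionCondition",
    "ComponentKind",
    "Genotype",
    "AgeClass",
    "Phase",
    "COMPONENT_POLARITY",
    "canonical_intensity",
    "Trace",
    "AmplitudeRecord",
    "FlashFamily",
    "make_flash_family",
    "baseline",
    "average_traces",
]

#: Pre-stimulus window (s) used for the baseline reference.  Long enough to
#: average out additive noise, short enough to precede slow drift.
DEFAULT_BASELINE_WINDOW = 0.100

#: Flash intensity range of the stimulus protocol, photons/um^2.
DEFAULT_INTENSITY_RANGE = (5.0, 50_000.0)


class ErgError(Exception):
    """Base class for all package-specific errors."""


class StructuralError(ErgError):
    """Traces or containers violate a structural invariant."""


class EmptyInputError(ErgError):
    """An operation received an empty collection."""


class WindowError(ErgError):
    """A baseline or search window does not fit inside the trace."""


class MissingConditionError(ErgError):
    """A perfusion condition required for subtraction is absent."""


class IntensityMismatchError(ErgError):
    """Intensity sets across perfusion conditions do not match."""


class SchemaError(ErgError):
    """An interchange file violates the documented schema."""


class DegenerateFitError(ErgError):
    """Intensity-response data cannot support a fit."""


class PerfusionCondition(Enum):
    """Sequentially applied perfusion solutions.

    Enum values encode the application order: normal Locke's first, then
    Locke's + BaCl2 (100 uM), then Locke's + BaCl2 + L-AP4 (14 uM) +
    aspartic acid (100 uM).
    """

    LOCKES = 1
    BACL2 = 2
    BACL2_LAP4_AA = 3


class ComponentKind(Enum):
    """Cellular generators of the ex vivo ERG."""

    PHOTORECEPTOR = "PHOTORECEPTOR"
    ON_BIPOLAR = "ON_BIPOLAR"
    MGC = "MGC"


class Genotype(Enum):
    """Wildtype and the three Rs1 mutant models of X-linked retinoschisis."""

    WT = "WT"
    KO = "KO"
    R141C = "R141C"
    C59S = "C59S"


class AgeClass(Enum):
    """Developmental stage relative to murine eye opening (~P12-14)."""

    PRE_EYE_OPENING = "PRE_EYE_OPENING"
    EYE_OPENING = "EYE_OPENING"
    ADULT = "ADULT"


class Phase(Enum):
    """Measurement phase of the photoreceptor a-wave.

    NOSE is the early hyperpolarisation trough; RECOVERY is the slower
    plateau that follows.  Components other than the photoreceptor use NA.
    """

    NOSE = "NOSE"
    RECOVERY = "RECOVERY"
    NA = "NA"


#: Deflection direction of each component relative to baseline.
COMPONENT_POLARITY = {
    ComponentKind.PHOTORECEPTOR: -1,
    ComponentKind.ON_BIPOLAR: +1,
    ComponentKind.MGC: -1,
}


def canonical_intensity(intensity: float) -> float:
    """Round a flash intensity to 4 significant figures.

    All intensity matching across perfusion conditions is done on this
    canonical value, so float noise in metadata cannot break the strict
    intensity-matched subtraction.
    """
    return float(f"{float(intensity):.4g}")


@dataclass(frozen=True, eq=False)
class Trace:
    """One uniformly sampled voltage sweep with stimulus metadata.

    Parameters
    ----------
    samples:
        Voltage samples in microvolts (1-D).
    sample_rate:
        Sampling rate in Hz.
    t0_flash:
        Flash onset in seconds relative to the first sample.  Must leave
        room for at least one default baseline window before the flash.
    flash_duration:
        Stimulus duration in seconds (metadata; the generator treats the
        flash as impulsive).
    intensity:
        Flash strength in photons/um^2.
    condition:
        Perfusion condition, or ``None`` for derived (subtracted) traces.
    """

    samples: np.ndarray
    sample_rate: float
    t0_flash: float
    flash_duration: float
    intensity: float
    condition: PerfusionCondition | None
    retina_id: str
    sweep_index: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise StructuralError("samples must be a non-empty 1-D sequence")
        object.__setattr__(self, "samples", arr)
        if not self.sample_rate > 0:
            raise StructuralError("sample_rate must be positive")
        if self.intensity < 0:
            raise StructuralError("intensity must be non-negative")
        if not self.flash_duration > 0:
            raise StructuralError("flash_duration must be positive")
        if self.t0_flash < DEFAULT_BASELINE_WINDOW:
            raise StructuralError(
                "t0_flash must leave at least one baseline window "
                f"({DEFAULT_BASELINE_WINDOW} s) of pre-stimulus recording"
            )
        if self.sweep_index < 0:
            raise StructuralError("sweep_index must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from the start of the record."""
        return np.arange(self.n_samples) / self.sample_rate

    @property
    def times_from_flash(self) -> np.ndarray:
        """Sample times in seconds relative to flash onset (t = 0)."""
        return self.times - self.t0_flash

    def index_at(self, t: float) -> int:
        """Sample index nearest to time ``t`` (s from record start)."""
        return int(round(t * self.sample_rate))

    def with_samples(self, samples: np.ndarray, **changes) -> "Trace":
        return replace(self, samples=samples, **changes)


def baseline(trace: Trace, window: float = DEFAULT_BASELINE_WINDOW) -> float:
    """Mean voltage over the pre-stimulus window ``[t0 - window, t0)``.

    Raises
    ------
    WindowError
        If the window does not fit in the pre-stimulus segment.
    """
    if not window > 0:
        raise WindowError("baseline window must be positive")
    i1 = trace.index_at(trace.t0_flash)
    i0 = i1 - int(round(window * trace.sample_rate))
    if i0 < 0:
        raise WindowError(
            f"baseline window of {window} s exceeds the {trace.t0_flash} s "
            "pre-stimulus segment"
        )
    if i1 <= i0:
        raise WindowError("baseline window contains no samples")
    return float(np.mean(trace.samples[i0:i1]))


def _check_consistent(traces: Sequence[Trace], attrs: Iterable[str]) -> None:
    first = traces[0]
    for attr in attrs:
        ref = getattr(first, attr)
        for t in traces[1:]:
            if getattr(t, attr) != ref:
                raise StructuralError(
                    f"traces disagree on {attr}: {getattr(t, attr)!r} != {ref!r}"
                )


def average_traces(traces: Sequence[Trace]) -> Trace:
    """Point-wise equal-weight average of repeated sweeps.

    All traces must share every attribute except ``sweep_index``.
    Averaging N identical sweeps returns the input sweep exactly.
    """
    traces = list(traces)
    if not traces:
        raise EmptyInputError("no traces to average")
    _check_consistent(
        traces,
        ("sample_rate", "t0_flash", "flash_duration", "intensity", "condition", "retina_id"),
    )
    lengths = {t.n_samples for t in traces}
    if len(lengths) != 1:
        raise StructuralError(f"traces have inconsistent lengths: {sorted(lengths)}")
    first = traces[0].samples
    if all(np.array_equal(t.samples, first) for t in traces[1:]):
        # identical sweeps: return them exactly, without float-mean rounding
        return traces[0].with_samples(first.copy(), sweep_index=0)
    stacked = np.stack([t.samples for t in traces])
    return traces[0].with_samples(stacked.mean(axis=0), sweep_index=0)


@dataclass(frozen=True)
class AmplitudeRecord:
    """Baseline-referenced response magnitude R at one intensity I.

    ``amplitude`` is the absolute deviation from the pre-stimulus
    baseline to the component's extremum (trough for photoreceptor and
    MGC, peak for ON-bipolar), always reported as a non-negative
    magnitude; ``polarity`` carries the deflection direction.
    """

    retina_id: str
    component: ComponentKind
    intensity: float
    amplitude: float
    polarity: int
    phase: Phase = Phase.NA

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise StructuralError("amplitude must be non-negative")
        if self.polarity != COMPONENT_POLARITY[self.component]:
            raise StructuralError(
                f"polarity {self.polarity} inconsistent with {self.component.name}"
            )
        if self.component is ComponentKind.PHOTORECEPTOR:
            if self.phase not in (Phase.NOSE, Phase.RECOVERY):
                raise StructuralError("photoreceptor records need phase NOSE or RECOVERY")
        elif self.phase is not Phase.NA:
            raise StructuralError("phase applies to the photoreceptor component only")


@dataclass
class FlashFamily:
    """All sweeps recorded from one retina across conditions and intensities."""

    retina_id: str
    genotype: Genotype
    age_days: int
    age_class: AgeClass
    traces: list[Trace]
    intensity_range: tuple[float, float] = DEFAULT_INTENSITY_RANGE

    def __post_init__(self) -> None:
        if not self.traces:
            raise EmptyInputError("flash family has no traces")
        _check_consistent(self.traces, ("sample_rate", "t0_flash"))
        lengths = {t.n_samples for t in self.traces}
        if len(lengths) != 1:
            raise StructuralError(f"traces have inconsistent lengths: {sorted(lengths)}")
        for t in self.traces:
            if t.retina_id != self.retina_id:
                raise StructuralError(
                    f"trace retina_id {t.retina_id!r} != family {self.retina_id!r}"
                )
        lo, hi = self.intensity_range
        bad = sorted(
            {canonical_intensity(t.intensity) for t in self.traces
             if not lo <= canonical_intensity(t.intensity) <= hi}
        )
        if bad:
            raise StructuralError(
                f"intensities outside configured range {self.intensity_range}: {bad}"
            )

    @property
    def sample_rate(self) -> float:
        return self.traces[0].sample_rate

    @property
    def t0_flash(self) -> float:
        return self.traces[0].t0_flash

    @property
    def n_samples(self) -> int:
        return self.traces[0].n_samples

    @property
    def conditions(self) -> list[PerfusionCondition]:
        present = {t.condition for t in self.traces if t.condition is not None}
        return sorted(present, key=lambda c: c.value)

    @property
    def intensities(self) -> list[float]:
        """Sorted, deduplicated canonical intensity index."""
        return sorted({canonical_intensity(t.intensity) for t in self.traces})

    def sweeps(self, condition: PerfusionCondition, intensity: float) -> list[Trace]:
        key = canonical_intensity(intensity)
        out = [
            t for t in self.traces
            if t.condition is condition and canonical_intensity(t.intensity) == key
        ]
        return sorted(out, key=lambda t: t.sweep_index)

    def scaled(self, factor: float) -> "FlashFamily":
        """Family with every sample multiplied by ``factor`` (for linearity checks)."""
        return replace(
            self, traces=[t.with_samples(t.samples * factor) for t in self.traces]
        )

    def __len__(self) -> int:
        return len(self.traces)


def make_flash_family(
    traces: Iterable[Trace],
    *,
    genotype: Genotype,
    age_days: int,
    age_class: AgeClass,
    retina_id: str | None = None,
    intensity_range: tuple[float, float] = DEFAULT_INTENSITY_RANGE,
) -> FlashFamily:
    """Validate a collection of sweeps into a :class:`FlashFamily`.

    The retina id defaults to the (unique) id carried by the traces.
    Raises :class:`EmptyInputError` for empty input and
    :class:`StructuralError` for inconsistent sample rates, lengths, or
    retina ids.
    """
    traces = list(traces)
    if not traces:
        raise EmptyInputError("cannot build a flash family from zero traces")
    ids = {t.retina_id for t in traces}
    if retina_id is None:
        if len(ids) != 1:
            raise StructuralError(f"traces carry multiple retina ids: {sorted(ids)}")
        retina_id = next(iter(ids))
    return FlashFamily(
        retina_id=retina_id,
        genotype=genotype,
        age_days=age_days,
        age_class=age_class,
        traces=traces,
        intensity_range=intensity_range,
    )
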