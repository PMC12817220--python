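"""Pharmacological component isolation: averaging, subtraction, measurement.

Implements the subtraction scheme for the three perfusion conditions:

* MGC          = (normal Locke's) - (Locke's + BaCl2)
* ON-bipolar   = (Locke's + BaCl2) - (Locke's + BaCl2 + L-AP4 + AA)
* photoreceptor = the (Locke's + BaCl2 + L-AP4 + AA) recording itself

The subtractions are oriented so the derived MGC wave is the slow
negative potential and the derived ON-bipolar wave is positive-going.
Triplicate sweeps are averaged point-wise before subtraction, and every
subtraction is strictly intensity-matched (canonical 4-significant-figure
intensities; an optional relative tolerance can relax this).

Amplitudes are measured from the pre-stimulus baseline to the component
extremum: trough for photoreceptor and MGC, peak for ON-bipolar.  The
photoreceptor a-wave is measured in two phases - the early NOSE trough
(global minimum of an early window, the default downstream measure) and
the RECOVERY plateau (mean of a late window).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    AgeClass,
    AmplitudeRecord,
    COMPONENT_POLARITY,
    ComponentKind,
    DEFAULT_BASELINE_WINDOW,
    FlashFamily,
    Genotype,
    IntensityMismatchError,
    MissingConditionError,
    PerfusionCondition,
    Phase,
    Trace,
    WindowError,
    average_traces,
    baseline,
    canonical_intensity,
)

__all__ = [
    "DEFAULT_SEARCH_WINDOWS",
    "ComponentSet",
    "average_sweeps",
    "derive_components",
    "measure_amplitude",
]

logger = logging.getLogger(__name__)

#: Post-flash search windows (s) keyed by (component, phase).  They follow
#: the kinetic ordering of the default waveforms: the photoreceptor nose is
#: earliest, the ON-bipolar peak intermediate, the MGC trough slowest.
#: Windows are clamped to the end of the record for short sweeps.
DEFAULT_SEARCH_WINDOWS: dict[tuple[ComponentKind, Phase], tuple[float, float]] = {
    (ComponentKind.PHOTORECEPTOR, Phase.NOSE): (0.0, 0.300),
    (ComponentKind.PHOTORECEPTOR, Phase.RECOVERY): (0.400, 0.600),
    (ComponentKind.ON_BIPOLAR, Phase.NA): (0.0, 1.0),
    (ComponentKind.MGC, Phase.NA): (0.0, 2.0),
}


def average_sweeps(family: FlashFamily) -> FlashFamily:
    """Collapse repeated sweeps to one averaged trace per (condition, intensity)."""
    averaged: list[Trace] = []
    for condition in family.conditions:
        for intensity in family.intensities:
            sweeps = family.sweeps(condition, intensity)
            if sweeps:
                averaged.append(average_traces(sweeps))
    return FlashFamily(
        retina_id=family.retina_id,
        genotype=family.genotype,
        age_days=family.age_days,
        age_class=family.age_class,
        traces=averaged,
        intensity_range=family.intensity_range,
    )


def measure_amplitude(
    trace: Trace,
    component: ComponentKind,
    *,
    baseline_window: float = DEFAULT_BASELINE_WINDOW,
    search_window: tuple[float, float] | None = None,
    phase: Phase = Phase.NA,
) -> AmplitudeRecord:
    """Baseline-to-extremum magnitude of a derived component trace.

    The extremum is the minimum within the search window for the
    photoreceptor (NOSE) and MGC, the maximum for the ON-bipolar.  The
    RECOVERY phase instead uses the mean over a late plateau window.
    Windows are expressed in seconds after flash onset and clamped to the
    record end; an empty window raises :class:`WindowError`.
    """
    if component is ComponentKind.PHOTORECEPTOR:
        if phase not in (Phase.NOSE, Phase.RECOVERY):
            phase = Phase.NOSE
    else:
        phase = Phase.NA
    if search_window is None:
        search_window = DEFAULT_SEARCH_WINDOWS[(component, phase)]
    w0, w1 = search_window
    if w0 < 0 or w1 <= w0:
        raise WindowError(f"invalid search window {search_window}")

    base = baseline(trace, baseline_window)
    i0 = trace.index_at(trace.t0_flash + w0)
    i1 = min(trace.index_at(trace.t0_flash + w1), trace.n_samples)
    if i1 <= i0 or i0 >= trace.n_samples:
        raise WindowError(
            f"search window {search_window} s after flash is empty for a "
            f"{trace.duration:.3f} s record"
        )
    segment = trace.samples[i0:i1]
    if phase is Phase.RECOVERY:
        extremum = float(np.mean(segment))
    elif COMPONENT_POLARITY[component] < 0:
        extremum = float(np.min(segment))
    else:
        extremum = float(np.max(segment))
    return AmplitudeRecord(
        retina_id=trace.retina_id,
        component=component,
        intensity=canonical_intensity(trace.intensity),
        amplitude=abs(extremum - base),
        polarity=COMPONENT_POLARITY[component],
        phase=phase,
    )


@dataclass
class ComponentSet:
    """Derived component traces and amplitudes for one retina."""

    retina_id: str
    genotype: Genotype
    age_class: AgeClass
    age_days: int
    traces: dict[tuple[ComponentKind, float], Trace]
    amplitudes: list[AmplitudeRecord]
    provenance: dict[str, str] = field(default_factory=dict)

    def trace(self, component: ComponentKind, intensity: float) -> Trace:
        return self.traces[(component, canonical_intensity(intensity))]

    @property
    def intensities(self) -> list[float]:
        return sorted({key[1] for key in self.traces})

    def amplitude_table(self) -> pd.DataFrame:
        """Tidy table: retina_id, genotype, age_class, component, phase, intensity, amplitude."""
        rows = [
            {
                "retina_id": rec.retina_id,
                "genotype": self.genotype.value,
                "age_class": self.age_class.value,
                "age_days": self.age_days,
                "component": rec.component.value,
                "phase": rec.phase.value,
                "intensity": rec.intensity,
                "amplitude": rec.amplitude,
                "polarity": rec.polarity,
            }
            for rec in self.amplitudes
        ]
        return pd.DataFrame(rows)


def _condition_index(
    family: FlashFamily, tolerance: float | None
) -> dict[PerfusionCondition, dict[float, Trace]]:
    index: dict[PerfusionCondition, dict[float, Trace]] = {}
    for condition in PerfusionCondition:
        table: dict[float, Trace] = {}
        for intensity in family.intensities:
            sweeps = family.sweeps(condition, intensity)
            if len(sweeps) == 1:
                table[intensity] = sweeps[0]
            elif len(sweeps) > 1:
                table[intensity] = average_traces(sweeps)
        if table:
            index[condition] = table
    missing = [c for c in PerfusionCondition if c not in index]
    if missing:
        raise MissingConditionError(
            "flash family is missing perfusion condition(s): "
            + ", ".join(c.name for c in missing)
        )
    if tolerance is not None:
        # tolerance mode: remap each condition's intensities onto the
        # LOCKES index when within the given relative tolerance
        ref = sorted(index[PerfusionCondition.LOCKES])
        for condition, table in index.items():
            remapped: dict[float, Trace] = {}
            for intensity, trace in table.items():
                match = min(ref, key=lambda r: abs(r - intensity) / r)
                if abs(match - intensity) / match <= tolerance:
                    remapped[match] = trace
                else:
                    remapped[intensity] = trace
            index[condition] = remapped
    return index


def derive_components(
    family: FlashFamily,
    *,
    baseline_window: float = DEFAULT_BASELINE_WINDOW,
    search_windows: dict[tuple[ComponentKind, Phase], tuple[float, float]] | None = None,
    intensity_tolerance: float | None = None,
    measure: bool = True,
) -> ComponentSet:
    """Derive photoreceptor, ON-bipolar and MGC traces by condition subtraction.

    Sweeps are averaged per (condition, intensity) first if needed.  All
    three conditions must be present and, by default, carry identical
    canonical intensity sets; mismatches raise
    :class:`IntensityMismatchError` listing the unmatched intensities
    (``intensity_tolerance`` enables relative-tolerance matching instead).
    """
    windows = dict(DEFAULT_SEARCH_WINDOWS)
    if search_windows:
        windows.update(search_windows)
    index = _condition_index(family, intensity_tolerance)

    sets = {c: set(t) for c, t in index.items()}
    common = sets[PerfusionCondition.LOCKES] & sets[PerfusionCondition.BACL2] \
        & sets[PerfusionCondition.BACL2_LAP4_AA]
    unmatched = sorted(set.union(*sets.values()) - common)
    if unmatched:
        raise IntensityMismatchError(
            f"intensities not present in all conditions: {unmatched}"
        )

    traces: dict[tuple[ComponentKind, float], Trace] = {}
    amplitudes: list[AmplitudeRecord] = []
    for intensity in sorted(common):
        lockes = index[PerfusionCondition.LOCKES][intensity]
        bacl2 = index[PerfusionCondition.BACL2][intensity]
        cocktail = index[PerfusionCondition.BACL2_LAP4_AA][intensity]
        mgc = lockes.with_samples(lockes.samples - bacl2.samples, condition=None)
        onb = bacl2.with_samples(bacl2.samples - cocktail.samples, condition=None)
        photoreceptor = cocktail
        traces[(ComponentKind.MGC, intensity)] = mgc
        traces[(ComponentKind.ON_BIPOLAR, intensity)] = onb
        traces[(ComponentKind.PHOTORECEPTOR, intensity)] = photoreceptor
        if measure:
            amplitudes.append(
                measure_amplitude(
                    mgc, ComponentKind.MGC,
                    baseline_window=baseline_window,
                    search_window=windows[(ComponentKind.MGC, Phase.NA)],
                )
            )
            amplitudes.append(
                measure_amplitude(
                    onb, ComponentKind.ON_BIPOLAR,
                    baseline_window=baseline_window,
                    search_window=windows[(ComponentKind.ON_BIPOLAR, Phase.NA)],
                )
            )
            for phase in (Phase.NOSE, Phase.RECOVERY):
                amplitudes.append(
                    measure_amplitude(
                        photoreceptor, ComponentKind.PHOTORECEPTOR,
                        baseline_window=baseline_window,
                        search_window=windows[(ComponentKind.PHOTORECEPTOR, phase)],
                        phase=phase,
                    )
                )
    return ComponentSet(
        retina_id=family.retina_id,
        genotype=family.genotype,
        age_class=family.age_class,
        age_days=family.age_days,
        traces=traces,
        amplitudes=amplitudes,
        provenance={
            "MGC": "LOCKES - BACL2",
            "ON_BIPOLAR": "BACL2 - BACL2_LAP4_AA",
            "PHOTORECEPTOR": "BACL2_LAP4_AA",
        },
    )
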