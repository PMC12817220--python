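"""End-to-end orchestration: simulate -> isolate -> fit -> compare -> trajectory.

`run_pipeline` executes the whole analysis under a validated
:class:`RunConfig` (loadable from TOML; unknown keys are errors) and
writes tidy result tables, each carrying a provenance header with the
package version, a hash of the configuration, and the seed.  Identical
config + seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd

from .core import AgeClass, ComponentKind, ErgError, Genotype, Phase
from .hill import IntensityResponse, fit_hill, fit_pooled
from .io import write_family, write_ground_truth, write_table
from .isolation import ComponentSet, derive_components
from .presets import simulate_cohort
from .stats import compare_parameters, compare_per_intensity, proportionality, trajectory
from .synthetic import SimConfig, SimResult, default_intensities

__all__ = [
    "RunConfig",
    "run_pipeline",
    "isolate_cohort",
    "amplitude_table",
    "fit_table",
    "pooled_fit_table",
]

logger = logging.getLogger(__name__)


def isolate_cohort(results: list[SimResult], **kwargs) -> list[ComponentSet]:
    """Derive components for every simulated retina."""
    out = [derive_components(r.family, **kwargs) for r in results]
    logger.info("derived components for %d retinas", len(out))
    return out


def amplitude_table(component_sets: list[ComponentSet]) -> pd.DataFrame:
    """Concatenate per-retina amplitude tables into one tidy frame."""
    return pd.concat(
        [cs.amplitude_table() for cs in component_sets], ignore_index=True
    )


def _responses(amplitudes: pd.DataFrame, phase: str):
    """Yield (metadata, IntensityResponse) per retina x component."""
    df = amplitudes[
        (amplitudes["component"] != ComponentKind.PHOTORECEPTOR.value)
        | (amplitudes["phase"] == phase)
    ]
    for (retina_id, component), cell in df.groupby(["retina_id", "component"]):
        cell = cell.sort_values("intensity")
        meta = cell.iloc[0]
        yield meta, IntensityResponse(
            retina_id=retina_id,
            component=ComponentKind(component),
            intensities=cell["intensity"].to_numpy(),
            amplitudes=cell["amplitude"].to_numpy(),
        )


def fit_table(
    amplitudes: pd.DataFrame,
    *,
    phase: str = "NOSE",
    fix_n: float | None = None,
) -> pd.DataFrame:
    """Per-retina Hill fits of every component's intensity-response series.

    Photoreceptor amplitudes use the given measurement phase (NOSE, the
    baseline-to-trough a-wave measure, by default).
    """
    rows = []
    n_failed = 0
    for meta, resp in _responses(amplitudes, phase):
        fit = fit_hill(resp, fix_n=fix_n)
        n_failed += not fit.converged
        rows.append({
            "retina_id": resp.retina_id,
            "genotype": meta["genotype"],
            "age_class": meta["age_class"],
            "age_days": meta["age_days"],
            "component": resp.component.value,
            "r_max": fit.r_max,
            "k": fit.k,
            "log10_k": fit.log10_k,
            "n": fit.n,
            "rss": fit.rss,
            "converged": fit.converged,
            "k_identifiable": fit.k_identifiable,
            "n_points": fit.n_points,
        })
    logger.info("fitted %d intensity-response series (%d flagged)", len(rows), n_failed)
    return pd.DataFrame(rows)


def pooled_fit_table(
    amplitudes: pd.DataFrame, *, phase: str = "NOSE", fix_n: float | None = None
) -> pd.DataFrame:
    """Pooled (collated) fit per genotype x age class x component; display only."""
    rows = []
    for (genotype, age_class), group in amplitudes.groupby(["genotype", "age_class"]):
        by_comp: dict[str, list[IntensityResponse]] = {}
        for _, resp in _responses(group, phase):
            by_comp.setdefault(resp.component.value, []).append(resp)
        for component, responses in sorted(by_comp.items()):
            fit = fit_pooled(responses, fix_n=fix_n)
            rows.append({
                "genotype": genotype, "age_class": age_class, "component": component,
                "n_retinas": len(responses),
                "r_max": fit.r_max, "log10_k": fit.log10_k, "n": fit.n,
                "rss": fit.rss, "converged": fit.converged,
            })
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Validated pipeline configuration (TOML-loadable, schema version 1)."""

    seed: int = 0
    outdir: str = "results"
    genotypes: list[str] = field(default_factory=lambda: [g.value for g in Genotype])
    age_classes: list[str] = field(default_factory=lambda: [a.value for a in AgeClass])
    retinas_per_group: int = 3
    intensities: list[float] = field(default_factory=lambda: list(default_intensities()))
    sweeps: int = 3
    sample_rate: float = 500.0
    pre_flash: float = 0.1
    record_duration: float = 1.1
    flash_duration: float = 0.002
    noise_sd: float = 2.0
    drift_sd: float = 0.0
    retina_cv_r_max: float = 0.15
    retina_cv_k: float = 0.10
    baseline_window: float = 0.1
    photoreceptor_phase: str = "NOSE"
    fix_n: float | None = None
    holm: bool = False
    n_boot: int = 2000
    write_traces: bool = False
    schema_version: int = 1

    def __post_init__(self) -> None:
        if not self.genotypes:
            raise ErgError("config.genotypes must not be empty")
        if Genotype.WT.value not in self.genotypes:
            raise ErgError("config.genotypes must include the WT reference")
        self.genotypes = [Genotype(g).value for g in self.genotypes]
        if not self.age_classes:
            raise ErgError("config.age_classes must not be empty")
        self.age_classes = [AgeClass(a).value for a in self.age_classes]
        if self.retinas_per_group < 1:
            raise ErgError("config.retinas_per_group must be >= 1")
        Phase(self.photoreceptor_phase)
        if self.schema_version != 1:
            raise ErgError(f"unsupported config schema_version {self.schema_version}")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        raw = tomllib.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ErgError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def sim_config(self) -> SimConfig:
        return SimConfig(
            intensities=tuple(self.intensities),
            sweeps=self.sweeps,
            sample_rate=self.sample_rate,
            pre_flash=self.pre_flash,
            record_duration=self.record_duration,
            flash_duration=self.flash_duration,
            noise_sd=self.noise_sd,
            drift_sd=self.drift_sd,
            retina_cv_r_max=self.retina_cv_r_max,
            retina_cv_k=self.retina_cv_k,
        )

    def digest(self) -> str:
        params = asdict(self)
        params.pop("outdir")  # output location does not change the analysis
        payload = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, seed: int | None = None) -> dict:
    """Run every stage and write result tables under ``config.outdir``.

    Returns the result bundle: the tidy DataFrames plus the output paths.
    Deterministic for a fixed config and seed.
    """
    seed = config.seed if seed is None else seed
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = {"config_sha256": config.digest(), "seed": seed}
    sim_config = config.sim_config()
    genotypes = [Genotype(g) for g in config.genotypes]
    age_classes = [AgeClass(a) for a in config.age_classes]

    all_results: list[SimResult] = []
    for offset, age_class in enumerate(age_classes):
        cohort = simulate_cohort(
            age_class,
            n_retinas=config.retinas_per_group,
            seed=seed + offset,
            config=sim_config,
            genotypes=genotypes,
        )
        all_results.extend(cohort)
    logger.info("simulated %d retinas", len(all_results))

    if config.write_traces:
        family_dir = outdir / "families"
        for result in all_results:
            write_family(result.family, family_dir)
        write_ground_truth(
            {r.family.retina_id: r.truth for r in all_results},
            outdir / "ground_truth.json",
        )

    component_sets = isolate_cohort(
        all_results, baseline_window=config.baseline_window
    )
    amplitudes = amplitude_table(component_sets)
    fits = fit_table(
        amplitudes, phase=config.photoreceptor_phase, fix_n=config.fix_n
    )
    pooled = pooled_fit_table(
        amplitudes, phase=config.photoreceptor_phase, fix_n=config.fix_n
    )

    per_intensity = compare_per_intensity(
        amplitudes[amplitudes["age_class"] == AgeClass.ADULT.value]
        if AgeClass.ADULT.value in config.age_classes else amplitudes,
        phase=config.photoreceptor_phase,
        holm=config.holm,
    )
    parameter_rows = []
    for age_class in config.age_classes:
        sub = fits[fits["age_class"] == age_class]
        table = compare_parameters(sub, holm=config.holm)
        if not table.empty:
            table.insert(0, "age_class", age_class)
            parameter_rows.append(table)
    parameters = (
        pd.concat(parameter_rows, ignore_index=True) if parameter_rows else pd.DataFrame()
    )

    prop_points_rows, prop_summary_rows = [], []
    for age_class in config.age_classes:
        sub = fits[fits["age_class"] == age_class]
        for pair in (
            (ComponentKind.PHOTORECEPTOR, ComponentKind.ON_BIPOLAR),
            (ComponentKind.PHOTORECEPTOR, ComponentKind.MGC),
        ):
            points, summary = proportionality(
                sub, pair, n_boot=config.n_boot, seed=seed
            )
            for frame, rows in ((points, prop_points_rows), (summary, prop_summary_rows)):
                frame = frame.copy()
                frame.insert(0, "age_class", age_class)
                rows.append(frame)
    prop_points = pd.concat(prop_points_rows, ignore_index=True)
    prop_summary = pd.concat(prop_summary_rows, ignore_index=True)

    traj = trajectory(fits)

    tables = {
        "amplitudes": amplitudes,
        "fits": fits,
        "pooled_fits": pooled,
        "per_intensity_comparisons": per_intensity,
        "parameter_comparisons": parameters,
        "proportionality_points": prop_points,
        "proportionality_summary": prop_summary,
        "trajectory": traj,
    }
    paths = {}
    for name, frame in tables.items():
        paths[name] = write_table(frame, outdir / f"{name}.csv", provenance)
    (outdir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True)
    )
    logger.info(
        "pipeline complete: %d retinas, %d fits (%d converged), %d comparisons",
        len(all_results), len(fits), int(fits["converged"].sum()),
        len(per_intensity) + len(parameters),
    )
    return {"tables": tables, "paths": paths, "provenance": provenance}
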