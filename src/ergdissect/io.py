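"""Interchange readers/writers.

A flash family is stored as a wide CSV (first column time in seconds,
one column per sweep) plus a JSON sidecar carrying the metadata and the
per-column (condition, intensity, sweep) mapping.  Voltages are
normalised to microvolts on read; the sidecar must state its unit
explicitly (no silent default).  Derived tables are tidy long-format
CSVs with a provenance comment header (package version, config hash,
seed).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .core import (
    AgeClass,
    FlashFamily,
    Genotype,
    PerfusionCondition,
    SchemaError,
    Trace,
)
from .synthetic import GroundTruth

__all__ = [
    "write_family",
    "read_family",
    "write_ground_truth",
    "write_table",
    "read_table",
]

SCHEMA_VERSION = 1

_UNIT_TO_UV = {"uV": 1.0, "mV": 1e3, "V": 1e6}


def _column_name(trace: Trace) -> str:
    cond = trace.condition.name if trace.condition is not None else "DERIVED"
    return f"{cond}|{trace.intensity:g}|{trace.sweep_index}"


def write_family(family: FlashFamily, directory: str | Path) -> tuple[Path, Path]:
    """Write ``<retina_id>.csv`` + ``<retina_id>.json`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path = directory / f"{family.retina_id}.csv"
    json_path = directory / f"{family.retina_id}.json"

    times = family.traces[0].times
    data = {"time_s": times}
    columns = []
    for trace in family.traces:
        name = _column_name(trace)
        data[name] = trace.samples
        columns.append({
            "name": name,
            "condition": trace.condition.name if trace.condition else None,
            "intensity": trace.intensity,
            "sweep_index": trace.sweep_index,
            "flash_duration_s": trace.flash_duration,
        })
    # %.17g guarantees exact float64 round-trip through the text format
    pd.DataFrame(data).to_csv(csv_path, index=False, float_format="%.17g")

    metadata = {
        "schema_version": SCHEMA_VERSION,
        "retina_id": family.retina_id,
        "genotype": family.genotype.value,
        "age_days": family.age_days,
        "age_class": family.age_class.value,
        "sample_rate_hz": family.sample_rate,
        "t0_flash_s": family.t0_flash,
        "voltage_unit": "uV",
        "time_unit": "s",
        "intensity_unit": "photons/um^2",
        "intensities": family.intensities,
        "intensity_range": list(family.intensity_range),
        "columns": columns,
    }
    json_path.write_text(json.dumps(metadata, indent=2, sort_keys=True))
    return csv_path, json_path


def _require(metadata: dict, key: str):
    if key not in metadata:
        raise SchemaError(f"metadata.{key}: required field is missing")
    return metadata[key]


def read_family(path: str | Path) -> FlashFamily:
    """Read a flash family written by :func:`write_family`.

    ``path`` is the CSV file or its stem; the JSON sidecar must sit next
    to it.  Schema violations raise :class:`SchemaError` naming the
    offending field; voltages are converted to microvolts using the
    sidecar's declared unit.
    """
    path = Path(path)
    if path.suffix == ".csv":
        csv_path, json_path = path, path.with_suffix(".json")
    else:
        csv_path, json_path = path.with_suffix(".csv"), path.with_suffix(".json")
    if not json_path.exists():
        raise SchemaError(f"metadata sidecar not found: {json_path}")
    metadata = json.loads(json_path.read_text())

    sample_rate = _require(metadata, "sample_rate_hz")
    t0_flash = _require(metadata, "t0_flash_s")
    unit = _require(metadata, "voltage_unit")
    if unit not in _UNIT_TO_UV:
        raise SchemaError(
            f"metadata.voltage_unit: unknown unit {unit!r} (expected one of "
            f"{sorted(_UNIT_TO_UV)})"
        )
    scale = _UNIT_TO_UV[unit]
    columns = _require(metadata, "columns")
    retina_id = _require(metadata, "retina_id")
    genotype = Genotype(_require(metadata, "genotype"))
    age_class = AgeClass(_require(metadata, "age_class"))
    age_days = int(_require(metadata, "age_days"))

    frame = pd.read_csv(csv_path, float_precision="round_trip")
    if frame.shape[1] != len(columns) + 1:
        raise SchemaError(
            f"columns: CSV has {frame.shape[1] - 1} trace columns but metadata "
            f"declares {len(columns)}"
        )
    traces = []
    for spec in columns:
        name = spec["name"]
        if name not in frame.columns:
            raise SchemaError(f"columns.{name}: declared column missing from CSV")
        condition = (
            PerfusionCondition[spec["condition"]] if spec.get("condition") else None
        )
        traces.append(
            Trace(
                samples=frame[name].to_numpy(dtype=float) * scale,
                sample_rate=float(sample_rate),
                t0_flash=float(t0_flash),
                flash_duration=float(spec.get("flash_duration_s", 0.002)),
                intensity=float(spec["intensity"]),
                condition=condition,
                retina_id=retina_id,
                sweep_index=int(spec["sweep_index"]),
            )
        )
    return FlashFamily(
        retina_id=retina_id,
        genotype=genotype,
        age_days=age_days,
        age_class=age_class,
        traces=traces,
        intensity_range=tuple(metadata.get("intensity_range", (5.0, 50_000.0))),
    )


def write_ground_truth(truths: dict[str, GroundTruth], path: str | Path) -> Path:
    """Serialise per-retina ground truth (true parameters and amplitudes)."""
    path = Path(path)
    payload = {}
    for retina_id, truth in truths.items():
        payload[retina_id] = {
            "models": {
                kind.value: {"r_max": m.r_max, "k": m.k, "n": m.n}
                for kind, m in truth.models.items()
            },
            "amplitudes": [
                {"component": kind.value, "intensity": intensity, "amplitude": amp}
                for (kind, intensity), amp in sorted(
                    truth.amplitudes.items(), key=lambda kv: (kv[0][0].value, kv[0][1])
                )
            ],
        }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def write_table(
    df: pd.DataFrame, path: str | Path, provenance: dict[str, object] | None = None
) -> Path:
    """Write a tidy CSV with a ``#``-comment provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {"ergdissect": __version__}
    header.update(provenance or {})
    with open(path, "w") as fh:
        for key, value in header.items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a tidy CSV written by :func:`write_table`."""
    return pd.read_csv(path, comment="#")
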