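"""Genotype comparisons, proportionality analysis and developmental trajectories.

Group inference follows the unequal-variance (Welch) two-sample t-test
with Welch-Satterthwaite degrees of freedom, two-sided p-values, and the
significance-star convention * (0.01 < p < 0.05), ** (0.001 < p < 0.01),
*** (p < 0.001); boundary p-values fall into the less-significant bin.

`compare_per_intensity` tests each mutant genotype against wildtype on
component amplitudes at every shared intensity; `compare_parameters`
does the same on fitted log10 K and R_max.  No multiplicity correction
is applied by default (matching the raw per-intensity star convention);
Holm step-down adjustment is available by flag.

`proportionality` normalises each retina's R_max by the wildtype mean of
the corresponding component and summarises, per genotype, the signed
perpendicular deviation of (x, y) points from the identity diagonal - a
proportional change in both components lies on the diagonal, a
disproportionate y-component loss falls below it (negative deviation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ComponentKind, ErgError, Genotype

__all__ = [
    "WelchResult",
    "welch_test",
    "star_from_p",
    "holm_adjust",
    "compare_per_intensity",
    "compare_parameters",
    "proportionality",
    "trajectory",
]

logger = logging.getLogger(__name__)


def star_from_p(p: float) -> str:
    """Significance stars; exact boundary values go to the less-significant bin."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class WelchResult:
    """Unequal-variance two-sample comparison."""

    label_x: str
    label_y: str
    n_x: int
    n_y: int
    mean_x: float
    mean_y: float
    var_x: float
    var_y: float
    t: float
    df: float
    p: float
    star: str


def welch_test(x, y, labels: tuple[str, str] = ("x", "y")) -> WelchResult:
    """Welch's t-test (closed form) with Welch-Satterthwaite df.

    Requires n >= 2 in each sample.  If both sample variances are zero,
    p = 1 when the means are equal (no evidence of a difference) and
    p = 0 otherwise, with df falling back to n_x + n_y - 2 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ErgError("Welch test needs at least 2 observations per sample")
    nx, ny = x.size, y.size
    mx, my = float(x.mean()), float(y.mean())
    vx, vy = float(x.var(ddof=1)), float(y.var(ddof=1))
    sx, sy = vx / nx, vy / ny
    se2 = sx + sy
    if se2 == 0.0:
        t = 0.0 if mx == my else float("inf") if mx > my else float("-inf")
        p = 1.0 if mx == my else 0.0
        df = float(nx + ny - 2)
    else:
        t = (mx - my) / np.sqrt(se2)
        df = se2 ** 2 / (sx ** 2 / (nx - 1) + sy ** 2 / (ny - 1))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return WelchResult(
        label_x=labels[0], label_y=labels[1],
        n_x=nx, n_y=ny, mean_x=mx, mean_y=my, var_x=vx, var_y=vy,
        t=float(t), df=float(df), p=p, star=star_from_p(p),
    )


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def _finalise(rows: list[dict], holm: bool) -> pd.DataFrame:
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    if holm:
        table["p_adjusted"] = holm_adjust(table["p"].to_numpy())
        table["star"] = [star_from_p(p) for p in table["p_adjusted"]]
        table["significant"] = table["p_adjusted"] < 0.05
    else:
        table["significant"] = table["p"] < 0.05
    return table


def compare_per_intensity(
    amplitudes: pd.DataFrame,
    reference: str = Genotype.WT.value,
    *,
    phase: str = "NOSE",
    holm: bool = False,
) -> pd.DataFrame:
    """Welch tests of each mutant vs wildtype amplitude at every shared intensity.

    ``amplitudes`` is the tidy table produced by the isolation stage
    (columns retina_id, genotype, component, phase, intensity,
    amplitude).  Photoreceptor rows are filtered to the given measurement
    phase (NOSE by default).  Cells with fewer than two retinas in either
    group are skipped with a logged warning.
    """
    df = amplitudes[
        (amplitudes["component"] != ComponentKind.PHOTORECEPTOR.value)
        | (amplitudes["phase"] == phase)
    ]
    rows: list[dict] = []
    for (component, intensity), cell in df.groupby(["component", "intensity"]):
        ref = cell.loc[cell["genotype"] == reference, "amplitude"].to_numpy()
        for genotype, group in cell.groupby("genotype"):
            if genotype == reference:
                continue
            mut = group["amplitude"].to_numpy()
            if ref.size < 2 or mut.size < 2:
                logger.warning(
                    "skipping %s vs %s at %s (%s): fewer than 2 retinas per group",
                    genotype, reference, intensity, component,
                )
                continue
            res = welch_test(mut, ref, labels=(genotype, reference))
            rows.append({
                "genotype": genotype, "reference": reference,
                "component": component, "intensity": intensity,
                "n": res.n_x, "n_ref": res.n_y,
                "mean": res.mean_x, "mean_ref": res.mean_y,
                "t": res.t, "df": res.df, "p": res.p, "star": res.star,
            })
    return _finalise(rows, holm)


def compare_parameters(
    fits: pd.DataFrame,
    reference: str = Genotype.WT.value,
    parameters: tuple[str, ...] = ("r_max", "log10_k"),
    *,
    holm: bool = False,
) -> pd.DataFrame:
    """Welch tests of fitted Hill parameters, each mutant vs wildtype.

    ``fits`` is the tidy per-retina fit table (columns retina_id,
    genotype, component, r_max, log10_k, ...).  Fits flagged
    non-identifiable for K are excluded from log10_k comparisons.
    """
    if fits.empty:
        return pd.DataFrame()
    rows: list[dict] = []
    for parameter in parameters:
        df = fits
        if parameter == "log10_k" and "k_identifiable" in fits.columns:
            df = fits[fits["k_identifiable"]]
        for component, cell in df.groupby("component"):
            ref = cell.loc[cell["genotype"] == reference, parameter].to_numpy()
            for genotype, group in cell.groupby("genotype"):
                if genotype == reference:
                    continue
                mut = group[parameter].to_numpy()
                if ref.size < 2 or mut.size < 2:
                    logger.warning(
                        "skipping %s vs %s on %s (%s): fewer than 2 retinas",
                        genotype, reference, parameter, component,
                    )
                    continue
                res = welch_test(mut, ref, labels=(genotype, reference))
                rows.append({
                    "genotype": genotype, "reference": reference,
                    "component": component, "parameter": parameter,
                    "n": res.n_x, "n_ref": res.n_y,
                    "mean": res.mean_x, "mean_ref": res.mean_y,
                    "t": res.t, "df": res.df, "p": res.p, "star": res.star,
                })
    return _finalise(rows, holm)


def proportionality(
    fits: pd.DataFrame,
    pair: tuple[ComponentKind, ComponentKind] = (
        ComponentKind.PHOTORECEPTOR,
        ComponentKind.ON_BIPOLAR,
    ),
    reference: str = Genotype.WT.value,
    *,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wildtype-normalised R_max pairs and their deviation from the diagonal.

    Each retina's R_max for the two components is divided by the
    wildtype mean R_max of that component, giving points that cluster at
    (1, 1) for wildtype.  The per-point deviation is the signed
    perpendicular distance (y - x) / sqrt(2) from the identity line; the
    per-genotype summary is its mean with a seeded bootstrap percentile
    interval.  Uniform scaling of both components gives deviation 0.
    """
    x_comp, y_comp = pair
    records: list[dict] = []
    denominators: dict[ComponentKind, float] = {}
    for comp in pair:
        wt = fits[
            (fits["genotype"] == reference) & (fits["component"] == comp.value)
        ]["r_max"]
        if wt.empty or wt.mean() <= 0:
            raise ErgError(
                f"no positive wildtype R_max baseline for component {comp.value}"
            )
        denominators[comp] = float(wt.mean())

    wide = fits.pivot_table(
        index=["genotype", "retina_id"], columns="component", values="r_max"
    )
    for (genotype, retina_id), row in wide.iterrows():
        if pd.isna(row.get(x_comp.value)) or pd.isna(row.get(y_comp.value)):
            continue
        x = row[x_comp.value] / denominators[x_comp]
        y = row[y_comp.value] / denominators[y_comp]
        records.append({
            "genotype": genotype, "retina_id": retina_id,
            "x_component": x_comp.value, "y_component": y_comp.value,
            "x": x, "y": y,
            "deviation": (y - x) / np.sqrt(2.0),
        })
    points = pd.DataFrame(records)

    rng = np.random.default_rng(seed)
    summaries: list[dict] = []
    for genotype, group in points.groupby("genotype"):
        dev = group["deviation"].to_numpy()
        boots = np.array([
            rng.choice(dev, size=dev.size, replace=True).mean() for _ in range(n_boot)
        ]) if dev.size > 1 else np.full(n_boot, dev.mean())
        lo, hi = np.percentile(boots, [2.5, 97.5])
        summaries.append({
            "genotype": genotype,
            "x_component": x_comp.value, "y_component": y_comp.value,
            "n": dev.size,
            "mean_deviation": float(dev.mean()),
            "ci_low": float(lo), "ci_high": float(hi),
        })
    return points, pd.DataFrame(summaries)


def trajectory(fits: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM of R_max per genotype x age class x component.

    SEM is reported only for cells with n >= 2 (NaN otherwise).
    """
    rows: list[dict] = []
    for (genotype, age_class, component), cell in fits.groupby(
        ["genotype", "age_class", "component"]
    ):
        vals = cell["r_max"].to_numpy()
        rows.append({
            "genotype": genotype, "age_class": age_class, "component": component,
            "n": vals.size,
            "mean_r_max": float(vals.mean()),
            "sem_r_max": float(vals.std(ddof=1) / np.sqrt(vals.size))
            if vals.size >= 2 else float("nan"),
        })
    return pd.DataFrame(rows)
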