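"""Hill-type intensity-response fitting.

Component amplitude R as a function of flash intensity I is fit to

    R(I) = R_max * I^n / (I^n + K^n)

where R_max is the saturated response (uV), K the half-maximal intensity
(photons/um^2, reported downstream as Log K), and n the Hill slope.  The
fit is plain (unweighted) nonlinear least squares in the parameter vector
(R_max, log10 K, n), with data-driven initialisation and bounds that keep
flat or degenerate data from diverging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .core import ComponentKind, DegenerateFitError, ErgError
from .synthetic import hill_amplitude

__all__ = ["IntensityResponse", "HillFit", "fit_hill", "fit_pooled"]

#: Relative amplitude spread below which K is flagged non-identifiable
#: (an essentially flat / fully saturated series carries no information
#: about the half-maximal intensity).
_K_IDENTIFIABILITY_SPREAD = 0.05


@dataclass(frozen=True)
class IntensityResponse:
    """Per-retina (intensity, amplitude) pairs for one component."""

    retina_id: str
    component: ComponentKind
    intensities: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        i = np.asarray(self.intensities, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        if i.shape != a.shape or i.ndim != 1:
            raise ErgError("intensities and amplitudes must be matching 1-D arrays")
        if np.unique(i).size < 4:
            raise DegenerateFitError(
                f"need >= 4 distinct intensities to fit, got {np.unique(i).size}"
            )
        if np.any(i <= 0):
            raise ErgError("intensities must be positive")
        if np.any(a < 0):
            raise ErgError("amplitudes must be non-negative")
        object.__setattr__(self, "intensities", i)
        object.__setattr__(self, "amplitudes", a)


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters with diagnostics.

    ``converged`` is True only when the optimiser terminated within
    tolerance; ``k_identifiable`` is False when the data carry no
    information about K (flat amplitude series); ``degenerate`` marks the
    all-zero-amplitude null fit, whose parameters are NaN rather than
    arbitrary numbers.
    """

    r_max: float
    k: float
    n: float
    rss: float
    converged: bool
    k_identifiable: bool = True
    degenerate: bool = False
    covariance: np.ndarray | None = None
    n_points: int = 0

    @property
    def log10_k(self) -> float:
        return math.log10(self.k) if self.k > 0 else float("nan")

    def predict(self, intensity: float | np.ndarray) -> float | np.ndarray:
        if self.degenerate:
            return np.zeros_like(np.asarray(intensity, dtype=float))
        return hill_amplitude(intensity, self.r_max, self.k, self.n)


def _initial_k(intensities: np.ndarray, amplitudes: np.ndarray, r_max0: float) -> float:
    """Intensity at half of the provisional R_max by log-linear interpolation."""
    order = np.argsort(intensities)
    i_sorted = intensities[order]
    a_sorted = amplitudes[order]
    half = r_max0 / 2.0
    above = np.nonzero(a_sorted >= half)[0]
    if above.size == 0:
        return float(i_sorted[-1])
    j = above[0]
    if j == 0:
        return float(i_sorted[0])
    a0, a1 = a_sorted[j - 1], a_sorted[j]
    l0, l1 = math.log10(i_sorted[j - 1]), math.log10(i_sorted[j])
    frac = (half - a0) / (a1 - a0) if a1 > a0 else 0.5
    return float(10 ** (l0 + frac * (l1 - l0)))


def fit_hill(
    data: IntensityResponse,
    init: tuple[float, float, float] | None = None,
    bounds: tuple[Sequence[float], Sequence[float]] | None = None,
    *,
    fix_n: float | None = None,
) -> HillFit:
    """Least-squares Hill fit of one retina's intensity-response series.

    Parameters
    ----------
    init:
        Optional starting point ``(r_max, k, n)``.  Default: R_max0 = max
        amplitude, K0 = interpolated half-max intensity, n0 = 1.
    bounds:
        Optional ``(lower, upper)`` bounds on ``(r_max, k, n)``.  Default:
        R_max in (0, 10 x max amplitude], K in [min I / 10, max I x 10],
        n in (0, 10].
    fix_n:
        Fit with the Hill slope clamped to this value.

    An all-zero amplitude series returns a flagged null fit (NaN
    parameters, ``degenerate=True``) rather than arbitrary numbers.
    """
    i = data.intensities
    a = data.amplitudes
    a_max = float(a.max())
    if a_max == 0:
        return HillFit(
            r_max=0.0, k=float("nan"), n=float("nan"), rss=0.0,
            converged=False, k_identifiable=False, degenerate=True,
            n_points=i.size,
        )

    if init is None:
        r0, k0, n0 = a_max, _initial_k(i, a, a_max), 1.0
    else:
        r0, k0, n0 = init
    if bounds is None:
        lower = (1e-9 * a_max, i.min() / 10.0, 1e-3)
        upper = (10.0 * a_max, i.max() * 10.0, 10.0)
    else:
        lower, upper = bounds
    if fix_n is not None:
        n0 = fix_n

    # optimise in (r_max, log10 k, n); log-K keeps the problem well scaled
    x0 = np.array([
        np.clip(r0, lower[0], upper[0]),
        np.clip(math.log10(k0), math.log10(lower[1]), math.log10(upper[1])),
        np.clip(n0, lower[2], upper[2]),
    ])
    lo = np.array([lower[0], math.log10(lower[1]), lower[2]])
    hi = np.array([upper[0], math.log10(upper[1]), upper[2]])
    if fix_n is not None:
        lo[2] = hi[2] = fix_n
        x0[2] = fix_n
        # least_squares requires lb < ub; nudge by a relative epsilon
        hi[2] += max(abs(fix_n), 1.0) * 1e-12

    log_i = np.log10(i)

    def residuals(x: np.ndarray) -> np.ndarray:
        r_max, log_k, n = x
        # R = r_max / (1 + 10^(n (log K - log I))) is overflow-safe
        expo = np.clip(n * (log_k - log_i), -300, 300)
        return r_max / (1.0 + 10.0 ** expo) - a

    res = least_squares(
        residuals, x0, bounds=(lo, hi), method="trf",
        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000,
    )
    r_max, log_k, n = res.x
    rss = float(np.sum(res.fun ** 2))

    dof = i.size - (2 if fix_n is not None else 3)
    covariance = None
    if dof > 0:
        jtj = res.jac.T @ res.jac
        try:
            covariance = np.linalg.pinv(jtj) * (rss / dof)
        except np.linalg.LinAlgError:  # pragma: no cover - pinv rarely fails
            covariance = None

    spread = (a.max() - a.min()) / a_max
    return HillFit(
        r_max=float(r_max),
        k=float(10 ** log_k),
        n=float(n),
        rss=rss,
        converged=bool(res.success),
        k_identifiable=spread >= _K_IDENTIFIABILITY_SPREAD,
        covariance=covariance,
        n_points=int(i.size),
    )


def fit_pooled(
    collection: Iterable[IntensityResponse],
    *,
    fix_n: float | None = None,
) -> HillFit:
    """Single Hill fit on all retinas' points pooled (display statistic).

    Pooling collapses between-retina structure, so the pooled fit
    summarises the collated cloud and is not used for inference.
    """
    items = list(collection)
    if not items:
        raise ErgError("cannot pool an empty collection of intensity responses")
    components = {d.component for d in items}
    if len(components) != 1:
        raise ErgError(f"pooled fit mixes components: {sorted(c.name for c in components)}")
    pooled = IntensityResponse(
        retina_id="pooled",
        component=items[0].component,
        intensities=np.concatenate([d.intensities for d in items]),
        amplitudes=np.concatenate([d.amplitudes for d in items]),
    )
    return fit_hill(pooled, fix_n=fix_n)
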