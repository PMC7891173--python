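"""How fast each recursion approaches its asymptote.

The lag and gain recursions are linear recurrences with constant forcing,
so their transients decay geometrically at the modulus of the dominant
root of the homogeneous characteristic polynomial.  This module makes that
rate explicit: it matters in practice because a self-sufficient passive
tier (small q) can take far longer than a typical 20-year evaluation
window to reach the asymptotic regime, which makes the closed-form
predictors look biased even though they are exact in the limit.

Recursions that couple only same-parity years (lags 2 and 4) are analyzed
per parity chain (substitute y = x^2, one step = two years) and the root
modulus is converted to a per-year factor by square root, so all four
recursions are comparable on a per-year basis.  Gain recursions are posed
on the population-mean level and carry a structural unit root (the linear
growth mode), which is identified and excluded from the transient modulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .scenario import MatingSystem, ParameterError, ScenarioParams

__all__ = [
    "RecursionName",
    "RecursionSpec",
    "RootAnalysis",
    "ConvergenceReport",
    "recursion_spec",
    "characteristic_roots",
    "iterate_recursion",
    "years_to_converge",
]

_UNIT_ROOT_TOL = 1e-8


class RecursionName(str, Enum):
    LAG_UNCONTROLLED = "lag_uncontrolled"
    GAIN_UNCONTROLLED = "gain_uncontrolled"
    GAIN_CONTROLLED = "gain_controlled"
    LAG_CONTROLLED = "lag_controlled"


@dataclass(frozen=True)
class RecursionSpec:
    """One linear recurrence x_n = sum_k coefficients[k-1] x_{n-k} + forcing.

    ``step_unit`` is the number of calendar years per recurrence step (2 for
    the parity-chain recursions).  ``has_unit_root`` marks slope-type
    (level) recursions whose characteristic polynomial contains the
    structural root 1 generating linear growth.
    """

    name: RecursionName
    coefficients: tuple[float, ...]
    forcing: float
    step_unit: int
    has_unit_root: bool


def recursion_spec(name: RecursionName | str, params: ScenarioParams) -> RecursionSpec:
    """Coefficients of the named recursion at the scenario's (p, q, S1, S2).

    * ``lag_uncontrolled``: D_t = (1-q)/2 D_{t-2} + S1/2
    * ``gain_uncontrolled``: level chain B_t = 1/2 B_{t-2} + 1/2 B_{t-4}
      + (p+q)/(1+q) S1 (valid once the lag has settled)
    * ``gain_controlled``: level B_t = 1/2 B_{t-2} + 1/2 B_{t-3} + (S1+S2)/2
    * ``lag_controlled``: D_t = (1-q)/2 D_{t-2} + (1-p)(1-q)/2 D_{t-4}
      + (6-5p)/10 S1 + 3/5 S2
    """
    name = RecursionName(name)
    p, q, s1 = params.p, params.q, params.s1
    if name is RecursionName.LAG_UNCONTROLLED:
        return RecursionSpec(name, ((1.0 - q) / 2.0,), s1 / 2.0, 2, False)
    if name is RecursionName.GAIN_UNCONTROLLED:
        return RecursionSpec(
            name, (0.5, 0.5), (p + q) / (1.0 + q) * s1, 2, True
        )
    if name is RecursionName.GAIN_CONTROLLED:
        _require_s2(params)
        return RecursionSpec(
            name, (0.0, 0.5, 0.5), (s1 + params.s2) / 2.0, 1, True
        )
    if name is RecursionName.LAG_CONTROLLED:
        _require_s2(params)
        forcing = (6.0 - 5.0 * p) / 10.0 * s1 + 0.6 * params.s2
        return RecursionSpec(
            name,
            ((1.0 - q) / 2.0, (1.0 - p) * (1.0 - q) / 2.0),
            forcing,
            2,
            False,
        )
    raise ParameterError(f"unknown recursion {name!r}")  # pragma: no cover


def _require_s2(params: ScenarioParams) -> None:
    if params.s2 is None:
        raise ParameterError("controlled recursions require s2")


@dataclass(frozen=True)
class RootAnalysis:
    """Characteristic roots of a recursion's homogeneous part.

    ``roots`` is the full root set (per recurrence step).  The structural
    unit root, when present, is excluded from ``dominant_transient``, whose
    modulus is also reported per calendar year for cross-recursion
    comparison.
    """

    roots: tuple[complex, ...]
    structural_root: complex | None
    dominant_transient_modulus: float
    per_year_modulus: float


def characteristic_roots(spec: RecursionSpec) -> RootAnalysis:
    """Roots of x^K - c1 x^{K-1} - ... - cK via the companion matrix."""
    coeffs = np.asarray(spec.coefficients, dtype=float)
    poly = np.concatenate(([1.0], -coeffs))
    roots = np.roots(poly) if len(poly) > 1 else np.array([], dtype=complex)
    roots = tuple(sorted(roots, key=lambda r: (-abs(r), r.real, r.imag)))

    structural = None
    transient = list(roots)
    if spec.has_unit_root:
        candidates = [r for r in transient if abs(r - 1.0) < _UNIT_ROOT_TOL]
        if not candidates:  # pragma: no cover - specs always carry the root
            raise ParameterError(
                f"{spec.name.value}: expected a structural unit root"
            )
        structural = candidates[0]
        transient.remove(structural)

    if len(coeffs) == 0 or np.all(coeffs == 0.0):
        # e.g. the lag recursion at q=1: the state is forgotten in one step
        dom = 0.0
    else:
        dom = max((abs(r) for r in transient), default=0.0)
    return RootAnalysis(
        roots=roots,
        structural_root=structural,
        dominant_transient_modulus=dom,
        per_year_modulus=dom ** (1.0 / spec.step_unit) if dom > 0 else 0.0,
    )


def iterate_recursion(
    spec: RecursionSpec, n_steps: int, init: tuple[float, ...] | None = None
) -> np.ndarray:
    """Forward-iterate the recurrence from (default zero) initial values."""
    k = len(spec.coefficients)
    init = init if init is not None else (0.0,) * k
    if len(init) != k:
        raise ParameterError(f"init must supply {k} lagged values")
    out = np.empty(n_steps + k)
    out[:k] = init
    c = np.asarray(spec.coefficients)[::-1]
    for n in range(k, n_steps + k):
        out[n] = float(np.dot(c, out[n - k:n])) + spec.forcing
    return out[k:]


@dataclass(frozen=True)
class ConvergenceReport:
    """Analytic and empirical convergence of one recursion.

    ``asymptote`` is the fixed point (lag recursions) or the per-year slope
    (gain recursions).  ``years_to_eps`` is the first calendar year at which
    the iterated quantity is within ``eps`` of the asymptote, ``inf`` when
    the recursion does not contract.  ``empirical_rate_per_year`` is the
    geometric decay rate fitted to the late-time distance sequence (None
    when the transient dies out too fast to fit).
    """

    name: RecursionName
    asymptote: float
    dominant_root_modulus: float
    years_to_eps: float
    empirical_rate_per_year: float | None
    roots: tuple[complex, ...]


def years_to_converge(
    params: ScenarioParams,
    eps: float = 1e-6,
    recursion: RecursionName | str | None = None,
    max_years: int = 10_000,
) -> ConvergenceReport:
    """Iterate the relevant recursion from zero and time its convergence.

    ``recursion`` defaults to the lag recursion of the scenario's mating
    system (the quantity whose slow convergence explains the small-q
    prediction misfit over short horizons).
    """
    if eps <= 0:
        raise ParameterError("eps must be > 0")
    if recursion is None:
        recursion = (
            RecursionName.LAG_CONTROLLED
            if params.mating_system is MatingSystem.CONTROLLED
            else RecursionName.LAG_UNCONTROLLED
        )
    name = RecursionName(recursion)
    spec = recursion_spec(name, params)
    analysis = characteristic_roots(spec)

    n_steps = max(8, max_years // spec.step_unit)
    values = iterate_recursion(spec, n_steps)

    if spec.has_unit_root:
        # slope recursion: the asymptote is the per-year gain
        weights = sum((k + 1) * c for k, c in enumerate(spec.coefficients))
        slope_per_step = spec.forcing / weights if weights > 0 else math.inf
        asymptote = slope_per_step / spec.step_unit
        quantity = np.diff(values) / spec.step_unit
    else:
        csum = sum(spec.coefficients)
        asymptote = spec.forcing / (1.0 - csum) if csum < 1.0 else math.inf
        quantity = values

    if not math.isfinite(asymptote) or analysis.dominant_transient_modulus >= 1.0:
        return ConvergenceReport(
            name=name,
            asymptote=asymptote,
            dominant_root_modulus=analysis.per_year_modulus,
            years_to_eps=math.inf,
            empirical_rate_per_year=None,
            roots=analysis.roots,
        )

    dist = np.abs(quantity - asymptote)
    hit = np.nonzero(dist < eps)[0]
    years_to_eps = (
        float((hit[0] + 1) * spec.step_unit) if hit.size else math.inf
    )

    empirical = _fit_geometric_rate(dist, spec.step_unit)
    return ConvergenceReport(
        name=name,
        asymptote=asymptote,
        dominant_root_modulus=analysis.per_year_modulus,
        years_to_eps=years_to_eps,
        empirical_rate_per_year=empirical,
        roots=analysis.roots,
    )


def _fit_geometric_rate(dist: np.ndarray, step_unit: int) -> float | None:
    """Per-year decay rate from a log-linear fit over usable late steps."""
    usable = np.nonzero((dist > 1e-13) & (dist < np.inf))[0]
    if usable.size < 6:
        return None
    # fit over the late half of the usable range to skip early transients
    idx = usable[usable >= usable[usable.size // 2]]
    if idx.size < 4:
        return None
    slope = np.polyfit(idx.astype(float), np.log(dist[idx]), 1)[0]
    return float(np.exp(slope / step_unit))
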