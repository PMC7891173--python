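"""Year-by-year gene-flow recursions for the two-tier honeybee population.

Colonies are indexed by the birth/mating year of their queen.  A colony's
worker group receives half its breeding value from the queen and half from
the drones she mated with, which yields linear recursions in the yearly mean
true breeding values B_t (breeding tier) and P_t (passive tier):

uncontrolled mating (constant parameters)::

    B_t = 1/2 B_{t-2} + (p+q-pq)/2 B_{t-4} + (1-p)(1-q)/2 P_{t-4}
          + (1+p)/2 S1
    P_t = q/2 B_{t-2} + (p+q-pq)/2 B_{t-4} + (1-q)/2 P_{t-2}
          + (1-p)(1-q)/2 P_{t-4} + p/2 S1

controlled mating (stations, paternal path three years deep)::

    B_t = 1/2 B_{t-2} + 1/2 B_{t-3} + (S1 + S2)/2

with the passive tier unchanged: passive queens always mate freely, so
controlled mating on the breeding side never alters their recursion.

Time-varying parameters are supported through the ungrouped forms, where
drone dams are unselected queens of year t-2 carrying p_t, q_{t-2},
S1_{t-2} and S1_{t-4} at the years the inheritance paths dictate.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .scenario import (
    InitialState,
    InsufficientHistoryError,
    MatingSystem,
    ParameterError,
    ScenarioParams,
    Trajectory,
)

__all__ = [
    "History",
    "step_breeding_uncontrolled",
    "step_passive",
    "step_breeding_controlled",
    "iterate",
]


class History:
    """Lagged mean breeding values, keyed by year."""

    def __init__(self, b: Mapping[int, float], p: Mapping[int, float]):
        self._b = dict(b)
        self._p = dict(p)

    def B(self, t: int) -> float:
        try:
            return self._b[t]
        except KeyError:
            raise InsufficientHistoryError(
                f"insufficient history: B_{{{t}}} is not available"
            ) from None

    def P(self, t: int) -> float:
        try:
            return self._p[t]
        except KeyError:
            raise InsufficientHistoryError(
                f"insufficient history: P_{{{t}}} is not available"
            ) from None

    def set(self, t: int, b: float, p: float) -> None:
        self._b[t] = b
        self._p[t] = p


def step_breeding_uncontrolled(
    history: History, params: ScenarioParams, t: int
) -> float:
    """Mean breeding-colony value B_t under free mating.

    Constant parameters use the grouped form; time-varying parameters use
    the ungrouped form with p_t, q_{t-2}, S1_{t-2}, S1_{t-4}.  The two
    coincide when the series are constant.
    """
    if params.is_time_varying:
        b2, b4, p4 = history.B(t - 2), history.B(t - 4), history.P(t - 4)
        pt = params.p_at(t)
        q2 = params.q_at(t - 2)
        return (
            (b2 + params.s1_at(t - 2)) / 2.0
            + pt * (b4 + params.s1_at(t - 4)) / 2.0
            + (1.0 - pt) * (q2 * b4 + (1.0 - q2) * p4) / 2.0
        )
    p, q, s1 = params.p, params.q, params.s1
    return (
        0.5 * history.B(t - 2)
        + (p + q - p * q) / 2.0 * history.B(t - 4)
        + (1.0 - p) * (1.0 - q) / 2.0 * history.P(t - 4)
        + (1.0 + p) / 2.0 * s1
    )


def step_passive(history: History, params: ScenarioParams, t: int) -> float:
    """Mean passive-colony value P_t (same for both mating systems)."""
    if params.is_time_varying:
        b2, b4 = history.B(t - 2), history.B(t - 4)
        p2, p4 = history.P(t - 2), history.P(t - 4)
        pt = params.p_at(t)
        qt = params.q_at(t)
        q2 = params.q_at(t - 2)
        return (
            (qt * b2 + (1.0 - qt) * p2) / 2.0
            + pt * (b4 + params.s1_at(t - 4)) / 2.0
            + (1.0 - pt) * (q2 * b4 + (1.0 - q2) * p4) / 2.0
        )
    p, q, s1 = params.p, params.q, params.s1
    return (
        q / 2.0 * history.B(t - 2)
        + (p + q - p * q) / 2.0 * history.B(t - 4)
        + (1.0 - q) / 2.0 * history.P(t - 2)
        + (1.0 - p) * (1.0 - q) / 2.0 * history.P(t - 4)
        + p / 2.0 * s1
    )


def step_breeding_controlled(
    history: History, params: ScenarioParams, t: int
) -> float:
    """Mean breeding-colony value B_t under station mating.

    Independent of the passive tier: half from the dam colony (two-year
    maternal interval, differential S1), half from station drones whose
    common granddam is a selected colony three years back (differential S2).
    """
    if params.s2 is None and params.s2_series is None:
        raise ParameterError("controlled mating requires s2")
    s1 = params.s1_at(t - 2)
    s2 = params.s2_at(t - 3)
    return 0.5 * history.B(t - 2) + 0.5 * history.B(t - 3) + (s1 + s2) / 2.0


def iterate(
    params: ScenarioParams,
    n_years: int,
    init: InitialState | None = None,
    tol: float = 1e-9,
) -> Trajectory:
    """Run the recursions forward for ``n_years`` and derive gains and lags.

    The breeding step follows the scenario's mating system; the passive step
    is always the free-mating one.  Convergence is reported as the first
    year where both ``|dB_t - dB_{t-2}|`` and ``|D_t - D_{t-2}|`` fall
    below ``tol``; both are compared two years apart because the
    free-mating recursions couple only same-parity years, so successive
    one-year differences cycle with period two even at the asymptote.
    """
    if n_years < 1:
        raise ParameterError("n_years must be >= 1")
    init = init or InitialState()
    depth = init.depth
    pre_years = range(1 - depth, 1)
    hist = History(
        {t: b for t, b in zip(pre_years, init.b_history)},
        {t: p for t, p in zip(pre_years, init.p_history)},
    )

    breeding_step = (
        step_breeding_controlled
        if params.mating_system is MatingSystem.CONTROLLED
        else step_breeding_uncontrolled
    )

    years = np.arange(1, n_years + 1)
    B = np.empty(n_years)
    P = np.empty(n_years)
    for t in years:
        b_t = breeding_step(hist, params, int(t))
        p_t = step_passive(hist, params, int(t))
        hist.set(int(t), b_t, p_t)
        B[t - 1] = b_t
        P[t - 1] = p_t

    b_prev = np.concatenate(([init.b_history[-1]], B[:-1]))
    p_prev = np.concatenate(([init.p_history[-1]], P[:-1]))
    dB = B - b_prev
    dP = P - p_prev
    D = B - P

    # transients can pass through flat spots, so require the settling
    # condition to hold over a short run of consecutive years
    converged_year = None
    run_needed, run = 4, 0
    for idx in range(3, n_years):
        gain_settled = abs(dB[idx] - dB[idx - 2]) < tol
        lag_settled = abs(D[idx] - D[idx - 2]) < tol
        run = run + 1 if (gain_settled and lag_settled) else 0
        if run >= run_needed:
            converged_year = int(years[idx - run_needed + 1])
            break

    return Trajectory(
        years=years, B=B, P=P, dB=dB, dP=dP, D=D,
        converged_year=converged_year,
    )
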