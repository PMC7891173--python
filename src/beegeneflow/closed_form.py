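"""Closed-form asymptotic predictors of gain, genetic lag and time lag.

For large t the gene-flow recursions settle onto linear growth with a
constant gap between the tiers.  The asymptotes, as functions of the drone
probability p, the passive-dam proportion q and the selection differentials
S1 (maternal path) and S2 (paternal/DPQ path), are

==============  ==========================  ============================
quantity        uncontrolled mating         controlled mating
==============  ==========================  ============================
annual gain     (p+q)/(3+3q) * S1           (S1+S2)/5
genetic lag D   S1/(1+q)                    6/(p+2q-pq)*(S1+S2)/5
                                              - p/(p+2q-pq)*S1
time lag T      3/(p+q)                     D / gain
==============  ==========================  ============================

Both tiers share the same asymptotic gain (parallel genetic progress).
Degenerate denominators (p+q = 0 uncontrolled, p+2q-pq = 0 controlled)
mean the passive tier never catches a moving target; the corresponding
quantity is reported as ``inf`` and flagged divergent rather than raised,
so parameter sweeps over the whole unit square complete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .scenario import MatingSystem, ParameterError, ScenarioParams

__all__ = [
    "AsymptoticPrediction",
    "SelectionParams",
    "predict_uncontrolled",
    "predict_controlled",
    "predict",
    "selection_differential",
    "time_lag",
]


@dataclass(frozen=True)
class AsymptoticPrediction:
    """The four long-run quantities for one scenario.

    ``dB``/``dP`` are the asymptotic annual gains of the breeding and
    passive tiers (always equal), ``D`` the genetic lag in breeding-value
    units and ``T`` the time lag in years.  ``divergent`` names the fields
    reported as ``inf`` because of a zero gene-flow denominator.
    """

    dB: float
    dP: float
    D: float
    T: float
    divergent: tuple[str, ...] = field(default=())

    def to_dict(self) -> dict:
        def enc(x: float):
            return None if math.isinf(x) else x

        return {
            "dB": enc(self.dB),
            "dP": enc(self.dP),
            "D": enc(self.D),
            "T": enc(self.T),
            "divergent": list(self.divergent),
        }


@dataclass(frozen=True)
class SelectionParams:
    """Inputs of the selection-differential predictor S = i * rho * sigma.

    ``i`` is the standardized selection intensity, ``rho`` the accuracy of
    breeding-value estimation and ``sigma`` the standard deviation of colony
    true breeding values.  Note sigma is the colony-level SD, which in
    general differs from the additive-genetic SD because queen and worker
    group variances are structured differently and selection erodes
    variance; it is therefore taken as an input.
    """

    i: float
    rho: float
    sigma: float

    def __post_init__(self) -> None:
        if self.i < 0:
            raise ParameterError(f"selection intensity i must be >= 0, got {self.i!r}")
        if not (0.0 <= self.rho <= 1.0):
            raise ParameterError(f"accuracy rho must lie in [0, 1], got {self.rho!r}")
        if self.sigma < 0:
            raise ParameterError(f"sigma must be >= 0, got {self.sigma!r}")


def time_lag(D: float, dB: float) -> float:
    """Years the passive tier trails the breeding tier: T = D / dB.

    Zero gain with a positive lag means the gap is never closed (``inf``);
    zero lag is zero time lag regardless of the gain.
    """
    if D == 0.0:
        return 0.0
    if dB == 0.0 or math.isinf(D):
        return math.inf
    return D / dB


def predict_uncontrolled(p: float, q: float, s1: float) -> AsymptoticPrediction:
    """Asymptotic gain, lag and time lag under free mating."""
    _validate_pq(p, q)
    gain = (p + q) / (3.0 + 3.0 * q) * s1
    lag = s1 / (1.0 + q)
    divergent: tuple[str, ...] = ()
    if p + q == 0.0:
        t = 0.0 if lag == 0.0 else math.inf
        if lag != 0.0:
            divergent = ("T",)
    else:
        t = 3.0 / (p + q)
    return AsymptoticPrediction(dB=gain, dP=gain, D=lag, T=t, divergent=divergent)


def predict_controlled(
    p: float, q: float, s1: float, s2: float
) -> AsymptoticPrediction:
    """Asymptotic gain, lag and time lag under station mating.

    The breeding-tier gain (S1+S2)/5 is the Rendel-Robertson ratio: summed
    selection differentials over summed generation intervals (2 y maternal +
    3 y paternal).  The lag denominator p+2q-pq vanishes only at p=q=0,
    where the self-sufficient passive tier falls behind without bound.
    """
    _validate_pq(p, q)
    gain = (s1 + s2) / 5.0
    denom = p + 2.0 * q - p * q
    divergent: tuple[str, ...] = ()
    if denom == 0.0:
        numerator = 6.0 * gain - p * s1  # forcing of the lag recursion
        if numerator == 0.0:
            lag = 0.0
        else:
            lag = math.inf
            divergent = ("D", "T")
    else:
        lag = 6.0 / denom * gain - p / denom * s1
    t = time_lag(lag, gain)
    if math.isinf(t) and "T" not in divergent:
        divergent = divergent + ("T",)
    return AsymptoticPrediction(dB=gain, dP=gain, D=lag, T=t, divergent=divergent)


def predict(params: ScenarioParams) -> AsymptoticPrediction:
    """Dispatch on the scenario's mating system."""
    if params.mating_system is MatingSystem.CONTROLLED:
        assert params.s2 is not None
        return predict_controlled(params.p, params.q, params.s1, params.s2)
    return predict_uncontrolled(params.p, params.q, params.s1)


def selection_differential(sel: SelectionParams) -> float:
    """Expected genetic selection differential S = i * rho * sigma."""
    return sel.i * sel.rho * sel.sigma


def _validate_pq(p: float, q: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ParameterError(f"p must lie in [0, 1], got {p!r}")
    if not (0.0 <= q <= 1.0):
        raise ParameterError(f"q must lie in [0, 1], got {q!r}")
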