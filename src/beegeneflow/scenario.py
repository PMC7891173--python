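"""Parameter sets and per-year trajectories for the two-tier honeybee model.

The population is split into a *breeding* tier under truncation selection and
an unselected *passive* tier that benefits from gene flow.  Two parameters
govern the exchange: ``p``, the probability that a drone in a free mating has
a dam from a breeding colony, and ``q``, the proportion of passive queens
whose dam is a breeding queen.  ``s1`` and ``s2`` are the genetic selection
differentials (in breeding-value units) for breeding-queen and
drone-producing-queen (DPQ) production, respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd


class MatingSystem(str, Enum):
    """How breeding queens mate: in free flight or on isolated stations."""

    UNCONTROLLED = "uncontrolled"
    CONTROLLED = "controlled"


class ParameterError(ValueError):
    """A scenario or simulation parameter is out of its valid range."""


class InsufficientHistoryError(KeyError):
    """A recursion step asked for a lagged year the history does not hold."""


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ParameterError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class ScenarioParams:
    """Deterministic-model parameters for one breeding scenario.

    Parameters
    ----------
    mating_system
        ``uncontrolled`` (free aerial mating) or ``controlled`` (isolated
        mating stations).
    p
        Probability that a sire drone in a free mating comes from a breeding
        colony.  Also used for the passive tier under controlled mating,
        because passive queens always mate freely.
    q
        Proportion of passive queens with a dam from the breeding population.
    s1, s2
        Genetic selection differentials for breeding-queen production (s1)
        and for DPQ production (s2, controlled mating only).
    p_series, q_series, s1_series, s2_series
        Optional year-indexed overrides enabling the time-varying recursions.
        When given they must cover every year the recursion touches.
    """

    mating_system: MatingSystem
    p: float
    q: float
    s1: float
    s2: float | None = None
    p_series: Mapping[int, float] | None = None
    q_series: Mapping[int, float] | None = None
    s1_series: Mapping[int, float] | None = None
    s2_series: Mapping[int, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "mating_system", MatingSystem(self.mating_system)
        )
        _check_prob("p", self.p)
        _check_prob("q", self.q)
        if not np.isfinite(self.s1):
            raise ParameterError(f"s1 must be finite, got {self.s1!r}")
        if self.mating_system is MatingSystem.CONTROLLED:
            if self.s2 is None:
                raise ParameterError(
                    "s2 is required for controlled mating (paternal "
                    "selection differential of the DPQ path)"
                )
            if not np.isfinite(self.s2):
                raise ParameterError(f"s2 must be finite, got {self.s2!r}")
        elif self.s2 is not None:
            raise ParameterError(
                "s2 is only meaningful under controlled mating"
            )
        if self.p_series is not None:
            for t, v in self.p_series.items():
                _check_prob(f"p_series[{t}]", v)
        if self.q_series is not None:
            for t, v in self.q_series.items():
                _check_prob(f"q_series[{t}]", v)

    # -- year-indexed accessors -------------------------------------------
    def _at(self, series: Mapping[int, float] | None, const: float | None,
            t: int, name: str) -> float:
        if series is not None:
            try:
                return series[t]
            except KeyError:
                raise ParameterError(
                    f"time-varying {name} has no value for year {t}"
                ) from None
        assert const is not None
        return const

    def p_at(self, t: int) -> float:
        return self._at(self.p_series, self.p, t, "p")

    def q_at(self, t: int) -> float:
        return self._at(self.q_series, self.q, t, "q")

    def s1_at(self, t: int) -> float:
        return self._at(self.s1_series, self.s1, t, "s1")

    def s2_at(self, t: int) -> float:
        return self._at(self.s2_series, self.s2, t, "s2")

    @property
    def is_time_varying(self) -> bool:
        return any(
            s is not None
            for s in (self.p_series, self.q_series,
                      self.s1_series, self.s2_series)
        )


@dataclass(frozen=True)
class InitialState:
    """Pre-start history of mean breeding values.

    ``b_history``/``p_history`` hold the breeding- and passive-tier means for
    the years immediately before year 1, oldest first, so
    ``b_history[-1]`` is year 0.  At least five lagged years are required so
    that the deepest recursion term (four years back, needed at year 1) is
    always defined.  The default is an unselected base population at level 0.
    """

    b_history: tuple[float, ...] = (0.0,) * 5
    p_history: tuple[float, ...] = (0.0,) * 5

    def __post_init__(self) -> None:
        if len(self.b_history) < 5 or len(self.p_history) < 5:
            raise ParameterError(
                "InitialState needs at least 5 pre-start years for B and P"
            )
        if len(self.b_history) != len(self.p_history):
            raise ParameterError("b_history and p_history differ in length")

    @property
    def depth(self) -> int:
        return len(self.b_history)


@dataclass(frozen=True)
class Trajectory:
    """Per-year series of population means and derived gains and lags.

    ``B``/``P`` are mean true breeding values of breeding/passive colonies,
    ``dB``/``dP`` the annual gains, and ``D = B - P`` the genetic lag.
    ``converged_year`` is the first year at which both the annual gain and
    the (parity-matched) lag have settled to within ``tol``.
    """

    years: np.ndarray
    B: np.ndarray
    P: np.ndarray
    dB: np.ndarray
    dP: np.ndarray
    D: np.ndarray
    converged_year: int | None = None

    def annual_gain(self, tier: str = "B") -> np.ndarray:
        """Parity-averaged annual gain (X_t - X_{t-2}) / 2.

        The free-mating recursions couple only years of equal parity, so
        from an aligned (all-zero) start the exact one-year difference
        settles into a two-year cycle around the asymptotic gain.  The
        two-year average is the quantity that converges to the asymptote
        and is therefore what should be read off a trajectory.  Defined
        from year 3 onward (first two entries are NaN).
        """
        x = {"B": self.B, "P": self.P}[tier]
        out = np.full_like(x, np.nan)
        out[2:] = (x[2:] - x[:-2]) / 2.0
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "B": self.B,
                "P": self.P,
                "dB": self.dB,
                "dP": self.dP,
                "D": self.D,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
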