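"""Individual-based stochastic simulator of a honeybee breeding program.

The simulated population mirrors the two-tier structure of the analytic
model: ``n_b`` breeding colonies and ``n_p`` passive colonies per year.
Each colony is a queen plus the mean of the drones she mated with; the
colony true breeding value (the worker group's value) is half queen, half
drone mean.  Breeding queens are daughters of truncation-selected colonies
two years back.  Under free mating every queen mates with
``drones_per_mating`` drones whose dams are breeding colonies with
probability p (default n_b/(n_b+n_p)) and whose ages are uniform on 1-3
years.  Under controlled mating, breeding queens instead mate on one of
``n_stations`` isolated stations, each holding a sister group of
drone-producing queens (DPQs) descended from one selected colony three
years back; passive reproduction is untouched by the mating system.

Selection uses an index of stated accuracy rho (true value plus scaled
noise) in place of a BLUP evaluation: the realized selection differentials
are measured, not assumed, so the validated predictions are
self-calibrating with respect to this choice.  Inheritance follows the
infinitesimal model; a daughter (or drone) deviates from her dam colony
(his dam queen) by a Mendelian-sampling draw with SD sigma_A/sqrt(2) per
component.  Genetics are either a single aggregate value or a
maternal+direct pair with heritabilities h2_m, h2_d and correlation r_md.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .scenario import MatingSystem, ParameterError

__all__ = [
    "SimConfig",
    "Cohort",
    "SimState",
    "genetic_covariance",
    "initialize",
    "select",
    "breed_year_uncontrolled",
    "breed_year_controlled",
    "run_replicate",
    "run",
]

logger = logging.getLogger(__name__)

_SUBPOPS = ("breeding", "passive")
_DAM_AGES = (1, 2, 3)  # free-mating dam ages, uniform (average two years)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated breeding program.

    ``dam_fraction`` is the selected proportion of breeding colonies used
    for queen replacement (each selected colony contributes an equal share
    of daughters).  ``rho`` is the accuracy of the selection index.  In
    ``maternal_direct`` mode the trait has a maternal (queen) and a direct
    (worker) component with heritabilities ``h2_m``/``h2_d`` and effect
    correlation ``r_md``, scaled so the total additive SD is ``sigma_a``.
    """

    n_b: int
    n_p: int
    mating_system: MatingSystem = MatingSystem.UNCONTROLLED
    q: float = 0.0
    p: float | None = None
    n_stations: int | None = None
    dpqs_per_station: int = 8
    drones_per_mating: int = 12
    years: int = 20
    sigma_a: float = 1.0
    rho: float = 0.8
    dam_fraction: float = 0.2
    genetics_mode: str = "aggregate"
    h2_m: float = 0.53
    h2_d: float = 0.34
    r_md: float = -0.53
    seed: int = 0
    replicates: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "mating_system", MatingSystem(self.mating_system)
        )
        if self.n_b < 1 or self.n_p < 1:
            raise ParameterError("n_b and n_p must be >= 1")
        if not (0.0 <= self.q <= 1.0):
            raise ParameterError(f"q must lie in [0, 1], got {self.q!r}")
        if self.p is not None and not (0.0 <= self.p <= 1.0):
            raise ParameterError(f"p must lie in [0, 1], got {self.p!r}")
        if not (1 <= self.drones_per_mating <= 20):
            raise ParameterError("drones_per_mating must lie in [1, 20]")
        if self.dpqs_per_station < 1:
            raise ParameterError("dpqs_per_station must be >= 1")
        if not (0.0 <= self.rho <= 1.0):
            raise ParameterError(f"rho must lie in [0, 1], got {self.rho!r}")
        if not (0.0 < self.dam_fraction <= 1.0):
            raise ParameterError("dam_fraction must lie in (0, 1]")
        if self.genetics_mode not in ("aggregate", "maternal_direct"):
            raise ParameterError(
                f"unknown genetics_mode {self.genetics_mode!r}"
            )
        if abs(self.r_md) > 1.0:
            raise ParameterError(f"r_md must lie in [-1, 1], got {self.r_md!r}")
        if self.mating_system is MatingSystem.CONTROLLED:
            if self.n_stations is None or self.n_stations < 1:
                raise ParameterError(
                    "controlled mating requires n_stations >= 1"
                )
            if self.n_stations > self.n_b:
                raise ParameterError("n_stations cannot exceed n_b")
        if self.years < 1:
            raise ParameterError("years must be >= 1")
        if self.replicates < 1:
            raise ParameterError("replicates must be >= 1")

    @property
    def p_effective(self) -> float:
        """Drone-origin probability: explicit p, else n_b/(n_b+n_p)."""
        if self.p is not None:
            return self.p
        return self.n_b / (self.n_b + self.n_p)

    @property
    def n_components(self) -> int:
        return 2 if self.genetics_mode == "maternal_direct" else 1

    @property
    def n_dams(self) -> int:
        return max(1, round(self.dam_fraction * self.n_b))


def genetic_covariance(config: SimConfig) -> np.ndarray:
    """Genetic covariance matrix of the breeding-value components.

    Aggregate mode: the 1x1 matrix [[sigma_a^2]].  Maternal/direct mode:
    component variances proportional to h2_m and h2_d with correlation
    r_md, rescaled so the variance of the total (sum) equals sigma_a^2.
    """
    if config.n_components == 1:
        return np.array([[config.sigma_a**2]])
    vm, vd = config.h2_m, config.h2_d
    cov = config.r_md * np.sqrt(vm * vd)
    total = vm + vd + 2.0 * cov
    if total <= 0:
        raise ParameterError(
            "h2_m, h2_d, r_md imply a non-positive total variance"
        )
    scale = config.sigma_a**2 / total
    return scale * np.array([[vm, cov], [cov, vd]])


@dataclass
class Cohort:
    """One year's colonies of one subpopulation.

    Arrays have shape (n, c) with c genetic components.  ``sire_bv`` is the
    mean breeding value of the drones each queen mated with, so
    ``colony_bv = (queen_bv + sire_bv) / 2`` by construction.  ``s1``/``s2``
    are the realized selection differentials (per component) once the cohort
    has been selected for queen or DPQ production, with the selected-group
    means in ``b1_mean``/``b2_mean``.
    """

    queen_bv: np.ndarray
    sire_bv: np.ndarray
    colony_bv: np.ndarray = field(init=False)
    s1: np.ndarray | None = None
    s2: np.ndarray | None = None
    b1_mean: np.ndarray | None = None
    b2_mean: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.colony_bv = 0.5 * (self.queen_bv + self.sire_bv)

    @property
    def n(self) -> int:
        return self.queen_bv.shape[0]


@dataclass
class SimState:
    """Evolving population: cohorts keyed by (subpopulation, year)."""

    config: SimConfig
    cohorts: dict[tuple[str, int], Cohort]
    chol: np.ndarray  # Cholesky factor of the genetic covariance

    def cohort(self, subpop: str, year: int) -> Cohort:
        try:
            return self.cohorts[(subpop, year)]
        except KeyError:
            raise ParameterError(
                f"missing cohort: {subpop} colonies of year {year}"
            ) from None


def _normal(rng: np.random.Generator, n: int, chol: np.ndarray,
            scale: float = 1.0) -> np.ndarray:
    """n draws from N(0, scale^2 * L L^T), shape (n, c)."""
    z = rng.standard_normal((n, chol.shape[0]))
    return scale * (z @ chol.T)


def _mendelian(rng: np.random.Generator, n: int, chol: np.ndarray) -> np.ndarray:
    """Mendelian-sampling deviations: N(0, G/2), i.e. SD sigma/sqrt(2)."""
    return _normal(rng, n, chol, scale=1.0 / np.sqrt(2.0))


def initialize(config: SimConfig, rng: np.random.Generator) -> SimState:
    """Unselected base population for pre-start years -3..0.

    Queens are drawn from N(0, G); colonies are assembled by random mating
    with drones drawn from the same base distribution.
    """
    chol = np.linalg.cholesky(genetic_covariance(config))
    cohorts: dict[tuple[str, int], Cohort] = {}
    sizes = {"breeding": config.n_b, "passive": config.n_p}
    for subpop in _SUBPOPS:
        n = sizes[subpop]
        for year in range(-3, 1):
            queens = _normal(rng, n, chol)
            drones = _normal(rng, n * config.drones_per_mating, chol)
            sire = drones.reshape(n, config.drones_per_mating, -1).mean(axis=1)
            cohorts[(subpop, year)] = Cohort(queen_bv=queens, sire_bv=sire)
    return SimState(config=config, cohorts=cohorts, chol=chol)


def select(
    cohort: Cohort,
    n_select: int,
    rho: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Truncation selection on an accuracy-``rho`` index of the colony value.

    The index is ``rho * total + sqrt(1 - rho^2) * sd(total) * noise``; at
    rho=1 this is selection on the true total breeding value, at rho=0 it
    is random choice.  Returns ``(indices, selected_mean, differential)``
    where the last two are per-component (the differential is the selected
    mean minus the cohort mean, measured on true values).
    """
    if cohort.n == 0:
        raise ParameterError("cannot select from an empty cohort")
    if n_select > cohort.n:
        raise ParameterError(
            f"n_select={n_select} exceeds cohort size {cohort.n}"
        )
    total = cohort.colony_bv.sum(axis=1)
    sd = float(total.std())
    index = rho * total + np.sqrt(1.0 - rho**2) * sd * rng.standard_normal(
        cohort.n
    )
    idx = np.argpartition(-index, n_select - 1)[:n_select]
    sel_mean = cohort.colony_bv[idx].mean(axis=0)
    diff = sel_mean - cohort.colony_bv.mean(axis=0)
    return idx, sel_mean, diff


def _free_mating_sires(
    state: SimState, t: int, n_queens: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean drone breeding value per queen under free mating, shape (n, c).

    Each drone's dam is a breeding queen with probability p and a passive
    queen otherwise, of age uniform on {1, 2, 3}; a drone carries his dam
    queen's value plus a Mendelian deviation.
    """
    cfg = state.config
    m = cfg.drones_per_mating
    total = n_queens * m
    from_breeding = rng.random(total) < cfg.p_effective
    ages = rng.integers(1, 4, size=total)
    drones = np.empty((total, cfg.n_components))
    for subpop, mask_pop in (("breeding", from_breeding),
                             ("passive", ~from_breeding)):
        for age in _DAM_AGES:
            mask = mask_pop & (ages == age)
            k = int(mask.sum())
            if k == 0:
                continue
            dams = state.cohort(subpop, t - age)
            pick = rng.integers(dams.n, size=k)
            drones[mask] = dams.queen_bv[pick]
    drones += _mendelian(rng, total, state.chol)
    return drones.reshape(n_queens, m, -1).mean(axis=1)


def _passive_queens(
    state: SimState, t: int, rng: np.random.Generator
) -> np.ndarray:
    """New passive queens: dam is a random (unselected) breeding colony
    with probability q, else a random passive colony; dam age uniform 1-3."""
    cfg = state.config
    n = cfg.n_p
    from_breeding = rng.random(n) < cfg.q
    ages = rng.integers(1, 4, size=n)
    queens = np.empty((n, cfg.n_components))
    for subpop, mask_pop in (("breeding", from_breeding),
                             ("passive", ~from_breeding)):
        for age in _DAM_AGES:
            mask = mask_pop & (ages == age)
            k = int(mask.sum())
            if k == 0:
                continue
            dams = state.cohort(subpop, t - age)
            pick = rng.integers(dams.n, size=k)
            queens[mask] = dams.colony_bv[pick]
    queens += _mendelian(rng, n, state.chol)
    return queens


def _breeding_queens_from_dams(
    state: SimState, t: int, rng: np.random.Generator
) -> np.ndarray:
    """New breeding queens: dams are the selected colonies of year t-2,
    each contributing an equal share of daughters."""
    cfg = state.config
    dam_cohort = state.cohort("breeding", t - 2)
    idx, sel_mean, diff = select(dam_cohort, cfg.n_dams, cfg.rho, rng)
    dam_cohort.s1 = diff
    dam_cohort.b1_mean = sel_mean
    dam_idx = np.resize(idx, cfg.n_b)
    queens = dam_cohort.colony_bv[dam_idx] + _mendelian(rng, cfg.n_b, state.chol)
    return queens


def breed_year_uncontrolled(
    state: SimState, t: int, rng: np.random.Generator
) -> None:
    """Produce the year-t cohorts under free mating everywhere."""
    cfg = state.config
    b_queens = _breeding_queens_from_dams(state, t, rng)
    b_sires = _free_mating_sires(state, t, cfg.n_b, rng)
    p_queens = _passive_queens(state, t, rng)
    p_sires = _free_mating_sires(state, t, cfg.n_p, rng)
    state.cohorts[("breeding", t)] = Cohort(queen_bv=b_queens, sire_bv=b_sires)
    state.cohorts[("passive", t)] = Cohort(queen_bv=p_queens, sire_bv=p_sires)


def breed_year_controlled(
    state: SimState, t: int, rng: np.random.Generator
) -> None:
    """Produce the year-t cohorts with station mating on the breeding side.

    Per station one colony of year t-3 is selected (DPQ purpose); its
    sister-group of DPQs supplies the station's drones (no further age
    lag on the DPQ-to-drone path).  Each new breeding queen mates on one
    uniformly chosen station.  Passive reproduction is exactly the
    free-mating routine: it never sees the mating system.
    """
    cfg = state.config
    assert cfg.n_stations is not None

    dpq_cohort = state.cohort("breeding", t - 3)
    idx, sel_mean, diff = select(dpq_cohort, cfg.n_stations, cfg.rho, rng)
    dpq_cohort.s2 = diff
    dpq_cohort.b2_mean = sel_mean

    n_dpq = cfg.dpqs_per_station
    # sister DPQs per station: daughters of the selected colony
    dpq_bv = (
        np.repeat(dpq_cohort.colony_bv[idx], n_dpq, axis=0)
        + _mendelian(rng, cfg.n_stations * n_dpq, state.chol)
    ).reshape(cfg.n_stations, n_dpq, -1)

    b_queens = _breeding_queens_from_dams(state, t, rng)

    m = cfg.drones_per_mating
    station_of_queen = rng.integers(cfg.n_stations, size=cfg.n_b)
    dpq_of_drone = rng.integers(n_dpq, size=(cfg.n_b, m))
    drone_dams = dpq_bv[station_of_queen[:, None], dpq_of_drone]
    drones = drone_dams + _mendelian(
        rng, cfg.n_b * m, state.chol
    ).reshape(cfg.n_b, m, -1)
    b_sires = drones.mean(axis=1)

    p_queens = _passive_queens(state, t, rng)
    p_sires = _free_mating_sires(state, t, cfg.n_p, rng)
    state.cohorts[("breeding", t)] = Cohort(queen_bv=b_queens, sire_bv=b_sires)
    state.cohorts[("passive", t)] = Cohort(queen_bv=p_queens, sire_bv=p_sires)


def _summaries(state: SimState) -> pd.DataFrame:
    """Per-year summary table of cohort means and realized differentials."""
    cfg = state.config
    c = cfg.n_components
    comp_names = ("maternal", "direct") if c == 2 else ()
    rows = []
    for t in range(1, cfg.years + 1):
        b = state.cohort("breeding", t)
        p = state.cohort("passive", t)
        row: dict[str, float] = {
            "year": t,
            "B_queen": float(b.queen_bv.sum(axis=1).mean()),
            "P_queen": float(p.queen_bv.sum(axis=1).mean()),
            "B": float(b.colony_bv.sum(axis=1).mean()),
            "P": float(p.colony_bv.sum(axis=1).mean()),
            "B1": float(b.b1_mean.sum()) if b.b1_mean is not None else np.nan,
            "B2": float(b.b2_mean.sum()) if b.b2_mean is not None else np.nan,
            "S1": float(b.s1.sum()) if b.s1 is not None else np.nan,
            "S2": float(b.s2.sum()) if b.s2 is not None else np.nan,
        }
        for k, name in enumerate(comp_names):
            row[f"B_{name}"] = float(b.colony_bv[:, k].mean())
            row[f"P_{name}"] = float(p.colony_bv[:, k].mean())
            row[f"S1_{name}"] = float(b.s1[k]) if b.s1 is not None else np.nan
            row[f"S2_{name}"] = float(b.s2[k]) if b.s2 is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def run_replicate(config: SimConfig, replicate: int = 0) -> pd.DataFrame:
    """One seeded replicate; returns the per-year summary table.

    The replicate RNG stream is derived from (seed, replicate) so that
    replicates are independent yet individually reproducible.
    """
    rng = np.random.default_rng([config.seed, replicate])
    state = initialize(config, rng)
    breed = (
        breed_year_controlled
        if config.mating_system is MatingSystem.CONTROLLED
        else breed_year_uncontrolled
    )
    for t in range(1, config.years + 1):
        breed(state, t, rng)
        logger.debug(
            "replicate %d year %d: B=%.4f P=%.4f",
            replicate, t,
            state.cohort("breeding", t).colony_bv.sum(axis=1).mean(),
            state.cohort("passive", t).colony_bv.sum(axis=1).mean(),
        )
    return _summaries(state)


def run(config: SimConfig) -> list[pd.DataFrame]:
    """All replicates of a configuration, one summary table each."""
    return [run_replicate(config, r) for r in range(config.replicates)]
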