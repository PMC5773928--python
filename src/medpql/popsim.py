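"""Stochastic stage-structured Medfly elimination simulator (ABS PQL).

A non-spatial agent-based model of a Medfly outbreak under eradication
pressure: every individual is tracked through egg, larva, pupa, immature
adult, and mature adult stages.  Development is thermal — each stage ``s``
requires ``DD_s`` degree-days above its base ``b_s``, accumulated hourly from
the driving temperature series.  Mortality has three components: a per-stage
daily baseline, additional daily mortality from control efforts (sprays,
fruit stripping), and acute hourly mortality below a cold-lethal or above a
heat-lethal temperature.  Sterile-male releases (SIT) are modelled as a daily
probability that an unmated mature female mates sterile and is lost to
reproduction; females mate once for life.  Fertile females oviposit a
Poisson number of eggs per day scaled by temperature.

Daily event ordering is fixed (development, acute mortality, daily
mortality, mating, oviposition) because reordering changes trajectories.

Most biological parameters are only known to within ranges, so each 'run'
sweeps them by Latin hypercube sampling: one simulation per sampled
parameter vector, and the ABS predicted quarantine length (ABS PQL) is the
day by which 95% of the run's simulations have reached elimination (the day
the last living agent dies).  A 'runset' repeats runs at a fixed start-date
spacing across the temperature record and linearly upsamples the PQL knots
to daily values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.stats import qmc

from .weather import HourlyTemperatureSeries

__all__ = [
    "STAGE_NAMES",
    "default_ranges",
    "BioParamRanges",
    "BioParamVector",
    "Population",
    "SimOutcome",
    "Run",
    "Runset",
    "lhs_sample",
    "init_population",
    "step_day",
    "run_simulation",
    "abs_pql_from_run",
    "run_runset",
    "approximate_r0",
]

STAGE_EGG, STAGE_LARVA, STAGE_PUPA, STAGE_IMMATURE, STAGE_MATURE = range(5)
STAGE_NAMES = ("egg", "larva", "pupa", "immature_adult", "mature_adult")

SEX_UNSET, SEX_F, SEX_M = -1, 0, 1
UNMATED, FERTILE_MATED, STERILE_MATED = 0, 1, 2

# temperature at which oviposition runs at the nominal fecundity
REFERENCE_TEMP_C = 25.0

# how strongly control-induced mortality hits each stage.  Adults are fully
# exposed to sprays and removal; eggs/larvae inside fruit and pupae in soil
# are only partially reached (fruit stripping).  Configurable per run.
DEFAULT_CONTROL_STAGE_MASK = (0.2, 0.2, 0.2, 1.0, 1.0)

# parameter order is the LHS dimension order; it is part of the seeded contract
PARAM_NAMES = (
    "n_initial_females",
    "p_sit_daily",
    "control_mortality_daily",
    "dd_egg",
    "dd_larva",
    "dd_pupa",
    "dd_immature_adult",
    "base_egg",
    "base_larva",
    "base_pupa",
    "base_immature_adult",
    "mu_egg",
    "mu_larva",
    "mu_pupa",
    "mu_immature_adult",
    "mu_mature_adult",
    "fecundity",
    "cold_lethal_c",
    "p_cold_hourly",
    "heat_lethal_c",
    "p_heat_hourly",
)

_PROB_PARAMS = {
    "p_sit_daily", "control_mortality_daily", "mu_egg", "mu_larva", "mu_pupa",
    "mu_immature_adult", "mu_mature_adult", "p_cold_hourly", "p_heat_hourly",
}


@dataclass(frozen=True)
class BioParamRanges:
    """(low, high) bounds for every swept simulation parameter."""

    bounds: dict

    def __post_init__(self) -> None:
        missing = set(PARAM_NAMES) - set(self.bounds)
        if missing:
            raise ValueError(f"missing parameter ranges: {sorted(missing)}")
        for name in PARAM_NAMES:
            lo, hi = self.bounds[name]
            if lo > hi:
                raise ValueError(f"{name}: low {lo} > high {hi}")
            if name.startswith("dd_") and lo <= 0:
                raise ValueError(f"{name}: thermal requirement must be > 0")
            if name in _PROB_PARAMS and not (0.0 <= lo and hi <= 1.0):
                raise ValueError(f"{name}: probability bounds outside [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "BioParamRanges":
        return cls(bounds={k: (float(v[0]), float(v[1])) for k, v in d.items()})

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[n][0] for n in PARAM_NAMES])
        hi = np.array([self.bounds[n][1] for n in PARAM_NAMES])
        return lo, hi


@dataclass(frozen=True)
class BioParamVector:
    """One sampled point in simulator parameter space."""

    values: dict

    def __getattr__(self, name):
        try:
            return self.values[name]
        except KeyError:
            raise AttributeError(name) from None

    @property
    def dd_stage(self) -> np.ndarray:
        v = self.values
        return np.array([v["dd_egg"], v["dd_larva"], v["dd_pupa"], v["dd_immature_adult"]])

    @property
    def base_stage(self) -> np.ndarray:
        v = self.values
        return np.array(
            [v["base_egg"], v["base_larva"], v["base_pupa"], v["base_immature_adult"]]
        )

    @property
    def mu_stage(self) -> np.ndarray:
        v = self.values
        return np.array(
            [v["mu_egg"], v["mu_larva"], v["mu_pupa"], v["mu_immature_adult"],
             v["mu_mature_adult"]]
        )


@dataclass
class Population:
    """Vectorised agent state; one array element per living agent."""

    stage: np.ndarray
    sex: np.ndarray
    dev: np.ndarray
    mated: np.ndarray

    @property
    def n(self) -> int:
        return len(self.stage)

    @classmethod
    def empty(cls) -> "Population":
        return cls(
            stage=np.empty(0, np.int8), sex=np.empty(0, np.int8),
            dev=np.empty(0, float), mated=np.empty(0, np.int8),
        )


@dataclass(frozen=True)
class SimOutcome:
    """Result of one simulation: elimination day (1-based) or censored."""

    elimination_day: int | None
    censored: bool
    peak_population: int


@dataclass
class Run:
    """One LHS ensemble for a single start date."""

    start_date: pd.Timestamp
    outcomes: list
    abs_pql: int | None
    censored: bool


@dataclass
class Runset:
    """Runs at fixed start-date spacing plus the daily-upsampled PQL series."""

    runs: list
    daily_pql: pd.Series
    site: object = None


def default_ranges() -> "BioParamRanges":
    """The packaged default LHS bounds (see data/default_config.yaml)."""
    with resources.files("medpql.data").joinpath("default_config.yaml").open() as fh:
        return BioParamRanges.from_dict(yaml.safe_load(fh)["ranges"])


# ---------------------------------------------------------------------------
# Parameter sampling
# ---------------------------------------------------------------------------

def lhs_sample(ranges: BioParamRanges, n: int, seed) -> list:
    """Draw ``n`` Latin-hypercube parameter vectors.

    Each parameter's range is split into ``n`` equal-width strata and exactly
    one sample lands in each stratum; the stratum permutations of different
    parameters are independent.  Fully determined by ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = ranges.as_arrays()
    sampler = qmc.LatinHypercube(d=len(PARAM_NAMES), seed=np.random.default_rng(seed))
    u = sampler.random(n)
    x = lo + u * (hi - lo)
    return [
        BioParamVector(values={name: float(row[j]) for j, name in enumerate(PARAM_NAMES)})
        for row in x
    ]


# ---------------------------------------------------------------------------
# Simulation core
# ---------------------------------------------------------------------------

def init_population(params: BioParamVector) -> Population:
    """The 'standard outbreak' initial population.

    ``n_initial_females`` (rounded, >= 1) unmated mature-adult females plus
    an equal number of mature-adult males, all with zero development
    accumulated; identical age profile in every simulation.
    """
    nf = max(int(round(params.n_initial_females)), 1)
    n = 2 * nf
    sex = np.empty(n, np.int8)
    sex[:nf] = SEX_F
    sex[nf:] = SEX_M
    return Population(
        stage=np.full(n, STAGE_MATURE, np.int8),
        sex=sex,
        dev=np.zeros(n),
        mated=np.full(n, UNMATED, np.int8),
    )


def step_day(
    pop: Population,
    day_hours,
    params: BioParamVector,
    rng: np.random.Generator,
    control_stage_mask=DEFAULT_CONTROL_STAGE_MASK,
) -> Population:
    """Advance the population one day against 24 hourly temperatures.

    Event order: (1) hourly thermal development with stage advancement,
    (2) hourly acute cold/heat mortality, (3) daily baseline + control
    mortality as independent hazards, (4) SIT mating of unmated mature
    females, (5) oviposition by fertile females.
    """
    hours = np.asarray(day_hours, dtype=float)
    if hours.shape != (24,):
        raise ValueError("day_hours must contain exactly 24 values")
    if pop.n == 0:
        return Population.empty()

    dd_req = params.dd_stage
    # (1) development: per-stage degree-days for this day, applied hourly
    gains = np.clip(hours[:, None] - params.base_stage[None, :], 0.0, None).sum(0) / 24.0
    gain5 = np.append(gains, 0.0)  # mature adults accumulate nothing
    stage = pop.stage.copy()
    sex = pop.sex.copy()
    dev = pop.dev + gain5[stage]
    mated = pop.mated.copy()
    while True:
        can = stage < STAGE_MATURE
        adv = can & (dev >= dd_req[np.minimum(stage, STAGE_IMMATURE)])
        if not adv.any():
            break
        dev[adv] -= dd_req[stage[adv]]
        stage[adv] += 1
        emerged = adv & (stage == STAGE_IMMATURE)  # pupa -> adult: assign sex
        k = int(emerged.sum())
        if k:
            sex[emerged] = (rng.random(k) < 0.5).astype(np.int8)

    # (2) acute temperature mortality, per hour outside the lethal bounds
    n_cold = int((hours < params.cold_lethal_c).sum())
    n_heat = int((hours > params.heat_lethal_c).sum())
    surv_acute = (1.0 - params.p_cold_hourly) ** n_cold * (1.0 - params.p_heat_hourly) ** n_heat
    n = len(stage)
    if surv_acute < 1.0:
        keep = rng.random(n) < surv_acute
    else:
        keep = np.ones(n, dtype=bool)

    # (3) daily baseline + control mortality, combined as independent hazards
    mask = np.asarray(control_stage_mask, dtype=float)
    p_control = mask[stage] * params.control_mortality_daily
    p_die = 1.0 - (1.0 - params.mu_stage[stage]) * (1.0 - p_control)
    keep &= rng.random(n) >= p_die

    stage = stage[keep]
    sex = sex[keep]
    dev = dev[keep]
    mated = mated[keep]

    # (4) mating: unmated mature females mate once, sterile w.p. p_sit_daily
    is_mature = stage == STAGE_MATURE
    um = is_mature & (sex == SEX_F) & (mated == UNMATED)
    k = int(um.sum())
    if k:
        sterile = rng.random(k) < params.p_sit_daily
        any_male = bool(np.any(is_mature & (sex == SEX_M)))
        outcome = np.where(
            sterile, STERILE_MATED, FERTILE_MATED if any_male else UNMATED
        ).astype(np.int8)
        mated[um] = outcome

    # (5) oviposition, scaled by the day's mean temperature; the ramp
    # saturates at the reference optimum rather than growing without bound
    t_bar = float(hours.mean())
    scale = min(
        max(t_bar - params.base_egg, 0.0) / (REFERENCE_TEMP_C - params.base_egg), 1.0
    )
    n_fertile = int((is_mature & (sex == SEX_F) & (mated == FERTILE_MATED)).sum())
    n_eggs = 0
    if n_fertile and scale > 0.0:
        n_eggs = int(rng.poisson(params.fecundity * scale, n_fertile).sum())
    if n_eggs:
        stage = np.concatenate([stage, np.full(n_eggs, STAGE_EGG, np.int8)])
        sex = np.concatenate([sex, np.full(n_eggs, SEX_UNSET, np.int8)])
        dev = np.concatenate([dev, np.zeros(n_eggs)])
        mated = np.concatenate([mated, np.full(n_eggs, UNMATED, np.int8)])

    return Population(stage=stage, sex=sex, dev=dev, mated=mated)


def run_simulation(
    series: HourlyTemperatureSeries,
    start_date,
    params: BioParamVector,
    max_days: int,
    rng: np.random.Generator,
    initial_population: Population | None = None,
    control_stage_mask=DEFAULT_CONTROL_STAGE_MASK,
) -> SimOutcome:
    """Simulate from ``start_date`` until the last agent dies.

    ``elimination_day`` is 1-based from the start date (0 if the initial
    population is empty).  Censored if ``max_days`` or the end of the
    temperature data is reached with agents still alive.
    """
    if max_days < 1:
        raise ValueError("max_days must be >= 1")
    start = pd.Timestamp(start_date).normalize()
    i0 = int((start - series.start) / pd.Timedelta(hours=1))
    if i0 < 0 or i0 + 24 > len(series.temps):
        raise IndexError(f"start_date {start.date()} outside temperature series")
    n_days = min(max_days, (len(series.temps) - i0) // 24)

    pop = init_population(params) if initial_population is None else initial_population
    peak = pop.n
    if pop.n == 0:
        return SimOutcome(elimination_day=0, censored=False, peak_population=0)
    temps = series.temps
    for d in range(1, n_days + 1):
        j = i0 + (d - 1) * 24
        pop = step_day(pop, temps[j : j + 24], params, rng, control_stage_mask)
        if pop.n > peak:
            peak = pop.n
        if pop.n == 0:
            return SimOutcome(elimination_day=d, censored=False, peak_population=peak)
    return SimOutcome(elimination_day=None, censored=True, peak_population=peak)


def abs_pql_from_run(outcomes, quantile: float = 0.95) -> int | None:
    """Day by which ``quantile`` of a run's simulations are eliminated.

    The smallest day ``d`` with at least ``ceil(quantile * n)`` elimination
    days <= ``d`` — i.e. the k-th order statistic.  None (censored) if fewer
    than k outcomes are uncensored.
    """
    if len(outcomes) == 0:
        raise ValueError("outcomes is empty")
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must be in (0, 1]")
    days = np.array(
        [np.inf if o.censored else o.elimination_day for o in outcomes], dtype=float
    )
    k = math.ceil(quantile * len(days))
    v = np.partition(days, k - 1)[k - 1]
    return None if np.isinf(v) else int(v)


def run_runset(
    series: HourlyTemperatureSeries,
    ranges: BioParamRanges,
    n_sims: int,
    seed: int,
    every_days: int = 7,
    quantile: float = 0.95,
    max_days: int = 730,
    start: pd.Timestamp | None = None,
    end: pd.Timestamp | None = None,
    control_stage_mask=DEFAULT_CONTROL_STAGE_MASK,
    progress=None,
) -> Runset:
    """A run (fresh seeded LHS ensemble) every ``every_days`` days.

    Per-run LHS designs and per-simulation RNG substreams are derived from
    ``(seed, run index, sim index)`` counters, so results are independent of
    execution order.  The 7-day-interval ABS PQL knots are upsampled to daily
    values by linear interpolation; censored knots break the interpolation
    (no bridging across them).
    """
    if n_sims < 20:
        raise ValueError("n_sims must be >= 20")
    dates, _ = series.day_matrix()
    lo = dates[0] if start is None else pd.Timestamp(start)
    hi = dates[-1] if end is None else pd.Timestamp(end)
    start_dates = [d for d in dates[::every_days] if lo <= d <= hi]
    if not start_dates:
        raise ValueError("no start dates in requested range")

    runs: list[Run] = []
    for r, d0 in enumerate(start_dates):
        vectors = lhs_sample(ranges, n_sims, seed=[seed, 1_000_000 + r])
        outcomes = []
        for s, vec in enumerate(vectors):
            rng = np.random.default_rng([seed, r, s])
            outcomes.append(
                run_simulation(series, d0, vec, max_days, rng,
                               control_stage_mask=control_stage_mask)
            )
        pql = abs_pql_from_run(outcomes, quantile)
        runs.append(Run(start_date=d0, outcomes=outcomes,
                        abs_pql=pql, censored=pql is None))
        if progress is not None:
            progress(r + 1, len(start_dates))

    daily = pd.Series(np.nan, index=pd.date_range(start_dates[0], start_dates[-1], freq="D"))
    for a, b in zip(runs[:-1], runs[1:]):
        if a.censored or b.censored:
            if not a.censored:
                daily.loc[a.start_date] = float(a.abs_pql)
            continue
        seg = pd.date_range(a.start_date, b.start_date, freq="D")
        x = (seg - a.start_date).days.to_numpy(float)
        span = float((b.start_date - a.start_date).days)
        daily.loc[seg] = a.abs_pql + (b.abs_pql - a.abs_pql) * x / span
    last = runs[-1]
    if not last.censored:
        daily.loc[last.start_date] = float(last.abs_pql)
    return Runset(runs=runs, daily_pql=daily, site=series.site)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def approximate_r0(
    params: BioParamVector, t_mean: float, control_stage_mask=DEFAULT_CONTROL_STAGE_MASK
) -> float:
    """Deterministic net reproduction number at a constant temperature.

    Expected daughters per female: (first-mating fertile probability) x
    (eggs/day at ``t_mean``) x (adult life expectancy) x (egg-to-maturity
    survival) x (daughter fraction 1/2).  A run whose parameter vectors sit
    almost entirely at R0 < 1 is in the elimination regime the quarantine
    question presumes.
    """
    gains = np.clip(t_mean - params.base_stage, 0.0, None)
    if np.any(gains <= 0.0):
        return 0.0
    durations = params.dd_stage / gains
    mask = np.asarray(control_stage_mask, dtype=float)
    control = params.control_mortality_daily
    p_day = 1.0 - (1.0 - params.mu_stage[:4]) * (1.0 - mask[:4] * control)
    survival = float(np.prod((1.0 - p_day) ** durations))
    p_adult = 1.0 - (1.0 - params.mu_stage[4]) * (1.0 - mask[4] * control)
    life = 1.0 / p_adult
    scale = min(
        max(t_mean - params.base_egg, 0.0) / (REFERENCE_TEMP_C - params.base_egg), 1.0
    )
    fertile = 1.0 - params.p_sit_daily
    return 0.5 * fertile * params.fecundity * scale * life * survival
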