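"""Stochastic simulation of the three-genotype rescue model.

Exact Gillespie simulation (SSA) of the nine-event birth/death/
missegregation/mutation model, tau-leaping acceleration, an optional
logistic (density-dependent) death-rate term, standing-variation
initialization, stopping rules, and replicate ensembles.

A run terminates when the population goes extinct, when the mutant count
reaches its stopping target, when simulated time exceeds ``t_max``, or
when the event budget is exhausted (censored).  The default mutant target
is the *establishment threshold*: the smallest count at which the joint
extinction probability of the mutant lineages falls below 0.1%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .params import ModelParams, derived_rates

__all__ = [
    "PopulationState",
    "StopRule",
    "Trajectory",
    "ReplicateSummary",
    "EVENT_NAMES",
    "event_rates",
    "mutant_establishment_threshold",
    "initial_state_with_standing_variation",
    "gillespie_run",
    "tau_leap_run",
    "run_replicates",
    "replicate_seed",
    "summaries_to_frame",
]

EVENT_NAMES = (
    "birth_s", "death_s", "missegregation", "mutation_s",
    "birth_a", "death_a", "mutation_a",
    "birth_m", "death_m",
)

_OUTCOMES = ("extinct", "rescued", "recurred", "censored")


@dataclass(frozen=True)
class PopulationState:
    """Cell counts (s, a, m) at time ``t`` (days)."""

    t: float
    s: int
    a: int
    m: int

    def __post_init__(self):
        if self.t < 0 or self.s < 0 or self.a < 0 or self.m < 0:
            raise ValueError("time and counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.s + self.a + self.m


@dataclass(frozen=True)
class StopRule:
    """Terminating conditions for a simulation run.

    ``establishment_threshold``: mutant count at which the run counts as
    rescued (``None`` = auto from the model rates).  ``recurrence_target``
    and ``detection_target`` optionally extend the run until the mutant
    population reaches the pretreatment size / the clinical detection
    size, recording the crossing times.  ``t_max`` (days) and
    ``max_events`` censor runaway runs.
    """

    establishment_threshold: Optional[int] = None
    recurrence_target: Optional[int] = None
    detection_target: Optional[int] = None
    t_max: float = 1e6
    max_events: int = 1_000_000_000

    def __post_init__(self):
        if self.t_max <= 0 and self.max_events <= 0:
            raise ValueError("at least one terminating condition is required")

    def resolve_establishment(self, params: ModelParams) -> int:
        if self.establishment_threshold is not None:
            return int(self.establishment_threshold)
        return mutant_establishment_threshold(params)


@dataclass
class Trajectory:
    """A recorded simulation run.

    ``times``/``s``/``a``/``m`` hold the state on the recording grid (the
    initial state is always included; for runs that end before the grid
    does, only extinction -- an absorbing state -- is extended).  Event
    counts are indexed by :data:`EVENT_NAMES`.
    """

    times: np.ndarray
    s: np.ndarray
    a: np.ndarray
    m: np.ndarray
    outcome: str
    seed: int
    event_counts: np.ndarray
    final_state: PopulationState
    rescue_time: float = math.nan
    establishment_time: float = math.nan
    recurrence_time: float = math.nan
    detection_time: float = math.nan
    first_mutant_time: float = math.nan
    method: str = "ssa"

    @property
    def final(self) -> PopulationState:
        return self.final_state


@dataclass(frozen=True)
class ReplicateSummary:
    """Per-replicate outcome record for ensembles."""

    replicate: int
    seed: int
    outcome: str
    rescue_time: float
    recurrence_time: float
    detection_time: float
    final_s: int
    final_a: int
    final_m: int
    final_t: float
    n_events: int


# ---------------------------------------------------------------------------


def event_rates(
    state: PopulationState,
    params: ModelParams,
    carrying_capacity: Optional[float] = None,
    exact_division_factors: bool = False,
) -> np.ndarray:
    """The nine event rates at a state, ordered as :data:`EVENT_NAMES`.

    By default the (1-u-v) and (1-v_a) division factors are dropped from
    the birth rates (they are within 1% of one for realistic rates);
    ``exact_division_factors=True`` restores them.  With a carrying
    capacity ``K``, each genotype's death rate gains the logistic term
    ``lambda_k (s+a+m)/K``.
    """
    k = carrying_capacity if carrying_capacity is not None else params.carrying_capacity
    inv_k = 0.0 if k is None else 1.0 / k
    dens = inv_k * state.total
    f_s = (1.0 - params.u - params.v) if exact_division_factors else 1.0
    f_a = (1.0 - params.v_a) if exact_division_factors else 1.0
    s, a, m = state.s, state.a, state.m
    return np.array([
        params.lambda_s * f_s * s,
        (params.mu_s + params.lambda_s * dens) * s,
        params.u * params.lambda_s * s,
        params.v * params.lambda_s * s,
        params.lambda_a * f_a * a,
        (params.mu_a + params.lambda_a * dens) * a,
        params.v_a * params.lambda_a * a,
        params.lambda_m * m,
        (params.mu_m + params.lambda_m * dens) * m,
    ])


def mutant_establishment_threshold(params: ModelParams) -> int:
    """Smallest mutant count with joint lineage-extinction probability < 0.1%.

    Solves ``1 - q_m^m >= 0.999`` for the count ``m``, i.e.
    ``floor(3 ln 10 / ln(lambda_m/mu_m)) + 1``.  An immortal mutant
    (``mu_m = 0``) establishes surely, giving 1.
    """
    if params.lambda_m <= params.mu_m:
        raise ValueError("mutant cannot establish: requires lambda_m > mu_m")
    if params.mu_m == 0:
        return 1
    return int(3.0 * math.log(10.0) // math.log(params.lambda_m / params.mu_m)) + 1


def initial_state_with_standing_variation(
    params: ModelParams, mode: str = "stochastic", seed: Optional[int] = None
) -> PopulationState:
    """Initial state with the pretreatment aneuploid fraction ``f = u_pre lambda_s / c``.

    ``stochastic`` draws ``a0 ~ Binomial(N, f)`` (requires ``seed``);
    ``expected`` uses ``a0 = round(f N)``.  Mutants are absent initially.
    """
    d = derived_rates(params)
    f = d.f_standing
    if f >= 1:
        raise ValueError("standing aneuploid fraction >= 1; check u_pre, lambda_s, c")
    n = params.n_init
    if mode == "expected":
        a0 = int(round(f * n))
    elif mode == "stochastic":
        if seed is None:
            raise ValueError("stochastic mode requires an explicit seed")
        a0 = int(np.random.default_rng(seed).binomial(n, f))
    else:
        raise ValueError("mode must be 'stochastic' or 'expected'")
    return PopulationState(t=0.0, s=n - a0, a=a0, m=0)


def _kernel_rates(params: ModelParams, exact_division_factors: bool):
    f_s = (1.0 - params.u - params.v) if exact_division_factors else 1.0
    f_a = (1.0 - params.v_a) if exact_division_factors else 1.0
    k = params.carrying_capacity
    inv_k = 0.0 if k is None else 1.0 / k
    return (
        params.lambda_s * f_s, params.mu_s,
        params.lambda_a * f_a, params.mu_a,
        params.lambda_m, params.mu_m,
        params.u * params.lambda_s,
        params.v * params.lambda_s,
        params.v_a * params.lambda_a,
        params.lambda_s, params.lambda_a, inv_k,
    )


def _grid(stop: StopRule, record_interval: Optional[float]) -> np.ndarray:
    if record_interval is None:
        return np.empty(0, dtype=np.float64)
    if record_interval <= 0:
        raise ValueError("record_interval must be positive")
    n_pts = int(math.floor(stop.t_max / record_interval)) + 1
    if n_pts > 2_000_000:
        raise ValueError("recording grid too fine for t_max; coarsen record_interval")
    return np.arange(1, n_pts, dtype=np.float64) * record_interval


def _kernel_seed(seed: int) -> int:
    # numba's np.random.seed accepts uint32; fold wider seeds stably
    return int(np.uint32(seed))


def gillespie_run(
    params: ModelParams,
    initial: PopulationState,
    stop: StopRule,
    seed: int,
    record_interval: Optional[float] = None,
    exact_division_factors: bool = False,
) -> Trajectory:
    """Exact stochastic simulation (Gillespie SSA) of one run.

    Waiting times are exponential with the summed event rate; events are
    selected proportionally to their rates.  The run is bit-reproducible
    from ``seed``.
    """
    m_est = stop.resolve_establishment(params)
    m_rec = int(stop.recurrence_target or 0)
    m_det = int(stop.detection_target or 0)
    rec_times = _grid(stop, record_interval)

    (t, s, a, m, outcome, events, counts,
     rescue_t, est_t, rec_t, det_t, first_mut,
     rec_s, rec_a, rec_m, i_rec, lin_ok) = _kernels.ssa_run(
        *_kernel_rates(params, exact_division_factors),
        initial.s, initial.a, initial.m,
        m_est, m_rec, m_det,
        float(stop.t_max), int(stop.max_events), _kernel_seed(seed),
        rec_times,
    )
    times = np.concatenate([[initial.t], rec_times[:i_rec]])
    return Trajectory(
        times=times,
        s=np.concatenate([[initial.s], rec_s[:i_rec]]),
        a=np.concatenate([[initial.a], rec_a[:i_rec]]),
        m=np.concatenate([[initial.m], rec_m[:i_rec]]),
        outcome=_OUTCOMES[outcome],
        seed=int(seed),
        event_counts=np.asarray(counts),
        final_state=PopulationState(t=float(t), s=int(s), a=int(a), m=int(m)),
        rescue_time=float(rescue_t),
        establishment_time=float(est_t),
        recurrence_time=float(rec_t),
        detection_time=float(det_t),
        first_mutant_time=float(first_mut),
        method="ssa",
    )


def tau_leap_run(
    params: ModelParams,
    initial: PopulationState,
    step: float,
    stop: StopRule,
    seed: int,
    record_interval: Optional[float] = None,
    exact_division_factors: bool = False,
) -> Trajectory:
    """Tau-leaping run: per step, each channel fires Poisson(rate * step) times.

    Net deltas are applied per genotype and negative counts are clamped to
    zero (this slightly biases totals near extinction; the SSA is exact).
    Default step for the melanoma rate scale: 0.1 days.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    m_est = stop.resolve_establishment(params)
    m_rec = int(stop.recurrence_target or 0)
    m_det = int(stop.detection_target or 0)
    rec_times = _grid(stop, record_interval)

    (t, s, a, m, outcome, events, counts,
     est_t, rec_t, det_t, first_mut,
     rec_s, rec_a, rec_m, i_rec) = _kernels.tau_leap_run_kernel(
        *_kernel_rates(params, exact_division_factors),
        initial.s, initial.a, initial.m,
        m_est, m_rec, m_det,
        float(stop.t_max), int(stop.max_events), _kernel_seed(seed), float(step),
        rec_times,
    )
    rescue_t = first_mut if outcome in (1, 2) else math.nan
    times = np.concatenate([[initial.t], rec_times[:i_rec]])
    return Trajectory(
        times=times,
        s=np.concatenate([[initial.s], rec_s[:i_rec]]),
        a=np.concatenate([[initial.a], rec_a[:i_rec]]),
        m=np.concatenate([[initial.m], rec_m[:i_rec]]),
        outcome=_OUTCOMES[outcome],
        seed=int(seed),
        event_counts=np.asarray(counts),
        final_state=PopulationState(t=float(t), s=int(s), a=int(a), m=int(m)),
        rescue_time=float(rescue_t),
        establishment_time=float(est_t),
        recurrence_time=float(rec_t),
        detection_time=float(det_t),
        first_mutant_time=float(first_mut),
        method="tau",
    )


def replicate_seed(base_seed: int, index: int) -> int:
    """Stable per-replicate seed derived from (base_seed, replicate index)."""
    return int(np.random.SeedSequence((int(base_seed), int(index))).generate_state(1)[0])


def run_replicates(
    params: ModelParams,
    n_replicates: int,
    base_seed: int,
    method: str = "ssa",
    stop: Optional[StopRule] = None,
    initial: Optional[PopulationState] = None,
    tau_step: float = 0.1,
    standing_variation: bool = False,
    exact_division_factors: bool = False,
    progress: bool = False,
) -> list[ReplicateSummary]:
    """Run an ensemble of independent replicates.

    Replicate ``i`` uses a seed derived deterministically from
    ``(base_seed, i)`` via :func:`replicate_seed`, so ensembles are
    reproducible across machines.  ``method`` is ``"ssa"``, ``"tau"`` or
    ``"logistic"`` (SSA with the carrying-capacity term; requires
    ``params.carrying_capacity``).  With ``standing_variation=True`` each
    replicate draws its own binomial aneuploid initial count.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if method not in ("ssa", "tau", "logistic"):
        raise ValueError("method must be 'ssa', 'tau', or 'logistic'")
    if method == "logistic" and params.carrying_capacity is None:
        raise ValueError("logistic method requires params.carrying_capacity")
    stop = stop or StopRule()

    out: list[ReplicateSummary] = []
    for i in range(n_replicates):
        seed_i = replicate_seed(base_seed, i)
        if initial is not None:
            init_i = initial
        elif standing_variation:
            init_i = initial_state_with_standing_variation(
                params, "stochastic", seed=replicate_seed(base_seed, -1 - i)
            )
        else:
            init_i = PopulationState(t=0.0, s=params.n_init, a=0, m=0)
        if method == "tau":
            traj = tau_leap_run(
                params, init_i, tau_step, stop, seed_i,
                exact_division_factors=exact_division_factors,
            )
        else:
            traj = gillespie_run(
                params, init_i, stop, seed_i,
                exact_division_factors=exact_division_factors,
            )
        out.append(ReplicateSummary(
            replicate=i,
            seed=seed_i,
            outcome=traj.outcome,
            rescue_time=traj.rescue_time,
            recurrence_time=traj.recurrence_time,
            detection_time=traj.detection_time,
            final_s=traj.final_state.s,
            final_a=traj.final_state.a,
            final_m=traj.final_state.m,
            final_t=traj.final_state.t,
            n_events=int(traj.event_counts.sum()),
        ))
        if progress and (i + 1) % max(1, n_replicates // 10) == 0:
            print(f"  replicates completed: {i + 1}/{n_replicates}")
    return out


def summaries_to_frame(summaries: Sequence[ReplicateSummary]):
    """Ensemble summaries as a pandas DataFrame with the documented columns."""
    import pandas as pd

    return pd.DataFrame([
        {
            "replicate": s.replicate,
            "seed": s.seed,
            "outcome": s.outcome,
            "rescue_time": s.rescue_time,
            "recurrence_time": s.recurrence_time,
            "detection_time": s.detection_time,
            "final_s": s.final_s,
            "final_a": s.final_a,
            "final_m": s.final_m,
        }
        for s in summaries
    ])
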