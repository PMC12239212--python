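"""Branching-process theory of evolutionary rescue.

The tumor is modeled as a collection of independent cell lineages.  A
lineage founded by one cell of type ``k`` goes extinct with probability
``q_k``, the smallest fixed point in [0, 1] of the probability generating
function (PGF) of the lineage's offspring process.  For the resistant
mutant this is the classic single-type result ``q_m = min(1, mu_m /
lambda_m)``; for aneuploid and sensitive founders the fixed points are
roots of quadratics that couple the types through missegregation and
mutation.

From ``p_s = 1 - q_s`` (the probability that one sensitive cell founds a
lineage that is eventually rescued by resistance) the rescue probability
of a tumor of ``N`` cells is ``1 - (1 - p_s)^N ~ 1 - exp(-N/N*)`` with
threshold size ``N* = 1/p_s``.  Closed-form approximations for the
thresholds, the rescue hazard, and the rescue/recurrence/detection time
scales are provided alongside the exact PGF computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import integrate, optimize, stats

from .params import ModelParams, classify_regime, derived_rates

__all__ = [
    "ExtinctionProbs",
    "TheoryResult",
    "TimeEstimate",
    "TimeSummaries",
    "extinction_probabilities",
    "extinction_probabilities_fixed_point",
    "rescue_probability",
    "threshold_direct",
    "threshold_aneuploid",
    "threshold_ratios",
    "theory_summary",
    "deterministic_trajectory",
    "rescue_hazard",
    "mean_rescue_time",
    "rescue_time_survival",
    "sample_rescue_lineages",
    "mean_recurrence_time",
    "mean_detection_time",
    "recurrence_survival",
]


@dataclass(frozen=True)
class ExtinctionProbs:
    """Lineage extinction probabilities by founder type.

    ``q_s``, ``q_a``, ``q_m`` are the extinction probabilities of lineages
    founded by a single sensitive, aneuploid, or mutant cell; ``p_s`` and
    ``p_m`` are the complementary rescue/establishment probabilities.
    """

    q_s: float
    q_a: float
    q_m: float

    @property
    def p_s(self) -> float:
        return 1.0 - self.q_s

    @property
    def p_m(self) -> float:
        return 1.0 - self.q_m


@dataclass(frozen=True)
class TheoryResult:
    """Threshold tumor sizes, their ratios, and the rescue probability."""

    n_star_direct: float
    n_star_aneuploid: float
    n_star_standing: float
    ratio_aneuploid_direct: float
    ratio_standing_aneuploid: float
    ratio_standing_direct: float
    regime: str
    branch: str
    rescue_prob_exact: float
    rescue_prob_approx: float
    n_init: int


@dataclass(frozen=True)
class TimeEstimate:
    """A time summary in days, tagged with the method that produced it."""

    value: float
    method: str
    stderr: Optional[float] = None
    n: Optional[int] = None


@dataclass(frozen=True)
class TimeSummaries:
    mean_rescue_time: TimeEstimate
    mean_recurrence_time: TimeEstimate
    mean_detection_time: Optional[TimeEstimate] = None


# ---------------------------------------------------------------------------
# Extinction probabilities (PGF fixed points)
# ---------------------------------------------------------------------------

def _smaller_root(a: float, b: float, c: float) -> float:
    """Smaller root of a*q^2 + b*q + c = 0 with b < 0, computed stably.

    Uses q = 2c / (-b + sqrt(b^2 - 4ac)) to avoid cancellation; falls back
    to the linear solution when a == 0.
    """
    if a == 0.0:
        root = c / (-b)
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0:
            # Numerically at the critical point: the two roots coincide.
            disc = 0.0
        root = 2.0 * c / (-b + math.sqrt(disc))
    if abs(root - 1.0) < 5e-13:
        # Subcritical lineages die surely; do not let rounding leave a
        # spurious ~1e-16 survival probability.
        return 1.0
    return root


def extinction_probabilities(params: ModelParams) -> ExtinctionProbs:
    """Exact lineage extinction probabilities via PGF fixed points.

    The mutant is single-type: ``q_m = min(1, mu_m/lambda_m)``.  An
    aneuploid lineage branches into aneuploid births (rate
    ``lambda_a (1 - v_a)``), deaths (``mu_a``) and mutant-founding
    divisions (``v_a lambda_a``), giving the quadratic

        lambda_a (1-v_a) q^2 - (lambda_a + mu_a - v_a lambda_a q_m) q + mu_a = 0,

    whose smaller root in [0, 1] is ``q_a``; ``q_s`` follows analogously
    with missegregation feeding into ``q_a`` and mutation into ``q_m``.
    """
    lam_m, mu_m = params.lambda_m, params.mu_m
    if lam_m == 0.0:
        q_m = 1.0
    else:
        q_m = min(1.0, mu_m / lam_m)

    lam_a, mu_a, v_a = params.lambda_a, params.mu_a, params.v_a
    q_a = min(1.0, _smaller_root(
        lam_a * (1.0 - v_a),
        -(lam_a + mu_a - v_a * lam_a * q_m),
        mu_a,
    )) if (lam_a + mu_a) > 0 else 1.0

    lam_s, mu_s, u, v = params.lambda_s, params.mu_s, params.u, params.v
    q_s = min(1.0, _smaller_root(
        lam_s * (1.0 - u - v),
        -(lam_s + mu_s - u * lam_s * q_a - v * lam_s * q_m),
        mu_s,
    )) if (lam_s + mu_s) > 0 else 1.0

    return ExtinctionProbs(q_s=q_s, q_a=q_a, q_m=q_m)


def extinction_probabilities_fixed_point(
    params: ModelParams, tol: float = 1e-14, max_iter: int = 2_000_000
) -> ExtinctionProbs:
    """Independent oracle: iterate the PGF maps from q = 0 to convergence.

    The extinction probability is the limit of ``q_{n+1} = G(q_n)`` from
    ``q_0 = 0``, where ``G`` is the offspring PGF evaluated at the
    extinction probabilities of the descendant types.  Monotone convergence
    to the smallest fixed point is guaranteed; iteration stops at Cauchy
    tolerance ``tol``.  Slower but independent of the closed-form roots.
    """

    def iterate(total: float, f: Callable[[float], float]) -> float:
        q = 0.0
        for _ in range(max_iter):
            q_next = f(q) / total
            if abs(q_next - q) < tol:
                return q_next
            q = q_next
        return q

    lam_m, mu_m = params.lambda_m, params.mu_m
    if lam_m + mu_m == 0:
        q_m = 1.0
    else:
        q_m = iterate(lam_m + mu_m, lambda q: lam_m * q * q + mu_m)

    lam_a, mu_a, v_a = params.lambda_a, params.mu_a, params.v_a
    if lam_a + mu_a == 0:
        q_a = 1.0
    else:
        q_a = iterate(
            lam_a + mu_a,
            lambda q: lam_a * (1 - v_a) * q * q + v_a * lam_a * q * q_m + mu_a,
        )

    lam_s, mu_s, u, v = params.lambda_s, params.mu_s, params.u, params.v
    if lam_s + mu_s == 0:
        q_s = 1.0
    else:
        q_s = iterate(
            lam_s + mu_s,
            lambda q: (
                lam_s * (1 - u - v) * q * q
                + u * lam_s * q * q_a
                + v * lam_s * q * q_m
                + mu_s
            ),
        )

    return ExtinctionProbs(q_s=q_s, q_a=q_a, q_m=q_m)


# ---------------------------------------------------------------------------
# Threshold tumor sizes
# ---------------------------------------------------------------------------

def threshold_direct(params: ModelParams) -> float:
    """Threshold tumor size for rescue by direct mutation.

    ``Nm* = (|r_s| / (v lambda_s)) * (lambda_m / r_m)``: the number of
    sensitive-cell deaths per successful mutation, times the inverse
    establishment probability of the mutant.  ``v = 0`` returns +inf.
    """
    d = derived_rates(params)
    if d.r_s >= 0:
        raise ValueError("threshold requires a declining sensitive population (r_s < 0)")
    if params.v == 0:
        return math.inf
    return (abs(d.r_s) / (params.v * params.lambda_s)) * (params.lambda_m / d.r_m)


def threshold_aneuploid(params: ModelParams) -> tuple[float, str]:
    """Threshold tumor size for aneuploidy-mediated rescue, with its branch.

    The prefactor ``|r_s| / (u lambda_s)`` counts sensitive deaths per
    aneuploid produced; the second factor is the expected number of
    aneuploid lineages needed for one to yield an established mutant:

    * tolerant:   ``(|r_a| / (v_a lambda_a)) * (lambda_m / r_m)``
    * stationary: ``2 lambda_a T* = sqrt(lambda_m / (v_a r_m))``
    * resistant:  ``lambda_a / r_a``

    In the direct-mutation regime the aneuploid route is negligible and
    the direct threshold is returned with branch ``"direct_mutation"``.
    """
    regime = classify_regime(params).regime
    if regime == "direct_mutation":
        return threshold_direct(params), "direct_mutation"
    d = derived_rates(params)
    pref = abs(d.r_s) / (params.u * params.lambda_s)
    if regime == "tolerant":
        factor = (abs(d.r_a) / (params.v_a * params.lambda_a)) * (params.lambda_m / d.r_m)
    elif regime == "stationary":
        factor = math.sqrt(params.lambda_m / (params.v_a * d.r_m))
    else:  # resistant
        factor = params.lambda_a / d.r_a
    return pref * factor, regime


def threshold_ratios(params: ModelParams) -> tuple[float, float, float]:
    """Threshold-size ratios (Na*/Nm*, standing/Na*, standing/Nm*).

    The aneuploid-to-direct ratio is computed branch-consistently as the
    quotient of the two threshold formulas.  The standing-variation ratio
    replaces the sensitive decline rate by the drug-free cost of
    aneuploidy and the induced by the pretreatment missegregation rate:
    ``(u/u_pre) * (c/|r_s|)``.  The third ratio is the product of the
    first two, by construction exact.
    """
    d = derived_rates(params)
    nm = threshold_direct(params)
    na, _branch = threshold_aneuploid(params)
    ratio_ad = na / nm if math.isfinite(nm) else math.nan
    if params.u_pre > 0 and params.u > 0:
        if params.c <= 0:
            raise ValueError("standing ratio undefined: c <= 0")
        ratio_sa = (params.u / params.u_pre) * (params.c / abs(d.r_s))
    else:
        ratio_sa = math.inf
    ratio_sd = ratio_sa * ratio_ad
    return ratio_ad, ratio_sa, ratio_sd


def rescue_probability(params: ModelParams, n: float, method: str = "exact") -> float:
    """Probability that a tumor of ``n`` cells is evolutionarily rescued.

    ``exact`` computes ``1 - q_s^n`` from the PGF fixed point.  ``approx``
    uses the threshold approximation ``1 - exp(-Lambda)`` where ``Lambda``
    sums ``n/Nm*`` and, outside the direct-mutation regime, ``n/Na*``.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if method == "exact":
        q_s = extinction_probabilities(params).q_s
        if q_s >= 1.0:
            return 0.0
        return -math.expm1(n * math.log(q_s))
    if method == "approx":
        lam = 0.0
        if params.v > 0:
            lam += n / threshold_direct(params)
        na, branch = threshold_aneuploid(params)
        if branch != "direct_mutation":
            lam += n / na
        return -math.expm1(-lam)
    raise ValueError(f"unknown method {method!r}; use 'exact' or 'approx'")


def theory_summary(params: ModelParams, n: Optional[int] = None) -> TheoryResult:
    """Gather thresholds, ratios, regime and rescue probability in one record."""
    n = params.n_init if n is None else int(n)
    nm = threshold_direct(params)
    na, branch = threshold_aneuploid(params)
    ratio_ad, ratio_sa, ratio_sd = threshold_ratios(params)
    n_standing = na * ratio_sa if math.isfinite(ratio_sa) else math.inf
    return TheoryResult(
        n_star_direct=nm,
        n_star_aneuploid=na,
        n_star_standing=n_standing,
        ratio_aneuploid_direct=ratio_ad,
        ratio_standing_aneuploid=ratio_sa,
        ratio_standing_direct=ratio_sd,
        regime=classify_regime(params).regime,
        branch=branch,
        rescue_prob_exact=rescue_probability(params, n, "exact"),
        rescue_prob_approx=rescue_probability(params, n, "approx"),
        n_init=n,
    )


# ---------------------------------------------------------------------------
# Deterministic (mean-field) trajectories
# ---------------------------------------------------------------------------

def _exp_diff(x: float, y: float, t: np.ndarray) -> np.ndarray:
    """(e^{x t} - e^{y t}) / (x - y), with the limit t e^{x t} as y -> x."""
    if abs(x - y) < 1e-12:
        return t * np.exp(x * t)
    return (np.exp(x * t) - np.exp(y * t)) / (x - y)


def deterministic_trajectory(
    params: ModelParams, n: float, t_grid: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-field cell counts (s, a, m) over a time grid.

    Starting from ``n`` sensitive cells, the expectations of the linear
    (density-independent) process are

        s(t) = N e^{r_s t}
        a(t) = u lambda_s N (e^{r_s t} - e^{r_a t}) / (r_s - r_a)
        m(t) : dm/dt = v lambda_s s + v_a lambda_a a + r_m m,  m(0) = 0,

    integrated in closed form.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or np.any(t < 0) or np.any(np.diff(t) < 0):
        raise ValueError("t_grid must be a sorted, nonnegative 1-D sequence")
    d = derived_rates(params)
    r_s, r_a, r_m = d.r_s, d.r_a, d.r_m

    s = n * np.exp(r_s * t)
    a = params.u * params.lambda_s * n * _exp_diff(r_s, r_a, t)

    # m(t) = int_0^t e^{r_m (t-tau)} [ v lam_s s(tau) + v_a lam_a a(tau) ] dtau
    m = params.v * params.lambda_s * n * _exp_diff(r_m, r_s, t)
    if params.u > 0 and params.v_a > 0:
        coeff = params.v_a * params.lambda_a * params.u * params.lambda_s * n
        if abs(r_s - r_a) < 1e-12:
            # a(tau) = u lam_s N tau e^{r_s tau}; integrate tau e^{r_s tau}
            # against e^{r_m (t - tau)} numerically (rare degenerate case).
            m = m + np.array([
                integrate.quad(
                    lambda tau, tt=tt: coeff * tau * math.exp(r_s * tau) * math.exp(r_m * (tt - tau)),
                    0.0, tt,
                )[0]
                for tt in t
            ])
        else:
            m = m + coeff / (r_s - r_a) * (_exp_diff(r_m, r_s, t) - _exp_diff(r_m, r_a, t))
    return s, a, m


# ---------------------------------------------------------------------------
# Rescue hazard and time summaries
# ---------------------------------------------------------------------------

def _hazard_closure(params: ModelParams, n: float, paths: str = "both"):
    """Return (Lambda(t) callable, Lambda(inf)) for tolerant/direct regimes.

    Successful (establishing) mutant lineages arrive as an inhomogeneous
    Poisson process with intensity
    ``p_m [ v lambda_s s(t) + v_a lambda_a a(t) ]`` over the deterministic
    sensitive/aneuploid trajectories.  Valid when both backgrounds decline
    (``r_s < 0`` and ``r_a < 0``, or ``u = 0``).

    ``paths`` restricts the hazard to one mutational route ("direct" for
    mutations in sensitive cells, "aneuploid" for mutations on the
    aneuploid background) -- useful for decomposing which route drives
    rescue; "both" is the full model.
    """
    if paths not in ("both", "direct", "aneuploid"):
        raise ValueError("paths must be 'both', 'direct', or 'aneuploid'")
    d = derived_rates(params)
    r_s, r_a = d.r_s, d.r_a
    if r_s >= 0:
        raise ValueError("rescue hazard requires r_s < 0")
    two_path = params.u > 0 and params.v_a > 0 and paths != "direct"
    if two_path and r_a >= 0:
        raise ValueError(
            "rescue hazard is unsupported for stationary/resistant aneuploids "
            "(r_a >= 0 with u > 0); use stochastic simulation instead"
        )
    p_m = d.p_m
    c_direct = params.v * params.lambda_s * n * p_m if paths != "aneuploid" else 0.0
    c_aneu = (
        params.v_a * params.lambda_a * params.u * params.lambda_s * n * p_m
        if two_path else 0.0
    )

    lam_inf = c_direct / abs(r_s)
    if two_path:
        lam_inf += c_aneu / (abs(r_s) * abs(r_a))

    def lam(t):
        t = np.asarray(t, dtype=float)
        out = c_direct * -np.expm1(r_s * t) / abs(r_s)
        if two_path:
            out = out + c_aneu / (r_s - r_a) * (
                -np.expm1(r_s * t) / abs(r_s) - -np.expm1(r_a * t) / abs(r_a)
            )
        return out

    return lam, lam_inf


def rescue_hazard(params: ModelParams, n: float):
    """Cumulative hazard of successful-mutant arrival.

    Returns ``(Lambda, Lambda_inf)`` where ``Lambda`` maps times (scalar or
    array, days) to the expected number of established mutant lineages
    born by that time, and ``Lambda_inf`` is its limit.  In the tolerant
    regime ``Lambda_inf = N/Nm* + N/Na*`` exactly.
    """
    return _hazard_closure(params, n)


def mean_rescue_time(params: ModelParams, n: float) -> TimeEstimate:
    """Mean waiting time for the first successful mutant lineage, given rescue.

    Small tumors (``N <= Na*/10``): ``-1/r_s - 1/r_a`` (two-step route;
    ``-1/r_s`` without aneuploidy).  Large tumors (``N >= 10 Nm*``):
    ``lambda_m / (v lambda_s N r_m)``.  In between, the conditional mean
    is integrated from the hazard: ``int (e^{-L(t)} - e^{-L_inf}) /
    (1 - e^{-L_inf}) dt``.
    """
    d = derived_rates(params)
    regime = classify_regime(params).regime
    if regime not in ("direct_mutation", "tolerant"):
        raise ValueError(
            f"mean rescue time has no analytic form in the {regime} regime; "
            "use stochastic simulation"
        )
    nm = threshold_direct(params)
    na, branch = threshold_aneuploid(params)
    two_path = branch != "direct_mutation"
    small_cut = (na if two_path else nm) / 10.0
    if n <= small_cut:
        val = -1.0 / d.r_s
        if two_path:
            val += -1.0 / d.r_a
        return TimeEstimate(val, "asymptotic_small_N")
    if n >= 10.0 * nm:
        return TimeEstimate(
            (1.0 / (params.v * params.lambda_s * n)) * (params.lambda_m / d.r_m),
            "asymptotic_large_N",
        )
    lam, lam_inf = _hazard_closure(params, n)
    tail = math.exp(-lam_inf)
    denom = 1.0 - tail
    scale = 1.0 / min(abs(d.r_a) if two_path else abs(d.r_s), abs(d.r_s))

    def integrand(t):
        return (math.exp(-float(lam(t))) - tail) / denom

    val, _err = integrate.quad(integrand, 0.0, 60.0 * scale, limit=400)
    return TimeEstimate(val, "hazard_integral")


def rescue_time_survival(
    params: ModelParams, n: float, t_grid: Sequence[float], conditioned: bool = False
) -> np.ndarray:
    """P(no successful mutant by t), optionally conditioned on eventual rescue.

    Unconditioned: ``e^{-Lambda(t)}`` (plateaus at ``1 - p_rescue``).
    Conditioned on rescue: ``(e^{-Lambda(t)} - e^{-Lambda_inf}) /
    (1 - e^{-Lambda_inf})``.
    """
    lam, lam_inf = _hazard_closure(params, n)
    t = np.asarray(t_grid, dtype=float)
    surv = np.exp(-lam(t))
    if conditioned:
        tail = math.exp(-lam_inf)
        surv = (surv - tail) / (1.0 - tail)
    return surv


# ---------------------------------------------------------------------------
# Recurrence and detection times (Monte-Carlo over rescue-lineage arrivals)
# ---------------------------------------------------------------------------

def _lambda_inverse_table(params: ModelParams, n: float, paths: str = "both", n_grid: int = 4096):
    """Monotone (Lambda, t) table for inverting the cumulative hazard."""
    lam, lam_inf = _hazard_closure(params, n, paths)
    d = derived_rates(params)
    two_path = params.u > 0 and params.v_a > 0 and paths != "direct"
    slow = abs(d.r_a) if two_path else abs(d.r_s)
    t_hi = 60.0 / slow
    t = np.concatenate([[0.0], np.geomspace(1e-4 / abs(d.r_s), t_hi, n_grid - 1)])
    lam_t = lam(t)
    return t, lam_t, lam_inf


def sample_rescue_lineages(
    params: ModelParams, n: float, draws: int, seed: int, paths: str = "both"
) -> list[np.ndarray]:
    """Sample birth times of successful mutant lineages, conditioned on rescue.

    Each draw is one rescued tumor: the number of establishing lineages is
    Poisson(``Lambda_inf``) conditioned to be >= 1, and their birth times
    are placed by inverting the cumulative hazard.  Returns a list of
    sorted arrays of lineage birth times (days).  ``paths`` restricts the
    arrival process to one mutational route (see :func:`rescue_hazard`).
    """
    rng = np.random.default_rng(seed)
    t_tab, lam_tab, lam_inf = _lambda_inverse_table(params, n, paths)
    p0 = math.exp(-lam_inf)
    u = rng.uniform(p0, 1.0, size=draws)
    ks = stats.poisson.ppf(u, lam_inf).astype(int)
    ks = np.maximum(ks, 1)
    out = []
    for k in ks:
        ell = rng.uniform(0.0, lam_inf, size=k)
        times = np.interp(ell, lam_tab, t_tab)
        times.sort()
        out.append(times)
    return out


def _recurrence_times_from_lineages(
    lineages: list[np.ndarray], p_m: float, r_m: float, target: float
) -> np.ndarray:
    """First time the summed lineage sizes reach ``target``.

    A successful lineage born at ``t_i`` grows, in conditional expectation,
    like ``(1/p_m) e^{r_m (t - t_i)}`` cells.  The crossing time solves
    ``sum_i (1/p_m) e^{r_m (t - t_i)} = target`` over the lineages already
    born by ``t``.
    """
    out = np.empty(len(lineages))
    log_tp = math.log(target * p_m)
    for j, ts in enumerate(lineages):
        w = np.cumsum(np.exp(-r_m * (ts - ts[0])))  # prefix sums, stabilized
        t_rec = ts[-1]  # fallback
        for k in range(len(ts)):
            cand = (log_tp - (math.log(w[k]) - r_m * ts[0])) / r_m
            cand = max(cand, ts[k])
            if k + 1 >= len(ts) or cand <= ts[k + 1]:
                t_rec = cand
                break
        out[j] = t_rec
    return out


def mean_recurrence_time(
    params: ModelParams,
    n: float,
    target: Optional[float] = None,
    draws: int = 2000,
    seed: int = 0,
) -> TimeEstimate:
    """Mean time for the mutant population to reach ``target`` cells, given rescue.

    Small tumors: mean rescue time plus the lineage growth time,
    ``-1/r_s - 1/r_a + ln(p_m N)/r_m``.  Large tumors: the deterministic
    constant ``(1/r_m) ln((r_m - r_s)/(v lambda_s))``, independent of
    ``N``.  In between, Monte-Carlo over the rescue-lineage arrival
    process (``draws`` conditioned samples; standard error reported).
    """
    target = float(n if target is None else target)
    if target < 1:
        raise ValueError("target must be >= 1 cell")
    d = derived_rates(params)
    regime = classify_regime(params).regime
    if regime not in ("direct_mutation", "tolerant"):
        raise ValueError(
            f"mean recurrence time has no analytic form in the {regime} regime; "
            "use stochastic simulation"
        )
    nm = threshold_direct(params)
    na, branch = threshold_aneuploid(params)
    two_path = branch != "direct_mutation"
    small_cut = (na if two_path else nm) / 10.0
    if n <= small_cut:
        val = -1.0 / d.r_s + math.log(d.p_m * target) / d.r_m
        if two_path:
            val += -1.0 / d.r_a
        return TimeEstimate(val, "asymptotic_small_N")
    if n >= 10.0 * nm:
        return TimeEstimate(
            math.log((d.r_m - d.r_s) / (params.v * params.lambda_s)) / d.r_m,
            "asymptotic_large_N",
        )
    lineages = sample_rescue_lineages(params, n, draws, seed)
    times = _recurrence_times_from_lineages(lineages, d.p_m, d.r_m, target)
    return TimeEstimate(
        float(times.mean()), "monte_carlo",
        stderr=float(times.std(ddof=1) / math.sqrt(len(times))), n=len(times),
    )


def mean_detection_time(
    params: ModelParams,
    n: float,
    detection_target: float,
    draws: int = 2000,
    seed: int = 0,
) -> TimeEstimate:
    """Mean time for the mutant population to reach the detection size ``M``.

    Same machinery as the recurrence time with ``target = M``; for large
    tumors (``N >= 10 Nm*``), where many lineages contribute and the mutant
    dynamics are deterministic, the crossing time of the mean-field
    trajectory ``m(t) = M`` is used instead.
    """
    m_target = float(detection_target)
    if m_target < 1:
        raise ValueError("detection target must be >= 1 cell")
    nm = threshold_direct(params)
    if n >= 10.0 * nm:
        def f(t):
            return deterministic_trajectory(params, n, [t])[2][0] - m_target

        t_hi = 1.0
        while f(t_hi) < 0:
            t_hi *= 2.0
            if t_hi > 1e9:
                raise RuntimeError("detection target never reached by mean trajectory")
        t_cross = optimize.brentq(f, 0.0, t_hi)
        return TimeEstimate(float(t_cross), "ode")
    return mean_recurrence_time(params, n, target=m_target, draws=draws, seed=seed)


def recurrence_survival(
    params: ModelParams,
    n: float,
    target: float,
    t_grid: Sequence[float],
    draws: int = 2000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """P(mutant population below ``target`` at t), conditioned on rescue.

    Monte-Carlo estimate over the rescue-lineage arrival process; returns
    ``(survival, ci_low, ci_high)`` with pointwise 95% binomial intervals.
    """
    d = derived_rates(params)
    lineages = sample_rescue_lineages(params, n, draws, seed)
    times = _recurrence_times_from_lineages(lineages, d.p_m, d.r_m, target)
    t = np.asarray(t_grid, dtype=float)
    surv = (times[None, :] > t[:, None]).mean(axis=1)
    half = 1.96 * np.sqrt(surv * (1.0 - surv) / len(times))
    return surv, np.clip(surv - half, 0, 1), np.clip(surv + half, 0, 1)
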