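"""Experiment drivers: theory-vs-simulation comparisons at desk scale.

Each driver sweeps one quantity, runs replicate ensembles, and tabulates
simulation estimates with confidence intervals next to the corresponding
analytic predictions.  Rescue fractions carry normal-approximation
binomial intervals (``p +/- 1.96 sqrt(p(1-p)/n)``); time statistics carry
percentile-bootstrap intervals.

Full-scale tumor parameters (N up to 1e10 with v = 1e-7) are not
simulated directly -- a single replicate would take ~1e8 events.  The
drivers default to *scaled* instances (larger mutation rate, smaller N)
chosen so the dimensionless operating point ``N/N*`` matches the regime
of interest, while the analytic layer is evaluated wherever asked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import theory
from .params import ModelParams, classify_regime, derived_rates
from .simulate import (
    PopulationState,
    StopRule,
    run_replicates,
)

__all__ = [
    "SweepSpec",
    "ComparisonTable",
    "bootstrap_ci",
    "binomial_ci",
    "rescue_curve_experiment",
    "threshold_vs_ra_experiment",
    "threshold_vs_rate_ratio_experiment",
    "standing_variation_experiment",
    "window_of_opportunity_experiment",
    "recurrence_experiment",
    "simulated_threshold",
    "scaled_melanoma",
]


@dataclass(frozen=True)
class SweepSpec:
    """A one-parameter sweep: which field to vary, over which grid."""

    parameter: str
    grid: tuple
    base: ModelParams
    replicates: int = 100
    base_seed: int = 0
    method: str = "ssa"

    def __post_init__(self):
        if len(self.grid) == 0:
            raise ValueError("grid must be nonempty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class ComparisonTable:
    """Tabulated theory-vs-simulation results plus a run manifest."""

    table: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def scaled_melanoma(n_init: int = 1000, v: float = 1e-3, **overrides) -> ModelParams:
    """Melanoma rates rescaled to a desk-runnable operating point.

    Raising the mutation rate from 1e-7 to ``v`` and shrinking ``N``
    keeps ``N/N*`` of order one while a replicate takes ~1e4 events.
    """
    from .params import preset

    return preset("melanoma_a375").with_(n_init=n_init, v=v, **overrides)


# ---------------------------------------------------------------------------
# Confidence intervals
# ---------------------------------------------------------------------------

def binomial_ci(p_hat: float, n: int) -> tuple[float, float]:
    """Normal-approximation 95% interval for a proportion."""
    half = 1.96 * math.sqrt(max(p_hat * (1.0 - p_hat), 0.0) / n)
    return max(0.0, p_hat - half), min(1.0, p_hat + half)


_STATS: dict[str, Callable] = {
    "mean": lambda x, axis: np.mean(x, axis=axis),
    "median": lambda x, axis: np.median(x, axis=axis),
    "proportion": lambda x, axis: np.mean(x, axis=axis),
}


def bootstrap_ci(
    samples: Sequence[float],
    statistic: str = "mean",
    b: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap 95% interval of a named statistic.

    Resamples with replacement ``b`` times and returns the empirical
    2.5th/97.5th percentiles of the statistic.  Constant input yields a
    degenerate zero-width interval.
    """
    if statistic not in _STATS:
        raise ValueError(f"statistic must be one of {sorted(_STATS)}")
    data = np.asarray(samples, dtype=float)
    if data.ndim != 1 or data.size < 2:
        raise ValueError("need at least 2 samples")
    if b < 100:
        raise ValueError("b must be >= 100")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, data.size, size=(b, data.size))
    stats = _STATS[statistic](data[idx], 1)
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

def _rescue_fraction(params: ModelParams, n: int, replicates: int, seed: int,
                     method: str = "ssa", standing: bool = False) -> float:
    res = run_replicates(
        params.with_(n_init=int(n)), replicates, seed, method=method,
        stop=StopRule(), standing_variation=standing,
    )
    return float(np.mean([r.outcome == "rescued" for r in res]))


def rescue_curve_experiment(spec: SweepSpec) -> ComparisonTable:
    """Rescue probability versus initial tumor size.

    Sweeps ``n_init``; per point, the simulated rescue fraction with its
    binomial interval next to the exact (``1 - q_s^N``) and threshold-
    approximation curves.  The manifest records the threshold sizes.
    """
    if spec.parameter != "n_init":
        raise ValueError("rescue curve sweeps n_init")
    rows = []
    for j, n in enumerate(spec.grid):
        n = int(n)
        frac = _rescue_fraction(spec.base, n, spec.replicates,
                                spec.base_seed + j, spec.method)
        lo, hi = binomial_ci(frac, spec.replicates)
        rows.append({
            "n_init": n,
            "sim_fraction": frac,
            "ci_low": lo,
            "ci_high": hi,
            "n_replicates": spec.replicates,
            "theory_exact": theory.rescue_probability(spec.base, n, "exact"),
            "theory_approx": theory.rescue_probability(spec.base, n, "approx"),
        })
    na, branch = theory.threshold_aneuploid(spec.base)
    manifest = {
        "experiment": "rescue_curve",
        "n_star_direct": theory.threshold_direct(spec.base),
        "n_star_aneuploid": na,
        "branch": branch,
        "base_seed": spec.base_seed,
        "method": spec.method,
    }
    return ComparisonTable(pd.DataFrame(rows), manifest)


def simulated_threshold(
    params: ModelParams,
    replicates: int = 100,
    base_seed: int = 0,
    n_lo: float = 1.0,
    n_hi: Optional[float] = None,
    iters: int = 10,
) -> float:
    """Estimate the threshold tumor size N* from simulations.

    Bisects over ``N`` (log scale) for the size at which the simulated
    rescue fraction crosses ``1 - 1/e ~ 0.632``, the defining property of
    ``N* = 1/p_s``.
    """
    target = 1.0 - math.exp(-1.0)
    if n_hi is None:
        q_s = theory.extinction_probabilities(params).q_s
        n_hi = 20.0 / max(1.0 - q_s, 1e-300)
    lo, hi = math.log(n_lo), math.log(n_hi)
    for k in range(iters):
        mid = 0.5 * (lo + hi)
        frac = _rescue_fraction(params, int(round(math.exp(mid))),
                                replicates, base_seed + 1000 * k)
        if frac < target:
            lo = mid
        else:
            hi = mid
    return math.exp(0.5 * (lo + hi))


def threshold_vs_ra_experiment(spec: SweepSpec, simulate: bool = True) -> ComparisonTable:
    """Threshold tumor size versus the aneuploid growth rate.

    Sweeps ``lambda_a``; per point, the branch approximation for ``Na*``,
    the exact threshold ``1/p_s`` from the PGF fixed point, and (optional)
    a bisection estimate of the threshold from simulated rescue fractions.
    """
    if spec.parameter != "lambda_a":
        raise ValueError("threshold sweep varies lambda_a")
    rows = []
    for j, lam_a in enumerate(spec.grid):
        p = spec.base.with_(lambda_a=float(lam_a))
        na, branch = theory.threshold_aneuploid(p)
        row = {
            "lambda_a": float(lam_a),
            "r_a": p.r_a,
            "n_star_branch": na,
            "branch": branch,
            "n_star_exact": 1.0 / max(theory.extinction_probabilities(p).p_s, 1e-300),
        }
        if simulate:
            row["n_star_sim"] = simulated_threshold(
                p, spec.replicates, spec.base_seed + 10_000 * j
            )
        rows.append(row)
    manifest = {
        "experiment": "threshold_vs_ra",
        "n_star_direct": theory.threshold_direct(spec.base),
        "base_seed": spec.base_seed,
    }
    return ComparisonTable(pd.DataFrame(rows), manifest)


def threshold_vs_rate_ratio_experiment(spec: SweepSpec) -> ComparisonTable:
    """Threshold tumor size versus the missegregation/mutation rate ratio u/v.

    Sweeps ``u``; reports the branch approximation and the exact
    ``1/p_s`` (the aneuploidy-free ``Nm*`` is in the manifest as the
    reference level).
    """
    if spec.parameter != "u":
        raise ValueError("rate-ratio sweep varies u")
    rows = []
    for u in spec.grid:
        p = spec.base.with_(u=float(u))
        na, branch = theory.threshold_aneuploid(p)
        rows.append({
            "u": float(u),
            "u_over_v": float(u) / p.v if p.v > 0 else math.inf,
            "n_star_branch": na,
            "branch": branch,
            "n_star_exact": 1.0 / max(theory.extinction_probabilities(p).p_s, 1e-300),
        })
    manifest = {
        "experiment": "threshold_vs_rate_ratio",
        "n_star_direct": theory.threshold_direct(spec.base),
    }
    return ComparisonTable(pd.DataFrame(rows), manifest)


def standing_variation_experiment(
    spec: SweepSpec, simulate: bool = False
) -> ComparisonTable:
    """Standing-variation threshold ratios across a sweep.

    Sweeps ``mu_s`` (changing the sensitive growth rate) or ``u_pre``;
    per point the ratio of standing to de novo thresholds
    ``(u/u_pre)(c/|r_s|)`` and the standing-to-direct ratio.  With
    ``simulate=True``, bisection threshold estimates with and without
    standing variation give a simulated ratio.
    """
    if spec.parameter not in ("mu_s", "u_pre"):
        raise ValueError("standing-variation sweep varies mu_s or u_pre")
    rows = []
    for j, val in enumerate(spec.grid):
        p = spec.base.with_(**{spec.parameter: float(val)})
        ratio_ad, ratio_sa, ratio_sd = theory.threshold_ratios(p)
        row = {
            spec.parameter: float(val),
            "r_s": p.r_s,
            "u_pre_over_u": p.u_pre / p.u if p.u > 0 else math.inf,
            "ratio_standing_aneuploid": ratio_sa,
            "ratio_standing_direct": ratio_sd,
            "ratio_aneuploid_direct": ratio_ad,
        }
        if simulate:
            n_dn = simulated_threshold(p, spec.replicates, spec.base_seed + 10_000 * j)
            # standing run: the same bisection with binomially seeded aneuploids
            target = 1.0 - math.exp(-1.0)
            q_s = theory.extinction_probabilities(p).q_s
            lo, hi = 0.0, math.log(20.0 / max(1.0 - q_s, 1e-300))
            for k in range(10):
                mid = 0.5 * (lo + hi)
                frac = _rescue_fraction(
                    p.with_(n_init=int(round(math.exp(mid)))), int(round(math.exp(mid))),
                    spec.replicates, spec.base_seed + 10_000 * j + 100 * k,
                    standing=True,
                )
                if frac < target:
                    lo = mid
                else:
                    hi = mid
            row["n_star_sim_denovo"] = n_dn
            row["n_star_sim_standing"] = math.exp(0.5 * (lo + hi))
            row["ratio_sim"] = row["n_star_sim_standing"] / n_dn
        rows.append(row)
    return ComparisonTable(pd.DataFrame(rows), {"experiment": "standing_variation"})


def window_of_opportunity_experiment(
    conditions: dict[str, ModelParams],
    n: int,
    t_grid: Sequence[float],
    replicates: int = 100,
    base_seed: int = 0,
) -> ComparisonTable:
    """Survival of the no-successful-mutant-yet state, per aneuploidy condition.

    For each named condition, the Monte-Carlo estimate (fraction of
    replicates whose eventually-successful first mutant lineage has not
    yet been born by ``t``) with binomial CI; the analytic curve
    ``e^{-Lambda(t)}`` is added where the hazard is defined (declining
    aneuploids or no aneuploidy).
    """
    t = np.asarray(t_grid, dtype=float)
    rows = []
    for j, (name, p) in enumerate(conditions.items()):
        p = p.with_(n_init=int(n))
        res = run_replicates(p, replicates, base_seed + 10_000 * j, stop=StopRule())
        rescue_times = np.array([
            r.rescue_time if r.outcome == "rescued" else math.inf for r in res
        ])
        try:
            analytic = theory.rescue_time_survival(p, n, t, conditioned=False)
        except ValueError:
            analytic = np.full_like(t, math.nan)
        for ti, ai in zip(t, analytic):
            frac = float(np.mean(rescue_times > ti))
            lo, hi = binomial_ci(frac, replicates)
            rows.append({
                "condition": name,
                "t": float(ti),
                "sim_survival": frac,
                "ci_low": lo,
                "ci_high": hi,
                "analytic_survival": float(ai),
            })
    return ComparisonTable(
        pd.DataFrame(rows),
        {"experiment": "window_of_opportunity", "n_init": int(n),
         "replicates": replicates, "base_seed": base_seed},
    )


def recurrence_experiment(
    spec: SweepSpec,
    draws: int = 2000,
    target: Optional[Callable[[int], float]] = None,
) -> ComparisonTable:
    """Mean recurrence time versus initial tumor size.

    Sweeps ``n_init``; per point, the small-tumor closed form, the
    Monte-Carlo estimate over rescue-lineage arrivals (with bootstrap CI),
    and the large-tumor constant.  The recurrence target defaults to the
    initial size ``N`` itself.
    """
    if spec.parameter != "n_init":
        raise ValueError("recurrence experiment sweeps n_init")
    p = spec.base
    d = derived_rates(p)
    large_n_constant = math.log((d.r_m - d.r_s) / (p.v * p.lambda_s)) / d.r_m
    rows = []
    for j, n in enumerate(spec.grid):
        n = float(n)
        tgt = float(target(n)) if target is not None else n
        small = -1.0 / d.r_s + math.log(d.p_m * tgt) / d.r_m
        if p.u > 0 and classify_regime(p).regime == "tolerant":
            small += -1.0 / d.r_a
        lineages = theory.sample_rescue_lineages(p, n, draws, spec.base_seed + j)
        times = theory._recurrence_times_from_lineages(lineages, d.p_m, d.r_m, tgt)
        lo, hi = bootstrap_ci(times, "mean", 1000, spec.base_seed + j)
        rows.append({
            "n_init": n,
            "target": tgt,
            "mc_mean": float(times.mean()),
            "mc_stderr": float(times.std(ddof=1) / math.sqrt(len(times))),
            "ci_low": lo,
            "ci_high": hi,
            "small_n_form": small,
            "large_n_constant": large_n_constant,
            "n_draws": draws,
        })
    return ComparisonTable(
        pd.DataFrame(rows),
        {"experiment": "recurrence", "large_n_constant": large_n_constant,
         "base_seed": spec.base_seed},
    )
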