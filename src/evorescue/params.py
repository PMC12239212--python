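"""Model parameters, literature presets, derived rates, and regime classification.

The model tracks three genotypes of cancer cells under drug treatment:
drug-sensitive (``s``), aneuploid (``a``), and resistant mutant (``m``).
Each genotype ``k`` divides at rate ``lambda_k`` and dies at rate ``mu_k``
(per day); the net growth rate is ``r_k = lambda_k - mu_k``.  Sensitive
cells missegregate into aneuploids at rate ``u`` per division, and both
sensitive and aneuploid cells acquire the resistance mutation at rates
``v`` and ``v_a`` per division, respectively.

Aneuploidy may be *tolerant* (``r_a < 0`` but declining slower than the
sensitive cells), *stationary* (``r_a ~ 0``), or *resistant* (``r_a > 0``),
and each case leads to a qualitatively different route to evolutionary
rescue of the tumor.  The scale on which "close to zero" is judged is the
critical lineage-survival time ``T*``: the time an aneuploid lineage must
survive, in expectation, to spawn a resistant mutant lineage that escapes
stochastic extinction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Optional

__all__ = [
    "ModelParams",
    "DerivedRates",
    "RegimeReport",
    "preset",
    "available_presets",
    "derived_rates",
    "classify_regime",
    "aneuploidy_cost_from_competition",
    "tnbc_sensitive_death_rate_recomputed",
]


@dataclass(frozen=True)
class ModelParams:
    """All per-genotype rates and mutation/missegregation parameters.

    Rates ``lambda_*`` and ``mu_*`` are per day; ``u``, ``u_pre``, ``v``
    and ``v_a`` are probabilities per cell division; ``c`` is the selection
    coefficient against aneuploidy in the drug-free environment (per day);
    ``n_init`` is the initial tumor size in cells.  ``carrying_capacity``
    enables the logistic (density-dependent) variant of the model; ``None``
    means density-independent growth.

    ``v_a`` defaults to ``v``; setting it higher models an elevated
    mutation rate in aneuploid cells.
    """

    lambda_s: float
    mu_s: float
    lambda_a: float
    mu_a: float
    lambda_m: float
    mu_m: float
    u: float
    v: float
    c: float
    n_init: int
    u_pre: float = 0.0
    v_a: Optional[float] = None
    carrying_capacity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.v_a is None:
            object.__setattr__(self, "v_a", self.v)
        rate_fields = (
            "lambda_s", "mu_s", "lambda_a", "mu_a", "lambda_m", "mu_m",
            "u", "u_pre", "v", "v_a", "c",
        )
        for name in rate_fields:
            val = getattr(self, name)
            if not math.isfinite(val) or val < 0:
                raise ValueError(f"{name} must be finite and nonnegative, got {val!r}")
        for name in ("u", "u_pre", "v", "v_a"):
            if getattr(self, name) >= 1:
                raise ValueError(f"{name} is a per-division probability and must be < 1")
        if self.u + self.v >= 1:
            raise ValueError("u + v must be < 1")
        if self.n_init < 0:
            raise ValueError("n_init must be a nonnegative cell count")
        object.__setattr__(self, "n_init", int(self.n_init))
        if self.carrying_capacity is not None and self.carrying_capacity <= 0:
            raise ValueError("carrying_capacity must be positive (or None)")
        if self.mu_s <= self.lambda_s:
            # Not fatal: drug-free runs legitimately have growing sensitive
            # cells, but every rescue analysis assumes r_s < 0.
            warnings.warn(
                "mu_s <= lambda_s: sensitive cells are not declining (r_s >= 0); "
                "rescue-theory results assume a declining sensitive population",
                stacklevel=2,
            )

    @property
    def r_s(self) -> float:
        return self.lambda_s - self.mu_s

    @property
    def r_a(self) -> float:
        return self.lambda_a - self.mu_a

    @property
    def r_m(self) -> float:
        return self.lambda_m - self.mu_m

    def with_(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced.

        If ``v`` is replaced while ``v_a`` currently equals ``v`` (i.e. it
        was never explicitly decoupled), ``v_a`` follows the new ``v``.
        """
        if "v" in changes and "v_a" not in changes and self.v_a == self.v:
            changes["v_a"] = changes["v"]
        return replace(self, **changes)


@dataclass(frozen=True)
class DerivedRates:
    """Quantities derived from a :class:`ModelParams`.

    ``p_m`` is the establishment probability of a single mutant lineage,
    ``r_m / lambda_m`` (clipped to [0, 1]).  ``t_star`` is the critical
    aneuploid-lineage survival time ``T* = sqrt(lambda_m / (v_a r_m)) /
    (2 lambda_a)`` in days, and ``ra_tstar = r_a * T*`` is the dimensionless
    change in aneuploid log-population size over that time.  ``f_standing``
    is the pretreatment aneuploid fraction at missegregation-selection
    balance, ``u_pre * lambda_s / c``.
    """

    r_s: float
    r_a: float
    r_m: float
    p_m: float
    t_star: float
    ra_tstar: float
    f_standing: float


@dataclass(frozen=True)
class RegimeReport:
    """Outcome of the rescue-regime classification.

    ``regime`` is one of ``direct_mutation``, ``tolerant``, ``stationary``,
    ``resistant``.  ``conditions`` records the numeric values entering the
    decision (``u*lambda_a``, ``u*lambda_a*T*``, ``ra*T*``, ``-r_a``,
    ``1/T*``) so stricter cutoffs can be applied by the caller.
    """

    regime: str
    ra_tstar: float
    u_lambda_a: float
    u_lambda_a_tstar: float
    conditions: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

# Melanoma A375 under vemurafenib.  The drug-free missegregation rate is
# 1e-3 per division; the drug raises it tenfold.  A single target gene at
# mutation rate 1e-7 per division confers resistance.
_MELANOMA = dict(
    lambda_s=0.1, mu_s=0.14,
    lambda_a=0.0899, mu_a=0.09,
    lambda_m=0.1, mu_m=0.09,
    u=1e-2, u_pre=1e-3, v=1e-7, c=0.07,
    n_init=10_000_000,
)

# Triple-negative breast cancer PDX clones under cisplatin.  Division rates
# are log(2)/8.2 = 0.0845 for all genotypes; clone identity enters only
# through the aneuploid death rate.  Remaining parameters are shared with
# the melanoma set.
def _tnbc(mu_a: float) -> dict:
    d = dict(_MELANOMA)
    d.update(
        lambda_s=0.0845, mu_s=0.1215,
        lambda_a=0.0845, mu_a=mu_a,
        lambda_m=0.0845, mu_m=0.076,
    )
    return d


_PRESETS = {
    "melanoma_a375": _MELANOMA,
    "tnbc_sa609": _tnbc(0.076),
    "tnbc_sa1035": _tnbc(0.1015),
    "tnbc_sa535": _tnbc(0.1115),
}


def available_presets() -> list[str]:
    return sorted(_PRESETS)


def preset(name: str) -> ModelParams:
    """Return a literature parameter set by name.

    Known presets: ``melanoma_a375`` (A375 melanoma / vemurafenib),
    ``tnbc_sa609``, ``tnbc_sa1035``, ``tnbc_sa535`` (TNBC PDX clones /
    cisplatin).
    """
    try:
        return ModelParams(**_PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available presets: {', '.join(available_presets())}"
        ) from None


def tnbc_sensitive_death_rate_recomputed() -> float:
    """Back-calculate the TNBC sensitive death rate from fitness estimates.

    The TNBC presets store mu_s = 0.1215 as published.  Recomputing it from
    the underlying estimates -- relative Wrightian fitness 1.047 of the
    fittest clone under drug, drug-free growth rate 0.0085/day, division
    rate log(2)/8.2/day, and the assumption that the drug acts on death
    rates only -- gives a slightly different value (~0.1219):

        r_s = r_SA609 - ln(1.047),  mu_s = lambda_s - r_s.

    This helper documents that recomputation path without overriding the
    stored preset value.
    """
    lambda_div = math.log(2) / 8.2
    r_fittest = 0.0085
    r_s = r_fittest - math.log(1.047)
    return lambda_div - r_s


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def derived_rates(params: ModelParams) -> DerivedRates:
    """Compute net growth rates, p_m, T*, r_a*T*, and the standing fraction.

    Raises if the mutant is not resistant (``r_m <= 0``) or if a positive
    pretreatment missegregation rate is combined with a vanishing cost of
    aneuploidy (the standing fraction would be undefined).
    """
    r_s, r_a, r_m = params.r_s, params.r_a, params.r_m
    if r_m <= 0:
        raise ValueError("mutant not resistant: requires lambda_m > mu_m (r_m > 0)")
    p_m = max(0.0, r_m / params.lambda_m)

    if params.v_a > 0:
        t_star = math.sqrt(params.lambda_m / (params.v_a * r_m)) / (2.0 * params.lambda_a)
    else:
        t_star = math.inf

    if params.u_pre > 0:
        if params.c <= 0:
            raise ValueError("standing fraction undefined: c <= 0 with u_pre > 0")
        f_standing = params.u_pre * params.lambda_s / params.c
    else:
        f_standing = 0.0

    return DerivedRates(
        r_s=r_s, r_a=r_a, r_m=r_m, p_m=p_m,
        t_star=t_star, ra_tstar=r_a * t_star, f_standing=f_standing,
    )


def classify_regime(params: ModelParams) -> RegimeReport:
    """Classify the rescue regime of a parameter set.

    Rescue proceeds by direct mutation alone when aneuploid lineages are
    too rare or short-lived to matter: when ``u*lambda_a*T* < 1``, or when
    aneuploidy is rare (``u*lambda_a < -r_a``) and drug-sensitive
    (``r_a*T* < -1``).  Otherwise the aneuploid route matters, and the
    regime follows the sign and size of ``r_a*T*``: tolerant
    (``r_a*T* <= -1``), stationary (``|r_a*T*| < 1``), or resistant
    (``r_a*T* >= 1``).  The asymptotic conditions are implemented as hard
    cutoffs at +/-1; the report exposes the raw values so callers can apply
    stricter ones.
    """
    d = derived_rates(params)
    u_la = params.u * params.lambda_a
    u_la_tstar = u_la * d.t_star if math.isfinite(d.t_star) else math.inf
    ra_tstar = d.ra_tstar

    # Type of the aneuploid genotype itself, judged purely on the r_a*T*
    # scale.  This can differ from the rescue-path regime: an aneuploid may
    # be strongly tolerant (r_a*T* << -1) and yet too rarely produced
    # (u*lambda_a < |r_a|) to beat the direct mutational route.
    if ra_tstar <= -1:
        aneuploid_type = "tolerant"
    elif ra_tstar < 1:
        aneuploid_type = "stationary"
    else:
        aneuploid_type = "resistant"

    conditions = {
        "u*lambda_a": u_la,
        "u*lambda_a*T*": u_la_tstar,
        "ra*T*": ra_tstar,
        "-r_a": -d.r_a,
        "1/T*": 1.0 / d.t_star if math.isfinite(d.t_star) else 0.0,
        "aneuploid_type": aneuploid_type,
    }

    if params.u == 0 or params.v_a == 0:
        # No aneuploid route to resistance exists at all.
        regime = "direct_mutation"
    elif u_la_tstar < 1 or (u_la < -d.r_a and ra_tstar < -1):
        regime = "direct_mutation"
    elif ra_tstar <= -1:
        regime = "tolerant"
    elif ra_tstar < 1:
        regime = "stationary"
    else:
        regime = "resistant"

    return RegimeReport(
        regime=regime,
        ra_tstar=ra_tstar,
        u_lambda_a=u_la,
        u_lambda_a_tstar=u_la_tstar,
        conditions=conditions,
    )


def aneuploidy_cost_from_competition(fraction_final: float, days: float) -> float:
    """Selection coefficient against aneuploidy from a 1:1 competition assay.

    Aneuploid and sensitive cells are mixed 1:1 in a drug-free environment;
    after ``days`` days the aneuploid fraction is ``fraction_final``.  Under
    exponential competition the cost per day is
    ``|ln(f/(1-f)) / days|``.
    """
    if days <= 0:
        raise ValueError("days must be positive")
    if not 0 < fraction_final < 1:
        raise ValueError("degenerate competition outcome: fraction must be in (0, 1)")
    return abs(math.log(fraction_final / (1.0 - fraction_final)) / days)


def params_to_dict(params: ModelParams) -> dict:
    """Flat dict of all parameter fields (for manifests and configs)."""
    return {f.name: getattr(params, f.name) for f in fields(params)}
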