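"""Likelihood-ratio testing of post-split migration and conversion of
isolation-with-migration scaled parameters to demographic units.

Because a zero migration rate lies on the boundary of the parameter
space, the null distribution of the -2 log(Lambda) statistic is the
50:50 mixture of a point mass at zero (chi-square with 0 df) and a
chi-square with 1 df; the alpha-level critical value is therefore the
chi-square(1) quantile at 1 - 2*alpha (2.71 at alpha = 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import chi2


@dataclass
class LrtResult:
    statistic: float
    p_value: float
    alpha: float
    critical_value: float
    decision: bool   # True: reject zero migration

    def __str__(self) -> str:
        verdict = "migration supported" if self.decision else "no significant migration"
        return (f"-2log(Lambda) = {self.statistic:.2f}, p = {self.p_value:.3f} "
                f"(critical value {self.critical_value:.2f} at alpha = {self.alpha}): "
                f"{verdict}")


def mixture_critical_value(alpha: float = 0.05) -> float:
    """Critical value of the 50:50 chi2(0)/chi2(1) boundary mixture: the
    (1 - 2*alpha) quantile of chi-square with 1 df."""
    if not 0.0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5): the point mass at zero "
                         "carries probability 0.5")
    return float(chi2.ppf(1.0 - 2.0 * alpha, df=1))


def mixture_lrt_pvalue(statistic: float, alpha: float = 0.05) -> LrtResult:
    """P-value of -2log(Lambda) under the 50:50 chi2(0)/chi2(1) mixture.

    p = 0.5 * P(chi2_1 >= statistic) for a positive statistic and 1 at
    zero (the point mass).
    """
    if statistic < 0:
        raise ValueError("the likelihood-ratio statistic cannot be negative")
    p = 1.0 if statistic == 0 else float(0.5 * chi2.sf(statistic, df=1))
    crit = mixture_critical_value(alpha)
    return LrtResult(statistic=float(statistic), p_value=p, alpha=alpha,
                     critical_value=crit, decision=statistic > crit)


# --------------------------------------------------------------------------
# IM parameter scaling


@dataclass
class ImScaling:
    """Locus-wide yearly mutation rates, generation time and inheritance
    scalars used to convert IM's scaled q and t estimates."""

    mu_cp: float = 1.67e-6
    mu_its: float = 1.24e-6
    generation_time: float = 25.0
    scalar_cp: float = 0.25
    scalar_nuclear: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mu_cp", "mu_its", "generation_time",
                     "scalar_cp", "scalar_nuclear"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def u_year(self) -> float:
        """Geometric mean of the per-locus yearly rates."""
        return math.sqrt(self.mu_cp * self.mu_its)

    @property
    def u_gen(self) -> float:
        return self.u_year * self.generation_time


def convert_im_estimates(q_values, t_values, scaling: ImScaling | None = None):
    """Convert scaled q and t to effective sizes (individuals) and years.

    Ne = q / (4 u_gen) with u_gen the geometric-mean yearly rate times the
    generation time; T_years = t / u_year (t scaled by the yearly rate, so
    times are reported directly in years).  Returns ``(Ne_list, years_list,
    meta)`` with the scaling constants echoed in ``meta``.
    """
    scaling = scaling or ImScaling()
    scalar_q = [float(q) for q in _aslist(q_values)]
    scalar_t = [float(t) for t in _aslist(t_values)]
    if any(q < 0 for q in scalar_q) or any(t < 0 for t in scalar_t):
        raise ValueError("q and t must be non-negative")
    ne = [q / (4.0 * scaling.u_gen) for q in scalar_q]
    years = [t / scaling.u_year for t in scalar_t]
    meta = {
        "u_year": scaling.u_year,
        "u_gen": scaling.u_gen,
        "generation_time": scaling.generation_time,
        "rate_combination": "geometric mean of per-locus yearly rates",
    }
    return ne, years, meta


def deconvert_im_estimates(ne_values, year_values, scaling: ImScaling | None = None):
    """Inverse of :func:`convert_im_estimates` (round-trip helper)."""
    scaling = scaling or ImScaling()
    q = [4.0 * scaling.u_gen * float(n) for n in _aslist(ne_values)]
    t = [scaling.u_year * float(y) for y in _aslist(year_values)]
    return q, t


def _aslist(x):
    try:
        return list(x)
    except TypeError:
        return [x]


def inheritance_scalar(ploidy: str, transmission: str,
                       sex_system: str = "dioecious_equal") -> float:
    """Relative effective size of a locus given its ploidy and transmission.

    The scalar is the product of a ploidy factor (haploid 1/2, diploid 1)
    and a transmitting-sex factor (uniparental 1/2 under an even dioecious
    sex ratio, biparental 1): a paternally inherited haploid chloroplast
    scores 0.25, a biparental diploid nuclear locus 1.
    """
    ploidy_factors = {"haploid": 0.5, "diploid": 1.0}
    transmission_factors = {"uniparental": 0.5, "biparental": 1.0}
    if sex_system != "dioecious_equal":
        raise ValueError(f"unsupported sex system {sex_system!r}")
    if ploidy not in ploidy_factors:
        raise ValueError(f"unsupported ploidy {ploidy!r}")
    if transmission not in transmission_factors:
        raise ValueError(f"unsupported transmission {transmission!r}")
    return ploidy_factors[ploidy] * transmission_factors[transmission]
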