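"""Product-of-coefficients mediation on the network-MR path X -> M -> Y.

The indirect effect of the exposure on the outcome through one mediator is
the product of the exposure->mediator and mediator->outcome causal
estimates; its variance comes from the multivariate delta method treating
the two estimates as independent (they derive from non-overlapping
two-sample MR fits):

    Var(ab) ≈ a²·Var(b) + b²·Var(a)

The proportion mediated divides the indirect effect by the total
exposure->outcome effect, again with a delta-method interval; it is
reported only when the indirect effect is statistically significant and
shares the sign of the total effect — a ratio of a noisy or opposing
numerator to the total is not interpretable as a proportion.

Mediators are tiered by two binary criteria: surviving multivariable
adjustment, and a significant positive (total-effect-aligned) mediation
effect.  Both -> strong; exactly one -> moderate; neither -> potential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

Z95 = stats.norm.ppf(0.975)

TIER_STRONG = "strong"
TIER_MODERATE = "moderate"
TIER_POTENTIAL = "potential"


@dataclass
class MediationEffect:
    """Indirect effect with delta-method CI (log-OR scale for binary Y)."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float

    @property
    def significant(self) -> bool:
        return self.ci_low > 0 or self.ci_high < 0


@dataclass
class MediatedProportion:
    """Proportion mediated, in percent, with delta-method CI."""

    percent: float
    se: float
    ci_low: float
    ci_high: float


@dataclass
class MediationResult:
    exposure: str
    mediator: str
    outcome: str
    beta_xm: float
    beta_my: float
    beta_total: float
    indirect: MediationEffect
    proportion: MediatedProportion | None
    mvmr_significant: bool | None = None
    tier: str | None = None


def indirect_effect(beta_xm: float, se_xm: float,
                    beta_my: float, se_my: float) -> MediationEffect:
    """Product of coefficients with delta-method 95% CI.

    ``beta_xm``: exposure->mediator effect (e.g. log10-unit metabolite
    change per exposure unit); ``beta_my``: mediator->outcome effect on the
    log-OR scale (take ln of an odds ratio before calling).
    """
    if se_xm <= 0 or se_my <= 0:
        raise ValidationError("standard errors must be positive")
    point = beta_xm * beta_my
    var = beta_xm ** 2 * se_my ** 2 + beta_my ** 2 * se_xm ** 2
    se = float(np.sqrt(var))
    if se > 0:
        p = 2.0 * stats.norm.sf(abs(point) / se)
    else:
        p = 1.0 if point == 0 else 0.0
    return MediationEffect(float(point), se, float(point - Z95 * se),
                           float(point + Z95 * se), float(p))


def proportion_mediated(indirect: MediationEffect,
                        total_beta: float,
                        total_se: float) -> MediatedProportion | None:
    """Indirect / total as a percentage, or None when suppressed.

    Suppressed when the indirect effect is not significant or points in the
    opposite direction from the total effect.  Delta-method variance for a
    ratio of independent estimates:

        Var(p)/p² ≈ Var(ind)/ind² + Var(total)/total²
    """
    if total_beta == 0:
        raise ValidationError("total effect is zero: proportion undefined")
    if not indirect.significant:
        return None
    if np.sign(indirect.beta) != np.sign(total_beta):
        return None
    p = indirect.beta / total_beta * 100.0
    rel_var = (indirect.se / indirect.beta) ** 2 + (total_se / total_beta) ** 2
    se = abs(p) * float(np.sqrt(rel_var))
    return MediatedProportion(float(p), se, float(p - Z95 * se),
                              float(p + Z95 * se))


def classify_mediator(mvmr_significant: bool,
                      mediation_significant_positive: bool) -> str:
    """Evidence tier from the two mediator criteria."""
    if mvmr_significant and mediation_significant_positive:
        return TIER_STRONG
    if mvmr_significant or mediation_significant_positive:
        return TIER_MODERATE
    return TIER_POTENTIAL
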