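"""Two-step MR mediation: product of coefficients with delta-method inference.

Step 1 estimates the exposure→mediator effect (beta1), step 2 the
mediator→outcome effect (beta2, log-OR); their product beta1*beta2 is the
indirect (mediated) effect of the exposure on the outcome, and dividing by
the total effect beta0 gives the proportion mediated.  The indirect-effect
SE uses the first-order delta method (Sobel):

    se = sqrt(beta1^2 se2^2 + beta2^2 se1^2)

with the exact second-order term (+ se1^2 se2^2) available behind a flag.
Confidence intervals are reported on both the log and the odds-ratio scale
(the OR-scale CI is the exponentiated log-scale CI).  Estimates from
multiple mediator datasets can be pooled by DerSimonian–Laird
random-effects meta-analysis before the mediation arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .mr import MREstimate, MRInputError, Z95

STATUS_ESTIMATED = "estimated"
STATUS_SCREENED_OUT = "screened_out"
STATUS_NOT_ESTIMABLE = "not_estimable"


@dataclass
class IndirectEffect:
    """Product-of-coefficients indirect effect with delta-method CI."""

    indirect: float
    se: float
    ci_low: float
    ci_high: float
    or_point: float
    or_ci_low: float
    or_ci_high: float
    pval: float

    def to_dict(self) -> dict:
        return {
            "indirect": self.indirect,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "or_point": self.or_point,
            "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high,
            "pval": self.pval,
        }


@dataclass
class MediationResult:
    mediator: str
    status: str
    beta_total: float | None = None
    beta_step1: float | None = None
    se_step1: float | None = None
    beta_step2: float | None = None
    se_step2: float | None = None
    indirect: IndirectEffect | None = None
    proportion_pct: float | None = None
    step1_pval: float | None = None
    step2_pval: float | None = None
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "mediator": self.mediator,
            "status": self.status,
            "beta_total": self.beta_total,
            "beta_step1": self.beta_step1,
            "se_step1": self.se_step1,
            "beta_step2": self.beta_step2,
            "se_step2": self.se_step2,
            "indirect": None if self.indirect is None else self.indirect.to_dict(),
            "proportion_pct": self.proportion_pct,
            "step1_pval": self.step1_pval,
            "step2_pval": self.step2_pval,
            "note": self.note,
        }


@dataclass
class MetaEstimate:
    """DerSimonian–Laird random-effects pooled estimate."""

    beta: float
    se: float
    tau2: float
    k: int

    def to_dict(self) -> dict:
        return {"beta": self.beta, "se": self.se, "tau2": self.tau2, "k": self.k}


def indirect_effect(
    beta1: float,
    se1: float,
    beta2: float,
    se2: float,
    second_order: bool = False,
) -> IndirectEffect:
    """Indirect effect beta1*beta2 with delta-method 95% CI and normal p."""
    if se1 <= 0 or se2 <= 0:
        raise MRInputError("indirect_effect requires positive SEs")
    indirect = beta1 * beta2
    var = beta1**2 * se2**2 + beta2**2 * se1**2
    if second_order:
        var += se1**2 * se2**2
    se = math.sqrt(var)
    lo, hi = indirect - Z95 * se, indirect + Z95 * se
    if se == 0:
        pval = 1.0 if indirect == 0 else 0.0
    else:
        pval = float(2.0 * stats.norm.sf(abs(indirect) / se))
    return IndirectEffect(
        indirect=indirect,
        se=se,
        ci_low=lo,
        ci_high=hi,
        or_point=math.exp(indirect),
        or_ci_low=math.exp(lo),
        or_ci_high=math.exp(hi),
        pval=pval,
    )


def proportion_mediated(beta_total: float, indirect: float) -> float:
    """Proportion of the total effect that is mediated, as a percentage."""
    if beta_total == 0:
        raise MRInputError("proportion_mediated undefined for zero total effect")
    return 100.0 * indirect / beta_total


def two_step_mediation(
    step1: MREstimate | None,
    step2: MREstimate | None,
    total: MREstimate,
    mediator: str = "mediator",
    screen_alpha: float = 0.05,
    second_order: bool = False,
) -> MediationResult:
    """Assemble a mediation result from the two step estimates.

    Mediators failing the step-1 screen (p >= ``screen_alpha``) are reported
    as screened-out; mediators with no usable step-2 instrument (``step2``
    is None, e.g. no cis-pQTL found) as not-estimable.  Step-2 significance
    is reported but does not gate the computation.
    """
    if step1 is None:
        return MediationResult(
            mediator,
            STATUS_NOT_ESTIMABLE,
            beta_total=total.beta,
            note="no step-1 estimate (no instruments for exposure->mediator)",
        )
    if step1.pval >= screen_alpha:
        return MediationResult(
            mediator,
            STATUS_SCREENED_OUT,
            beta_total=total.beta,
            beta_step1=step1.beta,
            se_step1=step1.se,
            step1_pval=step1.pval,
            note=f"step-1 p={step1.pval:.3g} >= {screen_alpha:g}",
        )
    if step2 is None:
        return MediationResult(
            mediator,
            STATUS_NOT_ESTIMABLE,
            beta_total=total.beta,
            beta_step1=step1.beta,
            se_step1=step1.se,
            step1_pval=step1.pval,
            note="no cis-pQTL instrument for mediator->outcome",
        )
    ind = indirect_effect(
        step1.beta, step1.se, step2.beta, step2.se, second_order=second_order
    )
    return MediationResult(
        mediator,
        STATUS_ESTIMATED,
        beta_total=total.beta,
        beta_step1=step1.beta,
        se_step1=step1.se,
        beta_step2=step2.beta,
        se_step2=step2.se,
        indirect=ind,
        proportion_pct=proportion_mediated(total.beta, ind.indirect),
        step1_pval=step1.pval,
        step2_pval=step2.pval,
    )


def meta_combine(estimates: list[tuple[float, float]]) -> MetaEstimate:
    """DerSimonian–Laird random-effects meta-analysis of (beta, se) pairs."""
    k = len(estimates)
    if k < 2:
        raise MRInputError(f"meta-analysis requires >= 2 estimates, got {k}")
    betas = [b for b, _ in estimates]
    ses = [s for _, s in estimates]
    if any(s <= 0 for s in ses):
        raise MRInputError("meta-analysis requires positive SEs")
    w = [1.0 / s**2 for s in ses]
    sw = sum(w)
    beta_fe = sum(wi * bi for wi, bi in zip(w, betas)) / sw
    q = sum(wi * (bi - beta_fe) ** 2 for wi, bi in zip(w, betas))
    c = sw - sum(wi**2 for wi in w) / sw
    tau2 = max(0.0, (q - (k - 1)) / c)
    w_star = [1.0 / (s**2 + tau2) for s in ses]
    sw_star = sum(w_star)
    beta_re = sum(wi * bi for wi, bi in zip(w_star, betas)) / sw_star
    return MetaEstimate(
        beta=float(beta_re),
        se=float(math.sqrt(1.0 / sw_star)),
        tau2=float(tau2),
        k=k,
    )
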