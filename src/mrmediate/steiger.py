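"""Directionality check: do the instruments explain more variance in the
exposure than in the outcome?

Per-variant variance explained is computed from the F statistic as
r^2 = F / (F + n - 2) with F = (beta/se)^2, summed over instruments (LD
between instruments is ignored, which is defensible after clumping at
r^2 < 0.001).  The two r^2 sums are compared with a z-test on the
Fisher-transformed correlations.  For binary traits r^2 is taken on the
log-odds scale directly, with no liability-scale conversion — the test is
used only as a sign check on the causal direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .harmonize import HarmonizedInstrument
from .mr import MRInputError


@dataclass
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    correct_direction: bool
    zval: float
    pval: float

    def to_dict(self) -> dict:
        return {
            "r2_exposure": self.r2_exposure,
            "r2_outcome": self.r2_outcome,
            "correct_direction": self.correct_direction,
            "zval": self.zval,
            "pval": self.pval,
        }


def snp_r2(beta: float, se: float, n: int) -> float:
    """Variance explained by one variant: F/(F + n - 2) with F = (beta/se)^2."""
    if n < 3:
        raise MRInputError(f"snp_r2 requires n >= 3, got {n}")
    if se <= 0:
        raise MRInputError("snp_r2 requires se > 0")
    f = (beta / se) ** 2
    return f / (f + n - 2)


def steiger_test(
    instruments: list[HarmonizedInstrument], n_exp: int, n_out: int
) -> SteigerResult:
    """Compare instrument variance explained in exposure vs outcome."""
    if not instruments:
        raise MRInputError("Steiger test requires >= 1 instrument")
    if n_exp <= 3 or n_out <= 3:
        raise MRInputError("Steiger test requires sample sizes > 3 on both sides")
    r2_exp = float(sum(snp_r2(h.beta_exp, h.se_exp, n_exp) for h in instruments))
    r2_out = float(sum(snp_r2(h.beta_out, h.se_out, n_out) for h in instruments))
    r2_exp = min(r2_exp, 1.0 - 1e-12)
    r2_out = min(r2_out, 1.0 - 1e-12)
    z = (np.arctanh(np.sqrt(r2_exp)) - np.arctanh(np.sqrt(r2_out))) / np.sqrt(
        1.0 / (n_exp - 3) + 1.0 / (n_out - 3)
    )
    return SteigerResult(
        r2_exposure=r2_exp,
        r2_outcome=r2_out,
        correct_direction=bool(r2_exp > r2_out),
        zval=float(z),
        pval=float(2.0 * stats.norm.sf(abs(z))),
    )
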