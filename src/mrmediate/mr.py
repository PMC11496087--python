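"""Two-sample MR estimators and heterogeneity/pleiotropy diagnostics.

Estimators operate on harmonized instruments and return causal-effect
estimates on the scale of the outcome betas (log odds ratio for binary
outcomes, SD units for quantitative ones) per unit of exposure.

Implemented methods
-------------------
* Wald ratio — single-instrument estimate beta_out / beta_exp with the
  first-order delta SE se_out / |beta_exp|;
* IVW — inverse-variance-weighted mean of per-instrument Wald ratios, in a
  fixed-effect flavour and a multiplicative-random-effects flavour whose SE
  is inflated by max(1, sqrt(Q / (n-1))) (the default report);
* MR-Egger — weighted regression of outcome on exposure betas with a free
  intercept (the intercept estimates directional pleiotropy); an optional
  parametric bootstrap supplies a resampling SE for the slope;
* weighted median — consistent when instruments carrying more than half the
  weight are valid; SE by parametric bootstrap;
* Cochran's Q heterogeneity test and leave-one-out reanalysis.

All confidence intervals are Wald-type at 95% (z = 1.96) and all p-values
two-sided normal, for consistency across methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .harmonize import HarmonizedInstrument

Z95 = 1.96

METHOD_WALD = "wald"
METHOD_IVW_FIXED = "ivw_fixed"
METHOD_IVW_MRE = "ivw_mre"
METHOD_EGGER = "egger"
METHOD_EGGER_BOOT = "egger_bootstrap"
METHOD_WMEDIAN = "weighted_median"


class MRInputError(ValueError):
    pass


@dataclass
class MREstimate:
    """A causal-effect estimate with Wald-type 95% CI and normal p-value."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "n_snp": self.n_snp,
        }


@dataclass
class HeterogeneityResult:
    q_stat: float
    df: int
    pval: float

    def to_dict(self) -> dict:
        return {"q_stat": self.q_stat, "df": self.df, "pval": self.pval}


@dataclass
class PleiotropyResult:
    egger_intercept: float
    intercept_se: float
    intercept_pval: float

    def to_dict(self) -> dict:
        return {
            "egger_intercept": self.egger_intercept,
            "intercept_se": self.intercept_se,
            "intercept_pval": self.intercept_pval,
        }


@dataclass
class EggerResult:
    estimate: MREstimate
    pleiotropy: PleiotropyResult
    bootstrap_estimate: MREstimate | None = None


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 1.0 if beta == 0 else 0.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def _make_estimate(method: str, beta: float, se: float, n_snp: int) -> MREstimate:
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pval=_normal_p(beta, se),
        n_snp=n_snp,
    )


def _arrays(instruments: list[HarmonizedInstrument]):
    be = np.array([h.beta_exp for h in instruments], dtype=float)
    se_e = np.array([h.se_exp for h in instruments], dtype=float)
    bo = np.array([h.beta_out for h in instruments], dtype=float)
    se_o = np.array([h.se_out for h in instruments], dtype=float)
    return be, se_e, bo, se_o


def wald_ratios(instruments: list[HarmonizedInstrument]):
    """Per-instrument Wald ratios and their first-order delta SEs."""
    be, _, bo, se_o = _arrays(instruments)
    if np.any(be == 0):
        bad = instruments[int(np.where(be == 0)[0][0])].variant_id
        raise MRInputError(f"exposure beta is 0 for {bad}; Wald ratio undefined")
    return bo / be, se_o / np.abs(be)


def wald_ratio(instrument: HarmonizedInstrument) -> MREstimate:
    """Single-instrument causal estimate (outcome beta / exposure beta)."""
    b, s = wald_ratios([instrument])
    return _make_estimate(METHOD_WALD, b[0], s[0], 1)


def ivw(
    instruments: list[HarmonizedInstrument], random_effects: bool = True
) -> MREstimate:
    """Inverse-variance-weighted combination of Wald ratios (>= 2 instruments).

    ``random_effects=True`` (default) applies the multiplicative
    random-effects SE inflation max(1, sqrt(Q/(n-1))); the point estimate is
    identical in both flavours and equals the slope of the zero-intercept
    weighted regression of outcome on exposure betas with weights 1/se_out^2.
    """
    if len(instruments) < 2:
        raise MRInputError(f"IVW requires >= 2 instruments, got {len(instruments)}")
    b, s = wald_ratios(instruments)
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se_fixed = float(np.sqrt(1.0 / np.sum(w)))
    if not random_effects:
        return _make_estimate(METHOD_IVW_FIXED, beta, se_fixed, len(instruments))
    q = float(np.sum(w * (b - beta) ** 2))
    infl = max(1.0, np.sqrt(q / (len(instruments) - 1)))
    return _make_estimate(METHOD_IVW_MRE, beta, se_fixed * infl, len(instruments))


def cochran_q(
    instruments: list[HarmonizedInstrument], ivw_beta: float | None = None
) -> HeterogeneityResult:
    """Cochran's Q heterogeneity test of the per-instrument Wald ratios."""
    if len(instruments) < 2:
        raise MRInputError("Cochran's Q requires >= 2 instruments")
    b, s = wald_ratios(instruments)
    w = 1.0 / s**2
    if ivw_beta is None:
        ivw_beta = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - ivw_beta) ** 2))
    df = len(instruments) - 1
    return HeterogeneityResult(q, df, float(stats.chi2.sf(q, df)))


def _egger_wls(be, bo, w):
    """Closed-form weighted least squares of bo on [1, be]."""
    sw = np.sum(w)
    swx = np.sum(w * be)
    swxx = np.sum(w * be**2)
    swy = np.sum(w * bo)
    swxy = np.sum(w * be * bo)
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    return slope, intercept, det, sw, swxx


def mr_egger(
    instruments: list[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int = 0,
) -> EggerResult:
    """MR-Egger regression with intercept test and optional bootstrap SE.

    Instrument pairs are oriented so every exposure beta is non-negative
    (both betas of a pair are sign-flipped together) before fitting, as
    required for the intercept to measure directional pleiotropy.  Analytic
    SEs come from the weighted fit (weights 1/se_out^2) with a
    multiplicative-dispersion floor max(1, sigma), matching the IVW
    random-effects convention; the parametric bootstrap redraws both betas
    from their sampling distributions and reports the SD of refit slopes.
    """
    n = len(instruments)
    if n < 3:
        raise MRInputError(f"MR-Egger requires >= 3 instruments, got {n}")
    be, se_e, bo, se_o = _arrays(instruments)
    sign = np.where(be < 0, -1.0, 1.0)
    be, bo = be * sign, bo * sign
    w = 1.0 / se_o**2
    slope, intercept, det, sw, swxx = _egger_wls(be, bo, w)
    resid = bo - intercept - slope * be
    sigma2 = max(1.0, float(np.sum(w * resid**2) / (n - 2)))
    se_slope = float(np.sqrt(sigma2 * sw / det))
    se_int = float(np.sqrt(sigma2 * swxx / det))
    estimate = _make_estimate(METHOD_EGGER, slope, se_slope, n)
    pleio = PleiotropyResult(float(intercept), se_int, _normal_p(intercept, se_int))
    boot_est = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        be_star = be + se_e * rng.standard_normal((n_boot, n))
        bo_star = bo + se_o * rng.standard_normal((n_boot, n))
        sgn = np.where(be_star < 0, -1.0, 1.0)
        be_star, bo_star = be_star * sgn, bo_star * sgn
        sw_b = np.sum(w)
        swx = be_star @ w
        swxx_b = (be_star**2) @ w
        swy = bo_star @ w
        swxy = (be_star * bo_star) @ w
        det_b = sw_b * swxx_b - swx**2
        slopes = (sw_b * swxy - swx * swy) / det_b
        se_boot = float(np.std(slopes, ddof=1))
        boot_est = _make_estimate(METHOD_EGGER_BOOT, slope, se_boot, n)
    return EggerResult(estimate, pleio, boot_est)


def _weighted_median_point(b: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(b)
    b_sorted = b[order]
    w_sorted = w[order] / np.sum(w)
    s = np.cumsum(w_sorted) - w_sorted / 2.0
    return float(np.interp(0.5, s, b_sorted))


def weighted_median(
    instruments: list[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Weighted-median MR estimate (inverse-variance weights on Wald ratios).

    The point estimate interpolates the sorted ratios at cumulative weight
    0.5; the SE is the SD of the estimate over ``n_boot`` parametric
    resamples of both exposure and outcome betas.
    """
    n = len(instruments)
    if n < 3:
        raise MRInputError(f"weighted median requires >= 3 instruments, got {n}")
    b, s = wald_ratios(instruments)
    w = 1.0 / s**2
    point = _weighted_median_point(b, w)
    rng = np.random.default_rng(seed)
    be, se_e, bo, se_o = _arrays(instruments)
    draws = np.empty(n_boot)
    for i in range(n_boot):
        be_star = be + se_e * rng.standard_normal(n)
        bo_star = bo + se_o * rng.standard_normal(n)
        be_star = np.where(be_star == 0, 1e-12, be_star)
        b_star = bo_star / be_star
        s_star = se_o / np.abs(be_star)
        draws[i] = _weighted_median_point(b_star, 1.0 / s_star**2)
    se = float(np.std(draws, ddof=1))
    return _make_estimate(METHOD_WMEDIAN, point, se, n)


def leave_one_out(
    instruments: list[HarmonizedInstrument],
) -> list[tuple[str, MREstimate]]:
    """IVW (multiplicative random effects) re-estimated omitting each instrument."""
    if len(instruments) < 3:
        raise MRInputError("leave-one-out requires >= 3 instruments")
    out = []
    for i, h in enumerate(instruments):
        rest = instruments[:i] + instruments[i + 1 :]
        out.append((h.variant_id, ivw(rest)))
    return out


def mr_estimate(
    instruments: list[HarmonizedInstrument], random_effects: bool = True
) -> MREstimate:
    """IVW when >= 2 instruments, Wald ratio when exactly one."""
    if len(instruments) == 0:
        raise MRInputError("no instruments")
    if len(instruments) == 1:
        return wald_ratio(instruments[0])
    return ivw(instruments, random_effects=random_effects)


def write_results_table(estimates: list[MREstimate], path) -> None:
    from pathlib import Path

    lines = ["method\tbeta\tse\tci_low\tci_high\tpval\tn_snp"]
    for e in estimates:
        lines.append(
            f"{e.method}\t{e.beta:.10g}\t{e.se:.10g}\t{e.ci_low:.10g}"
            f"\t{e.ci_high:.10g}\t{e.pval:.10g}\t{e.n_snp}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
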