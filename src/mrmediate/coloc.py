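"""Bayesian colocalization via per-SNP Wakefield approximate Bayes factors.

Given two studies over a shared region (here: a mediator's cis-pQTL window
and the outcome), the method asks whether the two association signals are
driven by the same causal variant.  Each SNP's evidence for association in
each trait is summarized by the Wakefield log approximate Bayes factor

    labf = 0.5 * [ln(V/(V+W)) + z^2 * W/(V+W)]

with V = se^2, W the prior effect-size variance, z = beta/se; combining the
per-SNP labfs under the single-causal-variant-per-trait assumption yields
posterior probabilities for five hypotheses: H0 (no association), H1/H2
(one trait only), H3 (two distinct causal variants), H4 (one shared causal
variant).  PP.H4 above 0.5 is conventionally taken as evidence of
colocalization.  All sums are computed in log space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .gwas_io import StudySummary

logger = logging.getLogger(__name__)

HYPOTHESES = ("PP.H0", "PP.H1", "PP.H2", "PP.H3", "PP.H4")


class ColocError(ValueError):
    pass


@dataclass
class ColocPriors:
    """Per-SNP priors of the ABF colocalization model.

    p1/p2: prior probability that a SNP is causal for trait 1/2 alone;
    p12: prior probability that a SNP is causal for both.  Effect-size prior
    SDs follow the cited method's convention: 0.15 (SD units) for
    quantitative traits, 0.2 (log-OR) for case-control traits.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    prior_sd_quant: float = 0.15
    prior_sd_cc: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2)):
            raise ColocError("priors must satisfy 0 < p12 <= min(p1, p2)")
        if self.prior_sd_quant <= 0 or self.prior_sd_cc <= 0:
            raise ColocError("prior SDs must be > 0")

    def prior_sd_for(self, trait_type: str) -> float:
        return self.prior_sd_cc if trait_type == "binary" else self.prior_sd_quant


@dataclass
class ColocResult:
    pp: dict[str, float]
    n_snps: int
    priors: ColocPriors

    def to_dict(self) -> dict:
        return {
            "pp": self.pp,
            "n_snps": self.n_snps,
            "priors": {
                "p1": self.priors.p1,
                "p2": self.priors.p2,
                "p12": self.priors.p12,
                "prior_sd_quant": self.priors.prior_sd_quant,
                "prior_sd_cc": self.priors.prior_sd_cc,
            },
        }

    @property
    def top_hypothesis(self) -> str:
        return max(self.pp, key=self.pp.get)


def select_region(
    study: StudySummary, lead_variant: str, window_bp: int = 100_000
) -> StudySummary:
    """Subset a study to the lead variant's chromosome within +/- window_bp."""
    lead = study.get(lead_variant)
    if lead is None:
        raise ColocError(f"lead variant {lead_variant} not present in study")
    region = StudySummary(study.trait_name, study.trait_type)
    for rec in study:
        if rec.chrom == lead.chrom and abs(rec.pos - lead.pos) <= window_bp:
            region.records[rec.variant_id] = rec
    return region


def wakefield_labf(beta: float, se: float, prior_sd: float) -> float:
    """Wakefield log approximate Bayes factor for one association."""
    if se <= 0:
        raise ColocError("wakefield_labf requires se > 0")
    v = se**2
    w = prior_sd**2
    z2 = (beta / se) ** 2
    return 0.5 * (np.log(v / (v + w)) + z2 * w / (v + w))


def posterior_probabilities(
    l1: np.ndarray, l2: np.ndarray, priors: ColocPriors
) -> np.ndarray:
    """Hypothesis posteriors from per-SNP log Bayes factors of two traits."""
    l1 = np.asarray(l1, dtype=float)
    l2 = np.asarray(l2, dtype=float)
    ls1 = logsumexp(l1)
    ls2 = logsumexp(l2)
    ls12 = logsumexp(l1 + l2)

    log_w = np.empty(5)
    log_w[0] = 0.0
    log_w[1] = np.log(priors.p1) + ls1
    log_w[2] = np.log(priors.p2) + ls2
    # H3: p1*p2*(S1*S2 - S12), computed in log space; the difference can
    # cancel to <= 0 in floating point, in which case H3 mass is clamped to 0
    d = ls12 - (ls1 + ls2)
    if d >= 0:
        if d > 1e-12:
            logger.warning("coloc: S12 exceeds S1*S2; H3 mass clamped to 0")
        log_w[3] = -np.inf
    else:
        log_w[3] = np.log(priors.p1) + np.log(priors.p2) + ls1 + ls2 + np.log1p(-np.exp(d))
    log_w[4] = np.log(priors.p12) + ls12

    pp = np.exp(log_w - logsumexp(log_w))
    return pp / pp.sum()


def coloc_abf(
    region1: StudySummary,
    region2: StudySummary,
    priors: ColocPriors | None = None,
) -> ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    Only variants present in both regions are used (non-shared variants are
    dropped with a warning); at least two shared variants are required.
    """
    if priors is None:
        priors = ColocPriors()
    shared = sorted(set(region1.records) & set(region2.records))
    n_drop = (len(region1) - len(shared)) + (len(region2) - len(shared))
    if n_drop:
        logger.warning("coloc: dropped %d variants not shared between regions", n_drop)
    if len(shared) < 2:
        raise ColocError(
            f"colocalization requires >= 2 shared variants, got {len(shared)}"
        )
    sd1 = priors.prior_sd_for(region1.trait_type)
    sd2 = priors.prior_sd_for(region2.trait_type)
    l1 = np.array(
        [wakefield_labf(region1.records[v].beta, region1.records[v].se, sd1) for v in shared]
    )
    l2 = np.array(
        [wakefield_labf(region2.records[v].beta, region2.records[v].se, sd2) for v in shared]
    )
    pp = posterior_probabilities(l1, l2, priors)
    return ColocResult(
        pp={h: float(p) for h, p in zip(HYPOTHESES, pp)},
        n_snps=len(shared),
        priors=priors,
    )


def write_locuscompare_tsv(region1: StudySummary, region2: StudySummary, path) -> None:
    """Two-trait -log10(p) table for locus-compare style plotting."""
    shared = sorted(set(region1.records) & set(region2.records))
    lines = ["variant_id\tpos\tneglog10p_trait1\tneglog10p_trait2"]
    for v in shared:
        r1, r2 = region1.records[v], region2.records[v]
        lines.append(
            f"{v}\t{r1.pos}\t{-np.log10(r1.pval):.6g}\t{-np.log10(r2.pval):.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
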