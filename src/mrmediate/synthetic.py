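"""Synthetic GWAS summary statistics with known mediation structure.

The generator emulates, at desk scale, the statistical structure of a
three-study two-sample MR mediation design: a binary exposure study with a
configurable number of genome-wide-significant loci, a quantitative
mediator (protein level) study with a planted cis-pQTL region, and a binary
outcome study linked to both through

    beta0 (total) = tau + alpha * delta

where alpha is the exposure→mediator effect (beta1 truth), delta the
mediator→outcome effect (beta2 truth), and tau the direct effect.  Defaults
mirror a celiac-disease → IL-18 → osteoporosis analysis: exposure study of
4,533 cases / 10,750 controls with 12 loci whose instrument F statistics
span roughly 29–101; mediator pQTL study of n = 21,758; outcome study of
6,484 cases / 401,279 controls; alpha = 0.066, delta = 0.2979
(= ln 1.347), tau = 0.0847 (so beta0 = ln 1.110 and the true proportion
mediated is ~18.8%).

Summary statistics are simulated directly at the marginal-association
level: for standardized genotypes the expected marginal beta vector of a
block is R @ b (R the block LD matrix, b the causal effects), the sampling
SE of each variant is 1/sqrt(2 maf (1-maf) n) for quantitative traits and
1/sqrt(2 maf (1-maf) n v), v = n_case n_control / n^2, for binary traits,
and estimation errors within a block are correlated through the Cholesky
factor of R.  No individual-level genotypes are simulated.

Planted pathologies: a configurable fraction of palindromic (A/T, C/G)
variants; optional directionally pleiotropic instruments with an extra
direct outcome effect; allele-representation scrambling (swapped and
strand-complemented records) so harmonization is exercised; and a one-entry
pleiotropy exclusion list naming one exposure lead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .gwas_io import (
    ExclusionList,
    GeneRegion,
    LDMatrix,
    StudySummary,
    SummaryStatRecord,
)

NONPALINDROMIC_PAIRS = [
    ("A", "G"),
    ("A", "C"),
    ("T", "G"),
    ("T", "C"),
    ("G", "A"),
    ("C", "A"),
    ("G", "T"),
    ("C", "T"),
]
PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ScenarioError(ValueError):
    pass


def _ar1(k: int, rho: float) -> np.ndarray:
    idx = np.arange(k)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def make_ld_blocks(n_blocks: int, block_size: int, rho: float) -> LDMatrix:
    """Block-diagonal AR(1) LD matrix: within a block r[i,j] = rho^|i-j|."""
    if not -1.0 < rho < 1.0:
        raise ScenarioError(f"rho must be in (-1, 1), got {rho}")
    k = n_blocks * block_size
    r = np.zeros((k, k))
    block = _ar1(block_size, rho)
    for b in range(n_blocks):
        sl = slice(b * block_size, (b + 1) * block_size)
        r[sl, sl] = block
    ids = [f"v{b}_{i}" for b in range(n_blocks) for i in range(block_size)]
    return LDMatrix(ids, r)


def _binary_se(maf: np.ndarray, n: int, n_case: int, n_control: int) -> np.ndarray:
    v = n_case * n_control / n**2
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n * v)


def _quant_se(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


@dataclass
class MediationScenario:
    """Study conditions for the three-study mediation simulation."""

    n_exposure_loci: int = 12
    #: per-locus causal effects on exposure liability; None calibrates them
    #: so expected instrument F statistics span ``f_range``
    gamma: tuple | None = None
    alpha: float = 0.066
    delta: float = 0.2979
    tau: float = 0.0847
    n_exp: int = 15_283
    n_med: int = 21_758
    n_out: int = 407_763
    n_case_exp: int = 4_533
    n_control_exp: int = 10_750
    n_case_out: int = 6_484
    n_control_out: int = 401_279
    maf_range: tuple = (0.1, 0.4)
    frac_palindromic: float = 0.1
    n_pleiotropic: int = 0
    pleio_effect: float = 0.1
    seed: int = 0
    # secondary structure knobs
    f_range: tuple = (29.0, 101.0)
    variants_per_locus: int = 3
    block_rho: float = 0.8
    cis_n_snps: int = 21
    cis_rho: float = 0.6
    cis_beta: float = 0.25
    mediator_gene: str = "IL18"
    frac_allele_swap: float = 0.25
    frac_strand_flip: float = 0.1
    exclude_one_lead: bool = True

    def __post_init__(self) -> None:
        for name in ("n_exp", "n_med", "n_out"):
            if getattr(self, name) < 100:
                raise ScenarioError(f"{name} must be >= 100")
        for name in ("frac_palindromic", "frac_allele_swap", "frac_strand_flip"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ScenarioError(f"{name} must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ScenarioError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.n_case_exp + self.n_control_exp != self.n_exp:
            raise ScenarioError("exposure case/control counts must sum to n_exp")
        if self.n_case_out + self.n_control_out != self.n_out:
            raise ScenarioError("outcome case/control counts must sum to n_out")
        if not 0 <= self.n_pleiotropic <= self.n_exposure_loci:
            raise ScenarioError("n_pleiotropic must be between 0 and n_exposure_loci")
        if self.gamma is not None and len(self.gamma) != self.n_exposure_loci:
            raise ScenarioError("gamma must have one entry per exposure locus")

    @property
    def beta_total(self) -> float:
        return self.tau + self.alpha * self.delta

    @property
    def true_proportion(self) -> float:
        """alpha*delta / beta0; NaN when the total effect is zero (null)."""
        if self.beta_total == 0:
            return float("nan")
        return self.alpha * self.delta / self.beta_total

    def pleiotropic_loci(self) -> list[int]:
        """Every other locus starting at 1, so valid instruments keep >50% weight."""
        spread = list(range(1, self.n_exposure_loci, 2)) + list(
            range(0, self.n_exposure_loci, 2)
        )
        return sorted(spread[: self.n_pleiotropic])


@dataclass
class ColocScenario:
    """One shared region simulated for two traits."""

    n_snps: int = 50
    ld_rho: float = 0.5
    mode: str = "shared"  # shared | distinct | null
    effect_size: float = 0.15
    n1: int = 20_000
    n2: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 2:
            raise ScenarioError("n_snps must be >= 2")
        if not abs(self.ld_rho) < 1.0:
            raise ScenarioError("|ld_rho| must be < 1")
        if self.mode not in ("shared", "distinct", "null"):
            raise ScenarioError(f"unknown mode {self.mode!r}")


@dataclass
class SimulatedMediation:
    """One simulated dataset plus the truth record used to generate it."""

    exposure: StudySummary
    mediator: StudySummary
    outcome: StudySummary
    ld: LDMatrix
    gene_region: GeneRegion
    exclusion_list: ExclusionList
    truth: dict = field(default_factory=dict)


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, 1e-300, 1.0)


def _draw_alleles(rng: np.random.Generator, n: int, frac_palindromic: float):
    pal = rng.random(n) < frac_palindromic
    pairs = []
    for is_pal in pal:
        pool = PALINDROMIC_PAIRS if is_pal else NONPALINDROMIC_PAIRS
        pairs.append(pool[rng.integers(len(pool))])
    return pairs, pal


def _sample_block(
    rng: np.random.Generator, mu: np.ndarray, se: np.ndarray, chol: np.ndarray
) -> np.ndarray:
    eps = rng.standard_normal(len(mu))
    return mu + se * (chol @ eps)


def simulate_mediation_scenario(scenario: MediationScenario) -> SimulatedMediation:
    """Generate exposure, mediator, and outcome studies with known truth.

    Deterministic given ``scenario.seed``: the same scenario yields
    byte-identical studies.
    """
    rng = np.random.default_rng(scenario.seed)
    n_loci = scenario.n_exposure_loci
    vpl = scenario.variants_per_locus

    # chromosome labels for exposure loci; the cis region always sits on
    # chromosome 11, which is excluded here so the cis/trans split is
    # unambiguous
    chrom_pool = [str(c) for c in range(1, 23) if c != 11]

    # --- layout -----------------------------------------------------------
    variant_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    block_slices: list[slice] = []
    lead_indices: list[int] = []
    for k in range(n_loci):
        chrom = chrom_pool[k % len(chrom_pool)]
        base = 40_000_000 + (k // len(chrom_pool)) * 25_000_000
        start = len(variant_ids)
        for j in range(vpl):
            variant_ids.append(f"rs{10_000 + 100 * k + j}")
            chroms.append(chrom)
            positions.append(base + 5_000 * j)
        block_slices.append(slice(start, start + vpl))
        lead_indices.append(start)

    cis_start_idx = len(variant_ids)
    cis_lead_offset = scenario.cis_n_snps // 2
    gene_region = GeneRegion(scenario.mediator_gene, "11", 111_990_000, 112_010_000)
    for i in range(scenario.cis_n_snps):
        variant_ids.append(f"rs{90_000 + i}")
        chroms.append("11")
        positions.append(112_000_000 + 4_000 * (i - cis_lead_offset))
    cis_slice = slice(cis_start_idx, cis_start_idx + scenario.cis_n_snps)
    cis_lead_id = variant_ids[cis_start_idx + cis_lead_offset]
    n_var = len(variant_ids)

    # --- per-variant frequencies and alleles ------------------------------
    maf = rng.uniform(scenario.maf_range[0], scenario.maf_range[1], n_var)
    allele_pairs, pal_mask = _draw_alleles(rng, n_var, scenario.frac_palindromic)

    # --- LD ---------------------------------------------------------------
    r = np.eye(n_var)
    block_r = _ar1(vpl, scenario.block_rho)
    for sl in block_slices:
        r[sl, sl] = block_r
    cis_r = _ar1(scenario.cis_n_snps, scenario.cis_rho)
    r[cis_slice, cis_slice] = cis_r
    ld = LDMatrix(list(variant_ids), r)
    chol_block = np.linalg.cholesky(block_r)
    chol_cis = np.linalg.cholesky(cis_r)

    # --- causal effects ---------------------------------------------------
    se_exp = _binary_se(maf, scenario.n_exp, scenario.n_case_exp, scenario.n_control_exp)
    se_med = _quant_se(maf, scenario.n_med)
    se_out = _binary_se(maf, scenario.n_out, scenario.n_case_out, scenario.n_control_out)

    if scenario.gamma is not None:
        gamma = np.asarray(scenario.gamma, dtype=float)
    else:
        f_targets = np.linspace(scenario.f_range[0], scenario.f_range[1], n_loci)
        gamma = np.sqrt(f_targets) * se_exp[lead_indices]

    pleio_loci = set(scenario.pleiotropic_loci())
    beta0 = scenario.beta_total

    mu_exp = np.zeros(n_var)
    mu_med = np.zeros(n_var)
    mu_out = np.zeros(n_var)
    for k, sl in enumerate(block_slices):
        lead_col = block_r[:, 0]
        mu_exp[sl] = lead_col * gamma[k]
        mu_med[sl] = lead_col * gamma[k] * scenario.alpha
        direct = gamma[k] * beta0
        if k in pleio_loci:
            direct = direct + scenario.pleio_effect
        mu_out[sl] = lead_col * direct
    b_cis = np.zeros(scenario.cis_n_snps)
    b_cis[cis_lead_offset] = scenario.cis_beta
    mu_med[cis_slice] = cis_r @ b_cis
    mu_out[cis_slice] = cis_r @ (b_cis * scenario.delta)

    # --- sampling noise (fixed draw order for determinism) ----------------
    def _sample_study(mu: np.ndarray, se: np.ndarray) -> np.ndarray:
        beta = np.empty(n_var)
        for sl in block_slices:
            beta[sl] = _sample_block(rng, mu[sl], se[sl], chol_block)
        beta[cis_slice] = _sample_block(rng, mu[cis_slice], se[cis_slice], chol_cis)
        return beta

    beta_exp = _sample_study(mu_exp, se_exp)
    beta_med = _sample_study(mu_med, se_med)
    beta_out = _sample_study(mu_out, se_out)

    # --- representation scrambling for mediator/outcome -------------------
    u_med = rng.random(n_var)
    u_out = rng.random(n_var)

    def _build_study(
        name, trait_type, beta, se, n, n_case, n_control, scramble
    ) -> StudySummary:
        study = StudySummary(name, trait_type)
        p = _pvals(beta, se)
        for i, vid in enumerate(variant_ids):
            ea, oa = allele_pairs[i]
            b, f = float(beta[i]), float(maf[i])
            if scramble is not None:
                u = scramble[i]
                if u < scenario.frac_allele_swap:
                    ea, oa = oa, ea
                    b, f = -b, 1.0 - f
                elif u < scenario.frac_allele_swap + scenario.frac_strand_flip:
                    ea, oa = COMPLEMENT[ea], COMPLEMENT[oa]
            study.records[vid] = SummaryStatRecord(
                variant_id=vid,
                chrom=chroms[i],
                pos=positions[i],
                effect_allele=ea,
                other_allele=oa,
                eaf=f,
                beta=b,
                se=float(se[i]),
                pval=float(p[i]),
                n=n,
                n_case=n_case,
                n_control=n_control,
                trait_type=trait_type,
            )
        return study

    exposure = _build_study(
        "exposure", "binary", beta_exp, se_exp, scenario.n_exp,
        scenario.n_case_exp, scenario.n_control_exp, None,
    )
    mediator = _build_study(
        scenario.mediator_gene, "quantitative", beta_med, se_med,
        scenario.n_med, None, None, u_med,
    )
    outcome = _build_study(
        "outcome", "binary", beta_out, se_out, scenario.n_out,
        scenario.n_case_out, scenario.n_control_out, u_out,
    )

    # the exclusion list covers every variant of the flagged locus so the
    # confounder removal applies whichever block member survives clumping
    excl = ExclusionList()
    excluded_locus: list[str] = []
    if scenario.exclude_one_lead:
        sl = block_slices[n_loci // 2]
        excluded_locus = variant_ids[sl]
        for vid in excluded_locus:
            excl.entries[vid] = "associated with confounder traits (smoking, diabetes)"

    truth = {
        "alpha": scenario.alpha,
        "delta": scenario.delta,
        "tau": scenario.tau,
        "beta0": beta0,
        "true_proportion": scenario.true_proportion,
        "gamma": [float(g) for g in gamma],
        "lead_variants": [variant_ids[i] for i in lead_indices],
        "pleiotropic_loci": sorted(pleio_loci),
        "pleiotropic_leads": [variant_ids[lead_indices[k]] for k in sorted(pleio_loci)],
        "excluded_locus_variants": excluded_locus,
        "palindromic_variants": [v for v, m in zip(variant_ids, pal_mask) if m],
        "cis_lead": cis_lead_id,
        "mediator_gene": scenario.mediator_gene,
        "scenario": asdict(scenario),
    }
    return SimulatedMediation(
        exposure=exposure,
        mediator=mediator,
        outcome=outcome,
        ld=ld,
        gene_region=gene_region,
        exclusion_list=excl,
        truth=truth,
    )


def simulate_coloc_region(scenario: ColocScenario):
    """Simulate one region for two traits under a sharing hypothesis.

    Returns ``(trait1 study, trait2 study, LDMatrix)``.  Expected marginal
    betas are R @ b where b has a single nonzero entry per causal trait:
    the same central variant for both traits (``shared``), two variants a
    quarter-region apart (``distinct``), or none (``null``).
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_snps
    r = _ar1(n, scenario.ld_rho)
    chol = np.linalg.cholesky(r)
    ids = [f"rs{80_000 + i}" for i in range(n)]
    positions = [111_900_000 + 4_000 * i for i in range(n)]
    maf = rng.uniform(0.2, 0.4, n)
    allele_pairs, _ = _draw_alleles(rng, n, 0.0)

    b1 = np.zeros(n)
    b2 = np.zeros(n)
    if scenario.mode == "shared":
        b1[n // 2] = scenario.effect_size
        b2[n // 2] = scenario.effect_size
    elif scenario.mode == "distinct":
        b1[n // 4] = scenario.effect_size
        b2[(3 * n) // 4] = scenario.effect_size

    def _study(name, b, n_samp):
        se = _quant_se(maf, n_samp)
        beta = r @ b + se * (chol @ rng.standard_normal(n))
        p = _pvals(beta, se)
        study = StudySummary(name, "quantitative")
        for i, vid in enumerate(ids):
            ea, oa = allele_pairs[i]
            study.records[vid] = SummaryStatRecord(
                variant_id=vid,
                chrom="11",
                pos=positions[i],
                effect_allele=ea,
                other_allele=oa,
                eaf=float(maf[i]),
                beta=float(beta[i]),
                se=float(se[i]),
                pval=float(p[i]),
                n=n_samp,
            )
        return study

    s1 = _study("trait1", b1, scenario.n1)
    s2 = _study("trait2", b2, scenario.n2)
    return s1, s2, LDMatrix(ids, r)
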