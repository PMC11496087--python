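"""End-to-end orchestration: selection → harmonization → MR → sensitivity →
mediation → Steiger → colocalization.

:func:`analyze_mediation` runs the whole analysis on in-memory studies and
returns a plain-dict report; :func:`run_pipeline` wraps it with file I/O
driven by a :class:`PipelineConfig`.  The report is deterministic for a
fixed config and seed (all stochastic sub-analyses draw from seeds derived
from the config seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .coloc import ColocPriors, coloc_abf, select_region, write_locuscompare_tsv
from .gwas_io import (
    ExclusionList,
    GeneRegion,
    LDMatrix,
    StudySummary,
    read_exclusion_list,
    read_gene_regions,
    read_ld_matrix,
    read_summary_stats,
)
from .harmonize import harmonize_studies, kept_instruments, write_harmonization_report
from .instruments import (
    SelectionAudit,
    compute_f_statistics,
    exclude_confounded,
    filter_genome_wide_significant,
    ld_clump,
    select_cis_pqtls,
)
from .mediation import two_step_mediation
from .mr import (
    MRInputError,
    cochran_q,
    ivw,
    leave_one_out,
    mr_egger,
    mr_estimate,
    weighted_median,
)
from .presso import presso_test
from .steiger import steiger_test

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage-labelled hard failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run; thresholds default to the
    conventional values (genome-wide 5e-8, clump r^2 0.001 in 10 Mb, cis
    flank 1 Mb, coloc window 100 kb, step-1 screen 0.05, PP.H4 0.5)."""

    exposure_path: str = ""
    outcome_path: str = ""
    mediator_paths: dict = field(default_factory=dict)  # gene -> path
    ld_path: str = ""
    gene_regions_path: str = ""
    exclusion_path: str = ""
    exposure_name: str = "exposure"
    exposure_type: str = "binary"
    outcome_name: str = "outcome"
    outcome_type: str = "binary"
    mediator_type: str = "quantitative"
    gwas_p: float = 5e-8
    clump_r2: float = 0.001
    clump_window: int = 10_000_000
    cis_flank: int = 1_000_000
    coloc_window: int = 100_000
    screen_alpha: float = 0.05
    coloc_alpha: float = 0.05
    pp_h4_threshold: float = 0.5
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "gwas_p",
            "clump_r2",
            "clump_window",
            "cis_flank",
            "coloc_window",
            "screen_alpha",
            "pp_h4_threshold",
        ):
            if getattr(self, name) <= 0:
                raise PipelineError("config", f"{name} must be positive")
        self.seed = int(self.seed)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load a flat key-value (YAML) config file."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _mr_suite(instruments, n_exp, n_out, seed, n_boot, n_sim) -> dict:
    """All estimators + diagnostics for one harmonized exposure-outcome pair."""
    n = len(instruments)
    out: dict = {"n_snp": n}
    if n == 0:
        out["error"] = "no instruments after harmonization"
        return out
    primary = mr_estimate(instruments)
    estimates = [primary.to_dict()]
    if n >= 2:
        estimates.append(ivw(instruments, random_effects=False).to_dict())
        out["heterogeneity"] = cochran_q(instruments, primary.beta).to_dict()
    if n >= 3:
        ss = np.random.SeedSequence(seed)
        s_egger, s_median = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
        egger = mr_egger(instruments, n_boot=n_boot, seed=s_egger)
        estimates.append(egger.estimate.to_dict())
        if egger.bootstrap_estimate is not None:
            estimates.append(egger.bootstrap_estimate.to_dict())
        estimates.append(weighted_median(instruments, n_boot=n_boot, seed=s_median).to_dict())
        out["pleiotropy"] = egger.pleiotropy.to_dict()
        out["leave_one_out"] = [
            {"omitted": vid, **est.to_dict()} for vid, est in leave_one_out(instruments)
        ]
    if n >= 4:
        try:
            out["presso"] = presso_test(
                instruments, n_sim=n_sim, seed=seed + 1
            ).to_dict()
        except MRInputError as exc:
            out["presso"] = {"error": str(exc)}
    out["estimates"] = estimates
    out["steiger"] = steiger_test(instruments, n_exp, n_out).to_dict()
    return out


def analyze_mediation(
    exposure: StudySummary,
    mediators: dict[str, tuple[StudySummary, GeneRegion]],
    outcome: StudySummary,
    ld: LDMatrix | None = None,
    exclusion_list: ExclusionList | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Run the full mediation MR analysis in memory and return the report.

    Stages: instrument selection for the exposure, harmonization against the
    outcome, the MR estimator suite with heterogeneity/pleiotropy/outlier/
    leave-one-out/Steiger diagnostics, a two-step mediation per configured
    mediator (step-1 screen at ``screen_alpha``; mediators without a
    cis-pQTL reported as not estimable), and colocalization of each
    estimated mediator's cis region with the outcome.
    """
    cfg = config or PipelineConfig()
    audit = SelectionAudit()

    # --- exposure instrument selection -----------------------------------
    sig = filter_genome_wide_significant(exposure, cfg.gwas_p, audit=audit)
    clumped = ld_clump(
        exposure, sig, ld, cfg.clump_r2, cfg.clump_window, audit=audit
    )
    kept_ids = exclude_confounded(
        clumped, exclusion_list, outcome, cfg.gwas_p, audit=audit
    )
    logger.info(
        "selection: %d significant -> %d after clumping -> %d after exclusions",
        len(sig), len(clumped), len(kept_ids),
    )
    instr_records = compute_f_statistics(exposure, kept_ids)

    # --- exposure -> outcome ---------------------------------------------
    harm_out = harmonize_studies(exposure, outcome, kept_ids)
    kept_out = kept_instruments(harm_out)
    logger.info("harmonization: %d/%d instruments kept", len(kept_out), len(harm_out))
    if not kept_out:
        raise PipelineError("mr", "no instruments survive harmonization")
    mr_report = _mr_suite(
        kept_out, exposure.max_n, outcome.max_n, cfg.seed, cfg.n_boot, cfg.n_sim
    )
    total = mr_estimate(kept_out)

    # --- per-mediator two-step mediation ----------------------------------
    mediation_report: dict = {}
    coloc_report: dict = {}
    for gene in sorted(mediators):
        med_study, region = mediators[gene]
        entry: dict = {}
        harm_med = harmonize_studies(exposure, med_study, kept_ids)
        kept_med = kept_instruments(harm_med)
        step1 = mr_estimate(kept_med) if kept_med else None
        if step1 is not None:
            entry["step1"] = step1.to_dict()
            entry["steiger_step1"] = steiger_test(
                kept_med, exposure.max_n, med_study.max_n
            ).to_dict()

        step2 = None
        cis_kept2: list = []
        cis_ids = select_cis_pqtls(
            med_study, region, cfg.gwas_p, cfg.cis_flank, audit=audit
        )
        cis_ids = ld_clump(
            med_study, cis_ids, ld, cfg.clump_r2, cfg.clump_window, audit=audit
        )
        entry["n_cis_pqtls"] = len(cis_ids)
        if cis_ids:
            harm2 = harmonize_studies(med_study, outcome, cis_ids)
            cis_kept2 = kept_instruments(harm2)
            if cis_kept2:
                step2 = mr_estimate(cis_kept2)
                entry["step2"] = step2.to_dict()
                entry["steiger_step2"] = steiger_test(
                    cis_kept2, med_study.max_n, outcome.max_n
                ).to_dict()
        med_result = two_step_mediation(
            step1, step2, total, mediator=gene, screen_alpha=cfg.screen_alpha
        )
        entry["mediation"] = med_result.to_dict()
        mediation_report[gene] = entry

        # --- colocalization, gated on an estimated significant mediation --
        if (
            med_result.status == "estimated"
            and med_result.indirect is not None
            and med_result.indirect.pval < cfg.coloc_alpha
            and cis_kept2
        ):
            lead = min(cis_ids, key=lambda v: (med_study.records[v].pval, v))
            region1 = select_region(med_study, lead, cfg.coloc_window)
            try:
                region2 = select_region(outcome, lead, cfg.coloc_window)
                res = coloc_abf(region1, region2, ColocPriors())
                coloc_report[gene] = {
                    "lead_variant": lead,
                    **res.to_dict(),
                    "colocalized": res.pp["PP.H4"] > cfg.pp_h4_threshold,
                }
            except Exception as exc:  # reportable, not fatal
                coloc_report[gene] = {"lead_variant": lead, "error": str(exc)}

    report = {
        "fingerprint": {"package": "mrmediate", "version": __version__, "seed": cfg.seed},
        "config": asdict(cfg),
        "selection": {
            "n_significant": len(sig),
            "n_clumped": len(clumped),
            "n_instruments": len(kept_ids),
            "instrument_ids": kept_ids,
            "f_statistics": {r.variant_id: r.f_stat for r in instr_records},
        },
        "harmonization": [
            {"variant_id": h.variant_id, "action": h.action} for h in harm_out
        ],
        "mr": {"exposure_outcome": mr_report},
        "mediation": mediation_report,
        "coloc": coloc_report,
        "audit": audit.entries,
    }
    report["_audit_obj"] = audit
    report["_harmonized"] = harm_out
    return report


def quick_mediation(data, config: PipelineConfig | None = None) -> dict:
    """Lightweight single-replicate analysis for Monte-Carlo studies.

    Runs selection, harmonization, the IVW/Wald point estimates for the
    total, step-1 and step-2 effects, and the mediation arithmetic — but no
    bootstraps, outlier simulation, leave-one-out or colocalization — so
    hundreds of replicates stay cheap.  ``data`` is a
    :class:`~mrmediate.synthetic.SimulatedMediation` (or any object with the
    same attributes).
    """
    cfg = config or PipelineConfig()
    sig = filter_genome_wide_significant(data.exposure, cfg.gwas_p)
    clumped = ld_clump(data.exposure, sig, data.ld, cfg.clump_r2, cfg.clump_window)
    kept_ids = exclude_confounded(clumped, data.exclusion_list, data.outcome, cfg.gwas_p)
    kept_out = kept_instruments(harmonize_studies(data.exposure, data.outcome, kept_ids))
    total = mr_estimate(kept_out) if kept_out else None
    kept_med = kept_instruments(harmonize_studies(data.exposure, data.mediator, kept_ids))
    step1 = mr_estimate(kept_med) if kept_med else None
    cis_ids = select_cis_pqtls(data.mediator, data.gene_region, cfg.gwas_p, cfg.cis_flank)
    cis_ids = ld_clump(data.mediator, cis_ids, data.ld, cfg.clump_r2, cfg.clump_window)
    step2 = None
    cis_kept = []
    if cis_ids:
        cis_kept = kept_instruments(harmonize_studies(data.mediator, data.outcome, cis_ids))
        if cis_kept:
            step2 = mr_estimate(cis_kept)
    mediation = (
        two_step_mediation(step1, step2, total, mediator=data.gene_region.gene,
                           screen_alpha=cfg.screen_alpha)
        if total is not None
        else None
    )
    return {
        "instrument_ids": kept_ids,
        "instruments_outcome": kept_out,
        "instruments_mediator": kept_med,
        "cis_instruments": cis_kept,
        "total": total,
        "step1": step1,
        "step2": step2,
        "mediation": mediation,
    }


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """File-driven end-to-end run; writes report.json and TSV tables."""
    try:
        exposure = read_summary_stats(
            config.exposure_path, config.exposure_name, config.exposure_type
        )
        outcome = read_summary_stats(
            config.outcome_path, config.outcome_name, config.outcome_type
        )
        regions = (
            read_gene_regions(config.gene_regions_path)
            if config.gene_regions_path
            else {}
        )
        mediators = {}
        for gene, path in config.mediator_paths.items():
            if gene not in regions:
                raise PipelineError("input", f"no gene region for mediator {gene}")
            mediators[gene] = (
                read_summary_stats(path, gene, config.mediator_type),
                regions[gene],
            )
        ld = read_ld_matrix(config.ld_path) if config.ld_path else None
        excl = (
            read_exclusion_list(config.exclusion_path)
            if config.exclusion_path
            else None
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("input", str(exc)) from exc

    report = analyze_mediation(exposure, mediators, outcome, ld, excl, config)
    audit = report.pop("_audit_obj")
    harmonized = report.pop("_harmonized")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_report(report, out_dir / "report.json")
        audit.write_tsv(out_dir / "selection_audit.tsv")
        write_harmonization_report(harmonized, out_dir / "harmonization.tsv")
        for gene, entry in report["coloc"].items():
            if "error" in entry:
                continue
            med_study, _ = mediators[gene]
            lead = entry["lead_variant"]
            write_locuscompare_tsv(
                select_region(med_study, lead, config.coloc_window),
                select_region(outcome, lead, config.coloc_window),
                out_dir / f"locuscompare_{gene}.tsv",
            )
    return report


def strip_private(report: dict) -> dict:
    return {k: v for k, v in report.items() if not k.startswith("_")}


def write_report(report: dict, path) -> None:
    Path(path).write_text(
        json.dumps(strip_private(report), indent=2, sort_keys=True) + "\n"
    )
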