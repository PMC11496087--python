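"""Instrumental-variable selection for two-sample MR.

Selection follows the standard recipe for summary-level MR: keep variants at
genome-wide significance (p < 5e-8, strict), prune them to independence by
greedy LD clumping (r^2 < 0.001 within +/-10 Mb of each retained index
variant), remove variants on a user-supplied pleiotropy exclusion list or
directly associated with the outcome at genome-wide significance, and grade
the survivors by the per-variant F statistic (beta/se)^2.  cis-pQTL selection
restricts a mediator study to significant variants within a flank (default
1 Mb) of the encoding gene body.

Every removal is recorded exactly once in a :class:`SelectionAudit` with its
stage and reason, so a run's instrument bookkeeping can be reconstructed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .gwas_io import ExclusionList, GeneRegion, LDMatrix, StudySummary, SummaryStatRecord

logger = logging.getLogger(__name__)

GWAS_P_THRESHOLD = 5e-8
CLUMP_R2 = 0.001
CLUMP_WINDOW_BP = 10_000_000
CIS_FLANK_BP = 1_000_000


@dataclass
class SelectionAudit:
    """Per-variant audit trail of selection decisions."""

    entries: list[dict] = field(default_factory=list)

    def record(self, variant_id: str, stage: str, decision: str, reason: str) -> None:
        self.entries.append(
            {
                "variant_id": variant_id,
                "stage": stage,
                "decision": decision,
                "reason": reason,
            }
        )

    def removed(self) -> list[dict]:
        return [e for e in self.entries if e["decision"] == "removed"]

    def write_tsv(self, path) -> None:
        lines = ["variant_id\tstage\tdecision\treason"]
        for e in self.entries:
            lines.append(
                f"{e['variant_id']}\t{e['stage']}\t{e['decision']}\t{e['reason']}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class InstrumentRecord:
    """A selected instrument: the summary record plus strength and flags."""

    record: SummaryStatRecord
    f_stat: float
    selection_flags: set = field(default_factory=set)

    @property
    def variant_id(self) -> str:
        return self.record.variant_id


def filter_genome_wide_significant(
    study: StudySummary,
    threshold: float = GWAS_P_THRESHOLD,
    audit: SelectionAudit | None = None,
) -> list[str]:
    """Variants with p strictly below the genome-wide threshold."""
    kept: list[str] = []
    for rec in study:
        if rec.pval < threshold:
            kept.append(rec.variant_id)
            if audit is not None:
                audit.record(rec.variant_id, "significance", "kept", f"p={rec.pval:.3g}")
        elif audit is not None:
            audit.record(
                rec.variant_id,
                "significance",
                "removed",
                f"p={rec.pval:.3g} >= {threshold:g}",
            )
    return kept


def ld_clump(
    study: StudySummary,
    candidates,
    ld: LDMatrix | None,
    r2_threshold: float = CLUMP_R2,
    window_bp: int = CLUMP_WINDOW_BP,
    audit: SelectionAudit | None = None,
) -> list[str]:
    """Greedy p-value-ordered LD clumping.

    Candidates are visited by ascending p-value (ties broken by ascending
    variant id for determinism); each retained index variant removes every
    remaining candidate on the same chromosome within ``window_bp`` whose
    r^2 with it is >= ``r2_threshold``.  Candidates absent from the LD
    matrix are treated as uncorrelated with a logged warning.
    """
    recs = {vid: study.records[vid] for vid in candidates}
    if ld is not None:
        for vid in recs:
            if vid not in ld:
                logger.warning(
                    "clumping: %s absent from LD matrix, assumed uncorrelated", vid
                )
                if audit is not None:
                    audit.record(vid, "clump", "flagged", "absent from LD matrix")
    order = sorted(recs, key=lambda v: (recs[v].pval, v))
    kept: list[str] = []
    removed: set[str] = set()
    for vid in order:
        if vid in removed:
            continue
        kept.append(vid)
        if audit is not None:
            audit.record(vid, "clump", "kept", "index variant")
        idx = recs[vid]
        for other in order:
            if other == vid or other in removed or other in kept:
                continue
            oth = recs[other]
            if oth.chrom != idx.chrom or abs(oth.pos - idx.pos) > window_bp:
                continue
            r2 = ld.r2(vid, other) if ld is not None else 0.0
            if r2 >= r2_threshold:
                removed.add(other)
                if audit is not None:
                    audit.record(
                        other,
                        "clump",
                        "removed",
                        f"r2={r2:.4g} with {vid} within {window_bp} bp",
                    )
    return sorted(kept, key=lambda v: order.index(v))


def select_cis_pqtls(
    study: StudySummary,
    gene_region: GeneRegion,
    threshold: float = GWAS_P_THRESHOLD,
    flank_bp: int = CIS_FLANK_BP,
    audit: SelectionAudit | None = None,
) -> list[str]:
    """Significant variants within ``flank_bp`` of the gene body (cis-pQTLs)."""
    lo = gene_region.start - flank_bp
    hi = gene_region.end + flank_bp
    kept: list[str] = []
    for rec in study:
        if rec.pval >= threshold:
            continue
        if rec.chrom != gene_region.chrom or not (lo <= rec.pos <= hi):
            if audit is not None:
                audit.record(
                    rec.variant_id,
                    "cis",
                    "removed",
                    f"significant but trans to {gene_region.gene}",
                )
            continue
        kept.append(rec.variant_id)
        if audit is not None:
            audit.record(rec.variant_id, "cis", "kept", f"cis to {gene_region.gene}")
    return kept


def exclude_confounded(
    variants,
    exclusion_list: ExclusionList | None,
    outcome_study: StudySummary | None,
    outcome_threshold: float = GWAS_P_THRESHOLD,
    audit: SelectionAudit | None = None,
) -> list[str]:
    """Drop variants on the exclusion list or genome-wide significant for the outcome."""
    kept: list[str] = []
    for vid in variants:
        if exclusion_list is not None and vid in exclusion_list:
            reason = f"pleiotropy exclusion list: {exclusion_list.reason(vid)}"
            logger.info("excluding %s (%s)", vid, reason)
            if audit is not None:
                audit.record(vid, "confounding", "removed", reason)
            continue
        out_rec = outcome_study.get(vid) if outcome_study is not None else None
        if out_rec is not None and out_rec.pval < outcome_threshold:
            reason = f"directly associated with outcome (p={out_rec.pval:.3g})"
            logger.info("excluding %s (%s)", vid, reason)
            if audit is not None:
                audit.record(vid, "confounding", "removed", reason)
            continue
        kept.append(vid)
        if audit is not None:
            audit.record(vid, "confounding", "kept", "no exclusion")
    return kept


def compute_f_statistics(study: StudySummary, variant_ids) -> list[InstrumentRecord]:
    """Attach the instrument-strength F statistic (beta/se)^2 to each variant."""
    out = []
    for vid in variant_ids:
        rec = study.records[vid]
        out.append(InstrumentRecord(rec, (rec.beta / rec.se) ** 2, {"significant"}))
    return out
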