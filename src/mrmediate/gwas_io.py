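"""Data model and I/O for GWAS summary statistics and companion tables.

The package works entirely at the summary level: each study is a table of
per-variant marginal associations (effect allele, other allele, effect-allele
frequency, beta, standard error, p-value, sample size).  Binary traits carry
betas on the log-odds-ratio scale, quantitative traits in SD units.  All
genomic coordinates are 1-based inclusive.

Canonical on-disk formats (all plain TSV):

* summary statistics — header
  ``variant_id chrom pos effect_allele other_allele eaf beta se pval n
  n_case n_control``, missing values as the literal ``NA``;
* LD matrix — square table, first row and first column are variant ids;
* gene regions — ``gene chrom start end``;
* exclusion list — ``variant_id reason``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
TRAIT_TYPES = ("quantitative", "binary")

SUMMARY_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
    "n_case",
    "n_control",
]

NA_TOKEN = "NA"

#: p-values of exactly zero in input are clamped here so that downstream
#: log-scale operations stay finite.
PVAL_FLOOR = 1e-300


class GwasIOError(ValueError):
    """Hard failure while reading or validating a GWAS input file."""


@dataclass
class SummaryStatRecord:
    """One variant's marginal association in one study."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int
    n_case: int | None = None
    n_control: int | None = None
    trait_type: str = "quantitative"

    def validation_errors(self) -> list[str]:
        """Return the list of invariant violations (empty when valid)."""
        errs: list[str] = []
        if not self.variant_id:
            errs.append("empty variant_id")
        if self.effect_allele not in VALID_ALLELES:
            errs.append(f"effect_allele {self.effect_allele!r} not a single nucleotide")
        if self.other_allele not in VALID_ALLELES:
            errs.append(f"other_allele {self.other_allele!r} not a single nucleotide")
        if (
            self.effect_allele in VALID_ALLELES
            and self.effect_allele == self.other_allele
        ):
            errs.append("effect_allele equals other_allele")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            errs.append(f"eaf {self.eaf} outside (0,1)")
        if not math.isfinite(self.beta):
            errs.append("beta not finite")
        if not (math.isfinite(self.se) and self.se > 0):
            errs.append(f"se {self.se} not > 0")
        if not (0.0 < self.pval <= 1.0):
            errs.append(f"pval {self.pval} outside (0,1]")
        if self.n < 1:
            errs.append(f"n {self.n} < 1")
        if self.pos < 1:
            errs.append(f"pos {self.pos} < 1")
        if self.trait_type not in TRAIT_TYPES:
            errs.append(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary":
            if self.n_case is None or self.n_control is None:
                errs.append("binary trait requires n_case and n_control")
            elif self.n_case + self.n_control != self.n:
                errs.append("n_case + n_control != n")
        return errs

    @property
    def zscore(self) -> float:
        return self.beta / self.se


@dataclass
class StudySummary:
    """A named study: validated records keyed by variant id."""

    trait_name: str
    trait_type: str
    records: dict[str, SummaryStatRecord] = field(default_factory=dict)
    #: (variant_id or row label, reason) pairs rejected during parsing
    rejected: list[tuple[str, str]] = field(default_factory=list, compare=False)

    def __post_init__(self) -> None:
        if self.trait_type not in TRAIT_TYPES:
            raise GwasIOError(f"unknown trait_type {self.trait_type!r}")

    def add(self, record: SummaryStatRecord) -> None:
        if record.variant_id in self.records:
            raise GwasIOError(f"duplicate variant_id {record.variant_id}")
        self.records[record.variant_id] = record

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.records

    def __iter__(self):
        return iter(self.records.values())

    def get(self, variant_id: str) -> SummaryStatRecord | None:
        return self.records.get(variant_id)

    def subset(self, variant_ids) -> "StudySummary":
        sub = StudySummary(self.trait_name, self.trait_type)
        for vid in variant_ids:
            if vid in self.records:
                sub.records[vid] = self.records[vid]
        return sub

    @property
    def max_n(self) -> int:
        return max((r.n for r in self), default=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records.values():
            rows.append(
                {
                    "variant_id": r.variant_id,
                    "chrom": r.chrom,
                    "pos": r.pos,
                    "effect_allele": r.effect_allele,
                    "other_allele": r.other_allele,
                    "eaf": r.eaf,
                    "beta": r.beta,
                    "se": r.se,
                    "pval": r.pval,
                    "n": r.n,
                    "n_case": r.n_case,
                    "n_control": r.n_control,
                }
            )
        return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


@dataclass
class LDMatrix:
    """Pairwise LD correlations (r, not r^2) for an ordered set of variants."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variant_ids)
        if self.r.shape != (k, k):
            raise GwasIOError(
                f"LD matrix shape {self.r.shape} does not match {k} variant ids"
            )
        if np.max(np.abs(self.r)) > 1.0 + 1e-8:
            raise GwasIOError("LD matrix has |r| > 1")
        if np.max(np.abs(self.r - self.r.T)) > 1e-8:
            raise GwasIOError("LD matrix is not symmetric within 1e-8")
        if np.max(np.abs(np.diag(self.r) - 1.0)) > 1e-8:
            raise GwasIOError("LD matrix diagonal is not 1 within 1e-8")
        # symmetrize and clip residual floating-point spill
        self.r = np.clip((self.r + self.r.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(self.r, 1.0)
        self._index = {v: i for i, v in enumerate(self.variant_ids)}
        if len(self._index) != k:
            raise GwasIOError("duplicate variant ids in LD matrix")

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def r2(self, a: str, b: str) -> float:
        """Squared correlation between two variants; 0 if either is absent."""
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r[ia, ib] ** 2)

    def subset(self, variant_ids: list[str]) -> "LDMatrix":
        idx = [self._index[v] for v in variant_ids]
        return LDMatrix(list(variant_ids), self.r[np.ix_(idx, idx)])


@dataclass(frozen=True)
class GeneRegion:
    """A gene body span; used to define cis windows (coordinates 1-based)."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GwasIOError(f"gene {self.gene}: start {self.start} > end {self.end}")


@dataclass
class ExclusionList:
    """Variants excluded a priori for pleiotropy, with the reason recorded."""

    entries: dict[str, str] = field(default_factory=dict)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.entries

    def reason(self, variant_id: str) -> str:
        return self.entries[variant_id]


# ---------------------------------------------------------------------------
# readers / writers


def _parse_optional_float(token: str) -> float | None:
    if token == NA_TOKEN or token == "":
        return None
    return float(token)


def _parse_optional_int(token: str) -> int | None:
    if token == NA_TOKEN or token == "":
        return None
    return int(float(token))


def read_summary_stats(path, trait_name: str, trait_type: str) -> StudySummary:
    """Read a canonical summary-statistics TSV into a validated study.

    Rows violating a record invariant (se <= 0, p outside (0,1], indel
    alleles, ...) are rejected individually and recorded in
    ``study.rejected``; a missing mandatory column is a hard failure.
    Input p-values of exactly 0 are clamped to ``PVAL_FLOOR`` with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise GwasIOError(f"summary-statistics file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in SUMMARY_COLUMNS:
        if col not in df.columns:
            raise GwasIOError(f"{path}: missing mandatory column {col!r}")
    study = StudySummary(trait_name=trait_name, trait_type=trait_type)
    for _, row in df.iterrows():
        vid = row["variant_id"]
        try:
            pval = float(row["pval"])
            if pval == 0.0:
                logger.warning("%s: pval 0 for %s clamped to %g", path, vid, PVAL_FLOOR)
                pval = PVAL_FLOOR
            rec = SummaryStatRecord(
                variant_id=vid,
                chrom=str(row["chrom"]),
                pos=int(float(row["pos"])),
                effect_allele=row["effect_allele"].upper(),
                other_allele=row["other_allele"].upper(),
                eaf=_parse_optional_float(row["eaf"]),
                beta=float(row["beta"]),
                se=float(row["se"]),
                pval=pval,
                n=int(float(row["n"])),
                n_case=_parse_optional_int(row["n_case"]),
                n_control=_parse_optional_int(row["n_control"]),
                trait_type=trait_type,
            )
        except (ValueError, TypeError) as exc:
            study.rejected.append((vid, f"unparseable row: {exc}"))
            logger.warning("%s: rejected %s (%s)", path, vid, exc)
            continue
        errs = rec.validation_errors()
        if errs:
            study.rejected.append((vid, "; ".join(errs)))
            logger.warning("%s: rejected %s (%s)", path, vid, "; ".join(errs))
            continue
        if vid in study.records:
            study.rejected.append((vid, "duplicate variant_id"))
            continue
        study.records[vid] = rec
    return study


def _fmt_float(x: float | None) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return NA_TOKEN
    return f"{x:.10g}"


def _fmt_int(x: int | None) -> str:
    return NA_TOKEN if x is None else str(int(x))


def write_summary_stats(study: StudySummary, path) -> None:
    """Write a study as a canonical TSV (missing values as ``NA``)."""
    path = Path(path)
    lines = ["\t".join(SUMMARY_COLUMNS)]
    for r in study:
        lines.append(
            "\t".join(
                [
                    r.variant_id,
                    r.chrom,
                    str(r.pos),
                    r.effect_allele,
                    r.other_allele,
                    _fmt_float(r.eaf),
                    _fmt_float(r.beta),
                    _fmt_float(r.se),
                    _fmt_float(r.pval),
                    str(r.n),
                    _fmt_int(r.n_case),
                    _fmt_int(r.n_control),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def read_ld_matrix(path) -> LDMatrix:
    """Read a square LD TSV (first row/column are variant ids)."""
    path = Path(path)
    if not path.exists():
        raise GwasIOError(f"LD matrix file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise GwasIOError(f"{path}: LD matrix is not square ({df.shape})")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise GwasIOError(f"{path}: row and column variant ids differ")
    return LDMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path) -> None:
    df = pd.DataFrame(ld.r, index=ld.variant_ids, columns=ld.variant_ids)
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_gene_regions(path) -> dict[str, GeneRegion]:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    for col in ("gene", "chrom", "start", "end"):
        if col not in df.columns:
            raise GwasIOError(f"{path}: missing column {col!r}")
    out: dict[str, GeneRegion] = {}
    for _, row in df.iterrows():
        out[row["gene"]] = GeneRegion(
            row["gene"], str(row["chrom"]), int(row["start"]), int(row["end"])
        )
    return out


def write_gene_regions(regions: dict[str, GeneRegion], path) -> None:
    lines = ["gene\tchrom\tstart\tend"]
    for g in regions.values():
        lines.append(f"{g.gene}\t{g.chrom}\t{g.start}\t{g.end}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_exclusion_list(path) -> ExclusionList:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("variant_id", "reason"):
        if col not in df.columns:
            raise GwasIOError(f"{path}: missing column {col!r}")
    entries = {}
    for _, row in df.iterrows():
        if not row["variant_id"]:
            raise GwasIOError(f"{path}: empty variant_id in exclusion list")
        entries[row["variant_id"]] = row["reason"]
    return ExclusionList(entries)


def write_exclusion_list(excl: ExclusionList, path) -> None:
    lines = ["variant_id\treason"]
    for vid, reason in excl.entries.items():
        lines.append(f"{vid}\t{reason}")
    Path(path).write_text("\n".join(lines) + "\n")
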