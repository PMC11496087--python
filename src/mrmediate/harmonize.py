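"""Allele harmonization between an exposure and an outcome (or mediator) study.

Two-sample MR requires each variant's exposure and outcome effects to be
expressed per copy of the *same* effect allele.  Outcome records whose alleles
are swapped relative to the exposure have their beta sign flipped (and EAF
complemented); records reported on the opposite strand are complemented first.
Palindromic variants (A/T or C/G) are dropped unconditionally — their strand
cannot be resolved from alleles alone and no frequency-based inference is
attempted.  Variants missing from the outcome study are reported as dropped
rather than silently skipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .gwas_io import StudySummary, SummaryStatRecord

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

KEPT_AS_IS = "kept_as_is"
FLIPPED = "flipped"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_MISSING = "dropped_missing"
DROPPED_MISMATCH = "dropped_mismatch"

KEPT_ACTIONS = frozenset({KEPT_AS_IS, FLIPPED})


class HarmonizationError(ValueError):
    pass


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the unordered allele pair is {A,T} or {C,G}."""
    return COMPLEMENT[effect_allele] == other_allele


@dataclass
class HarmonizedInstrument:
    """An exposure–outcome aligned variant (or the record of its dropping)."""

    variant_id: str
    beta_exp: float
    se_exp: float
    beta_out: float | None
    se_out: float | None
    action: str
    eaf_out: float | None = None
    complemented: bool = False

    @property
    def kept(self) -> bool:
        return self.action in KEPT_ACTIONS

    @property
    def f_stat(self) -> float:
        return (self.beta_exp / self.se_exp) ** 2

    @property
    def wald_numerator_z(self) -> float:
        return self.beta_out / self.se_out


def harmonize_pair(
    exposure: SummaryStatRecord, outcome: SummaryStatRecord
) -> HarmonizedInstrument:
    """Align one outcome record to the exposure's effect allele.

    Raises on a variant-id mismatch; every allele configuration otherwise
    maps to a kept or dropped instrument, never an exception.
    """
    if exposure.variant_id != outcome.variant_id:
        raise HarmonizationError(
            f"variant_id mismatch: {exposure.variant_id} vs {outcome.variant_id}"
        )
    ea, oa = exposure.effect_allele, exposure.other_allele
    if is_palindromic(ea, oa):
        return HarmonizedInstrument(
            exposure.variant_id,
            exposure.beta,
            exposure.se,
            None,
            None,
            DROPPED_PALINDROMIC,
        )
    pair = (outcome.effect_allele, outcome.other_allele)
    comp_pair = (COMPLEMENT[outcome.effect_allele], COMPLEMENT[outcome.other_allele])
    complemented = False
    if pair == (ea, oa) or pair == (oa, ea):
        oe, oo = pair
    elif comp_pair == (ea, oa) or comp_pair == (oa, ea):
        # opposite-strand report; safe to complement because not palindromic
        oe, oo = comp_pair
        complemented = True
    else:
        return HarmonizedInstrument(
            exposure.variant_id,
            exposure.beta,
            exposure.se,
            None,
            None,
            DROPPED_MISMATCH,
        )
    if (oe, oo) == (ea, oa):
        return HarmonizedInstrument(
            exposure.variant_id,
            exposure.beta,
            exposure.se,
            outcome.beta,
            outcome.se,
            KEPT_AS_IS,
            eaf_out=outcome.eaf,
            complemented=complemented,
        )
    return HarmonizedInstrument(
        exposure.variant_id,
        exposure.beta,
        exposure.se,
        -outcome.beta,
        outcome.se,
        FLIPPED,
        eaf_out=None if outcome.eaf is None else 1.0 - outcome.eaf,
        complemented=complemented,
    )


def harmonize_studies(
    exposure: StudySummary,
    outcome: StudySummary,
    variant_ids,
) -> list[HarmonizedInstrument]:
    """Harmonize the listed exposure variants against an outcome study.

    Returns one :class:`HarmonizedInstrument` per input variant, kept or
    dropped, so that kept + dropped always equals the input count.
    """
    out: list[HarmonizedInstrument] = []
    for vid in variant_ids:
        exp_rec = exposure.get(vid)
        if exp_rec is None:
            raise HarmonizationError(f"{vid} not present in exposure study")
        out_rec = outcome.get(vid)
        if out_rec is None:
            out.append(
                HarmonizedInstrument(
                    vid, exp_rec.beta, exp_rec.se, None, None, DROPPED_MISSING
                )
            )
        else:
            out.append(harmonize_pair(exp_rec, out_rec))
    return out


def kept_instruments(
    harmonized: list[HarmonizedInstrument],
) -> list[HarmonizedInstrument]:
    return [h for h in harmonized if h.kept]


def write_harmonization_report(harmonized, path) -> None:
    lines = ["variant_id\taction\tbeta_exp\tbeta_out"]
    for h in harmonized:
        bo = "NA" if h.beta_out is None else f"{h.beta_out:.10g}"
        lines.append(f"{h.variant_id}\t{h.action}\t{h.beta_exp:.10g}\t{bo}")
    Path(path).write_text("\n".join(lines) + "\n")
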