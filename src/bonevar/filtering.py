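"""The variant-retention funnel and genotype-pattern flagging.

Stages, in fixed order: call-quality (QD) filter, consequence restriction,
inheritance-aware population-frequency filter. Every input variant receives
exactly one :class:`FilterTrace`, so the funnel is fully auditable and the
retained + removed counts always sum to the input count. The funnel is
idempotent: re-running it on its own output changes nothing.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .records import (
    CandidateGene,
    Inheritance,
    VariantRecord,
    Zygosity,
)

DEFAULT_QD_THRESHOLD = 5.0


class FilterStage(str, enum.Enum):
    QD = "qd"
    CONSEQUENCE = "consequence"
    FREQUENCY = "frequency"
    NONE = "none"


@dataclass(frozen=True)
class FilterTrace:
    variant: VariantRecord
    stage_removed: FilterStage
    retained: bool
    note: str = ""

    def __post_init__(self) -> None:
        assert self.retained == (self.stage_removed is FilterStage.NONE)


class PatternType(str, enum.Enum):
    DOMINANT_HET = "dominant_het"
    RECESSIVE_HOM = "recessive_hom"
    RECESSIVE_COMPOUND_HET = "recessive_compound_het"
    RECESSIVE_CARRIER = "recessive_carrier"
    HEMIZYGOUS = "hemizygous"


@dataclass(frozen=True)
class GenotypePattern:
    patient_id: str
    gene: str
    pattern: PatternType
    variants: tuple[VariantRecord, ...]
    note: str = ""


#: consequence classes kept by the restriction stage: exonic coding changes,
#: splice-region variants, UTRs and exonic indels; synonymous and everything
#: outside transcripts are dropped.
RETAINED_CONSEQUENCES = frozenset(
    {
        "nonsynonymous",
        "stopgain",
        "stoploss",
        "splicing",
        "utr",
        "frameshift_indel",
        "inframe_indel",
    }
)


def qd_filter(
    variants: Sequence[VariantRecord], threshold: float = DEFAULT_QD_THRESHOLD
) -> tuple[list[VariantRecord], list[FilterTrace]]:
    """Remove low-confidence calls: QD (QUAL normalised by allele depth) <= threshold.

    Variants without a QD value (e.g. externally validated calls re-entered
    into the table) are retained with a note — the filter targets raw caller
    output, which always carries QD.
    """
    retained: list[VariantRecord] = []
    traces: list[FilterTrace] = []
    for v in variants:
        if v.qd is None:
            retained.append(v)
            traces.append(
                FilterTrace(v, FilterStage.NONE, True, note="qd absent: retained")
            )
        elif v.qd <= threshold:
            traces.append(FilterTrace(v, FilterStage.QD, False))
        else:
            retained.append(v)
            traces.append(FilterTrace(v, FilterStage.NONE, True))
    return retained, traces


def consequence_filter(variants: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Restrict to protein-altering / splice / UTR / indel consequence classes."""
    return [v for v in variants if v.consequence.value in RETAINED_CONSEQUENCES]


def frequency_filter(
    variants: Sequence[VariantRecord], panel: Sequence[CandidateGene]
) -> list[VariantRecord]:
    """Keep variants rarer than their gene's inheritance-class cutoff.

    The frequency compared to the cutoff is the maximum over both reference
    databases (a variant common in either one is not rare); absence from a
    database counts as frequency 0. The comparison is strictly ``<``.
    Variants in genes outside the panel are dropped with a warning.
    """
    cutoffs = {g.symbol: g.af_cutoff for g in panel}
    retained: list[VariantRecord] = []
    for v in variants:
        cutoff = cutoffs.get(v.gene)
        if cutoff is None:
            warnings.warn(f"variant in non-panel gene {v.gene}: dropped", stacklevel=2)
            continue
        if v.max_af < cutoff:
            retained.append(v)
    return retained


def run_funnel(
    variants: Sequence[VariantRecord],
    panel: Sequence[CandidateGene],
    qd_threshold: float = DEFAULT_QD_THRESHOLD,
) -> tuple[list[VariantRecord], list[FilterTrace]]:
    """Run the full funnel (qd -> consequence -> frequency), one trace per input."""
    traces: dict[tuple, FilterTrace] = {}
    after_qd, qd_traces = qd_filter(variants, threshold=qd_threshold)
    for t in qd_traces:
        traces[t.variant.key()] = t
    after_csq = consequence_filter(after_qd)
    removed_csq = {v.key() for v in after_qd} - {v.key() for v in after_csq}
    for v in after_qd:
        if v.key() in removed_csq:
            traces[v.key()] = FilterTrace(v, FilterStage.CONSEQUENCE, False)
    after_freq = frequency_filter(after_csq, panel)
    removed_freq = {v.key() for v in after_csq} - {v.key() for v in after_freq}
    for v in after_csq:
        if v.key() in removed_freq:
            traces[v.key()] = FilterTrace(v, FilterStage.FREQUENCY, False)
    ordered = [traces[v.key()] for v in variants]
    assert sum(t.retained for t in ordered) == len(after_freq)
    return after_freq, ordered


def genotype_patterns(
    variants: Sequence[VariantRecord], panel: Sequence[CandidateGene]
) -> list[GenotypePattern]:
    """Flag per-(patient, gene) genotype configurations on filtered variants.

    Dominant-gene carriers of any heterozygous (or homozygous) variant are
    flagged ``dominant_het``; hemizygous calls in X-linked genes are flagged
    ``hemizygous`` (interpreted along the dominant pathway). In recessive
    genes a homozygote is ``recessive_hom``, two or more distinct
    heterozygous variants form a putative (phase-unknown) compound
    heterozygote, and a single heterozygous variant marks a carrier — still
    a reportable finding.
    """
    modes = {g.symbol: g.inheritance for g in panel}
    by_patient_gene: dict[tuple[str, str], list[VariantRecord]] = {}
    for v in variants:
        by_patient_gene.setdefault((v.patient_id, v.gene), []).append(v)

    patterns: list[GenotypePattern] = []
    for (patient_id, gene), vs in sorted(by_patient_gene.items()):
        mode = modes.get(gene)
        if mode is None:
            continue
        vs_t = tuple(vs)
        if mode is Inheritance.DOMINANT:
            if any(v.zygosity is Zygosity.HEMI for v in vs):
                ptype = PatternType.HEMIZYGOUS
            else:
                ptype = PatternType.DOMINANT_HET
            patterns.append(GenotypePattern(patient_id, gene, ptype, vs_t))
        else:
            hets = [v for v in vs if v.zygosity is Zygosity.HET]
            distinct_het_sites = {v.site() for v in hets}
            if any(v.zygosity in (Zygosity.HOM, Zygosity.HEMI) for v in vs):
                patterns.append(
                    GenotypePattern(patient_id, gene, PatternType.RECESSIVE_HOM, vs_t)
                )
            elif len(distinct_het_sites) >= 2:
                patterns.append(
                    GenotypePattern(
                        patient_id,
                        gene,
                        PatternType.RECESSIVE_COMPOUND_HET,
                        vs_t,
                        note="phase unknown",
                    )
                )
            elif len(distinct_het_sites) == 1:
                patterns.append(
                    GenotypePattern(
                        patient_id, gene, PatternType.RECESSIVE_CARRIER, vs_t
                    )
                )
    return patterns
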