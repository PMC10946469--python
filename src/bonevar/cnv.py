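"""SNP-array QC, CNV call filtering, gene overlap and copy-number-loss scoring.

CNV *detection* (LRR/BAF segmentation) is upstream and out of scope: this
module consumes call tables. Scoring follows the joint ACMG/ClinGen
copy-number-loss rubric: section-based criteria each contribute points
(shipped as an editable table with the published defaults), the points sum
to a total, and fixed score bands map the total to a five-tier verdict.
Sections 2, 4 and 5 are evidence-strength judgments, so every assessment may
override a criterion's default points within its allowed range.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from functools import lru_cache
from importlib import resources
from typing import Mapping, Optional, Sequence

import pandas as pd

from .records import (
    CandidateGene,
    CnvCall,
    SampleQcRecord,
    SnpQcRecord,
    ValidationError,
    Verdict,
)

CLUSTER_SEPARATION_MIN = 0.27  # probes below this are unreliable and removed
CALL_RATE_MIN = 0.975  # samples must exceed this genotyping call rate
MIN_SNPS_PER_CNV = 10  # calls supported by fewer consecutive probes are dropped


@dataclass(frozen=True)
class RubricCriterion:
    criterion: str
    section: int
    default_points: float
    min_points: float
    max_points: float
    description: str


@dataclass(frozen=True)
class ClinGenAssessment:
    total_score: float
    verdict: Verdict
    points: Mapping[str, float] = None


@lru_cache(maxsize=None)
def load_loss_rubric(path: Optional[str] = None) -> dict[str, RubricCriterion]:
    """Load the copy-number-loss rubric table (packaged default or custom)."""
    if path is None:
        with resources.files("bonevar.data").joinpath("clingen_loss_rubric.tsv").open("rb") as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.itertuples(index=False):
        out[row.criterion] = RubricCriterion(
            criterion=row.criterion,
            section=int(row.section),
            default_points=float(row.default_points),
            min_points=float(row.min_points),
            max_points=float(row.max_points),
            description=row.description,
        )
    return out


@dataclass(frozen=True)
class ClinGenEvidence:
    """Selected loss-rubric criteria with their assessed points.

    ``assessments`` maps a criterion ID (e.g. ``3C``) to assessed points, or
    to None to use the criterion's rubric default. At most one criterion may
    be selected per rubric section.
    """

    assessments: Mapping[str, Optional[float]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "assessments", dict(self.assessments))
        rubric = load_loss_rubric()
        sections_seen: dict[int, str] = {}
        for crit_id, points in self.assessments.items():
            crit = rubric.get(crit_id)
            if crit is None:
                raise ValidationError(f"unknown loss-rubric criterion: {crit_id}")
            if crit.section in sections_seen:
                raise ValidationError(
                    f"criteria {sections_seen[crit.section]} and {crit_id} both "
                    f"selected from rubric section {crit.section}"
                )
            sections_seen[crit.section] = crit_id
            if points is not None and not (
                crit.min_points - 1e-9 <= points <= crit.max_points + 1e-9
            ):
                raise ValidationError(
                    f"{crit_id}: points {points} outside "
                    f"[{crit.min_points}, {crit.max_points}]"
                )

    def resolved_points(self) -> dict[str, float]:
        rubric = load_loss_rubric()
        return {
            cid: (pts if pts is not None else rubric[cid].default_points)
            for cid, pts in self.assessments.items()
        }


def snp_qc(
    snps: Sequence[SnpQcRecord], samples: Sequence[SampleQcRecord] = ()
) -> tuple[list[SnpQcRecord], list[SampleQcRecord]]:
    """Apply array QC: drop probes with cluster separation below 0.27
    (0.27 itself passes) and flag samples with call rate not above 97.5%."""
    passing_snps = [s for s in snps if s.cluster_separation >= CLUSTER_SEPARATION_MIN]
    passing_samples = [s for s in samples if s.call_rate > CALL_RATE_MIN]
    return passing_snps, passing_samples


def cnv_filter(
    calls: Sequence[CnvCall], min_snps: int = MIN_SNPS_PER_CNV
) -> list[CnvCall]:
    """Retain calls supported by at least ``min_snps`` consecutive probes.

    No minimal segment-size restriction is applied."""
    return [c for c in calls if c.n_snps >= min_snps]


def overlap_candidate_genes(
    call: CnvCall,
    panel: Sequence[CandidateGene],
    genome_build: str = "GRCh37",
) -> list[str]:
    """Panel genes whose interval intersects the call by >= 1 bp.

    Both intervals are 1-based inclusive, so a call ending exactly at a
    gene's start coordinate overlaps it by one base.
    """
    if call.genome_build != genome_build:
        raise ValidationError(
            f"genome build mismatch: call is {call.genome_build}, "
            f"panel assumed {genome_build}"
        )
    hits = []
    for gene in panel:
        if gene.chrom != call.chrom:
            continue
        if call.start <= gene.end and gene.start <= call.end:
            hits.append(gene.symbol)
    return hits


def cnv_span_mb(call: CnvCall) -> float:
    """Segment span in megabases, rounded half-up to one decimal place."""
    span = (call.end - call.start + 1) / 1e6
    return float(Decimal(str(span)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# score bands of the loss rubric (evaluated on the 2-decimal rounded total)
def _band(score: float) -> Verdict:
    if score >= 0.99:
        return Verdict.PATHOGENIC
    if score >= 0.90:
        return Verdict.LIKELY_PATHOGENIC
    if score > -0.90:
        return Verdict.UNCERTAIN_SIGNIFICANCE
    if score > -0.99:
        return Verdict.LIKELY_BENIGN
    return Verdict.BENIGN


def clingen_loss_score(evidence: ClinGenEvidence) -> ClinGenAssessment:
    """Sum the assessed rubric points and map the total to a verdict band."""
    points = evidence.resolved_points()
    total = float(
        Decimal(str(sum(Decimal(str(p)) for p in points.values()))).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )
    return ClinGenAssessment(total_score=total, verdict=_band(total), points=points)
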