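"""Core domain records for panel-based rare-variant interpretation.

The records model one annotated variant observation per patient (as emitted by
an ANNOVAR-style annotation of a joint-called exome VCF), the candidate-gene
panel with its inheritance mode and rarity cutoff, the patient manifest, and
SNP-array CNV calls. All genomic coordinates are 1-based inclusive.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class Consequence(str, enum.Enum):
    """Collapsed functional consequence classes of an exonic/splicing variant."""

    NONSYNONYMOUS = "nonsynonymous"
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    SPLICING = "splicing"
    UTR = "utr"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class Zygosity(str, enum.Enum):
    HET = "het"
    HOM = "hom"
    HEMI = "hemi"


class ClinVarStatus(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    UNCERTAIN = "uncertain"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"
    CONFLICTING = "conflicting"
    ABSENT = "absent"


class Inheritance(str, enum.Enum):
    DOMINANT = "dominant"
    RECESSIVE = "recessive"


class Verdict(str, enum.Enum):
    """Five-tier pathogenicity verdict."""

    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    UNCERTAIN_SIGNIFICANCE = "uncertain_significance"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


#: verdicts counted as a positive finding in prevalence estimates
PATHOGENIC_VERDICTS = frozenset(
    {Verdict.PATHOGENIC, Verdict.LIKELY_PATHOGENIC}
)


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class FormatError(ValueError):
    """An input file is malformed (missing column, unknown token, ...)."""


def normalize_chrom(label: str) -> str:
    """Normalise a chromosome label: strip a leading 'chr', keep the rest.

    Idempotent; 'chr6' and '6' map to the same label.
    """
    label = str(label).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    return label


@dataclass(frozen=True)
class CandidateGene:
    """One panel gene with its inheritance mode, rarity cutoff and interval.

    ``af_cutoff`` is the population allele-frequency threshold below which a
    variant in this gene is considered rare enough to pursue: 0.001 for genes
    of dominantly inherited disorders, 0.01 for recessive ones (one recessive
    disease allele need not be vanishingly rare in the population).
    X-linked genes are carried in the dominant cutoff class.
    """

    symbol: str
    inheritance: Inheritance
    chrom: str
    start: int
    end: int
    af_cutoff: float = 0.0
    is_x_linked: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbol", self.symbol.upper())
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.af_cutoff == 0.0:
            default = 0.001 if self.inheritance is Inheritance.DOMINANT else 0.01
            object.__setattr__(self, "af_cutoff", default)
        if not (0 < self.af_cutoff <= 1):
            raise ValidationError(
                f"{self.symbol}: af_cutoff must be in (0,1], got {self.af_cutoff}"
            )
        if self.start > self.end:
            raise ValidationError(f"{self.symbol}: start > end")
        if self.start < 1:
            raise ValidationError(f"{self.symbol}: coordinates are 1-based")


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant observed in one patient.

    ``af_db1``/``af_db2`` are overall-population allele frequencies from two
    reference databases (1000 Genomes and gnomAD in the default setup); None
    means the variant is absent from that database, the rarest possible state
    for threshold purposes. ``canonical_splice`` only matters for splicing
    consequences: True (the default, matching ANNOVAR's +-2 bp 'splicing'
    class) marks a canonical-dinucleotide site and hence loss of function.
    ``curated_evidence`` optionally carries a manually assigned ACMG profile;
    ``tags`` is free-form provenance ('assumed_af', 'reconstructed', ...).
    """

    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: Consequence
    zygosity: Zygosity
    qd: Optional[float] = None
    af_db1: Optional[float] = None
    af_db2: Optional[float] = None
    cadd: Optional[float] = None
    clinvar: ClinVarStatus = ClinVarStatus.ABSENT
    hgvs_c: Optional[str] = None
    canonical_splice: bool = True
    curated_evidence: Optional[tuple[str, ...]] = None
    tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(self, "gene", self.gene.upper())
        if not self.ref or not self.alt:
            raise ValidationError(f"{self.key()}: alleles must be non-empty")
        if self.ref == self.alt:
            raise ValidationError(f"{self.key()}: ref == alt")
        if self.pos < 1:
            raise ValidationError(f"{self.key()}: pos must be >= 1")
        for name in ("af_db1", "af_db2"):
            val = getattr(self, name)
            if val is not None and not (0.0 <= val <= 1.0):
                raise ValidationError(f"{self.key()}: {name}={val} outside [0,1]")
        if self.qd is not None and self.qd < 0:
            raise ValidationError(f"{self.key()}: qd must be non-negative")

    def key(self) -> tuple[str, str, int, str, str]:
        """Identity of the variant observation: (patient, chrom, pos, ref, alt)."""
        return (self.patient_id, self.chrom, self.pos, self.ref, self.alt)

    def site(self) -> tuple[str, int, str, str]:
        """Identity of the allele irrespective of the carrier."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def max_af(self) -> float:
        """Maximum frequency over both reference databases, absent treated as 0."""
        return max(self.af_db1 or 0.0, self.af_db2 or 0.0)

    @property
    def is_lof(self) -> bool:
        """Loss-of-function consequence: nonsense, frameshift, stop-loss, or
        canonical-site splice disruption."""
        if self.consequence in (
            Consequence.STOPGAIN,
            Consequence.STOPLOSS,
            Consequence.FRAMESHIFT_INDEL,
        ):
            return True
        return self.consequence is Consequence.SPLICING and self.canonical_splice

    @property
    def is_indel(self) -> bool:
        return self.consequence in (
            Consequence.FRAMESHIFT_INDEL,
            Consequence.INFRAME_INDEL,
        ) or len(self.ref) != len(self.alt)


@dataclass(frozen=True)
class PatientRecord:
    """Manifest entry: suspicion status, family and covariates."""

    patient_id: str
    suspected: bool
    family_id: str
    sex: str = "F"
    bp_use: bool = True
    bp_years: Optional[float] = None
    gc_long_term: bool = False
    center: str = ""
    age_at_aff: Optional[float] = None
    osteoporosis_flag: bool = True
    bilateral_flag: bool = False

    def __post_init__(self) -> None:
        if self.bp_years is not None and not self.bp_use:
            raise ValidationError(
                f"{self.patient_id}: bp_years present without bisphosphonate use"
            )


@dataclass(frozen=True)
class Cohort:
    """A set of patients with unique identifiers."""

    patients: tuple[PatientRecord, ...]

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient_id(s): {', '.join(dupes)}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def get(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(p.patient_id for p in self.patients)

    def subset(self, ids) -> "Cohort":
        keep = set(ids)
        return Cohort(tuple(p for p in self.patients if p.patient_id in keep))

    @property
    def suspected(self) -> tuple[PatientRecord, ...]:
        return tuple(p for p in self.patients if p.suspected)

    @property
    def non_suspected(self) -> tuple[PatientRecord, ...]:
        return tuple(p for p in self.patients if not p.suspected)


class CnvType(str, enum.Enum):
    LOSS = "loss"
    GAIN = "gain"


@dataclass(frozen=True)
class CnvCall:
    """An array-derived copy-number segment (PennCNV-style call)."""

    patient_id: str
    chrom: str
    start: int
    end: int
    cnv_type: CnvType
    n_snps: int
    genome_build: str = "GRCh37"
    gene_count: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start > self.end:
            raise ValidationError(f"CNV {self.patient_id}: start > end")
        if self.n_snps < 1:
            raise ValidationError(f"CNV {self.patient_id}: n_snps must be >= 1")


@dataclass(frozen=True)
class SnpQcRecord:
    """Array-probe QC: GenomeStudio cluster-separation score for one SNP."""

    snp_id: str
    cluster_separation: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.cluster_separation <= 1.0):
            raise ValidationError(
                f"{self.snp_id}: cluster_separation outside [0,1]"
            )


@dataclass(frozen=True)
class SampleQcRecord:
    """Per-sample genotyping call rate."""

    sample_id: str
    call_rate: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.call_rate <= 1.0):
            raise ValidationError(f"{self.sample_id}: call_rate outside [0,1]")
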