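"""Readers and writers for variant tables, gene panels, manifests and CNV calls.

TSV is the canonical dialect throughout (mandatory named header, one record
per row, empty cell = absent). A minimal VCF reader (GT plus configurable
INFO keys) is provided for convenience; it is deliberately not a full VCF 4.x
implementation.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .records import (
    CandidateGene,
    ClinVarStatus,
    CnvCall,
    CnvType,
    Cohort,
    Consequence,
    FormatError,
    Inheritance,
    PatientRecord,
    SampleQcRecord,
    SnpQcRecord,
    ValidationError,
    VariantRecord,
    Zygosity,
)

_VARIANT_COLUMNS = [
    "patient_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "zygosity",
    "qd",
    "af_db1",
    "af_db2",
    "cadd",
    "clinvar",
]

#: default mapping of VariantRecord fields to INFO keys in the VCF dialect
DEFAULT_VCF_INFO_MAP = {
    "gene": "GENE",
    "consequence": "CSQ_CLASS",
    "af_db1": "AF_DB1",
    "af_db2": "AF_DB2",
    "cadd": "CADD",
    "clinvar": "CLNSIG",
    "qd": "QD",
}


def _opt_float(value, row: int, name: str) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value in ("", ".", "NA", "N/A", "nan"):
            return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise FormatError(f"row {row}: cannot parse {name}={value!r} as a number")


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing mandatory column(s): {', '.join(missing)}")


def read_variant_table(
    path,
    dialect: str = "tsv",
    vcf_info_map: Optional[Mapping[str, str]] = None,
) -> list[VariantRecord]:
    """Read per-patient variant observations from a TSV table or minimal VCF.

    The TSV must name all mandatory columns; empty numeric cells are read as
    absent (never silently as 0). For the VCF dialect one record is emitted
    per carrier sample per ALT allele, with zygosity derived from GT.
    """
    if dialect == "tsv":
        return _read_variant_tsv(path)
    if dialect == "vcf":
        return _read_variant_vcf(path, vcf_info_map or DEFAULT_VCF_INFO_MAP)
    raise ValueError(f"unknown dialect: {dialect}")


def _read_variant_tsv(path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, _VARIANT_COLUMNS, f"variant table {path}")
    out: list[VariantRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            rec = VariantRecord(
                patient_id=row.patient_id,
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                gene=row.gene,
                consequence=Consequence(row.consequence),
                zygosity=Zygosity(row.zygosity),
                qd=_opt_float(row.qd, i, "qd"),
                af_db1=_opt_float(row.af_db1, i, "af_db1"),
                af_db2=_opt_float(row.af_db2, i, "af_db2"),
                cadd=_opt_float(row.cadd, i, "cadd"),
                clinvar=ClinVarStatus(row.clinvar) if row.clinvar else ClinVarStatus.ABSENT,
                hgvs_c=getattr(row, "hgvs_c", None) or None,
                canonical_splice=(
                    str(getattr(row, "canonical_splice", "1")).strip().lower()
                    not in ("0", "false", "no")
                ),
                curated_evidence=(
                    tuple(str(getattr(row, "curated_evidence")).split(","))
                    if getattr(row, "curated_evidence", "")
                    else None
                ),
                tags=tuple(t for t in str(getattr(row, "tags", "")).split(",") if t),
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
        except ValueError as exc:
            raise FormatError(f"row {i}: {exc}") from exc
        out.append(rec)
    return out


def _zygosity_from_genotype(alleles: list[int]) -> Optional[Zygosity]:
    """Map a per-sample genotype (allele indices, -1 = missing) to zygosity.

    Returns None for non-carriers (hom-ref or fully missing calls).
    """
    called = [a for a in alleles if a >= 0]
    alt = [a for a in called if a > 0]
    if not alt:
        return None
    if len(called) == 1:
        return Zygosity.HEMI
    if all(a > 0 for a in called):
        return Zygosity.HOM
    return Zygosity.HET


def _read_variant_vcf(path, info_map: Mapping[str, str]) -> list[VariantRecord]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out: list[VariantRecord] = []
    for var in vcf:
        info = {field: var.INFO.get(key) for field, key in info_map.items()}
        consequence = Consequence(info.get("consequence") or "other")
        clinvar = (
            ClinVarStatus(info["clinvar"]) if info.get("clinvar") else ClinVarStatus.ABSENT
        )
        for sample, genotype in zip(samples, var.genotypes):
            zyg = _zygosity_from_genotype([a for a in genotype[:-1]])
            if zyg is None:
                continue  # only carrier samples produce records
            out.append(
                VariantRecord(
                    patient_id=sample,
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=var.REF,
                    alt=var.ALT[0],
                    gene=info.get("gene") or "UNKNOWN",
                    consequence=consequence,
                    zygosity=zyg,
                    qd=float(info["qd"]) if info.get("qd") is not None else None,
                    af_db1=float(info["af_db1"]) if info.get("af_db1") is not None else None,
                    af_db2=float(info["af_db2"]) if info.get("af_db2") is not None else None,
                    cadd=float(info["cadd"]) if info.get("cadd") is not None else None,
                    clinvar=clinvar,
                )
            )
    return out


def write_variant_table(records: Iterable[VariantRecord], path) -> None:
    """Write records as canonical TSV; round-trips losslessly with the reader."""
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "gene": r.gene,
                "consequence": r.consequence.value,
                "zygosity": r.zygosity.value,
                "qd": "" if r.qd is None else r.qd,
                "af_db1": "" if r.af_db1 is None else r.af_db1,
                "af_db2": "" if r.af_db2 is None else r.af_db2,
                "cadd": "" if r.cadd is None else r.cadd,
                "clinvar": r.clinvar.value,
                "hgvs_c": r.hgvs_c or "",
                "canonical_splice": int(r.canonical_splice),
                "curated_evidence": ",".join(r.curated_evidence or ()),
                "tags": ",".join(r.tags),
            }
        )
    pd.DataFrame(rows, columns=_VARIANT_COLUMNS + ["hgvs_c", "canonical_splice", "curated_evidence", "tags"]).to_csv(
        path, sep="\t", index=False
    )


def load_gene_panel(path=None) -> list[CandidateGene]:
    """Load a gene panel TSV; without a path, the packaged 37-gene default.

    The rarity cutoff is auto-assigned from the inheritance class (0.001
    dominant, 0.01 recessive) unless an ``af_cutoff`` value is given per row.
    """
    if path is None:
        with resources.files("bonevar.data").joinpath("gene_panel.tsv").open("rb") as fh:
            df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["symbol", "inheritance", "chrom", "start", "end"], "gene panel")
    if df.empty:
        raise FormatError("panel contains no genes")
    genes: list[CandidateGene] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        symbol = row.symbol.upper()
        if symbol in seen:
            raise FormatError(f"duplicate gene symbol in panel: {symbol}")
        seen.add(symbol)
        try:
            inheritance = Inheritance(row.inheritance)
        except ValueError:
            raise FormatError(
                f"row {i}: unknown inheritance token {row.inheritance!r}"
            ) from None
        override = _opt_float(getattr(row, "af_cutoff", ""), i, "af_cutoff")
        genes.append(
            CandidateGene(
                symbol=symbol,
                inheritance=inheritance,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                af_cutoff=override if override is not None else 0.0,
                is_x_linked=(
                    str(getattr(row, "is_x_linked", "0")).strip().lower()
                    in ("1", "true", "yes")
                ),
            )
        )
    return genes


def load_manifest(path) -> Cohort:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["patient_id", "suspected", "family_id"], "manifest")
    patients = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        bp_use = row.bp_use in ("1", "true", "True") if hasattr(row, "bp_use") else True
        patients.append(
            PatientRecord(
                patient_id=row.patient_id,
                suspected=row.suspected in ("1", "true", "True"),
                family_id=row.family_id,
                sex=getattr(row, "sex", "F") or "F",
                bp_use=bp_use,
                bp_years=_opt_float(getattr(row, "bp_years", ""), i, "bp_years"),
                gc_long_term=getattr(row, "gc_long_term", "0") in ("1", "true", "True"),
                center=getattr(row, "center", ""),
                age_at_aff=_opt_float(getattr(row, "age_at_aff", ""), i, "age_at_aff"),
                osteoporosis_flag=getattr(row, "osteoporosis_flag", "1") in ("1", "true", "True"),
                bilateral_flag=getattr(row, "bilateral_flag", "0") in ("1", "true", "True"),
            )
        )
    return Cohort(tuple(patients))


def write_manifest(cohort: Cohort, path) -> None:
    rows = []
    for p in cohort:
        rows.append(
            {
                "patient_id": p.patient_id,
                "suspected": int(p.suspected),
                "family_id": p.family_id,
                "sex": p.sex,
                "bp_use": int(p.bp_use),
                "bp_years": "" if p.bp_years is None else p.bp_years,
                "gc_long_term": int(p.gc_long_term),
                "center": p.center,
                "age_at_aff": "" if p.age_at_aff is None else p.age_at_aff,
                "osteoporosis_flag": int(p.osteoporosis_flag),
                "bilateral_flag": int(p.bilateral_flag),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cnv_table(path) -> list[CnvCall]:
    """Read a PennCNV-rawcnv-like TSV of copy-number calls."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(
        df, ["patient_id", "chrom", "start", "end", "cnv_type", "n_snps"], "CNV table"
    )
    calls = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        gene_count = getattr(row, "gene_count", "")
        calls.append(
            CnvCall(
                patient_id=row.patient_id,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                cnv_type=CnvType(row.cnv_type),
                n_snps=int(row.n_snps),
                genome_build=getattr(row, "genome_build", "GRCh37") or "GRCh37",
                gene_count=int(gene_count) if gene_count else None,
            )
        )
    return calls


def read_snp_qc(path) -> list[SnpQcRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["snp_id", "cluster_separation"], "SNP QC table")
    return [
        SnpQcRecord(row.snp_id, float(row.cluster_separation))
        for row in df.itertuples(index=False)
    ]


def read_sample_qc(path) -> list[SampleQcRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["sample_id", "call_rate"], "sample QC table")
    return [
        SampleQcRecord(row.sample_id, float(row.call_rate))
        for row in df.itertuples(index=False)
    ]


def write_report(report: dict, path, format: str = "json") -> None:
    """Serialise a pipeline report to JSON or flat TSV."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    elif format == "tsv":
        rows = report.get("variants", [])
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format: {format}")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
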