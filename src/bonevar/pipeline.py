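"""Stage orchestration: filtering -> classification -> prevalence -> statistics.

`run_case_pipeline` chains the funnel, both classification layers and the
prevalence/enrichment statistics over in-memory objects and returns a plain
JSON-serialisable report; the CLI wraps it with file IO. Every report embeds
the effective configuration so a run is reproducible from its own output.
"""

from __future__ import annotations

from typing import Optional, Sequence

from pydantic import BaseModel, Field

from . import __version__
from .classification import (
    PM2_MAX_AF,
    PP3_MIN_CADD,
    VUS_REPORT_MIN_CADD,
    classify_variant,
    proxy_classify,
    vus_cadd_report,
)
from .cnv import (
    MIN_SNPS_PER_CNV,
    ClinGenEvidence,
    clingen_loss_score,
    cnv_filter,
    cnv_span_mb,
    overlap_candidate_genes,
)
from .filtering import DEFAULT_QD_THRESHOLD, genotype_patterns, run_funnel
from .records import (
    CandidateGene,
    CnvCall,
    Cohort,
    PATHOGENIC_VERDICTS,
    VariantRecord,
)
from .stats import (
    binomial_enrichment,
    carrier_prevalence,
    compare_categorical,
    crosstab_suspected,
)


class PipelineConfig(BaseModel):
    """Effective thresholds and options of a pipeline run.

    Defaults are the interpretation thresholds the package is built around:
    QD > 5 call quality, inheritance-class frequency cutoffs from the panel,
    rarity bound 1e-4 and CADD bound 15 for evidence assignment, CADD 20 for
    the VUS report, >= 10 SNPs per CNV call, 1% background carrier rate, and
    a one-sided (enrichment) binomial alternative.
    """

    qd_threshold: float = Field(DEFAULT_QD_THRESHOLD, ge=0)
    pm2_max_af: float = Field(PM2_MAX_AF, gt=0, lt=1)
    pp3_min_cadd: float = PP3_MIN_CADD
    vus_report_min_cadd: float = VUS_REPORT_MIN_CADD
    cnv_min_snps: int = Field(MIN_SNPS_PER_CNV, ge=1)
    background_rate: float = Field(0.01, gt=0, lt=1)
    alternative: str = "greater"
    dedup_families: bool = True
    seed: int = 0


def _prevalence_block(result) -> dict:
    return {
        "n_total": result.n_total,
        "n_carriers": result.n_carriers,
        "prevalence": result.prevalence,
        "percent": round(result.prevalence * 100, 1),
        "dedup_applied": result.dedup_applied,
        "carrier_ids": list(result.carrier_ids),
        "by_group": {
            label: {"n": g.n, "carriers": g.carriers, "fraction": g.fraction}
            for label, g in result.by_group.items()
        },
    }


def run_case_pipeline(
    cohort: Cohort,
    variants: Sequence[VariantRecord],
    panel: Sequence[CandidateGene],
    config: Optional[PipelineConfig] = None,
) -> dict:
    """Run the full case analysis and return the report dictionary."""
    config = config or PipelineConfig()

    retained, traces = run_funnel(variants, panel, qd_threshold=config.qd_threshold)
    patterns = genotype_patterns(retained, panel)

    acmg = [
        (
            v,
            classify_variant(
                v, pm2_max_af=config.pm2_max_af, pp3_min_cadd=config.pp3_min_cadd
            ),
        )
        for v in retained
    ]
    proxy = [
        (
            v,
            proxy_classify(
                v, pm2_max_af=config.pm2_max_af, pp3_min_cadd=config.pp3_min_cadd
            ),
        )
        for v in retained
    ]

    prev_acmg = carrier_prevalence(cohort, acmg, PATHOGENIC_VERDICTS, dedup_families=False)
    prev_acmg_dedup = carrier_prevalence(
        cohort, acmg, PATHOGENIC_VERDICTS, dedup_families=True
    )
    prev_proxy_dedup = carrier_prevalence(
        cohort, proxy, PATHOGENIC_VERDICTS, dedup_families=config.dedup_families
    )
    enrichment = binomial_enrichment(
        prev_proxy_dedup.n_carriers,
        prev_proxy_dedup.n_total,
        config.background_rate,
        alternative=config.alternative,
    )

    gc_table = crosstab_suspected(cohort, "gc_long_term")
    gc_test = compare_categorical(gc_table)

    vus = vus_cadd_report(acmg, min_cadd=config.vus_report_min_cadd)

    variant_rows = []
    cls_by_key = {v.key(): c for v, c in acmg}
    proxy_by_key = {v.key(): c for v, c in proxy}
    for t in traces:
        v = t.variant
        row = {
            "patient_id": v.patient_id,
            "gene": v.gene,
            "chrom": v.chrom,
            "pos": v.pos,
            "hgvs_c": v.hgvs_c,
            "consequence": v.consequence.value,
            "zygosity": v.zygosity.value,
            "cadd": v.cadd,
            "clinvar": v.clinvar.value,
            "retained": t.retained,
            "stage_removed": t.stage_removed.value,
            "note": t.note,
        }
        if t.retained:
            row["acmg_verdict"] = cls_by_key[v.key()].verdict.value
            row["acmg_rationale"] = list(cls_by_key[v.key()].rationale)
            row["proxy_verdict"] = proxy_by_key[v.key()].verdict.value
        variant_rows.append(row)

    return {
        "tool": {"name": "bonevar", "version": __version__},
        "config": config.model_dump(),
        "funnel": {
            "n_input": len(variants),
            "n_retained": len(retained),
            "n_removed": len(variants) - len(retained),
        },
        "variants": variant_rows,
        "genotype_patterns": [
            {
                "patient_id": p.patient_id,
                "gene": p.gene,
                "pattern": p.pattern.value,
                "n_variants": len(p.variants),
                "note": p.note,
            }
            for p in patterns
        ],
        "prevalence": {
            "acmg": _prevalence_block(prev_acmg),
            "acmg_dedup": _prevalence_block(prev_acmg_dedup),
            "proxy_dedup": _prevalence_block(prev_proxy_dedup),
        },
        "enrichment": {
            "k": prev_proxy_dedup.n_carriers,
            "n": prev_proxy_dedup.n_total,
            "p0": config.background_rate,
            "alternative": config.alternative,
            "p_value": enrichment.p_value,
        },
        "group_comparison": {
            "gc_long_term": {
                "table": gc_table.tolist(),
                "method": gc_test.method.value,
                "statistic": gc_test.statistic,
                "p_value": gc_test.p_value,
            }
        },
        "vus_report": [
            {
                "patient_id": v.patient_id,
                "gene": v.gene,
                "hgvs_c": v.hgvs_c,
                "cadd": v.cadd,
            }
            for v, _ in vus
        ],
    }


def run_cnv_pipeline(
    calls: Sequence[CnvCall],
    panel: Sequence[CandidateGene],
    evidence: Optional[dict[str, ClinGenEvidence]] = None,
    config: Optional[PipelineConfig] = None,
) -> dict:
    """Filter CNV calls, intersect with the panel and score assessed losses.

    ``evidence`` maps patient_id to a loss-rubric assessment for that
    patient's call; unassessed calls are reported without a score.
    """
    config = config or PipelineConfig()
    evidence = evidence or {}
    retained = cnv_filter(calls, min_snps=config.cnv_min_snps)
    rows = []
    for call in retained:
        row = {
            "patient_id": call.patient_id,
            "chrom": call.chrom,
            "start": call.start,
            "end": call.end,
            "cnv_type": call.cnv_type.value,
            "n_snps": call.n_snps,
            "span_mb": cnv_span_mb(call),
            "panel_genes": overlap_candidate_genes(call, panel),
        }
        ev = evidence.get(call.patient_id)
        if ev is not None:
            assessment = clingen_loss_score(ev)
            row["clingen"] = {
                "points": dict(assessment.points),
                "total_score": assessment.total_score,
                "verdict": assessment.verdict.value,
            }
        rows.append(row)
    return {
        "tool": {"name": "bonevar", "version": __version__},
        "config": config.model_dump(),
        "n_input": len(calls),
        "n_retained": len(retained),
        "calls": rows,
    }
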