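"""Synthetic cohort and control-population generators.

The generators emulate the statistical structure the analysis assumes: a
cohort split into clinically suspected and non-suspected groups, (likely)
pathogenic variants planted per-group at configurable carrier rates (with
annotation attributes guaranteed to satisfy the proxy rule), a Poisson
background of uncertain variants that fail the proxy rule, and sibling pairs
sharing a family identifier and carrier status. Variant attributes are drawn
from a small attribute grammar (consequence, frequency, CADD, ClinVar) —
the analysis never inspects sequence context, so no nucleotide-level
simulation is needed. All output is reproducible from the seed.

Defaults mirror the study conditions of the motivating cohort: 60 patients,
25% clinically suspected, carrier rates 8/15 in the suspected and 1/45 in
the non-suspected group, one sibling pair, a VUS burden putting roughly 30%
of patients at >=1 uncertain variant, and a 1% background carrier rate for
controls.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, Field

from .records import (
    CandidateGene,
    ClinVarStatus,
    Cohort,
    Consequence,
    Inheritance,
    PatientRecord,
    VariantRecord,
    Zygosity,
)

_BASES = ("A", "C", "G", "T")


class SimulationConfig(BaseModel):
    """Parameters of the synthetic cohort generator."""

    n_patients: int = Field(60, gt=0)
    prop_suspected: float = Field(0.25, ge=0.0, le=1.0)
    carrier_rate_suspected: float = Field(8 / 15, ge=0.0, le=1.0)
    carrier_rate_unsuspected: float = Field(1 / 45, ge=0.0, le=1.0)
    background_vus_rate: float = Field(0.35, ge=0.0)
    n_families_with_siblings: int = Field(1, ge=0)
    background_pathogenic_rate_controls: float = Field(0.01, ge=0.0, le=1.0)
    seed: int = 0


def _alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return _BASES[ref], _BASES[alt]


def _planted_pathogenic(
    rng: np.random.Generator, patient_id: str, gene: CandidateGene
) -> VariantRecord:
    """One variant whose attributes satisfy the proxy (likely)-pathogenic rule:
    extremely rare, loss of function, computationally supported."""
    ref, alt = _alleles(rng)
    consequence = Consequence(
        str(rng.choice(["stopgain", "frameshift_indel", "splicing"]))
    )
    if consequence is Consequence.FRAMESHIFT_INDEL:
        ref, alt = ref + "AC", ref  # simple deletion
        cadd = None
    else:
        cadd = float(np.round(rng.uniform(25, 45), 1))
    return VariantRecord(
        patient_id=patient_id,
        chrom=gene.chrom,
        pos=int(rng.integers(gene.start, gene.end + 1)),
        ref=ref,
        alt=alt,
        gene=gene.symbol,
        consequence=consequence,
        zygosity=Zygosity.HET,
        qd=float(np.round(rng.uniform(10, 35), 2)),
        af_db1=None,
        af_db2=None,
        cadd=cadd,
        clinvar=ClinVarStatus(
            str(rng.choice(["pathogenic", "likely_pathogenic", "absent"]))
        ),
        tags=("planted_pathogenic",),
    )


def _background_vus(
    rng: np.random.Generator, patient_id: str, gene: CandidateGene
) -> VariantRecord:
    """A rare missense variant that fails the proxy rule (no LOF, no ClinVar
    pathogenic assertion) and so stays uncertain."""
    ref, alt = _alleles(rng)
    return VariantRecord(
        patient_id=patient_id,
        chrom=gene.chrom,
        pos=int(rng.integers(gene.start, gene.end + 1)),
        ref=ref,
        alt=alt,
        gene=gene.symbol,
        consequence=Consequence.NONSYNONYMOUS,
        zygosity=Zygosity.HET,
        qd=float(np.round(rng.uniform(10, 35), 2)),
        af_db1=float(np.round(rng.uniform(0, gene.af_cutoff * 0.9), 8)),
        af_db2=None,
        cadd=float(np.round(rng.uniform(10, 30), 1)),
        clinvar=ClinVarStatus(str(rng.choice(["uncertain", "absent"]))),
        tags=("background_vus",),
    )


def generate_cohort(
    config: SimulationConfig, panel: Optional[list[CandidateGene]] = None
) -> tuple[Cohort, list[VariantRecord]]:
    """Generate a synthetic cohort and its variant table.

    Suspected status is assigned to the first ``round(n * prop_suspected)``
    patients; carriers are drawn per group at the configured rates and each
    receives one planted (likely) pathogenic variant; per-patient VUS counts
    are Poisson. Sibling pairs (one per configured family) share family_id,
    suspected status and carrier status.
    """
    from .io import load_gene_panel

    panel = panel if panel is not None else load_gene_panel()
    dominant = [g for g in panel if g.inheritance is Inheritance.DOMINANT]
    rng = np.random.default_rng(config.seed)

    n = config.n_patients
    n_suspected = int(round(n * config.prop_suspected))
    patients: list[PatientRecord] = []
    variants: list[VariantRecord] = []

    sibling_of: dict[int, int] = {}
    # pair up the first 2*k suspected (or overall) patients as siblings
    for f in range(config.n_families_with_siblings):
        a, b = 2 * f, 2 * f + 1
        if b < n:
            sibling_of[b] = a

    carrier_flags: dict[int, bool] = {}
    for i in range(n):
        suspected = i < n_suspected
        if i in sibling_of:
            carrier_flags[i] = carrier_flags[sibling_of[i]]
        else:
            rate = (
                config.carrier_rate_suspected
                if suspected
                else config.carrier_rate_unsuspected
            )
            carrier_flags[i] = bool(rng.random() < rate)

    for i in range(n):
        suspected = i < n_suspected
        pid = f"P{i + 1:04d}"
        family = f"FAM{sibling_of.get(i, i):04d}"
        bp_use = bool(rng.random() < 0.95)
        patients.append(
            PatientRecord(
                patient_id=pid,
                suspected=suspected,
                family_id=family,
                sex="F" if rng.random() < 0.73 else "M",
                bp_use=bp_use,
                bp_years=float(np.round(rng.uniform(1, 15), 1)) if bp_use else None,
                gc_long_term=bool(rng.random() < (0.27 if suspected else 0.69)),
                center="EMC" if rng.random() < 0.88 else "LUMC",
                age_at_aff=float(np.round(rng.normal(62.8, 12.7), 1)),
            )
        )
        if carrier_flags[i]:
            gene = dominant[int(rng.integers(len(dominant)))]
            variants.append(_planted_pathogenic(rng, pid, gene))
        for _ in range(int(rng.poisson(config.background_vus_rate))):
            gene = panel[int(rng.integers(len(panel)))]
            variants.append(_background_vus(rng, pid, gene))

    return Cohort(tuple(patients)), variants


def generate_control_population(
    n: int,
    background_rate: float,
    seed: int,
    panel: Optional[list[CandidateGene]] = None,
) -> list[VariantRecord]:
    """Variant table for a control population of size ``n``.

    Carriers of one proxy-qualifying (likely) pathogenic variant are planted
    at ``background_rate``; non-carriers contribute no rows. Used to
    exercise the enrichment comparison end-to-end at desk scale in place of
    a full reference-population call set.
    """
    if not (0.0 <= background_rate <= 1.0):
        raise ValueError(f"background_rate {background_rate} outside [0,1]")
    from .io import load_gene_panel

    panel = panel if panel is not None else load_gene_panel()
    dominant = [g for g in panel if g.inheritance is Inheritance.DOMINANT]
    rng = np.random.default_rng(seed)
    variants: list[VariantRecord] = []
    carrier_draws = rng.random(n) < background_rate if n else np.array([])
    for i in np.flatnonzero(carrier_draws):
        gene = dominant[int(rng.integers(len(dominant)))]
        variants.append(_planted_pathogenic(rng, f"CTRL{i + 1:07d}", gene))
    return variants
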