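"""Carrier-prevalence estimation and the cohort's statistical comparisons.

Prevalence follows the one-qualifying-variant-per-carrier assumption: a
patient counts as a carrier when at least one of their variants falls in the
verdict classes of interest, and the estimate is the carrier fraction of the
cohort. Relatives can be deduplicated so a familial variant is counted once.
Enrichment against a background population rate uses the exact binomial
test; group comparisons follow the cohort-table conventions (Pearson
chi-square, Fisher's exact test when any observed cell is below 5, and a
one-way F test for continuous variables).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .classification import Classification
from .records import Cohort, ValidationError, VariantRecord, Verdict, PATHOGENIC_VERDICTS


class TestMethod(str, enum.Enum):
    CHI_SQUARE = "chi_square"
    FISHER_EXACT = "fisher_exact"
    F_TEST = "f_test"
    BINOMIAL = "binomial"


@dataclass(frozen=True)
class TestResult:
    statistic_name: str
    statistic: float
    p_value: float
    method: TestMethod

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p_value {self.p_value} outside [0,1]")


@dataclass(frozen=True)
class GroupPrevalence:
    n: int
    carriers: int
    fraction: float


@dataclass(frozen=True)
class PrevalenceResult:
    n_total: int
    n_carriers: int
    prevalence: float
    by_group: Mapping[str, GroupPrevalence]
    dedup_applied: bool
    carrier_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        assert 0 <= self.n_carriers <= self.n_total


def carrier_prevalence(
    cohort: Cohort,
    classified: Sequence[tuple[VariantRecord, Classification]],
    classes_counted: Iterable[Verdict] = PATHOGENIC_VERDICTS,
    dedup_families: bool = False,
) -> PrevalenceResult:
    """Estimate the fraction of patients carrying >=1 qualifying variant.

    With ``dedup_families`` one carrier per family is retained; additional
    carrier relatives are removed from both the numerator and the
    denominator (so a variant segregating in a family is counted once).
    ``by_group`` splits the estimate on the clinical-suspicion flag.
    """
    if len(cohort) == 0:
        raise ValidationError("empty cohort")
    classes = set(classes_counted)
    known = cohort.ids
    carriers: set[str] = set()
    for variant, cls in classified:
        if variant.patient_id not in known:
            raise ValidationError(
                f"classification references unknown patient {variant.patient_id}"
            )
        if cls.verdict in classes:
            carriers.add(variant.patient_id)

    working = cohort
    if dedup_families:
        by_family: dict[str, list[str]] = {}
        for p in cohort:
            if p.patient_id in carriers:
                by_family.setdefault(p.family_id, []).append(p.patient_id)
        removed: set[str] = set()
        for fam_carriers in by_family.values():
            for extra in sorted(fam_carriers)[1:]:
                removed.add(extra)
        carriers -= removed
        working = cohort.subset(known - removed)

    def _group(patients) -> GroupPrevalence:
        ids = [p.patient_id for p in patients]
        k = sum(1 for i in ids if i in carriers)
        return GroupPrevalence(len(ids), k, k / len(ids) if ids else 0.0)

    total = _group(working.patients)
    return PrevalenceResult(
        n_total=total.n,
        n_carriers=total.carriers,
        prevalence=total.fraction,
        by_group={
            "suspected": _group(working.suspected),
            "non_suspected": _group(working.non_suspected),
        },
        dedup_applied=dedup_families,
        carrier_ids=tuple(sorted(carriers)),
    )


def binomial_enrichment(
    k: int, n: int, p0: float, alternative: str = "greater"
) -> TestResult:
    """Exact binomial test of k carriers in n against background rate p0.

    ``greater`` gives the enrichment tail P(X >= k); ``two_sided`` uses the
    minimum-likelihood convention (sum of all outcome probabilities not
    exceeding P(X = k)).
    """
    if not (0 < p0 < 1):
        raise ValidationError(f"background rate p0={p0} outside (0,1)")
    if not (0 <= k <= n):
        raise ValidationError(f"carrier count k={k} outside [0, n={n}]")
    alt = {"greater": "greater", "two_sided": "two-sided"}.get(alternative)
    if alt is None:
        raise ValueError(f"unknown alternative: {alternative}")
    res = sps.binomtest(k, n, p0, alternative=alt)
    return TestResult("carriers", float(k), float(res.pvalue), TestMethod.BINOMIAL)


def compare_categorical(table, alternative: str = "two_sided") -> TestResult:
    """Compare a 2x2 contingency table between the two clinical groups.

    Pearson chi-square (no continuity correction) when every observed cell
    is at least 5, otherwise the Fisher exact test (two-sided by the
    minimum-likelihood convention unless ``alternative`` says otherwise).
    Dispatch uses the observed, not the expected, counts; ``alternative``
    only affects the Fisher branch.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or (arr < 0).any() or (arr != np.floor(arr)).any():
        raise ValidationError("expected a 2x2 table of non-negative integers")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValidationError("zero margin in contingency table")
    alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}.get(
        alternative
    )
    if alt is None:
        raise ValueError(f"unknown alternative: {alternative}")
    if (arr >= 5).all():
        chi2, p, _, _ = sps.chi2_contingency(arr, correction=False)
        return TestResult("chi2", float(chi2), float(p), TestMethod.CHI_SQUARE)
    odds, p = sps.fisher_exact(arr.astype(int), alternative=alt)
    return TestResult("odds_ratio", float(odds), float(p), TestMethod.FISHER_EXACT)


def compare_continuous(values_a, values_b) -> TestResult:
    """One-way F test between two groups of continuous values."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValidationError("degenerate variance in both groups")
    f, p = sps.f_oneway(a, b)
    return TestResult("F", float(f), float(p), TestMethod.F_TEST)


def crosstab_suspected(cohort: Cohort, flag: str) -> np.ndarray:
    """2x2 table of a boolean patient attribute by clinical-suspicion group.

    Rows: attribute yes/no within the suspected group, then within the
    non-suspected group (columns yes, no).
    """
    sus = [getattr(p, flag) for p in cohort.suspected]
    non = [getattr(p, flag) for p in cohort.non_suspected]
    return np.array(
        [
            [sum(sus), len(sus) - sum(sus)],
            [sum(non), len(non) - sum(non)],
        ]
    )
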