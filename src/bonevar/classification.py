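"""ACMG/AMP evidence combination and the filter-based proxy classifier.

Two layers are provided. :func:`combine_acmg` is a pure function applying the
published evidence-combination matrix (shipped as an editable data table) to
a profile of evidence codes; it is used for case variants, where evidence is
curated. :func:`proxy_classify` is the coarse filter-rule surrogate used when
manually curating every variant is infeasible (large control sets): a variant
is called (likely) pathogenic when it is extremely rare, computationally
supported, and either loss of function or already asserted (likely)
pathogenic in ClinVar.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .records import ClinVarStatus, Consequence, VariantRecord, Verdict

# thresholds used by automatic evidence assignment and the proxy rule
PM2_MAX_AF = 0.0001  # "extremely rare": below 1e-4 in the reference populations
PP3_MIN_CADD = 15.0  # computational support: CADD strictly above 15
VUS_REPORT_MIN_CADD = 20.0  # reporting bound for uncertain variants


class Strength(str, enum.Enum):
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"
    STAND_ALONE = "stand_alone"


_PATHOGENIC_CODES = (
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
)
_BENIGN_CODES = ["BA1"] + [f"BS{i}" for i in range(1, 5)] + [f"BP{i}" for i in range(1, 8)]
KNOWN_CODES = frozenset(_PATHOGENIC_CODES + _BENIGN_CODES)

_DEFAULT_STRENGTH = {
    "PVS": Strength.VERY_STRONG,
    "PS": Strength.STRONG,
    "PM": Strength.MODERATE,
    "PP": Strength.SUPPORTING,
    "BA": Strength.STAND_ALONE,
    "BS": Strength.STRONG,
    "BP": Strength.SUPPORTING,
}

_CODE_RE = re.compile(r"^(PVS|PS|PM|PP|BA|BS|BP)\d$")


def default_strength(code: str) -> Strength:
    prefix = _CODE_RE.match(code).group(1)
    return _DEFAULT_STRENGTH[prefix]


def is_benign_code(code: str) -> bool:
    return code.startswith("B")


@dataclass(frozen=True)
class EvidenceProfile:
    """A set of ACMG evidence codes, each with an optional strength override.

    ``codes`` maps a code token (e.g. ``PVS1``) to its strength, or to None
    to use the code's default strength. Pathogenic and benign codes may
    coexist; the combiner resolves the conflict.
    """

    codes: Mapping[str, Optional[Strength]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "codes", dict(self.codes))
        for code in self.codes:
            if code not in KNOWN_CODES:
                raise ValueError(f"unknown ACMG code token: {code}")

    @classmethod
    def from_codes(cls, codes: Iterable[str]) -> "EvidenceProfile":
        return cls({c: None for c in codes})

    def strength_of(self, code: str) -> Strength:
        override = self.codes[code]
        return override if override is not None else default_strength(code)

    def counts(self) -> tuple[dict[str, int], dict[str, int]]:
        """(pathogenic-strength counts, benign-strength counts)."""
        path: dict[str, int] = {}
        benign: dict[str, int] = {}
        for code in self.codes:
            bucket = benign if is_benign_code(code) else path
            s = self.strength_of(code).value
            bucket[s] = bucket.get(s, 0) + 1
        return path, benign


@dataclass(frozen=True)
class Classification:
    verdict: Verdict
    rationale: tuple[str, ...] = ()


@lru_cache(maxsize=None)
def load_combining_rules(path: Optional[str] = None) -> dict:
    """Load the combining matrix (packaged default, or a replacement table)."""
    if path is None:
        text = resources.files("bonevar.data").joinpath("acmg_combining.yaml").read_text()
    else:
        text = open(path).read()
    rules = yaml.safe_load(text)
    for tier in ("pathogenic", "likely_pathogenic", "benign", "likely_benign"):
        if tier not in rules:
            raise ValueError(f"combining table missing tier: {tier}")
    return rules


def _satisfies(counts: Mapping[str, int], rule: Mapping[str, int]) -> bool:
    return all(counts.get(strength, 0) >= n for strength, n in rule.items())


def _rule_label(tier: str, rule: Mapping[str, int]) -> str:
    parts = "+".join(f"{n} {s}" for s, n in rule.items())
    return f"{tier}: {parts}"


def combine_acmg(
    evidence: EvidenceProfile, rules: Optional[dict] = None
) -> Classification:
    """Combine an evidence profile into a five-tier verdict.

    The pathogenic and benign arms are evaluated independently against the
    combining table; if both fire the evidence is contradictory and the
    verdict is uncertain significance, as is an empty or insufficient
    profile.
    """
    rules = rules or load_combining_rules()
    path_counts, benign_counts = evidence.counts()

    fired: list[str] = []
    path_tier: Optional[Verdict] = None
    for tier, verdict in (
        ("pathogenic", Verdict.PATHOGENIC),
        ("likely_pathogenic", Verdict.LIKELY_PATHOGENIC),
    ):
        for rule in rules[tier]:
            if _satisfies(path_counts, rule):
                path_tier = path_tier or verdict
                fired.append(_rule_label(tier, rule))
                break
        if path_tier:
            break

    benign_tier: Optional[Verdict] = None
    for tier, verdict in (
        ("benign", Verdict.BENIGN),
        ("likely_benign", Verdict.LIKELY_BENIGN),
    ):
        for rule in rules[tier]:
            if _satisfies(benign_counts, rule):
                benign_tier = benign_tier or verdict
                fired.append(_rule_label(tier, rule))
                break
        if benign_tier:
            break

    if path_tier and benign_tier:
        return Classification(
            Verdict.UNCERTAIN_SIGNIFICANCE, tuple(fired) + ("conflicting evidence",)
        )
    if path_tier:
        return Classification(path_tier, tuple(fired))
    if benign_tier:
        return Classification(benign_tier, tuple(fired))
    return Classification(Verdict.UNCERTAIN_SIGNIFICANCE, ("no combining rule fired",))


def auto_assign_evidence(
    variant: VariantRecord,
    pm2_max_af: float = PM2_MAX_AF,
    pp3_min_cadd: float = PP3_MIN_CADD,
) -> EvidenceProfile:
    """Derive the automatable evidence codes from a variant's annotations.

    PM2 for extreme rarity (max database frequency < 1e-4, absence counting
    as 0); PP3 for computational support (CADD strictly > 15); PVS1 for loss
    of function (nonsense, frameshift, stop-loss, canonical-site splice);
    PS1/PP5/BP6 from the ClinVar assertion. Codes needing manual judgment
    (segregation, functional data, hotspots...) are never auto-assigned.
    """
    codes: list[str] = []
    if variant.max_af < pm2_max_af:
        codes.append("PM2")
    if variant.cadd is not None and variant.cadd > pp3_min_cadd:
        codes.append("PP3")
    if variant.is_lof:
        codes.append("PVS1")
    if variant.clinvar is ClinVarStatus.PATHOGENIC:
        codes.append("PS1")
    elif variant.clinvar is ClinVarStatus.LIKELY_PATHOGENIC:
        codes.append("PP5")
    elif variant.clinvar in (ClinVarStatus.BENIGN, ClinVarStatus.LIKELY_BENIGN):
        codes.append("BP6")
    return EvidenceProfile.from_codes(codes)


def classify_variant(
    variant: VariantRecord,
    rules: Optional[dict] = None,
    pm2_max_af: float = PM2_MAX_AF,
    pp3_min_cadd: float = PP3_MIN_CADD,
) -> Classification:
    """Full-engine classification of one variant.

    A curated evidence profile attached to the variant is authoritative and
    used as-is; otherwise the automatable codes are derived from the
    annotations. (Merging curated with auto-derived codes would double-count
    the annotation evidence the curator already weighed.)
    """
    if variant.curated_evidence is not None:
        profile = EvidenceProfile.from_codes(variant.curated_evidence)
    else:
        profile = auto_assign_evidence(variant, pm2_max_af, pp3_min_cadd)
    return combine_acmg(profile, rules)


def proxy_classify(
    variant: VariantRecord,
    pm2_max_af: float = PM2_MAX_AF,
    pp3_min_cadd: float = PP3_MIN_CADD,
) -> Classification:
    """Filter-rule surrogate classifier for settings without manual curation.

    (Likely) pathogenic requires all three of: (i) extreme rarity
    (frequency < 1e-4 in both reference databases); (ii) computational
    support — CADD > 15, or no CADD score available for a loss-of-function
    variant (an indel without a score and without LOF consequence cannot
    satisfy this arm); (iii) loss of function or an existing (likely)
    pathogenic ClinVar assertion. Variants asserted (likely) benign in
    ClinVar are classified accordingly; everything else is uncertain.
    """
    if variant.clinvar is ClinVarStatus.BENIGN:
        return Classification(Verdict.BENIGN, ("clinvar benign",))
    if variant.clinvar is ClinVarStatus.LIKELY_BENIGN:
        return Classification(Verdict.LIKELY_BENIGN, ("clinvar likely benign",))
    rare = variant.max_af < pm2_max_af
    computational = (
        (variant.cadd is not None and variant.cadd > pp3_min_cadd)
        or (variant.cadd is None and variant.is_lof)
    )
    lof_or_asserted = variant.is_lof or variant.clinvar in (
        ClinVarStatus.PATHOGENIC,
        ClinVarStatus.LIKELY_PATHOGENIC,
    )
    if rare and computational and lof_or_asserted:
        return Classification(
            Verdict.LIKELY_PATHOGENIC,
            ("rare", "computational support", "LOF or ClinVar assertion"),
        )
    return Classification(Verdict.UNCERTAIN_SIGNIFICANCE, ("proxy criteria not met",))


def vus_cadd_report(
    classified: Sequence[tuple[VariantRecord, Classification]],
    min_cadd: float = VUS_REPORT_MIN_CADD,
) -> list[tuple[VariantRecord, Classification]]:
    """Reportable uncertain variants: VUS with CADD >= 20, plus VUS indels
    for which no CADD score is available."""
    out = []
    for variant, cls in classified:
        if cls.verdict is not Verdict.UNCERTAIN_SIGNIFICANCE:
            continue
        if variant.cadd is not None and variant.cadd >= min_cadd:
            out.append((variant, cls))
        elif variant.cadd is None and variant.is_indel:
            out.append((variant, cls))
    return out
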