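"""Normalization of variant annotations into filterable values.

Annotation sources (ANNOVAR-style tables) deliver free-text exonic function
strings, per-panel population allele frequencies, phred-scaled CADD scores
and ClinVar clinical-significance strings.  This module folds them into the
enums and scalars the filter tiers consume:

* **MMAF** — maximum minor allele frequency: each panel's allele frequency
  is folded to the minor allele, ``min(af, 1 - af)``, and the maximum over
  panels is taken.  A variant absent from every panel has MMAF 0.
* **Function class** — stop-gain, splicing, frameshift deletion, frameshift
  insertion, missense, or Other.
* **ClinVar class** — canonicalized clinical significance; unrecognized
  non-empty strings become a distinct class that is treated as *not benign*
  (retained) by the screens.
* **CADD** — phred-scaled deleteriousness (>20 ≈ top 1%, >30 ≈ top 0.1%).
  Comparisons are strict.  Frameshift indels are frequently un-scored in
  CADD annotation dumps, so an absent score passes a CADD threshold only
  for the frameshift classes; any other un-scored variant fails.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from famseg.cohort import CohortGenotypes, VariantKey


class FunctionClass(enum.Enum):
    STOPGAIN = "StopGain"
    SPLICING = "Splicing"
    FRAMESHIFT_DELETION = "FrameshiftDeletion"
    FRAMESHIFT_INSERTION = "FrameshiftInsertion"
    MISSENSE = "Missense"
    OTHER = "Other"


#: Protein-truncating / splice-disrupting classes treated as potentially
#: pathogenic irrespective of missense scores.
DELETERIOUS_CLASSES = frozenset(
    {
        FunctionClass.STOPGAIN,
        FunctionClass.SPLICING,
        FunctionClass.FRAMESHIFT_DELETION,
        FunctionClass.FRAMESHIFT_INSERTION,
    }
)

#: Classes whose variants keep passing a CADD threshold when un-scored.
FRAMESHIFT_CLASSES = frozenset(
    {FunctionClass.FRAMESHIFT_DELETION, FunctionClass.FRAMESHIFT_INSERTION}
)


class ClinvarClass(enum.Enum):
    PATHOGENIC = "Pathogenic"
    LIKELY_PATHOGENIC = "LikelyPathogenic"
    PATHOGENIC_OR_LIKELY_PATHOGENIC = "PathogenicOrLikelyPathogenic"
    UNCERTAIN = "Uncertain"
    CONFLICTING = "Conflicting"
    BENIGN = "Benign"
    LIKELY_BENIGN = "LikelyBenign"
    ABSENT = "Absent"
    UNRECOGNIZED = "Unrecognized"


BENIGN_CLASSES = frozenset({ClinvarClass.BENIGN, ClinvarClass.LIKELY_BENIGN})


@dataclass(frozen=True)
class AnnotationRow:
    """One raw annotation-table row, keyed by (chrom, pos, ref, alt).

    Absent numeric cells stay absent (``None``), never 0 — with the single
    exception of MMAF downstream, which is defined as 0 when no panel
    reports the allele.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    function_raw: str
    change: str = ""
    dbsnp_id: Optional[str] = None
    af_by_panel: Mapping[str, float] = field(default_factory=dict)
    cadd_phred: Optional[float] = None
    clinvar_raw: Optional[str] = None
    acmg_raw: Optional[str] = None

    def __post_init__(self) -> None:
        if int(self.pos) < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        for panel, af in self.af_by_panel.items():
            if not (0.0 <= af <= 1.0):
                raise ValueError(f"allele frequency {af} for panel {panel!r} outside [0, 1]")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError(f"negative CADD score {self.cadd_phred}")

    @property
    def key(self) -> VariantKey:
        return VariantKey.make(self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class VariantRecord:
    """A variant with its annotations normalized for tier filtering."""

    key: VariantKey
    gene: str
    function_class: FunctionClass
    function_raw: str = ""
    change: str = ""
    dbsnp_id: Optional[str] = None
    mmaf: float = 0.0
    mmaf_panel: Optional[str] = None  # panel that supplied the max, for audit
    cadd: Optional[float] = None
    clinvar_class: ClinvarClass = ClinvarClass.ABSENT
    clinvar_raw: Optional[str] = None
    acmg_raw: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.mmaf <= 0.5):
            raise ValueError(f"MMAF {self.mmaf} outside [0, 0.5]")


def compute_mmaf(af_by_panel: Mapping[str, float]) -> float:
    """Maximum minor allele frequency over population panels.

    Each panel's allele frequency is folded to the minor allele,
    ``min(af, 1 - af)``, and the maximum over panels is returned.  An empty
    map (variant absent from every panel) yields 0.
    """
    return compute_mmaf_with_source(af_by_panel)[0]


def compute_mmaf_with_source(
    af_by_panel: Mapping[str, float],
) -> tuple[float, Optional[str]]:
    """As :func:`compute_mmaf` but also reports which panel supplied the max."""
    best = 0.0
    source: Optional[str] = None
    for panel in sorted(af_by_panel):  # deterministic tie-break on panel name
        af = af_by_panel[panel]
        if not (0.0 <= af <= 1.0) or math.isnan(af):
            raise ValueError(f"allele frequency {af} for panel {panel!r} outside [0, 1]")
        folded = min(af, 1.0 - af)
        if folded > best:
            best = folded
            source = panel
    return best, source


_FUNCTION_MAP = {
    "stopgain": FunctionClass.STOPGAIN,
    "stopgain snv": FunctionClass.STOPGAIN,
    "splicing": FunctionClass.SPLICING,
    "splice": FunctionClass.SPLICING,
    "frameshift deletion": FunctionClass.FRAMESHIFT_DELETION,
    "deletion": FunctionClass.FRAMESHIFT_DELETION,
    "frameshift insertion": FunctionClass.FRAMESHIFT_INSERTION,
    "insertion": FunctionClass.FRAMESHIFT_INSERTION,
    "insert": FunctionClass.FRAMESHIFT_INSERTION,
    "nonsynonymous snv": FunctionClass.MISSENSE,
    "missense": FunctionClass.MISSENSE,
}


def classify_function(function_raw: Optional[str]) -> FunctionClass:
    """Map an annotation-source exonic/splicing function string to a class.

    Recognizes the ANNOVAR labels ("stopgain", "nonsynonymous SNV",
    "splicing", "frameshift deletion/insertion") and the shorthand used in
    report tables ("Missense", "Insert", "Deletion"), case-insensitively.
    Anything else — including explicitly non-frameshift indels — maps to
    ``Other``.
    """
    if function_raw is None:
        return FunctionClass.OTHER
    norm = " ".join(str(function_raw).strip().lower().split())
    if "nonframeshift" in norm:
        return FunctionClass.OTHER
    return _FUNCTION_MAP.get(norm, FunctionClass.OTHER)


def _canon(text: str) -> str:
    out = []
    for ch in text.lower():
        out.append(ch if ch.isalnum() else " ")
    return " ".join("".join(out).split())


_CLINVAR_MAP = {
    "pathogenic": ClinvarClass.PATHOGENIC,
    "likely pathogenic": ClinvarClass.LIKELY_PATHOGENIC,
    "pathogenic likely pathogenic": ClinvarClass.PATHOGENIC_OR_LIKELY_PATHOGENIC,
    "uncertain significance": ClinvarClass.UNCERTAIN,
    "uncertain": ClinvarClass.UNCERTAIN,
    "vus": ClinvarClass.UNCERTAIN,
    "conflicting interpretations of pathogenicity": ClinvarClass.CONFLICTING,
    "conflicting interpretation of pathogenicity": ClinvarClass.CONFLICTING,
    "conflicting": ClinvarClass.CONFLICTING,
    "benign": ClinvarClass.BENIGN,
    "likely benign": ClinvarClass.LIKELY_BENIGN,
    "benign likely benign": ClinvarClass.LIKELY_BENIGN,
}


def classify_clinvar(clinvar_raw: Optional[str]) -> ClinvarClass:
    """Canonicalize a ClinVar clinical-significance string.

    Case and punctuation variants of the standard labels are folded
    together; an absent/empty value maps to ``Absent``; an unrecognized
    non-empty string maps to ``Unrecognized``, which the screens treat as
    not-benign (retained).
    """
    if clinvar_raw is None:
        return ClinvarClass.ABSENT
    canon = _canon(str(clinvar_raw))
    if not canon or canon in {"na", "n a", "none", "not provided", "not reported"}:
        return ClinvarClass.ABSENT
    return _CLINVAR_MAP.get(canon, ClinvarClass.UNRECOGNIZED)


def is_deleterious_class(v: VariantRecord) -> bool:
    """Stop-gain, splicing or frameshift indel: potentially pathogenic
    regardless of missense scores."""
    return v.function_class in DELETERIOUS_CLASSES


def cadd_passes(v: VariantRecord, threshold: float) -> bool:
    """Strict CADD threshold with the frameshift exemption for missing scores.

    A scored variant passes iff ``cadd > threshold``.  An un-scored variant
    passes only if it is a frameshift indel (these are systematically
    missing from CADD dumps yet belong in the deleterious tiers); any other
    un-scored variant fails.
    """
    if threshold <= 0:
        raise ValueError(f"CADD threshold must be positive, got {threshold}")
    if v.cadd is None:
        return v.function_class in FRAMESHIFT_CLASSES
    return v.cadd > threshold


def annotation_to_record(row: AnnotationRow) -> VariantRecord:
    """Normalize one raw annotation row into a filterable VariantRecord."""
    mmaf, panel = compute_mmaf_with_source(row.af_by_panel)
    return VariantRecord(
        key=row.key,
        gene=row.gene,
        function_class=classify_function(row.function_raw),
        function_raw=row.function_raw,
        change=row.change,
        dbsnp_id=row.dbsnp_id,
        mmaf=mmaf,
        mmaf_panel=panel,
        cadd=row.cadd_phred,
        clinvar_class=classify_clinvar(row.clinvar_raw),
        clinvar_raw=row.clinvar_raw,
        acmg_raw=row.acmg_raw,
    )


def build_variant_records(
    rows: Iterable[AnnotationRow],
    cohort: Optional[CohortGenotypes] = None,
) -> tuple[dict[VariantKey, VariantRecord], list[AnnotationRow], list[VariantKey]]:
    """Join annotation rows to cohort variants on (chrom, pos, ref, alt).

    Returns ``(records, orphan_rows, unannotated_keys)``:

    * ``records`` — VariantRecord per annotated key (all rows if no cohort
      is given; otherwise only keys present in the cohort).
    * ``orphan_rows`` — annotation rows with no matching cohort variant
      (kept for audit, excluded from ``records``).
    * ``unannotated_keys`` — cohort variants with no annotation row; these
      are excluded from any tier that needs annotation.

    The join assumes both sides were normalized (multi-allelic sites
    decomposed, indels consistently left-aligned) upstream.
    """
    records: dict[VariantKey, VariantRecord] = {}
    orphans: list[AnnotationRow] = []
    cohort_keys = set(cohort.variants) if cohort is not None else None
    for row in rows:
        key = row.key
        if cohort_keys is not None and key not in cohort_keys:
            orphans.append(row)
            continue
        if key in records:
            raise ValueError(f"duplicate annotation row for {key}")
        records[key] = annotation_to_record(row)
    unannotated = (
        [k for k in cohort.variants if k not in records] if cohort is not None else []
    )
    return records, orphans, unannotated
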