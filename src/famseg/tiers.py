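"""The three filter tiers of the prioritization analysis.

Tier definitions (all comparisons strict, as printed):

==============  =======  ========  ======  ===========  ==========================
tier            BC_GF    MMAF      CADD    segregation  eligibility
==============  =======  ========  ======  ===========  ==========================
KnownGene       > 0.8    < 0.2     > 20    no           gene in 15-gene panel,
                                                        ClinVar not (likely) benign
NovelCandidate  > 0.8    < 0.01    > 20    yes          families not excluded
HighRisk        > 0.8    < 0.001   > 25    yes          WES-3s / WES-4s families
==============  =======  ========  ======  ===========  ==========================

The known-gene screen does not require within-family segregation: a single
carrier in a family is reported (clinical panels flag any carrier of a
possibly pathogenic allele).  The novel-candidate screen requires the
variant in *all* sequenced members of the family.  The high-risk tier is a
strict subset of the novel tier — rarer (MMAF < 0.001), more deleterious
(CADD > 25), and restricted to families with 3–4 sequenced members, where
chance segregation is least likely.

Families in which a clearly pathogenic known-gene variant was found are
excluded from the novel screens via an explicit exclusion list (supplied in
config), keeping each tier a pure function of its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from famseg.annotation import (
    BENIGN_CLASSES,
    FunctionClass,
    VariantRecord,
    cadd_passes,
)
from famseg.cohort import (
    CohortGenotypes,
    Family,
    VariantKey,
    compute_bc_gf,
    segregation_status,
)

#: Breast/ovarian-cancer genes routinely screened in clinical genetic
#: counseling; the default panel for the known-gene tier.
KNOWN_GENE_PANEL: frozenset[str] = frozenset(
    {
        "ATM",
        "BRCA1",
        "BRCA2",
        "BRIP1",
        "CHEK2",
        "EPCAM",
        "MLH1",
        "MSH2",
        "MSH6",
        "NBN",
        "PALB2",
        "PMS2",
        "RAD51C",
        "RAD51D",
        "TP53",
    }
)


@dataclass(frozen=True)
class TierSpec:
    """Thresholds and eligibility rules for one filter tier."""

    name: str
    bc_gf_min: float = 0.8
    mmaf_max: float = 0.2
    cadd_min: float = 20.0
    require_segregation: bool = False
    eligible_wes_classes: Optional[frozenset[int]] = None  # None = all
    gene_panel: Optional[frozenset[str]] = None  # None = all genes
    exclude_benign_clinvar: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.mmaf_max < 1.0):
            raise ValueError(f"mmaf_max must be in (0, 1), got {self.mmaf_max}")
        if self.cadd_min <= 0 or self.bc_gf_min < 0:
            raise ValueError("tier thresholds must be positive")


KNOWN_GENE_TIER = TierSpec(
    name="KnownGene",
    mmaf_max=0.2,
    cadd_min=20.0,
    require_segregation=False,
    gene_panel=KNOWN_GENE_PANEL,
    exclude_benign_clinvar=True,
)

NOVEL_CANDIDATE_TIER = TierSpec(
    name="NovelCandidate",
    mmaf_max=0.01,
    cadd_min=20.0,
    require_segregation=True,
)

HIGH_RISK_TIER = TierSpec(
    name="HighRisk",
    mmaf_max=0.001,
    cadd_min=25.0,
    require_segregation=True,
    eligible_wes_classes=frozenset({3, 4}),
)


@dataclass(frozen=True)
class CandidateCall:
    """One (variant, family) pair surviving a tier.

    ``provenance`` records every criterion evaluated with the observed
    value; a call only exists when all criteria passed, so every entry is a
    pass by construction — the map is the audit trail.
    """

    variant: VariantRecord
    family_id: str
    tier: str
    carriers: tuple[str, ...]
    homozygous_carriers: tuple[str, ...] = ()
    provenance: Mapping[str, tuple[bool, object]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not set(self.homozygous_carriers) <= set(self.carriers):
            raise ValueError("homozygous carriers must be a subset of carriers")
        failed = [c for c, (ok, _) in self.provenance.items() if not ok]
        if failed:
            raise ValueError(f"call created with failed criteria: {failed}")

    @property
    def key(self) -> VariantKey:
        return self.variant.key


def _hom_carriers_in_family(
    variant: VariantKey, family: Family, cohort: CohortGenotypes
) -> tuple[str, ...]:
    from famseg.cohort import HOM_ALT

    return tuple(s for s in family.members if cohort.call(variant, s) == HOM_ALT)


def screen_known_genes(
    cohort: CohortGenotypes,
    families: Sequence[Family],
    variants: Mapping[VariantKey, VariantRecord],
    panel: Optional[Iterable[str]] = None,
    tier: TierSpec = KNOWN_GENE_TIER,
) -> list[CandidateCall]:
    """Screen the clinical gene panel: any carrier of a rare, non-benign,
    high-CADD variant in a panel gene is reported.

    One call per (variant, family) with at least one carrier; segregation is
    not required.  Criteria: gene in panel; BC_GF > ``tier.bc_gf_min``;
    MMAF < ``tier.mmaf_max``; ClinVar not Benign/LikelyBenign; CADD passes
    ``tier.cadd_min`` (strict, with the frameshift exemption for un-scored
    indels).
    """
    panel_set = frozenset(panel) if panel is not None else (tier.gene_panel or frozenset())
    if not panel_set:
        raise ValueError("known-gene screen requires a non-empty gene panel")
    calls: list[CandidateCall] = []
    for key, rec in variants.items():
        if rec.gene not in panel_set:
            continue
        if key not in cohort._vindex:
            continue
        bc_gf = compute_bc_gf(key, cohort)
        checks = {
            "gene_in_panel": (True, rec.gene),
            "bc_gf": (bc_gf > tier.bc_gf_min, bc_gf),
            "mmaf": (rec.mmaf < tier.mmaf_max, rec.mmaf),
            "clinvar_not_benign": (
                rec.clinvar_class not in BENIGN_CLASSES,
                rec.clinvar_class.value,
            ),
            "cadd": (cadd_passes(rec, tier.cadd_min), rec.cadd),
        }
        if not all(ok for ok, _ in checks.values()):
            continue
        for fam in families:
            carr = tuple(
                s for s in fam.members if cohort.call(key, s) in (1, 2)
            )
            if not carr:
                continue
            calls.append(
                CandidateCall(
                    variant=rec,
                    family_id=fam.family_id,
                    tier=tier.name,
                    carriers=carr,
                    homozygous_carriers=_hom_carriers_in_family(key, fam, cohort),
                    provenance={**checks, "n_carriers_in_family": (True, len(carr))},
                )
            )
    return sort_calls(calls)


def screen_novel_candidates(
    cohort: CohortGenotypes,
    families: Sequence[Family],
    variants: Mapping[VariantKey, VariantRecord],
    excluded_families: Iterable[str] = (),
    tier: TierSpec = NOVEL_CANDIDATE_TIER,
) -> list[CandidateCall]:
    """Screen for rare, high-CADD variants segregating within a family.

    One call per (variant, family) where every sequenced member carries the
    variant (het or hom-alt; a missing genotype fails the family), with
    BC_GF > ``tier.bc_gf_min``, MMAF < ``tier.mmaf_max`` and CADD passing
    ``tier.cadd_min``.  ``excluded_families`` removes families already
    explained by a pathogenic known-gene finding.
    """
    excluded = set(excluded_families)
    eligible = [f for f in families if f.family_id not in excluded]
    calls: list[CandidateCall] = []
    for key, rec in variants.items():
        if key not in cohort._vindex:
            continue
        bc_gf = compute_bc_gf(key, cohort)
        checks = {
            "bc_gf": (bc_gf > tier.bc_gf_min, bc_gf),
            "mmaf": (rec.mmaf < tier.mmaf_max, rec.mmaf),
            "cadd": (cadd_passes(rec, tier.cadd_min), rec.cadd),
        }
        if not all(ok for ok, _ in checks.values()):
            continue
        for fam in eligible:
            status = segregation_status(key, fam, cohort)
            if not status.segregates:
                continue
            calls.append(
                CandidateCall(
                    variant=rec,
                    family_id=fam.family_id,
                    tier=tier.name,
                    carriers=tuple(fam.members),
                    homozygous_carriers=_hom_carriers_in_family(key, fam, cohort),
                    provenance={
                        **checks,
                        "segregates": (True, f"{status.n_carriers}/{len(fam.members)}"),
                    },
                )
            )
    return sort_calls(calls)


def screen_high_risk(
    candidates: Sequence[CandidateCall],
    families: Sequence[Family],
    tier: TierSpec = HIGH_RISK_TIER,
) -> list[CandidateCall]:
    """Narrow novel candidates to the high-risk tier.

    Keeps calls in families with 3–4 sequenced members whose variant has
    MMAF < ``tier.mmaf_max`` and CADD passing ``tier.cadd_min``; calls are
    relabelled ``HighRisk``.  The output is by construction a subset of the
    input restricted to eligible families (the thresholds nest strictly).
    """
    by_id = {f.family_id: f for f in families}
    eligible_classes = tier.eligible_wes_classes or frozenset({3, 4})
    out: list[CandidateCall] = []
    for call in candidates:
        fam = by_id.get(call.family_id)
        if fam is None or fam.wes_class not in eligible_classes:
            continue
        rec = call.variant
        checks = {
            "wes_class": (True, fam.wes_class),
            "mmaf": (rec.mmaf < tier.mmaf_max, rec.mmaf),
            "cadd": (cadd_passes(rec, tier.cadd_min), rec.cadd),
        }
        if not all(ok for ok, _ in checks.values()):
            continue
        out.append(
            replace(
                call,
                tier=tier.name,
                provenance={**dict(call.provenance), **checks},
            )
        )
    return sort_calls(out)


def label_strong_missense(
    calls: Sequence[CandidateCall], cadd_min: float = 30.0
) -> list[CandidateCall]:
    """Missense calls with CADD strictly above ``cadd_min`` (default 30,
    the top 0.1% most deleterious substitutions)."""
    return [
        c
        for c in calls
        if c.variant.function_class is FunctionClass.MISSENSE
        and c.variant.cadd is not None
        and c.variant.cadd > cadd_min
    ]


def _chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    if chrom.isdigit():
        return (0, int(chrom), "")
    return (1, 0, chrom)


def sort_calls(calls: Iterable[CandidateCall]) -> list[CandidateCall]:
    """Deterministic report order: (chrom, pos, alt, family_id)."""
    return sorted(
        calls,
        key=lambda c: (
            _chrom_sort_key(c.key.chrom),
            c.key.pos,
            c.key.alt,
            c.family_id,
        ),
    )
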