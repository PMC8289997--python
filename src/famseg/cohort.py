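"""Cohort model: families, the genotype matrix, and segregation queries.

Genotype calls are stored as a dense ``int8`` matrix with one row per
biallelic variant and one column per sequenced sample.  Only four call
states exist after multi-allelic decomposition:

====================  =====
state                 code
====================  =====
homozygous reference    0
heterozygous            1
homozygous alternate    2
missing (``./.``)      -1
====================  =====

A *carrier* is a sample with at least one alternate allele (het or hom-alt);
a missing call is never a carrier.  Genotype completeness per variant is
summarised by the cohort genotype frequency (``BC_GF``): the fraction of all
sequenced patients — cohort-wide, not per family — with a non-missing call.
A BC_GF of 0.8 means 80% of the patients had genotypes for that variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

_VALID_CALLS = frozenset({HOM_REF, HET, HOM_ALT, MISSING})


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so ``chr2`` and ``2`` key identically."""
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


class VariantKey(NamedTuple):
    """Identity of one biallelic variant: (chrom, pos, ref, alt), 1-based.

    Chromosome labels are stored normalized (no ``chr`` prefix).  Indels are
    keyed exactly as written by the caller; inputs must be consistently
    normalized (left-aligned) upstream.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    @classmethod
    def make(cls, chrom: str, pos: int, ref: str, alt: str) -> "VariantKey":
        pos = int(pos)
        if pos < 1:
            raise ValueError(f"position must be >= 1, got {pos}")
        ref = str(ref)
        alt = str(alt)
        if ref == alt:
            raise ValueError(f"ref and alt alleles are identical: {ref!r}")
        return cls(normalize_chrom(chrom), pos, ref, alt)

    def label(self) -> str:
        return f"chr{self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class Family:
    """A family with its sequenced affected members.

    ``wes_class`` is the number of sequenced members (1–4 in this study
    design); families are referred to as WES-1s … WES-4s.  ``degree_span``
    is the label of the most distant relationship among sequenced members
    (e.g. ``"3rd"`` when the family spans 1st- to 3rd-degree relatives).
    """

    family_id: str
    members: tuple[str, ...]
    degree_span: str = "1st"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"family {self.family_id!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"family {self.family_id!r} has duplicate members")

    @property
    def wes_class(self) -> int:
        return len(self.members)


@dataclass
class CohortGenotypes:
    """Genotype calls for every (variant, sample) pair in the cohort.

    ``calls[i, j]`` is the call of sample ``samples[j]`` at variant
    ``variants[i]`` using the module-level codes.  Order of both axes is
    preserved from the input and is part of the round-trip contract.
    """

    variants: list[VariantKey]
    samples: list[str]
    calls: np.ndarray
    _vindex: dict[VariantKey, int] = field(init=False, repr=False)
    _sindex: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"calls matrix shape {self.calls.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        bad = set(np.unique(self.calls)) - _VALID_CALLS
        if bad:
            raise ValueError(f"invalid genotype codes in matrix: {sorted(bad)}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids in cohort")
        self._vindex = {v: i for i, v in enumerate(self.variants)}
        self._sindex = {s: j for j, s in enumerate(self.samples)}
        if len(self._vindex) != len(self.variants):
            raise ValueError("duplicate variant keys in cohort")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def variant_index(self, variant: VariantKey) -> int:
        try:
            return self._vindex[variant]
        except KeyError:
            raise KeyError(f"variant {variant} not in cohort") from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sindex[sample_id]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} not in cohort") from None

    def call(self, variant: VariantKey, sample_id: str) -> int:
        return int(self.calls[self.variant_index(variant), self.sample_index(sample_id)])

    def row(self, variant: VariantKey) -> np.ndarray:
        return self.calls[self.variant_index(variant)]


@dataclass(frozen=True)
class CarrierSet:
    """Carriers of one variant across the cohort.

    ``carriers`` holds (family_id, sample_id) pairs for every sample with a
    het or hom-alt call; ``homozygous_carriers`` is the hom-alt subset.
    """

    variant: VariantKey
    carriers: frozenset[tuple[str, str]]
    homozygous_carriers: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.homozygous_carriers <= self.carriers:
            raise ValueError("homozygous carriers must be a subset of carriers")

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)

    def families(self) -> set[str]:
        return {fam for fam, _ in self.carriers}


class SegregationStatus(NamedTuple):
    """Per-family segregation verdict with the evidence behind it."""

    segregates: bool
    n_carriers: int
    n_missing: int
    failed_due_to_missing: bool


def validate_cohort(cohort: CohortGenotypes, families: Sequence[Family]) -> dict[str, Family]:
    """Check that every cohort sample belongs to exactly one family.

    Returns a sample_id -> Family map.  Raises ``ValueError`` on a sample
    present in the genotype data but absent from the family file, or on a
    sample claimed by two families.
    """
    by_sample: dict[str, Family] = {}
    for fam in families:
        for s in fam.members:
            if s in by_sample:
                raise ValueError(
                    f"sample {s!r} assigned to both {by_sample[s].family_id!r} "
                    f"and {fam.family_id!r}"
                )
            by_sample[s] = fam
    orphans = [s for s in cohort.samples if s not in by_sample]
    if orphans:
        raise ValueError(f"samples in genotype data but not in family file: {orphans}")
    return by_sample


def compute_bc_gf(variant: VariantKey, cohort: CohortGenotypes) -> float:
    """Fraction of all sequenced patients with a non-missing call.

    The denominator is the whole cohort (all sequenced patients), never a
    single family; the statistic guards against cohort-wide missingness and
    is unrelated to allele frequency.
    """
    row = cohort.row(variant)
    if row.size == 0:
        return 0.0
    return float(np.count_nonzero(row != MISSING)) / row.size


def carriers(
    variant: VariantKey,
    cohort: CohortGenotypes,
    families: Sequence[Family],
) -> CarrierSet:
    """Carriers (het or hom-alt) of ``variant``, tagged with their family."""
    by_sample = validate_cohort(cohort, families)
    row = cohort.row(variant)
    carr = []
    hom = []
    for j, sample_id in enumerate(cohort.samples):
        call = row[j]
        if call in (HET, HOM_ALT):
            pair = (by_sample[sample_id].family_id, sample_id)
            carr.append(pair)
            if call == HOM_ALT:
                hom.append(pair)
    return CarrierSet(variant, frozenset(carr), frozenset(hom))


def segregation_status(
    variant: VariantKey, family: Family, cohort: CohortGenotypes
) -> SegregationStatus:
    """Evaluate "detected in all family members" for one family.

    Strict rule: every sequenced member must be an observed carrier; a
    missing genotype in any member fails the family, exactly like a hom-ref
    call would.  ``failed_due_to_missing`` flags the families where the
    missing-genotype rule (rather than an explicit non-carrier) was what
    broke segregation, so the lenient alternative can be audited.
    """
    n_carriers = 0
    n_missing = 0
    any_hom_ref = False
    for sample_id in family.members:
        call = cohort.call(variant, sample_id)
        if call in (HET, HOM_ALT):
            n_carriers += 1
        elif call == MISSING:
            n_missing += 1
        else:
            any_hom_ref = True
    segregates = n_carriers == len(family.members)
    failed_due_to_missing = (not segregates) and n_missing > 0 and not any_hom_ref
    return SegregationStatus(segregates, n_carriers, n_missing, failed_due_to_missing)


def segregates_in_family(
    variant: VariantKey, family: Family, cohort: CohortGenotypes
) -> bool:
    """True iff every sequenced member of ``family`` carries ``variant``."""
    return segregation_status(variant, family, cohort).segregates


def family_carrier_counts(
    variant: VariantKey, cohort: CohortGenotypes, families: Sequence[Family]
) -> dict[str, list[str]]:
    """Map family_id -> carrier sample ids (families without carriers omitted)."""
    out: dict[str, list[str]] = {}
    for fam in families:
        carr = [
            s for s in fam.members if cohort.call(variant, s) in (HET, HOM_ALT)
        ]
        if carr:
            out[fam.family_id] = carr
    return out


def group_families(families: Iterable[Family]) -> dict[str, Family]:
    out = {}
    for fam in families:
        if fam.family_id in out:
            raise ValueError(f"duplicate family id {fam.family_id!r}")
        out[fam.family_id] = fam
    return out
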