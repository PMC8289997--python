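"""Cross-family aggregation of candidate calls.

Three views over the per-family screens:

* **Recurrent genes** — genes with segregating candidate variants in more
  than one family (same or different variants).
* **Shared variants** — single variants with carriers in at least three
  families, without requiring within-family segregation; this view runs on
  the full cohort (including families excluded from the novel screen),
  because a recurrently observed allele is informative even where it does
  not segregate.
* **Cohort summary** — a function-class x WES-class cross-tab of candidate
  calls, reporting unique variants (deduplicated across families) and
  total calls (one per variant-family pair).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from famseg.annotation import VariantRecord, cadd_passes
from famseg.cohort import (
    CohortGenotypes,
    Family,
    VariantKey,
    compute_bc_gf,
    family_carrier_counts,
)
from famseg.tiers import CandidateCall, _chrom_sort_key

#: Row order of the cohort summary; "Other" appears only when present.
FUNCTION_ROW_ORDER = [
    "StopGain",
    "Splicing",
    "FrameshiftDeletion",
    "FrameshiftInsertion",
    "Missense",
    "Other",
]


@dataclass(frozen=True)
class RecurrentGene:
    """A gene with segregating candidate variants in >= 2 families."""

    gene: str
    variants: tuple[VariantKey, ...]
    families_by_variant: Mapping[VariantKey, tuple[str, ...]]
    n_families_total: int
    n_variants: int

    def __post_init__(self) -> None:
        if self.n_families_total < 2:
            raise ValueError("a recurrent gene spans at least two families")


@dataclass(frozen=True)
class SharedVariant:
    """A variant carried in >= min_families distinct families."""

    variant: VariantRecord
    carriers_by_family: Mapping[str, tuple[str, ...]]
    n_families: int
    n_carriers: int


def find_recurrent_genes(calls: Sequence[CandidateCall]) -> list[RecurrentGene]:
    """Group segregating candidate calls by gene; keep genes spanning >= 2
    distinct families.  Sorted by descending variant count, then gene name.
    """
    per_gene: dict[str, dict[VariantKey, list[str]]] = {}
    for call in calls:
        fams = per_gene.setdefault(call.variant.gene, {}).setdefault(call.key, [])
        if call.family_id not in fams:
            fams.append(call.family_id)
    out = []
    for gene, by_variant in per_gene.items():
        families = {f for fams in by_variant.values() for f in fams}
        if len(families) < 2:
            continue
        keys = tuple(
            sorted(by_variant, key=lambda k: (_chrom_sort_key(k.chrom), k.pos, k.alt))
        )
        out.append(
            RecurrentGene(
                gene=gene,
                variants=keys,
                families_by_variant={k: tuple(sorted(by_variant[k])) for k in keys},
                n_families_total=len(families),
                n_variants=len(keys),
            )
        )
    return sorted(out, key=lambda g: (-g.n_variants, g.gene))


def find_shared_variants(
    cohort: CohortGenotypes,
    families: Sequence[Family],
    variants: Mapping[VariantKey, VariantRecord],
    min_families: int = 3,
    mmaf_max: Optional[float] = 0.01,
    cadd_min: Optional[float] = 25.0,
    bc_gf_min: Optional[float] = 0.8,
) -> list[SharedVariant]:
    """Rare, high-CADD variants observed in several families without
    requiring segregation.

    A variant qualifies when it has >= 1 carrier in >= ``min_families``
    distinct families, MMAF < ``mmaf_max`` and CADD passing ``cadd_min``
    (thresholds of ``None`` disable that check, which turns the scan into a
    plain carrier census).  Carriers are listed per family.
    """
    out: list[SharedVariant] = []
    for key, rec in variants.items():
        if key not in cohort._vindex:
            continue
        if mmaf_max is not None and not rec.mmaf < mmaf_max:
            continue
        if cadd_min is not None and not cadd_passes(rec, cadd_min):
            continue
        if bc_gf_min is not None and not compute_bc_gf(key, cohort) > bc_gf_min:
            continue
        by_family = family_carrier_counts(key, cohort, families)
        if len(by_family) < min_families:
            continue
        out.append(
            SharedVariant(
                variant=rec,
                carriers_by_family={f: tuple(s) for f, s in sorted(by_family.items())},
                n_families=len(by_family),
                n_carriers=sum(len(s) for s in by_family.values()),
            )
        )
    return sorted(
        out, key=lambda s: (_chrom_sort_key(s.variant.key.chrom), s.variant.key.pos)
    )


@dataclass(frozen=True)
class CohortSummary:
    """Function-class x WES-class cross-tab of candidate calls.

    ``table`` has one row per function class plus a ``Total`` row, and the
    columns ``unique_variants``, ``total_calls``, ``wes4``, ``wes3``,
    ``wes2``, ``wes1`` (per-class call counts).  ``n_families`` counts the
    families contributing at least one call.  Two carrier tallies are kept:
    ``n_carrier_observations`` counts (variant, carrier) pairs — a person
    carrying two variants counts twice — while ``n_distinct_carriers``
    counts persons once.
    """

    table: pd.DataFrame
    n_families: int
    n_carrier_observations: int
    n_distinct_carriers: int

    @property
    def n_unique_variants(self) -> int:
        return int(self.table.loc["Total", "unique_variants"])

    @property
    def n_total_calls(self) -> int:
        return int(self.table.loc["Total", "total_calls"])


def summarize_cohort(
    calls: Sequence[CandidateCall], families: Sequence[Family]
) -> CohortSummary:
    """Cross-tabulate calls by function class and family WES class.

    Unique counts deduplicate variant keys across families; total counts do
    not (one count per variant-family call).  WES-class columns partition
    the total calls, so each row's total equals the sum over classes.
    """
    wes_by_family = {f.family_id: f.wes_class for f in families}
    classes = sorted({c.variant.function_class.value for c in calls})
    rows = [c for c in FUNCTION_ROW_ORDER if c in classes]

    def _bucket(subset: Sequence[CandidateCall]) -> dict[str, int]:
        per_wes = {4: 0, 3: 0, 2: 0, 1: 0}
        for call in subset:
            per_wes[wes_by_family[call.family_id]] += 1
        return {
            "unique_variants": len({c.key for c in subset}),
            "total_calls": len(subset),
            "wes4": per_wes[4],
            "wes3": per_wes[3],
            "wes2": per_wes[2],
            "wes1": per_wes[1],
        }

    data = {
        fc: _bucket([c for c in calls if c.variant.function_class.value == fc])
        for fc in rows
    }
    data["Total"] = _bucket(list(calls))
    table = pd.DataFrame.from_dict(data, orient="index").astype(int)
    carrier_obs = [(c.key, s) for c in calls for s in c.carriers]
    return CohortSummary(
        table=table,
        n_families=len({c.family_id for c in calls}),
        n_carrier_observations=len(carrier_obs),
        n_distinct_carriers=len({s for _, s in carrier_obs}),
    )
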