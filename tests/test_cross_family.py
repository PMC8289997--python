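"""Recurrent-gene, shared-variant and cohort-summary aggregation."""

import numpy as np

from famseg.annotation import FunctionClass, VariantRecord
from famseg.cohort import Family, VariantKey
from famseg.cross_family import (
    find_recurrent_genes,
    find_shared_variants,
    summarize_cohort,
)
from famseg.tiers import CandidateCall, screen_known_genes, screen_novel_candidates


def _call(gene, chrom, pos, family, function=FunctionClass.MISSENSE, carriers=("x",)):
    rec = VariantRecord(
        key=VariantKey.make(chrom, pos, "A", "G"),
        gene=gene,
        function_class=function,
        mmaf=0.001,
        cadd=25.0,
    )
    return CandidateCall(rec, family, "NovelCandidate", tuple(carriers))


class TestRecurrentGenes:
    def test_same_variant_in_two_families_is_recurrent(self):
        calls = [_call("ALPP", "2", 100, "Br11"), _call("ALPP", "2", 100, "Br24")]
        (gene,) = find_recurrent_genes(calls)
        assert (gene.gene, gene.n_variants, gene.n_families_total) == ("ALPP", 1, 2)

    def test_three_distinct_variants_across_three_families(self):
        calls = [
            _call("DNAH14", "1", 1, "Br5"),
            _call("DNAH14", "1", 2, "Br7"),
            _call("DNAH14", "1", 3, "Br9"),
            _call("OTHER", "9", 9, "Br5"),
        ]
        (gene,) = find_recurrent_genes(calls)
        assert gene.n_variants == 3
        assert gene.n_families_total == 3

    def test_single_family_gene_not_recurrent(self):
        calls = [_call("G1", "1", 1, "Br5"), _call("G1", "1", 2, "Br5")]
        assert find_recurrent_genes(calls) == []

    def test_every_aggregated_call_exists_in_input(self, table3):
        _, fams, cohort, records = table3
        calls = screen_novel_candidates(cohort, fams, records)
        observed = {(c.variant.gene, c.key, c.family_id) for c in calls}
        for gene in find_recurrent_genes(calls):
            for key in gene.variants:
                for fam in gene.families_by_variant[key]:
                    assert (gene.gene, key, fam) in observed


class TestSharedVariants:
    def test_reported_carrier_pattern(self, shared_fixture):
        """Two of two members in one WES-2 family, two of four in a WES-4
        family and singletons in two further families: 4 families, 6
        carriers."""
        _, fams, cohort, records = shared_fixture
        shared = find_shared_variants(cohort, fams, records, min_families=3)
        (hit,) = shared
        assert hit.variant.gene == "FANCM"
        assert hit.n_families == 4
        assert hit.n_carriers == 6
        assert hit.carriers_by_family["Br21"] == ("Br21.1", "Br21.2")
        assert hit.carriers_by_family["Br3"] == ("Br3.1", "Br3.2")

    def test_two_family_variant_excluded_by_min_families(self, shared_fixture):
        _, fams, cohort, records = shared_fixture
        shared = find_shared_variants(cohort, fams, records, min_families=3)
        assert not any(s.variant.gene == "HTT" for s in shared)
        relaxed = find_shared_variants(cohort, fams, records, min_families=2)
        assert any(s.variant.gene == "HTT" for s in relaxed)

    def test_cadd_at_threshold_excluded(self, shared_fixture):
        # the decoy spans four families but sits exactly at CADD 25's
        # qualifying boundary of 20 < 25, so the strict rule drops it
        _, fams, cohort, records = shared_fixture
        shared = find_shared_variants(cohort, fams, records, min_families=3)
        assert not any(s.variant.gene == "MPO" for s in shared)

    def test_unthresholded_scan_equals_direct_matrix_census(self, shared_fixture):
        """Oracle: with min_families=1 and no thresholds the scan must
        return exactly the variants with >= 1 carrier in the raw matrix."""
        _, fams, cohort, records = shared_fixture
        scan = find_shared_variants(
            cohort, fams, records,
            min_families=1, mmaf_max=None, cadd_min=None, bc_gf_min=None,
        )
        got = {s.variant.key for s in scan}
        expected = {
            cohort.variants[i]
            for i in range(cohort.n_variants)
            if np.any((cohort.calls[i] == 1) | (cohort.calls[i] == 2))
        }
        assert got == expected


class TestCohortSummary:
    def test_unique_vs_total_counting(self):
        fams = [Family("Br1", ("a",)), Family("Br2", ("b", "c"))]
        calls = [
            _call("G", "1", 100, "Br1", carriers=("a",)),
            _call("G", "1", 100, "Br2", carriers=("b", "c")),
        ]
        summary = summarize_cohort(calls, fams)
        assert summary.n_unique_variants == 1
        assert summary.n_total_calls == 2
        assert summary.table.loc["Missense", "wes1"] == 1
        assert summary.table.loc["Missense", "wes2"] == 1

    def test_known_gene_table_bookkeeping(self, table1):
        _, fams, cohort, records = table1
        calls = screen_known_genes(cohort, fams, records)
        summary = summarize_cohort(calls, fams)
        assert summary.n_total_calls == 10
        assert summary.n_carrier_observations == 13
        assert summary.n_families == 9
        # one patient carries two variants, so persons < observations
        assert summary.n_distinct_carriers == 12

    def test_totals_and_wes_partition(self, table3):
        _, fams, cohort, records = table3
        calls = screen_novel_candidates(cohort, fams, records)
        summary = summarize_cohort(calls, fams)
        assert summary.n_total_calls == len(calls)
        assert summary.n_unique_variants == len({c.key for c in calls})
        table = summary.table
        wes_cols = ["wes4", "wes3", "wes2", "wes1"]
        assert (table[wes_cols].sum(axis=1) == table["total_calls"]).all()
        assert (table["unique_variants"] <= table["total_calls"]).all()

    def test_empty_calls_all_zero(self):
        summary = summarize_cohort([], [Family("Br1", ("a",))])
        assert summary.n_total_calls == 0
        assert summary.n_families == 0
        assert summary.n_carrier_observations == 0
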