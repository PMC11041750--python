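"""Clonotype calling, expansion bins, enrichment scoring and quantification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pairedtcr.clonality import (
    ABSENT,
    EXPANSION_ORDER,
    HYPER,
    LARGE,
    MEDIUM,
    PBMC_ENRICHED,
    SINGLE,
    SMALL,
    TISSUE_ENRICHED,
    UNENRICHED,
    build_clonotypes,
    bulk_classify,
    classify_expansion,
    clonotype_key,
    cluster_overlap,
    compute_abundance,
    match_annotations,
    quantify_by_group,
    score_enrichment,
)
from pairedtcr.config import EnrichmentParams, ExpansionThresholds
from pairedtcr.errors import ConfigurationError, ValidationError
from pairedtcr.io import AnnotationRecord, BulkCloneRecord, ChainRecord

from conftest import make_frame


def _chain(barcode, locus, cdr3, productive=True):
    return ChainRecord(
        barcode=barcode, chain_locus=locus, v_gene="TRBV9", j_gene="TRBJ1-1",
        cdr3_aa=cdr3 if productive else "", productive=productive,
    )


def _meta(barcodes, patient="P1", tissue="PBMC"):
    return pd.DataFrame(
        {"barcode": barcodes, "patient": patient, "tissue": tissue}
    )


class TestClonotypeKey:
    def test_order_independent_and_paired(self):
        assert clonotype_key(["CAVR"], ["CASS"]) == "CAVR|CASS"
        chains_a = [_chain("x", "TRA", "CAVR"), _chain("x", "TRB", "CASS")]
        chains_b = [_chain("y", "TRB", "CASS"), _chain("y", "TRA", "CAVR")]
        frame = build_clonotypes(chains_a + chains_b, _meta(["x", "y"]))
        assert frame["clonotype"].nunique() == 1

    def test_dual_tra_sorted_multiset(self):
        chains = [
            _chain("x", "TRA", "CAVR"),
            _chain("x", "TRA", "CAAA"),
            _chain("x", "TRB", "CASS"),
        ]
        frame = build_clonotypes(chains, _meta(["x"]))
        assert frame.loc[0, "clonotype"] == "CAAA;CAVR|CASS"

    def test_duplicate_sequences_collapse(self):
        assert clonotype_key(["CAVR", "CAVR"], ["CASS"]) == "CAVR|CASS"

    def test_missing_side_renders_na_and_both_chain_policy(self):
        chains = [_chain("x", "TRB", "CASS")]
        relaxed = build_clonotypes(chains, _meta(["x"]), require_both_chains=False)
        strict = build_clonotypes(chains, _meta(["x"]), require_both_chains=True)
        assert relaxed.loc[0, "clonotype"] == "NA|CASS"
        assert strict.loc[0, "clonotype"] == ""

    def test_nonproductive_excluded_by_default(self):
        chains = [_chain("x", "TRB", "CASS"), _chain("x", "TRA", "", productive=False)]
        frame = build_clonotypes(chains, _meta(["x"]))
        assert frame.loc[0, "clonotype"] == "NA|CASS"

    def test_unknown_barcode_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            frame = build_clonotypes(
                [_chain("ghost", "TRB", "CASS")], _meta(["x"])
            )
        assert frame.loc[0, "clonotype"] == ""


class TestClassifyExpansion:
    @pytest.mark.parametrize(
        "count,denom,expected",
        [
            (1, 10, SINGLE),        # Single precedence over the 10% it represents
            (2, 10_000, SMALL),     # 0.02%
            (2, 2_000, SMALL),      # exactly 0.1% -> Small (inclusive bound)
            (3, 2_000, MEDIUM),     # 0.15%
            (20, 2_000, MEDIUM),    # exactly 1%
            (21, 2_000, LARGE),
            (200, 2_000, LARGE),    # exactly 10%
            (201, 2_000, HYPER),
            (1_500, 10_000, HYPER),  # 15%
        ],
    )
    def test_printed_bins(self, count, denom, expected):
        assert classify_expansion(count, denom) == expected

    def test_count_zero_is_domain_error(self):
        with pytest.raises(ValidationError):
            classify_expansion(0, 100)

    def test_count_above_denominator_rejected(self):
        with pytest.raises(ValidationError):
            classify_expansion(5, 4)

    @given(
        sizes=st.lists(st.integers(1, 40), min_size=1, max_size=30),
        small=st.floats(0.05, 0.5),
    )
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_bruteforce_bins_on_random_repertoires(self, sizes, small):
        """Independent oracle: literal re-application of the printed bins."""
        denom = sum(sizes)
        thr = ExpansionThresholds(small_max_pct=small, medium_max_pct=1.0,
                                  large_max_pct=10.0)
        for count in sizes:
            pct = 100.0 * count / denom
            if count == 1:
                expected = SINGLE
            elif pct <= small:
                expected = SMALL
            elif pct <= 1.0:
                expected = MEDIUM
            elif pct <= 10.0:
                expected = LARGE
            else:
                expected = HYPER
            assert classify_expansion(count, denom, thr) == expected

    @given(denom=st.integers(10, 5000), count=st.integers(2, 999))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_count(self, denom, count):
        if count + 1 > denom:
            return
        rank = {c: i for i, c in enumerate(EXPANSION_ORDER)}
        assert (
            rank[classify_expansion(count + 1, denom)]
            >= rank[classify_expansion(count, denom)]
        )


def _ledger_row(cb, ct, db_, dt):
    return {
        "patient": "P1",
        "clonotype": "K|K",
        "scope": "all",
        "count_blood": cb,
        "count_tissue": ct,
        "freq_blood": 100.0 * cb / db_ if db_ else 0.0,
        "freq_tissue": 100.0 * ct / dt if dt else 0.0,
        "expansion_blood": "Single",
        "expansion_tissue": "Single",
    }


class TestComputeAbundance:
    def _paired_frame(self):
        rows = []
        # patient P1: plaque with a 3-cell clone among 300 TCR cells
        for i in range(3):
            rows.append((f"t{i}", "P1", "plaque", "C0", "all", "A|A"))
        for i in range(297):
            rows.append((f"t{i + 3}", "P1", "plaque", "C0", "all", f"U{i}|U{i}"))
        for i in range(100):
            rows.append((f"b{i}", "P1", "PBMC", "C0", "all", f"B{i}|B{i}"))
        return make_frame(rows)

    def test_percentage_definition(self):
        ledger = compute_abundance(self._paired_frame())
        clone = ledger[ledger["clonotype"] == "A|A"].iloc[0]
        assert clone["count_tissue"] == 3
        assert clone["freq_tissue"] == pytest.approx(1.0)
        assert clone["expansion_blood"] == ABSENT

    def test_frequencies_sum_to_100_per_stratum(self):
        ledger = compute_abundance(self._paired_frame())
        assert ledger["freq_tissue"].sum() == pytest.approx(100.0)
        assert ledger["freq_blood"].sum() == pytest.approx(100.0)

    def test_all_unique_fifty_cells(self):
        rows = [(f"c{i}", "P1", "PBMC", "C0", "all", f"K{i}|K{i}") for i in range(50)]
        ledger = compute_abundance(make_frame(rows))
        assert (ledger["freq_blood"] == 2.0).all()
        assert (ledger["count_blood"] == 1).all()

    def test_scoped_run_uses_scoped_denominator(self):
        rows = [(f"c{i}", "P1", "PBMC", "C0", "CD4", "A|A") for i in range(2)]
        rows += [(f"d{i}", "P1", "PBMC", "C0", "CD8", f"K{i}|K{i}") for i in range(8)]
        all_ledger = compute_abundance(make_frame(rows), "all")
        cd4_ledger = compute_abundance(make_frame(rows), "CD4")
        a_all = all_ledger[all_ledger["clonotype"] == "A|A"].iloc[0]
        a_cd4 = cd4_ledger[cd4_ledger["clonotype"] == "A|A"].iloc[0]
        assert a_all["freq_blood"] == pytest.approx(20.0)   # 2 of 10
        assert a_cd4["freq_blood"] == pytest.approx(100.0)  # 2 of 2 CD4 cells
        assert len(cd4_ledger) == 1

    def test_row_order_invariance(self, rng):
        frame = self._paired_frame()
        shuffled = frame.sample(frac=1.0, random_state=7).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            compute_abundance(frame), compute_abundance(shuffled)
        )


class TestScoreEnrichment:
    def test_absent_from_blood_is_tissue_enriched(self):
        ledger = pd.DataFrame([_ledger_row(0, 5, 1000, 1000)])
        assert score_enrichment(ledger)["enrichment"][0] == TISSUE_ENRICHED

    def test_one_cell_total_is_single(self):
        ledger = pd.DataFrame([_ledger_row(1, 0, 1000, 1000)])
        assert score_enrichment(ledger)["enrichment"][0] == SINGLE

    def test_equal_frequencies_unenriched(self):
        ledger = pd.DataFrame([_ledger_row(5, 5, 1000, 1000)])
        assert score_enrichment(ledger)["enrichment"][0] == UNENRICHED

    def test_fold_rule_two_sided(self):
        up = pd.DataFrame([_ledger_row(2, 8, 1000, 1000)])     # 4x toward tissue
        down = pd.DataFrame([_ledger_row(8, 2, 1000, 1000)])
        assert score_enrichment(up)["enrichment"][0] == TISSUE_ENRICHED
        assert score_enrichment(down)["enrichment"][0] == PBMC_ENRICHED

    def test_below_fold_threshold_unenriched(self):
        ledger = pd.DataFrame([_ledger_row(5, 8, 1000, 1000)])  # 1.6x < 2
        assert score_enrichment(ledger)["enrichment"][0] == UNENRICHED

    @given(
        clones=st.lists(
            st.tuples(st.integers(0, 30), st.integers(0, 30)).filter(
                lambda t: t[0] + t[1] > 0
            ),
            min_size=1,
            max_size=25,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_antisymmetric_under_tissue_swap(self, clones):
        db_ = sum(c[0] for c in clones) or 1
        dt = sum(c[1] for c in clones) or 1
        fwd = pd.DataFrame([_ledger_row(cb, ct, db_, dt) for cb, ct in clones])
        rev = pd.DataFrame([_ledger_row(ct, cb, dt, db_) for cb, ct in clones])
        mirror = {TISSUE_ENRICHED: PBMC_ENRICHED, PBMC_ENRICHED: TISSUE_ENRICHED,
                  SINGLE: SINGLE, UNENRICHED: UNENRICHED}
        fwd_labels = list(score_enrichment(fwd)["enrichment"])
        rev_labels = list(score_enrichment(rev)["enrichment"])
        assert [mirror[x] for x in fwd_labels] == rev_labels


class TestQuantifyByGroup:
    def test_cell_weighted_proportions(self):
        rows = [(f"s{i}", "P1", "PBMC", "C0", "all", f"U{i}|U{i}") for i in range(8)]
        rows += [(f"e{i}", "P1", "PBMC", "C0", "all", "E|E") for i in range(2)]
        frame = make_frame(rows)
        ledger = score_enrichment(compute_abundance(frame))
        table = quantify_by_group(frame, ledger, ["tissue"], "expansion")
        by_class = dict(zip(table["class"], table["proportion"]))
        assert by_class[SINGLE] == pytest.approx(0.8)
        assert by_class[HYPER] == pytest.approx(0.2)  # the 2-cell clone is 20% here

    def test_all_singletons(self):
        rows = [(f"c{i}", "P1", "plaque", "C0", "all", f"U{i}|U{i}") for i in range(5)]
        frame = make_frame(rows)
        ledger = compute_abundance(frame)
        table = quantify_by_group(frame, ledger, ["tissue"])
        assert table["proportion"].tolist() == [1.0]
        assert table["class"].tolist() == [SINGLE]

    def test_proportions_sum_to_one_per_group(self, small_dataset):
        from pairedtcr.clonality import MISSING

        chains = [r for recs in small_dataset.chains.values() for r in recs]
        meta = small_dataset.cell_meta[small_dataset.cell_meta["barcode"].isin(
            {c.barcode for c in chains}
        )]
        frame = build_clonotypes(chains, meta)
        ledger = score_enrichment(compute_abundance(frame))
        for label in ("expansion", "enrichment"):
            table = quantify_by_group(frame, ledger, ["patient", "tissue"], label)
            sums = table.groupby(["patient", "tissue"])["proportion"].sum()
            assert np.allclose(sums, 1.0)

    def test_unknown_group_key_rejected(self):
        frame = make_frame([("c0", "P1", "PBMC", "C0", "all", "A|A")])
        ledger = compute_abundance(frame)
        with pytest.raises(ConfigurationError):
            quantify_by_group(frame, ledger, ["flavour"])


class TestClusterOverlap:
    def _frame(self):
        rows = []
        for i, key in enumerate(["A|A", "B|B", "C|C"]):
            rows.append((f"a{i}", "P1", "PBMC", "C6", "all", key))
        for i, key in enumerate(["B|B", "C|C", "D|D"]):
            rows.append((f"b{i}", "P1", "plaque", "C3", "all", key))
        return make_frame(rows)

    def test_intersection(self):
        table = cluster_overlap(self._frame(), "C6", "C3")
        assert sorted(table["clonotype"]) == ["B|B", "C|C"]

    def test_disjoint_clusters_empty(self):
        rows = [
            ("a0", "P1", "PBMC", "C6", "all", "A|A"),
            ("b0", "P1", "plaque", "C3", "all", "B|B"),
        ]
        assert cluster_overlap(make_frame(rows), "C6", "C3").empty

    def test_sorted_by_combined_count_then_key(self):
        rows = [("x%d" % i, "P1", "PBMC", "C6", "all", "A|A") for i in range(3)]
        rows += [("y0", "P1", "plaque", "C3", "all", "A|A")]
        rows += [("z0", "P1", "PBMC", "C6", "all", "B|B"),
                 ("z1", "P1", "plaque", "C3", "all", "B|B")]
        table = cluster_overlap(make_frame(rows), "C6", "C3")
        assert table["clonotype"].tolist() == ["A|A", "B|B"]
        assert table["count_total"].tolist() == [4, 2]

    def test_unknown_cluster_rejected(self):
        with pytest.raises(ConfigurationError):
            cluster_overlap(self._frame(), "C6", "C99")


class TestMatchAnnotations:
    DB = [
        AnnotationRecord("TRA", "CAVSDNYQLIW", "CMV", "NLVPMVATV", "vdjdb"),
        AnnotationRecord("TRB", "CASSLG", "EBV", "X", "vdjdb"),
    ]

    def test_locus_aware_exact_hit(self):
        frame = make_frame([("c0", "P1", "PBMC", "C0", "all", "CAVSDNYQLIW|CASSX")])
        hits = match_annotations(frame, self.DB)
        assert len(hits) == 1 and hits.loc[0, "antigen_species"] == "CMV"

    def test_same_sequence_wrong_locus_no_hit(self):
        frame = make_frame([("c0", "P1", "PBMC", "C0", "all", "NA|CAVSDNYQLIW")])
        assert match_annotations(frame, self.DB).empty

    def test_empty_db_no_hits(self):
        frame = make_frame([("c0", "P1", "PBMC", "C0", "all", "CAVSDNYQLIW|CASSX")])
        assert match_annotations(frame, []).empty


class TestBulkClassify:
    def _records(self):
        recs = []
        # PBMC sample of patient P1: 1000 templates in total
        recs.append(BulkCloneRecord("CASSA", 1, "s1", "PBMC", "P1"))
        recs.append(BulkCloneRecord("CASSB", 150, "s1", "PBMC", "P1"))
        recs.append(BulkCloneRecord("CASSC", 10, "s1", "PBMC", "P1"))
        recs.append(BulkCloneRecord("CASSC", 5, "s1", "PBMC", "P1"))  # duplicate rows
        recs.append(BulkCloneRecord("CASSF", 834, "s1", "PBMC", "P1"))
        return recs

    def test_single_and_hyperexpanded_bins(self):
        table = bulk_classify(self._records())
        by_key = table.set_index("clonotype")
        assert by_key.loc["CASSA", "expansion_blood"] == SINGLE
        assert by_key.loc["CASSB", "expansion_blood"] == HYPER  # 15% of templates

    def test_duplicate_rows_aggregate_before_classification(self):
        table = bulk_classify(self._records())
        row = table.set_index("clonotype").loc["CASSC"]
        assert row["count_blood"] == 15
        assert row["freq_blood"] == pytest.approx(1.5)

    def test_enrichment_present(self):
        recs = self._records() + [BulkCloneRecord("CASSB", 10, "s2", "plaque", "P1"),
                                  BulkCloneRecord("CASSZ", 990, "s2", "plaque", "P1")]
        table = bulk_classify(recs)
        row = table.set_index("clonotype").loc["CASSB"]
        assert row["enrichment"] == PBMC_ENRICHED  # 15% blood vs 1% plaque
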