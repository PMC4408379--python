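"""Enrichment, matching, frequency and export behaviour."""

import math

import pytest

from conftest import make_record, mod_res
from ptmenrich.analysis import (
    ENRICHMENT_HEADER,
    crossref_markers,
    enrich,
    export_barchart,
    export_table,
    list_frequency,
    match,
    read_table,
)
from ptmenrich.enrich_stats import CorrectionMethod
from ptmenrich.errors import DatabaseError, ParameterError
from ptmenrich.ptm_db import build_database
from ptmenrich.ptm_vocab import default_vocabulary
from ptmenrich.synth_fixtures import (
    PlantedListSpec,
    example_spec,
    generate_records,
    plant_enriched_list,
)

ORG = "Homo sapiens"


@pytest.fixture(scope="module")
def twenty_protein_db(small_vocab):
    """20 proteins; term A (Phosphoprotein) on exactly 5; a universal term."""
    records = []
    for i in range(20):
        keywords = ["Acetylation"]  # universal: K = N
        if i < 5:
            keywords.append("Phosphoprotein")
        records.append(
            make_record(f"T{i:02d}_HUMAN", f"P70{i:03d}", keywords=keywords)
        )
    return build_database(records, small_vocab)


@pytest.fixture(scope="module")
def planted_db_and_truth():
    records, truth = generate_records(example_spec(n_proteins=600, seed=21))
    return build_database(records, default_vocabulary()), truth


class TestEnrich:
    def test_exact_closed_form_on_perfect_hit(self, twenty_protein_db):
        query = [f"P70{i:03d}" for i in range(5)]
        result = enrich(
            twenty_protein_db, ORG, query, correction=CorrectionMethod.NONE
        )
        row = next(r for r in result.rows if r.term_label == "Phosphoprotein")
        assert (row.freq_db, row.freq_list) == (5, 5)
        assert result.context.population_size == 20
        assert result.context.list_size == 5
        # C(5,5)*C(15,0)/C(20,5) = 1/15504
        assert row.p_value == pytest.approx(1 / 15504, rel=1e-12)

    def test_universal_term_has_p_one(self, twenty_protein_db):
        result = enrich(
            twenty_protein_db,
            ORG,
            ["P70005", "P70006", "P70007"],
            correction=CorrectionMethod.NONE,
        )
        row = next(r for r in result.rows if r.term_label == "Acetylation")
        assert row.freq_db == 20 and row.freq_list == 3
        assert row.p_value == 1.0
        assert not row.significant

    def test_full_background_list_gives_m_equals_k_and_p_one(
        self, twenty_protein_db
    ):
        everyone = sorted(twenty_protein_db.partition(ORG))
        result = enrich(
            twenty_protein_db, ORG, everyone, correction=CorrectionMethod.NONE
        )
        for row in result.rows:
            assert row.freq_list == row.freq_db
            assert row.p_value == 1.0

    def test_rows_exclude_misses_but_stats_keep_them(self, twenty_protein_db):
        result = enrich(twenty_protein_db, ORG, ["P70010"])
        assert {r.term_label for r in result.rows} == {"Acetylation"}
        assert result.term_stats["phosphoprotein"].m == 0

    def test_alpha_outside_unit_interval_rejected(self, twenty_protein_db):
        with pytest.raises(ParameterError, match="alpha"):
            enrich(twenty_protein_db, ORG, ["P70000"], alpha=1.5)

    def test_bonferroni_context_carries_adjusted_alpha(self, twenty_protein_db):
        result = enrich(twenty_protein_db, ORG, ["P70000"])
        T = len(result.term_stats)
        assert result.context.adjusted_alpha == pytest.approx(0.05 / T)

    def test_planted_term_recovered(self, planted_db_and_truth):
        db, truth = planted_db_and_truth
        hits = 0
        for seed in range(30):
            query = plant_enriched_list(
                truth,
                PlantedListSpec(ORG, "sulfotyrosine", 80, 6.0, seed=seed),
            )
            result = enrich(db, ORG, query)
            if result.rows[0].term_id == "sulfotyrosine" and result.rows[0].significant:
                hits += 1
        assert hits >= 29

    def test_deterministic_export_bytes(self, planted_db_and_truth):
        db, truth = planted_db_and_truth
        query = plant_enriched_list(
            truth, PlantedListSpec(ORG, "phosphoserine", 60, 2.0, seed=4)
        )
        t1 = export_table(enrich(db, ORG, query))
        t2 = export_table(enrich(db, ORG, query))
        assert t1 == t2


class TestMatch:
    def test_identical_results_match_everywhere(self, planted_db_and_truth):
        db, truth = planted_db_and_truth
        query = plant_enriched_list(
            truth, PlantedListSpec(ORG, "phosphoserine", 80, 3.0, seed=8)
        )
        result = enrich(db, ORG, query)
        matched = match(result, result)
        assert len(matched.rows) == len(result.significant_terms())
        for row in matched.rows:
            assert row.significant_in == "both"
            assert row.pct_list1 == row.pct_list2

    def test_no_significant_terms_yields_empty_table(self, twenty_protein_db):
        r = enrich(twenty_protein_db, ORG, ["P70005", "P70006"])
        matched = match(r, r)
        assert matched.rows == ()
        assert matched.context1.organism_key == ORG

    def test_terms_planted_in_opposite_lists(self, planted_db_and_truth):
        db, truth = planted_db_and_truth
        q1 = plant_enriched_list(
            truth, PlantedListSpec(ORG, "sulfotyrosine", 80, 6.0, seed=1)
        )
        q2 = plant_enriched_list(
            truth, PlantedListSpec(ORG, "4-hydroxyproline", 80, 6.0, seed=2)
        )
        matched = match(enrich(db, ORG, q1), enrich(db, ORG, q2))
        by_term = {row.term_id: row for row in matched.rows}
        assert by_term["sulfotyrosine"].significant_in in ("list1", "both")
        assert by_term["4-hydroxyproline"].significant_in in ("list2", "both")
        assert by_term["sulfotyrosine"].significant_in != "list2"

    def test_symmetric_up_to_column_swap(self, planted_db_and_truth):
        db, truth = planted_db_and_truth
        q1 = plant_enriched_list(
            truth, PlantedListSpec(ORG, "sulfotyrosine", 80, 6.0, seed=3)
        )
        q2 = plant_enriched_list(
            truth, PlantedListSpec(ORG, "phosphotyrosine", 80, 4.0, seed=4)
        )
        r1, r2 = enrich(db, ORG, q1), enrich(db, ORG, q2)
        ab, ba = match(r1, r2), match(r2, r1)
        assert {r.term_id for r in ab.rows} == {r.term_id for r in ba.rows}

    def test_different_backgrounds_incomparable(
        self, twenty_protein_db, planted_db_and_truth
    ):
        db, truth = planted_db_and_truth
        r1 = enrich(twenty_protein_db, ORG, ["P70000"])
        r2 = enrich(
            db,
            ORG,
            plant_enriched_list(
                truth, PlantedListSpec(ORG, "phosphoserine", 30, 1.0, seed=0)
            ),
        )
        with pytest.raises(DatabaseError, match="incomparable"):
            match(r1, r2)


class TestListFrequency:
    def test_whole_organism_list_equalizes_percentages(self, twenty_protein_db):
        everyone = sorted(twenty_protein_db.partition(ORG))
        result = list_frequency(twenty_protein_db, ORG, everyone)
        for row in result.rows:
            assert row.pct_list == pytest.approx(row.pct_db)

    def test_terms_with_zero_list_hits_still_listed(self, twenty_protein_db):
        result = list_frequency(twenty_protein_db, ORG, ["P70010"])
        by_label = {r.term_label: r for r in result.rows}
        assert by_label["Phosphoprotein"].freq_list == 0
        assert by_label["Phosphoprotein"].freq_db == 5

    def test_matches_brute_force_recount(self, planted_db_and_truth):
        db, truth = planted_db_and_truth
        query = plant_enriched_list(
            truth, PlantedListSpec(ORG, "phosphoserine", 50, 1.0, seed=9)
        )
        result = list_frequency(db, ORG, query)
        chosen = set(query)
        for row in result.rows:
            carriers = truth.terms.get((ORG, row.term_id))
            if carriers is None:
                continue  # ad-hoc or derived terms are not in the truth table
            assert row.freq_db == len(carriers)
            assert row.freq_list == len(carriers & chosen)


class TestCrossrefMarkers:
    class _Holder:
        def __init__(self, cross_refs):
            self.cross_refs = cross_refs

    def test_phosphosite_maps_to_marker_two(self):
        assert crossref_markers(self._Holder([("PhosphoSite", "X")])) == {2}

    def test_no_cross_refs_renders_unmarked(self):
        assert crossref_markers(self._Holder([])) == set()

    def test_multiple_databases_combine(self):
        holder = self._Holder([("PhosphoSitePlus", "X"), ("UniCarbKB", "Y")])
        assert crossref_markers(holder) == {2, 3}

    def test_rendered_accession_order(self, small_vocab):
        record = make_record(
            "MARK_HUMAN",
            "P80001",
            keywords=["Phosphoprotein"],
            cross_refs=[("UniCarbKB", "X"), ("PhosSite", "Y")],
        )
        db = build_database([record], small_vocab)
        result = enrich(db, ORG, ["P80001"], correction=CorrectionMethod.NONE)
        assert result.rows[0].member_accessions == ("P80001(1)(3)",)


class TestExport:
    def test_header_is_canonical(self, twenty_protein_db):
        text = export_table(enrich(twenty_protein_db, ORG, ["P70000"]))
        assert text.splitlines()[0] == "\t".join(ENRICHMENT_HEADER)

    def test_footer_records_context(self, twenty_protein_db):
        text = export_table(enrich(twenty_protein_db, ORG, ["P70000"]))
        footer = text.splitlines()[-1]
        assert footer.startswith("#")
        assert "N=20" in footer and "correction=bonferroni" in footer
        assert "adjusted_alpha=" in footer

    def test_empty_result_is_header_plus_footer(self, twenty_protein_db):
        result = enrich(twenty_protein_db, ORG, ["P70000"])
        empty = result.__class__(
            rows=(), context=result.context, term_stats=result.term_stats,
            term_labels=result.term_labels,
        )
        assert len(export_table(empty).splitlines()) == 2

    def test_reimport_reproduces_numbers_at_printed_precision(
        self, planted_db_and_truth, tmp_path
    ):
        db, truth = planted_db_and_truth
        query = plant_enriched_list(
            truth, PlantedListSpec(ORG, "phosphoserine", 60, 2.5, seed=13)
        )
        result = enrich(db, ORG, query)
        path = tmp_path / "out.tsv"
        export_table(result, path)
        frame = read_table(path)
        assert list(frame.columns) == ENRICHMENT_HEADER
        for row, (_, re_row) in zip(result.rows, frame.iterrows()):
            assert re_row["Frequency in list"] == row.freq_list
            assert re_row["Percent in list"] == pytest.approx(row.pct_list, abs=5e-3)
            assert re_row["P-value"] == pytest.approx(row.p_value, rel=1e-3)
            assert re_row["Corrected P-value"] == pytest.approx(
                row.adjusted_p, rel=1e-3
            )

    def test_enrichment_barchart_plots_log_decision_p(self, twenty_protein_db):
        result = enrich(
            twenty_protein_db, ORG, ["P70000"], correction=CorrectionMethod.NONE
        )
        fig = export_barchart(result)
        heights = sorted(p.get_width() for p in fig.axes[0].patches)
        expected = sorted(-math.log10(r.decision_p) for r in result.rows)
        assert heights == pytest.approx(expected)

    def test_matched_barchart_has_two_bars_per_term(self, planted_db_and_truth):
        db, truth = planted_db_and_truth
        query = plant_enriched_list(
            truth, PlantedListSpec(ORG, "sulfotyrosine", 80, 6.0, seed=5)
        )
        result = enrich(db, ORG, query)
        matched = match(result, result)
        fig = export_barchart(matched)
        assert len(fig.axes[0].patches) == 2 * len(matched.rows)
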