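import random

import pytest
from hypothesis import given, settings, strategies as st

from amalgam.duplication import (
    EvidenceFlags,
    GeneCopy,
    classify_mechanism,
    rank_evidence,
    screen_candidates,
    summarize_candidates,
    synteny_check,
)
from amalgam.io import OrthologyRow


def _rows_for_duplicate(anchor="G1", partner="M1", copies=("C1", "C2")):
    rows = [OrthologyRow(anchor, "human", "mouse", partner, "ortholog_one2one")]
    for c in copies:
        rows.append(OrthologyRow(anchor, "human", "cattle", c, "ortholog_one2many"))
        rows.append(OrthologyRow(partner, "mouse", "cattle", c, "ortholog_one2many"))
    return rows


class TestScreen:
    def test_definition_case_emits_one_candidate_with_two_copies(self):
        [cand] = screen_candidates(_rows_for_duplicate(), metabolic_gene_ids={"G1"})
        assert cand.anchor_gene_id == "G1" and cand.anchor_partner_id == "M1"
        assert sorted(c.gene_id for c in cand.copies) == ["C1", "C2"]
        assert cand.is_metabolic

    def test_one2one_target_is_not_a_candidate(self):
        rows = [
            OrthologyRow("G1", "human", "mouse", "M1", "ortholog_one2one"),
            OrthologyRow("G1", "human", "cattle", "C1", "ortholog_one2one"),
            OrthologyRow("M1", "mouse", "cattle", "C1", "ortholog_one2one"),
        ]
        assert screen_candidates(rows, {"G1"}) == []

    def test_partner_must_independently_show_duplication(self):
        rows = [
            OrthologyRow("G1", "human", "mouse", "M1", "ortholog_one2one"),
            OrthologyRow("G1", "human", "cattle", "C1", "ortholog_one2many"),
            OrthologyRow("G1", "human", "cattle", "C2", "ortholog_one2many"),
            OrthologyRow("M1", "mouse", "cattle", "C1", "ortholog_one2one"),
        ]
        assert screen_candidates(rows, {"G1"}) == []

    def test_non_metabolic_candidate_retained_but_flagged(self):
        [cand] = screen_candidates(_rows_for_duplicate(), metabolic_gene_ids={"OTHER"})
        assert not cand.is_metabolic

    def test_two_one2one_partners_is_malformed_table(self):
        rows = _rows_for_duplicate() + [
            OrthologyRow("G1", "human", "mouse", "M2", "ortholog_one2one")
        ]
        with pytest.raises(ValueError, match="one2one"):
            screen_candidates(rows, {"G1"})

    def test_row_order_invariance(self):
        from amalgam.fixtures import OrthologyPlan, gen_orthology_fixture

        rows, _, ci, met, truth = gen_orthology_fixture(
            OrthologyPlan(n_decoy_anchors=12), seed=4
        )
        ref = screen_candidates(rows, met, copy_info=ci)
        rng = random.Random(1)
        rng.shuffle(rows)
        again = screen_candidates(rows, met, copy_info=ci)
        assert [c.anchor_gene_id for c in ref] == [c.anchor_gene_id for c in again]
        assert len(ref) == truth.n_candidates


class TestRankEvidence:
    @pytest.mark.parametrize(
        "est, expr, complete, expected",
        [
            (True, True, True, "A"),
            (True, True, False, "B"),
            (True, False, False, "C"),
            (False, True, False, "C"),
            (False, False, False, "D"),
            # grid gap: assembly completeness only separates A from B
            (True, False, True, "C"),
            (False, False, True, "D"),
        ],
    )
    def test_rank_grid(self, est, expr, complete, expected):
        flags = EvidenceFlags(True, est, expr, complete)
        assert rank_evidence(flags) == expected

    def test_missing_nucleotide_chain_rejected(self):
        with pytest.raises(ValueError):
            rank_evidence(EvidenceFlags(False, True, True, True))

    def test_ranking_is_total_over_complete_flag_vectors(self):
        import itertools

        ranks = {
            rank_evidence(EvidenceFlags(True, *v))
            for v in itertools.product([True, False], repeat=3)
        }
        assert ranks <= {"A", "B", "C", "D"}


class TestMechanism:
    def test_nearby_same_chromosome_copies_are_segmental(self):
        # two multi-exon copies ~11.6 kb apart on one chromosome
        copies = [
            GeneCopy("c1", "19", 55904213, 55905449, exon_count=7),
            GeneCopy("c2", "19", 55917031, 55918872, exon_count=7),
        ]
        assert classify_mechanism(copies) == "segmental"

    def test_copies_on_different_chromosomes_are_rearrangement(self):
        copies = [
            GeneCopy("c1", "1", 3113948, 3122613, exon_count=5),
            GeneCopy("c2", "13", 51930067, 51930888, exon_count=5),
        ]
        assert classify_mechanism(copies) == "rearrangement"

    def test_intronless_polya_copy_is_retrogene_even_across_chromosomes(self):
        copies = [
            GeneCopy("c1", "4", 99223160, 99254542, exon_count=3, has_polya_signal=False),
            GeneCopy("c2", "10", 78463269, 78464048, exon_count=1, has_polya_signal=True),
        ]
        assert classify_mechanism(copies) == "retrotransposition"

    def test_same_chromosome_beyond_block_size_is_unknown(self):
        copies = [
            GeneCopy("c1", "2", 1000, 2000, exon_count=4),
            GeneCopy("c2", "2", 5_000_000, 5_001_000, exon_count=4),
        ]
        assert classify_mechanism(copies) == "unknown"

    @given(
        st.lists(
            st.tuples(st.sampled_from(["1", "2", "3"]), st.integers(1, 10**6)),
            min_size=2, max_size=5,
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_never_segmental_across_chromosomes(self, placements):
        copies = [
            GeneCopy(f"c{i}", chrom, start, start + 999, exon_count=4)
            for i, (chrom, start) in enumerate(placements)
        ]
        result = classify_mechanism(copies)
        if len({c.chrom for c in copies}) > 1:
            assert result != "segmental"


class TestSynteny:
    def test_adjacent_flanks_without_candidate_mean_inserted(self):
        call = synteny_check(
            "copy", ["X"], ["Y"],
            {"human": ["W", "X", "Y", "Z"]}, candidate_ortholog_id="G",
        )
        assert call.status == "inserted"

    def test_candidate_between_flanks_means_ancestral(self):
        call = synteny_check(
            "copy", ["X"], ["Y"],
            {"human": ["W", "X", "G", "Y", "Z"]}, candidate_ortholog_id="G",
        )
        assert call.status == "ancestral"

    def test_unanimous_references_required(self):
        call = synteny_check(
            "copy", ["X"], ["Y"],
            {"human": ["X", "Y"], "mouse": ["X", "G", "Y"]},
            candidate_ortholog_id="G",
        )
        assert call.status == "indeterminate"

    def test_all_references_abstain_is_indeterminate(self):
        call = synteny_check(
            "copy", ["X"], ["Y"], {"human": ["A", "B"]}, candidate_ortholog_id="G"
        )
        assert call.status == "indeterminate"

    def test_retrogene_style_insertion_supported_by_both_references(self):
        # conserved adjacent flanks in both references, no intervening ortholog
        refs = {
            "human": ["U2", "U1", "D1", "D2"],
            "mouse": ["U2", "U1", "D1", "D2"],
        }
        call = synteny_check("bpgm_chr10", ["U1", "U2"], ["D1", "D2"], refs,
                             candidate_ortholog_id="BPGM")
        assert call.status == "inserted"
        assert dict(call.evidence) == {"human": "inserted", "mouse": "inserted"}

    def test_reversed_reference_orientation_is_handled(self):
        call = synteny_check(
            "copy", ["X"], ["Y"],
            {"human": ["Z", "Y", "G", "X", "W"]}, candidate_ortholog_id="G",
        )
        assert call.status == "ancestral"


class TestSummary:
    def test_worked_example_counts_twelve_distinct_pathways(self):
        from amalgam.duplication import DuplicationCandidate
        from amalgam.fixtures import DUPLICATED_GENE_EXAMPLES

        candidates = []
        for entry in DUPLICATED_GENE_EXAMPLES:
            copies = [
                GeneCopy(f"{entry['symbol']}_{i}", c, s, e, exon_count=x, has_polya_signal=p)
                for i, (c, s, e, x, p) in enumerate(entry["copies"])
            ]
            candidates.append(
                DuplicationCandidate(
                    anchor_gene_id=entry["symbol"], anchor_partner_id="m",
                    copies=copies, is_metabolic=True,
                    pathways=frozenset({entry["pathways"]}),
                    rank=rank_evidence(EvidenceFlags(True, entry["est"], entry["expr"], False)),
                    mechanism=classify_mechanism(copies),
                )
            )
        summary = summarize_candidates(candidates)
        assert summary.n_genes == 8
        assert summary.n_pathways == 12
        assert summary.rank_histogram == {"A": 0, "B": 2, "C": 5, "D": 1}
        assert summary.mechanism_histogram == {
            "segmental": 4, "rearrangement": 3, "retrotransposition": 1, "unknown": 0,
        }

    def test_empty_candidate_list(self):
        s = summarize_candidates([])
        assert s.n_genes == 0 and s.n_pathways == 0
        assert set(s.rank_histogram.values()) == {0}

    def test_shared_pathway_counted_once(self):
        from amalgam.duplication import DuplicationCandidate

        copies = [GeneCopy("a", "1", 1, 10), GeneCopy("b", "1", 100, 110)]
        c1 = DuplicationCandidate("g1", "m1", list(copies), pathways=frozenset({"Glycolysis"}))
        c2 = DuplicationCandidate("g2", "m2", list(copies), pathways=frozenset({"glycolysis "}))
        assert summarize_candidates([c1, c2]).n_pathways == 1
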