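import pytest

from amalgam.io import BlastHit
from amalgam.pgdb import (
    apply_deletion_rules,
    apply_edits,
    compare_pgdbs,
    fill_hole_filter,
    hole_report,
    replay_actions,
)

from conftest import mk_pgdb


class TestHoleReport:
    def test_hand_enumerated_toy(self, toy_pgdb):
        rep = hole_report(toy_pgdb)
        assert rep.holes_per_pathway == {"P1": 1, "P2": 2}
        assert rep.total_holes == 3
        assert rep.total_reactions_in_pathways == 5  # r2 counted in both pathways
        assert rep.pct_holes == pytest.approx(60.0)
        assert rep.pathways_with_holes == 2

    def test_fully_assigned_pgdb_has_no_holes(self):
        pgdb = mk_pgdb({"P1": ["r1"], "P2": ["r2"]}, {"r1": ["g"], "r2": ["g"]})
        rep = hole_report(pgdb)
        assert rep.total_holes == 0
        assert rep.distribution[0] == 2

    def test_spontaneous_and_transport_reactions_are_never_holes(self):
        pgdb = mk_pgdb(
            {"P1": ["r1", "r2", "r3"]},
            {"r1": (None, "spontaneous"), "r2": (None, "transport"), "r3": None},
        )
        assert hole_report(pgdb).total_holes == 1

    def test_distribution_sums_to_pathway_count(self):
        from amalgam.fixtures import PGDBPlan, gen_toy_pgdb

        pgdb, truth = gen_toy_pgdb(
            PGDBPlan(hole_buckets={1: 4, 3: 2}, gt4_hole_counts=(6, 7),
                     n_no_hole_plain=5), seed=2,
        )
        rep = hole_report(pgdb)
        assert sum(rep.distribution.values()) == len(pgdb.pathways) == truth.n_pathways
        assert rep.total_holes == truth.total_holes


class TestComparePgdbs:
    def test_partition(self):
        a = mk_pgdb({p: ["r"] for p in ("p1", "p2", "p3")}, {"r": ["g"]})
        b = mk_pgdb({p: ["r"] for p in ("p2", "p4")}, {"r": ["g"]})
        rep = compare_pgdbs(a, b)
        assert rep.only_in_a == {"p1", "p3"}
        assert rep.only_in_b == {"p4"}
        assert rep.shared == {"p2"}

    def test_identical_pgdbs(self):
        a = mk_pgdb({"p1": ["r"]}, {"r": ["g"]})
        rep = compare_pgdbs(a, a)
        assert not rep.only_in_a and not rep.only_in_b and rep.shared == {"p1"}

    def test_symmetry(self):
        a = mk_pgdb({p: ["r"] for p in ("p1", "p2")}, {"r": ["g"]})
        b = mk_pgdb({p: ["r"] for p in ("p2", "p3")}, {"r": ["g"]})
        fwd, rev = compare_pgdbs(a, b), compare_pgdbs(b, a)
        assert fwd.only_in_a == rev.only_in_b
        assert fwd.only_in_b == rev.only_in_a
        assert fwd.shared == rev.shared

    def test_id_map_conflict_is_error(self):
        a = mk_pgdb({"p1": ["r"]}, {"r": ["g"]})
        with pytest.raises(ValueError, match="id_map"):
            compare_pgdbs(a, a, id_map=[("x", "p1"), ("x", "p2")])

    def test_reason_histogram(self):
        a = mk_pgdb({p: ["r"] for p in ("p1", "p2", "p3")}, {"r": ["g"]})
        b = mk_pgdb({"p9": ["r"]}, {"r": ["g"]})
        reasons = {"p1": "metacyc_update", "p2": "metacyc_update", "p3": "assembly_update"}
        rep = compare_pgdbs(a, b, reasons=reasons)
        assert rep.reason_histogram() == {"metacyc_update": 2, "assembly_update": 1}
        assert sum(rep.reason_histogram().values()) == len(rep.only_in_a)


class TestDeletionRules:
    def _five_pathway_toy(self):
        # one pathway per rule plus two survivors
        return mk_pgdb(
            {
                "P_main": ["r1", "r2"],
                "P_dup": ["r2"],  # R1: subset of P_main
                "P_nm": (["r3"], "non_mammal", "homolog"),  # R2
                "P_noev": (["r1", "r4"], "mammal", "none"),  # R3: shares r1
                "P_other": ["r5"],
            },
            {f"r{i}": ["g"] for i in range(1, 6)},
        )

    def test_one_action_per_rule_and_two_survivors(self):
        pgdb = self._five_pathway_toy()
        curated, actions = apply_deletion_rules(pgdb)
        assert {(a.target_id, a.reason) for a in actions} == {
            ("P_dup", "redundant"),
            ("P_nm", "non_mammal_metabolite"),
            ("P_noev", "no_evidence_with_alternative"),
        }
        assert set(curated.pathways) == {"P_main", "P_other"}

    def test_exact_duplicates_keep_lexicographically_smaller_id(self):
        pgdb = mk_pgdb({"Pa": ["r1"], "Pb": ["r1"]}, {"r1": ["g"]})
        curated, actions = apply_deletion_rules(pgdb)
        assert set(curated.pathways) == {"Pa"}
        assert actions[0].target_id == "Pb"

    def test_caller_flags_trigger_non_mammal_deletion(self):
        pgdb = mk_pgdb({"P1": ["r1"], "P2": ["r2"]}, {"r1": ["g"], "r2": ["g"]})
        curated, actions = apply_deletion_rules(pgdb, metabolite_taxon_flags={"P2"})
        assert set(curated.pathways) == {"P1"}
        assert actions[0].reason == "non_mammal_metabolite"

    def test_no_evidence_without_alternative_survives(self):
        pgdb = mk_pgdb(
            {"P1": (["r1"], "mammal", "none"), "P2": ["r2"]}, {"r1": [], "r2": ["g"]}
        )
        curated, _ = apply_deletion_rules(pgdb)
        assert "P1" in curated.pathways  # no reaction shared with any survivor

    def test_idempotence(self):
        pgdb = self._five_pathway_toy()
        once, actions1 = apply_deletion_rules(pgdb)
        twice, actions2 = apply_deletion_rules(once)
        assert actions2 == []
        assert set(twice.pathways) == set(once.pathways)


class TestFillHoleFilter:
    def _hit(self, q="q1", s="s1", pident=75.0, qstart=1, qend=85, qlen=100, bitscore=100.0):
        return BlastHit(q, s, pident, qend - qstart + 1, 0, 0, qstart, qend, 1, 50,
                        1e-30, bitscore, qlen)

    @pytest.mark.parametrize(
        "pident, qend, accepted",
        [
            (75.0, 85, True),   # coverage 85, identity 75: standard thresholds
            (70.0, 80, True),   # inclusive boundary of clause 1
            (69.9, 80, False),
            (70.0, 79, False),
        ],
    )
    def test_threshold_clause(self, pident, qend, accepted):
        got = fill_hole_filter([self._hit(pident=pident, qend=qend)])
        assert (got == [("q1", "s1")]) is accepted

    def test_best_hit_clause_is_exclusive_boundary(self):
        # best hit, coverage 60, identity 95 -> accepted via the best-hit clause
        assert fill_hole_filter([self._hit(pident=95.0, qend=60)]) == [("q1", "s1")]
        # boundary values fail the strict clause
        assert fill_hole_filter([self._hit(pident=90.0, qend=60)]) == []
        assert fill_hole_filter([self._hit(pident=95.0, qend=50)]) == []

    def test_non_best_hit_cannot_use_best_hit_clause(self):
        best = self._hit(s="best", pident=60.0, qend=90, bitscore=200.0)  # fails both
        second = self._hit(s="second", pident=95.0, qend=60, bitscore=100.0)
        assert fill_hole_filter([best, second]) == []

    def test_at_most_one_acceptance_per_query(self):
        h1 = self._hit(s="s1", bitscore=200.0)
        h2 = self._hit(s="s2", bitscore=100.0)
        assert fill_hole_filter([h2, h1]) == [("q1", "s1")]


class TestEditsAndReplay:
    def test_lipase_style_edit_updates_reaction_and_logs_two_actions(self):
        pgdb = mk_pgdb({"P1": ["r_lipase"]}, {"r_lipase": None})
        pgdb.reactions["r_lipase"] = pgdb.reactions["r_lipase"].__class__(
            reaction_id="r_lipase", ec="3.1.1.34", rxn_type="enzymatic",
            gene_ids=frozenset(),
        )
        edits = [
            {"action": "edit_reaction_ec", "target_id": "r_lipase",
             "old_value": "3.1.1.34", "new_value": "3.1.1.79", "reason": "manual"},
            {"action": "fill_hole", "target_id": "r_lipase",
             "new_value": "LIPE", "reason": "ortholog_found"},
        ]
        curated, actions = apply_edits(pgdb, edits)
        assert len(actions) == 2
        assert curated.reactions["r_lipase"].ec == "3.1.1.79"
        assert curated.reactions["r_lipase"].gene_ids == {"LIPE"}

    def test_empty_edit_list_is_identity(self):
        pgdb = mk_pgdb({"P1": ["r1"]}, {"r1": ["g"]})
        curated, actions = apply_edits(pgdb, [])
        assert actions == [] and curated.pathways == pgdb.pathways

    def test_delete_then_readd_leaves_one_copy_and_two_actions(self):
        pgdb = mk_pgdb({"P1": ["r1"]}, {"r1": ["g"]})
        edits = [
            {"action": "delete_pathway", "target_id": "P1", "reason": "manual"},
            {"action": "add_pathway", "target_id": "P1",
             "new_value": "demo;mammal;literature;r1", "reason": "manual"},
        ]
        curated, actions = apply_edits(pgdb, edits)
        assert len(actions) == 2
        assert list(curated.pathways) == ["P1"]

    def test_edit_referencing_missing_id_is_error(self):
        pgdb = mk_pgdb({"P1": ["r1"]}, {"r1": ["g"]})
        with pytest.raises(ValueError, match="unknown reaction"):
            apply_edits(pgdb, [{"action": "fill_hole", "target_id": "nope", "new_value": "G"}])

    def test_filling_a_shared_hole_decreases_totals_by_occurrences(self, toy_pgdb):
        before = hole_report(toy_pgdb).total_holes
        curated, _ = apply_edits(
            toy_pgdb, [{"action": "fill_hole", "target_id": "r2", "new_value": "GX"}]
        )
        # r2 is a hole in both P1 and P2
        assert hole_report(curated).total_holes == before - 2

    def test_action_log_replay_reproduces_curated_pgdb(self):
        from amalgam.fixtures import PGDBPlan, gen_toy_pgdb

        pgdb, _ = gen_toy_pgdb(
            PGDBPlan(hole_buckets={1: 2, 2: 1}, n_no_hole_plain=4,
                     n_redundant=1, n_non_mammal=1, n_no_evidence=1), seed=13,
        )
        curated, actions = apply_deletion_rules(pgdb)
        hole = next(rid for rid in curated.reactions if curated.is_hole(rid))
        curated, edit_actions = apply_edits(
            curated, [{"action": "fill_hole", "target_id": hole, "new_value": "GN"}]
        )
        replayed = replay_actions(pgdb, actions + edit_actions)
        assert replayed.pathways == curated.pathways
        assert replayed.reactions == curated.reactions
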