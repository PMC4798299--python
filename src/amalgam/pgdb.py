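"""Pathway-genome-database (PGDB) model, hole accounting and mechanical curation.

A PGDB links an organism's genes to enzymes, reactions and pathways. After an
automated reconstruction, an enzymatic reaction inside a pathway that has no
organism-specific gene assigned is a *pathway hole*. This module provides:

* hole accounting — per-pathway hole counts, the 0/1/2/3/4/>4 distribution,
  and holes as a percentage of reaction occurrences across pathways;
* comparison of two PGDBs (pathways only in one, the other, or shared), with
  caller-supplied reason tags;
* mechanical deletion rules mirroring standard manual-curation practice:
  R1 structurally redundant pathways (reaction multiset contained in another
  pathway's), R2 pathways whose input/output metabolite does not occur in the
  taxon of interest (caller-flagged — compounds are not chemically modelled),
  R3 pathways without enzyme-activity or homolog evidence when an alternative
  pathway (sharing at least one reaction) survives;
* a BLAST-threshold filter for hole filling, and a small edit language
  (fill hole, change a reaction's EC, add/delete pathway) with a complete,
  replayable action log.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .io import BlastHit, best_hit_order

RXN_TYPES = ("enzymatic", "spontaneous", "transport")
TAXON_RANGES = ("mammal", "non_mammal", "unknown")
EVIDENCE_KINDS = ("literature", "homolog", "none")


@dataclass(frozen=True)
class Reaction:
    reaction_id: str
    ec: str = ""
    rxn_type: str = "enzymatic"
    gene_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.rxn_type not in RXN_TYPES:
            raise ValueError(f"{self.reaction_id}: bad rxn_type {self.rxn_type!r}")


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str = ""
    taxon_range: str = "unknown"
    reaction_ids: tuple[str, ...] = ()
    evidence: str = "none"

    def __post_init__(self) -> None:
        if self.taxon_range not in TAXON_RANGES:
            raise ValueError(f"{self.pathway_id}: bad taxon_range {self.taxon_range!r}")
        if self.evidence not in EVIDENCE_KINDS:
            raise ValueError(f"{self.pathway_id}: bad evidence {self.evidence!r}")
        if not self.reaction_ids:
            raise ValueError(f"{self.pathway_id}: pathway must list at least one reaction")


@dataclass
class PGDB:
    pathways: dict[str, Pathway]
    reactions: dict[str, Reaction]

    def validate(self) -> None:
        for pw in self.pathways.values():
            for rid in pw.reaction_ids:
                if rid not in self.reactions:
                    raise ValueError(
                        f"pathway {pw.pathway_id!r} references missing reaction {rid!r}"
                    )

    def copy(self) -> "PGDB":
        return PGDB(pathways=dict(self.pathways), reactions=dict(self.reactions))

    def is_hole(self, reaction_id: str) -> bool:
        r = self.reactions[reaction_id]
        return r.rxn_type == "enzymatic" and not r.gene_ids


# ---------------------------------------------------------------------------
# hole accounting

DIST_BUCKETS = (0, 1, 2, 3, 4, "gt4")


@dataclass
class HoleReport:
    holes_per_pathway: dict[str, int]
    total_holes: int
    total_reactions_in_pathways: int
    pct_holes: float
    distribution: dict[object, int]  # keys 0,1,2,3,4,"gt4"
    pathways_with_holes: int


def hole_report(pgdb: PGDB) -> HoleReport:
    """Count pathway holes per (pathway, reaction) occurrence.

    A hole is an enzymatic reaction with no gene assigned, counted once per
    pathway containing it — a reaction shared by two pathways contributes an
    occurrence (and possibly a hole) to each. ``pct_holes`` is holes as a
    percentage of all reaction occurrences across pathways.
    """
    pgdb.validate()
    holes_per_pathway: dict[str, int] = {}
    total_occ = 0
    for pw in pgdb.pathways.values():
        total_occ += len(pw.reaction_ids)
        holes_per_pathway[pw.pathway_id] = sum(
            1 for rid in pw.reaction_ids if pgdb.is_hole(rid)
        )
    total_holes = sum(holes_per_pathway.values())
    dist = {b: 0 for b in DIST_BUCKETS}
    for n in holes_per_pathway.values():
        dist[n if n <= 4 else "gt4"] += 1
    return HoleReport(
        holes_per_pathway=holes_per_pathway,
        total_holes=total_holes,
        total_reactions_in_pathways=total_occ,
        pct_holes=100.0 * total_holes / total_occ if total_occ else 0.0,
        distribution=dist,
        pathways_with_holes=len(pgdb.pathways) - dist[0],
    )


# ---------------------------------------------------------------------------
# PGDB comparison


@dataclass
class ComparisonReport:
    only_in_a: frozenset[str]
    only_in_b: frozenset[str]
    shared: frozenset[str]
    reasons: dict[str, str]

    def reason_histogram(self) -> dict[str, int]:
        return dict(Counter(self.reasons.values()))


def compare_pgdbs(
    a: PGDB,
    b: PGDB,
    id_map: Mapping[str, str] | Iterable[tuple[str, str]] | None = None,
    reasons: Mapping[str, str] | None = None,
) -> ComparisonReport:
    """Partition the union of pathway ids into only-in-A / only-in-B / shared.

    ``id_map`` aligns B's pathway ids onto A's namespace (identity by
    default); mapping the same source id to two different targets is an error.
    ``reasons`` attaches caller-supplied annotation tags by pathway id.
    """
    mapping: dict[str, str] = {}
    if id_map is not None:
        items = id_map.items() if isinstance(id_map, Mapping) else id_map
        for src, dst in items:
            if src in mapping and mapping[src] != dst:
                raise ValueError(f"id_map maps {src!r} to both {mapping[src]!r} and {dst!r}")
            mapping[src] = dst
    a_ids = frozenset(a.pathways)
    b_ids = frozenset(mapping.get(p, p) for p in b.pathways)
    report = ComparisonReport(
        only_in_a=a_ids - b_ids,
        only_in_b=b_ids - a_ids,
        shared=a_ids & b_ids,
        reasons=dict(reasons or {}),
    )
    return report


# ---------------------------------------------------------------------------
# curation: deletion rules, BLAST filter, edits, action log

ACTION_KINDS = ("delete_pathway", "fill_hole", "edit_reaction_ec", "add_pathway")
REASON_KINDS = (
    "redundant",
    "non_mammal_metabolite",
    "no_evidence_with_alternative",
    "ortholog_found",
    "manual",
)


@dataclass(frozen=True)
class CurationAction:
    """One logged PGDB mutation; ``payload`` carries what replay needs."""

    action: str
    target_id: str
    reason: str
    detail: str = ""
    payload: tuple = ()

    def __post_init__(self) -> None:
        if self.action not in ACTION_KINDS:
            raise ValueError(f"bad action {self.action!r}")
        if self.reason not in REASON_KINDS:
            raise ValueError(f"bad reason {self.reason!r}")


def apply_deletion_rules(
    pgdb: PGDB, metabolite_taxon_flags: Iterable[str] = ()
) -> tuple[PGDB, list[CurationAction]]:
    """Apply the three mechanical deletion rules; every deletion is logged.

    R1: a pathway whose reaction multiset is contained in another pathway's is
    redundant and deleted (the superset survives; exact duplicates keep the
    lexicographically smaller id). R2: pathways flagged as having a
    non-mammalian input/output metabolite (or annotated ``non_mammal``) are
    deleted. R3: a pathway with no enzyme-activity or homolog evidence is
    deleted when a surviving pathway shares at least one reaction with it.
    Running the rules on their own output yields no further actions.
    """
    flags = set(metabolite_taxon_flags)
    actions: list[CurationAction] = []
    alive = dict(pgdb.pathways)

    # R1 — structural redundancy
    multisets = {pid: Counter(pw.reaction_ids) for pid, pw in alive.items()}
    for pid in sorted(alive):
        ms = multisets[pid]
        for qid, qms in multisets.items():
            if qid == pid:
                continue
            if ms == qms:
                if pid > qid:
                    break  # exact duplicate: larger id goes
            elif all(qms[r] >= n for r, n in ms.items()):
                break  # proper containment: subset goes
        else:
            continue
        actions.append(
            CurationAction("delete_pathway", pid, "redundant", f"contained in {qid}")
        )
        del alive[pid]

    # R2 — non-mammalian metabolite (caller-flagged or annotated)
    for pid in sorted(alive):
        if pid in flags or alive[pid].taxon_range == "non_mammal":
            actions.append(CurationAction("delete_pathway", pid, "non_mammal_metabolite"))
            del alive[pid]

    # R3 — no evidence, alternative pathway survives
    reaction_sets = {pid: set(pw.reaction_ids) for pid, pw in alive.items()}
    for pid in sorted(alive):
        if alive[pid].evidence != "none":
            continue
        mine = reaction_sets[pid]
        alt = next(
            (qid for qid in alive if qid != pid and reaction_sets[qid] & mine), None
        )
        if alt is not None:
            actions.append(
                CurationAction(
                    "delete_pathway", pid, "no_evidence_with_alternative", f"alternative {alt}"
                )
            )
            del alive[pid]

    return PGDB(pathways=alive, reactions=dict(pgdb.reactions)), actions


def fill_hole_filter(hits: Sequence[BlastHit]) -> list[tuple[str, str]]:
    """Accept at most one (query, subject) ortholog assignment per query.

    A hit passes if coverage >= 80 and identity >= 70 (the annotation-pipeline
    thresholds), or if it is the query's best hit with coverage > 50 and
    identity > 90. Coverage is ``100*(qend-qstart+1)/qlen``. The accepted hit
    per query is its best-ranked passing hit.
    """
    ordered = best_hit_order(hits)
    accepted: dict[str, str] = {}
    best_seen: set[str] = set()
    for h in ordered:
        is_best = h.qseqid not in best_seen
        best_seen.add(h.qseqid)
        if h.qseqid in accepted:
            continue
        clause1 = h.coverage >= 80.0 and h.pident >= 70.0
        clause2 = is_best and h.coverage > 50.0 and h.pident > 90.0
        if clause1 or clause2:
            accepted[h.qseqid] = h.sseqid
    return sorted(accepted.items())


def apply_edits(pgdb: PGDB, edits: Sequence[Mapping]) -> tuple[PGDB, list[CurationAction]]:
    """Apply a curation edit list (from :func:`amalgam.io.read_edits`), logging actions.

    Supported actions: ``fill_hole`` (set a reaction's gene_ids),
    ``edit_reaction_ec``, ``add_pathway`` (new_value =
    ``name;taxon_range;evidence;rid1|rid2``), ``delete_pathway``.
    """
    out = pgdb.copy()
    actions: list[CurationAction] = []
    for e in edits:
        action, target = e["action"], e["target_id"]
        reason = e.get("reason") or "manual"
        if action == "fill_hole":
            if target not in out.reactions:
                raise ValueError(f"fill_hole: unknown reaction {target!r}")
            genes = frozenset(g for g in str(e["new_value"]).split("|") if g)
            out.reactions[target] = replace(out.reactions[target], gene_ids=genes)
            actions.append(
                CurationAction("fill_hole", target, reason, e.get("detail", ""),
                               payload=tuple(sorted(genes)))
            )
        elif action == "edit_reaction_ec":
            if target not in out.reactions:
                raise ValueError(f"edit_reaction_ec: unknown reaction {target!r}")
            old = out.reactions[target].ec
            if e.get("old_value") and e["old_value"] != old:
                raise ValueError(
                    f"edit_reaction_ec {target!r}: recorded old EC {e['old_value']!r} "
                    f"!= current {old!r}"
                )
            out.reactions[target] = replace(out.reactions[target], ec=e["new_value"])
            actions.append(
                CurationAction("edit_reaction_ec", target, reason,
                               f"{old} -> {e['new_value']}", payload=(e["new_value"],))
            )
        elif action == "add_pathway":
            name, taxon, evidence, rids = str(e["new_value"]).split(";")
            pw = Pathway(
                pathway_id=target,
                name=name,
                taxon_range=taxon,
                reaction_ids=tuple(r for r in rids.split("|") if r),
                evidence=evidence,
            )
            for rid in pw.reaction_ids:
                if rid not in out.reactions:
                    raise ValueError(f"add_pathway {target!r}: unknown reaction {rid!r}")
            out.pathways[target] = pw
            actions.append(
                CurationAction("add_pathway", target, reason,
                               payload=(name, taxon, evidence, pw.reaction_ids))
            )
        elif action == "delete_pathway":
            if target not in out.pathways:
                raise ValueError(f"delete_pathway: unknown pathway {target!r}")
            del out.pathways[target]
            actions.append(CurationAction("delete_pathway", target, reason))
        else:
            raise ValueError(f"unknown edit action {action!r}")
    return out, actions


def replay_actions(pgdb: PGDB, actions: Sequence[CurationAction]) -> PGDB:
    """Re-apply a logged action list to the original PGDB.

    Replaying the full log of a curation run on the uncurated PGDB reproduces
    the curated PGDB exactly.
    """
    out = pgdb.copy()
    for act in actions:
        if act.action == "delete_pathway":
            out.pathways.pop(act.target_id, None)
        elif act.action == "fill_hole":
            out.reactions[act.target_id] = replace(
                out.reactions[act.target_id], gene_ids=frozenset(act.payload)
            )
        elif act.action == "edit_reaction_ec":
            out.reactions[act.target_id] = replace(
                out.reactions[act.target_id], ec=act.payload[0]
            )
        elif act.action == "add_pathway":
            name, taxon, evidence, rids = act.payload
            out.pathways[act.target_id] = Pathway(
                pathway_id=act.target_id, name=name, taxon_range=taxon,
                reaction_ids=tuple(rids), evidence=evidence,
            )
    return out
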