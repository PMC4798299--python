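"""Seeded synthetic-data generators with planted ground truth.

Every input format the toolkit consumes can be generated here with a known
answer key, so the matcher, the PGDB curation rules and the duplication
screen are all testable end to end without downloading any public resource.

Design of the virtual genome: 30 chromosomes of 10 Mb (echoing a cattle-like
29 autosomes + X karyotype), partitioned into fixed 3 kb slots. Each gene is
placed inside one slot with a small jitter, so genes in different slots can
never overlap — planted consensus pairs share a slot (hence overlap), decoys
never cross-match. Attribute values are unique per gene except for the single
attribute a planted pair is meant to match on, which makes the planted
criterion label identifiable. All generation is integer-based off one
``random.Random(seed)``, so identical plan + seed gives byte-identical files.

``DUPLICATED_GENE_EXAMPLES`` carries the worked example used throughout the
documentation: eight cattle genes, each with two genomic copies, evidence
flag vectors and pathway annotations, from which the screen recovers the
published rank histogram (B:2, C:5, D:1) and mechanism calls.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .duplication import EvidenceFlags, GeneCopy
from .io import GeneRecord, OrthologyRow
from .matching import MatchCriterion
from .pgdb import PGDB, Pathway, Reaction

N_CHROMS = 30
CHROM_LEN = 10_000_000
SLOT = 3_000
SLOTS_PER_CHROM = CHROM_LEN // SLOT
CHROM_NAMES = [str(i) for i in range(1, N_CHROMS)] + ["X"]


# ---------------------------------------------------------------------------
# annotation pair


@dataclass
class AnnotationPlan:
    """What to plant in a two-source annotation fixture.

    ``consensus`` maps each criterion to the number of pairs matchable *only*
    by that criterion. ``discrepancies`` are exact counts of planted pairs
    whose B-side disagrees on biotype, strand, or both.
    """

    consensus: dict[MatchCriterion, int] = field(default_factory=dict)
    n_only_a: int = 0
    n_only_b: int = 0
    n_scaffold: int = 0
    discrepancies: dict[str, int] = field(
        default_factory=lambda: {"biotype": 0, "strand": 0, "both": 0}
    )

    @property
    def n_pairs(self) -> int:
        return sum(self.consensus.values())

    def validate(self) -> None:
        if any(n < 0 for n in self.consensus.values()):
            raise ValueError("consensus counts must be >= 0")
        if MatchCriterion.MANUAL in self.consensus:
            raise ValueError("MANUAL pairs cannot be planted as matchable")
        if sum(self.discrepancies.values()) > self.n_pairs:
            raise ValueError("more discrepancies requested than planted pairs")
        need = self.n_pairs + self.n_only_a + self.n_only_b
        if need > N_CHROMS * SLOTS_PER_CHROM:
            raise ValueError(f"plan needs {need} loci; virtual genome has fewer slots")


@dataclass
class AnnotationTruth:
    pairs: list[tuple[str, str, MatchCriterion]]
    category_counts: dict[str, int]
    discrepancy_counts: dict[str, int]


def _slot_locus(slot: int, rng: random.Random) -> tuple[str, int, int]:
    chrom = CHROM_NAMES[slot // SLOTS_PER_CHROM]
    base = (slot % SLOTS_PER_CHROM) * SLOT
    start = base + 1 + rng.randrange(0, 500)
    end = start + rng.randrange(800, 2000)
    return chrom, start, end


def gen_annotation_pair(
    plan: AnnotationPlan, seed: int
) -> tuple[list[GeneRecord], list[GeneRecord], list[GeneRecord], AnnotationTruth]:
    """Generate (set_a, set_b, scaffold_set, truth) for the matcher."""
    plan.validate()
    rng = random.Random(seed)
    slots = rng.sample(range(N_CHROMS * SLOTS_PER_CHROM), plan.n_pairs + plan.n_only_a + plan.n_only_b)
    slot_iter = iter(slots)

    set_a: list[GeneRecord] = []
    set_b: list[GeneRecord] = []
    truth_pairs: list[tuple[str, str, MatchCriterion]] = []

    # discrepancy assignment: first biotype-count pairs, then strand, then both
    d = plan.discrepancies
    disc_seq = ["biotype"] * d.get("biotype", 0) + ["strand"] * d.get("strand", 0) + [
        "both"
    ] * d.get("both", 0)

    uid = 0
    pair_no = 0
    for criterion in sorted(plan.consensus):
        for _ in range(plan.consensus[criterion]):
            u = f"{uid:06d}"
            uid += 1
            chrom, start, end = _slot_locus(next(slot_iter), rng)
            a_kw = dict(
                chrom=chrom, start=start, end=end, strand="+", biotype="protein_coding",
                name=f"a.name.{u}", synonyms=frozenset({f"a.syn.{u}"}),
                function_name=f"a func {u}", unigene_ids=frozenset({f"a.ug.{u}"}),
                xref_ids=frozenset({f"dba:a{u}"}), protein_accs=frozenset({f"a_p{u}"}),
                ec_numbers=frozenset({f"7.7.7.{u}"}),
            )
            shift = 0 if criterion is MatchCriterion.COORD_EXACT else 101
            b_kw = dict(
                chrom=chrom, start=start + shift, end=end + shift, strand="+",
                biotype="protein_coding",
                name=f"b.name.{u}", synonyms=frozenset({f"b.syn.{u}"}),
                function_name=f"b func {u}", unigene_ids=frozenset({f"b.ug.{u}"}),
                xref_ids=frozenset({f"dbb:b{u}"}), protein_accs=frozenset({f"b_p{u}"}),
                ec_numbers=frozenset({f"8.8.8.{u}"}),
            )
            if criterion is MatchCriterion.NAME_OR_SYNONYM:
                a_kw["name"] = f"gene{u}"
                b_kw["synonyms"] = frozenset({f"GENE{u}"})  # case-fold on match
            elif criterion is MatchCriterion.FUNCTION_NAME:
                a_kw["function_name"] = b_kw["function_name"] = f"shared function {u}"
            elif criterion is MatchCriterion.UNIGENE:
                a_kw["unigene_ids"] = b_kw["unigene_ids"] = frozenset({f"bt.{u}"})
            elif criterion is MatchCriterion.XREF:
                a_kw["xref_ids"] = b_kw["xref_ids"] = frozenset({f"kegg:{u}"})
            elif criterion is MatchCriterion.PROTEIN_ACC:
                a_kw["protein_accs"] = b_kw["protein_accs"] = frozenset({f"np_{u}"})
            elif criterion is MatchCriterion.EC:
                a_kw["ec_numbers"] = b_kw["ec_numbers"] = frozenset({f"1.1.1.{u}"})

            if pair_no < len(disc_seq):
                kind = disc_seq[pair_no]
                if kind in ("biotype", "both"):
                    b_kw["biotype"] = "pseudogene"
                if kind in ("strand", "both"):
                    b_kw["strand"] = "-"
            pair_no += 1

            a_id, b_id = f"A{u}", f"B{u}"
            set_a.append(GeneRecord(gene_id=a_id, source="ncbi", **a_kw))
            set_b.append(GeneRecord(gene_id=b_id, source="ensembl", **b_kw))
            truth_pairs.append((a_id, b_id, criterion))

    for _ in range(plan.n_only_a):
        u = f"{uid:06d}"
        uid += 1
        chrom, start, end = _slot_locus(next(slot_iter), rng)
        set_a.append(
            GeneRecord(
                gene_id=f"A{u}", source="ncbi", chrom=chrom, start=start, end=end,
                strand="+", biotype="protein_coding", name=f"a.only.{u}",
            )
        )
    for _ in range(plan.n_only_b):
        u = f"{uid:06d}"
        uid += 1
        chrom, start, end = _slot_locus(next(slot_iter), rng)
        set_b.append(
            GeneRecord(
                gene_id=f"B{u}", source="ensembl", chrom=chrom, start=start, end=end,
                strand="+", biotype="protein_coding", name=f"b.only.{u}",
            )
        )
    scaffolds = []
    for i in range(plan.n_scaffold):
        u = f"{uid:06d}"
        uid += 1
        scaffolds.append(
            GeneRecord(
                gene_id=f"S{u}", source="scaffold", chrom=f"ScafK{i}", start=1,
                end=1 + rng.randrange(500, 1500), strand="unknown",
                biotype="protein_coding", name=f"scaf.{u}",
            )
        )

    rng.shuffle(set_a)
    rng.shuffle(set_b)
    truth = AnnotationTruth(
        pairs=truth_pairs,
        category_counts={
            "consensus": plan.n_pairs,
            "a_only": plan.n_only_a,
            "b_only": plan.n_only_b,
            "scaffold": plan.n_scaffold,
        },
        discrepancy_counts={
            "biotype_only": d.get("biotype", 0),
            "strand_only": d.get("strand", 0),
            "both": d.get("both", 0),
            "total": sum(d.values()),
        },
    )
    return set_a, set_b, scaffolds, truth


# ---------------------------------------------------------------------------
# toy PGDB


@dataclass
class PGDBPlan:
    """Hole distribution and rule-triggering pathways to plant.

    ``hole_buckets`` maps holes-per-pathway (1..4) to pathway counts;
    ``gt4_hole_counts`` lists hole counts (each >= 5) for the ``>4`` bucket.
    Rule-trigger pathways (redundant / non-mammal / no-evidence) are hole-free
    and count toward the no-hole bucket together with ``n_no_hole_plain``.
    ``total_reaction_occurrences``, when set, pads no-hole pathways with
    assigned filler reactions until reaction occurrences across pathways reach
    that total (fixing the hole percentage).
    """

    hole_buckets: dict[int, int] = field(default_factory=dict)
    gt4_hole_counts: tuple[int, ...] = ()
    n_no_hole_plain: int = 0
    n_redundant: int = 0
    n_non_mammal: int = 0
    n_no_evidence: int = 0
    total_reaction_occurrences: int | None = None

    def validate(self) -> None:
        if any(k not in (1, 2, 3, 4) for k in self.hole_buckets):
            raise ValueError("hole_buckets keys must be 1..4")
        if any(h < 5 for h in self.gt4_hole_counts):
            raise ValueError("gt4 pathways must have >= 5 holes")
        if self.n_no_hole_plain < self.n_redundant + self.n_no_evidence:
            raise ValueError(
                "need at least n_redundant + n_no_evidence plain pathways to host "
                "the planted rule triggers"
            )


@dataclass
class PGDBTruth:
    total_holes: int
    pathways_with_holes: int
    n_pathways: int
    distribution: dict[object, int]
    total_reaction_occurrences: int
    deletions: list[tuple[str, str]]  # (pathway_id, reason)


def gen_toy_pgdb(plan: PGDBPlan, seed: int) -> tuple[PGDB, PGDBTruth]:
    """Generate a PGDB with a planted hole distribution and rule firings."""
    plan.validate()
    rng = random.Random(seed)
    reactions: dict[str, Reaction] = {}
    pathways: dict[str, Pathway] = {}
    rid_n = 0
    gid_n = 0

    def new_rxn(assigned: bool, ec: str = "") -> str:
        nonlocal rid_n, gid_n
        rid_n += 1
        rid = f"R{rid_n:05d}"
        genes: frozenset[str] = frozenset()
        if assigned:
            gid_n += 1
            genes = frozenset({f"G{gid_n:05d}"})
        reactions[rid] = Reaction(reaction_id=rid, ec=ec or f"1.1.1.{rid_n}",
                                  rxn_type="enzymatic", gene_ids=genes)
        return rid

    pw_n = 0

    def add_pathway(rids: Sequence[str], taxon="mammal", evidence="homolog") -> str:
        nonlocal pw_n
        pw_n += 1
        pid = f"P{pw_n:04d}"
        pathways[pid] = Pathway(
            pathway_id=pid, name=f"pathway {pw_n}", taxon_range=taxon,
            reaction_ids=tuple(rids), evidence=evidence,
        )
        return pid

    occurrences = 0
    # holed pathways
    hole_counts = []
    for k in sorted(plan.hole_buckets):
        hole_counts += [k] * plan.hole_buckets[k]
    hole_counts += list(plan.gt4_hole_counts)
    for k in hole_counts:
        add_pathway([new_rxn(assigned=False) for _ in range(k)])
        occurrences += k

    # plain no-hole pathways; the first ones host the planted rule triggers
    plain_ids = []
    for _ in range(plan.n_no_hole_plain):
        plain_ids.append(add_pathway([new_rxn(assigned=True)]))
        occurrences += 1

    deletions: list[tuple[str, str]] = []
    for i in range(plan.n_redundant):
        host = plain_ids[i]
        extra = new_rxn(assigned=True)
        hostpw = pathways[host]
        pathways[host] = Pathway(
            pathway_id=host, name=hostpw.name, taxon_range=hostpw.taxon_range,
            reaction_ids=hostpw.reaction_ids + (extra,), evidence=hostpw.evidence,
        )
        occurrences += 1
        red = add_pathway([extra])  # proper subset of its host
        occurrences += 1
        deletions.append((red, "redundant"))

    for i in range(plan.n_no_evidence):
        host = plain_ids[plan.n_redundant + i]
        shared = new_rxn(assigned=True)
        hostpw = pathways[host]
        pathways[host] = Pathway(
            pathway_id=host, name=hostpw.name, taxon_range=hostpw.taxon_range,
            reaction_ids=hostpw.reaction_ids + (shared,), evidence=hostpw.evidence,
        )
        occurrences += 1
        own = new_rxn(assigned=True)
        noev = add_pathway([shared, own], evidence="none")
        occurrences += 2
        deletions.append((noev, "no_evidence_with_alternative"))

    for _ in range(plan.n_non_mammal):
        nm = add_pathway([new_rxn(assigned=True)], taxon="non_mammal")
        occurrences += 1
        deletions.append((nm, "non_mammal_metabolite"))

    # filler reactions to reach the requested occurrence total
    if plan.total_reaction_occurrences is not None:
        if plan.total_reaction_occurrences < occurrences:
            raise ValueError(
                f"total_reaction_occurrences {plan.total_reaction_occurrences} below "
                f"construction minimum {occurrences}"
            )
        targets = plain_ids or list(pathways)
        i = 0
        while occurrences < plan.total_reaction_occurrences:
            pid = targets[i % len(targets)]
            pw = pathways[pid]
            pathways[pid] = Pathway(
                pathway_id=pid, name=pw.name, taxon_range=pw.taxon_range,
                reaction_ids=pw.reaction_ids + (new_rxn(assigned=True),),
                evidence=pw.evidence,
            )
            occurrences += 1
            i += 1

    total_holes = sum(hole_counts)
    n_no_hole = plan.n_no_hole_plain + plan.n_redundant + plan.n_non_mammal + plan.n_no_evidence
    dist: dict[object, int] = {0: n_no_hole, 1: 0, 2: 0, 3: 0, 4: 0, "gt4": 0}
    for k in hole_counts:
        dist[k if k <= 4 else "gt4"] += 1
    truth = PGDBTruth(
        total_holes=total_holes,
        pathways_with_holes=len(hole_counts),
        n_pathways=len(pathways),
        distribution=dist,
        total_reaction_occurrences=occurrences,
        deletions=sorted(deletions),
    )
    return PGDB(pathways=pathways, reactions=reactions), truth


# ---------------------------------------------------------------------------
# orthology / duplication fixture

#: Worked example: eight duplicated cattle metabolic genes, two copies each,
#: with their printed coordinates, pathway annotations and evidence vectors.
#: Flags: (has_est, has_expression); assembly_complete is False for all (a
#: scaffold-gap possibility could not be excluded for any of them, which is
#: why no gene reaches rank A). The second BPGM copy is intronless with a
#: poly-A signal (a retrogene).
DUPLICATED_GENE_EXAMPLES: list[dict] = [
    dict(symbol="AANAT", est=True, expr=False,
         description="Arylalkylamine N-acetyltransferase",
         pathways="Serotonin and melatonin biosynthesis",
         copies=[("19", 55904213, 55905449, 7, False), ("19", 55917031, 55918872, 7, False)]),
    dict(symbol="ACOT4", est=True, expr=False,
         description="Acyl-CoA thioesterase 4",
         pathways="Acetyl-CoA hydrolysis, oleate biosynthesis II (animals)",
         copies=[("10", 85431609, 85435220, 3, False), ("10", 85375286, 85380537, 3, False)]),
    dict(symbol="ADK", est=True, expr=False,
         description="Adenosine kinase",
         pathways="Adenine and adenosine salvage VI",
         copies=[("15", 35836626, 35837711, 5, False), ("28", 30215525, 30732466, 5, False)]),
    dict(symbol="BPGM", est=False, expr=False,
         description="2,3-biphosphoglycerate mutase",
         pathways="Glycolysis/gluconeogenesis, Rapoport-Luebering glycolytic shunt",
         copies=[("4", 99223160, 99254542, 3, False), ("10", 78463269, 78464048, 1, True)]),
    dict(symbol="HEXB", est=True, expr=True,
         description="Hexosaminidase B",
         pathways="chondroitin sulfate degradation (metazoa), dermatan sulfate degradation (metazoa)",
         copies=[("20", 6721327, 6753670, 14, False), ("20", 6760133, 6794235, 14, False)]),
    dict(symbol="GSTO1", est=True, expr=True,
         description="Glutathione S-transferase omega 1",
         pathways="Arsenate detoxification I (glutaredoxin), glutathione-mediated detoxification",
         copies=[("26", 25060114, 25074160, 6, False), ("26", 25088448, 25097722, 6, False)]),
    dict(symbol="NDUFB4", est=True, expr=False,
         description="NADH hydrogenase (ubiquinone) 1 beta subcomplex, 4",
         pathways="Aerobic respiration (cytochrome c)",
         copies=[("1", 65922482, 65928620, 3, False), ("21", 13421643, 13422116, 3, False)]),
    dict(symbol="SOD1", est=True, expr=False,
         description="Superoxide dismutase 1, soluble",
         pathways="Superoxide radicals degradation",
         copies=[("1", 3113948, 3122613, 5, False), ("13", 51930067, 51930888, 5, False)]),
]


@dataclass
class OrthologyPlan:
    """Planted duplicates plus decoy anchors exercising every rejection branch."""

    planted: list[dict] = field(default_factory=lambda: list(DUPLICATED_GENE_EXAMPLES))
    n_decoy_anchors: int = 0
    n_nonmetabolic_duplicates: int = 0
    target_species: str = "cattle"
    anchor_species: str = "human"
    partner_species: str = "mouse"


@dataclass
class OrthologyTruth:
    candidate_anchors: list[str]
    ranks: dict[str, str]
    mechanisms: dict[str, str]
    rank_histogram: dict[str, int]
    n_candidates: int
    n_metabolic: int


def gen_orthology_fixture(
    plan: OrthologyPlan, seed: int
) -> tuple[
    list[OrthologyRow],
    dict[str, EvidenceFlags],
    dict[str, GeneCopy],
    frozenset[str],
    OrthologyTruth,
]:
    """Generate (orthology rows, flags by anchor, copy info, metabolic ids, truth)."""
    from .duplication import classify_mechanism, rank_evidence

    rng = random.Random(seed)
    rows: list[OrthologyRow] = []
    flags: dict[str, EvidenceFlags] = {}
    copy_info: dict[str, GeneCopy] = {}
    metabolic: set[str] = set()
    ranks: dict[str, str] = {}
    mechanisms: dict[str, str] = {}
    anchors: list[str] = []

    hs, mm, bt = plan.anchor_species, plan.partner_species, plan.target_species

    def plant_duplicate(entry: Mapping, metabolic_gene: bool) -> None:
        sym = entry["symbol"]
        anchor, partner = f"HS_{sym}", f"MM_{sym}"
        rows.append(OrthologyRow(anchor, hs, mm, partner, "ortholog_one2one"))
        rows.append(OrthologyRow(partner, mm, hs, anchor, "ortholog_one2one"))
        copies = []
        for i, (chrom, start, end, exons, polya) in enumerate(entry["copies"], start=1):
            cid = f"BT_{sym}_{i}"
            copies.append(
                GeneCopy(gene_id=cid, chrom=chrom, start=start, end=end,
                         exon_count=exons, has_polya_signal=polya)
            )
            copy_info[cid] = copies[-1]
            rows.append(OrthologyRow(anchor, hs, bt, cid, "ortholog_one2many"))
            rows.append(OrthologyRow(partner, mm, bt, cid, "ortholog_one2many"))
        fl = EvidenceFlags(
            has_nt_chain=True, has_est=entry["est"], has_expression=entry["expr"],
            assembly_complete=False,
        )
        flags[anchor] = fl
        if metabolic_gene:
            metabolic.add(anchor)
        anchors.append(anchor)
        ranks[anchor] = rank_evidence(fl)
        mechanisms[anchor] = classify_mechanism(copies)

    for entry in plan.planted:
        plant_duplicate(entry, metabolic_gene=True)

    for j in range(plan.n_nonmetabolic_duplicates):
        chrom = CHROM_NAMES[rng.randrange(len(CHROM_NAMES))]
        s1 = rng.randrange(1, CHROM_LEN // 2)
        entry = dict(
            symbol=f"NM{j:03d}", est=True, expr=True,
            copies=[(chrom, s1, s1 + 999, 4, False),
                    (chrom, s1 + 5000, s1 + 5999, 4, False)],
        )
        plant_duplicate(entry, metabolic_gene=False)

    # decoys: each violates exactly one screen condition
    for j in range(plan.n_decoy_anchors):
        kind = j % 4
        a, p = f"HS_D{j:04d}", f"MM_D{j:04d}"
        c1, c2 = f"BT_D{j:04d}_1", f"BT_D{j:04d}_2"
        if kind == 0:  # single-copy in the target
            rows.append(OrthologyRow(a, hs, mm, p, "ortholog_one2one"))
            rows.append(OrthologyRow(a, hs, bt, c1, "ortholog_one2one"))
            rows.append(OrthologyRow(p, mm, bt, c1, "ortholog_one2one"))
        elif kind == 1:  # many2many, not a clean duplication signature
            rows.append(OrthologyRow(a, hs, mm, p, "ortholog_one2one"))
            rows.append(OrthologyRow(a, hs, bt, c1, "ortholog_many2many"))
            rows.append(OrthologyRow(a, hs, bt, c2, "ortholog_many2many"))
        elif kind == 2:  # partner does not independently show the duplication
            rows.append(OrthologyRow(a, hs, mm, p, "ortholog_one2one"))
            rows.append(OrthologyRow(a, hs, bt, c1, "ortholog_one2many"))
            rows.append(OrthologyRow(a, hs, bt, c2, "ortholog_one2many"))
            rows.append(OrthologyRow(p, mm, bt, c1, "ortholog_one2one"))
        else:  # non-protein-coding anchor
            rows.append(OrthologyRow(a, hs, mm, p, "ortholog_one2one", "pseudogene"))
            rows.append(OrthologyRow(a, hs, bt, c1, "ortholog_one2many", "pseudogene"))
            rows.append(OrthologyRow(a, hs, bt, c2, "ortholog_one2many", "pseudogene"))
            rows.append(OrthologyRow(p, mm, bt, c1, "ortholog_one2many"))
            rows.append(OrthologyRow(p, mm, bt, c2, "ortholog_one2many"))

    rng.shuffle(rows)
    from collections import Counter

    hist = Counter(ranks[a] for a in anchors if a in metabolic)
    truth = OrthologyTruth(
        candidate_anchors=sorted(anchors),
        ranks=ranks,
        mechanisms=mechanisms,
        rank_histogram={r: hist.get(r, 0) for r in "ABCD"},
        n_candidates=len(anchors),
        n_metabolic=len(metabolic),
    )
    return rows, flags, copy_info, frozenset(metabolic), truth
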