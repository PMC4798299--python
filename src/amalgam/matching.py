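"""Sequential multi-criterion one-to-one matching of two gene-annotation sets.

Two independently produced annotation sets for the same assembly (for example
an NCBI-based and an Ensembl-based build) are reconciled by a sequential
matcher. Only gene pairs that share chromosomal location (partial or complete
overlap) are ever compared; among overlapping pairs, seven criteria are tried
in a fixed order of decreasing strictness:

1. exactly the same gene coordinates (strand and biotype deliberately ignored),
2. common gene name or synonym,
3. common function name,
4. common UniGene identifier,
5. common cross-referenced gene identifier,
6. common protein accession,
7. identical EC number (wildcard EC strings match only themselves).

Each pass commits one-to-one matches greedily; both partners of a committed
pair leave the candidate pool, so every gene appears in at most one pair.
The matcher reports two count columns per criterion: *sequential* (pairs
committed in that pass) and *non-exclusive* (all overlapping cross-pairs
satisfying the criterion, regardless of matching state).

Matched sets are then merged into an amalgamated database whose genes carry a
provenance category: consensus (matched pair), only-in-A, only-in-B, or
scaffold (genes on unplaced scaffolds, added verbatim).
"""
from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .io import GeneRecord, norm


class MatchCriterion(enum.IntEnum):
    """Ordered matching criteria; lower ordinal = tried first."""

    COORD_EXACT = 1
    NAME_OR_SYNONYM = 2
    FUNCTION_NAME = 3
    UNIGENE = 4
    XREF = 5
    PROTEIN_ACC = 6
    EC = 7
    MANUAL = 8  # curated pairs applied after the automatic passes

    @property
    def label(self) -> str:
        return _LABELS[self]


_LABELS = {
    MatchCriterion.COORD_EXACT: "Gene coordinates",
    MatchCriterion.NAME_OR_SYNONYM: "Gene name",
    MatchCriterion.FUNCTION_NAME: "Function name",
    MatchCriterion.UNIGENE: "Unigene ID",
    MatchCriterion.XREF: "Cross-reference gene ID",
    MatchCriterion.PROTEIN_ACC: "Protein accessions",
    MatchCriterion.EC: "EC numbers",
    MatchCriterion.MANUAL: "Manually matched",
}

AUTO_CRITERIA = tuple(c for c in MatchCriterion if c is not MatchCriterion.MANUAL)

DISCREPANCY_KINDS = ("none", "biotype", "strand", "both")


def loci_overlap(a: GeneRecord, b: GeneRecord) -> bool:
    """True iff same chromosome and the 1-based inclusive intervals share >= 1 bp."""
    if not (a.has_locus and b.has_locus):
        return False
    return a.chrom == b.chrom and a.start <= b.end and b.start <= a.end


def criterion_holds(a: GeneRecord, b: GeneRecord, criterion: MatchCriterion) -> bool:
    """Whether one criterion holds for an (already overlapping) pair."""
    if criterion is MatchCriterion.COORD_EXACT:
        return a.chrom == b.chrom and a.start == b.start and a.end == b.end
    if criterion is MatchCriterion.NAME_OR_SYNONYM:
        return bool(a.name_set() & b.name_set())
    if criterion is MatchCriterion.FUNCTION_NAME:
        fa, fb = norm(a.function_name), norm(b.function_name)
        return bool(fa) and fa == fb
    if criterion is MatchCriterion.UNIGENE:
        return bool(a.unigene_ids & b.unigene_ids)
    if criterion is MatchCriterion.XREF:
        return bool(a.xref_ids & b.xref_ids)
    if criterion is MatchCriterion.PROTEIN_ACC:
        return bool(a.protein_accs & b.protein_accs)
    if criterion is MatchCriterion.EC:
        # exact string equality; wildcard ECs like "3.1.1.-" match only themselves
        return bool(a.ec_numbers & b.ec_numbers)
    raise ValueError(f"criterion {criterion} is never evaluated automatically")


def match_criterion(a: GeneRecord, b: GeneRecord) -> MatchCriterion | None:
    """Lowest-ordinal satisfied criterion for an overlapping pair, or None."""
    for c in AUTO_CRITERIA:
        if criterion_holds(a, b, c):
            return c
    return None


def _discrepancy(a: GeneRecord, b: GeneRecord) -> str:
    biotype = norm(a.biotype) != norm(b.biotype)
    strand = a.strand in "+-" and b.strand in "+-" and a.strand != b.strand
    if biotype and strand:
        return "both"
    if biotype:
        return "biotype"
    if strand:
        return "strand"
    return "none"


@dataclass(frozen=True)
class GenePair:
    a_id: str
    b_id: str
    criterion: MatchCriterion
    discrepancy: str = "none"

    def __post_init__(self) -> None:
        if self.discrepancy not in DISCREPANCY_KINDS:
            raise ValueError(f"bad discrepancy {self.discrepancy!r}")


@dataclass
class MatchSet:
    """Result of the sequential matcher over two annotation sets."""

    pairs: list[GenePair]
    unmatched_a: frozenset[str]
    unmatched_b: frozenset[str]
    per_criterion_sequential: dict[MatchCriterion, int]
    per_criterion_nonexclusive: dict[MatchCriterion, int]

    def validate(self) -> None:
        a_ids = [p.a_id for p in self.pairs]
        b_ids = [p.b_id for p in self.pairs]
        if len(set(a_ids)) != len(a_ids) or len(set(b_ids)) != len(b_ids):
            raise AssertionError("one-to-one violated: a gene occurs in two pairs")
        if sum(self.per_criterion_sequential.values()) != len(self.pairs):
            raise AssertionError("sequential counts do not sum to pair count")
        if set(a_ids) & set(self.unmatched_a) or set(b_ids) & set(self.unmatched_b):
            raise AssertionError("matched gene listed as unmatched")


def _overlap_candidates(
    set_a: Sequence[GeneRecord], set_b: Sequence[GeneRecord]
) -> list[tuple[GeneRecord, GeneRecord, float]]:
    """All cross-pairs with overlapping loci, with their reciprocal-overlap fraction."""
    trees: dict[str, IntervalTree] = {}
    for a in set_a:
        if a.has_locus:
            trees.setdefault(a.chrom, IntervalTree()).addi(a.start, a.end + 1, a)
    out = []
    for b in set_b:
        if not b.has_locus or b.chrom not in trees:
            continue
        for iv in trees[b.chrom].overlap(b.start, b.end + 1):
            a = iv.data
            ov = min(a.end, b.end) - max(a.start, b.start) + 1
            recip = min(ov / a.length, ov / b.length)
            out.append((a, b, recip))
    return out


def sequential_match(
    set_a: Sequence[GeneRecord],
    set_b: Sequence[GeneRecord],
    manual_pairs: Iterable[tuple[str, str]] = (),
) -> MatchSet:
    """Run the seven sequential passes and return the committed one-to-one pairs.

    Within a pass, candidate pairs satisfying the criterion are committed in
    order of larger reciprocal overlap fraction, ties broken by
    lexicographically smaller ``(a_id, b_id)`` — a content-based rule, so the
    result is invariant to input row order. ``manual_pairs`` are applied after
    pass 7, bypassing the criteria but not the one-to-one constraint.
    """
    by_a = {a.gene_id: a for a in set_a}
    by_b = {b.gene_id: b for b in set_b}
    if len(by_a) != len(set_a):
        raise ValueError("duplicate gene_id in set A")
    if len(by_b) != len(set_b):
        raise ValueError("duplicate gene_id in set B")

    candidates = _overlap_candidates(set_a, set_b)

    nonexclusive: Counter = Counter()
    for a, b, _ in candidates:
        for c in AUTO_CRITERIA:
            if criterion_holds(a, b, c):
                nonexclusive[c] += 1

    matched_a: set[str] = set()
    matched_b: set[str] = set()
    pairs: list[GenePair] = []
    sequential: Counter = Counter()

    for c in AUTO_CRITERIA:
        eligible = [
            (-recip, a.gene_id, b.gene_id, a, b)
            for a, b, recip in candidates
            if a.gene_id not in matched_a
            and b.gene_id not in matched_b
            and criterion_holds(a, b, c)
        ]
        eligible.sort(key=lambda t: t[:3])
        for _, a_id, b_id, a, b in eligible:
            if a_id in matched_a or b_id in matched_b:
                continue
            matched_a.add(a_id)
            matched_b.add(b_id)
            pairs.append(GenePair(a_id, b_id, c, _discrepancy(a, b)))
            sequential[c] += 1

    for a_id, b_id in manual_pairs:
        if a_id not in by_a or b_id not in by_b:
            raise ValueError(f"manual pair ({a_id!r}, {b_id!r}) references unknown gene")
        if a_id in matched_a or b_id in matched_b:
            raise ValueError(
                f"manual pair ({a_id!r}, {b_id!r}) conflicts with an existing match"
            )
        matched_a.add(a_id)
        matched_b.add(b_id)
        pairs.append(
            GenePair(a_id, b_id, MatchCriterion.MANUAL, _discrepancy(by_a[a_id], by_b[b_id]))
        )
        sequential[MatchCriterion.MANUAL] += 1

    ms = MatchSet(
        pairs=pairs,
        unmatched_a=frozenset(by_a) - matched_a,
        unmatched_b=frozenset(by_b) - matched_b,
        per_criterion_sequential={c: sequential.get(c, 0) for c in MatchCriterion},
        per_criterion_nonexclusive={c: nonexclusive.get(c, 0) for c in AUTO_CRITERIA},
    )
    ms.validate()
    return ms


def discrepancy_report(match_set: MatchSet) -> dict[str, int]:
    """Count consensus pairs whose sources disagree on biotype, strand, or both."""
    n = Counter(p.discrepancy for p in match_set.pairs)
    out = {
        "biotype_only": n.get("biotype", 0),
        "strand_only": n.get("strand", 0),
        "both": n.get("both", 0),
    }
    out["total"] = sum(out.values())
    return out


# ---------------------------------------------------------------------------
# amalgamation

CATEGORIES = ("consensus", "a_only", "b_only", "scaffold")


@dataclass(frozen=True)
class MergedGene:
    category: str
    record: GeneRecord
    a_id: str | None = None
    b_id: str | None = None


@dataclass
class AmalgamatedDB:
    genes: list[MergedGene]

    @property
    def counts(self) -> dict[str, int]:
        c = Counter(g.category for g in self.genes)
        return {k: c.get(k, 0) for k in CATEGORIES}

    @property
    def total(self) -> int:
        return len(self.genes)


def _merge_pair(a: GeneRecord, b: GeneRecord) -> GeneRecord:
    """Merge a consensus pair: A's coordinates win, identifier sets are unioned."""
    return GeneRecord(
        gene_id=a.gene_id,
        source="consensus",
        chrom=a.chrom if a.has_locus else b.chrom,
        start=a.start if a.has_locus else b.start,
        end=a.end if a.has_locus else b.end,
        strand=a.strand if a.strand in "+-" else b.strand,
        biotype=a.biotype or b.biotype,
        name=a.name or b.name,
        synonyms=a.name_set() | b.name_set(),
        function_name=a.function_name or b.function_name,
        unigene_ids=a.unigene_ids | b.unigene_ids,
        xref_ids=a.xref_ids | b.xref_ids,
        protein_accs=a.protein_accs | b.protein_accs,
        ec_numbers=a.ec_numbers | b.ec_numbers,
    )


def amalgamate(
    match_set: MatchSet,
    set_a: Sequence[GeneRecord],
    set_b: Sequence[GeneRecord],
    scaffold_set: Sequence[GeneRecord] = (),
) -> AmalgamatedDB:
    """Merge matched sets into one database with provenance categories.

    Total genes = consensus pairs + unmatched A + unmatched B + scaffold genes.
    """
    by_a = {a.gene_id: a for a in set_a}
    by_b = {b.gene_id: b for b in set_b}
    matched_ids = {p.a_id for p in match_set.pairs} | {p.b_id for p in match_set.pairs}

    genes: list[MergedGene] = []
    for p in match_set.pairs:
        genes.append(
            MergedGene("consensus", _merge_pair(by_a[p.a_id], by_b[p.b_id]), p.a_id, p.b_id)
        )
    for gid in sorted(match_set.unmatched_a):
        genes.append(MergedGene("a_only", by_a[gid], a_id=gid))
    for gid in sorted(match_set.unmatched_b):
        genes.append(MergedGene("b_only", by_b[gid], b_id=gid))
    for rec in scaffold_set:
        if rec.gene_id in matched_ids:
            raise ValueError(f"scaffold gene id {rec.gene_id!r} collides with a matched gene")
        genes.append(MergedGene("scaffold", rec))
    return AmalgamatedDB(genes=genes)
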