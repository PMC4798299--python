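"""Screen for lineage-specific duplicated metabolic genes from orthology tables.

The screen looks for genes that are single-copy in two reference genomes
(human and mouse, linked one-to-one to each other) but present in multiple
copies in the target genome (e.g. cattle): a human protein-coding anchor with
a one-to-one mouse ortholog and a one-to-many target relation, where the
paired mouse gene independently shows the same one-to-many target relation.
Copies are enumerated from the one-to-many rows.

Candidates are then

* ranked A-D by evidence strength (nucleotide chain, EST, expression
  evidence, assembly completeness);
* classified by duplication mechanism: retrotransposition (an intronless copy
  bearing a poly-A signal), segmental duplication (same chromosome, copies
  within the typical 1-200 kb duplicated-block size), or chromosomal
  rearrangement (copies on different chromosomes);
* given a synteny call per copy: a copy whose flanking-gene orthologs sit
  adjacent in a reference genome with no ortholog of the gene between them is
  an *inserted* (derived) copy; one whose ortholog lies between the conserved
  flanks is *ancestral*.
"""
from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import OrthologyRow, norm

log = logging.getLogger(__name__)

RANKS = ("A", "B", "C", "D")
MECHANISMS = ("segmental", "rearrangement", "retrotransposition", "unknown")
SYNTENY_STATUSES = ("ancestral", "inserted", "indeterminate")

#: typical upper bound of a duplicated genomic block, in bp
SEGMENTAL_MAX_GAP = 200_000


@dataclass(frozen=True)
class GeneCopy:
    """One target-genome copy of a duplicated gene."""

    gene_id: str
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    exon_count: int | None = None
    has_polya_signal: bool | None = None
    near_assembly_gap: bool | None = None

    def __post_init__(self) -> None:
        if self.start is not None and self.end is not None and self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")

    @property
    def has_locus(self) -> bool:
        return self.chrom is not None and self.start is not None and self.end is not None


@dataclass(frozen=True)
class EvidenceFlags:
    has_nt_chain: bool
    has_est: bool
    has_expression: bool  # mRNA or protein evidence
    assembly_complete: bool  # no scaffold-gap possibility


@dataclass
class DuplicationCandidate:
    anchor_gene_id: str
    anchor_partner_id: str
    copies: list[GeneCopy]
    is_metabolic: bool = False
    pathways: frozenset[str] = field(default_factory=frozenset)
    flags: EvidenceFlags | None = None
    rank: str | None = None
    mechanism: str | None = None

    def __post_init__(self) -> None:
        if len(self.copies) < 2:
            raise ValueError(
                f"{self.anchor_gene_id}: a duplication candidate needs >= 2 copies"
            )


@dataclass(frozen=True)
class SyntenyCall:
    copy_id: str
    status: str
    evidence: tuple[tuple[str, str], ...] = ()  # (reference species, verdict)

    def __post_init__(self) -> None:
        if self.status not in SYNTENY_STATUSES:
            raise ValueError(f"bad synteny status {self.status!r}")


def screen_candidates(
    orthology_rows: Sequence[OrthologyRow],
    metabolic_gene_ids: Iterable[str],
    target_species: str = "cattle",
    anchor_species: str = "human",
    partner_species: str = "mouse",
    copy_info: Mapping[str, GeneCopy] | None = None,
) -> list[DuplicationCandidate]:
    """Emit duplication candidates from a three-species orthology table.

    A candidate requires: protein-coding anchor with exactly one one-to-one
    ``partner_species`` ortholog, one-to-many ``target_species`` orthologs
    (>= 2 copies), and the partner gene independently one-to-many to the
    target (the intersection of the two anchored lists). Non-metabolic
    candidates are retained but flagged. ``copy_info`` supplies coordinates
    and structural flags per target gene id when available.
    """
    metabolic = {norm(g) for g in metabolic_gene_ids}
    copy_info = copy_info or {}

    one2one: dict[str, list[str]] = defaultdict(list)  # anchor -> partner genes
    one2many: dict[tuple[str, str], list[str]] = defaultdict(list)
    for r in orthology_rows:
        if r.target_species == partner_species and r.anchor_species == anchor_species:
            if r.homology_type == "ortholog_one2one":
                one2one[r.anchor_gene_id].append(r.target_gene_id)
        if r.target_species == target_species:
            if r.homology_type == "ortholog_one2many":
                one2many[(r.anchor_species, r.anchor_gene_id)].append(r.target_gene_id)

    anchor_rows = {
        r.anchor_gene_id: r
        for r in orthology_rows
        if r.anchor_species == anchor_species and r.target_species == partner_species
    }

    candidates = []
    for anchor in sorted(one2one):
        partners = one2one[anchor]
        if len(partners) > 1:
            raise ValueError(
                f"anchor {anchor!r} has {len(partners)} one2one {partner_species} "
                "partners; orthology table malformed"
            )
        row = anchor_rows.get(anchor)
        if row is not None and row.anchor_biotype != "protein_coding":
            continue
        copies = sorted(set(one2many.get((anchor_species, anchor), ())))
        if len(copies) < 2:
            continue
        partner = partners[0]
        if not one2many.get((partner_species, partner)):
            continue  # the paired gene must independently show the duplication
        copy_objs = [copy_info.get(c, GeneCopy(gene_id=c)) for c in copies]
        is_metabolic = norm(anchor) in metabolic or any(
            norm(c) in metabolic for c in copies
        )
        candidates.append(
            DuplicationCandidate(
                anchor_gene_id=anchor,
                anchor_partner_id=partner,
                copies=copy_objs,
                is_metabolic=is_metabolic,
            )
        )
    return candidates


def rank_evidence(flags: EvidenceFlags) -> str:
    """Tier the duplication evidence from A (strongest) to D.

    A: EST + expression evidence + complete assembly; B: EST + expression but
    a possible assembly error; C: exactly one of EST/expression; D: neither.
    Assembly completeness only separates A from B — the combination of partial
    evidence with a complete assembly is not tiered separately and maps to
    C/D with a logged warning. Candidates without nucleotide-chain support
    must be rejected upstream.
    """
    if not flags.has_nt_chain:
        raise ValueError("rank_evidence requires has_nt_chain (reject upstream)")
    n_partial = int(flags.has_est) + int(flags.has_expression)
    if n_partial == 2:
        return "A" if flags.assembly_complete else "B"
    if flags.assembly_complete:
        log.warning(
            "evidence grid gap: partial evidence with complete assembly; "
            "mapping to %s", "C" if n_partial == 1 else "D",
        )
    return "C" if n_partial == 1 else "D"


def _gap(a: GeneCopy, b: GeneCopy) -> int:
    """Distance in bp between two same-chromosome copies (0 if they overlap)."""
    lo, hi = (a, b) if a.start <= b.start else (b, a)
    return max(0, hi.start - lo.end - 1)


def classify_mechanism(
    copies: Sequence[GeneCopy], max_segmental_gap: int = SEGMENTAL_MAX_GAP
) -> str:
    """Call the duplication mechanism from copy structure and placement.

    An intronless copy bearing a poly-A signal is a retrogene
    (retrotransposition) regardless of placement. Otherwise, copies on one
    chromosome within the typical duplicated-block size are a segmental
    duplication; copies on different chromosomes indicate chromosomal
    rearrangement.
    """
    if len(copies) < 2:
        raise ValueError("classify_mechanism needs >= 2 copies")
    if any(c.exon_count == 1 and c.has_polya_signal for c in copies):
        return "retrotransposition"
    if not all(c.has_locus for c in copies):
        return "unknown"
    chroms = {c.chrom for c in copies}
    if len(chroms) == 1:
        max_gap = max(
            _gap(a, b) for i, a in enumerate(copies) for b in copies[i + 1 :]
        )
        return "segmental" if max_gap <= max_segmental_gap else "unknown"
    return "rearrangement"


def synteny_check(
    copy: GeneCopy | str,
    flank_genes_up: Sequence[str],
    flank_genes_down: Sequence[str],
    reference_region_orders: Mapping[str, Sequence[str]],
    candidate_ortholog_id: str | None = None,
) -> SyntenyCall:
    """Call a copy ancestral or inserted from flanking-gene conservation.

    For each reference species an ordered gene list of the orthologous region
    is given. If the copy's up- and down-flank orthologs bracket the
    candidate's ortholog, that reference supports *ancestral*; if they are
    adjacent with no candidate ortholog between, it supports *inserted*.
    A reference missing the flank orthologs abstains. The call is unanimous
    or *indeterminate*.
    """
    copy_id = copy.gene_id if isinstance(copy, GeneCopy) else copy
    cand = norm(candidate_ortholog_id or copy_id)
    up = [norm(g) for g in flank_genes_up]
    down = [norm(g) for g in flank_genes_down]

    verdicts: list[tuple[str, str]] = []
    for species in sorted(reference_region_orders):
        order = [norm(g) for g in reference_region_orders[species]]
        pos = {g: i for i, g in enumerate(order)}
        up_pos = [pos[g] for g in up if g in pos]
        down_pos = [pos[g] for g in down if g in pos]
        if not up_pos or not down_pos:
            verdicts.append((species, "abstain"))
            continue
        # innermost flank hits bracket the examined segment; the reference may
        # list the region in either orientation
        if max(up_pos) < min(down_pos):
            lo, hi = max(up_pos), min(down_pos)
        elif max(down_pos) < min(up_pos):
            lo, hi = max(down_pos), min(up_pos)
        else:
            verdicts.append((species, "abstain"))  # interleaved flanks: no bracket
            continue
        between = order[lo + 1 : hi]
        verdicts.append((species, "ancestral" if cand in between else "inserted"))

    votes = {v for _, v in verdicts if v != "abstain"}
    if votes == {"inserted"}:
        status = "inserted"
    elif votes == {"ancestral"}:
        status = "ancestral"
    else:
        status = "indeterminate"
    return SyntenyCall(copy_id=copy_id, status=status, evidence=tuple(verdicts))


@dataclass
class CandidateSummary:
    n_genes: int
    pathways: frozenset[str]
    rank_histogram: dict[str, int]
    mechanism_histogram: dict[str, int]

    @property
    def n_pathways(self) -> int:
        return len(self.pathways)


def normalize_pathway_entries(entries: Iterable[str]) -> frozenset[str]:
    """Split comma-separated pathway strings and normalise each entry."""
    out = set()
    for entry in entries:
        for part in entry.split(","):
            p = norm(part)
            if p:
                out.add(p)
    return frozenset(out)


def summarize_candidates(candidates: Sequence[DuplicationCandidate]) -> CandidateSummary:
    """Gene count, distinct pathway set, and rank/mechanism histograms."""
    pathways = normalize_pathway_entries(
        p for c in candidates for p in c.pathways
    )
    ranks = Counter(c.rank for c in candidates if c.rank)
    mechs = Counter(c.mechanism for c in candidates if c.mechanism)
    return CandidateSummary(
        n_genes=len(candidates),
        pathways=pathways,
        rank_histogram={r: ranks.get(r, 0) for r in RANKS},
        mechanism_histogram={m: mechs.get(m, 0) for m in MECHANISMS},
    )
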