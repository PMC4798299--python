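"""Readers and writers for the toolkit's tabular formats.

Four dialects are handled, all plain TSV (UTF-8, tab-separated):

* gene tables — one annotated gene per row, multi-valued fields ``|``-separated;
* orthology tables — Biomart-style homology rows;
* BLAST tabular — the standard 12 columns plus ``qlen`` (13 columns, no header);
* simplified PGDB flat files — ``pathways.tsv`` + ``reactions.tsv``.

Coordinates are 1-based inclusive throughout (GFF3 input already uses this
convention; the printed coordinates of public annotation tables fix it for the
gene-table dialect). String matching elsewhere in the toolkit relies on the
normalisation applied here: case-fold, strip, collapse internal whitespace.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

log = logging.getLogger(__name__)

_WS = re.compile(r"\s+")

#: closed vocabulary of Biomart-style homology types
HOMOLOGY_TYPES = frozenset(
    {"ortholog_one2one", "ortholog_one2many", "ortholog_many2many", "none"}
)

GENE_TABLE_COLUMNS = [
    "gene_id",
    "source",
    "chrom",
    "start",
    "end",
    "strand",
    "biotype",
    "name",
    "synonyms",
    "function_name",
    "unigene_ids",
    "xref_ids",
    "protein_accs",
    "ec_numbers",
]

ORTHOLOGY_COLUMNS = [
    "anchor_gene_id",
    "anchor_species",
    "target_species",
    "target_gene_id",
    "homology_type",
    "anchor_biotype",
]

BLAST_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "align_len",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
    "qlen",
]


def norm(s: str) -> str:
    """Normalise a string for matching: strip, collapse whitespace, case-fold."""
    return _WS.sub(" ", s.strip()).casefold()


def norm_set(values: Iterable[str]) -> frozenset[str]:
    """Normalise and deduplicate a multi-valued field, dropping empties."""
    out = {norm(v) for v in values}
    out.discard("")
    return frozenset(out)


def split_multi(cell: str) -> frozenset[str]:
    """Split a ``|``-separated cell into a normalised set (empty cell = absent)."""
    if not cell:
        return frozenset()
    return norm_set(cell.split("|"))


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene from one source database.

    ``chrom``/``start``/``end`` may all be ``None`` for entries without a
    placed locus (some scaffold genes); such records never enter the
    overlap-gated matcher.
    """

    gene_id: str
    source: str
    chrom: str | None
    start: int | None
    end: int | None
    strand: str = "unknown"  # "+", "-", "unknown"
    biotype: str = ""
    name: str = ""
    synonyms: frozenset[str] = field(default_factory=frozenset)
    function_name: str = ""
    unigene_ids: frozenset[str] = field(default_factory=frozenset)
    xref_ids: frozenset[str] = field(default_factory=frozenset)
    protein_accs: frozenset[str] = field(default_factory=frozenset)
    ec_numbers: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        # set fields are stored normalized and deduplicated, however constructed
        for f in ("synonyms", "unigene_ids", "xref_ids", "protein_accs", "ec_numbers"):
            object.__setattr__(self, f, norm_set(getattr(self, f)))
        if (self.start is None) != (self.end is None):
            raise ValueError(f"{self.gene_id}: start/end must both be set or both absent")
        if self.start is not None:
            if self.start < 1:
                raise ValueError(f"{self.gene_id}: start must be >= 1 (got {self.start})")
            if self.start > self.end:  # type: ignore[operator]
                raise ValueError(
                    f"{self.gene_id}: start ({self.start}) > end ({self.end})"
                )

    @property
    def has_locus(self) -> bool:
        return bool(self.chrom) and self.start is not None

    @property
    def length(self) -> int:
        if not self.has_locus:
            raise ValueError(f"{self.gene_id} has no locus")
        return self.end - self.start + 1  # type: ignore[operator]

    def name_set(self) -> frozenset[str]:
        """Normalised gene name plus synonyms (the name-criterion match set)."""
        return norm_set([self.name]) | self.synonyms


@dataclass(frozen=True)
class OrthologyRow:
    anchor_gene_id: str
    anchor_species: str
    target_species: str
    target_gene_id: str
    homology_type: str
    anchor_biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.homology_type not in HOMOLOGY_TYPES:
            raise ValueError(
                f"unknown homology_type {self.homology_type!r} "
                f"(expected one of {sorted(HOMOLOGY_TYPES)})"
            )


@dataclass(frozen=True)
class BlastHit:
    qseqid: str
    sseqid: str
    pident: float
    align_len: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    qlen: int

    def __post_init__(self) -> None:
        if not (1 <= self.qstart <= self.qend <= self.qlen):
            raise ValueError(
                f"{self.qseqid}->{self.sseqid}: require 1 <= qstart <= qend <= qlen, "
                f"got {self.qstart}, {self.qend}, {self.qlen}"
            )
        if not (0.0 <= self.pident <= 100.0):
            raise ValueError(f"pident out of range: {self.pident}")

    @property
    def coverage(self) -> float:
        """Query coverage as a percentage: 100*(qend-qstart+1)/qlen."""
        return 100.0 * (self.qend - self.qstart + 1) / self.qlen


# ---------------------------------------------------------------------------
# gene tables


def _parse_coord(cell: str, what: str, lineno: int) -> int | None:
    if cell == "":
        return None
    try:
        return int(cell)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: bad {what} {cell!r}") from exc


def read_gene_table(path: str | Path, source_label: str | None = None) -> list[GeneRecord]:
    """Read a gene-table TSV into :class:`GeneRecord` rows, preserving file order.

    ``source_label``, if given, overrides the file's ``source`` column.
    Duplicate ``gene_id`` within a file is a hard error naming both lines;
    unknown strand symbols are mapped to ``unknown`` with a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != GENE_TABLE_COLUMNS:
        raise ValueError(
            f"{path}: bad gene-table header {list(df.columns)!r}, "
            f"expected {GENE_TABLE_COLUMNS!r}"
        )
    records: list[GeneRecord] = []
    seen: dict[str, int] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        lineno = i + 2  # header is line 1
        gid = row.gene_id
        if gid in seen:
            raise ValueError(
                f"{path}: duplicate gene_id {gid!r} on lines {seen[gid]} and {lineno}"
            )
        seen[gid] = lineno
        strand = row.strand
        if strand not in ("+", "-", "unknown"):
            log.warning("%s line %d: unknown strand %r mapped to 'unknown'", path, lineno, strand)
            strand = "unknown"
        try:
            rec = GeneRecord(
                gene_id=gid,
                source=source_label or row.source,
                chrom=row.chrom or None,
                start=_parse_coord(row.start, "start", lineno),
                end=_parse_coord(row.end, "end", lineno),
                strand=strand,
                biotype=row.biotype,
                name=row.name,
                synonyms=split_multi(row.synonyms),
                function_name=row.function_name,
                unigene_ids=split_multi(row.unigene_ids),
                xref_ids=split_multi(row.xref_ids),
                protein_accs=split_multi(row.protein_accs),
                ec_numbers=split_multi(row.ec_numbers),
            )
        except ValueError as exc:
            raise ValueError(f"{path} line {lineno}: {exc}") from exc
        records.append(rec)
    return records


def write_gene_table(records: Sequence[GeneRecord], path: str | Path) -> None:
    """Write records in canonical form (sorted set fields, fixed column order)."""
    rows = []
    for r in records:
        rows.append(
            {
                "gene_id": r.gene_id,
                "source": r.source,
                "chrom": r.chrom or "",
                "start": "" if r.start is None else r.start,
                "end": "" if r.end is None else r.end,
                "strand": r.strand,
                "biotype": r.biotype,
                "name": r.name,
                "synonyms": "|".join(sorted(r.synonyms)),
                "function_name": r.function_name,
                "unigene_ids": "|".join(sorted(r.unigene_ids)),
                "xref_ids": "|".join(sorted(r.xref_ids)),
                "protein_accs": "|".join(sorted(r.protein_accs)),
                "ec_numbers": "|".join(sorted(r.ec_numbers)),
            }
        )
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gff3_genes(path: str | Path, source_label: str) -> list[GeneRecord]:
    """Map GFF3 ``gene`` features into :class:`GeneRecord` (ID/Name/Alias/biotype).

    GFF3 is already 1-based inclusive, so coordinates carry over unchanged.
    """
    import gffutils.iterators

    records = []
    for feat in gffutils.iterators.DataIterator(str(path)):
        if feat.featuretype != "gene":
            continue
        attrs = feat.attributes
        gid = (attrs.get("ID") or [None])[0]
        if gid is None:
            raise ValueError(f"{path}: gene feature without ID at {feat.seqid}:{feat.start}")
        biotype = (attrs.get("biotype") or attrs.get("gene_biotype") or [""])[0]
        records.append(
            GeneRecord(
                gene_id=gid,
                source=source_label,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "unknown",
                biotype=biotype,
                name=(attrs.get("Name") or [""])[0],
                synonyms=norm_set(attrs.get("Alias") or []),
            )
        )
    return records


# ---------------------------------------------------------------------------
# orthology tables


def read_orthology_table(path: str | Path) -> list[OrthologyRow]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != ORTHOLOGY_COLUMNS:
        raise ValueError(
            f"{path}: bad orthology header {list(df.columns)!r}, expected {ORTHOLOGY_COLUMNS!r}"
        )
    rows = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            rows.append(OrthologyRow(*row))
        except ValueError as exc:
            raise ValueError(f"{path} line {i + 2}: {exc}") from exc
    return rows


def write_orthology_table(rows: Sequence[OrthologyRow], path: str | Path) -> None:
    pd.DataFrame(
        [
            (r.anchor_gene_id, r.anchor_species, r.target_species,
             r.target_gene_id, r.homology_type, r.anchor_biotype)
            for r in rows
        ],
        columns=ORTHOLOGY_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BLAST tabular


def read_blast_tab(path: str | Path) -> list[BlastHit]:
    """Read 13-column BLAST tabular output (standard 12 columns + qlen)."""
    path = Path(path)
    hits: list[BlastHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 13:
                raise ValueError(
                    f"{path} line {lineno}: expected 13 tab-separated columns, got {len(parts)}"
                )
            try:
                hits.append(
                    BlastHit(
                        qseqid=parts[0],
                        sseqid=parts[1],
                        pident=float(parts[2]),
                        align_len=int(parts[3]),
                        mismatch=int(parts[4]),
                        gapopen=int(parts[5]),
                        qstart=int(parts[6]),
                        qend=int(parts[7]),
                        sstart=int(parts[8]),
                        send=int(parts[9]),
                        evalue=float(parts[10]),
                        bitscore=float(parts[11]),
                        qlen=int(parts[12]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from exc
    return hits


def best_hit_order(hits: Sequence[BlastHit]) -> list[BlastHit]:
    """Sort hits so the first line per query is its best hit.

    Best = highest bitscore, tie broken by lower e-value, then input order.
    The sort is stable across the whole list so per-query slices keep this
    ordering too.
    """
    return [
        h
        for _, h in sorted(
            enumerate(hits), key=lambda ih: (ih[1].qseqid, -ih[1].bitscore, ih[1].evalue, ih[0])
        )
    ]


# ---------------------------------------------------------------------------
# simplified PGDB flat files


def read_pgdb(where: str | Path | tuple[str | Path, str | Path]):
    """Read a PGDB from a directory holding ``pathways.tsv`` + ``reactions.tsv``
    (or an explicit ``(pathways_path, reactions_path)`` pair)."""
    from .pgdb import PGDB, Pathway, Reaction

    if isinstance(where, tuple):
        ppath, rpath = Path(where[0]), Path(where[1])
    else:
        d = Path(where)
        ppath, rpath = d / "pathways.tsv", d / "reactions.tsv"
    for p in (ppath, rpath):
        if not p.exists():
            raise FileNotFoundError(p)

    rdf = pd.read_csv(rpath, sep="\t", dtype=str, keep_default_na=False)
    reactions = {}
    for row in rdf.itertuples(index=False):
        rxn = Reaction(
            reaction_id=row.reaction_id,
            ec=row.ec,
            rxn_type=row.rxn_type,
            gene_ids=frozenset(g for g in row.gene_ids.split("|") if g),
        )
        if rxn.reaction_id in reactions:
            raise ValueError(f"{rpath}: duplicate reaction_id {rxn.reaction_id!r}")
        reactions[rxn.reaction_id] = rxn

    pdf = pd.read_csv(ppath, sep="\t", dtype=str, keep_default_na=False)
    pathways = {}
    for row in pdf.itertuples(index=False):
        pw = Pathway(
            pathway_id=row.pathway_id,
            name=row.name,
            taxon_range=row.taxon_range,
            reaction_ids=tuple(r for r in row.reaction_ids.split("|") if r),
            evidence=row.evidence,
        )
        if pw.pathway_id in pathways:
            raise ValueError(f"{ppath}: duplicate pathway_id {pw.pathway_id!r}")
        for rid in pw.reaction_ids:
            if rid not in reactions:
                raise ValueError(
                    f"{ppath}: pathway {pw.pathway_id!r} references missing reaction {rid!r}"
                )
        pathways[pw.pathway_id] = pw
    return PGDB(pathways=pathways, reactions=reactions)


def write_pgdb(pgdb, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "pathway_id": p.pathway_id,
                "name": p.name,
                "taxon_range": p.taxon_range,
                "reaction_ids": "|".join(p.reaction_ids),
                "evidence": p.evidence,
            }
            for p in pgdb.pathways.values()
        ],
        columns=["pathway_id", "name", "taxon_range", "reaction_ids", "evidence"],
    ).to_csv(outdir / "pathways.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "reaction_id": r.reaction_id,
                "ec": r.ec,
                "rxn_type": r.rxn_type,
                "gene_ids": "|".join(sorted(r.gene_ids)),
            }
            for r in pgdb.reactions.values()
        ],
        columns=["reaction_id", "ec", "rxn_type", "gene_ids"],
    ).to_csv(outdir / "reactions.tsv", sep="\t", index=False)


EDIT_COLUMNS = ["action", "target_id", "field", "old_value", "new_value", "reason", "citation"]


def read_edits(path: str | Path) -> list[dict]:
    """Read a curation-edits TSV (action, target_id, field, old/new value, reason)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != EDIT_COLUMNS:
        raise ValueError(f"{path}: bad edits header, expected {EDIT_COLUMNS!r}")
    return df.to_dict(orient="records")
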