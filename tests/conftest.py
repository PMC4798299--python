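import pytest

from amalgam.io import GeneRecord
from amalgam.pgdb import PGDB, Pathway, Reaction


def mk_gene(gene_id, chrom="19", start=100, end=200, **kw):
    """Compact GeneRecord constructor for tests."""
    defaults = dict(source="test", strand="+", biotype="protein_coding")
    defaults.update(kw)
    return GeneRecord(gene_id=gene_id, chrom=chrom, start=start, end=end, **defaults)


def mk_pgdb(pathway_spec, reaction_spec):
    """Build a PGDB from terse specs.

    ``reaction_spec``: {rid: genes-iterable or None-for-hole} (all enzymatic),
    or {rid: (genes, rxn_type)}. ``pathway_spec``: {pid: [rids]} or
    {pid: ([rids], taxon_range, evidence)}.
    """
    reactions = {}
    for rid, spec in reaction_spec.items():
        if isinstance(spec, tuple):
            genes, rxn_type = spec
        else:
            genes, rxn_type = spec, "enzymatic"
        reactions[rid] = Reaction(
            reaction_id=rid, rxn_type=rxn_type,
            gene_ids=frozenset(genes or ()),
        )
    pathways = {}
    for pid, spec in pathway_spec.items():
        if isinstance(spec, tuple):
            rids, taxon, evidence = spec
        else:
            rids, taxon, evidence = spec, "mammal", "homolog"
        pathways[pid] = Pathway(
            pathway_id=pid, name=pid, taxon_range=taxon,
            reaction_ids=tuple(rids), evidence=evidence,
        )
    return PGDB(pathways=pathways, reactions=reactions)


@pytest.fixture
def toy_pgdb():
    """P1=(r1 assigned, r2 hole), P2=(r2 hole, r3 assigned, r4 hole)."""
    return mk_pgdb(
        {"P1": ["r1", "r2"], "P2": ["r2", "r3", "r4"]},
        {"r1": ["g1"], "r2": None, "r3": ["g3"], "r4": None},
    )
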