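# amalgam

A toolkit for building a consensus genome annotation from two independent
source databases, curating the pathway-genome database (PGDB) reconstructed
from it, and screening orthology tables for lineage-specific duplicated
metabolic genes.

## The problem

Genome-scale metabolic reconstruction needs one coherent gene catalogue, but
public annotation pipelines (e.g. an NCBI-based and an Ensembl-based build of
the same assembly) disagree on thousands of gene models — coordinates,
biotypes, even coding strand. Downstream, the automatically reconstructed
PGDB contains *pathway holes* (enzymatic reactions inside a pathway with no
organism-specific gene assigned) and false-positive pathways that demand
systematic curation. Finally, comparing orthology relations across a target
genome and two reference genomes reveals lineage-specific gene duplications
in the metabolic network. `amalgam` implements the mechanical parts of that
whole pipeline for any organism whose inputs can be expressed in its simple
TSV dialects.

## What it computes

**Sequential one-to-one matching.** Only gene pairs sharing chromosomal
location (≥ 1 bp overlap, 1-based inclusive coordinates) are compared. Seven
criteria are applied in order — identical coordinates; shared gene
name/synonym; shared function name; shared UniGene id; shared cross-reference
id; shared protein accession; identical EC number — and each pass commits
one-to-one matches greedily, retiring both partners. Matching deliberately
ignores strand and biotype disagreements, which are instead counted in a
discrepancy report. The merged database tags every gene as consensus,
source-A-only, source-B-only, or scaffold.

**Pathway-hole accounting and curation.** A hole is an enzymatic reaction
with no assigned gene, counted per (pathway, reaction) occurrence. The hole
report gives the 0/1/2/3/4/>4 holes-per-pathway distribution and holes as a
percentage of reaction occurrences. Three mechanical deletion rules mirror
standard curation practice (structural redundancy; non-mammalian
input/output metabolite; no evidence plus a surviving alternative pathway),
every mutation is logged, and the action log replays exactly. Candidate hole
fillers from BLAST are accepted when coverage ≥ 80 % and identity ≥ 70 %, or
for a query's best hit when coverage > 50 % and identity > 90 %.

**Duplication screen.** An anchor gene that is one-to-one between two
reference genomes (human/mouse) but one-to-many to the target genome — with
the partner gene independently showing the same one-to-many relation — is a
duplication candidate. Candidates are ranked A–D by evidence (EST,
expression, assembly completeness), classified as segmental duplication
(same chromosome, ≤ 200 kb apart), chromosomal rearrangement (different
chromosomes) or retrotransposition (an intronless copy with a poly-A
signal), and each copy receives a flanking-gene synteny call
(ancestral / inserted / indeterminate).

All inputs can also be *generated*: the `amalgam.fixtures` module plants
consensus pairs, pathway holes, rule-triggering pathways and duplicated
genes with a known answer key, deterministically per seed.

## Worked example

```
$ amalgam fixtures --seed 42 --out fx
$ amalgam amalgamate --a fx/genes_a.tsv --b fx/genes_b.tsv \
      --scaffolds fx/genes_scaffold.tsv --out run
consensus=20 a_only=10 b_only=10 scaffold=2 total=42
$ amalgam pgdb-holes fx/pgdb
pathways=12 holes=7 with_holes=5 pct=46.7
$ amalgam pgdb-curate fx/pgdb --out curated --log actions.tsv
actions=2 pathways=10
$ amalgam dupscreen --orthology fx/orthology.tsv \
      --metabolic-genes fx/metabolic_genes.txt \
      --flags fx/flags.tsv --copies fx/copies.tsv --out candidates.tsv
candidates=8 metabolic=8
```

The default fixture plants 20 matchable gene pairs (all recovered as
consensus, giving 42 merged genes), a 12-pathway PGDB with 7 holes in 5
pathways plus one redundant and one non-mammalian pathway (the 2 logged
deletions), and eight duplicated metabolic genes. The candidate table lists
one row per gene copy with its locus, evidence rank and mechanism call:

```
gene       copy_id     chrom  start     end       rank  mechanism
HS_AANAT   BT_AANAT_1  19     55904213  55905449  C     segmental
HS_AANAT   BT_AANAT_2  19     55917031  55918872  C     segmental
```

— the two AANAT copies sit ~11.6 kb apart on one chromosome, within the
typical 1–200 kb duplicated-block size, hence `segmental`.

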