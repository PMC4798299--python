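# Methods

This note records the models, rules and numerical choices behind `amalgam`,
and what the synthetic fixtures do and do not establish.

## Coordinate and string conventions

All coordinates are 1-based inclusive; a pair of genes overlaps when they
share a chromosome and at least one base (`a.start <= b.end and b.start <=
a.end`). GFF3 input, which already uses this convention, is mapped without
shifting. All string matching — names, synonyms, function names, identifier
sets — first normalises by stripping, collapsing internal whitespace and
case-folding. Multi-valued fields are stored as normalised, deduplicated
sets however a record is constructed, so programmatic and file-parsed
records behave identically. EC numbers are compared by exact string
equality; a wildcard class such as `3.1.1.-` matches only the identical
string, never its specialisations, because a wildcard does not attest the
specific activity.

## The sequential matcher

Matching is gated on locus overlap: genes without coordinates (some scaffold
entries) never enter the matcher and can only join the merged database via
the scaffold category. Seven criteria run as ordered passes; a pair is
committed at the first pass whose criterion it satisfies, and both partners
leave the pool, making the result one-to-one by construction. Criterion 1
(identical coordinates) deliberately ignores strand and biotype, which the
discrepancy report counts instead (biotype-only / strand-only / both; strand
counts only when both annotations commit to `+` or `-`).

Two counts are reported per criterion: *sequential* (pairs committed in that
pass) and *non-exclusive* (all overlapping cross-pairs satisfying the
criterion regardless of matching state, computed under the same overlap
gate). The non-exclusive count is by construction an upper bound of the
sequential count under these definitions.

**Tie-breaking.** When one gene could pair with several partners in the same
pass, candidates are committed in order of larger reciprocal overlap
fraction — `min(overlap/len_a, overlap/len_b)` — with ties broken by
lexicographically smaller `(a_id, b_id)`. The rule is content-based, so the
match set is invariant to input row order; this is asserted by tests.

**Manual pairs.** Curated pairs are applied after pass 7. They bypass the
criteria but not the one-to-one constraint: a manual pair touching an
already-matched gene raises a validation error rather than silently
rewiring the match set.

**Merging.** A consensus record keeps source A's coordinates when the two
differ (A is the designated primary build), takes the union of all
identifier sets, and keeps both source ids for provenance.

## Pathway holes and curation

A hole is an enzymatic reaction (never spontaneous or transport) with an
empty gene assignment, counted once per pathway containing it; a reaction
shared by two pathways therefore contributes an occurrence — and possibly a
hole — to each. The hole percentage divides total holes by total reaction
occurrences across pathways. This per-occurrence convention is what makes
the holes-per-pathway distribution (0/1/2/3/4/>4 buckets) sum to the
pathway count.

Deletion rules run in a fixed order and log one action per mutation:

* **R1 (redundancy)** is structural: a pathway whose reaction multiset is
  contained in another pathway's is deleted and the superset survives; exact
  duplicates keep the lexicographically smaller id. Name-similarity
  redundancy is out of scope for the rule and belongs in the manual edits
  file, because pathway names are free text.
* **R2 (non-mammalian metabolite)** consumes caller-supplied flags (or a
  `non_mammal` taxon annotation). Compounds are not chemically modelled;
  deciding whether a pathway's input or output occurs in the taxon of
  interest is a literature judgment that the caller encodes.
* **R3 (no evidence with alternative)** deletes a pathway whose evidence
  field is `none` when a pathway that survives curation shares at least one
  reaction with it. Candidates are processed in sorted id order; a
  no-evidence pathway whose only "alternative" was itself deleted survives.

The rules are idempotent (a second run emits no actions), and the action log
is complete: replaying it on the uncurated PGDB reproduces the curated one
exactly, which the tests assert.

**BLAST hole-filling thresholds.** Clause 1 is inclusive (coverage ≥ 80,
identity ≥ 70); clause 2, available only to a query's best hit (highest
bitscore, ties by lower e-value then input order), is exclusive (coverage
> 50, identity > 90) — the boundary semantics follow the wording of the two
threshold conventions they encode ("80 % coverage and 70 % identity" vs
"included > 50 % and exactly matched > 90 %"). The second phrase is read as
percent identity of the aligned region with > 50 % query coverage; coverage
is `100*(qend-qstart+1)/qlen`, which is why the BLAST dialect carries a 13th
`qlen` column. At most one assignment is accepted per query.

## Duplication screen

The screen takes the *intersection* of the two anchored lists: the
human-anchored condition (one-to-one mouse, one-to-many target) and the
independent mouse-partner condition (one-to-many target). Intersection is
the conservative reading and avoids single-table artefacts. Copy biotype is
not filtered; anchors must be protein-coding. An anchor with two one-to-one
partners is a malformed table and raises.

**Ranking.** A = EST + expression evidence + complete assembly; B = both
kinds of evidence but a possible assembly error; C = exactly one of
EST/expression; D = neither. Assembly completeness only separates A from B:
the undefined grid cells (partial or no evidence with a complete assembly)
map to C and D with a logged warning rather than inventing new tiers.

**Mechanism.** The retrogene test (any copy with one exon and a poly-A
signal) overrides positional tests, since retrotransposition can land a copy
anywhere, including the source chromosome. Otherwise same-chromosome copies
within 200 kb — the upper end of the typical 1–200 kb duplicated-block size
— are called segmental (the threshold is a keyword argument); copies on
different chromosomes are chromosomal rearrangement; same-chromosome copies
further apart are left `unknown` rather than guessed.

**Synteny.** For each reference species an ordered gene list of the
orthologous region is supplied. The innermost up- and down-flank orthologs
bracket the examined segment (either orientation); a candidate ortholog
inside the bracket supports *ancestral*, an empty or candidate-free bracket
supports *inserted*. References missing a flank, or with interleaved flanks,
abstain. The final status must be unanimous among non-abstaining references,
else *indeterminate*. Flank depth defaults to two genes per side.

## Synthetic fixtures: what they emulate and what they do not

The generators plant ground truth on a virtual genome of 30 × 10 Mb
chromosomes divided into 3 kb slots: a planted pair shares a slot (so it
overlaps), and shares exactly the one attribute its planted criterion
requires, with every other attribute unique genome-wide; decoys occupy their
own slots and share nothing. This makes the planted fixtures
*collision-free*: matcher precision/recall of 1.0 on them demonstrates that
the implementation recovers a recoverable signal exactly, not that real
annotation pairs are unambiguous — real databases contain overlapping gene
models with conflicting shared identifiers, where the tie-break rule, not
ground truth, decides. Likewise the PGDB generator plants structurally
clean rule triggers (each redundant pathway has exactly one superset; each
no-evidence pathway one surviving alternative), and the orthology generator
emits decoys that each violate exactly one screen condition. Discrepancy
planting uses exact counts rather than rates so the planted totals are
deterministic under any seed.

Generation is integer-only off a single `random.Random(seed)`; identical
plan + seed yields byte-identical files on any platform.

## Problem sizes

The acceptance script runs the matcher at the full published annotation
scale (52,415 genes across the two sources and scaffolds, ~19k planted
pairs), a 316-pathway and a 304-pathway PGDB with ~1,000 reaction
occurrences each, and a 200-anchor orthology screen; the whole script
completes in a few seconds on one CPU. The end-to-end test uses 10⁴ genes
per source, a 500-pathway PGDB and 200 anchors. One published
inconsistency is deliberately not reproduced: the initial hole distribution
as printed (219 hole-free + 93 holed pathways) sums to 312, not the printed
316 pathways, so the fixture pads the hole-free bucket to 223 to keep the
pathway total, the 202 holes and the 93 holed pathways simultaneously
consistent. The curated column (237 + 67 = 304) is internally consistent
and is used as printed. Similarly, the deletion/addition arithmetic
316 − 36 + 23 = 303 is reported as computed; the curated pathway count of
304 comes from the curated-state distribution.
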