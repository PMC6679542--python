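# Methods

This note documents the models and decision rules implemented in
`genecomplement`, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the design choices made where the
procedure was genuinely open.

## The orthology decision procedure

A gene's presence call is assembled from four kinds of evidence.

**Alignment significance.** Hits are scored with the web-BLAT formula
`matches + repMatches − misMatches − qNumInsert − tNumInsert`; a hit is
significant when its score is strictly greater than `blat_score_min`
(default 50). The formula is a design choice: browser BLAT reports this
score, and the published threshold ("scores above 50") is defined against
it. Ties among significant hits are ordered by (target name, target start)
so every run is deterministic.

**Reciprocality.** The gene model at a candidate locus must align
*preferentially* back to the querying locus: its top significant
back-alignment must overlap the query locus by at least one base.
"Preferentially" is operationalized as a unique top score — if the top two
back-hits tie exactly, the gene falls to `UNRESOLVED` rather than being
guessed. The analysis walks the forward hits best-first and accepts the
first locus passing the reciprocal test; this matters because a truncated
ortholog can score below its intact paralogs, and the reciprocal criterion
is what rescues it (the simulator reproduces exactly this situation).
Hits on unplaced assembly fragments (`chrUn`, `chr*_random`) are treated as
allelic variants: they never veto orthology and never count as candidate
novel paralogs.

**Synteny.** The flanking context is the `k` nearest genes on each side
(default `k = 2`, configurable; the number of neighbors a curator actually
inspects varies and is not canonical). Two contexts are *directly*
conserved when each side of each context shares at least one gene symbol
with the other context — order and orientation are deliberately ignored,
because inversions and local rearrangements routinely scramble both without
breaking the neighborhood. A side cut short by a scaffold end makes the
comparison *unresolvable* rather than negative. When direct comparison
fails, conservation may be established transitively: a breadth-first search
over candidate intermediate species finds the shortest chain of pairwise
directly-conserved contexts in which every intermediate also passes the
reciprocal back-alignment test (verdict `phylo-linked`, the `$` marker); if
no chain exists the synteny is `unresolved` (the `#` marker, weaker
evidence, but the gene can still be present). Tandem gene clusters are
resolved as a unit: an order-preserving assignment between the two clusters
maximizing a pair score (symbol match 1.0, positional fallback 0.25) via
alignment DP, with whole-cluster reversal allowed and ties preferring the
forward orientation; cluster synteny is tested against the flanks of the
cluster, not of each member.

**Status routing.** With reciprocality and usable synteny, the present tier
follows the model inventory: correctly annotated models
(`PRESENT_ANNOTATED`), models annotated only as "novel gene"
(`PRESENT_NOVEL_MODEL`, `^` marker), a verified locus with coordinates but
no model (`PRESENT_NO_MODEL`), or a locus found only in the gap-free
long-read assembly (`PRESENT_PACBIO_ONLY`). An aligned fraction below
`truncation_fraction` (default 0.25) *on a gap-free scaffold* is
`TRUNCATED` (`▽`): the published account gives only qualitative anchors
("short segments", "a few 3′ exons"), so the threshold is configurable and
deliberately permissive — real truncations in the worked example sit near
0.01–0.05. Markers accumulate independently of the tier; `MISSING` carries
none by construction.

## Missing loci and loss placement

Absence is asserted only on positive evidence (`call_missing_locus`): both
syntenic flanks adjacent on one gap-free scaffold and no significant
intergenic hit (`missing-high`); the same configuration with gaps is only
`missing-tentative`, and flanks stranded at the ends of different scaffolds
are `undetermined` — an incomplete assembly can hide a gene, so unknown is
never treated as absent. Truncation is distinguished from mere model
incompleteness the same way (`call_truncation`): a tiny aligned fraction on
a gap-free scaffold *without expression evidence* is a likely pseudogene;
with gaps nearby or expression support it is only a partial model.

Loss placement uses a Dollo model: a gene is gained once on the tree and may
be lost independently on several branches. For each maximal clade whose
known states are all absent, the loss is placed on that clade's stem.
Unknown-state leaves widen the candidate set to every branch that subtends
only absent-or-unknown leaves and covers all of that clade's absences; the
set therefore grows monotonically as knowledge is removed and always
contains the true branch of a planted single loss (both properties are
tested). Multiple independent losses are reported as multiple maximal
clades rather than forced into one branch. Confidence is `high` only when
every absence rests on gap-free evidence. Placement requires at least one
present leaf; a profile with no observable absence places nothing.

Category labels in reports ("Missing in Passeriformes", "Unique to
mammals") are the names of the maximal candidate branch's clade, taken from
internal node labels of the input tree.

## Completeness metrics

`length_ratio` divides the target model length (longest transcript variant;
non-overlapping split models summed — the summation rule is part of the
procedure) by the reference ortholog's length. The single-longest-variant
rule is used as stated in the source procedure; UTR merging across variants
is not attempted. Spliced transcript length is used, not genomic span,
since the ratio compares mRNA models.

`subtract_blocks` merges the aligned blocks of the better-annotated
sister-species model (top-scoring alignment only; secondary hits are
ignored) and of the target's own model, both in target-genome coordinates,
and returns their set difference as maximal disjoint intervals. The percent
of post-recovery length is `L / (L + basesRecovered)`; the flag threshold
is strict (`< 0.90`, second bin `< 0.75`). A gene without a reference
alignment is excluded from the analysis rather than scored. The interval
arithmetic is implemented directly (sorted sweep) and verified against a
per-base membership oracle on 1000 random instances.

## Expression reconciliation

Calls are categorical only (`higher` / `lower` / `nondifferential` /
`not-assessed`); no intensity quantification is attempted, matching the
underlying scoring. Reconciliation is in-situ-dominant: an assessed in situ
call is final regardless of the microarray, because the in situ compares the
nucleus with its surround in the same section while microarray contrast
regions were dissected separately. Genes without an in situ probe keep the
microarray call with `microarray-only` provenance. The
`sparsePopulation` flag annotates strong signal in sparse cells and is
orthogonal to the nucleus-level call (a gene can be a nucleus-level
negative marker yet blaze in a sparse subpopulation).

## The synthetic-data generator

The generator works at the score/block level, never at the nucleotide
level: the pipeline inspects scores, coordinates and neighborhoods, not
residues, so sequence simulation would add runtime without adding test
power. It emulates: a random rooted species tree with a designated
well-annotated outgroup query and a focal target; an ancestral gene order
(default 60 genes in 12 families, ~20% of families as tandem arrays)
evolved down the tree by inversions (0.5/branch) and translocations
(0.2/branch); planted losses (5% of genes, one random ingroup branch each)
that remove the gene while keeping its flanks adjacent; planted truncations
(5% of genes, kept fraction 0.08–0.2) in the focal species; assembly
fragmentation (scaffold breaks at 5% per junction; 20% of scaffolds gappy,
long-read-like scaffolds gap-free — scaffolds carrying planted truncations
are forced gap-free, matching the evidence situation in which truncation is
ever called); alignments whose ortholog score equals the alignable model
length with paralogs at 0.6 of it, optionally jittered by a configurable
fraction of that ortholog–paralog gap; and two-assay expression calls with
70% in situ availability and 10% planted microarray disagreement. All
randomness flows from one seed; identical seeds give byte-identical output
files.

What it does *not* emulate: sequence-level homology and alignment noise
correlated with divergence time, realistic karyotypes, segmental
duplications and novel paralogs, EST evidence, or assay-specific expression
noise beyond symmetric call flipping. Passing recovery tests therefore
demonstrates that the decision logic is correct under the stated evidence
model, not that the thresholds are optimal for any particular real genome.

Expected outcomes in recovery scoring are derived deterministically from
the simulation state: a present gene should return `PRESENT` at the true
locus; a truncated gene on a gap-free scaffold `TRUNCATED`; a lost gene
`MISSING` when its flanks end up adjacent on a gap-free scaffold and
`UNRESOLVED` (insufficient evidence — the correct answer) otherwise.

## Worked-example fixtures

The packaged fixtures encode the published 94-gene ion-channel complement
of the zebra finch at the *evidence* level (model inventory, synteny
verdict, discovery route, aligned fraction, scaffold gap state), so the
classifier genuinely recomputes each status and marker set rather than
reading it back. Per-gene alignment scores and coordinates are not part of
the published tables; the loader synthesizes a nominal score (100) and, for
genes whose printed locus is an annotation identifier, a nominal interval,
both documented as synthetic plumbing. The loss profiles encode the
published per-clade presence/absence statements over a 13-species tree with
named internal clades; the expression fixture encodes the calls stated in
the running text (the full published matrices are graphical and are left as
user-supplied input). Problem sizes throughout (94-gene fixture, 60-gene
simulations, 10–20 simulation replicates) keep the whole suite and the
acceptance script in the seconds-to-a-minute range on one CPU.

## Known limitations

* Synteny conservation is symbol-based; it assumes consistent gene symbols
  across the compared annotations (true for curated cross-species work,
  not for raw model identifiers).
* The reciprocal walk assumes back-alignments are available for the gene at
  every candidate locus; loci without models (e.g. long-read-only) rely on
  synteny alone, as the manual procedure does.
* Dollo placement reports ambiguity sets but does not weight branches by
  branch length or assembly quality; `confidence` is a two-level summary.
* The completeness metrics compare exactly two species; multi-reference
  recovery is out of scope.
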