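# Methods

This note documents the models and procedures genorepo implements, the
defaults and why they were chosen, what the synthetic data does and does not
emulate, and the numerical choices that affect results.

## Repository model

A repository is a folder tree in which metadata is authoritative and
file-level: `organism.json` (name, taxid, tags, `representative`,
`restricted`) and `genome.json` (identifier, owning organism, sequencing/
assembly/annotation tool fields, plus an open `custom` map for
project-specific columns). The invariants enforced by `validate_repo` are:
organism/genome names match their directory names; the representative names
an existing genome folder; genome identifiers are unique repository-wide;
every genome folder holds `<id>.fna`, `<id>.gbk`, `<id>.gff`; tags are
non-empty and whitespace-free. Violations are returned as a deterministic
report (sorted by path, then rule id), never raised, so a repair workflow can
see all problems at once.

Imports are strictly additive: `import_genome` refuses duplicate identifiers
and never rewrites an existing genome folder, which is what makes version
history trustworthy. The metadata schema is deliberately minimal plus an
open `custom` map — real projects accumulate dozens of idiosyncratic
metadata columns, and baking any particular catalogue into the schema would
hurt interoperability.

Selector grammar is deliberately small: `@tag:NAME`, `@tax:NAME`,
`@tax<rank>:NAME`, bare identifiers, and comma-union of those. Tag/taxon
selectors resolve to representative genomes only; bare identifiers may
address archived versions directly. `@tax:X` is, by construction, a superset
of `@tax<rank>:X` for every rank. Taxonomy comes from a flat TSV lineage
table (taxid, parent, rank, name) shipped inside the repository, so nothing
is downloaded at analysis time.

## Annotations and coverage

Annotation files are two-column TSVs (gene, identifier) per genome and per
annotation type; types are configured in `config.json` as (key, display
name, validating regex), with EC, KEGG gene (K#####), KEGG reaction
(R#####), GO and a free-form `custom` type preconfigured. Parsing is strict
about shape (wrong column count is an error with a line number) but lenient
about content: identifiers failing the type regex are excluded from the
table and collected for reporting, since one malformed annotator line should
not invalidate a genome.

Coverage counts **genes, not lines**: a gene annotated twice with the same
identifier counts once. `genes_for_annotation` is defined to return exactly
the gene set behind a matrix cell, and the test suite asserts cell-by-cell
agreement between the two code paths.

## Gene-trait matching

For groups $G_1, G_2$ (disjoint, non-empty) and each annotation present in
at least one selected genome, the 2×2 table is presence/absence at the
genome level (a genome has an annotation iff ≥ 1 gene carries it; copy
number is ignored — the phenotype being matched is binary, so the predictor
is too). The two-sided Fisher p-value uses probability-mass ordering (the
`fisher.test` convention): all tables with the observed margins whose
hypergeometric probability is ≤ that of the observed table contribute.
Computation is exact — integer binomial coefficients, rational comparison —
so ties in the discrete null are decided by arithmetic, not float noise; the
float returned to callers is the rounded exact value. Annotations absent
from every selected genome are excluded from the hypothesis count $m$;
including them would deflate power arbitrarily without changing any decision
about observable annotations.

Benjamini–Hochberg (step-up, q = min-running transform of $m p_{(j)}/j$,
default α = 0.10) is delegated to statsmodels' `fdr_bh` behind the
`benjamini_hochberg` surface; the test suite checks it against the literal
step-up definition and checks that its rejections contain Bonferroni's.
Because Fisher p-values on small groups are discrete and conservative, the
realised false-discovery rate on null data sits well below α — the
simulation in the acceptance checks (200 annotations, two groups of 10,
i.i.d. presence with per-annotation prevalence uniform on [0.1, 0.9], 500
replicates) typically rejects nothing at all.

No population-structure or phylogenetic correction is applied: hits are
candidates for inspection, not causal claims. That, and the smallest
attainable p-value of $2/\binom{n_1+n_2}{n_1}$, are the two caveats users
should know before interpreting results on few genomes.

## Genome-signature trees

Signatures are canonical k-mer frequency vectors (k = 6 by default —
hexanucleotides are a well-established signature resolution for separating
microbial genomes at roughly ANI-level accuracy while keeping the vector at
$4^6 = 4096$ entries). Canonical means each window is mapped to the
lexicographic minimum of itself and its reverse complement, making the
signature strand-independent; windows containing non-ACGT characters are
skipped, not expanded, which is deterministic and standard practice.

Pairwise dissimilarity is the total-variation distance
$d = \tfrac12\sum_i|p_i - q_i| \in [0,1]$ — a true metric on frequency
vectors (symmetry, identity, triangle inequality are property-tested), with
similarity $1-d$. UPGMA then merges the closest pair repeatedly, with
size-weighted arithmetic-mean update of cluster distances and node height =
half the merge distance, so the output is ultrametric by construction. Ties
are broken on the lexicographically smallest (label, label) pair, where a
cluster is labelled by its smallest leaf — this makes output invariant under
input permutation on exactly-tied inputs. The implementation is checked
against scipy's average-linkage cophenetic distances on random matrices.

The taxonomy tree is metadata-only: the lineage table pruned to the selected
genomes' lineages, unary nodes collapsed, genomes attached as leaves under
their organism's taxid, unit branch lengths (it is a classification diagram,
not an estimate of evolutionary distance).

Newick output uses 6 significant digits on branch lengths and quotes labels
containing Newick-special characters; parsing goes through scikit-bio with
underscore munging disabled, and write∘parse round-trips are tested.

## Pathway coverage

A map is any SVG whose coverable shapes carry `data-annotations` (whitespace-
separated identifiers) and a unique `id`; everything else is inert
decoration. This home-grown dialect exists because widely used commercial
pathway images cannot be redistributed; any vector editor can produce maps.
A genome covers a box iff it shares ≥ 1 identifier with it, so multiple
gene copies don't inflate counts and coverage is monotone in group
membership. Colors: 0 → `#FFFFFF`; counts 1…n map linearly in RGB from
`#FFFF00` to `#FF0000` (a single-genome group with a hit is red). Fixed hex
endpoints make rendering bit-exact and testable. Two groups are rendered as
a four-stop linear gradient with both middle stops at offset 0.5 — a
hard-edged 50/50 left/right split that works for any shape geometry without
editing paths. Group arity is capped at two.

## Flower statistics

Computed on distinct annotation identifiers (not gene counts): an
annotation carried by all $n$ genomes is core, by exactly one is unique to
it, otherwise shared. The per-genome identity unique + shared + core =
total is asserted against a brute-force classifier on random inputs.
Annotation level (rather than orthogroup level) keeps the statistic
available for any configured annotation type; the type is a parameter.

## Synthetic data

The fixture generator emulates a small sequencing project: 4–8 organisms
split across two phyla (two genera), 1–2 genome versions each, random
assemblies (~3 kb by default — long enough for thousands of hexanucleotide
windows, short enough to keep test suites fast), evenly spaced genes on
alternating strands written consistently to FASTA, a minimal-but-parseable
GenBank and a GFF3 (1-based inclusive on disk, 0-based half-open in
memory), KEGG-gene and EC annotation tables with a planted sharing
structure: 5 core annotations in every organism, 3 globally unique per
organism, a 10-identifier shared pool sampled at 50 %, and optionally one
trait annotation present in every first-tag organism and absent elsewhere.
Version 2 of an assembly is version 1 with ~1 % random substitutions. The
seed fully determines every byte (tests assert byte-identical regeneration).

What it does **not** emulate: real oligonucleotide composition (sequences
are i.i.d. uniform, so signature distances cluster near the random
baseline rather than forming taxon clades), orthology (annotations stand in
for orthogroups), contig fragmentation, annotation noise, or phylogenetic
correlation between trait and lineage. Passing tests therefore demonstrate
correctness of the computations and contracts, not biological discovery
performance on real data.

## Numerical and design choices

- Exact rational arithmetic for Fisher (ties matter in discrete nulls);
  floats only at the API boundary.
- UPGMA tie-break and JSON serialisation (sorted keys, UTF-8, trailing
  newline) chosen for cross-platform reproducibility of outputs and diffs.
- Degenerate inputs: empty p-vector → empty result; Fisher with a zero
  margin → p = 1; UPGMA needs ≥ 2 labels; flower needs ≥ 2 genomes;
  k-mer profiling with no valid window is an error rather than a NaN vector.
- Problem sizes in the acceptance checks (exhaustive Fisher grid to n = 30
  in tests and n = 24 in the script, 500 null replicates, 500/100 random
  UPGMA matrices, 1000/200 random sequences) were chosen to give the
  brute-force oracles full coverage of the small-sample regime these
  methods are actually used in while keeping a laptop run in seconds.
- The CLI is a thin shell: every subcommand calls exactly one library
  operation, and tests compare CLI output to direct library calls.

## Known limitations

- No orthogroup inference, multiple sequence alignment, BLAST, or dot-plot
  wrappers; annotations are taken as given in the tables.
- Trait matching has no correction for population structure.
- The signature distance is total variation on hexanucleotide frequencies;
  other signature metrics (cosine, Jensen–Shannon, ANI estimators) are not
  implemented.
- Pathway rendering caps at two groups and recolors fills only; it does not
  re-layout maps.
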