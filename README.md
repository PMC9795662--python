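# genorepo

A file-based, database-free toolkit for organising and comparing microbial
genome collections. It is aimed at sequencing projects — a lab or core
facility sitting on tens to hundreds of bacterial, archaeal or yeast
assemblies — that need FAIR-style, versioned storage of genomes and metadata
plus the comparative analyses that practitioners reach for first, without
standing up a web stack or a database server.

Everything lives in a plain folder tree, so the repository itself is the
database:

```
<root>/
  config.json                    # configured annotation types (key, name, regex)
  taxonomy.tsv                   # lineage table: taxid, parent, rank, name
  annotation-descriptions/       # <type>.tsv: identifier -> description
  pathway-maps/                  # *.svg maps with data-annotations attributes
  organisms/<organism>/organism.json        # tags, taxid, representative genome
  organisms/<organism>/genomes/<genome>/    # <genome>.fna/.gbk/.gff +
                                            # <genome>.<type>.tsv + genome.json
```

Each organism owns one or more genome *versions*; exactly one is the
**representative**, so assemblies can be updated transparently while legacy
versions are kept byte-for-byte (imports never modify existing folders).
Genome groups are addressed with selector strings: `@tag:halophile`
(representatives of organisms carrying a tag), `@taxphylum:Firmicutes` /
`@tax:Firmicutes` (lineage membership, optionally at a fixed rank), or bare
genome identifiers; comma-separated selectors union.

## What it computes

- **Coverage matrices** — for annotations $a$ and genomes $g$, cell
  $C_{ag} = |\{\text{genes of } g \text{ carrying } a\}|$, with per-cell
  drill-down to the gene identifiers.
- **Gene-trait matching** — for two disjoint genome groups and every
  annotation present in the selection, a 2×2 presence/absence table is tested
  with a two-sided Fisher's exact test,
  $p = \sum_{\{x:\ P(x) \le P(a)\}} P(x)$ over all tables with the observed
  margins (exact integer binomial coefficients, hypergeometric null), then
  Benjamini–Hochberg step-up correction
  $q_{(i)} = \min_{j \ge i} m\,p_{(j)}/j$ at α = 10 %.
- **Trees** — (1) a taxonomy tree pruned from the organisms' taxid lineages;
  (2) a genome-signature tree: canonical hexanucleotide frequency vectors per
  assembly, pairwise total-variation distance
  $d(p,q) = \tfrac12 \sum_i |p_i - q_i|$ (similarity $= 1-d$), UPGMA
  clustering into an ultrametric dendrogram, serialised as Newick.
- **Pathway coverage** — SVG maps whose shapes carry
  `data-annotations="K00031 EC:1.1.1.42"`; a genome covers a box iff any of
  its genes carries any listed identifier. Boxes are recolored white (0
  genomes) → yellow (1) → red (all), split 50/50 for two groups.
- **Flower statistics** — per genome selection, every distinct annotation is
  classified as core (in all genomes), unique (in exactly one) or shared,
  with the per-genome identity unique + shared + core = total.

## Worked example

The package ships a deterministic synthetic-repository generator (six
organisms in two phyla, tagged `halophile`/`mesophile`, with one annotation
`K09999` planted to separate the tag groups perfectly). From
`examples/03_gene_trait_matching.py`:

```
group1 (halophile):  ['ORG001-1', 'ORG002-1', 'ORG003-1']
group2 (mesophile):  ['ORG004-1', 'ORG005-1', 'ORG006-1']

annotation  a  b  c  d   p   q  significant
    K09999  3  0  0  3 0.1 1.0        False
    K20002  3  0  1  2 0.4 1.0        False
    K00001  3  0  3  0 1.0 1.0        False
```

`K09999` is present in all three group-1 genomes and none of group 2 — the
most extreme of the $\binom{6}{3} = 20$ tables with these margins. Two tables
(one per polarity) are that extreme, so the two-sided exact p-value is
2/20 = 0.1; with 3 + 3 genomes no annotation can survive multiple-testing
correction, which is itself a useful fact when sizing a comparative study.
The other examples (`examples/01`–`04`) build and query a repository, print
coverage/flower tables, and write Newick trees and a recolored pathway SVG.

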