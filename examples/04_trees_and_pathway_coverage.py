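"""Phylogenetic trees and pathway-coverage coloring.

Two tree flavours: a taxonomy tree read off the organisms' taxids (fast,
only as good as the metadata) and a genome-signature tree: canonical
hexanucleotide frequency vectors per assembly, total-variation distances
(similarity = 1 - d), UPGMA clustering into an ultrametric dendrogram.

Pathway maps are SVGs whose reaction boxes carry a data-annotations
attribute; a genome covers a box if any of its genes carries any of the
box's annotations.  Boxes are colored white (no genome) through yellow
(one) to red (all), split left/right for two groups.
"""

import tempfile
from pathlib import Path

from genorepo import resolve_selector, write_newick
from genorepo.cli import tree_for_genomes
from genorepo.fixtures import FixtureSpec, generate_fixture_repo
from genorepo.pathways import compute_coverage, parse_pathway_svg, render_colored_svg

root = Path(tempfile.mkdtemp()) / "repo"
generate_fixture_repo(FixtureSpec(n_organisms=6, seed=1), root)
g1 = sorted(resolve_selector("@tag:halophile", root))
g2 = sorted(resolve_selector("@tag:mesophile", root))
genomes = g1 + g2

taxonomy_tree = tree_for_genomes(root, genomes, method="taxid")
print("taxonomy tree (unit branch lengths):")
print(" ", write_newick(taxonomy_tree))

kmer_tree = tree_for_genomes(root, genomes, method="kmer", k=6)
print("\nhexanucleotide-signature UPGMA tree (branch lengths = distance/2):")
print(" ", write_newick(kmer_tree))
print(
    "\nThe fixture assemblies are random, so signature distances sit near the"
    "\nrandom-sequence baseline; real congeneric genomes would form tight clades."
)

pmap = parse_pathway_svg(root / "pathway-maps" / "demo_pathway.svg")
coverage = compute_coverage(pmap, [g1, g2], root)
print(f"\npathway '{pmap.name}' coverage (group1 = halophile, group2 = mesophile):\n")
print(coverage.to_frame().to_string(index=False))
out = root / "demo_pathway.colored.svg"
out.write_bytes(render_colored_svg(pmap, coverage))
print(
    f"\nrecolored SVG written to {out}"
    "\n#FF0000 = covered by every genome of the group, #FFFFFF = by none;"
    "\nbox-trait is red on the left (halophile) half and white on the right."
)
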