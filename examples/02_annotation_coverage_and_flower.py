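"""Annotation coverage matrices and shared-gene-content (flower) statistics.

The coverage matrix has one row per annotation and one column per genome;
each cell counts how many distinct genes of that genome carry the annotation
(0 means the function is absent).  The flower statistics partition every
distinct annotation of a genome selection into core (in all genomes),
unique (in exactly one) and shared (in some but not all).
"""

import tempfile
from pathlib import Path

from genorepo import compute_flower_stats, coverage_matrix, resolve_selector
from genorepo.annotations import describe
from genorepo.fixtures import FixtureSpec, generate_fixture_repo

root = Path(tempfile.mkdtemp()) / "repo"
generate_fixture_repo(FixtureSpec(n_organisms=6, seed=1), root)
genomes = sorted(resolve_selector("@tag:halophile,@tag:mesophile", root))

matrix = coverage_matrix(["K00001", "K00002", "K09999", "K99998"], genomes, root)
print("coverage matrix (gene counts per genome):\n")
print(matrix.to_string())
print(
    "\nK00001/K00002 are core functions (present everywhere, sometimes in two"
    "\ngene copies); K09999 is carried only by the halophile group; K99998 by"
    "\nnobody.  Description of K00001:", describe(root, "K00001"),
)

stats = compute_flower_stats(genomes, root, annotation_type="KG")
print(f"\nflower statistics over {len(genomes)} genomes (KEGG-gene annotations):")
print(stats.to_frame().to_string(index=False))
print(
    f"\n{stats.core} annotations are core (shared by all genomes); per genome,"
    "\nunique + shared + core always equals its total distinct annotations."
)
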