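"""Gene-trait matching: which annotations separate two phenotype groups?

For every annotation present in the selection, a 2x2 table (group membership
vs annotation presence) is tested with a two-sided Fisher's exact test, and
Benjamini-Hochberg correction is applied across all annotations at
alpha = 10%.  The synthetic repository plants one annotation (K09999) that
perfectly separates the halophile-tagged organisms from the mesophile ones.
"""

import tempfile
from pathlib import Path

from genorepo import gene_trait_match, resolve_selector
from genorepo.fixtures import FixtureSpec, generate_fixture_repo
from genorepo.traits import results_to_frame

root = Path(tempfile.mkdtemp()) / "repo"
spec = FixtureSpec(n_organisms=6, seed=1)
generate_fixture_repo(spec, root)

group1 = sorted(resolve_selector("@tag:halophile", root))
group2 = sorted(resolve_selector("@tag:mesophile", root))
print(f"group1 (halophile):  {group1}")
print(f"group2 (mesophile):  {group2}\n")

results = gene_trait_match(group1, group2, root, alpha=0.1, annotation_type="KG")
frame = results_to_frame(results)
print("top 5 annotations by adjusted p-value (a/b: group1 with/without,")
print("c/d: group2 with/without):\n")
print(frame.head(5).to_string(index=False))
print(
    f"\nThe planted annotation {spec.planted_trait_annotation} tops the list with"
    "\np = 0.1: a perfect 3-vs-3 split is the most extreme of the 20 tables with"
    "\nthese margins, and two tables (either polarity) are that extreme, so the"
    "\ntwo-sided exact p-value is 2/20.  With 3+3 genomes no annotation can reach"
    "\nsignificance after correction - a floor worth knowing before designing a"
    "\ncomparative study this small."
)
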