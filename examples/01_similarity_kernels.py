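"""Chemical and semantic similarity kernels on tiny hand-built inputs.

Tanimoto similarity counts the substructure bits two molecules share,
divided by the bits either one sets; Lin similarity compares two disease
descriptors through the information content of their closest shared
ancestor in a MeSH-style tree.
"""

import numpy as np

from drugwalk import Fingerprint, MeshHierarchy, lin_similarity, tanimoto


def fp(name, on_bits):
    bits = np.zeros(1024, dtype=bool)
    bits[list(on_bits)] = True
    return Fingerprint(name, bits)


aspirin_like = fp("drugA", {1, 2, 3, 10})
salicylate_like = fp("drugB", {2, 3, 10, 55})
unrelated = fp("drugC", {200, 300, 400})

print("Tanimoto (3 shared bits of 5 total):",
      round(tanimoto(aspirin_like, salicylate_like), 3))
print("Tanimoto (no shared bits):         ",
      round(tanimoto(aspirin_like, unrelated), 3))

# five-descriptor tree: R -> {A, B}, A -> {A1, A2}
tree = MeshHierarchy({
    "R": {"R"}, "A": {"R.A"}, "B": {"R.B"},
    "A1": {"R.A.1"}, "A2": {"R.A.2"},
})
print("Lin (siblings under A):            ",
      round(lin_similarity("A1", "A2", tree), 3))
print("Lin (only the root in common):     ",
      round(lin_similarity("A1", "B", tree), 3))

# siblings share the informative ancestor A (3 of 5 descriptors below it);
# a pair that meets only at the root (all 5 descriptors) has zero evidence
# of relatedness, hence similarity 0.
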