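"""Neighbor-joining tree of reverse-transcriptase domains with bootstraps.

Builds a small synthetic RT-domain alignment of two diverged clades,
computes p-distances (pairwise gap deletion), joins neighbors, and attaches
bootstrap supports (branches under 50% would collapse into polytomies).
"""

import numpy as np

from centeline.phylo import AlignedBlock, bootstrap_support, nj_tree, pdistance

rng = np.random.default_rng(7)
bases = np.array(list("ACGT"))
ancestor = "".join(bases[rng.integers(0, 4, 300)])


def mutate(seq, n, seed):
    r = np.random.default_rng(seed)
    s = list(seq)
    for p in r.choice(len(s), size=n, replace=False):
        s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
    return "".join(s)


cladeA = mutate(ancestor, 40, 1)
cladeB = mutate(ancestor, 40, 2)
block = AlignedBlock(
    names=["A1", "A2", "A3", "B1", "B2"],
    rows=[mutate(cladeA, 6, 3), mutate(cladeA, 7, 4), mutate(cladeA, 8, 5),
          mutate(cladeB, 6, 6), mutate(cladeB, 7, 7)],
)

D = pdistance(block)
print("p-distance matrix (pairwise gap deletion):")
print(np.round(D, 3))

tree = nj_tree(D, block.names)
print("\nNJ tree:", tree.to_newick())

st = bootstrap_support(block, n_reps=500, seed=11, cutoff=50.0)
print("tree with bootstrap supports:", st.to_newick())
for bip, sup in sorted(st.supports.items(), key=lambda kv: -kv[1]):
    print(f"  split {{{','.join(sorted(bip))}}}: {sup:.0f}% of 500 replicates")
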