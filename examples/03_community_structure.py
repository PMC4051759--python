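"""Phylogenetic evenness vs clustering of a species group (SES_MPD).

Compares the mean pairwise phylogenetic distance of a group against a null
of equally sized random draws from the pooled species list.  A clade-bound
group is clustered (z < 0, low quantile p); a deliberately spread group is
even (z > 0, high p).
"""

import numpy as np

from phylorates.community import mpd, n_pairs, ses
from phylorates.simulate import SimConfig, simulate_tree
from phylorates.tree import cophenetic_matrix

tree = simulate_tree(SimConfig(n_tips=134, seed=21, target_counts=None))
dist = cophenetic_matrix(tree)
print(f"pool: {len(dist.labels)} species, "
      f"{n_pairs(len(dist.labels))} unordered pairs in the null")

# a clustered group: all tips of one subtree
clade_root = max(tree.root.children,
                 key=lambda c: sum(1 for n in c.preorder() if n.is_leaf()))
clade = sorted(n.label for n in clade_root.preorder() if n.is_leaf())[:40]
r = ses(dist, clade, n_reps=999, seed=0, group_label="one-clade")
print(f"one-clade group:  MPD = {r.obs:6.1f} Myr, z = {r.z:+.2f}, p = {r.p:.3f}")

# an even group: greedily pick species maximizing total pairwise distance
labels = list(dist.labels)
chosen = [labels[0]]
while len(chosen) < 40:
    idx = [labels.index(c) for c in chosen]
    rest = [l for l in labels if l not in chosen]
    chosen.append(max(rest, key=lambda l: dist.values[labels.index(l), idx].sum()))
r2 = ses(dist, chosen, n_reps=999, seed=0, group_label="spread")
print(f"spread group:     MPD = {r2.obs:6.1f} Myr, z = {r2.z:+.2f}, p = {r2.p:.3f}")
print("p < 0.05 indicates clustering (closer relatives than chance);")
print("p > 0.95 indicates evenness (more distant relatives than chance).")
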