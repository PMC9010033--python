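"""Slow, direct reference implementations used for validation.

These deliberately share no code with :mod:`coalescekit.diversity`: each
pairwise distance is computed by walking the tree per pair and gathering
descendant tip sets per branch.  They exist so that the fast
implementations can be checked branch-by-branch on small instances.
"""

from __future__ import annotations

import numpy as np
from skbio import TreeNode


def bray_curtis_pair(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return 1.0 - 2.0 * np.minimum(x, y).sum() / (x.sum() + y.sum())


def _branches(tree: TreeNode):
    """(length, descendant tip-name set) for every non-root branch."""
    out = []
    for node in tree.traverse(include_self=False):
        if node.length is None or node.length <= 0:
            continue
        tips = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        out.append((node.length, tips))
    return out


def unweighted_unifrac_pair(tree: TreeNode, taxa_a, taxa_b) -> float:
    """Unique / observed branch length for two presence sets of tip names."""
    taxa_a, taxa_b = set(taxa_a), set(taxa_b)
    unique = observed = 0.0
    for length, tips in _branches(tree):
        in_a = bool(tips & taxa_a)
        in_b = bool(tips & taxa_b)
        if in_a or in_b:
            observed += length
            if in_a != in_b:
                unique += length
    return unique / observed if observed > 0 else 0.0


def weighted_unifrac_pair(tree: TreeNode, counts_a: dict, counts_b: dict) -> float:
    """Normalized weighted UniFrac for two tip-name -> count mappings."""
    tot_a = sum(counts_a.values())
    tot_b = sum(counts_b.values())
    num = den = 0.0
    for length, tips in _branches(tree):
        pa = sum(counts_a.get(t, 0) for t in tips) / tot_a
        pb = sum(counts_b.get(t, 0) for t in tips) / tot_b
        num += length * abs(pa - pb)
        den += length * (pa + pb)
    return num / den if den > 0 else 0.0
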