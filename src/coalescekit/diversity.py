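"""Alpha and beta diversity.

Alpha diversity: observed OTUs and Shannon entropy (natural log).  Beta
diversity: Bray-Curtis dissimilarity and both UniFrac variants computed
from first principles.  Weighted UniFrac is the *normalized* variant so
that all three metrics live on [0, 1] and can be pooled across patients.

UniFrac is evaluated from a single post-order pass that accumulates, for
every branch, the fraction of each sample's reads descending from that
branch; pairwise distances are then weighted sums over branches:

* unweighted:  sum_b l_b * [present in exactly one] / sum_b l_b * [present in either]
* weighted:    sum_b l_b * |A_b - B_b| / sum_b l_b * (A_b + B_b)

where ``A_b`` is the proportion of community A descending from branch ``b``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .data_io import OtuTable, SchemaError, validate_tree_covers

__all__ = [
    "DistanceMatrix",
    "shannon",
    "observed_otus",
    "bray_curtis",
    "unifrac",
    "branch_profile",
]


# ---------------------------------------------------------------------------
# Distance matrix container
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over ordered sample ids."""

    values: np.ndarray
    ids: list
    metric: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.ids):
            raise ValueError("ids do not match matrix size")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        self.values = (v + v.T) / 2.0
        self.ids = [str(i) for i in self.ids]
        self._index = {s: k for k, s in enumerate(self.ids)}

    def __getitem__(self, pair) -> float:
        a, b = pair
        return float(self.values[self._index[str(a)], self._index[str(b)]])

    def submatrix(self, ids) -> "DistanceMatrix":
        idx = [self._index[str(i)] for i in ids]
        return DistanceMatrix(self.values[np.ix_(idx, idx)], list(ids), self.metric)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    @classmethod
    def read(cls, path, metric: str = "") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), [str(i) for i in df.index], metric)


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------


def shannon(counts) -> float:
    """Shannon entropy H = -sum p_i ln p_i over taxa with nonzero counts."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("Shannon diversity undefined for a zero-count sample")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def observed_otus(counts) -> int:
    """Number of OTUs with at least one read."""
    c = np.asarray(counts)
    if c.sum() <= 0:
        raise ValueError("observed OTUs undefined for a zero-count sample")
    return int((c > 0).sum())


def alpha_diversity_table(table: OtuTable) -> pd.DataFrame:
    """Per-sample observed OTUs and Shannon diversity with metadata."""
    rows = []
    for sid, row in zip(table.sample_ids, table.counts):
        rows.append({"sample_id": sid, "observed_otus": observed_otus(row), "shannon": shannon(row)})
    out = pd.DataFrame(rows).set_index("sample_id")
    return out.join(table.meta)


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity on raw counts.

    BC(x, y) = 1 - 2 * sum_i min(x_i, y_i) / (sum x + sum y).
    """
    x = table.counts.astype(float)
    totals = x.sum(axis=1)
    zero = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    if zero:
        raise SchemaError(f"zero-sum sample(s): {zero}")
    n = table.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        shared = np.minimum(x[i], x[i + 1 :]).sum(axis=1)
        d[i, i + 1 :] = 1.0 - 2.0 * shared / (totals[i] + totals[i + 1 :])
    d = d + d.T
    return DistanceMatrix(d, list(table.sample_ids), "braycurtis")


# ---------------------------------------------------------------------------
# UniFrac
# ---------------------------------------------------------------------------


def branch_profile(table: OtuTable, tree: TreeNode):
    """Per-branch descendant proportions for every sample.

    Returns ``(lengths, profile)`` where ``lengths`` has one entry per
    non-root branch and ``profile[b, s]`` is the fraction of sample ``s``'s
    reads attached to tips descending from branch ``b``.
    """
    validate_tree_covers(table, tree)
    totals = table.counts.sum(axis=1).astype(float)
    zero = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    if zero:
        raise SchemaError(f"zero-sum sample(s): {zero}")
    col = {o: j for j, o in enumerate(table.otu_ids)}

    lengths = []
    rows = []
    # post-order accumulation: each node's count vector is the sum of its
    # children's; tips read their column of the count matrix.
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            j = col.get(node.name)
            if j is None:
                vec = np.zeros(table.n_samples)
            else:
                vec = table.counts[:, j].astype(float)
        else:
            vec = np.zeros(table.n_samples)
            for child in node.children:
                vec += child._ck_vec
        node._ck_vec = vec
        if not node.is_root() and node.length is not None and node.length > 0:
            lengths.append(node.length)
            rows.append(vec / totals)
    for node in tree.postorder(include_self=True):
        del node._ck_vec
    return np.asarray(lengths, dtype=float), np.asarray(rows, dtype=float)


def unifrac(table: OtuTable, tree: TreeNode, weighted: bool = False) -> DistanceMatrix:
    """Pairwise unweighted or weighted-normalized UniFrac distances."""
    lengths, profile = branch_profile(table, tree)
    n = table.n_samples
    d = np.zeros((n, n))
    if not weighted:
        present = profile > 0
        wl = lengths[:, None]
        for i in range(n):
            a = present[:, i : i + 1]
            b = present[:, i + 1 :]
            if b.shape[1] == 0:
                continue
            unique = (wl * (a ^ b)).sum(axis=0)
            observed = (wl * (a | b)).sum(axis=0)
            with np.errstate(invalid="ignore"):
                d[i, i + 1 :] = np.where(observed > 0, unique / observed, 0.0)
    else:
        wl = lengths[:, None]
        for i in range(n):
            a = profile[:, i : i + 1]
            b = profile[:, i + 1 :]
            if b.shape[1] == 0:
                continue
            num = (wl * np.abs(a - b)).sum(axis=0)
            den = (wl * (a + b)).sum(axis=0)
            with np.errstate(invalid="ignore"):
                d[i, i + 1 :] = np.where(den > 0, num / den, 0.0)
    d = d + d.T
    name = "unifrac-w" if weighted else "unifrac-u"
    return DistanceMatrix(np.clip(d, 0.0, 1.0), list(table.sample_ids), name)


def beta_diversity(table: OtuTable, metric: str, tree: TreeNode | None = None) -> DistanceMatrix:
    """Dispatch on metric name: ``braycurtis``, ``unifrac-u`` or ``unifrac-w``."""
    if metric == "braycurtis":
        return bray_curtis(table)
    if metric in ("unifrac-u", "unifrac-w"):
        if tree is None:
            raise ValueError("UniFrac requires a tree")
        return unifrac(table, tree, weighted=metric == "unifrac-w")
    raise ValueError(f"unknown metric {metric!r}")
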