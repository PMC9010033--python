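"""Global community structure: ordination, PERMANOVA, confidence-ellipse
overlap and hierarchical clustering of a distance matrix.

PCoA is classical metric scaling (Gower double-centering followed by an
eigendecomposition); PERMANOVA is Anderson's pseudo-F computed from squared
inter-point distances with a permutation p-value.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .diversity import DistanceMatrix

log = logging.getLogger(__name__)

__all__ = [
    "Ordination",
    "PermanovaResult",
    "pcoa",
    "pseudo_f",
    "permanova",
    "confidence_ellipse_overlap",
    "hierarchical_clusters",
]


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


@dataclass
class Ordination:
    """Sample coordinates from classical scaling.

    ``coordinates`` is samples x axes, axes ordered by decreasing
    eigenvalue; ``proportion_explained`` is relative to the sum of the
    retained (non-negative) eigenvalues.
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    ids: list


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> Ordination:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Negative eigenvalues (possible for semi-metric input such as
    Bray-Curtis) are dropped with a logged warning rather than corrected.
    """
    dm = d.values
    n = dm.shape[0]
    d2 = dm**2
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centerer @ d2 @ centerer
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(abs(eigvals[0]), 1.0) * 1e-10
    n_neg = int((eigvals < -tol).sum())
    if n_neg:
        log.warning("PCoA: dropping %d negative eigenvalue(s) (min %.3g)", n_neg, eigvals.min())
    keep = eigvals > tol
    eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]
    if n_axes is not None and n_axes > len(eigvals):
        log.warning("PCoA: requested %d axes, only %d available", n_axes, len(eigvals))
    if n_axes is not None:
        eigvals, eigvecs = eigvals[:n_axes], eigvecs[:, :n_axes]
    coords = eigvecs * np.sqrt(eigvals)
    total = eigvals.sum()
    prop = eigvals / total if total > 0 else eigvals
    return Ordination(coords, eigvals, prop, list(d.ids))


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    pseudo_F: float
    r_squared: float
    p_value: float
    n_permutations: int


def _group_stats(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    """(SS_total, SS_within) from squared distances and integer group codes."""
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def pseudo_f(d: DistanceMatrix | np.ndarray, labels) -> tuple[float, float]:
    """Anderson's pseudo-F and R^2 for a grouping of the samples."""
    dm = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, float)
    codes, uniques = pd.factorize(np.asarray(labels))
    k = len(uniques)
    if k < 2:
        raise ValueError("PERMANOVA requires at least two groups")
    n = dm.shape[0]
    ss_total, ss_within = _group_stats(dm**2, codes, k)
    ss_between = ss_total - ss_within
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    r2 = ss_between / ss_total
    return float(f), float(r2)


def permanova(
    d: DistanceMatrix,
    labels,
    n_permutations: int = 999,
    seed: int | None = 0,
    exact: bool = False,
) -> PermanovaResult:
    """Permutation-based multivariate analysis of variance.

    ``exact=True`` enumerates every label permutation (feasible for ~9
    samples or fewer) and reports p as the exact tail proportion including
    the identity; otherwise labels are shuffled ``n_permutations`` times
    and p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations).
    """
    labels = np.asarray(labels)
    dm = d.values
    codes, uniques = pd.factorize(labels)
    k = len(uniques)
    if k < 2:
        raise ValueError("PERMANOVA requires at least two groups")
    d2 = dm**2
    n = dm.shape[0]

    def f_of(c):
        ss_total, ss_within = _group_stats(d2, c, k)
        return ((ss_total - ss_within) / (k - 1)) / (ss_within / (n - k))

    f_obs = f_of(codes)
    _, r2 = pseudo_f(d, labels)

    if exact:
        if n > 9:
            raise ValueError("exact enumeration limited to 9 samples")
        count = total = 0
        for perm in itertools.permutations(range(n)):
            fp = f_of(codes[list(perm)])
            count += fp >= f_obs - 1e-12
            total += 1
        return PermanovaResult(float(f_obs), r2, count / total, total)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        fp = f_of(rng.permutation(codes))
        exceed += fp >= f_obs - 1e-12
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), r2, float(p), n_permutations)


# ---------------------------------------------------------------------------
# 95% confidence-ellipse overlap
# ---------------------------------------------------------------------------


def confidence_ellipse_overlap(
    ordination: Ordination, labels, level: float = 0.95
) -> pd.DataFrame:
    """Membership of each sample in each group's 2-D confidence ellipse.

    The ellipse for group g is {z : (z - mu_g)' Sigma_g^-1 (z - mu_g) <=
    chi2_2(level)} on the first two ordination axes, with mu_g the group
    mean and Sigma_g the sample covariance.  Returns per-sample boolean
    flags ``in_<group>`` for every group plus ``in_both`` when there are
    exactly two groups.
    """
    if ordination.coordinates.shape[1] < 2:
        raise ValueError("need at least two ordination axes")
    xy = ordination.coordinates[:, :2]
    labels = np.asarray(labels)
    groups = sorted(pd.unique(labels))
    crit = stats.chi2.ppf(level, df=2)
    out = pd.DataFrame(index=ordination.ids)
    for g in groups:
        pts = xy[labels == g]
        if len(pts) < 3:
            raise ValueError(f"group {g!r} needs >= 3 samples")
        mu = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False)
        if np.linalg.matrix_rank(cov) < 2:
            raise ValueError(f"singular covariance for group {g!r}")
        inv = np.linalg.inv(cov)
        diff = xy - mu
        maha = np.einsum("ij,jk,ik->i", diff, inv, diff)
        out[f"in_{g}"] = maha <= crit
    out["group"] = labels
    if len(groups) == 2:
        out["in_both"] = out[f"in_{groups[0]}"] & out[f"in_{groups[1]}"]
    return out


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------


def hierarchical_clusters(d: DistanceMatrix, k: int, method: str = "average") -> pd.Series:
    """Agglomerative clustering of the distance matrix cut into k clusters.

    Average linkage by default; ties in merge heights resolve by scipy's
    deterministic (index-ordered) rule, so results are reproducible for a
    fixed input order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(d.ids)
    if k > n:
        raise ValueError("k cannot exceed the number of samples")
    condensed = squareform(d.values, checks=False)
    z = linkage(condensed, method=method)
    labels = fcluster(z, t=k, criterion="maxclust")
    return pd.Series(labels, index=d.ids, name="cluster")
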