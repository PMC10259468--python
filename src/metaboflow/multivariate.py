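"""Scaling, PCA, hierarchical clustering, and dendrogram-vs-phylogeny
comparison.

The quantitative multivariate views of the data: a PCA of per-ion
scaled areas (fruits alone, flies alone, or the integral table), Ward
hierarchical clustering of samples on Euclidean distances, and a
Robinson-Foulds comparison of the diet-level chemical dendrogram with a
reference species phylogeny.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .core import FeatureTable

__all__ = [
    "PcaResult",
    "Dendrogram",
    "NonMonophylyError",
    "scale_matrix",
    "pca",
    "hclust_dendrogram",
    "diet_tree_newick",
    "rooted_rf",
    "topology_distance",
]

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    scores: pd.DataFrame       # samples x components
    loadings: pd.DataFrame     # ions x components
    variance_explained: np.ndarray  # fraction per component, non-increasing


@dataclass
class Dendrogram:
    """Agglomerative clustering of samples (scipy linkage encoding)."""

    linkage: np.ndarray   # (n-1, 4) scipy linkage matrix
    labels: list[str]     # sample ids in the order clustered

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


class NonMonophylyError(ValueError):
    """A diet's samples do not form a clade in the dendrogram."""


def scale_matrix(table: FeatureTable | pd.DataFrame) -> pd.DataFrame:
    """Per-ion centering and unit-variance scaling (samples x ions).

    Each ion is centred to mean 0 and scaled to sample standard
    deviation 1 (n-1 denominator).  Ions constant across samples carry
    no information for distances or PCA and are dropped with a logged
    count; an all-constant table is an error.
    """
    areas = table.areas if isinstance(table, FeatureTable) else table
    X = areas.T  # samples x ions
    if X.shape[0] < 2:
        raise ValueError("scaling requires at least 2 samples")
    sd = X.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.all():
        raise ValueError("every ion is constant across samples")
    if constant.any():
        logger.warning("dropping %d constant ions before scaling", int(constant.sum()))
    X = X.loc[:, ~constant]
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)


def pca(scaled: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """PCA of a scaled samples x ions matrix via SVD.

    Components are deterministic up to sign; the sign is fixed so that
    each component's largest-magnitude loading is positive.
    ``variance_explained`` fractions are relative to total variance and
    non-increasing.
    """
    X = scaled.to_numpy(dtype=float)
    X = X - X.mean(axis=0)  # defensive re-centre; no-op on scale_matrix output
    rank_cap = min(X.shape[0] - 1, X.shape[1])
    if n_components is None:
        n_components = rank_cap
    if not 1 <= n_components <= rank_cap:
        raise ValueError(f"n_components must be in [1, {rank_cap}]")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    if not np.any(S > 0):
        raise ValueError("degenerate input: zero total variance")
    var = S**2 / np.sum(S**2)
    k = n_components
    scores = U[:, :k] * S[:k]
    loadings = Vt[:k].T
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=scaled.index, columns=comp),
        loadings=pd.DataFrame(loadings, index=scaled.columns, columns=comp),
        variance_explained=var[:k],
    )


def hclust_dendrogram(scaled: pd.DataFrame, linkage: str = "ward") -> Dendrogram:
    """Agglomerative clustering of samples on Euclidean distances.

    Samples are sorted by id before clustering so that the result does
    not depend on input order (ties in the distance matrix are then
    broken identically for any input permutation).
    """
    if scaled.shape[0] < 2:
        raise ValueError("clustering requires at least 2 samples")
    ordered = scaled.sort_index()
    Z = hierarchy.linkage(ordered.to_numpy(dtype=float), method=linkage, metric="euclidean")
    return Dendrogram(linkage=Z, labels=list(ordered.index))


def _clade_sets(dend: Dendrogram) -> list[set[int]]:
    n = dend.n_leaves
    clades: dict[int, set[int]] = {i: {i} for i in range(n)}
    out = []
    for step, (a, b, _h, _c) in enumerate(dend.linkage):
        merged = clades[int(a)] | clades[int(b)]
        clades[n + step] = merged
        out.append(merged)
    return out


def diet_tree_newick(dend: Dendrogram, sample_diets: Mapping[str, str]) -> str:
    """Collapse a sample dendrogram to one leaf per diet (Newick).

    Requires each diet's samples to be monophyletic in the dendrogram;
    otherwise raises :class:`NonMonophylyError` naming the offending
    diet, since a diet-level topology is then not defined.
    """
    labels = dend.labels
    diets = [sample_diets[s] for s in labels]
    by_diet: dict[str, set[int]] = {}
    for i, d in enumerate(diets):
        by_diet.setdefault(d, set()).add(i)
    clades = _clade_sets(dend)
    clade_lookup = {frozenset(c) for c in clades}
    for d, members in by_diet.items():
        if len(members) > 1 and frozenset(members) not in clade_lookup:
            raise NonMonophylyError(f"samples of diet {d!r} are not monophyletic")

    n = len(labels)

    def render(node: int) -> tuple[str, set[str]]:
        if node < n:
            return diets[node], {diets[node]}
        a, b = int(dend.linkage[node - n, 0]), int(dend.linkage[node - n, 1])
        sa, da = render(a)
        sb, db = render(b)
        if da == db and len(da) == 1:
            return next(iter(da)), da
        if da & db:
            raise NonMonophylyError(f"diets {sorted(da & db)} straddle a merge")
        left, right = sorted([sa, sb])  # deterministic child order
        return f"({left},{right})", da | db

    root = 2 * n - 2
    body, _ = render(root)
    return body + ";"


def _rooted_clades(tree: dendropy.Tree) -> set[frozenset[str]]:
    clades = set()
    for node in tree.preorder_internal_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        clades.add(leaves)
    return clades


def rooted_rf(tree_a: str | dendropy.Tree, tree_b: str | dendropy.Tree) -> int:
    """Rooted Robinson-Foulds count: clades in exactly one topology.

    Symmetric in its two arguments; 0 iff the rooted topologies are
    identical.  The trivial root clade is never counted.
    """

    def as_tree(t):
        if isinstance(t, dendropy.Tree):
            return t
        return dendropy.Tree.get(data=t, schema="newick")

    t1, t2 = as_tree(tree_a), as_tree(tree_b)
    leaves1 = {l.taxon.label for l in t1.leaf_node_iter()}
    leaves2 = {l.taxon.label for l in t2.leaf_node_iter()}
    if leaves1 != leaves2:
        raise ValueError(f"leaf sets differ: {sorted(leaves1 ^ leaves2)}")
    c1, c2 = _rooted_clades(t1), _rooted_clades(t2)
    c1.discard(frozenset(leaves1))
    c2.discard(frozenset(leaves2))
    return len(c1 ^ c2)


def topology_distance(
    dend: Dendrogram,
    reference: str | dendropy.Tree,
    sample_diets: Mapping[str, str],
) -> int:
    """Robinson-Foulds distance between the diet-level dendrogram and a
    reference tree.

    The dendrogram is collapsed to one leaf per diet (requires
    monophyly), both trees are treated as rooted, and the count of
    clades present in exactly one of the two topologies is returned.
    0 means identical topologies.
    """
    return rooted_rf(diet_tree_newick(dend, sample_diets), reference)
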