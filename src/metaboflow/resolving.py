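"""Qualitative-vs-quantitative diet resolving power.

How many randomly chosen ions does it take to recover each sample's
diet?  Random ion batches of increasing size are drawn from the fly
table; samples are clustered (Ward, Euclidean, cut at the number of
diets) on either the quantitative areas or the per-sample 0/1 detection
profile, clusters are mapped to diets by the optimal one-to-one
assignment, and classification accuracy plus Adjusted Mutual
Information (AMI) are averaged over repetitions.

AMI follows the exact permutation-model correction: the expected mutual
information (EMI) under fixed margins is the exact hypergeometric sum,
and ``ami = (MI - EMI) / (max(H_u, H_v) - EMI)`` (the max-normalised
variant).  All information quantities are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from .core import FeatureTable

__all__ = [
    "AMIResult",
    "ResolvingCurve",
    "classify_by_clustering",
    "adjusted_mutual_information",
    "expected_mutual_information",
    "per_sample_presence",
    "resolving_power_curves",
    "DEFAULT_BATCH_SIZES",
]

DEFAULT_BATCH_SIZES = (10, 30, 100, 300, 1000, 3000, 10000)


@dataclass(frozen=True)
class AMIResult:
    mi: float    # mutual information (nats)
    emi: float   # expected MI under the fixed-margins permutation model
    h_u: float   # entropy of the first partition
    h_v: float   # entropy of the second partition
    ami: float   # adjusted score, <= 1


@dataclass
class ResolvingCurve:
    """Mean accuracy / AMI per (data mode, batch size)."""

    table: pd.DataFrame  # columns: mode, batch_size, mean_accuracy, mean_ami,
                         # se_accuracy, se_ami, n_reps

    def for_mode(self, mode: str) -> pd.DataFrame:
        sub = self.table[self.table["mode"] == mode]
        return sub.sort_values("batch_size").reset_index(drop=True)


def _contingency(labels_a, labels_b) -> np.ndarray:
    a = pd.Categorical(labels_a)
    b = pd.Categorical(labels_b)
    table = np.zeros((len(a.categories), len(b.categories)), dtype=int)
    np.add.at(table, (a.codes, b.codes), 1)
    return table


def _entropy(margins: np.ndarray, n: int) -> float:
    p = margins[margins > 0] / n
    return float(-np.sum(p * np.log(p)))


def expected_mutual_information(a_margins, b_margins) -> float:
    """Exact EMI (nats) under the hypergeometric fixed-margins model."""
    a = np.asarray(a_margins, dtype=int)
    b = np.asarray(b_margins, dtype=int)
    a, b = a[a > 0], b[b > 0]
    if a.sum() != b.sum():
        raise ValueError("margins must sum to the same total")
    n = int(a.sum())
    emi = 0.0
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            for nij in range(lo, hi + 1):
                log_w = (
                    gammaln(ai + 1) + gammaln(bj + 1)
                    + gammaln(n - ai + 1) + gammaln(n - bj + 1)
                    - gammaln(n + 1) - gammaln(nij + 1)
                    - gammaln(ai - nij + 1) - gammaln(bj - nij + 1)
                    - gammaln(n - ai - bj + nij + 1)
                )
                emi += (nij / n) * np.log(n * nij / (ai * bj)) * np.exp(log_w)
    return float(emi)


def adjusted_mutual_information(labels_a, labels_b) -> AMIResult:
    """AMI between two partitions (max-normalised, exact EMI).

    Degenerate cases: when the normaliser ``max(H_u, H_v) - EMI``
    vanishes, the score is 1 for identical trivial partitions and 0
    otherwise (so a single-cluster partition against anything
    non-identical scores 0).
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape or labels_a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    if labels_a.size == 0:
        raise ValueError("label vectors must be non-empty")
    table = _contingency(labels_a, labels_b)
    n = int(table.sum())
    a_m, b_m = table.sum(axis=1), table.sum(axis=0)
    h_u, h_v = _entropy(a_m, n), _entropy(b_m, n)

    nz = table > 0
    nij = table[nz].astype(float)
    outer = np.outer(a_m, b_m)[nz].astype(float)
    mi = float(np.sum((nij / n) * np.log(n * nij / outer)))
    emi = expected_mutual_information(a_m, b_m)

    denom = max(h_u, h_v) - emi
    if denom <= 1e-12:
        identical = np.all(table.max(axis=0) == b_m) and np.all(table.max(axis=1) == a_m)
        ami = 1.0 if identical else 0.0
    else:
        ami = (mi - emi) / denom
    return AMIResult(mi=mi, emi=emi, h_u=h_u, h_v=h_v, ami=float(ami))


def classify_by_clustering(X, true_labels, k: int | None = None) -> tuple[np.ndarray, float]:
    """Cluster samples and score the best cluster-to-diet assignment.

    Features are centred and scaled (constant features dropped), samples
    are Ward-clustered on Euclidean distances and the tree is cut at
    ``k`` clusters (default: the number of distinct true labels).
    Clusters are matched to labels by the one-to-one assignment
    maximising total matches; accuracy is the matched fraction, which
    makes the score invariant under any renaming of the true labels.
    """
    X = np.asarray(X, dtype=float)
    true_labels = np.asarray(true_labels)
    n = X.shape[0]
    if k is None:
        k = len(np.unique(true_labels))
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} samples")
    sd = X.std(axis=0)
    varying = sd > 0
    if varying.any():
        Xs = (X[:, varying] - X[:, varying].mean(axis=0)) / sd[varying]
        Z = hierarchy.linkage(Xs, method="ward", metric="euclidean")
        pred = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    else:
        # all samples indistinguishable: a single degenerate cluster
        pred = np.ones(n, dtype=int)
    table = _contingency(pred, true_labels)
    r, c = linear_sum_assignment(-table)
    accuracy = float(table[r, c].sum() / n)
    return pred, accuracy


def per_sample_presence(table: FeatureTable, area_threshold: float = 1000.0) -> pd.DataFrame:
    """Per-sample 0/1 detection profile (samples x ions).

    Unlike the group-level presence matrix, no replicate pooling is
    applied: each sample keeps its own profile, as required for
    clustering samples on qualitative data.
    """
    return (table.areas > area_threshold).T.astype(float)


def resolving_power_curves(
    fly_table: FeatureTable,
    batch_sizes=None,
    n_reps: int = 10_000,
    seed: int = 0,
    modes: tuple[str, ...] = ("quantitative", "qualitative"),
    area_threshold: float = 1000.0,
    k: int | None = None,
) -> ResolvingCurve:
    """Mean accuracy and AMI of diet recovery from random ion batches.

    For each batch size, ``n_reps`` uniform ion subsets (without
    replacement) are drawn; the same subset is used for both data modes
    so the qualitative/quantitative comparison is paired.  Reported
    standard errors are Monte-Carlo errors of the means.  ``n_reps``
    defaults to the full 10,000 repetitions; test suites and quick
    explorations typically use the reduced 200.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n_ions = fly_table.n_ions
    if batch_sizes is None:
        batch_sizes = [s for s in DEFAULT_BATCH_SIZES if s <= n_ions]
    batch_sizes = sorted(int(s) for s in batch_sizes)
    if batch_sizes[-1] > n_ions:
        raise ValueError(f"batch size {batch_sizes[-1]} exceeds the {n_ions} ions")
    bad = set(modes) - {"quantitative", "qualitative"}
    if bad:
        raise ValueError(f"unknown modes: {sorted(bad)}")

    sample_ids = list(fly_table.areas.columns)
    labels = fly_table.samples.loc[sample_ids, "diet"].to_numpy()
    data = {}
    if "quantitative" in modes:
        data["quantitative"] = fly_table.areas.T.to_numpy(dtype=float)
    if "qualitative" in modes:
        data["qualitative"] = per_sample_presence(fly_table, area_threshold).to_numpy()

    rng = np.random.default_rng(seed)
    rows = []
    for size in batch_sizes:
        acc = {m: np.empty(n_reps) for m in data}
        ami = {m: np.empty(n_reps) for m in data}
        for rep in range(n_reps):
            subset = rng.choice(n_ions, size=size, replace=False)
            for mode, mat in data.items():
                pred, a = classify_by_clustering(mat[:, subset], labels, k=k)
                acc[mode][rep] = a
                ami[mode][rep] = adjusted_mutual_information(pred, labels).ami
        for mode in data:
            rows.append({
                "mode": mode,
                "batch_size": size,
                "mean_accuracy": float(acc[mode].mean()),
                "mean_ami": float(ami[mode].mean()),
                "se_accuracy": float(acc[mode].std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0,
                "se_ami": float(ami[mode].std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0,
                "n_reps": n_reps,
            })
    return ResolvingCurve(table=pd.DataFrame(rows))
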