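"""Consensus fuzzy clustering of signatures and percentile-thresholded
signature networks.

Signatures are unit vectors, so Euclidean fuzzy c-means on the normalized
inputs optimizes the cosine geometry directly (for unit vectors, squared
Euclidean distance = 2 x cosine distance). Cluster labels are aligned across
repeated runs by greedy centroid matching, and each signature is assigned to
the cluster it lands in most often among runs where its membership clears
the cutoff.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import binomtest

logger = logging.getLogger(__name__)

#: Assignment value for conditions whose membership never clears the cutoff.
UNASSIGNED = -1

DEFAULT_K = 20
DEFAULT_EXPONENT = 1.22
DEFAULT_MEMBERSHIP_CUTOFF = 0.55
DEFAULT_N_RUNS = 101


@dataclass
class ClusterModel:
    k: int
    exponent: float
    membership_cutoff: float
    n_runs: int
    memberships: np.ndarray  # n_conditions x k, row-stochastic (median-objective run)
    assignment: np.ndarray   # cluster id per condition, UNASSIGNED where unstable
    centroids: np.ndarray    # k x G, from the median-objective run
    seed: int | None = None

    @property
    def n_assigned(self) -> int:
        return int(np.count_nonzero(self.assignment != UNASSIGNED))


@dataclass
class SignatureNetwork:
    nodes: list
    edges: list[tuple[int, int, float]]  # (i, j, cosine distance)
    q: float
    threshold: float

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.nodes)))
        g.add_weighted_edges_from(self.edges, weight="cosine_distance")
        return g


def _fcm_run(
    X: np.ndarray,
    k: int,
    m: float,
    rng: np.random.Generator,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One fuzzy c-means run. Returns (memberships, centroids, objective).

    Centroids are initialized from k distinct data points. Empty clusters
    (zero total membership mass) keep their previous centroid.
    """
    n = X.shape[0]
    centroids = X[rng.choice(n, size=k, replace=False)].copy()
    power = 2.0 / (m - 1.0)
    u = np.full((n, k), 1.0 / k)
    obj = np.inf
    for _ in range(max_iter):
        d2 = (
            np.sum(X**2, axis=1)[:, None]
            - 2.0 * X @ centroids.T
            + np.sum(centroids**2, axis=1)[None, :]
        )
        np.clip(d2, 1e-12, None, out=d2)
        inv = d2 ** (-power / 2.0)
        u = inv / inv.sum(axis=1, keepdims=True)
        um = u**m
        mass = um.sum(axis=0)
        new_centroids = centroids.copy()
        nonempty = mass > 1e-12
        new_centroids[nonempty] = (um.T[nonempty] @ X) / mass[nonempty, None]
        new_obj = float((um * d2).sum())
        shift = float(np.abs(new_centroids - centroids).max())
        centroids = new_centroids
        if abs(obj - new_obj) < tol and shift < tol:
            obj = new_obj
            break
        obj = new_obj
    return u, centroids, obj


def _align_to_reference(
    centroids: np.ndarray, reference: np.ndarray
) -> np.ndarray:
    """Greedy permutation mapping run clusters onto reference clusters by
    maximum centroid cosine similarity."""
    k = centroids.shape[0]

    def _unit(M):
        norms = np.linalg.norm(M, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return M / norms

    sim = _unit(centroids) @ _unit(reference).T
    perm = np.full(k, -1, dtype=int)
    used_rows, used_cols = set(), set()
    order = np.argsort(sim, axis=None)[::-1]
    for flat in order:
        r, c = divmod(int(flat), k)
        if r in used_rows or c in used_cols:
            continue
        perm[r] = c
        used_rows.add(r)
        used_cols.add(c)
        if len(used_rows) == k:
            break
    return perm


def fuzzy_cluster(
    vectors: np.ndarray,
    k: int = DEFAULT_K,
    exponent: float = DEFAULT_EXPONENT,
    membership_cutoff: float = DEFAULT_MEMBERSHIP_CUTOFF,
    n_runs: int = DEFAULT_N_RUNS,
    seed: int | None = None,
) -> ClusterModel:
    """Consensus fuzzy c-means over ``n_runs`` independent initializations.

    Per run, labels are aligned to run 1 by greedy centroid matching; a
    condition counts toward a cluster only in runs where its aligned maximum
    membership is >= ``membership_cutoff``. The majority cluster across
    qualifying runs is the assignment (ties broken toward the cluster with
    the higher mean membership); conditions with no qualifying run are
    UNASSIGNED. Reported memberships come from the run with median objective.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("vectors must be a non-empty n x G matrix")
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of conditions ({n})")
    X = X / np.linalg.norm(X, axis=1, keepdims=True)

    rng = np.random.default_rng(seed)
    reference: np.ndarray | None = None
    objectives: list[float] = []
    aligned_memberships: list[np.ndarray] = []
    votes = np.zeros((n, k), dtype=int)
    membership_sums = np.zeros((n, k))

    for run in range(n_runs):
        u, centroids, obj = _fcm_run(X, k, exponent, rng)
        if reference is None:
            reference = centroids
            perm = np.arange(k)
        else:
            perm = _align_to_reference(centroids, reference)
        u_aligned = np.empty_like(u)
        u_aligned[:, perm] = u
        aligned_memberships.append(u_aligned)
        objectives.append(obj)
        best = u_aligned.argmax(axis=1)
        best_u = u_aligned.max(axis=1)
        qualifies = best_u >= membership_cutoff
        votes[np.arange(n)[qualifies], best[qualifies]] += 1
        membership_sums += u_aligned

    assignment = np.full(n, UNASSIGNED, dtype=int)
    for i in range(n):
        total = votes[i].sum()
        if total == 0:
            continue
        top = votes[i].max()
        tied = np.flatnonzero(votes[i] == top)
        if len(tied) == 1:
            assignment[i] = int(tied[0])
        else:  # tie -> higher mean membership
            assignment[i] = int(tied[np.argmax(membership_sums[i, tied])])

    median_run = int(np.argsort(objectives)[len(objectives) // 2])
    logger.info(
        "fuzzy_cluster: n=%d k=%d runs=%d -> %d assigned, %d unassigned",
        n, k, n_runs,
        int(np.count_nonzero(assignment != UNASSIGNED)),
        int(np.count_nonzero(assignment == UNASSIGNED)),
    )
    return ClusterModel(
        k=k,
        exponent=exponent,
        membership_cutoff=membership_cutoff,
        n_runs=n_runs,
        memberships=aligned_memberships[median_run],
        assignment=assignment,
        centroids=reference if reference is not None else np.empty((0, X.shape[1])),
        seed=seed,
    )


def consensus_signature(members: list[np.ndarray]) -> np.ndarray | None:
    """Arithmetic mean of member signatures (not re-normalized).

    Returns None with a warning for an empty cluster; warns when members
    cancel to a (near-)zero vector.
    """
    if len(members) == 0:
        logger.warning("consensus_signature: empty cluster, no signature")
        return None
    mean = np.asarray(members, dtype=float).mean(axis=0)
    if np.linalg.norm(mean) < 1e-10:
        logger.warning("consensus_signature: members cancel to a zero vector")
    return mean


def build_network(vectors: np.ndarray, q: float, nodes: list | None = None) -> SignatureNetwork:
    """Connect signature pairs whose cosine distance falls in the lower
    ``q``-percentile of all pairwise distances (linear-interpolation
    percentile; ties at the threshold are included)."""
    X = np.asarray(vectors, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 signatures to build a network")
    unit = X / np.linalg.norm(X, axis=1, keepdims=True)
    gram = unit @ unit.T
    iu = np.triu_indices(n, k=1)
    dists = 1.0 - gram[iu]
    threshold = float(np.percentile(dists, q))
    mask = dists <= threshold
    edges = [
        (int(i), int(j), float(d))
        for i, j, d in zip(iu[0][mask], iu[1][mask], dists[mask])
    ]
    logger.info(
        "build_network: n=%d q=%g -> threshold %.4g, %d/%d edges",
        n, q, threshold, len(edges), dists.size,
    )
    return SignatureNetwork(
        nodes=list(nodes) if nodes is not None else list(range(n)),
        edges=edges,
        q=q,
        threshold=threshold,
    )


def cluster_enrichment(
    model: ClusterModel,
    labels: list,
) -> list[dict]:
    """One-sided binomial enrichment of each category in each cluster.

    For every (cluster, category) pair, tests whether the category's count in
    the cluster exceeds expectation under the category's global frequency.
    """
    labels = list(labels)
    if len(labels) != len(model.assignment):
        raise ValueError("one label required per condition")
    if any(l is None for l in labels):
        raise ValueError("every condition must be labeled")
    global_counts = Counter(labels)
    total = len(labels)
    rows = []
    for cluster in range(model.k):
        members = [labels[i] for i in np.flatnonzero(model.assignment == cluster)]
        size = len(members)
        if size == 0:
            continue
        counts = Counter(members)
        for category, gcount in global_counts.items():
            count = counts.get(category, 0)
            p = binomtest(
                count, n=size, p=gcount / total, alternative="greater"
            ).pvalue
            rows.append(
                {
                    "cluster": cluster,
                    "category": category,
                    "count": count,
                    "cluster_size": size,
                    "global_freq": gcount / total,
                    "p_value": float(p),
                }
            )
    return rows
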