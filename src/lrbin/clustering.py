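"""Choosing the number of read bins and clustering latent embeddings.

The bin count scales linearly with community diversity, k = a * H with
a = 8 and H the Shannon diversity (natural-log entropy of the species
abundance distribution), rounded half-up and floored at 2 -- e.g.
H = 3.75 gives k = 30 and H = 4.625 gives k = 37.

Clustering is Lloyd's k-means seeded by random-projection hashing
(RPH): points are hashed by the signs of random projections (taken
about the weighted data mean) into buckets, and buckets are collapsed
to centroids over one or more levels, forming a skeleton whose spatial
density is roughly uniform no matter how uneven the cluster masses are.
Seeds are picked and polished by k-means on the skeleton points with
uniform weights, which allocates one seed per structural cluster rather
than per unit of mass -- the property that makes the method robust to
strongly uneven bin sizes; the full data is then refined by Lloyd
iterations from those seeds.  Empty clusters are repaired
deterministically by re-seeding with the point currently farthest from
its assigned centroid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score


@dataclass(frozen=True)
class ClusteringConfig:
    """Bin-count rule and RPH-kmeans initialization parameters.

    Exactly one of ``shannon_diversity`` / ``k_override`` determines k.
    ``n_projections`` defaults to ceil(log2 k) + 4; ``init`` may be set
    to ``"kmeans++"`` to bypass the RPH skeleton.
    """

    a_coefficient: float = 8.0
    shannon_diversity: float | None = None
    k_override: int | None = None
    n_projections: int | None = None
    hash_levels: int = 2
    n_init: int = 8
    seed: int = 0
    max_iter: int = 300
    init: str = "rph"
    normalize: bool = True

    def resolve_k(self) -> int:
        if (self.shannon_diversity is None) == (self.k_override is None):
            raise ValueError("exactly one of shannon_diversity / k_override must be set")
        if self.k_override is not None:
            if self.k_override < 2:
                raise ValueError("k must be at least 2")
            return self.k_override
        return choose_k(self.shannon_diversity, self.a_coefficient)


@dataclass
class BinAssignment:
    """Barcode -> bin-id map produced by clustering."""

    labels: np.ndarray
    k: int
    barcodes: list[str] | None = None
    wcss_history: list[float] = field(default_factory=list)

    @property
    def bin_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)

    def mapping(self) -> dict[str, int]:
        if self.barcodes is None:
            raise ValueError("assignment carries no barcode names")
        return dict(zip(self.barcodes, map(int, self.labels)))


def choose_k(shannon_diversity: float, a: float = 8.0) -> int:
    """Bin count k = round(a * H), half-up, floored at 2."""
    if shannon_diversity is None or shannon_diversity <= 0:
        raise ValueError("shannon diversity must be positive")
    return max(2, int(math.floor(a * shannon_diversity + 0.5)))


def _rph_skeleton(X: np.ndarray, k: int, n_projections: int, hash_levels: int,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Collapse points into mass-weighted bucket centroids by grid hashing.

    Points are bucketed by the floor of randomly projected, randomly
    offset coordinates (p-stable LSH).  Cell occupancy then scales with
    the volume a cluster occupies, not with its mass or its position
    relative to the data mean, so the skeleton represents dense and
    sparse clusters about equally -- the key to imbalance robustness.
    Each level coarsens the previous skeleton with a wider grid.
    """
    pts = X
    wts = np.ones(X.shape[0])
    for level in range(hash_levels):
        if pts.shape[0] <= max(4 * k, 16):
            break
        proj = rng.standard_normal((X.shape[1], n_projections))
        proj /= np.linalg.norm(proj, axis=0, keepdims=True)
        y = pts @ proj
        scale = np.sqrt(np.average((y - np.average(y, axis=0, weights=wts)) ** 2,
                                   axis=0, weights=wts))
        width = scale * (1.0 + level)
        width[width <= 0] = 1.0
        cells = np.floor(y / width + rng.random(n_projections)).astype(np.int64)
        _, inverse = np.unique(cells, axis=0, return_inverse=True)
        n_buckets = int(inverse.max()) + 1
        mass = np.zeros(n_buckets)
        np.add.at(mass, inverse, wts)
        centroids = np.zeros((n_buckets, X.shape[1]))
        np.add.at(centroids, inverse, pts * wts[:, None])
        centroids /= mass[:, None]
        pts, wts = centroids, mass
    return pts, wts


def _weighted_kmeanspp(pts: np.ndarray, wts: np.ndarray, k: int,
                       rng: np.random.Generator) -> np.ndarray:
    """k-means++ over (optionally weighted) skeleton points."""
    n = pts.shape[0]
    seeds = np.empty((k, pts.shape[1]))
    first = rng.choice(n, p=wts / wts.sum())
    seeds[0] = pts[first]
    d2 = np.sum((pts - seeds[0]) ** 2, axis=1)
    for i in range(1, k):
        p = wts * d2
        total = p.sum()
        if total <= 0:  # all mass on chosen locations: spread deterministically
            idx = int(np.argmax(d2))
        else:
            idx = rng.choice(n, p=p / total)
        seeds[i] = pts[idx]
        d2 = np.minimum(d2, np.sum((pts - seeds[i]) ** 2, axis=1))
    return seeds


def _polish_on_skeleton(pts: np.ndarray, seeds: np.ndarray, iters: int = 30) -> tuple[np.ndarray, float]:
    """Unweighted Lloyd iterations on the skeleton points only.

    The skeleton has roughly uniform spatial density regardless of how
    many original points each bucket absorbed, so polishing seeds here
    places one centroid per structural cluster instead of allocating
    centroids proportionally to cluster mass -- the property that makes
    the initialization robust to strongly uneven bin sizes.  Returns the
    polished seeds and their skeleton-level objective.
    """
    k = seeds.shape[0]
    lab = None
    for _ in range(iters):
        d2 = np.sum((pts[:, None, :] - seeds[None, :, :]) ** 2, axis=2)
        lab = d2.argmin(axis=1)
        new = np.stack([
            pts[lab == j].mean(axis=0) if np.any(lab == j) else seeds[j]
            for j in range(k)
        ])
        if np.allclose(new, seeds):
            break
        seeds = new
    d2 = np.sum((pts[:, None, :] - seeds[None, :, :]) ** 2, axis=2)
    wcss = float(d2.min(axis=1).sum())
    return seeds, wcss


def _init_seeds(X: np.ndarray, k: int, config: ClusteringConfig,
                rng: np.random.Generator) -> np.ndarray:
    if config.init == "kmeans++":
        from sklearn.cluster import kmeans_plusplus

        seeds, _ = kmeans_plusplus(X, k, random_state=int(rng.integers(2**31)))
        return seeds
    n_proj = config.n_projections or (math.ceil(math.log2(max(k, 2))) + 4)
    pts, wts = _rph_skeleton(X, k, n_proj, config.hash_levels, rng)
    if pts.shape[0] >= k:
        # structure-driven seeding: several unweighted k-means++ starts on
        # the skeleton, keeping the best skeleton-level objective
        best_seeds, best_wcss = None, np.inf
        for _ in range(config.n_init):
            seeds = _weighted_kmeanspp(pts, np.ones(pts.shape[0]), k, rng)
            seeds, wcss = _polish_on_skeleton(pts, seeds)
            if wcss < best_wcss:
                best_seeds, best_wcss = seeds, wcss
        return best_seeds
    # fewer skeleton points than seeds: take all, pad by farthest-point traversal
    seeds = [p for p in pts]
    d2 = np.min(
        np.stack([np.sum((X - s) ** 2, axis=1) for s in seeds]), axis=0
    )
    while len(seeds) < k:
        idx = int(np.argmax(d2))
        seeds.append(X[idx])
        d2 = np.minimum(d2, np.sum((X - X[idx]) ** 2, axis=1))
    return np.stack(seeds)


def cluster_latent(
    embeddings: np.ndarray,
    k: int,
    config: ClusteringConfig = ClusteringConfig(k_override=2),
    barcodes: Sequence[str] | None = None,
) -> BinAssignment:
    """Partition embedding rows into k bins (RPH-seeded Lloyd iterations).

    Deterministic under ``config.seed``; permutation of the input rows
    permutes the labels identically up to bin relabeling.  ``n >= k``
    required.
    """
    X = np.asarray(embeddings, dtype=np.float64)
    n = X.shape[0]
    if n < k:
        raise ValueError(f"cannot form {k} bins from {n} points; choose a smaller k")
    if config.normalize:
        # cosine geometry: rows scaled to unit norm.  The embedder encodes
        # continuous per-barcode depth variation along a high-variance
        # radial direction; normalizing collapses it while preserving the
        # angular separation between genomes (the usual latent metric in
        # VAE-based metagenomic binning).
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        X = X / np.maximum(norms, 1e-12)
    rng = np.random.default_rng(config.seed)
    centroids = _init_seeds(X, k, config, rng)
    labels = np.full(n, -1, dtype=np.int64)
    history: list[float] = []
    for _ in range(config.max_iter):
        d2 = np.sum((X[:, None, :] - centroids[None, :, :]) ** 2, axis=2)
        new_labels = np.argmin(d2, axis=1)
        history.append(float(d2[np.arange(n), new_labels].sum()))
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            members = labels == j
            if members.any():
                centroids[j] = X[members].mean(axis=0)
        # empty-cluster repair: re-seed with the point farthest from its centroid
        dist_own = np.sqrt(np.sum((X - centroids[labels]) ** 2, axis=1))
        for j in range(k):
            if not np.any(labels == j):
                idx = int(np.argmax(dist_own))
                centroids[j] = X[idx]
                labels[idx] = j
                dist_own[idx] = 0.0
    return BinAssignment(labels=labels, k=k,
                         barcodes=list(barcodes) if barcodes is not None else None,
                         wcss_history=history)


def evaluate_binning(
    assignment: BinAssignment | np.ndarray,
    truth: Mapping[str, str] | Sequence,
) -> tuple[float, float, float]:
    """(precision, recall, adjusted Rand index) of a binning vs truth.

    Precision is the size-weighted purity of the bins (fraction of reads
    whose bin's majority genome is their own); recall is the
    size-weighted completeness of the genomes (fraction kept in their
    genome's largest bin).  ``truth`` is either a barcode -> genome map
    (requiring barcode names on the assignment) or a label sequence
    aligned with the assignment rows.
    """
    if isinstance(assignment, BinAssignment):
        labels = assignment.labels
        if isinstance(truth, Mapping):
            if assignment.barcodes is None:
                raise ValueError("assignment has no barcodes to join on")
            keep = [i for i, bc in enumerate(assignment.barcodes) if bc in truth]
            if not keep:
                raise ValueError("no overlap between assignment barcodes and truth")
            labels = labels[keep]
            truth_labels = np.array([truth[assignment.barcodes[i]] for i in keep])
        else:
            truth_labels = np.asarray(truth)
    else:
        labels = np.asarray(assignment)
        truth_labels = np.asarray(truth)
    if labels.size == 0 or labels.size != truth_labels.size:
        raise ValueError("assignment and truth must align on a non-empty set")
    genomes, g_idx = np.unique(truth_labels, return_inverse=True)
    bins, b_idx = np.unique(labels, return_inverse=True)
    table = np.zeros((bins.size, genomes.size), dtype=np.int64)
    np.add.at(table, (b_idx, g_idx), 1)
    n = labels.size
    precision = float(table.max(axis=1).sum() / n)
    recall = float(table.max(axis=0).sum() / n)
    ari = float(adjusted_rand_score(truth_labels, labels))
    return precision, recall, ari
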