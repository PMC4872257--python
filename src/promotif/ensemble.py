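"""Subsample-ensemble motif discovery and redundancy resolution.

Discovery engines that assume a motif is present in most input sequences
can miss motifs carried by only a fraction of a gene list.  Running the
engines over many small random subsets of the promoters raises the chance
that some subset is enriched enough for the motif to clear its
significance gate; the price is heavy redundancy, which is resolved by
k-medoids clustering of the pooled motifs under the inter-motif distance,
with each cluster represented by its position-wise average PWM.

The :class:`MotifDiscoveryModel` / :class:`MotifDiscoveryResults` pair is
the object interface over these stages: build the model from promoter
regions, ``fit`` runs subsets -> engines -> pooling -> clustering ->
averaging and returns results carrying the clusters, their representative
motifs and a summary table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .discovery import EngineConfig, discover_motifs
from .genome_io import BackgroundModel, UpstreamRegion, build_background
from .motifs import Motif, best_alignment, motif_distance

logger = logging.getLogger(__name__)

DEFAULT_N_SUBSETS = 5000
DEFAULT_SUBSET_SIZE = 10


@dataclass(frozen=True)
class SubsetCollection:
    """Random promoter subsets: independently drawn, each without
    replacement within itself (a gene may appear in many subsets)."""

    subsets: tuple[tuple[str, ...], ...]
    subset_size: int
    seed: int

    @property
    def n_subsets(self) -> int:
        return len(self.subsets)


@dataclass
class MotifCluster:
    """One redundancy cluster: members, medoid, average and within-cost."""

    members: list[Motif]
    medoid: int
    average: Motif
    total_within_cost: float

    @property
    def medoid_motif(self) -> Motif:
        return self.members[self.medoid]


def make_subsets(gene_ids: Sequence[str],
                 n_subsets: int = DEFAULT_N_SUBSETS,
                 subset_size: int = DEFAULT_SUBSET_SIZE,
                 seed: int = 0) -> SubsetCollection:
    """Draw ``n_subsets`` random subsets of ``subset_size`` distinct genes."""
    gene_ids = list(gene_ids)
    if subset_size > len(gene_ids):
        raise ValueError(
            f"subset_size {subset_size} exceeds population size "
            f"{len(gene_ids)}")
    rng = np.random.default_rng(seed)
    subsets = tuple(
        tuple(gene_ids[i] for i in rng.choice(len(gene_ids),
                                              size=subset_size,
                                              replace=False))
        for _ in range(n_subsets))
    return SubsetCollection(subsets, subset_size, seed)


def run_ensemble(regions: Sequence[UpstreamRegion],
                 collection: SubsetCollection,
                 background: BackgroundModel,
                 configs: Sequence[EngineConfig]) -> list[Motif]:
    """Run every engine on every subset and pool the significant motifs.

    Each pooled motif is tagged with its subset index, engine and rank;
    order is deterministic (subset index, engine order, rank).
    """
    by_gene: dict[str, UpstreamRegion] = {r.gene_id: r for r in regions}
    pooled: list[Motif] = []
    for si, subset_ids in enumerate(collection.subsets):
        try:
            subset = [by_gene[g] for g in subset_ids]
        except KeyError as exc:
            raise ValueError(
                f"subset {si} references gene {exc.args[0]!r} with no "
                f"upstream region") from None
        for config in configs:
            for rank, motif in enumerate(
                    discover_motifs(subset, background, config), start=1):
                pooled.append(motif.with_meta(
                    provenance=f"subset={si};engine={config.engine};"
                               f"rank={rank}"))
    logger.info("ensemble: %d subsets x %d engines -> %d pooled motifs",
                collection.n_subsets, len(configs), len(pooled))
    return pooled


# ---------------------------------------------------------------------------
# k-medoids (PAM) under the inter-motif distance

def pairwise_distances(motifs: Sequence[Motif],
                       min_overlap: int = 4) -> np.ndarray:
    n = len(motifs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = motif_distance(motifs[i], motifs[j],
                                               min_overlap)
    return D


def _pam(D: np.ndarray, k: int, rng: np.random.Generator,
         restarts: int = 10) -> tuple[np.ndarray, np.ndarray, float]:
    """PAM alternation with random restarts; returns (labels, medoids,
    cost) of the best restart."""
    n = D.shape[0]
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(restarts):
        medoids = np.sort(rng.choice(n, size=k, replace=False))
        prev_cost = np.inf
        while True:
            labels = np.argmin(D[:, medoids], axis=1)
            labels[medoids] = np.arange(k)  # a medoid stays in its cluster
            new_medoids = medoids.copy()
            for ci in range(k):
                members = np.nonzero(labels == ci)[0]
                if members.size == 0:
                    continue
                within = D[np.ix_(members, members)].sum(axis=1)
                new_medoids[ci] = members[int(np.argmin(within))]
            medoids = np.sort(np.unique(new_medoids))
            if medoids.size < k:  # degenerate collapse; refill randomly
                pool = np.setdiff1d(np.arange(n), medoids)
                extra = rng.choice(pool, size=k - medoids.size,
                                   replace=False)
                medoids = np.sort(np.concatenate([medoids, extra]))
            labels = np.argmin(D[:, medoids], axis=1)
            labels[medoids] = np.arange(medoids.size)
            cost = float(D[np.arange(n), medoids[labels]].sum())
            if cost >= prev_cost - 1e-12:
                break
            prev_cost = cost
        if best is None or cost < best[2]:
            best = (labels, medoids, cost)
    assert best is not None
    return best


def cluster_motifs_kmedoids(motifs: Sequence[Motif], k: int | str = "auto",
                            min_overlap: int = 4, restarts: int = 10,
                            seed: int = 0) -> list[MotifCluster]:
    """Cluster redundant motifs by PAM k-medoids under the inter-motif
    distance.

    ``k="auto"`` sweeps k = 2..min(20, n-1) and keeps the k with maximal
    mean silhouette (ties -> smallest k); when all pairwise distances are
    zero a single cluster is returned.
    """
    motifs = list(motifs)
    n = len(motifs)
    if n == 0:
        return []
    if n == 1:
        return [_make_cluster(motifs, np.array([0]), 0, 0.0)]
    D = pairwise_distances(motifs, min_overlap)
    rng = np.random.default_rng(seed)

    if isinstance(k, str):
        if k != "auto":
            raise ValueError(f"k must be an integer or 'auto', got {k!r}")
        k = _auto_k(D, rng, restarts)
    if k >= n:
        logger.warning("k=%d >= n=%d motifs: each motif its own cluster",
                       k, n)
        return [_make_cluster(motifs, np.array([i]), 0, 0.0)
                for i in range(n)]
    if k < 1:
        raise ValueError("k must be >= 1")

    labels, medoids, _ = _pam(D, k, rng, restarts)
    clusters = []
    for ci, medoid in enumerate(medoids):
        member_idx = np.nonzero(labels == ci)[0]
        cost = float(D[member_idx, medoid].sum())
        clusters.append(_make_cluster(
            [motifs[i] for i in member_idx], member_idx,
            int(np.nonzero(member_idx == medoid)[0][0]), cost))
    clusters.sort(key=lambda c: (-len(c.members), c.average.consensus))
    return clusters


def _auto_k(D: np.ndarray, rng: np.random.Generator, restarts: int) -> int:
    n = D.shape[0]
    if D.max() <= 1e-12 or n <= 2:
        return 1
    best_k, best_sil = 1, -np.inf
    for k in range(2, min(20, n - 1) + 1):
        labels, _, _ = _pam(D, k, rng, restarts)
        if len(np.unique(labels)) < 2:
            continue
        try:
            sil = float(silhouette_score(D, labels, metric="precomputed"))
        except ValueError:
            continue
        if np.isnan(sil):
            continue
        if sil > best_sil + 1e-12:
            best_k, best_sil = k, sil
    return best_k


def _make_cluster(members: list[Motif], member_idx: np.ndarray,
                  medoid_local: int, cost: float) -> MotifCluster:
    avg = average_cluster(members, medoid=medoid_local)
    return MotifCluster(members, medoid_local, avg, cost)


def average_cluster(members: Sequence[Motif], medoid: int | None = None,
                    min_overlap: int = 4,
                    min_coverage: float = 0.5) -> Motif:
    """Position-wise average PWM of a cluster.

    Every member is aligned to the medoid at its best offset and
    orientation; columns are averaged over the members covering each
    position; positions covered by fewer than ``min_coverage`` of the
    members are trimmed (longest contiguous covered run kept); columns are
    renormalized and the consensus recomputed.
    """
    members = list(members)
    if not members:
        raise ValueError("average_cluster requires at least one member")
    if medoid is None:
        if len(members) == 1:
            medoid = 0
        else:
            D = pairwise_distances(members, min_overlap)
            medoid = int(np.argmin(D.sum(axis=1)))
    ref = members[medoid]

    placements = []  # (offset, matrix in medoid orientation)
    for m in members:
        _, off, orient = best_alignment(ref, m, min_overlap)
        mat = m.matrix if orient == "+" else m.matrix[::-1, [3, 2, 1, 0]]
        placements.append((off, mat))
    lo = min(off for off, _ in placements)
    hi = max(off + mat.shape[0] for off, mat in placements)
    width = hi - lo
    total = np.zeros((width, 4))
    cover = np.zeros(width)
    for off, mat in placements:
        s = off - lo
        total[s:s + mat.shape[0]] += mat
        cover[s:s + mat.shape[0]] += 1
    keep = cover >= min_coverage * len(members)
    if not keep.any():
        keep = cover == cover.max()
    start, end = _longest_run(keep)
    avg = total[start:end] / cover[start:end, None]
    avg = avg / avg.sum(axis=1, keepdims=True)
    return Motif(avg, source="average",
                 provenance=f"n_members={len(members)}")


def _longest_run(mask: np.ndarray) -> tuple[int, int]:
    best = (0, 0)
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i > best[1] - best[0]:
                best = (i, j)
            i = j
        else:
            i += 1
    return best


# ---------------------------------------------------------------------------
# model / results interface

class MotifDiscoveryModel:
    """Subsample-ensemble motif discovery over a set of promoter regions.

    Parameters
    ----------
    regions
        Upstream flanking regions of the gene list under study.
    background
        Word-frequency background; when omitted it is built from the
        regions themselves (order ``background_order``).  For genome-scale
        analyses pass a background built over *all* genes' upstream
        regions.
    engine_configs
        Engines to run per subset; defaults to a single ``seed_qvalue``
        engine at q <= 0.05.
    n_subsets, subset_size
        Ensemble geometry; defaults 5000 subsets of 10 promoters.
    cluster_k
        Number of redundancy clusters, or ``"auto"`` for a silhouette
        sweep.
    """

    def __init__(self, regions: Sequence[UpstreamRegion],
                 background: BackgroundModel | None = None,
                 engine_configs: Sequence[EngineConfig] | None = None,
                 n_subsets: int = DEFAULT_N_SUBSETS,
                 subset_size: int = DEFAULT_SUBSET_SIZE,
                 cluster_k: int | str = "auto",
                 background_order: int = 4,
                 min_overlap: int = 4):
        if not regions:
            raise ValueError("no regions supplied")
        self.regions = list(regions)
        self.background = background if background is not None \
            else build_background(self.regions, background_order)
        self.engine_configs = list(engine_configs) if engine_configs \
            else [EngineConfig()]
        if subset_size > len(self.regions):
            raise ValueError(
                f"subset_size {subset_size} exceeds the {len(self.regions)} "
                f"available regions")
        self.n_subsets = n_subsets
        self.subset_size = subset_size
        self.cluster_k = cluster_k
        self.min_overlap = min_overlap

    def fit(self, seed: int = 0) -> "MotifDiscoveryResults":
        """Run subsets -> engines -> pooling -> clustering -> averaging."""
        rng = np.random.default_rng(seed)
        subset_seed = int(rng.integers(2 ** 31))
        cluster_seed = int(rng.integers(2 ** 31))
        collection = make_subsets([r.gene_id for r in self.regions],
                                  self.n_subsets, self.subset_size,
                                  subset_seed)
        pooled = run_ensemble(self.regions, collection, self.background,
                              self.engine_configs)
        if pooled:
            clusters = cluster_motifs_kmedoids(
                pooled, self.cluster_k, self.min_overlap, seed=cluster_seed)
        else:
            clusters = []
        return MotifDiscoveryResults(self, collection, pooled, clusters,
                                     seed)


class MotifDiscoveryResults:
    """Fitted ensemble: pooled motifs, redundancy clusters and their
    representative (average) motifs."""

    def __init__(self, model: MotifDiscoveryModel,
                 collection: SubsetCollection, pooled: list[Motif],
                 clusters: list[MotifCluster], seed: int):
        self.model = model
        self.collection = collection
        self.pooled_motifs = pooled
        self.clusters = clusters
        self.seed = seed

    @property
    def cluster_averages(self) -> list[Motif]:
        return [c.average.with_meta(provenance=f"cluster={i}")
                for i, c in enumerate(self.clusters)]

    def summary(self) -> pd.DataFrame:
        """Per-cluster report: size, medoid and average consensus,
        within-cluster cost and contributing engines."""
        rows = []
        for i, c in enumerate(self.clusters):
            engines = sorted({m.source for m in c.members})
            rows.append({
                "cluster": i,
                "n_members": len(c.members),
                "medoid_consensus": c.medoid_motif.consensus,
                "average_consensus": c.average.consensus,
                "width": c.average.width,
                "within_cost": round(c.total_within_cost, 6),
                "engines": ",".join(engines),
            })
        return pd.DataFrame(rows, columns=[
            "cluster", "n_members", "medoid_consensus", "average_consensus",
            "width", "within_cost", "engines"])

    def scan(self, regions: Sequence[UpstreamRegion] | None = None,
             score_fraction: float = 0.85):
        """Map every cluster average back onto regions (the model's own
        regions by default); returns the pooled instance list."""
        from .map_annotate import scan_regions
        regions = regions if regions is not None else self.model.regions
        instances = []
        for i, avg in enumerate(self.cluster_averages):
            instances.extend(scan_regions(avg, regions,
                                          self.model.background,
                                          score_fraction,
                                          motif_id=f"cluster={i}"))
        return instances

    def match_database(self, database, top_n: int = 5):
        """Rank database entries against every cluster average."""
        from .map_annotate import match_database
        return {f"cluster={i}": match_database(avg, database, top_n)
                for i, avg in enumerate(self.cluster_averages)}
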