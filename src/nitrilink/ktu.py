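"""Re-cluster amplicon sequence variants by k-mer composition.

ASVs are embedded as counts over the 4^k DNA k-mers (lexicographic order),
L2-normalized to remove length effects, and partitioned with the classical
PAM algorithm (BUILD + SWAP on Euclidean distance).  The number of clusters
is selected by mean silhouette width over a scanned range, and each
cluster's medoid ASV becomes its representative: cluster counts are the
per-sample sums of member-ASV counts.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

log = logging.getLogger("nitrilink")

_BASES = "ACGT"


class KtuInputError(ValueError):
    pass


def kmer_index(k: int) -> dict:
    """Lexicographic k-mer -> position map over the 4^k DNA k-mers."""
    return {
        "".join(p): i
        for i, p in enumerate(itertools.product(_BASES, repeat=k))
    }


def kmer_profile(sequence: str, k: int = 4) -> np.ndarray:
    """Sliding-window k-mer counts; windows containing N are skipped.

    Parameters
    ----------
    sequence : str
        DNA over {A,C,G,T,N}; must be at least ``k`` long.

    Returns
    -------
    ndarray of shape (4**k,)
        Counts in fixed lexicographic k-mer order.
    """
    seq = sequence.upper()
    if len(seq) < k:
        raise KtuInputError(
            f"sequence of length {len(seq)} is shorter than k={k}"
        )
    bad = set(seq) - set(_BASES + "N")
    if bad:
        raise KtuInputError(f"invalid characters in sequence: {sorted(bad)}")
    profile = np.zeros(4**k, dtype=float)
    digits = np.array(
        [{"A": 0, "C": 1, "G": 2, "T": 3}.get(c, -1) for c in seq]
    )
    powers = 4 ** np.arange(k - 1, -1, -1)
    for start in range(len(seq) - k + 1):
        window = digits[start : start + k]
        if (window < 0).any():
            continue
        profile[int(window @ powers)] += 1
    return profile


def _pairwise_euclidean(points: np.ndarray) -> np.ndarray:
    sq = np.sum(points**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * points @ points.T
    np.maximum(d2, 0.0, out=d2)
    return np.sqrt(d2)


def _pam_build(dist: np.ndarray, k: int) -> list:
    n = dist.shape[0]
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    nearest = dist[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        best = int(np.argmax(gains))
        medoids.append(best)
        nearest = np.minimum(nearest, dist[:, best])
    return medoids


def pam_cluster(profiles: np.ndarray, n_clusters: int, seed: int = 0):
    """Partitioning around medoids on Euclidean distance.

    Classical PAM: greedy BUILD initialization followed by SWAP steps that
    each apply the single best (medoid, non-medoid) exchange until no swap
    lowers the total distance of points to their nearest medoid.  The
    ``seed`` only breaks exact ties deterministically (the algorithm itself
    is deterministic).

    Returns
    -------
    labels : ndarray of int
        Cluster index per point, numbered by medoid order.
    medoids : ndarray of int
        Row indices of the medoid points, one per cluster.
    """
    points = np.asarray(profiles, dtype=float)
    if points.ndim != 2:
        raise KtuInputError("profiles must be a 2-D array")
    n = points.shape[0]
    if n_clusters < 1:
        raise KtuInputError("n_clusters must be >= 1")
    if n_clusters > n:
        raise KtuInputError("n_clusters exceeds the number of profiles")
    dist = _pairwise_euclidean(points)
    medoids = _pam_build(dist, n_clusters)

    def cost(meds):
        return dist[:, meds].min(axis=1).sum()

    current = cost(medoids)
    improved = True
    while improved:
        improved = False
        best_delta, best_swap = -1e-12, None
        med_set = set(medoids)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in med_set:
                    continue
                trial = list(medoids)
                trial[mi] = h
                delta = current - cost(trial)
                if delta > best_delta + 1e-12:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is not None:
            medoids[best_swap[0]] = best_swap[1]
            current -= best_delta
            improved = True
    medoids = sorted(medoids)
    labels = np.argmin(dist[:, medoids], axis=1)
    # a medoid always belongs to its own cluster even under ties
    for ci, m in enumerate(medoids):
        labels[m] = ci
    return labels.astype(int), np.asarray(medoids, dtype=int)


def _mean_silhouette(dist: np.ndarray, labels: np.ndarray) -> float:
    if len(set(labels.tolist())) < 2:
        return 0.0  # degenerate single-cluster partition
    return float(silhouette_score(dist, labels, metric="precomputed"))


@dataclass(frozen=True)
class KtuMapping:
    """ASV -> KTU assignment with per-KTU medoid ASVs."""

    asv_to_ktu: dict
    ktu_to_medoid: dict

    def to_frame(self) -> pd.DataFrame:
        medoids = set(self.ktu_to_medoid.values())
        return pd.DataFrame(
            {
                "asv_id": list(self.asv_to_ktu),
                "ktu_id": list(self.asv_to_ktu.values()),
                "is_medoid": [a in medoids for a in self.asv_to_ktu],
            }
        )


def cluster_asvs(
    sequences,
    counts: pd.DataFrame,
    k: int = 4,
    cluster_range=None,
    seed: int = 0,
):
    """Re-cluster ASVs into k-mer units and aggregate their counts.

    Parameters
    ----------
    sequences : list of (id, sequence)
        One record per ASV; every count-table column must have a sequence.
    counts : DataFrame
        Samples-by-ASV counts.
    cluster_range : iterable of int, optional
        Candidate cluster numbers; the partition maximizing mean silhouette
        width wins, ties broken toward fewer clusters.  Defaults to
        2..min(n_asvs - 1, 12) (plus the degenerate cases when n_asvs < 3).

    Returns
    -------
    ktu_counts : DataFrame
        Samples-by-KTU counts (per-sample sums of member-ASV counts).
    mapping : KtuMapping
    """
    seq_map = dict(sequences)
    missing = [t for t in counts.columns if t not in seq_map]
    if missing:
        raise KtuInputError(f"count-table taxa without sequences: {missing}")
    asv_ids = list(counts.columns)
    n = len(asv_ids)
    profiles = np.vstack([kmer_profile(seq_map[a], k) for a in asv_ids])
    norms = np.linalg.norm(profiles, axis=1)
    norms[norms == 0] = 1.0
    profiles = profiles / norms[:, None]

    if cluster_range is None:
        cluster_range = range(1, n + 1) if n < 3 else range(2, min(n - 1, 12) + 1)
    cluster_range = sorted(set(int(c) for c in cluster_range))
    if not cluster_range or cluster_range[0] < 1 or cluster_range[-1] > n:
        raise KtuInputError(
            f"cluster_range must lie within [1, {n}] and be nonempty"
        )

    dist = _pairwise_euclidean(profiles)
    best = None
    for n_clusters in cluster_range:
        labels, medoids = pam_cluster(profiles, n_clusters, seed=seed)
        score = _mean_silhouette(dist, labels)
        if best is None or score > best[0] + 1e-12:
            best = (score, labels, medoids)
    _, labels, medoids = best

    ktu_ids = [f"KTU{ci + 1:04d}" for ci in range(len(medoids))]
    asv_to_ktu = {asv_ids[i]: ktu_ids[labels[i]] for i in range(n)}
    ktu_to_medoid = {ktu_ids[ci]: asv_ids[m] for ci, m in enumerate(medoids)}
    agg = counts.T.groupby(pd.Series(asv_to_ktu)).sum().T
    agg = agg.loc[:, ktu_ids]
    return agg, KtuMapping(asv_to_ktu, ktu_to_medoid)
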