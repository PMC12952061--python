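"""Content-based image retrieval over embedding galleries.

A query embedding is compared against a gallery (training-split embeddings
only) under three complementary distances — correlation (1 - Pearson),
standardized Euclidean (per-feature variance weighting), and Spearman rank
correlation distance — each yielding its own top-k candidate set.  The three
sets are fused by majority voting: a candidate scores one vote per metric
whose set contains it, and the ``n`` highest-voted candidates (ties broken by
mean within-metric rank, then correlation distance, then gallery index) form
the final ranked retrieval shown alongside the classifier's prediction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

__all__ = [
    "DegenerateInputError", "MetricID", "METRICS",
    "EmbeddingGallery", "CandidateSet", "VoteTable", "RankedRetrieval",
    "correlation_distance", "standardized_euclidean", "spearman_distance",
    "build_gallery", "retrieve_candidates", "majority_vote", "select_final",
    "retrieve", "save_gallery", "load_gallery",
]

METRICS = ("C", "SE", "S")  # correlation, standardized Euclidean, Spearman
MetricID = str


class DegenerateInputError(ValueError):
    """Raised when a correlation-type distance is undefined (constant vector)."""


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _check_pair(x, y, min_len=2):
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < min_len:
        raise ValueError(f"vectors must have at least {min_len} entries")
    return x, y


def correlation_distance(x, y) -> float:
    """1 - Pearson correlation, in [0, 2]."""
    x, y = _check_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation distance undefined for a constant vector")
    return float(cdist(x[None], y[None], metric="correlation")[0, 0])


def standardized_euclidean(x, y, s) -> float:
    """sqrt(sum (x_i - y_i)^2 / s_i^2) with per-feature standard deviations s."""
    x, y = _check_pair(x, y, min_len=1)
    s = np.asarray(s, dtype=np.float64)
    if s.shape != x.shape:
        raise ValueError("std vector must match the feature dimension")
    if np.any(s <= 0):
        raise ValueError("feature standard deviations must be strictly positive "
                         "(gallery construction sanitizes zero variance)")
    return float(cdist(x[None], y[None], metric="seuclidean", V=s ** 2)[0, 0])


def spearman_distance(x, y) -> float:
    """1 - Spearman rank correlation, in [0, 2], tie-safe via average ranks."""
    x, y = _check_pair(x, y)
    rx = rankdata(x)
    ry = rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise DegenerateInputError("spearman distance undefined for a constant vector")
    return float(cdist(rx[None], ry[None], metric="correlation")[0, 0])


# ---------------------------------------------------------------------------
# gallery
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingGallery:
    """Search substrate: gallery embeddings with labels, patient ids and the
    per-feature standard deviations used by the standardized Euclidean metric."""
    embeddings: np.ndarray      # (n, d)
    labels: np.ndarray          # (n,)
    patient_ids: np.ndarray     # (n,)
    feature_stds: np.ndarray    # (d,)
    image_ids: np.ndarray | None = None

    def __len__(self):
        return self.embeddings.shape[0]


def build_gallery(embeddings, labels, patient_ids, image_ids=None) -> EmbeddingGallery:
    """Assemble a gallery; zero-variance features get unit std (with a warning)
    so the standardized Euclidean metric stays defined without dropping them."""
    emb = np.asarray(embeddings, dtype=np.float64)
    if emb.ndim != 2 or emb.shape[0] < 2:
        raise ValueError("gallery needs at least two embedding rows")
    labels = np.asarray(labels)
    patient_ids = np.asarray(patient_ids)
    if len(labels) != len(emb) or len(patient_ids) != len(emb):
        raise ValueError("labels and patient ids must align with embedding rows")
    stds = emb.std(axis=0, ddof=1)
    zero = stds == 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} zero-variance gallery feature(s); replacing their "
            "std with 1 (neutral) for the standardized Euclidean metric",
            stacklevel=2)
        stds = np.where(zero, 1.0, stds)
    image_ids = (np.arange(len(emb)) if image_ids is None else np.asarray(image_ids))
    return EmbeddingGallery(emb, labels, patient_ids, stds, image_ids)


# ---------------------------------------------------------------------------
# candidate sets, voting, final ranking
# ---------------------------------------------------------------------------

@dataclass
class CandidateSet:
    metric: MetricID
    indices: np.ndarray    # gallery row indices, ascending distance
    distances: np.ndarray  # aligned with indices

    def rank_of(self) -> dict[int, int]:
        return {int(j): r + 1 for r, j in enumerate(self.indices)}


@dataclass
class VoteTable:
    """Per-candidate vote counts with the tie-break keys used downstream."""
    candidates: np.ndarray       # unique gallery indices, any order
    votes: np.ndarray            # in {1, 2, 3}
    mean_rank: np.ndarray        # mean within-metric rank (absent -> k + 1)
    corr_distance: np.ndarray    # correlation distance to the query


@dataclass
class RankedRetrieval:
    indices: np.ndarray   # gallery rows, final ranks 1..len
    labels: np.ndarray
    votes: np.ndarray

    @property
    def ranks(self) -> np.ndarray:
        return np.arange(1, len(self.indices) + 1)


def _query_distances(query: np.ndarray, gallery: EmbeddingGallery,
                     metric: MetricID) -> np.ndarray:
    q = np.asarray(query, dtype=np.float64)[None]
    emb = gallery.embeddings
    if metric == "C":
        if np.ptp(q) == 0:
            raise DegenerateInputError("constant query under correlation distance")
        if np.any(np.ptp(emb, axis=1) == 0):
            raise DegenerateInputError("constant gallery row under correlation distance")
        return cdist(q, emb, metric="correlation")[0]
    if metric == "SE":
        return cdist(q, emb, metric="seuclidean", V=gallery.feature_stds ** 2)[0]
    if metric == "S":
        rq = rankdata(q[0])[None]
        remb = np.apply_along_axis(rankdata, 1, emb)
        if np.ptp(rq) == 0 or np.any(np.ptp(remb, axis=1) == 0):
            raise DegenerateInputError("constant vector under spearman distance")
        return cdist(rq, remb, metric="correlation")[0]
    raise ValueError(f"unknown metric id {metric!r}; expected one of {METRICS}")


def retrieve_candidates(query, gallery: EmbeddingGallery, metric: MetricID,
                        k: int = 30) -> CandidateSet:
    """Top-k gallery rows by ascending distance; ties broken by gallery index."""
    d = _query_distances(query, gallery, metric)
    order = np.lexsort((np.arange(len(d)), d))  # distance, then index
    top = order[:k]
    return CandidateSet(metric, top, d[top])


def majority_vote(sets: list[CandidateSet], query=None,
                  gallery: EmbeddingGallery | None = None, k: int = 30) -> VoteTable:
    """Count, per candidate, how many of the three metrics retrieved it."""
    ids = [s.metric for s in sets]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate metric ids in candidate sets")
    all_idx = np.unique(np.concatenate([s.indices for s in sets]))
    votes = np.zeros(len(all_idx), dtype=int)
    rank_sum = np.zeros(len(all_idx))
    rank_n = np.zeros(len(all_idx), dtype=int)
    pos = {int(j): i for i, j in enumerate(all_idx)}
    for s in sets:
        for r, j in enumerate(s.indices, start=1):
            i = pos[int(j)]
            votes[i] += 1
            rank_sum[i] += r
            rank_n[i] += 1
    # a metric that did not retrieve the candidate contributes rank k + 1
    mean_rank = (rank_sum + (len(sets) - rank_n) * (k + 1)) / len(sets)
    if query is not None and gallery is not None:
        corr = _query_distances(query, gallery, "C")[all_idx]
    else:
        cset = next((s for s in sets if s.metric == "C"), None)
        corr = np.full(len(all_idx), np.inf)
        if cset is not None:
            lookup = dict(zip(cset.indices.tolist(), cset.distances.tolist()))
            corr = np.array([lookup.get(int(j), np.inf) for j in all_idx])
    return VoteTable(all_idx, votes, mean_rank, corr)


def select_final(table: VoteTable, gallery: EmbeddingGallery | None = None,
                 n: int = 10) -> RankedRetrieval:
    """Final ranking: votes desc, mean within-metric rank asc, correlation
    distance asc, gallery index asc; the first ``n`` get ranks 1..n."""
    if len(table.candidates) == 0:
        raise ValueError("empty vote table")
    order = np.lexsort((table.candidates, table.corr_distance,
                        table.mean_rank, -table.votes))
    chosen = order[:n]
    idx = table.candidates[chosen]
    labels = gallery.labels[idx] if gallery is not None else np.full(len(idx), None)
    return RankedRetrieval(idx, labels, table.votes[chosen])


def retrieve(query, gallery: EmbeddingGallery, k: int = 30, n: int = 10,
             metrics: tuple[MetricID, ...] = METRICS) -> RankedRetrieval:
    """Full pipeline: per-metric candidate sets -> majority vote -> top-n."""
    sets = [retrieve_candidates(query, gallery, m, k=k) for m in metrics]
    table = majority_vote(sets, query=query, gallery=gallery, k=k)
    return select_final(table, gallery, n=n)


# ---------------------------------------------------------------------------
# persistence: array archive + delimited metadata + JSON manifest
# ---------------------------------------------------------------------------

def save_gallery(gallery: EmbeddingGallery, directory, seed: int | None = None,
                 source_split: str = "train"):
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "embeddings.npz", embeddings=gallery.embeddings)
    pd.DataFrame({
        "image_id": gallery.image_ids,
        "patient_id": gallery.patient_ids,
        "label": gallery.labels,
    }).to_csv(directory / "metadata.csv", index=False)
    manifest = {
        "n": int(len(gallery)),
        "d": int(gallery.embeddings.shape[1]),
        "feature_stds": gallery.feature_stds.tolist(),
        "creation_seed": seed,
        "source_split": source_split,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_gallery(directory) -> EmbeddingGallery:
    directory = Path(directory)
    with np.load(directory / "embeddings.npz") as archive:
        emb = archive["embeddings"]
    meta = pd.read_csv(directory / "metadata.csv")
    manifest = json.loads((directory / "manifest.json").read_text())
    return EmbeddingGallery(
        embeddings=emb,
        labels=meta["label"].to_numpy(),
        patient_ids=meta["patient_id"].to_numpy(),
        feature_stds=np.asarray(manifest["feature_stds"], dtype=np.float64),
        image_ids=meta["image_id"].to_numpy(),
    )
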