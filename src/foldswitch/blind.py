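"""Blind mode: detect alternative conformations without reference structures.

The predicted ensemble is first cleaned of unfolded models by an outlier
rule on secondary-structure content, then an all-against-all structural
similarity matrix is built from symmetrised TM-score and lDDT (an equal-
weight composite standing in for a structural bitscore; the sequence term
is irrelevant because every member shares one sequence).  PCA reduces the
matrix rows to a low-dimensional embedding, HDBSCAN groups the points, and
K-medoids picks up to three representative members per cluster.  Because
alternative conformations are often assigned low predictor confidence,
representatives carry their mean plDDT so users can weigh them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import HDBSCAN
from sklearn.decomposition import PCA

from .structure import (StructureModel, pairwise_lddt_matrix,
                        pairwise_tm_matrix, secondary_structure)

__all__ = [
    "SimilarityMatrix",
    "PcaEmbedding",
    "ClusterReport",
    "filter_unfolded",
    "similarity_matrix",
    "reduce_pca",
    "cluster_hdbscan",
    "select_representatives",
    "blind_pipeline",
]

NOISE = -1


@dataclass
class SimilarityMatrix:
    """Symmetric [0, 1] similarity with member ids on rows/columns."""

    matrix: np.ndarray
    ids: list

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("similarity matrix must be square")
        if len(self.ids) != m.shape[0]:
            raise ValueError("ids must match matrix size")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-8):
            raise ValueError("similarity diagonal must be 1")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class PcaEmbedding:
    coords: np.ndarray                 # (n, k)
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]


@dataclass
class ClusterReport:
    """Output of the blind pipeline."""

    ids: list                      # kept member ids, aligned to labels
    removed_ids: list
    similarity: SimilarityMatrix
    embedding: PcaEmbedding
    labels: np.ndarray             # cluster label per kept member; -1 = noise
    representatives: dict          # cluster label -> list of member ids
    representative_confidence: dict  # member id -> mean plDDT
    cluster_sizes: dict


# ---------------------------------------------------------------------------
# composition filter

def ss_content(model: StructureModel) -> float:
    """Fraction of residues assigned helix or strand."""
    labels = secondary_structure(model)
    return sum(1 for s in labels if s in ("H", "E")) / len(labels)


def filter_unfolded(models: list, ids: list | None = None):
    """Remove secondary-structure-content outliers (unfolded predictions).

    Member content s = fraction of H/E residues; members with
    s < Q1 - 1.5 IQR of the ensemble distribution are removed.  A zero-IQR
    (homogeneous) ensemble removes nothing, and at most half of the ensemble
    is ever removed (warning on cap).  Returns (kept models, kept ids,
    removed ids).
    """
    if ids is None:
        ids = list(range(len(models)))
    if len(models) < 4:
        warnings.warn("ensemble smaller than 4; skipping unfolded filter")
        return list(models), list(ids), []
    s = np.array([ss_content(m) for m in models])
    q1, q3 = np.percentile(s, [25, 75])
    low = q1 - 1.5 * (q3 - q1)
    drop = np.where(s < low)[0]
    cap = len(models) // 2
    if len(drop) > cap:
        warnings.warn(
            f"unfolded filter would remove {len(drop)}/{len(models)} members; "
            f"capped at 50%")
        drop = drop[np.argsort(s[drop])][:cap]
    drop_set = set(drop.tolist())
    kept = [m for k, m in enumerate(models) if k not in drop_set]
    kept_ids = [i for k, i in enumerate(ids) if k not in drop_set]
    removed_ids = [ids[k] for k in sorted(drop_set)]
    return kept, kept_ids, removed_ids


# ---------------------------------------------------------------------------
# similarity

def similarity_matrix(models: list, ids: list | None = None,
                      weights: dict | None = None,
                      external_scorer=None) -> SimilarityMatrix:
    """All-against-all composite structural similarity.

    S(i, j) = w_tm * TMsym + w_lddt * LDDTsym, both symmetrised over the
    two normalisation/reference directions.  ``external_scorer`` may
    substitute a true structural-bitscore backend: a callable
    ``models -> raw matrix``, rescaled here to [0, 1] with unit diagonal.
    """
    if ids is None:
        ids = [getattr(m, "name", "") or str(k) for k, m in enumerate(models)]
    if external_scorer is not None:
        raw = np.asarray(external_scorer(models), dtype=float)
        d = np.sqrt(np.outer(np.diag(raw), np.diag(raw)))
        S = np.clip(raw / np.where(d > 0, d, 1.0), 0.0, 1.0)
        S = 0.5 * (S + S.T)
        np.fill_diagonal(S, 1.0)
        return SimilarityMatrix(S, list(ids))
    weights = weights or {"tm": 0.5, "lddt": 0.5}
    if abs(sum(weights.values()) - 1.0) > 1e-9:
        raise ValueError("similarity weights must sum to 1")
    lengths = {len(m) for m in models}
    if len(lengths) != 1:
        raise ValueError("all ensemble members must share one sequence length")
    coords = np.stack([m.ca_coords() for m in models])
    S = np.zeros((len(models), len(models)))
    if weights.get("tm", 0.0):
        S += weights["tm"] * pairwise_tm_matrix(coords)
    if weights.get("lddt", 0.0):
        S += weights["lddt"] * pairwise_lddt_matrix(coords)
    S = 0.5 * (S + S.T)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S, list(ids))


# ---------------------------------------------------------------------------
# reduction and clustering

def reduce_pca(similarity: SimilarityMatrix, variance_target: float = 0.9,
               min_components: int = 2) -> PcaEmbedding:
    """PCA on the rows of the similarity matrix.

    Keeps the smallest component count whose cumulative explained variance
    reaches ``variance_target``, floored at ``min_components``.  Component
    signs are fixed by making each component's largest-magnitude loading
    positive, so the embedding is fully deterministic.
    """
    n = similarity.n
    if n < 3:
        raise ValueError("PCA reduction needs at least 3 members")
    max_comp = min(n - 1, n)
    pca = PCA(n_components=max_comp, svd_solver="full")
    scores = pca.fit_transform(similarity.matrix)
    if pca.explained_variance_.sum() < 1e-10:
        # degenerate: members indistinguishable up to numerical jitter
        k = min(min_components, max_comp)
    else:
        cum = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, variance_target) + 1)
        k = max(min_components, min(k, max_comp))
    comps = pca.components_[:k]
    scores = scores[:, :k]
    for c in range(k):
        j = int(np.argmax(np.abs(comps[c])))
        if comps[c, j] < 0:
            comps[c] *= -1.0
            scores[:, c] *= -1.0
    return PcaEmbedding(scores, pca.explained_variance_ratio_[:k])


def cluster_hdbscan(embedding: PcaEmbedding,
                    min_cluster_size: int | None = None) -> np.ndarray:
    """Density-based clustering of the embedded ensemble (noise = -1).

    Default ``min_cluster_size`` is max(5, n/20).  If every point lands in
    noise, all points are folded back into a single cluster with a warning.
    """
    X = embedding.coords
    n = len(X)
    if min_cluster_size is None:
        min_cluster_size = max(5, n // 20)
    if n < min_cluster_size:
        raise ValueError(
            f"need at least min_cluster_size={min_cluster_size} points")
    labels = HDBSCAN(min_cluster_size=min_cluster_size, copy=True).fit_predict(X)
    if (labels == NOISE).all():
        warnings.warn("all points labeled noise; falling back to one cluster")
        labels = np.zeros(n, dtype=int)
    return labels


def _pam_medoids(D: np.ndarray, k: int) -> list[int]:
    """Deterministic PAM: quantile-seeded init, greedy swaps to convergence."""
    m = D.shape[0]
    k = min(k, m)
    # seed medoids at quantiles of the total-distance ordering; among tied
    # distance values the lowest member index wins
    totals = D.sum(axis=1)
    order = np.argsort(totals, kind="stable")
    qs = np.linspace(0.0, 1.0, k) if k > 1 else np.array([0.0])
    medoids: list[int] = []
    for q in qs:
        pos = int(round(q * (m - 1)))
        target = totals[order[pos]]
        candidates = sorted(i for i in range(m)
                            if totals[i] == target and i not in medoids)
        if not candidates:
            candidates = sorted(i for i in range(m) if i not in medoids)
        medoids.append(candidates[0])

    def cost(meds):
        return float(D[:, meds].min(axis=1).sum())

    current = cost(medoids)
    improved = True
    while improved:
        improved = False
        for mi in range(k):
            for cand in range(m):
                if cand in medoids:
                    continue
                trial = list(medoids)
                trial[mi] = cand
                c = cost(trial)
                if c < current - 1e-12:
                    medoids, current, improved = trial, c, True
    return sorted(medoids)


def select_representatives(embedding: PcaEmbedding, labels: np.ndarray,
                           k: int = 3) -> dict:
    """K-medoids exemplars per non-noise cluster (up to ``k`` each).

    Distances are Euclidean in the embedding.  Returns
    {cluster label: [member positions]} with positions referring to the
    embedding row order.
    """
    X = embedding.coords
    out: dict = {}
    for lab in sorted(set(labels.tolist())):
        if lab == NOISE:
            continue
        members = np.where(labels == lab)[0]
        sub = X[members]
        D = np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=-1)
        meds = _pam_medoids(D, min(k, len(members)))
        out[int(lab)] = [int(members[i]) for i in meds]
    if not out:
        raise ValueError("no non-noise cluster to represent")
    return out


# ---------------------------------------------------------------------------
# pipeline

def blind_pipeline(models: list, ids: list | None = None,
                   weights: dict | None = None,
                   variance_target: float = 0.9, min_components: int = 2,
                   min_cluster_size: int | None = None,
                   k_representatives: int = 3,
                   external_scorer=None) -> ClusterReport:
    """Composition filter -> similarity -> PCA -> HDBSCAN -> representatives."""
    if len(models) < 4:
        raise ValueError("blind mode needs an ensemble of at least 4 members")
    if ids is None:
        ids = [getattr(m, "name", "") or str(k) for k, m in enumerate(models)]
    kept, kept_ids, removed_ids = filter_unfolded(models, ids)
    sim = similarity_matrix(kept, kept_ids, weights, external_scorer)
    emb = reduce_pca(sim, variance_target, min_components)
    labels = cluster_hdbscan(emb, min_cluster_size)
    reps_pos = select_representatives(emb, labels, k_representatives)
    representatives = {lab: [kept_ids[p] for p in pos]
                       for lab, pos in reps_pos.items()}
    rep_conf = {}
    id_to_model = dict(zip(kept_ids, kept))
    for pos_list in representatives.values():
        for mid in pos_list:
            rep_conf[mid] = id_to_model[mid].mean_confidence
    sizes = {int(lab): int((labels == lab).sum())
             for lab in sorted(set(labels.tolist()))}
    return ClusterReport(
        ids=kept_ids, removed_ids=removed_ids, similarity=sim,
        embedding=emb, labels=labels, representatives=representatives,
        representative_confidence=rep_conf, cluster_sizes=sizes,
    )
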