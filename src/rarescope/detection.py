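"""Rare-event detection: PCA plus hierarchical clustering on the features.

Common nucleated cells (overwhelmingly leukocytes) form large, homogeneous
clusters in principal-component space; events falling in small clusters are
flagged rare.  DAPI-negative candidates bypass the clustering and enter the
rare stream by definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage


@dataclass(frozen=True)
class DetectionParams:
    variance_explained: float = 0.95   # PCA components retained
    n_clusters: int = 10               # tree cut for the common/rare split
    common_fraction: float = 0.20      # clusters above this share are common
    min_bulk_distance: float = 4.0     # centroid distance from the dominant
                                       # cluster, in units of its RMS spread
    min_events: int = 5                # below this, everything is rare


@dataclass
class DetectionResult:
    event_id: int
    is_rare: bool
    cluster_id: int
    rarity_score: float  # 1 − own-cluster share of all in-scope events
    low_confidence: bool = False


def reduce_dimensions(
    features: np.ndarray,
    variance_explained: float = 0.95,
    robust: bool = True,
    z_clip: float = 10.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardize features and project onto the leading principal components.

    Standardization is per feature; with ``robust`` (the default) the center
    is the median and the scale 1.4826 × MAD, so that the rare minority
    cannot inflate the scale of the features that make it stand out from the
    common-cell bulk, and scores are winsorized at ``± z_clip`` (plain
    mean/sd z-scoring otherwise).  Constant columns
    are dropped with a warning.  Components are retained up to the requested
    explained-variance fraction, with a deterministic sign convention (the
    largest-magnitude loading of each component is positive).

    Returns (scores, components, explained_variance_ratio).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    sd = X.std(axis=0, ddof=0)
    keep = sd > 1e-12
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant feature column(s)",
            stacklevel=2,
        )
    X = X[:, keep]
    if X.shape[1] == 0:
        return np.zeros((X.shape[0], 1)), np.zeros((1, 0)), np.array([1.0])
    if robust:
        center = np.median(X, axis=0)
        scale = 1.4826 * np.median(np.abs(X - center), axis=0)
        scale = np.where(scale > 1e-12, scale, X.std(axis=0, ddof=0))
        Z = (X - center) / scale
        # winsorize so one extreme phenotype direction cannot absorb the
        # whole variance budget and project the milder ones out
        Z = np.clip(Z, -z_clip, z_clip)
    else:
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    var = S**2 / (len(Z) - 1 if len(Z) > 1 else 1)
    ratio = var / var.sum() if var.sum() > 0 else np.ones_like(var) / len(var)
    ncomp = int(np.searchsorted(np.cumsum(ratio), variance_explained) + 1)
    ncomp = min(max(ncomp, 1), len(ratio))
    comps = Vt[:ncomp]
    # sign convention: largest absolute loading positive
    for i in range(ncomp):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    scores = Z @ comps.T
    return scores, comps, ratio[:ncomp]


def detect_rare(
    pc_coords: np.ndarray,
    dapi_positive: np.ndarray,
    event_ids: np.ndarray | None = None,
    params: DetectionParams | None = None,
) -> list[DetectionResult]:
    """Partition events into common and rare.

    Ward/Euclidean hierarchical clustering of the DAPI-positive events' PC
    coordinates, cut at ``n_clusters``.  Clusters holding more than
    ``common_fraction`` of the in-scope events are common; smaller clusters
    are rare when their centroid lies at least ``min_bulk_distance`` RMS
    spreads away from the dominant (common) cluster — fragments of the
    homogeneous leukocyte cloud stay common.  DAPI-negative events are rare
    by definition and take cluster id −1.  Fewer than ``min_events``
    DAPI-positive events ⇒ all rare with the low-confidence flag set.
    """
    params = params or DetectionParams()
    pc_coords = np.asarray(pc_coords, dtype=float)
    dapi_positive = np.asarray(dapi_positive, dtype=bool)
    n = len(dapi_positive)
    if event_ids is None:
        event_ids = np.arange(n)
    event_ids = np.asarray(event_ids)
    order = np.argsort(event_ids, kind="stable")  # order-invariance by event_id

    results: dict[int, DetectionResult] = {}
    pos_idx = [i for i in order if dapi_positive[i]]
    neg_idx = [i for i in order if not dapi_positive[i]]
    for i in neg_idx:
        results[i] = DetectionResult(
            event_id=int(event_ids[i]), is_rare=True, cluster_id=-1, rarity_score=1.0
        )
    m = len(pos_idx)
    if m == 0:
        pass
    elif m < params.min_events:
        warnings.warn("fewer than min_events in scope: flagging all rare", stacklevel=2)
        for i in pos_idx:
            results[i] = DetectionResult(
                event_id=int(event_ids[i]), is_rare=True, cluster_id=0,
                rarity_score=1.0, low_confidence=True,
            )
    else:
        X = pc_coords[pos_idx]
        m_total = m
        rare_mask = np.zeros(m, dtype=bool)
        cluster_of = np.zeros(m, dtype=int)
        scope = np.arange(m)
        next_cluster = 1
        bulk_center = None
        bulk_rms = 1.0
        # iterated cut: cluster the in-scope events, peel every small cluster
        # that is clearly displaced from the dominant (common) cluster, then
        # re-cluster the remainder so that less extreme rare phenotypes are
        # not shadowed by earlier, more extreme ones
        for _ in range(8):
            if len(scope) < max(params.min_events, 2):
                break
            Xs = X[scope]
            if np.allclose(Xs.std(axis=0), 0.0):
                break
            Z = linkage(Xs, method="ward")
            k = min(params.n_clusters, len(scope))
            labels = fcluster(Z, t=k, criterion="maxclust")
            sizes = np.bincount(labels)
            bulk = int(np.argmax(sizes[1:])) + 1
            if bulk_center is None:
                # the common-cell prototype: fixed in the first round so the
                # displacement scale cannot shrink as peeling purifies it
                bulk_pts = Xs[labels == bulk]
                bulk_center = bulk_pts.mean(axis=0)
                bulk_rms = max(
                    float(np.sqrt(((bulk_pts - bulk_center) ** 2).sum(axis=1).mean())),
                    1e-9,
                )
            peeled = np.zeros(len(scope), dtype=bool)
            for cl in range(1, labels.max() + 1):
                if sizes[cl] == 0 or sizes[cl] > params.common_fraction * len(scope):
                    continue
                center = Xs[labels == cl].mean(axis=0)
                dist = float(np.linalg.norm(center - bulk_center))
                if dist >= params.min_bulk_distance * bulk_rms:
                    sel = labels == cl
                    rare_mask[scope[sel]] = True
                    cluster_of[scope[sel]] = next_cluster
                    next_cluster += 1
                    peeled |= sel
            if not peeled.any():
                break
            scope = scope[~peeled]
        for i, k_idx in enumerate(pos_idx):
            own = int(np.sum(cluster_of == cluster_of[i]))
            results[k_idx] = DetectionResult(
                event_id=int(event_ids[k_idx]),
                is_rare=bool(rare_mask[i]),
                cluster_id=int(cluster_of[i]),
                rarity_score=float(1.0 - own / m_total),
            )
    return [results[i] for i in range(n)]
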