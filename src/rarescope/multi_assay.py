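"""Multi-assay harmonization, joint clustering and cross-assay correlations.

Rare cells from the two staining protocols are pooled on the 8 shared
morphometric features (vesicles and QC failures removed, pooled z-scoring),
clustered by Ward/Euclidean agglomeration, with the cluster number chosen by
the average-silhouette criterion over k = 2…16.  Enumerations of matched
samples across protocols are compared by Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

from .synthetic import SHARED_FEATURES


@dataclass
class HarmonizedCells:
    """Pooled, z-scored rare-cell feature matrix with provenance."""

    features: pd.DataFrame  # z-scored, columns = SHARED_FEATURES
    protocol: pd.Series
    dropped: pd.DataFrame  # QC-failed rows with a reason column


@dataclass
class ClusterSolution:
    k: int
    assignments: np.ndarray
    silhouette_by_k: dict[int, float]
    occupancy: pd.DataFrame  # cluster × protocol counts


def harmonize(
    records: pd.DataFrame,
    min_solidity: float = 0.3,
) -> HarmonizedCells:
    """Pool rare cells from both protocols and z-score the shared features.

    ``records`` needs the 8 shared feature columns, a ``protocol`` column and,
    if present, ``is_oncosome`` (vesicles are excluded).  QC drops rows with
    nonfinite features, a nuclear-to-cell area ratio outside (0, 1], or an
    aberrant mask (cell solidity below ``min_solidity`` when available).
    """
    protocols = set(records["protocol"].unique())
    for p in ("Landscape", "CDX2"):
        if p not in protocols:
            raise ValueError(f"protocol {p!r} missing from the harmonization input")
    df = records.copy()
    if "is_oncosome" in df.columns:
        df = df[~df["is_oncosome"].astype(bool)]
    X = df[list(SHARED_FEATURES)]
    reasons = pd.Series("", index=df.index)
    bad_finite = ~np.isfinite(X).all(axis=1)
    reasons[bad_finite] = "nonfinite feature"
    ratio = df["nuclear_to_cell_area_ratio"]
    bad_ratio = (ratio <= 0) | (ratio > 1)
    reasons[bad_ratio & (reasons == "")] = "area ratio outside (0, 1]"
    if "cell_solidity" in df.columns:
        bad_mask = df["cell_solidity"] < min_solidity
        reasons[bad_mask & (reasons == "")] = "aberrant mask"
    bad = reasons != ""
    dropped = df[bad].copy()
    dropped["qc_reason"] = reasons[bad]
    kept = df[~bad]
    Xk = kept[list(SHARED_FEATURES)].astype(float)
    z = (Xk - Xk.mean()) / Xk.std(ddof=0).replace(0.0, 1.0)
    return HarmonizedCells(
        features=z.reset_index(drop=True),
        protocol=kept["protocol"].reset_index(drop=True),
        dropped=dropped,
    )


def cluster_multi_assay(
    cells: HarmonizedCells | pd.DataFrame,
    k_range: tuple[int, int] = (2, 16),
) -> ClusterSolution:
    """Ward/Euclidean agglomerative clustering with silhouette-selected k.

    Fits every k in ``k_range`` (inclusive; k above the cell count is
    skipped), scores each by the mean silhouette in the z-scored feature
    space, and returns the argmax solution with ties broken toward smaller k.
    """
    if isinstance(cells, HarmonizedCells):
        X = cells.features.to_numpy(dtype=float)
        protocol = cells.protocol
    else:
        X = cells[list(SHARED_FEATURES)].to_numpy(dtype=float)
        protocol = cells.get("protocol")
    n = len(X)
    lo, hi = k_range
    if n < max(2, lo):
        raise ValueError("not enough cells to cluster")
    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in range(lo, hi + 1):
        if k > n - 1:
            continue
        model = AgglomerativeClustering(n_clusters=k, linkage="ward")
        lab = model.fit_predict(X)
        sil[k] = float(silhouette_score(X, lab, metric="euclidean"))
        labels_by_k[k] = lab
    best_k = max(sorted(sil), key=lambda k: sil[k])  # ties -> smaller k
    lab = labels_by_k[best_k]
    if protocol is not None:
        occ = (
            pd.crosstab(pd.Series(lab, name="cluster"), protocol)
            .reindex(range(best_k), fill_value=0)
        )
    else:
        occ = pd.DataFrame(
            {"all": pd.Series(lab).value_counts().reindex(range(best_k), fill_value=0)}
        )
    return ClusterSolution(
        k=best_k, assignments=lab, silhouette_by_k=sil, occupancy=occ
    )


def cross_assay_correlations(
    landscape: pd.DataFrame,
    cdx2: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlations between matched-sample enumerations of the two
    protocols.

    Inputs are long enumeration tables with ``patient_id``, ``draw``,
    ``classification`` and ``events_per_ml``; samples are matched on
    (patient_id, draw).  Returns one row per (Landscape class, CDX2 class)
    pair with rho, the two-tailed p and a significance flag at p ≤ alpha;
    constant series yield missing rho.
    """
    key = ["patient_id", "draw"]
    wl = landscape.pivot_table(
        index=key, columns="classification", values="events_per_ml"
    )
    wc = cdx2.pivot_table(index=key, columns="classification", values="events_per_ml")
    common = wl.index.intersection(wc.index)
    if len(common) < 4:
        raise ValueError("need at least 4 matched samples")
    wl, wc = wl.loc[common], wc.loc[common]
    rows = []
    for cl in wl.columns:
        for cc in wc.columns:
            x, y = wl[cl].to_numpy(), wc[cc].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                rho, p = np.nan, np.nan
            else:
                rho, p = spearmanr(x, y)
            rows.append(
                {
                    "landscape_class": cl,
                    "cdx2_class": cc,
                    "rho": rho,
                    "p_value": p,
                    "significant": bool(np.isfinite(p) and p <= alpha),
                    "n": len(common),
                }
            )
    return pd.DataFrame(rows)
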