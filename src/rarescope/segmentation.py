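"""Event segmentation: nuclear and/or cytoplasm masks for every candidate.

DAPI-positive cells are found by thresholding the DAPI channel (Otsu with a
background-derived floor), splitting touching nuclei by watershed, then
growing a bounded cytoplasm mask over the union of the marker channels.
DAPI-negative candidates (vesicles, debris) are connected components in the
marker channels that do not touch any nucleus, kept within configurable area
bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import expand_labels, watershed

from .frame import Frame


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable segmentation settings (lengths in µm, intensities in counts)."""

    dapi_floor_nmads: float = 3.0       # DAPI floor above background, in robust SDs
    marker_floor_nmads: float = 4.0     # marker-channel threshold, in robust SDs
    min_nucleus_area_um2: float = 6.0
    split_min_distance_um: float = 3.0  # minimum separation of nucleus seeds
    cytoplasm_max_expand_um: float = 5.0
    dapi_neg_area_bounds_um2: tuple[float, float] = (2.0, 120.0)


@dataclass
class SegmentedEvent:
    """Masks and flags for one detected event.

    Masks are boolean arrays local to ``bbox`` (half-open, 0-based, row-major);
    ``nuclear_mask`` is None for DAPI-negative events, and the nuclear mask is
    a subset of the cell mask whenever both exist.
    """

    event_id: int
    frame_id: str
    bbox: tuple[int, int, int, int]
    cell_mask: np.ndarray
    nuclear_mask: np.ndarray | None
    centroid: tuple[float, float]
    dapi_positive: bool

    @property
    def cell_area_px(self) -> int:
        return int(self.cell_mask.sum())


def _robust_background(plane: np.ndarray) -> tuple[float, float]:
    """Median and robust sigma (1.4826×MAD) of a channel plane; with sparse
    events the majority of pixels are background."""
    med = float(np.median(plane))
    mad = float(np.median(np.abs(plane - med)))
    return med, 1.4826 * mad


def split_touching(
    mask: np.ndarray, dapi: np.ndarray, min_distance_px: int = 6
) -> list[np.ndarray]:
    """Split one connected nuclear component into per-nucleus masks.

    Watershed on the distance transform, seeded at DAPI-weighted distance
    maxima.  The union of the returned masks equals the input mask exactly.
    """
    from skimage.feature import peak_local_max

    dist = ndi.distance_transform_edt(mask)
    coords = peak_local_max(
        dist, min_distance=min_distance_px, labels=mask, exclude_border=False
    )
    if len(coords) <= 1:
        return [mask.copy()]
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    lab = watershed(-dist, markers=markers, mask=mask)
    return [lab == i for i in range(1, lab.max() + 1)]


def _extract(labels: np.ndarray, idx: int) -> tuple[tuple[int, int, int, int], np.ndarray]:
    rows, cols = np.nonzero(labels == idx)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    return (int(r0), int(c0), int(r1), int(c1)), (labels[r0:r1, c0:c1] == idx)


def segment_frame(
    frame: Frame, params: SegmentationParams | None = None
) -> list[SegmentedEvent]:
    """Detect every candidate event in a frame.

    Returns one `SegmentedEvent` per nucleus (touching nuclei are split) plus
    one per DAPI-negative marker component within the configured area bounds.
    An empty frame yields an empty list.
    """
    params = params or SegmentationParams()
    px_area = frame.um_per_px**2
    dapi = frame.pixels[0]
    bg, sig = frame.background_stats()[0]
    floor = bg + params.dapi_floor_nmads * max(sig, 1e-6)
    try:
        thr = max(float(threshold_otsu(dapi)), floor)
    except ValueError:  # constant image
        thr = floor
    nuc_bin = dapi > thr
    nuc_bin = ndi.binary_opening(nuc_bin, structure=np.ones((3, 3)))
    min_px = max(4, int(params.min_nucleus_area_um2 / px_area))
    nuc_cc = cc_label(nuc_bin)
    for prop in regionprops(nuc_cc):
        if prop.area < min_px:
            nuc_cc[nuc_cc == prop.label] = 0

    # split touching nuclei within each connected component
    min_dist_px = max(2, int(round(params.split_min_distance_um / frame.um_per_px)))
    nuclei = np.zeros(dapi.shape, dtype=np.int32)
    next_id = 1
    for prop in regionprops(cc_label(nuc_cc > 0)):
        r0, c0, r1, c1 = prop.bbox
        local = prop.image
        local_dapi = dapi[r0:r1, c0:c1]
        for m in split_touching(local, local_dapi, min_dist_px):
            if m.sum() < min_px:
                continue
            nuclei[r0:r1, c0:c1][m] = next_id
            next_id += 1

    # per-channel marker masks; components that touch no nucleus are
    # DAPI-negative candidates (vesicles, debris) and must not be absorbed
    # into a neighbouring cell's cytoplasm mask
    nuclei_dil = ndi.binary_dilation(nuclei > 0, structure=np.ones((3, 3)))
    marker_bin = np.zeros(dapi.shape, dtype=bool)
    candidate_bin = np.zeros(dapi.shape, dtype=bool)
    for c in range(1, 4):
        plane = frame.pixels[c]
        bg_c, sig_c = frame.background_stats()[c]
        chan = plane > bg_c + params.marker_floor_nmads * max(sig_c, 1e-6)
        chan = ndi.binary_closing(chan, structure=np.ones((3, 3)))
        marker_bin |= chan
        lab_c, n_c = ndi.label(chan)
        touching = np.unique(lab_c[nuclei_dil])
        free_ids = np.setdiff1d(np.arange(1, n_c + 1), touching)
        candidate_bin |= np.isin(lab_c, free_ids)

    expand_px = params.cytoplasm_max_expand_um / frame.um_per_px
    grown = expand_labels(nuclei, distance=expand_px)
    cells = np.where((marker_bin & ~candidate_bin) | (nuclei > 0), grown, 0)
    # keep cell masks connected to their nucleus
    events: list[SegmentedEvent] = []
    eid = 0
    for idx in range(1, next_id):
        nuc_rows = np.nonzero(nuclei == idx)
        if len(nuc_rows[0]) == 0:
            continue
        cell_full = cells == idx
        lab = cc_label(cell_full)
        keep_label = np.unique(lab[nuclei == idx])
        keep_label = keep_label[keep_label > 0]
        cell_full = np.isin(lab, keep_label)
        cell_full |= nuclei == idx
        rows, cols = np.nonzero(cell_full)
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        cell_local = cell_full[r0:r1, c0:c1]
        nuc_local = (nuclei == idx)[r0:r1, c0:c1]
        nr, nc = np.nonzero(nuc_local)
        events.append(
            SegmentedEvent(
                event_id=eid,
                frame_id=frame.frame_id,
                bbox=(int(r0), int(c0), int(r1), int(c1)),
                cell_mask=cell_local,
                nuclear_mask=nuc_local,
                centroid=(float(nr.mean() + r0), float(nc.mean() + c0)),
                dapi_positive=True,
            )
        )
        eid += 1

    # DAPI-negative candidates within the configured area bounds
    lo_px = params.dapi_neg_area_bounds_um2[0] / px_area
    hi_px = params.dapi_neg_area_bounds_um2[1] / px_area
    neg_cc = cc_label(candidate_bin)
    for prop in regionprops(neg_cc):
        if not lo_px <= prop.area <= hi_px:
            continue
        bbox, mask_local = _extract(neg_cc, prop.label)
        events.append(
            SegmentedEvent(
                event_id=eid,
                frame_id=frame.frame_id,
                bbox=bbox,
                cell_mask=mask_local,
                nuclear_mask=None,
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                dapi_positive=False,
            )
        )
        eid += 1
    return events


def match_to_truth(
    events: list[SegmentedEvent],
    truths: list,
    max_dist_px: float = 10.0,
) -> list[tuple[int, int]]:
    """Greedy centroid matching of detected events to ground-truth records.

    Returns (event index, truth index) pairs; each truth is matched at most
    once, nearest pairs first.
    """
    if not events or not truths:
        return []
    pairs = []
    for i, ev in enumerate(events):
        for j, tr in enumerate(truths):
            d = np.hypot(
                ev.centroid[0] - tr.centroid[0], ev.centroid[1] - tr.centroid[1]
            )
            if d <= max_dist_px:
                pairs.append((d, i, j))
    pairs.sort(key=lambda t: t[0])
    used_e: set[int] = set()
    used_t: set[int] = set()
    out = []
    for _, i, j in pairs:
        if i in used_e or j in used_t:
            continue
        used_e.add(i)
        used_t.add(j)
        out.append((i, j))
    return out
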