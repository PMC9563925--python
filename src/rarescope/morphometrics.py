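"""Morphometric features, per-channel positivity calls and signal texture.

The stable public contract is the 8 features shared across staining
protocols (DAPI and CK median intensity, cell and nucleus eccentricity and
area, nuclear-to-cell area ratio, mean distance of the cell outline to the
nucleus center).  A documented superset of per-channel intensity and shape
descriptors stands in for the much larger parameter set a production scanner
pipeline extracts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import regionprops

from .frame import Frame
from .segmentation import SegmentedEvent

TEXTURE_NONE = "none"


@dataclass(frozen=True)
class CallParams:
    """Positivity and texture-rule thresholds.

    A channel is positive when its median intensity inside the mask exceeds
    the frame background median by ``positivity_nmads`` robust SDs.  Texture
    thresholds were fixed once on the simulator and frozen.
    """

    positivity_nmads: float = 5.0
    diffuse_max_contrast: float = 0.20        # interior sd / median signal
    filamentous_min_orientation: float = 0.55  # gradient-orientation concentration


@dataclass
class ChannelCalls:
    """Per-channel positivity, texture and median intensity for one event."""

    positive: dict[str, bool]
    texture: dict[str, str]
    median_intensity: dict[str, float]

    def positive_roles(self) -> list[str]:
        return [r for r, p in self.positive.items() if p]


def _mask_pixels(frame: Frame, event: SegmentedEvent, channel: int) -> np.ndarray:
    r0, c0, r1, c1 = event.bbox
    return frame.pixels[channel, r0:r1, c0:c1][event.cell_mask]


def extract_features(event: SegmentedEvent, frame: Frame) -> dict[str, float]:
    """Compute the shared 8 features plus the documented extras for one event.

    All lengths are µm and areas µm² (via the frame scale).  For DAPI-negative
    events the nucleus features are 0 and ``nucleus_missing`` is 1; distances
    to the nucleus center then use the cell centroid.
    """
    if event.cell_mask.sum() == 0:
        raise ValueError("cannot extract features from an empty mask")
    um = frame.um_per_px
    r0, c0, r1, c1 = event.bbox
    feats: dict[str, float] = {}

    cell_props = regionprops(event.cell_mask.astype(np.uint8))[0]
    feats["cell_area_um2"] = float(cell_props.area) * um * um
    feats["cell_eccentricity"] = float(cell_props.eccentricity)
    feats["cell_perimeter_um"] = float(cell_props.perimeter) * um
    peri = max(cell_props.perimeter, 1e-9)
    feats["cell_circularity"] = float(
        min(4.0 * math.pi * cell_props.area / peri**2, 1.05)
    )
    feats["cell_solidity"] = float(cell_props.solidity)
    feats["cell_equivalent_diameter_um"] = float(cell_props.equivalent_diameter_area) * um

    has_nuc = event.nuclear_mask is not None and event.nuclear_mask.sum() > 0
    feats["nucleus_missing"] = 0.0 if has_nuc else 1.0
    if has_nuc:
        nuc_props = regionprops(event.nuclear_mask.astype(np.uint8))[0]
        feats["nucleus_area_um2"] = float(nuc_props.area) * um * um
        feats["nucleus_eccentricity"] = float(nuc_props.eccentricity)
        feats["nucleus_solidity"] = float(nuc_props.solidity)
        feats["nuclear_to_cell_area_ratio"] = float(
            min(nuc_props.area / cell_props.area, 1.0)
        )
        nuc_center = nuc_props.centroid
    else:
        feats["nucleus_area_um2"] = 0.0
        feats["nucleus_eccentricity"] = 0.0
        feats["nucleus_solidity"] = 0.0
        feats["nuclear_to_cell_area_ratio"] = 0.0
        nuc_center = cell_props.centroid

    # mean distance from the cell outline to the nucleus center
    from skimage.segmentation import find_boundaries

    outline = find_boundaries(event.cell_mask, mode="inner")
    oy, ox = np.nonzero(outline)
    d = np.hypot(oy - nuc_center[0], ox - nuc_center[1])
    feats["mean_outline_to_nucleus_center_distance_um"] = float(d.mean()) * um

    # per-channel intensity descriptors; DAPI is measured inside the nucleus
    for c, role in enumerate(frame.channel_roles):
        key = "dapi" if role == "DAPI" else role.lower().replace("/", "").replace("|", "")
        if role == "DAPI" and has_nuc:
            r0n, c0n = event.bbox[0], event.bbox[1]
            px = frame.pixels[c, r0n:r1, c0n:c1][event.nuclear_mask]
        else:
            px = _mask_pixels(frame, event, c)
        bg = float(frame.background_stats()[c, 0])
        feats[f"{key}_median_intensity"] = float(np.median(px))
        feats[f"{key}_mean_intensity"] = float(px.mean())
        feats[f"{key}_max_intensity"] = float(px.max())
        feats[f"{key}_sd_intensity"] = float(px.std())
        feats[f"{key}_cv_intensity"] = float(px.std() / max(px.mean(), 1e-9))
        feats[f"{key}_median_intensity_bgsub"] = float(np.median(px) - bg)
    # canonical shared names
    feats["ck_median_intensity"] = feats["ck_median_intensity"]
    feats["dapi_median_intensity"] = feats["dapi_median_intensity"]
    return feats


def classify_texture(
    patch: np.ndarray,
    mask: np.ndarray,
    background: float,
    params: CallParams | None = None,
    um_per_px: float = 0.5,
) -> str:
    """Categorize a positive channel's signal as filamentous, diffuse or
    punctate.

    Three-way rule on the mask interior (the rim carries edge gradients
    regardless of texture, so it is excluded):

    * diffuse — low interior contrast (sd of the smoothed signal relative to
      the median signal above background);
    * filamentous — textured with a concentrated gradient-orientation
      distribution (oriented ridges; orientations are folded mod π and
      summarized by the magnitude-weighted resultant length);
    * punctate — textured but isotropic (spot-like local maxima).
    """
    params = params or CallParams()
    from scipy.ndimage import binary_erosion, sobel
    from skimage.feature import peak_local_max
    from skimage.filters import gaussian

    interior = binary_erosion(mask, np.ones((3, 3)), iterations=3)
    if interior.sum() < 16:
        interior = mask
    sm = gaussian(patch.astype(float), sigma=1.0, preserve_range=True)
    med_sig = max(float(np.median(sm[mask])) - background, 1e-6)
    contrast = float(sm[interior].std()) / med_sig
    if contrast < params.diffuse_max_contrast:
        return "diffuse"
    gy, gx = sobel(sm, 0), sobel(sm, 1)
    w = np.hypot(gy, gx)[interior]
    theta = np.arctan2(gy, gx)[interior]
    orientation_r = float(
        abs(np.sum(w * np.exp(2j * theta))) / max(w.sum(), 1e-9)
    )
    if orientation_r >= params.filamentous_min_orientation:
        return "filamentous"
    return "punctate"


def count_spots(
    patch: np.ndarray, mask: np.ndarray, background: float
) -> int:
    """Local maxima at least 2× the median signal above background inside the
    eroded mask (a reported descriptor for punctate signals)."""
    from scipy.ndimage import binary_erosion
    from skimage.feature import peak_local_max
    from skimage.filters import gaussian

    interior = binary_erosion(mask, np.ones((3, 3)), iterations=3)
    if interior.sum() < 16:
        interior = mask
    sm = gaussian(patch.astype(float), sigma=1.0, preserve_range=True)
    med_sig = max(float(np.median(sm[mask])) - background, 1e-6)
    coords = peak_local_max(
        np.where(interior, sm, 0.0), min_distance=3,
        threshold_abs=background + 2.0 * med_sig, exclude_border=False,
    )
    return len(coords)


def call_channels(
    event: SegmentedEvent,
    frame: Frame,
    params: CallParams | None = None,
) -> ChannelCalls:
    """Per-channel positivity and texture for one segmented event.

    Positive iff the median intensity inside the relevant mask exceeds the
    frame background median plus ``positivity_nmads`` robust SDs; texture is
    assigned only for positive channels (``"none"`` otherwise).  DAPI
    positivity follows the segmentation flag.
    """
    params = params or CallParams()
    positive: dict[str, bool] = {}
    texture: dict[str, str] = {}
    medians: dict[str, float] = {}
    r0, c0, r1, c1 = event.bbox
    for c, role in enumerate(frame.channel_roles):
        plane = frame.pixels[c]
        bg, sigma = frame.background_stats()[c]
        thr = bg + params.positivity_nmads * max(sigma, 1e-6)
        if role == "DAPI":
            if event.dapi_positive and event.nuclear_mask is not None:
                px = plane[r0:r1, c0:c1][event.nuclear_mask]
            else:
                px = plane[r0:r1, c0:c1][event.cell_mask]
            medians[role] = float(np.median(px))
            positive[role] = bool(event.dapi_positive)
            texture[role] = TEXTURE_NONE
            continue
        px = plane[r0:r1, c0:c1][event.cell_mask]
        med = float(np.median(px))
        medians[role] = med
        pos = med > thr
        positive[role] = bool(pos)
        if pos:
            texture[role] = classify_texture(
                plane[r0:r1, c0:c1], event.cell_mask, bg, params, frame.um_per_px
            )
        else:
            texture[role] = TEXTURE_NONE
    return ChannelCalls(positive=positive, texture=texture, median_intensity=medians)
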