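"""Synthetic multi-channel immunofluorescence slides with full ground truth.

Real slides in this workflow are dense monolayers of nucleated blood cells
(~3 million per slide, 2304 scan frames) imaged in four fluorescence colors,
with rare tumor-associated events (circulating tumor cells, endothelial-like
cells, megakaryocyte-like cells, tumor-derived oncosomes) hidden among the
leukocytes.  This module renders scaled-down frames with the same statistical
structure — Poisson event counts per frame, per-channel expression with
filamentous / diffuse / punctate signal texture, crowding, oncosome attachment
to nucleated cells — and returns exact ground truth for every rendered event,
so each downstream stage can be scored without any external data.

Two faster generators share the same population rates: a count-level sampler
(`sample_enumeration_counts`) used for cohort statistics, and a feature-level
sampler (`draw_phenotype_features`) used for morphometric clustering studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .frame import CDX2_ROLES, LANDSCAPE_ROLES, Frame

TEXTURES = ("filamentous", "diffuse", "punctate")

#: the 8 morphometric features shared across staining protocols
SHARED_FEATURES = (
    "dapi_median_intensity",
    "ck_median_intensity",
    "cell_eccentricity",
    "nucleus_eccentricity",
    "cell_area_um2",
    "nucleus_area_um2",
    "nuclear_to_cell_area_ratio",
    "mean_outline_to_nucleus_center_distance_um",
)


@dataclass(frozen=True)
class ChannelProfile:
    """Expression of one fluorescence channel for a population.

    ``intensity_scale`` is the added signal in image counts above background;
    ``on_prob`` lets a marker be expressed in only a fraction of instances
    (variable expression, e.g. cytokeratin on endothelial-like cells).
    """

    expressed: bool = False
    texture: str = "diffuse"
    intensity_scale: float = 0.0
    on_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.texture not in TEXTURES:
            raise ValueError(f"unknown texture {self.texture!r}")
        if self.expressed and self.intensity_scale <= 0:
            raise ValueError("expressed channels need intensity_scale > 0")
        if not self.expressed and self.intensity_scale != 0:
            raise ValueError("intensity_scale must be 0 for silent channels")


@dataclass(frozen=True)
class PopulationSpec:
    """One event population and how it renders.

    ``cell_diameter_um`` is a truncated normal (mean, sd, min, max).
    ``nucleus_fraction`` is the fraction of cell area occupied by the nucleus.
    ``channel_profile`` maps channel role (e.g. "CK") to a `ChannelProfile`;
    DAPI is implied by ``dapi_positive``.  ``cluster_propensity`` is the
    probability an instance is placed adjacent to a previous instance (for
    vesicle populations this is the probability of attachment to a nucleated
    cell).  ``aspect_ratio`` controls rendered ellipse elongation.
    """

    label: str
    count_per_frame: float
    cell_diameter_um: tuple[float, float, float, float]
    nucleus_fraction: float
    channel_profile: dict[str, ChannelProfile]
    cluster_propensity: float = 0.0
    dapi_positive: bool = True
    aspect_ratio: tuple[float, float, float, float] = (1.15, 0.1, 1.0, 1.6)
    dapi_intensity: float = 150.0

    def __post_init__(self) -> None:
        if self.count_per_frame < 0:
            raise ValueError("count_per_frame must be nonnegative")
        if not 0.0 <= self.nucleus_fraction <= 1.0:
            raise ValueError("nucleus_fraction must lie in [0, 1]")
        if not 0.0 <= self.cluster_propensity <= 1.0:
            raise ValueError("cluster_propensity must lie in [0, 1]")
        if not self.dapi_positive:
            ck = self.channel_profile.get("CK")
            if ck is None or not ck.expressed:
                raise ValueError(
                    "DAPI-negative (vesicle) populations must express CK"
                )
            if self.cell_diameter_um[3] > 12.0:
                raise ValueError("vesicle diameters must stay ≤ 12 µm")

    @property
    def is_oncosome(self) -> bool:
        return not self.dapi_positive


@dataclass(frozen=True)
class SampleSpec:
    """One simulated blood sample / slide."""

    patient_id: str
    draw: int
    protocol: str  # "Landscape" | "CDX2"
    wbc_concentration_per_ml: float
    frames: int
    populations: tuple[PopulationSpec, ...]
    background_level: tuple[float, float, float, float] = (20.0, 20.0, 20.0, 20.0)
    noise_sd: tuple[float, float, float, float] = (3.0, 3.0, 3.0, 3.0)
    seed: int = 0
    frame_shape: tuple[int, int] = (512, 512)
    um_per_px: float = 0.5

    def __post_init__(self) -> None:
        if self.protocol not in ("Landscape", "CDX2"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.wbc_concentration_per_ml <= 0:
            raise ValueError("wbc_concentration_per_ml must be positive")
        if self.frames <= 0:
            raise ValueError("frames must be positive")

    @property
    def channel_roles(self) -> tuple[str, str, str, str]:
        return LANDSCAPE_ROLES if self.protocol == "Landscape" else CDX2_ROLES

    def expected_nucleated_per_frame(self) -> float:
        return sum(p.count_per_frame for p in self.populations if p.dapi_positive)


@dataclass
class GroundTruthEvent:
    """Exact truth for one rendered event."""

    frame_index: int
    label: str
    centroid: tuple[float, float]  # (row, col) px
    bbox: tuple[int, int, int, int]  # (rmin, cmin, rmax, cmax) half-open
    cell_mask: np.ndarray  # bool, local to bbox
    nucleus_mask: np.ndarray | None
    dapi_positive: bool
    channel_positive: dict[str, bool]
    attachment: str | None = None  # "isolated" | "adjacent" for vesicles
    radius_px: float = 0.0


class PlacementError(RuntimeError):
    """Raised when a population's density cannot be placed without exceeding
    the allowed mask overlap."""


# ---------------------------------------------------------------------------
# rendering primitives

def _ellipse_mask(a: float, b: float, theta: float) -> np.ndarray:
    """Boolean raster of an ellipse with semi-axes a, b (px) rotated by theta."""
    r = int(math.ceil(max(a, b))) + 1
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    ct, st = math.cos(theta), math.sin(theta)
    u = yy * ct + xx * st
    v = -yy * st + xx * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _render_filamentous(mask: np.ndarray, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Oriented bright ridges over a dim cytoplasmic pedestal."""
    from skimage.draw import line_aa

    h, w = mask.shape
    out = np.zeros((h, w), dtype=np.float32)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rad = max(h, w) / 2.0
    n_seg = int(rng.integers(3, 9))
    base_theta = rng.uniform(0, math.pi)
    for _ in range(n_seg):
        theta = base_theta + rng.normal(0, 0.25)
        off = rng.normal(0, rad / 3.0)
        oy, ox = -off * math.sin(theta), off * math.cos(theta)
        y0 = int(round(cy + oy - rad * math.cos(theta)))
        x0 = int(round(cx + ox + rad * math.sin(theta)))
        y1 = int(round(cy + oy + rad * math.cos(theta)))
        x1 = int(round(cx + ox - rad * math.sin(theta)))
        y0, x0 = np.clip(y0, 0, h - 1), np.clip(x0, 0, w - 1)
        y1, x1 = np.clip(y1, 0, h - 1), np.clip(x1, 0, w - 1)
        rr, cc, val = line_aa(y0, x0, y1, x1)
        out[rr, cc] = np.maximum(out[rr, cc], val.astype(np.float32))
    # thicken ridges slightly
    from scipy.ndimage import grey_dilation

    out = grey_dilation(out, size=(2, 2))
    out = out * scale + 0.35 * scale
    out[~mask] = 0.0
    return out


def _render_punctate(mask: np.ndarray, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Sparse bright Gaussian speckles over a dim pedestal."""
    h, w = mask.shape
    out = np.zeros((h, w), dtype=np.float32)
    inside = np.argwhere(mask)
    n_spots = int(rng.integers(8, 26))
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_spots):
        py, px = inside[rng.integers(len(inside))]
        sigma = rng.uniform(2.0, 3.5)
        amp = rng.uniform(0.8, 1.2)
        out += amp * np.exp(-((yy - py) ** 2 + (xx - px) ** 2) / (2 * sigma**2)).astype(
            np.float32
        )
    out = np.minimum(out, 1.3) * scale + 0.3 * scale
    out[~mask] = 0.0
    return out


def _render_diffuse(mask: np.ndarray, scale: float, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros(mask.shape, dtype=np.float32)
    out[mask] = scale
    return out


_TEXTURE_RENDERERS = {
    "filamentous": _render_filamentous,
    "punctate": _render_punctate,
    "diffuse": _render_diffuse,
}


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    for _ in range(64):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(mean, lo, hi))


# ---------------------------------------------------------------------------
# frame rendering

_MAX_PLACEMENT_TRIES = 200
_MAX_OVERLAP_FRACTION = 0.30


def _place_event(
    occupancy: np.ndarray,
    mask: np.ndarray,
    center: tuple[int, int],
) -> tuple[slice, slice] | None:
    """Try to stamp `mask` centered at `center`; reject > 30 % overlap."""
    h, w = occupancy.shape
    mh, mw = mask.shape
    r0 = center[0] - mh // 2
    c0 = center[1] - mw // 2
    if r0 < 0 or c0 < 0 or r0 + mh > h or c0 + mw > w:
        return None
    sl = (slice(r0, r0 + mh), slice(c0, c0 + mw))
    overlap = (occupancy[sl] & mask).sum()
    if overlap > _MAX_OVERLAP_FRACTION * mask.sum():
        return None
    return sl


def render_frame(
    spec: SampleSpec, frame_index: int
) -> tuple[Frame, list[GroundTruthEvent]]:
    """Render one 4-channel frame and its ground truth.

    Deterministic given (spec.seed, frame_index).  Nucleated populations are
    placed before DAPI-negative vesicles so that vesicle attachment has
    nucleated neighbours to bind to.  Raises `PlacementError` when a
    population's requested density cannot be placed.
    """
    if frame_index >= spec.frames:
        raise ValueError("frame_index out of range for this sample")
    rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, frame_index])
    h, w = spec.frame_shape
    roles = spec.channel_roles
    img = np.empty((4, h, w), dtype=np.float32)
    for c in range(4):
        img[c] = spec.background_level[c] + rng.normal(0, spec.noise_sd[c], (h, w))

    occupancy = np.zeros((h, w), dtype=bool)
    truths: list[GroundTruthEvent] = []
    nucleated: list[tuple[tuple[int, int], float]] = []  # (center, radius_px)

    populations = sorted(spec.populations, key=lambda p: p.is_oncosome)
    for pop in populations:
        n = int(rng.poisson(pop.count_per_frame))
        prev_centers: list[tuple[int, int]] = []
        for _ in range(n):
            d_um = _truncated_normal(rng, *pop.cell_diameter_um)
            r_px = d_um / 2.0 / spec.um_per_px
            q = _truncated_normal(rng, *pop.aspect_ratio)
            a, b = r_px * math.sqrt(q), r_px / math.sqrt(q)
            theta = rng.uniform(0, math.pi)
            cell_mask = _ellipse_mask(a, b, theta)

            attach = None
            placed = None
            for attempt in range(_MAX_PLACEMENT_TRIES):
                anchored = False
                if pop.is_oncosome and nucleated and rng.random() < pop.cluster_propensity:
                    (ay, ax), ar = nucleated[rng.integers(len(nucleated))]
                    dist = rng.uniform(0.85, 1.15) * (ar + r_px)
                    ang = rng.uniform(0, 2 * math.pi)
                    cy = int(round(ay + dist * math.sin(ang)))
                    cx = int(round(ax + dist * math.cos(ang)))
                    anchored = True
                elif (
                    not pop.is_oncosome
                    and prev_centers
                    and rng.random() < pop.cluster_propensity
                ):
                    ay, ax = prev_centers[rng.integers(len(prev_centers))]
                    dist = rng.uniform(1.8, 2.4) * r_px
                    ang = rng.uniform(0, 2 * math.pi)
                    cy = int(round(ay + dist * math.sin(ang)))
                    cx = int(round(ax + dist * math.cos(ang)))
                else:
                    cy = int(rng.integers(0, h))
                    cx = int(rng.integers(0, w))
                sl = _place_event(occupancy, cell_mask, (cy, cx))
                if sl is not None:
                    placed = (sl, (cy, cx))
                    if pop.is_oncosome:
                        attach = "adjacent" if anchored else "isolated"
                    break
            if placed is None:
                raise PlacementError(
                    f"could not place population {pop.label!r}: frame saturated"
                )
            sl, (cy, cx) = placed
            occupancy[sl] |= cell_mask

            # nucleus: concentric ellipse of the requested area fraction
            nuc_mask_local = None
            if pop.dapi_positive and pop.nucleus_fraction > 0:
                s = math.sqrt(pop.nucleus_fraction)
                nuc = _ellipse_mask(max(a * s, 1.2), max(b * s, 1.2), theta)
                pad = (cell_mask.shape[0] - nuc.shape[0]) // 2
                nuc_mask_local = np.zeros_like(cell_mask)
                nuc_mask_local[pad : pad + nuc.shape[0], pad : pad + nuc.shape[1]] = nuc
                nuc_mask_local &= cell_mask
                img[0][sl][nuc_mask_local] += pop.dapi_intensity * rng.uniform(0.85, 1.15)
                nucleated.append(((cy, cx), r_px))

            chan_pos = {role: False for role in roles[1:]}
            for c, role in enumerate(roles):
                if role == "DAPI":
                    continue
                prof = pop.channel_profile.get(role)
                if prof is None or not prof.expressed:
                    continue
                if rng.random() >= prof.on_prob:
                    continue
                tex = _TEXTURE_RENDERERS[prof.texture](
                    cell_mask, prof.intensity_scale * rng.uniform(0.85, 1.15), rng
                )
                img[c][sl] += tex
                chan_pos[role] = True

            prev_centers.append((cy, cx))
            rr, cc = np.nonzero(cell_mask)
            truths.append(
                GroundTruthEvent(
                    frame_index=frame_index,
                    label=pop.label,
                    centroid=(sl[0].start + rr.mean(), sl[1].start + cc.mean()),
                    bbox=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
                    cell_mask=cell_mask,
                    nucleus_mask=nuc_mask_local,
                    dapi_positive=pop.dapi_positive,
                    channel_positive=chan_pos,
                    attachment=attach,
                    radius_px=r_px,
                )
            )

    np.clip(img, 0, None, out=img)
    frame = Frame(
        pixels=img,
        channel_roles=roles,
        um_per_px=spec.um_per_px,
        frame_id=f"{spec.patient_id}-d{spec.draw}-{spec.protocol}-f{frame_index:04d}",
    )
    return frame, truths


# ---------------------------------------------------------------------------
# default population catalogues

def _prof(**kw) -> ChannelProfile:
    return ChannelProfile(expressed=True, **kw)


def landscape_populations(
    wbc_per_frame: float = 110.0, rare_scale: float = 1.0
) -> tuple[PopulationSpec, ...]:
    """Default Landscape-protocol populations for an mCRC-like sample.

    Rates are per 512×512 frame at 0.5 µm/px.  ``rare_scale`` multiplies every
    rare (non-WBC) rate and is the per-sample disease-burden dial.
    """
    r = rare_scale
    return (
        PopulationSpec(
            "WBC", wbc_per_frame, (10.0, 1.2, 7.0, 14.0), 0.65,
            {"CD45/CD31": _prof(texture="diffuse", intensity_scale=90.0)},
        ),
        PopulationSpec(
            "Epi.CTC", 0.9 * r, (16.0, 2.0, 11.0, 24.0), 0.45,
            {"CK": _prof(texture="filamentous", intensity_scale=130.0)},
        ),
        PopulationSpec(
            "Mes.CTC", 0.6 * r, (14.0, 2.0, 10.0, 20.0), 0.45,
            {
                "CK": _prof(texture="filamentous", intensity_scale=120.0),
                "Vim": _prof(texture="filamentous", intensity_scale=100.0),
            },
        ),
        PopulationSpec("DAPI only", 0.7 * r, (9.0, 1.0, 7.0, 12.0), 0.85, {}),
        PopulationSpec(
            "Vim", 0.5 * r, (11.0, 1.5, 8.0, 15.0), 0.6,
            {"Vim": _prof(texture="diffuse", intensity_scale=100.0)},
        ),
        PopulationSpec(
            "mega", 0.5 * r, (26.0, 3.0, 20.0, 34.0), 0.55,
            {"CD45/CD31": _prof(texture="punctate", intensity_scale=110.0)},
            aspect_ratio=(1.7, 0.2, 1.3, 2.3),
        ),
        PopulationSpec(
            "cec", 0.7 * r, (18.0, 2.0, 13.0, 24.0), 0.5,
            {
                "Vim": _prof(texture="filamentous", intensity_scale=115.0),
                "CD45/CD31": _prof(texture="punctate", intensity_scale=100.0),
                "CK": _prof(texture="diffuse", intensity_scale=90.0, on_prob=0.46),
            },
            cluster_propensity=0.36,
            aspect_ratio=(1.5, 0.2, 1.2, 2.0),
        ),
        PopulationSpec(
            "CK|Vim|CD45/CD31", 0.9 * r, (12.0, 1.5, 9.0, 16.0), 0.6,
            {
                "CK": _prof(texture="diffuse", intensity_scale=100.0),
                "Vim": _prof(texture="diffuse", intensity_scale=95.0),
                "CD45/CD31": _prof(texture="diffuse", intensity_scale=90.0),
            },
        ),
        PopulationSpec(
            "Onc CK", 0.9 * r, (6.0, 1.5, 3.5, 10.0), 0.0,
            {"CK": _prof(texture="diffuse", intensity_scale=120.0)},
            aspect_ratio=(1.02, 0.02, 1.0, 1.08), cluster_propensity=0.49, dapi_positive=False,
        ),
        PopulationSpec(
            "Onc CK|Vim", 0.5 * r, (6.0, 1.5, 3.5, 10.0), 0.0,
            {
                "CK": _prof(texture="diffuse", intensity_scale=110.0),
                "Vim": _prof(texture="diffuse", intensity_scale=95.0),
            },
            aspect_ratio=(1.02, 0.02, 1.0, 1.08), cluster_propensity=0.49, dapi_positive=False,
        ),
        PopulationSpec(
            "Onc CK|CD45/CD31", 0.05 * r, (6.0, 1.5, 3.5, 10.0), 0.0,
            {
                "CK": _prof(texture="diffuse", intensity_scale=110.0),
                "CD45/CD31": _prof(texture="diffuse", intensity_scale=90.0),
            },
            aspect_ratio=(1.02, 0.02, 1.0, 1.08), cluster_propensity=0.49, dapi_positive=False,
        ),
        PopulationSpec(
            "Onc CK|Vim|CD45/CD31", 0.7 * r, (6.5, 1.5, 3.5, 10.0), 0.0,
            {
                "CK": _prof(texture="diffuse", intensity_scale=110.0),
                "Vim": _prof(texture="diffuse", intensity_scale=95.0),
                "CD45/CD31": _prof(texture="diffuse", intensity_scale=85.0),
            },
            aspect_ratio=(1.02, 0.02, 1.0, 1.08), cluster_propensity=0.49, dapi_positive=False,
        ),
    )


def cdx2_populations(
    wbc_per_frame: float = 110.0, rare_scale: float = 1.0
) -> tuple[PopulationSpec, ...]:
    """Default CDX2-targeted populations (DAPI, CK, CDX2, CD45)."""
    r = rare_scale
    return (
        PopulationSpec(
            "WBC", wbc_per_frame, (10.0, 1.2, 7.0, 14.0), 0.65,
            {"CD45": _prof(texture="diffuse", intensity_scale=90.0)},
        ),
        PopulationSpec(
            "CK", 0.8 * r, (16.0, 2.0, 11.0, 24.0), 0.45,
            {"CK": _prof(texture="filamentous", intensity_scale=130.0)},
        ),
        PopulationSpec(
            "CK|CDX2", 0.6 * r, (15.0, 2.0, 10.0, 22.0), 0.45,
            {
                "CK": _prof(texture="filamentous", intensity_scale=120.0),
                "CDX2": _prof(texture="diffuse", intensity_scale=100.0),
            },
            cluster_propensity=0.2,
        ),
        PopulationSpec("DAPI only", 1.0 * r, (9.0, 1.0, 7.0, 12.0), 0.85, {}),
        PopulationSpec(
            "CDX2", 0.4 * r, (24.0, 3.0, 18.0, 32.0), 0.55,
            {"CDX2": _prof(texture="punctate", intensity_scale=110.0)},
            aspect_ratio=(1.6, 0.2, 1.2, 2.2),
        ),
        PopulationSpec(
            "CK|CD45", 0.6 * r, (13.0, 1.5, 9.0, 18.0), 0.6,
            {
                "CK": _prof(texture="diffuse", intensity_scale=100.0),
                "CD45": _prof(texture="diffuse", intensity_scale=90.0),
            },
        ),
        PopulationSpec(
            "CK|CDX2|CD45", 0.9 * r, (12.0, 1.5, 9.0, 16.0), 0.6,
            {
                "CK": _prof(texture="diffuse", intensity_scale=100.0),
                "CDX2": _prof(texture="diffuse", intensity_scale=95.0),
                "CD45": _prof(texture="diffuse", intensity_scale=90.0),
            },
        ),
        PopulationSpec(
            "Onc CK", 0.9 * r, (6.0, 1.5, 3.5, 10.0), 0.0,
            {"CK": _prof(texture="diffuse", intensity_scale=120.0)},
            aspect_ratio=(1.02, 0.02, 1.0, 1.08), cluster_propensity=0.49, dapi_positive=False,
        ),
        PopulationSpec(
            "Onc CK|CDX2", 1.0 * r, (6.0, 1.5, 3.5, 10.0), 0.0,
            {
                "CK": _prof(texture="diffuse", intensity_scale=110.0),
                "CDX2": _prof(texture="diffuse", intensity_scale=95.0),
            },
            aspect_ratio=(1.02, 0.02, 1.0, 1.08), cluster_propensity=0.49, dapi_positive=False,
        ),
        PopulationSpec(
            "Onc CK|CDX2|CD45", 0.3 * r, (6.0, 1.5, 3.5, 10.0), 0.0,
            {
                "CK": _prof(texture="diffuse", intensity_scale=110.0),
                "CDX2": _prof(texture="diffuse", intensity_scale=95.0),
                "CD45": _prof(texture="diffuse", intensity_scale=85.0),
            },
            aspect_ratio=(1.02, 0.02, 1.0, 1.08), cluster_propensity=0.49, dapi_positive=False,
        ),
    )


def normal_donor_populations(wbc_per_frame: float = 110.0) -> tuple[PopulationSpec, ...]:
    """Landscape populations for a normal donor: tumor phenotypes absent or
    strongly down-weighted, leukocyte-adjacent rare classes retained."""
    base = {p.label: p for p in landscape_populations(wbc_per_frame, rare_scale=1.0)}
    keep = []
    downweights = {
        "WBC": 1.0,
        "Epi.CTC": 0.02,
        "Mes.CTC": 0.3,
        "DAPI only": 0.35,
        "Vim": 0.8,
        "mega": 0.1,
        "cec": 0.15,
        "CK|Vim|CD45/CD31": 0.6,
        "Onc CK": 0.08,
        "Onc CK|Vim": 0.06,
        "Onc CK|CD45/CD31": 0.2,
        "Onc CK|Vim|CD45/CD31": 0.05,
    }
    for label, w in downweights.items():
        p = base[label]
        keep.append(replace(p, count_per_frame=p.count_per_frame * w))
    return tuple(keep)


def debris_population(rate: float = 1.0) -> PopulationSpec:
    """Elongated CK-positive DAPI-negative streaks; must NOT be called
    oncosomes (fails the circularity gate)."""
    return PopulationSpec(
        "debris", rate, (8.0, 1.5, 5.0, 11.0), 0.0,
        {"CK": _prof(texture="diffuse", intensity_scale=100.0)},
        dapi_positive=False, aspect_ratio=(4.0, 0.5, 3.0, 5.0),
    )


# ---------------------------------------------------------------------------
# cohort generation

@dataclass(frozen=True)
class PfsModel:
    """Monotone link between one analyte's Draw-1 concentration and PFS.

    ``strength`` in [0, 1]: 1 is a perfectly monotone link, 0 is independence.
    ``direction`` +1 (higher analyte, longer PFS) or −1.
    """

    analyte: str = "Onc CK|CD45/CD31"
    direction: int = 1
    strength: float = 0.7
    censor_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.censor_fraction >= 1.0:
            raise ValueError("censor_fraction must be < 1")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Study arm sizes and effect structure for a simulated cohort."""

    n_mcrc_patients: int = 10
    n_nd_donors: int = 50
    frames_per_slide: int = 64
    missing_draw2: int = 2
    pfs_model: PfsModel = field(default_factory=PfsModel)
    burden_sigma: float = 1.0  # log-normal sd of per-sample rare burden
    mcrc_burden_mean: float = 1.0  # multiplies default mCRC rare rates
    seed: int = 0


def _pfs_from_analyte(
    analyte: np.ndarray, model: PfsModel, rng: np.random.Generator
) -> np.ndarray:
    """PFS months with Spearman-controllable link to the analyte vector."""
    n = len(analyte)
    ranks = pd.Series(analyte).rank(method="average").to_numpy()
    from scipy.stats import norm

    scores = norm.ppf((ranks - 0.375) / (n + 0.25))  # Blom normal scores
    s = model.strength
    latent = model.direction * s * scores
    if s < 1.0:
        latent = latent + math.sqrt(1.0 - s * s) * rng.standard_normal(n)
    return np.exp(1.8 + 0.55 * latent)  # median ≈ 6 months


def generate_cohort(spec: CohortSpec) -> tuple[list[SampleSpec], pd.DataFrame]:
    """Build per-sample specs for both arms plus the survival table.

    mCRC patients get two draws (Landscape and CDX2 slides per draw) except
    for ``missing_draw2`` patients; normal donors get a single Landscape
    slide.  PFS is generated from the configured analyte's Draw-1 expected
    concentration through the monotone link in ``spec.pfs_model``.
    """
    rng = np.random.default_rng(spec.seed & 0x7FFFFFFF)
    samples: list[SampleSpec] = []
    analyte_conc = np.zeros(spec.n_mcrc_patients)
    missing = set(
        rng.choice(spec.n_mcrc_patients, size=spec.missing_draw2, replace=False)
        if spec.missing_draw2
        else []
    )
    for i in range(spec.n_mcrc_patients):
        pid = f"mCRC-{i + 1:02d}"
        draws = (1,) if i in missing else (1, 2)
        for draw in draws:
            burden = spec.mcrc_burden_mean * rng.lognormal(0.0, spec.burden_sigma)
            wbc_conc = rng.lognormal(math.log(5.0e6), 0.2)
            seed_l = int(rng.integers(0, 2**31 - 1))
            seed_c = int(rng.integers(0, 2**31 - 1))
            pops_l = landscape_populations(rare_scale=burden)
            samples.append(
                SampleSpec(pid, draw, "Landscape", wbc_conc,
                           spec.frames_per_slide, pops_l, seed=seed_l)
            )
            samples.append(
                SampleSpec(pid, draw, "CDX2", wbc_conc, spec.frames_per_slide,
                           cdx2_populations(rare_scale=burden), seed=seed_c)
            )
            if draw == 1:
                rates = {p.label: p.count_per_frame for p in pops_l}
                rates.update(
                    {p.label: p.count_per_frame
                     for p in cdx2_populations(rare_scale=burden)}
                )
                # expected concentration of the linked analyte, events/mL
                vol = spec.frames_per_slide * 110.0 / wbc_conc
                analyte_conc[i] = (
                    rates.get(spec.pfs_model.analyte, 0.0) * spec.frames_per_slide / vol
                )
    for j in range(spec.n_nd_donors):
        wbc_conc = rng.lognormal(math.log(5.0e6), 0.2)
        samples.append(
            SampleSpec(f"ND-{j + 1:02d}", 1, "Landscape", wbc_conc,
                       spec.frames_per_slide, normal_donor_populations(),
                       seed=int(rng.integers(0, 2**31 - 1)))
        )

    pfs = _pfs_from_analyte(analyte_conc, spec.pfs_model, rng)
    event = (rng.random(spec.n_mcrc_patients) >= spec.pfs_model.censor_fraction).astype(int)
    survival = pd.DataFrame(
        {
            "patient_id": [f"mCRC-{i + 1:02d}" for i in range(spec.n_mcrc_patients)],
            "pfs_months": np.round(pfs, 3),
            "event_flag": event,
            # expected Draw-1 concentration of the linked analyte (events/mL)
            "true_analyte_events_per_ml": analyte_conc,
        }
    )
    survival.attrs["linked_analyte"] = spec.pfs_model.analyte
    return samples, survival


# ---------------------------------------------------------------------------
# count-level fast path

def sample_enumeration_counts(
    spec: SampleSpec, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Ground-truth event counts and events/mL for one sample without
    rendering pixels.

    Counts per classification are Poisson with mean rate × frames — exactly
    the distribution of the renderer's ground-truth records.  The analyzed
    blood volume uses the realized DAPI-nuclei count, mirroring how slides
    are normalized to concentration.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed & 0x7FFFFFFF)
    rows = []
    nuclei = 0
    for pop in spec.populations:
        n = int(rng.poisson(pop.count_per_frame * spec.frames))
        if pop.dapi_positive:
            nuclei += n
        if pop.label != "WBC":
            rows.append({"classification": pop.label, "raw_count": n})
    volume_ml = nuclei / spec.wbc_concentration_per_ml
    df = pd.DataFrame(rows)
    df["events_per_ml"] = df["raw_count"] / volume_ml
    df.insert(0, "patient_id", spec.patient_id)
    df.insert(1, "draw", spec.draw)
    df.insert(2, "protocol", spec.protocol)
    df["blood_volume_ml"] = volume_ml
    df["dapi_nuclei_count"] = nuclei
    df["wbc_concentration_per_ml"] = spec.wbc_concentration_per_ml
    return df


# ---------------------------------------------------------------------------
# feature-level fast path for morphometric clustering studies

#: mean vectors of the 8 shared features for 8 morphologically distinct
#: rare-cell archetypes (intensities in counts, areas in µm², distances µm)
PHENOTYPE_FEATURE_MEANS: dict[str, tuple[float, ...]] = {
    # dapi_med, ck_med, cell_ecc, nuc_ecc, cell_area, nuc_area, ratio, outline_dist
    "epi_ctc":        (160.0, 170.0, 0.45, 0.40, 210.0, 95.0, 0.45, 8.2),
    "mes_ctc":        (150.0, 120.0, 0.72, 0.60, 160.0, 72.0, 0.45, 7.6),
    "dapi_only_small": (175.0, 22.0, 0.40, 0.35, 66.0, 56.0, 0.85, 4.7),
    "large_eccentric_nucleus": (165.0, 25.0, 0.85, 0.82, 300.0, 210.0, 0.70, 11.5),
    "large_round_nucleus":     (170.0, 24.0, 0.30, 0.25, 290.0, 205.0, 0.71, 9.6),
    "megakaryocyte":  (185.0, 35.0, 0.80, 0.55, 560.0, 310.0, 0.55, 14.5),
    "endothelial":    (150.0, 75.0, 0.78, 0.65, 260.0, 130.0, 0.50, 10.3),
    "wbc_like":       (155.0, 28.0, 0.35, 0.30, 82.0, 53.0, 0.65, 5.1),
}

#: relative sd of each feature around its archetype mean
_FEATURE_REL_SD = (0.05, 0.06, 0.06, 0.07, 0.06, 0.06, 0.04, 0.04)


def draw_phenotype_features(
    n_per_phenotype: int,
    rng: np.random.Generator,
    phenotypes: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Draw shared-feature vectors for morphologically distinct rare-cell
    archetypes (independent Gaussians around each archetype mean).

    Returns a DataFrame with the 8 shared features plus ``phenotype`` and an
    alternating ``protocol`` column, emulating a pooled two-assay rare-cell
    set.
    """
    if phenotypes is None:
        phenotypes = tuple(PHENOTYPE_FEATURE_MEANS)
    frames = []
    for ph in phenotypes:
        mu = np.asarray(PHENOTYPE_FEATURE_MEANS[ph])
        sd = mu * np.asarray(_FEATURE_REL_SD)
        x = rng.normal(mu, sd, size=(n_per_phenotype, len(mu)))
        x[:, 2:4] = np.clip(x[:, 2:4], 0.0, 0.999)  # eccentricities
        x[:, 6] = np.clip(x[:, 6], 0.05, 1.0)
        df = pd.DataFrame(x, columns=list(SHARED_FEATURES))
        df["phenotype"] = ph
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["protocol"] = np.where(np.arange(len(out)) % 2 == 0, "Landscape", "CDX2")
    return out
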