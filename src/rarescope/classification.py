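"""Channel-type nomenclature, CTC subtypes, oncosome calls and morphology
flags for rare events.

A rare event's channel-type label is the "|"-joined list of its positive
non-DAPI channels in fixed order (CK, then Vim or CDX2, then CD45/CD31 or
CD45), "DAPI only" when none are positive, and is prefixed "Onc " for
DAPI-negative vesicular events.  Epithelial CTCs are CK-positive only with a
clearly defined nucleus; mesenchymal CTCs add Vim; CDX2-expressing CTCs are
CK- and CDX2-positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .morphometrics import ChannelCalls

ARTIFACT = "artifact"

#: per-protocol channel order used to build labels
CHANNEL_ORDER = {
    "Landscape": ("CK", "Vim", "CD45/CD31"),
    "CDX2": ("CK", "CDX2", "CD45"),
}

#: the 12 enumerable classifications per protocol (8 cell + 4 vesicle)
def protocol_classes(protocol: str) -> list[str]:
    a, b, c = CHANNEL_ORDER[protocol]
    cells = [
        "DAPI only", a, b, c,
        f"{a}|{b}", f"{a}|{c}", f"{b}|{c}", f"{a}|{b}|{c}",
    ]
    oncs = [f"Onc {a}", f"Onc {a}|{b}", f"Onc {a}|{c}", f"Onc {a}|{b}|{c}"]
    return cells + oncs


@dataclass(frozen=True)
class ClassificationParams:
    oncosome_min_circularity: float = 0.85
    oncosome_max_diameter_um: float = 12.0
    clear_nucleus_min_area_um2: float = 20.0
    clear_nucleus_min_solidity: float = 0.90
    mega_area_factor: float = 2.0       # × median WBC cell area
    clustered_distance_factor: float = 1.5  # × cell diameter


@dataclass
class RareEventRecord:
    """One classified rare event with its label, subtype and flags."""

    event_id: int
    frame_id: str
    channel_type: str
    is_oncosome: bool
    subtype: str  # "Epi.CTC" | "Mes.CTC" | "CDX2.CTC" | "none"
    flags: dict[str, bool] = field(default_factory=dict)
    features: dict[str, float] = field(default_factory=dict)
    patient_id: str = ""
    draw: int = 0
    protocol: str = "Landscape"


def assign_channel_type(
    calls: ChannelCalls, dapi_positive: bool, protocol: str
) -> str:
    """Deterministic channel-type label under the fixed channel order.

    DAPI-negative events with no positive channel are labeled ``"artifact"``
    and are excluded from enumeration.
    """
    order = CHANNEL_ORDER[protocol]
    pos = [role for role in order if calls.positive.get(role, False)]
    if dapi_positive:
        return "|".join(pos) if pos else "DAPI only"
    if not pos:
        return ARTIFACT
    return "Onc " + "|".join(pos)


def _has_clear_nucleus(features: dict[str, float], params: ClassificationParams) -> bool:
    return (
        features.get("nucleus_area_um2", 0.0) >= params.clear_nucleus_min_area_um2
        and features.get("nucleus_solidity", 0.0) >= params.clear_nucleus_min_solidity
    )


def call_oncosome(
    dapi_positive: bool,
    calls: ChannelCalls,
    features: dict[str, float],
    params: ClassificationParams | None = None,
) -> bool:
    """True iff the event is a vesicular (oncosome) candidate: DAPI-negative,
    CK-positive, circular, and no larger than a leukocyte."""
    params = params or ClassificationParams()
    if dapi_positive:
        return False
    if not calls.positive.get("CK", False):
        return False
    if features.get("cell_circularity", 0.0) < params.oncosome_min_circularity:
        return False
    if features.get("cell_equivalent_diameter_um", 0.0) > params.oncosome_max_diameter_um:
        return False
    return True


def assign_subtype(
    channel_type: str, is_oncosome: bool, calls: ChannelCalls,
    features: dict[str, float], protocol: str,
    params: ClassificationParams | None = None,
) -> str:
    """Named CTC subtype for nucleated rare events; "none" otherwise.

    Epi.CTC: CK only (no second/third marker) with a clearly defined nucleus.
    Mes.CTC: CK and Vim, CD45/CD31-negative, clear nucleus (Landscape).
    CDX2.CTC: CK and CDX2 positive, any CD45 state (CDX2-targeted).
    """
    params = params or ClassificationParams()
    if is_oncosome or channel_type in (ARTIFACT, "DAPI only"):
        return "none"
    if not _has_clear_nucleus(features, params):
        return "none"
    a, b, c = CHANNEL_ORDER[protocol]
    ck = calls.positive.get("CK", False)
    third = calls.positive.get(c, False)
    second = calls.positive.get(b, False)
    if protocol == "Landscape":
        if ck and not second and not third:
            return "Epi.CTC"
        if ck and second and not third:
            return "Mes.CTC"
    else:
        if ck and second:
            return "CDX2.CTC"
        if ck and not second and not third:
            return "Epi.CTC"
    return "none"


def flag_morph_subtypes(
    channel_type: str,
    calls: ChannelCalls,
    features: dict[str, float],
    protocol: str,
    wbc_median_area_um2: float,
    params: ClassificationParams | None = None,
) -> dict[str, bool]:
    """Morphology-driven flags for the two distinct rare-cell populations.

    ``mega_candidate``: immune/endothelial-marker positive with punctate
    texture and a cell area at least ``mega_area_factor`` × the leukocyte
    median — the very large multilobular phenotype.
    ``cec_candidate``: filamentous Vim together with punctate CD45/CD31,
    regardless of CK — the endothelial-like phenotype (Landscape only).
    """
    params = params or ClassificationParams()
    third = CHANNEL_ORDER[protocol][2]
    second = CHANNEL_ORDER[protocol][1]
    flags = {"mega_candidate": False, "cec_candidate": False,
             "clustered": False, "attached_oncosome": False}
    area = features.get("cell_area_um2", 0.0)
    if (
        calls.positive.get(third, False)
        and calls.texture.get(third) == "punctate"
        and area >= params.mega_area_factor * wbc_median_area_um2
    ):
        flags["mega_candidate"] = True
    if protocol == "Landscape":
        if (
            calls.positive.get(second, False)
            and calls.texture.get(second) == "filamentous"
            and calls.positive.get(third, False)
            and calls.texture.get(third) == "punctate"
        ):
            flags["cec_candidate"] = True
    return flags


def flag_clustered(
    records: list[RareEventRecord],
    centroids: np.ndarray,
    um_per_px: float,
    params: ClassificationParams | None = None,
) -> None:
    """Set the ``clustered`` flag in place: a rare event is clustered when
    another rare event's centroid lies within 1.5 cell diameters."""
    params = params or ClassificationParams()
    if len(records) < 2:
        return
    centroids = np.asarray(centroids, dtype=float)
    diam_px = np.array(
        [r.features.get("cell_equivalent_diameter_um", 10.0) / um_per_px
         for r in records]
    )
    d2 = ((centroids[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    thr = (params.clustered_distance_factor * diam_px) ** 2
    near = (d2 <= thr[:, None]).any(axis=1)
    for r, flag in zip(records, near):
        r.flags["clustered"] = bool(flag)


def classify_rare_event(
    event_id: int,
    frame_id: str,
    dapi_positive: bool,
    calls: ChannelCalls,
    features: dict[str, float],
    protocol: str,
    wbc_median_area_um2: float = 80.0,
    params: ClassificationParams | None = None,
) -> RareEventRecord:
    """Full per-event classification: label, vesicle call, subtype, flags."""
    params = params or ClassificationParams()
    onc = call_oncosome(dapi_positive, calls, features, params)
    label = assign_channel_type(calls, dapi_positive, protocol)
    if not dapi_positive and not onc:
        # non-circular or oversized DAPI-negative events are not enumerable
        label = ARTIFACT
    subtype = assign_subtype(label, onc, calls, features, protocol, params)
    flags = flag_morph_subtypes(
        label, calls, features, protocol, wbc_median_area_um2, params
    )
    return RareEventRecord(
        event_id=event_id,
        frame_id=frame_id,
        channel_type=label,
        is_oncosome=onc,
        subtype=subtype,
        flags=flags,
        features=features,
        protocol=protocol,
    )
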