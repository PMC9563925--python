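"""The 4-channel image frame container and OME-TIFF round-trip."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

#: channel ordering for the two staining protocols
LANDSCAPE_ROLES = ("DAPI", "CK", "Vim", "CD45/CD31")
CDX2_ROLES = ("DAPI", "CK", "CDX2", "CD45")


@dataclass
class Frame:
    """One scanned field of view: 4 fluorescence channels plus scale.

    ``pixels`` is (4, H, W) float32; ``channel_roles`` maps channel index to
    marker role, DAPI always first.
    """

    pixels: np.ndarray
    channel_roles: tuple[str, str, str, str]
    um_per_px: float
    frame_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.shape[0] != 4:
            raise ValueError("frames must have exactly 4 channels (4, H, W)")
        if len(self.channel_roles) != 4 or self.channel_roles[0] != "DAPI":
            raise ValueError("channel_roles must list 4 roles with DAPI first")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")

    def background_stats(self) -> np.ndarray:
        """Per-channel background median and robust sigma (1.4826 × MAD),
        shape (4, 2).  Cached: with sparse events most pixels are background,
        and every stage thresholds against these statistics."""
        cached = getattr(self, "_bg_stats", None)
        if cached is None:
            stats = np.empty((4, 2), dtype=float)
            for c in range(4):
                plane = self.pixels[c]
                med = float(np.median(plane))
                mad = float(np.median(np.abs(plane - med)))
                stats[c] = (med, 1.4826 * mad)
            self._bg_stats = cached = stats
        return cached

    def channel(self, role: str) -> np.ndarray:
        """Pixel plane for a marker role (e.g. ``frame.channel("CK")``)."""
        try:
            return self.pixels[self.channel_roles.index(role)]
        except ValueError:
            raise KeyError(f"no channel with role {role!r}") from None

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]


def write_frame(frame: Frame, path: str | Path) -> None:
    """Write a frame as multi-page OME-TIFF, one page per channel, with
    channel names and pixel size recorded in the OME metadata."""
    tifffile.imwrite(
        str(path),
        frame.pixels,
        ome=True,
        metadata={
            "axes": "CYX",
            "Channel": {"Name": list(frame.channel_roles)},
            "PhysicalSizeX": frame.um_per_px,
            "PhysicalSizeY": frame.um_per_px,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeYUnit": "µm",
        },
    )


def read_frame(path: str | Path, frame_id: str | None = None) -> Frame:
    """Read a frame written by `write_frame` (channel names and scale are
    recovered from the OME metadata)."""
    with tifffile.TiffFile(str(path)) as tif:
        pixels = tif.asarray()
        ome = tif.ome_metadata
    import xml.etree.ElementTree as ET

    root = ET.fromstring(ome)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    channels = [
        ch.get("Name") for ch in root.iter(f"{{{ns['ome']}}}Channel") if ch.get("Name")
    ]
    px = root.find(".//ome:Pixels", ns)
    um = float(px.get("PhysicalSizeX", "1.0"))
    return Frame(
        pixels=pixels,
        channel_roles=tuple(channels),
        um_per_px=um,
        frame_id=frame_id or Path(path).stem,
    )
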