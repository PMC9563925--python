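"""Shared fixtures: small rendered samples reused across test modules."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from rarescope.synthetic import (
    SampleSpec,
    landscape_populations,
    render_frame,
)

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def default_sample_spec() -> SampleSpec:
    """A small Landscape slide at default population mix."""
    return SampleSpec(
        patient_id="P01",
        draw=1,
        protocol="Landscape",
        wbc_concentration_per_ml=5e6,
        frames=6,
        populations=landscape_populations(rare_scale=1.5),
        seed=11,
    )


@pytest.fixture(scope="session")
def rendered_frames(default_sample_spec):
    """All frames of the default sample with ground truth, rendered once."""
    return [
        render_frame(default_sample_spec, fi)
        for fi in range(default_sample_spec.frames)
    ]


@pytest.fixture(scope="session")
def segmented_frames(rendered_frames):
    """Segmentation output per rendered frame (cached for reuse)."""
    from rarescope.segmentation import segment_frame

    return [
        (frame, truths, segment_frame(frame))
        for frame, truths in rendered_frames
    ]
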