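"""Classification tests: channel-type nomenclature, oncosome gating, CTC
subtypes and morphology flags."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rarescope.classification import (
    ARTIFACT,
    ClassificationParams,
    assign_channel_type,
    assign_subtype,
    call_oncosome,
    classify_rare_event,
    flag_morph_subtypes,
    protocol_classes,
)
from rarescope.morphometrics import ChannelCalls


def _calls(protocol="Landscape", **pos):
    roles = (
        ("CK", "Vim", "CD45/CD31") if protocol == "Landscape"
        else ("CK", "CDX2", "CD45")
    )
    textures = pos.pop("textures", {})
    positive = {"DAPI": pos.pop("dapi", True)}
    positive.update({r: pos.get(r, False) for r in roles})
    texture = {r: textures.get(r, "diffuse" if positive[r] else "none")
               for r in roles}
    texture["DAPI"] = "none"
    medians = {r: 100.0 if positive[r] else 20.0 for r in positive}
    return ChannelCalls(positive=positive, texture=texture,
                        median_intensity=medians)


GOOD_NUCLEUS = {"nucleus_area_um2": 60.0, "nucleus_solidity": 0.95,
                "cell_circularity": 0.8, "cell_equivalent_diameter_um": 14.0,
                "cell_area_um2": 160.0}


def test_epithelial_ctc_label_and_subtype():
    calls = _calls(CK=True)
    label = assign_channel_type(calls, True, "Landscape")
    assert label == "CK"
    assert assign_subtype(label, False, calls, GOOD_NUCLEUS, "Landscape") == "Epi.CTC"


def test_mesenchymal_ctc_label_and_subtype():
    calls = _calls(CK=True, Vim=True)
    label = assign_channel_type(calls, True, "Landscape")
    assert label == "CK|Vim"
    assert assign_subtype(label, False, calls, GOOD_NUCLEUS, "Landscape") == "Mes.CTC"


def test_oncosome_label_prefix():
    calls = _calls(dapi=False, CK=True, Vim=True)
    assert assign_channel_type(calls, False, "Landscape") == "Onc CK|Vim"


def test_dapi_only_and_artifact_labels():
    assert assign_channel_type(_calls(), True, "Landscape") == "DAPI only"
    assert assign_channel_type(_calls(dapi=False), False, "Landscape") == ARTIFACT


def test_cdx2_ctc_subtype_is_cd45_agnostic():
    for cd45 in (False, True):
        calls = _calls("CDX2", CK=True, CDX2=True, CD45=cd45)
        label = assign_channel_type(calls, True, "CDX2")
        assert label == ("CK|CDX2|CD45" if cd45 else "CK|CDX2")
        assert assign_subtype(label, False, calls, GOOD_NUCLEUS, "CDX2") == "CDX2.CTC"


def test_subtype_requires_clear_nucleus():
    calls = _calls(CK=True)
    weak = dict(GOOD_NUCLEUS, nucleus_area_um2=10.0)
    assert assign_subtype("CK", False, calls, weak, "Landscape") == "none"


def test_oncosome_gate():
    params = ClassificationParams()
    feats = {"cell_circularity": 0.95, "cell_equivalent_diameter_um": 8.0}
    assert call_oncosome(False, _calls(dapi=False, CK=True), feats, params)
    # DAPI-positive events are never vesicles
    assert not call_oncosome(True, _calls(CK=True), feats, params)
    # elongated streak rejected
    streak = {"cell_circularity": 0.4, "cell_equivalent_diameter_um": 8.0}
    assert not call_oncosome(False, _calls(dapi=False, CK=True), streak, params)
    # oversized vesicle rejected
    big = {"cell_circularity": 0.95, "cell_equivalent_diameter_um": 14.0}
    assert not call_oncosome(False, _calls(dapi=False, CK=True), big, params)


def test_rendered_debris_rejected_from_oncosome_call():
    """Elongated CK+ DAPI− streaks from the simulator are rejected by the
    circularity gate in ≥95% of cases."""
    import warnings

    from rarescope.morphometrics import call_channels, extract_features
    from rarescope.segmentation import match_to_truth, segment_frame
    from rarescope.synthetic import SampleSpec, debris_population, render_frame

    spec = SampleSpec("P", 1, "Landscape", 5e6, 8, (debris_population(6.0),),
                      seed=8)
    n = rejected = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for fi in range(spec.frames):
            frame, truths = render_frame(spec, fi)
            events = segment_frame(frame)
            for i, _ in match_to_truth(events, truths):
                ev = events[i]
                feats = extract_features(ev, frame)
                calls = call_channels(ev, frame)
                n += 1
                rejected += not call_oncosome(False, calls, feats)
    assert n >= 30
    assert rejected / n >= 0.95


def test_mega_and_cec_flags():
    params = ClassificationParams()
    wbc_area = 80.0
    mega_calls = _calls(**{"CD45/CD31": True,
                           "textures": {"CD45/CD31": "punctate"}})
    flags = flag_morph_subtypes("CD45/CD31", mega_calls,
                                {"cell_area_um2": 400.0}, "Landscape",
                                wbc_area, params)
    assert flags["mega_candidate"]
    # CEC: filamentous Vim + punctate CD45/CD31, CK state irrelevant
    for ck in (False, True):
        cec_calls = _calls(CK=ck, Vim=True, **{"CD45/CD31": True,
                           "textures": {"Vim": "filamentous",
                                        "CD45/CD31": "punctate"}})
        flags = flag_morph_subtypes("Vim|CD45/CD31", cec_calls,
                                    {"cell_area_um2": 200.0}, "Landscape",
                                    wbc_area, params)
        assert flags["cec_candidate"]
    # an ordinary leukocyte raises no flags
    wbc_calls = _calls(**{"CD45/CD31": True})
    flags = flag_morph_subtypes("CD45/CD31", wbc_calls,
                                {"cell_area_um2": 80.0}, "Landscape",
                                wbc_area, params)
    assert not any(flags.values())


@settings(derandomize=True, max_examples=200, deadline=None)
@given(
    dapi=st.booleans(),
    ck=st.booleans(),
    second=st.booleans(),
    third=st.booleans(),
    protocol=st.sampled_from(["Landscape", "CDX2"]),
    circ=st.floats(0.0, 1.05),
    diam=st.floats(1.0, 20.0),
)
def test_every_event_maps_to_one_classification_or_artifact(
    dapi, ck, second, third, protocol, circ, diam
):
    """The channel-type labels partition rare events: each falls into exactly
    one of the 12 per-protocol classes or 'artifact'."""
    roles = ("CK", "Vim", "CD45/CD31") if protocol == "Landscape" else (
        "CK", "CDX2", "CD45")
    calls = _calls(protocol, dapi=dapi,
                   **{roles[0]: ck, roles[1]: second, roles[2]: third})
    feats = dict(GOOD_NUCLEUS, cell_circularity=circ,
                 cell_equivalent_diameter_um=diam)
    rec = classify_rare_event(0, "f", dapi, calls, feats, protocol)
    allowed = set(protocol_classes(protocol)) | {ARTIFACT}
    assert rec.channel_type in allowed
    if rec.is_oncosome:
        assert not dapi
        assert rec.channel_type.startswith("Onc ")
        assert rec.subtype == "none"
    if rec.channel_type.startswith("Onc "):
        assert rec.is_oncosome


def test_clustered_flag_set_for_adjacent_rare_events():
    from rarescope.classification import RareEventRecord, flag_clustered

    recs = [
        RareEventRecord(i, "f", "CK", False, "none",
                        flags={"clustered": False},
                        features={"cell_equivalent_diameter_um": 10.0})
        for i in range(3)
    ]
    centroids = np.array([[10.0, 10.0], [10.0, 22.0], [200.0, 200.0]])
    flag_clustered(recs, centroids, um_per_px=1.0)
    assert recs[0].flags["clustered"]
    assert recs[1].flags["clustered"]
    assert not recs[2].flags["clustered"]
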