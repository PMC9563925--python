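"""End-to-end pipeline: simulate → segment → features → detect → classify →
enumerate → (multi-assay) → survival statistics."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classification import (
    ClassificationParams,
    RareEventRecord,
    classify_rare_event,
    flag_clustered,
    protocol_classes,
)
from .detection import DetectionParams, detect_rare, reduce_dimensions
from .enumeration import build_enumeration_table
from .frame import Frame
from .morphometrics import CallParams, call_channels, extract_features
from .segmentation import SegmentationParams, segment_frame
from .synthetic import SampleSpec, render_frame

log = logging.getLogger("rarescope")

#: shape columns fed to the common/rare detector; every channel's median
#: intensity is appended per frame (channel roles differ by protocol)
DETECTION_SHAPE_FEATURES = [
    "cell_area_um2", "cell_eccentricity", "cell_circularity", "cell_solidity",
    "nucleus_area_um2", "nucleus_eccentricity", "nuclear_to_cell_area_ratio",
    "mean_outline_to_nucleus_center_distance_um",
]


def detection_feature_names(channel_roles) -> list[str]:
    keys = [
        "dapi" if r == "DAPI" else r.lower().replace("/", "").replace("|", "")
        for r in channel_roles
    ]
    return DETECTION_SHAPE_FEATURES + [f"{k}_median_intensity" for k in keys]


@dataclass
class SampleResult:
    """Everything the pipeline produced for one sample."""

    spec: SampleSpec
    records: list[RareEventRecord]
    enumeration: pd.DataFrame
    features: pd.DataFrame
    dapi_nuclei_count: int
    n_events: int


def process_frame(
    frame: Frame,
    seg_params: SegmentationParams,
    call_params: CallParams,
    det_params: DetectionParams,
    cls_params: ClassificationParams,
    protocol: str,
) -> tuple[list[RareEventRecord], pd.DataFrame, int]:
    """Segment, featurize, detect and classify the rare events of one frame.

    Returns (rare-event records, per-event feature table, nuclei count).
    """
    events = segment_frame(frame, seg_params)
    if not events:
        return [], pd.DataFrame(), 0
    feats = [extract_features(ev, frame) for ev in events]
    calls = [call_channels(ev, frame, call_params) for ev in events]
    fdf = pd.DataFrame(feats)
    fdf["event_id"] = [ev.event_id for ev in events]
    fdf["dapi_positive"] = [ev.dapi_positive for ev in events]
    fdf["frame_id"] = frame.frame_id

    dapi_flags = np.array([ev.dapi_positive for ev in events])
    n_nuclei = int(dapi_flags.sum())
    X = fdf[detection_feature_names(frame.channel_roles)].to_numpy(dtype=float)
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        # standardize and reduce over the clustering scope only: DAPI-negative
        # events bypass the common/rare split, and their zeroed nucleus
        # features would otherwise inflate the feature scales
        scores = np.zeros((len(events), 1))
        if dapi_flags.sum() >= 2:
            pos_scores, _, _ = reduce_dimensions(
                X[dapi_flags], det_params.variance_explained
            )
            scores = np.zeros((len(events), pos_scores.shape[1]))
            scores[dapi_flags] = pos_scores
        detections = detect_rare(
            scores, dapi_flags,
            event_ids=np.array([ev.event_id for ev in events]),
            params=det_params,
        )
    common_areas = [
        f["cell_area_um2"]
        for f, d, ev in zip(feats, detections, events)
        if not d.is_rare and ev.dapi_positive
    ]
    wbc_area = float(np.median(common_areas)) if common_areas else 80.0

    records: list[RareEventRecord] = []
    centroids = []
    for ev, f, c, d in zip(events, feats, calls, detections):
        if not d.is_rare:
            continue
        rec = classify_rare_event(
            ev.event_id, frame.frame_id, ev.dapi_positive, c, f,
            protocol, wbc_area, cls_params,
        )
        records.append(rec)
        centroids.append(ev.centroid)
    if records:
        flag_clustered(records, np.array(centroids), frame.um_per_px, cls_params)
    return records, fdf, n_nuclei


def process_sample(
    spec: SampleSpec,
    seg_params: SegmentationParams | None = None,
    call_params: CallParams | None = None,
    det_params: DetectionParams | None = None,
    cls_params: ClassificationParams | None = None,
    max_frames: int | None = None,
) -> SampleResult:
    """Run the full image pipeline on every frame of one simulated sample and
    enumerate the detected rare events to events/mL."""
    seg_params = seg_params or SegmentationParams()
    call_params = call_params or CallParams()
    det_params = det_params or DetectionParams()
    cls_params = cls_params or ClassificationParams()
    n_frames = min(spec.frames, max_frames) if max_frames else spec.frames

    all_records: list[RareEventRecord] = []
    all_feats: list[pd.DataFrame] = []
    nuclei = 0
    n_events = 0
    for fi in range(n_frames):
        frame, _ = render_frame(spec, fi)
        recs, fdf, n_nuc = process_frame(
            frame, seg_params, call_params, det_params, cls_params, spec.protocol
        )
        for r in recs:
            r.patient_id = spec.patient_id
            r.draw = spec.draw
        all_records.extend(recs)
        all_feats.append(fdf)
        nuclei += n_nuc
        n_events += len(fdf)

    counts: dict[str, int] = {}
    for r in all_records:
        if r.channel_type == "artifact":
            continue
        counts[r.channel_type] = counts.get(r.channel_type, 0) + 1
    # scale detected nuclei up to the full slide when only a frame subset ran
    scale = spec.frames / n_frames
    enum = build_enumeration_table(
        counts,
        protocol_classes(spec.protocol),
        dapi_nuclei_count=max(nuclei, 1),
        wbc_concentration_per_ml=spec.wbc_concentration_per_ml * scale,
        sample_meta={
            "patient_id": spec.patient_id,
            "draw": spec.draw,
            "protocol": spec.protocol,
        },
    )
    return SampleResult(
        spec=spec,
        records=all_records,
        enumeration=enum,
        features=pd.concat(all_feats, ignore_index=True) if all_feats else pd.DataFrame(),
        dapi_nuclei_count=nuclei,
        n_events=n_events,
    )


def records_to_frame(records: list[RareEventRecord]) -> pd.DataFrame:
    """Flatten rare-event records (labels, subtype, flags, features) into a
    tidy table."""
    rows = []
    for r in records:
        row = {
            "event_id": r.event_id,
            "frame_id": r.frame_id,
            "patient_id": r.patient_id,
            "draw": r.draw,
            "protocol": r.protocol,
            "channel_type": r.channel_type,
            "is_oncosome": r.is_oncosome,
            "subtype": r.subtype,
        }
        row.update({f"flag_{k}": v for k, v in r.flags.items()})
        row.update(r.features)
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Run the configured study pipeline and write the artifact tree.

    Stages: simulate the configured samples, process each end to end, write
    per-sample enumeration and classification CSVs, then a combined
    enumeration table and a JSON manifest.  Deterministic for a fixed config
    (the manifest timestamp aside).
    """
    from .config import validate_config

    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    rng = np.random.default_rng(seed)
    protocols = [config["protocol"]] if config["protocol"] != "both" else [
        "Landscape", "CDX2",
    ]
    from .synthetic import cdx2_populations, landscape_populations

    seg = SegmentationParams(**config.get("segmentation", {}))
    call = CallParams(**config.get("morphometrics", {}))
    det = DetectionParams(**config.get("detection", {}))
    cls = ClassificationParams(**config.get("classification", {}))

    enum_tables = []
    record_tables = []
    for i in range(int(config["n_patients"])):
        pid = f"P{i + 1:02d}"
        wbc_conc = float(rng.lognormal(np.log(5e6), 0.2))
        for protocol in protocols:
            pops = (
                landscape_populations(rare_scale=config.get("rare_scale", 1.0))
                if protocol == "Landscape"
                else cdx2_populations(rare_scale=config.get("rare_scale", 1.0))
            )
            spec = SampleSpec(
                patient_id=pid, draw=1, protocol=protocol,
                wbc_concentration_per_ml=wbc_conc,
                frames=int(config["frames_per_slide"]),
                populations=pops,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            log.info("processing %s (%s)", pid, protocol)
            res = process_sample(spec, seg, call, det, cls)
            enum_tables.append(res.enumeration)
            record_tables.append(records_to_frame(res.records))

    enum_all = pd.concat(enum_tables, ignore_index=True)
    rec_all = (
        pd.concat(record_tables, ignore_index=True)
        if any(len(t) for t in record_tables)
        else pd.DataFrame()
    )
    enum_all.to_csv(out / "enumeration.csv", index=False)
    rec_all.to_csv(out / "classification.csv", index=False)

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": {k: v for k, v in config.items()},
        "n_samples": len(enum_tables),
        "n_rare_events": int(len(rec_all)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
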