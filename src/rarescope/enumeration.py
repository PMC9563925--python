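"""Enumeration: events/mL conversion, positivity, frequencies and cohort
summaries.

Slide counts are converted to concentrations through the blood volume
actually analyzed: volume (mL) = DAPI-nuclei on slide ÷ leukocyte
concentration per mL measured at processing.  Sample positivity for a
classification uses a fixed ≥ 5 events/mL threshold.  Cohort summaries
follow the standard report shape: per classification, positivity k/n, mean,
standard error, percentage of the total rare-event profile (computed from
the classification means), median and range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

POSITIVITY_THRESHOLD = 5.0  # events/mL


def blood_volume(dapi_nuclei_count: float, wbc_concentration_per_ml: float) -> float:
    """Blood volume analyzed on a slide, in mL."""
    if dapi_nuclei_count <= 0 or wbc_concentration_per_ml <= 0:
        raise ValueError("nuclei count and WBC concentration must be positive")
    return dapi_nuclei_count / wbc_concentration_per_ml


def to_events_per_ml(raw_count: float, volume_ml: float) -> float:
    """Concentration of a classification given its raw slide count."""
    if volume_ml <= 0:
        raise ValueError("volume must be positive")
    return raw_count / volume_ml


def build_enumeration_table(
    counts: dict[str, int],
    classifications: list[str],
    dapi_nuclei_count: float,
    wbc_concentration_per_ml: float,
    sample_meta: dict | None = None,
) -> pd.DataFrame:
    """Per-sample enumeration rows, one per classification.

    Classifications absent from ``counts`` get raw_count 0 (zero-count
    samples still contribute to cohort means and medians).  Frequencies are
    percentages of the sample's total rare-event profile and sum to 100.
    """
    vol = blood_volume(dapi_nuclei_count, wbc_concentration_per_ml)
    rows = []
    for cls in classifications:
        raw = int(counts.get(cls, 0))
        epm = to_events_per_ml(raw, vol)
        rows.append({"classification": cls, "raw_count": raw, "events_per_ml": epm})
    df = pd.DataFrame(rows)
    total = df["events_per_ml"].sum()
    df["positive"] = df["events_per_ml"] >= POSITIVITY_THRESHOLD
    df["frequency_pct"] = np.where(
        total > 0, 100.0 * df["events_per_ml"] / total, 0.0
    )
    df["blood_volume_ml"] = vol
    df["dapi_nuclei_count"] = dapi_nuclei_count
    df["wbc_concentration_per_ml"] = wbc_concentration_per_ml
    for k, v in (sample_meta or {}).items():
        df[k] = v
    return df


def summarize_cohort(
    tables: list[pd.DataFrame] | pd.DataFrame,
    classifications: list[str] | None = None,
) -> pd.DataFrame:
    """Cohort summary across samples, one row per classification.

    Columns: ``sample_positivity`` ("k/n" at ≥ 5 events/mL), ``mean``,
    ``standard_error`` (sd/√n over samples), ``pct_of_total`` (100 × mean /
    Σ classification means), ``median``, ``range_min``/``range_max``.
    """
    if isinstance(tables, list):
        df = pd.concat(tables, ignore_index=True)
    else:
        df = tables.copy()
    if classifications is None:
        classifications = list(df["classification"].unique())
    df = df[df["classification"].isin(classifications)]
    g = df.groupby("classification")["events_per_ml"]
    n = g.size()
    mean = g.mean()
    sd = g.std(ddof=1).fillna(0.0)
    se = sd / np.sqrt(n)
    pos = df.groupby("classification")["events_per_ml"].apply(
        lambda s: int((s >= POSITIVITY_THRESHOLD).sum())
    )
    total_mean = mean.sum()
    out = pd.DataFrame(
        {
            "sample_positivity": [f"{pos[c]}/{n[c]}" for c in classifications],
            "mean": [mean[c] for c in classifications],
            "standard_error": [se[c] for c in classifications],
            "pct_of_total": [
                100.0 * mean[c] / total_mean if total_mean > 0 else 0.0
                for c in classifications
            ],
            "median": [g.get_group(c).median() for c in classifications],
            "range_min": [g.get_group(c).min() for c in classifications],
            "range_max": [g.get_group(c).max() for c in classifications],
        },
        index=pd.Index(classifications, name="classification"),
    )
    return out


def composition_shares(summary: pd.DataFrame) -> dict[str, float]:
    """Composition percentages of a cohort summary.

    Returns the vesicle (oncosome) share and rare-cell share of the total
    rare-event profile, the CK-positive share *of the rare cells*, and each
    classification's share of the total — all in percent, derived from the
    per-classification means.
    """
    mean = summary["mean"]
    is_onc = summary.index.str.startswith("Onc ")
    total = mean.sum()
    cells = mean[~is_onc]
    out = {
        "oncosome_pct": 100.0 * mean[is_onc].sum() / total,
        "rare_cell_pct": 100.0 * cells.sum() / total,
        "ck_positive_pct_of_cells": 100.0
        * cells[cells.index.str.contains("CK")].sum()
        / cells.sum(),
    }
    for cls in summary.index:
        out[f"share:{cls}"] = 100.0 * mean[cls] / total
    return out


# ---------------------------------------------------------------------------
# published reference enumerations for an 18-sample mCRC cohort
# (per-classification mean, standard error, median events/mL and range, as
# reported for the two 4-color staining protocols; used as fixed inputs for
# composition arithmetic and as realistic cohort anchors)

_L = [
    # classification, positive_k, mean, se, median, range_min, range_max
    ("DAPI only", 15, 13.69, 2.90, 10.84, 0.00, 51.57),
    ("CK", 7, 57.00, 36.36, 3.55, 0.00, 549.63),
    ("Vim", 11, 6.64, 1.27, 7.30, 0.00, 20.16),
    ("CD45/CD31", 10, 10.29, 2.44, 8.05, 0.00, 33.16),
    ("CK|Vim", 6, 7.60, 1.40, 1.40, 0.00, 91.29),
    ("CK|CD45/CD31", 4, 4.66, 1.86, 2.13, 0.00, 30.74),
    ("Vim|CD45/CD31", 11, 24.52, 8.73, 7.79, 0.00, 121.00),
    ("CK|Vim|CD45/CD31", 15, 100.40, 35.02, 12.89, 0.00, 453.13),
    ("Onc CK", 12, 71.59, 38.39, 6.64, 1.06, 657.60),
    ("Onc CK|Vim", 10, 32.72, 13.64, 7.38, 0.00, 217.65),
    ("Onc CK|CD45/CD31", 0, 1.47, 0.36, 1.12, 0.00, 4.47),
    ("Onc CK|Vim|CD45/CD31", 14, 55.37, 16.22, 34.32, 0.00, 268.32),
]

_C = [
    ("DAPI only", 18, 63.72, 12.80, 45.29, 16.94, 226.94),
    ("CK", 12, 88.14, 43.95, 11.97, 0.00, 597.32),
    ("CDX2", 12, 11.45, 3.28, 7.27, 1.04, 60.22),
    ("CD45", 3, 5.44, 3.35, 0.00, 0.00, 59.22),
    ("CK|CDX2", 14, 19.95, 6.71, 11.34, 0.00, 124.08),
    ("CK|CD45", 12, 36.66, 13.71, 10.02, 0.00, 203.63),
    ("CDX2|CD45", 12, 29.37, 12.46, 9.80, 0.00, 185.68),
    ("CK|CDX2|CD45", 14, 143.67, 101.35, 21.79, 1.44, 1843.34),
    ("Onc CK", 15, 123.55, 60.73, 26.00, 2.31, 1035.65),
    ("Onc CK|CDX2", 18, 222.40, 65.04, 114.87, 15.55, 1151.64),
    ("Onc CK|CD45", 0, 0.06, 0.06, 0.00, 0.00, 1.06),
    ("Onc CK|CDX2|CD45", 10, 20.27, 7.64, 14.50, 0.00, 1138.28),
]


def _reference_frame(rows: list[tuple]) -> pd.DataFrame:
    return pd.DataFrame(
        rows,
        columns=[
            "classification", "positive_k", "mean", "standard_error",
            "median", "range_min", "range_max",
        ],
    ).set_index("classification")


REFERENCE_COHORT_N = 18
LANDSCAPE_REFERENCE = _reference_frame(_L)
CDX2_REFERENCE = _reference_frame(_C)


def reference_summary(protocol: str) -> pd.DataFrame:
    """The published 18-sample cohort enumeration summary for a protocol, in
    `summarize_cohort` column shape."""
    ref = LANDSCAPE_REFERENCE if protocol == "Landscape" else CDX2_REFERENCE
    total = ref["mean"].sum()
    return pd.DataFrame(
        {
            "sample_positivity": [
                f"{k}/{REFERENCE_COHORT_N}" for k in ref["positive_k"]
            ],
            "mean": ref["mean"],
            "standard_error": ref["standard_error"],
            "pct_of_total": 100.0 * ref["mean"] / total,
            "median": ref["median"],
            "range_min": ref["range_min"],
            "range_max": ref["range_max"],
        },
        index=ref.index,
    )


def mean_table_as_single_sample(protocol: str) -> pd.DataFrame:
    """The published per-classification mean enumerations re-expressed as a
    one-sample enumeration table, for composition arithmetic."""
    ref = LANDSCAPE_REFERENCE if protocol == "Landscape" else CDX2_REFERENCE
    return pd.DataFrame(
        {
            "classification": ref.index,
            "raw_count": np.nan,
            "events_per_ml": ref["mean"].to_numpy(),
        }
    )
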