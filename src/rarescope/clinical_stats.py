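"""Clinical statistics: cohort contrasts, analyte–survival association,
Kaplan–Meier median stratification and draw-to-draw kinetics.

Patient cohorts are compared per classification by the Wilcoxon rank-sum
test (two-tailed).  Analyte concentrations are screened against
progression-free survival (PFS) by Spearman rank correlation at a raw
two-tailed p ≤ 0.05 (no multiplicity correction by default, with an optional
Benjamini–Hochberg adjustment).  Significant analytes are visualized by
Kaplan–Meier curves after splitting patients at the cohort median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats


@dataclass
class StratifiedKM:
    """Median-threshold Kaplan–Meier stratification of one analyte."""

    analyte: str
    threshold: float
    rule: str  # "gt": high group is value > median; "ge": value ≥ median
    groups: pd.Series  # patient_id -> "high" | "low"
    km_high: KaplanMeierFitter
    km_low: KaplanMeierFitter
    km_overall: KaplanMeierFitter

    def survival_at(self, group: str, t: float) -> float:
        km = {"high": self.km_high, "low": self.km_low, "overall": self.km_overall}[group]
        return float(km.predict(t))


def compare_cohorts(
    case_values: np.ndarray, control_values: np.ndarray
) -> tuple[float, float]:
    """Two-tailed Wilcoxon rank-sum (Mann–Whitney) test between two arms.

    Uses the exact null distribution for small tie-free samples and the
    normal approximation otherwise.  Returns (U statistic, two-tailed p).
    """
    case_values = np.asarray(case_values, dtype=float)
    control_values = np.asarray(control_values, dtype=float)
    if len(case_values) == 0 or len(control_values) == 0:
        raise ValueError("both arms must be non-empty")
    res = stats.mannwhitneyu(
        case_values, control_values, alternative="two-sided", method="auto"
    )
    return float(res.statistic), float(res.pvalue)


def compare_cohorts_by_class(
    case: pd.DataFrame, control: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-classification rank-sum contrast between two enumeration tables
    (long form with ``classification`` and ``events_per_ml``), ordered by
    ascending p."""
    rows = []
    for cls in case["classification"].unique():
        x = case.loc[case["classification"] == cls, "events_per_ml"].to_numpy()
        y = control.loc[control["classification"] == cls, "events_per_ml"].to_numpy()
        if len(y) == 0:
            continue
        u, p = compare_cohorts(x, y)
        rows.append({"classification": cls, "statistic": u, "p_value": p,
                     "significant": p <= alpha})
    return pd.DataFrame(rows).sort_values("p_value", ignore_index=True)


def analyte_pfs_correlation(
    values: np.ndarray,
    pfs_months: np.ndarray,
    method: str = "t",
) -> tuple[float, float]:
    """Spearman correlation between an analyte and PFS.

    ``method="t"`` uses the t-approximation for the two-tailed p (the default
    for the small cohorts this targets); ``method="exact"`` enumerates the
    permutation null (feasible for n ≤ 9).  A constant analyte yields
    (nan, nan).
    """
    values = np.asarray(values, dtype=float)
    pfs_months = np.asarray(pfs_months, dtype=float)
    if len(values) < 4:
        raise ValueError("need at least 4 patients")
    if np.std(values) == 0 or np.std(pfs_months) == 0:
        return float("nan"), float("nan")
    if method == "t":
        rho, p = stats.spearmanr(values, pfs_months)
        return float(rho), float(p)
    if method == "exact":
        from itertools import permutations

        n = len(values)
        rho_obs, _ = stats.spearmanr(values, pfs_months)
        count = 0
        total = 0
        ranks = stats.rankdata(pfs_months)
        for perm in permutations(ranks):
            r, _ = stats.spearmanr(values, np.asarray(perm))
            if abs(r) >= abs(rho_obs) - 1e-12:
                count += 1
            total += 1
        return float(rho_obs), count / total
    raise ValueError(f"unknown method {method!r}")


def screen_analytes(
    records: pd.DataFrame,
    alpha: float = 0.05,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Screen every analyte column against PFS by Spearman correlation.

    ``records`` has ``pfs_months`` plus one column per analyte.  Returns rho
    and two-tailed p per analyte with a ``keep`` flag at p ≤ alpha (or BH-
    adjusted p when ``bh_adjust``)."""
    analytes = [c for c in records.columns
                if c not in ("patient_id", "pfs_months", "event_flag")]
    rows = []
    for a in analytes:
        sub = records[[a, "pfs_months"]].dropna()
        if len(sub) < 4 or sub[a].std() == 0:
            rows.append({"analyte": a, "rho": np.nan, "p_value": np.nan})
            continue
        rho, p = analyte_pfs_correlation(sub[a].to_numpy(), sub["pfs_months"].to_numpy())
        rows.append({"analyte": a, "rho": rho, "p_value": p, "n": len(sub)})
    out = pd.DataFrame(rows)
    pv = out["p_value"].to_numpy()
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests

        ok = np.isfinite(pv)
        adj = np.full_like(pv, np.nan)
        if ok.any():
            adj[ok] = multipletests(pv[ok], method="fdr_bh")[1]
        out["p_adjusted"] = adj
        out["keep"] = out["p_adjusted"] <= alpha
    else:
        out["keep"] = out["p_value"] <= alpha
    return out


def km_stratify(
    records: pd.DataFrame,
    analyte: str,
    rule: str = "gt",
) -> StratifiedKM:
    """Kaplan–Meier curves after splitting patients at the analyte median.

    ``records`` needs ``patient_id``, ``pfs_months``, ``event_flag`` and the
    analyte column.  ``rule="gt"`` puts values strictly above the median in
    the high group (values equal to the median go low); ``rule="ge"`` uses ≥,
    the convention for kinetics deltas.  All identical values collapse to a
    single group with a warning.
    """
    if rule not in ("gt", "ge"):
        raise ValueError("rule must be 'gt' or 'ge'")
    sub = records[["patient_id", "pfs_months", "event_flag", analyte]].dropna()
    if len(sub) < 4:
        raise ValueError("need at least 4 patients")
    thr = float(sub[analyte].median())
    vals = sub[analyte].to_numpy()
    high = vals > thr if rule == "gt" else vals >= thr
    if high.all() or (~high).all():
        warnings.warn("analyte values do not split at the median: single group",
                      stacklevel=2)
    groups = pd.Series(np.where(high, "high", "low"), index=sub["patient_id"])
    kf = {}
    for name, m in (("high", high), ("low", ~high), ("overall", np.ones_like(high, bool))):
        km = KaplanMeierFitter(label=name)
        if m.any():
            km.fit(sub["pfs_months"][m], event_observed=sub["event_flag"][m])
        kf[name] = km
    return StratifiedKM(
        analyte=analyte, threshold=thr, rule=rule, groups=groups,
        km_high=kf["high"], km_low=kf["low"], km_overall=kf["overall"],
    )


def kinetics(
    records: pd.DataFrame,
    analyte_draw1: str = "draw1",
    analyte_draw2: str = "draw2",
) -> tuple[pd.DataFrame, int]:
    """Per-patient change in events/mL between draws (draw 2 − draw 1).

    Patients missing either draw are excluded; returns (deltas ordered by
    descending PFS when available, number excluded).
    """
    both = records.dropna(subset=[analyte_draw1, analyte_draw2])
    excluded = len(records) - len(both)
    out = both.copy()
    out["delta_events_per_ml"] = out[analyte_draw2] - out[analyte_draw1]
    if "pfs_months" in out.columns:
        out = out.sort_values("pfs_months", ascending=False, ignore_index=True)
    return out, excluded


def km_product_limit(
    times: np.ndarray, events: np.ndarray
) -> pd.DataFrame:
    """Closed-form product-limit estimate (used as an independent check of
    the fitted curves): S(t) = Π over event times ≤ t of (1 − d_i / n_i)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    uniq = np.unique(times[events == 1])
    rows = [(0.0, 1.0)]
    s = 1.0
    for t in uniq:
        n_at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / n_at_risk
        rows.append((float(t), s))
    return pd.DataFrame(rows, columns=["time", "survival"])
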