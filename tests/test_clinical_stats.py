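"""Clinical-statistics tests: rank-sum contrasts, analyte–PFS screening,
Kaplan–Meier stratification and draw-to-draw kinetics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rarescope.clinical_stats import (
    analyte_pfs_correlation,
    compare_cohorts,
    compare_cohorts_by_class,
    kinetics,
    km_product_limit,
    km_stratify,
    screen_analytes,
)


def test_identical_arms_give_p_one():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    _, p = compare_cohorts(x, x)
    assert p == pytest.approx(1.0)


def test_empty_arm_rejected():
    with pytest.raises(ValueError):
        compare_cohorts(np.array([]), np.array([1.0]))


def test_shifted_arm_detected():
    rng = np.random.default_rng(0)
    x = rng.lognormal(2.5, 0.5, 18)
    y = rng.lognormal(1.0, 0.5, 50)
    _, p = compare_cohorts(x, y)
    assert p < 1e-6


def test_class_ordering_by_p_value():
    rng = np.random.default_rng(1)
    rows_case, rows_ctrl = [], []
    for cls, shift in (("big", 3.0), ("none", 0.0)):
        for v in rng.lognormal(shift, 0.5, 12):
            rows_case.append({"classification": cls, "events_per_ml": v})
        for v in rng.lognormal(0.0, 0.5, 20):
            rows_ctrl.append({"classification": cls, "events_per_ml": v})
    res = compare_cohorts_by_class(pd.DataFrame(rows_case), pd.DataFrame(rows_ctrl))
    assert list(res["classification"]) == ["big", "none"]
    assert res.iloc[0]["significant"]


def test_perfect_monotone_analyte_gives_rho_one():
    pfs = np.array([2.0, 3.5, 5.0, 7.5, 9.0])
    rho, _ = analyte_pfs_correlation(pfs**2, pfs)
    assert rho == pytest.approx(1.0)


def test_printed_nine_patient_association_p_value():
    """rho = 0.70 at n = 9 gives a two-tailed p near 0.037 under the
    t-approximation."""
    x = np.arange(1.0, 10.0)
    y = np.array([4, 2, 3, 1, 8, 6, 7, 5, 9], dtype=float)  # Σd² = 36 → rho 0.7
    rho, p = analyte_pfs_correlation(x, y)
    assert rho == pytest.approx(0.70)
    assert p == pytest.approx(0.0372, abs=0.005)


def test_exact_permutation_p_close_to_t_approximation():
    x = np.arange(1.0, 9.0)
    y = np.array([2, 1, 4, 3, 6, 5, 8, 7], dtype=float)
    rho_t, p_t = analyte_pfs_correlation(x, y, method="t")
    rho_e, p_e = analyte_pfs_correlation(x, y, method="exact")
    assert rho_t == pytest.approx(rho_e)
    assert p_e == pytest.approx(p_t, abs=0.03)


def test_constant_analyte_reported_missing():
    rho, p = analyte_pfs_correlation(np.full(6, 2.0), np.arange(6.0))
    assert np.isnan(rho) and np.isnan(p)


def test_link_strength_recovery_at_n9():
    """With a 0.8-strength monotone link and n = 9, the median recovered
    |rho| over repeated cohorts lands near the configured strength."""
    from rarescope.synthetic import CohortSpec, PfsModel, generate_cohort

    rhos = []
    for seed in range(120):
        spec = CohortSpec(
            n_mcrc_patients=9, missing_draw2=0,
            pfs_model=PfsModel(analyte="Onc CK", strength=0.8), seed=seed,
        )
        _, surv = generate_cohort(spec)
        rho, _ = stats.spearmanr(
            surv["true_analyte_events_per_ml"], surv["pfs_months"]
        )
        rhos.append(abs(rho))
    assert abs(np.median(rhos) - 0.8) <= 0.15


def test_screen_keeps_only_significant_analytes():
    rng = np.random.default_rng(2)
    pfs = np.sort(rng.lognormal(1.8, 0.5, 9))
    df = pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(9)],
        "pfs_months": pfs,
        "linked": pfs + rng.normal(0, 1e-3, 9),
        "noise": rng.normal(size=9),
    })
    res = screen_analytes(df)
    kept = set(res[res["keep"]]["analyte"])
    assert "linked" in kept


def test_median_stratification_even_n():
    df = pd.DataFrame({
        "patient_id": list("abcd"), "pfs_months": [2.0, 4.0, 4.0, 7.0],
        "event_flag": [1, 1, 1, 1], "val": [1.0, 2.0, 3.0, 4.0],
    })
    strat = km_stratify(df, "val")
    assert strat.threshold == pytest.approx(2.5)
    assert set(strat.groups[strat.groups == "high"].index) == {"c", "d"}
    assert set(strat.groups[strat.groups == "low"].index) == {"a", "b"}


def test_tie_rule_gt_vs_ge():
    df = pd.DataFrame({
        "patient_id": list("abcde"), "pfs_months": [1, 2, 3, 4, 5.0],
        "event_flag": [1] * 5, "val": [1.0, 2.0, 3.0, 4.0, 5.0],
    })
    gt = km_stratify(df, "val", rule="gt")
    ge = km_stratify(df, "val", rule="ge")
    assert (gt.groups == "high").sum() == 2  # 3.0 == median goes low
    assert (ge.groups == "high").sum() == 3  # ≥ median goes high


def test_km_matches_hand_computed_product_limit():
    """Product-limit on a 4-patient fixture with one censoring: S = 1, 0.75
    after t=2, 0.25 after t=4, unchanged at the censored t=7."""
    times = np.array([2.0, 4.0, 4.0, 7.0])
    events = np.array([1, 1, 1, 0])
    pl = km_product_limit(times, events)
    expect = [(0.0, 1.0), (2.0, 0.75), (4.0, 0.25)]
    assert list(map(tuple, pl.to_numpy())) == expect
    df = pd.DataFrame({
        "patient_id": list("abcd"), "pfs_months": times,
        "event_flag": events, "val": [1.0, 2.0, 3.0, 4.0],
    })
    strat = km_stratify(df, "val")
    for t, s in expect:
        assert strat.survival_at("overall", t) == pytest.approx(s)


def test_all_events_observed_km_reaches_zero():
    times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    pl = km_product_limit(times, np.ones(6, dtype=int))
    assert pl["survival"].iloc[-1] == pytest.approx(0.0)
    df = pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(6)], "pfs_months": times,
        "event_flag": 1, "val": np.arange(6.0),
    })
    strat = km_stratify(df, "val")
    assert strat.survival_at("high", times.max()) == pytest.approx(0.0)
    assert strat.survival_at("low", times.max()) == pytest.approx(0.0)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    scale=st.floats(0.1, 50.0),
    power=st.floats(0.2, 3.0),
)
def test_stratification_invariant_to_monotone_transform(scale, power):
    df = pd.DataFrame({
        "patient_id": list("abcdefg"),
        "pfs_months": [1, 2, 3, 4, 5, 6, 7.0],
        "event_flag": [1] * 7,
        "val": [0.5, 1.1, 2.3, 3.1, 4.8, 7.2, 9.9],
    })
    base = km_stratify(df, "val")
    df2 = df.assign(val=scale * df["val"] ** power)
    trans = km_stratify(df2, "val")
    assert (base.groups == trans.groups).all()


def test_identical_values_collapse_to_single_group_with_warning():
    df = pd.DataFrame({
        "patient_id": list("abcd"), "pfs_months": [1, 2, 3, 4.0],
        "event_flag": [1] * 4, "val": [2.0] * 4,
    })
    with pytest.warns(UserWarning, match="single group"):
        km_stratify(df, "val")


def test_high_analyte_longer_pfs_curve_dominates():
    """When the generator links a higher analyte to longer survival, the
    high group's KM curve dominates the low group's in most cohorts."""
    from rarescope.synthetic import CohortSpec, PfsModel, generate_cohort

    wins = trials = 0
    for seed in range(40):
        spec = CohortSpec(
            n_mcrc_patients=10, missing_draw2=0,
            pfs_model=PfsModel(analyte="Onc CK", strength=0.9, direction=1),
            seed=seed,
        )
        _, surv = generate_cohort(spec)
        surv = surv.rename(columns={"true_analyte_events_per_ml": "val"})
        strat = km_stratify(surv, "val")
        grid = np.linspace(0.5, surv["pfs_months"].max(), 20)
        hi = np.array([strat.survival_at("high", t) for t in grid])
        lo = np.array([strat.survival_at("low", t) for t in grid])
        trials += 1
        wins += (hi >= lo - 1e-12).all()
    assert wins / trials >= 0.8


def test_kinetics_deltas_and_exclusions():
    df = pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(9)],
        "pfs_months": np.arange(1.0, 10.0),
        "draw1": [10.0, 5.0, 3.0] * 3,
        "draw2": [4.0, 5.0, 9.0, np.nan, 2.0, 1.0, 8.0, np.nan, 3.0],
    })
    out, excluded = kinetics(df)
    assert excluded == 2
    assert len(out) == 7
    first = out.iloc[0]  # longest PFS first
    assert first["pfs_months"] == 9.0
    d = dict(zip(out["patient_id"], out["delta_events_per_ml"]))
    assert d["p0"] == pytest.approx(-6.0)
    assert d["p1"] == pytest.approx(0.0)


def test_tumor_enriched_classes_separate_case_and_control_cohorts():
    """At default generator effect sizes (18 case vs 50 donor samples,
    count level), the epithelial CTC class and the three CK-positive
    vesicle classes are significant at p < 0.05 in ≥80% of cohorts."""
    from rarescope.synthetic import (
        CohortSpec, generate_cohort, sample_enumeration_counts,
    )

    targets = ["Epi.CTC", "Onc CK", "Onc CK|Vim", "Onc CK|Vim|CD45/CD31"]
    hits = {c: 0 for c in targets}
    n_seeds = 10
    for seed in range(n_seeds):
        rng = np.random.default_rng(1000 + seed)
        samples, _ = generate_cohort(CohortSpec(seed=seed))
        case, ctrl = [], []
        for s in samples:
            if s.protocol != "Landscape":
                continue
            t = sample_enumeration_counts(s, rng)
            (case if s.patient_id.startswith("mCRC") else ctrl).append(t)
        case_df = pd.concat(case)
        ctrl_df = pd.concat(ctrl)
        for cls in targets:
            x = case_df.loc[case_df.classification == cls, "events_per_ml"]
            y = ctrl_df.loc[ctrl_df.classification == cls, "events_per_ml"]
            _, p = compare_cohorts(x.to_numpy(), y.to_numpy())
            hits[cls] += p < 0.05
    for cls in targets:
        assert hits[cls] / n_seeds >= 0.8, (cls, hits[cls])
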