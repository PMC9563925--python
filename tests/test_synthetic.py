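"""Generator tests: determinism, count statistics, ground-truth fidelity and
cohort/survival structure."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rarescope.synthetic import (
    ChannelProfile,
    CohortSpec,
    PfsModel,
    PopulationSpec,
    SampleSpec,
    generate_cohort,
    landscape_populations,
    render_frame,
    sample_enumeration_counts,
)


def _wbc_only(rate: float, seed: int = 0, frames: int = 4) -> SampleSpec:
    pops = (dataclasses.replace(landscape_populations()[0], count_per_frame=rate),)
    return SampleSpec("P", 1, "Landscape", 5e6, frames, pops, seed=seed)


def test_render_is_deterministic_given_seed():
    spec = _wbc_only(40.0, seed=5)
    f1, t1 = render_frame(spec, 0)
    f2, t2 = render_frame(spec, 0)
    np.testing.assert_array_equal(f1.pixels, f2.pixels)
    assert len(t1) == len(t2)
    assert all(a.centroid == b.centroid for a, b in zip(t1, t2))


def test_distinct_frames_differ():
    spec = _wbc_only(40.0, seed=5)
    f0, _ = render_frame(spec, 0)
    f1, _ = render_frame(spec, 1)
    assert not np.array_equal(f0.pixels, f1.pixels)


def test_event_count_mean_matches_rate_over_seeds():
    """With only a WBC population at rate 100, the mean ground-truth count
    over 50 independent frames is within 3 standard errors of 100."""
    counts = []
    for seed in range(50):
        _, truths = render_frame(_wbc_only(100.0, seed=seed, frames=1), 0)
        counts.append(len(truths))
    mean = np.mean(counts)
    se = np.std(counts, ddof=1) / np.sqrt(len(counts))
    assert abs(mean - 100.0) <= 3 * se + 1e-9


def test_zero_rates_give_blank_frame():
    pops = (dataclasses.replace(landscape_populations()[0], count_per_frame=0.0),)
    spec = SampleSpec("P", 1, "Landscape", 5e6, 1, pops, seed=1)
    frame, truths = render_frame(spec, 0)
    assert truths == []
    # nothing but background + noise
    assert frame.pixels[0].max() < 20.0 + 6 * 3.0


def test_frame_counts_are_poisson():
    """Chi-square goodness of fit of per-frame ground-truth counts to the
    spec'd Poisson mean, over 250 frames."""
    rate = 4.0
    pops = (
        PopulationSpec(
            "Epi.CTC", rate, (12.0, 1.5, 9.0, 16.0), 0.5,
            {"CK": ChannelProfile(True, "diffuse", 100.0)},
        ),
    )
    spec = SampleSpec("P", 1, "Landscape", 5e6, 250, pops, seed=7,
                      frame_shape=(256, 256))
    counts = np.array(
        [len(render_frame(spec, fi)[1]) for fi in range(spec.frames)]
    )
    kmax = int(counts.max())
    observed = np.bincount(counts, minlength=kmax + 1).astype(float)
    expected = stats.poisson.pmf(np.arange(kmax + 1), rate) * len(counts)
    # pool the tail so expected counts stay reasonable
    observed[5] = observed[5:].sum()
    expected[5] = len(counts) - expected[:5].sum()
    chi2 = ((observed[:6] - expected[:6]) ** 2 / expected[:6]).sum()
    p = stats.chi2.sf(chi2, df=5 - 1)
    assert p > 0.01


def test_oncosomes_render_dapi_negative_and_circular():
    """Vesicle events leave no DAPI signal above background and have nearly
    circular ground-truth masks."""
    from skimage.measure import perimeter as sk_perimeter

    onc = [p for p in landscape_populations() if p.label == "Onc CK"][0]
    pops = (dataclasses.replace(onc, count_per_frame=8.0, cluster_propensity=0.0),)
    spec = SampleSpec("P", 1, "Landscape", 5e6, 4, pops, seed=3)
    for fi in range(spec.frames):
        frame, truths = render_frame(spec, fi)
        assert len(truths) > 0
        for t in truths:
            assert not t.dapi_positive
            r0, c0, r1, c1 = t.bbox
            dapi_in = frame.pixels[0, r0:r1, c0:c1][t.cell_mask]
            assert np.median(dapi_in) < 20.0 + 5 * 3.0
            area = t.cell_mask.sum()
            peri = max(sk_perimeter(t.cell_mask), 1.0)
            assert 4 * np.pi * area / peri**2 >= 0.9


def test_oncosome_attachment_states_recorded():
    onc = [p for p in landscape_populations() if p.label == "Onc CK"][0]
    wbc = landscape_populations()[0]
    spec = SampleSpec(
        "P", 1, "Landscape", 5e6, 8,
        (wbc, dataclasses.replace(onc, count_per_frame=4.0)), seed=9,
    )
    states = []
    for fi in range(spec.frames):
        _, truths = render_frame(spec, fi)
        states += [t.attachment for t in truths if not t.dapi_positive]
    assert set(states) == {"isolated", "adjacent"}


def test_population_spec_validation():
    with pytest.raises(ValueError, match="CK"):
        PopulationSpec("bad-onc", 1.0, (6, 1, 3, 10), 0.0, {}, dapi_positive=False)
    with pytest.raises(ValueError, match="12"):
        PopulationSpec(
            "big-onc", 1.0, (10, 2, 5, 14), 0.0,
            {"CK": ChannelProfile(True, "diffuse", 100.0)}, dapi_positive=False,
        )
    with pytest.raises(ValueError, match="texture"):
        ChannelProfile(True, "spotty", 100.0)


def test_cohort_structure_matches_study_design():
    """10 patients × 2 draws with 2 missing Draw 2 gives 18 samples per
    protocol; 50 donors give 50 Landscape slides; PFS positive for all."""
    samples, survival = generate_cohort(CohortSpec(seed=0))
    mcrc_l = [s for s in samples
              if s.patient_id.startswith("mCRC") and s.protocol == "Landscape"]
    mcrc_c = [s for s in samples
              if s.patient_id.startswith("mCRC") and s.protocol == "CDX2"]
    nd = [s for s in samples if s.patient_id.startswith("ND")]
    assert len(mcrc_l) == 18
    assert len(mcrc_c) == 18
    assert len(nd) == 50
    assert (survival["pfs_months"] > 0).all()
    assert len(survival) == 10


def test_perfect_link_gives_rho_one():
    spec = CohortSpec(pfs_model=PfsModel(analyte="Onc CK", strength=1.0), seed=3)
    _, survival = generate_cohort(spec)
    rho, _ = stats.spearmanr(
        survival["true_analyte_events_per_ml"], survival["pfs_months"]
    )
    assert rho == pytest.approx(1.0)


def test_null_link_p_values_are_uniform():
    """With link strength 0 the analyte–PFS Spearman p-value is uniform over
    repeated cohorts (Kolmogorov–Smirnov test over 200 seeds)."""
    pvals = []
    for seed in range(200):
        spec = CohortSpec(
            pfs_model=PfsModel(analyte="Onc CK", strength=0.0), seed=seed
        )
        _, survival = generate_cohort(spec)
        _, p = stats.spearmanr(
            survival["true_analyte_events_per_ml"], survival["pfs_months"]
        )
        pvals.append(p)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_censor_fraction_must_be_below_one():
    with pytest.raises(ValueError):
        PfsModel(censor_fraction=1.0)


def test_count_level_sampler_matches_rates():
    """The count-level fast path draws Poisson counts at rate × frames and
    normalizes by the realized blood volume."""
    spec = SampleSpec(
        "P", 1, "Landscape", 5e6, 64, landscape_populations(rare_scale=2.0),
        seed=2,
    )
    rng = np.random.default_rng(0)
    reps = [sample_enumeration_counts(spec, rng) for _ in range(40)]
    df = pd.concat(reps)
    got = df.groupby("classification")["raw_count"].mean()
    for pop in spec.populations:
        if pop.label == "WBC":
            continue
        expect = pop.count_per_frame * spec.frames
        se = np.sqrt(expect / len(reps))
        assert abs(got[pop.label] - expect) <= 4 * se + 1e-9


def test_unplaceable_density_raises_named_error():
    from rarescope.synthetic import PlacementError

    pops = (dataclasses.replace(landscape_populations()[0],
                                count_per_frame=400.0, label="WBC"),)
    spec = SampleSpec("P", 1, "Landscape", 5e6, 1, pops, seed=1,
                      frame_shape=(96, 96))
    with pytest.raises(PlacementError, match="WBC"):
        render_frame(spec, 0)
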