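"""Synthetic cohort generator: determinism, structure, ground-truth coupling."""

import numpy as np
import pandas as pd
import pytest

from sleepfactor.instruments import score_dataframe
from sleepfactor.rasch import PcmItem, pcm_probability
from sleepfactor.simulate import (
    GeneratorConfig,
    default_item_params,
    generate_cohort,
    generate_responses,
    severity_matrix,
)
from sleepfactor.validation import group_ttest


def test_same_seed_reproduces_identical_records():
    a = generate_cohort(GeneratorConfig(seed=42))
    b = generate_cohort(GeneratorConfig(seed=42))
    pd.testing.assert_frame_equal(a.records, b.records)
    pd.testing.assert_frame_equal(a.truth, b.truth)
    c = generate_cohort(GeneratorConfig(seed=43))
    assert not a.records.equals(c.records)


def test_identical_csv_bytes_for_fixed_seed(tmp_path):
    from sleepfactor.io import write_cohort

    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_cohort(generate_cohort(GeneratorConfig(seed=5)).records, p1)
    write_cohort(generate_cohort(GeneratorConfig(seed=5)).records, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_pinned_low_trait_floors_both_scores():
    """Latent traits at -10 logits put every patient at SQ 6, DTS 4."""
    cfg = GeneratorConfig(
        n_patients=30, n_questionnaire_complete=30, n_biomarker_complete=30,
        trait_sd=1e-9, followup_noise_sd=1e-9, seed=1,
    )
    for _, item in cfg.item_params.values():
        item.delta = item.delta + 10.0  # equivalent to theta pinned at -10
    coh = generate_cohort(cfg)
    scored = score_dataframe(coh.records)
    assert (scored["sq"] == 6).all()
    assert (scored["dts"] == 4).all()


def test_generated_ranks_within_bounds_and_schema(default_cohort):
    rec = default_cohort.records
    assert len(rec) == 2 * default_cohort.config.n_patients
    for i in range(1, 13):
        vals = rec[f"mos_q{i}"].dropna()
        assert vals.between(1, 5).all()
    for q in (10, 11, 18):
        assert rec[f"eortc_q{q}"].dropna().between(1, 4).all()
    assert rec["anamnesis_sleep"].dropna().isin([0, 1]).all()
    assert rec["sleep_med"].dropna().isin([0, 1, 2]).all()
    assert set(rec["timepoint"]) == {"baseline", "followup"}
    assert not rec.duplicated(["patient_id", "timepoint"]).any()


def test_attrition_marginals_follow_config(default_cohort):
    truth = default_cohort.truth
    cfg = default_cohort.config
    assert (~truth["questionnaire_incomplete"]).sum() == cfg.n_questionnaire_complete
    assert (~truth["biomarker_missing"]).sum() == cfg.n_biomarker_complete
    rec = default_cohort.records
    item_cols = [f"mos_q{i}" for i in range(1, 13)]
    incomplete_ids = set(truth.loc[truth["questionnaire_incomplete"], "patient_id"])
    has_missing = rec[rec[item_cols + [f"eortc_q{q}" for q in (10, 11, 18)]].isna().any(axis=1)]
    assert set(has_missing["patient_id"]) <= incomplete_ids


def test_generate_responses_extreme_theta_hits_worst_category():
    item = PcmItem(3, 4, 0.0, np.array([-1.0, -0.3, 0.3, 1.0]))
    rng = np.random.default_rng(0)
    ranks = generate_responses(np.full(2000, 10.0), item, rng)  # reversed item
    assert (ranks == 1).mean() > 0.999


def test_generate_responses_frequencies_match_model():
    """Empirical category frequencies track pcm_probability within 1.5%."""
    rng = np.random.default_rng(1)
    item = PcmItem(6, 4, 0.4, np.array([-1.1, -0.2, 0.4, 0.9]))
    theta = np.full(100_000, 0.3)
    ranks = generate_responses(theta, item, rng)  # reversed: rank = 5 - severity
    sev = 5 - ranks
    expected = pcm_probability(0.3, item)
    for x in range(5):
        assert (sev == x).mean() == pytest.approx(expected[x], abs=0.015)


def test_dichotomous_balance_at_matched_location():
    item = PcmItem(0, 1, 0.5, np.array([0.0]))
    rng = np.random.default_rng(2)
    ranks = generate_responses(np.full(10_000, 0.5), item, rng, worst_high=True)
    assert (ranks == 2).mean() == pytest.approx(0.5, abs=0.02)


def test_scores_span_full_legal_range_at_scale():
    cfg = GeneratorConfig(
        n_patients=30_000, n_questionnaire_complete=30_000, n_biomarker_complete=0,
        trait_sd=2.5, seed=3,
    )
    coh = generate_cohort(cfg)
    bl = coh.records[coh.records["timepoint"] == "baseline"]
    sq_items = [f"mos_q{i}" for i in (3, 4, 5, 7, 8, 12)]
    sev = severity_matrix(bl, (3, 4, 5, 7, 8, 12))
    sq = sev.sum(axis=1) + 6
    dts = severity_matrix(bl, (6, 9, 10, 11)).sum(axis=1) + 4
    assert sq.min() == 6 and sq.max() == 30
    assert dts.min() == 4 and dts.max() == 20


def test_sq_scores_track_latent_trait(complete_cohort):
    scored = score_dataframe(complete_cohort.records)
    bl = scored[scored["timepoint"] == "baseline"].set_index("patient_id")
    truth = complete_cohort.truth.set_index("patient_id")
    r = np.corrcoef(bl.loc[truth.index, "sq"], truth["theta_sq_baseline"])[0, 1]
    assert r > 0.8
    r2 = np.corrcoef(bl.loc[truth.index, "dts"], truth["theta_dts_baseline"])[0, 1]
    assert r2 > 0.8


def test_sex_effect_null_and_default():
    """With no sex effect the DTS t-test rejects at ~alpha; with the
    default negative effect it rejects in most replicates at n = 75."""
    null_rej, eff_rej, runs = 0, 0, 20
    for s in range(runs):
        for eff, counter in ((0.0, "null"), (None, "eff")):
            kwargs = {} if eff is None else {"sex_effect_dts": eff}
            coh = generate_cohort(
                GeneratorConfig(n_patients=75, n_questionnaire_complete=75,
                                n_biomarker_complete=54, seed=1200 + s, **kwargs)
            )
            scored = score_dataframe(coh.records)
            bl = scored[scored["timepoint"] == "baseline"]
            try:
                p = group_ttest(bl["dts"], bl["sex"]).p_value
            except ValueError:
                continue
            if counter == "null":
                null_rej += p < 0.05
            else:
                eff_rej += p < 0.05
    assert null_rej <= 0.25 * runs
    assert eff_rej >= 0.8 * runs


def test_config_validation():
    with pytest.raises(ValueError):
        GeneratorConfig(trait_corr=1.5)
    with pytest.raises(ValueError):
        GeneratorConfig(n_patients=10, n_questionnaire_complete=20)
    bad_items = default_item_params()
    trait, item = bad_items[3]
    bad_items[3] = ("nope", item)
    with pytest.raises(ValueError):
        GeneratorConfig(item_params=bad_items)


def test_truth_is_separate_from_records(default_cohort):
    assert "theta_sq_baseline" not in default_cohort.records.columns
    assert {"patient_id", "theta_sq_baseline", "theta_dts_baseline"} <= set(
        default_cohort.truth.columns
    )
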