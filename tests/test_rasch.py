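"""Partial credit model: probability formula, JML estimation, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleepfactor.rasch import (
    DegenerateDataError,
    PartialCreditModel,
    PcmItem,
    fit_pcm,
    pcm_probability,
)
from conftest import make_items, sample_pcm_scores


def test_dichotomous_probability_half_at_matched_location():
    item = PcmItem("i", 1, 0.7, np.array([0.0]))
    assert pcm_probability(0.7, item, 1) == pytest.approx(0.5, abs=1e-12)


def test_worked_three_category_probabilities():
    """beta = delta = 0, tau = (-1, 1): numerators 1, e, 1."""
    item = PcmItem("i", 2, 0.0, np.array([-1.0, 1.0]))
    e = np.e
    p = pcm_probability(0.0, item)
    assert p[0] == pytest.approx(1 / (2 + e), abs=1e-12)
    assert p[1] == pytest.approx(e / (2 + e), abs=1e-12)
    assert p[2] == pytest.approx(1 / (2 + e), abs=1e-12)


def test_probabilities_sum_to_one_over_random_draws():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        m = int(rng.integers(1, 6))
        item = PcmItem("i", m, rng.normal(0, 2), rng.normal(0, 1.5, m))
        beta = rng.normal(0, 3)
        assert pcm_probability(beta, item).sum() == pytest.approx(1.0, abs=1e-12)


def test_dichotomous_closed_form_equivalence():
    rng = np.random.default_rng(1)
    for _ in range(50):
        delta, beta = rng.normal(0, 2, 2)
        item = PcmItem("i", 1, delta, np.array([0.0]))
        expected = 1.0 / (1.0 + np.exp(-(beta - delta)))
        assert pcm_probability(beta, item, 1) == pytest.approx(expected, abs=1e-12)


def test_extreme_locations_do_not_overflow():
    item = PcmItem("i", 4, 0.0, np.array([-1.0, -0.3, 0.3, 1.0]))
    p = pcm_probability(np.array([-500.0, 500.0]), item)
    assert np.isfinite(p).all()
    assert p[0, 0] == pytest.approx(1.0)
    assert p[1, 4] == pytest.approx(1.0)


def test_category_out_of_range_rejected():
    item = PcmItem("i", 2, 0.0, np.array([-1.0, 1.0]))
    with pytest.raises(ValueError):
        pcm_probability(0.0, item, 3)


def test_shift_invariance_of_likelihood():
    """Adding c to all beta and delta leaves every probability unchanged."""
    rng = np.random.default_rng(2)
    items = make_items(rng, k=4)
    beta = rng.normal(0, 1, 10)
    c = 1.7
    for it in items:
        shifted = PcmItem(it.item_id, it.m, it.delta + c, it.tau)
        np.testing.assert_allclose(
            pcm_probability(beta, it), pcm_probability(beta + c, shifted), atol=1e-8
        )


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(10)
    items = make_items(rng, k=6)
    beta = rng.normal(0, 1, 500)
    X = sample_pcm_scores(beta, items, rng)
    fit = PartialCreditModel(X).fit()
    return items, beta, fit


class TestJointMaximumLikelihood:
    def test_converges_and_loglik_monotone(self, fitted):
        _, _, fit = fitted
        assert fit.converged
        assert np.all(np.diff(fit.loglik_path) >= -1e-9)

    def test_identification_constraints(self, fitted):
        _, _, fit = fitted
        assert np.mean([it.delta for it in fit.items]) == pytest.approx(0.0, abs=1e-8)
        for it in fit.items:
            assert it.tau.sum() == pytest.approx(0.0, abs=1e-8)

    def test_item_locations_recovered(self, fitted):
        items, _, fit = fitted
        true = np.array([it.delta for it in items])
        true = true - true.mean()
        est = np.array([it.delta for it in fit.items])
        assert np.sqrt(np.mean((est - true) ** 2)) < 0.15

    def test_person_locations_correlate_with_truth(self, fitted):
        items, beta, fit = fitted
        idx = np.asarray(fit.persons.index, dtype=int)
        r = np.corrcoef(beta[idx], fit.persons.to_numpy())[0, 1]
        assert r > 0.85

    def test_raw_score_sufficiency(self, fitted):
        """Persons with identical raw totals get identical estimated beta."""
        items, beta, fit = fitted
        rng = np.random.default_rng(11)
        X = sample_pcm_scores(rng.normal(0, 1, 200), items, rng)
        fit2 = PartialCreditModel(X).fit()
        raw = X.sum(axis=1)
        betas = fit2.persons
        for pid_a in betas.index:
            same = [p for p in betas.index if raw[p] == raw[pid_a]]
            np.testing.assert_allclose(betas[same], betas[pid_a], atol=1e-10)


def test_incomplete_and_extreme_persons_excluded():
    rng = np.random.default_rng(12)
    items = make_items(rng, k=3)
    X = sample_pcm_scores(rng.normal(0, 1, 80), items, rng).astype(float)
    X[0, 1] = np.nan               # incomplete
    X[1, :] = 0                    # floor
    X[2, :] = [it.m for it in items]  # ceiling
    fit = PartialCreditModel(X).fit()
    assert fit.n_excluded["incomplete"] == 1
    assert fit.n_excluded["extreme"] >= 2
    assert 0 not in fit.persons.index and 1 not in fit.persons.index


def test_all_extreme_scores_refused():
    X = np.zeros((10, 3))
    X[:5] = 4
    with pytest.raises(DegenerateDataError):
        fit_pcm(X)


def test_structural_zero_categories_collapsed():
    rng = np.random.default_rng(13)
    items = make_items(rng, k=3, m=2)
    X = sample_pcm_scores(rng.normal(0, 1, 150), items, rng)
    X[:, 0] = np.where(X[:, 0] == 2, 4, X[:, 0])  # categories 2,3 never observed
    fit = PartialCreditModel(X).fit()
    assert 0 in fit.collapsed
    assert fit.item_index[0].m == 2


def test_threshold_disorder_flags():
    ordered = PcmItem("a", 4, 0.0, np.array([-1.0, 0.0, 1.0, 2.0]) - 0.5)
    disordered = PcmItem("b", 4, 0.0, np.array([0.0, -0.5, 1.0, 2.0]) - 0.625)
    assert not ordered.disordered
    assert disordered.disordered


def test_disordered_thresholds_recovered_on_refit():
    """Generate with disordered tau; refits flag the item in most runs."""
    hits = 0
    runs = 12
    for s in range(runs):
        rng = np.random.default_rng(100 + s)
        tau = np.array([0.8, -0.8, -0.2, 0.2])  # middle categories rarely modal
        bad = PcmItem(0, 4, 0.0, tau - tau.mean())
        others = make_items(rng, k=3)
        items = [bad] + [PcmItem(j + 1, it.m, it.delta, it.tau) for j, it in enumerate(others)]
        X = sample_pcm_scores(rng.normal(0, 1.2, 400), items, rng)
        fit = PartialCreditModel(X).fit()
        hits += fit.threshold_disorder()[0]
    assert hits >= 0.9 * runs


def test_person_item_distribution_counts(complete_cohort):
    from sleepfactor.simulate import severity_matrix

    sev = severity_matrix(complete_cohort.records, (3, 4, 5, 7, 8, 12))
    fit = PartialCreditModel(sev).fit()
    dist = fit.person_item_distribution(bin_width=0.25)
    assert dist.person_counts.sum() == len(fit.persons)
    assert dist.threshold_counts.sum() == sum(it.m for it in fit.items)
    assert fit.targeting_spread() > 0


def test_summary_mentions_items_and_exclusions(default_cohort):
    from sleepfactor.simulate import severity_matrix

    sev = severity_matrix(default_cohort.records, (6, 9, 10, 11))
    fit = PartialCreditModel(sev).fit()
    text = fit.summary()
    assert "excluded persons" in text
    assert "delta=" in text
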