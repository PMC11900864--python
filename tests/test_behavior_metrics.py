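"""Tests of trial labelling, behavioral indices, and the ZOIB model."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from thermolearn import (
    AgentSpec,
    RatingSpec,
    compute_umti,
    error_rates,
    label_trials,
    post_pe_slowing,
    simulate_agent,
    tgi_quality_ratio,
    tgi_responsiveness,
    zoib_fit,
    zoib_logpdf,
)
from thermolearn.behavior_metrics import compute_metrics, uncertainty_bins
from thermolearn.learning_models import run_filter
from thermolearn.synthetic_data import DATASET_COLUMNS, BehavioralDataset


def _dataset(rows):
    """Build a dataset from (p_nominal, stimulus, prediction, rt, cold, warm, burn)."""
    n = len(rows)
    df = pd.DataFrame({
        "trial": np.arange(1, n + 1),
        "block": 0,
        "p_nominal": [r[0] for r in rows],
        "cue": "low",
        "stimulus": [r[1] for r in rows],
        "u": [0.5 if r[1] == "tgi" else (1.0 if r[1] == "warm" else 0.0) for r in rows],
        "rated": [any(x is not None for x in r[4:7]) for r in rows],
        "prediction": [r[2] if r[2] is not None else np.nan for r in rows],
        "response_time_s": [r[3] if r[3] is not None else np.nan for r in rows],
        "vas_cold": [r[4] if r[4] is not None else np.nan for r in rows],
        "vas_warm": [r[5] if r[5] is not None else np.nan for r in rows],
        "vas_burn": [r[6] if r[6] is not None else np.nan for r in rows],
    })
    return BehavioralDataset(df=df[DATASET_COLUMNS], subject_id="toy")


class TestLabelTrials:
    def test_exhaustive_truth_table(self):
        """Labelling is a pure function of (block probability, prediction,
        stimulus); enumerate all combinations."""
        for p in (0.82, 0.50, 0.18):
            for pred in ("cold", "warm", None):
                for stim in ("cold", "warm", "tgi"):
                    ds = _dataset([(p, stim, pred, 1.0, None, None, None)])
                    got = label_trials(ds).iloc[0]
                    if stim == "tgi":
                        expected = "tgi"
                    elif p == 0.50:
                        expected = "neutral"
                    elif pred is None:
                        expected = "missing"
                    else:
                        expected = "predicted" if pred == stim else "unpredicted"
                    assert got == expected, (p, pred, stim)

    def test_four_trial_toy_example(self):
        ds = _dataset([
            (0.82, "cold", "cold", 1.0, None, None, None),
            (0.82, "warm", "warm", 1.0, None, None, None),
            (0.18, "cold", "warm", 1.0, None, None, None),
            (0.82, "tgi", "cold", 1.0, None, None, None),
        ])
        assert label_trials(ds).tolist() == ["predicted", "predicted",
                                             "unpredicted", "tgi"]


class TestErrorRates:
    def test_all_correct_gives_zero_everywhere(self):
        ds = _dataset([(0.82, "cold", "cold", 1.0, None, None, None)] * 6)
        rates = error_rates(ds)
        assert rates["predicted"] == 0.0

    def test_one_error_among_four_followers(self):
        # trials 2-5 follow 'predicted' trials; exactly one is an error
        ds = _dataset([
            (0.82, "cold", "cold", 1.0, None, None, None),
            (0.82, "cold", "cold", 1.0, None, None, None),
            (0.82, "cold", "cold", 1.0, None, None, None),
            (0.82, "cold", "warm", 1.0, None, None, None),  # error, follows predicted
            (0.82, "cold", "cold", 1.0, None, None, None),  # follows unpredicted
        ])
        rates = error_rates(ds)
        assert rates["predicted"] == pytest.approx(1.0 / 3.0)
        assert rates["unpredicted"] == 0.0

    def test_empty_category_flagged_absent(self):
        ds = _dataset([(0.82, "cold", "cold", 1.0, None, None, None)] * 3)
        rates = error_rates(ds)
        assert rates["neutral"] is None
        assert rates["tgi"] is None

    def test_block_grouping(self):
        ds = _dataset([
            (0.82, "cold", "warm", 1.0, None, None, None),
            (0.82, "cold", "cold", 1.0, None, None, None),
            (0.50, "cold", "cold", 1.0, None, None, None),
            (0.50, "cold", "warm", 1.0, None, None, None),
        ])
        rates = error_rates(ds, by="block")
        assert rates["predictive"] == pytest.approx(0.5)
        assert rates["neutral"] == pytest.approx(0.5)

    def test_rates_bounded(self, hgf_dataset):
        for v in error_rates(hgf_dataset).values():
            if v is not None:
                assert 0.0 <= v <= 1.0


class TestPostPeSlowing:
    def test_constant_rts_equal_means(self):
        ds = _dataset([
            (0.82, "cold", "cold", 1.5, None, None, None),
            (0.82, "cold", "warm", 1.5, None, None, None),
            (0.50, "warm", "warm", 1.5, None, None, None),
            (0.82, "cold", "cold", 1.5, None, None, None),
        ])
        res = post_pe_slowing(ds, fit_glm=False)
        vals = [v for v in res["means"].values() if v is not None]
        assert all(v == pytest.approx(1.5) for v in vals)

    def test_order_sensitivity(self, hgf_dataset):
        """Unlike the set-level indices, RT slowing depends on trial order."""
        res = post_pe_slowing(hgf_dataset, fit_glm=False)
        df = hgf_dataset.df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        shuffled = BehavioralDataset(df=df, subject_id="shuffled")
        res_shuf = post_pe_slowing(shuffled, fit_glm=False)
        assert res["n"] != res_shuf["n"] or res["means"] != res_shuf["means"]

    def test_generative_slowing_after_unpredicted(self, sequence):
        """With a positive RT-uncertainty slope, trials following
        expectation violations are slower on average."""
        agent = AgentSpec(rt_uncertainty_slope=2.5, missing_rate=0.0)
        means = {"predicted": [], "unpredicted": []}
        for seed in range(4):
            ds = simulate_agent(sequence, agent, seed=seed)
            res = post_pe_slowing(ds, fit_glm=False)
            for k in means:
                means[k].append(res["means"][k])
        assert np.mean(means["unpredicted"]) > np.mean(means["predicted"])

    def test_gamma_glm_coefficients_positive_for_violations(self, hgf_dataset):
        res = post_pe_slowing(hgf_dataset, fit_glm=True)
        coefs = res["glm_coefficients"]
        assert coefs is not None and "unpredicted" in coefs

    def test_missing_successors_flagged(self):
        ds = _dataset([(0.50, "cold", "cold", 1.0, None, None, None)] * 2)
        res = post_pe_slowing(ds, fit_glm=False)
        assert res["means"]["tgi"] is None


class TestTgiQualityRatio:
    def test_arithmetic(self):
        ds = _dataset([(0.82, "tgi", "cold", 1.0, 40.0, 10.0, 50.0)])
        assert tgi_quality_ratio(ds) == pytest.approx(0.8)

    def test_ambiguity_point(self):
        ds = _dataset([(0.82, "tgi", "cold", 1.0, 25.0, 25.0, 50.0)])
        assert tgi_quality_ratio(ds) == pytest.approx(0.5)

    def test_mixed_trials_average(self):
        ds = _dataset([
            (0.82, "tgi", "cold", 1.0, 40.0, 10.0, 50.0),
            (0.82, "tgi", "cold", 1.0, 10.0, 10.0, 50.0),
        ])
        assert tgi_quality_ratio(ds) == pytest.approx(0.65)

    def test_zero_denominator_trials_skipped(self):
        ds = _dataset([
            (0.82, "tgi", "cold", 1.0, 0.0, 0.0, 50.0),
            (0.82, "tgi", "cold", 1.0, 40.0, 10.0, 50.0),
        ])
        assert tgi_quality_ratio(ds) == pytest.approx(0.8)

    def test_absent_without_usable_ratings(self):
        ds = _dataset([(0.82, "cold", "cold", 1.0, 40.0, 10.0, 5.0)])
        assert tgi_quality_ratio(ds) is None


class TestTgiResponsiveness:
    def _ds(self, tgi, cold, warm):
        return _dataset([
            (0.82, "tgi", "cold", 1.0, 10.0, 10.0, tgi),
            (0.82, "cold", "cold", 1.0, 50.0, 5.0, cold),
            (0.82, "warm", "warm", 1.0, 5.0, 50.0, warm),
        ])

    def test_responder(self):
        assert tgi_responsiveness(self._ds(60.0, 20.0, 10.0)) == pytest.approx(40.0)

    def test_nonresponder_negative(self):
        assert tgi_responsiveness(self._ds(5.0, 20.0, 10.0)) == pytest.approx(-15.0)

    def test_null_point(self):
        assert tgi_responsiveness(self._ds(20.0, 20.0, 20.0)) == pytest.approx(0.0)

    def test_absent_when_a_stimulus_set_missing(self):
        ds = _dataset([
            (0.82, "tgi", "cold", 1.0, 10.0, 10.0, 60.0),
            (0.82, "cold", "cold", 1.0, 50.0, 5.0, 20.0),
        ])
        assert tgi_responsiveness(ds) is None


class TestUmti:
    def _cohort(self, coef, n=16, seed=0):
        from thermolearn.synthetic_data import generate_cohort

        template = AgentSpec(rating=RatingSpec(burn_tgi_eu_coef=coef),
                             missing_rate=0.0)
        return generate_cohort(n, config=None, seed=seed, model="hgf2",
                               agent_template=template)

    def _umtis(self, cohort):
        out = []
        for ds in cohort:
            traj = run_filter("hgf2", ds.u, ds.agent.params)
            out.append(compute_umti(ds, traj))
        return [u for u in out if u is not None]

    def test_positive_generative_coupling_recovered(self):
        vals = self._umtis(self._cohort(6.0))
        assert np.mean(vals) > 0

    def test_sign_flip(self):
        pos = np.mean(self._umtis(self._cohort(6.0, seed=3)))
        neg = np.mean(self._umtis(self._cohort(-6.0, seed=3)))
        assert pos > 0 > neg

    def test_null_construction_near_zero(self):
        vals = self._umtis(self._cohort(0.0, n=12, seed=5))
        assert abs(np.mean(vals)) < 0.4

    def test_insufficient_tgi_trials_flagged(self):
        ds = _dataset([(0.82, "tgi", "cold", 1.0, 10.0, 10.0, 60.0)] * 2
                      + [(0.82, "cold", "cold", 1.0, 50.0, 5.0, 10.0)] * 5)
        traj = run_filter("hgf2", ds.u, {})
        assert compute_umti(ds, traj) is None


class TestZoibDensity:
    def test_point_masses(self):
        assert zoib_logpdf(0.0, 0.5, 2.0, 0.1, 0.2) == pytest.approx(math.log(0.1))
        assert zoib_logpdf(1.0, 0.5, 2.0, 0.1, 0.2) == pytest.approx(math.log(0.2))

    def test_uniform_beta_case(self):
        # mu=0.5, phi=2 gives Beta(1,1): density ln(1 - p0 - p1) on (0,1)
        assert zoib_logpdf(0.5, 0.5, 2.0, 0.1, 0.2) == pytest.approx(math.log(0.7))

    def test_total_mass_by_quadrature(self):
        p0, p1, mu, phi = 0.07, 0.12, 0.3, 9.0
        cont, _ = quad(lambda y: math.exp(zoib_logpdf(y, mu, phi, p0, p1)),
                       1e-12, 1 - 1e-12, limit=200)
        assert p0 + p1 + cont == pytest.approx(1.0, abs=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            zoib_logpdf(1.5, 0.5, 2.0, 0.1, 0.1)
        with pytest.raises(ValueError):
            zoib_logpdf(0.5, 0.5, 2.0, 0.6, 0.5)


class TestZoibFit:
    def _simulate(self, rng, n, beta, phi, p0, p1):
        x = rng.normal(size=n)
        eta = beta[0] + beta[1] * x
        mu = 1.0 / (1.0 + np.exp(-eta))
        y = rng.beta(mu * phi, (1 - mu) * phi)
        r = rng.random(n)
        y[r < p0] = 0.0
        y[(r >= p0) & (r < p0 + p1)] = 1.0
        return x, y

    def test_parameter_recovery_within_three_se(self, rng):
        beta_true = (0.4, 0.8)
        x, y = self._simulate(rng, 2000, beta_true, phi=8.0, p0=0.06, p1=0.03)
        fit = zoib_fit(y, pd.DataFrame({"x": x}))
        for name, true in zip(("intercept", "x"), beta_true):
            est, se = fit.coefficient(name), fit.coefficient_se(name)
            assert abs(est - true) < 3 * se
        assert fit.phi == pytest.approx(8.0, rel=0.25)
        assert fit.p0 == pytest.approx(0.06, abs=0.02)
        assert fit.p1 == pytest.approx(0.03, abs=0.02)

    def test_interior_data_drives_inflation_to_zero(self, rng):
        y = rng.beta(2.0, 2.0, size=400)
        fit = zoib_fit(y)
        assert fit.p0 < 1e-4 and fit.p1 < 1e-4
        assert fit.separation_flag

    def test_symmetric_data_zero_logit_intercept(self, rng):
        y = rng.beta(5.0, 5.0, size=1000)
        fit = zoib_fit(y)
        assert fit.coefficient("intercept") == pytest.approx(0.0, abs=0.1)

    def test_minimum_observations(self):
        with pytest.raises(ValueError, match="10 observations"):
            zoib_fit(np.full(5, 0.5))


class TestAggregation:
    def test_uncertainty_bins_equal_count(self, rng):
        vals = rng.random(306)
        bins = uncertainty_bins(vals, n_bins=9)
        counts = np.bincount(bins)[1:]
        assert bins.min() == 1 and bins.max() == 9
        assert counts.max() - counts.min() <= 1

    def test_cohort_metrics_report(self, hgf_dataset):
        traj = run_filter("hgf2", hgf_dataset.u, hgf_dataset.agent.params)
        rep = compute_metrics([hgf_dataset], [traj])
        assert len(rep.per_subject) == 1
        assert "umti" in rep.per_subject.columns
        assert rep.group["n_subjects"] == 1

    def test_set_level_indices_order_invariant(self, hgf_dataset):
        df = hgf_dataset.df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        shuffled = BehavioralDataset(df=df, subject_id="shuffled")
        assert tgi_quality_ratio(shuffled) == pytest.approx(
            tgi_quality_ratio(hgf_dataset))
        assert tgi_responsiveness(shuffled) == pytest.approx(
            tgi_responsiveness(hgf_dataset))
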