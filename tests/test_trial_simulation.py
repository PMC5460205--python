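"""Trial engine: RECIST classification, ORR, arms, scenarios, regression."""

import numpy as np
import pandas as pd
import pytest

from mapkqsp.core_model import SignalingParams
from mapkqsp.trial_simulation import (TrialSimulator, canonical_arm,
                                      classify_recist, compute_orr,
                                      compute_orr_binned, dose_surface,
                                      regress_biomarkers, run_trial_arm,
                                      scenario_biomarker_select,
                                      scenario_death_boost,
                                      simulate_response)
from mapkqsp.virtual_population import (CohortSpec, DEFAULT_CLINICAL_BINS,
                                        generate_cohort)


@pytest.fixture(scope="module")
def small_sim(fitted_params):
    from mapkqsp.fitted import clinical_baseline_params
    cohort = generate_cohort(CohortSpec(n=60, seed=12),
                             base=clinical_baseline_params())
    return TrialSimulator(cohort, seed=12)


class TestClassifyRecist:
    def test_confirmed_responder(self):
        label, resp, conf = classify_recist(-31.0, -35.0)
        assert resp and conf and label == "-50:-30"

    def test_transient_response_is_unconfirmed(self):
        label, resp, conf = classify_recist(-40.0, -10.0)
        assert resp and not conf

    def test_growth_bin_membership(self):
        label, resp, conf = classify_recist(25.0, 25.0)
        assert label == "20:50" and not resp

    def test_below_minus_100_rejected(self):
        with pytest.raises(ValueError):
            classify_recist(-120.0, 0.0)


class TestComputeOrr:
    def test_published_binned_distributions(self):
        bins = DEFAULT_CLINICAL_BINS
        orr = compute_orr_binned(bins.frequencies["cetuximab+vemurafenib"])
        assert orr * 100 == pytest.approx(23.1, abs=0.05)
        orr = compute_orr_binned(bins.frequencies["vemurafenib+cobimetinib"])
        assert orr * 100 == pytest.approx(13.1, abs=0.05)
        orr = compute_orr_binned(
            bins.frequencies["cetuximab+vemurafenib+cobimetinib"])
        assert orr * 100 == pytest.approx(37.1, abs=0.05)

    def test_all_responders(self):
        assert compute_orr(np.full(10, -50.0)) == 1.0

    def test_records_and_binned_agree(self, small_sim):
        recs = small_sim.records("gdc0994")
        pct = np.array([r.pct_change_8wk for r in recs])
        idx = DEFAULT_CLINICAL_BINS.assign(pct)
        freqs = np.bincount(idx, minlength=7)
        assert compute_orr(recs) == pytest.approx(
            compute_orr_binned(freqs))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_orr([])


class TestArms:
    def test_canonical_ordering_is_set_semantics(self):
        assert canonical_arm("gdc0994+cetuximab") == \
            canonical_arm(["cetuximab", "gdc0994"])
        with pytest.raises(ValueError):
            canonical_arm("aspirin")

    def test_arm_order_invariance(self, small_sim):
        a = small_sim.percent_changes("vemurafenib+cobimetinib")
        b = small_sim.percent_changes("cobimetinib+vemurafenib")
        assert np.array_equal(a["pct_best_8wk"], b["pct_best_8wk"])

    def test_untreated_arm_grows(self, small_sim):
        df = small_sim.percent_changes(())
        # weighted-median untreated tumor grows over 8 weeks
        assert np.median(df["pct_end_cycle2"]) > 0

    def test_treatment_reduces_growth(self, small_sim):
        ctrl = small_sim.percent_changes(())["pct_best_8wk"]
        gdc = small_sim.percent_changes("gdc0994")["pct_best_8wk"]
        assert np.mean(gdc) < np.mean(ctrl)

    def test_seed_reproducibility(self, fitted_params):
        from mapkqsp.fitted import clinical_baseline_params
        base = clinical_baseline_params()
        a = TrialSimulator(generate_cohort(CohortSpec(n=10, seed=3),
                                           base=base), seed=3)
        b = TrialSimulator(generate_cohort(CohortSpec(n=10, seed=3),
                                           base=base), seed=3)
        assert np.array_equal(
            a.percent_changes("cobimetinib")["pct_best_8wk"],
            b.percent_changes("cobimetinib")["pct_best_8wk"])

    def test_vectorized_engine_matches_reference_path(self, small_sim):
        """Cohort-engine % change agrees with the single-tumor adaptive
        solver + exact-PK reference chain."""
        i = 7
        params = small_sim.cohort.tumor(i)
        draws = {d: {k: float(v[i]) for k, v in tab.items()}
                 for d, tab in small_sim.pk_params.items()}
        rec = simulate_response(params, "gdc0994", pk_draws=draws,
                                tumor_id=i)
        df = small_sim.percent_changes("gdc0994")
        assert rec.pct_change_8wk == pytest.approx(
            df["pct_best_8wk"].iloc[i], abs=1.5)


class TestTrialSummary:
    def test_identical_tumors_yield_degenerate_waterfall(self, fitted_params):
        from mapkqsp.fitted import clinical_baseline_params
        base = clinical_baseline_params()
        dists = [(n, m, 0.0) for n, m, _ in
                 CohortSpec().distributions]
        cohort = generate_cohort(CohortSpec(distributions=dists, n=15,
                                            seed=2), base=base)
        sim = TrialSimulator(cohort, seed=2, population_pk=False)
        summary = run_trial_arm(sim, "gdc0994", seed=2, n_trials=10)
        assert summary.waterfall["pct_change"].std() < 1e-9

    def test_replicate_counts_match_binomial_oracle(self, small_sim):
        summary = run_trial_arm(small_sim, "gdc0994", seed=5,
                                n_trials=400, n_patients=18)
        # responder counts ~ Binomial(18, ORR) when patients are iid draws
        mean = summary.responder_counts.mean()
        expect = 18 * summary.orr
        sd = np.sqrt(18 * summary.orr * (1 - summary.orr))
        assert abs(mean - expect) < 3 * sd / np.sqrt(400) + 1e-9
        assert summary.ci90[0] <= np.median(summary.responder_counts) \
            <= summary.ci90[1]
        assert summary.expected_responders == pytest.approx(18 * summary.orr)


class TestDoseSurface:
    def test_edges_consistent_with_monotherapy(self, small_sim):
        surf = dose_surface(small_sim, doses_a=(0, 60), doses_b=(0, 400))
        assert surf.loc[0, 400] == pytest.approx(
            small_sim.arm_orr("gdc0994"))
        assert surf.loc[60, 0] == pytest.approx(
            small_sim.arm_orr("cobimetinib"))
        assert surf.loc[60, 400] == pytest.approx(
            small_sim.arm_orr("cobimetinib+gdc0994"))

    def test_combination_at_least_as_active_as_monotherapies(self, small_sim):
        surf = dose_surface(small_sim, doses_a=(0, 60), doses_b=(0, 400))
        assert surf.loc[60, 400] >= max(surf.loc[0, 400],
                                        surf.loc[60, 0]) - 1e-9


class TestScenarios:
    def test_full_percentile_is_identity(self, small_sim):
        sel = scenario_biomarker_select(small_sim.cohort, "wOR", 100.0)
        assert np.allclose(sel.weights, small_sim.cohort.weights /
                           small_sim.cohort.weights.sum())

    def test_top_half_selection_halves_mass_and_raises_median(self,
                                                              small_sim):
        cohort = small_sim.cohort
        sel = scenario_biomarker_select(cohort, "wOR", 50.0)
        kept = sel.weights > 0
        mass = cohort.weights[kept].sum() / cohort.weights.sum()
        assert mass == pytest.approx(0.5, abs=0.1)
        med_all = np.median(cohort.params["wOR"])
        med_sel = np.median(cohort.params["wOR"][kept])
        assert med_sel >= med_all

    def test_death_boost_identity_at_zero(self, small_sim):
        boosted = scenario_death_boost(small_sim.cohort, 0.0)
        assert boosted.params.equals(small_sim.cohort.params)

    def test_death_boost_deepens_every_response(self, small_sim):
        boosted = scenario_death_boost(small_sim.cohort, 0.10)
        assert np.allclose(boosted.params["deltaMAX"],
                           1.1 * small_sim.cohort.params["deltaMAX"])
        sim_b = TrialSimulator(boosted, seed=small_sim.seed)
        a = small_sim.percent_changes("gdc0994")["pct_best_8wk"].to_numpy()
        b = sim_b.percent_changes("gdc0994")["pct_best_8wk"].to_numpy()
        assert np.all(b <= a + 1e-6)
        assert sim_b.arm_orr("gdc0994") >= small_sim.arm_orr("gdc0994")


class TestBiomarkerRegression:
    def test_pure_linear_response_identified(self, small_sim):
        """A response constructed as a linear function of one parameter
        puts all standardized weight on that coefficient."""
        x = small_sim.cohort.params["deltaMAX"].to_numpy()
        fake = (x - x.mean()) / x.std()

        class _Fake:
            cohort = small_sim.cohort
            pk_params = small_sim.pk_params
            drugs = small_sim.drugs

            def percent_changes(self, arm):
                return pd.DataFrame({"pct_best_8wk": fake})

        res = regress_biomarkers(_Fake(), arms=["gdc0994"])
        top = res["gdc0994"].abs().idxmax()
        assert top == "deltaMAX"
        assert res["gdc0994"]["deltaMAX"] == pytest.approx(1.0, abs=0.05)

    def test_permuted_response_has_no_signal(self, small_sim, rng):
        df = small_sim.percent_changes("gdc0994")
        y = df["pct_best_8wk"].to_numpy().copy()
        rng2 = np.random.default_rng(0)

        class _Perm:
            cohort = small_sim.cohort
            pk_params = small_sim.pk_params
            drugs = small_sim.drugs

            def percent_changes(self, arm):
                return pd.DataFrame({"pct_best_8wk": rng2.permutation(y)})

        res = regress_biomarkers(_Perm(), arms=["gdc0994"])
        real = regress_biomarkers(small_sim, arms=["gdc0994"])
        assert res["gdc0994"].abs().max() < real["gdc0994"].abs().max()

    def test_wor_and_death_rate_among_top_predictors(self, small_sim):
        res = regress_biomarkers(small_sim, arms=["gdc0994",
                                                  "cobimetinib+gdc0994"])
        for arm in res.columns:
            top5 = res[arm].abs().nlargest(5).index
            assert "wOR" in top5 or "deltaMAX" in top5
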