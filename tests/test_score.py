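"""Composite susceptibility score, quantile FAR, ROC/AUC and power."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from copdlc import (
    SusceptibilityScoreModel,
    auc_detection_power,
    auc_detection_power_mc,
    bin_scores,
    clinical_component_score,
    compute_scores,
    empirical_auc,
    far_contrast_error,
    floated_absolute_risk,
    or_weights_from_battery,
    snp_component_score,
    score_panel,
)
from copdlc.panel import MISSING
from copdlc.score import BinnedScores


def genotype_strategy(panel):
    """Random genotype call (or missing) per scored panel SNP."""
    return st.fixed_dictionaries(
        {
            e.snp_id: st.sampled_from(list(e.alphabet) + [MISSING])
            for e in score_panel(panel)
        }
    )


class TestSnpComponent:
    def test_all_protective_risk_genotypes(self, panel):
        genos = {
            e.snp_id: next(iter(e.risk_genotypes))
            for e in score_panel(panel)
            if e.direction < 0
        }
        assert snp_component_score(genos, panel) == -5

    def test_all_susceptible_risk_genotypes(self, panel):
        genos = {
            e.snp_id: next(iter(e.risk_genotypes))
            for e in score_panel(panel)
            if e.direction > 0
        }
        assert snp_component_score(genos, panel) == +4

    def test_missing_genotypes_are_neutral(self, panel):
        assert snp_component_score({}, panel) == 0
        genos = {e.snp_id: MISSING for e in panel}
        assert snp_component_score(genos, panel) == 0


class TestClinicalComponent:
    @pytest.mark.parametrize(
        "age, fhx, copd, expected",
        [
            (70, True, True, 11),
            (60, False, False, 0),  # strict >60 boundary
            (61, False, True, 8),
            (61, False, False, 4),
            (50, True, False, 3),
            (70, False, True, 8),
            (70, True, False, 7),
        ],
    )
    def test_weights(self, age, fhx, copd, expected):
        assert clinical_component_score(age, fhx, copd) == expected

    def test_missing_age_scores_zero_points(self):
        assert clinical_component_score(float("nan"), True, False) == 3

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            clinical_component_score(-1, False, False)


class TestScoreAlgebra:
    @given(genos=st.data())
    @settings(max_examples=150, derandomize=True)
    def test_bounds_and_single_snp_sensitivity(self, panel, genos):
        g = genos.draw(genotype_strategy(panel))
        total = snp_component_score(g, panel)
        assert -5 <= total <= 4
        # dropping any single panel entry moves the score by at most 1
        for drop in score_panel(panel):
            reduced = [e for e in panel if e.snp_id != drop.snp_id]
            assert abs(snp_component_score(g, reduced) - total) <= 1

    @given(
        age=st.integers(0, 100), fhx=st.booleans(), copd=st.booleans()
    )
    @settings(max_examples=100, derandomize=True)
    def test_clinical_score_support(self, age, fhx, copd):
        assert clinical_component_score(age, fhx, copd) in {0, 3, 4, 7, 8, 11}

    def test_vectorised_scores_match_scalar(self, fixture_cohort, panel):
        from copdlc import subjects_from_frame, susceptibility_score

        scores = compute_scores(fixture_cohort, panel)
        sample = fixture_cohort.iloc[::151]
        for subj, (_, row) in zip(
            subjects_from_frame(sample), scores.loc[sample.index].iterrows()
        ):
            rec = susceptibility_score(subj, panel)
            assert rec.total == row["total"]
            assert rec.total == rec.snp_component + rec.clinical_component


class TestBinning:
    def test_distinct_scores_split_evenly(self):
        totals = pd.Series(np.arange(100, dtype=float))
        binned = bin_scores(totals, pd.Series([False] * 100), k=5)
        counts = np.bincount(binned.assignment)
        assert counts.tolist() == [20] * 5

    def test_degenerate_scores_merge_with_warning(self):
        totals = pd.Series([3.0] * 50)
        with pytest.warns(UserWarning, match="merged"):
            binned = bin_scores(totals, pd.Series([True] * 50), k=5)
        assert len(binned.n_cases) == 1

    def test_tie_goes_to_lower_bin(self):
        totals = pd.Series([0.0, 1.0, 1.0, 2.0])
        binned = bin_scores(totals, pd.Series([False] * 4), k=2)
        assert binned.edges == (1.0,)
        # scores equal to the edge must not leak upward
        assert binned.assignment.tolist() == [0, 0, 0, 1]


class TestFloatedAbsoluteRisk:
    def test_binary_closed_form(self):
        """With two bins the floated variances are each bin's own
        1/n_cases + 1/n_controls and sum to the Woolf variance of the OR."""
        binned = BinnedScores(
            edges=(0.5,), labels=("lo", "hi"),
            n_cases=(30, 70), n_controls=(80, 20),
            assignment=pd.Series(dtype=int),
        )
        far = floated_absolute_risk(binned, referent=0)
        assert far[0].floated_variance == pytest.approx(1 / 30 + 1 / 80, rel=1e-12)
        assert far[1].floated_variance == pytest.approx(1 / 70 + 1 / 20, rel=1e-12)
        woolf = 1 / 30 + 1 / 80 + 1 / 70 + 1 / 20
        assert far[0].floated_variance + far[1].floated_variance == pytest.approx(
            woolf, rel=1e-12
        )
        assert far[1].floated_log_risk == pytest.approx(
            math.log((70 / 20) / (30 / 80)), rel=1e-12
        )

    def test_identical_distributions_are_flat(self):
        binned = BinnedScores(
            edges=(1.0, 2.0), labels=("a", "b", "c"),
            n_cases=(50, 50, 50), n_controls=(100, 100, 100),
            assignment=pd.Series(dtype=int),
        )
        for f in floated_absolute_risk(binned):
            assert f.floated_log_risk == pytest.approx(0.0, abs=1e-12)
            assert f.floated_variance > 0

    def test_referent_gets_a_proper_interval(self):
        binned = BinnedScores(
            edges=(0.5,), labels=("lo", "hi"),
            n_cases=(30, 70), n_controls=(80, 20),
            assignment=pd.Series(dtype=int),
        )
        ref = floated_absolute_risk(binned, referent=0)[0]
        assert ref.is_referent
        assert ref.ci95[0] < 1 < ref.ci95[1]

    def test_bin_empty_in_both_arms_rejected(self):
        binned = BinnedScores(
            edges=(0.5,), labels=("lo", "hi"),
            n_cases=(0, 70), n_controls=(0, 20),
            assignment=pd.Series(dtype=int),
        )
        with pytest.raises(ValueError, match="both arms"):
            floated_absolute_risk(binned)

    def test_contrast_variance_reconstruction_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            k = int(rng.integers(3, 8))
            cases = rng.integers(5, 200, k)
            ctrls = rng.integers(5, 200, k)
            binned = BinnedScores(
                edges=tuple(range(1, k)), labels=tuple(f"b{i}" for i in range(k)),
                n_cases=tuple(int(x) for x in cases),
                n_controls=tuple(int(x) for x in ctrls),
                assignment=pd.Series(dtype=int),
            )
            far = floated_absolute_risk(binned, referent=0)
            assert far_contrast_error(far) < 0.02


class TestEmpiricalAuc:
    def test_identical_multisets(self):
        assert empirical_auc([1, 2, 3], [1, 2, 3]).auc == pytest.approx(0.5)

    def test_perfect_separation(self):
        assert empirical_auc([4, 5, 6], [1, 2, 3]).auc == pytest.approx(1.0)

    def test_brute_force_pairwise_with_ties(self):
        cases, ctrls = [2, 2, 3], [1, 2, 2]
        wins = sum(
            1.0 if c > k else (0.5 if c == k else 0.0)
            for c in cases for k in ctrls
        )
        assert empirical_auc(cases, ctrls).auc == pytest.approx(wins / 9)

    @given(
        cases=st.lists(st.integers(-5, 15), min_size=1, max_size=30),
        ctrls=st.lists(st.integers(-5, 15), min_size=1, max_size=30),
    )
    @settings(max_examples=100, derandomize=True)
    def test_complement_symmetry(self, cases, ctrls):
        assert empirical_auc(cases, ctrls).auc + empirical_auc(ctrls, cases).auc \
            == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(7)
        cases = rng.integers(-5, 16, 200)
        ctrls = rng.integers(-6, 12, 250)
        from sklearn.metrics import roc_auc_score

        y = np.r_[np.ones(200), np.zeros(250)]
        s = np.r_[cases, ctrls]
        assert empirical_auc(cases, ctrls).auc == pytest.approx(
            roc_auc_score(y, s), rel=1e-12
        )

    def test_curve_shape(self):
        roc = empirical_auc([2, 2, 3, 5], [1, 2, 2, 4])
        curve = np.asarray(roc.curve)
        assert tuple(curve[0]) == (0.0, 0.0)
        assert tuple(curve[-1]) == (1.0, 1.0)
        assert (np.diff(curve[:, 0]) >= 0).all()
        assert (np.diff(curve[:, 1]) >= 0).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            empirical_auc([], [1, 2])


class TestAucPower:
    def test_null_limit_approaches_alpha(self):
        assert auc_detection_power(500, 500, 0.5001, 0.05) == pytest.approx(
            0.05, abs=0.01
        )

    def test_large_samples_approach_one(self):
        assert auc_detection_power(200000, 200000, 0.55, 0.05) > 0.999

    def test_power_increases_with_effect_and_n(self):
        p1 = auc_detection_power(200, 200, 0.55)
        p2 = auc_detection_power(200, 200, 0.60)
        p3 = auc_detection_power(800, 800, 0.55)
        assert p2 > p1 and p3 > p1

    def test_invalid_alternatives_rejected(self):
        with pytest.raises(ValueError):
            auc_detection_power(100, 100, 0.5)
        with pytest.raises(ValueError):
            auc_detection_power(100, 100, 0.4)

    def test_analytic_agrees_with_monte_carlo(self):
        reps = 800
        mc = auc_detection_power_mc(150, 150, 0.58, n_reps=reps, seed=3)
        an = auc_detection_power(150, 150, 0.58)
        se = math.sqrt(an * (1 - an) / reps)
        assert abs(mc - an) < 3.5 * se


class TestScoreModel:
    def test_fixture_fit_is_structurally_sound(self, fixture_cohort, panel):
        res = SusceptibilityScoreModel(fixture_cohort, panel).fit()
        assert 0 < res.auc < 1
        assert len(res.far) == 5
        assert sum(f.is_referent for f in res.far) == 1
        assert far_contrast_error(res.far) < 1e-9
        # COPD cases never enter the score analysis
        assert set(res.scores["group"]) <= {"CONTROL", "LC_ALL", "LC_WITH_COPD", "LC_ONLY"}
        assert "AUC" in res.summary()

    def test_case_odds_rise_across_bins_on_gradient_cohorts(self, panel):
        """Sign test over seeds: on cohorts generated with the published
        case-control frequency and clinical gradients, adjacent score bins
        have nondecreasing case fractions nearly everywhere."""
        from copdlc import sample_cohort, table_spec

        up = down = 0
        for seed in (1, 2, 3):
            cohort = sample_cohort(table_spec(n_per_group=2000), seed=seed)
            res = SusceptibilityScoreModel(cohort, panel).fit()
            frac = [f.n_cases / (f.n_cases + f.n_controls) for f in res.far]
            for lo, hi in zip(frac, frac[1:]):
                up += hi >= lo
                down += hi < lo
        assert up >= 11 and down <= 1

    def test_weighted_variant_runs_and_differs(self, fixture_cohort, panel):
        from copdlc import SnpAssociationModel

        battery = SnpAssociationModel(fixture_cohort, panel).fit()
        w = or_weights_from_battery(battery)
        assert set(w) == {e.snp_id for e in score_panel(panel)}
        unweighted = SusceptibilityScoreModel(fixture_cohort, panel).fit()
        weighted = SusceptibilityScoreModel(fixture_cohort, panel, weights=w).fit()
        assert not np.allclose(
            unweighted.scores["snp_component"], weighted.scores["snp_component"]
        )
        # signs agree with directions: protective SNPs carry negative weight
        for e in score_panel(panel):
            assert math.copysign(1, w[e.snp_id]) == e.direction
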