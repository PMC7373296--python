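"""Association scan: design building, LRT, Hochberg, aOR machinery, utilities."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ccproteo.association import (
    STRATA,
    aor_between_levels,
    aor_curve,
    build_design,
    detection_frequency_test,
    find_reference_level,
    hochberg_stepup,
    lrt_quadratic,
    run_scan,
    wilcoxon_rank_sum,
)
from ccproteo.cohort import CohortConfig, EffectSpec, generate_cohort
from ccproteo.logistic import ModelFit, fit_logistic
from ccproteo.preprocess import preprocess_cohort


def _fit(ll: float, coefs=(0.0,)) -> ModelFit:
    p = len(coefs)
    return ModelFit(np.asarray(coefs, float), np.eye(p), ll, True, False)


class TestBuildDesign:
    def test_four_level_site_gives_three_dummies(self, tiny_cohort):
        X, _ = build_design(tiny_cohort.subjects)
        assert sum(c.startswith("site[") for c in X.columns) == \
            tiny_cohort.subjects["site"].nunique() - 1

    def test_sparse_level_collapsed_and_reported(self, tiny_cohort):
        subjects = tiny_cohort.subjects.copy()
        subjects["race"] = ["white"] * (len(subjects) - 4) + \
            ["asian", "hispanic", "hispanic", "hispanic"]
        X, report = build_design(subjects)
        assert "asian" in report["collapsed"]["race"]
        assert not any("asian" in c for c in X.columns)

    def test_lone_sparse_level_folds_into_reference(self, tiny_cohort):
        subjects = tiny_cohort.subjects.copy()
        subjects["race"] = ["white"] * (len(subjects) - 1) + ["asian"]
        X, report = build_design(subjects)
        # asian (1 subject) collapses to "other" (still 1) -> folded away
        assert not any(c.startswith("race[") for c in X.columns)

    def test_dropped_covariate_absent(self, tiny_cohort):
        X, _ = build_design(tiny_cohort.subjects,
                            covariates=("age", "sex", "bmi_class"))
        assert "sr_ibs" not in X.columns

    def test_constant_covariate_dropped_with_report(self, tiny_cohort):
        subjects = tiny_cohort.subjects.copy()
        subjects["sex"] = "female"
        _, report = build_design(subjects)
        assert "sex" in report["dropped_constant"]

    def test_aliased_columns_named(self, tiny_cohort):
        subjects = tiny_cohort.subjects.copy()
        subjects["season"] = np.where(subjects["sex"] == "female", "summer", "fall")
        with pytest.raises(ValueError, match="aliased"):
            build_design(subjects, covariates=("sex", "season"))


class TestLRT:
    @pytest.mark.parametrize("stat,printed_p", [
        (17.57, 2.77e-5),
        (19.44, 1.04e-5),
        (14.87, 1.15e-4),
        (17.31, 3.18e-5),
        (16.27, 5.50e-5),
    ])
    def test_chi_square_tail_at_reference_statistics(self, stat, printed_p):
        ll0 = -40.0
        s, p = lrt_quadratic(_fit(ll0), _fit(ll0 + stat / 2))
        assert s == pytest.approx(stat)
        assert p == pytest.approx(printed_p, rel=0.01)

    def test_identical_fits_give_null_result(self):
        f = _fit(-30.0)
        assert lrt_quadratic(f, f) == (0.0, 1.0)

    def test_worse_quadratic_likelihood_raises(self):
        with pytest.raises(ValueError, match="optimizer"):
            lrt_quadratic(_fit(-30.0), _fit(-31.0))

    def test_invariant_to_affine_covariate_recoding(self, tiny_cohort):
        tm = preprocess_cohort(tiny_cohort)
        subjects = tiny_cohort.subjects
        y = tiny_cohort.case_mask.to_numpy(float)
        t = tm.values["P0001"].to_numpy()
        c = t - t.mean()
        for age in (subjects["age"].to_numpy(), 2.0 * subjects["age"].to_numpy() - 50):
            Xl = np.column_stack([np.ones(len(y)), age, c])
            Xq = np.column_stack([Xl, c * c])
            s, _ = lrt_quadratic(fit_logistic(Xl, y), fit_logistic(Xq, y))
            try:
                ref
            except NameError:
                ref = s
        assert s == pytest.approx(ref, abs=1e-8)


def _brute_force_hochberg(p, alpha):
    m = len(p)
    order = np.argsort(p)
    reject = np.zeros(m, bool)
    for k in range(m, 0, -1):
        if p[order[k - 1]] <= alpha / (m - k + 1):
            reject[order[:k]] = True
            break
    return reject


class TestHochberg:
    def test_single_test_reduces_to_unadjusted(self):
        rej, adj = hochberg_stepup([0.03], alpha=0.05)
        assert rej[0] and adj[0] == 0.03

    def test_equal_small_pvalues_all_rejected(self):
        rej, _ = hochberg_stepup([0.01] * 4, alpha=0.05)
        assert rej.all()

    def test_stepup_example_rejects_only_smallest(self):
        p = [0.001, 0.02, 0.04, 0.2]
        rej, _ = hochberg_stepup(p, alpha=0.05)
        assert list(rej) == [True, False, False, False]
        assert (rej == _brute_force_hochberg(np.array(p), 0.05)).all()

    def test_matches_statsmodels_and_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            m = rng.integers(1, 11)
            p = rng.random(m)
            rej, adj = hochberg_stepup(p, 0.05)
            assert (rej == _brute_force_hochberg(p, 0.05)).all()
            sm_rej, sm_adj, _, _ = multipletests(p, 0.05, method="simes-hochberg")
            np.testing.assert_allclose(adj, sm_adj, atol=1e-12)
            assert (rej == sm_rej).all()

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12),
           st.floats(0.01, 0.2))
    def test_never_rejects_fewer_than_bonferroni(self, p, alpha):
        rej, adj = hochberg_stepup(p, alpha)
        bonf = np.asarray(p) <= alpha / len(p)
        assert rej[bonf].all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()  # adjusted p monotone

    def test_rejection_set_monotone_in_alpha(self):
        rng = np.random.default_rng(1)
        p = rng.random(8)
        prev = np.zeros(8, bool)
        for alpha in (0.01, 0.05, 0.1, 0.2):
            rej, _ = hochberg_stepup(p, alpha)
            assert rej[prev].all()
            prev = rej

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            hochberg_stepup([], 0.05)


class TestReferenceLevel:
    def test_interior_vertex(self):
        assert find_reference_level(-2.0, 1.0, (-3, 3)) == pytest.approx(1.0)

    def test_linear_increasing_risk_picks_lower_boundary(self):
        assert find_reference_level(0.7, 0.0, (-3, 3)) == -3.0

    def test_inverted_u_matches_grid_search(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            b1, b2 = rng.normal(size=2)
            b2 = -abs(b2) - 0.01
            lo, hi = sorted(rng.normal(scale=3, size=2))
            if hi - lo < 1e-3:
                continue
            got = find_reference_level(b1, b2, (lo, hi))
            grid = np.linspace(lo, hi, 10_000)
            best = grid[np.argmin(b1 * grid + b2 * grid**2)]
            assert got == pytest.approx(best, abs=(hi - lo) / 5000)

    def test_flat_profile_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            find_reference_level(0.0, 0.0, (-1, 1))

    def test_inverse_transform_applied(self):
        raw = find_reference_level(-2.0, 1.0, (-3, 3),
                                   inverse_transform=lambda t: 10.0 ** t)
        assert raw == pytest.approx(10.0)


class TestAorContrasts:
    def test_identity_contrast(self):
        aor, lo, hi, p = aor_between_levels(np.array([1.0, 2.0]), np.eye(2), 1.5, 1.5)
        assert (aor, lo, hi, p) == (1.0, 1.0, 1.0, 1.0)

    def test_closed_form_doubling(self):
        aor, *_ = aor_between_levels(np.array([0.0, np.log(2)]),
                                     np.zeros((2, 2)), 1.0, 0.0)
        assert aor == pytest.approx(2.0)

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            aor_between_levels(np.zeros(2), np.array([[1.0, 0], [0, -1.0]]), 1, 0)

    def test_curve_minimum_at_reference(self):
        beta = np.array([-2.0, 1.0])          # vertex at t = 1
        sd = 0.5
        ref_raw = 10 ** (1.0 * sd)
        grid = np.append(np.geomspace(10 ** (-1.0 * sd), 10 ** (2.5 * sd), 41),
                         ref_raw)
        curve = aor_curve(beta, 0.01 * np.eye(2), ref_raw, grid,
                          transform=lambda x: np.log10(x) / sd)
        assert (curve.grid["aor"] >= 1.0 - 1e-12).all()
        at_ref = curve.grid.iloc[(curve.grid["level_raw"] - ref_raw).abs().argmin()]
        assert at_ref["aor"] == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_grid_symmetric_aor(self):
        beta = np.array([0.0, 0.8])           # vertex at t = 0
        grid_t = np.array([-2.0, -1.0, 1.0, 2.0])
        curve = aor_curve(beta, np.zeros((2, 2)), 1.0, 10.0 ** grid_t,
                          transform=np.log10)
        aors = curve.grid["aor"].to_numpy()
        np.testing.assert_allclose(aors[:2], aors[:1:-1])

    def test_nonpositive_grid_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            aor_curve(np.zeros(2), np.zeros((2, 2)), 1.0, [0.0, 1.0],
                      transform=np.log10)


class TestRunScan:
    def test_injected_ushape_found_without_false_positives(self, signal_config):
        table = generate_cohort(signal_config)
        tm = preprocess_cohort(table)
        results = run_scan(tm, table.subjects)
        selected = {r.protein for r in results if r.quadratic_selected}
        assert "P0001" in selected
        assert len(selected - {"P0001"}) == 0
        r = {x.protein: x for x in results}["P0001"]
        assert r.fwer_adjusted_p >= r.lrt_p
        assert r.lrt_stat >= 0
        assert np.isfinite(r.reference_level_raw) and r.reference_level_raw > 0

    def test_linear_effect_shows_in_linear_aor(self, signal_config):
        table = generate_cohort(signal_config)
        tm = preprocess_cohort(table)
        r = {x.protein: x for x in run_scan(tm, table.subjects)}["P0002"]
        assert r.linear_aor > 1.0          # injected beta1 = +0.8
        assert r.linear_p < 0.05

    def test_effect_restricted_to_subgroup_found_only_there(self):
        """U-effect removed from sr-IBS cases: only the without-sr-IBS
        stratum scan selects the protein."""
        cfg = CohortConfig(
            n_cases=39, n_controls=41, n_proteins=15,
            effect_specs=(EffectSpec(0, beta1=0.0, beta2=1.8),),
            seed=21,
        )
        table = generate_cohort(cfg)
        rng = np.random.default_rng(0)
        ibs_cases = (table.subjects["sr_ibs"] == "yes") & table.case_mask
        ctrl_vals = table.quantities.loc[~table.case_mask, "P0001"].to_numpy()
        table.quantities.loc[ibs_cases, "P0001"] = rng.choice(
            ctrl_vals, size=int(ibs_cases.sum()))
        tm = preprocess_cohort(table)
        res_without = run_scan(tm, table.subjects, stratum="non_sr_ibs_cases")
        res_with = run_scan(tm, table.subjects, stratum="sr_ibs_cases")
        sel_without = {r.protein for r in res_without if r.quadratic_selected}
        sel_with = {r.protein for r in res_with if r.quadratic_selected}
        assert "P0001" in sel_without
        assert "P0001" not in sel_with

    def test_stratum_below_minimum_class_size_rejected(self, tiny_cohort):
        tm = preprocess_cohort(tiny_cohort)
        stratum = STRATA["sr_ibs_cases"]
        with pytest.raises(ValueError, match="at least"):
            run_scan(tm, tiny_cohort.subjects, stratum=stratum)

    def test_two_valued_protein_yields_null_lrt(self, tiny_cohort):
        tm = preprocess_cohort(tiny_cohort)
        binary = np.where(tm.values["P0001"] > tm.values["P0001"].median(), 1.0, 2.0)
        tm.values["P0001"] = binary
        r = {x.protein: x for x in run_scan(tm, tiny_cohort.subjects,
                                            min_class_size=5)}["P0001"]
        assert r.lrt_stat == 0.0 and r.lrt_p == 1.0


class TestAuxiliaryTests:
    def test_wilcoxon_symmetric_groups_give_zero_z(self):
        z, p = wilcoxon_rank_sum([1, 4, 5, 8], [2, 3, 6, 7])
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_wilcoxon_z_to_two_sided_p(self):
        # a z-score of 0.126 corresponds to a two-sided p of 0.899
        assert 2 * stats.norm.sf(0.126) == pytest.approx(0.899, abs=1e-3)

    def test_wilcoxon_small_sample_vs_exact_enumeration(self):
        """{1,2} vs {3,4}: 1 of the 6 equally likely orderings is as
        extreme, so the exact two-sided p is 1/3; the normal approximation
        is reported alongside and should not be wildly off."""
        z, p = wilcoxon_rank_sum([1, 2], [3, 4])
        from itertools import combinations
        ranks = [1, 2, 3, 4]
        observed = 1 + 2
        sums = [sum(c) for c in combinations(ranks, 2)]
        as_extreme = np.mean([s <= observed for s in sums])
        assert 2 * as_extreme == pytest.approx(1 / 3)
        assert z < 0 and 0.05 < p < 0.5

    def test_wilcoxon_all_tied_degenerates(self):
        z, p = wilcoxon_rank_sum([5, 5], [5, 5])
        assert (z, p) == (0.0, 1.0)

    def test_detection_frequency_example_counts(self):
        # 22/39 detected (56.4%) vs 11/41 (26.8%)
        chi2, p = detection_frequency_test(22, 39, 11, 41)
        a, b, c, d = 22, 17, 11, 30
        n = a + b + c + d
        oracle = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chi2 == pytest.approx(oracle, abs=1e-12)
        assert p == pytest.approx(0.007, abs=5e-4)

    def test_detection_frequency_equal_proportions_null(self):
        chi2, p = detection_frequency_test(5, 10, 5, 10)
        assert chi2 == 0.0 and p == 1.0

    def test_detection_frequency_matches_closed_form(self):
        chi2, _ = detection_frequency_test(10, 10, 0, 10)
        oracle = 20 * (10 * 10 - 0) ** 2 / (10 * 10 * 10 * 10)
        assert chi2 == pytest.approx(oracle, abs=1e-12)

    def test_detection_frequency_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            detection_frequency_test(0, 10, 0, 10)
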