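import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rootvoi import (
    bland_altman,
    icc_triplicate,
    split_mouth_report,
    wilcoxon_signed_rank,
)

from .oracles import icc21_reference, wilcoxon_enumeration


class TestICC:
    def test_identical_repeats_give_exactly_one(self):
        x = np.array([[0.3, 0.3, 0.3], [0.5, 0.5, 0.5], [0.7, 0.7, 0.7]])
        icc, form = icc_triplicate(x)
        assert icc == 1.0 and form == "ICC(2,1)"

    def test_three_by_three_matches_anova_oracle(self):
        x = np.array([[1.0, 2, 3], [4, 5, 6], [7, 8, 9]])
        icc, _ = icc_triplicate(x)
        assert icc == pytest.approx(icc21_reference(x), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_matrices_match_oracle_and_pingouin(self, seed):
        rng = np.random.default_rng(seed)
        n, k = int(rng.integers(4, 12)), int(rng.integers(2, 5))
        x = rng.normal(0.5, 0.1, (n, k)) + rng.normal(0, 0.05, (n, 1))
        icc, _ = icc_triplicate(x)
        assert icc == pytest.approx(icc21_reference(x), abs=1e-10)
        pg = pytest.importorskip("pingouin")
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "rater": np.tile(np.arange(k), n),
                "score": x.ravel(),
            }
        )
        table = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        ref = float(table.loc[table["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0])
        assert icc == pytest.approx(ref, abs=1e-8)

    def test_variance_ratio_recovered_in_simulation(self):
        rng = np.random.default_rng(7)
        sigma_s, sigma_e = 0.1, 0.01
        subjects = rng.normal(0.5, sigma_s, (50, 1))
        x = subjects + rng.normal(0, sigma_e, (50, 3))
        icc, _ = icc_triplicate(x)
        expect = sigma_s**2 / (sigma_s**2 + sigma_e**2)
        assert icc == pytest.approx(expect, abs=0.02)

    def test_noise_monotonically_decreases_icc(self):
        rng = np.random.default_rng(3)
        subjects = rng.normal(0.5, 0.1, (80, 1))
        base_noise = rng.normal(0, 1.0, (80, 3))
        iccs = [icc_triplicate(subjects + s * base_noise)[0] for s in (0.01, 0.05, 0.1)]
        assert iccs[0] > iccs[1] > iccs[2]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            icc_triplicate(np.full((3, 3), 0.5))
        with pytest.raises(ValueError):
            icc_triplicate(np.array([[1.0, 2.0]]))
        with pytest.raises(ValueError, match="missing"):
            icc_triplicate(np.array([[1.0, np.nan], [2.0, 3.0]]))

    def test_consistency_form_on_shifted_raters(self):
        x = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]])  # rater 2 = rater 1 + 1
        icc3, form = icc_triplicate(x, form="ICC(3,1)")
        assert form == "ICC(3,1)" and icc3 == pytest.approx(1.0)
        icc2, _ = icc_triplicate(x)
        assert icc2 < 1.0  # absolute agreement penalizes the shift


class TestBlandAltman:
    def test_identical_series(self):
        a = np.array([1.0, 2.0, 3.0])
        r = bland_altman(a, a)
        assert r.mean_diff == 0 and r.sd_diff == 0 and (r.loa_low, r.loa_high) == (0, 0)

    def test_hand_computed_three_element_case(self):
        r = bland_altman(np.array([1.0, 2, 3]), np.array([2.0, 3, 5]))
        assert r.mean_diff == pytest.approx(-4 / 3)
        assert r.sd_diff == pytest.approx(1 / np.sqrt(3))
        assert r.loa_low == pytest.approx(-4 / 3 - 1.96 / np.sqrt(3))
        assert r.loa_high == pytest.approx(-4 / 3 + 1.96 / np.sqrt(3))
        assert r.critical_diff == pytest.approx(1.96 / np.sqrt(3))

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=20))
    @settings(deadline=None, derandomize=True)
    def test_swapping_series_negates_mean_and_limits(self, values):
        a = np.asarray(values)
        b = a[::-1].copy()
        r1, r2 = bland_altman(a, b), bland_altman(b, a)
        assert r1.mean_diff == pytest.approx(-r2.mean_diff, abs=1e-9)
        assert r1.loa_low == pytest.approx(-r2.loa_high, abs=1e-9)

    def test_limits_cover_95pc_of_gaussian_differences(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 20000)
        b = rng.normal(0, 1, 20000)
        r = bland_altman(a, b)
        inside = ((r.differences >= r.loa_low) & (r.differences <= r.loa_high)).mean()
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bland_altman(np.array([1.0]), np.array([2.0]))
        with pytest.raises(ValueError):
            bland_altman(np.array([1.0, 2]), np.array([1.0, 2, 3]))


class TestWilcoxon:
    def test_three_positive_distinct_differences(self):
        r = wilcoxon_signed_rank(np.array([5.0, 7, 9]), np.array([4.0, 5, 6]))
        assert r.statistic == 6.0
        assert r.p_value == pytest.approx(0.25)
        assert r.method == "exact"

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_full_enumeration_up_to_n10(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        # integer differences provoke ties and zeros
        d = rng.integers(-4, 5, n).astype(float)
        if np.all(d == 0):
            d[0] = 1.0
        for alt in ("two-sided", "greater", "less"):
            w_ref, p_ref = wilcoxon_enumeration(d, alt)
            r = wilcoxon_signed_rank(d, alternative=alt)
            assert r.statistic == pytest.approx(w_ref)
            assert r.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        from scipy import stats as sps

        d = rng.normal(0.3, 1.0, 15)
        mine = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, method="exact")
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_antisymmetric_inputs_share_p(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.2, 1, 12)
        r1 = wilcoxon_signed_rank(a, b)
        r2 = wilcoxon_signed_rank(b, a)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_zero_differences_dropped(self):
        r = wilcoxon_signed_rank(np.array([1.0, 2, 3, 4]), np.array([1.0, 1, 1, 4]))
        assert r.n_used == 2

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank(np.zeros(5))

    def test_normal_approximation_close_to_scipy_for_large_n(self, rng):
        from scipy import stats as sps

        d = rng.normal(0.1, 1.0, 60)
        mine = wilcoxon_signed_rank(d)
        assert mine.method == "normal"
        ref = sps.wilcoxon(d, method="approx", correction=False)
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-9)


class TestSplitMouthReport:
    def _table(self, rng, n=10, effect=-0.08):
        control = rng.normal(0.41, 0.05, n)
        return pd.DataFrame(
            {"bv_tv_control": control, "bv_tv_test": control + effect + rng.normal(0, 0.02, n)}
        )

    def test_report_schema_and_consistency(self, rng):
        rep = split_mouth_report(self._table(rng))
        d = rep.to_dict()
        assert d["ba_critical_diff"] == pytest.approx(1.96 * d["ba_sd_diff"])
        assert d["ba_loa_low"] == pytest.approx(d["ba_mean_diff"] - d["ba_critical_diff"])
        assert 0 < d["wilcoxon_p"] <= 1
        assert d["n_pairs"] == 10

    def test_explicit_repeat_matrix_used_for_icc(self, rng):
        repeats = np.tile(rng.normal(0.4, 0.05, (6, 1)), (1, 3))
        rep = split_mouth_report(self._table(rng, n=6), repeats=repeats)
        assert rep.icc == 1.0

    def test_single_animal_rejected(self):
        table = pd.DataFrame({"bv_tv_control": [0.4], "bv_tv_test": [0.3]})
        with pytest.raises(ValueError, match="2 animals"):
            split_mouth_report(table)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="lacks column"):
            split_mouth_report(pd.DataFrame({"bv_tv_test": [0.3, 0.4]}))
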