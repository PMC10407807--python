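"""Two-way ANOVA, contrasts, Spearman by sex, ICC and reproducibility."""

import numpy as np
import pandas as pd
import pytest

from carotexture import stats as cs
from carotexture.errors import CarotextureError
from carotexture.synth import CohortSpec, generate_cohort


def cohort_frame(cell_values):
    """Build a tidy frame from {(sex, week): [values]}."""
    rows = [
        {"sex": sex, "week": week, "y": v}
        for (sex, week), values in cell_values.items()
        for v in values
    ]
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_flat_noise_free_design_all_f_zero(self):
        df = cohort_frame({(s, w): [5.0, 5.0, 5.0] for s in "MF" for w in (6, 16, 24)})
        res = cs.two_way_anova(df, "y")
        for term in ("sex", "week", "sex:week"):
            assert res.effect(term)["F"] == 0.0

    def test_pure_additive_effect_has_zero_interaction_ss(self):
        df = cohort_frame({
            ("M", 6): [10, 10], ("M", 24): [14, 14],
            ("F", 6): [12, 12], ("F", 24): [16, 16],
        })
        res = cs.two_way_anova(df, "y")
        assert res.effect("sex:week")["sum_sq"] == pytest.approx(0.0, abs=1e-9)

    def test_balanced_ss_decomposition(self, rng):
        df = cohort_frame({
            (s, w): rng.normal(size=6).tolist() for s in "MF" for w in (6, 16, 24)
        })
        res = cs.two_way_anova(df, "y")
        t = res.anova_table
        total = ((df["y"] - df["y"].mean()) ** 2).sum()
        assert t["sum_sq"].sum() == pytest.approx(total, abs=1e-9)

    def test_empty_cell_flags_interaction(self, rng):
        df = cohort_frame({
            ("M", 6): rng.normal(size=4).tolist(),
            ("F", 6): rng.normal(size=4).tolist(),
            ("F", 24): rng.normal(size=4).tolist(),
        })
        res = cs.two_way_anova(df, "y")
        assert "sex:week" in res.inestimable
        assert "sex" in res.anova_table.index

    def test_residual_plot_data(self, rng):
        df = cohort_frame({(s, w): rng.normal(size=5).tolist() for s in "MF" for w in (6, 24)})
        res = cs.two_way_anova(df, "y")
        rp = cs.residual_plot_data(res)
        assert set(rp.columns) == {"fitted", "residual"}
        assert len(rp) == len(df)
        assert rp["residual"].sum() == pytest.approx(0.0, abs=1e-9)

    def test_matches_closed_form_on_balanced_null(self, rng):
        """two_way_anova agrees with the vectorized balanced closed form."""
        a, b, n = 2, 3, 8
        for _ in range(3):
            y = rng.standard_normal((1, a, b, n))
            seed_state = y.copy()
            df = pd.DataFrame([
                {"sex": "MF"[i], "week": (6, 16, 24)[j], "y": y[0, i, j, k]}
                for i in range(a) for j in range(b) for k in range(n)
            ])
            res = cs.two_way_anova(df, "y")
            # recompute the closed-form p from the same draws
            cell = seed_state.mean(axis=3)
            row = cell.mean(axis=2, keepdims=True)
            col = cell.mean(axis=1, keepdims=True)
            grand = cell.mean(axis=(1, 2), keepdims=True)
            ss_int = n * np.sum((cell - row - col + grand) ** 2)
            sse = np.sum((seed_state - cell[..., None]) ** 2)
            f = (ss_int / ((a - 1) * (b - 1))) / (sse / (a * b * (n - 1)))
            assert res.effect("sex:week")["F"] == pytest.approx(f, abs=1e-9)

    def test_interaction_type1_error_calibrated(self):
        p = cs.simulate_null_interaction_pvalues(n_per_cell=40, n_reps=400, rng=3)
        assert abs((p < 0.05).mean() - 0.05) < 0.03


class TestContrasts:
    def test_identical_cells_give_zero_estimate_p_one(self, rng):
        vals = rng.normal(size=6).tolist()
        df = cohort_frame({("M", 6): vals, ("M", 24): vals,
                           ("F", 6): vals, ("F", 24): vals})
        c = cs.week_contrast_within_sex(cs.cell_statistics(df, "y"), "M", 6, 24)
        assert c.estimate == pytest.approx(0.0)
        assert c.p == pytest.approx(1.0)

    def test_noise_free_contrast_is_cell_difference(self):
        df = cohort_frame({("M", 6): [10, 10], ("M", 24): [14, 14],
                           ("F", 6): [10, 10], ("F", 24): [10, 10]})
        c = cs.week_contrast_within_sex(cs.cell_statistics(df, "y"), "M", 6, 24)
        assert c.estimate == 4.0
        assert c.zero_variance and c.p == 0.0

    def test_contrast_from_anova_result(self, rng):
        df = cohort_frame({(s, w): (rng.normal(size=5) + (2 if w == 24 else 0)).tolist()
                           for s in "MF" for w in (6, 24)})
        res = cs.two_way_anova(df, "y")
        c = cs.week_contrast_within_sex(res, "F", 6, 24)
        cells = res.cells
        expect = cells.cell("F", 24)["mean"] - cells.cell("F", 6)["mean"]
        assert c.estimate == pytest.approx(expect)
        assert 0 <= c.p <= 1

    def test_empty_cell_rejected(self, rng):
        df = cohort_frame({("M", 6): rng.normal(size=3).tolist(),
                           ("F", 6): rng.normal(size=3).tolist()})
        with pytest.raises(CarotextureError):
            cs.week_contrast_within_sex(cs.cell_statistics(df, "y"), "M", 6, 24)

    def test_power_against_small_group_shift(self):
        """A +0.04 homogeneity shift at sigma 0.03 is detected in most reps.

        Cell sizes are per-side readings: 5 and 3 animals contribute two
        carotid sides each (10 and 6 readings), the unit of analysis of
        the fixed-effects design.
        """
        rng = np.random.default_rng(42)
        hits = 0
        reps = 500
        for _ in range(reps):
            cells = {}
            for sex in "MF":
                shift = 0.04 if sex == "M" else 0.0
                cells[(sex, 6)] = rng.normal(0.14, 0.03, size=10).tolist()
                cells[(sex, 24)] = rng.normal(0.14 + shift, 0.03, size=6).tolist()
            df = cohort_frame(cells)
            c = cs.week_contrast_within_sex(cs.cell_statistics(df, "y"), "M", 6, 24)
            hits += c.p < 0.05
        assert hits / reps > 0.5

    def test_generated_cohort_contrast_recovers_week_effect(self):
        means = {"y": {("M", 6): 0.0, ("M", 24): 10.0, ("F", 6): 0.0, ("F", 24): 10.0}}
        spec = CohortSpec(n_per_cell=50, weeks=(6, 24), cell_means=means,
                          residual_sd={"y": 1.0}, seed=11)
        df = generate_cohort(spec)
        c = cs.week_contrast_within_sex(cs.cell_statistics(df, "y"), "M", 6, 24)
        assert c.estimate == pytest.approx(10.0, abs=0.5)


class TestSpearman:
    def frame(self, x, y, sex="M"):
        return pd.DataFrame({"sex": sex, "x": x, "y": y})

    @pytest.mark.parametrize("y,expected", [([10, 20, 30], 1.0), ([3, 2, 1], -1.0)])
    def test_perfect_monotone(self, y, expected):
        out = cs.spearman_by_sex(self.frame([1, 2, 3], y), "x", "y")
        assert out["rho"].iloc[0] == pytest.approx(expected)

    def test_tie_case_mid_rank_value(self):
        out = cs.spearman_by_sex(self.frame([1, 2, 3, 4], [1, 1, 3, 4]), "x", "y")
        assert out["rho"].iloc[0] == pytest.approx(0.948683, abs=1e-6)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        df1 = self.frame(x, y)
        df2 = self.frame(np.exp(x), y**3)
        a = cs.spearman_by_sex(df1, "x", "y")["rho"].iloc[0]
        b = cs.spearman_by_sex(df2, "x", "y")["rho"].iloc[0]
        assert a == pytest.approx(b, abs=1e-12)

    def test_pairwise_complete_and_split_by_sex(self, rng):
        df = pd.DataFrame({
            "sex": ["M"] * 5 + ["F"] * 5,
            "x": [1, 2, 3, 4, np.nan, 1, 2, 3, 4, 5],
            "y": [1, 2, 3, 4, 5, 5, 4, 3, 2, np.nan],
        })
        out = cs.spearman_by_sex(df, "x", "y")
        assert list(out["n"]) == [4, 4]  # sorted by sex: F first
        assert out.loc[out["sex"] == "M", "rho"].iloc[0] == pytest.approx(1.0)
        assert out.loc[out["sex"] == "F", "rho"].iloc[0] == pytest.approx(-1.0)

    def test_constant_vector_flagged(self):
        out = cs.spearman_by_sex(self.frame([1, 1, 1], [1, 2, 3]), "x", "y")
        assert not out["defined"].iloc[0]
        assert np.isnan(out["rho"].iloc[0])


class TestIcc:
    def test_identical_pairs_icc_one(self):
        t1 = np.array([3.0, 7.0, 11.0, 2.0])
        r = cs.icc_single(t1, t1.copy())
        assert r.icc == pytest.approx(1.0)

    def test_independent_noise_near_zero(self, rng):
        r = cs.icc_single(rng.normal(size=200), rng.normal(size=200))
        assert abs(r.icc) < 0.15

    def test_variance_ratio_recovery(self, rng):
        subject = rng.normal(0, 10, size=500)
        t1 = subject + rng.normal(0, 1, size=500)
        t2 = subject + rng.normal(0, 1, size=500)
        r = cs.icc_single(t1, t2)
        assert r.icc == pytest.approx(100 / 101, abs=0.02)
        assert r.ci_low < r.icc < r.ci_high

    def test_matches_pingouin_two_way_random_single(self, rng):
        pg = pytest.importorskip("pingouin")
        subject = rng.normal(50, 8, size=40)
        t1 = subject + rng.normal(0, 3, size=40)
        t2 = subject + 1.0 + rng.normal(0, 3, size=40)
        mine = cs.icc_single(t1, t2)
        long = pd.DataFrame({
            "subject": np.tile(np.arange(40), 2),
            "rater": np.repeat(["a", "b"], 40),
            "y": np.concatenate([t1, t2]),
        })
        ref = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="y")
        row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        assert mine.icc == pytest.approx(row["ICC"], abs=1e-6)
        # pingouin rounds the CI to two decimals
        assert mine.ci_low == pytest.approx(row[ci_col][0], abs=0.01)
        assert mine.ci_high == pytest.approx(row[ci_col][1], abs=0.01)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(CarotextureError):
            cs.icc_single([1, 2], [1, 2])


class TestReproSummary:
    def test_identical_pairs_zero_error(self):
        t = np.array([5.0, 6.0, 7.0])
        r = cs.repro_summary(t, t.copy(), feature="gsm")
        assert r.mean_abs_diff == 0.0 and r.within_subject_sd == 0.0

    def test_within_subject_sd_formula(self):
        r = cs.repro_summary(np.array([0.0, 0.0, 0]), np.array([2.0, 2.0, 0]), "f")
        # here d = (2, 2, 0): s_w = sqrt(8 / 6)
        assert r.within_subject_sd == pytest.approx(np.sqrt(8 / 6))
        r2 = cs.repro_summary(np.array([0.0, 0.0]), np.array([2.0, 2.0]), "f")
        assert r2.mean_abs_diff == 2.0
        assert r2.within_subject_sd == pytest.approx(np.sqrt(2))

    def test_sign_insensitive(self):
        r = cs.repro_summary(np.array([0.0, 3.0, 1.0]), np.array([3.0, 0.0, 1.0]), "f")
        assert r.mean_abs_diff == pytest.approx(2.0)
        assert r.within_subject_sd == pytest.approx(np.sqrt(18 / 6))

    def test_summary_line_mentions_icc(self, rng):
        t1 = rng.normal(size=10)
        r = cs.repro_summary(t1, t1 + rng.normal(0, 0.1, size=10), "gsm")
        assert "ICC" in r.summary() and "gsm" in r.summary()
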