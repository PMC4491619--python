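import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from alphamark.errors import DesignError, NormError
from alphamark.stats import (ControlNorm, TertileCutoffs, classify_tertile,
                             derive_tertiles, fit_control_norm, group_summary,
                             mixed_anova, pairwise_group_contrasts, pearson_r,
                             w_score, gg_epsilon, _orthonormal_contrasts)


# ---------------------------------------------------------------------------
# independent split-plot oracle: nested OLS model comparison

def oracle_split_plot_f(values: np.ndarray, groups: np.ndarray) -> tuple[float, int, int]:
    """Textbook oracle for the group x B x C interaction F.

    Builds explicit dummy design matrices and compares residual sums of
    squares of the nested models by least squares: the full model carries
    subject, subject x B, subject x C, and group x B x C cell effects; the
    reduced model drops the three-way cells down to all two-way margins.
    """
    n, f, p = values.shape
    y = values.reshape(-1)
    rows = [(i, j, k) for i in range(n) for j in range(f) for k in range(p)]

    def dummies(keys):
        uniq = sorted(set(keys))
        out = np.zeros((len(keys), len(uniq)))
        for r, key in enumerate(keys):
            out[r, uniq.index(key)] = 1.0
        return out

    subj = dummies([i for i, j, k in rows])
    subj_b = dummies([(i, j) for i, j, k in rows])
    subj_c = dummies([(i, k) for i, j, k in rows])
    gbc = dummies([(groups[i], j, k) for i, j, k in rows])
    gb = dummies([(groups[i], j) for i, j, k in rows])
    gc = dummies([(groups[i], k) for i, j, k in rows])
    bc = dummies([(j, k) for i, j, k in rows])

    def rss(x):
        resid = y - x @ np.linalg.lstsq(x, y, rcond=None)[0]
        return float(resid @ resid)

    full = np.hstack([subj, subj_b, subj_c, gbc])
    reduced = np.hstack([subj, subj_b, subj_c, gb, gc, bc])
    g = len(set(groups))
    df_num = (g - 1) * (f - 1) * (p - 1)
    df_den = (n - g) * (f - 1) * (p - 1)
    ss_num = rss(reduced) - rss(full)
    ss_den = rss(full)
    return (ss_num / df_num) / (ss_den / df_den), df_num, df_den


def _simulate(n_per_group, f, p, seed, effect=0.0):
    rng = np.random.default_rng(seed)
    groups = np.repeat([f"g{i}" for i in range(len(n_per_group))], n_per_group)
    n = groups.size
    values = rng.normal(size=(n, f, p)) + rng.normal(size=(n, 1, 1))
    if effect:
        bump = rng.normal(size=(len(n_per_group), f, p))
        for gi, lab in enumerate(sorted(set(groups))):
            values[groups == lab] += effect * bump[gi]
    return values, groups


class TestClassifyTertile:
    @pytest.mark.parametrize("ratio,expected", [
        (1.29, "high"), (0.9, "low"), (1.08, "middle"),
        (1.0, "middle"), (1.17, "high"), (1.165, "middle"), (0.999, "low"),
    ])
    def test_published_examples_and_boundaries(self, ratio, expected):
        assert classify_tertile(ratio) == expected

    @given(st.floats(0.0, 10.0, allow_nan=False))
    def test_totality(self, ratio):
        assert classify_tertile(ratio) in {"low", "middle", "high"}

    def test_invalid_cutoffs(self):
        with pytest.raises(DesignError):
            TertileCutoffs(low_hi=1.2, high_lo=1.0)


class TestDeriveTertiles:
    def test_uniform_grid_partitions_evenly(self):
        cuts = derive_tertiles(np.arange(1.0, 10.0))
        labels = [classify_tertile(r, cuts) for r in np.arange(1.0, 10.0)]
        assert labels.count("low") == labels.count("middle") == labels.count("high") == 3

    def test_balanced_split_on_table_like_sample(self):
        rng = np.random.default_rng(8)
        ratios = np.concatenate([rng.uniform(0.77, 0.98, 25),
                                 rng.uniform(1.0, 1.16, 25),
                                 rng.uniform(1.17, 1.52, 24)])
        cuts = derive_tertiles(ratios)
        counts = pd.Series([classify_tertile(r, cuts) for r in ratios]).value_counts()
        assert counts.max() - counts.min() <= 1
        # quantile oracle
        np.testing.assert_allclose(
            [cuts.low_hi, cuts.high_lo], np.quantile(ratios, [1 / 3, 2 / 3]))

    def test_degenerate_values_warn(self):
        with pytest.warns(UserWarning, match="degenerate"):
            derive_tertiles([1.0, 1.0, 1.0, 2.0])

    def test_too_few_values(self):
        with pytest.raises(DesignError):
            derive_tertiles([1.0, 2.0])


class TestMixedAnova:
    def test_paper_shape_has_14_numerator_df(self):
        values, groups = _simulate([10, 10], 8, 3, seed=0)
        res = mixed_anova(values, groups)
        assert res["df_num"] == 14
        assert res["df_den"] == (20 - 2) * 7 * 2

    def test_cloned_groups_give_zero_f(self):
        values, groups = _simulate([6], 4, 3, seed=1)
        doubled = np.concatenate([values, values])
        groups2 = np.array(["a"] * 6 + ["b"] * 6)
        res = mixed_anova(doubled, groups2)
        assert res["F"] == pytest.approx(0.0, abs=1e-20)

    @pytest.mark.parametrize("shape", [
        ([3, 3], 2, 2), ([4, 3], 3, 2), ([5, 4, 3], 3, 3), ([6, 6], 2, 3),
    ])
    def test_matches_sums_of_squares_oracle(self, shape):
        n_per, f, p = shape
        values, groups = _simulate(n_per, f, p, seed=hash(str(shape)) % 1000,
                                   effect=0.5)
        res = mixed_anova(values, groups)
        f_oracle, df1, df2 = oracle_split_plot_f(values, groups)
        assert res["df_num"] == df1 and res["df_den"] == df2
        assert res["F"] == pytest.approx(f_oracle, rel=1e-10)

    def test_gg_correction_weakens_significance(self):
        values, groups = _simulate([8, 8], 5, 3, seed=3, effect=0.8)
        res = mixed_anova(values, groups)
        assert 0 < res["gg_epsilon"] <= 1
        assert res["gg_p"] >= res["p"]

    def test_mauchly_reported_when_estimable(self):
        values, groups = _simulate([25, 25], 3, 2, seed=4)
        res = mixed_anova(values, groups)
        assert 0 < res["mauchly_w"] <= 1
        assert 0 <= res["mauchly_p"] <= 1

    def test_missing_cells_rejected(self):
        values, groups = _simulate([3, 3], 2, 2, seed=5)
        values[0, 0, 0] = np.nan
        with pytest.raises(DesignError):
            mixed_anova(values, groups)

    def test_single_group_rejected(self):
        values, groups = _simulate([6], 2, 2, seed=6)
        with pytest.raises(DesignError):
            mixed_anova(values, groups)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="R not available")
    def test_matches_r_aov_split_plot(self):
        """Cross-language oracle: R aov with Error(subject/(B*C))."""
        values, groups = _simulate([4, 4], 3, 2, seed=11, effect=0.7)
        n, f, p = values.shape
        rows = []
        for i in range(n):
            for j in range(f):
                for k in range(p):
                    rows.append({"y": values[i, j, k], "subj": f"s{i}",
                                 "grp": groups[i], "b": f"b{j}", "c": f"c{k}"})
        df = pd.DataFrame(rows)
        with tempfile.TemporaryDirectory() as td:
            csv = Path(td) / "d.csv"
            df.to_csv(csv, index=False)
            script = Path(td) / "m.R"
            script.write_text(
                'd <- read.csv("%s")\n'
                'd$subj <- factor(d$subj); d$grp <- factor(d$grp)\n'
                'd$b <- factor(d$b); d$c <- factor(d$c)\n'
                'm <- aov(y ~ grp*b*c + Error(subj/(b*c)), data=d)\n'
                's <- summary(m)[["Error: subj:b:c"]][[1]]\n'
                'cat(sprintf("%%.12g", s["grp:b:c", "F value"]))\n' % csv)
            out = subprocess.run(["Rscript", str(script)], capture_output=True,
                                 text=True, check=True)
        f_r = float(out.stdout.strip())
        res = mixed_anova(values, groups)
        assert res["F"] == pytest.approx(f_r, rel=1e-6)


class TestGgEpsilon:
    def test_matches_pingouin_single_factor(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(12)
        base = rng.normal(size=(12, 1))
        scores = base + rng.normal(scale=[0.5, 1.0, 2.0, 4.0], size=(12, 4))
        ours = gg_epsilon(scores, _orthonormal_contrasts(4))
        theirs = float(pingouin.epsilon(pd.DataFrame(scores), correction="gg"))
        assert ours == pytest.approx(theirs, rel=1e-8)

    def test_spherical_data_epsilon_near_one(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=(200, 4))
        assert gg_epsilon(scores, _orthonormal_contrasts(4)) > 0.9


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson_r(x, x)["r"] == pytest.approx(1.0)
        assert pearson_r(x, -2 * x + 5)["r"] == pytest.approx(-1.0)

    def test_sampling_interval_of_bivariate_normal(self):
        """r for n=13, rho=0.7 lies inside the Monte-Carlo 95% interval."""
        rho, n = 0.7, 13
        orng = np.random.default_rng(1000)
        sims = []
        for _ in range(10000):
            a = orng.standard_normal(n)
            b = rho * a + np.sqrt(1 - rho**2) * orng.standard_normal(n)
            sims.append(np.corrcoef(a, b)[0, 1])
        lo, hi = np.quantile(sims, [0.025, 0.975])
        rng = np.random.default_rng(17)
        x = rng.standard_normal(n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        r = pearson_r(x, y)["r"]
        assert lo <= r <= hi

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(5), np.arange(5.0))


class TestWScore:
    def test_control_on_fitted_line_scores_zero(self):
        norm = ControlNorm(intercept=2.0, slope=0.5, resid_sd=1.5)
        assert w_score(2.0 + 0.5 * 70, 70, norm) == pytest.approx(0.0)
        assert w_score(2.0 + 0.5 * 70 + 1.5, 70, norm) == pytest.approx(1.0)

    def test_recovers_generating_line(self):
        rng = np.random.default_rng(5)
        ages = rng.uniform(60, 85, 17)
        values = 10.0 - 0.08 * ages + rng.normal(0, 0.5, 17)
        norm = fit_control_norm(values, ages)
        slope_oracle, intercept_oracle = np.polyfit(ages, values, 1)
        assert norm.slope == pytest.approx(slope_oracle)
        assert norm.intercept == pytest.approx(intercept_oracle)

    def test_control_sample_standardized_exactly(self):
        rng = np.random.default_rng(6)
        ages = rng.uniform(60, 85, 17)
        values = 3.0 + 0.02 * ages + rng.normal(0, 0.3, 17)
        norm = fit_control_norm(values, ages)
        ws = np.array([w_score(v, a, norm) for v, a in zip(values, ages)])
        assert ws.mean() == pytest.approx(0.0, abs=1e-10)
        assert ws.std(ddof=1) == pytest.approx(1.0, rel=1e-10)

    def test_degenerate_norms_rejected(self):
        with pytest.raises(NormError):
            fit_control_norm([1.0, 2.0], [60.0, 61.0])
        with pytest.raises(NormError):
            fit_control_norm([1.0, 2.0, 3.0], [60.0, 60.0, 60.0])
        with pytest.raises(NormError):
            ControlNorm(intercept=0, slope=0, resid_sd=0)


class TestGroupSummary:
    def test_hand_cohort(self):
        df = pd.DataFrame({
            "group": ["low", "low", "high"],
            "age": [60.0, 70.0, 80.0],
            "alpha3_alpha2": [0.9, 0.8, 1.3],
        })
        out = group_summary(df, columns=("age", "alpha3_alpha2"))
        low = out[out.group == "low"].iloc[0]
        assert low["age_mean"] == pytest.approx(65.0)
        assert low["age_sd"] == pytest.approx(np.std([60, 70], ddof=1))
        assert low["alpha3_alpha2_min"] == pytest.approx(0.8)
        high = out[out.group == "high"].iloc[0]
        assert high["sd_degenerate"] and high["age_sd"] == 0.0

    def test_groups_ordered_low_middle_high(self):
        df = pd.DataFrame({"group": ["high", "low", "middle"],
                           "age": [1.0, 2.0, 3.0]})
        out = group_summary(df, columns=("age",))
        assert out.group.tolist() == ["low", "middle", "high"]


class TestPairwiseContrasts:
    def test_contrast_table_shape(self):
        values, groups = _simulate([5, 5, 5], 2, 2, seed=9, effect=1.0)
        table = pairwise_group_contrasts(values, groups)
        assert len(table) == 3
        assert set(table.columns) >= {"group_a", "group_b", "t", "p_uncorrected"}
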