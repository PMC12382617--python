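"""Removal tables, the two-way ANOVA decomposition and Tukey's HSD."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import ebeamkin as ek
from ebeamkin.exceptions import InsufficientDataError, ValidationError
from ebeamkin.removal_stats import removal_long_frame


def _table_from_areas(areas_by_dose, analyte="ab", reps=3):
    rows = []
    for dose, area in areas_by_dose.items():
        for rep in range(1, reps + 1):
            rows.append(ek.Observation(dose, rep, analyte, 1.0, None, area))
    return ek.PeakTable(tuple(rows))


class TestRemovalTable:
    def test_area_equal_to_baseline_is_zero_removal(self):
        table = _table_from_areas({0.0: 2.0e9, 1.0: 2.0e9})
        recs = {r.dose_kGy: r for r in ek.removal_table(table, "ab")}
        assert recs[1.0].mean == pytest.approx(0.0, abs=1e-9)

    def test_halved_area_is_fifty_percent(self):
        table = _table_from_areas({0.0: 2.0e9, 3.0: 1.0e9})
        recs = {r.dose_kGy: r for r in ek.removal_table(table, "ab")}
        assert recs[3.0].mean == pytest.approx(50.0, rel=1e-12)

    def test_censored_rows_count_as_complete_removal(self):
        rows = [ek.Observation(0.0, r, "ab", 1.0, None, 1e9) for r in (1, 2, 3)]
        rows.append(ek.Observation(7.0, 1, "ab", 1.0, None, 0.0, censored=True))
        recs = {r.dose_kGy: r for r in ek.removal_table(ek.PeakTable(tuple(rows)), "ab")}
        assert recs[7.0].mean == 100.0

    def test_ci_halfwidth_from_student_t(self):
        rows = [
            ek.Observation(0.0, r, "ab", 1.0, None, 1.0e9) for r in (1, 2, 3)
        ] + [
            ek.Observation(1.0, r, "ab", 1.0, None, a)
            for r, a in zip((1, 2, 3), (4.0e8, 5.0e8, 6.0e8))
        ]
        rec = {r.dose_kGy: r for r in ek.removal_table(ek.PeakTable(tuple(rows)), "ab")}[1.0]
        removals = 100.0 * (1.0 - np.array([0.4, 0.5, 0.6]))
        expected = 4.302652729911275 * removals.std(ddof=1) / math.sqrt(3)
        assert rec.ci_halfwidth == pytest.approx(expected, rel=1e-9)

    def test_seven_kgy_removal_at_least_98_for_all_antibiotics(self, registry):
        table = ek.simulate_noiseless(registry, [0.0, 7.0])
        for name in registry.antibiotics:
            recs = {r.dose_kGy: r for r in ek.removal_table(table, name)}
            assert recs[7.0].mean >= 98.0

    def test_missing_dose0_rejected(self):
        table = _table_from_areas({1.0: 1.0e9})
        with pytest.raises(InsufficientDataError):
            ek.removal_table(table, "ab")


def _anova_oracle(df):
    """Brute-force sums-of-squares decomposition for a balanced layout."""
    y = df["removal_percent"].to_numpy(float)
    grand = y.mean()
    levels_a = df["antibiotic"].unique()
    levels_b = df["dose_kGy"].unique()
    n = len(df) // (len(levels_a) * len(levels_b))
    ss_a = sum(
        len(df[df.antibiotic == a]) * (df[df.antibiotic == a].removal_percent.mean() - grand) ** 2
        for a in levels_a
    )
    ss_b = sum(
        len(df[df.dose_kGy == b]) * (df[df.dose_kGy == b].removal_percent.mean() - grand) ** 2
        for b in levels_b
    )
    ss_ab = 0.0
    ss_err = 0.0
    for a, b in itertools.product(levels_a, levels_b):
        cell = df[(df.antibiotic == a) & (df.dose_kGy == b)].removal_percent
        ma = df[df.antibiotic == a].removal_percent.mean()
        mb = df[df.dose_kGy == b].removal_percent.mean()
        ss_ab += n * (cell.mean() - ma - mb + grand) ** 2
        ss_err += ((cell - cell.mean()) ** 2).sum()
    return ss_a, ss_b, ss_ab, ss_err


def _random_removal_df(rng, na=3, nb=4, n=3, effects=True):
    rows = []
    for i in range(na):
        for j in range(nb):
            mu = 10.0 * i * effects + 5.0 * j + rng.normal(0, 2)
            for r in range(n):
                rows.append(
                    {
                        "antibiotic": f"ab{i}",
                        "dose_kGy": float(j + 1),
                        "removal_percent": mu + rng.normal(0, 3),
                    }
                )
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_identical_cells_give_zero_f(self):
        df = pd.DataFrame(
            {
                "antibiotic": ["a", "a", "b", "b"] * 2,
                "dose_kGy": [1.0, 1.0, 1.0, 1.0, 3.0, 3.0, 3.0, 3.0],
                "removal_percent": [50.0] * 8,
            }
        )
        res = ek.two_way_anova(df)
        assert res.f_a == 0.0 and res.f_b == 0.0
        assert res.p_a == 1.0 and res.p_b == 1.0

    def test_2x2x3_matches_hand_decomposition(self, rng):
        df = _random_removal_df(rng, na=2, nb=2, n=3)
        res = ek.two_way_anova(df)
        ss_a, ss_b, ss_ab, ss_err = _anova_oracle(df)
        assert res.ss_a == pytest.approx(ss_a, rel=1e-9)
        assert res.ss_b == pytest.approx(ss_b, rel=1e-9)
        assert res.ss_ab == pytest.approx(ss_ab, rel=1e-9)
        assert res.ss_error == pytest.approx(ss_err, rel=1e-9)

    def test_decomposition_identity_and_df_bookkeeping(self, rng):
        for _ in range(20):
            df = _random_removal_df(rng, na=4, nb=3, n=2)
            res = ek.two_way_anova(df)
            assert res.ss_total == pytest.approx(
                res.ss_a + res.ss_b + res.ss_ab + res.ss_error, rel=1e-9
            )
            assert res.df_a + res.df_b + res.df_ab + res.df_error == len(df) - 1

    def test_matches_statsmodels_anova_lm(self, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        df = _random_removal_df(rng, na=3, nb=4, n=3)
        fit = ols("removal_percent ~ C(antibiotic) * C(dose_kGy)", data=df).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        res = ek.two_way_anova(df)
        assert res.ss_a == pytest.approx(ref.loc["C(antibiotic)", "sum_sq"], rel=1e-8)
        assert res.ss_b == pytest.approx(ref.loc["C(dose_kGy)", "sum_sq"], rel=1e-8)
        assert res.ss_ab == pytest.approx(
            ref.loc["C(antibiotic):C(dose_kGy)", "sum_sq"], rel=1e-8
        )
        assert res.p_a == pytest.approx(ref.loc["C(antibiotic)", "PR(>F)"], rel=1e-6)

    def test_unbalanced_design_rejected(self, rng):
        df = _random_removal_df(rng, na=2, nb=2, n=3).iloc[:-1]
        with pytest.raises(ValidationError, match="unbalanced"):
            ek.two_way_anova(df)

    def test_pipeline_from_peak_table(self, registry):
        cfg = ek.GeneratorConfig(registry=registry, seed=3)
        table = ek.generate(cfg)
        long = removal_long_frame(table, list(registry.antibiotics))
        res = ek.two_way_anova(long)
        # antibiotics genuinely differ in radiosensitivity
        assert res.p_a < 0.05


class TestTukey:
    def test_identical_groups_not_significant(self):
        df = pd.DataFrame(
            [
                {"antibiotic": a, "dose_kGy": b, "removal_percent": 50.0 + 0.1 * r}
                for a in ("x", "y", "z")
                for b in (1.0, 3.0)
                for r in range(3)
            ]
        )
        out = ek.tukey_hsd(df)
        assert not out["significant"].any()

    def test_separated_group_significant_and_q_formula(self, rng):
        df = _random_removal_df(rng, na=3, nb=2, n=3, effects=False)
        df.loc[df.antibiotic == "ab2", "removal_percent"] += 60.0
        anova = ek.two_way_anova(df)
        out = ek.tukey_hsd(df, anova=anova)
        m = anova.cell_n * len(anova.b_levels)
        for _, row in out.iterrows():
            means = df.groupby("antibiotic")["removal_percent"].mean()
            q_manual = abs(means[row.level_1] - means[row.level_2]) / math.sqrt(
                anova.mse / m
            )
            assert row.q == pytest.approx(q_manual, rel=1e-9)
        sep = out[(out.level_1 == "ab0") & (out.level_2 == "ab2")]
        assert bool(sep["significant"].iloc[0])

    def test_matches_statsmodels_pairwise_tukeyhsd(self, rng):
        """One-way layout (a single dose level duplicated) reproduces the
        reference implementation's rejections and p-values."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rows = [
            {
                "antibiotic": f"ab{i}",
                "dose_kGy": float(j + 1),
                "removal_percent": float(rng.normal(50, 3))
                + (25.0 if i == 3 else 0.0),
            }
            for i in range(4)
            for j in range(2)
            for _ in range(3)
        ]
        df = pd.DataFrame(rows)
        out = ek.tukey_hsd(df)
        # reference: one-way on the same observations (no dose or cell
        # effects were generated, so the error terms estimate the same
        # variance and the rejections coincide)
        ref = pairwise_tukeyhsd(
            df["removal_percent"], df["antibiotic"], alpha=0.05
        )
        ref_df = pd.DataFrame(
            ref.summary().data[1:], columns=ref.summary().data[0]
        )
        ours = dict(zip(zip(out.level_1, out.level_2), out.significant))
        for _, row in ref_df.iterrows():
            assert ours[(row.group1, row.group2)] == bool(row.reject)

    def test_permutation_agrees_with_distributional_calls(self, rng):
        df = _random_removal_df(rng, na=3, nb=2, n=3, effects=False)
        df.loc[df.antibiotic == "ab1", "removal_percent"] += 80.0
        dist = ek.tukey_hsd(df, method="studentized-range")
        perm = ek.tukey_hsd(df, method="permutation", n_permutations=10000, seed=7)
        assert list(dist["significant"]) == list(perm["significant"])
        again = ek.tukey_hsd(df, method="permutation", n_permutations=10000, seed=7)
        assert list(perm["p"]) == list(again["p"])

    def test_single_level_rejected(self):
        df = pd.DataFrame(
            [
                {"antibiotic": "only", "dose_kGy": b, "removal_percent": float(r)}
                for b in (1.0, 3.0)
                for r in range(3)
            ]
        )
        with pytest.raises(InsufficientDataError):
            ek.tukey_hsd(df)
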