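import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from emgmap import cell_contrast, rm_anova, tukey_pairwise
from emgmap.exceptions import (
    InsufficientDataError,
    InvalidDesignError,
    InvalidInputError,
)

pingouin = pytest.importorskip("pingouin")


def make_table(n_subjects, level_spec, effects=None, noise_sd=1.0, seed=0):
    """Balanced within-subject table with optional additive level effects.

    ``level_spec`` maps factor name -> number of levels; ``effects`` maps
    factor name -> per-level additive shifts.
    """
    rng = np.random.default_rng(seed)
    factors = {f: [f"{f}{i}" for i in range(n)] for f, n in level_spec.items()}
    rows = []
    for s in range(n_subjects):
        subj_offset = rng.normal(0, 1.0)
        for combo in itertools.product(*factors.values()):
            value = subj_offset + rng.normal(0, noise_sd)
            if effects:
                for fname, levels in factors.items():
                    if fname in effects:
                        idx = levels.index(combo[list(factors).index(fname)])
                        value += effects[fname][idx]
            row = {"subject": f"s{s}", "y": value}
            row.update(dict(zip(factors.keys(), combo)))
            rows.append(row)
    return pd.DataFrame(rows)


def oracle_two_way_rm(table, dv="y", subject="subject", factors=("a", "b")):
    """Brute-force sums-of-squares for a two-factor within design.

    Computes every marginal mean with explicit loops and assembles the
    classical repeated-measures F ratios, independently of the package
    implementation.
    """
    fa, fb = factors
    subjects = sorted(table[subject].unique())
    la = sorted(table[fa].unique())
    lb = sorted(table[fb].unique())
    S, A, B = len(subjects), len(la), len(lb)

    def cell(s=None, a=None, b=None):
        sel = table
        if s is not None:
            sel = sel[sel[subject] == s]
        if a is not None:
            sel = sel[sel[fa] == a]
        if b is not None:
            sel = sel[sel[fb] == b]
        return sel[dv].mean()

    grand = table[dv].mean()
    ss = {}
    ss[fa] = S * B * sum((cell(a=a) - grand) ** 2 for a in la)
    ss[fb] = S * A * sum((cell(b=b) - grand) ** 2 for b in lb)
    ss[f"{fa}:{fb}"] = S * sum(
        (cell(a=a, b=b) - cell(a=a) - cell(b=b) + grand) ** 2 for a in la for b in lb
    )
    err = {}
    err[fa] = B * sum(
        (cell(s=s, a=a) - cell(s=s) - cell(a=a) + grand) ** 2 for s in subjects for a in la
    )
    err[fb] = A * sum(
        (cell(s=s, b=b) - cell(s=s) - cell(b=b) + grand) ** 2 for s in subjects for b in lb
    )
    err[f"{fa}:{fb}"] = sum(
        (
            cell(s=s, a=a, b=b)
            - cell(s=s, a=a)
            - cell(s=s, b=b)
            - cell(a=a, b=b)
            + cell(s=s)
            + cell(a=a)
            + cell(b=b)
            - grand
        )
        ** 2
        for s in subjects
        for a in la
        for b in lb
    )
    dfs = {fa: A - 1, fb: B - 1, f"{fa}:{fb}": (A - 1) * (B - 1)}
    out = {}
    for effect, df1 in dfs.items():
        df2 = (S - 1) * df1
        out[effect] = (ss[effect] / df1) / (err[effect] / df2), df1, df2
    return out


class TestRmAnovaOracle:
    def test_matches_brute_force_two_way(self):
        table = make_table(
            10, {"a": 3, "b": 2}, effects={"a": [0.0, 0.5, 1.0]}, seed=42
        )
        result = rm_anova(table, dv="y", subject="subject", within=["a", "b"]).set_index("effect")
        oracle = oracle_two_way_rm(table)
        for effect, (f_val, df1, df2) in oracle.items():
            row = result.loc[effect]
            assert row["F"] == pytest.approx(f_val, rel=1e-10)
            assert row["df1"] == df1
            assert row["df2"] == df2

    def test_one_way_matches_pingouin(self):
        table = make_table(12, {"a": 4}, effects={"a": [0.0, 0.3, 0.6, 0.9]}, seed=3)
        mine = rm_anova(table, dv="y", subject="subject", within=["a"]).iloc[0]
        ping = pingouin.rm_anova(
            data=table, dv="y", subject="subject", within="a", correction=True, detailed=True
        ).iloc[0]
        assert mine["F"] == pytest.approx(ping["F"], rel=1e-9)
        assert mine["p_unc"] == pytest.approx(ping["p_unc"], rel=1e-9)
        assert mine["eps"] == pytest.approx(ping["eps"], rel=1e-6)
        spher = pingouin.sphericity(data=table, dv="y", subject="subject", within="a")
        assert mine["mauchly_W"] == pytest.approx(spher.W, rel=1e-9)
        assert mine["p_sphericity"] == pytest.approx(spher.pval, rel=1e-6)

    def test_two_way_f_matches_pingouin(self):
        table = make_table(9, {"a": 3, "b": 2}, effects={"b": [0.0, 0.8]}, seed=11)
        mine = rm_anova(table, dv="y", subject="subject", within=["a", "b"]).set_index("effect")
        ping = pingouin.rm_anova(
            data=table, dv="y", subject="subject", within=["a", "b"]
        ).set_index("Source")
        assert mine.loc["a", "F"] == pytest.approx(ping.loc["a", "F"], rel=1e-9)
        assert mine.loc["b", "F"] == pytest.approx(ping.loc["b", "F"], rel=1e-9)
        assert mine.loc["a:b", "F"] == pytest.approx(ping.loc["a * b", "F"], rel=1e-9)


class TestRmAnovaBehaviour:
    def test_two_level_factor_has_unit_epsilon_and_no_correction(self):
        table = make_table(8, {"a": 2}, seed=1)
        row = rm_anova(table, dv="y", subject="subject", within=["a"]).iloc[0]
        assert row["eps"] == 1.0
        assert not row["gg_applied"]

    def test_constant_response_gives_zero_f(self):
        table = make_table(6, {"a": 3, "b": 2}, noise_sd=0.0, seed=0)
        table["y"] = 5.0
        result = rm_anova(table, dv="y", subject="subject", within=["a", "b"])
        assert (result["F"] == 0.0).all()

    def test_invariant_to_adding_a_constant(self):
        table = make_table(8, {"a": 3}, effects={"a": [0, 0.4, 0.8]}, seed=5)
        f1 = rm_anova(table, dv="y", subject="subject", within=["a"])["F"].iloc[0]
        shifted = table.copy()
        shifted["y"] = shifted["y"] + 1234.5
        f2 = rm_anova(shifted, dv="y", subject="subject", within=["a"])["F"].iloc[0]
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_invariant_to_relabeling_levels(self):
        table = make_table(8, {"a": 3}, effects={"a": [0, 0.4, 0.8]}, seed=5)
        relabeled = table.copy()
        relabeled["a"] = relabeled["a"].map({"a0": "zebra", "a1": "ant", "a2": "moth"})
        f1 = rm_anova(table, dv="y", subject="subject", within=["a"])["F"].iloc[0]
        f2 = rm_anova(relabeled, dv="y", subject="subject", within=["a"])["F"].iloc[0]
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_three_way_design_runs(self):
        table = make_table(6, {"a": 5, "b": 2, "c": 2}, effects={"a": [0, 0, 0, 0, 2.0]}, seed=9)
        result = rm_anova(table, dv="y", subject="subject", within=["a", "b", "c"])
        assert len(result) == 7  # 3 mains + 3 two-way + 1 three-way
        assert result.loc[result["effect"] == "a", "p"].iloc[0] < 0.05

    def test_gg_correction_uses_epsilon_scaled_dfs(self):
        table = make_table(10, {"a": 4}, effects={"a": [0, 0.2, 0.4, 0.6]}, seed=2)
        always = rm_anova(
            table, dv="y", subject="subject", within=["a"], correction="always"
        ).iloc[0]
        assert always["gg_applied"]
        expected = sp_stats.f.sf(
            always["F"], always["eps"] * always["df1"], always["eps"] * always["df2"]
        )
        assert always["p"] == pytest.approx(expected, rel=1e-12)

    def test_unbalanced_table_rejected(self):
        table = make_table(6, {"a": 3}, seed=0)
        with pytest.raises(InvalidDesignError):
            rm_anova(table.iloc[:-1], dv="y", subject="subject", within=["a"])

    def test_single_subject_rejected(self):
        table = make_table(1, {"a": 3}, seed=0)
        with pytest.raises(InsufficientDataError):
            rm_anova(table, dv="y", subject="subject", within=["a"])

    def test_missing_column_rejected(self):
        table = make_table(6, {"a": 3}, seed=0)
        with pytest.raises(InvalidInputError):
            rm_anova(table, dv="nope", subject="subject", within=["a"])

    def test_too_many_factors_rejected(self):
        table = make_table(4, {"a": 2, "b": 2, "c": 2}, seed=0)
        table["d"] = "x"
        with pytest.raises(InvalidInputError):
            rm_anova(table, dv="y", subject="subject", within=["a", "b", "c", "d"])


class TestTukeyPairwise:
    def test_two_levels_equal_paired_t_test(self):
        table = make_table(10, {"a": 2}, effects={"a": [0.0, 0.6]}, seed=7)
        out = tukey_pairwise(table, dv="y", subject="subject", factor="a")
        assert len(out) == 1
        wide = table.pivot(index="subject", columns="a", values="y")
        t_res = sp_stats.ttest_rel(wide["a0"], wide["a1"])
        assert out["p_adj"].iloc[0] == pytest.approx(t_res.pvalue, rel=1e-6)

    def test_all_equal_means_give_p_near_one(self):
        rng = np.random.default_rng(0)
        rows = []
        for s in range(8):
            base = rng.normal()
            for level in ("a0", "a1", "a2"):
                rows.append({"subject": s, "a": level, "y": base})  # identical per subject
        out = tukey_pairwise(pd.DataFrame(rows), dv="y", subject="subject", factor="a")
        assert (out["p_adj"] == 1.0).all()

    def test_only_shifted_level_comparisons_flagged(self):
        table = make_table(
            12,
            {"a": 5},
            effects={"a": [0.0, 0.0, 0.0, 0.0, 3.0]},
            noise_sd=0.5,
            seed=13,
        )
        out = tukey_pairwise(table, dv="y", subject="subject", factor="a")
        involving = out[(out["level_a"] == "a4") | (out["level_b"] == "a4")]
        others = out[(out["level_a"] != "a4") & (out["level_b"] != "a4")]
        assert (involving["p_adj"] < 0.05).all()
        assert (others["p_adj"] > 0.05).all()

    def test_adjusted_p_monotone_in_mean_difference(self):
        table = make_table(10, {"a": 4}, effects={"a": [0.0, 0.5, 1.0, 2.0]}, seed=21)
        out = tukey_pairwise(table, dv="y", subject="subject", factor="a")
        ordered = out.sort_values("p_adj")
        diffs = ordered["mean_diff"].abs().to_numpy()
        assert np.all(np.diff(diffs) <= 1e-12)

    def test_matches_permutation_oracle_on_shifted_level(self):
        # sign-flip permutation test on the paired differences of the
        # clearly shifted comparison: adjusted p and permutation p must
        # agree on significance at alpha = 0.05
        table = make_table(10, {"a": 3}, effects={"a": [0.0, 0.0, 2.0]}, noise_sd=0.5, seed=3)
        out = tukey_pairwise(table, dv="y", subject="subject", factor="a").set_index(
            ["level_a", "level_b"]
        )
        wide = table.pivot(index="subject", columns="a", values="y")
        rng = np.random.default_rng(99)
        for pair in [("a0", "a2"), ("a0", "a1")]:
            d = (wide[pair[0]] - wide[pair[1]]).to_numpy()
            observed = abs(d.mean())
            flips = rng.choice([-1.0, 1.0], size=(10_000, d.size))
            perm = np.abs((flips * d).mean(axis=1))
            p_perm = (np.sum(perm >= observed) + 1) / (10_000 + 1)
            p_tukey = out.loc[pair, "p_adj"]
            assert (p_perm < 0.05) == (p_tukey < 0.05)

    def test_degenerate_factor_rejected(self):
        table = make_table(6, {"a": 2}, seed=0)
        table["a"] = "only"
        with pytest.raises(InvalidInputError):
            tukey_pairwise(table, dv="y", subject="subject", factor="a")

    def test_incomplete_levels_rejected(self):
        table = make_table(6, {"a": 3}, seed=0)
        table = table[~((table["subject"] == "s0") & (table["a"] == "a2"))]
        with pytest.raises(InvalidDesignError):
            tukey_pairwise(table, dv="y", subject="subject", factor="a")


class TestCellContrast:
    def test_known_shift_detected(self):
        table = make_table(10, {"a": 2, "b": 2}, effects={"a": [0.0, 2.0]}, noise_sd=0.3, seed=8)
        res = cell_contrast(
            table, dv="y", subject="subject", cell_a={"a": "a0"}, cell_b={"a": "a1"}
        )
        assert res["p"] < 0.01
        assert res["mean_diff"] == pytest.approx(-2.0, abs=0.5)
        assert res["n"] == 10

    def test_empty_cell_rejected(self):
        table = make_table(5, {"a": 2}, seed=0)
        with pytest.raises(InvalidInputError):
            cell_contrast(table, dv="y", subject="subject", cell_a={"a": "zz"}, cell_b={"a": "a0"})


class TestNullCalibration:
    def test_type_one_error_near_alpha_smoke(self):
        # scaled-down version of the acceptance calibration (300 tables)
        rng = np.random.default_rng(2024)
        n_reject = 0
        n_tables = 300
        for _ in range(n_tables):
            y = rng.normal(size=(8, 3))
            table = pd.DataFrame(
                {
                    "subject": np.repeat(np.arange(8), 3),
                    "a": np.tile(["a0", "a1", "a2"], 8),
                    "y": y.ravel(),
                }
            )
            row = rm_anova(table, dv="y", subject="subject", within=["a"]).iloc[0]
            n_reject += row["p"] < 0.05
        rate = n_reject / n_tables
        se = np.sqrt(0.05 * 0.95 / n_tables)
        assert abs(rate - 0.05) < 4 * se
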