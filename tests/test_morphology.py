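"""Welch's t-test, group splitting and the median-position diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from urbanheat import (
    compare_all,
    median_position_diagnostic,
    split_groups,
    welch_t,
)

# Reference (t, df, p) for the fixed vectors below, computed independently
# with scipy.stats.ttest_ind(equal_var=False).
_X = [27.5, 27.9, 28.1, 28.6]
_Y = [29.1, 29.4, 30.0]
_REF = (-4.2178738679491685, 4.449017624653002, 0.01075622454292099)


class TestWelchT:
    def test_fixed_vectors_match_reference(self):
        t, df, p = welch_t(_X, _Y)
        assert t == pytest.approx(_REF[0], abs=1e-10)
        assert df == pytest.approx(_REF[1], abs=1e-10)
        assert p == pytest.approx(_REF[2], abs=1e-10)

    def test_identical_samples(self):
        t, _, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_large_separation(self):
        x = [2.1, 2.2, 2.3]
        y = [12.1, 12.2, 12.3]
        _, _, p = welch_t(x, y)
        assert p < 1e-6

    def test_matches_scipy_on_random_samples(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            x = rng.normal(0, 1, rng.integers(2, 30))
            y = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), rng.integers(2, 30))
            t, df, p = welch_t(x, y)
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert df == pytest.approx(ref.df, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_antisymmetric(self):
        rng = np.random.default_rng(13)
        x, y = rng.normal(size=8), rng.normal(0.5, 1, 11)
        t1, df1, p1 = welch_t(x, y)
        t2, df2, p2 = welch_t(y, x)
        assert t1 == -t2 and df1 == df2 and p1 == p2

    def test_zero_variance_cases(self):
        t, df, p = welch_t([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0) and math.isnan(df)
        t, _, p = welch_t([3.0, 3.0], [2.0, 2.0])
        assert math.isinf(t) and t > 0 and p == 0.0

    def test_too_small_sample_errors(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


def test_null_pvalues_are_uniform():
    """Under a true null, Welch p-values look uniform (KS at alpha 0.01)."""
    rng = np.random.default_rng(20)
    pvals = [
        welch_t(rng.normal(0, 1, 20), rng.normal(0, 1, 20))[2] for _ in range(500)
    ]
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_power_monotone_in_effect_size():
    """On matched seeds, a larger planted mean shift never lowers power."""
    effects = [0.0, 0.04, 0.08]
    rates = []
    for effect in effects:
        hits = 0
        for i in range(200):
            rng = np.random.default_rng(10_000 + i)  # matched across effects
            x = rng.normal(0.10, 0.04, 25)
            y = rng.normal(0.10 + effect, 0.04, 25)
            hits += welch_t(x, y)[2] < 0.05
        rates.append(hits / 200)
    assert rates == sorted(rates)


class TestSplitGroups:
    def test_strict_partition(self):
        df = pd.DataFrame({"mat": [28.0, 30.0, 29.0]})
        below, above = split_groups(df)
        assert len(below) == 2 and len(above) == 1  # 29.0 exactly goes below
        assert len(below) + len(above) == len(df)

    def test_all_below(self):
        below, above = split_groups(pd.DataFrame({"mat": [20.0, 21.0]}))
        assert above.empty and len(below) == 2


def _city_table(rng, n=60, effect=0.0):
    continents = rng.choice(["Africa", "Asia"], size=n)
    mat = np.where(rng.uniform(size=n) < 0.5, 31.0, 25.0)
    hot = mat > 29
    bare = rng.normal(0.10 + effect * hot, 0.04, n).clip(0, 1)
    green = rng.normal(0.2, 0.05, n).clip(0, 1)
    return pd.DataFrame(
        {"city_id": [f"c{i}" for i in range(n)], "continent": continents,
         "mat": mat, "bare_natural": bare, "green": green}
    )


class TestCompareAll:
    def test_rows_cover_strata_and_groups(self):
        rng = np.random.default_rng(14)
        out = compare_all(_city_table(rng), ["bare_natural", "green"])
        assert set(out["continent"]) == {"ALL", "Africa", "Asia"}
        assert len(out) == 3 * 2

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(15)
        out = compare_all(_city_table(rng, n=80, effect=0.08), ["bare_natural"])
        pooled = out[(out["continent"] == "ALL")].iloc[0]
        assert pooled["significant"]
        assert pooled["mean_above"] > pooled["mean_below"]

    def test_empty_stratum_emits_missing_result(self):
        df = pd.DataFrame(
            {"city_id": ["a", "b", "c"], "continent": ["Europe"] * 3,
             "mat": [20.0, 21.0, 22.0], "green": [0.1, 0.2, 0.3]}
        )
        out = compare_all(df, ["green"])
        assert (out["significant"] == False).all()  # noqa: E712
        assert out["p_value"].isna().all()
        assert (out["n_above"] == 0).all()

    def test_bh_correction_only_shrinks_flags(self):
        rng = np.random.default_rng(16)
        tbl = _city_table(rng, n=80, effect=0.08)
        raw = compare_all(tbl, ["bare_natural", "green"])
        adj = compare_all(tbl, ["bare_natural", "green"], correction="bh")
        assert set(adj[adj["significant"]].index) <= set(raw[raw["significant"]].index)


class TestMedianPositionDiagnostic:
    def test_all_ties_give_zero(self):
        df = pd.DataFrame(
            {"continent": ["Asia"] * 3, "mat": [31.0, 31.0, 31.0],
             "bare_natural": [0.2, 0.2, 0.2]}
        )
        assert median_position_diagnostic(df, "bare_natural", "above") == 0.0

    def test_counting(self):
        # 4 exceeders, 3 above the continent median computed over all cities
        df = pd.DataFrame(
            {
                "continent": ["Asia"] * 9,
                "mat": [31.0] * 4 + [20.0] * 5,
                "bare_natural": [0.9, 0.8, 0.7, 0.1, 0.3, 0.3, 0.3, 0.3, 0.3],
            }
        )
        assert median_position_diagnostic(df, "bare_natural", "above") == 0.75

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            df = _city_table(rng, n=40)
            if not (df["mat"] > 29).any():
                continue
            got = median_position_diagnostic(df, "bare_natural", "below")
            medians = df.groupby("continent")["bare_natural"].median()
            exc = df[df["mat"] > 29]
            want = sum(
                r["bare_natural"] < medians[r["continent"]] for _, r in exc.iterrows()
            ) / len(exc)
            assert got == pytest.approx(want)

    def test_no_exceeders_errors(self):
        df = pd.DataFrame({"continent": ["Asia"], "mat": [20.0], "green": [0.5]})
        with pytest.raises(ValueError, match="no exceeding"):
            median_position_diagnostic(df, "green", "above")
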