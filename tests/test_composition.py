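import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from barocomp.composition import (
    AA_INDEX,
    DegenerateComparisonError,
    compare_groups,
    group_mean,
    preference_summary,
    relative_abundance,
    significance_stars,
    welch_t,
)
from barocomp.io import AMINO_ACIDS


def welch_oracle(x, y):
    """Independent brute-force evaluation of the Welch t closed form."""
    x, y = list(map(float, x)), list(map(float, y))
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * (1.0 - stats.t.cdf(abs(t), df))
    return t, df, p


class TestRelativeAbundance:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAA", {"A": 1.0}),
            ("RRKD", {"R": 0.5, "K": 0.25, "D": 0.25}),
            ("RXK", {"R": 0.5, "K": 0.5}),  # X excluded from both counts
        ],
    )
    def test_examples(self, seq, expected):
        vec = relative_abundance(seq)
        for aa in AMINO_ACIDS:
            assert vec[AA_INDEX[aa]] == pytest.approx(expected.get(aa, 0.0))

    def test_all_ambiguous_gives_no_observation(self):
        assert relative_abundance("XXZU") is None
        assert relative_abundance("") is None

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.text(alphabet=AMINO_ACIDS + "XBZU", min_size=1, max_size=200))
    def test_sums_to_one(self, seq):
        vec = relative_abundance(seq)
        if vec is None:
            assert all(c in "XBZU" for c in seq)
        else:
            assert abs(vec.sum() - 1.0) < 1e-9


class TestGroupMean:
    def test_mean_of_two(self):
        a = relative_abundance("AAA")
        c = relative_abundance("CCC")
        m = group_mean([a, c])
        assert m[AA_INDEX["A"]] == pytest.approx(0.5)
        assert m[AA_INDEX["C"]] == pytest.approx(0.5)

    def test_identity_and_idempotence(self):
        v = relative_abundance("RRKD")
        assert np.allclose(group_mean([v]), v)
        assert np.allclose(group_mean([v] * 5), v)

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            group_mean([])


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_worked_example(self):
        t, df, p = welch_t([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.224745, abs=1e-6)
        assert df == pytest.approx(4.0, abs=1e-9)
        assert p == pytest.approx(0.288, abs=5e-3)

    def test_scale_invariance(self):
        t1, df1, p1 = welch_t([1, 2, 3], [2, 3, 5])
        t2, df2, p2 = welch_t([10, 20, 30], [20, 30, 50])
        assert (t1, df1, p1) == pytest.approx((t2, df2, p2))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            nx, ny = rng.integers(2, 12, size=2)
            x = rng.normal(size=nx)
            y = rng.normal(loc=rng.normal(), size=ny)
            t, df, p = welch_t(x, y)
            t0, df0, p0 = welch_oracle(x, y)
            assert abs(t - t0) < 1e-10
            assert abs(df - df0) < 1e-10
            assert abs(p - p0) < 1e-8

    def test_degenerate_constant_samples(self):
        t, df, p = welch_t([2, 2], [2, 2])
        assert (t, p) == (0.0, 1.0)
        with pytest.raises(DegenerateComparisonError):
            welch_t([1, 1], [2, 2])

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            welch_t([1], [2, 3])


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.5, ""),
            (0.1, ""),  # tiers are strict inequalities
            (0.05, "*"),
            (0.009, "**"),
            (0.0009, "***"),
            (0.00005, "****"),
            (0.0, "****"),
            (1.0, ""),
        ],
    )
    def test_tiers(self, p, expected):
        assert significance_stars(p) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            significance_stars(1.5)


def _random_obs(rng, n):
    raw = rng.dirichlet(np.ones(20), size=n)
    return [row for row in raw]


class TestCompareGroups:
    def test_identical_groups_all_null(self, ref):
        rng = np.random.default_rng(0)
        obs = _random_obs(rng, 5)
        comp = compare_groups(obs, obs, ref)
        assert np.allclose(comp["diff"], 0.0)
        assert np.allclose(comp["p"], 1.0)

    def test_antisymmetry_under_group_swap(self, ref):
        rng = np.random.default_rng(1)
        a, b = _random_obs(rng, 6), _random_obs(rng, 9)
        fwd = compare_groups(a, b, ref)
        rev = compare_groups(b, a, ref)
        assert np.allclose(fwd["diff"], -rev["diff"])
        assert np.allclose(fwd["t"], -rev["t"])
        assert np.allclose(fwd["p"], rev["p"])
        assert np.allclose(fwd["df"], rev["df"])

    def test_row_order_and_annotation(self, ref):
        rng = np.random.default_rng(2)
        comp = compare_groups(_random_obs(rng, 4), _random_obs(rng, 4), ref)
        assert list(comp.index) == list(ref.table_order())
        assert comp.loc["R", "class"] == "B"
        assert comp.loc["R", "rank"] == 20
        assert (comp["diff"] == comp["maa_a"] - comp["maa_b"]).all()


def _fake_comparison(ref, letters):
    """Build a comparison frame assigning a significant letter per aa, or none."""
    rows = []
    for aa in ref.table_order():
        letter = letters.get(aa, "")
        rows.append(
            {
                "aa": aa,
                "diff": {"B": 1.0, "N": -1.0}.get(letter, 0.0),
                "p": 0.01 if letter else 0.9,
            }
        )
    return pd.DataFrame(rows).set_index("aa")


class TestPreferenceSummary:
    def test_four_congruent_contexts_flagged(self, ref):
        comparisons = {
            f"c{i}": _fake_comparison(ref, {"R": "B"}) for i in range(4)
        }
        comparisons["c4"] = _fake_comparison(ref, {})
        grid = preference_summary(comparisons, ref)
        assert grid.loc["R", "consistent"]

    def test_two_congruent_contexts_not_flagged(self, ref):
        comparisons = {f"c{i}": _fake_comparison(ref, {"V": "B"}) for i in range(2)}
        comparisons.update(
            {f"d{i}": _fake_comparison(ref, {}) for i in range(4)}
        )
        grid = preference_summary(comparisons, ref)
        assert not grid.loc["V", "consistent"]

    def test_one_incongruent_context_vetoes(self, ref):
        comparisons = {f"c{i}": _fake_comparison(ref, {"I": "N"}) for i in range(5)}
        comparisons["bad"] = _fake_comparison(ref, {"I": "B"})
        grid = preference_summary(comparisons, ref)
        assert not grid.loc["I", "consistent"]

    def test_indifferent_class_never_flagged(self, ref):
        comparisons = {f"c{i}": _fake_comparison(ref, {"L": "B"}) for i in range(6)}
        grid = preference_summary(comparisons, ref)
        assert not grid.loc["L", "consistent"]

    def test_letters_recorded_per_context(self, ref):
        grid = preference_summary(
            {"ctx": _fake_comparison(ref, {"R": "B", "K": "N"})}, ref
        )
        assert grid.loc["R", "ctx"] == "B"
        assert grid.loc["K", "ctx"] == "N"
        assert grid.loc["G", "ctx"] == ""
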