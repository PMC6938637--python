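"""Rank tests, Spearman correlation, table builders.

The exact-mode implementations are cross-checked against brute-force
enumeration oracles written here from the definitions.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

from dgemric.stats import (
    CorrelationResult,
    build_tables,
    confound_analysis,
    mann_whitney,
    spearman,
    wilcoxon_signed_rank,
)

# ---------------------------------------------------------------------------
# brute-force oracles (definitions, independent of scipy)
# ---------------------------------------------------------------------------

def brute_force_mann_whitney_p(x, y):
    """Two-sided exact p by enumerating all C(n, nx) rank assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx = x.size
    ranks = rankdata(np.concatenate([x, y]))
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    n = nx + y.size
    all_ranks = np.arange(1, n + 1)
    us = []
    for combo in itertools.combinations(range(n), nx):
        u = all_ranks[list(combo)].sum() - nx * (nx + 1) / 2
        us.append(u)
    us = np.asarray(us)
    mu = us.mean()
    # two-sided: mass at least as extreme in either direction
    p = np.mean(np.abs(us - mu) >= np.abs(u_obs - mu) - 1e-9)
    return float(p)


def brute_force_wilcoxon_p(diffs):
    """Two-sided exact p by enumerating all 2^n sign patterns."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = d.size
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(ranks[np.array(signs, dtype=bool)].sum())
    ws = np.asarray(ws)
    mu = ws.mean()
    p = np.mean(np.abs(ws - mu) >= np.abs(w_obs - mu) - 1e-9)
    return float(p)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_fully_separated_pairs(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_center_of_null(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.9

    def test_exact_matches_brute_force_small_n(self):
        rng = np.random.default_rng(0)
        for nx in range(2, 7):
            for ny in range(2, 7):
                x = rng.normal(size=nx)
                y = rng.normal(0.8, size=ny)
                _, p = mann_whitney(x, y, mode="exact")
                assert p == pytest.approx(brute_force_mann_whitney_p(x, y),
                                          abs=1e-12)

    def test_exact_and_approx_agree_at_study_sizes(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=8), rng.normal(0.5, size=9)
        _, pe = mann_whitney(x, y, mode="exact")
        _, pa = mann_whitney(x, y, mode="approx")
        assert abs(pe - pa) < 0.02

    def test_empty_or_singleton_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([1.0], [2.0, 3.0])

    def test_ties_fall_back_to_approximation(self):
        u, p = mann_whitney([1, 1, 2, 3], [2, 2, 3, 4], mode="auto")
        assert 0 <= p <= 1


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

class TestWilcoxon:
    def test_three_concordant_differences(self):
        _, p = wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert p == pytest.approx(0.25)

    def test_sign_flip_symmetry(self):
        d = np.array([0.5, -1.2, 2.0, 0.8, -0.1])
        _, p1 = wilcoxon_signed_rank(d)
        _, p2 = wilcoxon_signed_rank(-d)
        assert p1 == pytest.approx(p2)

    def test_exact_matches_brute_force_small_n(self):
        rng = np.random.default_rng(2)
        for n in range(3, 7):
            d = rng.normal(0.5, 1.0, size=n)
            _, p = wilcoxon_signed_rank(d, mode="exact")
            assert p == pytest.approx(brute_force_wilcoxon_p(d), abs=1e-12)

    def test_all_zero_differences_degenerate(self):
        with pytest.warns(UserWarning, match="zero"):
            _, p = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert p == 1.0

    def test_zero_differences_dropped(self):
        _, p_with = wilcoxon_signed_rank([0.0, 1.0, 2.0, 3.0])
        _, p_without = wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert p_with == pytest.approx(p_without)

    def test_minimum_attainable_p_at_n8(self):
        # eight concordant pairs: exact two-sided p = 2 / 2^8
        _, p = wilcoxon_signed_rank(np.arange(1.0, 9.0))
        assert p == pytest.approx(2 / 256)


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_perfect_monotone(self):
        r = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert r.rho == pytest.approx(1.0)

    def test_reversal_flips_sign(self):
        r = spearman([1, 2, 3, 4], [40, 30, 20, 10])
        assert r.rho == pytest.approx(-1.0)

    def test_toy_pairs_rank_formula(self):
        # d = (-1, 1, -1, 1, 0): rho = 1 - 6*4 / (5*24) = 0.8
        r = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r.rho == pytest.approx(1 - 6 * 4 / (5 * 24))

    @pytest.mark.parametrize("n", [5, 6])
    def test_exact_permutation_p_matches_brute_force(self, n):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=n), rng.normal(size=n)
        res = spearman(x, y)
        rx, ry = rankdata(x), rankdata(y)
        rhos = [
            np.corrcoef(rx, ry[list(perm)])[0, 1]
            for perm in itertools.permutations(range(n))
        ]
        p_brute = np.mean(np.abs(rhos) >= abs(res.rho) - 1e-12)
        assert res.p_value == pytest.approx(p_brute, abs=1e-12)

    def test_constant_input_undefined(self):
        with pytest.warns(UserWarning, match="constant"):
            r = spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert np.isnan(r.rho)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [2, 1])


# ---------------------------------------------------------------------------
# invariance properties
# ---------------------------------------------------------------------------

@st.composite
def two_untied_samples(draw):
    # unique integers so monotone transforms cannot introduce ties
    pool = draw(
        st.lists(st.integers(-50, 50), min_size=8, max_size=14, unique=True)
    )
    split = draw(st.integers(3, len(pool) - 3))
    return pool[:split], pool[split:]


@settings(max_examples=25, deadline=None, derandomize=True)
@given(two_untied_samples())
def test_rank_tests_invariant_under_monotone_transform(samples):
    """Rank-based p-values depend only on the ordering of the data."""
    x, y = map(np.asarray, samples)
    transform = lambda v: np.exp(v / 25.0) * 3 + 1
    _, p_raw = mann_whitney(x, y)
    _, p_tr = mann_whitney(transform(x), transform(y))
    assert p_raw == pytest.approx(p_tr)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(-20, 20), st.integers(-20, 20)),
        min_size=4, max_size=8,
    )
)
def test_spearman_invariant_under_monotone_transform(pairs):
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return
    r1 = spearman(x, y)
    # exp is strictly monotone; the affine map preserves ties exactly
    r2 = spearman(np.exp(x / 10.0), 5 * y + 2)
    assert r1.rho == pytest.approx(r2.rho)
    assert r1.p_value == pytest.approx(r2.p_value)


# ---------------------------------------------------------------------------
# table builders
# ---------------------------------------------------------------------------

def synthetic_summary_frame(seed=0, n_ex=8, n_sed=9):
    """A tidy cohort frame with a known group structure, no imaging."""
    rng = np.random.default_rng(seed)
    rows = []
    params = {
        "exercise": {"thick": {"WB": 2.9, "NWB": 1.81}, "sup": 1100, "deep": 700,
                     "gd": 0.37},
        "sedentary": {"thick": {"WB": 1.7, "NWB": 1.54}, "sup": 1000,
                      "deep": 690, "gd": 0.39},
    }
    for group, n in (("exercise", n_ex), ("sedentary", n_sed)):
        p = params[group]
        for i in range(n):
            sid = f"{group}-{i}"
            for comp in ("medial", "lateral"):
                for seg in ("WB", "NWB"):
                    thick = p["thick"][seg] + rng.normal(0, 0.2)
                    base = {
                        "subject_id": sid, "group": group,
                        "compartment": comp, "segment": seg,
                        "thickness_mm": thick, "bmi": 22.0, "n_pixels": 50,
                    }
                    sup_t1 = p["sup"] + rng.normal(0, 60)
                    deep_t1 = p["deep"] + rng.normal(0, 60)
                    gd = p["gd"] + rng.normal(0, 0.05)
                    rows.append({**base, "layer": "full",
                                 "t1pre_ms": (sup_t1 + deep_t1) / 2,
                                 "gd_mM": gd / 2, "index_ms": 450 + 30 * thick})
                    rows.append({**base, "layer": "superficial",
                                 "t1pre_ms": sup_t1, "gd_mM": gd,
                                 "index_ms": np.nan})
                    rows.append({**base, "layer": "deep", "t1pre_ms": deep_t1,
                                 "gd_mM": gd / 4 - 0.02 * thick,
                                 "index_ms": np.nan})
    return pd.DataFrame(rows)


class TestBuildTables:
    @pytest.fixture(scope="class")
    def tables(self):
        return build_tables(synthetic_summary_frame())

    def test_table1_structure_and_group_means(self, tables):
        t1 = tables["table1"]
        assert set(t1.segment) == {"WB", "NWB"}
        row = t1[(t1.segment == "WB") & (t1.compartment == "medial")].iloc[0]
        assert row.exercise_mean == pytest.approx(2.9, abs=0.3)
        assert row.sedentary_mean == pytest.approx(1.7, abs=0.4)
        assert row.p_between_groups < 0.05

    def test_table2_between_group_and_paired_rows(self, tables):
        t2 = tables["table2"]
        between = t2[t2.layer.isin(["superficial", "deep"])]
        assert between.p_between_groups.between(0, 1).all()
        paired = t2[t2.layer == "superficial_vs_deep"]
        assert len(paired) == 2 * 2 * 2  # segment x compartment x group
        assert (paired.p_paired < 0.05).all()

    def test_table3_has_paired_segment_contrast(self, tables):
        t3 = tables["table3"]
        assert (t3[t3.segment != "NWB_vs_WB"].p_between_groups
                .between(0, 1).all())
        assert (t3[t3.segment == "NWB_vs_WB"].p_paired.between(0, 1).all())

    def test_pooled_compartment_option(self):
        tables = build_tables(synthetic_summary_frame(), pool_compartments=True)
        assert set(tables["table2"].compartment) == {"pooled"}

    def test_missing_segment_handled_pairwise_complete(self):
        df = synthetic_summary_frame()
        df = df[~((df.subject_id == "exercise-0") & (df.segment == "WB"))]
        tables = build_tables(df)
        assert not tables["table1"].empty

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            build_tables(pd.DataFrame({"subject_id": []}))


class TestConfoundAnalysis:
    def test_known_structure_recovered(self):
        res = confound_analysis(synthetic_summary_frame(seed=4))
        assert isinstance(res["rho_thickness_index"], CorrelationResult)
        assert res["rho_thickness_index"].rho > 0
        assert res["rho_thickness_index"].p_value < 0.05
        assert res["rho_thickness_gd_deep"].rho < 0

    def test_too_few_observations_rejected(self):
        df = synthetic_summary_frame(n_ex=2, n_sed=2).head(12)
        with pytest.raises(ValueError, match="observations"):
            confound_analysis(df)
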