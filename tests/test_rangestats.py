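"""Range metrics and from-formula statistics vs independent oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from pteridiv import occurrences as occ
from pteridiv import rangestats as rs
from pteridiv.errors import AbsentTaxonError, DegenerateGroupError

from conftest import make_table, make_taxon, matrix_of


# ---------------------------------------------------------------------------
# Range metrics
# ---------------------------------------------------------------------------

def test_range_summary_single_cell(tiny_table):
    m = matrix_of([("t1", "453034")], tiny_table)
    s = rs.range_summary(m, "t1")
    assert s.n_cells == 1 and s.lat_breadth == 0.0


def test_range_summary_breadth_from_centroids(tiny_table):
    m = matrix_of([("t1", "453034"), ("t1", "503547")], tiny_table)
    s = rs.range_summary(m, "t1")
    # Centroids 30.2916 and 33.7083: breadth 41/12 degrees.
    assert s.lat_breadth == pytest.approx(41 / 12, abs=1e-12)
    assert s.n_cells == 2


def test_range_summary_absent_taxon(tiny_table):
    m = matrix_of([("t1", "453034")], tiny_table)
    with pytest.raises(AbsentTaxonError):
        rs.range_summary(m, "t2")


def test_range_table_matches_scalar_summaries(tiny_table):
    m = matrix_of([("t1", "453034"), ("t1", "503547"), ("t2", "453044"),
                   ("t4", "402801"), ("t4", "362346")], tiny_table)
    table = rs.range_table(m)
    for taxon in m.taxa:
        s = rs.range_summary(m, taxon)
        row = table.loc[taxon]
        assert row["n_cells"] == s.n_cells
        assert row["lat_breadth"] == pytest.approx(s.lat_breadth)


# ---------------------------------------------------------------------------
# ANOVA / t / Tukey vs oracles
# ---------------------------------------------------------------------------

def _random_groups(rng, k, balanced=False):
    ns = [rng.integers(3, 25) for _ in range(k)] if not balanced \
        else [int(rng.integers(3, 25))] * k
    return [rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=n)
            for n in ns]


def test_anova_identical_groups_f_zero_p_one():
    g = [np.full(4, 2.5), np.full(3, 2.5), np.full(5, 2.5)]
    assert rs.one_way_anova(g) == (0.0, 1.0)


def test_anova_two_groups_equals_t_squared():
    rng = np.random.default_rng(5)
    a, b = rng.normal(0, 1, 12), rng.normal(0.4, 1, 9)
    f_stat, p_f = rs.one_way_anova([a, b])
    t_stat, p_t = rs.student_t(a, b)
    assert f_stat == pytest.approx(t_stat ** 2, rel=1e-12)
    assert p_f == pytest.approx(p_t, rel=1e-12)


def test_anova_matches_library_oracles():
    rng = np.random.default_rng(11)
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    import pandas as pd
    for _ in range(50):
        groups = _random_groups(rng, int(rng.integers(2, 6)))
        f_stat, p = rs.one_way_anova(groups)
        sp = sps.f_oneway(*groups)
        assert f_stat == pytest.approx(sp.statistic, abs=1e-10, rel=1e-10)
        assert p == pytest.approx(sp.pvalue, abs=1e-10, rel=1e-10)
    # One fixture against a second, model-based oracle.
    groups = _random_groups(rng, 3)
    long = pd.DataFrame({
        "y": np.concatenate(groups),
        "g": np.repeat([f"g{i}" for i in range(3)],
                       [len(g) for g in groups])})
    table = sm.stats.anova_lm(ols("y ~ C(g)", data=long).fit())
    f_stat, p = rs.one_way_anova(groups)
    assert f_stat == pytest.approx(table["F"].iloc[0], rel=1e-10)
    assert p == pytest.approx(table["PR(>F)"].iloc[0], abs=1e-10)


def test_anova_rejects_degenerate_groups():
    with pytest.raises(DegenerateGroupError):
        rs.one_way_anova([[1.0], [1.0, 2.0]])
    with pytest.raises(DegenerateGroupError):
        rs.one_way_anova([[1.0, 2.0]])


def test_student_t_identical_samples():
    a = np.array([1.0, 2.0, 3.0])
    assert rs.student_t(a, a.copy()) == (0.0, 1.0)


def test_student_t_sign_flips_p_unchanged():
    rng = np.random.default_rng(3)
    a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 14)
    t_ab, p_ab = rs.student_t(a, b)
    t_ba, p_ba = rs.student_t(b, a)
    assert t_ab == pytest.approx(-t_ba)
    assert p_ab == pytest.approx(p_ba)


@pytest.mark.parametrize("welch", [False, True])
def test_t_matches_scipy_oracle(welch):
    rng = np.random.default_rng(17)
    for _ in range(50):
        a, b = _random_groups(rng, 2)
        t_stat, p = rs.student_t(a, b, welch=welch)
        sp = sps.ttest_ind(a, b, equal_var=not welch)
        assert t_stat == pytest.approx(sp.statistic, abs=1e-10, rel=1e-10)
        assert p == pytest.approx(sp.pvalue, abs=1e-10, rel=1e-10)


@pytest.mark.parametrize("k, df", [(2, 5), (3, 10), (3, 497), (4, 30),
                                   (6, 100)])
def test_studentized_range_sf_matches_scipy(k, df):
    for q in (0.1, 0.5, 1.0, 2.0, 3.36, 5.0, 8.0):
        mine = rs.studentized_range_sf(q, k, df)
        ref = float(sps.studentized_range.sf(q, k, df))
        assert mine == pytest.approx(ref, abs=1e-6)


def test_tukey_two_identical_groups():
    g = [np.array([1.0, 2.0, 3.0]), np.array([2.0, 1.0, 3.0])]
    res = rs.tukey_hsd(g, labels=["x", "y"])
    assert res.pairwise["p"].iloc[0] == 1.0
    assert res.letters == ["a", "a"]


def test_tukey_three_separated_groups_three_letters():
    rng = np.random.default_rng(8)
    g = [rng.normal(0, 0.1, 20), rng.normal(5, 0.1, 20),
         rng.normal(10, 0.1, 20)]
    res = rs.tukey_hsd(g, labels=["lo", "mid", "hi"])
    assert res.pairwise["significant"].all()
    assert sorted(res.letters) == ["a", "b", "c"]


@pytest.mark.parametrize("balanced", [True, False])
def test_tukey_matches_scipy_oracle(balanced):
    rng = np.random.default_rng(23)
    for _ in range(40):
        groups = _random_groups(rng, int(rng.integers(2, 5)),
                                balanced=balanced)
        res = rs.tukey_hsd(groups)
        ref = sps.tukey_hsd(*groups)
        for row_idx, row in res.pairwise.iterrows():
            i = res.labels.index(row["group_a"])
            j = res.labels.index(row["group_b"])
            assert row["p"] == pytest.approx(ref.pvalue[i, j], abs=1e-6)


def test_compact_letters_partial_overlap():
    # Only the extreme pair differs: middle group shares both letters.
    letters = rs.compact_letters(3, [(0, 2)])
    assert letters[0] != letters[2]
    assert set(letters[1]) == set(letters[0]) | set(letters[2])
    assert rs.compact_letters(3, []) == ["a", "a", "a"]
    assert rs.compact_letters(3, [(0, 1), (0, 2), (1, 2)]) \
        == ["a", "b", "c"]


# ---------------------------------------------------------------------------
# Trait comparisons
# ---------------------------------------------------------------------------

def _trait_fixture():
    rows, pairs = [], []
    rng = np.random.default_rng(42)
    lat_units = np.arange(24 * 12, 46 * 12)
    specs = [("sexual", 40, 8.0), ("apomictic", 30, 4.0), ("both", 6, 8.0)]
    idx = 0
    for mode, n, breadth in specs:
        for _ in range(n):
            idx += 1
            tid = f"x{idx:03d}"
            rows.append(make_taxon(
                tid, reproductive_mode=mode,
                ploidy_class="diploid" if mode == "sexual" else "unknown"))
            center = rng.uniform(30, 40)
            band = lat_units[(lat_units / 12 >= center - breadth / 2)
                             & (lat_units / 12 <= center + breadth / 2)]
            chosen = rng.choice(band, size=min(8, len(band)), replace=False)
            for u in chosen:
                lat_idx, row = divmod(int(u), 8)
                pairs.append((tid, f"{lat_idx:02d}40{row}0"))
    return make_table(rows), pairs


def test_compare_by_trait_three_mode_groups():
    table, pairs = _trait_fixture()
    m = matrix_of(pairs, table)
    res = rs.compare_by_trait(m, table, metric="lat_breadth",
                              trait="reproductive_mode")
    assert res.test == "anova+tukey"
    assert list(res.groups["group"]) == ["sexual", "apomictic", "both"]
    assert res.groups["n"].sum() == 76
    assert res.pairwise is not None and len(res.pairwise) == 3
    assert len(res.letters) == 3
    # Sample sd uses n-1; check one group against numpy directly.
    assert res.groups["sd"].iloc[0] > 0


def test_compare_by_trait_excludes_hybrids_and_unknowns(tiny_table):
    pairs = [("t1", "453034"), ("t1", "453044"), ("t2", "453034"),
             ("t2", "503547"), ("t6", "453034"), ("t6", "453044"),
             ("h1", "453034"), ("h1", "503547")]
    m = matrix_of(pairs, tiny_table)
    with pytest.warns(UserWarning):
        # 'both' has a single taxon at most -> dropped with warning; the
        # unknown-mode t6 and hybrid h1 never enter any group.
        with pytest.raises(DegenerateGroupError):
            rs.compare_by_trait(m, tiny_table, metric="n_cells",
                                trait="reproductive_mode")


def test_compare_by_trait_ploidy_restricted_to_sexual():
    rows = [make_taxon(f"d{i}", ploidy_class="diploid") for i in range(4)]
    rows += [make_taxon(f"p{i}", ploidy_class="polyploid")
             for i in range(4)]
    # An apomictic polyploid must not leak into the ploidy comparison.
    rows.append(make_taxon("apo", reproductive_mode="apomictic",
                           ploidy_class="polyploid"))
    table = make_table(rows)
    pairs = [(r["taxon_id"], code) for r in rows
             for code in ("453034", "503547")]
    m = matrix_of(pairs, table)
    res = rs.compare_by_trait(m, table, metric="n_cells",
                              trait="ploidy_class")
    assert res.test == "student_t"
    assert res.n_analysed == 8


def test_compare_by_trait_two_group_letters_reflect_significance():
    rows = [make_taxon(f"e{i}", phenology="evergreen") for i in range(10)]
    rows += [make_taxon(f"s{i}", phenology="seasonal_green")
             for i in range(10)]
    table = make_table(rows)
    pairs = []
    # Evergreen taxa occupy 2 cells, seasonal 12: a strong n_cells effect.
    codes = [f"45{30 + j:02d}00" for j in range(12)]
    for r in rows:
        k = 2 if r["phenology"] == "evergreen" else 12
        pairs += [(r["taxon_id"], c) for c in codes[:k]]
    m = matrix_of(pairs, table)
    res = rs.compare_by_trait(m, table, metric="n_cells",
                              trait="phenology")
    assert res.p_value < 1e-6
    assert res.letters == ["a", "b"]


def test_group_stats_invariant_to_taxon_order():
    table, pairs = _trait_fixture()
    m1 = matrix_of(pairs, table)
    m2 = matrix_of(list(reversed(pairs)), table)
    r1 = rs.compare_by_trait(m1, table, metric="lat_breadth",
                             trait="reproductive_mode")
    r2 = rs.compare_by_trait(m2, table, metric="lat_breadth",
                             trait="reproductive_mode")
    assert r1.groups.equals(r2.groups)
    assert r1.p_value == pytest.approx(r2.p_value)
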