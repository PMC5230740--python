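"""Introduction-history analyses: censoring, quartiles, nulls, realm/GDP."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from shapely.geometry import box

import alienrich as ar
from alienrich.core import (IntroductionRecord, PROVENANCE_CONSERVATION,
                            RangeMap)
from conftest import make_records


class TestCensorRecords:
    def test_window_status_and_provenance_rules(self):
        raw = make_records(["A", "B", "C", "D", "E"],
                           years=[1499, 1500, 2000, 2001, None])
        kept = ar.censor_records(raw)
        assert [r.country_id for r in kept] == ["B", "C"]

    def test_first_record_per_species_country_kept(self):
        raw = make_records(["A", "A"], years=[1900, 1850],
                           species=["s", "s"])
        kept = ar.censor_records(raw)
        assert len(kept) == 1 and kept[0].year == 1850

    def test_conservation_translocations_excluded_by_count(self):
        raw = make_records([f"C{i}" for i in range(93)],
                           years=[1600 + i for i in range(93)])
        raw += make_records([f"X{i}" for i in range(7)],
                            years=[1700] * 7,
                            species=[f"t{i}" for i in range(7)],
                            provenance=PROVENANCE_CONSERVATION)
        assert len(ar.censor_records(raw)) == 93

    def test_unknown_status_excluded_from_dated_set(self):
        raw = make_records(["A", "B"], years=[1900, 1901], status=6)
        assert ar.censor_records(raw) == []


class TestSplitQuartiles:
    def test_distinct_years_split_evenly(self):
        recs = make_records(list("ABCDEFGH"),
                            years=[1510, 1600, 1700, 1800, 1850, 1900,
                                   1950, 2000])
        s = ar.split_quartiles(recs)
        assert s.sizes == [2, 2, 2, 2]

    def test_boundary_year_block_stays_together(self):
        # 20 early records, then 40 sharing the year at the first boundary
        years = [1500 + i for i in range(20)] + [1700] * 40 \
            + [1800 + i for i in range(40)]
        recs = make_records([f"C{i}" for i in range(100)], years=years)
        s = ar.split_quartiles(recs)
        counts = [sum(1 for r in q if r.year == 1700) for q in s.quartiles]
        assert sorted(counts) == [0, 0, 0, 40]
        # snapping rule: cut after the block (rank 60) is as close to the
        # ideal rank 25 as any cut can be without splitting the year
        assert s.sizes[0] in (20, 60)

    def test_union_preserved_and_spans_ordered(self):
        rng = np.random.default_rng(5)
        years = rng.integers(1500, 2001, size=237).tolist()
        recs = make_records([f"C{i}" for i in range(237)], years=years)
        s = ar.split_quartiles(recs)
        assert sum(s.sizes) == 237
        for (a, b), (c, d) in zip(s.spans[:-1], s.spans[1:]):
            assert b < c

    def test_too_few_records_error(self):
        with pytest.raises(ValueError):
            ar.split_quartiles(make_records(["A", "B"], years=[1600, 1700]))


class TestColonisationPressure:
    def test_counts_and_totals(self):
        recs = make_records(["A", "A", "B"], years=[1600, 1700, 1800],
                            species=["s1", "s2", "s1"])
        table, totals = ar.country_colonisation_pressure(recs)
        assert totals == {"n_species": 2, "n_countries": 2, "n_records": 3}
        assert table.set_index("country_id").loc["A", "n_records"] == 2

    def test_empty_input(self):
        table, totals = ar.country_colonisation_pressure([])
        assert table.empty
        assert totals == {"n_species": 0, "n_countries": 0, "n_records": 0}


class TestNullCountryCount:
    def test_matches_exhaustive_enumeration(self):
        """Empirical null pmf agrees with brute force over all C(6,2) draws."""
        recs = make_records(["A", "A", "B", "B", "C", "C"],
                            years=[1600] * 6)
        exact = {}
        for pair in itertools.combinations(range(6), 2):
            k = len({recs[i].country_id for i in pair})
            exact[k] = exact.get(k, 0) + 1
        exact = {k: v / 15 for k, v in exact.items()}
        null = ar.null_country_count(recs, recs[:2], iterations=20_000,
                                     seed=1)
        emp = pd.Series(null.draws).value_counts(normalize=True)
        for k, p in exact.items():
            assert emp.get(k, 0.0) == pytest.approx(p, abs=0.02)

    def test_full_draw_degenerate(self):
        recs = make_records(["A", "B", "C"], years=[1600, 1700, 1800])
        null = ar.null_country_count(recs, recs, iterations=500, seed=0)
        assert null.p_value == 1.0
        assert (null.draws == 3).all()
        assert not null.significant

    def test_draws_bounded_by_country_count(self):
        recs = make_records(["A", "B", "A", "B", "C"], years=[1600] * 5)
        null = ar.null_country_count(recs, recs[:3], iterations=300, seed=2)
        assert null.draws.min() >= 1
        assert null.draws.max() <= 3

    def test_overdraw_raises(self):
        recs = make_records(["A", "B"], years=[1600, 1700])
        with pytest.raises(ValueError):
            ar.null_country_count(recs, recs, n_draw=5, iterations=10, seed=0)


class TestNullCountryOverlap:
    def test_identical_full_eras_degenerate(self):
        recs = make_records(["A", "B", "C", "A"], years=[1600] * 4,
                            species=list("wxyz"))
        null = ar.null_country_overlap(recs, recs, recs, iterations=200,
                                       seed=0)
        assert (null.draws == 3).all()
        assert null.p_value == 1.0

    def test_matches_exhaustive_paired_enumeration(self):
        recs = make_records(["A", "A", "B", "C", "C"], years=[1600] * 5,
                            species=list("vwxyz"))
        exact = {}
        total = 0
        for pa in itertools.combinations(range(5), 2):
            for pb in itertools.combinations(range(5), 2):
                k = len({recs[i].country_id for i in pa}
                        & {recs[i].country_id for i in pb})
                exact[k] = exact.get(k, 0) + 1
                total += 1
        exact = {k: v / total for k, v in exact.items()}
        null = ar.null_country_overlap(recs, recs[:2], recs[:2],
                                       iterations=20_000, seed=3)
        emp = pd.Series(null.draws).value_counts(normalize=True)
        for k, p in exact.items():
            assert emp.get(k, 0.0) == pytest.approx(p, abs=0.02)


class TestFamilyTest:
    def test_hypergeometric_toy(self):
        """Two equal families of 5; all 5 introductions from family A."""
        avif = pd.DataFrame({"species": [f"s{i}" for i in range(10)],
                             "family": ["A"] * 5 + ["B"] * 5})
        res = ar.null_family_counts([f"s{i}" for i in range(5)], avif,
                                    iterations=20_000, seed=4)
        row = res.table.set_index("family_id").loc["A"]
        exact = 1.0 / 252.0  # P(X >= 5) hypergeometric
        assert row["p_over"] == pytest.approx(exact, abs=0.003)
        assert row["direction"] == "over"

    def test_drawing_entire_avifauna_degenerate(self):
        avif = pd.DataFrame({"species": list("abcdef"),
                             "family": ["F1"] * 3 + ["F2"] * 3})
        res = ar.null_family_counts(list("abcdef"), avif, iterations=500,
                                    seed=0)
        assert (res.table["Psim"] == 1.0).all()
        assert not res.table["significant"].any()

    def test_unknown_species_rejected(self):
        avif = pd.DataFrame({"species": ["a"], "family": ["F"]})
        with pytest.raises(ValueError, match="ghost"):
            ar.null_family_counts(["ghost"], avif, iterations=10, seed=0)

    def test_sequential_bonferroni_never_flags_more_than_uncorrected(self):
        rng = np.random.default_rng(7)
        avif = pd.DataFrame({
            "species": [f"s{i}" for i in range(120)],
            "family": [f"F{i % 6}" for i in range(120)]})
        intro = rng.choice(avif["species"], size=30, replace=False)
        res = ar.null_family_counts(list(intro), avif, iterations=2000,
                                    seed=8)
        uncorrected = (res.table["Psim"] <= res.alpha / 2).sum()
        assert res.table["significant"].sum() <= uncorrected

    def test_clumped_families_flagged(self):
        """Dirichlet-clumped introductions over-represent heavy families."""
        rng = np.random.default_rng(9)
        avif = pd.DataFrame({"species": [f"s{i}" for i in range(200)],
                             "family": [f"F{i % 10}" for i in range(200)]})
        members = {f: g["species"].to_list()
                   for f, g in avif.groupby("family")}
        hits = 0
        n_seeds = 10
        for s in range(n_seeds):
            r = np.random.default_rng(100 + s)
            w = r.dirichlet(np.full(10, 0.3))
            intro = set()
            while len(intro) < 50:
                fam = f"F{r.choice(10, p=w)}"
                intro.add(members[fam][r.integers(20)])
            res = ar.null_family_counts(sorted(intro), avif,
                                        iterations=2000, seed=s)
            over = res.table.loc[res.table["significant"]
                                 & (res.table["direction"] == "over")]
            hits += len(over) > 0
        assert hits >= 9


class TestRealmAssignment:
    def test_majority_realm_selected(self):
        realms = {"X": box(0, 0, 10, 10), "Y": box(10, 0, 20, 10)}
        rm = RangeMap("sp", "native", geometry=box(3, 0, 13, 10),
                      crs="behrmann")
        assert ar.assign_native_realm(rm, realms) == "X"

    def test_exact_tie_excluded(self):
        realms = {"X": box(0, 0, 10, 10), "Y": box(10, 0, 20, 10)}
        rm = RangeMap("sp", "native", geometry=box(5, 0, 15, 10),
                      crs="behrmann")
        assert ar.assign_native_realm(rm, realms) is ar.EXCLUDED_TIE

    def test_multipolygon_area_sums(self):
        realms = {"X": box(0, 0, 10, 10), "Y": box(10, 0, 20, 10),
                  "Z": box(20, 0, 30, 10)}
        geom = box(6, 0, 10, 10).union(box(10, 0, 13.5, 10)).union(
            box(20, 0, 22.5, 10))  # 40 / 35 / 25
        rm = RangeMap("sp", "native", geometry=geom, crs="behrmann")
        assert ar.assign_native_realm(rm, realms) == "X"

    def test_disjoint_range_errors(self):
        realms = {"X": box(0, 0, 1, 1)}
        rm = RangeMap("sp", "native", geometry=box(5, 5, 6, 6),
                      crs="behrmann")
        with pytest.raises(ValueError, match="sp"):
            ar.assign_native_realm(rm, realms)

    def test_cell_set_mode(self):
        realms = {"X": {0, 1, 2}, "Y": {3, 4}}
        rm = RangeMap("sp", "native", cells={0, 1, 3})
        assert ar.assign_native_realm(rm, realms) == "X"


class TestRealmChisq:
    def test_hand_computed_two_by_two(self):
        chi2, p = ar.realm_chisq([10, 0], [0, 10], replicates=2000, seed=0)
        assert chi2 == pytest.approx(20.0)
        assert p < 0.01

    def test_identical_proportions(self):
        chi2, p = ar.realm_chisq([10, 20, 30], [20, 40, 60],
                                 replicates=2000, seed=1)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p > 0.9

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            ar.realm_chisq([0, 0], [0, 0])

    def test_simulated_p_tracks_asymptotic(self):
        rng = np.random.default_rng(11)
        h = rng.integers(5, 60, size=7)
        m = rng.integers(5, 60, size=7)
        chi2, p_sim = ar.realm_chisq(h, m, replicates=4000, seed=2)
        p_asym = stats.chi2_contingency(np.vstack([h, m]),
                                        correction=False)[1]
        assert p_sim == pytest.approx(p_asym, abs=0.05)


class TestColonialTest:
    def test_rank_sum_matches_exact_enumeration(self):
        counts = {"A": 1, "B": 2, "C": 3, "D": 4, "E": 5, "F": 6}
        flags = {"A": True, "B": True, "C": True,
                 "D": False, "E": False, "F": False}
        W, p = ar.colonial_test(counts, flags)
        # U statistic of the colonial group {1,2,3} vs {4,5,6} is 0
        assert W == 0.0

    def test_symmetric_groups_high_p(self):
        counts = {c: v for c, v in zip("ABCDEF", [1, 5, 9, 2, 6, 10])}
        flags = {c: c in "ABC" for c in "ABCDEF"}
        _, p = ar.colonial_test(counts, flags)
        assert p > 0.5

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            ar.colonial_test({"A": 1}, {"A": True})

    def test_zero_fill_mode_adds_countries(self):
        counts = {"A": 3}
        flags = {"A": True, "B": False, "C": False}
        W, _ = ar.colonial_test(counts, flags, include_missing_as_zero=True)
        assert W == 2.0  # 3 beats both zeros


class TestGdpRegression:
    def test_matches_closed_form_ols(self):
        counts = {"A": 3, "B": 10, "C": 1, "D": 7, "E": 0}
        gdp = {"A": 1000.0, "B": 9000.0, "C": 400.0, "D": 5000.0,
               "E": 200.0}
        res = ar.gdp_regression(counts, gdp)
        x = np.log1p([gdp[c] for c in counts])
        y = np.log1p([counts[c] for c in counts])
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        assert res.slope == pytest.approx(slope, rel=1e-10)
        sse = ((y - (y.mean() + slope * (x - x.mean()))) ** 2).sum()
        sst = ((y - y.mean()) ** 2).sum()
        f = (sst - sse) / (sse / (len(x) - 2))
        assert res.f_statistic == pytest.approx(f, rel=1e-10)
        assert res.n == 5 and res.df == (1, 3)

    def test_perfect_fit_adj_r2_one(self):
        gdp = {c: g for c, g in zip("ABCD", [100.0, 500.0, 2000.0, 9000.0])}
        counts = {c: np.expm1(0.5 * np.log1p(g)) for c, g in gdp.items()}
        res = ar.gdp_regression(counts, gdp)
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-10)

    def test_missing_gdp_dropped_and_min_n(self):
        with pytest.raises(ValueError):
            ar.gdp_regression({"A": 1, "B": 2, "C": 3},
                              {"A": 10.0, "B": None, "C": None})

    def test_not_scale_invariant_through_log1p(self):
        counts = {c: v for c, v in zip("ABCDE", [1, 4, 9, 16, 25])}
        gdp = {c: float(g) for c, g in zip("ABCDE",
                                           [100, 400, 900, 1600, 2500])}
        r1 = ar.gdp_regression(counts, gdp)
        r2 = ar.gdp_regression(counts, {c: g * 1000 for c, g in gdp.items()})
        assert r1.slope != pytest.approx(r2.slope, rel=1e-3)
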