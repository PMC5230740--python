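"""Who, where and when of alien bird introductions.

Analyses of the first-record table: censoring to the 1500-2000 analysis
window, the date-quartile split, country-level colonisation pressure, the
bespoke randomization nulls (number of receiving countries, between-era
country overlap, per-family introduction counts with a sequential Bonferroni
correction), realm-of-origin assignment and chi-squared shift test, and the
colonial / GDP analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .core import (IntroductionRecord, KNOWN_OUTCOME_STATUSES,
                   PROVENANCE_INTRODUCTION)

logger = logging.getLogger(__name__)

#: sentinel for species whose native range ties across realms
EXCLUDED_TIE = "EXCLUDED_TIE"

YEAR_MIN = 1500
YEAR_MAX = 2000


# ---------------------------------------------------------------------------
# censoring and quartiles
# ---------------------------------------------------------------------------

def censor_records(raw, year_min: int = YEAR_MIN, year_max: int = YEAR_MAX):
    """Reduce raw records to the dated analysis set.

    Keeps human introductions (not natural colonisations or conservation
    translocations) with a known outcome (statuses 1-5) dated within
    [year_min, year_max], and collapses to the first record per
    (species, country).  Exclusion counts are logged, not raised.
    """
    counts = {"no_year": 0, "out_of_window": 0, "bad_status": 0,
              "provenance": 0, "duplicate": 0}
    first: dict[tuple, IntroductionRecord] = {}
    order: list[tuple] = []
    for rec in raw:
        if rec.provenance != PROVENANCE_INTRODUCTION:
            counts["provenance"] += 1
            continue
        if rec.year is None:
            counts["no_year"] += 1
            continue
        if not (year_min <= rec.year <= year_max):
            counts["out_of_window"] += 1
            continue
        if rec.status not in KNOWN_OUTCOME_STATUSES:
            counts["bad_status"] += 1
            continue
        key = (rec.species_id, rec.country_id)
        prev = first.get(key)
        if prev is None:
            first[key] = rec
            order.append(key)
        elif rec.year < prev.year:
            first[key] = rec
            counts["duplicate"] += 1
        else:
            counts["duplicate"] += 1
    logger.info("censor_records exclusions: %s", counts)
    return [first[k] for k in order]


@dataclass
class QuartileSplit:
    quartiles: list
    spans: list  # (min_year, max_year) per quartile
    boundaries: list  # cumulative cut ranks

    @property
    def sizes(self):
        return [len(q) for q in self.quartiles]


def split_quartiles(records) -> QuartileSplit:
    """Split dated records into four date quartiles with year-level snapping.

    Records are stably sorted by year and cut near ranks n/4, n/2 and 3n/4;
    all records sharing a boundary year fall into the same quartile.  The
    shared-year block goes to the earlier quartile when that leaves the cut
    closer to the ideal rank, otherwise to the later (ties favour the
    earlier quartile).  Quartile date spans are therefore contiguous and
    non-overlapping.
    """
    records = list(records)
    n = len(records)
    if n < 4:
        raise ValueError("need at least 4 dated records to form quartiles")
    if any(r.year is None for r in records):
        raise ValueError("all records must be dated")
    order = np.argsort([r.year for r in records], kind="stable")
    recs = [records[i] for i in order]
    years = np.array([r.year for r in recs])

    cuts = []
    prev = 0
    for q in (1, 2, 3):
        target = q * n / 4.0
        # year group containing the target rank
        idx = min(int(np.ceil(target)) - 1, n - 1)
        idx = max(idx, prev)
        y = years[idx]
        lo = int(np.searchsorted(years, y, side="left"))
        hi = int(np.searchsorted(years, y, side="right"))
        lo = max(lo, prev)
        # cut after the shared-year block (earlier quartile takes it) or
        # before it, whichever lands closer to the ideal rank
        cut = hi if abs(hi - target) <= abs(lo - target) else lo
        cut = min(max(cut, prev + 1), n - (3 - q))
        cuts.append(cut)
        prev = cut

    edges = [0, *cuts, n]
    quartiles = [recs[a:b] for a, b in zip(edges[:-1], edges[1:])]
    spans = [(int(min(r.year for r in q)), int(max(r.year for r in q)))
             for q in quartiles]
    return QuartileSplit(quartiles=quartiles, spans=spans, boundaries=cuts)


def country_colonisation_pressure(records):
    """Per-country introduction counts plus era totals.

    Because the analysis set keeps one record per (species, country), the
    species count per country equals its record count.  Returns the
    per-country table and totals over the era (distinct species, distinct
    countries, records).
    """
    records = list(records)
    rows: dict[str, int] = {}
    species = set()
    for r in records:
        rows[r.country_id] = rows.get(r.country_id, 0) + 1
        species.add(r.species_id)
    table = pd.DataFrame(
        {"country_id": list(rows.keys()),
         "n_species": list(rows.values()),
         "n_records": list(rows.values())}
    ).sort_values("country_id").reset_index(drop=True)
    totals = {"n_species": len(species), "n_countries": len(rows),
              "n_records": len(records)}
    return table, totals


# ---------------------------------------------------------------------------
# randomization nulls
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    statistic_name: str
    observed: float
    draws: np.ndarray
    quantiles: tuple  # (2.5%, 50%, 97.5%)
    p_value: float
    iterations: int
    seed: int | None
    significant: bool = field(init=False)

    def __post_init__(self):
        self.significant = bool(self.observed < self.quantiles[0]
                                or self.observed > self.quantiles[2])

    def to_dict(self):
        return {"statistic": self.statistic_name,
                "observed": float(self.observed),
                "expected_median": float(self.quantiles[1]),
                "range_2.5": float(self.quantiles[0]),
                "range_97.5": float(self.quantiles[2]),
                "p_value": float(self.p_value),
                "iterations": int(self.iterations),
                "seed": self.seed, "significant": self.significant}


def _two_tailed_p(draws: np.ndarray, observed: float) -> float:
    """+1-corrected two-tailed Monte-Carlo p (doubled smaller tail, capped)."""
    m = len(draws)
    lo = int(np.sum(draws <= observed))
    hi = int(np.sum(draws >= observed))
    p = (1 + 2 * min(lo, hi)) / (m + 1)
    return min(p, 1.0)


def _finish_null(name, observed, draws, iterations, seed) -> NullDistribution:
    q = tuple(np.quantile(draws, [0.025, 0.5, 0.975]))
    return NullDistribution(
        statistic_name=name, observed=float(observed),
        draws=np.asarray(draws), quantiles=q,
        p_value=_two_tailed_p(np.asarray(draws), observed),
        iterations=iterations, seed=seed)


def _draw_matrix(rng, n_pop: int, n_draw: int, iterations: int) -> np.ndarray:
    """iterations x n_draw indices, each row a without-replacement sample."""
    keys = rng.random((iterations, n_pop))
    return np.argpartition(keys, n_draw - 1, axis=1)[:, :n_draw]


def _distinct_counts(codes: np.ndarray, idx: np.ndarray) -> np.ndarray:
    sel = np.sort(codes[idx], axis=1)
    return 1 + (np.diff(sel, axis=1) != 0).sum(axis=1)


def null_country_count(all_records, era_records, n_draw: int | None = None,
                       iterations: int = 10_000, seed: int | None = None,
                       statistic: str = "countries") -> NullDistribution:
    """Null for the number of distinct receiving countries (or species).

    Each iteration samples ``n_draw`` records at random without replacement
    from the full censored set and counts the distinct country units (or
    species).  The observed value is the count in the actual era subset and
    is judged significant when outside the [2.5%, 97.5%] quantiles.
    """
    all_records = list(all_records)
    era_records = list(era_records)
    if n_draw is None:
        n_draw = len(era_records)
    if n_draw > len(all_records):
        raise ValueError("cannot draw more records than the population holds")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    key = "country_id" if statistic == "countries" else "species_id"
    labels = pd.factorize(np.asarray([getattr(r, key) for r in all_records]))[0]
    observed = len({getattr(r, key) for r in era_records})
    rng = np.random.default_rng(seed)
    idx = _draw_matrix(rng, len(all_records), n_draw, iterations)
    draws = _distinct_counts(labels, idx)
    return _finish_null(f"n_{statistic}", observed, draws, iterations, seed)


def null_country_overlap(all_records, era_a, era_b,
                         n_draw_a: int | None = None,
                         n_draw_b: int | None = None,
                         iterations: int = 10_000, seed: int | None = None,
                         disjoint: bool = False) -> NullDistribution:
    """Null for the between-era overlap in receiving countries.

    Per iteration two random record subsets are drawn (independently by
    default; ``disjoint=True`` forces them not to share records) and the
    number of shared countries recorded; the pairs are matched by iteration
    index.  Observed = overlap between the real era country sets.
    """
    all_records = list(all_records)
    era_a, era_b = list(era_a), list(era_b)
    n_a = len(era_a) if n_draw_a is None else n_draw_a
    n_b = len(era_b) if n_draw_b is None else n_draw_b
    N = len(all_records)
    if n_a > N or n_b > N or (disjoint and n_a + n_b > N):
        raise ValueError("draw sizes exceed the record population")
    codes = pd.factorize(np.asarray([r.country_id for r in all_records]))[0]
    n_c = codes.max() + 1
    observed = len({r.country_id for r in era_a}
                   & {r.country_id for r in era_b})
    rng = np.random.default_rng(seed)
    draws = np.empty(iterations, dtype=int)
    for it in range(iterations):
        if disjoint:
            perm = rng.permutation(N)
            ia, ib = perm[:n_a], perm[n_a:n_a + n_b]
        else:
            ia = rng.choice(N, size=n_a, replace=False)
            ib = rng.choice(N, size=n_b, replace=False)
        seen_a = np.zeros(n_c, dtype=bool)
        seen_b = np.zeros(n_c, dtype=bool)
        seen_a[codes[ia]] = True
        seen_b[codes[ib]] = True
        draws[it] = int(np.sum(seen_a & seen_b))
    return _finish_null("country_overlap", observed, draws, iterations, seed)


# ---------------------------------------------------------------------------
# family over/under-representation with sequential Bonferroni
# ---------------------------------------------------------------------------

@dataclass
class FamilyTestResult:
    table: pd.DataFrame  # per family: observed, expected stats, Psim, flags
    alpha: float
    iterations: int
    seed: int | None

    @property
    def significant_families(self):
        return list(self.table.loc[self.table["significant"], "family_id"])


def null_family_counts(introduced_species, avifauna: pd.DataFrame,
                       n_draw: int | None = None, iterations: int = 10_000,
                       seed: int | None = None,
                       alpha: float = 0.05) -> FamilyTestResult:
    """Are the introduced species a random draw from the global avifauna?

    Each iteration draws ``n_draw`` species without replacement from the
    avifauna and counts the draws per family; speciose families are expected
    to contribute more species by chance.  Per family the Monte-Carlo tail
    probability Psim is the +1-corrected probability of a count as or more
    extreme than observed (the smaller of the two tails; the direction is
    reported).  Significance applies a sequential Bonferroni over families
    ordered by Psim: at step k the threshold is beta_k / 2 with
    beta_k = alpha / (m - k + 1), halved because the test is two-sided.
    """
    avifauna = avifauna.reset_index(drop=True)
    introduced = list(introduced_species)
    pool = set(avifauna["species"])
    missing = sorted(set(introduced) - pool)
    if missing:
        raise ValueError(f"species absent from the avifauna: {missing[:10]}")
    if n_draw is None:
        n_draw = len(set(introduced))
    if n_draw > len(avifauna):
        raise ValueError("cannot draw more species than the avifauna holds")

    fam_codes, fam_labels = pd.factorize(avifauna["family"])
    m = len(fam_labels)
    sp_to_fam = dict(zip(avifauna["species"], fam_codes))
    observed = np.zeros(m, dtype=int)
    for sp in set(introduced):
        observed[sp_to_fam[sp]] += 1

    rng = np.random.default_rng(seed)
    N = len(avifauna)
    ge = np.zeros(m, dtype=int)  # draws >= observed
    le = np.zeros(m, dtype=int)  # draws <= observed
    mean = np.zeros(m)
    block = max(1, min(iterations, int(2e7 // max(N, 1))))
    done = 0
    while done < iterations:
        b = min(block, iterations - done)
        idx = _draw_matrix(rng, N, n_draw, b)
        counts = np.zeros((b, m), dtype=int)
        flat = fam_codes[idx]
        for r in range(b):
            counts[r] = np.bincount(flat[r], minlength=m)
        ge += (counts >= observed).sum(axis=0)
        le += (counts <= observed).sum(axis=0)
        mean += counts.sum(axis=0)
        done += b
    mean /= iterations

    p_over = (1 + ge) / (iterations + 1)
    p_under = (1 + le) / (iterations + 1)
    psim = np.minimum(p_over, p_under)
    direction = np.where(p_over <= p_under, "over", "under")

    table = pd.DataFrame({
        "family_id": fam_labels, "family_size": np.bincount(fam_codes,
                                                            minlength=m),
        "observed": observed, "expected_mean": mean,
        "p_over": p_over, "p_under": p_under, "Psim": psim,
        "direction": direction,
    }).sort_values("Psim", kind="stable").reset_index(drop=True)

    k = np.arange(1, m + 1)
    beta = alpha / (m - k + 1)
    table["bonferroni_threshold"] = beta / 2.0
    sig = table["Psim"].to_numpy() <= beta / 2.0
    # sequential: stop at the first non-significant ordered Psim
    stop = np.argmin(sig) if not sig.all() else m
    sig[stop:] = False
    table["significant"] = sig
    return FamilyTestResult(table=table, alpha=alpha, iterations=iterations,
                            seed=seed)


# ---------------------------------------------------------------------------
# realm of origin
# ---------------------------------------------------------------------------

def assign_native_realm(native_range, realms, grid=None, rtol: float = 1e-9):
    """Realm holding the largest share of a species' native range.

    ``realms`` maps realm label to a shapely geometry (or, for cell-set
    ranges, to a set of cell ids).  An exact tie across realms (relative
    tolerance ``rtol`` on area fractions) excludes the species; a range
    disjoint from every realm is an error.
    """
    if native_range.cells is not None:
        areas = {lab: len(set(native_range.cells) & set(cells))
                 for lab, cells in realms.items()}
    else:
        geom = native_range.geometry
        if not geom.is_valid:
            raise ValueError(
                f"native range of {native_range.species_id} is invalid")
        areas = {lab: geom.intersection(g).area for lab, g in realms.items()}
    total = sum(areas.values())
    if total <= 0:
        raise ValueError(
            f"native range of {native_range.species_id} does not intersect "
            "any realm")
    items = sorted(areas.items())  # deterministic label order
    best_label, best = max(items, key=lambda kv: kv[1])
    ties = [lab for lab, a in items
            if lab != best_label and np.isclose(a, best, rtol=rtol, atol=0)]
    if ties:
        return EXCLUDED_TIE
    return best_label


def realm_chisq(hist_counts, modern_counts, replicates: int = 2000,
                seed: int | None = None):
    """Pearson chi-squared for a shift in realm of origin between eras.

    The p-value is Monte-Carlo: era labels are permuted over the pooled
    species, which preserves both margins of the 2 x k table.
    """
    hist = np.asarray(hist_counts, dtype=int)
    modern = np.asarray(modern_counts, dtype=int)
    if hist.shape != modern.shape:
        raise ValueError("count vectors must have equal length")
    if hist.sum() + modern.sum() == 0:
        raise ValueError("zero total count")
    obs = np.vstack([hist, modern])
    chi2 = float(stats.chi2_contingency(obs, correction=False)[0])

    col = hist + modern
    n_hist = hist.sum()
    pool = np.repeat(np.arange(len(col)), col)
    row_tot = np.array([n_hist, modern.sum()])
    expected = np.outer(row_tot, col) / (row_tot.sum())
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(replicates):
        lab = rng.permutation(pool)[:n_hist]
        h = np.bincount(lab, minlength=len(col))
        tab = np.vstack([h, col - h])
        c = ((tab - expected) ** 2 / np.where(expected > 0, expected, 1)).sum()
        if c >= chi2 - 1e-12:
            exceed += 1
    p = (1 + exceed) / (replicates + 1)
    return chi2, p


# ---------------------------------------------------------------------------
# colonial and GDP analyses
# ---------------------------------------------------------------------------

def colonial_test(counts_by_country: dict, colony_flags: dict,
                  include_missing_as_zero: bool = False):
    """Two-sample Wilcoxon rank-sum of introduction counts by colonial status.

    By default only the era's receiving countries enter; with
    ``include_missing_as_zero`` every flagged country enters, with zero
    counts where it received no introductions.  The statistic is the
    rank-sum W for the former-colony group (the Mann-Whitney U of that
    group), with a normal approximation and tie correction for the p-value.
    """
    counts = dict(counts_by_country)
    if include_missing_as_zero:
        for c in colony_flags:
            counts.setdefault(c, 0)
    missing = [c for c in counts if c not in colony_flags]
    if missing:
        raise ValueError(f"countries without a colonial flag: {missing[:5]}")
    x = [v for c, v in counts.items() if colony_flags[c]]
    y = [v for c, v in counts.items() if not colony_flags[c]]
    if not x or not y:
        raise ValueError("both colonial groups must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclass
class GdpRegressionResult:
    slope: float
    intercept: float
    f_statistic: float
    df: tuple
    adj_r2: float
    p_value: float
    n: int


def gdp_regression(counts_by_country: dict, gdp_by_country: dict
                   ) -> GdpRegressionResult:
    """OLS of log(1 + introductions) on log(1 + GDP per capita).

    Countries without GDP data are excluded.  Note the log(1+x) transform
    means the fit is not invariant to rescaling the GDP currency.
    """
    rows = [(c, n, gdp_by_country[c]) for c, n in counts_by_country.items()
            if gdp_by_country.get(c) is not None]
    if len(rows) < 3:
        raise ValueError("need at least 3 countries with GDP data")
    y = np.log1p([r[1] for r in rows])
    x = np.log1p([r[2] for r in rows])
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return GdpRegressionResult(
        slope=float(fit.params[1]), intercept=float(fit.params[0]),
        f_statistic=float(fit.fvalue), df=(int(fit.df_model),
                                           int(fit.df_resid)),
        adj_r2=float(fit.rsquared_adj), p_value=float(fit.f_pvalue),
        n=len(rows))
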