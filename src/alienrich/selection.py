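"""AIC-based model selection for gridded alien species richness.

Implements the selection protocol around a SAR engine: a single-predictor
scan, the quadratic-inclusion rule, forward stepwise construction of the
minimum adequate model (MAM) with an AIC-improvement threshold of 4 and a
final re-add pass, per-term removal impacts, the comparison run without
colonisation pressure, and realm-holdout cross-validation.

Terms are column names of the transformed grid table; a quadratic term is
written ``<name>^2`` and may only enter a model that already contains its
linear term (dropping the linear term drops the quadratic with it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sar import SpatialErrorModel, SpatialLagModel, SarResults
from .weights import SpatialWeights, build_weights

AIC_THRESHOLD = 4.0


def _base_name(term: str) -> str:
    return term[:-2] if term.endswith("^2") else term


def is_quadratic(term: str) -> bool:
    return term.endswith("^2")


class SarEngine:
    """Fits SAR models for arbitrary term subsets of one grid table.

    Caches fits by term set; the weights' eigendecomposition is shared
    across fits, so repeated stepwise refits stay cheap.
    """

    def __init__(self, table: pd.DataFrame, weights: SpatialWeights,
                 response: str = "log1p_ASR", model: str = "err"):
        if len(table) != weights.n:
            raise ValueError("table and weights disagree in size")
        self.table = table.reset_index(drop=True)
        self.weights = weights
        self.response = response
        self.model = model
        self._cache: dict[tuple, SarResults] = {}

    def design(self, terms) -> tuple[np.ndarray, list]:
        cols = [np.ones(len(self.table))]
        names = ["intercept"]
        for t in terms:
            base = _base_name(t)
            x = self.table[base].to_numpy(dtype=float)
            cols.append(x ** 2 if is_quadratic(t) else x)
            names.append(t)
        return np.column_stack(cols), names

    def fit(self, terms) -> SarResults:
        key = tuple(terms)
        if key not in self._cache:
            X, names = self.design(terms)
            y = self.table[self.response].to_numpy(dtype=float)
            cls = SpatialErrorModel if self.model == "err" else SpatialLagModel
            self._cache[key] = cls(y, X, self.weights,
                                   exog_names=names).fit()
        return self._cache[key]

    def aic(self, terms) -> float:
        return self.fit(terms).aic


# ---------------------------------------------------------------------------
# scan and quadratic rule
# ---------------------------------------------------------------------------

def single_predictor_scan(engine: SarEngine, predictors) -> pd.DataFrame:
    """One SAR fit per predictor; coefficient, s.e. and AIC, sorted by AIC."""
    rows = []
    for p in predictors:
        res = engine.fit((p,))
        rows.append({"term": p, "coef": float(res.params[1]),
                     "se": float(res.bse[1]), "aic": res.aic,
                     "pseudo_r2": res.pseudo_r2})
    return (pd.DataFrame(rows)
            .sort_values("aic", kind="stable")
            .reset_index(drop=True))


def quadratic_rule(engine: SarEngine, predictor: str,
                   candidates=None, threshold: float = AIC_THRESHOLD) -> bool:
    """Admit the quadratic form iff it improves the single-predictor AIC > 4.

    Only the six designated candidates may carry a quadratic term; the
    comparison is strict, so an improvement of exactly 4 does not qualify.
    """
    from .grid import QUADRATIC_CANDIDATES

    candidates = QUADRATIC_CANDIDATES if candidates is None else candidates
    if predictor not in candidates:
        raise ValueError(f"{predictor!r} is not a quadratic candidate")
    aic_lin = engine.aic((predictor,))
    aic_quad = engine.aic((predictor, f"{predictor}^2"))
    return aic_quad < aic_lin - threshold


# ---------------------------------------------------------------------------
# forward stepwise MAM
# ---------------------------------------------------------------------------

@dataclass
class SelectionTrace:
    steps: list = field(default_factory=list)
    readd: list = field(default_factory=list)
    terms: list = field(default_factory=list)
    final_aic: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def _eligible(candidates, current) -> list:
    """Unused candidates whose hierarchy requirement is met."""
    out = []
    for c in candidates:
        if c in current:
            continue
        if is_quadratic(c) and _base_name(c) not in current:
            continue
        out.append(c)
    return out


def forward_stepwise(engine: SarEngine, candidates,
                     threshold: float = AIC_THRESHOLD,
                     quadratics: str | list = "auto"):
    """Forward stepwise selection of the minimum adequate model.

    ``candidates`` are linear terms; quadratic terms are appended for the
    designated candidates (``quadratics='auto'`` applies the
    quadratic-inclusion rule first; a list supplies them explicitly; None
    disables them).  Starting from the best single-predictor model, the
    candidate with the largest AIC improvement > ``threshold`` is added at
    each step (ties broken lexicographically); after no candidate qualifies,
    every excluded term is offered once more (re-add pass).  Returns
    ``(results, trace)`` where results is the fitted MAM.
    """
    from .grid import QUADRATIC_CANDIDATES

    candidates = list(candidates)
    if quadratics == "auto":
        quads = [f"{p}^2" for p in candidates
                 if p in QUADRATIC_CANDIDATES
                 and quadratic_rule(engine, p, threshold=threshold)]
    elif quadratics is None:
        quads = []
    else:
        quads = list(quadratics)
    pool = candidates + quads

    trace = SelectionTrace()
    if not candidates:
        res = engine.fit(())
        trace.terms, trace.final_aic = [], res.aic
        return res, trace

    scan = single_predictor_scan(engine, candidates)
    current = [scan.loc[0, "term"]]
    aic = float(scan.loc[0, "aic"])
    trace.steps.append({"term": current[0], "aic_before": np.nan,
                        "aic_after": aic, "decision": "start",
                        "margin": np.nan})

    def best_addition(current, aic):
        best = None
        for t in sorted(_eligible(pool, current)):
            a = engine.aic(tuple(current) + (t,))
            margin = aic - a
            if margin > threshold and (best is None or margin > best[1]):
                best = (t, margin, a)
        return best

    while True:
        add = best_addition(current, aic)
        if add is None:
            break
        term, margin, new_aic = add
        trace.steps.append({"term": term, "aic_before": aic,
                            "aic_after": new_aic, "decision": "add",
                            "margin": margin})
        current.append(term)
        aic = new_aic

    # re-add pass: offer each excluded predictor once more
    for t in sorted(set(pool) - set(current)):
        if is_quadratic(t) and _base_name(t) not in current:
            continue
        a = engine.aic(tuple(current) + (t,))
        qualified = aic - a > threshold
        trace.readd.append({"term": t, "aic_before": aic, "aic_after": a,
                            "decision": "add" if qualified else "reject",
                            "margin": aic - a})
        if qualified:
            current.append(t)
            aic = a

    trace.terms = list(current)
    trace.final_aic = aic
    return engine.fit(tuple(current)), trace


def removal_impacts(mam_terms, engine: SarEngine, terms=None) -> pd.DataFrame:
    """AIC increase from removing each MAM term (refit without it).

    Removing a linear term also removes its quadratic.  Larger positive
    values mark terms that influence the model more strongly.  Asking for
    the impact of a term the MAM never selected is an error.
    """
    mam_terms = list(mam_terms)
    terms = mam_terms if terms is None else list(terms)
    outside = [t for t in terms if t not in mam_terms]
    if outside:
        raise ValueError(f"terms not in the MAM: {outside}")
    aic_full = engine.aic(tuple(mam_terms))
    rows = []
    for t in terms:
        reduced = [u for u in mam_terms
                   if u != t and not (is_quadratic(u) and _base_name(u) == t)]
        rows.append({"term": t, "delta_aic": engine.aic(tuple(reduced))
                     - aic_full})
    return (pd.DataFrame(rows)
            .sort_values("delta_aic", ascending=False, kind="stable")
            .reset_index(drop=True))


def compare_without_cp(engine: SarEngine, candidates,
                       cp_term: str = "log1p_CP",
                       threshold: float = AIC_THRESHOLD):
    """Re-run the full selection with colonisation pressure removed.

    Returns ``(mam_nocp, trace_nocp, delta_aic, newly_admitted)`` where
    ``delta_aic`` is AIC(no-CP MAM) - AIC(full MAM) and ``newly_admitted``
    lists terms in the no-CP MAM that the full MAM did not contain.
    """
    candidates = list(candidates)
    if cp_term not in candidates:
        raise ValueError(f"{cp_term!r} must be among the candidates")
    full_res, full_trace = forward_stepwise(engine, candidates,
                                            threshold=threshold)
    reduced = [c for c in candidates if c != cp_term]
    nocp_res, nocp_trace = forward_stepwise(engine, reduced,
                                            threshold=threshold)
    delta = nocp_res.aic - full_res.aic
    newly = [t for t in nocp_trace.terms if t not in full_trace.terms]
    return nocp_res, nocp_trace, delta, newly, full_trace


# ---------------------------------------------------------------------------
# realm-holdout cross-validation
# ---------------------------------------------------------------------------

def _design_from_table(table: pd.DataFrame, terms) -> np.ndarray:
    cols = [np.ones(len(table))]
    for t in terms:
        x = table[_base_name(t)].to_numpy(dtype=float)
        cols.append(x ** 2 if is_quadratic(t) else x)
    return np.column_stack(cols)


@dataclass
class CvReport:
    folds: pd.DataFrame       # realm, n_train, n_test, rmse, terms
    mean_rmse: float
    excluded_realms: list


def realm_holdout_cv(table: pd.DataFrame, candidates,
                     response: str = "log1p_ASR", realm_col: str = "realm",
                     model: str = "err", min_n: int = 100,
                     threshold: float = AIC_THRESHOLD,
                     threshold_km: float = 150.0) -> CvReport:
    """Hold out one biogeographic realm at a time.

    Stepwise selection runs on the remaining realms with the neighbour
    weights rebuilt on the training cells only (no information crosses the
    held-out boundary); the held-out realm is predicted from the regression
    trend alone and scored by RMSE on the transformed response.  Realms
    below ``min_n`` cells are excluded and reported.
    """
    table = table.reset_index(drop=True)
    counts = table[realm_col].value_counts()
    retained = sorted(counts[counts >= min_n].index)
    excluded = sorted(counts[counts < min_n].index)
    if len(retained) < 2:
        raise ValueError("need at least 2 realms above min_n for holdout CV")

    rows = []
    for realm in retained:
        test_mask = (table[realm_col] == realm).to_numpy()
        train = table.loc[~test_mask].reset_index(drop=True)
        test = table.loc[test_mask].reset_index(drop=True)
        w_train = build_weights(train, threshold_km=threshold_km)
        engine = SarEngine(train, w_train, response=response, model=model)
        res, trace = forward_stepwise(engine, candidates, threshold=threshold)
        X_test = _design_from_table(test, trace.terms)
        pred = res.predict_trend(X_test)
        rmse = float(np.sqrt(np.mean(
            (test[response].to_numpy(dtype=float) - pred) ** 2)))
        rows.append({"realm": realm, "n_train": len(train),
                     "n_test": len(test), "rmse": rmse,
                     "terms": list(trace.terms)})
    folds = pd.DataFrame(rows)
    return CvReport(folds=folds, mean_rmse=float(folds["rmse"].mean()),
                    excluded_realms=excluded)
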