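"""Stepwise-AIC regression engine with relative-weights importance.

The modelling objects follow the statsmodels convention: ``StepwiseOLS`` is
built from data and ``fit()`` returns a ``StepwiseResults`` carrying the
selected terms, coefficients, p-values, fit metrics, a seeded k-fold
cross-validation and Johnson's relative weights, plus a ``summary()`` table.

Selection protocol: start from all base main effects; forward passes add
the pairwise-interaction candidate that most improves (lowers) the AIC, if
any improves it at all; backward passes remove the term whose removal
improves the AIC by at least ``drop_tol`` (default 0.01); passes alternate
until neither changes the model.  No polynomial or three-way terms are
considered.  Interaction columns are products of *centred, scaled* main
effects, which makes the AIC path invariant to affine rescaling of the
predictors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import KFold

__all__ = [
    "StepwiseOLS",
    "StepwiseResults",
    "RelativeWeightTable",
    "SubsetSearchResult",
    "pearson_collinearity",
    "adjusted_r2",
    "relative_weights",
    "best_shape_subset",
    "N_SHAPE_SUBSETS",
]

N_SHAPE_SUBSETS = 252  # C(10, 5)


def pearson_collinearity(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of a parameter table.

    Requires at least 3 subjects and 2 parameters; a zero-variance column
    is an error (its correlations are undefined).
    """
    if table.shape[0] < 3 or table.shape[1] < 2:
        raise ValueError("need at least 3 subjects and 2 parameters")
    sd = table.std(ddof=1)
    dead = sd[sd == 0].index.tolist()
    if dead:
        raise ValueError(f"zero-variance columns: {dead}")
    return table.corr(method="pearson")


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """1 - (1 - R^2)(n - 1)/(n - p - 1), p = number of model terms."""
    if n - p - 1 <= 0:
        raise ValueError("too few observations for the number of terms")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _aic_from_rss(rss: float, n: int, n_terms: int) -> float:
    """Gaussian-likelihood AIC up to an additive constant shared across models."""
    return n * np.log(max(rss, 1e-300) / n) + 2.0 * (n_terms + 1)


@dataclass
class RelativeWeightTable:
    """Per-term relative weights: shares of a model's explained variance."""

    table: pd.DataFrame  # columns: term, raw_weight, pct_of_r2, p_value; sorted desc
    r2: float

    def top_significant(self, k: int = 3, alpha: float = 0.05) -> pd.DataFrame:
        sig = self.table[self.table["p_value"] < alpha]
        return sig.head(k).reset_index(drop=True)


def relative_weights(x: pd.DataFrame, y: np.ndarray,
                     p_values: pd.Series | None = None) -> RelativeWeightTable:
    """Johnson's relative weights for (possibly correlated) predictors.

    The standardized design is replaced by its closest orthonormal matrix
    (via SVD); y is regressed on the orthogonal variables and the explained
    variance attributed back to the original predictors through squared
    loadings.  The raw weights sum to the model R^2; they are reported as
    percentages of R^2, with duplicated predictors receiving equal shares.
    """
    xv = x.to_numpy(dtype=float)
    n, p = xv.shape
    sd = xv.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance predictor in relative-weights design")
    xs = (xv - xv.mean(axis=0)) / sd / np.sqrt(n - 1)
    yc = np.asarray(y, dtype=float)
    ys = (yc - yc.mean()) / yc.std(ddof=1) / np.sqrt(n - 1)

    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    if s[-1] < 1e-10 * s[0]:
        raise ValueError("rank-deficient design; relative weights undefined")
    z = u @ vt                      # best-fitting orthonormal approximation
    lam = vt.T @ np.diag(s) @ vt    # loadings of x on z (symmetric)
    beta = z.T @ ys                 # correlation-metric coefficients
    raw = (lam**2) @ (beta**2)
    r2 = float(np.sum(beta**2))

    tbl = pd.DataFrame({
        "term": list(x.columns),
        "raw_weight": raw,
        "pct_of_r2": 100.0 * raw / r2 if r2 > 0 else np.zeros(p),
    })
    if p_values is not None:
        tbl["p_value"] = [p_values.get(t, np.nan) for t in x.columns]
    else:
        tbl["p_value"] = np.nan
    tbl = tbl.sort_values("raw_weight", ascending=False).reset_index(drop=True)
    return RelativeWeightTable(table=tbl, r2=r2)


class StepwiseOLS:
    """OLS with forward/backward AIC selection over pairwise interactions.

    Parameters
    ----------
    endog : array-like
        Dependent variable.
    exog : DataFrame
        Base main-effect terms (no constant; one is always included).
    interactions : "pairwise" | list[tuple[str, str]] | None
        Candidate interaction terms; default all pairs of base terms.
    drop_tol : float
        Backward hysteresis: a term is removed only if removal improves the
        AIC by at least this much.
    hierarchy : bool
        If True, a main effect cannot be dropped while one of its
        interactions remains in the model.
    """

    def __init__(self, endog, exog: pd.DataFrame, interactions="pairwise",
                 drop_tol: float = 0.01, hierarchy: bool = False,
                 max_passes: int = 200):
        self.endog = np.asarray(endog, dtype=float)
        if not isinstance(exog, pd.DataFrame):
            raise TypeError("exog must be a DataFrame of named base terms")
        self.exog = exog.reset_index(drop=True)
        self.base_terms = list(exog.columns)
        n = len(self.endog)
        if n != len(self.exog):
            raise ValueError("endog and exog lengths differ")
        if n <= len(self.base_terms) + 1:
            raise ValueError("need n > number of base terms + 1")
        self.drop_tol = drop_tol
        self.hierarchy = hierarchy
        self.max_passes = max_passes

        if interactions == "pairwise":
            pairs = list(itertools.combinations(self.base_terms, 2))
        elif interactions is None:
            pairs = []
        else:
            pairs = [tuple(p) for p in interactions]

        cols = {t: self.exog[t].to_numpy(dtype=float) for t in self.base_terms}
        self._columns: dict[str, np.ndarray] = dict(cols)
        self.interaction_terms: list[str] = []
        for a, b in pairs:
            za = self._standardize(cols[a])
            zb = self._standardize(cols[b])
            name = f"{a}:{b}"
            self._columns[name] = za * zb
            self.interaction_terms.append(name)

    @staticmethod
    def _standardize(v: np.ndarray) -> np.ndarray:
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError("zero-variance base term")
        return (v - v.mean()) / sd

    # -- internals ---------------------------------------------------------

    def _design(self, terms: list[str]) -> np.ndarray:
        n = len(self.endog)
        x = np.empty((n, len(terms) + 1))
        x[:, 0] = 1.0
        for j, t in enumerate(terms):
            x[:, j + 1] = self._columns[t]
        return x

    def _rss(self, terms: list[str]) -> float | None:
        x = self._design(terms)
        coef, rss, rank, _ = np.linalg.lstsq(x, self.endog, rcond=None)
        if rank < x.shape[1]:
            return None  # rank deficient: not an admissible model
        if rss.size == 0:
            resid = self.endog - x @ coef
            return float(resid @ resid)
        return float(rss[0])

    def _aic(self, terms: list[str]) -> float:
        rss = self._rss(terms)
        if rss is None:
            return np.inf
        return _aic_from_rss(rss, len(self.endog), len(terms))

    def fit(self) -> "StepwiseResults":
        terms = list(self.base_terms)
        if not np.isfinite(self._aic(terms)):
            raise ValueError("rank-deficient base design matrix")
        current = self._aic(terms)
        trace: list[tuple[str, str, float]] = [("start", "", current)]
        remaining = list(self.interaction_terms)
        seen = {tuple(terms)}

        for _ in range(self.max_passes):
            changed = False

            # forward: best admissible interaction candidate that lowers AIC
            best_add, best_aic = None, current
            for cand in remaining:
                aic = self._aic(terms + [cand])
                if aic < best_aic - 1e-12:
                    best_add, best_aic = cand, aic
            if best_add is not None:
                terms.append(best_add)
                remaining.remove(best_add)
                current = best_aic
                trace.append(("add", best_add, current))
                changed = True

            # backward: removal must improve AIC by >= drop_tol; the model
            # always keeps at least one term
            best_drop, best_aic = None, current
            for t in terms if len(terms) > 1 else []:
                if self.hierarchy and ":" not in t:
                    if any(":" in other and t in other.split(":") for other in terms):
                        continue
                aic = self._aic([u for u in terms if u != t])
                if current - aic >= self.drop_tol and aic < best_aic:
                    best_drop, best_aic = t, aic
            if best_drop is not None:
                terms.remove(best_drop)
                if ":" in best_drop:
                    remaining.append(best_drop)
                current = best_aic
                trace.append(("drop", best_drop, current))
                changed = True

            if not changed:
                break
            key = tuple(sorted(terms))
            if key in seen:
                break  # cycle guard: deterministic stop at a revisited state
            seen.add(key)
        if not terms:
            raise ValueError("stepwise selection removed every term")

        x = self._design(terms)
        ols = sm.OLS(self.endog, x).fit()
        return StepwiseResults(model=self, terms=list(terms), ols=ols,
                               aic_trace=trace)


@dataclass
class StepwiseResults:
    """Fitted stepwise model: estimates, metrics, CV and importance."""

    model: StepwiseOLS
    terms: list[str]
    ols: "sm.regression.linear_model.RegressionResultsWrapper" = field(repr=False)
    aic_trace: list[tuple[str, str, float]] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        names = ["const"] + self.terms
        self.params = pd.Series(self.ols.params, index=names)
        self.pvalues = pd.Series(self.ols.pvalues, index=names)

    @property
    def nobs(self) -> int:
        return len(self.model.endog)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def rsquared(self) -> float:
        return float(self.ols.rsquared)

    @property
    def rsquared_adj(self) -> float:
        return adjusted_r2(self.rsquared, self.nobs, self.n_terms)

    @property
    def rmse(self) -> float:
        resid = np.asarray(self.ols.resid)
        return float(np.sqrt(np.mean(resid**2)))

    @property
    def aic(self) -> float:
        return self.aic_trace[-1][2] if self.aic_trace else np.nan

    def design_frame(self) -> pd.DataFrame:
        return pd.DataFrame({t: self.model._columns[t] for t in self.terms})

    def cross_validate(self, k: int = 10, seed: int = 0) -> float:
        """Pooled held-out RMSE of a seeded k-fold CV.

        The selected term structure is frozen; only the coefficients are
        refit within each training fold (per-fold reselection is available
        via ``cross_validate_reselect`` for honesty analyses).
        """
        y = self.model.endog
        n = len(y)
        if n < k:
            raise ValueError("need at least k observations for k-fold CV")
        x = self.model._design(self.terms)
        sq = np.empty(n)
        for train, test in KFold(n_splits=k, shuffle=True, random_state=seed).split(x):
            coef, *_ = np.linalg.lstsq(x[train], y[train], rcond=None)
            sq[test] = (y[test] - x[test] @ coef) ** 2
        return float(np.sqrt(sq.mean()))

    def cross_validate_reselect(self, k: int = 10, seed: int = 0) -> float:
        """k-fold CV re-running the stepwise selection inside every fold."""
        y = self.model.endog
        exog = self.model.exog
        sq = np.empty(len(y))
        for train, test in KFold(n_splits=k, shuffle=True,
                                 random_state=seed).split(exog):
            sub = StepwiseOLS(y[train], exog.iloc[train],
                              drop_tol=self.model.drop_tol,
                              hierarchy=self.model.hierarchy)
            res = sub.fit()
            # rebuild the fold's selected columns on the full-data transforms
            xf = self.model._design(res.terms)
            coef, *_ = np.linalg.lstsq(xf[train], y[train], rcond=None)
            sq[test] = (y[test] - xf[test] @ coef) ** 2
        return float(np.sqrt(sq.mean()))

    def relative_weights(self) -> RelativeWeightTable:
        return relative_weights(self.design_frame(), self.model.endog,
                                p_values=self.pvalues)

    def summary(self) -> str:
        lines = [
            "Stepwise OLS results",
            "=" * 64,
            f"n obs            {self.nobs}",
            f"terms selected   {self.n_terms}"
            f"  ({sum(':' in t for t in self.terms)} interactions)",
            f"R-squared        {self.rsquared:.4f}",
            f"adj. R-squared   {self.rsquared_adj:.4f}",
            f"RMSE             {self.rmse:.4g}",
            f"AIC              {self.aic:.2f}",
            "-" * 64,
            f"{'term':<28}{'coef':>12}{'p-value':>12}",
        ]
        for name in self.params.index:
            lines.append(f"{name:<28}{self.params[name]:>12.4g}"
                         f"{self.pvalues[name]:>12.3g}")
        lines.append("=" * 64)
        return "\n".join(lines)


@dataclass
class SubsetSearchResult:
    subset: tuple[str, ...]
    mse: float
    n_evaluated: int
    results: "StepwiseResults"
    skipped: list[tuple[tuple[str, ...], str]] = field(default_factory=list)


def best_shape_subset(endog, shape: pd.DataFrame, size: pd.DataFrame,
                      n_choose: int = 5, **stepwise_kwargs) -> SubsetSearchResult:
    """Exhaustive search over all C(10,5)=252 shape-parameter subsets.

    Each candidate model combines 5 shape parameters with the 5 size
    parameters, is fit by the stepwise procedure, and is scored by training
    mean squared error; ties break lexicographically (the enumeration order
    of sorted column names).  Subsets whose fit fails are skipped with a
    record.
    """
    if shape.shape[1] < n_choose:
        raise ValueError("fewer shape parameters than subset size")
    y = np.asarray(endog, dtype=float)
    best: SubsetSearchResult | None = None
    skipped: list[tuple[tuple[str, ...], str]] = []
    count = 0
    for combo in itertools.combinations(sorted(shape.columns), n_choose):
        count += 1
        exog = pd.concat([shape[list(combo)], size], axis=1)
        try:
            res = StepwiseOLS(y, exog, **stepwise_kwargs).fit()
        except ValueError as exc:
            skipped.append((combo, str(exc)))
            continue
        mse = res.rmse**2
        if best is None or mse < best.mse - 1e-15:
            best = SubsetSearchResult(subset=combo, mse=mse, n_evaluated=0,
                                      results=res)
    if best is None:
        raise ValueError("every candidate subset failed to fit")
    best.n_evaluated = count
    best.skipped = skipped
    return best
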