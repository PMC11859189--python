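"""Empirical retrieval-algorithm calibration with k-fold cross-validation.

A retrieval algorithm maps one two-band spectral index to one
water-quality variable through a fitted function. Five function
families are supported; the nonlinear families are fitted by
linearizing transform (ordinary least squares in the transformed
space), which is the standard practice for empirical bio-optical
regressions:

======================  ==========================  =================
family                  model                       fitted as
======================  ==========================  =================
linear                  y = c1*x + c0               OLS on (x, y)
polynomial (degree d)   y = sum c_i x^i             OLS on (x^i, y)
exponential             y = a * exp(b*x)            OLS on (x, ln y)
power                   y = a * x^b                 OLS on (ln x, ln y)
logarithmic             y = a + b * ln x            OLS on (ln x, y)
======================  ==========================  =================

Validation statistics follow the usual matchup-analysis suite: R^2
(squared Pearson correlation of observed vs estimated), RMSE, NRMSE
(RMSE as a percentage of the observed min-max range), MAE, and bias
(mean of estimated minus observed). Cross-validation shuffles once
under a seed, splits into k near-equal folds, fits on k-1 and scores
the held-out fold, and reports the across-fold mean (bias is pooled
over all held-out predictions).

The estimators follow the scikit-learn protocol: `BandIndexRegressor`
is one (index, family) regression over 4-band spectra, and
`IndexRankingSearch` exhaustively evaluates every enumerated index x
family combination and ranks by cross-validated RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .bands import PERUSAT1, BandSet
from .indices import IndexSpec, compute_index, enumerate_indices

__all__ = [
    "FIT_FAMILIES",
    "FitModel",
    "ValidationStats",
    "summary_stats",
    "fit_model",
    "crossvalidate",
    "BandIndexRegressor",
    "IndexRankingSearch",
    "rank_indices",
]

FIT_FAMILIES = ["linear", "exponential", "power", "logarithmic", "polynomial"]


def _check_domain(x: np.ndarray, y: np.ndarray, family: str) -> None:
    if family in ("power", "logarithmic") and np.any(x <= 0):
        bad = x[x <= 0][:3]
        raise ValueError(
            f"{family} fit requires strictly positive index values; got e.g. {bad}"
        )
    if family in ("exponential", "power") and np.any(y <= 0):
        bad = y[y <= 0][:3]
        raise ValueError(
            f"{family} fit requires strictly positive target values; got e.g. {bad}"
        )


def _fit_coefficients(x: np.ndarray, y: np.ndarray, family: str, degree: int):
    """Least-squares coefficients for one family (linearizing transform)."""
    if np.ptp(x) == 0:
        raise ValueError("index values are constant: rank-deficient fit")
    if np.ptp(y) == 0:
        raise ValueError("target values are constant: rank-deficient fit")
    _check_domain(x, y, family)
    if family == "linear":
        c1, c0 = np.polyfit(x, y, 1)
        return [float(c1), float(c0)]
    if family == "polynomial":
        return [float(c) for c in np.polyfit(x, y, degree)]
    if family == "exponential":
        b, ln_a = np.polyfit(x, np.log(y), 1)
        return [float(np.exp(ln_a)), float(b)]
    if family == "power":
        b, ln_a = np.polyfit(np.log(x), np.log(y), 1)
        return [float(np.exp(ln_a)), float(b)]
    if family == "logarithmic":
        b, a = np.polyfit(np.log(x), y, 1)
        return [float(a), float(b)]
    raise ValueError(f"unknown fit family {family!r}")


def _predict(x: np.ndarray, family: str, coefficients) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    c = coefficients
    if family in ("linear", "polynomial"):
        return np.polyval(c, x)
    if family == "exponential":
        return c[0] * np.exp(c[1] * x)
    if family == "power":
        with np.errstate(invalid="ignore"):
            return c[0] * np.power(x, c[1])
    if family == "logarithmic":
        with np.errstate(invalid="ignore", divide="ignore"):
            return c[0] + c[1] * np.log(x)
    raise ValueError(f"unknown fit family {family!r}")


def _format_term(value: float, first: bool) -> str:
    s = f"{value:.6g}"
    if first:
        return s
    return f"+ {s}" if value >= 0 else f"− {abs(value):.6g}"


@dataclass(frozen=True)
class FitModel:
    """One calibrated (index, family, coefficients) retrieval function."""

    family: str
    coefficients: tuple[float, ...]
    variable: str = "y"
    index: IndexSpec | None = None
    degree: int = 2

    def predict(self, x) -> np.ndarray:
        return _predict(x, self.family, list(self.coefficients))

    @property
    def formula(self) -> str:
        c = self.coefficients
        xname = "x"
        if self.family == "linear":
            return f"y = {_format_term(c[0], True)}{xname} {_format_term(c[1], False)}"
        if self.family == "polynomial":
            terms = []
            deg = len(c) - 1
            for i, ci in enumerate(c):
                p = deg - i
                xpart = "" if p == 0 else (xname if p == 1 else f"{xname}^{p}")
                terms.append(f"{_format_term(ci, i == 0)}{xpart}")
            return "y = " + " ".join(terms)
        if self.family == "exponential":
            return f"y = {c[0]:.6g}·exp({c[1]:.6g}{xname})"
        if self.family == "power":
            return f"y = {c[0]:.6g}·{xname}^{c[1]:.6g}"
        if self.family == "logarithmic":
            return f"y = {_format_term(c[0], True)} {_format_term(c[1], False)}·ln({xname})"
        raise ValueError(self.family)


@dataclass
class ValidationStats:
    """Matchup validation statistics, calibration or cross-validated."""

    r_squared: float
    rmse: float
    nrmse_pct: float | None
    mae: float
    bias: float
    n: int
    k_folds: int | None = None
    #: R^2 over pooled held-out predictions (cross-validation only)
    r_squared_pooled: float | None = field(default=None, repr=False)
    #: RMSE over pooled held-out predictions (cross-validation only)
    rmse_pooled: float | None = field(default=None, repr=False)
    #: standard error of the fold RMSEs (cross-validation only)
    rmse_se: float | None = field(default=None, repr=False)

    def as_dict(self) -> dict:
        return {
            "r2": self.r_squared,
            "rmse": self.rmse,
            "nrmse_pct": self.nrmse_pct,
            "mae": self.mae,
            "bias": self.bias,
            "n": self.n,
            "k_folds": self.k_folds,
        }


def _r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    if len(observed) < 2 or np.ptp(observed) == 0 or np.ptp(predicted) == 0:
        return np.nan
    return float(np.corrcoef(observed, predicted)[0, 1] ** 2)


def summary_stats(
    observed,
    predicted,
    observed_range: tuple[float, float] | None = None,
    k_folds: int | None = None,
) -> ValidationStats:
    """Validation statistics for paired observed/estimated values.

    NRMSE is normalized by the observed min-max range unless
    ``observed_range`` overrides it; with a zero range NRMSE is
    reported missing (None).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    if obs.size < 2:
        raise ValueError("need at least 2 paired values")
    resid = pred - obs
    rmse = float(np.sqrt(np.mean(resid**2)))
    lo, hi = observed_range if observed_range is not None else (obs.min(), obs.max())
    span = hi - lo
    nrmse = 100.0 * rmse / span if span > 0 else None
    return ValidationStats(
        r_squared=_r_squared(obs, pred),
        rmse=rmse,
        nrmse_pct=nrmse,
        mae=float(np.mean(np.abs(resid))),
        bias=float(np.mean(resid)),
        n=int(obs.size),
        k_folds=k_folds,
    )


def _finite_pairs(x, y) -> tuple[np.ndarray, np.ndarray, int]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep], int(np.sum(~keep))


def fit_model(
    x,
    y,
    family: str = "linear",
    variable: str = "y",
    index: IndexSpec | None = None,
    degree: int = 2,
) -> tuple[FitModel, ValidationStats]:
    """Calibrate one fit family on index values; statistics on the original scale."""
    xv, yv, _ = _finite_pairs(x, y)
    if xv.size < 3:
        raise ValueError(f"need at least 3 finite pairs, got {xv.size}")
    coeffs = _fit_coefficients(xv, yv, family, degree)
    model = FitModel(family, tuple(coeffs), variable=variable, index=index, degree=degree)
    stats = summary_stats(yv, model.predict(xv))
    return model, stats


def crossvalidate(
    x,
    y,
    family: str = "linear",
    k: int = 10,
    seed: int = 0,
    degree: int = 2,
) -> ValidationStats:
    """Fold-averaged k-fold cross-validation statistics.

    A single seeded shuffle assigns samples to k near-equal folds; each
    fold is held out once. RMSE, MAE and R^2 are averaged across folds;
    bias is the mean of (estimated - observed) pooled over all held-out
    predictions; NRMSE normalizes the mean RMSE by the full-sample
    observed range.
    """
    xv, yv, _ = _finite_pairs(x, y)
    n = xv.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(
            f"n = {n} samples cannot fill k = {k} folds; reduce k to at most {n}"
        )
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    rmses, maes, r2s = [], [], []
    pooled_obs, pooled_pred = [], []
    for train, test in splitter.split(xv):
        coeffs = _fit_coefficients(xv[train], yv[train], family, degree)
        pred = _predict(xv[test], family, coeffs)
        resid = pred - yv[test]
        rmses.append(np.sqrt(np.mean(resid**2)))
        maes.append(np.mean(np.abs(resid)))
        r2 = _r_squared(yv[test], pred)
        if np.isfinite(r2):
            r2s.append(r2)
        pooled_obs.append(yv[test])
        pooled_pred.append(pred)
    pooled_obs = np.concatenate(pooled_obs)
    pooled_pred = np.concatenate(pooled_pred)
    mean_rmse = float(np.mean(rmses))
    span = float(np.ptp(yv))
    return ValidationStats(
        r_squared=float(np.mean(r2s)) if r2s else np.nan,
        rmse=mean_rmse,
        nrmse_pct=100.0 * mean_rmse / span if span > 0 else None,
        mae=float(np.mean(maes)),
        bias=float(np.mean(pooled_pred - pooled_obs)),
        n=n,
        k_folds=k,
        r_squared_pooled=_r_squared(pooled_obs, pooled_pred),
        rmse_pooled=float(np.sqrt(np.mean((pooled_pred - pooled_obs) ** 2))),
        rmse_se=float(np.std(rmses, ddof=1) / np.sqrt(k)),
    )


class BandIndexRegressor(RegressorMixin, BaseEstimator):
    """One two-band-index retrieval regression over multispectral spectra.

    Parameters
    ----------
    index : IndexSpec
        Which two-band index to compute from the input spectra.
    family : str
        Fit family, one of ``FIT_FAMILIES``.
    degree : int
        Polynomial degree (polynomial family only).
    band_labels : list of str, optional
        Band order of the input columns; defaults to the 4-band
        standard order B1..B4.

    Attributes
    ----------
    model_ : FitModel
        Calibrated retrieval function.
    coef_ : ndarray
        Fitted coefficients (family-specific order).
    calibration_stats_ : ValidationStats
        Goodness of fit on the training data.
    """

    def __init__(
        self,
        index: IndexSpec = IndexSpec("ND", "B4", "B1"),
        family: str = "linear",
        degree: int = 2,
        band_labels: list[str] | None = None,
    ):
        self.index = index
        self.family = family
        self.degree = degree
        self.band_labels = band_labels

    def _labels(self) -> list[str]:
        return self.band_labels if self.band_labels is not None else PERUSAT1.labels

    def _index_values(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_bands)")
        return np.asarray(compute_index(X, self.index, self._labels()))

    def fit(self, X, y):
        y = np.asarray(y, dtype=float).ravel()
        x = self._index_values(X)
        if x.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        self.model_, self.calibration_stats_ = fit_model(
            x, y, family=self.family, index=self.index, degree=self.degree
        )
        self.coef_ = np.asarray(self.model_.coefficients)
        self.n_features_in_ = X.shape[1] if hasattr(X, "shape") else len(X[0])
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(self._index_values(X))

    def cross_validate(self, X, y, k: int = 10, seed: int = 0) -> ValidationStats:
        """k-fold CV statistics for this (index, family) on the given data."""
        y = np.asarray(y, dtype=float).ravel()
        return crossvalidate(
            self._index_values(X), y, family=self.family, k=k, seed=seed,
            degree=self.degree,
        )


class IndexRankingSearch(BaseEstimator):
    """Exhaustive two-band index x fit-family search ranked by CV RMSE.

    Every enumerated SR/ND index is combined with every fit family,
    cross-validated with seeded k-fold splitting, and ranked by
    ascending cross-validated RMSE (ties: higher R^2, then lexical
    index name). With ``parsimony='one_se'`` (default) the standard
    one-standard-error rule applies on top: among combinations whose
    CV RMSE lies within one fold standard error of the minimum, the
    one with the fewest fitted parameters ranks first — a nested
    polynomial never displaces a sufficient linear fit on CV noise
    alone. Combinations whose domain constraints fail (e.g. a power
    fit on negative index values) are recorded as failures, not
    errors; the search errors only if every combination fails.

    Attributes
    ----------
    results_ : DataFrame
        Full ranked table (band_comb, family, formula, r2, rmse,
        nrmse_pct, mae, bias, calibration columns).
    ranking_ : DataFrame
        Top ``top_n`` rows of ``results_``.
    best_estimator_ : BandIndexRegressor
        Rank-1 combination refitted on the full data.
    failures_ : dict
        Per-combination failure messages.
    """

    def __init__(
        self,
        families: list[str] | None = None,
        k: int = 10,
        seed: int = 0,
        degree: int = 2,
        top_n: int = 5,
        band_set: BandSet = PERUSAT1,
        parsimony: str = "one_se",
    ):
        self.families = families
        self.k = k
        self.seed = seed
        self.degree = degree
        self.top_n = top_n
        self.band_set = band_set
        self.parsimony = parsimony

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        families = self.families if self.families is not None else FIT_FAMILIES
        labels = self.band_set.labels
        rows = []
        failures: dict[str, str] = {}
        for spec in enumerate_indices(self.band_set):
            x_all = np.asarray(compute_index(X, spec, labels))
            for family in families:
                key = f"{spec.name}|{family}"
                try:
                    cv = crossvalidate(
                        x_all, y, family=family, k=self.k, seed=self.seed,
                        degree=self.degree,
                    )
                    model, cal = fit_model(
                        x_all, y, family=family, index=spec, degree=self.degree
                    )
                except ValueError as exc:
                    failures[key] = str(exc)
                    continue
                rows.append(
                    {
                        "band_comb": spec.name,
                        "family": family,
                        "formula": model.formula,
                        "r2": cv.r_squared,
                        "rmse": cv.rmse,
                        "rmse_se": cv.rmse_se,
                        "nrmse_pct": cv.nrmse_pct,
                        "mae": cv.mae,
                        "bias": cv.bias,
                        "cal_r2": cal.r_squared,
                        "cal_rmse": cal.rmse,
                        "n": cv.n,
                        "n_params": len(model.coefficients),
                        "_spec": spec,
                        "_model": model,
                    }
                )
        if not rows:
            raise ValueError(
                "every index x family combination failed: "
                + "; ".join(f"{k}: {v}" for k, v in list(failures.items())[:5])
            )
        table = pd.DataFrame(rows)
        table["_neg_r2"] = -table["r2"].fillna(-np.inf)
        table = (
            table.sort_values(["rmse", "_neg_r2", "band_comb"], kind="mergesort")
            .reset_index(drop=True)
        )
        if self.parsimony == "one_se":
            # one-standard-error rule: among combinations within one fold
            # SE of the best CV RMSE, prefer the fewest fitted parameters
            threshold = table.loc[0, "rmse"] + table.loc[0, "rmse_se"]
            cand = table["rmse"] <= threshold
            head = table[cand].sort_values(
                ["n_params", "rmse", "_neg_r2", "band_comb"], kind="mergesort"
            )
            table = pd.concat([head, table[~cand]]).reset_index(drop=True)
        elif self.parsimony != "none":
            raise ValueError(f"unknown parsimony rule {self.parsimony!r}")
        table = table.drop(columns="_neg_r2")
        table.index += 1
        table.index.name = "rank"
        self.results_ = table
        self.ranking_ = table.head(self.top_n)
        self.failures_ = failures
        best = table.iloc[0]
        self.best_estimator_ = BandIndexRegressor(
            index=best["_spec"], family=best["family"], degree=self.degree,
            band_labels=labels,
        ).fit(X, y)
        return self

    def predict(self, X):
        check_is_fitted(self, "best_estimator_")
        return self.best_estimator_.predict(X)


def rank_indices(
    spectra,
    y,
    families: list[str] | None = None,
    k: int = 10,
    seed: int = 0,
    top_n: int = 5,
    degree: int = 2,
    band_set: BandSet = PERUSAT1,
    parsimony: str = "one_se",
) -> IndexRankingSearch:
    """Run the exhaustive index search; returns the fitted search object.

    ``spectra`` is (n, n_bands) ROI-mean reflectance; ``y`` the field
    variable. The fitted object exposes ``ranking_`` (top table),
    ``results_`` (full table) and ``best_estimator_``.
    """
    return IndexRankingSearch(
        families=families, k=k, seed=seed, degree=degree, top_n=top_n,
        band_set=band_set, parsimony=parsimony,
    ).fit(spectra, y)
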