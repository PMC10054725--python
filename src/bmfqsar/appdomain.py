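"""Applicability domain by leverage and standardized residuals.

A query chemical is inside the structural applicability domain (AD) of an
MLR model when its leverage h = x'(X'X)^-1 x (intercept included, X the
training design) does not exceed h* = 3 p'/n, with p' the number of model
variables plus one.  Chemicals with |standardized residual| > 2.5 are
response outliers; > 3 marks the stronger tier that is reported but does
not drive categorization.  The leverage / standardized-residual scatter is
the Williams plot.

The same machinery drives the consistency screen for low-quality data:
records outside the AD are unreliable, in-AD records are split into
consistent and inconsistent by the 2.5-standard-deviation rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .models import LinearModel
from .validation import RankDeficiencyError, _design

OUTLIER_SD = 2.5
STRONG_OUTLIER_SD = 3.0


def leverage_cutoff(n_train: int, n_descriptors: int) -> float:
    """h* = 3 (n_descriptors + 1) / n_train."""
    if n_train <= 0:
        raise ValueError("n_train must be positive")
    return 3.0 * (n_descriptors + 1) / n_train


def leverages(X_train, X_query=None, add_intercept: bool = True) -> np.ndarray:
    """Leverage of query points w.r.t. a training design.

    h_q = x_q' (X'X)^-1 x_q with the intercept column included; with
    ``X_query=None`` returns the training hat diagonal.
    """
    d_train = _design(np.asarray(X_train, float), add_intercept)
    gram = d_train.T @ d_train
    if np.linalg.matrix_rank(d_train) < d_train.shape[1]:
        raise RankDeficiencyError(["<training design>"])
    gram_inv = np.linalg.inv(gram)
    d_query = d_train if X_query is None else _design(np.asarray(X_query, float), add_intercept)
    if d_query.shape[1] != d_train.shape[1]:
        raise ValueError("query columns do not match the training design")
    return np.einsum("ij,jk,ik->i", d_query, gram_inv, d_query)


def standardized_residuals(residuals, s: float) -> np.ndarray:
    """residual / s with s = sqrt(RSS/(n-p')) from the training fit."""
    if s <= 0:
        raise ValueError("s must be positive")
    return np.asarray(residuals, dtype=float) / s


class LeverageDomain(BaseEstimator):
    """Leverage-based applicability domain of a linear QSAR.

    ``fit(X, y)`` stores the training design of the model's descriptors,
    the cutoff h* = 3p'/n and the training residual scale s (computed from
    the supplied model's predictions when ``model`` is given, else from a
    fresh OLS fit).  ``report(X, y)`` emits the Williams-plot table.

    Parameters
    ----------
    model : LinearModel, optional
        Frozen model whose predictions define the residuals.  When None, an
        OLS model is fitted on the training data instead.
    """

    def __init__(self, model: LinearModel | None = None):
        self.model = model

    def fit(self, X: pd.DataFrame, y):
        from .validation import fit_ols

        y = np.asarray(y, dtype=float)
        if self.model is not None:
            names = self.model.descriptor_names
            design = X[names].to_numpy(dtype=float)
            resid = y - self.model.predict(X)
            p_prime = len(names) + 1
            dof = len(y) - p_prime
            if dof <= 0:
                raise ValueError("not enough training records for the model size")
            self.s_ = float(np.sqrt(np.sum(resid**2) / dof))
            self.model_ = self.model
        else:
            names = list(X.columns)
            design = X[names].to_numpy(dtype=float)
            ols = fit_ols(design, y)
            self.s_ = ols.s
            from .models import MLRModel

            est = MLRModel(descriptor_names=names).fit(X, y)
            self.model_ = est.model_
        self.descriptor_names_ = names
        self.X_train_ = design
        self.n_train_ = len(design)
        self.h_star_ = leverage_cutoff(self.n_train_, len(names))
        return self

    def leverage(self, X: pd.DataFrame | None = None) -> np.ndarray:
        check_is_fitted(self, "X_train_")
        if X is None:
            return leverages(self.X_train_)
        return leverages(self.X_train_, X[self.descriptor_names_].to_numpy(dtype=float))

    def report(self, X: pd.DataFrame, y=None, ids=None) -> pd.DataFrame:
        """Williams-plot table: leverage, standardized residual and flags.

        Flags use strict inequalities: ``high_leverage`` iff h > h*,
        ``response_outlier`` iff |std residual| > 2.5 (NaN residuals when
        ``y`` is not given), ``strong_outlier`` iff > 3, ``in_domain`` iff
        h <= h*.
        """
        check_is_fitted(self, "X_train_")
        h = self.leverage(X)
        if y is not None:
            resid = np.asarray(y, dtype=float) - self.model_.predict(X)
            std_res = standardized_residuals(resid, self.s_)
        else:
            std_res = np.full(len(h), np.nan)
        df = pd.DataFrame(
            {
                "h": h,
                "std_residual": std_res,
                "in_domain": h <= self.h_star_,
                "high_leverage": h > self.h_star_,
                "response_outlier": np.abs(std_res) > OUTLIER_SD,
                "strong_outlier": np.abs(std_res) > STRONG_OUTLIER_SD,
            },
            index=ids if ids is not None else (X.index if isinstance(X, pd.DataFrame) else None),
        )
        df.attrs["h_star"] = self.h_star_
        df.attrs["s"] = self.s_
        return df


def williams(model: LinearModel, X_train: pd.DataFrame, y_train, X_query=None, y_query=None,
             ids=None) -> pd.DataFrame:
    """Williams-plot table of a model over a query set (default: training set)."""
    dom = LeverageDomain(model=model).fit(X_train, y_train)
    if X_query is None:
        X_query, y_query = X_train, y_train
    return dom.report(X_query, y_query, ids=ids)


#: screen categories, mutually exclusive and exhaustive for records with responses
CATEGORIES = ("consistent_in_AD", "inconsistent_in_AD", "outside_AD_unreliable")


def screen_external(
    model: LinearModel,
    X_train: pd.DataFrame,
    y_train,
    X_query: pd.DataFrame,
    y_query,
    ids=None,
) -> pd.DataFrame:
    """Consistency screen of externally measured data against a trained model.

    Each record is categorized: ``outside_AD_unreliable`` when its leverage
    exceeds h* of the training configuration (no judgement on the value is
    possible there); otherwise ``inconsistent_in_AD`` when |standardized
    residual| > 2.5, else ``consistent_in_AD``.  Records that are
    consistent and in-AD are the ones eligible for pooling into an extended
    training set.
    """
    dom = LeverageDomain(model=model).fit(X_train, y_train)
    rep = dom.report(X_query, y_query, ids=ids)
    pred = model.predict(X_query)
    cat = np.where(
        rep["high_leverage"],
        "outside_AD_unreliable",
        np.where(rep["response_outlier"], "inconsistent_in_AD", "consistent_in_AD"),
    )
    out = pd.DataFrame(
        {
            "predicted": pred,
            "residual": np.asarray(y_query, dtype=float) - pred,
            "h": rep["h"].to_numpy(),
            "std_residual": rep["std_residual"].to_numpy(),
            "category": cat,
        },
        index=rep.index,
    )
    out.attrs["h_star"] = dom.h_star_
    out.attrs["counts"] = out["category"].value_counts().to_dict()
    return out
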