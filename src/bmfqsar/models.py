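"""Frozen MLR-QSAR equations for dietary Log BMF_L and the fitted-model API.

Four published multiple-linear-regression equations are shipped verbatim at
printed precision.  ``eq1``/``eq2`` come from the high/medium-quality
dataset (split model and full-data recalibration), ``eq3``/``eq4`` from the
extended dataset that adds screened low-quality data.  ``eq2`` and ``eq4``
are the recommended application models; ``eq4`` has the wider applicability
domain.

The endpoint is Log10 of the dietary biomagnification factor normalized by
fish and diet lipid content (Log BMF_L); a chemical with Log BMF_L > 0
(BMF_L > 1) is classed as a biomagnifier.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


@dataclass(frozen=True)
class Term:
    name: str
    coefficient: float
    se: float


@dataclass(frozen=True)
class LinearModel:
    """Intercept + linear terms over named descriptors, with printed SEs."""

    model_id: str
    intercept: float
    intercept_se: float
    terms: tuple[Term, ...]
    training_n: int
    endpoint: str = "Log BMF_L (dietary)"

    def __post_init__(self):
        names = [t.name for t in self.terms]
        if len(names) != len(set(names)):
            raise ValueError("duplicate descriptor names in model terms")

    @property
    def descriptor_names(self) -> list[str]:
        return [t.name for t in self.terms]

    def term(self, name: str) -> Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def predict_one(self, x: dict[str, float]) -> float:
        missing = [t.name for t in self.terms if t.name not in x]
        if missing:
            raise ValueError(f"missing descriptor(s) for {self.model_id}: {missing}")
        return self.intercept + sum(t.coefficient * float(x[t.name]) for t in self.terms)

    def predict(self, X: pd.DataFrame | dict) -> np.ndarray:
        if isinstance(X, dict):
            return np.array([self.predict_one(X)])
        missing = [n for n in self.descriptor_names if n not in X.columns]
        if missing:
            raise ValueError(f"missing descriptor column(s) for {self.model_id}: {missing}")
        coefs = np.array([t.coefficient for t in self.terms])
        return self.intercept + X[self.descriptor_names].to_numpy(dtype=float) @ coefs

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LinearModel":
        d = json.loads(text)
        d["terms"] = tuple(Term(**t) for t in d["terms"])
        return cls(**d)


def _model(model_id, intercept, intercept_se, terms, n):
    return LinearModel(
        model_id=model_id,
        intercept=intercept,
        intercept_se=intercept_se,
        terms=tuple(Term(*t) for t in terms),
        training_n=n,
    )


#: the four published equations, coefficients at printed precision
_BUILTINS: dict[str, LinearModel] = {
    "eq1": _model(
        "eq1", -103.01, 25.20,
        [
            ("AATS5i", -0.08, 0.02),
            ("BCUTw-1l", 9.74, 2.03),
            ("PubchemFP257", -0.88, 0.27),
            ("C3SP2", -0.15, 0.05),
            ("MATS1i", 3.14, 1.50),
            ("GATS5m", -0.54, 0.40),
            ("GGI5", 0.29, 0.25),
        ],
        115,
    ),
    "eq2": _model(
        "eq2", -103.72, 22.93,
        [
            ("AATS5i", -0.07, 0.02),
            ("BCUTw-1l", 9.74, 1.85),
            ("PubchemFP257", -0.83, 0.25),
            ("C3SP2", -0.15, 0.05),
            ("MATS1i", 3.73, 1.36),
            ("GGI5", 0.42, 0.21),
            ("GATS5m", -0.55, 0.34),
        ],
        152,
    ),
    "eq3": _model(
        "eq3", -0.90, 0.19,
        [
            ("PubchemFP503", 1.41, 0.19),
            ("SubFPC295", -0.40, 0.07),
            ("R_TpiPCTPC", -0.06, 0.02),
            ("MLFER_S", 0.56, 0.23),
            ("maxHother", -1.39, 0.60),
            ("GGI5", 0.65, 0.26),
            ("VE3_Dt", -4.00e-3, 2.5e-3),
        ],
        194,
    ),
    "eq4": _model(
        "eq4", -1.04, 0.16,
        [
            ("SubFPC295", -0.42, 0.06),
            ("PubchemFP503", 1.38, 0.18),
            ("R_TpiPCTPC", -0.06, 0.02),
            ("MLFER_S", 0.57, 0.23),
            ("GGI5", 0.73, 0.22),
            ("maxHother", -1.05, 0.55),
            ("VE3_Dt", -5.00e-3, 2.4e-3),
        ],
        258,
    ),
}


def builtin_model(model_id: str) -> LinearModel:
    """Return one of the frozen published equations (eq1..eq4)."""
    try:
        return _BUILTINS[model_id]
    except KeyError:
        raise ValueError(f"unknown model id {model_id!r}; choose from {sorted(_BUILTINS)}") from None


def classify_biomagnifier(log_bmf_l: float) -> bool:
    """True iff the chemical is predicted to biomagnify (BMF_L > 1,
    i.e. Log BMF_L strictly greater than 0)."""
    if not np.isfinite(log_bmf_l):
        raise ValueError("Log BMF_L must be finite")
    return bool(log_bmf_l > 0.0)


class MLRModel(RegressorMixin, BaseEstimator):
    """Multiple linear regression over named molecular descriptors.

    scikit-learn style: ``fit(X, y)`` runs OLS on the ``descriptor_names``
    columns of a DataFrame (all columns when None), ``predict`` applies the
    linear equation.  ``MLRModel.from_builtin("eq2")`` returns a frozen,
    already-"fitted" instance of a published equation.

    Attributes
    ----------
    coef_, intercept_ : fitted coefficients
    se_, intercept_se_ : their standard errors
    model_ : the equivalent :class:`LinearModel`
    ols_ : the underlying :class:`bmfqsar.validation.OLSFit` (None for
        frozen builtins)
    """

    def __init__(self, descriptor_names: list[str] | None = None):
        self.descriptor_names = descriptor_names

    def fit(self, X: pd.DataFrame, y):
        from .validation import fit_ols

        names = list(self.descriptor_names) if self.descriptor_names else list(X.columns)
        design = X[names].to_numpy(dtype=float)
        ols = fit_ols(design, np.asarray(y, dtype=float), add_intercept=True)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = len(names)
        self.intercept_ = float(ols.coefficients[0])
        self.coef_ = ols.coefficients[1:].copy()
        self.intercept_se_ = float(ols.se[0])
        self.se_ = ols.se[1:].copy()
        self.ols_ = ols
        self.model_ = LinearModel(
            model_id="custom",
            intercept=self.intercept_,
            intercept_se=self.intercept_se_,
            terms=tuple(
                Term(n, float(c), float(s)) for n, c, s in zip(names, self.coef_, self.se_)
            ),
            training_n=len(design),
        )
        return self

    @classmethod
    def from_builtin(cls, model_id: str) -> "MLRModel":
        lm = builtin_model(model_id)
        est = cls(descriptor_names=lm.descriptor_names)
        est.feature_names_in_ = np.asarray(lm.descriptor_names, dtype=object)
        est.n_features_in_ = len(lm.terms)
        est.intercept_ = lm.intercept
        est.coef_ = np.array([t.coefficient for t in lm.terms])
        est.intercept_se_ = lm.intercept_se
        est.se_ = np.array([t.se for t in lm.terms])
        est.model_ = lm
        est.ols_ = None
        return est

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        if isinstance(X, pd.DataFrame):
            return self.model_.predict(X)
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_
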