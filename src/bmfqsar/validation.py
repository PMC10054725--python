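"""Dataset splitting, OLS fitting and internal/external validation statistics.

The statistics follow standard QSAR practice: R2/RMSE/MAE on the training
set, leave-one-out and leave-many-out cross-validated Q2, the external
Q2-F3 (external error against training variance) and Lin's concordance
correlation coefficient.  Leave-one-out PRESS is computed through the OLS
hat-matrix identity e_i/(1-h_i) rather than by n refits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .io import Dataset


class RankDeficiencyError(np.linalg.LinAlgError):
    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear column(s): {self.columns}")


@dataclass
class OLSFit:
    """Ordinary least squares fit with the diagnostics the QSAR layer needs."""

    coefficients: np.ndarray  # intercept first when add_intercept
    se: np.ndarray
    residuals: np.ndarray
    fitted: np.ndarray
    hat_diag: np.ndarray
    s: float  # sqrt(RSS / (n - p'))
    xtx_inv: np.ndarray
    n: int
    p_prime: int  # number of estimated parameters (variables + intercept)
    add_intercept: bool

    @property
    def rss(self) -> float:
        return float(np.sum(self.residuals**2))

    @property
    def y(self) -> np.ndarray:
        return self.fitted + self.residuals

    @property
    def r2(self) -> float:
        y = self.y
        tss = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - self.rss / tss


def _design(X: np.ndarray, add_intercept: bool) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if add_intercept:
        return np.column_stack([np.ones(len(X)), X])
    return X


def fit_ols(X, y, add_intercept: bool = True, column_names=None) -> OLSFit:
    """Fit y = Xb by ordinary least squares.

    ``X`` is the descriptor design (without intercept column unless
    ``add_intercept=False``).  Raises :class:`RankDeficiencyError` naming
    the collinear columns when the design is not full column rank.
    """
    d = _design(X, add_intercept)
    y = np.asarray(y, dtype=float)
    n, p = d.shape
    if n <= p:
        raise ValueError(f"need n > p' (got n={n}, p'={p})")
    rank = np.linalg.matrix_rank(d)
    if rank < p:
        # pivoted QR: columns pivoted beyond the rank are the dependent ones
        _, _, piv = linalg.qr(d, pivoting=True, mode="economic")
        bad = sorted(piv[rank:])
        if column_names is None:
            column_names = (["<intercept>"] if add_intercept else []) + [
                f"col{i}" for i in range(p - int(add_intercept))
            ]
        else:
            column_names = (["<intercept>"] if add_intercept else []) + list(column_names)
        raise RankDeficiencyError([column_names[i] for i in bad])
    xtx_inv = np.linalg.inv(d.T @ d)
    beta = xtx_inv @ d.T @ y
    fitted = d @ beta
    resid = y - fitted
    dof = n - p
    s2 = float(resid @ resid) / dof
    se = np.sqrt(np.diag(xtx_inv) * s2)
    hat = np.einsum("ij,jk,ik->i", d, xtx_inv, d)
    return OLSFit(
        coefficients=beta,
        se=se,
        residuals=resid,
        fitted=fitted,
        hat_diag=hat,
        s=float(np.sqrt(s2)),
        xtx_inv=xtx_inv,
        n=n,
        p_prime=p,
        add_intercept=add_intercept,
    )


def basic_stats(y, y_hat) -> tuple[float, float, float]:
    """(R2, RMSE, MAE); R2 is computed against the mean of ``y``."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if len(y) != len(y_hat) or len(y) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("zero variance in y; R2 undefined")
    err = y - y_hat
    r2 = 1.0 - float(np.sum(err**2)) / tss
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    return r2, rmse, mae


def press_loo(fit: OLSFit) -> float:
    """Leave-one-out PRESS via the hat identity sum (e_i/(1-h_i))^2."""
    if np.any(fit.hat_diag >= 1.0 - 1e-12):
        raise ValueError("a leverage equals 1 (exact-fit point); LOO undefined")
    return float(np.sum((fit.residuals / (1.0 - fit.hat_diag)) ** 2))


def q2_loo(X, y, add_intercept: bool = True) -> float:
    """Leave-one-out cross-validated Q2 = 1 - PRESS/TSS."""
    y = np.asarray(y, dtype=float)
    fit = fit_ols(X, y, add_intercept=add_intercept)
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press_loo(fit) / tss


def rmse_cv_loo(X, y, add_intercept: bool = True) -> float:
    """RMSE of the leave-one-out predictions."""
    fit = fit_ols(X, np.asarray(y, float), add_intercept=add_intercept)
    return float(np.sqrt(press_loo(fit) / fit.n))


def q2_lmo(
    X, y, leave_fraction: float = 0.3, iterations: int = 1000, seed: int | None = 0,
    add_intercept: bool = True,
) -> float:
    """Leave-many-out Q2: mean over seeded random deletions of
    1 - PRESS_out/TSS_out (TSS_out against the retained-set mean)."""
    if not 0 < leave_fraction <= 0.5:
        raise ValueError("leave_fraction must be in (0, 0.5]")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n = len(y)
    n_out = max(1, int(round(n * leave_fraction)))
    p_prime = X.shape[1] + int(add_intercept)
    if n - n_out <= p_prime:
        raise ValueError("retained set too small for the model size")
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(iterations):
        out = rng.choice(n, size=n_out, replace=False)
        mask = np.ones(n, dtype=bool)
        mask[out] = False
        fit = fit_ols(X[mask], y[mask], add_intercept=add_intercept)
        d_out = _design(X[out], add_intercept)
        pred = d_out @ fit.coefficients
        press = float(np.sum((y[out] - pred) ** 2))
        tss = float(np.sum((y[out] - y[mask].mean()) ** 2))
        if tss == 0:
            continue
        vals.append(1.0 - press / tss)
    return float(np.mean(vals))


def q2_f3(y_train, y_ext, y_ext_hat) -> float:
    """External Q2-F3: 1 - [SSE_ext/n_ext] / [TSS_train/n_train]."""
    y_train = np.asarray(y_train, dtype=float)
    y_ext = np.asarray(y_ext, dtype=float)
    y_ext_hat = np.asarray(y_ext_hat, dtype=float)
    if len(y_train) == 0 or len(y_ext) == 0:
        raise ValueError("both sets must be non-empty")
    tss = float(np.sum((y_train - y_train.mean()) ** 2))
    if tss == 0:
        raise ValueError("zero training variance")
    mse_ext = float(np.mean((y_ext - y_ext_hat) ** 2))
    return 1.0 - mse_ext / (tss / len(y_train))


def ccc(y, y_hat) -> float:
    """Lin's concordance correlation coefficient (population moments):
    2 cov(y, y_hat) / [var(y) + var(y_hat) + (mean gap)^2]."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if len(y) != len(y_hat) or len(y) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    vy = float(np.var(y))
    vh = float(np.var(y_hat))
    gap = float(y.mean() - y_hat.mean())
    denom = vy + vh + gap**2
    if denom == 0:
        raise ValueError("degenerate inputs; CCC undefined")
    cov = float(np.mean((y - y.mean()) * (y_hat - y_hat.mean())))
    return 2.0 * cov / denom


# ---------------------------------------------------------------------------
# splitting

def split_indices(y, stride: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Response-ordered split: sort ascending, send every record whose
    1-based sorted position is a multiple of ``stride`` to the prediction
    set, but always keep the global minimum and maximum in training.

    Returns (train_idx, test_idx) into the original order.
    """
    if stride < 2:
        raise ValueError("stride must be >= 2")
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < stride + 2:
        raise ValueError(f"need at least stride+2={stride + 2} records")
    order = np.argsort(y, kind="stable")
    test_pos = {p for p in range(stride, n + 1, stride)} - {1, n}
    test_idx = np.array(sorted(order[p - 1] for p in test_pos))
    train_idx = np.array(sorted(set(range(n)) - set(test_idx.tolist())))
    return train_idx, test_idx


def split_by_response(ds: Dataset, stride: int = 4) -> tuple[Dataset, Dataset]:
    """Split a dataset into training and prediction sets by the response rule."""
    train_idx, test_idx = split_indices(ds.responses(), stride=stride)
    return (
        Dataset([ds.records[i] for i in train_idx], name=f"{ds.name}-train"),
        Dataset([ds.records[i] for i in test_idx], name=f"{ds.name}-test"),
    )


# ---------------------------------------------------------------------------
# reports

def validation_report(
    X_train, y_train, X_ext=None, y_ext=None, seed: int | None = 0,
    lmo_fraction: float = 0.3, lmo_iterations: int = 1000,
) -> dict:
    """Full internal (and optionally external) validation of an OLS model."""
    fit = fit_ols(X_train, y_train)
    r2, rmse_tr, mae_tr = basic_stats(y_train, fit.fitted)
    report = {
        "n_training": fit.n,
        "R2": r2,
        "RMSE_tr": rmse_tr,
        "MAE_tr": mae_tr,
        "Q2_LOO": q2_loo(X_train, y_train),
        "RMSE_cv": rmse_cv_loo(X_train, y_train),
        "Q2_LMO": q2_lmo(X_train, y_train, lmo_fraction, lmo_iterations, seed),
    }
    if X_ext is not None and y_ext is not None:
        d_ext = _design(np.asarray(X_ext, float), fit.add_intercept)
        pred = d_ext @ fit.coefficients
        r2_ext, rmse_ext, mae_ext = basic_stats(y_ext, pred)
        report.update(
            {
                "n_prediction": len(pred),
                "RMSE_ext": rmse_ext,
                "MAE_ext": mae_ext,
                "R2_ext": r2_ext,
                "Q2_F3": q2_f3(y_train, y_ext, pred),
                "CCC_ext": ccc(y_ext, pred),
            }
        )
    return report


def average_fold_stats(per_fold: list[dict]) -> dict:
    """Mean of each numeric statistic across cross-validation folds."""
    keys = [k for k in per_fold[0] if isinstance(per_fold[0][k], (int, float))]
    return {k: float(np.mean([f[k] for f in per_fold])) for k in keys}


def kfold_cv(
    ds: Dataset,
    pool: pd.DataFrame,
    k: int = 5,
    model_size: int = 7,
    seed: int | None = 0,
    ga_config=None,
    reselect: bool = True,
    shuffle: bool = False,
) -> dict:
    """k-fold cross-validation with per-fold descriptor re-selection.

    Folds are venetian blinds over response-sorted records (record of sorted
    rank r goes to fold r mod k), deterministic; ``shuffle=True`` uses a
    seeded random assignment instead.  In each round a fresh GA variable
    selection of ``model_size`` descriptors is run on the retained folds
    (skipped when ``reselect`` is False or the pool is already at model
    size), an OLS model is fitted, and RMSE/MAE are measured on the
    held-out fold.

    Returns a dict with ``per_fold`` stats, their ``average``, and the
    descriptor selection ``frequencies`` across folds.
    """
    from .modelbuild import GAConfig, ga_vss

    if k < 2:
        raise ValueError("k must be >= 2")
    if pool.shape[1] < model_size:
        raise ValueError("descriptor pool smaller than model_size")
    y = np.asarray(ds.responses(), dtype=float)
    n = len(y)
    ranks = np.empty(n, dtype=int)
    ranks[np.argsort(y, kind="stable")] = np.arange(n)
    if shuffle:
        rng = np.random.default_rng(seed)
        folds = rng.permutation(n) % k
    else:
        folds = ranks % k
    per_fold = []
    freq: dict[str, int] = {}
    for fold in range(k):
        test = folds == fold
        train = ~test
        if train.sum() <= model_size + 1:
            raise ValueError("training fold too small for the model size")
        X_tr = pool.iloc[train]
        y_tr = y[train]
        if reselect and pool.shape[1] > model_size:
            cfg = ga_config or GAConfig(model_size=model_size, seed=(seed or 0) + fold)
            pop = ga_vss(X_tr, y_tr, cfg)
            names = list(pop.best.subset)
        else:
            names = list(pool.columns[:model_size])
        fit = fit_ols(X_tr[names].to_numpy(), y_tr)
        d_test = _design(pool.iloc[test][names].to_numpy(dtype=float), True)
        pred = d_test @ fit.coefficients
        err = y[test] - pred
        per_fold.append(
            {
                "fold": fold,
                "n_test": int(test.sum()),
                "RMSE_test": float(np.sqrt(np.mean(err**2))),
                "MAE_test": float(np.mean(np.abs(err))),
                "descriptors": names,
            }
        )
        for name in names:
            freq[name] = freq.get(name, 0) + 1
    numeric = [
        {k_: v for k_, v in f.items() if isinstance(v, float)} for f in per_fold
    ]
    return {
        "per_fold": per_fold,
        "average": average_fold_stats(numeric),
        "frequencies": dict(sorted(freq.items(), key=lambda kv: -kv[1])),
    }
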