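"""Partial least squares regression of gait changes on lobular E-fields.

Two-block regression-mode PLS (PLS2), implemented from scratch on
centered, unscaled data.  Each component extracts the dominant singular
direction of the current cross-covariance matrix X'Y (the "salience"),
projects X onto it to form a latent variable (score), regresses both
blocks on that score to obtain loadings, and deflates.  Latent variables
are therefore the linear combinations of predictors carrying the most
covariance with the responses; per-component fractions of the centered
sums of squares of X and Y quantify what each latent variable captures.

The estimator follows the scikit-learn protocol (``fit`` / ``predict`` /
``score`` / ``get_params`` / ``set_params``, fitted attributes with a
trailing underscore) so it composes with sklearn model-selection tooling;
the module-level functions are thin wrappers kept for pipeline use.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .events import SchemaError
from .indices import InvalidInputError

_EPS = np.finfo(float).eps


def center_columns(matrix) -> tuple[np.ndarray, np.ndarray]:
    """Subtract column means; return the centered matrix and the means.

    No scaling to unit variance is applied — predictors are all in V/m and
    responses all in percent change, so the blocks are kept in their
    natural units.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InvalidInputError("need a 2-D matrix with at least 2 rows")
    means = X.mean(axis=0)
    return X - means, means


def response_r2(y_observed, y_fitted) -> float:
    """Pooled coefficient of determination over all response columns.

    ``1 - SS_res / SS_tot`` with both sums pooled across columns about the
    observed column means.
    """
    Y = np.asarray(y_observed, dtype=float)
    F = np.asarray(y_fitted, dtype=float)
    if Y.shape != F.shape:
        raise InvalidInputError("observed and fitted shapes differ")
    ss_tot = float(((Y - Y.mean(axis=0)) ** 2).sum())
    if ss_tot == 0:
        raise InvalidInputError("zero total sum of squares: R^2 undefined")
    ss_res = float(((Y - F) ** 2).sum())
    return 1.0 - ss_res / ss_tot


class PLSEFieldRegressor:
    """PLS2 regression estimator relating E-field predictors to gait changes.

    Parameters
    ----------
    n_components : int, default 10
        Number of latent variables requested; capped at
        ``min(n_rows - 1, n_predictors)`` and truncated early if the
        residual cross-covariance becomes rank deficient.

    Attributes (after ``fit``)
    --------------------------
    x_mean_, y_mean_ : column means used for centering.
    x_weights_ : (p, K) saliences; the deterministic sign convention makes
        each component's largest-magnitude weight positive.
    x_scores_ : (n, K) latent variables, mutually orthogonal.
    x_loadings_, y_loadings_ : (p, K) and (m, K) regression loadings.
    coef_ : (p, m) coefficient matrix mapping centered X to centered Y.
    pct_var_x_, pct_var_y_ : per-component % of each block's centered sum
        of squares captured.
    r_squared_ : pooled R^2 of the training fit.
    """

    def __init__(self, n_components: int = 10, max_rank_tol: float = 1e-12):
        self.n_components = n_components
        self.max_rank_tol = max_rank_tol

    # -- sklearn protocol ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components,
                "max_rank_tol": self.max_rank_tol}

    def set_params(self, **params) -> "PLSEFieldRegressor":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    # -----------------------------------------------------------------------
    def _validate(self, X, Y) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            if isinstance(Y, pd.DataFrame) and not X.index.equals(Y.index):
                raise SchemaError("X and Y row keys do not match")
        else:
            self.feature_names_in_ = None
        self.response_names_ = (np.asarray(Y.columns, dtype=object)
                                if isinstance(Y, pd.DataFrame) else None)
        Xa = np.asarray(X, dtype=float)
        Ya = np.asarray(Y, dtype=float)
        if Ya.ndim == 1:
            Ya = Ya[:, None]
        if Xa.shape[0] != Ya.shape[0]:
            raise InvalidInputError("X and Y row counts differ")
        if not np.isfinite(Xa).all() or not np.isfinite(Ya).all():
            raise InvalidInputError("inputs contain non-finite values")
        return Xa, Ya

    def fit(self, X, Y) -> "PLSEFieldRegressor":
        Xa, Ya = self._validate(X, Y)
        n, p = Xa.shape
        m = Ya.shape[1]
        if n < 2:
            raise InvalidInputError("need at least 2 observations")
        k_max = min(n - 1, p)
        if not 1 <= self.n_components:
            raise InvalidInputError("n_components must be >= 1")
        k_req = min(self.n_components, k_max)

        Xc, self.x_mean_ = center_columns(Xa)
        Yc, self.y_mean_ = center_columns(Ya)
        ss_x = float((Xc ** 2).sum())
        ss_y = float((Yc ** 2).sum())

        Xk, Yk = Xc.copy(), Yc.copy()
        W = np.zeros((p, k_req))
        T = np.zeros((n, k_req))
        P = np.zeros((p, k_req))
        Q = np.zeros((m, k_req))
        var_x, var_y = [], []
        s0 = None
        k_eff = 0
        for k in range(k_req):
            S = Xk.T @ Yk
            U, sv, _ = np.linalg.svd(S, full_matrices=False)
            if s0 is None:
                s0 = sv[0] if sv.size else 0.0
            if sv.size == 0 or sv[0] <= self.max_rank_tol * max(s0, 1.0):
                warnings.warn(
                    f"cross-covariance rank deficient at component {k + 1}; "
                    f"model truncated to {k} components", RuntimeWarning)
                break
            w = U[:, 0]
            w = w * np.sign(w[np.argmax(np.abs(w))])  # deterministic sign
            t = Xk @ w
            tt = float(t @ t)
            if tt <= _EPS * n:
                warnings.warn(
                    f"degenerate score at component {k + 1}; model truncated",
                    RuntimeWarning)
                break
            p_load = Xk.T @ t / tt
            q_load = Yk.T @ t / tt
            Xk = Xk - np.outer(t, p_load)
            Yk = Yk - np.outer(t, q_load)
            W[:, k], T[:, k], P[:, k], Q[:, k] = w, t, p_load, q_load
            var_x.append(tt * float(p_load @ p_load) / ss_x * 100.0 if ss_x else 0.0)
            var_y.append(tt * float(q_load @ q_load) / ss_y * 100.0 if ss_y else 0.0)
            k_eff += 1

        if k_eff == 0:
            raise InvalidInputError("no PLS component could be extracted")
        W, T, P, Q = W[:, :k_eff], T[:, :k_eff], P[:, :k_eff], Q[:, :k_eff]
        # coefficients for the direct map: B = W (P'W)^-1 Q'
        R = W @ np.linalg.inv(P.T @ W)
        self.coef_ = R @ Q.T
        self.n_components_ = k_eff
        self.x_weights_, self.x_scores_ = W, T
        self.x_loadings_, self.y_loadings_ = P, Q
        self.pct_var_x_ = np.asarray(var_x)
        self.pct_var_y_ = np.asarray(var_y)
        fitted = Xc @ self.coef_ + self.y_mean_
        self.r_squared_ = response_r2(Ya, fitted)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "coef_"):
            raise InvalidInputError("model is not fitted")

    def _align(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame) and self.feature_names_in_ is not None:
            missing = set(self.feature_names_in_) - set(X.columns)
            if missing:
                raise SchemaError(f"missing predictor columns: {sorted(missing)}")
            X = X.loc[:, list(self.feature_names_in_)]
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa[None, :]
        if Xa.shape[1] != self.coef_.shape[0]:
            raise SchemaError("predictor column count does not match training")
        return Xa

    def predict(self, X):
        """Fitted responses: ``(X - x_means) @ coef + y_means``."""
        self._check_fitted()
        Xa = self._align(X)
        out = (Xa - self.x_mean_) @ self.coef_ + self.y_mean_
        if isinstance(X, pd.DataFrame) and self.response_names_ is not None:
            return pd.DataFrame(out, index=X.index, columns=self.response_names_)
        return out

    def transform(self, X) -> np.ndarray:
        """Project new predictors onto the latent variables."""
        self._check_fitted()
        Xa = self._align(X) - self.x_mean_
        # scores via the direct projection R = W (P'W)^-1
        R = self.x_weights_ @ np.linalg.inv(
            self.x_loadings_.T @ self.x_weights_)
        return Xa @ R

    def score(self, X, Y) -> float:
        """Pooled R^2 of predictions on (X, Y)."""
        pred = self.predict(X)
        return response_r2(np.asarray(Y, dtype=float).reshape(np.asarray(pred).shape),
                           np.asarray(pred, dtype=float))

    # -- reporting ----------------------------------------------------------
    def explained_variance(self) -> pd.DataFrame:
        """Per-component and cumulative % variance captured in X and Y."""
        self._check_fitted()
        k = np.arange(1, self.n_components_ + 1)
        return pd.DataFrame({
            "component": k,
            "pct_var_x": self.pct_var_x_,
            "pct_var_y": self.pct_var_y_,
            "cum_pct_var_x": np.cumsum(self.pct_var_x_),
            "cum_pct_var_y": np.cumsum(self.pct_var_y_),
        })

    def predictor_importance(self) -> pd.Series:
        """L2 norm of each predictor's row of the coefficient matrix."""
        self._check_fitted()
        norms = np.linalg.norm(self.coef_, axis=1)
        index = (self.feature_names_in_ if self.feature_names_in_ is not None
                 else np.arange(self.coef_.shape[0]))
        return pd.Series(norms, index=index, name="importance")

    def to_dict(self) -> dict:
        """JSON-serializable summary of the fitted model."""
        self._check_fitted()
        names_x = (list(self.feature_names_in_)
                   if self.feature_names_in_ is not None else None)
        names_y = (list(self.response_names_)
                   if self.response_names_ is not None else None)
        return {
            "n_components": int(self.n_components_),
            "predictors": names_x,
            "responses": names_y,
            "x_means": self.x_mean_.tolist(),
            "y_means": self.y_mean_.tolist(),
            "x_weights": self.x_weights_.tolist(),
            "x_loadings": self.x_loadings_.tolist(),
            "y_loadings": self.y_loadings_.tolist(),
            "coefficients": self.coef_.tolist(),
            "pct_var_x": self.pct_var_x_.tolist(),
            "pct_var_y": self.pct_var_y_.tolist(),
            "r_squared": float(self.r_squared_),
        }


# -- functional wrappers ----------------------------------------------------

def fit_pls(X, Y, n_components: int = 10) -> PLSEFieldRegressor:
    """Fit a :class:`PLSEFieldRegressor` and return it."""
    return PLSEFieldRegressor(n_components=n_components).fit(X, Y)


def explained_variance(model: PLSEFieldRegressor) -> pd.DataFrame:
    return model.explained_variance()


def predict_responses(model: PLSEFieldRegressor, X_new):
    return model.predict(X_new)


def extract_loadings(
    model: PLSEFieldRegressor,
    efield: pd.DataFrame | None = None,
    montage_a: str = "dentate",
    montage_b: str = "leg",
) -> dict[str, pd.DataFrame]:
    """Tidy long-format loading tables, plus a montage field contrast.

    Returns ``x_loadings`` and ``y_loadings`` as (component, variable,
    loading) tables; when an E-field matrix with a montage index level is
    given, adds ``contrast`` — the per-lobule difference of montage-mean
    field strengths (montage_a minus montage_b).
    """
    model._check_fitted()
    out: dict[str, pd.DataFrame] = {}
    for key, loadings, names in (
        ("x_loadings", model.x_loadings_, model.feature_names_in_),
        ("y_loadings", model.y_loadings_, model.response_names_),
    ):
        labels = (list(names) if names is not None
                  else [f"var{i}" for i in range(loadings.shape[0])])
        rows = [
            {"component": k + 1, "variable": labels[j],
             "loading": float(loadings[j, k])}
            for k in range(loadings.shape[1])
            for j in range(loadings.shape[0])
        ]
        out[key] = pd.DataFrame(rows)
    if efield is not None:
        means = efield.groupby(level="montage").mean()
        contrast = means.loc[montage_a] - means.loc[montage_b]
        out["contrast"] = contrast.rename("contrast").rename_axis("lobule").reset_index()
    return out
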