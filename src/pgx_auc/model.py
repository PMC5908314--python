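"""Exponential standard-AUC regression with subset selection, plus the
quartile-based dose-advice rule.

The model is y = exp(b0 + sum_i b_i x_i) where y is the standard AUC
(AUC / daily dose, ng*hr/ml per mg/day) and the x_i are drawn from 13
candidate covariates: two genotype indicators per panel locus plus the
daily dose.  Fitting is ordinary least squares of ln(y) on a selected
subset of exactly k candidates (default k = 8), with the subset chosen by
forward selection on leave-one-out squared error (exhaustive best-subset
optional).  "Calculated AUC" = predicted standard AUC x dose is the
pre-treatment exposure estimate; training-cohort quartiles of calculated
AUC freeze the low / mid / high stratification used for dose advice.
"""

from __future__ import annotations

import hashlib
import itertools
import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .panel import DOSE_LABEL, candidate_labels
from .stats import kruskal_wallis, simple_linear_regression

AUC_LOW = "low"
AUC_MID = "mid"
AUC_HIGH = "high"

DOSE_ACTIONS = {
    AUC_LOW: "consider_increase",
    AUC_MID: "maintain",
    AUC_HIGH: "consider_decrease",
}


def _loo_press(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Leave-one-out mean squared prediction error for OLS of y on
    [1 | X], via the hat-matrix shortcut e_loo = e / (1 - h)."""
    n = X.shape[0]
    Z = np.column_stack([np.ones(n), X])
    coef, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    if rank < Z.shape[1]:
        return np.inf, coef
    resid = y - Z @ coef
    # h_ii = z_i' (Z'Z)^{-1} z_i
    G = np.linalg.inv(Z.T @ Z)
    h = np.einsum("ij,jk,ik->i", Z, G, Z)
    denom = 1.0 - h
    # leverage-one points force a zero residual and an indeterminate LOO
    # error; they carry no information, so drop them from the mean
    mask = denom > 1e-8
    if not mask.any():
        return np.inf, coef
    return float(np.mean((resid[mask] / denom[mask]) ** 2)), coef


class ExponentialAUCRegressor(BaseEstimator, RegressorMixin):
    """Predict standard AUC from genotype indicators and dose.

    Parameters
    ----------
    k : int, default 8
        Number of candidate covariates to select (out of 13).
    selection : {"forward", "exhaustive"} or sequence of column indices
        Subset-selection strategy.  "forward" adds the candidate that most
        reduces leave-one-out squared error on the log scale, ties broken
        by lower column index; "exhaustive" scores every k-subset by the
        same criterion; an explicit index sequence forces the subset.
    feature_names : sequence of str, optional
        Labels for the 13 candidates; defaults to the six-locus panel order.

    Attributes
    ----------
    intercept_ : float
        b0, log ng*hr/ml per mg/day.
    coef_ : ndarray of shape (k,)
        Coefficients b_i of the selected covariates, in selection order of
        ``selected_idx_``.
    selected_idx_, selected_labels_ : the chosen candidate subset.
    coef_se_, intercept_se_ : OLS standard errors on the log scale.
    training_quartiles_ : (Q1, Q3) of training calculated AUC (ng*hr/ml),
        linear-interpolation percentile convention.
    r_squared_log_, r_squared_auc_ : in-sample fit diagnostics.
    """

    def __init__(self, k: int = 8, selection="forward", feature_names=None):
        self.k = k
        self.selection = selection
        self.feature_names = feature_names

    # -- fitting -----------------------------------------------------------

    def _validate_X(self, X) -> tuple[np.ndarray, list[str]]:
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            names = (
                list(self.feature_names)
                if self.feature_names is not None
                else candidate_labels()
            )
            if len(names) != X.shape[1]:
                names = [f"x{j}" for j in range(X.shape[1])]
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if np.isnan(X).any():
            raise ValueError("X contains NaN (non-evaluable patients?); drop them first")
        return X, names

    def fit(self, X, y) -> "ExponentialAUCRegressor":
        """Fit on standard AUC values y (> 0, ng*hr/ml per mg/day).

        The dose column of X (last column by panel convention) is also used
        to compute training calculated-AUC quartiles.
        """
        X, names = self._validate_X(X)
        y = np.asarray(y, dtype=float)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y differ in length")
        bad = np.where(y <= 0)[0]
        if bad.size:
            raise ValueError(
                f"standard AUC must be positive; offending rows: {bad.tolist()}"
            )
        if X.shape[0] < self.k + 2:
            raise ValueError(f"need n >= k + 2 = {self.k + 2}, got n = {X.shape[0]}")
        logy = np.log(y)

        if isinstance(self.selection, str) and self.selection == "forward":
            idx = self._forward_select(X, logy)
        elif isinstance(self.selection, str) and self.selection == "exhaustive":
            idx = self._exhaustive_select(X, logy)
        elif isinstance(self.selection, str):
            raise ValueError(f"unknown selection method {self.selection!r}")
        else:
            idx = list(self.selection)
            if len(idx) != self.k:
                raise ValueError("explicit selection must supply exactly k indices")

        Z = np.column_stack([np.ones(X.shape[0]), X[:, idx]])
        coef, _, rank, _ = np.linalg.lstsq(Z, logy, rcond=None)
        if rank < Z.shape[1]:
            raise ValueError("selected design is rank-deficient")
        resid = logy - Z @ coef
        dof = max(X.shape[0] - Z.shape[1], 1)
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(Z.T @ Z)
        se = np.sqrt(np.diag(cov))

        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = names
        self.selected_idx_ = list(idx)
        self.selected_labels_ = [names[j] for j in idx]
        self.intercept_ = float(coef[0])
        self.coef_ = coef[1:]
        self.intercept_se_ = float(se[0])
        self.coef_se_ = se[1:]
        self.sigma_log_ = float(np.sqrt(sigma2))

        fitted_log = Z @ coef
        ss = float(((logy - logy.mean()) ** 2).sum())
        self.r_squared_log_ = 1.0 - float(resid @ resid) / ss if ss > 0 else 1.0
        fitted_auc = np.exp(fitted_log) * X[:, -1]
        actual_auc = y * X[:, -1]
        ssa = float(((actual_auc - actual_auc.mean()) ** 2).sum())
        self.r_squared_auc_ = (
            1.0 - float(((actual_auc - fitted_auc) ** 2).sum()) / ssa if ssa > 0 else 1.0
        )

        calc = np.exp(fitted_log) * X[:, -1]
        self.training_quartiles_ = (
            float(np.percentile(calc, 25)),
            float(np.percentile(calc, 75)),
        )
        self.training_hash_ = hashlib.sha256(
            np.ascontiguousarray(X).tobytes() + np.ascontiguousarray(y).tobytes()
        ).hexdigest()[:16]
        return self

    def _usable(self, X: np.ndarray, j: int) -> bool:
        return np.ptp(X[:, j]) > 0

    def _forward_select(self, X: np.ndarray, logy: np.ndarray) -> list[int]:
        selected: list[int] = []
        candidates = [j for j in range(X.shape[1]) if self._usable(X, j)]
        if len(candidates) < self.k:
            raise ValueError(
                f"only {len(candidates)} non-constant candidates for k = {self.k}"
            )
        for _ in range(self.k):
            best_j, best_score = None, np.inf
            for j in candidates:
                if j in selected:
                    continue
                score, _ = _loo_press(X[:, selected + [j]], logy)
                if score < best_score - 1e-15:  # strict improvement; ties -> lower index
                    best_j, best_score = j, score
            if best_j is None:
                raise ValueError("forward selection found no admissible candidate")
            selected.append(best_j)
        return selected

    def _exhaustive_select(self, X: np.ndarray, logy: np.ndarray) -> list[int]:
        candidates = [j for j in range(X.shape[1]) if self._usable(X, j)]
        best_subset, best_score = None, np.inf
        for subset in itertools.combinations(candidates, self.k):
            score, _ = _loo_press(X[:, list(subset)], logy)
            if score < best_score - 1e-15:
                best_subset, best_score = list(subset), score
        if best_subset is None:
            raise ValueError("no full-rank k-subset exists")
        return best_subset

    # -- prediction --------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "coef_"):
            raise AttributeError("model is not fitted")

    def predict(self, X) -> np.ndarray:
        """Predicted standard AUC, y = exp(b0 + sum b_i x_i); strictly positive."""
        self._check_fitted()
        if isinstance(X, pd.DataFrame):
            missing = [l for l in self.selected_labels_ if l not in X.columns]
            if missing:
                raise ValueError(f"design is missing selected covariates: {missing}")
            Xs = X[self.selected_labels_].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim == 1:
                X = X[None, :]
            if X.shape[1] == len(self.selected_idx_):
                Xs = X
            elif X.shape[1] == self.n_features_in_:
                Xs = X[:, self.selected_idx_]
            else:
                raise ValueError(
                    f"X has {X.shape[1]} columns; expected {self.n_features_in_} "
                    f"candidates or {len(self.selected_idx_)} selected covariates"
                )
        return np.exp(self.intercept_ + Xs @ self.coef_)

    def predict_calculated_auc(self, X, dose) -> np.ndarray:
        """Calculated AUC (ng*hr/ml) = predicted standard AUC x daily dose."""
        dose = np.asarray(dose, dtype=float)
        if np.any((dose < 2.0) | (dose > 20.0)):
            raise ValueError("dose outside the supported 2-20 mg/day range")
        return self.predict(X) * dose

    def categorize(self, calculated_auc) -> np.ndarray:
        """low / mid / high against the frozen training quartiles
        (boundaries inclusive: <= Q1 is low, >= Q3 is high)."""
        self._check_fitted()
        q1, q3 = self.training_quartiles_
        calc = np.atleast_1d(np.asarray(calculated_auc, dtype=float))
        out = np.full(calc.shape, AUC_MID, dtype=object)
        out[calc <= q1] = AUC_LOW
        out[calc >= q3] = AUC_HIGH
        return out

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "intercept": self.intercept_,
            "coefficients": dict(zip(self.selected_labels_, self.coef_.tolist())),
            "selected_labels": self.selected_labels_,
            "selected_idx": self.selected_idx_,
            "k": self.k,
            "selection": self.selection if isinstance(self.selection, str) else "forced",
            "training_quartiles": list(self.training_quartiles_),
            "r_squared_log": self.r_squared_log_,
            "r_squared_auc": self.r_squared_auc_,
            "sigma_log": self.sigma_log_,
            "feature_names": self.feature_names_in_,
            "training_hash": self.training_hash_,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ExponentialAUCRegressor":
        m = cls(k=d["k"], selection=d.get("selection", "forward"))
        m.feature_names_in_ = list(d["feature_names"])
        m.n_features_in_ = len(m.feature_names_in_)
        m.selected_labels_ = list(d["selected_labels"])
        m.selected_idx_ = list(d["selected_idx"])
        m.intercept_ = float(d["intercept"])
        m.coef_ = np.array([d["coefficients"][l] for l in m.selected_labels_])
        m.training_quartiles_ = tuple(d["training_quartiles"])
        m.r_squared_log_ = d.get("r_squared_log", float("nan"))
        m.r_squared_auc_ = d.get("r_squared_auc", float("nan"))
        m.sigma_log_ = d.get("sigma_log", float("nan"))
        m.training_hash_ = d.get("training_hash", "")
        return m

    @classmethod
    def load(cls, path) -> "ExponentialAUCRegressor":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# -- module-level functional surface ---------------------------------------


def fit_exponential_model(
    design, standard_auc, k: int = 8, selection_method="forward"
) -> ExponentialAUCRegressor:
    """Fit the exponential standard-AUC model; see ExponentialAUCRegressor."""
    return ExponentialAUCRegressor(k=k, selection=selection_method).fit(
        design, standard_auc
    )


def predict_standard_auc(model: ExponentialAUCRegressor, design) -> np.ndarray:
    return model.predict(design)


def predict_calculated_auc(model: ExponentialAUCRegressor, design, dose) -> np.ndarray:
    return model.predict_calculated_auc(design, dose)


def categorize_auc(calculated_auc, model: ExponentialAUCRegressor) -> np.ndarray:
    return model.categorize(calculated_auc)


def recommend_dose_action(category: str) -> dict:
    """Advisory dose action for an exposure category (no mg mapping).

    low exposure -> consider a higher starting dose (efficacy is
    exposure-linked); high -> consider a lower one (toxicity is
    exposure-linked); mid -> keep the standard dose.
    """
    if category not in DOSE_ACTIONS:
        raise ValueError(f"unknown category {category!r}")
    code = DOSE_ACTIONS[category]
    text = {
        "consider_increase": "Calculated AUC in the lowest quartile: consider a higher initial dose.",
        "maintain": "Calculated AUC mid-range: maintain the standard initial dose.",
        "consider_decrease": "Calculated AUC in the highest quartile: consider a lower initial dose.",
    }[code]
    return {"code": code, "advice": text}


def evaluate_calibration(calculated, actual, quartiles=None) -> dict:
    """Linear regression of actual on calculated AUC plus a Kruskal-Wallis
    test of actual AUC across low/mid/high calculated-AUC categories.

    quartiles : (Q1, Q3) to freeze the categories (e.g. the training
        quartiles for a validation split); defaults to the quartiles of the
        supplied calculated values.
    """
    calculated = np.asarray(calculated, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if calculated.size != actual.size:
        raise ValueError("calculated and actual differ in length")
    reg = simple_linear_regression(calculated, actual)
    if quartiles is None:
        q1, q3 = np.percentile(calculated, 25), np.percentile(calculated, 75)
    else:
        q1, q3 = quartiles
    groups = [
        actual[calculated <= q1],
        actual[(calculated > q1) & (calculated < q3)],
        actual[calculated >= q3],
    ]
    groups = [g for g in groups if g.size > 0]
    if len(groups) >= 2:
        kw = kruskal_wallis(*groups)
        kw_p = kw.p_value
    else:
        kw_p = float("nan")
    return {
        "r_squared": reg["r_squared"],
        "regression_p": reg["p_value"],
        "slope": reg["slope"],
        "intercept": reg["intercept"],
        "kw_p_by_category": kw_p,
        "n": int(calculated.size),
    }
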