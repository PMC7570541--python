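"""From-scratch PLS1 calibration with PRESS-based model selection.

Partial least squares regresses the analyte concentration ``y`` on the
(preprocessed) spectra ``X`` by sequentially extracting latent variables
(LVs) that maximize covariance with ``y``.  The NIPALS recursion used here
is, per component::

    w = X'y / ||X'y||        (unit-norm weight)
    t = X w                  (score)
    p = X't / t't            (x-loading)
    q = y't / t't            (y-loading)
    X <- X - t p',  y <- y - q t        (deflation)

after mean-centering X and y; the prediction-ready regression vector is
``b = W (P'W)^{-1} q`` so that ``y_hat = (X_new - x_mean) b + y_mean``.
Channels are mean-centered only (no unit-variance scaling), the standard
choice for absorbance spectra.

The latent-variable count is chosen from the PRESS curve: for each
candidate k, the prediction error sum of squares over leave-one-out folds,
picking the smallest k whose PRESS is within a tolerance (default 5%) of
the curve minimum.  The selected model is then summarized by leave-one-out
cross-validation as R^2 = 1 - SS_res/SS_tot on the CV predictions and
RMSECV = sqrt(SS_res / N) in mmol/L.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import RankExhaustedError, ValidationError

__all__ = [
    "PLSModel",
    "CVReport",
    "fit_pls1",
    "predict",
    "press_curve",
    "select_n_lv",
    "loocv_evaluate",
    "calibrate",
    "default_max_lv",
]


@dataclass
class PLSModel:
    """A fitted PLS1 model (centered-data latent-variable decomposition)."""

    x_mean: np.ndarray  # (P,)
    y_mean: float
    weights: np.ndarray  # W, (P, k), unit-norm columns
    x_loadings: np.ndarray  # P matrix, (P, k)
    y_loadings: np.ndarray  # q, (k,)
    scores: np.ndarray  # T, (N, k), training scores
    regression_vector: np.ndarray  # (P,)
    n_lv: int


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValidationError("X must be a 2-D matrix (samples x channels)")
    if X.shape[0] != y.size:
        raise ValidationError("X and y sample counts differ")
    if X.shape[0] < 2:
        raise ValidationError("calibration requires at least 2 samples")
    return X, y


def _nipals(
    Xc: np.ndarray, yc: np.ndarray, n_lv: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Run the NIPALS recursion; stop early if covariance is exhausted.

    Returns (W, P, q, T, n_achieved).
    """
    n, p = Xc.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    Xc = Xc.copy()
    yc = yc.copy()
    floor = 1e-12 * np.linalg.norm(Xc) * np.linalg.norm(yc)
    achieved = 0
    for k in range(n_lv):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw <= floor:
            break
        w /= nw
        t = Xc @ w
        tt = t @ t
        if tt <= 1e-300:  # guard division on a numerically null direction
            break
        pk = Xc.T @ t / tt
        qk = yc @ t / tt
        Xc -= np.outer(t, pk)
        yc -= qk * t
        W[:, k], P[:, k], q[k], T[:, k] = w, pk, qk, t
        achieved = k + 1
    return W[:, :achieved], P[:, :achieved], q[:achieved], T[:, :achieved], achieved


def _regression_vector(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    if W.shape[1] == 0:
        return np.zeros(W.shape[0])
    return W @ np.linalg.solve(P.T @ W, q)


def fit_pls1(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSModel:
    """Fit a PLS1 model with exactly ``n_lv`` latent variables.

    Raises :class:`RankExhaustedError` (carrying the achievable count) if
    the residual cross-covariance vanishes before ``n_lv`` components, and
    :class:`ValidationError` for zero-variance ``y`` or out-of-range
    ``n_lv``.
    """
    X, y = _validate_xy(X, y)
    n, p = X.shape
    if np.ptp(y) == 0:
        raise ValidationError("y has zero variance; nothing to calibrate")
    max_allowed = min(n - 1, p)
    if not 1 <= n_lv <= max_allowed:
        raise ValidationError(
            f"n_lv must be in [1, {max_allowed}] for {n} samples x {p} channels"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, T, achieved = _nipals(X - x_mean, y - y_mean, n_lv)
    if achieved < n_lv:
        raise RankExhaustedError(
            f"cross-covariance exhausted after {achieved} of {n_lv} latent "
            "variables",
            n_achievable=achieved,
        )
    return PLSModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        regression_vector=_regression_vector(W, P, q),
        n_lv=achieved,
    )


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict concentrations for new spectra rows."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.size:
        raise ValidationError(
            f"channel count {X_new.shape[1]} does not match model "
            f"({model.x_mean.size})"
        )
    return (X_new - model.x_mean) @ model.regression_vector + model.y_mean


def default_max_lv(n_samples: int) -> int:
    """Default PRESS search depth: min(15, N - 2)."""
    return min(15, n_samples - 2)


def _loocv_prediction_matrix(
    X: np.ndarray, y: np.ndarray, max_lv: int
) -> np.ndarray:
    """(N, max_lv) matrix: column k-1 holds LOO predictions with k LVs.

    Each fold is fitted once with up to ``max_lv`` components; if the fold
    exhausts rank earlier, predictions for larger k reuse the deepest
    achievable model (the PRESS curve goes flat there).
    """
    n = X.shape[0]
    preds = np.empty((n, max_lv))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xt, yt = X[mask], y[mask]
        x_mean = Xt.mean(axis=0)
        y_mean = yt.mean()
        W, P, q, _, achieved = _nipals(Xt - x_mean, yt - y_mean, max_lv)
        xi = X[i] - x_mean
        for k in range(1, max_lv + 1):
            kk = min(k, achieved)
            b = _regression_vector(W[:, :kk], P[:, :kk], q[:kk])
            preds[i, k - 1] = xi @ b + y_mean
    return preds


def press_curve(X: np.ndarray, y: np.ndarray, max_lv: int) -> np.ndarray:
    """PRESS(k), k = 1..max_lv, from leave-one-out folds in index order."""
    X, y = _validate_xy(X, y)
    n = X.shape[0]
    if n < 3:
        raise ValidationError("PRESS needs at least 3 samples")
    limit = min(n - 2, X.shape[1])
    if not 1 <= max_lv <= limit:
        raise ValidationError(f"max_lv must be in [1, {limit}]")
    preds = _loocv_prediction_matrix(X, y, max_lv)
    resid = preds - y[:, None]
    return np.sum(resid**2, axis=0)


def select_n_lv(press: Sequence[float], tolerance: float = 0.05) -> int:
    """Smallest k with PRESS(k) <= (1 + tolerance) * min(PRESS)."""
    press = np.asarray(press, dtype=float)
    if press.size == 0:
        raise ValidationError("PRESS curve is empty")
    bound = (1.0 + tolerance) * press.min()
    return int(np.argmax(press <= bound)) + 1


@dataclass
class CVReport:
    """Leave-one-out cross-validation summary of a PLS calibration."""

    press: np.ndarray  # PRESS per candidate LV count, (mmol/L)^2
    chosen_n_lv: int
    cv_predictions: np.ndarray  # one per sample, mmol/L
    references: np.ndarray  # reference concentrations, mmol/L
    r2: float
    rmsecv: float  # mmol/L

    def to_dict(self) -> dict:
        return {
            "press": [float(v) for v in self.press],
            "chosen_n_lv": int(self.chosen_n_lv),
            "predictions": [
                {"reference": float(r), "predicted": float(p)}
                for r, p in zip(self.references, self.cv_predictions)
            ],
            "r2": float(self.r2),
            "rmsecv": float(self.rmsecv),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def predictions_to_csv(self, path) -> None:
        """Predicted-vs-reference table (one row per sample)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("reference_mmol_per_l,predicted_mmol_per_l\n")
            for r, p in zip(self.references, self.cv_predictions):
                fh.write(f"{float(r)!r},{float(p)!r}\n")


def _summarize(press: np.ndarray, n_lv: int, preds: np.ndarray,
               y: np.ndarray) -> CVReport:
    resid = y - preds
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    rmsecv = float(np.sqrt(ss_res / y.size))
    return CVReport(
        press=press,
        chosen_n_lv=int(n_lv),
        cv_predictions=preds,
        references=y.copy(),
        r2=r2,
        rmsecv=rmsecv,
    )


def loocv_evaluate(X: np.ndarray, y: np.ndarray, n_lv: int) -> CVReport:
    """LOOCV report for a fixed latent-variable count."""
    X, y = _validate_xy(X, y)
    if X.shape[0] < 3:
        raise ValidationError("LOOCV needs at least 3 samples")
    press = press_curve(X, y, n_lv)
    preds = _loocv_prediction_matrix(X, y, n_lv)[:, n_lv - 1]
    return _summarize(press, n_lv, preds, y)


def calibrate(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int | None = None,
    press_tolerance: float = 0.05,
) -> CVReport:
    """Full calibration: PRESS curve, LV selection, LOOCV summary."""
    X, y = _validate_xy(X, y)
    if max_lv is None:
        max_lv = default_max_lv(X.shape[0])
    max_lv = min(max_lv, X.shape[0] - 2, X.shape[1])
    preds = _loocv_prediction_matrix(X, y, max_lv)
    press = np.sum((preds - y[:, None]) ** 2, axis=0)
    n_lv = select_n_lv(press, press_tolerance)
    return _summarize(press, n_lv, preds[:, n_lv - 1], y)
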