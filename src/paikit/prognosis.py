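"""Arm-specific elastic-net prognostic models with nested cross-validation.

Two prognostic models are fit, one per trial arm, each predicting the
distress-change slope from baseline covariates.  Honest predictions for a
participant's own arm come from nested cross-validation: outer folds supply
out-of-fold test predictions, inner folds (run only on the outer-training
partition) choose the elastic-net hyperparameters, so no participant's
outcome ever influences the model that predicts it.  Counterfactual
predictions — the outcome a participant would be expected to have under the
arm they were not assigned to — come from the other arm's model fit on that
arm's full sample.

The penalized objective is

    (1/2n) * sum (y - b0 - X beta)^2  +  lambda * (alpha*||beta||_1
                                                   + (1-alpha)/2*||beta||_2^2)

with the intercept unpenalized; alpha mixes ridge (0) and lasso (1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, Ridge

from .preprocess import StandardizationStats, standardize

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# settings and fitted-model containers


@dataclass
class ENRSettings:
    """Hyperparameter search space and fold structure for the nested CV."""

    alphas: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.01, 0.1), 2))
    n_lambdas: int = 100
    lambda_decades: float = 4.0
    lambdas: tuple[float, ...] | None = None  # explicit grid; overrides the data-driven path
    outer_folds: int = 10
    inner_folds: int = 10
    seed: int = 0

    def validate(self) -> None:
        if not self.alphas:
            raise ValueError("alpha grid must be nonempty")
        if any(not 0 <= a <= 1 for a in self.alphas):
            raise ValueError("alpha values must lie in [0,1]")
        if self.lambdas is not None and len(self.lambdas) == 0:
            raise ValueError("explicit lambda grid must be nonempty")
        if self.lambdas is None and self.n_lambdas < 1:
            raise ValueError("n_lambdas must be >= 1")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("outer_folds and inner_folds must be >= 2")


@dataclass
class FittedENR:
    """A fitted elastic-net model (zero coefficients retained)."""

    intercept: float
    coefficients: dict[str, float]
    alpha: float
    lam: float
    arm: str | None = None
    stats: StandardizationStats | None = None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Linear score intercept + X.beta; applies stored standardization."""
        missing = set(self.coefficients) - set(X.columns)
        if missing:
            raise ValueError(f"design table lacks model columns: {sorted(missing)}")
        if self.stats is not None:
            X, _ = standardize(X, stats=self.stats)
        names = list(self.coefficients)
        beta = np.array([self.coefficients[c] for c in names])
        return self.intercept + X[names].to_numpy(dtype=float) @ beta

    def retained(self) -> dict[str, float]:
        return {k: v for k, v in self.coefficients.items() if v != 0.0}

    def to_dict(self) -> dict:
        return {
            "arm": self.arm,
            "alpha": self.alpha,
            "lambda": self.lam,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "retained": self.retained(),
        }


# ---------------------------------------------------------------------------
# folds


def make_outer_folds(ids: Sequence, k: int, rng: np.random.Generator) -> pd.Series:
    """Random partition of ids into k folds with sizes differing by <=1."""
    ids = list(ids)
    if k > len(ids):
        raise ValueError(f"cannot make {k} folds from {len(ids)} ids")
    perm = rng.permutation(len(ids))
    fold = np.empty(len(ids), dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        fold[chunk] = f
    return pd.Series(fold, index=ids, name="fold")


def _kfold_indices(n: int, k: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    for chunk in np.array_split(perm, k):
        test = np.zeros(n, dtype=bool)
        test[chunk] = True
        yield np.where(~test)[0], np.where(test)[0]


# ---------------------------------------------------------------------------
# single fits


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        cols = [c for c in X.columns if c not in ("id", "arm")]
        return X[cols].to_numpy(dtype=float), cols
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def fit_enr(X, y, alpha: float, lam: float) -> FittedENR:
    """Minimize the stated elastic-net objective at one (alpha, lambda).

    lambda=0 reduces to ordinary least squares (solved directly); alpha=0 is
    ridge (closed-form solver); otherwise coordinate descent to tight
    tolerance.
    """
    Xm, cols = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if np.isnan(Xm).any() or np.isnan(y).any():
        raise ValueError("NaN in design matrix or outcome; impute first")
    n = len(y)
    if lam == 0:
        A = np.column_stack([np.ones(n), Xm])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        b0, beta = float(coef[0]), coef[1:]
    elif alpha == 0:
        model = Ridge(alpha=n * lam, fit_intercept=True).fit(Xm, y)
        b0, beta = float(model.intercept_), model.coef_
    else:
        model = ElasticNet(
            alpha=lam, l1_ratio=alpha, fit_intercept=True, tol=1e-8, max_iter=100_000
        ).fit(Xm, y)
        b0, beta = float(model.intercept_), model.coef_
    return FittedENR(
        intercept=b0,
        coefficients={c: float(b) for c, b in zip(cols, beta)},
        alpha=float(alpha),
        lam=float(lam),
    )


def lambda_path(X, y, alpha: float, n_lambdas: int = 100, decades: float = 4.0) -> np.ndarray:
    """Descending log-spaced path from lambda_max (smallest lambda with all
    coefficients zero at this alpha; glmnet's alpha=0.001 surrogate for pure
    ridge)."""
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    Xc = Xm - Xm.mean(axis=0)
    yc = y - y.mean()
    lam_max = np.abs(Xc.T @ yc).max() / (n * max(alpha, 1e-3))
    if lam_max <= 0 or not np.isfinite(lam_max):
        lam_max = 1.0
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades, n_lambdas)


def _path_fit_predict(X_tr, y_tr, X_te, alpha, lambdas) -> np.ndarray:
    """Predictions of the test block at every lambda (descending, warm-started).

    Returns array (len(lambdas), len(X_te)).
    """
    out = np.empty((len(lambdas), len(X_te)))
    if alpha == 0:
        for i, lam in enumerate(lambdas):
            if lam == 0:
                f = fit_enr(X_tr, y_tr, alpha, 0.0)
                beta = np.array(list(f.coefficients.values()))
                out[i] = f.intercept + X_te @ beta
            else:
                m = Ridge(alpha=len(y_tr) * lam, fit_intercept=True).fit(X_tr, y_tr)
                out[i] = m.predict(X_te)
        return out
    model = ElasticNet(l1_ratio=alpha, fit_intercept=True, tol=1e-7, max_iter=50_000, warm_start=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for i, lam in enumerate(lambdas):
            if lam == 0:
                f = fit_enr(X_tr, y_tr, alpha, 0.0)
                beta = np.array(list(f.coefficients.values()))
                out[i] = f.intercept + X_te @ beta
                continue
            model.set_params(alpha=lam)
            model.fit(X_tr, y_tr)
            out[i] = model.predict(X_te)
    return out


# ---------------------------------------------------------------------------
# inner CV hyperparameter selection


def inner_cv_select(X, y, settings: ENRSettings, rng: np.random.Generator) -> tuple[float, float]:
    """Grid pair (alpha, lambda) minimizing mean inner-CV squared error.

    Run only on an outer-training partition.  Ties (within 1e-12 relative)
    break toward larger lambda (parsimony), then smaller alpha.
    """
    settings.validate()
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    k = min(settings.inner_folds, n)
    if k < 2:
        raise ValueError("need at least 2 rows for inner CV")
    folds = list(_kfold_indices(n, k, rng))

    best = None  # (mse, -lam, alpha)
    for alpha in settings.alphas:
        if settings.lambdas is not None:
            lambdas = np.asarray(sorted(settings.lambdas, reverse=True), dtype=float)
        else:
            lambdas = lambda_path(Xm, y, alpha, settings.n_lambdas, settings.lambda_decades)
        sq = np.zeros(len(lambdas))
        for tr, te in folds:
            preds = _path_fit_predict(Xm[tr], y[tr], Xm[te], alpha, lambdas)
            sq += ((preds - y[te]) ** 2).sum(axis=1)
        mse = sq / n
        for lam, m in zip(lambdas, mse):
            key = (m, -lam, alpha)
            if best is None:
                best = key
                continue
            if m < best[0] * (1 - 1e-12) - 1e-300:
                best = key
            elif abs(m - best[0]) <= 1e-12 * max(abs(m), abs(best[0]), 1e-30):
                # tie: prefer larger lambda, then smaller alpha
                if (-lam, alpha) < (best[1], best[2]):
                    best = key
    if best is None:
        raise ValueError("empty hyperparameter grid")
    return float(best[2]), float(-best[1])


# ---------------------------------------------------------------------------
# nested CV and full-arm models


def nested_cv_predict(
    design: pd.DataFrame,
    y: pd.Series | np.ndarray,
    settings: ENRSettings,
    rng: np.random.Generator | None = None,
    continuous: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[int, tuple[float, float]]]:
    """Out-of-fold predictions under nested CV.

    design carries an 'id' column plus predictor columns.  For each outer
    fold, standardization statistics and hyperparameters are derived from the
    outer-training partition only, then the fold's rows are scored.  Returns
    (DataFrame[id, fold, pred], {fold: (alpha, lambda)}).
    """
    settings.validate()
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    ids = design["id"].to_numpy()
    y = np.asarray(y, dtype=float)
    if len(y) != len(ids):
        raise ValueError("y must align with design rows")
    folds = make_outer_folds(ids, min(settings.outer_folds, len(ids)), rng)
    pred = np.full(len(ids), np.nan)
    fold_of = folds.loc[ids].to_numpy()
    hyper: dict[int, tuple[float, float]] = {}
    Xcols = [c for c in design.columns if c not in ("id", "arm")]
    for f in np.unique(fold_of):
        tr = fold_of != f
        te = ~tr
        X_tr, stats = standardize(design.loc[tr, Xcols], continuous=continuous)
        y_tr = y[tr]
        if np.var(y_tr) == 0:
            logger.warning("outer fold %d: zero variance in training outcome", f)
        alpha, lam = inner_cv_select(X_tr, y_tr, settings, rng)
        model = fit_enr(X_tr, y_tr, alpha, lam)
        X_te, _ = standardize(design.loc[te, Xcols], stats=stats)
        names = list(model.coefficients)
        beta = np.array([model.coefficients[c] for c in names])
        pred[te] = model.intercept + X_te[names].to_numpy(dtype=float) @ beta
        hyper[int(f)] = (alpha, lam)
    out = pd.DataFrame({"id": ids, "fold": fold_of, "pred": pred})
    return out, hyper


def fit_full_arm_model(
    design: pd.DataFrame,
    y: pd.Series | np.ndarray,
    settings: ENRSettings,
    rng: np.random.Generator | None = None,
    arm: str | None = None,
    continuous: list[str] | None = None,
) -> FittedENR:
    """One arm's model on its full sample (for counterfactual prediction).

    Hyperparameters are chosen by inner CV on the full arm sample; the final
    model is refit on all of it.  Standardization stats are stored on the
    model so other-arm rows are scored on this arm's scale.
    """
    settings.validate()
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    if len(design) < settings.inner_folds:
        raise ValueError(
            f"arm has {len(design)} rows; fewer than inner_folds={settings.inner_folds}"
        )
    Xcols = [c for c in design.columns if c not in ("id", "arm")]
    X_std, stats = standardize(design[Xcols], continuous=continuous)
    y = np.asarray(y, dtype=float)
    alpha, lam = inner_cv_select(X_std, y, settings, rng)
    model = fit_enr(X_std, y, alpha, lam)
    model.arm = arm
    model.stats = stats
    return model


def counterfactual_predict(model: FittedENR, X_other_arm: pd.DataFrame) -> np.ndarray:
    """Score other-arm participants with this arm's full model."""
    return model.predict(X_other_arm)


def evaluate_predictions(pred, obs) -> dict:
    """Pearson r (two-sided p) and RMSE between predictions and observations."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if len(pred) != len(obs) or len(pred) < 3:
        raise ValueError("pred and obs must have equal length >= 3")
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    if np.std(pred) == 0 or np.std(obs) == 0:
        return {"r": float("nan"), "p": float("nan"), "rmse": rmse, "degenerate": True}
    r, p = _stats.pearsonr(pred, obs)
    return {"r": float(r), "p": float(p), "rmse": rmse, "degenerate": False}


# ---------------------------------------------------------------------------
# the 2-model construction feeding the PAI


def arm_predictions(
    design: pd.DataFrame,
    slopes: pd.DataFrame,
    settings: ENRSettings,
    treatment_label: str = "treatment",
    control_label: str = "control",
    symmetric: bool = False,
) -> tuple[pd.DataFrame, dict[str, FittedENR]]:
    """Own-arm nested-CV predictions plus counterfactual full-model predictions.

    design: encoded/imputed table with id and arm columns; slopes: id, slope.
    Returns (PrognosticPredictions frame [id, arm, pred_own_arm,
    pred_other_arm, fold], {arm: full-sample FittedENR}).

    symmetric=True replaces the own-arm nested-CV predictions with full-model
    in-sample predictions for both arms (sensitivity variant).
    """
    merged = design.merge(slopes[["id", "slope"]], on="id", how="inner")
    models: dict[str, FittedENR] = {}
    parts = []
    rng_by_arm = {
        arm: np.random.default_rng(
            np.random.SeedSequence([settings.seed, hash_arm])
        )
        for arm, hash_arm in ((control_label, 0), (treatment_label, 1))
    }
    for arm in (control_label, treatment_label):
        sub = merged[merged["arm"] == arm]
        if sub.empty:
            raise ValueError(f"no rows for arm {arm!r}")
        models[arm] = fit_full_arm_model(
            sub.drop(columns=["slope"]), sub["slope"], settings, rng_by_arm[arm], arm=arm
        )
    for arm in (control_label, treatment_label):
        sub = merged[merged["arm"] == arm]
        if symmetric:
            own = models[arm].predict(sub.drop(columns=["slope"]))
            oof = pd.DataFrame({"id": sub["id"], "fold": -1, "pred": own})
        else:
            oof, _ = nested_cv_predict(
                sub.drop(columns=["slope"]), sub["slope"], settings, rng_by_arm[arm]
            )
        other = treatment_label if arm == control_label else control_label
        cf = counterfactual_predict(models[other], sub.drop(columns=["slope"]))
        parts.append(
            pd.DataFrame(
                {
                    "id": sub["id"].to_numpy(),
                    "arm": arm,
                    "pred_own_arm": oof.set_index("id").loc[sub["id"], "pred"].to_numpy(),
                    "pred_other_arm": cf,
                    "fold": oof.set_index("id").loc[sub["id"], "fold"].to_numpy(),
                }
            )
        )
    return pd.concat(parts, ignore_index=True), models
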