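"""Per-participant distress-change slopes: the prediction target.

The primary outcome is each participant's slope of distress change over the
intervention period, estimated from the weekly long table with a linear
mixed (growth) model — fixed week effect (plus arm x week when arm labels
are supplied) and correlated person-level random intercepts and slopes,
fit by REML.  A participant's slope is the fixed part plus their
empirical-Bayes random-slope deviation, which shrinks noisy individual
trends toward the group mean.  Per-person OLS slopes serve as the
no-shrinkage reference and as the fallback when the mixed model fails to
converge.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

METHOD_EB = "mixed-model EB"
METHOD_OLS = "per-person OLS"


def per_person_ols_slopes(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Independent least-squares slope of distress on week for each id.

    Participants with fewer than two distinct observed weeks get no slope;
    their ids are logged and listed in the result's ``attrs['excluded']``.
    """
    rows = []
    excluded = []
    for pid, g in outcomes.dropna(subset=["distress"]).groupby("id", sort=False):
        w = g["week"].to_numpy(dtype=float)
        if len(np.unique(w)) < 2:
            excluded.append(pid)
            continue
        y = g["distress"].to_numpy(dtype=float)
        slope = np.polyfit(w, y, 1)[0]
        rows.append((pid, float(slope)))
    if excluded:
        logger.warning("excluded %d participant(s) with <2 timepoints: %s", len(excluded), excluded)
    out = pd.DataFrame(rows, columns=["id", "slope"])
    out["method"] = METHOD_OLS
    out.attrs["excluded"] = excluded
    return out


def fit_random_slopes(
    outcomes: pd.DataFrame,
    arms: pd.Series | dict | None = None,
    per_arm: bool = False,
) -> pd.DataFrame:
    """Empirical-Bayes slopes from a random-intercept-and-slope growth model.

    Fits ``distress ~ week`` (plus ``week:arm`` when arm labels are given and
    ``per_arm`` is False) with an unstructured 2x2 random-effects covariance,
    by REML.  Returns one row per participant: id, slope, method.  On
    non-convergence the per-person OLS fallback is used, flagged in
    ``method``.

    per_arm=True fits each arm's growth model separately instead of a single
    model with an arm x week fixed effect.
    """
    data = outcomes.dropna(subset=["distress"]).copy()
    n_weeks = data.groupby("id")["week"].nunique()
    excluded = n_weeks.index[n_weeks < 2].tolist()
    if excluded:
        logger.warning("excluded %d participant(s) with <2 timepoints", len(excluded))
        data = data[~data["id"].isin(excluded)]
    if arms is not None:
        arm_map = arms if isinstance(arms, dict) else dict(arms)
        data["arm"] = data["id"].map(arm_map)
        if per_arm:
            parts = [
                fit_random_slopes(g.drop(columns="arm"), arms=None)
                for _, g in data.groupby("arm", sort=False)
            ]
            return pd.concat(parts, ignore_index=True)

    formula = "distress ~ week"
    if arms is not None:
        formula += " + week:C(arm)"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data, groups=data["id"], re_formula="~week")
            fit = model.fit(reml=True)
        if not np.all(np.isfinite(fit.params)):
            raise np.linalg.LinAlgError("non-finite mixed-model parameters")
        if fit.scale <= 1e-10 * max(float(np.var(data["distress"])), 1e-30):
            # residual variance is numerically zero: shrinkage is vacuous and
            # per-person least squares is exact
            logger.info("near-zero residual variance; using exact per-person OLS slopes")
            return per_person_ols_slopes(outcomes)
    except Exception as exc:  # non-convergence, singular covariance, ...
        logger.warning("mixed model failed (%s); falling back to per-person OLS", exc)
        return per_person_ols_slopes(outcomes)

    fixed_week = float(fit.params["week"])
    arm_week = {
        name.split("[T.", 1)[1].rstrip("]"): float(val)
        for name, val in fit.params.items()
        if name.startswith("week:C(arm)[T.")
    }
    re = fit.random_effects

    rows = []
    for pid, g in data.groupby("id", sort=False):
        slope = fixed_week
        if arms is not None:
            slope += arm_week.get(str(g["arm"].iloc[0]), 0.0)
        dev = re.get(pid)
        if dev is not None and "week" in dev.index:
            slope += float(dev["week"])
        rows.append((pid, slope))
    out = pd.DataFrame(rows, columns=["id", "slope"])
    out["method"] = METHOD_EB
    out.attrs["excluded"] = excluded
    return out
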