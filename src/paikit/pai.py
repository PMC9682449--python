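"""Personalized Advantage Index: scores, moderation test, recommendation zones.

The PAI is the predicted distress-change slope under the active condition
minus the predicted slope under control; negative values mean the model
expects the person to do better in the active condition.  Whether the PAI
carries real signal is evaluated by regressing the observed outcome on
group, PAI, and their interaction: a positive interaction slope means that
as PAI scores decrease, observed group differences favoring treatment grow.

Recommendation strength is stratified into zones using three landmarks on
the PAI axis: the intersection of the two arm regression lines (to its right
the model favors control — red), the left margin of a bootstrap CI for that
intersection, and the Johnson–Neyman boundary below which the conditional
group difference is statistically significant.  Left of both of the latter
is a confident (green) recommendation; between, a cautious (yellow) one.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

logger = logging.getLogger(__name__)

GREEN, YELLOW, RED = "green", "yellow", "red"


# ---------------------------------------------------------------------------
# PAI scores and recommendations


def compute_pai(pred_treat, pred_control) -> np.ndarray:
    """Predicted treatment slope minus predicted control slope, per person."""
    t = np.asarray(pred_treat, dtype=float)
    c = np.asarray(pred_control, dtype=float)
    if t.shape != c.shape:
        raise ValueError("prediction vectors must align")
    return t - c


def recommend(pai, threshold: float = 0.0) -> np.ndarray:
    """'treatment' where pai < threshold, else 'control' (ties conservative)."""
    pai = np.asarray(pai, dtype=float)
    return np.where(pai < threshold, "treatment", "control")


def build_pai_table(predictions: pd.DataFrame, treatment_label: str = "treatment") -> pd.DataFrame:
    """Assemble the per-participant PAI table from prognostic predictions.

    predictions: frame with id, arm, pred_own_arm, pred_other_arm.  For a
    treated participant pred_treat is their own (out-of-fold) prediction and
    pred_control the counterfactual one; mirrored for controls.
    """
    is_treat = predictions["arm"] == treatment_label
    pred_treat = np.where(is_treat, predictions["pred_own_arm"], predictions["pred_other_arm"])
    pred_control = np.where(is_treat, predictions["pred_other_arm"], predictions["pred_own_arm"])
    pai = compute_pai(pred_treat, pred_control)
    return pd.DataFrame(
        {
            "id": predictions["id"].to_numpy(),
            "arm": predictions["arm"].to_numpy(),
            "pred_treat": pred_treat,
            "pred_control": pred_control,
            "pai": pai,
            "recommended": recommend(pai),
        }
    )


# ---------------------------------------------------------------------------
# moderation model


@dataclass
class ModerationReport:
    """Fit of outcome ~ group + PAI + group x PAI (+ optional covariates).

    Group coding: control=0, treatment=1.  Arm lines: control
    a_c + b_c * x; treatment (a_c + g) + (b_c + b_int) * x.
    """

    coef: dict[str, float]
    se: dict[str, float]
    interaction_t: float
    df_resid: int
    interaction_p: float
    adj_r2: float
    n: int
    cov_g_int: float  # covariance of (group, interaction) estimates
    pai_range: tuple[float, float]
    intersection: float | None = None
    ci_level: float | None = None
    ci_B: int | None = None
    ci_lower: float | None = None
    ci_upper: float | None = None
    ci_degenerate: int | None = None
    ci_unreliable: bool | None = None
    jn_boundaries: list[float] = field(default_factory=list)
    jn_flags: list[str] = field(default_factory=list)
    jn_alpha: float | None = None

    # -- derived geometry --------------------------------------------------
    @property
    def control_line(self) -> tuple[float, float]:
        return self.coef["intercept"], self.coef["pai"]

    @property
    def treatment_line(self) -> tuple[float, float]:
        return (
            self.coef["intercept"] + self.coef["group"],
            self.coef["pai"] + self.coef["group_x_pai"],
        )

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["control_line"] = list(self.control_line)
        d["treatment_line"] = list(self.treatment_line)
        d["pai_range"] = list(self.pai_range)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _moderation_design(group, pai, covariates=None) -> tuple[np.ndarray, list[str]]:
    group = np.asarray(group, dtype=float)
    pai = np.asarray(pai, dtype=float)
    cols = [np.ones_like(pai), group, pai, group * pai]
    names = ["intercept", "group", "pai", "group_x_pai"]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(pai):
            cov = cov.T
        for j in range(cov.shape[1]):
            cols.append(cov[:, j])
            names.append(f"cov{j + 1}")
    return np.column_stack(cols), names


def test_moderation(outcome, group, pai, covariates=None) -> ModerationReport:
    """OLS moderation test of the group x PAI interaction.

    outcome: observed slopes; group: 0/1 (or control/treatment labels);
    pai: PAI scores; covariates: optional adjustment columns (e.g., baseline
    depressive symptoms for a sensitivity analysis).
    """
    y = np.asarray(outcome, dtype=float)
    group = np.asarray(group)
    if group.dtype.kind in "UOS":
        group = (group == "treatment").astype(float)
    group = group.astype(float)
    pai = np.asarray(pai, dtype=float)
    if len(set(np.unique(group))) < 2:
        raise ValueError("group must take both values")
    if np.std(pai) == 0:
        raise ValueError("PAI is constant; interaction model is collinear")
    X, names = _moderation_design(group, pai, covariates)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > {p + 1} observations for the moderation model")

    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * XtX_inv
    se = np.sqrt(np.diag(cov))
    i_int = names.index("group_x_pai")
    i_g = names.index("group")
    t_int = float(beta[i_int] / se[i_int])
    p_int = float(2 * _stats.t.sf(abs(t_int), df))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1 - float(resid @ resid) / ss_tot if ss_tot > 0 else float("nan")
    adj_r2 = 1 - (1 - r2) * (n - 1) / df

    report = ModerationReport(
        coef={nm: float(b) for nm, b in zip(names, beta)},
        se={nm: float(s) for nm, s in zip(names, se)},
        interaction_t=t_int,
        df_resid=df,
        interaction_p=p_int,
        adj_r2=float(adj_r2),
        n=n,
        cov_g_int=float(cov[i_g, i_int]),
        pai_range=(float(pai.min()), float(pai.max())),
    )
    try:
        report.intersection = intersection_point(report)
    except ValueError:
        report.intersection = None
    return report


def intersection_point(report: ModerationReport) -> float:
    """PAI value where the two arm regression lines cross.

    Solves a_c + b_c x = a_t + b_t x, i.e. x* = -(a_t - a_c)/(b_t - b_c).
    """
    a_c, b_c = report.control_line
    a_t, b_t = report.treatment_line
    if abs(b_t - b_c) < 1e-12:
        raise ValueError("arm lines are parallel; no intersection")
    return float(-(a_t - a_c) / (b_t - b_c))


# ---------------------------------------------------------------------------
# bootstrap CI for the intersection


def bootstrap_intersection(
    outcome,
    group,
    pai,
    B: int = 1000,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Percentile bootstrap CI for the regression-line intersection.

    Rows (outcome, group, pai) are resampled with replacement B times, the
    interaction model refit, and the intersection recomputed; replicates with
    (near-)parallel lines or a single-valued group are counted as degenerate
    and dropped.  A CI built from fewer than half of B finite replicates is
    flagged unreliable.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(group)
    if g.dtype.kind in "UOS":
        g = (g == "treatment").astype(float)
    g = g.astype(float)
    x = np.asarray(pai, dtype=float)
    n = len(y)
    X = np.column_stack([np.ones(n), g, x, g * x])

    points = []
    degenerate = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        Xb, yb = X[idx], y[idx]
        if len(np.unique(Xb[:, 1])) < 2:
            degenerate += 1
            continue
        beta, *_ = np.linalg.lstsq(Xb, yb, rcond=None)
        db = beta[3]
        if abs(db) < 1e-12 or not np.isfinite(db):
            degenerate += 1
            continue
        pt = -beta[1] / db
        if np.isfinite(pt):
            points.append(pt)
        else:
            degenerate += 1
    points = np.asarray(points)
    lo = float(np.percentile(points, 100 * (1 - level) / 2)) if points.size else float("nan")
    hi = float(np.percentile(points, 100 * (1 + level) / 2)) if points.size else float("nan")
    return {
        "level": level,
        "B": B,
        "lower": lo,
        "upper": hi,
        "degenerate": degenerate,
        "unreliable": degenerate > B / 2,
    }


# ---------------------------------------------------------------------------
# Johnson-Neyman


def johnson_neyman(report: ModerationReport, alpha: float = 0.05) -> dict:
    """Moderator values where the conditional group difference turns significant.

    The group difference at PAI = x is g + b_int * x with squared standard
    error se_g^2 + 2x cov(g, b_int) + x^2 se_int^2; boundaries solve
    t(x)^2 = t_crit^2 (t with the model's residual df).  Roots are reported
    within the observed PAI range, each sub-interval flagged significant or
    not.
    """
    g = report.coef["group"]
    b = report.coef["group_x_pai"]
    vg = report.se["group"] ** 2
    vb = report.se["group_x_pai"] ** 2
    cgb = report.cov_g_int
    tc2 = _stats.t.ppf(1 - alpha / 2, report.df_resid) ** 2

    # (g + b x)^2 = tc2 (vg + 2 cgb x + vb x^2)
    A = b**2 - tc2 * vb
    Bq = 2 * (g * b - tc2 * cgb)
    C = g**2 - tc2 * vg

    lo, hi = report.pai_range

    def signif(x: float) -> bool:
        num = g + b * x
        den = np.sqrt(vg + 2 * cgb * x + vb * x**2)
        return num**2 / den**2 > tc2 if den > 0 else False

    if abs(A) < 1e-300:
        roots = [] if abs(Bq) < 1e-300 else [-C / Bq]
    else:
        disc = Bq**2 - 4 * A * C
        roots = [] if disc < 0 else sorted([(-Bq - np.sqrt(disc)) / (2 * A), (-Bq + np.sqrt(disc)) / (2 * A)])
    in_range = [float(r) for r in roots if lo <= r <= hi]

    edges = [lo] + in_range + [hi]
    flags = []
    for a_, b_ in zip(edges[:-1], edges[1:]):
        flags.append("significant" if signif((a_ + b_) / 2) else "nonsignificant")
    if not in_range:
        overall = "everywhere significant" if flags and flags[0] == "significant" else "nowhere significant"
    else:
        overall = "boundary"
    return {
        "alpha": alpha,
        "boundaries": in_range,
        "interval_flags": flags,
        "overall": overall,
    }


# ---------------------------------------------------------------------------
# zones


def assign_zones(pai, intersection: float, ci_lower: float, jn_boundary: float | None) -> np.ndarray:
    """green/yellow/red strata on the PAI axis.

    green: pai < min(ci_lower, jn_boundary); yellow: up to (excluding) the
    intersection; red: at or beyond the intersection.  Without a JN boundary
    zones degrade to yellow/red only.
    """
    pai = np.asarray(pai, dtype=float)
    if not np.isfinite(intersection):
        raise ValueError("intersection must be finite")
    if jn_boundary is None:
        logger.warning("no Johnson-Neyman boundary; zones degrade to yellow/red")
        green_cut = -np.inf
    else:
        green_cut = min(ci_lower, jn_boundary)
    # the intersection dominates: at or beyond it the model favors control
    zones = np.where(
        pai >= intersection, RED, np.where(pai < green_cut, GREEN, YELLOW)
    )
    return zones


# ---------------------------------------------------------------------------
# percentile translation


def pooled_sd(sds, ns) -> float:
    """SD pooled across groups from per-group SDs and sample sizes."""
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=float)
    return float(np.sqrt(((ns - 1) * sds**2).sum() / (ns - 1).sum()))


def percentile_translation(
    slope_per_week: float, weeks: float, baseline_sd: float, start_percentile: float
) -> int:
    """Expected percentile (relative to baseline scores) after the program.

    Converts the starting percentile to a z-score, shifts it by
    weeks * slope / baseline_sd (the predicted change in baseline-SD units),
    and maps back through the standard normal CDF, rounded to the nearest
    integer percentile.
    """
    if baseline_sd <= 0:
        raise ValueError("baseline_sd must be positive")
    if not 0 < start_percentile < 100:
        raise ValueError("start_percentile must lie in (0,100)")
    z0 = _stats.norm.ppf(start_percentile / 100)
    z1 = z0 + weeks * slope_per_week / baseline_sd
    return int(round(100 * _stats.norm.cdf(z1)))


# ---------------------------------------------------------------------------
# single-predictor comparison model


def _simple_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope/intercept of y ~ x by least squares."""
    b = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
    a = y.mean() - b * x.mean()
    return float(a), float(b)


def comparison_model_pai(
    predictor,
    outcome,
    group,
    k: int = 10,
    repeats: int = 100,
    rng: np.random.Generator | int | None = None,
    ids=None,
) -> tuple[pd.DataFrame, dict]:
    """Single-predictor comparison PAI (simple regression per arm).

    Per arm, out-of-fold predictions from y ~ predictor under k-fold CV,
    averaged over ``repeats`` random fold partitions; counterfactual
    predictions from the other arm's full-sample simple regression.  Returns
    the PAI table and a per-arm coefficient report (full-sample slope with t,
    df, p).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(group)
    if g.dtype.kind in "UOS":
        g01 = (g == "treatment").astype(int)
    else:
        g01 = g.astype(int)
    if np.isnan(x).any():
        raise ValueError("predictor must be complete")
    n = len(x)
    ids = np.asarray(ids) if ids is not None else np.arange(n)

    full = {}
    report = {}
    for label, mask in (("control", g01 == 0), ("treatment", g01 == 1)):
        xa, ya = x[mask], y[mask]
        if k > mask.sum():
            raise ValueError(f"k={k} exceeds arm size {int(mask.sum())}")
        a, b = _simple_fit(xa, ya)
        full[label] = (a, b)
        resid = ya - (a + b * xa)
        df = len(xa) - 2
        se_b = np.sqrt((resid @ resid) / df / ((xa - xa.mean()) ** 2).sum())
        t = b / se_b
        report[label] = {
            "intercept": a,
            "slope": b,
            "t": float(t),
            "df": int(df),
            "p": float(2 * _stats.t.sf(abs(t), df)),
        }

    pred_own = np.zeros(n)
    for mask in (g01 == 0, g01 == 1):
        idx = np.where(mask)[0]
        xa, ya = x[idx], y[idx]
        acc = np.zeros(len(idx))
        for _ in range(repeats):
            perm = rng.permutation(len(idx))
            for chunk in np.array_split(perm, k):
                tr = np.setdiff1d(np.arange(len(idx)), chunk)
                a, b = _simple_fit(xa[tr], ya[tr])
                acc[chunk] += a + b * xa[chunk]
        pred_own[idx] = acc / repeats

    a_c, b_c = full["control"]
    a_t, b_t = full["treatment"]
    pred_treat = np.where(g01 == 1, pred_own, a_t + b_t * x)
    pred_control = np.where(g01 == 0, pred_own, a_c + b_c * x)
    pai = compute_pai(pred_treat, pred_control)
    table = pd.DataFrame(
        {
            "id": ids,
            "arm": np.where(g01 == 1, "treatment", "control"),
            "pred_treat": pred_treat,
            "pred_control": pred_control,
            "pai": pai,
            "recommended": recommend(pai),
        }
    )
    return table, report


# ---------------------------------------------------------------------------
# figure


def plot_zones(report: ModerationReport, pai, outcome, group, path=None):
    """Two arm regression lines over PAI with intersection/CI/JN landmarks
    and green/yellow/red shading."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pai = np.asarray(pai, dtype=float)
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(group)
    if g.dtype.kind in "UOS":
        g = (g == "treatment").astype(int)
    fig, ax = plt.subplots(figsize=(7, 5))
    xs = np.linspace(pai.min(), pai.max(), 200)
    a_c, b_c = report.control_line
    a_t, b_t = report.treatment_line
    ax.scatter(pai[g == 0], y[g == 0], s=8, alpha=0.3, color="firebrick")
    ax.scatter(pai[g == 1], y[g == 1], s=8, alpha=0.3, color="steelblue")
    ax.plot(xs, a_c + b_c * xs, color="firebrick", label="control")
    ax.plot(xs, a_t + b_t * xs, color="steelblue", label="treatment")
    x_int = report.intersection
    if x_int is not None and np.isfinite(x_int):
        ax.axvline(x_int, ls="--", color="gray", label="intersection")
        jn = report.jn_boundaries[0] if report.jn_boundaries else None
        green_cut = None
        if report.ci_lower is not None and jn is not None:
            green_cut = min(report.ci_lower, jn)
        if report.ci_lower is not None:
            ax.axvline(report.ci_lower, ls="--", color="red", label="CI left margin")
        if jn is not None:
            ax.axvline(jn, ls="-", color="dimgray", label="Johnson-Neyman")
        lo = min(pai.min(), x_int)
        if green_cut is not None and green_cut > lo:
            ax.axvspan(lo, green_cut, color="green", alpha=0.12)
            ax.axvspan(green_cut, x_int, color="yellow", alpha=0.12)
        else:
            ax.axvspan(lo, x_int, color="yellow", alpha=0.12)
        ax.axvspan(x_int, max(pai.max(), x_int), color="red", alpha=0.10)
    ax.set_xlabel("PAI (predicted treatment minus control slope)")
    ax.set_ylabel("observed distress slope")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return path
    return fig
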