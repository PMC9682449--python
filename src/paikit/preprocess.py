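"""Predictor encoding, random-forest imputation, and standardization.

Baseline covariates are imputed once on the pooled table with an iterative
random-forest scheme (missForest-style), with the outcome variable excluded
from the procedure by construction so predicted slopes never leak into the
predictor matrix.  Encoding turns binary fields into 0/1 columns and ordinal
income into reference-coded indicators; standardization statistics are kept
so test folds can be scored on their training fold's scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# encoding


@dataclass
class EncodingScheme:
    """Declares how each non-continuous predictor column is encoded.

    binary: {column: reference_level}; ordinal: {column: [levels in order]}
    (first level is the reference and gets no indicator column).
    """

    binary: dict[str, object] = field(default_factory=dict)
    ordinal: dict[str, list] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"binary": self.binary, "ordinal": self.ordinal}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "EncodingScheme":
        with open(path) as fh:
            d = json.load(fh)
        return cls(binary=d["binary"], ordinal=d["ordinal"])


def default_scheme() -> EncodingScheme:
    """Scheme matching the default synthetic trial's covariate table."""
    return EncodingScheme(
        binary={"gender": 0, "race": 0, "marital": 0},
        ordinal={"income": [1, 2, 3, 4]},
    )


def encode_predictors(table: pd.DataFrame, scheme: EncodingScheme) -> pd.DataFrame:
    """Build the numeric design table (id kept; arm passed through if present).

    Binary columns become a single 0/1 indicator against the declared
    reference; a K-level ordinal becomes K-1 reference-coded indicators named
    ``col_<level>``.  Unseen categories at scoring time raise, rather than
    silently extrapolate.
    """
    out = {}
    passthrough = [c for c in ("id", "arm") if c in table.columns]
    for c in passthrough:
        out[c] = table[c].to_numpy()
    handled = set(passthrough) | set(scheme.binary) | set(scheme.ordinal)
    for c in table.columns:
        if c in handled:
            continue
        out[c] = table[c].to_numpy(dtype=float)
    for c, ref in scheme.binary.items():
        col = table[c]
        observed = set(col.dropna().unique().tolist())
        if len(observed - {ref}) > 1:
            extra = sorted(observed - {ref}, key=repr)
            raise ValueError(f"binary column {c!r} has unexpected categories {extra}")
        vals = np.where(col.isna(), np.nan, (col != ref).astype(float))
        out[c] = vals
    for c, levels in scheme.ordinal.items():
        col = table[c]
        unseen = set(col.dropna().unique().tolist()) - set(levels)
        if unseen:
            raise ValueError(f"ordinal column {c!r} has unseen categories {sorted(unseen, key=repr)}")
        for lev in levels[1:]:
            vals = np.where(col.isna(), np.nan, (col == lev).astype(float))
            out[f"{c}_{lev}"] = vals
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# iterative random-forest imputation


def _criterion_continuous(new: pd.DataFrame, old: pd.DataFrame, cols: list[str]) -> float:
    num = 0.0
    den = 0.0
    for c in cols:
        a, b = new[c].to_numpy(dtype=float), old[c].to_numpy(dtype=float)
        num += float(np.nansum((a - b) ** 2))
        den += float(np.nansum(a**2))
    return num / den if den > 0 else 0.0


def _criterion_categorical(new: pd.DataFrame, old: pd.DataFrame, masks: dict[str, np.ndarray]) -> float:
    changed = 0
    total = 0
    for c, m in masks.items():
        changed += int((new[c].to_numpy()[m] != old[c].to_numpy()[m]).sum())
        total += int(m.sum())
    return changed / total if total else 0.0


def impute_iterative_forest(
    table: pd.DataFrame,
    excluded: list[str] | None = None,
    rng: np.random.Generator | int | None = None,
    max_iter: int = 10,
    n_trees: int = 100,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """missForest-style imputation of the baseline table.

    Missing cells are initialized with the column mean (continuous) or mode
    (categorical); columns are then revisited in increasing-missingness
    order, each fit by a random forest on all other predictors' observed
    rows.  Iteration stops the first time the convergence criterion (sum of
    the normalized squared change over continuous columns and the proportion
    of changed categorical cells) increases, returning the previous iterate,
    or at max_iter.

    ``excluded`` columns (always including id/arm) are neither imputed nor
    used as features; their missing cells survive untouched.
    """
    excluded = list(excluded or [])
    excluded += [c for c in ("id", "arm") if c in table.columns and c not in excluded]
    categorical = [c for c in (categorical or []) if c not in excluded]

    work = table.copy()
    feature_cols = [c for c in work.columns if c not in excluded]
    na = {c: work[c].isna().to_numpy() for c in feature_cols}
    target_cols = [c for c in feature_cols if na[c].any()]
    if not target_cols:
        return work

    for c in target_cols:
        if na[c].all():
            raise ValueError(f"column {c!r} is entirely missing; cannot initialize")

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    # mean/mode initialization
    for c in target_cols:
        obs = work.loc[~na[c], c]
        fill = obs.mode().iloc[0] if c in categorical else obs.astype(float).mean()
        work.loc[na[c], c] = fill

    target_cols.sort(key=lambda c: (na[c].sum(), c))
    cont_targets = [c for c in target_cols if c not in categorical]
    cat_masks = {c: na[c] for c in target_cols if c in categorical}

    prev = work.copy()
    prev_crit = np.inf
    for _ in range(max_iter):
        for c in target_cols:
            feats = [f for f in feature_cols if f != c]
            X_obs = work.loc[~na[c], feats].to_numpy(dtype=float)
            y_obs = work.loc[~na[c], c].to_numpy()
            X_mis = work.loc[na[c], feats].to_numpy(dtype=float)
            seed = int(rng.integers(0, 2**31 - 1))
            if c in categorical:
                forest = RandomForestClassifier(
                    n_estimators=n_trees, max_features="sqrt", random_state=seed
                )
            else:
                forest = RandomForestRegressor(
                    n_estimators=n_trees, max_features="sqrt", random_state=seed
                )
                y_obs = y_obs.astype(float)
            forest.fit(X_obs, y_obs)
            work.loc[na[c], c] = forest.predict(X_mis)
        crit = _criterion_continuous(work, prev, cont_targets) + _criterion_categorical(
            work, prev, cat_masks
        )
        if crit >= prev_crit:
            return prev
        prev, prev_crit = work.copy(), crit
    return prev


# ---------------------------------------------------------------------------
# standardization


@dataclass
class StandardizationStats:
    """Training-fold means/SDs for continuous columns, plus dropped columns."""

    means: dict[str, float]
    sds: dict[str, float]
    dropped: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"means": self.means, "sds": self.sds, "dropped": self.dropped}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "StandardizationStats":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def standardize(
    table: pd.DataFrame,
    continuous: list[str] | None = None,
    stats: StandardizationStats | None = None,
) -> tuple[pd.DataFrame, StandardizationStats]:
    """Center/scale continuous columns; indicator columns pass through.

    With ``stats`` supplied (scoring a test fold), the stored training
    means/SDs are applied and stored drops honored.  Otherwise stats are
    computed from this table; zero-variance continuous columns are dropped
    with a warning and recorded.
    """
    out = table.copy()
    if stats is not None:
        missing = set(stats.means) - set(out.columns)
        if missing:
            raise ValueError(f"columns expected by stats are absent: {sorted(missing)}")
        out = out.drop(columns=[c for c in stats.dropped if c in out.columns])
        for c, m in stats.means.items():
            out[c] = (out[c].to_numpy(dtype=float) - m) / stats.sds[c]
        return out, stats

    if continuous is None:
        continuous = [
            c for c in out.columns if c not in ("id", "arm") and out[c].dropna().nunique() > 2
        ]
    means, sds, dropped = {}, {}, []
    for c in continuous:
        v = out[c].to_numpy(dtype=float)
        m, s = float(np.nanmean(v)), float(np.nanstd(v, ddof=1))
        if not np.isfinite(s) or s == 0:
            dropped.append(c)
            logger.warning("dropping zero-variance column %r during standardization", c)
            continue
        means[c], sds[c] = m, s
        out[c] = (v - m) / s
    out = out.drop(columns=dropped)
    return out, StandardizationStats(means=means, sds=sds, dropped=dropped)
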