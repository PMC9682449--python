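"""Synthetic two-arm trial generator with known individual treatment effects.

Emulates a 4-week app-based intervention trial: a baseline table of 12
continuous questionnaire scores plus 5 demographic fields, 1:1 randomized
allocation, weekly distress measurements at weeks 0-4 driven by person-level
slopes, arm-specific prognostic coefficients on standardized covariates, a
moderated individual treatment advantage, and sparse MCAR missingness.

Because both counterfactual slopes are generated for every participant, the
module serves as a ground-truth oracle for the downstream Personalized
Advantage Index (PAI) pipeline: the true advantage (treatment slope minus
control slope; negative favors treatment) is known exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

CONTROL = "control"
TREATMENT = "treatment"

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal specification for one baseline covariate.

    kind is "continuous" (needs mean and sd), "binary" (needs probs = P(1)),
    or "ordinal" (needs probs over levels 1..K).
    """

    name: str
    kind: str
    mean: float | None = None
    sd: float | None = None
    probs: tuple[float, ...] | float | None = None

    def validate(self) -> None:
        if self.kind == "continuous":
            if self.mean is None or self.sd is None or self.sd <= 0:
                raise ValueError(f"continuous covariate {self.name!r} needs mean and sd>0")
        elif self.kind == "binary":
            p = self.probs
            if not isinstance(p, (int, float)) or not 0 < p < 1:
                raise ValueError(f"binary covariate {self.name!r} needs probs=P(1) in (0,1)")
        elif self.kind == "ordinal":
            p = np.asarray(self.probs, dtype=float)
            if p.ndim != 1 or p.size < 2 or (p <= 0).any() or abs(p.sum() - 1) > 1e-8:
                raise ValueError(f"ordinal covariate {self.name!r} needs probs summing to 1")
        else:
            raise ValueError(f"unknown covariate kind {self.kind!r}")

    def population_moments(self) -> tuple[float, float]:
        """Population mean/SD implied by the marginal (used for standardization)."""
        if self.kind == "continuous":
            return float(self.mean), float(self.sd)
        if self.kind == "binary":
            p = float(self.probs)
            return p, float(np.sqrt(p * (1 - p)))
        probs = np.asarray(self.probs, dtype=float)
        levels = np.arange(1, probs.size + 1)
        m = float(levels @ probs)
        return m, float(np.sqrt((levels - m) ** 2 @ probs))


@dataclass
class TrialConfig:
    """Everything needed to generate one synthetic trial.

    control_coeffs / treat_coeffs map covariate names to the contribution of
    one standard deviation of that covariate to the true per-week distress
    slope in the given arm.  main_effect is the arm difference in mean slope
    (negative: treatment reduces distress faster).  slope_sd is the SD of a
    person-level slope deviation shared across both counterfactual arms;
    residual_sd is week-level measurement noise.
    """

    n_participants: int
    covariate_spec: list[CovariateSpec]
    correlation_matrix: np.ndarray
    arm_ratio: float = 0.5
    control_coeffs: dict[str, float] = field(default_factory=dict)
    treat_coeffs: dict[str, float] = field(default_factory=dict)
    main_effect: float = 0.0
    slope_intercept: float = 0.0
    slope_sd: float = 0.0
    residual_sd: float = 0.0
    weeks: tuple[int, ...] = (0, 1, 2, 3, 4)
    missing_rate: float = 0.0
    seed: int = 0

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        names = [s.name for s in self.covariate_spec]
        if len(set(names)) != len(names):
            raise ValueError("duplicate covariate names")
        for s in self.covariate_spec:
            s.validate()
        k = len(self.continuous_names())
        R = np.asarray(self.correlation_matrix, dtype=float)
        if R.shape != (k, k):
            raise ValueError(f"correlation_matrix must be {k}x{k} (continuous covariates)")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("correlation_matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-10):
            raise ValueError("correlation_matrix must have unit diagonal")
        w = np.linalg.eigvalsh(R)
        if w.min() < -1e-8:
            raise ValueError(
                f"correlation_matrix is not positive semidefinite "
                f"(smallest eigenvalue {w.min():.3e})"
            )
        if not 0 < self.arm_ratio < 1:
            raise ValueError("arm_ratio must lie in (0,1)")
        if self.slope_sd < 0 or self.residual_sd < 0:
            raise ValueError("slope_sd and residual_sd must be nonnegative")
        wk = list(self.weeks)
        if len(wk) < 2 or any(b <= a for a, b in zip(wk, wk[1:])):
            raise ValueError("weeks must be strictly increasing with >=2 entries")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must lie in [0,1]")
        for coeffs in (self.control_coeffs, self.treat_coeffs):
            unknown = set(coeffs) - set(names)
            if unknown:
                raise ValueError(f"coefficient names not in covariate_spec: {sorted(unknown)}")

    def continuous_names(self) -> list[str]:
        return [s.name for s in self.covariate_spec if s.kind == "continuous"]

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["correlation_matrix"] = np.asarray(self.correlation_matrix).tolist()
        d["covariate_spec"] = [dataclasses.asdict(s) for s in self.covariate_spec]
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "TrialConfig":
        d = dict(d)
        d["covariate_spec"] = [
            CovariateSpec(
                name=s["name"],
                kind=s["kind"],
                mean=s.get("mean"),
                sd=s.get("sd"),
                probs=tuple(s["probs"]) if isinstance(s.get("probs"), (list, tuple)) else s.get("probs"),
            )
            for s in d["covariate_spec"]
        ]
        d["correlation_matrix"] = np.asarray(d["correlation_matrix"], dtype=float)
        d["weeks"] = tuple(d["weeks"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "TrialConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def factor_correlation_matrix(loadings: Sequence[float]) -> np.ndarray:
    """Single-factor correlation matrix R = ll' + diag(1-l^2); PSD by construction."""
    lam = np.asarray(loadings, dtype=float)
    if np.any(np.abs(lam) >= 1):
        raise ValueError("loadings must lie in (-1, 1)")
    R = np.outer(lam, lam)
    np.fill_diagonal(R, 1.0)
    return R


#: baseline marginals for the default configuration: pooled means/SDs of the
#: kind seen in a distressed-but-subclinical adult sample (distress composite
#: standardized at baseline; PROMIS T-scores for depression/anxiety).
_DEFAULT_MARGINALS: list[CovariateSpec] = [
    CovariateSpec("distress", "continuous", 0.00, 0.895),
    CovariateSpec("depression", "continuous", 55.42, 6.31),
    CovariateSpec("anxiety", "continuous", 59.91, 7.03),
    CovariateSpec("stress", "continuous", 2.88, 0.58),
    CovariateSpec("rnt", "continuous", 29.76, 10.85),
    CovariateSpec("awareness", "continuous", 24.68, 6.02),
    CovariateSpec("loneliness", "continuous", 2.55, 0.77),
    CovariateSpec("defusion", "continuous", 24.67, 8.02),
    CovariateSpec("presence", "continuous", 26.01, 5.45),
    CovariateSpec("search", "continuous", 21.85, 6.70),
    CovariateSpec("self_compassion", "continuous", 2.96, 0.695),
    CovariateSpec("wellbeing", "continuous", 12.62, 4.53),
    CovariateSpec("age", "continuous", 42.58, 10.66),
    CovariateSpec("gender", "binary", probs=0.873),
    CovariateSpec("race", "binary", probs=0.864),
    CovariateSpec("marital", "binary", probs=0.693),
    CovariateSpec("income", "ordinal", probs=(0.169, 0.410, 0.304, 0.117)),
]

#: single-factor loadings on a general-distress factor, giving a 0.3-0.7
#: correlation block among symptom measures and negative correlations with
#: the mindfulness/wellbeing scales.  Illustrative, not estimated.
_DEFAULT_LOADINGS = {
    "distress": 0.90,
    "depression": 0.75,
    "anxiety": 0.70,
    "stress": 0.70,
    "rnt": 0.65,
    "awareness": -0.50,
    "loneliness": 0.45,
    "defusion": -0.45,
    "presence": -0.40,
    "search": 0.25,
    "self_compassion": -0.55,
    "wellbeing": -0.60,
    "age": -0.10,
}

#: arm-specific prognostic coefficients (per SD of covariate, per week of
#: slope).  Sign pattern: in both arms higher baseline symptoms predict larger
#: distress reductions, but repetitive negative thinking (rnt) predicts
#: better outcomes under treatment and worse outcomes under control -- the
#: moderation the PAI is meant to capture.
_DEFAULT_CONTROL_COEFFS = {
    "distress": -0.020, "depression": -0.012, "anxiety": -0.015, "stress": -0.012,
    "rnt": 0.035, "loneliness": -0.008, "defusion": -0.028, "presence": -0.018,
    "self_compassion": -0.010, "marital": -0.012,
}
_DEFAULT_TREAT_COEFFS = {
    "distress": -0.032, "depression": -0.028, "stress": -0.010, "rnt": -0.015,
}


def default_config(n_participants: int = 662, seed: int = 0, **overrides) -> TrialConfig:
    """The package's reference trial configuration (see docs/methods.md)."""
    spec = list(_DEFAULT_MARGINALS)
    cont = [s.name for s in spec if s.kind == "continuous"]
    R = factor_correlation_matrix([_DEFAULT_LOADINGS[c] for c in cont])
    cfg = TrialConfig(
        n_participants=n_participants,
        covariate_spec=spec,
        correlation_matrix=R,
        arm_ratio=0.5,
        control_coeffs=dict(_DEFAULT_CONTROL_COEFFS),
        treat_coeffs=dict(_DEFAULT_TREAT_COEFFS),
        main_effect=-0.07,
        slope_intercept=0.01,
        slope_sd=0.05,
        residual_sd=0.15,
        weeks=(0, 1, 2, 3, 4),
        missing_rate=0.004,
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# random substreams


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child stream: toggling one generation stage never shifts another."""
    entropy = [int(seed), int.from_bytes(name.encode("utf-8"), "little")]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# generation stages


def _psd_sqrt(R: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(R)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def generate_covariates(config: TrialConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the baseline covariate table (without arm labels).

    Continuous covariates are drawn jointly from a Gaussian copula with the
    configured correlation matrix and rescaled to target mean/SD; binary and
    ordinal fields threshold independent latent normals at the quantiles
    matching their category probabilities.
    """
    config.validate()
    n = config.n_participants
    cont = config.continuous_names()
    width = len(str(max(n, 1)))
    out = {"id": [f"P{i + 1:0{width}d}" for i in range(n)]}

    L = _psd_sqrt(np.asarray(config.correlation_matrix, dtype=float))
    z = rng.standard_normal((n, len(cont))) @ L.T
    by_name = {s.name: s for s in config.covariate_spec}
    for j, name in enumerate(cont):
        s = by_name[name]
        out[name] = s.mean + s.sd * z[:, j]

    for s in config.covariate_spec:
        if s.kind == "binary":
            latent = rng.standard_normal(n)
            out[s.name] = (latent > _stats.norm.ppf(1 - float(s.probs))).astype(int)
        elif s.kind == "ordinal":
            latent = rng.standard_normal(n)
            cuts = _stats.norm.ppf(np.cumsum(np.asarray(s.probs)[:-1]))
            out[s.name] = (np.searchsorted(cuts, latent) + 1).astype(int)

    cols = ["id"] + [s.name for s in config.covariate_spec]
    return pd.DataFrame(out)[cols]


def assign_arms(ids: Sequence, ratio: float, rng: np.random.Generator) -> np.ndarray:
    """Permutation-based 1:ratio allocation; sizes off the exact ratio by <1."""
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("participant ids must be unique")
    n = len(ids)
    if n == 0:
        return np.array([], dtype=object)
    n_treat = int(round(n * ratio))
    labels = np.array([TREATMENT] * n_treat + [CONTROL] * (n - n_treat), dtype=object)
    return labels[rng.permutation(n)]


def standardized_covariates(covariates: pd.DataFrame, config: TrialConfig) -> pd.DataFrame:
    """Covariates on the z-scale of their configured population marginals."""
    z = {}
    for s in config.covariate_spec:
        m, sd = s.population_moments()
        z[s.name] = (covariates[s.name].to_numpy(dtype=float) - m) / sd
    return pd.DataFrame(z, index=covariates.index)


def generate_trajectories(
    covariates: pd.DataFrame, config: TrialConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Weekly distress observations plus both counterfactual true slopes.

    True slope under arm a: slope_intercept + dot(coeffs_a, z-covariates)
    (+ main_effect under treatment) + a N(0, slope_sd^2) person deviation
    shared across the two counterfactual arms.  Observed distress at week t:
    baseline distress + assigned-arm slope * t + N(0, residual_sd^2).
    """
    if "arm" not in covariates.columns:
        raise ValueError("covariates must carry an 'arm' column; run assign_arms first")
    for coeffs in (config.control_coeffs, config.treat_coeffs):
        missing = set(coeffs) - set(covariates.columns)
        if missing:
            raise ValueError(f"coefficient covariates absent from table: {sorted(missing)}")

    n = len(covariates)
    z = standardized_covariates(covariates, config)

    def lin(coeffs: dict[str, float]) -> np.ndarray:
        v = np.zeros(n)
        for name, b in coeffs.items():
            v += b * z[name].to_numpy()
        return v

    deviation = rng.normal(0.0, config.slope_sd, size=n) if config.slope_sd > 0 else np.zeros(n)
    slope_control = config.slope_intercept + lin(config.control_coeffs) + deviation
    slope_treat = (
        config.slope_intercept + lin(config.treat_coeffs) + config.main_effect + deviation
    )

    arm = covariates["arm"].to_numpy()
    assigned = np.where(arm == TREATMENT, slope_treat, slope_control)
    baseline = covariates["distress"].to_numpy(dtype=float)

    weeks = np.asarray(config.weeks)
    ids = np.repeat(covariates["id"].to_numpy(), len(weeks))
    wk = np.tile(weeks, n)
    y = np.repeat(baseline, len(weeks)) + np.repeat(assigned, len(weeks)) * wk
    if config.residual_sd > 0:
        y = y + rng.normal(0.0, config.residual_sd, size=y.size)
    outcomes = pd.DataFrame({"id": ids, "week": wk, "distress": y})

    true_slopes = pd.DataFrame(
        {
            "id": covariates["id"].to_numpy(),
            "slope_control": slope_control,
            "slope_treat": slope_treat,
        }
    )
    return outcomes, true_slopes


def inject_missingness(
    table: pd.DataFrame, rate: float, rng: np.random.Generator
) -> pd.DataFrame:
    """MCAR: each eligible cell (not id/arm) set missing with probability rate."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0,1]")
    out = table.copy()
    eligible = [c for c in out.columns if c not in ("id", "arm")]
    if rate == 0 or not eligible:
        return out
    mask = rng.random((len(out), len(eligible))) < rate
    for j, c in enumerate(eligible):
        col = out[c].astype(float)
        col[mask[:, j]] = np.nan
        out[c] = col
    return out


# ---------------------------------------------------------------------------
# assembled trial


@dataclass
class GeneratedTrial:
    """One simulated trial plus its ground truth."""

    config: TrialConfig
    covariates: pd.DataFrame
    outcomes: pd.DataFrame
    true_slopes: pd.DataFrame

    @property
    def true_advantage(self) -> pd.Series:
        """treat slope - control slope per person; negative favors treatment."""
        return pd.Series(
            self.true_slopes["slope_treat"].to_numpy()
            - self.true_slopes["slope_control"].to_numpy(),
            index=self.true_slopes["id"],
            name="true_advantage",
        )


def true_individual_effect(trial: GeneratedTrial) -> np.ndarray:
    """Per-person counterfactual slope difference (treatment minus control)."""
    return trial.true_advantage.to_numpy()


def generate_trial(config: TrialConfig) -> GeneratedTrial:
    """Run all stages with named substreams of config.seed."""
    config.validate()
    cov = generate_covariates(config, substream(config.seed, "covariates"))
    cov.insert(1, "arm", assign_arms(cov["id"], config.arm_ratio, substream(config.seed, "arms")))
    outcomes, true_slopes = generate_trajectories(cov, config, substream(config.seed, "trajectories"))
    cov = inject_missingness(cov, config.missing_rate, substream(config.seed, "missingness"))
    return GeneratedTrial(config=config, covariates=cov, outcomes=outcomes, true_slopes=true_slopes)


def write_trial(trial: GeneratedTrial, outdir) -> dict[str, str]:
    """covariates.csv + outcomes.csv (+ truth.csv for test harnesses) + config.json."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "covariates": os.path.join(outdir, "covariates.csv"),
        "outcomes": os.path.join(outdir, "outcomes.csv"),
        "truth": os.path.join(outdir, "truth.csv"),
        "config": os.path.join(outdir, "config.json"),
    }
    trial.covariates.to_csv(paths["covariates"], index=False)
    trial.outcomes.to_csv(paths["outcomes"], index=False)
    trial.true_slopes.assign(true_advantage=trial.true_advantage.to_numpy()).to_csv(
        paths["truth"], index=False
    )
    trial.config.to_json(paths["config"])
    return paths
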