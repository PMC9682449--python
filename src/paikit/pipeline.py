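"""End-to-end orchestration: simulate/load -> impute -> slopes -> prognosis
-> PAI -> moderation -> report, with a manifest for reproducibility.

Every run directory contains the serialized configuration, all intermediate
CSV/JSON artifacts, a manifest recording per-stage seeds and artifact
hashes, and a human-readable summary report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pai as pai_mod
from . import preprocess, prognosis, slopes as slopes_mod, synthetic

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Either ``simulate`` holds a TrialConfig, or covariates_path/outcomes_path
    point at existing CSV tables (covariates: one row per participant with id
    and arm; outcomes: long id,week,distress).
    """

    outdir: str
    simulate: synthetic.TrialConfig | None = None
    covariates_path: str | None = None
    outcomes_path: str | None = None
    enr: prognosis.ENRSettings = field(default_factory=prognosis.ENRSettings)
    adjust_columns: list[str] = field(default_factory=list)
    bootstrap_B: int = 1000
    ci_level: float = 0.95
    alpha: float = 0.05
    seed: int = 0
    make_plot: bool = False
    impute_trees: int = 100

    def validate(self) -> None:
        if self.simulate is None and (self.covariates_path is None or self.outcomes_path is None):
            raise ValueError("config needs either a simulate block or covariates+outcomes paths")
        if self.simulate is not None:
            self.simulate.validate()
        self.enr.validate()
        if self.bootstrap_B < 100:
            raise ValueError("bootstrap_B must be >= 100")
        if not 0 < self.ci_level < 1 or not 0 < self.alpha < 1:
            raise ValueError("ci_level and alpha must lie in (0,1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        d["enr"] = dataclasses.asdict(self.enr)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("simulate"):
            d["simulate"] = synthetic.TrialConfig.from_dict(d["simulate"])
        if d.get("enr"):
            enr = dict(d["enr"])
            for k in ("alphas", "lambdas"):
                if enr.get(k) is not None:
                    enr[k] = tuple(enr[k])
            d["enr"] = prognosis.ENRSettings(**enr)
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def select_jn_boundary(jn: dict, intersection: float) -> float | None:
    """The Johnson-Neyman boundary delimiting the treatment-favoring
    significant region: the largest boundary at or below the intersection
    whose left-side interval is significant."""
    candidates = [
        b
        for i, b in enumerate(jn["boundaries"])
        if jn["interval_flags"][i] == "significant" and b <= intersection
    ]
    return max(candidates) if candidates else None


def run_pipeline(config: RunConfig) -> str:
    """Execute all stages; returns the run directory.

    On a stage failure, partial outputs are kept and the manifest records
    the failure point before the exception propagates.
    """
    config.validate()
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {"stages": [], "seed": config.seed, "failure": None}

    def stage(name: str):
        manifest["stages"].append({"name": name, "t_start": time.time()})
        logger.info("stage: %s", name)

    def done(**artifacts):
        rec = manifest["stages"][-1]
        rec["seconds"] = round(time.time() - rec.pop("t_start"), 3)
        rec["artifacts"] = {k: _sha256(v) for k, v in artifacts.items()}

    with open(os.path.join(outdir, "run_config.json"), "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)

    try:
        # ---- data ---------------------------------------------------------
        stage("data")
        if config.simulate is not None:
            trial = synthetic.generate_trial(config.simulate)
            paths = synthetic.write_trial(trial, outdir)
            covariates, outcomes = trial.covariates, trial.outcomes
            done(covariates=paths["covariates"], outcomes=paths["outcomes"])
        else:
            covariates = pd.read_csv(config.covariates_path)
            outcomes = pd.read_csv(config.outcomes_path)
            done(covariates=config.covariates_path, outcomes=config.outcomes_path)
        if "arm" not in covariates.columns:
            raise ValueError("covariate table must carry an 'arm' column")

        # ---- imputation + encoding ---------------------------------------
        stage("preprocess")
        scheme = preprocess.default_scheme()
        scheme.binary = {c: r for c, r in scheme.binary.items() if c in covariates.columns}
        scheme.ordinal = {c: l for c, l in scheme.ordinal.items() if c in covariates.columns}
        categorical = list(scheme.binary) + list(scheme.ordinal)
        imputed = preprocess.impute_iterative_forest(
            covariates,
            excluded=[],
            rng=np.random.default_rng(np.random.SeedSequence([config.seed, 1])),
            n_trees=config.impute_trees,
            categorical=categorical,
        )
        for c in categorical:  # forests return floats; restore integer levels
            imputed[c] = imputed[c].round().astype(int)
        design = preprocess.encode_predictors(imputed, scheme)
        design_path = os.path.join(outdir, "design.csv")
        design.to_csv(design_path, index=False)
        scheme.to_json(os.path.join(outdir, "encoding.json"))
        done(design=design_path)

        # ---- outcome slopes ----------------------------------------------
        stage("slopes")
        arms = covariates.set_index("id")["arm"]
        slope_set = slopes_mod.fit_random_slopes(outcomes, arms=arms)
        slopes_path = os.path.join(outdir, "slopes.csv")
        slope_set.to_csv(slopes_path, index=False)
        done(slopes=slopes_path)

        # ---- prognosis ----------------------------------------------------
        stage("prognosis")
        settings = dataclasses.replace(config.enr, seed=int(config.seed * 1000003 % 2**31))
        predictions, models = prognosis.arm_predictions(design, slope_set, settings)
        pred_path = os.path.join(outdir, "predictions.csv")
        predictions.to_csv(pred_path, index=False)
        models_path = os.path.join(outdir, "models.json")
        with open(models_path, "w") as fh:
            json.dump({arm: m.to_dict() for arm, m in models.items()}, fh, indent=2)
        done(predictions=pred_path, models=models_path)

        # ---- PAI + moderation ---------------------------------------------
        stage("pai")
        table = pai_mod.build_pai_table(predictions)
        merged = table.merge(slope_set[["id", "slope"]], on="id")
        group01 = (merged["arm"] == "treatment").astype(int).to_numpy()
        adjust = None
        if config.adjust_columns:
            adjust = (
                design.set_index("id")
                .loc[merged["id"], config.adjust_columns]
                .to_numpy(dtype=float)
            )
        report = pai_mod.test_moderation(merged["slope"], group01, merged["pai"], adjust)
        ci = pai_mod.bootstrap_intersection(
            merged["slope"],
            group01,
            merged["pai"],
            B=config.bootstrap_B,
            level=config.ci_level,
            rng=np.random.default_rng(np.random.SeedSequence([config.seed, 2])),
        )
        report.ci_level, report.ci_B = ci["level"], ci["B"]
        report.ci_lower, report.ci_upper = ci["lower"], ci["upper"]
        report.ci_degenerate, report.ci_unreliable = ci["degenerate"], ci["unreliable"]
        jn = pai_mod.johnson_neyman(report, alpha=config.alpha)
        report.jn_boundaries, report.jn_flags = jn["boundaries"], jn["interval_flags"]
        report.jn_alpha = config.alpha

        if report.intersection is not None:
            jn_boundary = select_jn_boundary(jn, report.intersection)
            table["zone"] = pai_mod.assign_zones(
                table["pai"], report.intersection, report.ci_lower, jn_boundary
            )
        else:
            table["zone"] = "yellow"
        pai_path = os.path.join(outdir, "pai.csv")
        table.to_csv(pai_path, index=False)
        mod_path = os.path.join(outdir, "moderation_report.json")
        report.to_json(mod_path)
        if config.make_plot:
            pai_mod.plot_zones(
                report, merged["pai"], merged["slope"], group01,
                os.path.join(outdir, "zones.png"),
            )
        done(pai=pai_path, moderation_report=mod_path)

        # ---- report --------------------------------------------------------
        stage("report")
        rpt = write_report(outdir)
        done(report=rpt)
    except Exception as exc:
        manifest["failure"] = f"{manifest['stages'][-1]['name']}: {exc}"
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir


def write_report(outdir: str) -> str:
    """Summarize a completed run into report.json (+ report.md).

    Includes the per-arm retained elastic-net coefficients, the 2x2 block of
    prediction r/RMSE (each arm's model evaluated in each arm), PAI
    descriptives and recommendation counts, the interaction statistics,
    intersection with bootstrap CI and Johnson-Neyman boundaries, and zone
    counts.
    """
    needed = {
        name: os.path.join(outdir, name)
        for name in ("predictions.csv", "pai.csv", "slopes.csv", "models.json",
                     "moderation_report.json")
    }
    missing = [n for n, p in needed.items() if not os.path.exists(p)]
    if missing:
        raise ValueError(f"run incomplete; missing artifacts: {missing}")
    predictions = pd.read_csv(needed["predictions.csv"])
    table = pd.read_csv(needed["pai.csv"])
    slope_set = pd.read_csv(needed["slopes.csv"])
    with open(needed["models.json"]) as fh:
        models = json.load(fh)
    with open(needed["moderation_report.json"]) as fh:
        moderation = json.load(fh)

    obs = slope_set.set_index("id")["slope"]
    block = {}
    for arm_model in ("control", "treatment"):
        for arm_eval in ("control", "treatment"):
            sub = predictions[predictions["arm"] == arm_eval]
            pred = sub["pred_own_arm"] if arm_model == arm_eval else sub["pred_other_arm"]
            block[f"{arm_model}_model_on_{arm_eval}"] = prognosis.evaluate_predictions(
                pred, obs.loc[sub["id"]].to_numpy()
            )

    pai = table["pai"].to_numpy()
    report = {
        "n": int(len(table)),
        "retained_coefficients": {arm: m["retained"] for arm, m in models.items()},
        "hyperparameters": {
            arm: {"alpha": m["alpha"], "lambda": m["lambda"]} for arm, m in models.items()
        },
        "prediction_block": block,
        "pai": {
            "mean": float(np.mean(pai)),
            "sd": float(np.std(pai, ddof=1)),
            "min": float(np.min(pai)),
            "max": float(np.max(pai)),
        },
        "recommendations": table["recommended"].value_counts().to_dict(),
        "interaction": {
            "t": moderation["interaction_t"],
            "df": moderation["df_resid"],
            "p": moderation["interaction_p"],
            "adj_r2": moderation["adj_r2"],
        },
        "intersection": moderation["intersection"],
        "bootstrap_ci": [moderation["ci_lower"], moderation["ci_upper"]],
        "jn_boundaries": moderation["jn_boundaries"],
        "zones": table["zone"].value_counts().to_dict() if "zone" in table else {},
    }
    path = os.path.join(outdir, "report.json")
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)

    lines = [
        "# Run summary",
        "",
        f"Participants: {report['n']}",
        "",
        "## Retained elastic-net coefficients",
    ]
    for arm, coefs in report["retained_coefficients"].items():
        hy = report["hyperparameters"][arm]
        lines.append(f"### {arm} (alpha={hy['alpha']}, lambda={hy['lambda']:.4g})")
        if coefs:
            lines += [f"- {k}: {v:.4f}" for k, v in coefs.items()]
        else:
            lines.append("- (none retained)")
    lines += ["", "## Prediction accuracy (model x evaluation arm)"]
    for k, v in report["prediction_block"].items():
        lines.append(f"- {k}: r={v['r']:.3f} (p={v['p']:.3g}), RMSE={v['rmse']:.3f}")
    p = report["pai"]
    lines += [
        "",
        f"## PAI: mean {p['mean']:.3f} (SD {p['sd']:.3f}; range {p['min']:.3f} to {p['max']:.3f})",
        f"Recommendations: {report['recommendations']}",
        "",
        "## Moderation",
        f"group x PAI interaction: t({report['interaction']['df']})="
        f"{report['interaction']['t']:.2f}, p={report['interaction']['p']:.3g}, "
        f"adjusted r2={report['interaction']['adj_r2']:.3f}",
        f"intersection: {report['intersection']}",
        f"bootstrap CI: {report['bootstrap_ci']}",
        f"Johnson-Neyman boundaries: {report['jn_boundaries']}",
        f"zones: {report['zones']}",
    ]
    with open(os.path.join(outdir, "report.md"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path
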