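import dataclasses

import numpy as np
import pandas as pd
import pytest

import paikit
from paikit import prognosis


@pytest.fixture(scope="session")
def fast_settings() -> paikit.ENRSettings:
    """Reduced hyperparameter search used throughout the simulation tests."""
    return paikit.ENRSettings(
        alphas=(0.0, 0.5, 1.0), n_lambdas=20, outer_folds=5, inner_folds=3, seed=0
    )


@pytest.fixture(scope="session")
def small_trial() -> paikit.GeneratedTrial:
    """One default-configuration trial at n=200, shared across tests."""
    return paikit.generate_trial(paikit.default_config(n_participants=200, seed=11))


def make_noise_arm_data(rng, n=300, p=10):
    """Design + outcome where predictors carry no signal (null PAI inputs)."""
    y = rng.standard_normal(n) * 0.1
    g = np.repeat([0, 1], n // 2)
    X = pd.DataFrame(rng.standard_normal((n, p)), columns=[f"x{j}" for j in range(p)])
    X.insert(0, "id", np.arange(n))
    X.insert(1, "arm", np.where(g == 1, "treatment", "control"))
    slopes = pd.DataFrame({"id": np.arange(n), "slope": y, "method": "test"})
    return X, slopes


def null_pai_interaction_t(rng, settings, n=300, p=10) -> float:
    """Interaction t from one full noise-predictor PAI construction."""
    X, slopes = make_noise_arm_data(rng, n=n, p=p)
    s = dataclasses.replace(settings, seed=int(rng.integers(2**31)))
    preds, _ = prognosis.arm_predictions(X, slopes, s)
    table = paikit.build_pai_table(preds)
    merged = table.merge(slopes[["id", "slope"]], on="id")
    report = paikit.test_moderation(
        merged["slope"], (merged["arm"] == "treatment").astype(int), merged["pai"]
    )
    return report.interaction_t
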