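"""Monte Carlo power analysis for group x moderator interaction tests.

Per replicate the simulator draws a balanced binary group variable x1 (a
median-split of a latent standard normal), a continuous moderator x2
correlated with the latent group variable, and an outcome

    y = b1*x1 + b2*x2 + b3*x1*x2 + e,

with b1, b2 solved so the simple correlations corr(y,x1) and corr(y,x2) hit
their targets, b3 the interaction effect on the standardized-coefficient
(partial correlation) scale, and e scaled so var(y) = 1.  Each replicate
fits y ~ x1 + x2 + x1:x2 by OLS and records whether the interaction is
rejected at the stated alpha; power is the rejection proportion with its
binomial Monte Carlo standard error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

# point-biserial attenuation of a latent-normal correlation under a median
# split: corr(1{z>0}, x) = rho * phi(0)/sqrt(1/4) = rho * sqrt(2/pi)
_MEDIAN_SPLIT_FACTOR = float(np.sqrt(2 / np.pi))


@dataclass
class PowerSpec:
    """Inputs for the interaction power simulation."""

    n: int
    r_y_x1: float = 0.0
    r_y_x2: float = 0.0
    r_x1_x2: float = 0.0
    beta3: float = 0.0
    alpha: float = 0.05
    reps: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if self.n < 10:
            raise ValueError("n must be >= 10")
        if self.reps < 100:
            raise ValueError("reps must be >= 100")
        for r in (self.r_y_x1, self.r_y_x2, self.r_x1_x2):
            if not -1 < r < 1:
                raise ValueError("correlations must lie in (-1,1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")
        self._solve_coefficients()  # raises if infeasible

    def _solve_coefficients(self) -> tuple[float, float, float, float]:
        """(latent rho12, b1, b2, residual sd) implied by the targets."""
        rho_latent = self.r_x1_x2 / _MEDIAN_SPLIT_FACTOR
        if not -1 < rho_latent < 1:
            raise ValueError(
                f"r_x1_x2={self.r_x1_x2} is unattainable under a median split "
                f"(max magnitude {_MEDIAN_SPLIT_FACTOR:.3f})"
            )
        # x1 standardized binary, x2 standard normal, corr r12; the product
        # term is uncorrelated with both by symmetry.  Solve
        #   corr(y,x1) = b1 + b2*r12,  corr(y,x2) = b1*r12 + b2  (var(y)=1)
        r12 = self.r_x1_x2
        M = np.array([[1.0, r12], [r12, 1.0]])
        b1, b2 = np.linalg.solve(M, np.array([self.r_y_x1, self.r_y_x2]))
        var_inter = 1.0  # var(x1s * x2) ~ 1 for a standardized median split
        var_expl = (
            b1**2 + b2**2 + 2 * b1 * b2 * r12 + self.beta3**2 * var_inter
        )
        var_e = 1.0 - var_expl
        if var_e <= 0:
            raise ValueError(
                f"requested correlations and beta3 explain variance {var_expl:.3f} >= 1"
            )
        return rho_latent, float(b1), float(b2), float(np.sqrt(var_e))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PowerSpec":
        with open(path) as fh:
            return cls(**json.load(fh))


def _draw(spec: PowerSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rho, b1, b2, sd_e = spec._solve_coefficients()
    n = spec.n
    z1 = rng.standard_normal(n)
    x2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    x1 = (z1 > 0).astype(float)
    x1s = (x1 - 0.5) / 0.5  # standardized binary (+/-1)
    inter = x1s * x2
    y = b1 * x1s + b2 * x2 + spec.beta3 * inter + sd_e * rng.standard_normal(n)
    return x1s, x2, y


def simulate_interaction_power(
    spec: PowerSpec, rng: np.random.Generator | int | None = None
) -> dict:
    """Rejection proportion of the interaction test, with binomial MC SE."""
    spec.validate()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(
        spec.seed if rng is None else rng
    )
    tc = _stats.t.ppf(1 - spec.alpha / 2, spec.n - 4)
    rejections = 0
    for _ in range(spec.reps):
        x1, x2, y = _draw(spec, rng)
        X = np.column_stack([np.ones(spec.n), x1, x2, x1 * x2])
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ y
        resid = y - X @ beta
        sigma2 = resid @ resid / (spec.n - 4)
        se3 = np.sqrt(sigma2 * XtX_inv[3, 3])
        if abs(beta[3] / se3) > tc:
            rejections += 1
    power = rejections / spec.reps
    return {
        "power": power,
        "mc_se": float(np.sqrt(power * (1 - power) / spec.reps)),
        "reps": spec.reps,
        "n": spec.n,
        "alpha": spec.alpha,
    }


def min_sample_size(
    target_power: float,
    spec: PowerSpec,
    n_range: tuple[int, int] = (20, 2000),
    rng: np.random.Generator | int | None = None,
    step: int = 1,
) -> dict:
    """Smallest n in range with simulated power >= target (bisection).

    spec.n is ignored; each probe reuses spec with the probed n.  Returns the
    chosen n plus the power curve at every probed point.  Raises if even the
    upper end of the range falls short.
    """
    if not spec.alpha < target_power < 1:
        raise ValueError("target_power must lie in (alpha, 1)")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(
        spec.seed if rng is None else rng
    )

    curve: dict[int, dict] = {}

    def power_at(n: int) -> float:
        if n not in curve:
            probe = PowerSpec(**{**spec.__dict__, "n": n})
            curve[n] = simulate_interaction_power(probe, rng)
        return curve[n]["power"]

    lo, hi = n_range
    if power_at(hi) < target_power:
        raise ValueError(
            f"target power {target_power} unreachable in n range {n_range}; "
            f"max achieved {power_at(hi):.3f} at n={hi}"
        )
    if power_at(lo) >= target_power:
        best = lo
    else:
        a, b = lo, hi  # power(a) < target <= power(b)
        while b - a > step:
            mid = (a + b) // 2
            if power_at(mid) >= target_power:
                b = mid
            else:
                a = mid
        best = b
    return {
        "n": int(best),
        "target_power": target_power,
        "curve": [
            {"n": n, "power": curve[n]["power"], "mc_se": curve[n]["mc_se"]}
            for n in sorted(curve)
        ],
    }


def example_spec(n: int = 153, reps: int = 1000, seed: int = 0) -> PowerSpec:
    """A documented example specification with a moderate interaction.

    The correlation inputs behind any particular published sample-size
    figure are study-specific; this example (weak main-effect correlations,
    interaction effect 0.2) is illustrative only.
    """
    return PowerSpec(
        n=n, r_y_x1=0.1, r_y_x2=0.15, r_x1_x2=0.05, beta3=0.2, alpha=0.05, reps=reps, seed=seed
    )
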