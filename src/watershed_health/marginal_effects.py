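"""Marginal effects at means: policy-comparable changes in probability.

Binary covariates get discrete effects — the difference in predicted
probability between the variable at 1 and at 0, all other covariates held
at their sample means and random effects at zero (the median of their
distribution). The continuous tree-cover index gets instantaneous-rate
scenario effects: the derivative of the probability at means multiplied by
a 10, 20 or 30 percentage-point increase in the index. Confidence
intervals are delta-method on the probability scale.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .model_fit import FitResult
from .schema import BINARY_POLICY_TERMS

_Z95 = 1.96

__all__ = ["MarginalEffect", "me_binary", "me_continuous_scenario", "policy_table"]


@dataclass
class MarginalEffect:
    variable: str
    baseline_probability: float
    delta_probability: float
    percent_reduction: float  # 100 * |delta| / baseline
    ci_low: float
    ci_high: float
    scenario_size: float | None = None  # percent-point increase, or None for binary


def _mean_vector(fit: FitResult) -> np.ndarray:
    """Covariate vector at sample means (intercept slot = 1)."""
    x = np.empty(len(fit.names))
    for i, name in enumerate(fit.names):
        x[i] = 1.0 if name == "intercept" else fit.x_mean[name]
    return x


def _interval(delta: float, grad: np.ndarray, cov: np.ndarray) -> tuple[float, float]:
    var = float(grad @ cov @ grad)
    half = _Z95 * np.sqrt(max(var, 0.0))
    return delta - half, delta + half


def _simulation_interval(
    fit: FitResult, delta_fn, n_draws: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Percentile interval from draws of the coefficient sampling distribution."""
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(fit.beta, fit.cov_beta, size=n_draws)
    deltas = delta_fn(draws)
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    return float(lo), float(hi)


def me_binary(fit: FitResult, variable: str, ci_method: str = "delta") -> MarginalEffect:
    """Discrete 0-to-1 effect of a binary covariate at sample means.

    ``ci_method`` is "delta" (default) or "simulation" (percentiles over
    draws from the coefficient sampling distribution).
    """
    if variable not in fit.names or variable == "intercept":
        raise KeyError(f"{variable!r} is not a fixed effect of this fit; have {fit.names[1:]}")
    idx = fit.names.index(variable)
    x1 = _mean_vector(fit)
    x0 = x1.copy()
    x1[idx], x0[idx] = 1.0, 0.0
    p1, p0 = expit(x1 @ fit.beta), expit(x0 @ fit.beta)
    delta = float(p1 - p0)
    grad = p1 * (1 - p1) * x1 - p0 * (1 - p0) * x0
    if ci_method == "simulation":
        lo, hi = _simulation_interval(fit, lambda b: expit(b @ x1) - expit(b @ x0))
    else:
        lo, hi = _interval(delta, grad, fit.cov_beta)
    baseline = float(expit(_mean_vector(fit) @ fit.beta))
    return MarginalEffect(
        variable=variable,
        baseline_probability=baseline,
        delta_probability=delta,
        percent_reduction=100.0 * abs(delta) / baseline,
        ci_low=lo,
        ci_high=hi,
    )


def me_continuous_scenario(
    fit: FitResult, variable: str, increase: float, ci_method: str = "delta"
) -> MarginalEffect:
    """Instantaneous-rate effect of a continuous covariate, scaled to a scenario.

    delta = beta_v * pbar * (1 - pbar) * increase, with pbar the predicted
    probability at means and random effects zero; exactly linear in the
    scenario size. Refuses binary covariates (use ``me_binary``).
    """
    if variable not in fit.names or variable == "intercept":
        raise KeyError(f"{variable!r} is not a fixed effect of this fit; have {fit.names[1:]}")
    if variable in BINARY_POLICY_TERMS:
        raise ValueError(f"{variable!r} is binary; scenario effects need a continuous covariate")
    idx = fit.names.index(variable)
    xbar = _mean_vector(fit)
    pbar = float(expit(xbar @ fit.beta))
    beta_v = float(fit.beta[idx])
    w = pbar * (1 - pbar)
    delta = beta_v * w * increase
    # d delta / d beta_k = increase * [ w * 1{k=v} + beta_v * w * (1-2p) * xbar_k ]
    grad = increase * (w * (1 - 2 * pbar) * beta_v * xbar)
    grad[idx] += increase * w
    if ci_method == "simulation":
        def sim_delta(b):
            p = expit(b @ xbar)
            return b[:, idx] * p * (1 - p) * increase

        lo, hi = _simulation_interval(fit, sim_delta)
    else:
        lo, hi = _interval(delta, grad, fit.cov_beta)
    return MarginalEffect(
        variable=variable,
        baseline_probability=pbar,
        delta_probability=delta,
        percent_reduction=100.0 * abs(delta) / pbar,
        ci_low=lo,
        ci_high=hi,
        scenario_size=increase,
    )


def policy_table(
    fit: FitResult,
    variables: tuple[str, ...] = BINARY_POLICY_TERMS,
    continuous: str = "tree_index",
    scenarios: tuple[float, ...] = (10.0, 20.0, 30.0),
) -> list[MarginalEffect]:
    """One marginal effect per binary policy variable plus one per scenario.

    Rows are sorted by effect magnitude, largest first, so the leading row
    is the policy with the biggest change in predicted probability.
    """
    effects = [me_binary(fit, v) for v in variables if v in fit.names]
    if continuous in fit.names:
        effects.extend(me_continuous_scenario(fit, continuous, s) for s in scenarios)
    effects.sort(key=lambda e: abs(e.delta_probability), reverse=True)
    return effects


def effects_frame(effects: list[MarginalEffect]) -> pd.DataFrame:
    return pd.DataFrame([asdict(e) for e in effects])


def effects_to_json(effects: list[MarginalEffect], path) -> None:
    with open(path, "w") as fh:
        json.dump([asdict(e) for e in effects], fh, indent=2)
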