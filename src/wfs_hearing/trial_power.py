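"""Simulation-based power and sample size for progression-slowing trials.

Emulates a two-arm (treatment vs. placebo) trial that measures an
audiometric outcome every six months for three years.  Each subject's
trajectory follows the random-slope model: subject i in arm g has slope

    slope_i = beta_g + N(0, delta^2),   beta_treatment = (1 - r) * beta_placebo

with homoscedastic residual error N(0, epsilon^2) around a linear
trajectory from a common baseline mean (arms are assumed equal at
baseline).  Each simulated trial is analyzed with the random-slope mixed
model ``y ~ time + group + group:time``; empirical power is the fraction
of simulated trials in which the group-by-time effect is significant at
the two-sided alpha.

For balanced complete data the mixed-model interaction test reduces
exactly to a pooled two-sample t-test on per-subject OLS slopes (the
per-subject slope is the sufficient statistic; its variance is
delta^2 + epsilon^2 / Sxx).  ``analyze_trial`` uses that reduction by
default and falls back to a numerical REML fit for unbalanced tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import fit_lmm
from .audiometry import ValidationError

logger = logging.getLogger(__name__)

#: Six-monthly visits over a 3-year follow-up.
DEFAULT_VISITS: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)


@dataclass(frozen=True)
class TrialDesign:
    """Two-arm design with equal allocation."""

    n_per_arm: int
    visit_times: tuple[float, ...] = DEFAULT_VISITS
    reduction: float = 0.6
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise ValidationError("n_per_arm must be at least 2")
        vt = tuple(self.visit_times)
        if vt[0] != 0 or any(b <= a for a, b in zip(vt, vt[1:])):
            raise ValidationError("visit_times must start at 0 and strictly increase")
        if not 0.0 <= self.reduction <= 1.0:
            raise ValidationError("reduction must be in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class SimulationParams:
    """Generative quantities of the power simulation."""

    beta_placebo: float  # mean annual progression, placebo arm (outcome units/yr)
    delta: float  # SD of the subject-level random slope
    epsilon: float  # residual SD
    baseline_mean: float = 0.0
    n_sims: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta < 0 or self.epsilon < 0:
            raise ValidationError("delta and epsilon must be non-negative")
        if self.n_sims < 1:
            raise ValidationError("n_sims must be at least 1")


@dataclass(frozen=True)
class TrialTestResult:
    """Outcome of analyzing one simulated trial."""

    estimate: float  # group-by-time coefficient (treatment - placebo slope)
    p_value: float
    rejected: bool
    method: str  # "closed_form" | "reml"
    converged: bool = True


@dataclass(frozen=True)
class PowerResult:
    """Empirical power over simulated trials."""

    empirical_power: float
    n_sims: int
    n_rejections: int
    mc_se: float
    n_nonconverged: int = 0


@dataclass
class SampleSizeResult:
    """Smallest per-arm n reaching the target power, with the search trace."""

    n_required: int | None
    target_power: float
    achieved: bool
    trace: list[tuple[int, float]] = field(default_factory=list)


def simulate_trial(
    design: TrialDesign, params: SimulationParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Simulate one trial as a long table (subject, arm, t, y).

    ``arm`` is 0 for placebo, 1 for treatment; reproducible given ``rng``.
    """
    t = np.asarray(design.visit_times)
    n, k = design.n_per_arm, len(t)
    arm = np.repeat([0, 1], n)
    beta = np.where(arm == 1, (1.0 - design.reduction) * params.beta_placebo, params.beta_placebo)
    slopes = beta + rng.normal(0.0, params.delta, size=2 * n)
    noise = rng.normal(0.0, params.epsilon, size=(2 * n, k))
    y = params.baseline_mean + slopes[:, None] * t[None, :] + noise
    return pd.DataFrame(
        {
            "subject_id": np.repeat(np.arange(2 * n), k),
            "arm": np.repeat(arm, k),
            "t": np.tile(t, 2 * n),
            "y": y.ravel(),
        }
    )


def _slope_test(table: pd.DataFrame, alpha: float) -> TrialTestResult:
    """Exact reduction for balanced complete tables: t-test on OLS slopes."""
    wide = table.pivot_table(index=["arm", "subject_id"], columns="t", values="y")
    t = wide.columns.to_numpy(dtype=float)
    sxx = float(np.sum((t - t.mean()) ** 2))
    w = (t - t.mean()) / sxx
    slopes = wide.to_numpy() @ w
    arm = wide.index.get_level_values("arm").to_numpy()
    a, b = slopes[arm == 0], slopes[arm == 1]
    est = float(b.mean() - a.mean())
    df = len(a) + len(b) - 2
    pooled = math.sqrt(
        ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    )
    if pooled == 0.0:
        p = 0.0 if est != 0 else 1.0
    else:
        tstat = est / (pooled * math.sqrt(1 / len(a) + 1 / len(b)))
        p = 2.0 * stats.t.sf(abs(tstat), df)
    return TrialTestResult(est, float(p), p < alpha, "closed_form")


def _reml_test(table: pd.DataFrame, alpha: float) -> TrialTestResult:
    """Numerical REML fit of the pure random-slope trial model."""
    df = table
    t = df["t"].to_numpy(dtype=float)
    arm = df["arm"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), t, arm, t * arm])
    res = fit_lmm(df["y"].to_numpy(dtype=float), X, df["subject_id"].to_numpy(), [t])
    est = float(res.beta[3])
    ddf = max(res.n_groups - 2, 1)
    tstat = est / float(np.sqrt(res.cov_beta[3, 3]))
    p = 2.0 * stats.t.sf(abs(tstat), ddf)
    return TrialTestResult(est, float(p), p < alpha, "reml", bool(res.converged))


def analyze_trial(table: pd.DataFrame, alpha: float = 0.05, method: str = "auto") -> TrialTestResult:
    """Test the group-by-time (progression-slowing) effect in one trial.

    ``method='auto'`` uses the exact closed-form reduction when every
    subject was observed at the same set of at least two visits, and the
    numerical REML fit otherwise.
    """
    counts = table.groupby("subject_id")["t"].count()
    if counts.min() < 2:
        raise ValidationError("slope not estimable: subjects need >= 2 visits")
    balanced = (
        counts.nunique() == 1
        and table.groupby("subject_id")["t"].apply(tuple).nunique() == 1
    )
    if method == "auto":
        method = "closed_form" if balanced else "reml"
    if method == "closed_form":
        if not balanced:
            raise ValidationError("closed-form analysis requires a balanced table")
        return _slope_test(table, alpha)
    if method == "reml":
        return _reml_test(table, alpha)
    raise ValidationError(f"unknown analysis method {method!r}")


def empirical_power(
    design: TrialDesign, params: SimulationParams, method: str = "auto"
) -> PowerResult:
    """Empirical power over ``params.n_sims`` simulated trials.

    One master seed spawns an independent substream per replicate, so the
    result does not depend on replicate execution order.  Replicates whose
    analysis fails to converge are excluded from the denominator and
    counted.
    """
    streams = np.random.SeedSequence(params.seed).spawn(params.n_sims)
    n_rej = n_bad = 0
    for ss in streams:
        table = simulate_trial(design, params, np.random.default_rng(ss))
        result = analyze_trial(table, design.alpha, method=method)
        if not result.converged:
            n_bad += 1
            continue
        n_rej += result.rejected
    n_eff = params.n_sims - n_bad
    if n_bad:
        logger.warning("%d/%d replicates did not converge; excluded", n_bad, params.n_sims)
    power = n_rej / n_eff if n_eff else math.nan
    mc_se = math.sqrt(power * (1 - power) / n_eff) if n_eff else math.nan
    return PowerResult(power, n_eff, n_rej, mc_se, n_bad)


def analytic_slope_power(design: TrialDesign, params: SimulationParams) -> float:
    """Closed-form power of the two-sample test on per-subject OLS slopes.

    Normal approximation with known variances: the per-subject slope has
    variance delta^2 + epsilon^2/Sxx, and the detectable difference is
    r * beta_placebo.  Exact (up to the t-vs-normal df correction) when
    delta = 0; serves as the independent oracle for the simulation.
    """
    t = np.asarray(design.visit_times)
    sxx = float(np.sum((t - t.mean()) ** 2))
    var_slope = params.delta**2 + params.epsilon**2 / sxx
    delta_effect = design.reduction * abs(params.beta_placebo)
    se = math.sqrt(2.0 * var_slope / design.n_per_arm)
    if se == 0.0:
        return 1.0 if delta_effect > 0 else design.alpha
    z = stats.norm.ppf(1.0 - design.alpha / 2.0)
    shift = delta_effect / se
    return float(stats.norm.cdf(shift - z) + stats.norm.cdf(-shift - z))


def _analytic_n(design: TrialDesign, params: SimulationParams, target: float) -> int:
    """Normal-approximation n per arm (search starting point)."""
    t = np.asarray(design.visit_times)
    sxx = float(np.sum((t - t.mean()) ** 2))
    var_slope = params.delta**2 + params.epsilon**2 / sxx
    delta_effect = design.reduction * abs(params.beta_placebo)
    if delta_effect == 0 or var_slope == 0:
        return 2
    za = stats.norm.ppf(1.0 - design.alpha / 2.0)
    zb = stats.norm.ppf(target)
    return max(2, math.ceil(2.0 * (za + zb) ** 2 * var_slope / delta_effect**2))


def sample_size_search(
    params: SimulationParams,
    reduction: float,
    target_power: float = 0.8,
    alpha: float = 0.05,
    visit_times: tuple[float, ...] = DEFAULT_VISITS,
    step: int = 5,
    refine: bool = True,
    n_max: int = 1000,
    method: str = "auto",
) -> SampleSizeResult:
    """Smallest per-arm n whose empirical power reaches ``target_power``.

    Walks a step-``step`` grid starting from the analytic approximation,
    then (optionally) refines to step 1 just below the located boundary.
    Reports the full power-vs-n trace.
    """
    if params.beta_placebo == 0 or reduction <= 0:
        raise ValidationError("sample size requires beta_placebo != 0 and reduction > 0")
    base = TrialDesign(
        n_per_arm=2, visit_times=visit_times, reduction=reduction, alpha=alpha
    )
    if params.delta == 0 and params.epsilon == 0:
        design = replace(base, n_per_arm=2)
        res = empirical_power(design, params, method=method)
        return SampleSizeResult(2, target_power, True, [(2, res.empirical_power)])

    seen: dict[int, float] = {}

    def power_at(n: int) -> float:
        if n not in seen:
            res = empirical_power(replace(base, n_per_arm=n), params, method=method)
            seen[n] = res.empirical_power
            logger.info("n_per_arm=%d -> empirical power %.3f", n, res.empirical_power)
        return seen[n]

    grid = lambda n: max(step, min(n_max, step * math.ceil(n / step)))
    n = grid(_analytic_n(base, params, target_power))
    if power_at(n) >= target_power:
        while n > step and power_at(n - step) >= target_power:
            n -= step
    else:
        while n < n_max and power_at(n) < target_power:
            n += step
        if power_at(n) < target_power:
            return SampleSizeResult(None, target_power, False, sorted(seen.items()))
    if refine:
        while n > 2 and power_at(n - 1) >= target_power:
            n -= 1
    return SampleSizeResult(n, target_power, True, sorted(seen.items()))
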