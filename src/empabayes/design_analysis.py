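"""Frequentist power analysis and Monte-Carlo Bayes-factor design analysis.

Three pieces of study planning machinery:

* :func:`r_to_d` — conversion of a correlation effect size to Cohen's d.
* :func:`interaction_power` / :func:`required_n` — power of the
  group-by-time interaction in a 2 (between) x 2 (within) mixed ANOVA
  under the GPower "as in SPSS" convention: effect size f = d/2,
  noncentrality lambda = f^2 * N * m / (1 - rho) with m repeated
  measures correlated rho.
* :func:`bfda` — Bayes-factor design analysis: simulate many datasets at
  a given true effect size, apply the one-sided default JZS two-sample
  t-test (on change scores for pre/post designs, raw scores for
  single-session designs) and tally how often the Bayes factor crosses
  the evidence thresholds (BF > 3 for H1, BF < 1/3 for H0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from empabayes import bayes_factors, synthetic_data


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the within-between interaction power computation."""

    d: float
    N: int
    rho: float = 0.5
    alpha: float = 0.05
    groups: int = 2
    measurements: int = 2

    def __post_init__(self) -> None:
        if self.N <= self.groups:
            raise ValueError("N must exceed the number of groups")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class BFDAResult:
    """Monte-Carlo probabilities of the three evidence outcomes."""

    p_inconclusive: float
    p_H0: float
    p_H1: float
    n_reps: int
    se_inconclusive: float
    se_H0: float
    se_H1: float

    def __post_init__(self) -> None:
        total = self.p_inconclusive + self.p_H0 + self.p_H1
        if abs(total - 1.0) > 1e-9:
            raise ValueError("outcome probabilities must sum to 1")


def r_to_d(r: float) -> float:
    """Cohen's d equivalent of a point-biserial-style correlation: 2r/sqrt(1-r^2)."""
    if abs(r) >= 1.0:
        raise ValueError("|r| must be below 1")
    return 2.0 * r / math.sqrt(1.0 - r * r)


def interaction_power(spec: PowerSpec) -> float:
    """Power of the within-between interaction F test.

    The interaction F statistic has df1 = (groups-1)(m-1) and
    df2 = (N-groups)(m-1); under an effect d the statistic is noncentral F
    with lambda = (d/2)^2 * N * m / (1 - rho). Power is the probability of
    exceeding the central-F critical value at level alpha.
    """
    g, m = spec.groups, spec.measurements
    df1 = (g - 1) * (m - 1)
    df2 = (spec.N - g) * (m - 1)
    f2 = (spec.d / 2.0) ** 2
    lam = f2 * spec.N * m / (1.0 - spec.rho)
    fcrit = stats.f.ppf(1.0 - spec.alpha, df1, df2)
    if lam == 0.0:
        return float(spec.alpha)
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def required_n(
    d: float,
    target_power: float = 0.8,
    rho: float = 0.5,
    alpha: float = 0.05,
    max_n: int = 10**6,
) -> int:
    """Smallest even total N (equal groups) reaching the target power."""
    if not 0.0 < target_power < 1.0:
        raise ValueError("target power must be in (0, 1)")
    n = 4  # minimum admissible: two per group
    while n <= max_n:
        if interaction_power(PowerSpec(d=d, N=n, rho=rho, alpha=alpha)) >= target_power:
            return n
        n += 2
    raise ValueError(f"power {target_power} unreachable with N <= {max_n}")


def bfda(
    d: float,
    rho: float | None,
    n1: int = 44,
    n2: int = 45,
    n_reps: int = 10_000,
    seed: int = 0,
    bf_scale: float = bayes_factors.DEFAULT_CAUCHY_SCALE,
    h1_threshold: float = bayes_factors.H1_THRESHOLD,
    h0_threshold: float = bayes_factors.H0_THRESHOLD,
) -> BFDAResult:
    """Monte-Carlo Bayes-factor design analysis for one scenario.

    Parameters
    ----------
    d:
        True standardized effect, applied to the post measurement of the
        experimental group (pre/post scenarios) or to the raw score
        (single-session scenario).
    rho:
        Test-retest correlation of the pre/post measurements; ``None``
        selects the single-session design (raw-score test).
    n1, n2:
        Control and experimental group sizes (the study's 44 and 45).
    n_reps:
        Simulated datasets (the study's own analysis used 10,000).

    For each dataset a pooled two-sample t statistic (experimental minus
    control, change scores or raw scores) is converted to a one-sided
    (positive-direction) JZS Bayes factor, and the fractions of BF > 3
    (H1), BF < 1/3 (H0) and inconclusive outcomes are reported with their
    Monte-Carlo standard errors.
    """
    if n_reps < 100:
        raise ValueError("need at least 100 Monte-Carlo repetitions")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ts = np.empty(n_reps)
    for rep in range(n_reps):
        if rho is None:
            sample = synthetic_data.generate_single_session_groups(d, n1, n2, rng)
        else:
            sample = synthetic_data.generate_prepost_groups(d, rho, n1, n2, rng)
        score = sample.change if rho is not None else sample.post
        x1 = score[sample.group == 1]
        x2 = score[sample.group == 2]
        ts[rep] = bayes_factors.summary_t(
            float(x2.mean()), float(x2.std(ddof=1)), n2,
            float(x1.mean()), float(x1.std(ddof=1)), n1,
        )
    bfs = bayes_factors.jzs_ttest_bf_many(
        ts, n2, n1, scale=bf_scale, direction="positive"
    )
    p_h1 = float(np.mean(bfs > h1_threshold))
    p_h0 = float(np.mean(bfs < h0_threshold))
    p_inc = 1.0 - p_h1 - p_h0

    def se(p: float) -> float:
        return math.sqrt(p * (1.0 - p) / n_reps)

    return BFDAResult(
        p_inconclusive=p_inc,
        p_H0=p_h0,
        p_H1=p_h1,
        n_reps=n_reps,
        se_inconclusive=se(p_inc),
        se_H0=se(p_h0),
        se_H1=se(p_h1),
    )


#: The study's design-analysis grid: scenario name -> test-retest rho
#: (None = single-session raw-score design).
TABLE_SCENARIOS: dict[str, float | None] = {
    "painfulness": 0.75,
    "unpleasantness": 0.90,
    "neural": 0.0,
    "reactivity": None,
}

TABLE_EFFECT_SIZES: tuple[float, ...] = (0.0, 0.2, 0.3, 0.4)


def bfda_grid(
    n_reps: int = 10_000,
    seed: int = 0,
    scenarios: dict[str, float | None] | None = None,
    effect_sizes: tuple[float, ...] = TABLE_EFFECT_SIZES,
    n1: int = 44,
    n2: int = 45,
):
    """Run the full design-analysis grid; returns a tidy DataFrame."""
    import pandas as pd

    scenarios = TABLE_SCENARIOS if scenarios is None else scenarios
    seeds = np.random.SeedSequence(seed).spawn(len(scenarios) * len(effect_sizes))
    rows = []
    k = 0
    for name, rho in scenarios.items():
        for d in effect_sizes:
            res = bfda(
                d, rho, n1=n1, n2=n2, n_reps=n_reps,
                seed=seeds[k].generate_state(1)[0] % (2**31),
            )
            rows.append({
                "scenario": name,
                "rho": rho,
                "d": d,
                "inconclusive": res.p_inconclusive,
                "H0": res.p_H0,
                "H1": res.p_H1,
                "n_reps": n_reps,
            })
            k += 1
    return pd.DataFrame(rows)
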