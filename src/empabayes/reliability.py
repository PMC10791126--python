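"""Test-retest reliability from random-effect variance components.

In a two-session design the subject-level empathic response in session
s = ±1 is the random Intensity effect plus s times the random
Intensity-by-Session effect, b_I + s * b_I:S. The test-retest
reliability is therefore the correlation between (b_I - b_I:S) and
(b_I + b_I:S) under the random-effect distribution, which in terms of
the model parameters is

    rho = (sd_I^2 - sd_IS^2) /
          sqrt[(sd_I^2 + sd_IS^2 - 2 r sd_I sd_IS)
               (sd_I^2 + sd_IS^2 + 2 r sd_I sd_IS)]

with r the correlation between the two random effects. Applied per
posterior draw, the posterior of rho propagates the full parameter
uncertainty.

For neural measures the reliability is the correlation between the
subject-level contrast effects of session 1 and session 2, either the
model's correlation parameter or the per-draw Pearson correlation of the
two random-effect vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from empabayes.censored_model import PosteriorDraws


@dataclass(frozen=True)
class ReliabilityEstimate:
    """Posterior summary of a test-retest correlation."""

    rho_mean: float
    ci_low: float
    ci_high: float
    source: Literal["behavioral", "neural"]

    def __post_init__(self) -> None:
        eps = 1e-9  # tolerate quantile round-off on near-constant draws
        ok = (
            -1.0 - eps <= self.ci_low <= self.rho_mean + eps
            and self.rho_mean <= self.ci_high + eps <= 1.0 + 2 * eps
        )
        if not ok:
            raise ValueError("reliability summary violates -1 <= lo <= mean <= hi <= 1")


def behavioral_reliability(
    sigma_bI: float | np.ndarray,
    sigma_bIS: float | np.ndarray,
    r: float | np.ndarray,
) -> float | np.ndarray:
    """Reliability of the session contrast from variance components.

    Parameters are the SDs of the random Intensity and Intensity:Session
    effects and their correlation ``r``; accepts scalars or arrays of
    posterior draws (evaluated elementwise).
    """
    sigma_bI = np.asarray(sigma_bI, dtype=float)
    sigma_bIS = np.asarray(sigma_bIS, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(sigma_bI < 0) or np.any(sigma_bIS < 0):
        raise ValueError("random-effect SDs must be nonnegative")
    if np.any(np.abs(r) > 1):
        raise ValueError("correlation must lie in [-1, 1]")
    v1 = sigma_bI**2
    v2 = sigma_bIS**2
    cross = 2.0 * r * sigma_bI * sigma_bIS
    denom_sq = (v1 + v2 - cross) * (v1 + v2 + cross)
    if np.any(denom_sq <= 0):
        raise ValueError("degenerate random effects: zero session-response variance")
    out = (v1 - v2) / np.sqrt(denom_sq)
    return float(out) if out.ndim == 0 else out


def behavioral_reliability_posterior(
    draws: PosteriorDraws,
    effect_term: str = "intensity",
    interaction_term: str = "session:intensity",
    ci: float = 0.95,
) -> ReliabilityEstimate:
    """Apply the variance-component formula per posterior draw and summarize."""
    sd_i = draws.re_sd_draws(effect_term)
    sd_is = draws.re_sd_draws(interaction_term)
    r = draws.re_corr_draws(effect_term, interaction_term)
    rho = behavioral_reliability(sd_i, sd_is, r)
    lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2
    return ReliabilityEstimate(
        rho_mean=float(np.mean(rho)),
        ci_low=float(np.quantile(rho, lo)),
        ci_high=float(np.quantile(rho, hi)),
        source="behavioral",
    )


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two (draws, subjects) arrays."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = np.sum(a * b, axis=1)
    den = np.sqrt(np.sum(a**2, axis=1) * np.sum(b**2, axis=1))
    return num / den


def neural_reliability(
    draws: PosteriorDraws,
    session1_term: str = "contrast_session1",
    session2_term: str = "contrast_session2",
    use_model_correlation: bool = False,
    ci: float = 0.95,
) -> ReliabilityEstimate:
    """Cross-session correlation of subject-level neural contrast effects.

    Per posterior draw, the Pearson correlation between the subjects'
    session-1 and session-2 contrast random effects (or, with
    ``use_model_correlation``, the model's correlation parameter between
    the two random-effect terms), summarized as posterior mean and
    central credible interval.
    """
    if len(draws.subjects) < 3:
        raise ValueError("need at least three subjects for a correlation")
    if use_model_correlation:
        rho = draws.re_corr_draws(session1_term, session2_term)
    else:
        b1 = draws.random_effect_draws(session1_term)
        b2 = draws.random_effect_draws(session2_term)
        rho = _pearson_rows(b1, b2)
    lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2
    return ReliabilityEstimate(
        rho_mean=float(np.mean(rho)),
        ci_low=float(np.quantile(rho, lo)),
        ci_high=float(np.quantile(rho, hi)),
        source="neural",
    )


def cross_task_correlations(
    measures: Mapping[str, np.ndarray],
    subject_ids: Mapping[str, Sequence[str]] | None = None,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Posterior correlations between subject-level measures across tasks.

    Parameters
    ----------
    measures:
        Map measure name -> (draws, subjects) array of subject-level
        effects (e.g. random Intensity effects from the rating model and
        contrast effects from ROI models). All arrays must share the
        subject dimension; draw counts may differ (arrays are trimmed to
        the shortest).
    subject_ids:
        Optional map measure name -> subject id sequence, checked for
        consistency across measures.

    Returns
    -------
    A square DataFrame in the study's tabular convention: posterior mean
    correlations above the diagonal, ``[lo, hi]`` credible intervals as
    strings below the diagonal, empty diagonal.
    """
    names = list(measures)
    if subject_ids is not None:
        ref = list(subject_ids[names[0]])
        for n in names[1:]:
            if list(subject_ids[n]) != ref:
                raise ValueError(f"subject ids of {n!r} do not match {names[0]!r}")
    n_subj = {a.shape[1] for a in measures.values()}
    if len(n_subj) != 1:
        raise ValueError("all measures must cover the same subjects")
    if n_subj.pop() < 3:
        raise ValueError("need at least three subjects")
    d_min = min(a.shape[0] for a in measures.values())
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    out = pd.DataFrame("", index=names, columns=names, dtype=object)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i >= j:
                continue
            rho = _pearson_rows(measures[a][:d_min], measures[b][:d_min])
            out.loc[a, b] = f"{np.mean(rho):.3f}"
            out.loc[b, a] = f"({np.quantile(rho, lo_q):.3f},{np.quantile(rho, hi_q):.3f})"
    return out


def cross_task_correlation_arrays(
    measures: Mapping[str, np.ndarray], ci: float = 0.95
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Numeric companion to :func:`cross_task_correlations`.

    Returns (posterior-mean matrix, ci-low matrix, ci-high matrix) as
    symmetric DataFrames with unit diagonal.
    """
    names = list(measures)
    d_min = min(a.shape[0] for a in measures.values())
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    mean = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    low = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    high = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i >= j:
                continue
            rho = _pearson_rows(measures[a][:d_min], measures[b][:d_min])
            mean.loc[a, b] = mean.loc[b, a] = float(np.mean(rho))
            low.loc[a, b] = low.loc[b, a] = float(np.quantile(rho, lo_q))
            high.loc[a, b] = high.loc[b, a] = float(np.quantile(rho, hi_q))
    return mean, low, high
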