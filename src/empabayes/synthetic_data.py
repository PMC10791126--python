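"""Synthetic-data generators for every input the analysis pipeline consumes.

The generators emulate the statistical structure the downstream models
assume, so the whole pipeline is testable without any external download:

* :func:`generate_empathy_ratings` — 0-100 visual-analog-scale ratings
  from a two-group (control vs. violent game), two-session
  empathy-for-pain design with ±1-coded factors Group, Session and
  Intensity, per-subject random effects and per-subject residual SDs,
  clamped to the scale bounds with censoring flags.
* :func:`generate_reactivity_ratings` — single-session
  emotional-reactivity ratings with factors Group, Content and Context.
* :func:`generate_prepost_groups` — subject-level bivariate-normal
  pre/post scores for Monte-Carlo design analysis.
* :func:`generate_empathy_events` / :func:`generate_roi_timecourse` —
  BIDS-events-style task timings and HRF-convolved ROI signal time
  courses.

All generators are deterministic given their seed; each subject receives
a child random stream spawned from the master seed, so subject i's data
do not change when more subjects are requested.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from empabayes import roi_model

# Canonical factor-term order of the two rating designs.
EMPATHY_FIXED_TERMS: tuple[str, ...] = (
    "intercept", "group", "session", "intensity",
    "group:session", "group:intensity", "session:intensity",
    "group:session:intensity",
)
EMPATHY_RANDOM_TERMS: tuple[str, ...] = (
    "intercept", "session", "intensity", "session:intensity",
)
REACTIVITY_FIXED_TERMS: tuple[str, ...] = (
    "intercept", "group", "content", "context",
    "group:content", "group:context", "content:context",
    "group:content:context",
)
REACTIVITY_RANDOM_TERMS: tuple[str, ...] = (
    "intercept", "content", "context", "content:context",
)


def _default_empathy_effects() -> dict[str, float]:
    # Generative defaults mirror the magnitudes of the painfulness-rating
    # analysis: a large pain-intensity effect, negligible everything else.
    return {"intercept": 45.0, "intensity": 27.86}


def default_reactivity_effects() -> dict[str, float]:
    """Generative defaults mirroring the reactivity-rating magnitudes."""
    return {"intercept": 45.0, "content": 37.08, "context": -7.24,
            "content:context": -5.36}


def _default_re_sd(terms: Sequence[str]) -> dict[str, float]:
    scale = {"intercept": 12.0}
    return {t: scale.get(t, 4.0) for t in terms}


@dataclass
class StudyConfig:
    """Generative configuration of a two-group rating study.

    Parameters
    ----------
    n_control, n_experimental:
        Group sizes (the study design uses 44 and 45).
    ratings_per_cell:
        Ratings per factor cell per session. Default 8: participants rate
        after half of the 16 trials per condition in the empathy task.
        Use 4 for the reactivity task (one rating per picture block).
    censor_low, censor_high:
        Bounds of the rating scale (0 and 100).
    fixed_effects:
        Map term -> generative effect size beta in rating units; terms not
        listed are zero.
    re_sd:
        Map random-effect term -> SD in rating units; terms not listed get
        defaults (12 for the intercept, 4 otherwise).
    re_corr:
        Correlation matrix over the design's random-effect terms, in
        canonical order; identity when omitted.
    subject_sigma_dist:
        ``(log_median, log_sd)`` of the log-normal distribution of
        per-subject residual SDs — strictly positive with a realistic
        heavy-ish right tail. ``log_sd = 0`` makes all subjects share
        ``exp(log_median)``.
    seed:
        Master seed; per-subject child streams are spawned from it.
    """

    n_control: int = 44
    n_experimental: int = 45
    ratings_per_cell: int = 8
    censor_low: float = 0.0
    censor_high: float = 100.0
    fixed_effects: Mapping[str, float] = field(default_factory=_default_empathy_effects)
    re_sd: Mapping[str, float] | None = None
    re_corr: np.ndarray | None = None
    subject_sigma_dist: tuple[float, float] = (np.log(10.0), 0.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_experimental < 2:
            raise ValueError("need at least two subjects per group")
        if self.censor_low >= self.censor_high:
            raise ValueError("censor_low must be below censor_high")
        if self.re_sd is not None and any(s < 0 for s in self.re_sd.values()):
            raise ValueError("random-effect SDs must be nonnegative")
        if self.subject_sigma_dist[1] < 0:
            raise ValueError("sigma log-sd must be nonnegative")


@dataclass
class PrePostSample:
    """Subject-level pre/post scores of a two-group design."""

    group: np.ndarray  # 1 (control) or 2 (experimental)
    pre: np.ndarray
    post: np.ndarray

    @property
    def change(self) -> np.ndarray:
        return self.post - self.pre

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": [f"s{i + 1:03d}" for i in range(self.group.size)],
            "group": self.group,
            "pre": self.pre,
            "post": self.post,
        })


def _corr_cholesky(corr: np.ndarray | None, k: int) -> np.ndarray:
    if corr is None:
        return np.eye(k)
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (k, k):
        raise ValueError(f"re_corr must be {k}x{k}, got {corr.shape}")
    if not np.allclose(corr, corr.T):
        raise ValueError("re_corr must be symmetric")
    if not np.allclose(np.diag(corr), 1.0):
        raise ValueError("re_corr must have unit diagonal")
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("re_corr must be positive definite") from exc


def _term_value(term: str, levels: Mapping[str, float]) -> float:
    if term == "intercept":
        return 1.0
    out = 1.0
    for f in term.split(":"):
        out *= levels[f]
    return out


def _generate_ratings(
    config: StudyConfig,
    within_factors: Sequence[str],
    fixed_terms: Sequence[str],
    random_terms: Sequence[str],
    sessions: Sequence[int],
    extra_columns: Mapping[str, object] | None = None,
) -> pd.DataFrame:
    re_sd = dict(config.re_sd) if config.re_sd is not None else _default_re_sd(random_terms)
    unknown = set(re_sd) - set(random_terms)
    if unknown:
        raise ValueError(f"random-effect SDs for unknown terms: {sorted(unknown)}")
    # An explicit re_sd map is complete (missing terms mean SD 0);
    # defaults apply only when no map is given.
    fallback = 0.0 if config.re_sd is not None else None
    defaults = _default_re_sd(random_terms)
    sd_vec = np.array(
        [re_sd.get(t, defaults[t] if fallback is None else fallback)
         for t in random_terms]
    )
    chol = _corr_cholesky(config.re_corr, len(random_terms)) * sd_vec[:, None]
    betas = dict(config.fixed_effects)
    unknown = set(betas) - set(fixed_terms)
    if unknown:
        raise ValueError(f"fixed effects for unknown terms: {sorted(unknown)}")

    n_total = config.n_control + config.n_experimental
    groups = np.repeat([-1.0, 1.0], [config.n_control, config.n_experimental])
    streams = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(config.seed).spawn(n_total)
    ]
    log_mu, log_sd = config.subject_sigma_dist
    cells = list(itertools.product(*[(-1.0, 1.0)] * len(within_factors)))
    rows: list[dict] = []
    for i, (g, rng) in enumerate(zip(groups, streams)):
        b = chol @ rng.standard_normal(len(random_terms))
        sigma = float(np.exp(log_mu + log_sd * rng.standard_normal()))
        for session in sessions:
            for cell in cells:
                levels = {"group": g, "session": float(session)}
                levels.update(dict(zip(within_factors, cell)))
                mu = sum(betas.get(t, 0.0) * _term_value(t, levels) for t in fixed_terms)
                mu += sum(
                    bk * _term_value(t, levels) for bk, t in zip(b, random_terms)
                )
                latent = mu + sigma * rng.standard_normal(config.ratings_per_cell)
                for val in latent:
                    if val <= config.censor_low:
                        rating, cen = config.censor_low, "low"
                    elif val >= config.censor_high:
                        rating, cen = config.censor_high, "high"
                    else:
                        rating, cen = float(val), "none"
                    row = {
                        "subject_id": f"s{i + 1:03d}",
                        "group": int(g),
                        "session": int(session),
                    }
                    if extra_columns:
                        row.update(extra_columns)
                    row.update({f: int(v) for f, v in zip(within_factors, cell)})
                    row.update({"rating": rating, "censored": cen})
                    rows.append(row)
    return pd.DataFrame(rows)


def generate_empathy_ratings(config: StudyConfig) -> pd.DataFrame:
    """Simulate ratings from the two-session empathy-for-pain task.

    Latent ratings follow the full ±1-coded Group x Session x Intensity
    fixed-effect structure plus per-subject random effects (intercept,
    Session, Intensity, Session:Intensity) and subject-specific Gaussian
    noise, then are clamped to the scale bounds with a censoring flag.
    Only the rated Other-condition trials are emitted (``target`` column
    constant ``"other"``): those are the trials the rating models analyze.
    """
    return _generate_ratings(
        config,
        within_factors=("intensity",),
        fixed_terms=EMPATHY_FIXED_TERMS,
        random_terms=EMPATHY_RANDOM_TERMS,
        sessions=(-1, 1),
        extra_columns={"target": "other"},
    )


def generate_reactivity_ratings(config: StudyConfig) -> pd.DataFrame:
    """Simulate single-session emotional-reactivity ratings.

    Factors Group x Content x Context with per-subject random effects for
    Content, Context and their interaction; one rating per picture block
    (pass ``ratings_per_cell=4`` for the study's 4 blocks per condition).
    The single session is coded +1.
    """
    return _generate_ratings(
        config,
        within_factors=("content", "context"),
        fixed_terms=REACTIVITY_FIXED_TERMS,
        random_terms=REACTIVITY_RANDOM_TERMS,
        sessions=(1,),
    )


def generate_prepost_groups(
    d: float, rho: float, n1: int, n2: int, seed: int | np.random.Generator
) -> PrePostSample:
    """Simulate subject-level pre/post scores of a two-group design.

    Each subject's (pre, post) pair is bivariate normal with unit
    marginal SDs and correlation ``rho``; group 2 receives a mean shift
    ``d`` on the post measurement only. The implied standardized effect
    on change scores (post - pre) is d / sqrt(2 (1 - rho)).
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must be in (-1, 1)")
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two subjects per group")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = n1 + n2
    pre = rng.standard_normal(n)
    post = rho * pre + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    group = np.repeat([1, 2], [n1, n2])
    post = post + d * (group == 2)
    return PrePostSample(group=group, pre=pre, post=post)


def generate_single_session_groups(
    d: float, n1: int, n2: int, seed: int | np.random.Generator
) -> PrePostSample:
    """Two independent groups measured once (standardized mean shift ``d``).

    Returned as a :class:`PrePostSample` with the measurement in ``post``
    and ``pre`` set to zero, so downstream code analyzes ``post`` raw.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two subjects per group")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    group = np.repeat([1, 2], [n1, n2])
    post = rng.standard_normal(n1 + n2) + d * (group == 2)
    return PrePostSample(group=group, pre=np.zeros(n1 + n2), post=post)


def generate_empathy_events(
    n_trials_per_condition: int = 16,
    cue_duration: float = 2.0,
    stim_duration_self: float = 0.5,
    stim_duration_other: float = 1.0,
    rating_duration: float = 4.0,
    jitter: tuple[float, float] = (3.0, 7.0),
    iti: tuple[float, float] = (2.0, 4.0),
    rating_fraction: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Build a BIDS-events-style timing table for the empathy-for-pain task.

    Each trial is cue (2 s) -> jittered interval (3-7 s) -> stimulation
    (0.5 s self / 1 s other) and, after roughly ``rating_fraction`` of the
    trials, a rating event. Conditions (self/other x pain/no-pain) are
    interleaved in pseudorandom order. Columns: onset, duration,
    trial_type (e.g. ``stim_other_pain``, ``cue_self_nopain``,
    ``rating``).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    conditions = [
        ("self", "nopain"), ("self", "pain"), ("other", "nopain"), ("other", "pain")
    ]
    trials = [c for c in conditions for _ in range(n_trials_per_condition)]
    order = rng.permutation(len(trials))
    rows = []
    t = 0.0
    for idx in order:
        target, intensity = trials[idx]
        rows.append({"onset": t, "duration": cue_duration,
                     "trial_type": f"cue_{target}_{intensity}"})
        t += cue_duration + rng.uniform(*jitter)
        dur = stim_duration_self if target == "self" else stim_duration_other
        rows.append({"onset": t, "duration": dur,
                     "trial_type": f"stim_{target}_{intensity}"})
        t += dur
        if rng.random() < rating_fraction:
            t += rng.uniform(*jitter)
            rows.append({"onset": t, "duration": rating_duration,
                         "trial_type": "rating"})
            t += rating_duration
        t += rng.uniform(*iti)
    return pd.DataFrame(rows)


def generate_roi_timecourse(
    events: pd.DataFrame,
    amplitudes: Mapping[str, float],
    noise_sd: float,
    tr: float = 1.2,
    n_scans: int = 1000,
    seed: int | np.random.Generator = 0,
    hrf_config: "roi_model.HRFConfig | None" = None,
) -> np.ndarray:
    """Simulate an ROI-averaged signal from event timings.

    signal = sum over trial types of (HRF-convolved boxcar x amplitude)
    plus white Gaussian noise of SD ``noise_sd``. Trial types missing
    from ``amplitudes`` contribute amplitude 0.
    """
    if noise_sd < 0:
        raise ValueError("noise SD must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X, names = roi_model.build_design_matrix(
        events, tr=tr, n_scans=n_scans, hrf_config=hrf_config, drift=False
    )
    unknown = set(amplitudes) - set(names)
    if unknown:
        raise ValueError(f"amplitudes for unknown trial types: {sorted(unknown)}")
    amp = np.array([amplitudes.get(name, 0.0) for name in names])
    return X @ amp + noise_sd * rng.standard_normal(n_scans)


def generate_roi_study(
    n_control: int = 4,
    n_experimental: int = 4,
    amp_mean: float = 1.0,
    contrast_mean: float = 1.0,
    group_session_intensity: float = 0.0,
    re_sd_amp: float = 0.3,
    re_sd_contrast: float = 0.3,
    contrast_session_corr: float = 0.5,
    noise_sd: float = 1.0,
    tr: float = 1.2,
    n_scans: int = 420,
    n_trials_per_condition: int = 8,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[tuple[str, int], pd.DataFrame]]:
    """Simulate a full two-session ROI dataset matching the hierarchical model.

    For every subject and session, Other-condition stimulation amplitudes
    are mean amplitude ± half the pain/no-pain contrast, with subject
    random effects for the mean amplitude and session-specific contrast
    effects correlated ``contrast_session_corr`` across sessions, plus an
    optional Group x Session x Intensity interaction
    ``group_session_intensity`` on the ±1-coded scale. Returns the long
    series table and the per-run event tables.
    """
    master = np.random.SeedSequence(seed)
    n_total = n_control + n_experimental
    streams = [np.random.default_rng(s) for s in master.spawn(n_total + 1)]
    groups = np.repeat([-1.0, 1.0], [n_control, n_experimental])
    rows = []
    events_map: dict[tuple[str, int], pd.DataFrame] = {}
    for i, (g, rng) in enumerate(zip(groups, streams[:-1])):
        subject = f"s{i + 1:03d}"
        u_amp = re_sd_amp * rng.standard_normal()
        z1 = rng.standard_normal()
        z2 = contrast_session_corr * z1 + np.sqrt(
            1.0 - contrast_session_corr**2
        ) * rng.standard_normal()
        c_sess = {-1: re_sd_contrast * z1, 1: re_sd_contrast * z2}
        for t in (-1, 1):
            ev = generate_empathy_events(
                n_trials_per_condition=n_trials_per_condition, seed=rng
            )
            end = (ev["onset"] + ev["duration"]).max()
            if end > n_scans * tr:
                raise ValueError(
                    f"events ({end:.0f} s) exceed scan duration "
                    f"({n_scans * tr:.0f} s); increase n_scans"
                )
            events_map[(subject, t)] = ev
            half = 0.5 * (
                2.0 * contrast_mean + 2.0 * c_sess[t]
                + 2.0 * group_session_intensity * g * t
            )
            amps = {
                "stim_other_pain": amp_mean + u_amp + half,
                "stim_other_nopain": amp_mean + u_amp - half,
                "stim_self_pain": amp_mean,
                "stim_self_nopain": amp_mean,
                "cue_other_pain": 0.5 * amp_mean,
                "cue_other_nopain": 0.5 * amp_mean,
                "cue_self_pain": 0.5 * amp_mean,
                "cue_self_nopain": 0.5 * amp_mean,
                "rating": 0.2 * amp_mean,
            }
            sig = generate_roi_timecourse(
                ev, amps, noise_sd=noise_sd, tr=tr, n_scans=n_scans, seed=rng
            )
            rows.append(pd.DataFrame({
                "subject_id": subject,
                "group": int(g),
                "session": t,
                "roi": "aMCC",
                "volume": np.arange(n_scans),
                "value": sig,
            }))
    return pd.concat(rows, ignore_index=True), events_map


def write_table(df: pd.DataFrame, path) -> None:
    """Write any of the package's tables as TSV with 6 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
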