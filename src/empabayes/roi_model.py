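"""Hierarchical Bayesian model for ROI-averaged fMRI time courses.

A simplified two-level model of region-of-interest signal: event boxcars
are convolved with a canonical double-gamma hemodynamic response function
(HRF) to form regressors; the amplitudes of the pain / no-pain
stimulation regressors in the Other condition carry a group-level
±1-coded Group x Session x Intensity fixed-effect structure plus
per-subject random effects, including session-specific subject effects of
the pain-minus-no-pain contrast whose cross-session correlation defines
the neural test-retest reliability. Nuisance structure (cue and
self-condition regressors, rating events, low-frequency drift) is
projected out of each run before the hierarchical fit, in the spirit of
standard high-pass filtering. Observation noise is white Gaussian with a
per-subject SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from empabayes import _gibbs
from empabayes.censored_model import FixedEffectSummary, PosteriorDraws, PriorSpec

ROI_FIXED_TERMS: tuple[str, ...] = (
    "intercept", "group", "session", "intensity",
    "group:session", "group:intensity", "session:intensity",
    "group:session:intensity",
)
ROI_RANDOM_TERMS: tuple[str, ...] = (
    "amplitude", "contrast_session1", "contrast_session2",
)


@dataclass(frozen=True)
class HRFConfig:
    """Canonical double-gamma HRF parameters (seconds).

    The response is the difference of two gamma densities: a positive
    lobe peaking around ``peak_delay`` and an undershoot around
    ``undershoot_delay`` scaled by ``undershoot_ratio``; the sampled
    kernel is rescaled to unit peak.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_disp: float = 1.0
    undershoot_disp: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    length: float = 32.0

    def __post_init__(self) -> None:
        for name in ("peak_delay", "undershoot_delay", "peak_disp",
                     "undershoot_disp", "length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.undershoot_ratio < 0:
            raise ValueError("undershoot_ratio must be nonnegative")
        if self.length < self.undershoot_delay:
            raise ValueError("kernel length must cover the undershoot")


def _gamma_density(t: np.ndarray, delay: float, disp: float) -> np.ndarray:
    # Gamma density with shape delay/disp and scale disp (mode at
    # delay - disp), evaluated without scipy for tight inner loops.
    shape = delay / disp
    from scipy.special import gammaln

    with np.errstate(divide="ignore", invalid="ignore"):
        logpdf = (
            (shape - 1.0) * np.log(t) - t / disp - shape * np.log(disp) - gammaln(shape)
        )
    out = np.exp(logpdf)
    out[~np.isfinite(out)] = 0.0
    out[t <= 0] = 0.0
    return out


def canonical_hrf(
    config: HRFConfig | None = None, tr: float = 1.2, dt: float | None = None
) -> np.ndarray:
    """Sample the canonical double-gamma HRF at spacing ``dt`` (default tr).

    Returns the kernel on the grid 0, dt, 2*dt, ... up to ``length``,
    scaled so that its maximum is exactly 1.
    """
    config = config or HRFConfig()
    step = tr if dt is None else dt
    if step <= 0:
        raise ValueError("sampling interval must be positive")
    t = np.arange(0.0, config.length + step / 2.0, step)
    h = _gamma_density(t, config.peak_delay, config.peak_disp)
    if config.undershoot_ratio > 0:
        h = h - config.undershoot_ratio * _gamma_density(
            t, config.undershoot_delay, config.undershoot_disp
        )
    peak = np.max(h)
    if peak <= 0:
        raise ValueError("degenerate HRF: nonpositive peak")
    return h / peak


def dct_drift_basis(n_scans: int, tr: float, cutoff: float = 128.0) -> np.ndarray:
    """Discrete-cosine high-pass drift basis (frequencies below 1/cutoff).

    Columns are cos(pi * k * (2i + 1) / (2 n)) for k = 1..K with
    K = floor(2 * n * tr / cutoff); a constant column is appended last.
    """
    total = n_scans * tr
    K = int(np.floor(2.0 * total / cutoff))
    i = np.arange(n_scans)
    cols = [np.cos(np.pi * k * (2 * i + 1) / (2.0 * n_scans)) for k in range(1, K + 1)]
    cols.append(np.ones(n_scans))
    return np.column_stack(cols)


def build_design_matrix(
    events: pd.DataFrame,
    tr: float,
    n_scans: int,
    hrf_config: HRFConfig | None = None,
    oversample: int = 16,
    drift: bool = True,
    drift_cutoff: float = 128.0,
    known_trial_types: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """HRF-convolved condition regressors (plus optional drift columns).

    Each distinct ``trial_type`` becomes one column: the event boxcars are
    laid out on an oversampled time grid (``tr / oversample`` resolution),
    convolved with the canonical HRF and sampled at scan onsets.

    Returns the (n_scans, n_columns) matrix and its column names; drift
    columns are named ``drift_1`` ... and ``constant``.
    """
    required = {"onset", "duration", "trial_type"}
    if not required <= set(events.columns):
        raise ValueError(f"events table needs columns {sorted(required)}")
    if (events["duration"] < 0).any():
        raise ValueError("durations must be nonnegative")
    end = events["onset"] + events["duration"]
    if (end > n_scans * tr).any():
        raise ValueError("events extend past the end of the scan")
    types = sorted(events["trial_type"].unique())
    if known_trial_types is not None:
        unknown = set(types) - set(known_trial_types)
        if unknown:
            raise ValueError(f"unknown trial_type values: {sorted(unknown)}")
    dt = tr / oversample
    grid_n = n_scans * oversample
    kernel = canonical_hrf(hrf_config, tr=tr, dt=dt)
    cols, names = [], []
    for ttype in types:
        box = np.zeros(grid_n)
        sel = events[events["trial_type"] == ttype]
        for onset, dur in zip(sel["onset"], sel["duration"]):
            a = int(np.round(onset / dt))
            b = max(int(np.round((onset + dur) / dt)), a + 1)
            box[a: min(b, grid_n)] = 1.0
        conv = np.convolve(box, kernel)[:grid_n]
        cols.append(conv[::oversample])
        names.append(ttype)
    if drift:
        basis = dct_drift_basis(n_scans, tr, drift_cutoff)
        for k in range(basis.shape[1] - 1):
            cols.append(basis[:, k])
            names.append(f"drift_{k + 1}")
        cols.append(basis[:, -1])
        names.append("constant")
    return np.column_stack(cols), names


def _residualize(y: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Project out the column space of N (nuisance/high-pass filtering)."""
    if N.shape[1] == 0:
        return y
    coef, *_ = np.linalg.lstsq(N, y, rcond=None)
    return y - N @ coef


def fit_roi_hierarchical(
    series: pd.DataFrame,
    events: pd.DataFrame | Mapping[tuple[str, int], pd.DataFrame],
    tr: float = 1.2,
    contrast_regressors: tuple[str, str] = ("stim_other_pain", "stim_other_nopain"),
    hrf_config: HRFConfig | None = None,
    priors: PriorSpec | None = None,
    n_chains: int = 4,
    n_warmup: int = 1000,
    n_draws: int = 1000,
    seed: int = 0,
    check_rhat: bool = True,
    rhat_tol: float = 1.01,
) -> PosteriorDraws:
    """Fit the hierarchical ROI model to per-run signal time courses.

    Parameters
    ----------
    series:
        Long table with columns ``subject_id``, ``group`` (±1),
        ``session`` (±1), ``volume`` and ``value`` — one row per scan per
        run, one ROI at a time. Every subject must have both sessions.
    events:
        Either one timing table shared by all runs or a mapping
        ``(subject_id, session) -> events``.
    contrast_regressors:
        The (pain, no-pain) trial types whose amplitudes carry the
        hierarchical structure; every other design column is treated as
        nuisance and projected out per run.

    Returns labelled draws whose fixed terms are the ±1-coded Group x
    Session x Intensity structure on the contrast amplitudes and whose
    random terms are the subject amplitude and the two session-specific
    contrast effects (used downstream for neural reliability).
    """
    priors = priors or PriorSpec(
        beta_scale=5.0, intercept_scale=5.0, re_sd_scale=5.0, sigma_scale=5.0
    )
    required = {"subject_id", "group", "session", "volume", "value"}
    if not required <= set(series.columns):
        raise ValueError(f"series table needs columns {sorted(required)}")
    if not np.all(np.isfinite(series["value"].to_numpy(dtype=float))):
        raise ValueError("series values must be finite")
    subjects = np.unique(series["subject_id"])
    pain_name, nopain_name = contrast_regressors

    rows_X, rows_Z, rows_y, rows_subj = [], [], [], []
    for si, subject in enumerate(subjects):
        sub = series[series["subject_id"] == subject]
        sessions = np.unique(sub["session"])
        if set(sessions) != {-1, 1}:
            raise ValueError(f"subject {subject} must have sessions -1 and 1")
        g = float(sub["group"].iloc[0])
        for t in (-1, 1):
            run = sub[sub["session"] == t].sort_values("volume")
            y = run["value"].to_numpy(dtype=float)
            ev = events[(subject, t)] if isinstance(events, Mapping) else events
            X_full, names = build_design_matrix(
                ev, tr=tr, n_scans=y.size, hrf_config=hrf_config
            )
            rank = np.linalg.matrix_rank(X_full)
            if rank < X_full.shape[1]:
                # Name the columns involved in the deficiency via QR pivots.
                _, R = np.linalg.qr(X_full)
                bad = [names[j] for j in np.where(np.abs(np.diag(R)) < 1e-8)[0]]
                raise ValueError(
                    f"design matrix rank deficient for {subject} session {t}; "
                    f"collinear columns: {bad or names}"
                )
            for nm in (pain_name, nopain_name):
                if nm not in names:
                    raise ValueError(f"contrast regressor {nm!r} not in design")
            pain = X_full[:, names.index(pain_name)]
            nopain = X_full[:, names.index(nopain_name)]
            nuis_idx = [
                j for j, nm in enumerate(names) if nm not in contrast_regressors
            ]
            N = X_full[:, nuis_idx]
            yf = _residualize(y, N)
            sumf = _residualize(pain + nopain, N)
            diff = _residualize(pain - nopain, N)
            # Columns in ROI_FIXED_TERMS order.
            X = np.column_stack([
                sumf,            # intercept (mean amplitude)
                g * sumf,        # group
                t * sumf,        # session
                diff,            # intensity
                g * t * sumf,    # group:session
                g * diff,        # group:intensity
                t * diff,        # session:intensity
                g * t * diff,    # group:session:intensity
            ])
            Z = np.column_stack([
                sumf,
                diff if t == -1 else np.zeros_like(diff),
                diff if t == 1 else np.zeros_like(diff),
            ])
            rows_X.append(X)
            rows_Z.append(Z)
            rows_y.append(yf)
            rows_subj.append(np.full(y.size, si))

    X = np.vstack(rows_X)
    Z = np.vstack(rows_Z)
    y = np.concatenate(rows_y)
    subj = np.concatenate(rows_subj).astype(int)

    gspec = _gibbs.GibbsSpec(
        X=X,
        Z=Z,
        subject=subj,
        y=y,
        censored=np.zeros(y.size, dtype=int),
        low=-np.inf,
        high=np.inf,
        beta_scale=np.array(
            [priors.intercept_scale if t == "intercept" else priors.beta_scale
             for t in ROI_FIXED_TERMS]
        ),
        re_sd_scale=priors.re_sd_scale,
        sigma_scale=priors.sigma_scale,
        lkj_eta=priors.re_corr_concentration,
    )
    raw = _gibbs.sample(
        gspec, n_chains=n_chains, n_warmup=n_warmup, n_draws=n_draws, seed=seed
    )
    import arviz as az

    rhat = {}
    if n_chains > 1:
        for k, term in enumerate(ROI_FIXED_TERMS):
            rhat[term] = float(
                az.rhat(az.convert_to_dataset(raw.beta[:, :, k][..., None]))["x"][0]
            )
    if check_rhat and n_chains > 1:
        worst = max(rhat, key=rhat.get)
        if rhat[worst] > rhat_tol:
            raise RuntimeError(
                f"split-R-hat {rhat[worst]:.3f} on {worst!r} exceeds {rhat_tol}"
            )
    return PosteriorDraws(
        fixed_terms=list(ROI_FIXED_TERMS),
        random_terms=list(ROI_RANDOM_TERMS),
        subjects=[str(s) for s in subjects],
        beta=raw.beta,
        b=raw.b,
        re_sd=raw.tau,
        re_corr=raw.corr,
        sigma=raw.sigma,
        priors=priors,
        diagnostics={"rhat": rhat, "acceptance": raw.accept, "divergences": 0},
    )


def roi_contrast(draws: PosteriorDraws, ci: float = 0.95) -> FixedEffectSummary:
    """Posterior summary of the Other Pain minus Other No Pain amplitude.

    With ±1 coding of the pain factor, the amplitude difference equals
    twice the ``intensity`` fixed effect; summarized per draw.
    """
    if "intensity" not in draws.fixed_terms:
        raise ValueError("draws lack an 'intensity' term")
    flat = 2.0 * draws.term_draws("intensity")
    lo, hi = (1.0 - ci) / 2.0, 1.0 - (1.0 - ci) / 2.0
    return FixedEffectSummary(
        term="other_pain-other_nopain",
        posterior_mean=float(np.mean(flat)),
        ci_low=float(np.quantile(flat, lo)),
        ci_high=float(np.quantile(flat, hi)),
    )
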