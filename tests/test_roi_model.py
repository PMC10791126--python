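"""HRF, design matrices, and the hierarchical ROI model."""

import numpy as np
import pandas as pd
import pytest

from empabayes import roi_model as rm
from empabayes import synthetic_data as sd


class TestCanonicalHRF:
    def test_peak_near_five_seconds(self):
        # Dense-grid oracle: with peak_delay 6 and dispersion 1 the
        # positive gamma lobe has its mode at 5 s; the undershoot shifts
        # it only marginally.
        tr = 1.2
        h = rm.canonical_hrf(tr=tr)
        dense = rm.canonical_hrf(tr=tr, dt=0.001)
        t_dense = np.argmax(dense) * 0.001
        assert abs(np.argmax(h) * tr - t_dense) <= tr
        assert t_dense == pytest.approx(5.0, abs=0.1)

    def test_unit_peak_normalization(self):
        h = rm.canonical_hrf(tr=0.5)
        assert np.max(h) == pytest.approx(1.0)

    def test_no_undershoot_means_nonnegative(self):
        cfg = rm.HRFConfig(undershoot_ratio=0.0)
        h = rm.canonical_hrf(cfg, tr=1.0)
        assert (h >= 0).all()

    def test_default_has_undershoot(self):
        h = rm.canonical_hrf(tr=1.0)
        assert h.min() < 0

    def test_matches_reference_spm_shape(self):
        nilearn = pytest.importorskip("nilearn.glm.first_level.hemodynamic_models")
        ours = rm.canonical_hrf(tr=1.0, dt=0.1)
        ref = nilearn.spm_hrf(1.0, oversampling=10, time_length=32.1)
        ref = ref / ref.max()
        n = min(ours.size, ref.size)
        assert np.corrcoef(ours[:n], ref[:n])[0, 1] > 0.999

    def test_config_validation(self):
        with pytest.raises(ValueError):
            rm.HRFConfig(peak_delay=-1.0)
        with pytest.raises(ValueError):
            rm.HRFConfig(length=5.0)


class TestDesignMatrix:
    def test_empty_events_leave_only_drift(self):
        ev = pd.DataFrame(columns=["onset", "duration", "trial_type"])
        X, names = rm.build_design_matrix(ev, tr=1.0, n_scans=100)
        assert all(n.startswith("drift") or n == "constant" for n in names)

    def test_impulse_event_reproduces_shifted_kernel(self):
        tr = 1.0
        ev = pd.DataFrame(
            [{"onset": 10.0, "duration": tr / 16, "trial_type": "stim"}]
        )
        X, names = rm.build_design_matrix(ev, tr=tr, n_scans=60, drift=False)
        col = X[:, names.index("stim")]
        kernel = rm.canonical_hrf(tr=tr, dt=tr / 16)[::16]
        assert np.allclose(col[:10], 0.0)
        lag = np.argmax(col) - 10
        assert abs(lag - np.argmax(kernel)) <= 1

    def test_matches_naive_convolution_oracle(self):
        # Direct O(n^2) summation over the oversampled boxcar.
        tr, n_scans, ov = 1.2, 120, 16
        ev = sd.generate_empathy_events(n_trials_per_condition=2, seed=1)
        ev = ev[ev["onset"] + ev["duration"] < n_scans * tr * 0.9]
        X, names = rm.build_design_matrix(
            ev, tr=tr, n_scans=n_scans, oversample=ov, drift=False
        )
        dt = tr / ov
        kernel = rm.canonical_hrf(tr=tr, dt=dt)
        for k, name in enumerate(names):
            box = np.zeros(n_scans * ov)
            for _, e in ev[ev["trial_type"] == name].iterrows():
                a = int(round(e["onset"] / dt))
                b = max(int(round((e["onset"] + e["duration"]) / dt)), a + 1)
                box[a:b] = 1.0
            naive = np.zeros(n_scans * ov)
            for i in range(n_scans * ov):
                j0 = max(0, i - kernel.size + 1)
                naive[i] = np.dot(box[j0: i + 1], kernel[: i - j0 + 1][::-1])
            np.testing.assert_allclose(X[:, k], naive[::ov], atol=1e-10)

    def test_convolution_linearity_over_event_subsets(self):
        tr, n_scans = 1.2, 150
        ev = sd.generate_empathy_events(n_trials_per_condition=3, seed=2)
        ev = ev[ev["onset"] + ev["duration"] < n_scans * tr * 0.9].reset_index(drop=True)
        ev_a, ev_b = ev.iloc[::2], ev.iloc[1::2]
        ev_a = ev_a.assign(trial_type="x")
        ev_b = ev_b.assign(trial_type="x")
        both = pd.concat([ev_a, ev_b]).sort_values("onset")
        Xa, _ = rm.build_design_matrix(ev_a, tr=tr, n_scans=n_scans, drift=False)
        Xb, _ = rm.build_design_matrix(ev_b, tr=tr, n_scans=n_scans, drift=False)
        Xab, _ = rm.build_design_matrix(both, tr=tr, n_scans=n_scans, drift=False)
        np.testing.assert_allclose(Xab[:, 0], Xa[:, 0] + Xb[:, 0], atol=1e-12)

    def test_nonnegative_columns_for_nonnegative_kernel(self):
        ev = pd.DataFrame([{"onset": 5.0, "duration": 2.0, "trial_type": "a"}])
        X, names = rm.build_design_matrix(
            ev, tr=1.0, n_scans=60,
            hrf_config=rm.HRFConfig(undershoot_ratio=0.0), drift=False,
        )
        assert (X >= 0).all()

    def test_unknown_trial_type_rejected(self):
        ev = pd.DataFrame([{"onset": 1.0, "duration": 1.0, "trial_type": "mystery"}])
        with pytest.raises(ValueError):
            rm.build_design_matrix(
                ev, tr=1.0, n_scans=50, known_trial_types=["stim_other_pain"]
            )

    def test_events_past_scan_end_rejected(self):
        ev = pd.DataFrame([{"onset": 100.0, "duration": 5.0, "trial_type": "a"}])
        with pytest.raises(ValueError):
            rm.build_design_matrix(ev, tr=1.0, n_scans=50)


@pytest.fixture(scope="module")
def roi_fit():
    series, events = sd.generate_roi_study(
        n_control=3, n_experimental=3, n_scans=380, n_trials_per_condition=6,
        contrast_session_corr=0.5, seed=5,
    )
    draws = rm.fit_roi_hierarchical(
        series, events, n_chains=2, n_warmup=300, n_draws=300, seed=9,
        check_rhat=False,
    )
    return draws


class TestHierarchicalFit:
    def test_contrast_amplitude_recovered(self, roi_fit):
        c = rm.roi_contrast(roi_fit)
        # generative pain-minus-no-pain difference is 2.0
        assert c.ci_low < 2.0 < c.ci_high
        assert c.posterior_mean == pytest.approx(2.0, abs=0.5)

    def test_near_noiseless_identifiability(self):
        series, events = sd.generate_roi_study(
            n_control=2, n_experimental=2, n_scans=300,
            n_trials_per_condition=4, noise_sd=0.01,
            re_sd_amp=0.0, re_sd_contrast=0.0, seed=6,
        )
        draws = rm.fit_roi_hierarchical(
            series, events, n_chains=1, n_warmup=250, n_draws=250, seed=10,
            check_rhat=False,
        )
        c = rm.roi_contrast(draws)
        assert c.posterior_mean == pytest.approx(2.0, abs=0.05)
        # residual noise is pinned near its true (tiny) value
        assert draws.sigma.mean() < 0.05
        # per-run reconstructed pain-minus-no-pain amplitudes concentrate
        # on the generative value for every subject and session
        idx = {t: draws.fixed_terms.index(t) for t in draws.fixed_terms}
        beta = draws.beta.reshape(-1, len(draws.fixed_terms))
        b1 = draws.random_effect_draws("contrast_session1")
        b2 = draws.random_effect_draws("contrast_session2")
        groups = np.repeat([-1.0, 1.0], 2)
        for si, g in enumerate(groups):
            for t, bc in ((-1.0, b1), (1.0, b2)):
                diff = 2.0 * (
                    beta[:, idx["intensity"]]
                    + g * beta[:, idx["group:intensity"]]
                    + t * beta[:, idx["session:intensity"]]
                    + g * t * beta[:, idx["group:session:intensity"]]
                    + bc[:, si]
                )
                assert np.mean(diff) == pytest.approx(2.0, abs=0.08)

    def test_reduces_to_ols_on_large_data(self):
        # With noise and random effects present, the group-level mean
        # amplitude should match per-run least squares averaged over
        # runs (the classical two-level summary-statistics estimate).
        series, events = sd.generate_roi_study(
            n_control=3, n_experimental=3, n_scans=380,
            n_trials_per_condition=6, seed=7,
        )
        draws = rm.fit_roi_hierarchical(
            series, events, n_chains=1, n_warmup=250, n_draws=250, seed=11,
            check_rhat=False,
        )
        diffs = []
        for (subject, sess), ev in events.items():
            run = series[
                (series["subject_id"] == subject) & (series["session"] == sess)
            ].sort_values("volume")
            X, names = rm.build_design_matrix(
                ev, tr=1.2, n_scans=len(run)
            )
            coef, *_ = np.linalg.lstsq(X, run["value"].to_numpy(), rcond=None)
            diffs.append(
                coef[names.index("stim_other_pain")]
                - coef[names.index("stim_other_nopain")]
            )
        ols = float(np.mean(diffs))
        bayes = rm.roi_contrast(draws).posterior_mean
        assert bayes == pytest.approx(ols, abs=0.35)

    def test_missing_session_rejected(self):
        series, events = sd.generate_roi_study(
            n_control=2, n_experimental=2, n_scans=300,
            n_trials_per_condition=4, seed=8,
        )
        broken = series[
            ~((series["subject_id"] == "s001") & (series["session"] == 1))
        ]
        with pytest.raises(ValueError):
            rm.fit_roi_hierarchical(broken, events, n_chains=1,
                                    n_warmup=10, n_draws=10)

    def test_session_random_effects_exposed_for_reliability(self, roi_fit):
        from empabayes import reliability as rel

        est = rel.neural_reliability(roi_fit)
        assert -1.0 <= est.rho_mean <= 1.0
        assert est.source == "neural"


class TestROIContrast:
    def test_identical_amplitudes_give_zero_width(self, roi_fit):
        clone = roi_fit
        zeroed = type(clone)(
            fixed_terms=clone.fixed_terms,
            random_terms=clone.random_terms,
            subjects=clone.subjects,
            beta=np.zeros_like(clone.beta),
            b=clone.b,
            re_sd=clone.re_sd,
            re_corr=clone.re_corr,
            sigma=clone.sigma,
            priors=clone.priors,
        )
        c = rm.roi_contrast(zeroed)
        assert c.posterior_mean == 0.0
        assert c.ci_high - c.ci_low == 0.0

    def test_linearity_under_scaling(self, roi_fit):
        scaled = type(roi_fit)(
            fixed_terms=roi_fit.fixed_terms,
            random_terms=roi_fit.random_terms,
            subjects=roi_fit.subjects,
            beta=3.0 * roi_fit.beta,
            b=roi_fit.b,
            re_sd=roi_fit.re_sd,
            re_corr=roi_fit.re_corr,
            sigma=roi_fit.sigma,
            priors=roi_fit.priors,
        )
        assert rm.roi_contrast(scaled).posterior_mean == pytest.approx(
            3.0 * rm.roi_contrast(roi_fit).posterior_mean
        )

    def test_missing_term_rejected(self, roi_fit):
        broken = type(roi_fit)(
            fixed_terms=["foo"],
            random_terms=roi_fit.random_terms,
            subjects=roi_fit.subjects,
            beta=roi_fit.beta[..., :1],
            b=roi_fit.b,
            re_sd=roi_fit.re_sd,
            re_corr=roi_fit.re_corr,
            sigma=roi_fit.sigma,
            priors=roi_fit.priors,
        )
        with pytest.raises(ValueError):
            rm.roi_contrast(broken)
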