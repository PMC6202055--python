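"""Filtering, nuisance regression, scrubbing and QA metrics."""

import numpy as np
import pytest

import pharmaconn as pc
from pharmaconn.preprocess import (
    apply_scrub,
    build_design,
    dct_basis,
    framewise_displacement,
    global_signal,
    highpass_array,
    highpass_filter,
    preprocess_run,
    qa_metrics,
    regress_nuisance,
    scrub,
)


def _run(bold, tr=2.5, motion=None, subject="s0", condition="Pla"):
    t = bold.shape[0]
    return pc.BoldRun(
        subject=subject,
        condition=condition,
        session=1,
        bold=bold,
        tr=tr,
        motion=np.zeros((t, 6)) if motion is None else motion,
        ventricle_ts=np.zeros(t) + 0.0,
        wm_ts=np.zeros(t) + 0.0,
    )


def _amplitude_ratio(freq_hz, t=240, tr=2.5, cutoff=0.008):
    """Output/input RMS ratio of the high-pass filter for a pure sinusoid."""
    time = np.arange(t) * tr
    x = np.sin(2 * np.pi * freq_hz * time)
    y = highpass_array(x, tr, cutoff)
    return np.sqrt((y**2).mean()) / np.sqrt((x**2).mean())


class TestHighpass:
    def test_constant_series_zeroed(self):
        out = highpass_array(np.full(100, 7.3), tr=2.5)
        assert np.abs(out).max() < 1e-10

    @pytest.mark.parametrize(
        "freq,low,high",
        [
            (0.05, 0.95, 1.001),   # deep passband
            (0.032, 0.90, 1.001),  # 4 x cutoff
            (0.002, 0.0, 0.05),    # cutoff / 4: stopband
        ],
    )
    def test_frequency_response(self, freq, low, high):
        ratio = _amplitude_ratio(freq)
        assert low < ratio < high

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            dct_basis(100, 2.5, 0.3)


class TestDesign:
    def test_column_counts(self, rng):
        t = 60
        bold = rng.normal(size=(t, 4))
        motion = rng.normal(size=(t, 6)) * 0.01
        run = pc.BoldRun(
            subject="a", condition="Pla", session=1, bold=bold, tr=2.5,
            motion=motion, ventricle_ts=rng.normal(size=t), wm_ts=rng.normal(size=t),
        )
        d, names = build_design(run, include_gs=False)
        assert d.shape[1] == 17 and len(names) == 17
        gs = rng.normal(size=t)
        d, names = build_design(run, include_gs=True, gs=gs)
        assert d.shape[1] == 19
        assert names[0] == "intercept" and "gs" in names and "d_gs" in names

    def test_constant_channel_and_derivative_dropped(self, rng):
        """A constant channel and its (zero) derivative are both removed."""
        t = 60
        run = pc.BoldRun(
            subject="a", condition="Pla", session=1,
            bold=rng.normal(size=(t, 3)), tr=2.5,
            motion=rng.normal(size=(t, 6)) * 0.01,
            ventricle_ts=np.full(t, 3.7),
            wm_ts=rng.normal(size=t),
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            d, names = build_design(run, include_gs=True, gs=rng.normal(size=t))
        assert d.shape[1] == 17
        assert "ventricle" not in names and "d_ventricle" not in names

    def test_gs_required_iff_flag(self, cohort_small):
        run = list(cohort_small[2].values())[0]
        with pytest.raises(ValueError):
            build_design(run, include_gs=True, gs=None)


class TestRegression:
    def test_beta_recovery(self, rng):
        t = 240
        gs = rng.normal(size=t)
        run = pc.BoldRun(
            subject="a", condition="Pla", session=1,
            bold=(2.0 * gs + rng.normal(size=t) * 0.1)[:, None],
            tr=2.5, motion=rng.normal(size=(t, 6)) * 0.01,
            ventricle_ts=rng.normal(size=t), wm_ts=rng.normal(size=t),
        )
        d, names = build_design(run, include_gs=True, gs=gs)
        fit = regress_nuisance(run, d, names)
        b_gs = fit.betas[names.index("gs"), 0]
        assert 1.9 <= b_gs <= 2.1

    def test_orthogonal_bold_untouched(self, rng):
        t, g = 200, 5
        design = np.column_stack([np.ones(t), rng.normal(size=(t, 3))])
        bold = rng.normal(size=(t, g))
        bold -= design @ np.linalg.lstsq(design, bold, rcond=None)[0]
        fit = regress_nuisance(bold, design)
        assert np.abs(fit.betas).max() < 1e-10
        assert np.abs(fit.residual - bold).max() < 1e-10

    def test_residual_orthogonality(self, cohort_small, space_small):
        run = list(cohort_small[2].values())[0]
        prep = preprocess_run(run, space_small, gsr=True)
        d = prep.fit.design
        r = prep.fit.residual[:, ::20]
        cors = np.corrcoef(np.c_[r, d[:, 1:]].T)[: r.shape[1], r.shape[1]:]
        assert np.abs(cors).max() < 1e-8

    def test_rank_deficient_design_rejected(self, rng):
        t = 50
        x = rng.normal(size=t)
        design = np.column_stack([np.ones(t), x, 2 * x])
        with pytest.raises(ValueError, match="rank"):
            regress_nuisance(rng.normal(size=(t, 2)), design)

    def test_gsr_idempotent_against_original_gs(self, cohort_small, space_small):
        """Re-regressing the GS regressor from GSR residuals gives b ~ 0."""
        run = list(cohort_small[2].values())[0]
        prep = preprocess_run(run, space_small, gsr=True)
        gs = prep.gs
        x = np.column_stack([np.ones(gs.size), gs])
        b = np.linalg.lstsq(x, prep.fit.residual, rcond=None)[0]
        assert np.abs(b[1]).max() < 1e-8


class TestScrub:
    def _smooth_bold(self, t, g=30):
        time = np.arange(t)[:, None]
        return 1000.0 + np.sin(time * 0.1) * np.ones((1, g))

    def test_clean_run_not_flagged(self):
        run = _run(self._smooth_bold(100))
        mask = scrub(run)
        assert not mask.flagged.any()
        assert not mask.subject_excluded

    def test_single_translation_jump_dilation(self):
        """A 0.6 mm step at frame 50 flags exactly {49, 50, 51, 52}."""
        t = 100
        motion = np.zeros((t, 6))
        motion[50:, 0] = 0.6  # step: displacement occurs at frame 50 only
        run = _run(self._smooth_bold(t), motion=motion)
        mask = scrub(run)
        assert set(np.flatnonzero(mask.flagged)) == {49, 50, 51, 52}

    def test_rotation_arc_length_conversion(self):
        fd = framewise_displacement(
            np.column_stack([np.zeros((3, 3)), np.array([[0, 0, 0], [0.02, 0, 0], [0.02, 0, 0]])])
        )
        assert fd[1] == pytest.approx(0.02 * 50)
        assert fd[2] == 0.0

    def test_dvars_flags_intensity_jump(self):
        t = 100
        bold = self._smooth_bold(t).copy()
        bold[60] += 50.0  # transient brain-wide intensity jump
        run = _run(bold + np.random.default_rng(0).normal(size=bold.shape) * 0.5)
        mask = scrub(run)
        flagged = set(np.flatnonzero(mask.flagged))
        assert {59, 60, 61, 62, 63} <= flagged  # jump in at 60, out at 61, dilated

    def test_majority_flags_exclude_subject(self):
        t = 100
        motion = np.zeros((t, 6))
        motion[1::2, 0] = 1.0  # alternating jumps: every frame transition > 0.5
        run = _run(self._smooth_bold(t), motion=motion)
        mask = scrub(run)
        assert mask.fraction_flagged > 0.5
        assert mask.subject_excluded

    def test_initial_position_does_not_flag(self):
        """A large but constant head offset produces no displacement flags."""
        t = 50
        motion = np.zeros((t, 6))
        motion[:, 0] = 5.0  # static offset: frame 0 has no defined displacement
        run = _run(self._smooth_bold(t), motion=motion)
        assert not scrub(run).flagged.any()

    def test_jump_at_frame1_dilates_into_frame0(self):
        t = 50
        motion = np.zeros((t, 6))
        motion[1:, 0] = 0.8
        run = _run(self._smooth_bold(t), motion=motion)
        flagged = set(np.flatnonzero(scrub(run).flagged))
        assert flagged == {0, 1, 2, 3}


class TestApplyScrub:
    def test_empty_mask_identity(self, rng):
        x = rng.normal(size=(50, 4))
        mask = pc.ScrubMask(flagged=np.zeros(50, bool), fd=np.zeros(50), dvars_norm=np.zeros(50))
        assert np.array_equal(apply_scrub(x, mask), x)

    def test_row_deletion_count(self, rng):
        x = rng.normal(size=(240, 4))
        flagged = np.zeros(240, bool)
        flagged[[3, 77, 100, 101]] = True
        mask = pc.ScrubMask(flagged=flagged, fd=np.zeros(240), dvars_norm=np.zeros(240))
        assert apply_scrub(x, mask).shape == (236, 4)

    def test_insufficient_frames_rejected(self, rng):
        x = rng.normal(size=(10, 2))
        flagged = np.ones(10, bool)
        flagged[:3] = False
        mask = pc.ScrubMask(flagged=flagged, fd=np.zeros(10), dvars_norm=np.zeros(10))
        with pytest.raises(ValueError, match="frames"):
            apply_scrub(x, mask)

    def test_censoring_clean_data_barely_changes_connectivity(self, rng):
        t, g = 240, 20
        latent = rng.normal(size=(t, 1))
        x = latent * rng.uniform(0.5, 1.0, g) + rng.normal(size=(t, g))
        flagged = np.zeros(t, bool)
        flagged[rng.choice(t, 10, replace=False)] = True
        mask = pc.ScrubMask(flagged=flagged, fd=np.zeros(t), dvars_norm=np.zeros(t))
        c_full = np.corrcoef(x.T)
        c_cens = np.corrcoef(apply_scrub(x, mask).T)
        iu = np.triu_indices(g, 1)
        assert np.abs(c_full[iu] - c_cens[iu]).mean() < 0.02


class TestQA:
    def test_snr_moments(self, rng):
        t = 2000
        bold = 100.0 + rng.normal(size=(t, 3)) * 10.0
        run = _run(bold)
        snr, pct = qa_metrics(run)
        assert np.abs(snr - 10).max() < 1.0
        assert pct == 0.0

    def test_zero_variance_grayordinate_masked(self):
        t = 50
        bold = np.column_stack([np.full(t, 5.0), np.random.default_rng(0).normal(size=t)])
        with pytest.warns(UserWarning, match="zero-variance"):
            snr, _ = qa_metrics(_run(bold))
        assert np.isnan(snr[0]) and np.isfinite(snr[1])

    def test_qa_uncoupled_from_connectivity(self, rng):
        """QA metrics and mean Fz are uncorrelated on uncoupled data."""
        n_sig = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            qa = r.normal(size=24)
            fz = r.normal(size=24)
            _, p = pc.preprocess.qa_fz_correlation(qa, fz)
            n_sig += p < 0.05
        assert n_sig <= 1


def test_global_signal_excludes_proxies(space_small, cohort_small):
    run = list(cohort_small[2].values())[0]
    gs = global_signal(run.bold, space_small)
    manual = run.bold[:, space_small.gray_mask].mean(axis=1)
    assert np.array_equal(gs, manual)
    assert space_small.gray_mask.sum() < space_small.n_gray
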