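"""Denoising after minimal preprocessing.

Fixed stage order (each stage is also usable standalone):

1. high-pass filtering (> 0.008 Hz) by projecting out a discrete-cosine
   basis — exactly linear, composable with the nuisance GLM, no edge
   transients;
2. scrub-mask computation on the *raw* (unfiltered, un-regressed)
   intensities and motion traces;
3. nuisance regression (ventricle, white matter, 6 motion parameters,
   optionally the global signal, each with its first temporal
   derivative, plus an intercept), fit on all frames;
4. frame censoring by row deletion of flagged frames.

An alternative ordering (censor before regression) is exposed via the
``censor_before_regression`` flag on :func:`preprocess_run`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import BoldRun, GrayordinateSpace

#: framewise-displacement threshold in mm
FD_THRESHOLD_MM = 0.5
#: rotation-to-arc-length conversion radius in mm
HEAD_RADIUS_MM = 50.0
#: DVARS threshold as a multiple of the run median
DVARS_MEDIAN_FACTOR = 1.6
#: frames censored around each flagged frame (before, after)
DILATE_BEFORE, DILATE_AFTER = 1, 2
#: a subject is dropped when more than this fraction of frames is flagged
EXCLUSION_FRACTION = 0.5


@dataclass
class ScrubMask:
    flagged: np.ndarray  # length-T boolean
    fd: np.ndarray  # length-T framewise displacement, mm (fd[0] = 0, undefined)
    dvars_norm: np.ndarray  # length-T normalized RMS frame difference

    @property
    def fraction_flagged(self) -> float:
        return float(self.flagged.mean())

    @property
    def subject_excluded(self) -> bool:
        return self.fraction_flagged > EXCLUSION_FRACTION


@dataclass
class NuisanceFit:
    names: list
    design: np.ndarray  # T x R
    betas: np.ndarray  # R x G
    residual: np.ndarray  # T x G


def dct_basis(t: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """DCT-II regressors with frequencies in (0, cutoff_hz]."""
    nyquist = 0.5 / tr
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist} Hz")
    n = np.arange(t)
    cols = []
    k = 1
    while k / (2.0 * t * tr) <= cutoff_hz:
        cols.append(np.cos(np.pi * k * (n + 0.5) / t))
        k += 1
    if not cols:
        return np.empty((t, 0))
    return np.column_stack(cols)


def highpass_filter(run: BoldRun, cutoff_hz: float = 0.008) -> BoldRun:
    """Remove the mean and fluctuations slower than ``cutoff_hz``."""
    if run.n_frames < 8:
        raise ValueError("need at least 8 frames to filter")
    filt = highpass_array(run.bold, run.tr, cutoff_hz)
    return run.with_bold(filt)


def highpass_array(x: np.ndarray, tr: float, cutoff_hz: float = 0.008) -> np.ndarray:
    """High-pass a T x K array by regressing out [intercept, slow DCT basis]."""
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    t = x.shape[0]
    basis = np.column_stack([np.ones(t), dct_basis(t, tr, cutoff_hz)])
    beta, *_ = np.linalg.lstsq(basis, x, rcond=None)
    out = x - basis @ beta
    return out[:, 0] if squeeze else out


# -------------------------------------------------------------- scrub

def framewise_displacement(motion: np.ndarray) -> np.ndarray:
    """Sum over the 6 rigid-body parameters of |frame-to-frame change|.

    Rotations (radians) are converted to arc length on a
    ``HEAD_RADIUS_MM`` sphere.  Element 0 is 0 (undefined).
    """
    motion = np.asarray(motion, dtype=float)
    d = np.abs(np.diff(motion, axis=0))
    d[:, 3:] *= HEAD_RADIUS_MM
    fd = np.zeros(motion.shape[0])
    fd[1:] = d.sum(axis=1)
    return fd


def dvars(bold: np.ndarray) -> np.ndarray:
    """Normalized RMS frame-to-frame intensity change (element 0 is 0)."""
    bold = np.asarray(bold, dtype=float)
    diff = np.diff(bold, axis=0)
    rms = np.sqrt((diff**2).mean(axis=1))
    mean_intensity = bold.mean()
    out = np.zeros(bold.shape[0])
    out[1:] = rms / mean_intensity if mean_intensity != 0 else rms
    return out


def scrub(run: BoldRun) -> ScrubMask:
    """Flag frames with excess motion or intensity change, then dilate.

    Criterion 1: framewise displacement > 0.5 mm.  Criterion 2:
    normalized DVARS > 1.6x its within-run median.  Flags are the union,
    dilated by one frame back and two frames forward.  Frame 0 has no
    defined displacement and can only be flagged by dilation.
    """
    if run.n_frames < 4:
        raise ValueError("need at least 4 frames to scrub")
    fd = framewise_displacement(run.motion)
    dv = dvars(run.bold)
    c1 = fd > FD_THRESHOLD_MM
    med = np.median(dv[1:])
    c2 = dv > DVARS_MEDIAN_FACTOR * med
    c1[0] = c2[0] = False
    core = c1 | c2
    flagged = core.copy()
    t = run.n_frames
    for f in np.flatnonzero(core):
        lo = max(0, f - DILATE_BEFORE)
        hi = min(t, f + DILATE_AFTER + 1)
        flagged[lo:hi] = True
    return ScrubMask(flagged=flagged, fd=fd, dvars_norm=dv)


def apply_scrub(data: np.ndarray, mask: ScrubMask) -> np.ndarray:
    """Delete flagged frames (rows).  Errors if fewer than 8 frames remain."""
    data = np.asarray(data)
    if mask.flagged.size != data.shape[0]:
        raise ValueError("scrub mask length does not match frame count")
    kept = data[~mask.flagged]
    if kept.shape[0] < 8:
        raise ValueError(
            f"only {kept.shape[0]} frames remain after censoring (need >= 8)"
        )
    return kept


# ------------------------------------------------------------- design

def global_signal(bold: np.ndarray, space: GrayordinateSpace) -> np.ndarray:
    """Mean BOLD over gray matter, explicitly excluding ventricle/WM proxies."""
    return np.asarray(bold, dtype=float)[:, space.gray_mask].mean(axis=1)


def _derivative(x: np.ndarray) -> np.ndarray:
    d = np.zeros_like(x)
    d[1:] = np.diff(x, axis=0)
    return d


def build_design(run: BoldRun, include_gs: bool = False, gs: np.ndarray | None = None):
    """Nuisance design matrix and column names.

    Columns: intercept, ventricle, WM, 6 motion parameters, (GS), then
    the first temporal difference of each non-intercept column in the
    same order (first element 0).  Zero-variance regressors other than
    the intercept are dropped with a warning.
    """
    if include_gs and gs is None:
        raise ValueError("gs vector required when include_gs=True")
    if not include_gs and gs is not None:
        raise ValueError("gs supplied but include_gs=False")
    t = run.n_frames
    base = [("ventricle", run.ventricle_ts), ("wm", run.wm_ts)]
    base += [(f"motion{i + 1}", run.motion[:, i]) for i in range(6)]
    if include_gs:
        base.append(("gs", np.asarray(gs, dtype=float)))
    names = ["intercept"]
    cols = [np.ones(t)]
    for name, col in base:
        names.append(name)
        cols.append(col)
    for name, col in base:
        names.append(f"d_{name}")
        cols.append(_derivative(col))
    design = np.column_stack(cols)
    keep = [0]
    dropped = []
    for j in range(1, design.shape[1]):
        col = design[:, j]
        if col.std() <= 1e-12 * (1.0 + np.abs(col).max()):
            dropped.append(names[j])
        else:
            keep.append(j)
    if dropped:
        warnings.warn(f"dropping zero-variance regressors: {dropped}")
        design = design[:, keep]
        names = [names[j] for j in keep]
    return design, names


def regress_nuisance(run_or_bold, design: np.ndarray, names=None) -> NuisanceFit:
    """Per-grayordinate OLS of BOLD on the design; returns betas and residuals."""
    bold = run_or_bold.bold if isinstance(run_or_bold, BoldRun) else np.asarray(run_or_bold)
    design = np.asarray(design, dtype=float)
    t, r = design.shape
    if t <= r:
        raise ValueError(f"T={t} must exceed R={r} regressors")
    rank = np.linalg.matrix_rank(design)
    if rank < r:
        corr = np.corrcoef(design[:, 1:], rowvar=False)
        np.fill_diagonal(corr, 0.0)
        pairs = np.argwhere(np.abs(corr) > 1 - 1e-10)
        raise ValueError(
            f"design is rank deficient (rank {rank} < {r}); "
            f"collinear column pairs (0-based, excl. intercept): {pairs[: 5].tolist()}"
        )
    betas, *_ = np.linalg.lstsq(design, bold, rcond=None)
    residual = bold - design @ betas
    if names is None:
        names = [f"x{j}" for j in range(r)]
    return NuisanceFit(names=list(names), design=design, betas=betas, residual=residual)


# ----------------------------------------------------------------- QA

def qa_metrics(run: BoldRun, mask: ScrubMask | None = None):
    """Per-grayordinate temporal SNR map and percent of frames scrubbed.

    SNR is the mean of the raw time series divided by its standard
    deviation; zero-variance grayordinates are returned as NaN with a
    warning.
    """
    mean = run.bold.mean(axis=0)
    sd = run.bold.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = mean / sd
    if (sd == 0).any():
        warnings.warn(f"run {run.run_id}: zero-variance grayordinates in SNR map")
        snr[sd == 0] = np.nan
    pct = 100.0 * mask.fraction_flagged if mask is not None else 0.0
    return snr, pct


def qa_fz_correlation(qa_values: np.ndarray, mean_fz: np.ndarray):
    """Pearson correlation of a QA metric with mean Fz across subjects."""
    from scipy import stats

    return stats.pearsonr(np.asarray(qa_values, float), np.asarray(mean_fz, float))


# ------------------------------------------------------- full stage

@dataclass
class PreprocessedRun:
    run: BoldRun
    fit: NuisanceFit
    mask: ScrubMask
    censored: np.ndarray  # T' x G residual with flagged frames removed
    gs: np.ndarray | None  # the regressed global signal (None without GSR)


def preprocess_run(
    run: BoldRun,
    space: GrayordinateSpace,
    gsr: bool,
    cutoff_hz: float = 0.008,
    gs_after_filter: bool = True,
    censor_before_regression: bool = False,
) -> PreprocessedRun:
    """Filter, regress nuisance (with or without GSR), scrub, censor."""
    mask = scrub(run)  # on raw intensities, per the cited censoring practice
    filtered = highpass_filter(run, cutoff_hz)
    gs = None
    if gsr:
        gs_src = filtered.bold if gs_after_filter else run.bold
        gs = global_signal(gs_src, space)
    filt_channels = BoldRun(
        subject=run.subject,
        condition=run.condition,
        session=run.session,
        bold=filtered.bold,
        tr=run.tr,
        motion=run.motion,
        ventricle_ts=highpass_array(run.ventricle_ts, run.tr, cutoff_hz),
        wm_ts=highpass_array(run.wm_ts, run.tr, cutoff_hz),
    )
    design, names = build_design(filt_channels, include_gs=gsr, gs=gs)
    if censor_before_regression:
        keep = ~mask.flagged
        fit_full = regress_nuisance(filtered.bold[keep], design[keep], names)
        censored = fit_full.residual
        fit = fit_full
    else:
        fit = regress_nuisance(filt_channels, design, names)
        censored = apply_scrub(fit.residual, mask)
    return PreprocessedRun(run=run, fit=fit, mask=mask, censored=censored, gs=gs)
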