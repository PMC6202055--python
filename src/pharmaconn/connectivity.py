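"""Per-run connectivity and signal-property maps.

Global brain connectivity (GBC) summarizes each grayordinate's coupling
with the rest of the brain as the mean of its Fisher-transformed
correlations (or, alternatively, its covariances) with every *other*
grayordinate.  The computation is blocked so the full G x G association
matrix never has to be materialized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import ScalarMap

DEFAULT_CLIP_R = 1.0 - 1e-7


@dataclass
class ConnectivityOptions:
    method: str = "correlation"  # or "covariance"
    fisher: bool = True  # correlation only
    clip_r: float = DEFAULT_CLIP_R
    exclude_self: bool = True
    block_size: int = 512

    def __post_init__(self) -> None:
        if self.method not in ("correlation", "covariance"):
            raise ValueError("method must be 'correlation' or 'covariance'")
        if not 0.0 < self.clip_r < 1.0:
            raise ValueError("clip_r must be in (0, 1)")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")


def fisher_z(r, clip_r: float = DEFAULT_CLIP_R):
    """Variance-stabilizing atanh transform, clipped to keep Fz finite."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise ValueError("|r| > 1")
    out = np.arctanh(np.clip(r, -clip_r, clip_r))
    return float(out) if out.ndim == 0 else out


def _standardized(bold: np.ndarray):
    """Column-centered data, per-column sd, and the zero-variance mask."""
    x = np.asarray(bold, dtype=float)
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0, ddof=1)
    degenerate = sd == 0
    return xc, sd, degenerate


def gbc_map(bold: np.ndarray, options: ConnectivityOptions | None = None) -> ScalarMap:
    """Mean association of each grayordinate with every other grayordinate.

    ``bold`` is the censored T' x G residual time series.  Correlations
    are clipped and Fisher-transformed before averaging; the covariance
    variant uses the unbiased (T'-1) normalization and no transform.
    Zero-variance grayordinates are masked (NaN) with a warning and are
    excluded from every other grayordinate's mean.
    """
    opts = options or ConnectivityOptions()
    x = np.asarray(bold, dtype=float)
    t, g = x.shape
    if t < 8:
        raise ValueError("need at least 8 frames")
    if g < 2:
        raise ValueError("need at least 2 grayordinates")
    xc, sd, degenerate = _standardized(x)
    if degenerate.any() and opts.method == "correlation":
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance grayordinates masked in GBC"
        )
    if opts.method == "correlation":
        z = np.zeros_like(xc)
        valid = ~degenerate
        z[:, valid] = xc[:, valid] / (sd[valid] * np.sqrt(t - 1))
        # now z.T @ z gives correlations for valid columns
        n_valid = int(valid.sum())
        out = np.empty(g)
        out[degenerate] = np.nan
        for start in range(0, g, opts.block_size):
            stop = min(start + opts.block_size, g)
            block = z[:, start:stop].T @ z  # B x G correlations
            fz = np.arctanh(np.clip(block, -opts.clip_r, opts.clip_r))
            fz[:, degenerate] = 0.0
            sums = fz.sum(axis=1)
            denom = np.full(stop - start, n_valid, dtype=float)
            idx = np.arange(start, stop)
            if opts.exclude_self:
                self_vals = np.take_along_axis(fz, idx[:, None], axis=1)[:, 0]
                sums -= self_vals
                denom -= 1
            bad = degenerate[start:stop]
            with np.errstate(invalid="ignore", divide="ignore"):
                out[start:stop] = np.where(bad, np.nan, sums / denom)
        kind = "gbc_r_fz"
    else:
        out = np.empty(g)
        for start in range(0, g, opts.block_size):
            stop = min(start + opts.block_size, g)
            block = xc[:, start:stop].T @ xc / (t - 1)  # B x G covariances
            sums = block.sum(axis=1)
            denom = float(g)
            if opts.exclude_self:
                idx = np.arange(start, stop)
                sums -= np.take_along_axis(block, idx[:, None], axis=1)[:, 0]
                denom -= 1
            out[start:stop] = sums / denom
        kind = "gbc_cov"
    return ScalarMap(values=out, kind=kind)


def seed_fc_map(
    bold: np.ndarray, seed_mask: np.ndarray, options: ConnectivityOptions | None = None
) -> ScalarMap:
    """Association of the mean seed time series with every grayordinate."""
    opts = options or ConnectivityOptions()
    x = np.asarray(bold, dtype=float)
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if not seed_mask.any():
        raise ValueError("empty seed mask")
    seed_ts = x[:, seed_mask].mean(axis=1)
    t = x.shape[0]
    sc = seed_ts - seed_ts.mean()
    xc, sd, degenerate = _standardized(x)
    cov = xc.T @ sc / (t - 1)
    if opts.method == "covariance":
        return ScalarMap(values=cov, kind="seed_cov")
    seed_sd = sc.std(ddof=1)
    if seed_sd == 0:
        raise ValueError("seed time series has zero variance")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / (sd * seed_sd)
    r[degenerate] = np.nan
    if degenerate.any():
        warnings.warn("zero-variance grayordinates masked in seed FC map")
    vals = np.where(
        np.isnan(r), np.nan, np.arctanh(np.clip(r, -opts.clip_r, opts.clip_r))
    ) if opts.fisher else r
    return ScalarMap(values=vals, kind="seed_r_fz")


def gs_beta_map(bold: np.ndarray, gray_mask: np.ndarray) -> ScalarMap:
    """Per-grayordinate regression weight of BOLD on the global signal.

    The GS here is the spatial mean over gray-matter grayordinates of
    the supplied (typically nuisance-regressed, non-GSR) time series;
    each grayordinate is regressed on [intercept, GS] and the GS beta is
    returned.  These betas measure how much each grayordinate
    contributes to / co-varies with the global signal — they are not
    functional-connectivity values.
    """
    x = np.asarray(bold, dtype=float)
    gray_mask = np.asarray(gray_mask, dtype=bool)
    gs = x[:, gray_mask].mean(axis=1)
    gsc = gs - gs.mean()
    var = gsc @ gsc
    if var == 0:
        raise ValueError("global signal has zero variance")
    beta = (x.T @ gsc) / var
    return ScalarMap(values=beta, kind="gs_beta")


def variance_summaries(bold: np.ndarray, gray_mask: np.ndarray):
    """(per-grayordinate temporal variance map, variance of the mean GS)."""
    x = np.asarray(bold, dtype=float)
    local = ScalarMap(values=x.var(axis=0, ddof=1), kind="local_var")
    gs = x[:, np.asarray(gray_mask, dtype=bool)].mean(axis=1)
    return local, float(gs.var(ddof=1))
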