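"""Second-level inference: TFCE permutation tests and summary analyses.

Group contrasts are tested nonparametrically: the observed statistic map
is enhanced with threshold-free cluster enhancement (TFCE) and compared
against the null distribution of the *maximum* |TFCE| over permutations
(sign flips of within-subject difference maps for paired contrasts,
within-subject condition relabelings for the repeated-measures main
effect), which controls the family-wise error rate over grayordinates.

TFCE definition used throughout (and by the brute-force oracle in the
test suite): with step ``dh = max(|stat|)/n_steps`` the enhanced value
at grayordinate ``k`` is ``sum over thresholds h = dh, 2dh, ... <= max``
of ``e_k(h)**E * h**H * dh`` where ``e_k(h)`` is the size of the
connected component containing ``k`` among grayordinates with value
``>= h``.  Negative values are enhanced on the negated map and
re-negated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import stats

from .model import NETWORKS, ScalarMap

TFCE_H = 2.0
TFCE_E = 0.5
TFCE_STEPS = 100


# ----------------------------------------------------------- kernels

@njit(cache=True)
def _find(parent, i):
    root = i
    while parent[root] != root:
        root = parent[root]
    while parent[i] != root:
        nxt = parent[i]
        parent[i] = root
        i = nxt
    return root


@njit(cache=True)
def _tfce_pos(values, e0, e1, h_exp, e_exp, dh):
    """TFCE of a non-negative map over the edge list (e0[i], e1[i])."""
    g = values.size
    out = np.zeros(g)
    vmax = values.max()
    if vmax <= 0.0 or dh <= 0.0:
        return out
    parent = np.empty(g, np.int64)
    size = np.zeros(g, np.int64)
    n_steps = int(np.floor(vmax / dh + 1e-12))
    for s in range(1, n_steps + 1):
        h = dh * s
        for i in range(g):
            parent[i] = i if values[i] >= h else -1
        for e in range(e0.size):
            a = e0[e]
            b = e1[e]
            if parent[a] != -1 and parent[b] != -1:
                ra = _find(parent, a)
                rb = _find(parent, b)
                if ra != rb:
                    parent[rb] = ra
        for i in range(g):
            size[i] = 0
        for i in range(g):
            if parent[i] != -1:
                size[_find(parent, i)] += 1
        inc = h**h_exp * dh
        for i in range(g):
            if parent[i] != -1:
                out[i] += size[_find(parent, i)] ** e_exp * inc
    return out


@njit(cache=True)
def _max_abs_tfce_batch(maps, e0, e1, h_exp, e_exp, n_steps):
    """Max |TFCE| per row of ``maps`` with per-map adaptive dh."""
    out = np.empty(maps.shape[0])
    for p in range(maps.shape[0]):
        v = maps[p]
        pos = np.maximum(v, 0.0)
        neg = np.maximum(-v, 0.0)
        vmax = max(pos.max(), neg.max())
        dh = vmax / n_steps
        m = 0.0
        if dh > 0.0:
            tp = _tfce_pos(pos, e0, e1, h_exp, e_exp, dh)
            tn = _tfce_pos(neg, e0, e1, h_exp, e_exp, dh)
            for i in range(v.size):
                if tp[i] > m:
                    m = tp[i]
                if tn[i] > m:
                    m = tn[i]
        out[p] = m
    return out


def tfce(
    stat_map: np.ndarray,
    edges: np.ndarray,
    H: float = TFCE_H,
    E: float = TFCE_E,
    dh: float | None = None,
    n_steps: int = TFCE_STEPS,
) -> np.ndarray:
    """Signed two-branch TFCE over an adjacency edge list."""
    v = np.asarray(stat_map, dtype=np.float64)
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    if edges.size and edges.max() >= v.size:
        raise ValueError("adjacency references grayordinates outside the map")
    vmax = np.abs(v).max() if v.size else 0.0
    if dh is None:
        if vmax == 0.0:
            return np.zeros_like(v)
        dh = vmax / n_steps
    if dh <= 0:
        raise ValueError("dh must be positive")
    e0 = np.ascontiguousarray(edges[:, 0])
    e1 = np.ascontiguousarray(edges[:, 1])
    pos = _tfce_pos(np.maximum(v, 0.0), e0, e1, float(H), float(E), float(dh))
    neg = _tfce_pos(np.maximum(-v, 0.0), e0, e1, float(H), float(E), float(dh))
    return pos - neg


# ------------------------------------------------------- statistics

def _t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Map t statistics to standard-normal quantiles, sign preserved."""
    t = np.asarray(t, dtype=float)
    p = stats.t.sf(np.abs(t), df)
    z = stats.norm.isf(np.clip(p, 1e-300, 1.0))
    return np.clip(np.sign(t) * z, -40.0, 40.0)


def _paired_t(d: np.ndarray):
    """One-sample t on each column of the n x G difference matrix."""
    n = d.shape[0]
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = m / (sd / np.sqrt(n))
    return np.where(sd == 0, 0.0, t)


@dataclass
class ContrastResult:
    z_map: ScalarMap
    tfce_map: ScalarMap
    fwe_p: ScalarMap
    sig_mask_pos: np.ndarray
    sig_mask_neg: np.ndarray
    n_perm: int
    seed: int

    @property
    def n_significant(self) -> int:
        return int(self.sig_mask_pos.sum() + self.sig_mask_neg.sum())


def _fwe_from_null(tfce_obs: np.ndarray, null_max: np.ndarray) -> np.ndarray:
    """FWE p per grayordinate from the max-statistic null distribution."""
    n_perm = null_max.size
    srt = np.sort(null_max)
    below = np.searchsorted(srt, np.abs(tfce_obs), side="left")
    return (1.0 + n_perm - below) / (n_perm + 1.0)


def paired_contrast(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    edges: np.ndarray,
    n_perm: int = 1000,
    H: float = TFCE_H,
    E: float = TFCE_E,
    n_steps: int = TFCE_STEPS,
    alpha: float = 0.05,
    seed: int = 0,
) -> ContrastResult:
    """Within-subject A-vs-B contrast with sign-flip max-TFCE inference.

    ``maps_a`` and ``maps_b`` are n_subjects x G, paired by row.  The
    statistic is the one-sample t on the difference maps converted to z;
    the null is built by random sign flips of whole difference maps and
    summarized by the maximum |TFCE|, giving two-sided FWE-corrected
    p-values.  Deterministic for a fixed ``seed``.
    """
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired map stacks must have identical shape")
    n = a.shape[0]
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    d = a - b
    t = _paired_t(d)
    z = _t_to_z(t, n - 1)
    tfce_obs = tfce(z, edges, H=H, E=E, n_steps=n_steps)

    rng = np.random.default_rng(seed)
    signs = rng.choice(np.array([-1.0, 1.0]), size=(n_perm, n))
    m = signs @ d / n
    sumsq = (d**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd2 = (sumsq - n * m**2) / (n - 1)
        t_null = m / np.sqrt(sd2 / n)
    t_null[~np.isfinite(t_null)] = 0.0
    z_null = _t_to_z(t_null, n - 1)
    e0 = np.ascontiguousarray(np.asarray(edges, np.int64).reshape(-1, 2)[:, 0])
    e1 = np.ascontiguousarray(np.asarray(edges, np.int64).reshape(-1, 2)[:, 1])
    null_max = _max_abs_tfce_batch(
        np.ascontiguousarray(z_null), e0, e1, float(H), float(E), n_steps
    )
    fwe = _fwe_from_null(tfce_obs, null_max)
    sig = fwe < alpha
    return ContrastResult(
        z_map=ScalarMap(values=z, kind="z"),
        tfce_map=ScalarMap(values=tfce_obs, kind="z"),
        fwe_p=ScalarMap(values=fwe, kind="z"),
        sig_mask_pos=sig & (z > 0),
        sig_mask_neg=sig & (z < 0),
        n_perm=n_perm,
        seed=seed,
    )


def _rm_f(maps: np.ndarray):
    """Repeated-measures F over conditions for n x C x G map stacks."""
    n, c, _ = maps.shape
    grand = maps.mean(axis=(0, 1))
    subj_m = maps.mean(axis=1)
    cond_m = maps.mean(axis=0)
    ss_cond = n * ((cond_m - grand) ** 2).sum(axis=0)
    resid = maps - subj_m[:, None, :] - cond_m[None, :, :] + grand
    ss_err = (resid**2).sum(axis=(0, 1))
    df1 = c - 1
    df2 = (n - 1) * (c - 1)
    # degenerate columns (identical condition sets): both sums vanish up to
    # rounding; report F = 0 rather than a 0/0 artifact
    ss_total = ((maps - grand) ** 2).sum(axis=(0, 1))
    tol = 1e-12 * np.maximum(ss_total, 1e-300)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (ss_cond / df1) / (ss_err / df2)
    f = np.where(ss_cond <= tol, 0.0, f)
    f = np.where((ss_err <= tol) & (ss_cond > tol), np.inf, f)
    return np.nan_to_num(f, nan=0.0, posinf=1e12), df1, df2


def main_effect_contrast(
    maps: np.ndarray,
    edges: np.ndarray,
    n_perm: int = 1000,
    H: float = TFCE_H,
    E: float = TFCE_E,
    n_steps: int = TFCE_STEPS,
    alpha: float = 0.05,
    seed: int = 0,
    perm_chunk: int = 100,
) -> ContrastResult:
    """Condition main effect (repeated-measures F) with permutation FWE.

    ``maps`` is n_subjects x n_conditions x G (complete crossing; NaN
    anywhere raises, naming the subject).  The null permutes condition
    labels within subject; the F map is TFCE-enhanced one-sidedly.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 3:
        raise ValueError("maps must be n_subjects x n_conditions x G")
    n, c, g = maps.shape
    bad = ~np.isfinite(maps)
    if bad.any():
        subj = int(np.argwhere(bad)[0][0])
        raise ValueError(f"missing/non-finite cell for subject index {subj}")
    f_obs, df1, df2 = _rm_f(maps)
    z = np.clip(stats.norm.isf(np.clip(stats.f.sf(f_obs, df1, df2), 1e-300, 1.0)), 0, 40)
    tfce_obs = tfce(f_obs, edges, H=H, E=E, n_steps=n_steps)

    rng = np.random.default_rng(seed)
    edges = np.asarray(edges, np.int64).reshape(-1, 2)
    e0 = np.ascontiguousarray(edges[:, 0])
    e1 = np.ascontiguousarray(edges[:, 1])
    null_max = np.empty(n_perm)
    done = 0
    subj_idx = np.arange(n)[:, None]
    while done < n_perm:
        k = min(perm_chunk, n_perm - done)
        f_null = np.empty((k, g))
        for p in range(k):
            perm = rng.permuted(np.tile(np.arange(c), (n, 1)), axis=1)
            f_null[p], _, _ = _rm_f(maps[subj_idx, perm, :])
        null_max[done : done + k] = _max_abs_tfce_batch(
            f_null, e0, e1, float(H), float(E), n_steps
        )
        done += k
    fwe = _fwe_from_null(tfce_obs, null_max)
    sig = fwe < alpha
    return ContrastResult(
        z_map=ScalarMap(values=z, kind="z"),
        tfce_map=ScalarMap(values=tfce_obs, kind="z"),
        fwe_p=ScalarMap(values=fwe, kind="z"),
        sig_mask_pos=sig,
        sig_mask_neg=np.zeros(g, dtype=bool),
        n_perm=n_perm,
        seed=seed,
    )


def lsd_vs_rest(maps_by_condition: dict) -> tuple:
    """Drug-vs-(blocked + placebo) paired stacks.

    Returns ``(A, B)`` where A is the drug-condition map stack and B the
    within-subject mean of the two control conditions, ready for
    :func:`paired_contrast`.
    """
    a = np.asarray(maps_by_condition["LSD"], dtype=float)
    b = 0.5 * (
        np.asarray(maps_by_condition["Pla"], dtype=float)
        + np.asarray(maps_by_condition["KetLSD"], dtype=float)
    )
    return a, b


# ------------------------------------------------------- summaries

def mask_means(maps: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-subject mean map value inside a boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return np.asarray(maps, dtype=float)[..., mask].mean(axis=-1)


def change_score_correlation(x: np.ndarray, y: np.ndarray):
    """Pearson r (with two-sided p) between paired per-subject scores."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired vectors of length >= 4")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def spatial_correlation(map1, map2, mask=None) -> float:
    """Pearson r between two maps across (in-mask) grayordinates."""
    v1 = map1.values if isinstance(map1, ScalarMap) else np.asarray(map1, float)
    v2 = map2.values if isinstance(map2, ScalarMap) else np.asarray(map2, float)
    if v1.size != v2.size:
        raise ValueError("maps live on different spaces")
    if mask is None:
        mask = np.ones(v1.size, dtype=bool)
    mask = np.asarray(mask, dtype=bool) & np.isfinite(v1) & np.isfinite(v2)
    if not mask.any():
        raise ValueError("empty mask")
    return float(stats.pearsonr(v1[mask], v2[mask])[0])


@dataclass
class ConjunctionMask:
    top: np.ndarray
    bottom: np.ndarray
    fraction: float


def _rank_sets(values: np.ndarray, k: int):
    """Top-k and bottom-k index sets, ties broken by lower index."""
    order_desc = np.argsort(-values, kind="stable")
    order_asc = np.argsort(values, kind="stable")
    return set(order_desc[:k].tolist()), set(order_asc[:k].tolist())


def top_bottom_conjunction(maps, fraction: float = 0.10, eligible=None) -> ConjunctionMask:
    """Intersection of per-map top/bottom rank sets across analysis variants.

    ``maps`` is a sequence of maps on the same space (typically the
    {correlation, covariance} x {GSR, no-GSR} group means).  ``eligible``
    optionally restricts the ranking (e.g. to cortex, excluding the seed
    structure itself); NaN entries are ineligible in every map.
    """
    if not 0.0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    arrays = [m.values if isinstance(m, ScalarMap) else np.asarray(m, float) for m in maps]
    g = arrays[0].size
    if any(a.size != g for a in arrays):
        raise ValueError("maps live on different spaces")
    eligible = (
        np.ones(g, dtype=bool) if eligible is None else np.asarray(eligible, bool).copy()
    )
    for a in arrays:
        eligible &= np.isfinite(a)
    k = int(np.floor(fraction * int(eligible.sum())))
    tops, bottoms = None, None
    idx_eligible = np.flatnonzero(eligible)
    for a in arrays:
        t, b = _rank_sets(a[eligible], k)
        t = {int(idx_eligible[i]) for i in t}
        b = {int(idx_eligible[i]) for i in b}
        tops = t if tops is None else tops & t
        bottoms = b if bottoms is None else bottoms & b
    top_mask = np.zeros(g, dtype=bool)
    bot_mask = np.zeros(g, dtype=bool)
    top_mask[sorted(tops)] = True
    bot_mask[sorted(bottoms)] = True
    return ConjunctionMask(top=top_mask, bottom=bot_mask, fraction=fraction)


def network_means(map_, space) -> np.ndarray:
    """Mean map value per functional network (NaN for empty networks)."""
    v = map_.values if isinstance(map_, ScalarMap) else np.asarray(map_, float)
    out = np.full(len(NETWORKS), np.nan)
    for i, net in enumerate(NETWORKS):
        m = space.network_mask(net)
        if m.any():
            out[i] = np.nanmean(v[m])
    return out


def symptom_correlations(delta_fz: np.ndarray, scores: np.ndarray, m_tests: int = 7):
    """Per-network Pearson correlation with Bonferroni-adjusted p-values.

    ``delta_fz`` is n_subjects x n_networks (connectivity change per
    network), ``scores`` the per-subject behavioral score.  Returns a
    DataFrame (network, r, p, p_bonferroni).
    """
    import pandas as pd

    delta_fz = np.asarray(delta_fz, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if delta_fz.shape[0] != scores.size or scores.size < 4:
        raise ValueError("need paired data with n >= 4")
    if scores.std() == 0:
        raise ValueError("constant scores")
    rows = []
    for j in range(delta_fz.shape[1]):
        name = NETWORKS[j] if j < len(NETWORKS) else f"net{j}"
        col = delta_fz[:, j]
        if col.std() == 0:
            rows.append({"network": name, "r": np.nan, "p": np.nan, "p_bonferroni": np.nan})
            continue
        r, p = stats.pearsonr(col, scores)
        rows.append(
            {
                "network": name,
                "r": float(r),
                "p": float(p),
                "p_bonferroni": float(min(1.0, m_tests * p)),
            }
        )
    return pd.DataFrame(rows)
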