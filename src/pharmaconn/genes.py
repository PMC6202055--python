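"""Spatial matching of contrast maps against cortical expression maps.

Matching is done at parcel level: the dense contrast map is averaged
within left-hemisphere cortical parcels and correlated with each gene's
z-scored parcel expression profile.  The percentile rank of a named
target gene among all supplied genes quantifies how preferentially the
contrast topography matches that gene.  Reported p-values use naive
parcel-count degrees of freedom; spatial autocorrelation of cortical
maps inflates them, so an optional parcel-permutation p-value is
available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import NETWORKS, ExpressionMatrix, GrayordinateSpace, ScalarMap


def parcellate_map(
    map_: ScalarMap | np.ndarray,
    space: GrayordinateSpace,
    hemisphere: str = "cortex-L",
) -> np.ndarray:
    """Mean map value per parcel over the selected hemisphere's cortex."""
    v = map_.values if isinstance(map_, ScalarMap) else np.asarray(map_, float)
    if v.size != space.n_gray:
        raise ValueError("map length does not match space")
    if hemisphere == "both":
        hemi_mask = space.cortex_mask
    else:
        hemi_mask = space.structure_mask(hemisphere)
    p = space.n_parcels
    out = np.full(p, np.nan)
    for parcel in range(p):
        m = hemi_mask & (space.parcel == parcel)
        if m.any():
            out[parcel] = v[m].mean()
        else:
            warnings.warn(f"parcel {parcel} empty in {hemisphere}; masked")
    return out


@dataclass
class GeneMatchResult:
    genes: list
    r: np.ndarray  # per-gene correlation with the parcel map
    targets: dict  # symbol -> percentile of its r among all genes
    n_parcels: int

    def table(self) -> pd.DataFrame:
        pct = 100.0 * (
            np.argsort(np.argsort(self.r)) / (max(len(self.genes) - 1, 1))
        )
        return pd.DataFrame({"gene": self.genes, "r": self.r, "percentile": pct})


def gene_map_correlations(
    parcel_map: np.ndarray,
    expr: ExpressionMatrix,
    targets: list | None = None,
) -> GeneMatchResult:
    """Pearson r of every gene's expression profile with a parcel map.

    Masked (NaN) parcels are dropped pairwise.  The percentile of a
    target gene is ``100 * #{genes with r < r_target} / (n_genes - 1)``.
    """
    pm = np.asarray(parcel_map, dtype=float)
    if pm.size != expr.n_parcels:
        raise ValueError(
            f"map has {pm.size} parcels, expression has {expr.n_parcels}"
        )
    if pm.size < 4:
        raise ValueError("need at least 4 parcels")
    n_genes = len(expr.genes)
    r = np.full(n_genes, np.nan)
    for i in range(n_genes):
        row = expr.values[i]
        ok = np.isfinite(pm) & np.isfinite(row)
        if ok.sum() < 4 or row[ok].std() == 0 or pm[ok].std() == 0:
            continue
        r[i] = stats.pearsonr(pm[ok], row[ok])[0]
    targets = targets or []
    pct = {}
    valid = np.isfinite(r)
    for sym in targets:
        i = expr.genes.index(sym)
        if not np.isfinite(r[i]):
            pct[sym] = np.nan
            continue
        below = int((r[valid] < r[i]).sum())
        pct[sym] = 100.0 * below / max(n_genes - 1, 1)
    return GeneMatchResult(genes=list(expr.genes), r=r, targets=pct, n_parcels=pm.size)


def parcel_permutation_p(parcel_map, gene_row, n_perm: int = 1000, seed: int = 0) -> float:
    """Two-sided permutation p for one map-gene correlation (parcel shuffles)."""
    pm = np.asarray(parcel_map, float)
    row = np.asarray(gene_row, float)
    ok = np.isfinite(pm) & np.isfinite(row)
    r_obs = stats.pearsonr(pm[ok], row[ok])[0]
    rng = np.random.default_rng(seed)
    hits = 0
    x = pm[ok]
    y = row[ok]
    for _ in range(n_perm):
        r = stats.pearsonr(x, rng.permutation(y))[0]
        if abs(r) >= abs(r_obs):
            hits += 1
    return (1.0 + hits) / (n_perm + 1.0)


def compare_dependent_correlations(r_ag: float, r_bg: float, r_ab: float, n: int):
    """Steiger's Z for two dependent correlations sharing one variable.

    Tests whether map A and map B correlate differently with the shared
    gene map G given the A-B correlation, using Steiger's (1980) Z-bar*
    with the Fisher-transformed difference.  Returns ``(z, two-sided p)``.
    """
    for r in (r_ag, r_bg, r_ab):
        if abs(r) >= 1.0:
            raise ValueError("degenerate correlation |r| >= 1")
    if n < 10:
        raise ValueError("need n >= 10")
    z1 = np.arctanh(r_ag)
    z2 = np.arctanh(r_bg)
    rm2 = 0.5 * (r_ag**2 + r_bg**2)
    f = min((1.0 - r_ab) / (2.0 * (1.0 - rm2)), 1.0)
    h = (1.0 - f * rm2) / (1.0 - rm2)
    z = (z1 - z2) * np.sqrt((n - 3.0) / (2.0 * (1.0 - r_ab) * h))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    m = m if m is not None else p.size
    return np.minimum(1.0, m * p)


def parcel_networks(space: GrayordinateSpace, hemisphere: str = "cortex-L") -> list:
    """Majority network label of each parcel's member grayordinates."""
    hemi = space.structure_mask(hemisphere) if hemisphere != "both" else space.cortex_mask
    out = []
    for parcel in range(space.n_parcels):
        m = hemi & (space.parcel == parcel)
        if not m.any():
            out.append("none")
            continue
        labels, counts = np.unique(space.network[m].astype(str), return_counts=True)
        out.append(labels[np.argmax(counts)])
    return out


def expression_network_summary(expr: ExpressionMatrix, space: GrayordinateSpace):
    """Mean z-scored expression per network per gene, plus gene-gene correlations."""
    nets = np.array(parcel_networks(space), dtype=object)
    summary = pd.DataFrame(index=expr.genes, columns=list(NETWORKS), dtype=float)
    for net in NETWORKS:
        m = nets == net
        if m.any():
            summary[net] = expr.values[:, m].mean(axis=1)
    gene_corr = pd.DataFrame(
        np.corrcoef(expr.values), index=expr.genes, columns=expr.genes
    )
    return summary, gene_corr
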