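"""Synthetic multi-subject, multi-condition BOLD cohort generator.

The generator emulates the statistical structure a pharmacological
resting-state connectivity analysis has to disentangle:

* latent network signals with condition-dependent loadings — the drug
  condition raises loadings in sensory/somatomotor networks and lowers
  them in associative networks,
* a global slow fluctuation ``g(t)`` whose *spatial* contribution map
  (the GS topography ``w_k``) shifts under drug while its overall
  amplitude stays constant across conditions,
* subject-level hyper/hypo effect sizes drawn from a bivariate normal so
  that sensory coupling gains and associative coupling losses are
  correlated across subjects,
* motion spikes with co-occurring intensity jumps so frame censoring is
  exercised, and
* behavioral scores coupled to the subject's somatomotor effect under
  drug and flat under placebo and under antagonist pre-treatment.

The model for grayordinate ``k`` at frame ``t`` is::

    bold_k(t) = baseline + w_k[cond] * g(t) + L_k[cond, subj] * eta_net(k)(t)
                + spike_k(t) + eps_k(t)

with ``eta_c`` unit-variance AR(1) latent signals (one per network),
``g`` a unit-variance AR(1) fluctuation low-passed below 0.1 Hz and
scaled by ``gs_amplitude``, and ``L`` the per-grayordinate loading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    ASSOCIATIVE_NETWORKS,
    CONDITIONS,
    NETWORKS,
    SENSORY_NETWORKS,
    BoldRun,
    CohortDesign,
    ExpressionMatrix,
    GrayordinateSpace,
)

#: structure composition of a synthetic space (fractions of n_gray)
_STRUCTURE_FRACTIONS = (
    ("cortex-L", 0.42),
    ("cortex-R", 0.42),
    ("thalamus", 0.05),
    ("amygdala", 0.02),
    ("other-subcortex", 0.05),
    ("ventricle-proxy", 0.02),
    ("wm-proxy", 0.02),
)

BEHAV_TIMES_MIN = (180, 250, 360)


class ConfigError(ValueError):
    pass


def _default_loading_base() -> dict:
    # associative hubs carry stronger shared signal at baseline, so they
    # occupy the top of the baseline connectivity distribution
    return {
        "visual": 0.50,
        "somatomotor": 0.50,
        "dorsal-attention": 0.75,
        "ventral-attention": 0.75,
        "limbic": 0.65,
        "frontoparietal": 0.80,
        "default": 0.85,
    }


def _default_lsd_delta() -> dict:
    return {
        "visual": 0.25,
        "somatomotor": 0.25,
        "dorsal-attention": -0.20,
        "ventral-attention": -0.20,
        "limbic": -0.15,
        "frontoparietal": -0.25,
        "default": -0.25,
    }


@dataclass
class GeneratorConfig:
    """All knobs of the cohort generator; every field has a study default.

    ``loading_delta`` maps condition -> network -> loading change; the
    antagonist condition is derived from the drug condition scaled by
    ``ket_fraction`` (default 0: full blockade).  ``gs_topo_delta`` is
    the amplitude of the drug-induced GS-topography shift (positive in
    associative, negative in sensory regions, mean-centered so the GS
    variance itself does not differ between conditions).
    """

    n_subjects: int = 24
    n_gray: int = 2000
    T: int = 240
    tr: float = 2.5
    n_networks: int = 7
    n_parcels: int = 180
    loading_base: dict = field(default_factory=_default_loading_base)
    loading_delta: dict | None = None  # condition -> network -> delta
    ket_fraction: float = 0.0
    gs_amplitude: dict | None = None  # condition -> amplitude
    gs_topo_delta: dict | None = None  # condition -> topography shift
    gs_topography: dict | None = None  # condition -> explicit length-G w_k
    rho_hh: float = -0.9
    effect_sd: float = 0.3
    behav_coupling: float = 25.0
    behav_base: float = 30.0
    behav_noise_sd: float = 5.0
    noise_sd: float = 1.0
    baseline: float = 1000.0
    motion_spike_rate: float = 0.02
    spike_amp: float = 6.0
    subcortical_scale: float = 0.6
    thalamic_scale: float = 1.5
    vent_g_share: float = 0.4
    g_phi: float = 0.4
    g_lowpass_hz: float = 0.1
    net_phi: float = 0.3
    layout: str = "ring"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loading_delta is None:
            lsd = _default_lsd_delta()
            self.loading_delta = {
                "Pla": {n: 0.0 for n in NETWORKS},
                "LSD": lsd,
                "KetLSD": {n: self.ket_fraction * d for n, d in lsd.items()},
            }
        if self.gs_amplitude is None:
            self.gs_amplitude = {c: 1.0 for c in CONDITIONS}
        if self.gs_topo_delta is None:
            self.gs_topo_delta = {
                "Pla": 0.0,
                "LSD": 0.4,
                "KetLSD": self.ket_fraction * 0.4,
            }
        self.validate()

    def validate(self) -> None:
        for name in ("n_subjects", "n_gray", "T", "n_networks", "n_parcels"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not 0.0 <= self.motion_spike_rate <= 1.0:
            raise ConfigError("motion_spike_rate must be a probability")
        if abs(self.rho_hh) > 1.0:
            raise ConfigError("|rho_hh| must be <= 1")
        if self.n_networks > len(NETWORKS):
            raise ConfigError(f"n_networks > {len(NETWORKS)} supported labels")
        if self.layout not in ("ring", "grid"):
            raise ConfigError("layout must be 'ring' or 'grid'")


@dataclass
class GroundTruth:
    """What the generator injected, for recovery checks downstream."""

    gs_topography: dict  # condition -> length-G w_k
    coupling_change: np.ndarray  # signed expected LSD-Pla loading change per grayordinate
    hyper_effect: np.ndarray  # per-subject signed sensory effect size
    hypo_effect: np.ndarray  # per-subject signed associative effect size
    behav_scores: np.ndarray  # n_subjects x 3 conditions x 3 times
    subjects: list

    def as_arrays(self) -> dict:
        out = {
            "coupling_change": self.coupling_change,
            "hyper_effect": self.hyper_effect,
            "hypo_effect": self.hypo_effect,
            "behav_scores": self.behav_scores,
        }
        for c, w in self.gs_topography.items():
            out[f"gs_topography_{c}"] = w
        return out


# ------------------------------------------------------------- space

def _structure_counts(n_gray: int) -> dict:
    counts = {name: int(np.floor(frac * n_gray)) for name, frac in _STRUCTURE_FRACTIONS}
    if n_gray >= 20:
        for name in ("thalamus", "amygdala", "ventricle-proxy", "wm-proxy"):
            counts[name] = max(counts[name], 1)
    # hand the remainder to the cortical blocks, alternating hemispheres
    rem = n_gray - sum(counts.values())
    side = 0
    while rem > 0:
        counts["cortex-L" if side == 0 else "cortex-R"] += 1
        side ^= 1
        rem -= 1
    while rem < 0:  # rounding overshoot on tiny spaces
        big = max(counts, key=lambda k: counts[k])
        counts[big] -= 1
        rem += 1
    return counts


def _split_blocks(n: int, k: int) -> list:
    """Split n items into k contiguous near-equal blocks (sizes differ by <=1)."""
    base, extra = divmod(n, k)
    sizes = [base + (1 if i < extra else 0) for i in range(k)]
    out, start = [], 0
    for s in sizes:
        out.append((start, start + s))
        start += s
    return out


def make_space(
    n_gray: int,
    n_networks: int = 7,
    n_parcels: int = 10,
    seed: int = 0,
    layout: str = "ring",
) -> GrayordinateSpace:
    """Build a labeled synthetic grayordinate space.

    Grayordinates are laid out on a ring (or 2-D grid) so adjacency is
    well defined for cluster enhancement; structures, networks and
    parcels are contiguous blocks.  Networks and parcels are assigned
    per hemisphere, so every parcel has members in the left cortex.
    """
    if n_networks > len(NETWORKS):
        raise ConfigError(f"n_networks > {len(NETWORKS)} supported labels")
    counts = _structure_counts(n_gray)
    structure = np.empty(n_gray, dtype=object)
    pos = 0
    bounds = {}
    for name, _ in _STRUCTURE_FRACTIONS:
        c = counts[name]
        structure[pos : pos + c] = name
        bounds[name] = (pos, pos + c)
        pos += c

    n_cortical = counts["cortex-L"] + counts["cortex-R"]
    if n_parcels > n_cortical:
        raise ConfigError(
            f"n_parcels={n_parcels} exceeds cortical grayordinate count {n_cortical}"
        )

    network = np.full(n_gray, "none", dtype=object)
    parcel = np.full(n_gray, -1, dtype=np.int64)
    for hemi in ("cortex-L", "cortex-R"):
        lo, hi = bounds[hemi]
        if hi == lo:
            continue
        for i, (a, b) in enumerate(_split_blocks(hi - lo, n_networks)):
            network[lo + a : lo + b] = NETWORKS[i]
        for p, (a, b) in enumerate(_split_blocks(hi - lo, n_parcels)):
            parcel[lo + a : lo + b] = p

    if layout == "ring":
        i = np.arange(n_gray)
        edges = np.column_stack([i, (i + 1) % n_gray])
    elif layout == "grid":
        ncol = int(np.ceil(np.sqrt(n_gray)))
        idx = np.arange(n_gray)
        r, c = divmod(idx, ncol)
        right = idx + 1
        ok_r = (c < ncol - 1) & (right < n_gray)
        down = idx + ncol
        ok_d = down < n_gray
        edges = np.vstack(
            [np.column_stack([idx[ok_r], right[ok_r]]), np.column_stack([idx[ok_d], down[ok_d]])]
        )
    else:
        raise ConfigError("layout must be 'ring' or 'grid'")
    return GrayordinateSpace(structure=structure, network=network, parcel=parcel, edges=edges)


# ----------------------------------------------------------- signals

def _ar1(rng: np.random.Generator, t: int, phi: float) -> np.ndarray:
    x = np.empty(t)
    innov_sd = np.sqrt(1.0 - phi * phi)
    x[0] = rng.standard_normal()
    eps = rng.standard_normal(t - 1) * innov_sd
    for i in range(1, t):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def _lowpass(x: np.ndarray, tr: float, cutoff_hz: float) -> np.ndarray:
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=tr)
    spec[freqs > cutoff_hz] = 0.0
    return np.fft.irfft(spec, n=x.size)


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def _signal_network_index(space: GrayordinateSpace) -> np.ndarray:
    """Network driving each grayordinate's latent signal.

    Cortical grayordinates follow their own network label; subcortical
    gray matter is distributed round-robin across networks (the thalamus
    and basal ganglia participate in every large-scale system); the
    ventricle/WM proxies carry no network signal (-1).
    """
    net_idx = np.full(space.n_gray, -1, dtype=np.int64)
    lut = {n: i for i, n in enumerate(NETWORKS)}
    for k in range(space.n_gray):
        if space.network[k] != "none":
            net_idx[k] = lut[space.network[k]]
    present = sorted({v for v in net_idx if v >= 0}) or [0]
    assoc = [i for i in present if NETWORKS[i] in ASSOCIATIVE_NETWORKS] or present
    sens = [i for i in present if NETWORKS[i] in SENSORY_NETWORKS] or present
    # thalamus: predominantly association nuclei, with a small sensory
    # (relay) segment — baseline thalamo-associative coupling is strong
    # and thalamo-sensory coupling weak
    thal = np.flatnonzero(space.thalamus_mask)
    n_sens_thal = max(1, len(thal) // 10) if len(thal) else 0
    for j, k in enumerate(thal):
        if j < n_sens_thal:
            net_idx[k] = sens[j % len(sens)]
        else:
            net_idx[k] = assoc[j % len(assoc)]
    other = np.flatnonzero(space.structure_mask("amygdala", "other-subcortex"))
    for j, k in enumerate(other):
        net_idx[k] = present[j % len(present)]
    return net_idx


def _gs_topography(space: GrayordinateSpace, config: GeneratorConfig) -> dict:
    """Per-condition GS spatial weight maps w_k (mean 1 over gray matter)."""
    if config.gs_topography is not None:
        return {c: np.asarray(config.gs_topography[c], dtype=float) for c in CONDITIONS}
    g = space.n_gray
    gray = space.gray_mask
    w_base = np.where(gray, 1.0, 0.2)
    sens = np.isin(space.network, SENSORY_NETWORKS)
    assoc = np.isin(space.network, ASSOCIATIVE_NETWORKS)
    net_idx = _signal_network_index(space)
    sens_idx = [i for i, n in enumerate(NETWORKS) if n in SENSORY_NETWORKS]
    subgray = space.structure_mask("thalamus", "amygdala", "other-subcortex")
    sens = sens | (subgray & np.isin(net_idx, sens_idx))
    assoc = assoc | (subgray & ~np.isin(net_idx, sens_idx) & (net_idx >= 0))
    pattern = np.zeros(g)
    pattern[assoc] = 1.0
    pattern[sens] = -1.0
    pattern[gray] -= pattern[gray].mean()  # keep GS variance condition-invariant
    pattern[~gray] = 0.0
    return {
        c: w_base + config.gs_topo_delta[c] * pattern for c in CONDITIONS
    }


def _loading_vectors(space, config, net_idx):
    """Baseline loading L0_k and per-condition delta_k (before subject scaling)."""
    g = space.n_gray
    scale = np.where(space.cortex_mask, 1.0, config.subcortical_scale)
    scale = np.where(space.thalamus_mask, config.thalamic_scale, scale)
    base = np.zeros(g)
    delta = {c: np.zeros(g) for c in CONDITIONS}
    for k in range(g):
        if net_idx[k] < 0:
            continue
        net = NETWORKS[net_idx[k]]
        base[k] = config.loading_base.get(net, 0.0) * scale[k]
        for c in CONDITIONS:
            delta[c][k] = config.loading_delta[c].get(net, 0.0) * scale[k]
    return base, delta


def _subject_effects(rng, config):
    """Signed hyper/hypo effect multipliers with the requested coupling.

    Draw (h, l) with corr = -rho_hh and negate the associative branch's
    sign downstream (the associative loading deltas are negative), so
    the *signed* change contributions hyper = h, hypo = -l satisfy
    corr(hyper, hypo) = rho_hh.
    """
    rho = -config.rho_hh
    cov = config.effect_sd**2 * np.array([[1.0, rho], [rho, 1.0]])
    hl = rng.multivariate_normal([1.0, 1.0], cov, size=config.n_subjects)
    return hl[:, 0], hl[:, 1]


def simulate_cohort(space: GrayordinateSpace, config: GeneratorConfig):
    """Generate the full 3-condition x 2-session crossing with ground truth.

    Returns ``(design, runs, truth)`` where ``runs`` maps run id to
    :class:`BoldRun`.  All randomness flows from ``config.seed``.
    """
    config.validate()
    if space.n_gray != config.n_gray:
        raise ConfigError(
            f"space has {space.n_gray} grayordinates, config expects {config.n_gray}"
        )
    root = np.random.SeedSequence(config.seed)
    ss_subj, ss_runs, ss_behav = root.spawn(3)
    rng_subj = np.random.default_rng(ss_subj)

    net_idx = _signal_network_index(space)
    w = _gs_topography(space, config)
    base_load, delta_load = _loading_vectors(space, config, net_idx)
    h_mult, l_mult = _subject_effects(rng_subj, config)

    sens_idx = [i for i, n in enumerate(NETWORKS) if n in SENSORY_NETWORKS]
    is_sens_net = np.isin(net_idx, sens_idx) & (net_idx >= 0)

    subjects = [f"sub{s:03d}" for s in range(config.n_subjects)]
    n_net = len(NETWORKS)
    t, g = config.T, space.n_gray

    run_streams = ss_runs.spawn(config.n_subjects * len(CONDITIONS) * 2)
    runs: dict = {}
    rows = []
    stream_i = 0
    for si, subj in enumerate(subjects):
        mult = np.where(is_sens_net, h_mult[si], l_mult[si])
        for condition in CONDITIONS:
            load = base_load + delta_load[condition] * mult
            for session in (1, 2):
                rng = np.random.default_rng(run_streams[stream_i])
                stream_i += 1
                gsig = _standardize(
                    _lowpass(_ar1(rng, t, config.g_phi), config.tr, config.g_lowpass_hz)
                ) * config.gs_amplitude[condition]
                eta = np.empty((t, n_net))
                for c in range(n_net):
                    eta[:, c] = _standardize(_ar1(rng, t, config.net_phi))
                bold = np.outer(gsig, w[condition])
                active = net_idx >= 0
                bold[:, active] += eta[:, net_idx[active]] * load[active]
                # coupling changes are variance-preserving: per-grayordinate
                # noise variance compensates the condition's loading change so
                # the drug shifts coupling structure, not local signal
                # amplitude (local variance is approximately condition-
                # invariant, and exactly so once the global component is
                # regressed out)
                sigma = np.sqrt(
                    np.maximum(
                        config.noise_sd**2 + base_load**2 - load**2,
                        0.04 * config.noise_sd**2,
                    )
                )
                bold += rng.standard_normal((t, g)) * sigma

                # slow drift: ~0.01 mm translation steps, ~1e-4 rad rotation steps
                motion = np.cumsum(
                    rng.standard_normal((t, 6)) * np.array([0.01] * 3 + [1e-4] * 3),
                    axis=0,
                )
                spikes = np.flatnonzero(
                    rng.random(t - 1) < config.motion_spike_rate
                ) + 1
                for f in spikes:
                    # transient head excursion: frame f only, returning at f+1,
                    # with a co-occurring brain-wide intensity jump
                    motion[f, 0] += rng.uniform(0.6, 1.5)
                    bold[f] += (
                        rng.standard_normal(g) * config.spike_amp * config.noise_sd
                    )
                bold += config.baseline

                vent = config.vent_g_share * gsig + rng.standard_normal(t)
                wm = config.vent_g_share * gsig + rng.standard_normal(t)
                run = BoldRun(
                    subject=subj,
                    condition=condition,
                    session=session,
                    bold=bold,
                    tr=config.tr,
                    motion=motion,
                    ventricle_ts=vent,
                    wm_ts=wm,
                )
                runs[run.run_id] = run
                rows.append(
                    {
                        "subject": subj,
                        "condition": condition,
                        "session": session,
                        "run_id": run.run_id,
                    }
                )

    rng_behav = np.random.default_rng(ss_behav)
    time_profile = np.array([1.0, 0.85, 0.6])
    behav = np.zeros((config.n_subjects, len(CONDITIONS), len(BEHAV_TIMES_MIN)))
    for si in range(config.n_subjects):
        for ci, condition in enumerate(CONDITIONS):
            for ti in range(len(BEHAV_TIMES_MIN)):
                if condition == "LSD":
                    score = (
                        config.behav_base
                        + config.behav_coupling * (h_mult[si] - 1.0)
                    ) * time_profile[ti] + rng_behav.normal(0, config.behav_noise_sd)
                else:
                    # antagonist pre-treatment blocks subjective effects;
                    # placebo scores hover near zero
                    score = abs(rng_behav.normal(0, 1.5))
                behav[si, ci, ti] = max(score, 0.0)

    truth = GroundTruth(
        gs_topography=w,
        coupling_change=delta_load["LSD"] - delta_load["Pla"],
        hyper_effect=h_mult,
        hypo_effect=-l_mult,
        behav_scores=behav,
        subjects=subjects,
    )
    design = CohortDesign(table=pd.DataFrame(rows))
    return design, runs, truth


# -------------------------------------------------------- expression

def simulate_expression(
    space: GrayordinateSpace,
    reference_parcel_map: np.ndarray,
    n_genes: int,
    r_target: float = 0.5,
    r_anti: float = -0.5,
    seed: int = 0,
    symbols: list | None = None,
) -> ExpressionMatrix:
    """Synthetic gene x parcel expression with two constructed genes.

    Gene 0 is built to correlate ``r_target`` with the reference parcel
    map (an HTR2A-like pattern relative to the drug contrast), gene 1 to
    correlate ``r_anti`` (an HTR7-like anticorrelated pattern); the rest
    are spatially random.  Every row is z-scored across parcels.
    """
    ref = np.asarray(reference_parcel_map, dtype=float)
    p = ref.size
    if p < 4:
        raise ConfigError("need at least 4 parcels for correlation targets")
    if n_genes < 3:
        raise ConfigError("n_genes must be >= 3")
    for r in (r_target, r_anti):
        if not abs(r) < 1.0:
            raise ConfigError("|r_target| and |r_anti| must be < 1")
    rng = np.random.default_rng(seed)

    def zrow(x):
        return (x - x.mean()) / x.std()

    zref = zrow(ref)
    values = np.empty((n_genes, p))
    for row, r in ((0, r_target), (1, r_anti)):
        noise = rng.standard_normal(p)
        perp = noise - (noise @ zref) / (zref @ zref) * zref
        perp = zrow(perp)
        values[row] = r * zref + np.sqrt(1.0 - r * r) * perp
    for row in range(2, n_genes):
        values[row] = rng.standard_normal(p)
    values = (values - values.mean(axis=1, keepdims=True)) / values.std(
        axis=1, keepdims=True
    )
    if symbols is None:
        symbols = ["TARGET", "ANTI"] + [f"G{i:04d}" for i in range(2, n_genes)]
    return ExpressionMatrix(genes=list(symbols), values=values)
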