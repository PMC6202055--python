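"""Permutation inference, TFCE (vs brute-force oracle), and summary analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

import pharmaconn as pc
from pharmaconn.inference import (
    TFCE_STEPS,
    _rm_f,
    main_effect_contrast,
    paired_contrast,
    tfce,
)


def ring_edges(g):
    i = np.arange(g)
    return np.column_stack([i, (i + 1) % g])


def brute_force_tfce(values, edges, g, H=2.0, E=0.5, n_steps=TFCE_STEPS):
    """Independent threshold-sum TFCE using scipy connected components."""
    values = np.asarray(values, float)
    out = np.zeros(g)
    vmax = np.abs(values).max()
    if vmax == 0:
        return out
    dh = vmax / n_steps
    for signed in (values, -values):
        branch = np.zeros(g)
        bmax = branch_max = np.maximum(signed, 0).max()
        nst = int(np.floor(branch_max / dh + 1e-12))
        for s in range(1, nst + 1):
            h = dh * s
            active = signed >= h
            keep = active[edges[:, 0]] & active[edges[:, 1]]
            adj = sparse.coo_matrix(
                (np.ones(keep.sum()), (edges[keep, 0], edges[keep, 1])), shape=(g, g)
            )
            n_comp, labels = connected_components(adj, directed=False)
            sizes = np.bincount(labels, minlength=g)
            extent = sizes[labels].astype(float)
            branch[active] += extent[active] ** E * h**H * dh
        if signed is values:
            out += branch
        else:
            out -= branch
    return out


class TestTFCE:
    def test_zero_map(self):
        edges = ring_edges(20)
        assert (tfce(np.zeros(20), edges) == 0).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_ring(self, seed):
        g = 50
        edges = ring_edges(g)
        vals = np.random.default_rng(seed).normal(size=g)
        ours = tfce(vals, edges)
        oracle = brute_force_tfce(vals, edges, g)
        assert np.abs(ours - oracle).max() < 1e-9

    def test_matches_brute_force_on_random_graph(self):
        rng = np.random.default_rng(3)
        g = 100
        pairs = {tuple(sorted(p)) for p in rng.integers(0, g, (260, 2)) if p[0] != p[1]}
        edges = np.array(sorted(pairs))
        vals = rng.normal(size=g)
        assert np.abs(tfce(vals, edges) - brute_force_tfce(vals, edges, g)).max() < 1e-9

    def test_scaling_monotonicity(self):
        g = 40
        edges = ring_edges(g)
        vals = np.random.default_rng(4).normal(size=g)
        t1 = tfce(vals, edges)
        t2 = tfce(2.5 * vals, edges)
        assert (np.abs(t2) >= np.abs(t1) - 1e-12).all()

    def test_invalid_dh_rejected(self):
        with pytest.raises(ValueError, match="dh"):
            tfce(np.ones(5), ring_edges(5), dh=-1.0)


class TestPairedContrast:
    def test_identical_maps_null(self, rng):
        maps = rng.normal(size=(8, 30))
        res = paired_contrast(maps, maps.copy(), ring_edges(30), n_perm=100, seed=0)
        assert (res.z_map.values == 0).all()
        assert res.n_significant == 0

    def test_injected_shift_detected(self):
        """A 1-SD mean shift in 20 contiguous grayordinates is detected."""
        g, n = 100, 20
        edges = ring_edges(g)
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            a = r.normal(size=(n, g))
            b = r.normal(size=(n, g))
            a[:, 40:60] += np.sqrt(2.0)  # 1 SD of the within-subject difference
            res = paired_contrast(a, b, edges, n_perm=300, seed=seed)
            hits += res.sig_mask_pos[40:60].mean() > 0.5
        assert hits >= 9

    def test_deterministic_given_seed(self, rng):
        a = rng.normal(size=(10, 40))
        b = rng.normal(size=(10, 40))
        r1 = paired_contrast(a, b, ring_edges(40), n_perm=150, seed=5)
        r2 = paired_contrast(a, b, ring_edges(40), n_perm=150, seed=5)
        assert np.array_equal(r1.fwe_p.values, r2.fwe_p.values)

    def test_too_few_subjects_rejected(self, rng):
        a = rng.normal(size=(4, 10))
        with pytest.raises(ValueError, match="subjects"):
            paired_contrast(a, a, ring_edges(10), n_perm=100)


class TestMainEffect:
    def test_identical_conditions_null_f(self, rng):
        base = rng.normal(size=(10, 1, 25))
        maps = np.repeat(base, 3, axis=1)
        f, _, _ = _rm_f(maps)
        assert np.abs(f).max() < 1e-18
        res = main_effect_contrast(maps, ring_edges(25), n_perm=100, seed=1)
        assert res.n_significant == 0

    def test_rm_f_matches_scipy_anova(self, rng):
        """Per-grayordinate repeated-measures F agrees with a direct fit."""
        n, c = 12, 3
        maps = rng.normal(size=(n, c, 4))
        f, df1, df2 = _rm_f(maps)
        for k in range(4):
            x = maps[:, :, k]
            grand = x.mean()
            ss_cond = n * ((x.mean(0) - grand) ** 2).sum()
            resid = x - x.mean(1, keepdims=True) - x.mean(0, keepdims=True) + grand
            f_ref = (ss_cond / (c - 1)) / ((resid**2).sum() / ((n - 1) * (c - 1)))
            assert f[k] == pytest.approx(f_ref, rel=1e-10)

    def test_single_condition_effect_detected(self):
        g = 60
        hits = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            maps = r.normal(size=(15, 3, g))
            maps[:, 1, 20:35] += 2.0
            res = main_effect_contrast(maps, ring_edges(g), n_perm=300, seed=seed)
            hits += res.sig_mask_pos[20:35].mean() >= 0.9
        assert hits >= 4

    def test_missing_cell_rejected(self, rng):
        maps = rng.normal(size=(6, 3, 10))
        maps[2, 1, 3] = np.nan
        with pytest.raises(ValueError, match="subject index 2"):
            main_effect_contrast(maps, ring_edges(10), n_perm=100)


class TestSummaries:
    def test_mask_means_hand_example(self):
        maps = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]])
        mask = np.array([True, False, True])
        assert np.allclose(pc.mask_means(maps, mask), [2.0, 5.0, 8.0])
        one = np.array([False, True, False])
        assert np.allclose(pc.mask_means(maps, one), [2.0, 5.0, 8.0])
        with pytest.raises(ValueError, match="empty"):
            pc.mask_means(maps, np.zeros(3, bool))

    def test_change_score_correlation(self, rng):
        x = rng.normal(size=100)
        r, _ = pc.change_score_correlation(x, x)
        assert r == pytest.approx(1.0)
        y = -x + rng.normal(size=100) * 0.1
        r, p = pc.change_score_correlation(x, y)
        assert r < -0.95 and p < 1e-10
        with pytest.raises(ValueError):
            pc.change_score_correlation(x, np.zeros(100))

    def test_spatial_correlation(self, rng):
        m = rng.normal(size=200)
        assert pc.spatial_correlation(m, m) == pytest.approx(1.0)
        assert pc.spatial_correlation(m, -m) == pytest.approx(-1.0)
        other = rng.normal(size=200)
        mc, oc = m - m.mean(), other - other.mean()
        oracle = (mc @ oc) / np.sqrt((mc @ mc) * (oc @ oc))
        assert pc.spatial_correlation(m, other) == pytest.approx(oracle, abs=1e-12)
        with pytest.raises(ValueError, match="space"):
            pc.spatial_correlation(m, rng.normal(size=100))


class TestConjunction:
    @staticmethod
    def brute_force(maps, fraction):
        g = maps[0].size
        k = int(np.floor(fraction * g))
        tops, bots = [], []
        for m in maps:
            order = sorted(range(g), key=lambda i: (-m[i], i))
            tops.append(set(order[:k]))
            order = sorted(range(g), key=lambda i: (m[i], i))
            bots.append(set(order[:k]))
        return set.intersection(*tops), set.intersection(*bots)

    def test_identical_maps(self, rng):
        m = rng.normal(size=100)
        conj = pc.top_bottom_conjunction([m, m, m, m], 0.10)
        t_ref, b_ref = self.brute_force([m] * 4, 0.10)
        assert set(np.flatnonzero(conj.top)) == t_ref
        assert set(np.flatnonzero(conj.bottom)) == b_ref
        assert conj.top.sum() == 10

    def test_disjoint_top_ranks_empty(self):
        a = np.arange(20.0)
        b = a[::-1].copy()
        conj = pc.top_bottom_conjunction([a, b, a, b], 0.10)
        assert not conj.top.any() and not conj.bottom.any()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force(self, seed):
        r = np.random.default_rng(seed)
        maps = [r.normal(size=200) for _ in range(4)]
        # correlate the maps so intersections are non-trivial
        maps = [maps[0] * 0.8 + m * 0.2 for m in maps]
        conj = pc.top_bottom_conjunction(maps, 0.10)
        t_ref, b_ref = self.brute_force(maps, 0.10)
        assert set(np.flatnonzero(conj.top)) == t_ref
        assert set(np.flatnonzero(conj.bottom)) == b_ref
        assert not (conj.top & conj.bottom).any()

    def test_invalid_fraction(self, rng):
        with pytest.raises(ValueError, match="fraction"):
            pc.top_bottom_conjunction([rng.normal(size=10)] * 4, 0.7)


class TestNetworkSummaries:
    def test_uniform_and_one_hot(self, space_small):
        uniform = np.full(space_small.n_gray, 2.5)
        nm = pc.network_means(uniform, space_small)
        assert np.allclose(nm, 2.5)
        vals = np.zeros(space_small.n_gray)
        vis = space_small.network_mask("visual")
        vals[vis] = 3.0
        nm = pc.network_means(vals, space_small)
        assert nm[0] == pytest.approx(3.0)
        assert np.nanmax(nm[1:]) < 3.0

    def test_hand_computed_toy(self):
        sp = pc.make_space(100, 7, 10)
        vals = np.arange(100.0)
        nm = pc.network_means(vals, sp)
        vis = sp.network_mask("visual")
        assert nm[0] == pytest.approx(vals[vis].mean())

    def test_symptom_correlations_bonferroni(self, rng):
        delta = rng.normal(size=(24, 7))
        scores = delta[:, 1] * 2.0 + rng.normal(size=24) * 0.1
        tab = pc.symptom_correlations(delta, scores, m_tests=7)
        row = tab[tab.network == "somatomotor"].iloc[0]
        assert row.p_bonferroni == pytest.approx(min(1.0, 7 * row.p))
        assert row.r > 0.9 and row.p_bonferroni < 0.05

    def test_symptom_correlations_null(self):
        n_sig = 0
        for seed in range(10):
            r = np.random.default_rng(100 + seed)
            tab = pc.symptom_correlations(r.normal(size=(24, 7)), r.normal(size=24))
            n_sig += (tab.p_bonferroni < 0.05).any()
        assert n_sig <= 1


def test_somatomotor_symptom_association_is_selective():
    """Scores coupled to the somatomotor effect single out that network.

    The drug effect is confined to somatomotor with independent subject
    effects.  Somatomotor must carry the unique significant *positive*
    symptom correlation and the largest |r|.  Other networks pick up
    small negative leak correlations through GBC's sum constraint (any
    concentrated coupling gain is redistributed across the remaining
    pairs), so they are not required to be exactly null.
    """
    g = 300
    sp = pc.make_space(g, 7, 10)
    delta = {n: 0.0 for n in pc.NETWORKS}
    delta["somatomotor"] = 0.3
    hits_somato, top_rank, pos_other = 0, 0, 0
    n_seeds = 4
    for seed in range(n_seeds):
        cfg = pc.GeneratorConfig(
            n_subjects=20, n_gray=g, T=180, n_parcels=10, seed=200 + seed,
            rho_hh=0.0, behav_noise_sd=2.0,
            loading_delta={"Pla": {n: 0.0 for n in pc.NETWORKS},
                           "LSD": delta,
                           "KetLSD": {n: 0.0 for n in pc.NETWORKS}},
            gs_topo_delta={"Pla": 0.0, "LSD": 0.0, "KetLSD": 0.0},
        )
        design, runs, truth = pc.simulate_cohort(sp, cfg)
        maps = {}
        for rid, run in runs.items():
            if run.session != 2 or run.condition not in ("LSD", "Pla"):
                continue
            prep = pc.preprocess_run(run, sp, gsr=True)
            maps[(run.subject, run.condition)] = pc.gbc_map(prep.censored).values
        dnet = np.array(
            [
                pc.network_means(maps[(s, "LSD")] - maps[(s, "Pla")], sp)
                for s in truth.subjects
            ]
        )
        scores = truth.behav_scores[:, list(pc.CONDITIONS).index("LSD"), 1]
        tab = pc.symptom_correlations(dnet, scores, m_tests=7)
        somato = tab[tab.network == "somatomotor"].iloc[0]
        other = tab[tab.network != "somatomotor"]
        hits_somato += (somato.p_bonferroni < 0.05) and (somato.r > 0)
        top_rank += somato.r == tab.r.max()
        pos_other += ((other.p_bonferroni < 0.05) & (other.r > 0)).any()
    assert hits_somato >= 3
    assert top_rank == n_seeds
    assert pos_other <= 1
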