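"""Full study orchestration: cohort -> preprocessing -> maps -> inference -> report.

``run_study`` executes the complete analysis battery on a cohort
container (or an in-memory synthetic cohort): preprocessing with and
without global signal regression, per-run GBC / thalamic-seed /
GS-beta / variance maps, permutation contrasts, hyper-hypo coupling
analyses, the 4-way conjunction analysis, network summaries, behavioral
correlations and gene-expression matching.  Every stochastic step draws
from a named substream of the master seed, and the report tables are
byte-reproducible for a fixed configuration.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import CONDITIONS, NETWORKS, ScalarMap
from . import io as pio
from .synth import GeneratorConfig, make_space, simulate_cohort, simulate_expression
from .preprocess import preprocess_run
from .connectivity import ConnectivityOptions, gbc_map, gs_beta_map, seed_fc_map, variance_summaries
from .inference import (
    ContrastResult,
    change_score_correlation,
    lsd_vs_rest,
    main_effect_contrast,
    mask_means,
    network_means,
    paired_contrast,
    spatial_correlation,
    symptom_correlations,
    top_bottom_conjunction,
)
from .genes import compare_dependent_correlations, gene_map_correlations, parcellate_map

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Configuration of a full study run."""

    out_dir: str = "report"
    cohort_path: str | None = None  # load this container instead of simulating
    gsr: str = "both"  # both / on / off
    n_perm: int = 1000
    tfce_h: float = 2.0
    tfce_e: float = 0.5
    conjunction_fraction: float = 0.10
    alpha: float = 0.05
    seed: int = 0
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides
    n_genes: int = 200
    gene_r_target: float = 0.5
    gene_r_anti: float = -0.5

    def __post_init__(self) -> None:
        if self.gsr not in ("both", "on", "off"):
            raise ValueError("gsr must be 'both', 'on' or 'off'")


def _condition_stack(maps: dict, subjects, condition: str, g: int) -> np.ndarray:
    """n_subjects x G session-averaged map stack for one condition."""
    out = np.empty((len(subjects), g))
    for i, s in enumerate(subjects):
        out[i] = 0.5 * (maps[(s, condition, 1)] + maps[(s, condition, 2)])
    return out


def _session_stack(maps, subjects, condition, session, g):
    out = np.empty((len(subjects), g))
    for i, s in enumerate(subjects):
        out[i] = maps[(s, condition, session)]
    return out


def run_study(config: PipelineConfig):
    """Execute the full analysis battery; returns the report as a dict.

    Writes TSV tables, a map container and a manifest JSON under
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "sections": {},
        "timing_s": {},
    }
    t_start = time.time()
    ss = np.random.SeedSequence(config.seed)
    seed_cohort, seed_contrast, seed_genes = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))

    # ---------------------------------------------------------- cohort
    stage_t = time.time()
    truth_arrays = None
    expression = None
    if config.cohort_path is not None:
        space, design, runs = pio.load_cohort(config.cohort_path)
        try:
            truth_arrays = pio.load_truth(config.cohort_path)
        except Exception:
            truth_arrays = None
        try:
            expression = pio.load_expression(config.cohort_path)
        except Exception:
            expression = None
        gen_cfg = None
    else:
        gen_cfg = GeneratorConfig(seed=seed_cohort, **config.generator)
        space = make_space(
            gen_cfg.n_gray, gen_cfg.n_networks, gen_cfg.n_parcels, layout=gen_cfg.layout
        )
        design, runs, truth = simulate_cohort(space, gen_cfg)
        truth_arrays = truth.as_arrays()
    g = space.n_gray
    manifest["timing_s"]["cohort"] = round(time.time() - stage_t, 3)

    gsr_modes = {"both": [True, False], "on": [True], "off": [False]}[config.gsr]
    report: dict = {"manifest": manifest}

    # ---------------------------------------------- preprocessing + maps
    stage_t = time.time()
    scrub_rows = []
    maps: dict = {gsr: {k: {} for k in ("gbc_r", "gbc_cov", "seed_r", "seed_cov")} for gsr in gsr_modes}
    gsbeta: dict = {}
    var_rows = []
    thal = space.thalamus_mask
    opts_r = ConnectivityOptions(method="correlation")
    opts_cov = ConnectivityOptions(method="covariance")
    excluded = dict(design.excluded)
    for rid in sorted(runs):
        run = runs[rid]
        key = (run.subject, run.condition, run.session)
        prep_nogsr = preprocess_run(run, space, gsr=False)
        if prep_nogsr.mask.subject_excluded:
            excluded[run.subject] = f"run {rid}: >50% frames flagged"
        scrub_rows.append(
            {
                "subject": run.subject,
                "condition": run.condition,
                "session": run.session,
                "fraction_flagged": prep_nogsr.mask.fraction_flagged,
                "excluded": prep_nogsr.mask.subject_excluded,
            }
        )
        for gsr in gsr_modes:
            prep = preprocess_run(run, space, gsr=True) if gsr else prep_nogsr
            maps[gsr]["gbc_r"][key] = gbc_map(prep.censored, opts_r).values
            maps[gsr]["gbc_cov"][key] = gbc_map(prep.censored, opts_cov).values
            maps[gsr]["seed_r"][key] = seed_fc_map(prep.censored, thal, opts_r).values
            maps[gsr]["seed_cov"][key] = seed_fc_map(prep.censored, thal, opts_cov).values
        gsbeta[key] = gs_beta_map(prep_nogsr.censored, space.gray_mask).values
        local_var, gs_var = variance_summaries(prep_nogsr.censored, space.gray_mask)
        var_rows.append(
            {
                "subject": run.subject,
                "condition": run.condition,
                "session": run.session,
                "mean_local_var": float(np.nanmean(local_var.values)),
                "gs_variance": gs_var,
            }
        )
    scrub_df = pd.DataFrame(scrub_rows)
    _write(scrub_df, out / "scrub_report.tsv")
    _write(pd.DataFrame(var_rows), out / "variance_summaries.tsv")
    manifest["sections"]["preprocess"] = "scrub_report.tsv"
    manifest["sections"]["variance"] = "variance_summaries.tsv"
    manifest["timing_s"]["maps"] = round(time.time() - stage_t, 3)

    subjects = [s for s in design.subjects if s not in excluded]
    edges = space.edges

    # -------------------------------------------------------- contrasts
    stage_t = time.time()
    contrast_rows = []
    contrasts: dict = {}
    rng_contrast = np.random.SeedSequence(seed_contrast)
    child_seeds = iter(
        int(s.generate_state(1)[0] % 2**31) for s in rng_contrast.spawn(64)
    )
    for gsr in gsr_modes:
        tag = "gsr" if gsr else "nogsr"
        stacks = {
            c: _condition_stack(maps[gsr]["gbc_r"], subjects, c, g) for c in CONDITIONS
        }
        me = main_effect_contrast(
            np.stack([stacks[c] for c in CONDITIONS], axis=1),
            edges,
            n_perm=config.n_perm,
            H=config.tfce_h,
            E=config.tfce_e,
            alpha=config.alpha,
            seed=next(child_seeds),
        )
        contrasts[("main_effect", tag)] = me
        pairs = [
            ("lsd_vs_rest", *lsd_vs_rest(stacks)),
            ("lsd_vs_pla", stacks["LSD"], stacks["Pla"]),
            ("lsd_vs_ketlsd", stacks["LSD"], stacks["KetLSD"]),
            ("ketlsd_vs_pla", stacks["KetLSD"], stacks["Pla"]),
        ]
        for name, a, b in pairs:
            res = paired_contrast(
                a,
                b,
                edges,
                n_perm=config.n_perm,
                H=config.tfce_h,
                E=config.tfce_e,
                alpha=config.alpha,
                seed=next(child_seeds),
            )
            contrasts[(name, tag)] = res
        for condition in CONDITIONS:
            s1 = _session_stack(maps[gsr]["gbc_r"], subjects, condition, 1, g)
            s2 = _session_stack(maps[gsr]["gbc_r"], subjects, condition, 2, g)
            res = paired_contrast(
                s1, s2, edges, n_perm=config.n_perm, H=config.tfce_h,
                E=config.tfce_e, alpha=config.alpha, seed=next(child_seeds),
            )
            contrasts[(f"session1_vs_2_{condition}", tag)] = res
        for (name, t_), res in list(contrasts.items()):
            if t_ != tag:
                continue
            contrast_rows.append(
                {
                    "contrast": name,
                    "gsr": tag,
                    "max_abs_z": float(np.abs(res.z_map.values).max()),
                    "n_sig_pos": int(res.sig_mask_pos.sum()),
                    "n_sig_neg": int(res.sig_mask_neg.sum()),
                    "min_fwe_p": float(res.fwe_p.values.min()),
                    "n_perm": res.n_perm,
                    "seed": res.seed,
                }
            )
    _write(pd.DataFrame(contrast_rows), out / "contrasts.tsv")
    manifest["sections"]["contrasts"] = "contrasts.tsv"
    manifest["timing_s"]["contrasts"] = round(time.time() - stage_t, 3)

    # ------------------------------------- hyper/hypo coupling analyses
    stage_t = time.time()
    if True in gsr_modes:
        ref = contrasts[("lsd_vs_rest", "gsr")]
        hyper = ref.sig_mask_pos
        hypo = ref.sig_mask_neg
        if not hyper.any() or not hypo.any():
            z = ref.z_map.values
            hyper = z >= np.quantile(z, 0.9)
            hypo = z <= np.quantile(z, 0.1)
            manifest["sections"]["hyper_hypo_masks"] = (
                "no significant grayordinates; fell back to z-map deciles"
            )
        stacks = {
            c: _condition_stack(maps[True]["gbc_r"], subjects, c, g) for c in CONDITIONS
        }
        rows = []
        for c in CONDITIONS:
            rows.append(
                {
                    "condition": c,
                    "mean_fz_hyper": float(mask_means(stacks[c], hyper).mean()),
                    "mean_fz_hypo": float(mask_means(stacks[c], hypo).mean()),
                }
            )
        _write(pd.DataFrame(rows), out / "hyper_hypo_means.tsv")
        d_hyper = mask_means(stacks["LSD"], hyper) - mask_means(stacks["Pla"], hyper)
        d_hypo = mask_means(stacks["LSD"], hypo) - mask_means(stacks["Pla"], hypo)
        r_hh, p_hh = change_score_correlation(d_hyper, d_hypo)
        _write(
            pd.DataFrame([{"r": r_hh, "p": p_hh, "n": len(subjects)}]),
            out / "hyper_hypo_change_correlation.tsv",
        )
        manifest["sections"]["hyper_hypo"] = "hyper_hypo_means.tsv"
        report["hyper_hypo_change_r"] = r_hh
    else:
        manifest["sections"]["hyper_hypo"] = "skipped: requires GSR maps (gsr=off)"

    # ------------------------------------------------ GS-beta analyses
    beta_stacks = {c: _condition_stack(gsbeta, subjects, c, g) for c in CONDITIONS}
    gs_res = paired_contrast(
        beta_stacks["LSD"], beta_stacks["Pla"], edges,
        n_perm=config.n_perm, H=config.tfce_h, E=config.tfce_e,
        alpha=config.alpha, seed=next(child_seeds),
    )
    contrasts[("gsbeta_lsd_vs_pla", "nogs")] = gs_res
    rows = [{"contrast": "gsbeta_lsd_vs_pla", "max_abs_z": float(np.abs(gs_res.z_map.values).max()), "n_sig": gs_res.n_significant}]
    gs_corr_rows = []
    for gsr in gsr_modes:
        tag = "gsr" if gsr else "nogsr"
        r = spatial_correlation(gs_res.z_map, contrasts[("lsd_vs_pla", tag)].z_map)
        gs_corr_rows.append({"gbc_contrast": f"lsd_vs_pla_{tag}", "r_with_gsbeta_contrast": r})
        report[f"gsbeta_vs_gbc_{tag}_r"] = r
    _write(pd.DataFrame(rows), out / "gsbeta_contrast.tsv")
    _write(pd.DataFrame(gs_corr_rows), out / "gsbeta_gbc_correlations.tsv")
    manifest["sections"]["gsbeta"] = "gsbeta_contrast.tsv"
    manifest["timing_s"]["gsbeta"] = round(time.time() - stage_t, 3)

    # ------------------------------------------------------ conjunction
    stage_t = time.time()
    if len(gsr_modes) == 2:
        conj_rows = []
        # conjunction mask from baseline thalamic-seed maps (the family
        # robust to GS transforms), ranked over cortex only; extraction
        # then runs across both the seed and GBC families
        four = [
            _condition_stack(maps[gsr][f"seed_{m}"], subjects, "Pla", g).mean(axis=0)
            for gsr in (True, False)
            for m in ("r", "cov")
        ]
        conj = top_bottom_conjunction(
            four, fraction=config.conjunction_fraction, eligible=space.cortex_mask
        )
        if not conj.top.any() or not conj.bottom.any():
            conj_rows.append({"family": "seed", "note": "empty conjunction"})
        for family in ("seed", "gbc"):
            if not conj.top.any() or not conj.bottom.any():
                break
            for gsr in gsr_modes:
                tag = "gsr" if gsr else "nogsr"
                for m in ("r", "cov"):
                    stacks_m = {
                        c: _condition_stack(maps[gsr][f"{family}_{m}"], subjects, c, g)
                        for c in ("LSD", "Pla")
                    }
                    d_top = mask_means(stacks_m["LSD"], conj.top) - mask_means(
                        stacks_m["Pla"], conj.top
                    )
                    d_bot = mask_means(stacks_m["LSD"], conj.bottom) - mask_means(
                        stacks_m["Pla"], conj.bottom
                    )
                    conj_rows.append(
                        {
                            "family": family,
                            "gsr": tag,
                            "method": m,
                            "n_top": int(conj.top.sum()),
                            "n_bottom": int(conj.bottom.sum()),
                            "mean_delta_top": float(d_top.mean()),
                            "mean_delta_bottom": float(d_bot.mean()),
                            "r_top_bottom": float(
                                change_score_correlation(d_top, d_bot)[0]
                            ),
                        }
                    )
        conj_df = pd.DataFrame(conj_rows)
        _write(conj_df, out / "conjunction.tsv")
        manifest["sections"]["conjunction"] = "conjunction.tsv"
        report["conjunction"] = conj_df
    else:
        manifest["sections"]["conjunction"] = (
            "skipped: conjunction needs both GSR and no-GSR maps"
        )
    manifest["timing_s"]["conjunction"] = round(time.time() - stage_t, 3)

    # -------------------------------------------------- network means
    stage_t = time.time()
    net_rows = []
    for gsr in gsr_modes:
        tag = "gsr" if gsr else "nogsr"
        for c in CONDITIONS:
            for session in (1, 2):
                stack = _session_stack(maps[gsr]["gbc_r"], subjects, c, session, g)
                nm = network_means(ScalarMap(stack.mean(axis=0), kind="z"), space)
                row = {"gsr": tag, "condition": c, "session": session}
                row.update({net: nm[i] for i, net in enumerate(NETWORKS)})
                net_rows.append(row)
    _write(pd.DataFrame(net_rows), out / "network_means.tsv")
    manifest["sections"]["network_means"] = "network_means.tsv"

    # ------------------------------------------- symptom correlations
    if truth_arrays is not None and "behav_scores" in truth_arrays and True in gsr_modes:
        behav = truth_arrays["behav_scores"]
        scores = behav[: len(subjects), list(CONDITIONS).index("LSD"), 1]  # 250 min
        delta = np.empty((len(subjects), len(NETWORKS)))
        for i, s in enumerate(subjects):
            m_lsd = maps[True]["gbc_r"][(s, "LSD", 2)]
            m_pla = maps[True]["gbc_r"][(s, "Pla", 2)]
            delta[i] = network_means(ScalarMap(m_lsd - m_pla, kind="z"), space)
        sym = symptom_correlations(delta, scores, m_tests=len(NETWORKS))
        _write(sym, out / "symptom_correlations.tsv")
        manifest["sections"]["symptoms"] = "symptom_correlations.tsv"
        report["symptom_correlations"] = sym
    else:
        manifest["sections"]["symptoms"] = "skipped: no behavioral scores available"

    # --------------------------------------------------- gene matching
    if expression is None and config.n_genes >= 3:
        ref_tag = "gsr" if True in gsr_modes else "nogsr"
        ref_parcel = parcellate_map(contrasts[("lsd_vs_rest", ref_tag)].z_map, space)
        expression = simulate_expression(
            space,
            ref_parcel,
            n_genes=config.n_genes,
            r_target=config.gene_r_target,
            r_anti=config.gene_r_anti,
            seed=seed_genes,
        )
    if expression is not None:
        gene_rows = []
        match = {}
        for gsr in gsr_modes:
            tag = "gsr" if gsr else "nogsr"
            pm = parcellate_map(contrasts[("lsd_vs_rest", tag)].z_map, space)
            res = gene_map_correlations(
                pm, expression, targets=[expression.genes[0], expression.genes[1]]
            )
            match[tag] = res
            for sym in (expression.genes[0], expression.genes[1]):
                i = expression.genes.index(sym)
                gene_rows.append(
                    {
                        "gsr": tag,
                        "gene": sym,
                        "r": float(res.r[i]),
                        "percentile": float(res.targets[sym]),
                    }
                )
        if len(gsr_modes) == 2:
            pm_a = parcellate_map(contrasts[("lsd_vs_rest", "gsr")].z_map, space)
            pm_b = parcellate_map(contrasts[("lsd_vs_rest", "nogsr")].z_map, space)
            ok = np.isfinite(pm_a) & np.isfinite(pm_b)
            r_ab = float(np.corrcoef(pm_a[ok], pm_b[ok])[0, 1])
            for sym in (expression.genes[0], expression.genes[1]):
                i = expression.genes.index(sym)
                z, p = compare_dependent_correlations(
                    float(match["gsr"].r[i]), float(match["nogsr"].r[i]), r_ab, int(ok.sum())
                )
                gene_rows.append(
                    {"gsr": "gsr_vs_nogsr", "gene": sym, "steiger_z": z, "steiger_p": p}
                )
        _write(pd.DataFrame(gene_rows), out / "gene_match.tsv")
        manifest["sections"]["genes"] = "gene_match.tsv"
        report["gene_match"] = match
    else:
        manifest["sections"]["genes"] = "skipped: no expression matrix"
    manifest["timing_s"]["total"] = round(time.time() - t_start, 3)

    # timings vary between runs; keep them out of the deterministic manifest
    timing = manifest.pop("timing_s")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "timing.log").write_text(json.dumps(timing, indent=2))
    report["contrasts"] = contrasts
    report["space"] = space
    report["excluded"] = excluded
    return report


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
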