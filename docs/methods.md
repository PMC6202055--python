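# Methods

## Data model

Analyses run on a geometry-free brain model: `G` grayordinates carrying
a structure label (left/right cortex, thalamus, amygdala, other
subcortex, ventricle/white-matter proxies), a functional-network label
(seven canonical networks: visual and somatomotor as the sensory group;
dorsal-attention, ventral-attention, limbic, frontoparietal and default
as the associative group), a parcel index assigned per hemisphere, and
an adjacency graph (ring by default, 2-D grid optional) that defines
connected components for cluster enhancement. "Gray matter" means
cortex plus labeled subcortex; the ventricle/WM proxies never enter the
global signal. Indexing is 0-based everywhere, including files, and
loaders verify the index column is `0..G-1` so maps can never be
silently reordered.

## Synthetic cohort generator

Each run (subject x condition x session) is

```
bold_k(t) = baseline + w_k[cond] * g(t) + L_k[cond, subj] * eta_net(k)(t)
            + spike_k(t) + eps_k(t)
```

* `g(t)` — global fluctuation: unit-variance AR(1) (phi = 0.4)
  low-passed below 0.1 Hz, emulating a respiratory-like slow artifact;
  its amplitude (`gs_amplitude`, default 1.0) is identical across
  conditions, so mean GS variance does not differ by condition.
* `w_k` — GS topography: 1.0 over gray matter (0.2 on proxies) under
  placebo. Under drug, a mean-centered shift of amplitude
  `gs_topo_delta` (default 0.4) raises the associative and lowers the
  sensory contribution. Centering keeps the GS itself (and its
  variance) condition-invariant; only its spatial composition moves.
* `eta_c(t)` — one unit-variance AR(1) latent per network (phi = 0.3).
  Cortical grayordinates load on their own network's latent
  (`loading_base`: sensory 0.50, associative 0.65–0.85 — associative
  hubs sit at the top of the baseline connectivity distribution).
  Subcortex loads at 0.6 of the cortical value, distributed round-robin
  across networks; the thalamus is predominantly associative (loading
  scale 1.5, one tenth of its grayordinates assigned to sensory
  latents), giving the strong thalamo-associative / weak
  thalamo-sensory baseline the conjunction analysis presupposes.
* Condition effect — `loading_delta` (drug: +0.25 sensory, −0.15 to
  −0.25 associative; antagonist+drug: `ket_fraction` x drug, default 0,
  i.e. full blockade). Crucially, coupling perturbations are
  **variance-preserving**: per-grayordinate noise variance compensates
  the loading change (`sigma_k^2 = noise_sd^2 + L_base^2 − L^2`,
  floored at 4% of `noise_sd^2`), so the drug shifts coupling
  structure, not local signal amplitude. This matters because in-sample
  GSR pins each residual row-sum of the covariance matrix to −var_k:
  an uncompensated loading increase leaks into all cross-pairs and
  *inverts* the post-GSR contrast. With variance preserved, the
  within-network correlation changes (amplified by the convexity of the
  Fisher transform) carry the contrast, and the generator also
  reproduces the empirical observation that local variance is
  essentially condition-invariant. The GS-topography shift is *not*
  compensated — it is exactly the kind of global artifact GSR is meant
  to absorb, and absorbing it changes residual variance slightly, which
  is what makes the pre-GSR contrast track the topography shift.
* Subject effects — a bivariate normal (mean 1, sd 0.3) yields
  multiplicative hyper (sensory) and hypo (associative) effect sizes
  whose *signed* change contributions correlate at `rho_hh` (default
  −0.9): subjects with the largest sensory gain show the largest
  associative loss. Internally the draw uses correlation `−rho_hh` and
  the associative branch is sign-flipped by its negative delta.
* Artifacts — with probability `motion_spike_rate` (0.02/frame) a
  transient single-frame head excursion (0.6–1.5 mm) co-occurs with a
  brain-wide intensity jump (6 x noise sd), so both censoring criteria
  fire. Baseline drift is a slow random walk (0.01 mm / 1e-4 rad
  steps). Ventricle/WM channels are unit noise plus 0.4 x `g(t)`.
* Behavior — under drug, scores follow
  `behav_base + behav_coupling * (h_s − 1)` (defaults 30 and 25, as a
  percentage of scale maximum) decaying over the three assessment times
  (x1.0 / x0.85 / x0.6) plus noise (sd 5); under placebo and under
  antagonist pre-treatment scores are near zero — the antagonist blocks
  the subjective effects entirely.

All randomness flows from a single seed through named `SeedSequence`
substreams; identical configs give bit-identical cohorts.

Synthetic expression matrices place one gene at a chosen correlation
`r_target` to a reference parcel map (constructed exactly via an
orthogonalized mixture), one at `r_anti`, and the rest spatially
random; rows are z-scored across parcels (population sd).

### What the generator does not emulate

Hemodynamic response functions and neurovascular coupling changes,
scanner noise spectra (1/f, thermal), spatial autocorrelation within
networks beyond block structure, real anatomical geometry, and
session-order or habituation effects. Passing tests demonstrate that
the *analysis machinery* recovers what was injected under this model
class — not that the drug effects in real data are of this form.

## Preprocessing

Fixed stage order: (1) high-pass filter, (2) scrub-mask computation on
the raw intensities, (3) nuisance regression on all frames, (4) frame
censoring by row deletion. An alternative censor-before-regression
ordering is exposed via a flag.

* **High-pass** (> 0.008 Hz) by projecting out an intercept plus the
  DCT-II regressors with frequencies in (0, cutoff] — exactly linear,
  composable with the GLM, no IIR edge transients. Measured response at
  T=240, TR=2.5 s: gain < 0.05 at 0.002 Hz, > 0.90 at 0.032 Hz.
* **Nuisance design**: intercept; ventricle, white matter, six motion
  parameters, optionally the global signal (mean over gray matter of
  the filtered data by default; a flag switches to pre-filter); plus
  the first temporal difference of every non-intercept column (first
  element 0). 17 columns without GSR, 19 with. Zero-variance columns
  (relative tolerance 1e-12) are dropped with a warning. Note that a
  channel whose derivative is constant is itself constant, so such
  drops always come in pairs.
* **Scrubbing**: criterion 1 — framewise displacement, the sum over the
  six parameters of |frame-to-frame change| with rotations converted to
  arc length on a 50 mm sphere, above 0.5 mm; criterion 2 — RMS
  frame-difference intensity across grayordinates divided by mean
  intensity, above 1.6 x its within-run median. The union is dilated
  one frame back and two forward. Frame 0 has no defined displacement
  and can only be flagged by dilation. Runs with more than 50% flagged
  frames mark the subject for exclusion. Censoring requires at least 8
  surviving frames.
* **QA**: per-grayordinate temporal SNR (mean/sd) and percent scrubbed,
  with a helper correlating QA metrics against mean Fz across subjects.

GSR "idempotence" holds in the regressor sense: re-regressing the
original GS from the residuals gives betas < 1e-8 (exact OLS
orthogonality). Re-deriving a *new* GS from the residuals is not a null
operation for finite G (the mean of any set of columns correlates ~1
with each column's own contribution) and is not claimed.

## Connectivity maps

* **GBC** — mean over all other grayordinates of the Fisher-z
  correlation (r clipped at 1−1e-7 before atanh so duplicated series
  stay finite) or of the unbiased covariance (denominator T'−1;
  "non-normalized" means not variance-normalized, i.e. not a
  correlation). Computed in column blocks so the G x G matrix is never
  materialized; blocked and dense paths agree to 1e-10. Zero-variance
  grayordinates are masked and excluded from every mean. Self-pairs are
  excluded (denominator G−1).
* **Seed FC** — mean time series over a structure mask (bilateral
  thalamus in the study battery) correlated/covaried with every
  grayordinate.
* **GS-beta map** — per-grayordinate OLS weight of (nuisance-regressed,
  non-GSR) BOLD on [intercept, GS]. These betas measure each
  grayordinate's contribution to the global signal; they are not
  connectivity values.
* **Variance summaries** — per-grayordinate temporal variance and the
  variance of the mean gray-matter time series.

## Group inference

* **Paired contrast** — one-sample t on within-subject difference maps,
  mapped through the t CDF to z (clipped at ±40). Null: random whole-map
  sign flips (vectorized via the sign-invariance of sum-of-squares).
* **Condition main effect** — per-grayordinate repeated-measures F with
  subject blocking; null permutes condition labels within subject.
  Degenerate columns (identical condition sets) report F = 0 via a
  relative tolerance on the sums of squares.
* **TFCE** — threshold step `dh = max(|stat|)/100` (adaptive per map,
  identical rule for observed and permuted maps), thresholds
  `h = dh, 2dh, …`, active set `value >= h`, enhancement
  `sum e(h)^0.5 h^2 dh` per branch with the negative branch computed on
  the negated map and re-negated. H = 2, E = 0.5 follow the published
  volume-mode defaults of the reference permutation tool; both are
  configurable. The kernel is a numba-compiled per-threshold union-find;
  tests verify exact agreement (1e-9) with a brute-force
  connected-components oracle.
* **FWE** — p per grayordinate from the permutation distribution of the
  maximum |TFCE|, `p = (1 + #{max_null >= |tfce|}) / (n_perm + 1)`;
  two-sided by taking the max over both signs. Calibration is verified:
  family-wise error 0.01–0.10 at alpha = 0.05 over 200 null datasets,
  max-statistic p-values uniform.
* **Drug vs rest** — the "drug vs (blocked + placebo)" contrast is the
  paired contrast of drug maps against the within-subject mean of the
  two control conditions.
* **Conjunction** — per map, the top/bottom `floor(f * G_eligible)`
  ranks (stable sort, ties to the lower index), intersected across the
  four variants {correlation, covariance} x {GSR, no-GSR} of the
  baseline thalamic-seed maps, ranked over cortex only (the seed
  structure itself is excluded). The mask then extracts per-subject
  means from both the seed-FC and GBC families. Post-GSR, the
  conjunction-top (thalamo-associative) mean decreases and the
  conjunction-bottom (thalamo-sensory) mean increases under drug;
  GBC-covariance post-GSR is pinned near −var/G by the GSR row-sum
  constraint and is reported but not directional.
* **Summaries** — mask means, per-network means over the seven labels,
  change-score Pearson correlations, and per-network symptom
  correlations with Bonferroni adjustment (`min(1, m·p)`, m = 7 for the
  network family, m = 5 for the five short-scale breakdown).

A note on specificity: because GBC sums over all pairs, a coupling gain
concentrated in one network is redistributed (with opposite sign)
across the remaining pairs under GSR. Symptom correlations therefore
show the driving network as the unique significant *positive*
association, while other networks can carry small negative leak
correlations — exact nullity elsewhere is not attainable with this
metric and is not asserted.

## Transcriptomic matching

Contrast z-maps are averaged within left-hemisphere cortical parcels
and correlated (Pearson) with each gene's z-scored parcel profile;
masked parcels drop pairwise. The percentile of a target gene is
`100 · #{genes with r < r_target} / (n_genes − 1)`. Reported p-values
use naive parcel-count degrees of freedom — spatial autocorrelation
inflates them, so an optional parcel-permutation p-value is provided
(off by default). Dependent correlations sharing the gene map (GSR vs
no-GSR contrasts) are compared with Steiger's (1980) Z̄* on
Fisher-transformed correlations. Parcels map to networks by the
majority label of their member grayordinates.

## Pipeline and reproducibility

`run_study` executes: preprocessing (both GSR modes) → per-run GBC
(r, cov), thalamic seed FC (r, cov), GS-beta and variance maps →
permutation contrasts (main effect; drug vs rest; all pairwise; session
1 vs 2 within condition) → hyper/hypo mask means and change-score
correlation → conjunction → network means → symptom correlations →
gene matching. Every stochastic stage draws a named substream of the
master seed; report tables are byte-identical across runs with the same
config. Sections that cannot run under the chosen configuration (e.g.
conjunction with only one GSR mode) are recorded as skipped, with the
reason, in the manifest. Timing goes to a separate log so the manifest
stays deterministic.

## Problem sizes

Test and acceptance runs use desk-scale cohorts chosen to keep every
check minutes-scale while leaving clear statistical margins: G = 120–
1000 grayordinates, 6–24 subjects (100 for the subject-coupling
recovery, matching the precision the ±[−0.97, −0.75] band requires),
T = 120–240 frames, 100–1000 permutations, 100–200 null datasets for
calibration. The generator's condition parameters (deltas, topography
shift, rho_hh = −0.9) are the study defaults described above and are
identical across all tests.

## Known limitations

* The ring/grid adjacency gives 1-D/2-D cluster geometry; TFCE
  parameter defaults are the volume-mode published values, and no
  surface-mode (E = 1) calibration is claimed.
* Exchangeability is limited to sign flips and within-subject condition
  relabelings; no variance smoothing, exchangeability blocks, or
  cluster-extent alternatives.
* Expression matching is parcel-level only; no dense interpolation, no
  donor-level normalization, and the percentile depends on whatever
  gene set is supplied.
* The generator's latents are network-homogeneous blocks; real
  parcel-level heterogeneity, distance-dependent correlations, and
  hemodynamics are out of scope.
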