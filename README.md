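# qppdyn

Quasi-periodic pattern (QPP) analysis of single-slice resting-state BOLD
image series: detection of recurring spatiotemporal patterns by iterated
sliding template correlation, cross-group comparison by projection,
voxel-wise regression of a pattern's contribution from the data, the
resulting functional-connectivity (FC) changes, and elastic-net
classification of subjects from QPP-derived measures.

## Who this is for

Infra-slow BOLD activity is not stationary: stereotyped spatiotemporal
patterns — a wave of default-mode-network (DMN) activation with
task-positive-network (TPN) de-activation, or a global-signal-like wave —
recur quasi-periodically and carry a large share of what static FC
measures summarise. `qppdyn` implements the full analysis chain used to
study such patterns in two-group (e.g. wild-type vs transgenic mouse)
rsfMRI designs, together with a synthetic cohort generator that plants
known patterns so every stage can be validated against ground truth.

## The method

**Detection.** For a window of `W` frames, a template `T ∈ R^{L×W}`
(`L` in-mask voxels) is seeded from `W` consecutive frames at a random
start of the concatenated group series `X ∈ R^{L×T_total}`. The sliding
template correlation (STC) is

    STC(t) = corr(vec(T), vec(X[:, t:t+W)))

for every window start `t` that stays inside one subject's scan. Strict
local maxima of the STC above θ = 0.2 mark pattern occurrences; the image
chunks at those peaks are averaged into an updated template, and the loop
repeats until the STC stabilises (correlation ≥ 0.9999 between successive
iterations, twice). The procedure runs from `N` random starts (500 for a
full run) and the converged record with the highest sum of peak
correlations is selected as the group's QPP.

**Projection, rates, matching.** A fixed template slid over another
group's series gives the projection STC (pSTC), so occurrence rates
(peaks/minute, per subject) are comparable across groups; QPPs from the
two groups are matched by the cross-correlation of pSTC and STC traces,
with sign and lag recording phase-inverted or shifted correspondence.

**Regression and FC.** A QPP's image series is reconstructed by
convolving its template with its STC, and removed voxel-wise by ordinary
least squares. ROI-pair Pearson correlations are Fisher z-transformed
(zFC); DMN, TPN and DMN–TPN network averages before and after regression,
and their per-subject differences (ΔFC), quantify how much of each FC
measure the pattern carried.

**Classification.** 17 measures per subject (3 network FC values, 3 QPP
occurrence rates, 6 post-regression FC values, 5 ΔFC values) feed
elastic-net logistic regressions (each measure alone, and all jointly);
performance is the cross-validated ROC AUC over 10 repeats of stratified
10-fold CV, and models are compared by 2000-replicate stratified paired
bootstrap of the AUC difference with Bonferroni correction.

## Worked example

```python
from qppdyn import PipelineConfig, run_pipeline
from qppdyn.pipeline import recovery_summary

cfg = PipelineConfig.fast()          # 8+10 subjects, 10-min scans, 50 restarts
res = run_pipeline(cfg, seed=1)

summary = recovery_summary(res)
print(round(summary["QPP_WT"]["spatial_r"], 3),
      round(summary["QPP_WT"]["rate_median_rel_error"], 3))
# 0.953 0.038
print(res.rate_tests[["qpp", "mean_rate_wt", "mean_rate_tg"]].round(2))
#       qpp  mean_rate_wt  mean_rate_tg
# 0  QPP_WT          2.72          1.09
# 1  QPP_TG          0.54          1.89
# 2  QPP_GS          3.38          1.61
print(round(res.report.models["combined"]["mean_auc"], 2))
# 1.0
```

The first line says the wild-type group's 3 s QPP was recovered with
spatial correlation 0.95 to the planted template and its per-subject
occurrence rate with ~4% median error. The rate table shows the planted
group structure (the DMN-burst pattern and the global wave occur more
often in WT, the disrupted-DMN pattern more often in TG), and the
combined elastic-net model separates the groups perfectly on this cohort.

The same pipeline is scriptable from the shell:

```bash
qppdyn run-all --fast --seed 1 --out out/
qppdyn simulate --fast --seed 1 --out cohort/   # NIfTI + ground-truth JSON
```

## Layout

| module | contents |
|---|---|
| `qppdyn.core` | `BoldSeries` / `ConcatSeries` / `RoiAtlas`, NIfTI + JSON I/O |
| `qppdyn.simulate` | synthetic cohorts with planted patterns and ground truth |
| `qppdyn.preprocess` | trim, nuisance regression, smoothing, band-pass, detrend, unit variance, GSR |
| `qppdyn.detect` | STC, peak detection, template refinement, `QPPDetector` |
| `qppdyn.metrics` | contrast, selection, projection, rates, matching, window extension, significance maps |
| `qppdyn.regress` | STC-convolution regressors, voxel-wise removal, `QPPRegressor` |
| `qppdyn.fc` | Fisher-z FC matrices, seed maps, network averages, group statistics, BH-FDR |
| `qppdyn.classify` | measure table, AUC, elastic-net CV, bootstrap model comparison |
| `qppdyn.pipeline` | end-to-end orchestration; `qppdyn.cli` exposes it as subcommands |

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
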