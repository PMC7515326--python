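# plzcmeg

Permutation Lempel-Ziv complexity (PLZC) analysis of source-space
neurophysiological recordings, with cluster-based permutation statistics
and a synthetic cohort generator.

## What this package is for

Resting-state MEG/EEG studies increasingly quantify signal *irregularity*
rather than band power.  PLZC does this with symbolic dynamics: a series is
converted into ordinal patterns (the rank permutation of each window of
`m` samples at delay `tau`, `m! ` possible motifs), the motif stream is
parsed with the Lempel-Ziv-76 exhaustive-history scheme, and the word
count `c(n)` is normalized to a value in `[0, 1]`:

    PLZC = c(n) · log_{m!}(α) / α          (long-signal form, default)
    PLZC = c(n) · (log_{m!} c(n) + 1) / α  (general form)

with `α` the motif-sequence length.  Higher values mean more irregular
dynamics; the measure is exactly invariant under any strictly increasing
amplitude transform.

On top of the estimator, the package implements the full comparative
workflow used to map group differences on a source grid:

* zero-phase FIR band-pass filtering (Hamming windowed-sinc, order 2000 at
  1 kHz) into the canonical bands — broadband 2–45 Hz, theta 4–8, alpha
  8–12, low beta 12–20, high beta 20–30, gamma 30–45;
* per-subject, per-source epoch-averaged PLZC maps;
* cluster-based permutation tests (CBPT) with spatial contiguity and
  max-statistic correction, for between-group t contrasts and for Pearson
  correlations with anatomical covariates (e.g. ICV-normalized hippocampal
  volume), plus Cohen's d / cluster-average rho effect sizes;
* a synthetic cohort generator (two sex groups, band-structured signals,
  a contiguous band-confined irregularity effect planted in one group, and
  a volume–complexity coupling in that group only) that stands in for
  non-public recordings and makes every statistical claim testable.

The audience is methods-oriented: anyone who wants a tested, reproducible
reference implementation of PLZC + CBPT, or a sandbox for power and
calibration experiments on source-space complexity statistics.

## Worked example

```python
import plzcmeg as pm

# a cohort of 2 x 49 subjects with a high-beta irregularity increase
# planted in group F over a contiguous posterior patch of the grid
cohort = pm.simulate_cohort(pm.SimulationConfig(seed=7))

cfg = pm.AnalysisConfig(bands=("theta", "alpha", "low_beta", "high_beta", "gamma"),
                        n_perm=2000, correlation_regions=("hipp_right",), seed=7)
maps = pm.compute_band_maps(cohort, cfg)

for res in pm.run_group_analysis(cohort, cfg, maps=maps):
    best = max(res.clusters, key=lambda c: abs(c.cluster_stat), default=None)
    print(res.band, "p = %.4f" % best.p_value if best else "no cluster",
          "| d = %.3f" % best.effect_size if best else "")

corr = pm.run_correlation_analysis(cohort, cfg, "F", "hipp_right", maps=maps)
top = corr.clusters[0]
print("F ~ hipp_right: rho = %.3f, p = %.4f, %d sources"
      % (top.effect_size, top.p_value, top.n_sources))
```

Typical output (seed 7):

```
theta p = 0.6552 | d = 0.423
alpha p = 0.5657 | d = -0.436
low_beta p = 0.2779 | d = 0.507
high_beta p = 0.0020 | d = 1.093
gamma no cluster
F ~ hipp_right: rho = 0.360, p = 0.0070, 5 sources
```

The planted effect is recovered exactly where it was put: only the high
beta band shows a significant female-greater cluster (permutation
p = 0.0020; Cohen's d = 1.09 on per-subject cluster means, which averages
away per-source noise and therefore exceeds the per-source d of ~0.8),
the other bands stay at chance level, and within the female group the
high-beta complexity map correlates with the ICV-normalized
right-hippocampal volume (cluster average rho = 0.36 against a planted
population rho of 0.45, attenuated by epoch noise and regional jitter).

The same flow is available from the shell:

```bash
plzc-pipeline simulate --out cohort.h5 --covariates cov.tsv --seed 7
plzc-pipeline run --cohort cohort.h5 --covariates cov.tsv --out report/
```

which writes `group_clusters.tsv`, `correlation_clusters.tsv`,
`region_means.tsv`, per-source membership tables and `run_meta.json`
(fixed seeds make the report byte-reproducible).  `filter`, `complexity`
and `cbpt` subcommands expose the individual stages on the HDF5/TSV
layouts described in `docs/methods.md`.

## Layout

```
src/plzcmeg/
  complexity.py     ordinal symbolization, LZ76 counter, PLZC normalizations
  preprocessing.py  band table, FIR design, epoch filtering
  grid.py           homogeneous source grids, adjacency, region partitions
  synthetic.py      signal model and cohort generator
  cluster_stats.py  per-source statistics, clustering, permutation engine
  pipeline.py       study orchestration, maps, reports
  io.py             HDF5 cohort layout, TSV maps and covariates
  cli.py            plzc-pipeline command line
docs/methods.md     model, parameters, design choices, limitations
```
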