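# Methods

## Scope

`plzcmeg` implements the analysis stack of a resting-state source-space
complexity study: permutation Lempel-Ziv complexity (PLZC) of band-limited
multichannel time series, group comparison and brain-structure correlation
via cluster-based permutation tests (CBPT) on a homogeneous source grid,
and a synthetic cohort generator that stands in for non-public MEG
recordings.  Everything upstream of source-space epochs (acquisition,
artefact removal, head modelling, beamforming, MRI segmentation) is out of
scope; the generator emits source-space epochs directly.

## Permutation Lempel-Ziv complexity

A series `x` is symbolized into ordinal patterns: each window
`(x_t, x_{t+tau}, ..., x_{t+(m-1)tau})` maps to the lexicographic index of
its rank permutation, with ties broken by order of occurrence (stable
sort).  Defaults are `m = 5`, `tau = 1`, requiring `m! <= alpha`, where
`alpha` is the symbol-sequence length `n - (m-1)tau`.

The symbol stream is parsed with the LZ76 exhaustive-history scheme: each
word is the shortest prefix of the remainder that cannot be reproduced as a
substring of all preceding material (self-overlap allowed); the final word
counts even if reproducible.  With `c = c(n)` words, two normalizations are
offered:

* `eq2`: `PLZC = c (log_{m!} c + 1) / alpha`
* `eq3` (default): `PLZC = c log_{m!}(alpha) / alpha`, the long-signal
  simplification, appropriate here since epochs carry thousands of samples.

Normalizing by the symbol-sequence length `alpha` (not the raw sample
count) keeps the normalization internally consistent with `c(n)`; at
`n = 4000`, `m = 5` the difference is below 0.1%.

Properties relied on elsewhere: PLZC is exactly invariant under strictly
increasing amplitude transforms; values lie in `[0, 1 + eps]` with a
finite-length allowance `eps = 0.05` (the `eq3` bound can overshoot 1
slightly for short, highly irregular streams).  Note that for ordinal
streams the asymptotic ceiling of white noise is `log(m)/log(m!)`, not 1
(successive windows overlap in `m - 1` samples, so the conditional entropy
per symbol is at most `log m`); at `n = 4000`, `m = 5` white noise sits
near 0.52.  Non-finite samples are an error rather than silently dropped,
because dropped samples would distort motif windows.

Per-subject, per-source values are the arithmetic mean of per-epoch PLZC.
Averaging (rather than concatenating epochs) avoids spurious motifs at
epoch boundaries.

## Filtering

Band limits follow the canonical table: broadband 2-45 Hz, theta 4-8,
alpha 8-12, low beta 12-20, high beta 20-30, gamma 30-45.  The filter is a
linear-phase windowed-sinc band-pass (Hamming window) of order 2000 at
1000 Hz, scaled proportionally with the sampling rate (order 500 at
250 Hz); it is applied in a single pass with group-delay compensation, so
the output is zero-phase without squaring the magnitude response (which
forward-backward filtering would do).  The tap mean is subtracted after
design, nulling the DC gain exactly (~1e-17 instead of ~1e-4) while
perturbing other gains by less than 1e-4.

Epochs are filtered with two seconds of context per side: real adjacent
signal when the data carry it (the synthetic generator stores it), reflect
padding otherwise (logged).  Padding is removed after filtering.  Filtering
is per padded epoch, matching a pipeline in which clean trials are padded
and band-passed individually.  Because refiltering squares the response in
the transition bands, in-band idempotence is only approximate: the
response-derived RMS change for the high-beta design is 1.5%.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are desk-scale
(sizes chosen so the full test battery runs on one CPU in minutes) while
the cohort structure mirrors the emulated study: two sex groups of 49
subjects aged 65-80 (age-matched by construction: each F/M pair shares a
base age plus small jitter), a per-subject epoch count drawn from a
truncated normal (scaled default mean 12, SD 3, bounds [4, 80];
study-scale values 47.5 +/- 8.7 in [10, 80] remain configurable), 2-s
epochs at 250 Hz with 2 s of stored context per side (study scale: 4-s
epochs at 1000 Hz), and a 3x3x3 source grid with 10 mm spacing partitioned
into 4 contiguous regions (study scale: 1485 sources, 64 regions).
Adjacency is 6-connectivity (distance <= 1.1 x spacing), the minimal
unambiguous contiguity rule on a homogeneous lattice.

### Signal model

Each epoch is a Gaussian process synthesized in the frequency domain
(random phases on a deterministic amplitude profile, inverse rFFT, exact
standardization to zero mean and unit variance) from three components:

1. **Rhythmic base**: one Gaussian spectral peak per configured band,
   centered in the lower third of the band with width (hi-lo)/6 and a
   1/f-like weight hierarchy (amplitude 2/lo).  Narrow peaks on a quiet
   background are the regular end of the irregularity axis.
2. **Irregularity** `r in [0, 1]`: spectrally flat background whose total
   power is `r^2` times the base power and whose upper edge extends
   linearly from the top of the modeled range (45 Hz) toward 0.8 x Nyquist
   as `r -> 1` - emulating broadband desynchronization with progressively
   faster dynamics.  Both levers (power and bandwidth) are needed for a
   graded, strictly monotone PLZC dose-response over the whole range:
   power alone saturates once flat noise dominates the top octave, and
   slope/bandwidth alone barely moves the low end.
3. **Planted effect**: a spectrally flat component confined to the effect
   band (default 20-30 Hz), applied only to group F subjects at a
   contiguous patch of sources.  Against the band's narrow peak it
   broadens the in-band spectrum and raises band-limited PLZC in that band
   only.  An early design used band-limited carriers that were already
   flat within each band; that variant is ordinal-invisible (for Gaussian
   processes band-filtered PLZC depends only on the in-band spectral
   shape, and flat plus flat is flat), which motivated the peaky base.

Between-subject variability is a mixed model: a subject-level baseline
irregularity (SD 0.05 around 0.2) plus independent per-source jitter
(SD 0.05).  The subject-level share produces realistic partial spatial
correlation of complexity maps and carries the volume coupling; the
per-source share keeps the permutation null of the cluster test from being
dominated by whole-map shifts.

The default planted patch covers 9 of 27 sources, grown from the corner of
the grid with the largest coordinate sum - a "posterior third" matching
the spatial extent of a precuneus/parietal/occipital cluster.  The default
planted increment (`effect_size = 0.06`) was calibrated once by Monte
Carlo so that per-source high-beta PLZC shows Cohen's d of about 0.8
between groups under the default cohort (measured 0.77 +/- 0.06 at 49 per
group); this realizes the planted-effect regime the recovery analyses are
specified at.

### Covariates

ICV ~ N(1.4e6, 1e5) mm^3; hippocampal volumes are generated as
ICV x ratio with ratio ~ N(2.5e-3, 2.5e-4), so volumes scale with head
size and the ICV-normalized ratio - the quantity the analysis actually
correlates - carries the planted coupling directly without attenuation by
independent head-size noise.  In group F the right-hippocampal ratio is a
linear function of the subject's standardized baseline irregularity plus
Gaussian noise sized so the population correlation equals
`volume_corr_rho` (default 0.45); group M volumes are independent of the
signals.  Sample correlations then scatter around the target (recovered
cluster-average rho typically 0.3-0.45 after attenuation by epoch noise
and per-source jitter).

All randomness flows from one seed through six named substreams (grid,
ages, epoch counts, irregularity, volumes, signals; signals drawn in
subject order, group F first), making cohorts bit-for-bit reproducible.

### What the generator does not emulate

No volume conduction or source leakage, no spatial correlation of the
signals beyond the shared subject baseline, no non-Gaussian or
non-stationary dynamics, no artefacts, no realistic anatomy.  Passing
recovery tests therefore demonstrates that the statistical machinery
detects the planted structure under idealized conditions; it does not
certify performance on real MEG.

## Cluster-based permutation test

Per-source statistics are the classic pooled-variance two-sample t
(group contrast, F minus M) or the Pearson correlation with a subject
covariate.  Sources with two-sided parametric p below the cluster-forming
alpha (0.05) are partitioned into maximal spatially contiguous components
of equal statistic sign; each cluster's statistic is the sum of its
members' statistics.  The design is relabeled (group labels shuffled, or
the covariate shuffled across the analyzed subjects) - 10,000 times at
study scale, 500 in the test battery - and the maximum absolute cluster
statistic per relabeling forms the null (max-statistic correction, strong
family-wise control).  Cluster p-values use the +1 correction and count
ties inclusively, so they are valid and never exactly zero.  Sources with
undefined statistics (zero variance) are flagged, logged and treated as
non-significant.  Cohen's d for a group cluster is computed on per-subject
means over the cluster's sources; a correlation cluster's effect size is
the arithmetic mean of its members' rho.

Design notes: the null uses the maximum statistic rather than pooling all
cluster statistics (the standard strong-control choice); candidate
selection uses parametric per-source p-values rather than per-source
permutation nulls (the common default in this family of tests - the
cluster-forming threshold only defines candidates, validity comes from the
cluster-level permutation null); correlation permutations shuffle the
covariate within the analyzed group, preserving the map's spatial
structure.

## Pipeline

The full study flow: band decomposition -> per-subject per-source
epoch-mean PLZC -> group CBPT per band (broadband included and expected
non-significant; every band is reported) -> region-mean summary table ->
volume correlations on the high-beta map (whole sample first, then per
group) for each configured region, ICV-normalized.  Stage seeds derive
from one master seed and the stage name, so a fixed configuration
reproduces every report file byte for byte; run metadata carries the
configuration, seeds and package version (no timestamps, to keep reports
deterministic).

## Numerical choices and degenerate inputs

Ties in ordinal ranking: stable order of occurrence.  Logarithms: base
`m!` computed as `log x / log m!`.  The LZ76 counter is a Kaspar-Schuster
scan verified exhaustively against a naive substring-search parser.
Filter orders must be even; bands must lie strictly inside (0, Nyquist).
Constant synthesized signals, empty epoch lists, inconsistent epoch
lengths, constant covariates and empty clusters raise errors rather than
returning silent defaults.

## Problem sizes in the test battery

Type-I calibration: 100 placebo cohorts, 20 subjects/group, 27 sources,
500 permutations.  Planted-effect recovery: 50 cohorts at the same scale
across five narrow bands.  Correlation recovery: 25 default cohorts (49
subjects/group).  These sizes were chosen as the smallest at which the
binomial acceptance bands are meaningful.

## Known limitations

PLZC values depend jointly on `m`, `tau`, the sampling rate and the band;
absolute values are not comparable across parameterizations.  The
generator's Gaussianity means PLZC differences are driven purely by
spectral shape; real signals can differ in higher-order structure
invisible to this model.  The eq3/eq2 choice matters for short epochs.
The correlation analysis assumes a linear volume-complexity relation.
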