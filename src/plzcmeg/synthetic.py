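"""Synthetic source-space cohorts with a planted, band-confined group effect.

The generator emulates the statistical structure of a resting-state MEG
study in source space: two sex-matched groups of elderly subjects, each
subject carrying a few dozen fixed-length epochs per source on a homogeneous
grid, plus anatomical covariates (hippocampal volumes, intracranial volume).

Signal model
------------
Every epoch is a zero-mean, unit-variance Gaussian process synthesized in
the frequency domain from three additive components:

* a *base* component of narrow oscillatory peaks, one per configured band
  (a Gaussian-shaped spectral bump in the lower third of the band, weighted
  1/f-like by default), emulating rhythmic activity on a quiet background;
* an *irregularity* component: spectrally flat (desynchronized) activity
  starting at the low edge of the modeled range, whose total power grows as
  ``irregularity**2`` relative to the base power and whose upper edge
  extends from the top of the modeled range toward 0.8x the Nyquist
  frequency as irregularity goes to 1 - emulating the growth of broadband,
  progressively faster background dynamics.  Both levers raise ordinal
  entropy, so PLZC increases monotonically and near-linearly with this
  parameter, broadband as well as within each analysis band;
* an optional *planted effect*: spectrally flat noise confined to
  ``effect_band``, applied only to group F subjects at ``effect_sources``.
  It broadens the in-band spectrum relative to the band's oscillatory peak
  and therefore raises band-limited PLZC in that band only.

Each subject draws a scalar baseline irregularity, and every source adds
independent regional jitter around it, giving between-subject complexity
variance with realistic partial spatial correlation; in group F the
right-hippocampal volume is coupled to the subject baseline to a
configurable correlation, while group M volumes are independent of the
signals.

All randomness flows from a single seed through named substreams (grid,
ages, epochs, irregularity, volumes, signals), so identical configurations
reproduce cohorts bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .grid import SourceGrid, contiguous_patch, is_contiguous, make_grid
from .preprocessing import SourceEpochData

#: (low Hz, high Hz, amplitude weight) triples; peak weights 2/low give the
#: rhythm amplitudes a ~1/f hierarchy across 2-45 Hz.
DEFAULT_BASE_SPECTRUM: tuple[tuple[float, float, float], ...] = tuple(
    (lo, hi, 2.0 / lo) for lo, hi in
    ((2.0, 4.0), (4.0, 8.0), (8.0, 12.0), (12.0, 20.0), (20.0, 30.0), (30.0, 45.0))
)

#: Planted band-confined irregularity increment; calibrated by Monte Carlo so
#: that the default cohort yields a source-level Cohen's d of about 0.8 on
#: high-beta PLZC at the effect sources (see docs/methods.md).
DEFAULT_EFFECT_SIZE = 0.06


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation settings (defaults are desk-scale)."""

    n_per_group: int = 49
    n_sources_per_axis: tuple[int, int, int] = (3, 3, 3)
    spacing_mm: float = 10.0
    n_regions: int = 4
    n_epochs_mean: float = 12.0
    n_epochs_sd: float = 3.0
    n_epochs_min: int = 4
    n_epochs_max: int = 80
    epoch_len_s: float = 2.0
    pad_s: float = 2.0
    fs: float = 250.0
    effect_band: tuple[float, float] = (20.0, 30.0)
    effect_sources: tuple[int, ...] | None = None  # None -> default posterior patch
    #: default planted patch covers the posterior third of the grid, matching
    #: the extent of a precuneus/parietal/occipital cluster
    n_effect_sources: int = 9
    effect_size: float = DEFAULT_EFFECT_SIZE
    irregularity_baseline: float = 0.2
    irregularity_subject_sd: float = 0.05
    irregularity_source_sd: float = 0.05
    volume_corr_rho: float = 0.45
    base_spectrum: tuple[tuple[float, float, float], ...] = DEFAULT_BASE_SPECTRUM
    age_mean: float = 72.7
    age_sd: float = 4.2
    age_range: tuple[float, float] = (65.0, 80.0)
    icv_mean: float = 1.4e6
    icv_sd: float = 1.0e5
    hippocampus_mean: float = 3500.0
    hippocampus_sd: float = 350.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        lo, hi = self.effect_band
        if not (0 < lo < hi < self.fs / 2):
            raise ValueError(
                f"effect band ({lo}, {hi}) outside (0, {self.fs / 2}) at fs={self.fs}")
        if abs(self.volume_corr_rho) >= 1:
            raise ValueError("|volume_corr_rho| must be < 1")
        if not (0 <= self.irregularity_baseline <= 1):
            raise ValueError("irregularity_baseline must lie in [0, 1]")
        if self.irregularity_subject_sd < 0 or self.irregularity_source_sd < 0:
            raise ValueError("irregularity spreads must be non-negative")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not self.base_spectrum:
            raise ValueError("base_spectrum must contain at least one band")
        if self.n_epochs_min < 1 or self.n_epochs_max < self.n_epochs_min:
            raise ValueError("invalid epoch-count truncation bounds")
        if self.epoch_len_s * self.fs < 2:
            raise ValueError("epoch too short")


@dataclass
class Cohort:
    """A simulated cohort: grid, covariate table and per-subject epoch data.

    ``table`` columns: subject_id, group, age, hipp_left_mm3, hipp_right_mm3,
    icv_mm3.  ``planted`` records each subject's generative irregularity (used
    by tests and calibration, never by the analysis itself).
    """

    grid: SourceGrid
    table: pd.DataFrame
    data: dict[str, SourceEpochData]
    effect_sources: np.ndarray | None = None
    planted: pd.DataFrame | None = None
    config: SimulationConfig | None = None

    @property
    def subject_ids(self) -> list[str]:
        return list(self.table["subject_id"])

    @property
    def n_subjects(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# frequency-domain synthesis
# ---------------------------------------------------------------------------

def _amplitude_profile(freqs: np.ndarray,
                       base_spectrum: Sequence[tuple[float, float, float]]) -> np.ndarray:
    """Base amplitude spectrum: one Gaussian oscillatory peak per band.

    The peak sits in the lower third of the band (center lo + (hi-lo)/3,
    width (hi-lo)/6), scaled by the band weight - narrow rhythms on a quiet
    background, the regular end of the irregularity axis.
    """
    amp = np.zeros_like(freqs)
    for lo, hi, w in base_spectrum:
        center = lo + (hi - lo) / 3.0
        sigma = (hi - lo) / 6.0
        amp += w * np.exp(-0.5 * ((freqs - center) / sigma) ** 2)
    return amp


def _component_amplitudes(
    n_samples: int,
    fs: float,
    base_spectrum: Sequence[tuple[float, float, float]],
    irregularity: float,
    effect: float,
    effect_band: tuple[float, float] | None,
) -> np.ndarray:
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    base = _amplitude_profile(freqs, base_spectrum)
    p_base = float((base ** 2).sum())
    if p_base == 0:
        raise ValueError("base spectrum has no support below the Nyquist frequency")
    amp2 = base ** 2
    # irregularity: flat background noise with power irregularity^2 * base
    # power, reaching from the low edge of the modeled range up to an edge
    # that extends toward 0.8 * Nyquist as irregularity -> 1
    if irregularity > 0:
        lo_all = min(b[0] for b in base_spectrum)
        hi_all = max(b[1] for b in base_spectrum)
        f_hi = hi_all + irregularity * max(0.8 * fs / 2 - hi_all, 0.0)
        flat_mask = (freqs >= lo_all) & (freqs < f_hi)
        if not flat_mask.any():
            raise ValueError("no frequency bins inside the modeled range")
        amp2[flat_mask] += irregularity ** 2 * (p_base / flat_mask.sum())
    if effect > 0:
        if effect_band is None:
            raise ValueError("effect > 0 requires an effect band")
        band_mask = (freqs >= effect_band[0]) & (freqs < effect_band[1])
        if not band_mask.any():
            raise ValueError("effect band contains no frequency bins")
        amp2[band_mask] += effect ** 2 * (p_base / band_mask.sum())
    return np.sqrt(amp2)


def _amplitude_matrix(
    n_samples: int,
    fs: float,
    base_spectrum: Sequence[tuple[float, float, float]],
    irregularity: np.ndarray,
    effect: float,
    effect_band: tuple[float, float] | None,
    effect_mask: np.ndarray | None,
) -> np.ndarray:
    """Per-source amplitude spectra, (n_sources, n_bins); vectorized over
    per-source irregularity values, with the planted effect added only at
    masked sources."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    base = _amplitude_profile(freqs, base_spectrum)
    p_base = float((base ** 2).sum())
    if p_base == 0:
        raise ValueError("base spectrum has no support below the Nyquist frequency")
    irregularity = np.asarray(irregularity, dtype=float)
    lo_all = min(b[0] for b in base_spectrum)
    hi_all = max(b[1] for b in base_spectrum)
    f_hi = hi_all + irregularity * max(0.8 * fs / 2 - hi_all, 0.0)
    flat_mask = (freqs[None, :] >= lo_all) & (freqs[None, :] < f_hi[:, None])
    n_flat = flat_mask.sum(axis=1)
    if np.any(n_flat == 0):
        raise ValueError("no frequency bins inside the modeled range")
    amp2 = np.broadcast_to(base ** 2, (irregularity.size, freqs.size)).copy()
    amp2 += flat_mask * (irregularity ** 2 * p_base / n_flat)[:, None]
    if effect > 0:
        if effect_band is None or effect_mask is None:
            raise ValueError("effect > 0 requires an effect band and mask")
        band_mask = (freqs >= effect_band[0]) & (freqs < effect_band[1])
        if not band_mask.any():
            raise ValueError("effect band contains no frequency bins")
        amp2[np.ix_(effect_mask, band_mask)] += effect ** 2 * (p_base / band_mask.sum())
    return np.sqrt(amp2)


def _synthesize(amp: np.ndarray, n_samples: int, shape: tuple[int, ...],
                rng: np.random.Generator) -> np.ndarray:
    """Gaussian signals with amplitude spectrum ``amp``; exactly standardized.

    ``amp`` must broadcast against ``shape + (n_bins,)``.
    """
    nb = amp.shape[-1]
    z = rng.standard_normal(shape + (nb, 2))
    spec = (z[..., 0] + 1j * z[..., 1]) * amp
    spec[..., 0] = 0.0
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("degenerate (constant) synthesized signal")
    x /= sd
    return x


def simulate_signal(
    duration_s: float,
    fs: float,
    base_spectrum: Sequence[tuple[float, float, float]] | None = None,
    irregularity: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """One synthetic source signal; zero mean and unit variance exactly.

    ``irregularity`` in [0, 1] mixes spectrally flat noise into the band-
    structured pink background; 0 is the most regular setting, 1 the most
    irregular.  Identical arguments yield bitwise-identical output.
    """
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    n = int(round(duration_s * fs))
    if n < 2:
        raise ValueError("duration_s * fs must be at least 2 samples")
    if not (0 <= irregularity <= 1):
        raise ValueError(f"irregularity must lie in [0, 1], got {irregularity}")
    spectrum = tuple(base_spectrum) if base_spectrum is not None else DEFAULT_BASE_SPECTRUM
    if not spectrum:
        raise ValueError("base_spectrum must contain at least one band")
    amp = _component_amplitudes(n, fs, spectrum, irregularity, 0.0, None)
    rng = np.random.default_rng(seed)
    return _synthesize(amp, n, (), rng)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size) -> np.ndarray:
    return np.clip(rng.normal(mean, sd, size=size), lo, hi)


def simulate_cohort(cfg: SimulationConfig) -> Cohort:
    """Generate a full cohort according to ``cfg`` (deterministic given seed).

    Substream order: grid, ages, epoch counts, irregularity, volumes, signals
    (signals drawn subject by subject in table order, F group first).
    """
    cfg.validate()
    streams = np.random.SeedSequence(cfg.seed).spawn(6)
    grid_seed = int(streams[0].generate_state(1)[0])
    rng_age, rng_epochs, rng_irr, rng_vol, rng_signal = (
        np.random.default_rng(s) for s in streams[1:])

    grid = make_grid(cfg.n_sources_per_axis, cfg.spacing_mm, cfg.n_regions, grid_seed)

    if cfg.effect_sources is not None:
        effect_sources = np.asarray(sorted(cfg.effect_sources), dtype=np.int64)
        if effect_sources.size and (effect_sources.min() < 0
                                    or effect_sources.max() >= grid.n_sources):
            raise ValueError("effect_sources outside the grid")
        if effect_sources.size and not is_contiguous(effect_sources, grid):
            raise ValueError("effect_sources must be contiguous under grid adjacency")
    else:
        effect_sources = contiguous_patch(grid, min(cfg.n_effect_sources, grid.n_sources))
    effect_mask = np.zeros(grid.n_sources, dtype=bool)
    effect_mask[effect_sources] = True

    n = cfg.n_per_group
    groups = ["F"] * n + ["M"] * n
    width = max(2, len(str(n)))
    ids = [f"F{i + 1:0{width}d}" for i in range(n)] + \
          [f"M{i + 1:0{width}d}" for i in range(n)]

    # age-matched pairs: one base age per pair plus small within-pair jitter
    lo_age, hi_age = cfg.age_range
    base_age = _truncnorm(rng_age, cfg.age_mean, cfg.age_sd, lo_age, hi_age, n)
    jitter = rng_age.normal(0.0, 0.5, size=(2, n))
    ages = np.clip(np.concatenate([base_age + jitter[0], base_age + jitter[1]]),
                   lo_age, hi_age)

    n_epochs = np.clip(
        np.round(rng_epochs.normal(cfg.n_epochs_mean, cfg.n_epochs_sd, size=2 * n)),
        cfg.n_epochs_min, cfg.n_epochs_max).astype(int)

    # subject baseline irregularity plus independent per-source regional jitter
    irregularity = np.clip(
        rng_irr.normal(cfg.irregularity_baseline, cfg.irregularity_subject_sd,
                       size=2 * n), 0.0, 1.0)
    source_jitter = rng_irr.normal(0.0, cfg.irregularity_source_sd,
                                   size=(2 * n, grid.n_sources))

    # volumes scale with head size: regional volume = ICV * ratio, so the
    # ICV-normalized ratio (the quantity the analysis correlates) carries the
    # planted coupling directly
    icv = np.clip(rng_vol.normal(cfg.icv_mean, cfg.icv_sd, size=2 * n),
                  0.5 * cfg.icv_mean, None)
    ratio_mean = cfg.hippocampus_mean / cfg.icv_mean
    ratio_sd = cfg.hippocampus_sd / cfg.icv_mean
    hipp_left = icv * np.clip(
        rng_vol.normal(ratio_mean, ratio_sd, size=2 * n), 0.1 * ratio_mean, None)
    # group F right hippocampus: ratio linear in the subject's planted
    # irregularity plus Gaussian noise sized to the target correlation rho
    irr_f = irregularity[:n]
    sd_f = irr_f.std()
    z = (irr_f - irr_f.mean()) / sd_f if sd_f > 0 else np.zeros(n)
    rho = cfg.volume_corr_rho
    eps = rng_vol.standard_normal(2 * n)
    ratio_right = np.empty(2 * n)
    ratio_right[:n] = ratio_mean + ratio_sd * (rho * z + np.sqrt(1 - rho ** 2) * eps[:n])
    # group M: independent of the signals
    ratio_right[n:] = ratio_mean + ratio_sd * eps[n:]
    hipp_right = icv * np.clip(ratio_right, 0.1 * ratio_mean, None)

    n_core = int(round(cfg.epoch_len_s * cfg.fs))
    pad = int(round(cfg.pad_s * cfg.fs))
    n_total = n_core + 2 * pad

    data: dict[str, SourceEpochData] = {}
    for j, sid in enumerate(ids):
        irr_sources = np.clip(irregularity[j] + source_jitter[j], 0.0, 1.0)
        planted_here = groups[j] == "F" and cfg.effect_size > 0
        amp = _amplitude_matrix(
            n_total, cfg.fs, cfg.base_spectrum, irr_sources,
            cfg.effect_size if planted_here else 0.0,
            cfg.effect_band, effect_mask if planted_here else None)
        block = _synthesize(amp[:, None, :], n_total,
                            (grid.n_sources, int(n_epochs[j])), rng_signal)
        data[sid] = SourceEpochData(values=block.astype(np.float32, copy=False),
                                    fs=cfg.fs, band="raw", pad_samples=pad)

    table = pd.DataFrame({
        "subject_id": ids,
        "group": groups,
        "age": ages,
        "hipp_left_mm3": hipp_left,
        "hipp_right_mm3": hipp_right,
        "icv_mm3": icv,
    })
    planted = pd.DataFrame({
        "subject_id": ids,
        "irregularity": irregularity,
        "has_effect": [g == "F" and cfg.effect_size > 0 for g in groups],
        "n_epochs": n_epochs,
    })
    return Cohort(grid=grid, table=table, data=data,
                  effect_sources=effect_sources, planted=planted, config=cfg)
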