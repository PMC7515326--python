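"""Band-limited FIR filtering and the epoch container.

The canonical analysis bands are broadband (2-45 Hz), theta (4-8), alpha
(8-12), low beta (12-20), high beta (20-30) and gamma (30-45).  Filtering
uses a linear-phase windowed-sinc band-pass (Hamming window, order 2000 at
1000 Hz, scaled proportionally with the sampling rate) applied once with
group-delay compensation, so the output is zero-phase.  Epochs are padded
with real adjacent signal when the data carry it, otherwise by reflection;
padding is removed after filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Union

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

#: FIR order used at a 1000 Hz sampling rate; scales proportionally with fs.
ORDER_AT_1KHZ = 2000
#: Seconds of signal context used on each side of an epoch while filtering.
DEFAULT_PAD_S = 2.0


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band, edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"invalid band edges ({self.low}, {self.high})")


CANONICAL_BANDS: dict[str, BandSpec] = {
    "broadband": BandSpec("broadband", 2.0, 45.0),
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 12.0),
    "low_beta": BandSpec("low_beta", 12.0, 20.0),
    "high_beta": BandSpec("high_beta", 20.0, 30.0),
    "gamma": BandSpec("gamma", 30.0, 45.0),
}

#: The narrow bands (broadband excluded).
NARROW_BANDS = ("theta", "alpha", "low_beta", "high_beta", "gamma")


def get_band(band: Union[str, BandSpec]) -> BandSpec:
    if isinstance(band, BandSpec):
        return band
    try:
        return CANONICAL_BANDS[band]
    except KeyError:
        raise ValueError(
            f"unknown band {band!r}; known: {sorted(CANONICAL_BANDS)}") from None


@dataclass
class SourceEpochData:
    """Per-subject source-space epochs: values[source, epoch, sample].

    ``pad_samples`` context samples of real signal are stored at each end of
    every epoch (0 once filtered/trimmed).  ``band`` is "raw" or the BandSpec
    the data were filtered to.
    """

    values: np.ndarray
    fs: float
    band: Union[str, BandSpec] = "raw"
    pad_samples: int = 0

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError(
                f"values must be [source, epoch, sample], got shape {self.values.shape}")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.pad_samples < 0 or 2 * self.pad_samples >= self.values.shape[-1]:
            raise ValueError(f"invalid pad_samples {self.pad_samples}")

    @property
    def n_sources(self) -> int:
        return self.values.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.values.shape[1]

    @property
    def epoch_len_samples(self) -> int:
        return self.values.shape[-1] - 2 * self.pad_samples

    def core(self) -> np.ndarray:
        """Epoch samples without the padding context."""
        if self.pad_samples == 0:
            return self.values
        return self.values[..., self.pad_samples:-self.pad_samples]


def default_order(fs: float) -> int:
    """FIR order scaled from 2000 at 1000 Hz, rounded to even."""
    return 2 * int(round(ORDER_AT_1KHZ * fs / 1000.0 / 2))


def design_bandpass(band: Union[str, BandSpec], fs: float, order: int | None = None) -> np.ndarray:
    """Windowed-sinc (Hamming) linear-phase band-pass taps with exact DC null.

    The tap mean is subtracted so that the DC gain is exactly zero; the
    perturbation to pass- and stop-band gains is below 1e-4.
    """
    band = get_band(band)
    if order is None:
        order = default_order(fs)
    if order <= 0 or order % 2 != 0:
        raise ValueError(f"FIR order must be a positive even integer, got {order}")
    if not (0 < band.low < band.high < fs / 2):
        raise ValueError(
            f"band ({band.low}, {band.high}) Hz outside (0, {fs / 2}) at fs={fs}")
    taps = sps.firwin(order + 1, [band.low, band.high], window="hamming",
                      pass_zero=False, fs=fs)
    return taps - taps.mean()


def _apply_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Delay-compensated single-pass FIR along the last axis (zero phase)."""
    delay = (len(taps) - 1) // 2
    full = sps.oaconvolve(x, taps[(np.newaxis,) * (x.ndim - 1) + (slice(None),)],
                          axes=-1)
    return full[..., delay:delay + x.shape[-1]]


def fir_bandpass(
    x: np.ndarray,
    band: Union[str, BandSpec],
    fs: float,
    order: int | None = None,
    pad_s: float = DEFAULT_PAD_S,
    has_context: bool = False,
) -> np.ndarray:
    """Zero-phase band-pass filter a series; output length equals the core input.

    If ``has_context`` is true, the first and last ``round(pad_s * fs)``
    samples of ``x`` are real context that is dropped from the output.
    Otherwise the series is reflect-padded by that amount before filtering
    (and this fallback is logged), so edge transients fall on the padding.
    """
    band = get_band(band)
    if order is None:
        order = default_order(fs)
    taps = design_bandpass(band, fs, order)
    x = np.asarray(x, dtype=float)
    pad = int(round(pad_s * fs))
    if has_context:
        if 2 * pad >= x.shape[-1]:
            raise ValueError(
                f"context of {pad} samples per side exceeds series length {x.shape[-1]}")
        padded = x
    else:
        if pad > 0:
            if pad >= x.shape[-1]:
                raise ValueError(
                    f"reflect pad of {pad} samples needs series longer than {x.shape[-1]}")
            logger.debug("no context available; reflect-padding %d samples per side", pad)
            padded = np.concatenate(
                [x[..., 1:pad + 1][..., ::-1], x, x[..., -pad - 1:-1][..., ::-1]], axis=-1)
        else:
            padded = x
    if order >= padded.shape[-1]:
        raise ValueError(
            f"FIR order {order} >= padded length {padded.shape[-1]}")
    out = _apply_fir(padded, taps)
    if pad > 0:
        out = out[..., pad:-pad]
    return out


def band_decompose(
    data: SourceEpochData,
    bands: list[Union[str, BandSpec]] | tuple[Union[str, BandSpec], ...] | None = None,
    order: int | None = None,
    pad_s: float = DEFAULT_PAD_S,
) -> Mapping[str, SourceEpochData]:
    """Filter raw source epochs into one copy per requested band.

    Epoch shape is preserved (padding context, if stored, is consumed and the
    outputs are trimmed to the core epoch length).
    """
    if data.band != "raw":
        raise ValueError(f"band_decompose expects raw data, got band {data.band!r}")
    if bands is None:
        bands = list(CANONICAL_BANDS)
    out: dict[str, SourceEpochData] = {}
    for band in bands:
        spec = get_band(band)
        if data.pad_samples > 0:
            filtered = fir_bandpass(
                data.values, spec, data.fs, order=order,
                pad_s=data.pad_samples / data.fs, has_context=True)
        else:
            filtered = fir_bandpass(data.values, spec, data.fs, order=order, pad_s=pad_s)
        out[spec.name] = replace(data, values=filtered, band=spec, pad_samples=0)
    return out
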