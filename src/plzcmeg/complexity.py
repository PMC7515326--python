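"""Permutation Lempel-Ziv complexity (PLZC).

A time series is symbolized into ordinal patterns (motifs): each window of
``m`` samples taken at delay ``tau`` is mapped to the lexicographic index of
its rank permutation, giving a symbol stream over an alphabet of size ``m!``.
The stream is parsed with the LZ76 exhaustive-history scheme, whose word
count ``c(n)`` is normalized to a dimensionless complexity in [0, 1]:

* ``eq2``:  PLZC = c(n) * (log_{m!} c(n) + 1) / alpha
* ``eq3``:  PLZC = c(n) * log_{m!}(alpha) / alpha   (long-signal simplification)

where ``alpha`` is the length of the symbol sequence.  Low values indicate
regular dynamics, values near 1 indicate irregular (noise-like) dynamics.
PLZC is invariant under any strictly increasing amplitude transform, since
only ordinal relations between samples enter the symbolization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from numba import njit


@dataclass(frozen=True)
class ComplexityParams:
    """Parameters of the PLZC estimator.

    m : motif (ordinal pattern) length, >= 2.  Default 5.
    tau : time delay between the samples of a motif, in samples, >= 1.
    normalization : "eq3" (default, long-signal form) or "eq2".
    tie_rule : how equal samples are ranked; only stable order of occurrence
        is implemented (earlier sample ranks lower).
    """

    m: int = 5
    tau: int = 1
    normalization: Literal["eq2", "eq3"] = "eq3"
    tie_rule: Literal["stable_order"] = "stable_order"

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError(f"motif length m must be >= 2, got {self.m}")
        if self.tau < 1:
            raise ValueError(f"time delay tau must be >= 1, got {self.tau}")
        if self.normalization not in ("eq2", "eq3"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.tie_rule != "stable_order":
            raise ValueError(f"unknown tie rule {self.tie_rule!r}")

    @property
    def alphabet_size(self) -> int:
        return math.factorial(self.m)


@dataclass(frozen=True)
class SymbolSequence:
    """Ordinal symbol stream produced from a numeric series."""

    symbols: np.ndarray  # int64, values in [0, alphabet_size)
    alphabet_size: int
    source_length: int

    def __len__(self) -> int:
        return self.symbols.shape[0]


@dataclass(frozen=True)
class ComplexityValue:
    """A PLZC estimate together with its raw ingredients."""

    plzc: float
    c_n: int          # LZ76 word count of the symbol sequence
    n_symbols: int    # alpha, length of the symbol sequence


# ---------------------------------------------------------------------------
# ordinal symbolization
# ---------------------------------------------------------------------------

def _lehmer_index(perm: np.ndarray) -> np.ndarray:
    """Lexicographic index of each row permutation (Lehmer code)."""
    m = perm.shape[-1]
    fact = [math.factorial(m - 1 - i) for i in range(m)]
    idx = np.zeros(perm.shape[:-1], dtype=np.int64)
    for i in range(m - 1):
        smaller = (perm[..., i + 1:] < perm[..., i:i + 1]).sum(axis=-1)
        idx += smaller * fact[i]
    return idx


def _symbolize_nd(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Ordinal symbols along the last axis of ``x``; stable tie-breaking."""
    span = (m - 1) * tau
    if x.shape[-1] < span + 1:
        raise ValueError(
            f"series of length {x.shape[-1]} too short for m={m}, tau={tau} "
            f"(needs at least {span + 1} samples)")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")
    win = np.lib.stride_tricks.sliding_window_view(x, span + 1, axis=-1)[..., ::tau]
    perm = np.argsort(win, axis=-1, kind="stable")
    return _lehmer_index(perm)


def ordinal_symbolize(x: Sequence[float] | np.ndarray, params: ComplexityParams) -> SymbolSequence:
    """Map a 1-D numeric series to its ordinal-pattern symbol sequence.

    Each window ``(x_t, x_{t+tau}, ..., x_{t+(m-1)tau})`` is replaced by the
    lexicographic index of the permutation that sorts it; ties are broken by
    order of occurrence (stable sort), so equal samples keep their original
    relative order.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D series, got shape {x.shape}")
    symbols = _symbolize_nd(x, params.m, params.tau)
    return SymbolSequence(symbols=symbols, alphabet_size=params.alphabet_size,
                          source_length=x.shape[0])


# ---------------------------------------------------------------------------
# LZ76 exhaustive-history word count
# ---------------------------------------------------------------------------

@njit(cache=True)
def _lz76_kernel(s: np.ndarray) -> int:  # pragma: no cover - exercised via wrapper
    n = s.shape[0]
    if n == 1:
        return 1
    c = 1
    l = 1
    i = 0
    k = 1
    kmax = 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            if k > kmax:
                kmax = k
            i += 1
            if i == l:
                c += 1
                l += kmax
                if l + 1 > n:
                    break
                i = 0
                k = 1
                kmax = 1
            else:
                k = 1
    return c


@njit(cache=True)
def _lz76_batch_kernel(S: np.ndarray) -> np.ndarray:  # pragma: no cover
    out = np.empty(S.shape[0], dtype=np.int64)
    for r in range(S.shape[0]):
        out[r] = _lz76_kernel(S[r])
    return out


def lz76_count(s: SymbolSequence | Sequence[int] | np.ndarray) -> int:
    """Number of words in the LZ76 exhaustive-history parsing of ``s``.

    Each word is the shortest prefix of the remaining sequence that cannot be
    reproduced (as a substring, self-overlap allowed) from the material before
    its last symbol; the final word counts even if it is reproducible.
    """
    if isinstance(s, SymbolSequence):
        arr = s.symbols
    else:
        arr = np.asarray(s)
    arr = np.ascontiguousarray(arr, dtype=np.int64)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("lz76_count requires a non-empty 1-D symbol sequence")
    return int(_lz76_kernel(arr))


# ---------------------------------------------------------------------------
# normalized complexity
# ---------------------------------------------------------------------------

def _normalize(c: np.ndarray | int, alpha: int, m: int,
               normalization: str) -> np.ndarray | float:
    log_mfact = math.log(math.factorial(m))
    c = np.asarray(c, dtype=float)
    if normalization == "eq3":
        out = c * (math.log(alpha) / log_mfact) / alpha
    else:  # eq2
        out = c * (np.log(c) / log_mfact + 1.0) / alpha
    return out


def plzc(x: Sequence[float] | np.ndarray, params: ComplexityParams | None = None) -> ComplexityValue:
    """Permutation Lempel-Ziv complexity of a 1-D numeric series."""
    params = params or ComplexityParams()
    seq = ordinal_symbolize(x, params)
    alpha = len(seq)
    if params.alphabet_size > alpha:
        raise ValueError(
            f"alphabet size m! = {params.alphabet_size} exceeds symbol sequence "
            f"length {alpha}; use a shorter motif or a longer series")
    c = lz76_count(seq)
    value = float(_normalize(c, alpha, params.m, params.normalization))
    return ComplexityValue(plzc=value, c_n=c, n_symbols=alpha)


def epoch_plzc(epochs: Iterable[np.ndarray], params: ComplexityParams | None = None) -> float:
    """Arithmetic mean of per-epoch PLZC values (the per-subject aggregate)."""
    params = params or ComplexityParams()
    epochs = [np.asarray(e, dtype=float) for e in epochs]
    if not epochs:
        raise ValueError("epoch_plzc requires at least one epoch")
    lengths = {e.shape[-1] for e in epochs}
    if len(lengths) != 1:
        raise ValueError(f"epochs have inconsistent lengths: {sorted(lengths)}")
    return float(np.mean([plzc(e, params).plzc for e in epochs]))


def plzc_array(x: np.ndarray, params: ComplexityParams | None = None,
               chunk_rows: int = 2048) -> np.ndarray:
    """PLZC along the last axis of an N-D array, returned with that axis dropped.

    Vectorized symbolization plus a batched LZ76 kernel; used by the pipeline
    to process whole [source, epoch, sample] blocks at once.
    """
    params = params or ComplexityParams()
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return np.asarray(plzc(x, params).plzc)
    lead_shape = x.shape[:-1]
    flat = x.reshape(-1, x.shape[-1])
    alpha = flat.shape[-1] - (params.m - 1) * params.tau
    if params.alphabet_size > alpha:
        raise ValueError(
            f"alphabet size m! = {params.alphabet_size} exceeds symbol sequence "
            f"length {alpha}")
    counts = np.empty(flat.shape[0], dtype=np.int64)
    for start in range(0, flat.shape[0], chunk_rows):
        block = flat[start:start + chunk_rows]
        syms = _symbolize_nd(block, params.m, params.tau)
        counts[start:start + block.shape[0]] = _lz76_batch_kernel(
            np.ascontiguousarray(syms))
    values = _normalize(counts, alpha, params.m, params.normalization)
    return np.asarray(values, dtype=float).reshape(lead_shape)
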