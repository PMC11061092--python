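"""Ordinal-pattern (symbolic-dynamics) measures of variability and coupling.

A time series is symbolised in the Bandt–Pompe way: each embedding vector of
``n`` samples spaced ``tau`` apart is replaced by the rank ordering of its
amplitudes, giving one of n! ordinal patterns.  Three readouts are built on
the resulting symbol streams:

* permutation entropy (PE) — normalised Shannon entropy of one region's
  pattern distribution; 0 for fully regular signals, 1 for maximally
  variable ones;
* weighted symbolic mutual information (wsMI) — mutual information between
  two regions' co-occurring patterns, with identical and sign-opposite
  pattern pairs zero-weighted (the volume-conduction correction);
* inverted joint permutation entropy (JPE_inv) — one minus the normalised
  joint entropy of the co-occurrence distribution; higher values mean
  stronger coupling, and it is sensitive to both local regularity and
  interregional dependence.

Conventions fixed here: ties in the amplitude ranking are broken by temporal
order (the earlier sample ranks lower); a pattern's integer symbol is the
lexicographic rank of its argsort permutation; all entropies use natural
logarithms with explicit normalisation constants; 0*log(0) := 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import signal as _signal

__all__ = [
    "SymbolizationParams",
    "OrdinalPatternSequence",
    "ConnectivityMatrix",
    "bandpass",
    "symbolize",
    "permutation_entropy",
    "joint_symbol_distribution",
    "wsmi",
    "jpe_inv",
    "connectivity_matrix",
    "opposite_pattern_map",
]


@dataclass(frozen=True)
class SymbolizationParams:
    """Embedding dimension ``n``, delay ``tau`` (samples), optional pass-band.

    The study grid uses n = 4 (24 patterns) with (band, tau) conditions
    (0.5-70 Hz, 1), (6-13 Hz, 1) and (0.5-70 Hz, 50).
    """

    n: int = 4
    tau: int = 1
    band: tuple[float, float] | None = None

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("embedding dimension n must be >= 2")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.band is not None and not (0 < self.band[0] < self.band[1]):
            raise ValueError("band must satisfy 0 < low < high")

    @property
    def n_patterns(self) -> int:
        return math.factorial(self.n)


@dataclass(frozen=True)
class OrdinalPatternSequence:
    """Symbol stream of one signal: integers in [0, n!-1]."""

    symbols: np.ndarray
    n: int
    tau: int
    source_length: int

    def __post_init__(self):
        object.__setattr__(
            self, "symbols", np.asarray(self.symbols, dtype=np.int64)
        )

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def n_patterns(self) -> int:
        return math.factorial(self.n)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Region-by-region symmetric matrix of a pairwise coupling measure."""

    measure: str  # "wsmi" or "jpe_inv"
    values: np.ndarray
    params: SymbolizationParams

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def bandpass(
    series: np.ndarray, fs: float, band: tuple[float, float], order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    Forward-backward filtering (sosfiltfilt) doubles the effective order and
    cancels the phase response, so ordinal patterns are not shifted in time.
    """
    low, high = band
    nyq = fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band {band} must lie strictly inside (0, {nyq}) Hz")
    sos = _signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return _signal.sosfiltfilt(sos, np.asarray(series, dtype=float), axis=-1)


def _lehmer_rank(perms: np.ndarray, n: int) -> np.ndarray:
    """Lexicographic rank of each permutation row (Lehmer code)."""
    m = perms.shape[0]
    rank = np.zeros(m, dtype=np.int64)
    for k in range(n - 1):
        smaller_later = np.zeros(m, dtype=np.int64)
        for j in range(k + 1, n):
            smaller_later += perms[:, j] < perms[:, k]
        rank += smaller_later * math.factorial(n - 1 - k)
    return rank


def symbolize(
    series: np.ndarray, params: SymbolizationParams
) -> OrdinalPatternSequence:
    """Map a real time series to its ordinal-pattern symbol stream.

    Windows advance one sample at a time; a series of length L yields
    L - (n-1)*tau symbols.  Ties rank by temporal order (stable argsort).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    n, tau = params.n, params.tau
    count = len(x) - (n - 1) * tau
    if count < 1:
        raise ValueError(
            f"series of length {len(x)} too short for n={n}, tau={tau}"
        )
    idx = np.arange(count)[:, None] + tau * np.arange(n)[None, :]
    perms = np.argsort(x[idx], axis=1, kind="stable")
    symbols = _lehmer_rank(perms, n)
    return OrdinalPatternSequence(symbols, n=n, tau=tau, source_length=len(x))


def _symbolize_symbols(x: np.ndarray, n: int, tau: int) -> np.ndarray:
    """symbolize() without the dataclass wrapper (hot path)."""
    count = x.shape[-1] - (n - 1) * tau
    idx = np.arange(count)[:, None] + tau * np.arange(n)[None, :]
    perms = np.argsort(x[..., idx], axis=-1, kind="stable")
    flat = perms.reshape(-1, n)
    return _lehmer_rank(flat, n).reshape(perms.shape[:-1])


def opposite_pattern_map(n: int) -> np.ndarray:
    """Symbol of the amplitude-inverted pattern, per symbol.

    Negating a window reverses its sort order, so the argsort permutation is
    reversed; the map sends each lexicographic rank to the rank of its
    reversed permutation.  Never the identity for n >= 2.
    """
    perms = np.array(list(permutations(range(n))), dtype=np.int64)
    return _lehmer_rank(perms[:, ::-1], n)


def _check_pair(seqX: OrdinalPatternSequence, seqY: OrdinalPatternSequence):
    if (seqX.n, seqX.tau) != (seqY.n, seqY.tau):
        raise ValueError("sequences have mismatched (n, tau) parameters")
    if len(seqX) != len(seqY):
        raise ValueError("sequences have different lengths")
    if len(seqX) == 0:
        raise ValueError("empty symbol sequences")


def permutation_entropy(seq: OrdinalPatternSequence) -> float:
    """Normalised Shannon entropy of the pattern distribution, in [0, 1]."""
    if len(seq) == 0:
        raise ValueError("empty symbol sequence")
    counts = np.bincount(seq.symbols, minlength=seq.n_patterns)
    p = counts[counts > 0] / len(seq)
    return float(-(p * np.log(p)).sum() / math.log(seq.n_patterns))


def joint_symbol_distribution(
    seqX: OrdinalPatternSequence, seqY: OrdinalPatternSequence
) -> np.ndarray:
    """n! x n! matrix of co-occurrence probabilities p(x, y), summing to 1."""
    _check_pair(seqX, seqY)
    nf = seqX.n_patterns
    counts = np.bincount(seqX.symbols * nf + seqY.symbols, minlength=nf * nf)
    return counts.reshape(nf, nf) / len(seqX)


def _volume_conduction_mask(nf: int, opposite: np.ndarray) -> np.ndarray:
    """False on identical and sign-opposite pattern pairs, True elsewhere."""
    mask = np.ones((nf, nf), dtype=bool)
    idx = np.arange(nf)
    mask[idx, idx] = False
    mask[idx, opposite] = False
    return mask


def _wsmi_from_joint(pxy: np.ndarray, mask: np.ndarray, nf: int) -> float:
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    prod = np.outer(px, py)
    nz = (pxy > 0) & mask
    val = (pxy[nz] * np.log(pxy[nz] / prod[nz])).sum()
    return float(val / math.log(nf))


def _jpe_inv_from_joint(pxy: np.ndarray, mask: np.ndarray) -> float:
    masked = pxy[mask]
    total = masked.sum()
    if total <= 0:
        raise ValueError(
            "joint distribution is empty after the volume-conduction mask"
        )
    p = masked[masked > 0] / total
    h = -(p * np.log(p)).sum()
    return float(1.0 - h / math.log(mask.sum()))


def wsmi(
    seqX: OrdinalPatternSequence,
    seqY: OrdinalPatternSequence,
    corrected: bool = True,
) -> float:
    """Weighted symbolic mutual information between two symbol streams.

    Sum of p(x,y) log(p(x,y)/(p(x)p(y))) over pattern pairs, normalised by
    log(n!).  With ``corrected`` (default) identical and sign-opposite
    pattern pairs get weight 0 — co-occurrences a common source mixed into
    both signals would produce — and all other pairs weight 1.
    """
    _check_pair(seqX, seqY)
    nf = seqX.n_patterns
    pxy = joint_symbol_distribution(seqX, seqY)
    if corrected:
        mask = _volume_conduction_mask(nf, opposite_pattern_map(seqX.n))
    else:
        mask = np.ones((nf, nf), dtype=bool)
    return _wsmi_from_joint(pxy, mask, nf)


def jpe_inv(
    seqX: OrdinalPatternSequence,
    seqY: OrdinalPatternSequence,
    corrected: bool = True,
) -> float:
    """Inverted joint permutation entropy, in [0, 1]; higher = more coupled.

    One minus the Shannon entropy of the co-occurrence distribution —
    masked of identical and sign-opposite pattern pairs and renormalised
    when ``corrected`` — divided by the log of the number of admissible
    joint states, so independent maximally-variable streams score 0 and
    perfectly regular joint dynamics score 1.
    """
    _check_pair(seqX, seqY)
    nf = seqX.n_patterns
    pxy = joint_symbol_distribution(seqX, seqY)
    if corrected:
        mask = _volume_conduction_mask(nf, opposite_pattern_map(seqX.n))
    else:
        mask = np.ones((nf, nf), dtype=bool)
    return _jpe_inv_from_joint(pxy, mask)


def _pairwise_measures(
    symbols: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """(wsMI, JPE_inv) matrices over all region pairs of one run.

    ``symbols`` is (n_regions, n_symbols) int; the joint histogram of each
    pair is computed once and feeds both measures.
    """
    n_regions, length = symbols.shape
    nf = math.factorial(n)
    mask = _volume_conduction_mask(nf, opposite_pattern_map(n))
    wsmi_mat = np.zeros((n_regions, n_regions))
    jpe_mat = np.zeros((n_regions, n_regions))
    scaled = symbols * nf
    for i in range(n_regions):
        for j in range(i + 1, n_regions):
            counts = np.bincount(scaled[i] + symbols[j], minlength=nf * nf)
            pxy = counts.reshape(nf, nf) / length
            w = _wsmi_from_joint(pxy, mask, nf)
            jp = _jpe_inv_from_joint(pxy, mask)
            wsmi_mat[i, j] = wsmi_mat[j, i] = w
            jpe_mat[i, j] = jpe_mat[j, i] = jp
    return wsmi_mat, jpe_mat


def connectivity_matrix(
    sequences, measure: str
) -> ConnectivityMatrix:
    """Pairwise coupling matrix over regions, averaged across runs.

    ``sequences`` is either one run — a list of per-region
    OrdinalPatternSequence — or a list of such runs; run matrices are
    averaged elementwise.  ``measure`` is "wsmi" or "jpe_inv".
    """
    if measure not in ("wsmi", "jpe_inv"):
        raise ValueError(f"unknown measure {measure!r}")
    runs = sequences
    if runs and isinstance(runs[0], OrdinalPatternSequence):
        runs = [runs]
    if not runs or len(runs[0]) < 2:
        raise ValueError("need at least 2 regions")

    first = runs[0][0]
    n, tau = first.n, first.tau
    params = SymbolizationParams(n=n, tau=tau)
    mats = []
    for run in runs:
        if len(run) != len(runs[0]):
            raise ValueError("runs have different numbers of regions")
        for s in run:
            if (s.n, s.tau) != (n, tau) or len(s) != len(run[0]):
                raise ValueError("ragged or mismatched sequences within a run")
        symbols = np.stack([s.symbols for s in run])
        wsmi_mat, jpe_mat = _pairwise_measures(symbols, n)
        mats.append(wsmi_mat if measure == "wsmi" else jpe_mat)
    values = np.mean(mats, axis=0)
    return ConnectivityMatrix(measure=measure, values=values, params=params)
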