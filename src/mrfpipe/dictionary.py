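"""Dictionary generation, SVD compression and pattern matching.

The dictionary holds one simulated fingerprint (atom) per (T1, T2) pair on
a piecewise-uniform grid whose step size coarsens with the relaxation time,
mirroring the exponential character of relaxation curves.  Matching selects,
for a measured voxel signal, the atom maximizing the magnitude of the
normalized inner product; the matched pair's grid values become the voxel's
T1/T2 estimates and the least-squares amplitude of the matched atom is the
proton-density surrogate.

Compression projects atoms onto the top left singular vectors of the atom
matrix (a rank-limited temporal basis), so volumes can be matched in a
15-dimensional space instead of the full timepoint dimension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .signal_model import (
    DEFAULT_N_STATES,
    SequenceSchedule,
    simulate_fingerprints,
)

__all__ = [
    "DEFAULT_T1_SEGMENTS",
    "DEFAULT_T2_SEGMENTS",
    "DEFAULT_RANK",
    "InvalidGridError",
    "InvalidRankError",
    "EmptyDictionaryError",
    "NoMatchError",
    "DictionaryGrid",
    "Dictionary",
    "MatchResult",
    "ParameterMaps",
    "build_grid",
    "default_grid",
    "build_dictionary",
    "compress",
    "compression_error",
    "match",
    "match_many",
    "match_volume",
]

# Piecewise (start, step, stop) segments of the default dictionary axes;
# steps widen with the relaxation time.  T1 spans 10-3000 ms, T2 10-2000 ms.
DEFAULT_T1_SEGMENTS: Tuple[Tuple[float, float, float], ...] = (
    (10, 5, 100),
    (110, 10, 1000),
    (1050, 50, 2000),
    (2100, 100, 3000),
)
DEFAULT_T2_SEGMENTS: Tuple[Tuple[float, float, float], ...] = (
    (10, 1, 100),
    (105, 5, 500),
    (525, 25, 1000),
    (1100, 100, 2000),
)
DEFAULT_RANK = 15


class InvalidGridError(ValueError):
    pass


class InvalidRankError(ValueError):
    pass


class EmptyDictionaryError(ValueError):
    pass


class NoMatchError(ValueError):
    pass


def _expand_segments(segments: Sequence[Tuple[float, float, float]]) -> np.ndarray:
    values = []
    prev_stop = -np.inf
    for start, step, stop in segments:
        if step <= 0:
            raise InvalidGridError(f"segment step must be positive: {step}")
        if stop < start:
            raise InvalidGridError(f"decreasing segment ({start}, {step}, {stop})")
        if start <= prev_stop:
            raise InvalidGridError(
                f"segment starting at {start} overlaps previous stop {prev_stop}"
            )
        n = int(round((stop - start) / step))
        seg = start + step * np.arange(n + 1)
        # inclusive stop only when it lands on the step lattice
        seg = seg[seg <= stop + 1e-9]
        values.append(seg)
        prev_stop = seg[-1]
    return np.round(np.concatenate(values), 9)


@dataclass(frozen=True)
class DictionaryGrid:
    """The (T1, T2) parameter lattice of a dictionary.

    ``pairs`` is the full cross-product in T1-major order, i.e. the linear
    index runs fastest over T2; an optional physical-validity filter keeps
    only pairs with T2 <= T1.
    """

    t1_values_ms: np.ndarray
    t2_values_ms: np.ndarray
    pairs: np.ndarray  # (n_pairs, 2)

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]


def build_grid(
    t1_segments: Sequence[Tuple[float, float, float]] = DEFAULT_T1_SEGMENTS,
    t2_segments: Sequence[Tuple[float, float, float]] = DEFAULT_T2_SEGMENTS,
    physical_t2_le_t1: bool = False,
) -> DictionaryGrid:
    """Expand piecewise (start, step, stop) segments into a (T1, T2) grid.

    Segments are inclusive arithmetic sequences and must be strictly
    increasing and non-overlapping.  With ``physical_t2_le_t1`` the
    cross-product is restricted to T2 <= T1 (off by default: the plain
    ranges are kept as stated).
    """
    t1 = _expand_segments(t1_segments)
    t2 = _expand_segments(t2_segments)
    if np.unique(t1).size != t1.size or np.unique(t2).size != t2.size:
        raise InvalidGridError("duplicate grid values")
    pairs = np.column_stack(
        [np.repeat(t1, t2.size), np.tile(t2, t1.size)]
    )
    if physical_t2_le_t1:
        pairs = pairs[pairs[:, 1] <= pairs[:, 0]]
    return DictionaryGrid(t1_values_ms=t1, t2_values_ms=t2, pairs=pairs)


def default_grid() -> DictionaryGrid:
    return build_grid()


@dataclass(frozen=True)
class Dictionary:
    """A fingerprint dictionary, optionally with a rank-limited basis.

    ``atoms`` has one unit-L2-norm fingerprint per row (pair-major order
    matching ``grid.pairs`` after zero-atom removal).  When ``basis`` is
    present its columns are the orthonormal top left singular vectors of
    the atom matrix and ``compressed_atoms = atoms @ basis``.
    """

    grid: DictionaryGrid
    pairs: np.ndarray  # (n_atoms, 2), post-filtering
    atoms: np.ndarray  # (n_atoms, n_timepoints), unit rows
    schedule: SequenceSchedule
    basis: Optional[np.ndarray] = None  # (n_timepoints, rank)
    compressed_atoms: Optional[np.ndarray] = None  # (n_atoms, rank)
    singular_values: Optional[np.ndarray] = None  # full spectrum, descending

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.atoms.shape[1]

    @property
    def rank(self) -> Optional[int]:
        return None if self.basis is None else self.basis.shape[1]


@dataclass(frozen=True)
class MatchResult:
    t1_ms: float
    t2_ms: float
    pd: float
    correlation: float
    index: int


@dataclass
class ParameterMaps:
    """Co-registered quantitative maps on a shared voxel grid (ms units)."""

    t1_ms: np.ndarray
    t2_ms: np.ndarray
    pd: np.ndarray
    correlation: np.ndarray

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.t1_ms.shape


def build_dictionary(
    grid: DictionaryGrid,
    schedule: SequenceSchedule,
    n_states: int = DEFAULT_N_STATES,
) -> Dictionary:
    """Simulate and L2-normalize one atom per grid pair.

    Pairs whose simulated signal is identically zero (e.g. under an all-0
    flip schedule) carry no information and are dropped with a warning; if
    nothing survives, the schedule cannot support matching at all.
    """
    if grid.n_pairs == 0:
        raise EmptyDictionaryError("grid has no (T1, T2) pairs")
    raw = simulate_fingerprints(
        grid.pairs[:, 0], grid.pairs[:, 1], schedule, n_states=n_states
    )
    norms = np.linalg.norm(raw, axis=1)
    keep = norms > 0.0
    if not np.all(keep):
        warnings.warn(
            f"dropping {np.count_nonzero(~keep)} zero-signal dictionary pairs",
            stacklevel=2,
        )
    if not np.any(keep):
        raise EmptyDictionaryError("schedule produced all-zero fingerprints")
    atoms = raw[keep] / norms[keep, None]
    return Dictionary(
        grid=grid,
        pairs=grid.pairs[keep],
        atoms=np.ascontiguousarray(atoms),
        schedule=schedule,
    )


def compress(dic: Dictionary, rank: int = DEFAULT_RANK, keep_atoms: bool = True) -> Dictionary:
    """Attach a rank-``rank`` temporal SVD basis to a dictionary.

    The basis is computed from the eigendecomposition of the small
    timepoint-by-timepoint Gram matrix (equivalent to the top left singular
    vectors of the atom matrix, at a fraction of the cost for wide
    dictionaries).  Set ``keep_atoms=False`` to drop the uncompressed atoms.
    """
    max_rank = min(dic.n_timepoints, dic.n_atoms)
    if not (1 <= rank <= max_rank):
        raise InvalidRankError(f"rank must be in [1, {max_rank}], got {rank}")
    A = dic.atoms.T  # (n_t, n_atoms)
    gram = A @ A.T
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    basis = evecs[:, order[:rank]]
    # fix sign for determinism: largest-magnitude element positive
    for j in range(basis.shape[1]):
        i = np.argmax(np.abs(basis[:, j]))
        if basis[i, j] < 0:
            basis[:, j] = -basis[:, j]
    compressed = dic.atoms @ basis
    return replace(
        dic,
        atoms=dic.atoms if keep_atoms else np.empty((dic.n_atoms, 0)),
        basis=np.ascontiguousarray(basis),
        compressed_atoms=np.ascontiguousarray(compressed),
        singular_values=np.sqrt(evals),
    )


def compression_error(dic: Dictionary, rank: int) -> float:
    """Relative Frobenius error of the rank-``rank`` atom approximation."""
    if dic.singular_values is None:
        raise InvalidRankError("dictionary has no SVD spectrum; call compress first")
    s2 = dic.singular_values**2
    return float(np.sqrt(s2[rank:].sum() / s2.sum()))


def _match_matrices(dic: Dictionary) -> Tuple[np.ndarray, np.ndarray, bool]:
    """Return (atom matrix, per-atom norms, compressed?) for matching."""
    if dic.basis is not None:
        assert dic.compressed_atoms is not None
        atoms = dic.compressed_atoms
    else:
        atoms = dic.atoms
    norms = np.linalg.norm(atoms, axis=1)
    return atoms, norms, dic.basis is not None


def match_many(signals: np.ndarray, dic: Dictionary, chunk: int = 4096):
    """Exhaustively match rows of ``signals`` against the dictionary.

    ``signals`` may be real or complex, shaped (n_signals, n_timepoints) or,
    for a compressed dictionary, already projected to (n_signals, rank).
    Returns arrays (t1, t2, pd, correlation, index).  Ties in correlation
    break deterministically toward the smaller linear atom index.
    """
    signals = np.atleast_2d(signals)
    atoms, atom_norms, compressed = _match_matrices(dic)
    n_t = dic.n_timepoints if dic.atoms.shape[1] else None
    if compressed and signals.shape[1] == dic.basis.shape[0]:
        signals = signals @ dic.basis
    elif compressed and signals.shape[1] != dic.basis.shape[1]:
        raise NoMatchError(
            f"signal length {signals.shape[1]} matches neither the schedule "
            f"({dic.basis.shape[0]}) nor the basis rank ({dic.basis.shape[1]})"
        )
    elif not compressed and signals.shape[1] != atoms.shape[1]:
        raise NoMatchError(
            f"signal length {signals.shape[1]} != schedule length {atoms.shape[1]}"
        )
    sig_norms = np.linalg.norm(signals, axis=1)
    if np.any(sig_norms == 0.0):
        raise NoMatchError("all-zero signal cannot be matched")

    n = signals.shape[0]
    idx = np.empty(n, dtype=np.intp)
    corr = np.empty(n)
    pd = np.empty(n)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        inner = np.abs(signals[lo:hi] @ atoms.T.conj())
        best = np.argmax(inner, axis=1)  # first max: smallest linear index
        rows = np.arange(hi - lo)
        idx[lo:hi] = best
        corr[lo:hi] = inner[rows, best] / (sig_norms[lo:hi] * atom_norms[best])
        # least-squares amplitude of the matched (unit-timecourse) atom
        pd[lo:hi] = inner[rows, best] / atom_norms[best] ** 2
    corr = np.clip(corr, 0.0, 1.0)
    t1 = dic.pairs[idx, 0]
    t2 = dic.pairs[idx, 1]
    return t1, t2, pd, corr, idx


def match(signal: np.ndarray, dic: Dictionary) -> MatchResult:
    """Match a single fingerprint; see :func:`match_many`."""
    t1, t2, pd, corr, idx = match_many(np.asarray(signal)[None, :], dic)
    return MatchResult(
        t1_ms=float(t1[0]),
        t2_ms=float(t2[0]),
        pd=float(pd[0]),
        correlation=float(corr[0]),
        index=int(idx[0]),
    )


def match_volume(
    series: np.ndarray,
    dic: Dictionary,
    mask: Optional[np.ndarray] = None,
) -> ParameterMaps:
    """Voxel-wise matching of a signal time-series volume.

    ``series`` has the timepoint (or basis) dimension last.  Voxels outside
    ``mask`` (default: voxels with any nonzero signal) are set to 0 in every
    output map.
    """
    series = np.asarray(series)
    spatial = series.shape[:-1]
    if mask is None:
        mask = np.any(np.abs(series) > 0.0, axis=-1)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != spatial:
        raise ValueError(f"mask shape {mask.shape} != spatial shape {spatial}")
    if not np.any(mask):
        raise NoMatchError("empty mask")
    flat = series[mask]
    t1, t2, pd, corr, _ = match_many(flat, dic)
    maps = ParameterMaps(
        t1_ms=np.zeros(spatial),
        t2_ms=np.zeros(spatial),
        pd=np.zeros(spatial),
        correlation=np.zeros(spatial),
    )
    maps.t1_ms[mask] = t1
    maps.t2_ms[mask] = t2
    maps.pd[mask] = pd
    maps.correlation[mask] = corr
    return maps


def upsample_maps(maps: ParameterMaps, factor: int, order: str = "nearest") -> ParameterMaps:
    """Cosmetic display upsampling (nearest or linear); never used in any
    quantitative path."""
    from scipy.ndimage import zoom

    o = 0 if order == "nearest" else 1
    z = lambda a: zoom(a, factor, order=o, grid_mode=True, mode="grid-constant")
    return ParameterMaps(
        t1_ms=z(maps.t1_ms),
        t2_ms=z(maps.t2_ms),
        pd=z(maps.pd),
        correlation=z(maps.correlation),
    )
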