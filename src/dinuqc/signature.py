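"""Dinucleotide genomic signatures.

The genomic signature of a sequence is the vector of 16 odds ratios

    rho_XY = f_XY / (f_X * f_Y)

where f_X is the frequency of base X among informative (non-N) positions and
f_XY the frequency of dinucleotide XY among counted overlapping pairs. Because
genomic DNA is double stranded, the symmetrized form rho*_XY is computed after
pooling the counts of a sequence with those of its reverse complement, so that
rho*_XY == rho*_revcomp(XY) by construction. The coarse compositional distance
between two signatures f and g is

    delta* (f, g) = (1/16) * sum_XY | rho*_XY(f) - rho*_XY(g) |.

For compositionally random DNA every rho* entry is close to 1; in 50 kb windows
of random sequence, values above 1.23 or below 0.78 occur less than one time in
a thousand, which is the classical over-/under-representation criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple, Union

import numpy as np

from ._seq import BASES, DINUCS, RC_DINUC_INDEX, encode, iter_window_counts
from .errors import ConfigurationError, DegenerateSequenceError

__all__ = [
    "DinucCounts",
    "SignatureVector",
    "SignatureThresholds",
    "WindowProfile",
    "count_dinucleotides",
    "rho_star",
    "delta_star",
    "genome_signature",
    "delta_profile",
]


@dataclass
class DinucCounts:
    """Mono- and dinucleotide occurrence counts of one sequence (or window).

    ``informative_length`` is the number of non-N bases counted. Dinucleotides
    are counted with overlap; a pair spanning an N, or the junction of two
    separately counted sequences, is never counted, hence
    ``sum(dinuc.values()) <= informative_length``.
    """

    mono: Dict[str, int]
    dinuc: Dict[str, int]
    informative_length: int

    @classmethod
    def from_arrays(cls, mono: np.ndarray, pair: np.ndarray) -> "DinucCounts":
        return cls(
            mono={b: int(c) for b, c in zip(BASES, mono)},
            dinuc={d: int(c) for d, c in zip(DINUCS, pair)},
            informative_length=int(mono.sum()),
        )

    def mono_array(self) -> np.ndarray:
        return np.array([self.mono.get(b, 0) for b in BASES], dtype=np.int64)

    def dinuc_array(self) -> np.ndarray:
        return np.array([self.dinuc.get(d, 0) for d in DINUCS], dtype=np.int64)

    def __add__(self, other: "DinucCounts") -> "DinucCounts":
        """Pool counts of two disjoint sequences (no pair across the junction)."""
        return DinucCounts(
            mono={b: self.mono.get(b, 0) + other.mono.get(b, 0) for b in BASES},
            dinuc={d: self.dinuc.get(d, 0) + other.dinuc.get(d, 0) for d in DINUCS},
            informative_length=self.informative_length + other.informative_length,
        )


@dataclass
class SignatureVector:
    """The 16 (optionally symmetrized) dinucleotide odds ratios rho*_XY.

    Entries whose denominator f_X * f_Y is zero are undefined: they carry NaN
    in ``rho`` and False in ``defined`` (never 0 or infinity).
    """

    rho: Dict[str, float]
    symmetrized: bool
    defined: Dict[str, bool]

    def values(self) -> np.ndarray:
        """(16,) array in lexicographic dinucleotide order; NaN where undefined."""
        return np.array([self.rho[d] for d in DINUCS], dtype=float)

    def defined_mask(self) -> np.ndarray:
        return np.array([self.defined[d] for d in DINUCS], dtype=bool)

    @classmethod
    def from_arrays(cls, rho: np.ndarray, symmetrized: bool) -> "SignatureVector":
        defined = np.isfinite(rho)
        return cls(
            rho={d: float(v) for d, v in zip(DINUCS, rho)},
            symmetrized=symmetrized,
            defined={d: bool(m) for d, m in zip(DINUCS, defined)},
        )


@dataclass(frozen=True)
class SignatureThresholds:
    """Classical tail thresholds for rho* on random 50 kb windows.

    In i.i.d. random sequence, a defined rho*_XY falls outside (lower, upper)
    with probability below ``tail_probability``; values outside the band flag
    over-/under-represented dinucleotides.
    """

    upper: float = 1.23
    lower: float = 0.78
    tail_probability: float = 0.001

    def __post_init__(self) -> None:
        if not self.lower < 1.0 < self.upper:
            raise ConfigurationError("thresholds must satisfy lower < 1 < upper")


@dataclass
class WindowProfile:
    """Per-window metric values over half-open 0-based genomic intervals.

    ``values`` holds one float per window with NaN marking a missing window
    (too little informative sequence, or an undefined signature entry).
    Only the terminal window may be shorter than ``window_size``.
    """

    sequence_id: str
    windows: List[Tuple[int, int]]
    values: np.ndarray
    metric: str
    window_size: int
    step: int
    strand_symmetric: bool = True
    informative: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.windows) != self.values.size:
            raise ConfigurationError("values length must equal windows length")
        if self.informative is not None:
            self.informative = np.asarray(self.informative, dtype=np.int64)
            if self.informative.size != self.values.size:
                raise ConfigurationError("informative length must equal windows length")
        starts = [w[0] for w in self.windows]
        if starts != sorted(starts):
            raise ConfigurationError("windows must be sorted by start")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def starts(self) -> np.ndarray:
        return np.array([w[0] for w in self.windows], dtype=np.int64)

    @property
    def ends(self) -> np.ndarray:
        return np.array([w[1] for w in self.windows], dtype=np.int64)

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    @property
    def short(self) -> np.ndarray:
        """Flag for windows shorter than window_size (at most the terminal one)."""
        return np.array([e - s < self.window_size for s, e in self.windows], dtype=bool)

    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0

    def to_frame(self):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "sequence_id": self.sequence_id,
                "start": self.starts,
                "end": self.ends,
                "metric": self.metric,
                "value": self.values,
            }
        )
        frame["informative_length"] = (
            self.informative if self.informative is not None else pd.NA
        )
        return frame

    def reversed_values(self) -> np.ndarray:
        return self.values[::-1].copy()


def count_dinucleotides(sequence: str) -> DinucCounts:
    """Count bases and overlapping dinucleotides, excluding N entirely.

    N positions are excluded from the mononucleotide counts, and a dinucleotide
    is counted only when both members are non-N and adjacent: the flanks of an
    N run are never joined into a pair. An empty sequence yields zero counts.
    """
    codes = encode(sequence)
    from ._seq import mono_pair_counts

    mono, pair = mono_pair_counts(codes)
    return DinucCounts.from_arrays(mono, pair)


def _rho_from_arrays(
    mono: np.ndarray, pair: np.ndarray, symmetrize: bool
) -> np.ndarray:
    """(16,) rho vector from count arrays; NaN where f_X * f_Y == 0."""
    m = mono.astype(float)
    d = pair.astype(float)
    if symmetrize:
        m = m + m[::-1]  # A<->T, C<->G pooling
        d = d + d[RC_DINUC_INDEX]
    f_x = m / m.sum()
    f_xy = d / d.sum()
    denom = np.repeat(f_x, 4) * np.tile(f_x, 4)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, f_xy / np.where(denom > 0, denom, 1.0), np.nan)
    return rho


def rho_star(counts: DinucCounts, symmetrize: bool = True) -> SignatureVector:
    """Signature vector from counts, symmetrized by reverse-complement pooling.

    Symmetrization adds the counts of the reverse complement before forming
    frequencies: mononucleotide counts are pooled A with T and C with G, and
    each dinucleotide with its reverse complement. Entries whose component
    base frequencies vanish are flagged undefined (NaN), not set to 0.
    """
    if counts.informative_length < 2:
        raise DegenerateSequenceError(
            "need informative_length >= 2 to form a signature "
            f"(got {counts.informative_length})"
        )
    mono = counts.mono_array()
    pair = counts.dinuc_array()
    if pair.sum() == 0:
        raise DegenerateSequenceError(
            "no adjacent non-N base pairs: dinucleotide frequencies undefined"
        )
    return SignatureVector.from_arrays(_rho_from_arrays(mono, pair, symmetrize), symmetrize)


def delta_star(
    f: SignatureVector, g: SignatureVector, skip_undefined: bool = False
) -> float:
    """Mean absolute difference of two signature vectors ((1/16) * L1 norm).

    Both operands must carry the same symmetrization flag. By default an entry
    undefined in either vector is an error; with ``skip_undefined=True`` the
    distance is the mean |difference| over the entries defined in both (i.e.
    the sum is renormalized by the number of shared defined entries).
    """
    if f.symmetrized != g.symmetrized:
        raise ConfigurationError(
            "cannot compare signatures with different symmetrization flags"
        )
    va, vb = f.values(), g.values()
    shared = f.defined_mask() & g.defined_mask()
    if not skip_undefined and not shared.all():
        missing = [d for d, m in zip(DINUCS, shared) if not m]
        raise DegenerateSequenceError(
            f"undefined signature entries {missing}; "
            "enable skip_undefined to average over shared defined entries"
        )
    if shared.sum() == 0:
        raise DegenerateSequenceError("no entry defined in both signatures")
    return float(np.abs(va - vb)[shared].mean())


def genome_signature(
    records: Union[Mapping[str, str], Iterable[str]], symmetrize: bool = True
) -> SignatureVector:
    """Signature of a whole (multi-record) genome from pooled counts.

    Counts are pooled across records before forming the odds ratios; no
    dinucleotide spans a record boundary.
    """
    if isinstance(records, Mapping):
        seqs = list(records.values())
    else:
        seqs = list(records)
    if not seqs:
        raise DegenerateSequenceError("no records supplied")
    total: Optional[DinucCounts] = None
    for seq in seqs:
        counts = count_dinucleotides(seq)
        total = counts if total is None else total + counts
    assert total is not None
    return rho_star(total, symmetrize=symmetrize)


def delta_profile(
    record: str,
    baseline: SignatureVector,
    window_size: int = 50_000,
    step: Optional[int] = None,
    sequence_id: str = "seq",
) -> WindowProfile:
    """Windowed delta* of a sequence against a baseline signature.

    One delta* value per window of ``window_size`` bases (non-overlapping by
    default). A window is missing (NaN) when its informative length is below
    half the window size, when it contains no counted dinucleotide, or when
    any of its rho* entries is undefined. The terminal window may be shorter
    and is retained (see :attr:`WindowProfile.short`).
    """
    if window_size < 1_000:
        raise ConfigurationError("window_size must be >= 1000")
    if step is None:
        step = window_size
    if step < 1:
        raise ConfigurationError("step must be >= 1")
    if not baseline.defined_mask().all():
        raise ConfigurationError(
            "baseline signature has undefined entries; cannot scan against it"
        )
    base = baseline.values()
    codes = encode(record, name=sequence_id)
    windows: List[Tuple[int, int]] = []
    values: List[float] = []
    informative: List[int] = []
    half = window_size / 2.0
    for start, end, mono, pair, n_inf in iter_window_counts(codes, window_size, step):
        windows.append((start, end))
        informative.append(n_inf)
        if n_inf < half or pair.sum() == 0:
            values.append(np.nan)
            continue
        rho = _rho_from_arrays(mono, pair, baseline.symmetrized)
        if not np.isfinite(rho).all():
            values.append(np.nan)
            continue
        values.append(float(np.abs(rho - base).mean()))
    return WindowProfile(
        sequence_id=sequence_id,
        windows=windows,
        values=np.array(values, dtype=float),
        metric="delta_star",
        window_size=window_size,
        step=step,
        strand_symmetric=baseline.symmetrized,
        informative=np.array(informative, dtype=np.int64),
    )
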