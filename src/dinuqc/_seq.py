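"""Low-level sequence encoding shared by all modules.

Sequences are encoded as int8 arrays: A=0, C=1, G=2, T=3, N=-1. The complement
of code ``c`` is ``3 - c``, so reverse complementation is ``(3 - codes)[::-1]``
and the A<->T / C<->G pooling used for signature symmetrization is a simple
array reversal of the 4-vector of mononucleotide counts.
"""

from __future__ import annotations

from typing import Iterator, Tuple

import numpy as np

from .errors import InvalidSequenceError

BASES = "ACGT"
DINUCS = tuple(x + y for x in BASES for y in BASES)

#: code of revcomp(XY) for dinucleotide code 4x+y: (3-y, 3-x) -> 4*(3-y)+(3-x)
RC_DINUC_INDEX = np.array(
    [4 * (3 - (c % 4)) + (3 - (c // 4)) for c in range(16)], dtype=np.intp
)

_LUT = np.full(256, -2, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i
_LUT[ord("N")] = -1
_LUT[ord("n")] = -1

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)  # index -1 wraps to "N"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a string over {A,C,G,T,N} (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str, name: str = "sequence") -> np.ndarray:
    """Encode ``seq`` (uppercased implicitly) to int8 codes; N -> -1.

    Raises
    ------
    InvalidSequenceError
        If any character is outside {A, C, G, T, N} (either case); the message
        names ``name`` and the 0-based offending position.
    """
    try:
        raw = seq.encode("ascii")
    except UnicodeEncodeError as exc:
        raise InvalidSequenceError(
            f"invalid non-ASCII character in {name} at position {exc.start}"
        ) from None
    codes = _LUT[np.frombuffer(raw, dtype=np.uint8)]
    bad = np.flatnonzero(codes == -2)
    if bad.size:
        pos = int(bad[0])
        raise InvalidSequenceError(
            f"invalid character {seq[pos]!r} in {name} at position {pos}"
        )
    return codes


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; code -1 decodes to 'N'."""
    return _DECODE[codes].tobytes().decode("ascii")


def mono_pair_counts(codes: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """(4,) mononucleotide and (16,) overlapping-dinucleotide counts.

    N positions contribute to neither; a pair is counted only when both its
    bases are non-N and physically adjacent (no pairing across N runs).
    """
    mono = np.bincount(codes[codes >= 0], minlength=4)[:4].astype(np.int64)
    if codes.size < 2:
        return mono, np.zeros(16, dtype=np.int64)
    a = codes[:-1]
    b = codes[1:]
    valid = (a >= 0) & (b >= 0)
    pair = np.bincount((a[valid] * 4 + b[valid]).astype(np.int64), minlength=16)[
        :16
    ].astype(np.int64)
    return mono, pair


def make_windows(length: int, window_size: int, step: int) -> list[tuple[int, int]]:
    """0-based half-open windows covering [0, length); terminal window may be short."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")
    return [(s, min(s + window_size, length)) for s in range(0, length, step)]


def iter_window_counts(
    codes: np.ndarray, window_size: int, step: int
) -> Iterator[Tuple[int, int, np.ndarray, np.ndarray, int]]:
    """Yield (start, end, mono4, pair16, informative) for each window."""
    for start, end in make_windows(codes.size, window_size, step):
        mono, pair = mono_pair_counts(codes[start:end])
        yield start, end, mono, pair, int(mono.sum())
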