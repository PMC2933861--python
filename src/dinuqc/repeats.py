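"""Satellite monomer search, tandem-array clustering, and periodicity scan.

Centromeric satellite arrays are tandem repeats of a short monomer (~91 bp in
soybean) whose composition differs sharply from the genome background. The
search here is deliberately ungapped: a hit is a full-length alignment of the
monomer (either strand) with identity = matches / monomer length at or above
the identity floor. Hits closer than a gap threshold (a multiple of the
monomer length, default 10x) chain into arrays.

The matcher uses pigeonhole-seeded exact k-mers with Hamming verification:
with at most m mismatches allowed, the monomer is split into m+1 disjoint
k-mers, at least one of which must match exactly; every exact occurrence of a
seed nominates one candidate offset, which is then verified over the full
monomer length. This is exhaustive for ungapped matches. When the monomer is
too short to give informative seeds the scan falls back to verifying every
offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Union

import numpy as np

from ._seq import encode
from .errors import ConfigurationError, InvalidSequenceError
from .signature import SignatureVector, count_dinucleotides, rho_star

__all__ = [
    "RepeatSearchParams",
    "MonomerHit",
    "RepeatArray",
    "PeriodScore",
    "find_monomer_hits",
    "cluster_arrays",
    "array_signature",
    "detect_tandem_periods",
]


@dataclass(frozen=True)
class RepeatSearchParams:
    """Monomer search parameters.

    ``max_gap_factor`` sets the array-chaining threshold to
    ``max_gap_factor * len(monomer)`` bases between consecutive hit starts
    (e.g. 910 bp for a 91-mer at the default factor of 10).
    """

    monomer: str
    min_identity: float = 0.90
    max_gap_factor: float = 10.0

    def __post_init__(self) -> None:
        if len(self.monomer) < 20:
            raise ConfigurationError("monomer must be at least 20 bases")
        if "N" in self.monomer.upper():
            raise InvalidSequenceError("monomer must be N-free")
        encode(self.monomer, name="monomer")  # alphabet check
        if not 0.0 < self.min_identity <= 1.0:
            raise ConfigurationError("min_identity must be in (0, 1]")
        if self.max_gap_factor < 1.0:
            raise ConfigurationError("max_gap_factor must be >= 1")

    @property
    def monomer_length(self) -> int:
        return len(self.monomer)

    @property
    def gap_threshold(self) -> float:
        return self.max_gap_factor * self.monomer_length

    @property
    def max_mismatches(self) -> int:
        return int((1.0 - self.min_identity) * self.monomer_length + 1e-9)


@dataclass(frozen=True)
class MonomerHit:
    """One ungapped full-length monomer match (0-based start on the + strand)."""

    sequence_id: str
    start: int
    end: int
    strand: str
    identity: float


@dataclass(frozen=True)
class RepeatArray:
    """A tandem array: >= 2 hits chained within the gap threshold."""

    sequence_id: str
    start: int
    end: int
    hit_count: int
    mean_identity: float
    strand_mix: float  # fraction of reverse-strand hits


@dataclass(frozen=True)
class PeriodScore:
    """Lag-match score for one candidate period; harmonic_of marks multiples."""

    period: int
    score: float
    harmonic_of: int | None = None


def _kmer_hit_positions(codes: np.ndarray, kmer: np.ndarray) -> np.ndarray:
    """Start positions of exact occurrences of ``kmer`` in ``codes``."""
    k = kmer.size
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    match = codes[:n] == kmer[0]
    for t in range(1, k):
        match &= codes[t : t + n] == kmer[t]
    return np.flatnonzero(match).astype(np.int64)


def _candidate_starts(codes: np.ndarray, pattern: np.ndarray, max_mm: int) -> np.ndarray:
    """Candidate alignment starts for ``pattern`` with <= max_mm mismatches."""
    L = pattern.size
    k = L // (max_mm + 1)
    if k < 4:
        # Degenerate seeding: verify every offset.
        n = codes.size - L + 1
        return np.arange(max(n, 0), dtype=np.int64)
    starts = []
    for i in range(max_mm + 1):
        off = i * k
        pos = _kmer_hit_positions(codes, pattern[off : off + k])
        starts.append(pos - off)
    cand = np.unique(np.concatenate(starts)) if starts else np.empty(0, np.int64)
    return cand[(cand >= 0) & (cand + L <= codes.size)]


def _verify(codes: np.ndarray, starts: np.ndarray, pattern: np.ndarray) -> np.ndarray:
    """Identity (matches / length) of the full-length alignment at each start."""
    if starts.size == 0:
        return np.empty(0, dtype=float)
    idx = starts[:, None] + np.arange(pattern.size)[None, :]
    return (codes[idx] == pattern[None, :]).sum(axis=1) / pattern.size


def _local_identity_maxima(
    starts: np.ndarray, idents: np.ndarray, L: int
) -> np.ndarray:
    """Keep indices that are local identity maxima among overlapping hits.

    Two hits overlap when their starts differ by less than L. A hit survives
    unless some overlapping hit has strictly higher identity, or equal
    identity and a smaller start (so the earliest hit of a tie plateau wins).
    """
    n = starts.size
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        j = i - 1
        while j >= 0 and starts[i] - starts[j] < L:
            if idents[j] >= idents[i]:
                keep[i] = False
                break
            j -= 1
        if not keep[i]:
            continue
        j = i + 1
        while j < n and starts[j] - starts[i] < L:
            if idents[j] > idents[i]:
                keep[i] = False
                break
            j += 1
    return np.flatnonzero(keep)


def find_monomer_hits(
    genome: Union[Mapping[str, str], str], params: RepeatSearchParams
) -> List[MonomerHit]:
    """All full-length ungapped monomer matches at >= min_identity, both strands.

    N bases in the genome count as mismatches. Overlapping hits on the same
    strand are reduced to local identity maxima. Hits are returned sorted by
    (sequence_id, start, strand).
    """
    if isinstance(genome, str):
        genome = {"seq": genome}
    fwd = encode(params.monomer, name="monomer")
    rev = (3 - fwd)[::-1]
    L = params.monomer_length
    hits: List[MonomerHit] = []
    for seq_id, seq in genome.items():
        codes = encode(seq, name=seq_id)
        if codes.size < L:
            continue
        for strand, pattern in (("+", fwd), ("-", rev)):
            cand = _candidate_starts(codes, pattern, params.max_mismatches)
            idents = _verify(codes, cand, pattern)
            ok = idents >= params.min_identity - 1e-12
            starts, idents = cand[ok], idents[ok]
            kept = _local_identity_maxima(starts, idents, L)
            for i in kept:
                hits.append(
                    MonomerHit(
                        sequence_id=seq_id,
                        start=int(starts[i]),
                        end=int(starts[i]) + L,
                        strand=strand,
                        identity=float(idents[i]),
                    )
                )
    hits.sort(key=lambda h: (h.sequence_id, h.start, h.strand))
    return hits


def cluster_arrays(
    hits: Sequence[MonomerHit], params: RepeatSearchParams
) -> List[RepeatArray]:
    """Chain hits into tandem arrays by single linkage on start positions.

    Consecutive hits (per sequence, sorted by start, strands mixed freely)
    whose starts differ by at most ``params.gap_threshold`` join one array;
    arrays need at least 2 hits, and the interval spans the first hit start to
    the last hit end. Input ordering does not matter.
    """
    by_seq: Dict[str, List[MonomerHit]] = {}
    for h in hits:
        by_seq.setdefault(h.sequence_id, []).append(h)
    arrays: List[RepeatArray] = []
    for seq_id in sorted(by_seq):
        rows = sorted(by_seq[seq_id], key=lambda h: h.start)
        chain: List[MonomerHit] = []
        for h in rows + [None]:  # type: ignore[list-item]
            if chain and (h is None or h.start - chain[-1].start > params.gap_threshold):
                if len(chain) >= 2:
                    arrays.append(
                        RepeatArray(
                            sequence_id=seq_id,
                            start=chain[0].start,
                            end=max(c.end for c in chain),
                            hit_count=len(chain),
                            mean_identity=float(
                                np.mean([c.identity for c in chain])
                            ),
                            strand_mix=float(
                                np.mean([c.strand == "-" for c in chain])
                            ),
                        )
                    )
                chain = []
            if h is not None:
                chain.append(h)
    return arrays


def array_signature(
    genome: Union[Mapping[str, str], str],
    array: RepeatArray,
    symmetrize: bool = True,
) -> SignatureVector:
    """Symmetrized rho* of the array's sequence slice."""
    if isinstance(genome, str):
        genome = {"seq": genome}
    if array.sequence_id not in genome:
        raise ConfigurationError(f"sequence {array.sequence_id!r} not in genome")
    seq = genome[array.sequence_id]
    if not 0 <= array.start < array.end <= len(seq):
        raise ConfigurationError(
            f"array interval [{array.start}, {array.end}) outside sequence "
            f"of length {len(seq)}"
        )
    return rho_star(count_dinucleotides(seq[array.start : array.end]), symmetrize)


def detect_tandem_periods(
    sequence: str, max_period: int = 200, harmonic_tolerance: float = 0.02
) -> List[PeriodScore]:
    """Rank candidate tandem periods by the lag-match score.

    score(p) is the fraction of positions i with base(i) == base(i+p), over
    positions where both bases are non-N. An exactly p-periodic sequence
    scores 1.0 at p and at its multiples; i.i.d. uniform sequence scores
    about 0.25 everywhere. Results are sorted by descending score (ties by
    smaller period). A period is annotated as a harmonic of its smallest
    divisor scoring within ``harmonic_tolerance`` of it — multiples of the
    fundamental score the same in expectation, so sampling noise alone must
    not promote a harmonic to fundamental.
    """
    codes = encode(sequence)
    if codes.size < 2 * max_period:
        raise ConfigurationError(
            f"sequence length {codes.size} < 2 * max_period ({2 * max_period})"
        )
    scores: Dict[int, float] = {}
    for p in range(1, max_period + 1):
        a, b = codes[:-p], codes[p:]
        valid = (a >= 0) & (b >= 0)
        n = int(valid.sum())
        scores[p] = float((a[valid] == b[valid]).mean()) if n else float("nan")
    ranked = sorted(
        scores.items(), key=lambda t: (-(t[1] if np.isfinite(t[1]) else -1), t[0])
    )
    out: List[PeriodScore] = []
    for p, score in ranked:
        base = next(
            (
                q
                for q in range(2, p)
                if p % q == 0
                and np.isfinite(scores[q])
                and scores[q] >= score - harmonic_tolerance
            ),
            None,
        )
        out.append(PeriodScore(period=p, score=score, harmonic_of=base))
    return out
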