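"""Synthetic genomes with known compositional architecture, plus shredding.

The generator emulates a plant chromosome as seen through windowed composition
profiles: euchromatic arms of low GC, a pericentromere whose elevated GC comes
from dense GC-rich LTR-like insertions (background without them matches the
arms), and a centromeric tandem array of a short CG-enriched satellite
monomer. Region backgrounds are first-order Markov chains, so dinucleotide
step biases are controllable independently of GC — the satellite's CG
enrichment produces a delta* peak distinct from the broad GC-driven
binding-energy pattern.

Region GC values are *realized* targets: when LTR-like elements occupy a
fraction f of a region at GC g_ltr, the background is generated at
(gc_target - f * g_ltr) / (1 - f), so the mixed region lands on target.

``shred_genome`` cuts a chromosome into scaffolds, reverse-complements a
seeded subset in the emitted object, and writes an AGP that (wrongly) claims
"+" orientation for everything — the truth table keeps the real orientations,
giving ground truth for flip evaluation.

All randomness flows from numpy Generators seeded by the spec seeds; a fixed
seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from ._seq import DINUCS, decode, encode
from .assembly_qc import AssemblyLayout, Placement
from .errors import SpecError

__all__ = [
    "RegionSpec",
    "SatelliteSpec",
    "LTRSpec",
    "GenomeSpec",
    "ShredSpec",
    "TruthTable",
    "default_genome_spec",
    "make_genome",
    "shred_genome",
    "random_windows",
]

#: Mild step depletions typical of plant nuclear backgrounds; applied to every
#: region so the genome is signature-homogeneous outside the satellite array.
DEFAULT_STEP_BIAS: Dict[str, float] = {"CG": 0.85, "TA": 0.90}

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    @njit(cache=False)
    def _walk(cum: np.ndarray, u: np.ndarray, start: int) -> np.ndarray:
        out = np.empty(u.size, dtype=np.int8)
        s = start
        for i in range(u.size):
            x = 0
            row = cum[s]
            while row[x] < u[i]:
                x += 1
            out[i] = x
            s = x
        return out

except ImportError:  # pragma: no cover

    def _walk(cum: np.ndarray, u: np.ndarray, start: int) -> np.ndarray:
        out = np.empty(u.size, dtype=np.int8)
        s = start
        for i in range(u.size):
            x = 0
            row = cum[s]
            while row[x] < u[i]:
                x += 1
            out[i] = x
            s = x
        return out


def _stationary(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of a 4-state transition matrix."""
    A = np.vstack([T.T - np.eye(4), np.ones(4)])
    b = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return np.clip(pi, 0.0, None) / pi.sum()


def _symmetrized_bias(step_bias: Mapping[str, float]) -> np.ndarray:
    """(4,4) multiplicative step weights, applied to each step and its revcomp."""
    B = np.ones((4, 4), dtype=float)
    for dinuc, w in step_bias.items():
        dinuc = dinuc.upper()
        if dinuc not in DINUCS:
            raise SpecError(f"unknown dinucleotide {dinuc!r} in step bias")
        if w <= 0:
            raise SpecError(f"step bias for {dinuc} must be positive (got {w})")
        x, y = "ACGT".index(dinuc[0]), "ACGT".index(dinuc[1])
        B[x, y] = w
        B[3 - y, 3 - x] = w  # reverse-complement step shares the weight
    return B


def transition_matrix(
    gc: float, step_bias: Optional[Mapping[str, float]] = None
) -> np.ndarray:
    """First-order transition matrix whose stationary GC equals ``gc``.

    Rows are T[x, y] proportional to q[y] * B[x, y]; the emission weights q
    are solved by fixed-point iteration so the chain's stationary composition
    hits the strand-symmetric target (A=T=(1-gc)/2, C=G=gc/2) despite the
    step bias.
    """
    if not 0.0 < gc < 1.0:
        raise SpecError(f"GC target must be in (0, 1), got {gc}")
    target = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    B = _symmetrized_bias(step_bias if step_bias is not None else DEFAULT_STEP_BIAS)
    q = target.copy()
    T = q[None, :] * B
    for _ in range(500):
        T = q[None, :] * B
        T /= T.sum(axis=1, keepdims=True)
        pi = _stationary(T)
        err = np.abs(pi - target).max()
        if err < 1e-12:
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            q = q * target / np.where(pi > 0, pi, 1.0)
        if not np.all(np.isfinite(q)) or q.sum() <= 0:
            raise SpecError("infeasible composition/bias combination")
        q /= q.sum()
    else:
        if err > 1e-6:
            raise SpecError(
                f"no Markov chain found for gc={gc} with the given step bias "
                f"(residual {err:.2g})"
            )
    return T


def _sample_chain(
    T: np.ndarray, n: int, rng: np.random.Generator, start: Optional[int] = None
) -> np.ndarray:
    if n <= 0:
        return np.empty(0, dtype=np.int8)
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.1  # guard against u ~ 1.0 rounding past the last bin
    if start is None:
        pi = _stationary(T)
        start = int(rng.choice(4, p=pi))
    return _walk(cum, rng.random(n), start)


@dataclass(frozen=True)
class RegionSpec:
    """One chromosomal region.

    ``gc`` is the realized regional GC target (including LTR-like insertions).
    ``gc_end`` turns the region into a linear GC ramp from ``gc`` to
    ``gc_end``. ``ltr_density`` is insertions per Mb.
    """

    label: str
    length: int
    gc: float
    gc_end: Optional[float] = None
    ltr_density: float = 0.0
    step_bias: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise SpecError(f"region {self.label!r}: length must be positive")
        for g in (self.gc, self.gc_end):
            if g is not None and not 0.0 < g < 1.0:
                raise SpecError(f"region {self.label!r}: GC {g} outside (0, 1)")
        if self.ltr_density < 0:
            raise SpecError(f"region {self.label!r}: negative LTR density")


@dataclass(frozen=True)
class SatelliteSpec:
    """Centromeric tandem array specification.

    If ``monomer`` is None a monomer of ``monomer_length`` bases is generated
    from a Markov chain with a strong CG step enrichment and CC/GG depletion,
    giving the array a high rho*_CG and low rho*_CC/GG relative to the genome.
    Copies are head-to-tail with independent per-base substitutions.
    """

    monomer: Optional[str] = None
    monomer_length: int = 91
    array_length: int = 200_000
    substitution_rate: float = 0.02
    gc: float = 0.50
    cg_step_weight: float = 6.0
    cc_step_weight: float = 0.30
    region: str = "pericentromere"

    def __post_init__(self) -> None:
        if self.monomer is None and self.monomer_length < 20:
            raise SpecError("monomer_length must be >= 20")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise SpecError("substitution_rate must be in [0, 1)")
        if self.array_length <= 0:
            raise SpecError("array_length must be positive")


@dataclass(frozen=True)
class LTRSpec:
    """LTR-retrotransposon-like element family (GC-rich relative to arms)."""

    length: int = 5_000
    gc: float = 0.39
    step_bias: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise SpecError("LTR length must be positive")
        if not 0.0 < self.gc < 1.0:
            raise SpecError("LTR GC must be in (0, 1)")


@dataclass
class GenomeSpec:
    """Full synthetic-chromosome specification (one chromosome per spec)."""

    regions: List[RegionSpec]
    satellite: Optional[SatelliteSpec] = None
    ltr: LTRSpec = field(default_factory=LTRSpec)
    seed: int = 0
    name: str = "chr1"

    def __post_init__(self) -> None:
        if not self.regions:
            raise SpecError("at least one region is required")
        if self.satellite is not None:
            labels = [r.label for r in self.regions]
            if self.satellite.region not in labels:
                raise SpecError(
                    f"satellite region {self.satellite.region!r} not among "
                    f"regions {labels}"
                )


@dataclass(frozen=True)
class ShredSpec:
    """How to cut a chromosome into scaffolds with known (hidden) flips."""

    min_length: int = 400_000
    max_length: int = 800_000
    fraction_flipped: float = 0.0
    gap_length: int = 100
    seed: int = 0
    flip_region: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.min_length > self.max_length:
            raise SpecError("min_length > max_length")
        if self.min_length < 1:
            raise SpecError("min_length must be positive")
        if not 0.0 <= self.fraction_flipped <= 1.0:
            raise SpecError("fraction_flipped must be in [0, 1]")
        if self.gap_length < 0:
            raise SpecError("gap_length must be non-negative")


@dataclass
class TruthTable:
    """Ground truth emitted alongside generated/shredded sequences.

    ``regions``/``satellite``/``insertions`` are in source-chromosome
    coordinates; ``scaffolds`` maps scaffold id to (source_start, source_end,
    true_orientation) and ``scaffold_objects`` to the object each scaffold was
    placed on.
    """

    regions: List[Tuple[str, int, int]] = field(default_factory=list)
    satellite: Optional[Tuple[int, int]] = None
    insertions: List[Tuple[int, int]] = field(default_factory=list)
    scaffolds: Dict[str, Tuple[int, int, str]] = field(default_factory=dict)
    scaffold_objects: Dict[str, str] = field(default_factory=dict)

    def region_boundaries(self) -> List[int]:
        """Internal region cut positions, usable with region_stats."""
        return [end for _, _, end in self.regions[:-1]]


def _region_background(
    region: RegionSpec, ltr: LTRSpec, rng: np.random.Generator
) -> Tuple[np.ndarray, List[Tuple[int, int]]]:
    """Region codes with LTR-like insertions; returns (codes, insertion intervals)."""
    n_ins = int(round(region.ltr_density * region.length / 1e6))
    ltr_total = n_ins * ltr.length
    if ltr_total >= region.length:
        raise SpecError(
            f"region {region.label!r}: LTR occupancy {ltr_total} exceeds length"
        )
    frac = ltr_total / region.length
    bg_len = region.length - ltr_total

    def background_gc(target: float) -> float:
        g = (target - frac * ltr.gc) / (1.0 - frac) if frac else target
        if not 0.0 < g < 1.0:
            raise SpecError(
                f"region {region.label!r}: background GC {g:.3f} infeasible for "
                f"target {target} with LTR fraction {frac:.2f}"
            )
        return g

    # Background, possibly a GC ramp sampled in chunks with chained state.
    chunks: List[np.ndarray] = []
    if region.gc_end is None:
        T = transition_matrix(background_gc(region.gc), region.step_bias)
        bg = _sample_chain(T, bg_len, rng)
    else:
        chunk = 100_000
        start_state: Optional[int] = None
        done = 0
        while done < bg_len:
            size = min(chunk, bg_len - done)
            mid_frac = (done + size / 2) / bg_len
            gc_here = region.gc + (region.gc_end - region.gc) * mid_frac
            T = transition_matrix(background_gc(gc_here), region.step_bias)
            piece = _sample_chain(T, size, rng, start=start_state)
            start_state = int(piece[-1])
            chunks.append(piece)
            done += size
        bg = np.concatenate(chunks) if chunks else np.empty(0, np.int8)

    if n_ins == 0:
        return bg, []
    T_ltr = transition_matrix(ltr.gc, ltr.step_bias)
    # Split the background into n_ins + 1 chunks of random (multinomial) sizes.
    sizes = rng.multinomial(bg_len, np.full(n_ins + 1, 1.0 / (n_ins + 1)))
    parts: List[np.ndarray] = []
    intervals: List[Tuple[int, int]] = []
    cursor = 0
    offset = 0
    for i in range(n_ins + 1):
        parts.append(bg[cursor : cursor + sizes[i]])
        cursor += sizes[i]
        offset += sizes[i]
        if i < n_ins:
            element = _sample_chain(T_ltr, ltr.length, rng)
            parts.append(element)
            intervals.append((offset, offset + ltr.length))
            offset += ltr.length
    return np.concatenate(parts), intervals


def _satellite_array(
    sat: SatelliteSpec, rng: np.random.Generator
) -> Tuple[np.ndarray, str]:
    """(array codes, monomer string) for the centromeric tandem array."""
    if sat.monomer is not None:
        monomer = encode(sat.monomer, name="satellite monomer")
        if (monomer < 0).any():
            raise SpecError("satellite monomer must be N-free")
    else:
        T = transition_matrix(
            sat.gc,
            {"CG": sat.cg_step_weight, "CC": sat.cc_step_weight},
        )
        monomer = _sample_chain(T, sat.monomer_length, rng)
    L = monomer.size
    copies = int(np.ceil(sat.array_length / L))
    array = np.tile(monomer, copies)[: sat.array_length].copy()
    if sat.substitution_rate > 0:
        hit = rng.random(array.size) < sat.substitution_rate
        # substitute uniformly among the three other bases
        shift = rng.integers(1, 4, size=int(hit.sum()))
        array[hit] = (array[hit] + shift) % 4
    return array.astype(np.int8), decode(monomer)


def default_genome_spec(seed: int = 0) -> GenomeSpec:
    """The default study chromosome: 5 Mb arms (GC 0.32) around a 5 Mb
    pericentromere (GC 0.37 via ~2/3 occupancy of GC-0.39 LTR-like elements
    over a GC-0.33 background) carrying a 200 kb CG-enriched satellite array.
    """
    return GenomeSpec(
        regions=[
            RegionSpec(label="arm_left", length=5_000_000, gc=0.32, ltr_density=4.0),
            RegionSpec(
                label="pericentromere",
                length=5_000_000,
                gc=0.37,
                ltr_density=133.0,
            ),
            RegionSpec(label="arm_right", length=5_000_000, gc=0.32, ltr_density=4.0),
        ],
        satellite=SatelliteSpec(),
        ltr=LTRSpec(),
        seed=seed,
    )


def make_genome(spec: GenomeSpec) -> Tuple[Dict[str, str], TruthTable]:
    """Generate the chromosome described by ``spec``.

    Returns ({name: sequence}, truth) where the truth table records region
    intervals, LTR-like insertion intervals, and the satellite array interval
    (all 0-based half-open). Deterministic in ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    truth = TruthTable()
    pieces: List[np.ndarray] = []
    offset = 0
    region_offsets: Dict[str, int] = {}
    for region in spec.regions:
        codes, insertions = _region_background(region, spec.ltr, rng)
        region_offsets[region.label] = offset
        truth.regions.append((region.label, offset, offset + region.length))
        truth.insertions.extend((offset + a, offset + b) for a, b in insertions)
        pieces.append(codes)
        offset += region.length
    genome = np.concatenate(pieces)

    if spec.satellite is not None:
        sat = spec.satellite
        array, _monomer = _satellite_array(sat, rng)
        region = next(r for r in spec.regions if r.label == sat.region)
        if array.size > region.length:
            raise SpecError("satellite array longer than its host region")
        mid = region_offsets[sat.region] + region.length // 2
        start = mid - array.size // 2
        end = start + array.size
        genome[start:end] = array
        truth.satellite = (start, end)
        # insertions overwritten by the array are no longer present
        truth.insertions = [
            (a, b) for a, b in truth.insertions if b <= start or a >= end
        ]
    return {spec.name: decode(genome)}, truth


def shred_genome(
    sequences: Mapping[str, str], shred: ShredSpec
) -> Tuple[Dict[str, str], AssemblyLayout, TruthTable]:
    """Cut chromosomes into scaffolds, secretly flipping a seeded subset.

    Returns (object sequences, layout, truth). Each chromosome ``c`` becomes
    one object ``c_asm``: its scaffolds in original order, a seeded subset
    reverse-complemented, joined by N-gaps of ``gap_length``. The layout
    claims "+" orientation for every scaffold (the assembly's believed state);
    the truth table holds each scaffold's source interval and true
    orientation. Only scaffolds fully inside ``flip_region`` (if set) are
    flip candidates.
    """
    rng = np.random.default_rng(shred.seed)
    objects: Dict[str, str] = {}
    placements: List[Placement] = []
    truth = TruthTable()
    for chrom, seq in sequences.items():
        codes = encode(seq, name=chrom)
        n = codes.size
        # cut positions
        cuts = [0]
        while n - cuts[-1] > shred.max_length:
            cuts.append(cuts[-1] + int(rng.integers(shred.min_length, shred.max_length + 1)))
        cuts.append(n)
        if len(cuts) > 2 and cuts[-1] - cuts[-2] < shred.min_length // 2:
            # merge a runt terminal piece into its neighbor
            cuts.pop(-2)
        object_id = f"{chrom}_asm"
        parts: List[np.ndarray] = []
        cursor = 0
        for i, (a, b) in enumerate(zip(cuts[:-1], cuts[1:])):
            scaffold_id = f"{chrom}_scaf{i + 1}"
            candidate = shred.flip_region is None or (
                a >= shred.flip_region[0] and b <= shred.flip_region[1]
            )
            flip = bool(candidate and rng.random() < shred.fraction_flipped)
            piece = codes[a:b]
            if flip:
                piece = (3 - piece)[::-1]
                piece[piece > 3] = -1  # N (code -1) maps to 4 under 3-c; restore
            if i > 0 and shred.gap_length > 0:
                placements.append(
                    Placement(
                        object_id=object_id,
                        object_start=cursor,
                        object_end=cursor + shred.gap_length,
                        component_id=None,
                        component_type="gap",
                        gap_length=shred.gap_length,
                    )
                )
                parts.append(np.full(shred.gap_length, -1, dtype=np.int8))
                cursor += shred.gap_length
            placements.append(
                Placement(
                    object_id=object_id,
                    object_start=cursor,
                    object_end=cursor + piece.size,
                    component_id=scaffold_id,
                    orientation="+",  # the assembly's (possibly wrong) belief
                    component_type="sequence",
                )
            )
            parts.append(piece)
            cursor += piece.size
            truth.scaffolds[scaffold_id] = (a, b, "-" if flip else "+")
            truth.scaffold_objects[scaffold_id] = object_id
        objects[object_id] = decode(np.concatenate(parts))
    return objects, AssemblyLayout(placements), truth


def random_windows(
    n: int,
    window_size: int,
    composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> List[str]:
    """n i.i.d. random sequences of ``window_size`` bases (A, C, G, T order).

    The null model behind the rho* tail thresholds. Deterministic under
    ``seed``; generated in chunks to bound memory.
    """
    p = np.asarray(composition, dtype=float)
    if p.size != 4 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise SpecError("composition must be 4 non-negative frequencies summing to 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    cum = np.cumsum(p)
    cum[-1] = 1.0
    out: List[str] = []
    chunk = max(1, int(2e7) // max(window_size, 1))
    done = 0
    while done < n:
        m = min(chunk, n - done)
        u = rng.random((m, window_size))
        codes = np.searchsorted(cum, u).astype(np.int8)
        out.extend(decode(codes[i]) for i in range(m))
        done += m
    return out
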