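# Methods

## Dinucleotide signature

For a sequence with mononucleotide frequencies f_X and overlapping-
dinucleotide frequencies f_XY, the signature entry is the odds ratio
ρ_XY = f_XY / (f_X f_Y). Frequencies are taken over *informative* content
only: N positions are excluded from the base counts, and a dinucleotide is
counted only when both bases are non-N and physically adjacent — the flanks
of an N run (and therefore of an assembly gap) are never joined into a pair.
Dinucleotides are counted with overlap (every position i contributes the
pair at i, i+1), for signatures and for binding energy alike.

Because genomic DNA is double stranded, the symmetrized form ρ\*_XY pools
the counts of the sequence with those of its reverse complement before
forming frequencies: base counts are pooled A↔T and C↔G, and each
dinucleotide with its reverse complement. This makes ρ\*_XY = ρ\*_revcomp(XY)
an identity of the construction, and makes every windowed signature metric
strand symmetric — the property the flip evaluation relies on. An entry
whose denominator f_X f_Y vanishes is *undefined* and propagates as missing
(NaN), never as 0 or ∞; δ\* over vectors with undefined entries is an error
unless the caller opts into skip-and-renormalize (mean |difference| over
the entries defined in both).

δ\*(f, g) = (1/16) Σ |ρ\*_XY(f) − ρ\*_XY(g)| is 1/16 of an L1 norm, hence
symmetric, zero on identical vectors, and triangle-inequality-consistent.

Windowed δ\* compares each window of a chromosome (default 50 kb,
non-overlapping) against a baseline signature, normally the whole-genome
signature pooled over all records. A window is missing when its informative
length is below half the window size or any ρ\* entry is undefined; the
terminal window may be shorter and is flagged. Windows are 0-based
half-open throughout; AGP is converted at the I/O boundary. Soft-masked
(lowercase) bases are uppercased and counted — masking carries no signal
for these statistics.

The classical null calibration — a defined ρ\*_XY outside (0.78, 1.23) less
than one time in a thousand — is checked against i.i.d. *uniform* 50 kb
windows (10,000 of them in the acceptance suite). Uniform composition is
the default null; genome-matched composition can be passed to
`random_windows` instead.

## Nearest-neighbor binding energy

The packaged table holds the consensus free energy of binding ΔG° (kcal/mol
at 37 °C) for the 10 unique nearest-neighbor pairs, expanded to 16
dinucleotides by reverse-complement sharing (AA/TT −1.00, AC/GT −1.44,
AG/CT −1.28, AT −0.88, CA/TG −1.45, CC/GG −1.84, CG −2.17, GC −2.24,
GA/TC −1.30, TA −0.58). Alternative parameter sets load from a two-column
TSV. Window energy is the mean ΔG° over counted dinucleotides — the
denominator is the number of counted *pairs*, not bases — so any N-free
window lies in [−2.24, −0.58]. Values are stored signed; profiles report
the positive magnitude by default because the per-window means are
conventionally quoted on that scale, and a flag restores signed output.
Profile correlation is Pearson's r (the correlation type is otherwise
unconstrained), computed after dropping windows missing in either profile,
requiring ≥ 3 survivors.

## Junction scores and flip evaluation

Given a profile and a scaffold layout, each scaffold–scaffold junction is
scored as |mean of the k nearest non-missing windows fully inside the left
scaffold − same on the right| (default k = 3, i.e. 150 kb per side at the
default window: wide enough to damp single-window noise, narrow enough for
short pericentromeric scaffolds). Windows straddling a junction or a
scaffold end belong to neither side; gaps between scaffolds do not create
junctions of their own.

A flip is evaluated by reversing the order of the windows fully inside the
scaffold — exact for strand-symmetric metrics, no sequence re-read — and
comparing the sum of the scaffold's junction discontinuities before and
after. A junction unscorable in either orientation is dropped from both
sums for comparability. The suggestion threshold defaults to 2× the median
absolute successive-window difference of the whole profile, a robust noise
scale: the underlying judgment is inherently a judgment call, so the
threshold is explicit and configurable rather than hidden. Scaffolds
spanning fewer than 2k windows are reported low-confidence and never
suggested. Because flips are evaluated on window values, profiles built
from non-symmetrized signatures are refused rather than silently
approximated.

Region statistics assign each window to the region containing its midpoint,
exclude missing windows, and report mean and sample SD (n−1). Region
boundaries are caller input — euchromatin/heterochromatin limits are
assembly-specific and never hard-coded.

## Satellite search and periodicity

The monomer matcher is deliberately ungapped: at ~90 % identity over a
~91 bp monomer, indel-free matching covers the tandem-array use case while
keeping identity exactly matches/monomer-length (full-length alignments
only; N counts as mismatch). Candidates come from pigeonhole seeding —
with m mismatches allowed, one of m+1 disjoint k-mers must match exactly —
followed by full Hamming verification, which is exhaustive for ungapped
matches; monomers too short for informative seeds fall back to scoring
every offset. Overlapping same-strand hits reduce to local identity maxima
(ties resolve to the earliest start). Arrays are single-linkage chains of
hits whose starts lie within max_gap_factor × monomer length (default 10×,
e.g. 910 bp for a 91-mer), need ≥ 2 hits, ignore strand for chaining, and
span first hit start to last hit end.

The periodicity scan scores each candidate period p by the fraction of
non-N positions matching at lag p (≈ 0.25 for random DNA, 1.0 for exact
periodicity). All multiples of a fundamental have the same expected score,
so sampling noise alone can re-order them; a period is therefore annotated
as a harmonic of its smallest divisor scoring within 0.02 of it, and
callers should treat the best non-harmonic entry as the fundamental.

## Synthetic genomes

Backgrounds are first-order Markov chains — not i.i.d. — so dinucleotide
step biases can be set independently of GC; the emission weights are solved
by fixed-point iteration so the chain's stationary composition hits the GC
target despite the bias (infeasible combinations are rejected). Every
region shares a mild CG/TA step depletion (0.85/0.90) typical of plant
euchromatin, keeping the genome δ\*-flat outside the satellite array.

The default chromosome is 15.2 Mb: two 5 Mb arms at GC 0.32 (2 % LTR-like
occupancy) around a 5 Mb pericentromere at GC 0.37, carrying a 200 kb
satellite array at its midpoint. Regional GC values are *realized* targets:
the pericentromere reaches 0.37 as a GC-0.33 background with GC-0.39,
5 kb LTR-like elements at ~2/3 occupancy — the decomposition observed when
repeats are removed from real heterochromatin. Element copies are sampled
independently from the family chain (compositionally identical in
expectation); insertion positions are multinomial splits of the background.
GC-ramp regions are sampled in 100 kb chunks with linearly interpolated
targets and chained state.

The satellite monomer (default 91 bp, generated; the real monomer sequence
is not public) comes from a chain with a strong CG step enrichment (6×) and
CC/GG depletion (0.3×) at GC 0.5, tiled head-to-tail and mutated at 2 % per
base per copy. Its realized ρ\*_CG sits far above the genome baseline and
ρ\*_CC/GG far below — the directional contrast is asserted, not exact
values, since they depend on the sampled monomer. The sequential Markov
walk is JIT-compiled with numba (a pure-Python fallback is kept).

Shredding cuts a chromosome at uniform-random lengths (default
400–800 kb), reverse-complements a seeded subset of pieces (optionally only
those inside a designated interval), joins them with N gaps (default
100 bp), and emits an AGP claiming "+" for every scaffold while the truth
table records real orientations — reassembling per truth restores the
source byte-exactly.

### What the generator does and does not emulate

It reproduces the compositional architecture the profiles respond to:
regional GC contrasts, repeat-driven pericentromeric elevation, a
signature-divergent satellite array, gradients, gaps, and hidden
inversions. It does **not** emulate read-level assembly artifacts,
segmental duplication, gene/ribosomal content, diverged repeat families, or
gapped satellite variants — so passing tests demonstrate that the
statistics and the QC logic behave as designed on DNA with the stated
composition, not that real assemblies will show equally clean gradients.

## Problem sizes and numerical choices

Test and acceptance workloads are sized for minutes-scale runs as the
package's own operating points: the null calibration uses 10,000 uniform
50 kb windows; oracle agreement uses 1,000 random sequences (counting), a
60 kb genome (sliding-Hamming hits), and 2,000 positions (O(n²)
clustering); flip recovery uses 50 seeded 4 Mb full-gradient chromosomes
(GC 0.31 → 0.41) shredded at 30 % flips, scoring recovery on truly flipped
scaffolds and false suggestions on the rest. Determinism: every stochastic
path takes a seed or Generator; fixed seed implies byte-identical output.
Ties, degenerate inputs, and missing-value rules are stated with each
operation above; floating-point comparisons in tests use exact equality
only where the arithmetic is exact (homopolymer energies, count pooling,
strand-symmetry identities).

## Known limitations

Ungapped matching misses satellite copies with indels; junction scoring
assumes the profile grid is fine relative to scaffold lengths (scaffolds
under 2k windows are only flagged); flip evaluation cannot distinguish an
inversion from a translocation that produces the same window pattern; and
the suggestion threshold, while robust, is a declared heuristic — borderline
calls should be confirmed with independent evidence (markers, physical
maps, synteny).
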