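"""Monomer search, tandem-array clustering, and the periodicity scan."""

import numpy as np
import pytest

from dinuqc import revcomp
from dinuqc.errors import ConfigurationError, InvalidSequenceError
from dinuqc.repeats import (
    MonomerHit,
    RepeatArray,
    RepeatSearchParams,
    array_signature,
    cluster_arrays,
    detect_tandem_periods,
    find_monomer_hits,
)
from dinuqc.signature import delta_star, genome_signature

from conftest import random_dna


def oracle_hits(genome, params):
    """Exhaustive sliding-Hamming oracle, written independently of the matcher.

    Scores every offset on both strands, applies the same local-maxima
    contract (a hit survives unless an overlapping hit beats it, or ties it
    from an earlier start).
    """
    L = len(params.monomer)
    out = []
    for seq_id, seq in genome.items():
        seq = seq.upper()
        for strand, pattern in (("+", params.monomer.upper()),
                                ("-", revcomp(params.monomer.upper()))):
            raw = []
            for start in range(len(seq) - L + 1):
                window = seq[start : start + L]
                matches = sum(
                    1 for a, b in zip(window, pattern) if a == b and a != "N"
                )
                identity = matches / L
                if identity >= params.min_identity - 1e-12:
                    raw.append((start, identity))
            for i, (start, ident) in enumerate(raw):
                beaten = False
                for j, (other, oident) in enumerate(raw):
                    if i == j or abs(other - start) >= L:
                        continue
                    if oident > ident or (oident == ident and other < start):
                        beaten = True
                        break
                if not beaten:
                    out.append((seq_id, start, strand, round(ident, 10)))
    return sorted(out)


def oracle_arrays(starts, threshold):
    """O(n^2) pairwise-gap clustering oracle on sorted start positions."""
    starts = sorted(starts)
    n = len(starts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(starts[j] - starts[i]) <= threshold:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(starts[i])
    return sorted(sorted(g) for g in groups.values() if len(g) >= 2)


def plant(background, copies):
    """Overwrite copies [(pos, seq), ...] into a background string."""
    seq = list(background)
    for pos, copy in copies:
        seq[pos : pos + len(copy)] = copy
    return "".join(seq)


def mutate_exact(seq, n_subs, rng):
    """Substitute exactly n_subs positions (each to a different base)."""
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_subs, replace=False):
        out[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[pos]]
    return "".join(out)


class TestParams:
    def test_monomer_with_n_rejected(self):
        with pytest.raises(InvalidSequenceError):
            RepeatSearchParams(monomer="ACGTN" * 5)

    def test_short_monomer_rejected(self):
        with pytest.raises(ConfigurationError):
            RepeatSearchParams(monomer="ACGTACGTAC")

    def test_gap_threshold_arithmetic(self):
        rng = np.random.default_rng(0)
        params = RepeatSearchParams(monomer=random_dna(rng, 91))
        assert params.gap_threshold == 910
        assert params.max_mismatches == 9


class TestFindHits:
    def test_exact_tandem_copies_all_found(self):
        rng = np.random.default_rng(41)
        monomer = random_dna(rng, 91)
        genome = random_dna(rng, 2_000) + monomer * 10 + random_dna(rng, 2_000)
        params = RepeatSearchParams(monomer=monomer)
        hits = find_monomer_hits({"c": genome}, params)
        exact = [h for h in hits if h.identity == 1.0]
        assert len(exact) >= 10
        starts = {h.start for h in exact}
        assert {2_000 + i * 91 for i in range(10)} <= starts

    def test_reverse_complement_copy_hits_minus_strand(self):
        rng = np.random.default_rng(42)
        monomer = random_dna(rng, 91)
        genome = (
            random_dna(rng, 1_000) + monomer + random_dna(rng, 1_000)
            + revcomp(monomer) + random_dna(rng, 1_000)
        )
        hits = find_monomer_hits({"c": genome}, RepeatSearchParams(monomer=monomer))
        strands = sorted((h.strand, h.start) for h in hits if h.identity == 1.0)
        assert ("+", 1_000) in strands
        assert ("-", 2_091) in strands

    def test_mutation_tolerance_boundary(self):
        rng = np.random.default_rng(43)
        monomer = random_dna(rng, 91)
        # 7 substitutions -> identity 84/91 = 0.923 (kept);
        # 14 substitutions -> 77/91 = 0.846 (rejected at 0.90)
        kept = mutate_exact(monomer, 7, rng)
        rejected = mutate_exact(monomer, 14, rng)
        genome = plant(random_dna(rng, 3_000), [(500, kept), (2_000, rejected)])
        hits = find_monomer_hits({"c": genome}, RepeatSearchParams(monomer=monomer))
        starts = {h.start for h in hits}
        assert 500 in starts
        assert 2_000 not in starts

    def test_agrees_with_sliding_hamming_oracle(self):
        rng = np.random.default_rng(44)
        monomer = random_dna(rng, 40)
        copies = []
        for pos in (300, 800, 1_200, 2_500, 4_000):
            n_subs = int(rng.integers(0, 5))
            copy = mutate_exact(monomer, n_subs, rng)
            if rng.random() < 0.4:
                copy = revcomp(copy)
            copies.append((pos, copy))
        genome = {"c": plant(random_dna(rng, 5_000, n_fraction=0.02), copies)}
        params = RepeatSearchParams(monomer=monomer, min_identity=0.85)
        hits = find_monomer_hits(genome, params)
        got = sorted(
            (h.sequence_id, h.start, h.strand, round(h.identity, 10)) for h in hits
        )
        assert got == oracle_hits(genome, params)


class TestClusterArrays:
    def params(self, L=91):
        rng = np.random.default_rng(0)
        return RepeatSearchParams(monomer=random_dna(rng, L))

    def hits_at(self, starts, L=91):
        return [
            MonomerHit(sequence_id="c", start=s, end=s + L, strand="+", identity=1.0)
            for s in starts
        ]

    def test_threshold_arithmetic_example(self):
        arrays = cluster_arrays(self.hits_at([0, 500, 2_000]), self.params())
        assert len(arrays) == 1
        assert (arrays[0].start, arrays[0].end, arrays[0].hit_count) == (0, 591, 2)

    def test_all_within_threshold_single_array(self):
        arrays = cluster_arrays(self.hits_at(list(range(0, 9_100, 910))), self.params())
        assert len(arrays) == 1
        assert arrays[0].hit_count == 10

    def test_order_independence(self):
        rng = np.random.default_rng(45)
        starts = sorted(rng.choice(100_000, size=200, replace=False).tolist())
        hits = self.hits_at(starts)
        shuffled = list(hits)
        rng.shuffle(shuffled)
        assert cluster_arrays(hits, self.params()) == cluster_arrays(
            shuffled, self.params()
        )

    def test_agrees_with_pairwise_gap_oracle(self):
        rng = np.random.default_rng(46)
        starts = sorted(rng.choice(2_000_000, size=2_000, replace=False).tolist())
        params = self.params()
        arrays = cluster_arrays(self.hits_at(starts), params)
        expected = oracle_arrays(starts, params.gap_threshold)
        got = []
        for a in arrays:
            members = [s for s in starts if a.start <= s < a.end]
            got.append(sorted(members))
        assert sorted(got) == expected

    def test_empty_input(self):
        assert cluster_arrays([], self.params()) == []


class TestArraySignature:
    def test_poly_a_monomer_array(self):
        genome = {"c": "A" * 1_000 + "C" * 50}
        array = RepeatArray("c", 0, 1_000, 11, 1.0, 0.0)
        assert array_signature(genome, array).rho["AA"] == pytest.approx(2.0)

    def test_array_equal_to_genome_has_zero_delta(self):
        rng = np.random.default_rng(47)
        genome = {"c": random_dna(rng, 10_000)}
        array = RepeatArray("c", 0, 10_000, 2, 1.0, 0.0)
        sig = array_signature(genome, array)
        assert delta_star(sig, genome_signature(genome)) == 0.0

    def test_out_of_bounds_interval(self):
        with pytest.raises(ConfigurationError):
            array_signature({"c": "ACGT" * 10}, RepeatArray("c", 0, 100, 2, 1.0, 0.0))


class TestDetectPeriods:
    def test_exact_periodicity_with_harmonics(self):
        rng = np.random.default_rng(48)
        monomer = random_dna(rng, 91)
        results = detect_tandem_periods((monomer * 120)[:10_000], max_period=200)
        top = results[0]
        assert (top.period, top.score) == (91, 1.0)
        by_period = {r.period: r for r in results}
        assert by_period[182].harmonic_of == 91

    def test_random_sequence_scores_near_quarter(self):
        rng = np.random.default_rng(49)
        results = detect_tandem_periods(random_dna(rng, 20_000), max_period=100)
        scores = np.array([r.score for r in results])
        assert abs(scores.mean() - 0.25) < 0.01
        assert scores.max() < 0.30

    def test_mutated_periodicity_matches_expectation(self):
        # each copy mutated independently at q=0.1: lag-91 match probability is
        # (1-q)^2 + q^2/3 = 0.8133
        rng = np.random.default_rng(50)
        monomer = random_dna(rng, 91)
        seq = list((monomer * 120)[:10_000])
        hit = rng.random(len(seq)) < 0.1
        for i in np.flatnonzero(hit):
            others = [b for b in "ACGT" if b != seq[i]]
            seq[i] = others[int(rng.integers(3))]
        results = detect_tandem_periods("".join(seq), max_period=200)
        top = results[0]
        # the winner must be the 91-base fundamental or an annotated harmonic
        assert top.period == 91 or top.harmonic_of == 91
        by_period = {r.period: r for r in results}
        assert by_period[91].harmonic_of is None
        assert by_period[91].score == pytest.approx(0.8133, abs=0.02)

    def test_short_sequence_rejected(self):
        with pytest.raises(ConfigurationError):
            detect_tandem_periods("ACGT" * 20, max_period=200)
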