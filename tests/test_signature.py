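"""Dinucleotide counting, rho* signatures, delta*, and windowed profiles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dinuqc import revcomp
from dinuqc.errors import (
    ConfigurationError,
    DegenerateSequenceError,
    InvalidSequenceError,
)
from dinuqc.signature import (
    SignatureThresholds,
    SignatureVector,
    count_dinucleotides,
    delta_profile,
    delta_star,
    genome_signature,
    rho_star,
)

from conftest import random_dna

DINUCS = [x + y for x in "ACGT" for y in "ACGT"]


def naive_counts(seq):
    """Independent character-by-character oracle for count_dinucleotides."""
    seq = seq.upper()
    mono = {b: 0 for b in "ACGT"}
    dinuc = {d: 0 for d in DINUCS}
    for c in seq:
        if c != "N":
            mono[c] += 1
    for a, b in zip(seq, seq[1:]):
        if a != "N" and b != "N":
            dinuc[a + b] += 1
    return mono, dinuc, sum(mono.values())


def uniform_signature(value=1.0, override=None, symmetrized=True):
    rho = {d: value for d in DINUCS}
    if override:
        rho.update(override)
    return SignatureVector(
        rho=rho, symmetrized=symmetrized, defined={d: True for d in DINUCS}
    )


class TestCounting:
    @pytest.mark.parametrize(
        "seq,mono,dinuc",
        [
            ("ACGT", {"A": 1, "C": 1, "G": 1, "T": 1}, {"AC": 1, "CG": 1, "GT": 1}),
            ("AANTT", {"A": 2, "T": 2}, {"AA": 1, "TT": 1}),
            ("acgt", {"A": 1, "C": 1, "G": 1, "T": 1}, {"AC": 1, "CG": 1, "GT": 1}),
            ("NNNN", {}, {}),
        ],
    )
    def test_examples(self, seq, mono, dinuc):
        counts = count_dinucleotides(seq)
        for b in "ACGT":
            assert counts.mono[b] == mono.get(b, 0)
        for d in DINUCS:
            assert counts.dinuc[d] == dinuc.get(d, 0)

    def test_empty_sequence_is_all_zero(self):
        counts = count_dinucleotides("")
        assert counts.informative_length == 0
        assert sum(counts.dinuc.values()) == 0

    def test_invalid_character_names_position(self):
        with pytest.raises(InvalidSequenceError, match="position 2"):
            count_dinucleotides("ACRGT")

    def test_matches_bruteforce_oracle_on_random_sequences(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(0, 3000))
            seq = random_dna(rng, n, n_fraction=float(rng.random() * 0.3))
            counts = count_dinucleotides(seq)
            mono, dinuc, informative = naive_counts(seq)
            assert counts.mono == {b: mono[b] for b in "ACGT"}
            assert counts.dinuc == dinuc
            assert counts.informative_length == informative

    def test_merge_equals_pooled_count_across_gap(self):
        rng = np.random.default_rng(7)
        a = random_dna(rng, 500)
        b = random_dna(rng, 700)
        merged = count_dinucleotides(a) + count_dinucleotides(b)
        pooled = count_dinucleotides(a + "N" + b)
        assert merged == pooled or (
            merged.mono == pooled.mono
            and merged.dinuc == pooled.dinuc
            and merged.informative_length == pooled.informative_length
        )


class TestRhoStar:
    def test_polya_closed_form(self):
        sig = rho_star(count_dinucleotides("A" * 1000))
        assert sig.rho["AA"] == pytest.approx(2.0, rel=1e-3)
        assert sig.rho["TT"] == pytest.approx(2.0, rel=1e-3)
        defined_zero = [d for d in ("AT", "TA") if sig.defined[d]]
        for d in defined_zero:
            assert sig.rho[d] == 0.0
        # entries touching C or G are undefined after pooling (f_C = f_G = 0)
        assert not sig.defined["CC"]
        assert np.isnan(sig.rho["CC"])

    def test_symmetrized_entries_match_revcomp_pairs(self):
        rng = np.random.default_rng(1)
        sig = rho_star(count_dinucleotides(random_dna(rng, 5000)))
        for d in DINUCS:
            assert sig.rho[d] == pytest.approx(sig.rho[revcomp(d)])

    @given(st.text(alphabet="ACGTN", min_size=10, max_size=300))
    def test_signature_invariant_under_reverse_complement(self, seq):
        counts = count_dinucleotides(seq)
        if counts.informative_length < 2 or sum(counts.dinuc.values()) == 0:
            return
        a = rho_star(counts).values()
        b = rho_star(count_dinucleotides(revcomp(seq))).values()
        np.testing.assert_array_equal(a, b)

    def test_degenerate_input_rejected(self):
        with pytest.raises(DegenerateSequenceError):
            rho_star(count_dinucleotides("A"))
        with pytest.raises(DegenerateSequenceError):
            rho_star(count_dinucleotides("ANC"))  # no adjacent pair

    def test_unsymmetrized_flags_missing_bases_undefined(self):
        sig = rho_star(count_dinucleotides("ACACAC"), symmetrize=False)
        assert not sig.defined["GG"]
        assert sig.defined["AC"]

    def test_random_50kb_entries_near_one(self):
        rng = np.random.default_rng(3)
        sig = rho_star(count_dinucleotides(random_dna(rng, 50_000)))
        vals = sig.values()
        assert np.isfinite(vals).all()
        assert (vals > 0.9).all() and (vals < 1.1).all()


class TestDeltaStar:
    def test_identity_and_symmetry(self):
        rng = np.random.default_rng(5)
        f = rho_star(count_dinucleotides(random_dna(rng, 4000)))
        g = rho_star(count_dinucleotides(random_dna(rng, 4000)))
        assert delta_star(f, f) == 0.0
        assert delta_star(f, g) == delta_star(g, f)

    def test_single_entry_scaling(self):
        f = uniform_signature()
        g = uniform_signature(override={"CG": 1.16})
        assert delta_star(f, g) == pytest.approx(0.01, abs=1e-12)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(8)
        sigs = [
            rho_star(count_dinucleotides(random_dna(rng, 3000))) for _ in range(6)
        ]
        for f in sigs:
            for g in sigs:
                for h in sigs:
                    assert delta_star(f, h) <= delta_star(f, g) + delta_star(g, h) + 1e-12

    def test_symmetrization_mismatch_is_configuration_error(self):
        counts = count_dinucleotides("ACGTACGT" * 10)
        with pytest.raises(ConfigurationError):
            delta_star(rho_star(counts), rho_star(counts, symmetrize=False))

    def test_undefined_entries_error_unless_skipped(self):
        full = rho_star(count_dinucleotides("ACGTACGT" * 100))
        partial = rho_star(count_dinucleotides("A" * 100))
        with pytest.raises(DegenerateSequenceError):
            delta_star(full, partial)
        # renormalized over the shared defined entries
        value = delta_star(full, partial, skip_undefined=True)
        shared = [d for d in DINUCS if partial.defined[d]]
        expected = np.mean([abs(full.rho[d] - partial.rho[d]) for d in shared])
        assert value == pytest.approx(expected)


class TestGenomeSignature:
    def test_pooling_matches_n_separated_concatenation(self):
        rng = np.random.default_rng(9)
        a, b = random_dna(rng, 2000), random_dna(rng, 3000)
        two = genome_signature([a, b])
        joined = genome_signature([a + "N" + b])
        np.testing.assert_array_equal(two.values(), joined.values())

    def test_single_record_equals_rho_star(self):
        rng = np.random.default_rng(10)
        seq = random_dna(rng, 2000)
        np.testing.assert_array_equal(
            genome_signature([seq]).values(),
            rho_star(count_dinucleotides(seq)).values(),
        )

    def test_all_n_input_rejected(self):
        with pytest.raises(DegenerateSequenceError):
            genome_signature(["N" * 100, "NN"])


class TestDeltaProfile:
    def test_homogeneous_genome_has_small_delta_everywhere(self):
        rng = np.random.default_rng(12)
        seq = random_dna(rng, 1_000_000)
        baseline = genome_signature([seq])
        prof = delta_profile(seq, baseline, window_size=50_000)
        assert prof.n_windows == 20
        assert np.all(prof.values < 0.05)

    def test_all_n_window_is_missing(self):
        rng = np.random.default_rng(13)
        seq = random_dna(rng, 2_000) + "N" * 2_000 + random_dna(rng, 2_000)
        baseline = genome_signature([seq])
        prof = delta_profile(seq, baseline, window_size=2_000)
        assert np.isnan(prof.values[1])
        assert np.isfinite(prof.values[0]) and np.isfinite(prof.values[2])

    def test_strand_symmetry_reverses_window_values(self):
        rng = np.random.default_rng(14)
        seq = random_dna(rng, 200_000)
        baseline = genome_signature([seq])
        fwd = delta_profile(seq, baseline, window_size=10_000)
        rev = delta_profile(revcomp(seq), baseline, window_size=10_000)
        np.testing.assert_array_equal(rev.values, fwd.values[::-1])

    def test_terminal_short_window_flagged(self):
        rng = np.random.default_rng(15)
        seq = random_dna(rng, 5_500)
        baseline = genome_signature([seq])
        prof = delta_profile(seq, baseline, window_size=2_000)
        assert list(prof.short) == [False, False, True]
        assert np.isfinite(prof.values[2])  # 1500 >= half window, retained

    def test_undefined_baseline_rejected_before_scan(self):
        partial = rho_star(count_dinucleotides("A" * 100))
        with pytest.raises(ConfigurationError):
            delta_profile("ACGT" * 1000, partial, window_size=1_000)

    def test_window_size_floor(self):
        baseline = genome_signature(["ACGT" * 1000])
        with pytest.raises(ConfigurationError):
            delta_profile("ACGT" * 1000, baseline, window_size=500)


def test_thresholds_must_bracket_one():
    assert SignatureThresholds().upper == 1.23
    with pytest.raises(ConfigurationError):
        SignatureThresholds(upper=0.9, lower=0.8)
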