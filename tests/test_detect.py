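"""De novo detector: seed chains, boundary refinement, validation, truncation."""

import numpy as np
import pytest

from crisprforge.detect import (
    REPEATING_SPACERS,
    SPACER_SIZE,
    DetectParams,
    CrisprArray,
    RepeatMatch,
    attach_truncated_ends,
    extend_and_refine,
    find_crisprs,
    find_seed_chains,
    validate_array,
    write_gff3,
)
from crisprforge.seqcore import NucSeq
from crisprforge.simulate import LocusSpec, make_genome, make_locus


def _planted_contig(rng, repeat_len=30, n_copies=4, spacer_len=35, pad=400):
    spec = LocusSpec(repeat_len=repeat_len, n_copies=n_copies,
                     spacer_len=(spacer_len, spacer_len))
    locus, truth = make_locus(spec, rng)
    left = "".join("ACGT"[i] for i in rng.integers(0, 4, pad))
    right = "".join("ACGT"[i] for i in rng.integers(0, 4, pad))
    return NucSeq("c", left + locus + right), truth, pad


class TestSeedChains:
    def test_planted_array_yields_chain(self, rng):
        contig, truth, pad = _planted_contig(rng, n_copies=3)
        chains = find_seed_chains(contig, DetectParams())
        assert any(len(c) == 3 for c in chains)

    def test_random_sequence_rarely_chains(self):
        params = DetectParams()
        n_with_chains = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            contig = NucSeq("r", "".join("ACGT"[i] for i in r.integers(0, 4, 10_000)))
            # chains may appear by chance but must never survive validation
            if find_seed_chains(contig, params):
                n_with_chains += 1
            assert find_crisprs(contig, params) == []
        assert n_with_chains <= 5

    def test_gap_outside_window_excluded(self, rng):
        # same 8-mer recurring every 200 bp: outside the period window
        k8 = "ACGTTGCA"
        filler = "".join("ACGT"[i] for i in rng.integers(0, 4, 192))
        contig = NucSeq("g", (k8 + filler) * 4)
        assert find_seed_chains(contig, DetectParams()) == []

    def test_short_contig_empty(self):
        assert find_seed_chains(NucSeq("s", "ACGT" * 5), DetectParams()) == []


class TestExtendAndRefine:
    def test_exact_copies_recover_interval(self, rng):
        contig, truth, pad = _planted_contig(rng, repeat_len=32, n_copies=5)
        params = DetectParams()
        chain = max(find_seed_chains(contig, params), key=len)
        arr = extend_and_refine(chain, contig, params)
        assert arr.consensus == truth.repeat
        assert arr.start == pad
        assert arr.end == pad + truth.length

    def test_single_substitution_tracked(self, rng):
        spec = LocusSpec(repeat_len=30, n_copies=5, spacer_len=(34, 34))
        locus, truth = make_locus(spec, rng)
        # mutate the middle of copy 2
        pos = truth.repeat_offsets[2] + 15
        base = "A" if locus[pos] != "A" else "C"
        locus = locus[:pos] + base + locus[pos + 1 :]
        pad = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        contig = NucSeq("m", pad + locus + pad)
        arrays = find_crisprs(contig)
        assert len(arrays) == 1
        assert arrays[0].consensus == truth.repeat
        assert arrays[0].repeats[2].mismatches_to_consensus == 1

    def test_boundary_accuracy_under_mutation(self):
        # per-copy per-base substitutions at 2%: both boundaries within 1 bp
        # of truth in at least 95% of arrays
        ok = 0
        n_sim = 100
        for seed in range(n_sim):
            r = np.random.default_rng(1000 + seed)
            spec = LocusSpec(repeat_len=30, n_copies=6, spacer_len=(30, 38),
                             mutation_rate=0.02)
            locus, truth = make_locus(spec, r)
            pad_l = "".join("ACGT"[i] for i in r.integers(0, 4, 300))
            pad_r = "".join("ACGT"[i] for i in r.integers(0, 4, 300))
            contig = NucSeq("b", pad_l + locus + pad_r)
            arrays = find_crisprs(contig)
            if len(arrays) != 1:
                continue
            if (
                abs(arrays[0].start - 300) <= 1
                and abs(arrays[0].end - (300 + len(locus))) <= 1
            ):
                ok += 1
        assert ok >= 95


class TestValidateArray:
    def _toy_array(self, contig_seq, intervals, consensus):
        contig = NucSeq("t", contig_seq)
        repeats = tuple(
            RepeatMatch("t", s, e) for s, e in intervals
        )
        spacers = tuple((a.end, b.start) for a, b in zip(repeats, repeats[1:]))
        return contig, CrisprArray("t", repeats, spacers, consensus, 0.0)

    def test_identical_spacers_rejected(self, dna):
        rep, sp = dna(30), dna(30)
        seq = rep + sp + rep + sp + rep + sp + rep
        intervals = [(i * 60, i * 60 + 30) for i in range(4)]
        contig, arr = self._toy_array(seq, intervals, rep)
        ok, reason = validate_array(arr, DetectParams(), contig)
        assert not ok and reason == REPEATING_SPACERS

    def test_spacer_length_spread_rejected(self, dna):
        rep = dna(30)
        s1, s2, s3 = dna(20), dna(60), dna(22)
        seq = rep + s1 + rep + s2 + rep + s3 + rep
        pos, intervals = 0, []
        for s in (s1, s2, s3, None):
            intervals.append((pos, pos + 30))
            pos += 30 + (len(s) if s else 0)
        contig, arr = self._toy_array(seq, intervals, rep)
        ok, reason = validate_array(arr, DetectParams(), contig)
        assert not ok and reason == SPACER_SIZE  # 60 > 2.5 * 20

    def test_planted_valid_arrays_accepted(self):
        for seed in range(100):
            r = np.random.default_rng(2000 + seed)
            spec = LocusSpec(repeat_len=int(r.integers(24, 41)),
                             n_copies=int(r.integers(4, 9)),
                             spacer_len=(28, 40))
            locus, truth = make_locus(spec, r)
            contig = NucSeq("v", locus)
            intervals = [
                (off, off + len(c))
                for off, c in zip(truth.repeat_offsets, truth.copies)
            ]
            repeats = tuple(RepeatMatch("v", s, e) for s, e in intervals)
            spacers = tuple(
                (a.end, b.start) for a, b in zip(repeats, repeats[1:])
            )
            arr = CrisprArray("v", repeats, spacers, truth.repeat, 0.0)
            ok, reason = validate_array(arr, DetectParams(), contig)
            assert ok, reason


class TestTruncatedEnds:
    def test_left_fragment_attached(self, rng):
        spec = LocusSpec(repeat_len=30, n_copies=4, spacer_len=(35, 35))
        locus, truth = make_locus(spec, rng)
        frag = truth.repeat[-12:]
        spacer = "".join("ACGT"[i] for i in rng.integers(0, 4, 35))
        tail = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        contig = NucSeq("t", frag + spacer + locus + tail)
        arrays = find_crisprs(contig)
        assert len(arrays) == 1
        arr = arrays[0]
        assert len(arr.repeats) == 5
        assert arr.repeats[0].truncated == "left"
        assert arr.repeats[0].start == 0 and arr.repeats[0].end == 12
        assert len(arr.spacers) == len(arr.repeats) - 1

    def test_no_fragment_unchanged(self, rng):
        contig, truth, pad = _planted_contig(rng, n_copies=4)
        arrays = find_crisprs(contig)
        arr = arrays[0]
        assert attach_truncated_ends(arr, contig, DetectParams()) == arr

    def test_cut_mid_repeat_recovered(self):
        recovered = 0
        n_sim = 50
        for seed in range(n_sim):
            r = np.random.default_rng(3000 + seed)
            spec = LocusSpec(repeat_len=30, n_copies=5, spacer_len=(30, 36))
            locus, truth = make_locus(spec, r)
            cut = int(r.integers(5, 30))  # keep >= 5 bases of the first copy
            tail = "".join("ACGT"[i] for i in r.integers(0, 4, 300))
            contig = NucSeq("cut", locus[30 - cut :] + tail)
            arrays = find_crisprs(contig)
            if (
                len(arrays) == 1
                and arrays[0].repeats[0].truncated == "left"
                and arrays[0].repeats[0].end == cut
            ):
                recovered += 1
        assert recovered == n_sim


class TestFindCrisprs:
    def test_two_planted_arrays_exact(self, rng):
        specs = [
            LocusSpec(repeat_len=30, n_copies=5),
            LocusSpec(repeat_len=36, n_copies=4),
        ]
        genome, truth = make_genome(specs, 12_000, rng)
        arrays = find_crisprs(genome)
        assert len(arrays) == 2
        for arr, lt, start in zip(arrays, truth.loci, truth.locus_starts):
            assert arr.consensus == lt.repeat
            assert arr.start == start
            assert arr.end == start + lt.length

    def test_48_copies_47_spacers(self, rng):
        spec = LocusSpec(repeat_len=36, n_copies=48, spacer_len=(30, 30))
        locus, _ = make_locus(spec, rng)
        pad = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        arrays = find_crisprs(NucSeq("big", pad + locus + pad))
        assert len(arrays) == 1
        assert len(arrays[0].repeats) == 48
        assert len(arrays[0].spacers) == 47

    def test_invariants_on_emitted_arrays(self, rng):
        genome, _ = make_genome(
            [LocusSpec(repeat_len=28, n_copies=6)], 10_000, rng
        )
        for arr in find_crisprs(genome):
            assert len(arr.spacers) == len(arr.repeats) - 1
            for a, b in zip(arr.repeats, arr.repeats[1:]):
                assert a.end <= b.start
            for r in arr.repeats:
                if r.truncated == "none":
                    assert r.mismatches_to_consensus <= 3

    def test_gff3_deterministic(self, tmp_path, rng):
        genome, _ = make_genome([LocusSpec(n_copies=5)], 8_000, rng)
        p1, p2 = tmp_path / "a.gff3", tmp_path / "b.gff3"
        write_gff3(find_crisprs(genome), p1)
        write_gff3(find_crisprs(genome), p2)
        assert p1.read_bytes() == p2.read_bytes()
        text = p1.read_text()
        assert text.startswith("##gff-version 3")
        assert "direct_repeat" in text and "spacer" in text


class TestParams:
    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            DetectParams(seed_len=0)
        with pytest.raises(ValueError):
            DetectParams(min_repeat_len=50, max_repeat_len=40)
        with pytest.raises(ValueError):
            DetectParams(column_agreement=1.5)
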