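"""Spacer analytics: dedup, clustering, sharing, proto-spacers, PAM."""

import numpy as np
import pytest

from crisprforge.seqcore import NucSeq, canonical, revcomp
from crisprforge.simulate import make_phage
from crisprforge.spacers import (
    MetadataError,
    ProtospacerHit,
    SpacerRecord,
    cluster_spacers,
    dedupe_spacers,
    find_protospacers,
    pairwise_shared_counts,
    pam_profile,
    sharing_matrix,
)


def _rec(seq, sample="s1", subject="p1", site="tongue", i=0):
    return SpacerRecord(f"sp{i}", seq, sample, subject, site)


class TestDedupe:
    def test_seq_and_revcomp_collapse(self, dna):
        s = dna(30)
        uniq = dedupe_spacers([_rec(s, i=0), _rec(revcomp(s), i=1)])
        assert len(uniq) == 1
        assert uniq[0].multiplicity == 2
        assert uniq[0].canonical_seq == canonical(s)

    def test_disjoint_identity_mapping(self, dna):
        recs = [_rec(dna(30), i=i) for i in range(5)]
        uniq = dedupe_spacers(recs)
        assert len(uniq) == 5
        assert all(u.multiplicity == 1 for u in uniq)

    def test_multiplicity_conserved(self, rng):
        pool = ["".join("ACGT"[i] for i in rng.integers(0, 4, 30)) for _ in range(10)]
        recs = [
            _rec(pool[int(rng.integers(0, 10))], i=i) for i in range(200)
        ]
        uniq = dedupe_spacers(recs)
        assert sum(u.multiplicity for u in uniq) == 200


class TestClusterSpacers:
    def test_identical_single_cluster(self, dna):
        s = dna(30)
        uniq = dedupe_spacers([_rec(s, i=0), _rec(s, i=1)])
        assert cluster_spacers(uniq, 0.98).n_clusters == 1

    def test_planted_families_recovered(self, rng):
        # 100 families, ~1% intra-family and ~40+% inter-family divergence
        uniq_seqs = []
        for _f in range(100):
            base = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
            var = list(base)
            p = int(rng.integers(0, 40))
            var[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[var[p]]
            uniq_seqs += [base, "".join(var)]
        recs = [_rec(s, i=i) for i, s in enumerate(uniq_seqs)]
        cs = cluster_spacers(dedupe_spacers(recs), 0.90)
        assert cs.n_clusters == 100

    def test_threshold_monotonicity(self, rng):
        seqs = []
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, 32))
        for _ in range(30):
            arr = list(base)
            for p in rng.choice(32, size=int(rng.integers(0, 10)), replace=False):
                arr[p] = "ACGT"[int(rng.integers(0, 4))]
            seqs.append("".join(arr))
        uniq = dedupe_spacers([_rec(s, i=i) for i, s in enumerate(seqs)])
        counts = [
            cluster_spacers(uniq, t).n_clusters for t in (0.98, 0.90, 0.80)
        ]
        assert counts[0] >= counts[1] >= counts[2]


class TestSharingMatrix:
    META = {
        "a1": {"subject_id": "p1", "body_site": "tongue"},
        "a2": {"subject_id": "p1", "body_site": "tongue"},
        "b1": {"subject_id": "p2", "body_site": "stool"},
    }

    def test_counts(self, dna):
        s = dna(30)
        recs = [
            _rec(s, sample="a1", i=0),
            _rec(s, sample="a2", i=1),
            _rec(s, sample="b1", i=2),
        ]
        uniq = dedupe_spacers(recs)
        cs = cluster_spacers(uniq, 0.98)
        mat = sharing_matrix(cs, uniq, self.META)
        assert mat.n_clusters == 1
        row = mat.summary.iloc[0]
        assert (row.n_samples, row.n_subjects) == (3, 2)
        # marginals equal a brute-force recount
        assert mat.incidence.to_numpy().sum() == 3

    def test_missing_metadata_hard_error(self, dna):
        recs = [_rec(dna(30), sample="ghost")]
        uniq = dedupe_spacers(recs)
        cs = cluster_spacers(uniq, 0.98)
        with pytest.raises(MetadataError, match="ghost"):
            sharing_matrix(cs, uniq, self.META)

    def test_empty_input(self):
        uniq = []
        cs = cluster_spacers(
            dedupe_spacers([_rec("ACGTACGTACGTACGTACGT")]), 0.98
        )
        # empty record set -> empty matrix path
        mat = sharing_matrix(
            type(cs)(threshold=0.98, clusters=[], dropped=[]), uniq, self.META
        )
        assert mat.incidence.empty and mat.summary.empty


def brute_force_protospacers(spacer, genome, min_identity, min_len):
    """Oracle: every full-spacer window on both strands, no reduction."""
    m = len(spacer.seq)
    out = set()
    if m < min_len:
        return out
    for strand, q in (("+", spacer.seq), ("-", revcomp(spacer.seq))):
        for p in range(len(genome.seq) - m + 1):
            w = genome.seq[p : p + m]
            mm = sum(a != b or a == "N" or b == "N" for a, b in zip(w, q))
            if 1.0 - mm / m >= min_identity:
                out.add((p, p + m, strand))
    return out


class TestFindProtospacers:
    def test_verbatim_spacer_found(self, dna):
        sp = NucSeq("sp", dna(32))
        genome = NucSeq("g", dna(200) + sp.seq + dna(200))
        hits = find_protospacers([sp], [genome])
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand, h.identity) == (200, 232, "+", 1.0)

    def test_identity_threshold_arithmetic(self, dna):
        base = dna(30)
        for n_mm, expect_hit in ((3, True), (4, False)):
            mutated = list(base)
            for p in range(n_mm):
                pos = 2 + 7 * p
                mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
            genome = NucSeq("g", dna(100) + "".join(mutated) + dna(100))
            hits = find_protospacers([NucSeq("sp", base)], [genome], 0.90, 30)
            assert bool(hits) == expect_hit  # 27/30 = 0.90; 26/30 = 0.867

    def test_short_spacer_cannot_hit(self, dna):
        sp = NucSeq("sp", dna(25))
        genome = NucSeq("g", dna(50) + sp.seq + dna(50))
        assert find_protospacers([sp], [genome], min_len=30) == []

    def test_equals_brute_force_oracle(self, rng):
        n_positive = 0
        for _ in range(200):
            m = int(rng.integers(30, 41))
            sp = NucSeq("sp", "".join("ACGT"[i] for i in rng.integers(0, 4, m)))
            g = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
            if rng.random() < 0.6:
                planted = list(sp.seq)
                for p in rng.choice(m, size=int(rng.integers(0, 5)), replace=False):
                    planted[p] = "ACGT"[int(rng.integers(0, 4))]
                block = "".join(planted)
                if rng.random() < 0.5:
                    block = revcomp(block)
                pos = int(rng.integers(0, 400 - m))
                g = g[:pos] + block + g[pos + m :]
            genome = NucSeq("g", g)
            got = {
                (h.start, h.end, h.strand)
                for h in find_protospacers([sp], [genome], 0.90, 30)
            }
            expected = brute_force_protospacers(sp, genome, 0.90, 30)
            assert got == expected
            n_positive += bool(expected)
        assert n_positive > 30

    def test_flanks_clipped_and_padded(self, dna):
        sp = NucSeq("sp", dna(30))
        genome = NucSeq("g", sp.seq + dna(40))  # hit at the very start
        (h,) = find_protospacers([sp], [genome], flank=10)
        assert h.flank_up == "N" * 10
        assert len(h.flank_down) == 10 and "N" not in h.flank_down


class TestPamProfile:
    def test_planted_gg_downstream(self, rng):
        spacers = [
            NucSeq(f"sp{i}", "".join("ACGT"[b] for b in rng.integers(0, 4, 32)))
            for i in range(20)
        ]
        phage, _ = make_phage(
            spacers, pam="GG", genome_len=8_000, seed=5, minus_strand_fraction=0.5
        )
        hits = find_protospacers(spacers, [phage])
        prof = pam_profile(hits)
        assert prof.top_dinucleotide["down"] == ("GG", 1.0)
        # frequency matrices: downstream columns 0 and 1 are all G
        assert prof.down_freq.loc["G", 0] == 1.0
        assert prof.down_freq.loc["G", 1] == 1.0

    def test_uniform_flanks_no_strong_dinucleotide(self, rng):
        hits = []
        for i in range(1000):
            up = "".join("ACGT"[b] for b in rng.integers(0, 4, 10))
            down = "".join("ACGT"[b] for b in rng.integers(0, 4, 10))
            hits.append(
                ProtospacerHit(f"s{i}", "g", 0, 30, "+", 1.0, 30, up, down)
            )
        prof = pam_profile(hits)
        for flank in ("up", "down"):
            _, freq = prof.top_dinucleotide[flank]
            assert freq < 0.2

    def test_single_hit_one_hot(self, dna):
        h = ProtospacerHit("s", "g", 0, 30, "+", 1.0, 30, "ACGTACGTAC", "GGACGTACGT")
        prof = pam_profile([h])
        assert set(np.unique(prof.up_freq.to_numpy())) <= {0.0, 1.0}
        assert prof.top_dinucleotide["down"][1] == 1.0

    def test_no_hits_rejected(self):
        with pytest.raises(ValueError):
            pam_profile([])


class TestSharingTiers:
    def test_configured_ordering_recovered_from_truth(self):
        from crisprforge.simulate import CommunitySpec, make_community

        truth = make_community(CommunitySpec(tiers=(0.8, 0.2, 0.0)), seed=3)
        meta = {r["sample_id"]: r for r in truth.metadata_rows()}
        recs = []
        for s in truth.samples:
            for i, sp in enumerate(s.spacers):
                recs.append(
                    SpacerRecord(
                        f"{s.sample_id}:{i}", sp, s.sample_id, s.subject_id, s.body_site
                    )
                )
        uniq = dedupe_spacers(recs)
        cs = cluster_spacers(uniq, 0.98)
        mat = sharing_matrix(cs, uniq, meta)
        means = (
            pairwise_shared_counts(mat, meta).groupby("tier")["shared"].mean()
        )
        assert (
            means["same_site_resample"]
            > means["same_subject_cross_site"]
            > means["cross_subject"]
        )
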