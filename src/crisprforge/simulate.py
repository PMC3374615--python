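"""Synthetic data with planted truth for every stage of the toolchain.

The generator emulates the structure of multi-sample human-microbiome
shotgun data at desk scale: genomes carrying CRISPR loci (a direct repeat
interleaved with unique random spacers), uniformly sampled error-prone
short reads, multi-sample communities whose spacer inventories share more
between resamples of the same subject and body site than across sites or
subjects, and mock phage genomes carrying planted proto-spacers with a PAM
immediately downstream.

Everything is driven by ``numpy.random.default_rng`` seeds and is byte
deterministic.  Read errors are substitution-only; backgrounds are i.i.d.
uniform over ACGT (no GC bias, no strain mixtures) — see the methods note
for what this does and does not exercise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqcore import NucSeq, revcomp
from . import seqcore

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimConfigError(ValueError):
    pass


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently with probability ``rate``."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hit):
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _plain_identity(a: str, b: str) -> float:
    return 1.0 - seqcore.levenshtein(a, b) / max(len(a), len(b))


@dataclass(frozen=True)
class LocusSpec:
    """One planted CRISPR locus: repeat consensus x copies x spacers."""

    repeat: str | None = None  # None -> random repeat of repeat_len
    repeat_len: int = 32
    n_copies: int = 5
    spacer_len: tuple[int, int] = (28, 36)
    mutation_rate: float = 0.0  # per-copy per-base substitution rate

    def __post_init__(self) -> None:
        if self.n_copies < 2:
            raise SimConfigError("n_copies must be >= 2")
        if not (0 <= self.mutation_rate <= 1):
            raise SimConfigError("mutation_rate must lie in [0, 1]")
        if self.spacer_len[0] > self.spacer_len[1] or self.spacer_len[0] < 1:
            raise SimConfigError("empty spacer length range")


@dataclass
class LocusTruth:
    repeat: str
    copies: list[str]  # actual (possibly mutated) repeat copies in order
    spacers: list[str]
    repeat_offsets: list[int]  # start of each copy within the locus

    @property
    def length(self) -> int:
        return self.repeat_offsets[-1] + len(self.copies[-1])


def make_locus(
    spec: LocusSpec, seed: int | np.random.Generator = 0
) -> tuple[str, LocusTruth]:
    """Build ``R s1 R s2 ... R`` with unique random spacers.

    Spacers are i.i.d. uniform DNA, re-drawn until every pair (and every
    spacer vs the repeat) stays below 80% identity, so a planted locus
    always satisfies the detector's spacer-uniqueness checks.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    repeat = spec.repeat or _rand_dna(rng, spec.repeat_len)
    spacers: list[str] = []
    for _ in range(spec.n_copies - 1):
        for _attempt in range(200):
            n = int(rng.integers(spec.spacer_len[0], spec.spacer_len[1] + 1))
            s = _rand_dna(rng, n)
            if _plain_identity(s, repeat) >= 0.8:
                continue
            if any(_plain_identity(s, prev) >= 0.8 for prev in spacers):
                continue
            spacers.append(s)
            break
        else:
            raise SimConfigError(
                "could not draw mutually dissimilar spacers; widen spacer_len"
            )
    parts: list[str] = []
    offsets: list[int] = []
    copies: list[str] = []
    pos = 0
    for i in range(spec.n_copies):
        copy = _mutate(rng, repeat, spec.mutation_rate)
        offsets.append(pos)
        copies.append(copy)
        parts.append(copy)
        pos += len(copy)
        if i < spec.n_copies - 1:
            parts.append(spacers[i])
            pos += len(spacers[i])
    return "".join(parts), LocusTruth(repeat, copies, spacers, offsets)


@dataclass
class GenomeTruth:
    genome_id: str
    loci: list[LocusTruth]
    locus_starts: list[int]  # locus start coordinate on the genome


def make_genome(
    specs: list[LocusSpec],
    genome_len: int = 20_000,
    seed: int | np.random.Generator = 0,
    genome_id: str = "genome",
    margin: int = 200,
) -> tuple[NucSeq, GenomeTruth]:
    """i.i.d. background with loci inserted at non-overlapping positions.

    ``margin`` keeps loci away from the genome ends and from each other so
    detection tests see complete arrays; truncated-array fixtures cut the
    genome afterwards instead.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    built = [make_locus(sp, rng) for sp in specs]
    total_loci = sum(len(s) for s, _ in built)
    if total_loci + 2 * margin * (len(specs) + 1) > genome_len:
        raise SimConfigError("genome too short for requested loci")
    background = _rand_dna(rng, genome_len - total_loci)
    # choose insertion points in the background, left to right, with margin
    n = len(built)
    free = len(background) - 2 * margin - (n - 1) * margin
    if free < n:
        raise SimConfigError("genome too short for requested loci and margins")
    cuts = np.sort(rng.choice(free, size=n, replace=False))
    bg_points = [int(c) + margin + i * margin for i, c in enumerate(cuts)]
    pieces: list[str] = []
    starts: list[int] = []
    prev = 0
    offset = 0
    for (locus, _truth), cut in zip(built, bg_points):
        pieces.append(background[prev:cut])
        offset += cut - prev
        starts.append(offset)
        pieces.append(locus)
        offset += len(locus)
        prev = cut
    pieces.append(background[prev:])
    genome = NucSeq(genome_id, "".join(pieces))
    truth = GenomeTruth(genome_id, [t for _, t in built], starts)
    return genome, truth


def make_reads(
    genome: NucSeq,
    read_len: int = 100,
    coverage: float = 50.0,
    error_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    id_prefix: str = "read",
) -> list[NucSeq]:
    """Uniform single-end reads from both strands with substitution errors.

    The read count is ``round(coverage * genome_len / read_len)``; start
    positions are uniform, strands equiprobable.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = len(genome.seq)
    if read_len > L:
        raise SimConfigError("read_len exceeds genome length")
    n_reads = int(round(coverage * L / read_len))
    if n_reads == 0:
        return []
    starts = rng.integers(0, L - read_len + 1, size=n_reads)
    strands = rng.random(n_reads) < 0.5
    reads: list[NucSeq] = []
    for i, (s, minus) in enumerate(zip(starts, strands)):
        seq = genome.seq[int(s) : int(s) + read_len]
        if minus:
            seq = revcomp(seq)
        seq = _mutate(rng, seq, error_rate)
        reads.append(NucSeq(f"{id_prefix}_{i}", seq))
    return reads


# ---------------------------------------------------------------------------
# Multi-sample communities with tiered spacer sharing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommunitySpec:
    """A cohort with controlled spacer sharing between sample pairs.

    ``tiers = (f1, f2, f3)`` are the fractions of a sample's spacer
    inventory shared with (1) a resample of the same subject and site,
    (2) a different site of the same subject, and (3) a different subject;
    they must be strictly decreasing, mirroring the empirical ordering seen
    in oral microbiomes.
    """

    n_subjects: int = 6
    sites: tuple[str, ...] = ("plaque", "tongue")
    n_visits: int = 2
    n_spacers: int = 20
    tiers: tuple[float, float, float] = (0.8, 0.2, 0.0)
    repeat_len: int = 36
    spacer_len: tuple[int, int] = (30, 30)

    def __post_init__(self) -> None:
        f1, f2, f3 = self.tiers
        if not (f1 > f2 > f3 >= 0):
            raise SimConfigError("tier fractions must satisfy f1 > f2 > f3 >= 0")


@dataclass
class SampleTruth:
    sample_id: str
    subject_id: str
    body_site: str
    visit: int
    spacers: list[str]


@dataclass
class CommunityTruth:
    repeat: str
    samples: list[SampleTruth]

    def metadata_rows(self) -> list[dict]:
        return [
            {
                "sample_id": s.sample_id,
                "subject_id": s.subject_id,
                "body_site": s.body_site,
                "visit": s.visit,
            }
            for s in self.samples
        ]


def make_community(
    spec: CommunitySpec, seed: int = 0
) -> CommunityTruth:
    """Construct per-sample spacer inventories with the configured tiers.

    All samples carry the same repeat (one CRISPR type across the cohort).
    Each (subject, site) lineage holds a base inventory; a fraction f2 of it
    comes from a subject-wide core (shared across that subject's sites), a
    fraction f3 from a cohort-wide core.  Later visits keep a fraction f1 of
    the previous visit's inventory and replace the rest with fresh spacers.
    """
    rng = np.random.default_rng(seed)
    f1, f2, f3 = spec.tiers
    n = spec.n_spacers

    def fresh(count: int) -> list[str]:
        return [
            _rand_dna(rng, int(rng.integers(spec.spacer_len[0], spec.spacer_len[1] + 1)))
            for _ in range(count)
        ]

    repeat = _rand_dna(rng, spec.repeat_len)
    n_global = int(round(f3 * n))
    n_subject = int(round(f2 * n)) - n_global
    global_core = fresh(n_global)
    samples: list[SampleTruth] = []
    for si in range(spec.n_subjects):
        subject = f"subj{si + 1}"
        subject_core = fresh(max(n_subject, 0))
        for site in spec.sites:
            private = fresh(n - n_global - max(n_subject, 0))
            inventory = global_core + subject_core + private
            for visit in range(1, spec.n_visits + 1):
                if visit > 1:
                    n_keep = int(round(f1 * n))
                    keep_idx = rng.choice(n, size=n_keep, replace=False)
                    kept = [inventory[int(i)] for i in sorted(keep_idx)]
                    inventory = kept + fresh(n - n_keep)
                sid = f"{site}_v{visit}_{subject}"
                samples.append(
                    SampleTruth(sid, subject, site, visit, list(inventory))
                )
    return CommunityTruth(repeat, samples)


def sample_locus(
    truth: SampleTruth, repeat: str
) -> tuple[str, LocusTruth]:
    """Deterministically lay a sample's spacer inventory into one array."""
    spacers = truth.spacers
    parts = [repeat]
    offsets = [0]
    pos = len(repeat)
    for s in spacers:
        parts.append(s)
        pos += len(s)
        offsets.append(pos)
        parts.append(repeat)
        pos += len(repeat)
    locus = "".join(parts)
    return locus, LocusTruth(repeat, [repeat] * (len(spacers) + 1), list(spacers), offsets)


def community_reads(
    truth: CommunityTruth,
    genome_len: int = 4000,
    read_len: int = 100,
    coverage: float = 40.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, list[NucSeq]]:
    """Per-sample read sets: each sample's array embedded in its own genome."""
    rng = np.random.default_rng(seed)
    out: dict[str, list[NucSeq]] = {}
    for s in truth.samples:
        locus, _lt = sample_locus(s, truth.repeat)
        pad = genome_len - len(locus)
        if pad < 200:
            raise SimConfigError("genome_len too small for community loci")
        left = int(rng.integers(100, pad - 100))
        genome = NucSeq(
            s.sample_id,
            _rand_dna(rng, left) + locus + _rand_dna(rng, pad - left),
        )
        out[s.sample_id] = make_reads(
            genome, read_len, coverage, error_rate, rng, id_prefix=s.sample_id
        )
    return out


# ---------------------------------------------------------------------------
# Mock phage genomes with planted proto-spacers + PAM
# ---------------------------------------------------------------------------

@dataclass
class PlantedProtospacer:
    spacer_id: str
    start: int
    end: int
    strand: str
    n_mismatches: int


@dataclass
class PhageTruth:
    genome_id: str
    hits: list[PlantedProtospacer]


def make_phage(
    spacers: list[NucSeq],
    pam: str = "GG",
    genome_len: int = 30_000,
    seed: int = 0,
    mismatches: int = 0,
    minus_strand_fraction: float = 0.0,
    genome_id: str = "phage",
) -> tuple[NucSeq, PhageTruth]:
    """Embed proto-spacers with the PAM immediately downstream of each.

    Each spacer (optionally with ``mismatches`` substitutions) is inserted
    at a non-overlapping position; on the minus strand the reverse
    complement of spacer+PAM is inserted, so the PAM is always downstream in
    proto-spacer orientation.  Truth records coordinates and strand.
    """
    rng = np.random.default_rng(seed)
    inserts: list[tuple[str, str, str, int]] = []
    for sp in spacers:
        seq = sp.seq
        if mismatches:
            pos = rng.choice(len(seq), size=min(mismatches, len(seq)), replace=False)
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            for p in pos:
                choices = _BASES[_BASES != arr[p]]
                arr[p] = rng.choice(choices)
            seq = arr.tobytes().decode()
        strand = "-" if rng.random() < minus_strand_fraction else "+"
        block = seq + pam
        if strand == "-":
            block = revcomp(block)
        inserts.append((sp.id, block, strand, min(mismatches, len(sp.seq))))
    total = sum(len(b) for _, b, _, _ in inserts)
    if total + 2 * (len(inserts) + 1) > genome_len:
        raise SimConfigError("phage genome too short for requested spacers")
    background = _rand_dna(rng, genome_len - total)
    free = len(background) - 2 * (len(inserts) + 1)
    cuts = np.sort(rng.choice(free, size=len(inserts), replace=False)) + np.arange(
        len(inserts)
    ) * 2 + 2
    pieces: list[str] = []
    truth_hits: list[PlantedProtospacer] = []
    prev = 0
    offset = 0
    for (sid, block, strand, n_mm), cut in zip(inserts, cuts):
        cut = int(cut)
        pieces.append(background[prev:cut])
        offset += cut - prev
        sp_len = len(block) - len(pam)
        if strand == "+":
            truth_hits.append(
                PlantedProtospacer(sid, offset, offset + sp_len, "+", n_mm)
            )
        else:
            truth_hits.append(
                PlantedProtospacer(
                    sid, offset + len(pam), offset + len(block), "-", n_mm
                )
            )
        pieces.append(block)
        offset += len(block)
        prev = cut
    pieces.append(background[prev:])
    genome = NucSeq(genome_id, "".join(pieces))
    return genome, PhageTruth(genome_id, truth_hits)
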