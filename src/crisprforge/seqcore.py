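"""Nucleotide sequence primitives shared by every other module.

The toolkit operates on plain uppercase DNA strings over ``{A, C, G, T, N}``.
``N`` is treated conservatively: it matches nothing, not even another ``N``,
in both Hamming and edit-distance computations.  All strand-aware operations
(repeat scanning, k-mer canonicalisation, repeat-network distances) are built
on :func:`revcomp` and :func:`oriented_distance`.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceError(ValueError):
    """Raised for malformed sequence input (bad alphabet, length mismatch)."""


def _validate(seq: str, *, name: str = "sequence") -> str:
    """Uppercase ``seq`` and reject characters outside {A,C,G,T,N}."""
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in ALPHABET:
            raise SequenceError(
                f"{name} contains non-ACGTN character {ch!r} at position {i}"
            )
    return seq


@dataclass(frozen=True)
class NucSeq:
    """A named nucleotide sequence with an optional per-base quality string."""

    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", _validate(self.seq, name=f"sequence {self.id!r}"))
        if not self.seq:
            raise SequenceError(f"sequence {self.id!r} is empty")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise SequenceError(
                f"sequence {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def revcomp(self) -> "NucSeq":
        qual = self.qual[::-1] if self.qual is not None else None
        return NucSeq(self.id, revcomp(self.seq), qual)


@dataclass(frozen=True)
class AlignmentDistance:
    """Edit distance of a repeat pair in both orientations.

    ``oriented`` is the minimum of the forward-forward distance and the
    forward-reverse-complement distance; repeat orientation is generally
    unknowable without cas context, so the oriented value is what the repeat
    network uses.
    """

    raw_forward: int
    raw_revcomp: int
    oriented: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "oriented", min(self.raw_forward, self.raw_revcomp))


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string; complement of ``N`` is ``N``."""
    seq = _validate(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Ungapped mismatch count between equal-length strings.

    Any position involving ``N`` (in either sequence) counts as a mismatch.
    """
    if len(a) != len(b):
        raise SequenceError(f"hamming requires equal lengths ({len(a)} vs {len(b)})")
    return sum(x != y or x == "N" for x, y in zip(a, b))


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (substitution, insertion, deletion).

    ``N`` never matches, consistently with :func:`hamming`.  Implemented as a
    rolling-row dynamic program vectorised over numpy; repeats and spacers are
    short (< ~80 bp) so the quadratic cost is irrelevant.
    """
    if not a or not b:
        raise SequenceError("levenshtein requires non-empty inputs")
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)
    n_mark = ord("N")
    m = len(xb)
    js = np.arange(m + 1)
    prev = js.copy()
    for i, ca in enumerate(xa, start=1):
        sub_cost = (xb != ca) | (xb == n_mark) | (ca == n_mark)
        best = np.minimum(prev[:-1] + sub_cost, prev[1:] + 1)
        # left-to-right +1 chain (cur[j] = min(best[j], cur[j-1]+1)) is a
        # serial recurrence; solve it via a running-minimum of best[j]-j
        shifted = np.empty(m + 1, dtype=prev.dtype)
        shifted[0] = i  # cur[0] - 0
        shifted[1:] = best - js[1:]
        prev = np.minimum.accumulate(shifted) + js
    return int(prev[-1])


def oriented_distance(a: str, b: str) -> AlignmentDistance:
    """Edit distance between two repeats ignoring strand.

    Computes the distance of ``a`` to ``b`` and to ``revcomp(b)`` and keeps
    the smaller as the oriented distance.
    """
    return AlignmentDistance(levenshtein(a, b), levenshtein(a, revcomp(b)))


def identity(a: str, b: str) -> float:
    """Orientation-aware identity: 1 - oriented edit distance / longer length."""
    return 1.0 - oriented_distance(a, b).oriented / max(len(a), len(b))


def canonical(seq: str) -> str:
    """Deterministic strand representative: lexicographic min of seq/revcomp."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def column_consensus(seqs: list[str]) -> str:
    """Per-column majority consensus of equal-length sequences.

    ``N`` does not vote; ties break alphabetically A < C < G < T; an all-N
    column yields ``N``.
    """
    if not seqs:
        raise SequenceError("column_consensus requires at least one sequence")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise SequenceError("column_consensus requires equal-length sequences")
    out = []
    for col in zip(*seqs):
        counts = {b: 0 for b in "ACGT"}
        for ch in col:
            if ch != "N":
                counts[ch] += 1
        best = max("ACGT", key=lambda b: (counts[b], ))
        out.append(best if counts[best] > 0 else "N")
    return "".join(out)


def window_mismatches(target: str, query: str) -> np.ndarray:
    """Hamming mismatches of ``query`` against every window of ``target``.

    Returns an int32 array of length ``len(target) - len(query) + 1`` (empty
    if the target is shorter than the query).  Position ``p`` holds the
    mismatch count of ``target[p:p+m]`` vs ``query``; ``N`` mismatches
    everything.  This is the exact sliding-window semantics every repeat
    scanner in the package reduces to.
    """
    n, m = len(target), len(query)
    if n < m:
        return np.zeros(0, dtype=np.int32)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    n_mark = ord("N")
    out = np.zeros(n - m + 1, dtype=np.int32)
    for j in range(m):
        tj = t[j : j + n - m + 1]
        out += (tj != q[j]) | (tj == n_mark) | (q[j] == n_mark)
    return out


# ---------------------------------------------------------------------------
# FASTA / FASTQ I/O (Biopython-backed, gzip-transparent)
# ---------------------------------------------------------------------------

def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _sniff_format(path: str | Path) -> str:
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    return "fasta"


def read_seqs(path: str | Path, fmt: str | None = None) -> Iterator[NucSeq]:
    """Stream records from a FASTA/FASTQ file (``.gz`` transparently).

    The format is inferred from the filename unless ``fmt`` is given.
    Sequences are uppercased; non-ACGTN characters raise
    :class:`SequenceError`.
    """
    fmt = fmt or _sniff_format(path)
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            qual = None
            if fmt == "fastq":
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
            yield NucSeq(rec.id, str(rec.seq), qual)


def write_fasta(path: str | Path, seqs: Iterable[NucSeq]) -> int:
    """Write records as FASTA; returns the number written."""
    n = 0
    with _open_text(path, "wt") as fh:
        for s in seqs:
            SeqIO.write(SeqRecord(Seq(s.seq), id=s.id, description=""), fh, "fasta")
            n += 1
    return n


def write_fastq(path: str | Path, seqs: Iterable[NucSeq]) -> int:
    """Write records as FASTQ; missing qualities are emitted as 'I' (Q40)."""
    n = 0
    with _open_text(path, "wt") as fh:
        for s in seqs:
            qual = s.qual or "I" * len(s.seq)
            rec = SeqRecord(Seq(s.seq), id=s.id, description="")
            rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
            SeqIO.write(rec, fh, "fastq")
            n += 1
    return n
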