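"""Repeat-query CRISPR detection (similarity search).

Given a direct-repeat consensus, find every window of a target sequence (or
its reverse complement) matching the repeat within a Hamming mismatch
budget, chain consecutive hits whose gaps look like spacers into arrays,
and decide novelty of a repeat against a reference collection.  Matching is
gapless: at repeat lengths of 24-48 bp a full-length alignment with a small
mismatch budget has no room for indels worth modelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import detect as _detect
from .seqcore import NucSeq, SequenceError, column_consensus, revcomp, window_mismatches


@dataclass(frozen=True)
class QueryRepeat:
    """A named direct-repeat consensus used as a search query."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq:
            raise SequenceError(f"query repeat {self.id!r} is empty")


@dataclass(frozen=True)
class RepeatHit:
    """A full-length match of a query repeat on a target (0-based half-open).

    ``strand`` is '+' when the forward target window equals the query within
    the budget, '-' when it equals the query's reverse complement.
    """

    query_id: str
    target_id: str
    start: int
    end: int
    strand: str
    mismatches: int
    truncated: bool = False


def _reduce_overlaps(
    hits: list[tuple[int, int]], half_len: int
) -> list[tuple[int, int]]:
    """Collapse same-strand hits whose starts lie within half a query length.

    ``hits`` are (start, mismatches) sorted by start.  Within each cluster of
    nearby starts the lowest-mismatch hit wins; ties go to the leftmost.
    """
    kept: list[tuple[int, int]] = []
    for start, mm in hits:
        if kept and start - kept[-1][0] < half_len:
            if mm < kept[-1][1]:
                kept[-1] = (start, mm)
        else:
            kept.append((start, mm))
    return kept


def scan_repeat(
    target: NucSeq, query: QueryRepeat, max_mm: int
) -> list[RepeatHit]:
    """All full-length windows on either strand within ``max_mm`` mismatches.

    Equivalent to a brute-force sliding scan of the query (and its reverse
    complement) along the target, followed by the overlap reduction above.
    A target shorter than the query yields an empty list.
    """
    m = len(query.seq)
    if len(target.seq) < m:
        return []
    out: list[RepeatHit] = []
    for strand, qseq in (("+", query.seq), ("-", revcomp(query.seq))):
        mm = window_mismatches(target.seq, qseq)
        raw = [(int(p), int(mm[p])) for p in np.flatnonzero(mm <= max_mm)]
        for start, n_mm in _reduce_overlaps(raw, m // 2):
            out.append(
                RepeatHit(query.id, target.id, start, start + m, strand, n_mm)
            )
    out.sort(key=lambda h: (h.start, h.strand))
    return out


def hits_to_arrays(
    hits: Sequence[RepeatHit],
    target: NucSeq,
    params: _detect.DetectParams | None = None,
) -> list[_detect.CrisprArray]:
    """Chain repeat hits separated by spacer-sized gaps into arrays.

    Consecutive same-strand hits whose gap lies in the spacer band are
    chained; chains of >= 2 elements become arrays (a lone repeat copy is
    not an array).  Spacer-level checks from the de novo detector are then
    applied, and truncated boundary copies attached.
    """
    params = params or _detect.DetectParams()
    arrays: list[_detect.CrisprArray] = []
    for strand in "+-":
        strand_hits = sorted(
            (h for h in hits if h.strand == strand), key=lambda h: h.start
        )
        run: list[RepeatHit] = []
        for h in strand_hits + [None]:  # type: ignore[list-item]
            if h is not None and (
                not run
                or params.min_spacer_len
                <= h.start - run[-1].end
                <= params.max_spacer_len
            ):
                run.append(h)
                continue
            if len(run) >= 2:
                arrays.append(_chain_to_array(run, target, strand, params))
            run = [h] if h is not None else []
    checked: list[_detect.CrisprArray] = []
    for arr in arrays:
        ok, _ = _detect.validate_array(
            arr, _relaxed_copies(params), target
        )
        if ok:
            checked.append(_detect.attach_truncated_ends(arr, target, params))
    checked.sort(key=lambda a: a.start)
    return checked


def _relaxed_copies(params: _detect.DetectParams) -> _detect.DetectParams:
    """Similarity-search arrays need only 2 chained copies."""
    if params.min_copies <= 2:
        return params
    from dataclasses import replace

    return replace(params, min_copies=2)


def _chain_to_array(
    run: list[RepeatHit],
    target: NucSeq,
    strand: str,
    params: _detect.DetectParams,
) -> _detect.CrisprArray:
    intervals = [(h.start, h.end) for h in run]
    copies = [target.seq[s:e] for s, e in intervals]
    if strand == "-":
        copies = [revcomp(c) for c in copies]
    cons = column_consensus(copies)
    # consensus stored in target-forward orientation so coordinate logic
    # (truncated-end attachment, spacer extraction) stays strand-agnostic
    cons_fwd = revcomp(cons) if strand == "-" else cons
    return _detect._array_from_intervals(target, intervals, cons_fwd, strand=strand)


def is_novel(
    query: QueryRepeat,
    references: Iterable[NucSeq],
    max_mm: int = 4,
    params: _detect.DetectParams | None = None,
) -> tuple[bool, RepeatHit | None]:
    """A repeat is novel if no reference contains an *array* of it.

    An instance is a chained array of >= 2 repeat copies within ``max_mm``
    mismatches; a lone repeat occurrence does not disqualify novelty.
    Returns ``(novel, witness)`` with the first witness hit when not novel.
    """
    params = params or _detect.DetectParams()
    for ref in references:
        hits = scan_repeat(ref, query, max_mm)
        arrays = hits_to_arrays(hits, ref, params)
        if arrays:
            first = arrays[0].repeats[0]
            witness = RepeatHit(
                query.id,
                ref.id,
                first.start,
                first.end,
                arrays[0].strand,
                first.mismatches_to_consensus,
            )
            return False, witness
    return True, None


def write_hits_tsv(
    hits: Iterable[RepeatHit],
    path: str | Path,
    in_array: set[tuple[str, int]] | None = None,
) -> int:
    """TSV: query_id, target_id, start, end, strand, mismatches, in_array."""
    in_array = in_array or set()
    n = 0
    with open(path, "w") as fh:
        fh.write("query_id\ttarget_id\tstart\tend\tstrand\tmismatches\tin_array\n")
        for h in hits:
            flag = int((h.target_id, h.start) in in_array)
            fh.write(
                f"{h.query_id}\t{h.target_id}\t{h.start}\t{h.end}\t"
                f"{h.strand}\t{h.mismatches}\t{flag}\n"
            )
            n += 1
    return n
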