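"""De novo CRISPR array detection on contigs and genomes.

The detector follows the CRT recipe: find an exact short seed k-mer that
recurs at CRISPR-like intervals, extend the repeat boundaries by column
agreement across the copies, then apply structural checks (copy number,
spacer length band and similarity, spacer uniqueness).  On metagenome
contigs, arrays are frequently cut mid-repeat by the contig boundary, so an
extra pass recovers incomplete repeat copies abutting either contig end and
flags them as truncated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .seqcore import (
    NucSeq,
    column_consensus,
    hamming,
    levenshtein,
    window_mismatches,
)

TRUNC_NONE = "none"
TRUNC_LEFT = "left"
TRUNC_RIGHT = "right"


@dataclass(frozen=True)
class DetectParams:
    """Tunable knobs of the de novo detector.

    Defaults are CRT-style reimplementation choices: an 8-bp exact seed,
    repeat lengths 19-48, spacer lengths 18-72, at least 3 copies, spacers
    rejected when any pair (or a spacer and the repeat) reaches 80% identity,
    spacer length spread capped at 2.5x, and boundary extension while >=75%
    of copies agree with the column majority.
    """

    seed_len: int = 8
    min_repeat_len: int = 19
    max_repeat_len: int = 48
    min_spacer_len: int = 18
    max_spacer_len: int = 72
    min_copies: int = 3
    spacer_identity_max: float = 0.80
    spacer_len_ratio_max: float = 2.5
    column_agreement: float = 0.75
    # mismatch budget when re-scanning the contig with the refined consensus
    # to pick up copies whose seed k-mer was mutated
    rescan_max_mm: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.seed_len <= self.min_repeat_len):
            raise ValueError("require 0 < seed_len <= min_repeat_len")
        if self.min_repeat_len > self.max_repeat_len:
            raise ValueError("min_repeat_len > max_repeat_len")
        if self.min_spacer_len > self.max_spacer_len:
            raise ValueError("min_spacer_len > max_spacer_len")
        for frac in (self.spacer_identity_max, self.column_agreement):
            if not (0 < frac <= 1):
                raise ValueError("fractions must lie in (0, 1]")
        if self.min_copies < 2:
            raise ValueError("min_copies must be >= 2")

    @property
    def min_period(self) -> int:
        return self.min_repeat_len + self.min_spacer_len

    @property
    def max_period(self) -> int:
        return self.max_repeat_len + self.max_spacer_len


@dataclass(frozen=True)
class RepeatMatch:
    """One repeat copy on a contig (0-based half-open coordinates)."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"
    mismatches_to_consensus: int = 0
    truncated: str = TRUNC_NONE

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad repeat interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.truncated not in (TRUNC_NONE, TRUNC_LEFT, TRUNC_RIGHT):
            raise ValueError(f"bad truncation flag {self.truncated!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CrisprArray:
    """An ordered run of repeat copies and the spacers between them."""

    contig_id: str
    repeats: tuple[RepeatMatch, ...]
    spacers: tuple[tuple[int, int], ...]
    consensus: str
    avg_mismatch: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.spacers) != len(self.repeats) - 1:
            raise ValueError(
                f"{len(self.repeats)} repeats require {len(self.repeats) - 1} "
                f"spacers, got {len(self.spacers)}"
            )
        starts = [r.start for r in self.repeats]
        if starts != sorted(starts):
            raise ValueError("repeats must be sorted by start")
        for a, b in zip(self.repeats, self.repeats[1:]):
            if b.start < a.end:
                raise ValueError("repeats overlap")

    @property
    def start(self) -> int:
        return self.repeats[0].start

    @property
    def end(self) -> int:
        return self.repeats[-1].end

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def n_complete(self) -> int:
        return sum(r.truncated == TRUNC_NONE for r in self.repeats)

    def spacer_seqs(self, contig: NucSeq) -> list[str]:
        return [contig.seq[s:e] for s, e in self.spacers]


# reject reasons for validate_array
OK = "ok"
TOO_FEW_COPIES = "too_few_copies"
REPEAT_LENGTH = "repeat_length"
SPACER_LENGTH = "spacer_length"
SPACER_SIZE = "spacer_size"
REPEATING_SPACERS = "repeating_spacers"
SPACER_MATCHES_REPEAT = "spacer_matches_repeat"


def _seq_identity(a: str, b: str) -> float:
    """Plain (same-strand) identity: 1 - edit distance / longer length."""
    return 1.0 - levenshtein(a, b) / max(len(a), len(b))


def find_seed_chains(contig: NucSeq, params: DetectParams) -> list[list[int]]:
    """Positions of exact seed k-mers recurring at CRISPR-like periods.

    Each returned chain is a sorted list of >= ``min_copies`` start positions
    of one exact ``seed_len``-mer where every consecutive gap lies within
    [min_repeat+min_spacer, max_repeat+max_spacer].  Chains are maximal runs.
    """
    k = params.seed_len
    seq = contig.seq
    if len(seq) < 2 * params.min_repeat_len + params.min_spacer_len:
        return []
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    lo, hi = params.min_period, params.max_period
    chains: list[list[int]] = []
    for positions in index.values():
        if len(positions) < params.min_copies:
            continue
        run = [positions[0]]
        for p in positions[1:]:
            if lo <= p - run[-1] <= hi:
                run.append(p)
            else:
                if len(run) >= params.min_copies:
                    chains.append(run)
                run = [p]
        if len(run) >= params.min_copies:
            chains.append(run)
    chains.sort(key=lambda c: (-len(c), c[0]))
    return chains


def _extend_from_cores(
    contig: NucSeq,
    starts: list[int],
    core_len: int,
    params: DetectParams,
    floor_len: int,
) -> CrisprArray:
    """Grow repeat boundaries around per-copy core intervals by column vote.

    Each copy occupies ``[p, p + core_len)``; both flanks are extended one
    column at a time while the fraction of copies matching the column
    majority stays at or above ``column_agreement``, the repeat stays within
    ``max_repeat_len``, all voting copies stay on the contig, and adjacent
    copies do not collide.  A final trim removes terminal columns with more
    than ``floor(copies/6)`` dissenting copies (but never below
    ``floor_len``): with few copies a random spacer column clears the
    agreement threshold disturbingly often, and the trim keeps such
    single-column overshoots out of the boundary while tolerating the odd
    mutated copy in deeper arrays.
    """
    seq = contig.seq
    chain = starts
    k = core_len
    min_gap = min(b - a for a, b in zip(chain, chain[1:])) if len(chain) > 1 else len(seq)

    def col_stats(offsets: list[int]) -> tuple[float, int, int]:
        """(majority fraction, dissenting votes, voting copies) over the
        offsets that fall on the contig; boundary-clipped copies abstain."""
        col = [seq[p] for p in offsets if 0 <= p < len(seq)]
        if not col:
            return 0.0, 0, 0
        counts = {b: col.count(b) for b in "ACGT"}
        top = max(counts.values())
        return top / len(col), len(col) - top, len(col)

    max_len = min(params.max_repeat_len, min_gap)
    bridge = 2  # failing columns tolerated when a passing column lies beyond

    def col_passes(offsets: list[int]) -> bool:
        # a repeat column must be near-unanimous: at most one dissenting
        # copy per six voters (so unanimity below six copies).  A plain
        # majority-fraction threshold lets random spacer columns through
        # far too often at low copy number.
        frac, dissent, voters = col_stats(offsets)
        return (
            voters >= 2
            and frac >= params.column_agreement
            and dissent <= voters // 6
        )

    def extend(base: int, offsets_at) -> int:
        """Columns to add in one direction.

        Contiguous passing columns extend directly.  Up to ``bridge``
        failing columns (e.g. a position mutated in two copies) may be
        jumped, but are committed only once TWO consecutive passing columns
        follow — a single chance near-unanimous spacer column beyond the
        true boundary must not drag flanking junk into the repeat.
        """
        committed = cols_pending = fails_pending = pass_streak = 0
        while base + committed + cols_pending + 1 <= max_len:
            if col_passes(offsets_at(committed + cols_pending)):
                pass_streak += 1
                cols_pending += 1
                if fails_pending == 0 or pass_streak >= 2:
                    committed += cols_pending
                    cols_pending = fails_pending = 0
            else:
                pass_streak = 0
                fails_pending += 1
                cols_pending += 1
                if fails_pending > bridge:
                    break
        return committed

    left = 0
    right = k + extend(k, lambda d: [p + k + d for p in chain])
    left = extend(right, lambda d: [p - left - d - 1 for p in chain])

    while (
        left + right > floor_len
        and right > 0
        and not col_passes([p + right - 1 for p in chain])
    ):
        right -= 1
    while left + right > floor_len and not col_passes(
        [p - left for p in chain]
    ):
        left -= 1  # may go negative: shrink into the core

    intervals = [
        (p - left, p + right)
        for p in chain
        if p - left >= 0 and p + right <= len(seq)
    ]
    copies = [seq[s:e] for s, e in intervals]
    consensus = column_consensus(copies)
    return _array_from_intervals(contig, intervals, consensus)


def extend_and_refine(
    chain: list[int], contig: NucSeq, params: DetectParams
) -> CrisprArray:
    """Grow repeat boundaries around the exact seed k-mer occurrences."""
    return _extend_from_cores(
        contig, chain, params.seed_len, params, floor_len=params.seed_len
    )


def _array_from_intervals(
    contig: NucSeq,
    intervals: list[tuple[int, int]],
    consensus: str,
    strand: str = "+",
) -> CrisprArray:
    repeats = tuple(
        RepeatMatch(
            contig.id,
            s,
            e,
            strand=strand,
            mismatches_to_consensus=hamming(contig.seq[s:e], consensus),
        )
        for s, e in intervals
    )
    spacers = tuple(
        (a.end, b.start) for a, b in zip(repeats, repeats[1:])
    )
    mms = [r.mismatches_to_consensus for r in repeats]
    return CrisprArray(
        contig_id=contig.id,
        repeats=repeats,
        spacers=spacers,
        consensus=consensus,
        avg_mismatch=float(np.mean(mms)) if mms else 0.0,
        strand=strand,
    )


def validate_array(
    candidate: CrisprArray,
    params: DetectParams,
    contig: NucSeq | None = None,
) -> tuple[bool, str]:
    """Structural acceptance checks: copies, spacer band/spread/uniqueness.

    Spacer- and repeat-identity checks need the underlying sequence, so they
    run only when ``contig`` is supplied; the purely coordinate-level checks
    always run.  Returns ``(accepted, reason)`` with an enumerated reason.
    """
    if candidate.n_complete < params.min_copies:
        return False, TOO_FEW_COPIES
    if not (
        params.min_repeat_len <= len(candidate.consensus) <= params.max_repeat_len
    ):
        return False, REPEAT_LENGTH
    lens = [e - s for s, e in candidate.spacers]
    if any(
        not (params.min_spacer_len <= n <= params.max_spacer_len) for n in lens
    ):
        return False, SPACER_LENGTH
    if lens and max(lens) > params.spacer_len_ratio_max * min(lens):
        return False, SPACER_SIZE
    if contig is not None:
        spacer_seqs = candidate.spacer_seqs(contig)
        for i, a in enumerate(spacer_seqs):
            for b in spacer_seqs[i + 1 :]:
                if _seq_identity(a, b) >= params.spacer_identity_max:
                    return False, REPEATING_SPACERS
            if _seq_identity(a, candidate.consensus) >= params.spacer_identity_max:
                return False, SPACER_MATCHES_REPEAT
    return True, OK


def attach_truncated_ends(
    array: CrisprArray, contig: NucSeq, params: DetectParams
) -> CrisprArray:
    """Recover incomplete repeat copies cut by the contig boundary.

    If less than (max spacer + repeat length) of sequence precedes the first
    repeat, a contig prefix of length t >= 5 matching the consensus suffix
    within ceil(3 t / L) mismatches — L the repeat length — is attached as a
    left-truncated copy, provided a plausible spacer gap separates it from
    the first full copy.  The right end is handled symmetrically.
    """
    seq = contig.seq
    cons = array.consensus
    L = len(cons)
    repeats = list(array.repeats)

    def budget(t: int) -> int:
        return math.ceil(3 * t / L)

    def best_fragment(candidates: list[tuple[int, int]]) -> tuple[int, int] | None:
        """Pick (t, mm) maximizing matched length penalized by mismatches.

        The consensus end can be locally self-similar (e.g. short tandem
        structure), in which case a longer-but-inexact placement can sneak
        under the prorated budget; scoring t - 3*mm prefers the exact
        fragment while still tolerating genuinely mutated fragments.
        """
        within = [(t, mm) for t, mm in candidates if mm <= budget(t)]
        if not within:
            return None
        return max(within, key=lambda tm: (tm[0] - 3 * tm[1], tm[0]))

    # left end
    first = repeats[0]
    if 0 < first.start < params.max_spacer_len + L:
        t_hi = min(first.start - params.min_spacer_len, L - 1)
        candidates = [
            (t, hamming(seq[:t], cons[L - t :]))
            for t in range(5, t_hi + 1)
            if first.start - t <= params.max_spacer_len
        ]
        best = best_fragment(candidates)
        if best is not None:
            t, mm = best
            repeats.insert(
                0,
                RepeatMatch(
                    contig.id, 0, t,
                    strand=array.strand,
                    mismatches_to_consensus=mm,
                    truncated=TRUNC_LEFT,
                ),
            )
    # right end
    last = repeats[-1]
    tail = len(seq) - last.end
    if 0 < tail < params.max_spacer_len + L:
        t_hi = min(tail - params.min_spacer_len, L - 1)
        candidates = [
            (t, hamming(seq[len(seq) - t :], cons[:t]))
            for t in range(5, t_hi + 1)
            if tail - t <= params.max_spacer_len
        ]
        best = best_fragment(candidates)
        if best is not None:
            t, mm = best
            repeats.append(
                RepeatMatch(
                    contig.id, len(seq) - t, len(seq),
                    strand=array.strand,
                    mismatches_to_consensus=mm,
                    truncated=TRUNC_RIGHT,
                )
            )

    if len(repeats) == len(array.repeats):
        return array
    spacers = tuple((a.end, b.start) for a, b in zip(repeats, repeats[1:]))
    complete = [r.mismatches_to_consensus for r in repeats if r.truncated == TRUNC_NONE]
    return CrisprArray(
        contig_id=array.contig_id,
        repeats=tuple(repeats),
        spacers=spacers,
        consensus=cons,
        avg_mismatch=float(np.mean(complete)) if complete else 0.0,
        strand=array.strand,
    )


def _rescan_consensus(
    contig: NucSeq, consensus: str, params: DetectParams
) -> list[CrisprArray]:
    """Re-locate all copies of a refined consensus and chain them into arrays.

    The seed stage only sees copies sharing an exact k-mer; a copy carrying a
    mutation inside every shared seed would be missed.  Scanning with the
    consensus at a small mismatch budget recovers such copies, and also
    separates multiple arrays sharing one repeat (chains break where the gap
    leaves the spacer band).
    """
    mm = window_mismatches(contig.seq, consensus)
    L = len(consensus)
    hits = np.flatnonzero(mm <= params.rescan_max_mm)
    # suppress overlapping windows: keep best within half a repeat length
    kept: list[int] = []
    for p in hits:
        if kept and p - kept[-1] < L // 2:
            if mm[p] < mm[kept[-1]]:
                kept[-1] = int(p)
        else:
            kept.append(int(p))
    arrays: list[CrisprArray] = []
    run: list[int] = []
    for p in kept + [None]:  # type: ignore[list-item]
        if p is not None and (
            not run
            or params.min_spacer_len <= p - (run[-1] + L) <= params.max_spacer_len
        ):
            run.append(p)
            continue
        if len(run) >= params.min_copies:
            # re-extend boundaries with the full copy set: the seed-chain
            # vote may have had too few copies to fix the flanks reliably
            arrays.append(
                _extend_from_cores(
                    contig, run, L, params, floor_len=params.min_repeat_len
                )
            )
        run = [p] if p is not None else []
    return arrays


def find_crisprs(contig: NucSeq, params: DetectParams | None = None) -> list[CrisprArray]:
    """De novo detection: seed chains -> refine -> validate -> truncated ends.

    Output arrays are deduplicated (overlapping candidates resolved by more
    copies, then longer span, then leftmost) and sorted by position; the
    result is deterministic for fixed input and parameters.
    """
    params = params or DetectParams()
    accepted: list[CrisprArray] = []
    for chain in find_seed_chains(contig, params):
        if any(
            arr.start <= chain[0] and chain[-1] + params.seed_len <= arr.end
            for arr in accepted
        ):
            continue  # seeds fully inside an already accepted array
        candidate = extend_and_refine(chain, contig, params)
        for arr in _rescan_consensus(contig, candidate.consensus, params):
            ok, _ = validate_array(arr, params, contig)
            if ok:
                accepted.append(attach_truncated_ends(arr, contig, params))

    # resolve overlaps: more copies, then longer span, then leftmost
    accepted.sort(key=lambda a: (-len(a.repeats), -a.span, a.start))
    chosen: list[CrisprArray] = []
    for arr in accepted:
        if all(arr.end <= c.start or arr.start >= c.end for c in chosen):
            chosen.append(arr)
    chosen.sort(key=lambda a: a.start)
    return chosen


def find_crisprs_many(
    contigs: Iterable[NucSeq], params: DetectParams | None = None
) -> list[CrisprArray]:
    """Run :func:`find_crisprs` over a collection of contigs."""
    out: list[CrisprArray] = []
    for contig in contigs:
        out.extend(find_crisprs(contig, params))
    return out


# ---------------------------------------------------------------------------
# GFF3 emission (1-based inclusive coordinates)
# ---------------------------------------------------------------------------

def write_gff3(arrays: Iterable[CrisprArray], path: str | Path) -> int:
    """Write arrays as GFF3: repeat_region parents with direct_repeat and
    spacer children.  Internal 0-based half-open coordinates become 1-based
    inclusive."""
    n = 0
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, arr in enumerate(sorted(arrays, key=lambda a: (a.contig_id, a.start))):
            n += 1
            aid = f"crispr_{i + 1}"
            trunc = ",".join(
                r.truncated for r in arr.repeats if r.truncated != TRUNC_NONE
            ) or "none"
            fh.write(
                "\t".join(
                    [
                        arr.contig_id,
                        "crisprforge",
                        "repeat_region",
                        str(arr.start + 1),
                        str(arr.end),
                        ".",
                        arr.strand,
                        ".",
                        f"ID={aid};consensus={arr.consensus};"
                        f"avg_mismatch={arr.avg_mismatch:.3f};truncated={trunc}",
                    ]
                )
                + "\n"
            )
            for j, r in enumerate(arr.repeats):
                fh.write(
                    "\t".join(
                        [
                            arr.contig_id,
                            "crisprforge",
                            "direct_repeat",
                            str(r.start + 1),
                            str(r.end),
                            str(r.mismatches_to_consensus),
                            r.strand,
                            ".",
                            f"ID={aid}.r{j + 1};Parent={aid};truncated={r.truncated}",
                        ]
                    )
                    + "\n"
                )
            for j, (s, e) in enumerate(arr.spacers):
                fh.write(
                    "\t".join(
                        [
                            arr.contig_id,
                            "crisprforge",
                            "spacer",
                            str(s + 1),
                            str(e),
                            ".",
                            arr.strand,
                            ".",
                            f"ID={aid}.s{j + 1};Parent={aid}",
                        ]
                    )
                    + "\n"
                )
    return n
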