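"""Spacer-level analytics: uniqueness, clustering, sharing, proto-spacers.

Spacers are the immunological memory of a CRISPR locus; comparing them
across samples reveals how much history two communities share, and matching
them against phage or plasmid genomes locates the proto-spacers they were
acquired from, whose flanks carry the PAM (proto-spacer adjacent motif).

Spacer orientation is not observable without knowing array direction, so
uniqueness and clustering operate on the canonical orientation (the
lexicographic minimum of a spacer and its reverse complement).
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import QueryRepeat
from .catalog import ClusterSet, cluster_repeats
from .seqcore import NucSeq, canonical, revcomp, window_mismatches


@dataclass(frozen=True)
class SpacerRecord:
    """One observed spacer with its provenance."""

    spacer_id: str
    seq: str
    sample_id: str
    subject_id: str
    body_site: str
    array_id: str = ""
    index_in_array: int = 0

    @property
    def canonical_seq(self) -> str:
        return canonical(self.seq)


@dataclass
class UniqueSpacer:
    canonical_seq: str
    multiplicity: int
    records: list[SpacerRecord]


def dedupe_spacers(records: Iterable[SpacerRecord]) -> list[UniqueSpacer]:
    """Collapse records to unique canonical sequences, keeping multiplicity.

    The sum of multiplicities equals the input count; first-seen order of
    canonical sequences is preserved.
    """
    table: "OrderedDict[str, UniqueSpacer]" = OrderedDict()
    for rec in records:
        key = rec.canonical_seq
        if key not in table:
            table[key] = UniqueSpacer(key, 0, [])
        table[key].multiplicity += 1
        table[key].records.append(rec)
    return list(table.values())


def cluster_spacers(
    unique: Sequence[UniqueSpacer], threshold: float = 0.90
) -> ClusterSet:
    """Greedy orientation-aware identity clustering of unique spacers.

    Same algorithm as repeat clustering; ids are the canonical sequences
    themselves, so cluster membership maps straight back to records.
    """
    queries = [QueryRepeat(u.canonical_seq, u.canonical_seq) for u in unique]
    return cluster_repeats(queries, threshold)


@dataclass
class SharingMatrix:
    incidence: pd.DataFrame  # clusters x samples, 0/1
    summary: pd.DataFrame  # per cluster: n_samples, n_subjects

    @property
    def n_clusters(self) -> int:
        return len(self.incidence.index)


class MetadataError(KeyError):
    pass


def sharing_matrix(
    clusters: ClusterSet,
    unique: Sequence[UniqueSpacer],
    sample_meta: Mapping[str, Mapping[str, str]] | pd.DataFrame,
) -> SharingMatrix:
    """Binary cluster-by-sample incidence plus per-cluster sharing summary.

    ``sample_meta`` maps sample_id to at least ``subject_id`` (and usually
    ``body_site``); samples appearing in records but missing from the
    metadata raise :class:`MetadataError` listing all offenders.  The
    summary is sorted by the number of subjects sharing the cluster,
    descending.
    """
    if isinstance(sample_meta, pd.DataFrame):
        sample_meta = sample_meta.set_index("sample_id").to_dict("index")
    by_seq = {u.canonical_seq: u for u in unique}
    cluster_samples: dict[str, set[str]] = {}
    for rep, members in clusters.clusters:
        samples: set[str] = set()
        for m in members:
            for rec in by_seq[m].records:
                samples.add(rec.sample_id)
        cluster_samples[rep] = samples

    all_samples = sorted({s for ss in cluster_samples.values() for s in ss})
    missing = [s for s in all_samples if s not in sample_meta]
    if missing:
        raise MetadataError(
            f"samples without metadata: {', '.join(missing)}"
        )
    if not cluster_samples:
        return SharingMatrix(
            incidence=pd.DataFrame(dtype=int),
            summary=pd.DataFrame(
                columns=["cluster", "n_samples", "n_subjects"]
            ),
        )
    incidence = pd.DataFrame(
        0, index=sorted(cluster_samples), columns=all_samples, dtype=int
    )
    rows = []
    for rep, samples in cluster_samples.items():
        incidence.loc[rep, sorted(samples)] = 1
        subjects = {sample_meta[s]["subject_id"] for s in samples}
        rows.append(
            {"cluster": rep, "n_samples": len(samples), "n_subjects": len(subjects)}
        )
    summary = (
        pd.DataFrame(rows)
        .sort_values(["n_subjects", "n_samples", "cluster"], ascending=[False, False, True])
        .reset_index(drop=True)
    )
    return SharingMatrix(incidence=incidence, summary=summary)


def pairwise_shared_counts(
    matrix: SharingMatrix,
    sample_meta: Mapping[str, Mapping[str, str]] | pd.DataFrame,
) -> pd.DataFrame:
    """Shared-cluster counts for every sample pair, tagged by relationship.

    Relationship tiers: ``same_site_resample`` (same subject, same body
    site), ``same_subject_cross_site``, ``cross_subject``.  The mean shared
    count per tier is the statistic that recovers the configured sharing
    ordering on simulated communities.
    """
    if isinstance(sample_meta, pd.DataFrame):
        sample_meta = sample_meta.set_index("sample_id").to_dict("index")
    samples = list(matrix.incidence.columns)
    mat = matrix.incidence.to_numpy()
    rows = []
    for i, a in enumerate(samples):
        for j in range(i + 1, len(samples)):
            b = samples[j]
            shared = int(np.sum((mat[:, i] == 1) & (mat[:, j] == 1)))
            ma, mb = sample_meta[a], sample_meta[b]
            if ma["subject_id"] == mb["subject_id"]:
                tier = (
                    "same_site_resample"
                    if ma.get("body_site") == mb.get("body_site")
                    else "same_subject_cross_site"
                )
            else:
                tier = "cross_subject"
            rows.append(
                {"sample_a": a, "sample_b": b, "tier": tier, "shared": shared}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Proto-spacer search and PAM profiling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtospacerHit:
    """A spacer's gapless match on a phage/plasmid genome.

    Coordinates are on the genome forward strand, 0-based half-open.
    ``flank_up``/``flank_down`` are taken in proto-spacer orientation (the
    strand on which the spacer sequence reads forward), clipped at genome
    ends and padded with N.
    """

    spacer_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    identity: float
    aligned_len: int
    flank_up: str
    flank_down: str


def _flanks(genome: str, start: int, end: int, strand: str, f: int) -> tuple[str, str]:
    def seg(a: int, b: int) -> str:
        left_pad = max(0, -a)
        right_pad = max(0, b - len(genome))
        return "N" * left_pad + genome[max(a, 0) : min(b, len(genome))] + "N" * right_pad

    up_fwd = seg(start - f, start)
    down_fwd = seg(end, end + f)
    if strand == "+":
        return up_fwd, down_fwd
    return revcomp(down_fwd), revcomp(up_fwd)


def find_protospacers(
    spacers: Iterable[NucSeq],
    genomes: Iterable[NucSeq],
    min_identity: float = 0.90,
    min_len: int = 30,
    flank: int = 10,
) -> list[ProtospacerHit]:
    """Gapless full-spacer matches on either strand of each genome.

    A hit places the entire spacer at a genome offset with Hamming identity
    >= ``min_identity``; spacers shorter than ``min_len`` cannot hit.  Every
    window of every genome is evaluated (the scan is vectorised, so no
    seeding heuristic is needed and the result is exactly the brute-force
    window scan).  Overlapping hits of one spacer on one genome are reduced
    to the best-identity one (ties leftmost), independently per strand.
    """
    genome_list = list(genomes)
    if not genome_list:
        raise ValueError("find_protospacers requires at least one genome")
    out: list[ProtospacerHit] = []
    for sp in spacers:
        m = len(sp.seq)
        if m < min_len:
            continue
        # epsilon guards the inclusive threshold against float representation
        # (e.g. (1-0.9)*30 evaluating just below 3)
        max_mm = int(np.floor((1.0 - min_identity) * m + 1e-9))
        for g in genome_list:
            if len(g.seq) < m:
                continue
            for strand, qseq in (("+", sp.seq), ("-", revcomp(sp.seq))):
                mm = window_mismatches(g.seq, qseq)
                raw = [(int(p), int(mm[p])) for p in np.flatnonzero(mm <= max_mm)]
                kept: list[tuple[int, int]] = []
                for pos, n_mm in raw:
                    if kept and pos < kept[-1][0] + m:
                        if n_mm < kept[-1][1]:
                            kept[-1] = (pos, n_mm)
                    else:
                        kept.append((pos, n_mm))
                for pos, n_mm in kept:
                    up, down = _flanks(g.seq, pos, pos + m, strand, flank)
                    out.append(
                        ProtospacerHit(
                            spacer_id=sp.id,
                            genome_id=g.id,
                            start=pos,
                            end=pos + m,
                            strand=strand,
                            identity=1.0 - n_mm / m,
                            aligned_len=m,
                            flank_up=up,
                            flank_down=down,
                        )
                    )
    out.sort(key=lambda h: (h.genome_id, h.start, h.spacer_id, h.strand))
    return out


@dataclass
class PamProfile:
    """Base-frequency matrices of proto-spacer flanks and the top dinucleotide.

    ``up_freq``/``down_freq`` are 4 x flank DataFrames (rows ACGT) whose
    columns sum to 1 over the non-N mass; ``n_fraction`` reports the excluded
    N mass per flank.  ``top_dinucleotide`` maps flank name to the dinucleotide
    and frequency of the single most conserved adjacent position pair.
    """

    up_freq: pd.DataFrame
    down_freq: pd.DataFrame
    n_fraction: dict[str, float]
    top_dinucleotide: dict[str, tuple[str, float]]
    n_hits: int


def _freq_matrix(flanks: list[str]) -> tuple[pd.DataFrame, float]:
    width = len(flanks[0])
    counts = np.zeros((4, width))
    n_count = 0
    idx = {b: i for i, b in enumerate("ACGT")}
    for fl in flanks:
        for j, ch in enumerate(fl):
            if ch == "N":
                n_count += 1
            else:
                counts[idx[ch], j] += 1
    col_tot = counts.sum(axis=0)
    col_tot[col_tot == 0] = 1.0
    freq = counts / col_tot
    df = pd.DataFrame(freq, index=list("ACGT"), columns=range(width))
    return df, n_count / (len(flanks) * width)


def _top_dinucleotide(flanks: list[str]) -> tuple[str, float]:
    width = len(flanks[0])
    best: tuple[float, str, int] | None = None
    for j in range(width - 1):
        counts: dict[str, int] = {}
        valid = 0
        for fl in flanks:
            d = fl[j : j + 2]
            if "N" in d:
                continue
            valid += 1
            counts[d] = counts.get(d, 0) + 1
        if not valid:
            continue
        d, c = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
        f = c / len(flanks)
        if best is None or f > best[0]:
            best = (f, d, j)
    if best is None:
        raise ValueError("flanks contain only N")
    return best[1], best[0]


def pam_profile(hits: Sequence[ProtospacerHit]) -> PamProfile:
    """Flank base-frequency matrices oriented by hit strand.

    The PAM shows up as one adjacent position pair of near-fixed identity in
    the downstream flank (GG for the streptococcal-type systems this models).
    """
    if not hits:
        raise ValueError("pam_profile requires at least one hit")
    ups = [h.flank_up for h in hits]
    downs = [h.flank_down for h in hits]
    if all(set(u) == {"N"} for u in ups) and all(set(d) == {"N"} for d in downs):
        raise ValueError("all flanks are N")
    up_df, up_n = _freq_matrix(ups)
    down_df, down_n = _freq_matrix(downs)
    return PamProfile(
        up_freq=up_df,
        down_freq=down_df,
        n_fraction={"up": up_n, "down": down_n},
        top_dinucleotide={
            "up": _top_dinucleotide(ups),
            "down": _top_dinucleotide(downs),
        },
        n_hits=len(hits),
    )


def write_hits_tsv(hits: Iterable[ProtospacerHit], path: str | Path) -> int:
    """BED-convertible proto-spacer hit table."""
    n = 0
    with open(path, "w") as fh:
        fh.write(
            "spacer_id\tgenome_id\tstart\tend\tstrand\tidentity\t"
            "aligned_len\tflank_up\tflank_down\n"
        )
        for h in hits:
            fh.write(
                f"{h.spacer_id}\t{h.genome_id}\t{h.start}\t{h.end}\t{h.strand}\t"
                f"{h.identity:.4f}\t{h.aligned_len}\t{h.flank_up}\t{h.flank_down}\n"
            )
            n += 1
    return n
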