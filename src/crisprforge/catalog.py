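"""CRISPR catalog construction: selection, redundancy reduction, network.

A de novo detection run over many genomes or contigs yields candidate
arrays; the catalog stage keeps the trustworthy ones (repeat length 24-40,
at least 4 complete copies, average <=1 mismatch per copy vs the
consensus), collapses near-identical repeats with a greedy CD-HIT-style
clustering that is aware of reverse complements, links the survivors into
an edit-distance network, and classifies each repeat by the body sites in
which it is found.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .align import QueryRepeat
from .detect import CrisprArray
from .seqcore import identity, oriented_distance, revcomp


@dataclass(frozen=True)
class SelectionParams:
    """Filter for trustworthy CRISPRs (all bounds inclusive)."""

    min_repeat_len: int = 24
    max_repeat_len: int = 40
    min_copies: int = 4
    max_avg_mismatch: float = 1.0
    redundancy_identity: float = 0.90

    def __post_init__(self) -> None:
        if self.min_repeat_len > self.max_repeat_len:
            raise ValueError("min_repeat_len > max_repeat_len")
        if not (0 < self.redundancy_identity <= 1):
            raise ValueError("redundancy_identity must lie in (0, 1]")


REJECT_REPEAT_LEN = "repeat_length"
REJECT_COPIES = "too_few_copies"
REJECT_AVG_MM = "avg_mismatch"


def select_crisprs(
    arrays: Iterable[CrisprArray], params: SelectionParams | None = None
) -> tuple[list[CrisprArray], list[tuple[CrisprArray, str]]]:
    """Apply the known-CRISPR selection filter.

    Accepts an array iff its consensus length lies in
    [min_repeat_len, max_repeat_len], it has >= min_copies complete
    (non-truncated) repeat copies, and the mean mismatch of complete copies
    vs the consensus is <= max_avg_mismatch.  Returns the accepted arrays
    and the rejected ones with an enumerated reason each.
    """
    params = params or SelectionParams()
    accepted: list[CrisprArray] = []
    rejected: list[tuple[CrisprArray, str]] = []
    for arr in arrays:
        if not (
            params.min_repeat_len <= len(arr.consensus) <= params.max_repeat_len
        ):
            rejected.append((arr, REJECT_REPEAT_LEN))
        elif arr.n_complete < params.min_copies:
            rejected.append((arr, REJECT_COPIES))
        elif arr.avg_mismatch > params.max_avg_mismatch:
            rejected.append((arr, REJECT_AVG_MM))
        else:
            accepted.append(arr)
    return accepted, rejected


@dataclass
class ClusterSet:
    """Greedy identity clusters with orientation-aware membership."""

    threshold: float
    clusters: list[tuple[str, list[str]]]  # (representative id, member ids)
    dropped: list[str]  # representative ids removed as revcomp redundancy

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def representative_of(self, member_id: str) -> str:
        for rep, members in self.clusters:
            if member_id in members:
                return rep
        raise KeyError(member_id)


def cluster_repeats(
    repeats: list[QueryRepeat], threshold: float = 0.90
) -> ClusterSet:
    """Greedy CD-HIT-style clustering of repeat consensuses.

    Sequences are sorted by (length descending, sequence ascending); each
    joins the first existing representative with orientation-aware identity
    >= threshold (identity = 1 - min-orientation edit distance / longer
    length) or founds a new cluster.  A final pass drops, for every pair of
    clusters whose representatives match each other's reverse complement at
    the threshold, the cluster with the lexicographically larger
    representative.
    """
    if not repeats:
        raise ValueError("cluster_repeats requires at least one repeat")
    by_id = {r.id: r for r in repeats}
    if len(by_id) != len(repeats):
        raise ValueError("repeat ids must be unique")
    order = sorted(repeats, key=lambda r: (-len(r.seq), r.seq))
    reps: list[QueryRepeat] = []
    members: dict[str, list[str]] = {}
    for r in order:
        for rep in reps:
            if identity(rep.seq, r.seq) >= threshold:
                members[rep.id].append(r.id)
                break
        else:
            reps.append(r)
            members[r.id] = [r.id]

    dropped: list[str] = []
    alive = {r.id: r for r in reps}
    rep_list = sorted(alive.values(), key=lambda r: r.seq)
    for i, a in enumerate(rep_list):
        for b in rep_list[i + 1 :]:
            if a.id not in alive or b.id not in alive or a.id == b.id:
                continue
            # redundancy between a cluster and another's reverse complement
            if (
                identity(a.seq, revcomp(b.seq)) >= threshold
                and identity(b.seq, revcomp(a.seq)) >= threshold
            ):
                loser = a if a.seq > b.seq else b
                if loser.id in alive:
                    del alive[loser.id]
                    dropped.append(loser.id)
    clusters = [
        (rep.id, members[rep.id]) for rep in reps if rep.id in alive
    ]
    return ClusterSet(threshold=threshold, clusters=clusters, dropped=dropped)


def build_network(
    repeats: list[QueryRepeat],
    max_dist: int = 10,
    site_classes: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Edit-distance network over repeat consensuses.

    Nodes are repeat ids; an edge joins two repeats whose orientation-aware
    edit distance is <= ``max_dist`` (strand is unknowable, so the smaller
    of forward and reverse-complement distances is used).  Edge attribute
    ``distance`` carries the value; optional ``site_class`` node attributes
    annotate body-site assignment.
    """
    if len(repeats) < 2:
        raise ValueError("build_network requires at least 2 repeats")
    g = nx.Graph(threshold=max_dist)
    for r in repeats:
        attrs = {"seq": r.seq}
        if site_classes and r.id in site_classes:
            attrs["site_class"] = site_classes[r.id]
        g.add_node(r.id, **attrs)
    for i, a in enumerate(repeats):
        for b in repeats[i + 1 :]:
            if a.id == b.id:
                continue
            d = oriented_distance(a.seq, b.seq).oriented
            if d <= max_dist:
                g.add_edge(a.id, b.id, distance=d)
    return g


def write_network_tsv(g: nx.Graph, path: str | Path) -> int:
    """Edge list as TSV (id_a, id_b, distance), ids ordered a < b."""
    n = 0
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tdistance\n")
        for a, b, data in sorted(
            (tuple(sorted((u, v))) + (d,) for u, v, d in g.edges(data=True)),
            key=lambda t: (t[0], t[1]),
        ):
            fh.write(f"{a}\t{b}\t{data['distance']}\n")
            n += 1
    return n


def write_network_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, path)


def reference_repeats() -> list[QueryRepeat]:
    """The bundled direct-repeat consensuses from human-microbiome studies.

    Sixteen named repeat consensuses (13 from complete/draft reference
    genomes, 3 first seen in human-microbiome metagenome assemblies), useful
    as ready-made queries for similarity search, targeted assembly and the
    repeat network.
    """
    from importlib.resources import files

    out: list[QueryRepeat] = []
    text = (files("crisprforge") / "data" / "reference_repeats.fasta").read_text()
    rid, chunks = None, []
    for line in text.splitlines():
        if line.startswith(">"):
            if rid is not None:
                out.append(QueryRepeat(rid, "".join(chunks)))
            rid, chunks = line[1:].split()[0], []
        elif line.strip():
            chunks.append(line.strip())
    if rid is not None:
        out.append(QueryRepeat(rid, "".join(chunks)))
    return out


RARE = "rare"
UNASSIGNED = "unassigned"


def classify_by_site(
    crispr_sample_counts: Mapping[str, Mapping[str, int]],
    samples_per_site: Mapping[str, int],
    min_samples: int = 5,
    site_fraction: float = 0.10,
) -> dict[str, str]:
    """Assign each CRISPR to body site(s) by prevalence.

    A CRISPR found in fewer than ``min_samples`` samples overall is "rare";
    otherwise it is assigned to every site where it appears in more than
    ``site_fraction`` of that site's samples (multi-site assignments join
    site names with '+', sorted); no qualifying site yields "unassigned".
    """
    for site, total in samples_per_site.items():
        if total <= 0:
            raise ValueError(f"site {site!r} has non-positive sample total")
    out: dict[str, str] = {}
    for crispr_id, counts in crispr_sample_counts.items():
        total = sum(counts.values())
        if total < min_samples:
            out[crispr_id] = RARE
            continue
        sites = sorted(
            site
            for site, n in counts.items()
            if site in samples_per_site
            and n / samples_per_site[site] > site_fraction
        )
        out[crispr_id] = "+".join(sites) if sites else UNASSIGNED
    return out
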