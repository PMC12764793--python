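"""Allelic-contig pairing and haplotig purging.

A primary assembly of a heterozygous diploid retains pairs of allelic
contigs — two contigs covering the same region on the two haplotypes.
Three parallel lines of evidence identify such pairs: all-by-all contig
alignment coverage, micro-synteny of mapped transcripts (a pair needs more
than five shared genes in a collinear run), and shared single-copy
ortholog markers (one shared marker suffices). Edges from any evidence
line form an allelic-evidence graph; within each connected component one
contig is retained (the longest by default) and the rest are purged.

A purge is judged successful when, on the retained set, the duplicated
single-copy-marker rate is below 10% and the loss of distinct markers is
below 5%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import networkx as nx

__all__ = [
    "GenePlacement",
    "EvidenceEdge",
    "AllelicEvidenceGraph",
    "pair_by_synteny",
    "pair_by_marker",
    "pair_by_alignment",
    "purge_redundant",
    "duplication_metrics",
    "read_gene_placements",
    "read_paf",
]

TRANSCRIPT = "transcript"
MARKER = "marker"


@dataclass(frozen=True)
class GenePlacement:
    """One placement of a gene on a contig (0-based half-open coordinates)."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    category: str = TRANSCRIPT

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"invalid placement interval for {self.gene_id}: "
                             f"[{self.start}, {self.end})")


@dataclass(frozen=True)
class EvidenceEdge:
    a: str
    b: str
    evidence: str  # alignment | synteny | marker
    weight: float

    def key(self) -> tuple[str, str, str]:
        x, y = sorted((self.a, self.b))
        return x, y, self.evidence


@dataclass
class AllelicEvidenceGraph:
    """Contigs as nodes, typed allelic-pair evidence as edges."""

    lengths: dict[str, int]
    edges: list[EvidenceEdge] = field(default_factory=list)

    def add_edges(self, edges: Iterable[EvidenceEdge]) -> None:
        seen = {e.key() for e in self.edges}
        for e in edges:
            if e.a == e.b:
                raise ValueError(f"self-edge on contig {e.a}")
            if e.a not in self.lengths or e.b not in self.lengths:
                raise ValueError(f"edge references unknown contig: {e.a} or {e.b}")
            if e.key() not in seen:
                self.edges.append(e)
                seen.add(e.key())

    def filtered(self, require_n_evidences: int = 1) -> "AllelicEvidenceGraph":
        """Keep only contig pairs supported by >= n distinct evidence types."""
        support: dict[tuple[str, str], set[str]] = {}
        for e in self.edges:
            x, y, ev = e.key()
            support.setdefault((x, y), set()).add(ev)
        keep = {pair for pair, evs in support.items() if len(evs) >= require_n_evidences}
        return AllelicEvidenceGraph(
            self.lengths,
            [e for e in self.edges if (e.key()[0], e.key()[1]) in keep],
        )


def read_gene_placements(path) -> list[GenePlacement]:
    """Read a gene-placement TSV: gene_id, contig, start, end, strand, category."""
    out: list[GenePlacement] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{i}: expected 6 tab-separated columns")
            out.append(GenePlacement(fields[0], fields[1], int(fields[2]),
                                     int(fields[3]), fields[4], fields[5]))
    return out


def _shared_collinear_genes(
    genes_a: list[GenePlacement],
    genes_b: list[GenePlacement],
    window: int,
) -> int:
    """Size of the largest collinear chain of genes shared by two contigs.

    Shared genes are ordered by position on each contig; a chain is
    collinear when its genes appear in the same (or fully reversed) order
    on both contigs, allowing up to ``window`` intervening shared genes
    between consecutive chain members.
    """
    order_a = [g.gene_id for g in sorted(genes_a, key=lambda g: g.start)]
    pos_b = {g.gene_id: g.start for g in genes_b}
    shared = [g for g in order_a if g in pos_b]
    if not shared:
        return 0
    rank_b = {g: i for i, g in enumerate(sorted(shared, key=lambda g: pos_b[g]))}
    ranks = [rank_b[g] for g in shared]  # B-ranks in A order
    return max(_longest_run(ranks, window, reverse=False),
               _longest_run(ranks, window, reverse=True))


def _longest_run(ranks: Sequence[int], window: int, reverse: bool) -> int:
    """Longest chain with monotone ranks and rank gaps <= window + 1 (DP)."""
    n = len(ranks)
    best = [1] * n
    for i in range(n):
        for j in range(i):
            gap = ranks[i] - ranks[j]
            if reverse:
                gap = -gap
            if 1 <= gap <= window + 1 and best[j] + 1 > best[i]:
                best[i] = best[j] + 1
    return max(best) if n else 0


def pair_by_synteny(
    placements: Iterable[GenePlacement],
    min_shared_genes: int = 5,
    collinearity_window: int = 5,
) -> list[EvidenceEdge]:
    """Edge for each contig pair sharing *more than* ``min_shared_genes`` collinear genes.

    The threshold is strict: a pair sharing exactly five genes does not
    qualify. Weight is the collinear shared-gene count. Only
    transcript-category placements are considered.
    """
    by_contig: dict[str, list[GenePlacement]] = {}
    gene_contigs: dict[str, set[str]] = {}
    for p in placements:
        if p.category != TRANSCRIPT:
            continue
        by_contig.setdefault(p.contig_id, []).append(p)
        gene_contigs.setdefault(p.gene_id, set()).add(p.contig_id)

    candidate_pairs: set[tuple[str, str]] = set()
    for contigs in gene_contigs.values():
        sc = sorted(contigs)
        for i in range(len(sc)):
            for j in range(i + 1, len(sc)):
                candidate_pairs.add((sc[i], sc[j]))

    edges = []
    for a, b in sorted(candidate_pairs):
        n = _shared_collinear_genes(by_contig[a], by_contig[b], collinearity_window)
        if n > min_shared_genes:
            edges.append(EvidenceEdge(a, b, "synteny", float(n)))
    return edges


def pair_by_marker(placements: Iterable[GenePlacement], min_shared: int = 1) -> list[EvidenceEdge]:
    """Edge for every contig pair sharing at least ``min_shared`` marker genes."""
    marker_contigs: dict[str, set[str]] = {}
    for p in placements:
        if p.category != MARKER:
            continue
        marker_contigs.setdefault(p.gene_id, set()).add(p.contig_id)

    shared: dict[tuple[str, str], int] = {}
    for contigs in marker_contigs.values():
        sc = sorted(contigs)
        for i in range(len(sc)):
            for j in range(i + 1, len(sc)):
                shared[(sc[i], sc[j])] = shared.get((sc[i], sc[j]), 0) + 1
    return [
        EvidenceEdge(a, b, "marker", float(n))
        for (a, b), n in sorted(shared.items())
        if n >= min_shared
    ]


@dataclass(frozen=True)
class PafRecord:
    query: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target: str
    target_len: int
    target_start: int
    target_end: int


def read_paf(path) -> list[PafRecord]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"malformed PAF at {path}:{i}: fewer than 12 columns")
            try:
                out.append(PafRecord(f[0], int(f[1]), int(f[2]), int(f[3]), f[4],
                                     f[5], int(f[6]), int(f[7]), int(f[8])))
            except ValueError as exc:
                raise ValueError(f"malformed PAF at {path}:{i}: {exc}") from None
    return out


def _merged_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    end = -1
    for s, e in sorted(intervals):
        if s > end:
            total += e - s
            end = e
        elif e > end:
            total += e - end
            end = e
    return total


def pair_by_alignment(
    records: Iterable[PafRecord],
    min_coverage_fraction: float = 0.5,
) -> list[EvidenceEdge]:
    """Edge when merged alignments cover >= the given fraction of the shorter contig.

    For each unordered contig pair, alignment intervals on the shorter
    member (from either alignment direction) are merged before the
    coverage fraction is computed; the fraction is the edge weight.
    """
    per_pair: dict[tuple[str, str], dict] = {}
    for r in records:
        if r.query == r.target:
            continue
        a, b = sorted((r.query, r.target))
        entry = per_pair.setdefault((a, b), {"lens": {}, "ivals": {a: [], b: []}})
        entry["lens"][r.query] = r.query_len
        entry["lens"][r.target] = r.target_len
        entry["ivals"][r.query].append((r.query_start, r.query_end))
        entry["ivals"][r.target].append((r.target_start, r.target_end))

    edges = []
    for (a, b), entry in sorted(per_pair.items()):
        shorter = a if entry["lens"][a] <= entry["lens"][b] else b
        cov = _merged_length(entry["ivals"][shorter]) / entry["lens"][shorter]
        if cov >= min_coverage_fraction:
            edges.append(EvidenceEdge(a, b, "alignment", cov))
    return edges


def purge_redundant(
    graph: AllelicEvidenceGraph,
    retained_policy: Callable[[list[str], dict[str, int]], str] | None = None,
) -> tuple[list[str], list[str], list[dict]]:
    """Keep one contig per connected component of the evidence graph.

    Default policy keeps the longest contig (ties broken lexicographically
    by id); isolated nodes are always kept. Returns (kept, purged, log)
    where the log records, per purged contig, the kept partner and the
    evidence edges that connected its component.
    """
    if retained_policy is None:
        retained_policy = lambda nodes, lengths: max(
            nodes, key=lambda c: (lengths[c], [-ord(ch) for ch in c])
        )

    g = nx.Graph()
    g.add_nodes_from(graph.lengths)
    for e in graph.edges:
        g.add_edge(e.a, e.b)

    edges_by_pair: dict[tuple[str, str], list[EvidenceEdge]] = {}
    for e in graph.edges:
        x, y, _ = e.key()
        edges_by_pair.setdefault((x, y), []).append(e)

    kept: list[str] = []
    purged: list[str] = []
    log: list[dict] = []
    for component in nx.connected_components(g):
        nodes = sorted(component)
        if len(nodes) == 1:
            kept.append(nodes[0])
            continue
        winner = retained_policy(nodes, graph.lengths)
        kept.append(winner)
        component_edges = [
            f"{e.a}-{e.b}:{e.evidence}:{e.weight:g}"
            for pair, es in sorted(edges_by_pair.items())
            if pair[0] in component and pair[1] in component
            for e in es
        ]
        for node in nodes:
            if node == winner:
                continue
            purged.append(node)
            log.append({
                "purged": node,
                "kept": winner,
                "evidence": component_edges,
            })
    return sorted(kept), sorted(purged), log


@dataclass(frozen=True)
class PurgeMetrics:
    n_markers_before: int
    n_markers_after: int
    retention_pct: float
    loss_pct: float
    duplicated_pct: float
    success: bool


def duplication_metrics(
    contigs_before: Iterable[str],
    contigs_after: Iterable[str],
    marker_placements: Iterable[GenePlacement],
) -> PurgeMetrics:
    """Marker retention and duplication after purging.

    Success requires a duplicated-marker rate strictly below 10% of
    retained markers and a loss of distinct markers strictly below 5%
    (both thresholds strict).
    """
    before = set(contigs_before)
    after = set(contigs_after)
    marker_contigs: dict[str, set[str]] = {}
    for p in marker_placements:
        if p.category != MARKER:
            continue
        marker_contigs.setdefault(p.gene_id, set()).add(p.contig_id)

    present_before = {m for m, cs in marker_contigs.items() if cs & before}
    present_after = {m for m, cs in marker_contigs.items() if cs & after}
    if not present_before:
        raise ValueError("no markers placed on the pre-purge assembly")
    retention = 100.0 * len(present_after) / len(present_before)
    loss = 100.0 - retention
    duplicated = {m for m in present_after if len(marker_contigs[m] & after) > 1}
    dup_pct = 100.0 * len(duplicated) / len(present_after) if present_after else 0.0
    return PurgeMetrics(
        n_markers_before=len(present_before),
        n_markers_after=len(present_after),
        retention_pct=retention,
        loss_pct=loss,
        duplicated_pct=dup_pct,
        success=dup_pct < 10.0 and loss < 5.0,
    )
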