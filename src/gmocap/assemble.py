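"""De novo ("blind") assembly of positive reads.

Reads assigned to detected elements — plus their mates, even when the mate
itself did not align — are assembled without any reference guidance, so the
reconstruction cannot be biased towards a known construct sequence and
deviations from announced sequences (or entirely unknown events) remain
visible.

The assembler is a compact de Bruijn graph over canonical k-mers (odd k,
default 31, suited to 75 bp reads): low-coverage edges are dropped, short
dead-end tips are clipped, near-identical bubbles are popped keeping the
higher-coverage branch, and maximal unbranched paths become contigs.
Output ordering and orientation are canonical, so an identical read multiset
yields byte-identical contig FASTA.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import edlib

from .dna import DNA_ALPHABET, canonical, revcomp

_ACGT = set(DNA_ALPHABET)


@dataclass(frozen=True)
class Contig:
    contig_id: str
    sequence: str
    mean_coverage: float

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


class DeBruijnGraph:
    """Canonical k-mer graph; nodes are oriented k-mers, edges implicit."""

    def __init__(self, k: int, counts: dict[str, int]):
        if k % 2 == 0:
            raise ValueError("k must be odd (avoids palindromic k-mers)")
        self.k = k
        self.counts = counts  # canonical kmer -> coverage

    def __contains__(self, kmer: str) -> bool:
        return canonical(kmer) in self.counts

    def coverage(self, kmer: str) -> int:
        return self.counts.get(canonical(kmer), 0)

    def succs(self, kmer: str) -> list[str]:
        out = []
        stem = kmer[1:]
        for b in DNA_ALPHABET:
            nxt = stem + b
            if canonical(nxt) in self.counts:
                out.append(nxt)
        return out

    def preds(self, kmer: str) -> list[str]:
        out = []
        stem = kmer[:-1]
        for b in DNA_ALPHABET:
            prv = b + stem
            if canonical(prv) in self.counts:
                out.append(prv)
        return out

    def remove(self, kmers) -> None:
        for km in kmers:
            self.counts.pop(canonical(km), None)


def count_kmers(reads, k: int) -> Counter:
    counts: Counter = Counter()
    any_long = False
    for seq in reads:
        if len(seq) < k:
            continue
        any_long = True
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if set(kmer) <= _ACGT:
                counts[canonical(kmer)] += 1
    if not any_long:
        raise ValueError(
            f"all reads are shorter than k={k}; use a smaller k"
        )
    return counts


def _unitig_from(graph: DeBruijnGraph, start: str, visited: set[str]):
    """Maximal unbranched oriented path through ``start``; marks visited."""
    path = [start]
    visited.add(canonical(start))
    # extend right
    cur = start
    while True:
        ss = graph.succs(cur)
        if len(ss) != 1:
            break
        nxt = ss[0]
        if len(graph.preds(nxt)) != 1 or canonical(nxt) in visited:
            break
        path.append(nxt)
        visited.add(canonical(nxt))
        cur = nxt
    # extend left
    cur = start
    while True:
        ps = graph.preds(cur)
        if len(ps) != 1:
            break
        prv = ps[0]
        if len(graph.succs(prv)) != 1 or canonical(prv) in visited:
            break
        path.insert(0, prv)
        visited.add(canonical(prv))
        cur = prv
    return path


def _unitigs(graph: DeBruijnGraph) -> list[list[str]]:
    visited: set[str] = set()
    out = []
    for km in sorted(graph.counts):
        if km in visited:
            continue
        out.append(_unitig_from(graph, km, visited))
    return out


def _path_seq(path: list[str]) -> str:
    return path[0] + "".join(km[-1] for km in path[1:])


def _clip_tips(graph: DeBruijnGraph, max_tip_len: int) -> int:
    """Remove short dead-end unitigs hanging off branch points."""
    removed = 0
    for path in _unitigs(graph):
        seq_len = len(_path_seq(path))
        if seq_len >= max_tip_len:
            continue
        left_open = len(graph.preds(path[0])) == 0
        right_open = len(graph.succs(path[-1])) == 0
        # a tip dangles at exactly one end and attaches at the other
        if left_open != right_open:
            graph.remove(path)
            removed += len(path)
    return removed


def _walk_branch(graph: DeBruijnGraph, node: str, limit: int):
    """Follow a unipath from ``node`` until a merge node (in-degree >= 2)."""
    path = [node]
    cur = node
    for _ in range(limit):
        ss = graph.succs(cur)
        if len(ss) != 1:
            return path, None
        nxt = ss[0]
        if len(graph.preds(nxt)) >= 2:
            return path, nxt
        path.append(nxt)
        cur = nxt
    return path, None


def _pop_bubbles(graph: DeBruijnGraph, min_branch_identity: float = 0.95) -> int:
    """Collapse simple two-branch bubbles, keeping the higher-coverage side."""
    removed = 0
    k = graph.k
    limit = 4 * k
    branch_nodes = []
    for km in sorted(graph.counts):
        for node in (km, revcomp(km)):
            if len(graph.succs(node)) == 2:
                branch_nodes.append(node)
    for node in branch_nodes:
        ss = graph.succs(node)
        if len(ss) != 2:
            continue  # may have changed after earlier pops
        (p1, m1) = _walk_branch(graph, ss[0], limit)
        (p2, m2) = _walk_branch(graph, ss[1], limit)
        if m1 is None or m1 != m2:
            continue
        s1, s2 = _path_seq(p1), _path_seq(p2)
        d = edlib.align(s1, s2)["editDistance"]
        identity = 1.0 - d / max(len(s1), len(s2))
        if identity < min_branch_identity:
            continue
        cov1 = sum(graph.coverage(x) for x in p1) / len(p1)
        cov2 = sum(graph.coverage(x) for x in p2) / len(p2)
        loser = p2 if cov1 >= cov2 else p1
        graph.remove(loser)
        removed += len(loser)
    return removed


def build_graph(reads, k: int = 31, min_edge_cov: int = 2) -> DeBruijnGraph:
    counts = count_kmers(reads, k)
    counts = {km: c for km, c in counts.items() if c >= min_edge_cov}
    return DeBruijnGraph(k, counts)


def assemble_contigs(reads, k: int = 31, min_edge_cov: int = 2,
                     min_contig_len: int = 100) -> list[Contig]:
    """Assemble read sequences into contigs.

    ``reads`` is an iterable of DNA strings (both strands are handled through
    canonical k-mers).  Contigs are reported in canonical orientation,
    ordered by descending length then sequence.
    """
    graph = build_graph(reads, k=k, min_edge_cov=min_edge_cov)
    for _round in range(4):
        changed = _clip_tips(graph, max_tip_len=2 * k)
        changed += _pop_bubbles(graph)
        if changed == 0:
            break
    contigs = []
    for path in _unitigs(graph):
        seq = _path_seq(path)
        if len(seq) < min_contig_len:
            continue
        cov = sum(graph.coverage(x) for x in path) / len(path)
        contigs.append((canonical(seq), cov))
    contigs.sort(key=lambda t: (-len(t[0]), t[0]))
    return [
        Contig(contig_id=f"contig{i + 1:04d}", sequence=seq, mean_coverage=round(cov, 3))
        for i, (seq, cov) in enumerate(contigs)
    ]


def extract_positive_reads(assignments, pairs_or_fastq, detected_elements,
                           fastq2=None) -> list[tuple[str, str]]:
    """Positive-read subset feeding assembly: assigned reads plus mates.

    ``assignments`` is the classification DataFrame; ``pairs_or_fastq`` is
    either a list of ReadPair objects or the mate-1 FASTQ path (with
    ``fastq2``).  A read is included when it, or its mate, was assigned to a
    detected element; the output is deduplicated by read id and kept in
    input order.  Assigned read ids absent from the FASTQ are an error.
    """
    detected = set(detected_elements)
    pos_pairs = set()
    assigned_ids = []
    for row in assignments.itertuples(index=False):
        if row.element_id and row.element_id in detected:
            base = str(row.read_id).rsplit("/", 1)[0]
            pos_pairs.add(base)
            assigned_ids.append(str(row.read_id))

    reads: list[tuple[str, str]] = []
    seen_ids = set()
    if isinstance(pairs_or_fastq, (str, Path)):
        from Bio import SeqIO
        for path in (pairs_or_fastq, fastq2):
            if path is None:
                continue
            for rec in SeqIO.parse(str(path), "fastq"):
                seen_ids.add(rec.id)
                if rec.id.rsplit("/", 1)[0] in pos_pairs:
                    reads.append((rec.id, str(rec.seq).upper()))
    else:
        for p in pairs_or_fastq:
            seen_ids.update((f"{p.read_id}/1", f"{p.read_id}/2"))
            if p.read_id in pos_pairs:
                reads.append((f"{p.read_id}/1", p.mate1))
                reads.append((f"{p.read_id}/2", p.mate2))
    missing = [rid for rid in assigned_ids if rid not in seen_ids]
    if missing:
        raise ValueError(f"assigned read ids missing from FASTQ: {missing[:5]}")
    # dedup preserving order
    out, seen = [], set()
    for rid, seq in reads:
        if rid not in seen:
            seen.add(rid)
            out.append((rid, seq))
    return out


def write_contigs_fasta(contigs: list[Contig], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for c in contigs:
            fh.write(f">{c.contig_id} length={c.length_bp} cov={c.mean_coverage}\n")
            for i in range(0, len(c.sequence), 80):
                fh.write(c.sequence[i : i + 80] + "\n")
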