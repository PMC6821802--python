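"""Contig annotation, insert-layout reconstruction and junction calling.

Assembled contigs are compared back to the element database (both strands)
and, when a host reference is available, to the host genome.  Overlapping
hits are resolved greedily by alignment score, uncovered stretches become
"unknown" intervals, and adjacencies between host-derived and
construct-derived intervals are called as plant-construct junctions (the
event-specific left/right borders of the insert).  Finally, per-sample
layouts report the ordered element structure of each inferred construct,
flagging gaps where unprobed sequence interrupted assembly.

Internally coordinates are 0-based half-open; GFF3 / report output is
1-based.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from .align import banded_local_align
from .assemble import Contig
from .dna import revcomp
from .element_db import ElementCategory, ElementDatabase
from .simulate import HostGenome


@dataclass
class AnnotParams:
    k: int = 15
    min_identity: float = 0.90
    min_hit_len: int = 30
    max_overlap: int = 10       # tolerated overlap between accepted intervals
    unknown_min_len: int = 30   # uncovered stretches at least this long are reported
    junction_gap: int = 20
    band: int = 24
    min_seeds: int = 2
    max_clusters: int = 8
    # stiff scoring keeps local alignments from drifting past junctions into
    # unrelated sequence (a +1/-1 scheme can random-walk tens of bases)
    match: int = 1
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


@dataclass(frozen=True)
class AnnotationInterval:
    contig_start: int
    contig_end: int
    hit_kind: str          # element | host | unknown
    ref_id: str
    ref_start: int
    ref_end: int
    identity: float
    strand: str            # + | - | .
    score: int = 0


@dataclass
class ContigAnnotation:
    contig_id: str
    length_bp: int
    intervals: list = field(default_factory=list)  # sorted by contig_start

    def of_kind(self, kind: str) -> list:
        return [iv for iv in self.intervals if iv.hit_kind == kind]


@dataclass(frozen=True)
class JunctionCall:
    contig_id: str
    breakpoint: int            # contig coordinate (0-based)
    host_genome_id: str
    host_coord: int            # 0-based position on the host reference
    host_strand: str
    construct_ref: str         # adjacent element (or 'unknown') on the construct side
    border: str                # left | right


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    pos = defaultdict(list)
    for i in range(len(seq) - k + 1):
        pos[seq[i : i + k]].append(i)
    return pos


def _seed_hits(query: str, target_index: dict[str, list[int]], k: int):
    """Diagonal support map {diag: n_seeds} of query vs indexed target."""
    diags: dict[int, int] = defaultdict(int)
    for q in range(len(query) - k + 1):
        for t in target_index.get(query[q : q + k], ()):
            diags[t - q] += 1
    return diags


def _clustered_diagonals(diags: dict[int, int], band: int, min_seeds: int,
                         max_clusters: int):
    if not diags:
        return []
    sorted_d = sorted(diags)
    clusters = [[sorted_d[0]]]
    for d in sorted_d[1:]:
        if d - clusters[-1][-1] <= band:
            clusters[-1].append(d)
        else:
            clusters.append([d])
    reps = []
    for cl in clusters:
        support = sum(diags[d] for d in cl)
        if support < min_seeds:
            continue
        rep = max(cl, key=lambda d: (diags[d], -abs(d)))
        reps.append((support, rep))
    reps.sort(key=lambda t: (-t[0], t[1]))
    return [rep for _s, rep in reps[:max_clusters]]


def _align_query_to_target(query: str, target: str, target_index, params: AnnotParams):
    """All well-supported banded local alignments of query against target."""
    hits = []
    diags = _seed_hits(query, target_index, params.k)
    for rep in _clustered_diagonals(diags, params.band, params.min_seeds,
                                    params.max_clusters):
        res = banded_local_align(query, target, rep, band=params.band,
                                 match=params.match, mismatch=params.mismatch,
                                 gap_open=params.gap_open,
                                 gap_extend=params.gap_extend)
        if res is None:
            continue
        if res.identity < params.min_identity or res.aligned_len < params.min_hit_len:
            continue
        hits.append(res)
    return hits


def _trim(iv: AnnotationInterval, new_start: int, new_end: int):
    """Clip an interval to [new_start, new_end) on the contig.

    Reference coordinates are shifted by the clipped amounts assuming an
    ungapped (diagonal) alignment; the forward/reverse mapping of contig to
    reference follows the interval's strand.
    """
    if new_end - new_start <= 0:
        return None
    dl = new_start - iv.contig_start
    dr = iv.contig_end - new_end
    if iv.strand == "-":
        rs, re_ = iv.ref_start + dr, iv.ref_end - dl
    else:
        rs, re_ = iv.ref_start + dl, iv.ref_end - dr
    if re_ - rs <= 0:
        return None
    return AnnotationInterval(
        contig_start=new_start, contig_end=new_end,
        hit_kind=iv.hit_kind, ref_id=iv.ref_id,
        ref_start=rs, ref_end=re_,
        identity=iv.identity, strand=iv.strand, score=iv.score,
    )


def annotate_contig(contig: Contig, db: ElementDatabase,
                    host_refs: list[HostGenome] | None = None,
                    params: AnnotParams | None = None,
                    _host_indexes=None) -> ContigAnnotation:
    """Annotate one contig with element, host and unknown intervals."""
    params = params or AnnotParams()
    cseq = contig.sequence
    contig_index = _kmer_positions(cseq, params.k)
    raw: list[AnnotationInterval] = []

    # element hits: query = element (either strand), target = contig
    for el in db:
        for strand in ("+", "-"):
            q = el.sequence if strand == "+" else revcomp(el.sequence)
            for res in _align_query_to_target(q, cseq, contig_index, params):
                if strand == "+":
                    rs, re_ = res.q_start, res.q_end
                else:
                    rs, re_ = el.length_bp - res.q_end, el.length_bp - res.q_start
                raw.append(AnnotationInterval(
                    contig_start=res.t_start, contig_end=res.t_end,
                    hit_kind="element", ref_id=el.element_id,
                    ref_start=rs, ref_end=re_,
                    identity=round(res.identity, 6), strand=strand,
                    score=res.score,
                ))

    # host hits: query = contig (either orientation), target = host genome
    if host_refs:
        if _host_indexes is None:
            _host_indexes = {
                h.genome_id: _kmer_positions(h.sequence, params.k) for h in host_refs
            }
        Lc = len(cseq)
        for h in host_refs:
            hidx = _host_indexes[h.genome_id]
            for strand in ("+", "-"):
                q = cseq if strand == "+" else revcomp(cseq)
                for res in _align_query_to_target(q, h.sequence, hidx, params):
                    if strand == "+":
                        cs, ce = res.q_start, res.q_end
                    else:
                        cs, ce = Lc - res.q_end, Lc - res.q_start
                    raw.append(AnnotationInterval(
                        contig_start=cs, contig_end=ce,
                        hit_kind="host", ref_id=h.genome_id,
                        ref_start=res.t_start, ref_end=res.t_end,
                        identity=round(res.identity, 6), strand=strand,
                        score=res.score,
                    ))

    # greedy score-based interval resolution; a lower-scoring hit protruding
    # past an accepted one is trimmed back to the boundary (ungapped
    # approximation, exact for the high-identity hits that survive filtering)
    raw.sort(key=lambda iv: (-iv.score, iv.ref_id, iv.contig_start))
    accepted: list[AnnotationInterval] = []
    for iv in raw:
        for acc in accepted:
            if iv is None:
                break
            ov = min(iv.contig_end, acc.contig_end) - max(iv.contig_start, acc.contig_start)
            if ov <= params.max_overlap:
                continue
            if acc.contig_start <= iv.contig_start and acc.contig_end >= iv.contig_end:
                iv = None   # fully shadowed
            elif acc.contig_start <= iv.contig_start:
                iv = _trim(iv, acc.contig_end, iv.contig_end)
            elif acc.contig_end >= iv.contig_end:
                iv = _trim(iv, iv.contig_start, acc.contig_start)
            else:  # acc strictly inside iv: keep the larger flank
                left = acc.contig_start - iv.contig_start
                right = iv.contig_end - acc.contig_end
                if left >= right:
                    iv = _trim(iv, iv.contig_start, acc.contig_start)
                else:
                    iv = _trim(iv, acc.contig_end, iv.contig_end)
            if iv is not None and iv.contig_end - iv.contig_start < params.min_hit_len:
                iv = None
        if iv is not None:
            accepted.append(iv)
    accepted.sort(key=lambda iv: (iv.contig_start, iv.contig_end))

    # label long uncovered stretches
    intervals: list[AnnotationInterval] = []
    cursor = 0
    for iv in accepted:
        if iv.contig_start - cursor >= params.unknown_min_len:
            intervals.append(AnnotationInterval(
                cursor, iv.contig_start, "unknown", "unknown", -1, -1, 0.0, "."))
        intervals.append(iv)
        cursor = max(cursor, iv.contig_end)
    if len(cseq) - cursor >= params.unknown_min_len:
        intervals.append(AnnotationInterval(
            cursor, len(cseq), "unknown", "unknown", -1, -1, 0.0, "."))

    return ContigAnnotation(contig_id=contig.contig_id, length_bp=len(cseq),
                            intervals=intervals)


def annotate_contigs(contigs: list[Contig], db: ElementDatabase,
                     host_refs: list[HostGenome] | None = None,
                     params: AnnotParams | None = None) -> list[ContigAnnotation]:
    params = params or AnnotParams()
    host_indexes = None
    if host_refs:
        host_indexes = {
            h.genome_id: _kmer_positions(h.sequence, params.k) for h in host_refs
        }
    return [
        annotate_contig(c, db, host_refs, params, _host_indexes=host_indexes)
        for c in contigs
    ]


def call_junctions(ann: ContigAnnotation,
                   params: AnnotParams | None = None) -> list[JunctionCall]:
    """Plant-construct junctions from host/non-host adjacencies in one contig.

    The border is 'left' when, read on the host forward strand, plant DNA
    precedes the construct, 'right' otherwise.  The reported host coordinate
    is the reference base immediately flanking the insert (the insertion
    site), 0-based here and 1-based in JSON reports.
    """
    params = params or AnnotParams()
    calls = []
    ivs = ann.intervals
    for a, b in zip(ivs, ivs[1:]):
        gap = b.contig_start - a.contig_end
        if gap > params.junction_gap:
            continue
        if a.hit_kind == "host" and b.hit_kind in ("element", "unknown"):
            host, other, host_first = a, b, True
        elif b.hit_kind == "host" and a.hit_kind in ("element", "unknown"):
            host, other, host_first = b, a, False
        else:
            continue
        left = (host_first and host.strand == "+") or \
               (not host_first and host.strand == "-")
        calls.append(JunctionCall(
            contig_id=ann.contig_id,
            breakpoint=host.contig_end if host_first else host.contig_start,
            host_genome_id=host.ref_id,
            host_coord=host.ref_end if left else host.ref_start,
            host_strand=host.strand,
            construct_ref=other.ref_id,
            border="left" if left else "right",
        ))
    return calls


def reconstruct_layout(annotations: list[ContigAnnotation],
                       db: ElementDatabase) -> dict:
    """Per-sample insert layout report.

    Contigs are grouped into inferred constructs by shared gene-category
    elements (a union of contigs sharing the same coding gene).  Contigs
    carrying only shared element classes (promoters/terminators/misc) attach
    to the single gene group when exactly one exists; with no gene group at
    all, all element-bearing contigs form one layout; with several, they are
    reported as 'shared' since flanking evidence cannot place them.
    """
    def gene_ids(ann: ContigAnnotation) -> set[str]:
        out = set()
        for iv in ann.of_kind("element"):
            if db[iv.ref_id].category == ElementCategory.GENE:
                out.add(iv.ref_id)
        return out

    element_bearing = [a for a in annotations if a.of_kind("element")]
    other = [a.contig_id for a in annotations if not a.of_kind("element")]

    # union-find over contigs sharing gene elements
    parent: dict[str, str] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    gene_owner: dict[str, str] = {}
    with_genes = []
    for ann in element_bearing:
        gs = gene_ids(ann)
        if not gs:
            continue
        with_genes.append(ann)
        parent.setdefault(ann.contig_id, ann.contig_id)
        for g in sorted(gs):
            if g in gene_owner:
                union(ann.contig_id, gene_owner[g])
            else:
                gene_owner[g] = ann.contig_id

    groups: dict[str, list[ContigAnnotation]] = defaultdict(list)
    for ann in with_genes:
        groups[find(ann.contig_id)].append(ann)

    no_gene = [a for a in element_bearing if not gene_ids(a)]
    shared = []
    if len(groups) == 1:
        root = next(iter(groups))
        groups[root].extend(no_gene)
    elif len(groups) == 0:
        if no_gene:
            groups["layout"] = list(no_gene)
    else:
        shared = no_gene

    layouts = []
    for i, root in enumerate(sorted(groups)):
        members = sorted(groups[root], key=lambda a: (-a.length_bp, a.contig_id))
        contig_entries = []
        for ann in members:
            contig_entries.append({
                "contig_id": ann.contig_id,
                "length_bp": ann.length_bp,
                "elements": [
                    {
                        "ref_id": iv.ref_id,
                        "contig_start": iv.contig_start,
                        "contig_end": iv.contig_end,
                        "strand": iv.strand,
                        "identity": iv.identity,
                        "category": db[iv.ref_id].category.value,
                    }
                    for iv in ann.of_kind("element")
                ],
            })
        layouts.append({
            "layout_id": f"construct{i + 1}",
            "contigs": contig_entries,
            "element_order": [
                e["ref_id"] for c in contig_entries for e in c["elements"]
            ],
            "n_gaps": max(0, len(members) - 1),
        })
    return {
        "layouts": layouts,
        "shared_contigs": sorted(a.contig_id for a in shared),
        "contigs_without_elements": sorted(other),
    }


def write_gff3(annotations: list[ContigAnnotation], path: str | Path) -> None:
    """GFF3 of contig annotations (contig as landmark, 1-based closed)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for ann in annotations:
            fh.write(f"##sequence-region {ann.contig_id} 1 {ann.length_bp}\n")
            for iv in ann.intervals:
                attrs = f"ID={ann.contig_id}.{iv.contig_start};kind={iv.hit_kind}"
                if iv.hit_kind != "unknown":
                    attrs += (f";ref={iv.ref_id};ref_start={iv.ref_start + 1};"
                              f"ref_end={iv.ref_end};identity={iv.identity}")
                fh.write(
                    f"{ann.contig_id}\tgmocap\t{iv.hit_kind}\t"
                    f"{iv.contig_start + 1}\t{iv.contig_end}\t"
                    f"{iv.score if iv.hit_kind != 'unknown' else '.'}\t"
                    f"{iv.strand}\t.\t{attrs}\n"
                )


def junctions_to_json(calls: list[JunctionCall], path: str | Path) -> None:
    data = [
        {
            "contig_id": c.contig_id,
            "breakpoint_1based": c.breakpoint + 1,
            "host_genome_id": c.host_genome_id,
            "host_coord_1based": c.host_coord + 1,
            "host_strand": c.host_strand,
            "construct_ref": c.construct_ref,
            "border": c.border,
        }
        for c in calls
    ]
    with open(path, "w", newline="\n") as fh:
        json.dump(data, fh, indent=2)
        fh.write("\n")


def layout_to_json(layout: dict, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(layout, fh, indent=2)
        fh.write("\n")
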