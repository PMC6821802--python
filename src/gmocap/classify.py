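"""Read classification against the enrichment database.

The first half of the detection workflow: every sequenced read is aligned
onto the structural-element sequences used for enrichment and filtered on its
alignment score.  Alignment is seed-and-extend: exact k-mer seeds (default
k = 15) locate candidate elements and diagonals, a banded Smith–Waterman
extension scores them, and the single best-scoring element wins.  Reads
passing the identity/length filter are "positive" reads; ties within the
score tolerance are flagged ambiguous and broken lexicographically so counts
stay deterministic (they are not split fractionally).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .align import banded_local_align
from .dna import revcomp
from .element_db import ElementDatabase


@dataclass
class KmerIndex:
    """Exact k-mer index over both strands of every element (dual entry)."""

    k: int
    # kmer -> list of (element_id, forward offset, strand of the element k-mer)
    index: dict[str, list[tuple[str, int, str]]]
    n_forward_positions: int

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        return self.index.get(kmer, [])


def index_database(db: ElementDatabase, k: int = 15) -> KmerIndex:
    """Index every length-k substring of every element, both strands."""
    if k > db.min_element_length():
        raise ValueError(
            f"k={k} exceeds the shortest element length {db.min_element_length()}"
        )
    index: dict[str, list[tuple[str, int, str]]] = defaultdict(list)
    n_fwd = 0
    for el in db:
        seq = el.sequence
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            index[kmer].append((el.element_id, i, "+"))
            index[revcomp(kmer)].append((el.element_id, i, "-"))
            n_fwd += 1
    return KmerIndex(k=k, index=dict(index), n_forward_positions=n_fwd)


@dataclass
class AlignParams:
    min_identity: float = 0.90
    min_len: int = 40          # minimum alignment columns for a positive read
    tie_tol: int = 0           # score ties within this margin set the ambiguous flag
    band: int = 16
    max_clusters: int = 3      # seed-diagonal clusters evaluated per element/strand
    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1


@dataclass
class ReadAssignment:
    read_id: str
    element_id: str | None = None
    alignment_score: int = 0
    identity: float = 0.0
    aligned_len: int = 0
    element_start: int | None = None   # 0-based half-open on the element
    element_end: int | None = None
    strand: str | None = None
    ambiguous: bool = False

    @property
    def assigned(self) -> bool:
        return self.element_id is not None


def _seed_clusters(read: str, index: KmerIndex):
    """Collect seed hits grouped by (element, strand) into diagonal clusters.

    A '-' index hit means the reverse complement of the read matches the
    element forward strand; its diagonal is expressed in revcomp-read
    coordinates so extension can run on oriented query vs forward element.
    """
    k = index.k
    L = len(read)
    diags: dict[tuple[str, str], dict[int, int]] = defaultdict(lambda: defaultdict(int))
    for p in range(L - k + 1):
        for eid, off, strand in index.lookup(read[p : p + k]):
            if strand == "+":
                diags[(eid, "+")][off - p] += 1
            else:
                diags[(eid, "-")][off - (L - p - k)] += 1
    return diags


def align_read(read: str, index: KmerIndex, db: ElementDatabase,
               params: AlignParams | None = None,
               read_id: str = "read") -> ReadAssignment:
    """Best-element assignment for one read (both orientations tried)."""
    params = params or AlignParams()
    if len(read) < index.k:
        return ReadAssignment(read_id=read_id)
    diags = _seed_clusters(read, index)
    if not diags:
        return ReadAssignment(read_id=read_id)

    rc = revcomp(read)
    best_per_element: dict[str, tuple] = {}
    for (eid, strand), dmap in diags.items():
        # cluster nearby diagonals; one representative per cluster
        sorted_diags = sorted(dmap)
        clusters: list[list[int]] = [[sorted_diags[0]]]
        for dg in sorted_diags[1:]:
            if dg - clusters[-1][-1] <= params.band:
                clusters[-1].append(dg)
            else:
                clusters.append([dg])
        reps = []
        for cl in clusters:
            rep = max(cl, key=lambda dg: (dmap[dg], -abs(dg)))
            reps.append((sum(dmap[dg] for dg in cl), rep))
        reps.sort(key=lambda t: (-t[0], t[1]))
        query = read if strand == "+" else rc
        target = db[eid].sequence
        for _support, rep in reps[: params.max_clusters]:
            res = banded_local_align(
                query, target, rep, band=params.band,
                match=params.match, mismatch=params.mismatch,
                gap_open=params.gap_open, gap_extend=params.gap_extend,
            )
            if res is None:
                continue
            # prefer higher score; on equal score prefer '+' strand
            key = (res.score, strand == "+")
            cur = best_per_element.get(eid)
            if cur is None or key > (cur[0].score, cur[1] == "+"):
                best_per_element[eid] = (res, strand)

    if not best_per_element:
        return ReadAssignment(read_id=read_id)

    # global best: highest score, lexicographic element id on ties
    ranked = sorted(
        best_per_element.items(),
        key=lambda kv: (-kv[1][0].score, kv[0]),
    )
    best_eid, (best_res, best_strand) = ranked[0]
    ambiguous = (
        len(ranked) > 1
        and ranked[1][1][0].score >= best_res.score - params.tie_tol
    )
    if best_res.identity < params.min_identity or best_res.aligned_len < params.min_len:
        return ReadAssignment(read_id=read_id)
    return ReadAssignment(
        read_id=read_id,
        element_id=best_eid,
        alignment_score=best_res.score,
        identity=best_res.identity,
        aligned_len=best_res.aligned_len,
        element_start=best_res.t_start,
        element_end=best_res.t_end,
        strand=best_strand,
        ambiguous=ambiguous,
    )


ASSIGNMENT_COLUMNS = [
    "read_id", "mate", "element_id", "alignment_score", "identity",
    "aligned_len", "element_start", "element_end", "strand", "ambiguous",
]


def _parse_fastq(path: str | Path):
    """Yield (read_id, sequence); malformed records raise with the record number."""
    n = 0
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            n += 1
            yield rec.id, str(rec.seq).upper()
    except ValueError as exc:
        raise ValueError(f"{path}: malformed FASTQ at record {n + 1}: {exc}") from exc


def classify_reads(fastq1: str | Path, fastq2: str | Path | None,
                   index: KmerIndex, db: ElementDatabase,
                   params: AlignParams | None = None):
    """Classify every mate of a FASTQ pair independently.

    Returns ``(assignments, summary)``: a DataFrame with one row per mate in
    input order (pairing recorded in the ``mate`` column) and a summary dict
    with total reads, reads aligned and % aligned.
    """
    params = params or AlignParams()
    rows = []
    sources = [(1, fastq1)] + ([(2, fastq2)] if fastq2 is not None else [])
    for mate, path in sources:
        for read_id, seq in _parse_fastq(path):
            a = align_read(seq, index, db, params, read_id=read_id)
            rows.append((
                read_id, mate, a.element_id if a.assigned else "",
                a.alignment_score, round(a.identity, 6), a.aligned_len,
                a.element_start if a.assigned else -1,
                a.element_end if a.assigned else -1,
                a.strand if a.assigned else ".",
                a.ambiguous,
            ))
    df = pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)
    total = len(df)
    aligned = int((df["element_id"] != "").sum())
    summary = {
        "total_reads": total,
        "reads_aligned": aligned,
        "pct_aligned": (100.0 * aligned / total) if total else 0.0,
    }
    return df, summary


def classify_read_pairs(pairs, index: KmerIndex, db: ElementDatabase,
                        params: AlignParams | None = None):
    """In-memory variant of :func:`classify_reads` for simulated ReadPairs."""
    params = params or AlignParams()
    rows = []
    for p in pairs:
        for mate, seq in ((1, p.mate1), (2, p.mate2)):
            a = align_read(seq, index, db, params, read_id=f"{p.read_id}/{mate}")
            rows.append((
                a.read_id, mate, a.element_id if a.assigned else "",
                a.alignment_score, round(a.identity, 6), a.aligned_len,
                a.element_start if a.assigned else -1,
                a.element_end if a.assigned else -1,
                a.strand if a.assigned else ".",
                a.ambiguous,
            ))
    df = pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)
    total = len(df)
    aligned = int((df["element_id"] != "").sum())
    summary = {
        "total_reads": total,
        "reads_aligned": aligned,
        "pct_aligned": (100.0 * aligned / total) if total else 0.0,
    }
    return df, summary


def write_assignments(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_assignments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"element_id": str, "strand": str})
    df["ambiguous"] = df["ambiguous"].astype(bool)
    return df


def write_sam(df: pd.DataFrame, db: ElementDatabase, reads: dict[str, str],
              path: str | Path) -> None:
    """Minimal unsorted SAM export of assignments (TSV stays canonical).

    ``reads`` maps read_id to sequence; unassigned mates are emitted unmapped.
    CIGAR is simplified to soft-clipped matches from the recorded interval.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": el.element_id, "LN": el.length_bp} for el in db],
    }
    ref_ids = {el.element_id: i for i, el in enumerate(db)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in df.itertuples(index=False):
            a = pysam.AlignedSegment(out.header)
            a.query_name = row.read_id
            seq = reads.get(row.read_id, "")
            if row.element_id == "":
                a.flag = 4
                a.query_sequence = seq or None
            else:
                a.flag = 16 if row.strand == "-" else 0
                a.reference_id = ref_ids[row.element_id]
                a.reference_start = int(row.element_start)
                a.mapping_quality = 60
                qseq = revcomp(seq) if row.strand == "-" else seq
                a.query_sequence = qseq or None
                if qseq:
                    # simplified CIGAR: the export records placement, not the
                    # exact gap structure (the TSV carries the scored interval)
                    a.cigartuples = [(0, len(qseq))]
            out.write(a)
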