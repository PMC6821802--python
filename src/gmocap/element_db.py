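"""Screening-element database and capture-probe design.

The enrichment step of the workflow targets a panel of structural elements
(promoters, terminators, coding genes and miscellaneous sequences) that recur
in transgenic constructs.  This module holds the in-memory database of those
elements, validates it, persists it as FASTA + a tab-separated metadata table,
and tiles hybridisation capture probes (~120 bp, low overlap, no degeneracy)
over every element.

Coordinates are 0-based half-open throughout the package; human-readable
reports convert to 1-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dna import validate_dna


class ElementCategory(str, Enum):
    PROMOTER = "promoter"
    TERMINATOR = "terminator"
    GENE = "gene"
    MISCELLANEOUS = "miscellaneous"


@dataclass(frozen=True)
class StructuralElement:
    """One enrichment target: a screening element of a transgenic construct."""

    element_id: str
    category: ElementCategory
    sequence: str
    source: str = ""
    allow_ambiguous: bool = False

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"element {self.element_id!r}: empty sequence")
        validate_dna(self.sequence, name=f"element {self.element_id!r}",
                     allow_ambiguous=self.allow_ambiguous)
        object.__setattr__(self, "category", ElementCategory(self.category))

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


class ElementDatabase:
    """Ordered, id-unique collection of structural elements."""

    def __init__(self, elements: Sequence[StructuralElement]):
        elements = list(elements)
        if not elements:
            raise ValueError("element database must contain at least one element")
        seen: set[str] = set()
        for el in elements:
            if el.element_id in seen:
                raise ValueError(f"duplicate element id: {el.element_id!r}")
            seen.add(el.element_id)
        self.elements: list[StructuralElement] = elements
        self._by_id = {el.element_id: el for el in elements}

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    def __contains__(self, element_id: str) -> bool:
        return element_id in self._by_id

    def __getitem__(self, element_id: str) -> StructuralElement:
        return self._by_id[element_id]

    @property
    def element_ids(self) -> list[str]:
        return [el.element_id for el in self.elements]

    @property
    def total_length_bp(self) -> int:
        return sum(el.length_bp for el in self.elements)

    def min_element_length(self) -> int:
        return min(el.length_bp for el in self.elements)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(el.sequence), id=el.element_id, description="")
            for el in self.elements
        ]
        with open(path, "w", newline="\n") as fh:
            SeqIO.write(records, fh, "fasta")

    def to_metadata(self, path: str | Path) -> None:
        with open(path, "w", newline="\n") as fh:
            fh.write("element_id\tcategory\tsize_bp\tsource\n")
            for el in self.elements:
                fh.write(
                    f"{el.element_id}\t{el.category.value}\t{el.length_bp}\t{el.source}\n"
                )


def database_checksum(db: ElementDatabase) -> int:
    """Total length of the enrichment database in bp (sum of element lengths)."""
    return db.total_length_bp


def build_database(element_fasta: str | Path, metadata_table: str | Path,
                   allow_ambiguous: bool = False) -> ElementDatabase:
    """Build a validated database from a FASTA file and a metadata TSV.

    The metadata table must have a header line with columns
    ``element_id  category  size_bp  source`` and one row per FASTA record.
    FASTA ids and metadata rows must match one-to-one.
    """
    meta: dict[str, tuple[str, int, str]] = {}
    with open(metadata_table) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {c: i for i, c in enumerate(header)}
        for need in ("element_id", "category", "source"):
            if need not in cols:
                raise ValueError(f"metadata table missing column {need!r}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            eid = parts[cols["element_id"]]
            if eid in meta:
                raise ValueError(f"duplicate metadata row for element id {eid!r}")
            size = int(parts[cols["size_bp"]]) if "size_bp" in cols else -1
            meta[eid] = (parts[cols["category"]], size, parts[cols["source"]])

    elements = []
    seen = set()
    for rec in SeqIO.parse(str(element_fasta), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate element id in FASTA: {rec.id!r}")
        seen.add(rec.id)
        if rec.id not in meta:
            raise ValueError(f"no metadata row for FASTA id {rec.id!r}")
        category, size, source = meta[rec.id]
        seq = str(rec.seq).upper()
        if size >= 0 and size != len(seq):
            raise ValueError(
                f"element {rec.id!r}: metadata size_bp {size} != sequence length {len(seq)}"
            )
        elements.append(
            StructuralElement(rec.id, ElementCategory(category), seq, source,
                              allow_ambiguous=allow_ambiguous)
        )
    missing = set(meta) - seen
    if missing:
        raise ValueError(f"metadata rows without FASTA record: {sorted(missing)}")
    return ElementDatabase(elements)


@dataclass(frozen=True)
class Probe:
    probe_id: str
    element_id: str
    start: int  # 0-based, half-open on element coordinates
    end: int
    sequence: str


@dataclass
class ProbeSet:
    probes: list[Probe] = field(default_factory=list)
    probe_length_bp: int = 120
    step_bp: int = 110

    def __len__(self) -> int:
        return len(self.probes)

    def intervals_for(self, element_id: str) -> list[tuple[int, int]]:
        return [(p.start, p.end) for p in self.probes if p.element_id == element_id]


def design_probes(db: ElementDatabase, probe_length_bp: int = 120,
                  step_bp: int = 110) -> ProbeSet:
    """Tile verbatim capture probes over every element of the database.

    Probes start at 0 and advance by ``step_bp``; the last probe of each
    element is end-anchored so the final base is always covered.  Elements
    shorter than ``probe_length_bp`` yield a single probe spanning the whole
    element.  ``step_bp`` greater than ``probe_length_bp`` would leave
    uncovered gaps and is rejected.
    """
    if probe_length_bp < 1 or step_bp < 1:
        raise ValueError("probe_length_bp and step_bp must be >= 1")
    if step_bp > probe_length_bp:
        raise ValueError(
            f"step_bp {step_bp} > probe_length_bp {probe_length_bp} would leave gaps"
        )
    probes: list[Probe] = []
    for el in db:
        L = el.length_bp
        starts: list[int]
        if L <= probe_length_bp:
            starts = [0]
            ends = [L]
        else:
            starts = list(range(0, L - probe_length_bp + 1, step_bp))
            if starts[-1] + probe_length_bp < L:
                starts.append(L - probe_length_bp)  # end-anchored terminal probe
            ends = [s + probe_length_bp for s in starts]
        for i, (s, e) in enumerate(zip(starts, ends)):
            probes.append(Probe(
                probe_id=f"{el.element_id}_p{i:03d}",
                element_id=el.element_id,
                start=s, end=e,
                sequence=el.sequence[s:e],
            ))
    return ProbeSet(probes, probe_length_bp=probe_length_bp, step_bp=step_bp)


def expected_probe_count(element_len: int, probe_len: int, step: int) -> int:
    """Closed-form probe count for one element (used as a tiling cross-check)."""
    if element_len <= probe_len:
        return 1
    n = 1 + math.floor((element_len - probe_len) / step)
    if (n - 1) * step + probe_len < element_len:
        n += 1  # end-anchored final probe
    return n


def write_probe_bed(ps: ProbeSet, out: str | Path) -> None:
    """Write probes as BED intervals (0-based half-open, element coordinates)."""
    with open(out, "w", newline="\n") as fh:
        for p in ps.probes:
            fh.write(f"{p.element_id}\t{p.start}\t{p.end}\t{p.probe_id}\n")


def read_probe_bed(path: str | Path, db: ElementDatabase,
                   probe_length_bp: int = 120, step_bp: int = 110) -> ProbeSet:
    """Read a probe BED back into a ProbeSet, restoring sequences from the db."""
    probes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            eid, s, e, pid = line.rstrip("\n").split("\t")[:4]
            start, end = int(s), int(e)
            el = db[eid]
            probes.append(Probe(pid, eid, start, end, el.sequence[start:end]))
    return ProbeSet(probes, probe_length_bp=probe_length_bp, step_bp=step_bp)


def covered_intervals(ps: ProbeSet, element_id: str) -> list[tuple[int, int]]:
    """Union of probe intervals on one element, merged and sorted."""
    ivs = sorted(ps.intervals_for(element_id))
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]
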