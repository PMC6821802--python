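"""In-silico capture enrichment and paired-end sequencing of GM mixtures.

Emulates the wet workflow: genomic DNA from a mixture of non-GM and GM
genomes is sheared to ~150-200 bp fragments, hybridisation probes capture
fragments overlapping the screening elements (probes can pull down fragments
of up to 500 bp, so captured fragments reach past element boundaries into
junction and flanking plant DNA), and the captured library is sequenced as
2 x 75 bp paired-end reads with i.i.d. substitution errors.

Capture is modelled as deterministic interval overlap (>= ``min_overlap``
bases of probe-covered sequence) plus a small uniform off-target survival
probability; every step is reproducible from ``SampleSpec.seed``.  The
simulator records per-fragment ground truth (source genome, coordinates,
host/insert/junction origin) for downstream validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dna import add_substitution_errors, random_dna, revcomp, validate_dna
from .element_db import ElementDatabase, ProbeSet


@dataclass(frozen=True)
class HostGenome:
    genome_id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"genome {self.genome_id!r}: empty sequence")
        validate_dna(self.sequence, name=f"genome {self.genome_id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GMConstruct:
    """Ordered layout of an insert: element parts (db references) and fillers."""

    construct_id: str
    parts: tuple  # of (kind in {"element","filler"}, element_id or literal seq)
    host_id: str
    insertion_pos: int

    def part_sequences(self, db: ElementDatabase) -> list[tuple[str, str, str]]:
        """List of (kind, ref_id, sequence); fillers carry ref_id 'filler'."""
        out = []
        for kind, ref in self.parts:
            if kind == "element":
                if ref not in db:
                    raise KeyError(f"construct part references unknown element {ref!r}")
                out.append(("element", ref, db[ref].sequence))
            elif kind == "filler":
                out.append(("filler", "filler", ref))
            else:
                raise ValueError(f"unknown part kind {kind!r}")
        return out

    def insert_sequence(self, db: ElementDatabase) -> str:
        return "".join(seq for _k, _r, seq in self.part_sequences(db))


@dataclass(frozen=True)
class SimulatedGenome:
    """A mixture component: plain host or host carrying one insert.

    ``part_intervals`` are genome-coordinate intervals of the insert parts;
    ``embedded`` marks endogenous copies of screening elements present in the
    host itself (e.g. pUbi in maize), which capture probes also pull down.
    """

    genome_id: str
    sequence: str
    host_id: str
    insert_start: int | None = None
    insert_end: int | None = None
    construct_id: str | None = None
    part_intervals: tuple = ()      # (start, end, kind, ref_id) in genome coords
    embedded: tuple = ()            # (start, end, element_id) endogenous copies

    def __len__(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_host(cls, host: HostGenome, embedded: tuple = ()) -> "SimulatedGenome":
        return cls(genome_id=host.genome_id, sequence=host.sequence,
                   host_id=host.genome_id, embedded=embedded)


def build_gm_genome(host: HostGenome, construct: GMConstruct,
                    db: ElementDatabase) -> SimulatedGenome:
    """Insert a construct into its host at ``insertion_pos``.

    The output genome is exactly ``host + insert`` in length, with host
    sequence flanking the insert unchanged at both junctions.
    """
    if construct.host_id != host.genome_id:
        raise ValueError(
            f"construct targets host {construct.host_id!r}, got {host.genome_id!r}"
        )
    pos = construct.insertion_pos
    if not (0 <= pos <= len(host)):
        raise ValueError(
            f"insertion_pos {pos} out of range for host of length {len(host)}"
        )
    parts = construct.part_sequences(db)
    insert = "".join(seq for _k, _r, seq in parts)
    genome_seq = host.sequence[:pos] + insert + host.sequence[pos:]
    intervals = []
    off = pos
    for kind, ref, seq in parts:
        intervals.append((off, off + len(seq), kind, ref))
        off += len(seq)
    return SimulatedGenome(
        genome_id=f"{host.genome_id}:{construct.construct_id}",
        sequence=genome_seq,
        host_id=host.genome_id,
        insert_start=pos,
        insert_end=pos + len(insert),
        construct_id=construct.construct_id,
        part_intervals=tuple(intervals),
    )


@dataclass
class SampleSpec:
    """Study conditions for one simulated enriched sequencing run."""

    components: list  # of (SimulatedGenome, fraction); fractions sum to 1
    n_fragments: int
    fragment_len_range: tuple = (150, 200)
    max_capture_len: int = 500
    read_len: int = 75
    error_rate: float = 0.002
    off_target_rate: float = 1e-4
    min_overlap: int = 20
    quality_char: str = "I"
    seed: int = 0

    def __post_init__(self):
        total = sum(f for _g, f in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component fractions sum to {total}, expected 1")
        lo, hi = self.fragment_len_range
        if not (0 < lo <= hi <= self.max_capture_len):
            raise ValueError(
                f"fragment_len_range {self.fragment_len_range} must lie in "
                f"(0, max_capture_len={self.max_capture_len}]"
            )
        if not (0 <= self.error_rate < 1):
            raise ValueError(f"error_rate {self.error_rate} outside [0, 1)")


@dataclass(frozen=True)
class Fragment:
    genome_id: str
    component: int
    start: int
    end: int
    origin: str  # host | insert | junction


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    mate1: str
    mate2: str
    truth: Fragment


def probe_cover_mask(genome: SimulatedGenome, probes: ProbeSet) -> np.ndarray:
    """Boolean probe coverage over genome coordinates.

    Probe intervals on elements are projected through the construct part
    coordinates and through any embedded endogenous element copies.
    """
    mask = np.zeros(len(genome), dtype=bool)
    targets = [
        (s, e, ref) for (s, e, kind, ref) in genome.part_intervals if kind == "element"
    ] + [(s, e, ref) for (s, e, ref) in genome.embedded]
    for gstart, gend, ref in targets:
        for ps, pe in probes.intervals_for(ref):
            a, b = gstart + ps, min(gstart + pe, gend)
            if a < b:
                mask[a:b] = True
    return mask


def draw_fragments(spec: SampleSpec):
    """Pre-capture fragment stream: (component, start, end) arrays.

    Fragments are drawn from components proportional to fraction x genome
    length (the fraction is a genome-copy fraction, so total DNA scales with
    copies times length), with uniform start positions and uniform lengths in
    ``fragment_len_range``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    lengths = np.array([len(g) for g, _f in spec.components], dtype=np.float64)
    weights = np.array([f for _g, f in spec.components]) * lengths
    weights = weights / weights.sum()
    comp = rng.choice(len(spec.components), size=spec.n_fragments, p=weights)
    lo, hi = spec.fragment_len_range
    flen = rng.integers(lo, hi + 1, size=spec.n_fragments)
    glen = lengths.astype(np.int64)[comp]
    flen = np.minimum(flen, glen)
    start = np.floor(rng.random(spec.n_fragments) * (glen - flen + 1)).astype(np.int64)
    return comp, start, start + flen


def capture_mask(spec: SampleSpec, probes: ProbeSet, comp, start, end) -> np.ndarray:
    """Apply the capture rule to a fragment stream.

    A fragment is retained when it overlaps probe-covered genome sequence by
    at least ``min_overlap`` bases, or otherwise survives as off-target
    background with probability ``off_target_rate``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    off_draw = rng.random(len(comp)) < spec.off_target_rate
    keep = off_draw.copy()
    for ci, (genome, _f) in enumerate(spec.components):
        sel = comp == ci
        if not sel.any():
            continue
        cover = probe_cover_mask(genome, probes)
        cs = np.concatenate([[0], np.cumsum(cover)])
        overlap = cs[end[sel]] - cs[start[sel]]
        keep[sel] |= overlap >= spec.min_overlap
    return keep


def _origin(genome: SimulatedGenome, s: int, e: int) -> str:
    if genome.insert_start is None:
        return "host"
    if e <= genome.insert_start or s >= genome.insert_end:
        return "host"
    if s >= genome.insert_start and e <= genome.insert_end:
        return "insert"
    return "junction"


def fragment_and_capture(spec: SampleSpec, probes: ProbeSet) -> list[Fragment]:
    """Shear + capture: the retained (enriched) fragment collection."""
    if len(probes) == 0 and spec.off_target_rate == 0:
        warnings.warn("no probes and off_target_rate=0: capture retains nothing")
        return []
    comp, start, end = draw_fragments(spec)
    keep = capture_mask(spec, probes, comp, start, end)
    frags = []
    for i in np.flatnonzero(keep):
        g = spec.components[comp[i]][0]
        s, e = int(start[i]), int(end[i])
        frags.append(Fragment(g.genome_id, int(comp[i]), s, e, _origin(g, s, e)))
    return frags


def make_read_pairs(fragments: list[Fragment], spec: SampleSpec) -> list[ReadPair]:
    """Sequence each fragment as a 2 x ``read_len`` pair.

    Mate 1 is the first ``read_len`` bases of the fragment; mate 2 is the
    first ``read_len`` bases of its reverse complement.  Substitution errors
    are applied i.i.d. per base at ``error_rate``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    raw: list[str] = []
    for f in fragments:
        seq = spec.components[f.component][0].sequence[f.start:f.end]
        raw.append(seq[: spec.read_len])
        raw.append(revcomp(seq)[: spec.read_len])
    noisy = add_substitution_errors(raw, spec.error_rate, rng)
    pairs = []
    for i, f in enumerate(fragments):
        pairs.append(ReadPair(
            read_id=f"frag{i:07d}",
            mate1=noisy[2 * i],
            mate2=noisy[2 * i + 1],
            truth=f,
        ))
    return pairs


def write_fastq_pair(pairs: list[ReadPair], out1: str | Path, out2: str | Path,
                     quality_char: str = "I") -> None:
    with open(out1, "w", newline="\n") as f1, open(out2, "w", newline="\n") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.mate1}\n+\n{quality_char * len(p.mate1)}\n")
            f2.write(f"@{p.read_id}/2\n{p.mate2}\n+\n{quality_char * len(p.mate2)}\n")


def write_truth(pairs: list[ReadPair], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("read_id\tgenome_id\tfrag_start\tfrag_end\torigin\n")
        for p in pairs:
            t = p.truth
            fh.write(f"{p.read_id}\t{t.genome_id}\t{t.start}\t{t.end}\t{t.origin}\n")


def sequence_reads(fragments: list[Fragment], spec: SampleSpec,
                   out1: str | Path, out2: str | Path,
                   truth_path: str | Path | None = None) -> list[ReadPair]:
    """Sequence captured fragments to paired FASTQ (+ truth TSV) on disk."""
    pairs = make_read_pairs(fragments, spec)
    write_fastq_pair(pairs, out1, out2, spec.quality_char)
    if truth_path is not None:
        write_truth(pairs, truth_path)
    return pairs


def simulate_sample(spec: SampleSpec, probes: ProbeSet, out_dir: str | Path,
                    prefix: str = "sample"):
    """Run shear + capture + sequencing, writing FASTQ pair and truth TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frags = fragment_and_capture(spec, probes)
    out1 = out_dir / f"{prefix}_R1.fastq"
    out2 = out_dir / f"{prefix}_R2.fastq"
    truth = out_dir / f"{prefix}_truth.tsv"
    pairs = sequence_reads(frags, spec, out1, out2, truth)
    return {"fastq1": out1, "fastq2": out2, "truth": truth,
            "n_pairs": len(pairs), "fragments": frags}


def random_host(genome_id: str, length: int, seed: int) -> HostGenome:
    """Deterministic synthetic host genome (stands in for a plant reference)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    return HostGenome(genome_id, random_dna(length, rng))
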