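"""Standard simulation scenarios used throughout tests and examples.

These encode the study conditions the simulator emulates:

* ``gts_like`` — a glyphosate-tolerant soybean analogue: one insert of
  p35S - linker - EPSPS1 - linker - tNOS followed by an unknown rearranged
  tail, at a fixed site in a synthetic soybean-like host, mixed with the
  non-GM host at genome-copy fractions 0.001 / 0.01 / 0.1 (the 0.1 % / 1 % /
  10 % certified-reference-material ladder) or 0 / 1.
* ``mixed_pat_bar`` — a 50/50 mix of two events in different species whose
  constructs share promoter (p35S) and terminator (t35S) but carry
  herbicide-tolerance genes (pat vs bar) that are only ~60 % identical, the
  classic test that near-homologous constructs remain distinguishable.

Hosts are synthetic random genomes; their sizes (tens of kb) keep the
enrichment geometry (insert:genome ratio, junction reach) realistic at desk
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dna import random_dna
from .element_db import ElementDatabase, ProbeSet
from .simulate import (
    GMConstruct, HostGenome, SampleSpec, SimulatedGenome,
    build_gm_genome, random_host,
)

DEFAULT_HOST_LEN = 60_000


@dataclass
class Scenario:
    name: str
    spec: SampleSpec
    hosts: list
    constructs: list
    gm_genomes: list
    db: ElementDatabase
    probes: ProbeSet
    expected_elements: set = field(default_factory=set)

    @property
    def insertion_positions(self) -> dict:
        return {c.construct_id: c.insertion_pos for c in self.constructs}


def gts_like_construct(db: ElementDatabase, host: HostGenome,
                       seed: int) -> GMConstruct:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    linker1 = random_dna(45, rng)
    linker2 = random_dna(30, rng)
    tail = random_dna(150, rng)  # unknown rearranged sequence right of tNOS
    return GMConstruct(
        construct_id="gts_like",
        parts=(
            ("element", "p35S"),
            ("filler", linker1),
            ("element", "EPSPS1"),
            ("filler", linker2),
            ("element", "tNOS"),
            ("filler", tail),
        ),
        host_id=host.genome_id,
        insertion_pos=(3 * len(host)) // 5,
    )


def make_gts_like(db: ElementDatabase, probes: ProbeSet, gm_fraction: float,
                  n_fragments: int, seed: int,
                  host_len: int = DEFAULT_HOST_LEN,
                  error_rate: float = 0.002,
                  off_target_rate: float = 1e-4) -> Scenario:
    """GM/non-GM mixture of the GTS-like event at the given copy fraction."""
    host = random_host("host_soy", host_len, seed=1000 + seed)
    construct = gts_like_construct(db, host, seed)
    gm = build_gm_genome(host, construct, db)
    plain = SimulatedGenome.from_host(host)
    if gm_fraction <= 0:
        components = [(plain, 1.0)]
    elif gm_fraction >= 1:
        components = [(gm, 1.0)]
    else:
        components = [(plain, 1.0 - gm_fraction), (gm, gm_fraction)]
    spec = SampleSpec(
        components=components,
        n_fragments=n_fragments,
        error_rate=error_rate,
        off_target_rate=off_target_rate,
        seed=seed,
    )
    return Scenario(
        name=f"gts_like_{gm_fraction:g}",
        spec=spec, hosts=[host], constructs=[construct], gm_genomes=[gm],
        db=db, probes=probes,
        expected_elements={"p35S", "EPSPS1", "tNOS"},
    )


def make_mixed_pat_bar(db: ElementDatabase, probes: ProbeSet,
                       n_fragments: int, seed: int,
                       host_len: int = DEFAULT_HOST_LEN,
                       error_rate: float = 0.002,
                       off_target_rate: float = 1e-4) -> Scenario:
    """50/50 mix of two events sharing p35S/t35S with ~60 %-identical genes."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 6]))
    host_a = random_host("host_soy", host_len, seed=1000 + seed)
    host_b = random_host("host_rice", host_len - 10_000, seed=2000 + seed)
    c_a = GMConstruct(
        construct_id="a2704_like",
        parts=(
            ("element", "p35S"),
            ("filler", random_dna(40, rng)),
            ("element", "pat"),
            ("filler", random_dna(35, rng)),
            ("element", "t35S"),
        ),
        host_id=host_a.genome_id,
        insertion_pos=(2 * len(host_a)) // 5,
    )
    c_b = GMConstruct(
        construct_id="ll62_like",
        parts=(
            ("element", "p35S"),
            ("filler", random_dna(38, rng)),
            ("element", "bar"),
            ("filler", random_dna(42, rng)),
            ("element", "t35S"),
        ),
        host_id=host_b.genome_id,
        insertion_pos=(3 * len(host_b)) // 5,
    )
    gm_a = build_gm_genome(host_a, c_a, db)
    gm_b = build_gm_genome(host_b, c_b, db)
    spec = SampleSpec(
        components=[(gm_a, 0.5), (gm_b, 0.5)],
        n_fragments=n_fragments,
        error_rate=error_rate,
        off_target_rate=off_target_rate,
        seed=seed,
    )
    return Scenario(
        name="mixed_pat_bar",
        spec=spec, hosts=[host_a, host_b], constructs=[c_a, c_b],
        gm_genomes=[gm_a, gm_b], db=db, probes=probes,
        expected_elements={"p35S", "pat", "bar", "t35S"},
    )
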