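"""In-memory convenience wrapper: simulate a scenario and analyse it.

A lighter-weight counterpart to :mod:`gmocap.pipeline` for scripted studies
and notebooks: nothing is written to disk, and the negative-control
background model is supplied by the caller (or floor-only when omitted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotate import annotate_contigs, call_junctions, reconstruct_layout
from .assemble import assemble_contigs, extract_positive_reads
from .classify import AlignParams, KmerIndex, classify_read_pairs, index_database
from .detect import BackgroundModel, call_detection, count_table, mask_endogenous
from .scenarios import Scenario
from .simulate import fragment_and_capture, make_read_pairs


@dataclass
class ScenarioResult:
    scenario: Scenario
    pairs: list
    assignments: pd.DataFrame
    summary: dict
    counts: pd.DataFrame
    calls: pd.DataFrame
    detected: list
    contigs: list = field(default_factory=list)
    annotations: list = field(default_factory=list)
    junctions: list = field(default_factory=list)
    layout: dict = field(default_factory=dict)


def analyse_scenario(sc: Scenario, index: KmerIndex | None = None,
                     bg: BackgroundModel | None = None,
                     floor: float = 25.0,
                     sample_species: list[str] | None = None,
                     align_params: AlignParams | None = None,
                     do_assembly: bool = True) -> ScenarioResult:
    """Simulate, classify, detect and (optionally) assemble + annotate."""
    if index is None:
        index = index_database(sc.db)
    frags = fragment_and_capture(sc.spec, sc.probes)
    pairs = make_read_pairs(frags, sc.spec)
    assignments, summary = classify_read_pairs(pairs, index, sc.db, align_params)
    counts = count_table(assignments, sc.db, max(summary["total_reads"], 1))
    calls = call_detection(counts, bg, floor=floor)
    if sample_species:
        calls = mask_endogenous(calls, sample_species)
    detected = sorted(calls.loc[calls["detected"], "element_id"])
    result = ScenarioResult(
        scenario=sc, pairs=pairs, assignments=assignments, summary=summary,
        counts=counts, calls=calls, detected=detected,
    )
    if do_assembly and detected:
        pos = extract_positive_reads(assignments, pairs, detected)
        if pos:
            result.contigs = assemble_contigs([s for _rid, s in pos])
        result.annotations = annotate_contigs(result.contigs, sc.db,
                                              host_refs=sc.hosts)
        result.junctions = [
            j for ann in result.annotations for j in call_junctions(ann)
        ]
        result.layout = reconstruct_layout(result.annotations, sc.db)
    return result


def negative_background(db, probes, index, make_scenario, n_controls: int,
                        n_fragments: int, base_seed: int,
                        align_params: AlignParams | None = None):
    """Background model from ``n_controls`` simulated 0 %-GM runs."""
    from .detect import fit_background

    tables = []
    for i in range(n_controls):
        sc = make_scenario(db, probes, 0.0, n_fragments, base_seed + i)
        frags = fragment_and_capture(sc.spec, probes)
        pairs = make_read_pairs(frags, sc.spec)
        df, summary = classify_read_pairs(pairs, index, db, align_params)
        tables.append(count_table(df, db, max(summary["total_reads"], 1)))
    return fit_background(tables)
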