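"""Build the screening-element database and tile capture probes over it.

The enrichment database gathers the promoters, terminators, genes and
miscellaneous sequences most commonly introduced into transgenic plants.
Capture probes (~120 bp, ~8 % overlap, no degeneracy) are tiled over every
element so that any library fragment overlapping an element can be pulled
down prior to sequencing.
"""

from gmocap import database_checksum, design_probes, write_probe_bed
from gmocap.panel import synthetic_panel_database

db = synthetic_panel_database(seed=0)
print(f"screening panel: {len(db)} elements, {database_checksum(db)} bp total")

probes = design_probes(db, probe_length_bp=120, step_bp=110)
print(f"designed {len(probes)} capture probes of {probes.probe_length_bp} bp")

write_probe_bed(probes, "probes.bed")
print("probe intervals written to probes.bed (0-based, element coordinates)")

# The checksum (52,534 bp) is the sum of the 40 per-element lengths; every
# element base is covered by at least one probe, which the tiling guarantees
# by end-anchoring the final probe of each element.
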