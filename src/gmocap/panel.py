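"""Default screening panel of 40 structural elements.

The panel lists the promoters, terminators, genes and miscellaneous elements
most commonly introduced into transgenic plants, with their lengths and
public provenance (NCBI accession or patent).  Antibiotic-resistance and
other selection-marker sequences are deliberately excluded: traces of
bacterial/plasmid DNA from the enzymes used in library preparation would
generate spurious signals for them.

The real sequences live in NCBI / patent databases and are not bundled;
:func:`synthetic_panel_database` generates a synthetic stand-in with the
panel's exact per-element lengths (total 52,534 bp) from a seed, so the whole
pipeline is testable offline.  Two sequence correlations present in the real
panel are emulated because the method's behaviour depends on them:

* ``cry1Ab_c`` / ``cry1Ac`` are generated ~92 % identical (cry variants are
  highly similar, and best-hit read assignment must still resolve them);
* ``pat`` / ``bar`` share a ~60 %-identical stretch (the two herbicide
  tolerance genes used by the A2704 / LL62 analogue mixed sample).
"""

from __future__ import annotations

import numpy as np

from .dna import mutate_fraction, random_dna
from .element_db import ElementCategory, ElementDatabase, StructuralElement

# (element_id, category, length_bp, source)
PANEL = [
    ("p35S", "promoter", 867, "NCBI KX880509"),
    ("pFMV", "promoter", 981, "NCBI X06166"),
    ("pUbi", "promoter", 2018, "NCBI S94464"),
    ("pNOS", "promoter", 398, "Patent WO2006074956"),
    ("pmas", "promoter", 660, "NCBI DQ225747"),
    ("Ps7s7", "promoter", 1046, "NCBI AY181091"),
    ("pRice_actin1", "promoter", 660, "NCBI S44221"),
    ("pRice_actin2", "promoter", 259, "NCBI EU161577"),
    ("pSSuAra", "promoter", 1727, "NCBI CP002684"),
    ("pTA29", "promoter", 627, "NCBI X52283"),
    ("pMTL", "promoter", 2556, "NCBI S57628"),
    ("tOCS", "terminator", 823, "NCBI LT727071"),
    ("tE9", "terminator", 648, "Patent WO2007027777"),
    ("tNOS", "terminator", 300, "NCBI AB809952"),
    ("tg7", "terminator", 203, "Patent WO2006074956"),
    ("tpinII", "terminator", 318, "NCBI KP784700"),
    ("t35S", "terminator", 211, "NCBI GU734649"),
    ("gus", "gene", 576, "NCBI CP029981"),
    ("gox", "gene", 1296, "Patent US5463175"),
    ("cry1Ab_1", "gene", 1854, "Patent US20030226171"),
    ("cry1Ab_2", "gene", 3844, "NCBI AY326434"),
    ("cry1Ab_3", "gene", 1947, "Patent US5625136"),
    ("cry1B", "gene", 1950, "NCBI KC414884"),
    ("cry1Aa", "gene", 1848, "NCBI GU583855"),
    ("cry1Ab_c", "gene", 1923, "NCBI GU583854"),
    ("cry1Ac", "gene", 1923, "NCBI KF630361"),
    ("cry1A105_1", "gene", 3537, "Patent WO2007027777"),
    ("cry1A105_2", "gene", 3433, "NCBI DI362404"),
    ("cry2Ab2", "gene", 1900, "NCBI DI362404"),
    ("cry3A055", "gene", 1797, "Patent EP2289311"),
    ("cry34Ab1", "gene", 424, "Patent WO2006039376"),
    ("cry35Ab1", "gene", 981, "Patent WO2006039376"),
    ("EPSPS1", "gene", 1415, "NCBI AB209952"),
    ("EPSPS2", "gene", 1367, "Patent WO2004074492"),
    ("2mEPSPS", "gene", 1338, "Patent WO2011063411"),
    ("bar", "gene", 835, "NCBI X05822"),
    ("pat", "gene", 569, "NCBI GQ497217"),
    ("Prsv_cp1", "gene", 1601, "NCBI F5490192"),
    ("Prsv_cp2", "gene", 1070, "NCBI GZ450610"),
    ("hsp70", "miscellaneous", 804, "NCBI AY326434"),
]

PANEL_TOTAL_BP = sum(row[2] for row in PANEL)  # 52534

# Donor organism of elements whose donor is a plant species that may itself be
# the sampled matrix; a detection of such an element in its donor species is an
# expected (endogenous) signal that must be flagged, not suppressed.
DEFAULT_DONOR_MAP = {
    "pUbi": "maize",
    "pMTL": "maize",
    "hsp70": "maize",
    "pRice_actin1": "rice",
    "pRice_actin2": "rice",
}

# Elements that are not endogenous to a species but share a short stretch with
# its genome, producing expected low-grade cross-mapping.
HOST_HOMOLOGY = {
    "EPSPS1": ("maize", "shares a 46-bp stretch with the maize genome"),
}

# Fixture paralog correlations: (element_a, element_b, identity over the
# common prefix).  b is derived from a by substituting (1-identity) of bases.
_CORRELATED = [
    ("cry1Ab_c", "cry1Ac", 0.92),
    ("pat", "bar", 0.60),
]


def synthetic_panel_database(seed: int = 0) -> ElementDatabase:
    """Synthetic stand-in for the 40-element screening panel.

    Random A/C/G/T sequences with the panel's exact lengths (checksum
    52,534 bp), deterministic under ``seed``, with the documented paralog
    correlations applied.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 94]))
    seqs: dict[str, str] = {}
    for eid, _cat, length, _src in PANEL:
        seqs[eid] = random_dna(length, rng)
    for a, b, ident in _CORRELATED:
        la, lb = len(seqs[a]), len(seqs[b])
        n = min(la, lb)
        prefix = mutate_fraction(seqs[a][:n], 1.0 - ident, rng)
        seqs[b] = prefix + seqs[b][n:]
    return ElementDatabase([
        StructuralElement(eid, ElementCategory(cat), seqs[eid], src)
        for eid, cat, _length, src in PANEL
    ])
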