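"""Statistical detection of screening elements from read counts.

Per-element read counts are normalised to RPKM (reads per kilobase of
element per million total sequenced reads) and compared with a background
threshold estimated from non-GM negative-control runs: the per-element mean
background RPKM plus five standard deviations.  Five sigma gives a
correct-classification probability well above 99 % for roughly Gaussian
background (and >= 96 % distribution-free by Chebyshev).  A fixed RPKM floor
(default 25) guards elements whose background was estimated as (near-)zero;
the effective threshold is the maximum of the two.

An element detected in a sample of its own donor species (e.g. pUbi, pMTL or
hsp70 in maize) is an expected endogenous signal: it is flagged and
annotated, never suppressed.

RPKM uses total sequenced reads in the denominator.  With capture enrichment
the mapped-read total is tiny and varies with GM content, which would make
samples incomparable and negative controls degenerate; the total-read
denominator keeps the statistic stable across samples.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .element_db import ElementDatabase
from .panel import DEFAULT_DONOR_MAP, HOST_HOMOLOGY

RPKM_FLOOR_DEFAULT = 25.0


def compute_rpkm(read_count: int, element_length_bp: int, total_reads: int) -> float:
    """reads / (element length in kb) / (total reads in millions)."""
    if element_length_bp <= 0:
        raise ValueError("element_length_bp must be positive")
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return read_count / (element_length_bp / 1000.0) / (total_reads / 1e6)


def count_table(assignments: pd.DataFrame, db: ElementDatabase,
                total_reads: int | None = None) -> pd.DataFrame:
    """Per-element read counts + RPKM from a classification table.

    Ambiguous assignments count for their tie-broken element.  Every database
    element appears in the output, with zero counts where nothing mapped.
    """
    if total_reads is None:
        total_reads = len(assignments)
    assigned = assignments[assignments["element_id"] != ""]
    counts = assigned.groupby("element_id").size()
    rows = []
    for el in db:
        c = int(counts.get(el.element_id, 0))
        rows.append((
            el.element_id, c,
            compute_rpkm(c, el.length_bp, total_reads) if total_reads else 0.0,
        ))
    df = pd.DataFrame(rows, columns=["element_id", "read_count", "rpkm"])
    df.attrs["total_reads"] = total_reads
    return df


class BackgroundModel:
    """Per-element background RPKM mean and SD over negative-control runs."""

    def __init__(self, table: pd.DataFrame, n_controls: int):
        # table columns: element_id, mean_rpkm, sd_rpkm
        self.table = table.set_index("element_id") if "element_id" in table.columns else table
        self.n_controls = n_controls

    def thresholds(self, floor: float = RPKM_FLOOR_DEFAULT) -> pd.Series:
        """Effective detection threshold per element: max(mean + 5*sd, floor)."""
        t = self.table["mean_rpkm"] + 5.0 * self.table["sd_rpkm"]
        return t.clip(lower=floor)


def fit_background(negative_tables: list[pd.DataFrame]) -> BackgroundModel:
    """Estimate the background model from negative-control count tables.

    With >= 2 controls the SD is the per-element sample SD across runs; with a
    single control it falls back to the SD of RPKM values pooled across
    elements of that run (a crude but conservative spread estimate).
    """
    if not negative_tables:
        raise ValueError(
            "no negative-control samples: fit_background needs at least one; "
            "use floor-only detection (call_detection with bg=None) instead"
        )
    mat = pd.concat(
        [t.set_index("element_id")["rpkm"].rename(i) for i, t in enumerate(negative_tables)],
        axis=1,
    )
    mean = mat.mean(axis=1)
    if len(negative_tables) >= 2:
        sd = mat.std(axis=1, ddof=1)
    else:
        pooled = float(mat.iloc[:, 0].std(ddof=1))
        sd = pd.Series(pooled, index=mat.index)
    out = pd.DataFrame({"mean_rpkm": mean, "sd_rpkm": sd})
    out.index.name = "element_id"
    return BackgroundModel(out, n_controls=len(negative_tables))


def call_detection(sample: pd.DataFrame, bg: BackgroundModel | None,
                   floor: float = RPKM_FLOOR_DEFAULT) -> pd.DataFrame:
    """Detection calls for one sample count table.

    ``detected`` is strict: rpkm > threshold (boundary equality belongs to the
    background).  Elements absent from the background model get a floor-only
    threshold with a warning.
    """
    sample = sample.set_index("element_id")
    if bg is None:
        thr = pd.Series(floor, index=sample.index)
    else:
        thr = bg.thresholds(floor).reindex(sample.index)
        missing = thr.index[thr.isna()]
        if len(missing):
            warnings.warn(
                f"elements missing from background model, using floor only: "
                f"{sorted(missing)}"
            )
            thr = thr.fillna(floor)
    out = pd.DataFrame({
        "rpkm": sample["rpkm"],
        "read_count": sample["read_count"],
        "threshold": thr,
        "detected": sample["rpkm"] > thr,
    })
    out.reset_index(inplace=True)
    out["endogenous_flag"] = False
    out["note"] = ""
    return out


def mask_endogenous(calls: pd.DataFrame, sample_species: list[str],
                    donor_map: dict[str, str] | None = None,
                    homology_map: dict[str, tuple[str, str]] | None = None) -> pd.DataFrame:
    """Flag detections expected from the sampled species' own genome.

    ``donor_map`` maps element -> donor species; ``homology_map`` maps
    element -> (species, note) for partial host homologies.  The detected
    flag itself is left untouched.
    """
    donor_map = DEFAULT_DONOR_MAP if donor_map is None else donor_map
    homology_map = HOST_HOMOLOGY if homology_map is None else homology_map
    species = {s.lower() for s in sample_species}
    calls = calls.copy()
    for i, row in calls.iterrows():
        eid = row["element_id"]
        donor = donor_map.get(eid)
        if donor and donor.lower() in species:
            calls.at[i, "endogenous_flag"] = True
            calls.at[i, "note"] = (
                f"{donor} is the donor organism of {eid}; expected endogenous signal"
            )
            continue
        hom = homology_map.get(eid)
        if hom and hom[0].lower() in species:
            calls.at[i, "endogenous_flag"] = True
            calls.at[i, "note"] = f"partial host homology: {eid} {hom[1]}"
    return calls


def simulate_background_specificity(bg_mean: np.ndarray, bg_sd: np.ndarray,
                                    n_draws: int, rng: np.random.Generator,
                                    n_controls: int = 30) -> float:
    """Monte-Carlo specificity of the mean + 5*SD rule on Gaussian background.

    Fits the background model on ``n_controls`` simulated negative runs, then
    classifies ``n_draws`` fresh background draws per element with a zero
    floor (testing the statistical rule itself).  Returns the fraction of
    draws correctly classified as negative, as a percentage.
    """
    n_el = len(bg_mean)
    ids = [f"el{i:02d}" for i in range(n_el)]
    controls = []
    for _ in range(n_controls):
        vals = rng.normal(bg_mean, bg_sd)
        controls.append(pd.DataFrame({
            "element_id": ids, "read_count": 0, "rpkm": np.maximum(vals, 0.0),
        }))
    bg = fit_background(controls)
    thr = bg.thresholds(floor=0.0).reindex(ids).to_numpy()
    draws = rng.normal(bg_mean[None, :], bg_sd[None, :], size=(n_draws, n_el))
    draws = np.maximum(draws, 0.0)
    correct = (draws <= thr[None, :]).mean()
    return 100.0 * correct
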