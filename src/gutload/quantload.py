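"""dPCR-anchored absolute abundance and Poisson limit-of-detection filtering.

The anchoring step multiplies each sample's dPCR total microbial load
(16S copies/mL) by every taxon's relative read abundance.  Two detection
limits then apply per sample:

* the library-input LOD: the relative abundance at which an average of three
  template copies enters the library amplification reaction (Poisson: the
  chance of drawing at least one copy at mean 3 is 1 - e^-3 ~ 95%), and
* the read-depth LOD: the empirical power law 7.115 * depth^-0.115, whose
  output is a percentage (at typical depths its raw value exceeds 1).

The minimum of the two is the effective LOD; any taxon whose relative
abundance falls strictly below it is zeroed.  A separate blank filter
removes samples whose total load is not distinguishable from water blanks.
"""

from __future__ import annotations

import math
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    AbsoluteAbundanceTable,
    DPCRRecord,
    FeatureTable,
    LODRecord,
    TotalLoad,
    ValidationError,
)

DEFAULT_TEMPLATE_VOLUME_UL = 3.5  # uL of extract entering the library reaction
LOD_DEPTH_COEF = 7.115
LOD_DEPTH_EXPONENT = -0.115


def poisson_detection_probability(mean_copies: float = 3.0) -> float:
    """P(at least one copy sampled) under Poisson sampling at ``mean_copies``."""
    if mean_copies < 0:
        raise ValueError("mean_copies must be >= 0")
    return 1.0 - math.exp(-mean_copies)


def total_load(record: DPCRRecord) -> TotalLoad:
    """Convert a dPCR reaction concentration into copies/mL of sample.

    copies/mL = reaction concentration (copies/uL) x dilution factor
    x extract volume (uL) / collected sample volume (mL).
    """
    if record.collected_sample_volume is None:
        raise ValidationError(f"{record.sample_id}: collected volume missing (impute first)")
    if record.collected_sample_volume <= 0:
        raise ValidationError(f"{record.sample_id}: collected volume must be > 0")
    copies_per_ml = (
        record.dpcr_concentration
        * record.dilution_factor
        * record.extract_volume
        / record.collected_sample_volume
    )
    return TotalLoad(sample_id=record.sample_id, copies_per_ml=copies_per_ml)


def total_loads(records: Iterable[DPCRRecord]) -> pd.Series:
    loads = {r.sample_id: total_load(r).copies_per_ml for r in records}
    return pd.Series(loads, name="total_load")


def extract_concentration(record: DPCRRecord) -> float:
    """Copies/uL of the undiluted extract (reaction concentration x dilution)."""
    return record.dpcr_concentration * record.dilution_factor


def blank_threshold(blank_loads: Sequence[float]) -> float:
    """Upper bound of the 95% CI of log10 blank loads, in copies/mL.

    Computed as mean + 1.96 * SD of the log10 blank loads (normality on the
    log scale, population SD), back-transformed.
    """
    blanks = np.asarray(list(blank_loads), dtype=float)
    if blanks.size < 2:
        raise ValidationError("need at least 2 blank measurements")
    if (blanks <= 0).any():
        raise ValidationError("blank loads must be > 0")
    logs = np.log10(blanks)
    return float(10 ** (logs.mean() + 1.96 * logs.std(ddof=0)))


def filter_samples_by_blank(loads: pd.Series, threshold: float) -> pd.Series:
    """Boolean mask: True where a sample's total load exceeds the blank
    threshold (samples at or below it are excluded)."""
    return loads > threshold


def library_input_lod(
    extract_concentration: float,
    template_volume: float = DEFAULT_TEMPLATE_VOLUME_UL,
    min_copies: float = 3.0,
) -> tuple[float, bool]:
    """Relative abundance matching ``min_copies`` input copies; returns
    (lod fraction, flagged) where flagged marks a degenerate (zero-input)
    sample whose LOD saturates at 1."""
    if template_volume <= 0:
        raise ValidationError("template volume must be > 0")
    if extract_concentration <= 0:
        return 1.0, True
    input_copies = extract_concentration * template_volume
    return min(1.0, min_copies / input_copies), False


def read_depth_lod(
    depth: float, units: Literal["percent", "fraction"] = "percent"
) -> float:
    """Read-depth LOD, 7.115 * depth^-0.115, as a relative-abundance fraction.

    The power law's output is a percentage under the default interpretation
    (its raw value at common depths exceeds 1); ``units="fraction"`` keeps
    the raw value.
    """
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    raw = LOD_DEPTH_COEF * depth**LOD_DEPTH_EXPONENT
    lod = raw / 100.0 if units == "percent" else raw
    return min(1.0, lod)


def compute_lod_records(
    dpcr_records: Iterable[DPCRRecord],
    depths: pd.Series,
    template_volume: float = DEFAULT_TEMPLATE_VOLUME_UL,
    blank_thresh: Optional[float] = None,
    lod_depth_units: Literal["percent", "fraction"] = "percent",
) -> dict[str, LODRecord]:
    """Per-sample LOD provenance for every dPCR record with a read depth."""
    records = {}
    for r in dpcr_records:
        if r.sample_id not in depths.index:
            continue
        lib, flagged = library_input_lod(extract_concentration(r), template_volume)
        dep = read_depth_lod(float(depths[r.sample_id]), units=lod_depth_units)
        load = total_load(r).copies_per_ml
        records[r.sample_id] = LODRecord(
            sample_id=r.sample_id,
            lod_library=lib,
            lod_depth=dep,
            blank_threshold=blank_thresh,
            passed_blank_filter=(blank_thresh is None) or (load > blank_thresh),
            library_input_flagged=flagged,
        )
    return records


def rarefy(table: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Subsample every row to ``depth`` reads without replacement.

    Multivariate hypergeometric draw per sample; deterministic under a fixed
    seed.  Samples shallower than the target raise an error listing them.
    """
    depths = table.depths
    shallow = depths.index[depths < depth].tolist()
    if shallow:
        raise ValidationError(f"samples shallower than rarefaction depth {depth}: {shallow}")
    rng = np.random.default_rng(seed)
    counts = table.counts.to_numpy()
    out = np.empty_like(counts)
    for i in range(counts.shape[0]):
        out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    return FeatureTable(pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns))


def anchor_absolute_abundance(
    counts: FeatureTable,
    loads: pd.Series,
    lod_records: Optional[dict[str, LODRecord]] = None,
) -> AbsoluteAbundanceTable:
    """A[s, t] = total_load[s] * count[s, t] / depth[s] (copies/mL)."""
    missing = set(counts.sample_ids) - set(loads.index)
    if missing:
        raise ValidationError(f"samples without total load: {sorted(missing)}")
    depths = counts.depths
    if (depths == 0).any():
        zero = depths.index[depths == 0].tolist()
        raise ValidationError(f"zero-depth samples: {zero}")
    loads = loads.loc[counts.sample_ids].astype(float)
    abundance = counts.counts.div(depths, axis=0).mul(loads, axis=0)
    return AbsoluteAbundanceTable(abundance, loads, lod_records=lod_records)


def apply_lod_filter(table: AbsoluteAbundanceTable) -> AbsoluteAbundanceTable:
    """Zero every entry whose relative abundance is strictly below the
    sample's effective LOD.  Entries exactly at the LOD survive; the
    operation is idempotent (relative abundance is always taken against the
    sample's anchored total load, not the filtered row sum)."""
    if not table.lod_records:
        raise ValidationError("LOD records missing; compute them before filtering")
    loads = table.loads.copy()
    totals = table.total_loads
    for sample_id, lod in table.lod_records.items():
        if sample_id not in loads.index:
            continue
        total = totals[sample_id]
        if total <= 0:
            loads.loc[sample_id] = 0.0
            continue
        rel = loads.loc[sample_id] / total
        loads.loc[sample_id] = loads.loc[sample_id].where(rel >= lod.lod_effective, 0.0)
    return AbsoluteAbundanceTable(loads, table.total_loads, table.lod_records, filtered=True)


def cq_to_copies(cq: Optional[float], efficiency: float = 1.0) -> float:
    """qPCR Cq -> copies/uL anchored at Cq 22.4 = 1000 copies/uL.

    One cycle is a factor of (1 + efficiency); the default of 1.0 (perfect
    doubling) gives 1000 * 2^(22.4 - cq).  ``cq=None`` (no amplification)
    maps to 0.
    """
    if cq is None:
        return 0.0
    if cq <= 0:
        raise ValidationError("cq must be > 0")
    if not (0 < efficiency <= 1):
        raise ValidationError("efficiency must be in (0, 1]")
    return 1000.0 * (1.0 + efficiency) ** (22.4 - cq)


def qpcr_load(record, efficiency: float = 1.0) -> float:
    """Copies/mL of sample from a qPCR record (mirrors the dPCR arithmetic)."""
    if record.collected_sample_volume is None or record.collected_sample_volume <= 0:
        raise ValidationError(f"{record.sample_id}: collected volume missing or nonpositive")
    copies_per_ul = cq_to_copies(record.cq, efficiency=efficiency)
    return copies_per_ul * record.dilution_factor * record.extract_volume / record.collected_sample_volume


def genome_load(copies_16s: float, copies_per_genome: int) -> float:
    """Convert 16S copies/mL to genomes/mL given the rRNA operon copy number
    (e.g. 8 for Enterobacteriaceae; 1 for single-copy marker genes)."""
    if copies_per_genome < 1:
        raise ValidationError("copies_per_genome must be >= 1")
    return copies_16s / copies_per_genome
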