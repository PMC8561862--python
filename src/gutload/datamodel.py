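"""Domain types shared by every analysis stage.

Two kinds of containers live here: per-sample records (pydantic models with
field-level validation) and tabular containers (thin wrappers around pandas
DataFrames with the invariants the pipeline relies on: integer non-negative
counts, unique identifiers, row-sum conservation of absolute loads).
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

SYMPTOM_NAMES = (
    "bloating",
    "incomplete_evacuation",
    "constipation",
    "urgency",
    "excess_gas",
    "diarrhea",
)

CYTOKINE_NAMES = (
    "GM-CSF",
    "IFNg",
    "IL10",
    "IL12P70",
    "IL13",
    "IL1B",
    "IL2",
    "IL4",
    "IL5",
    "IL6",
    "IL8",
    "MCP1",
    "TNFa",
)

OXYGEN_CLASSES = ("strict_anaerobe", "facultative_anaerobe", "aerobe", "unknown")


class ValidationError(ValueError):
    """Raised when an input file or table violates a documented invariant."""


class FeatureTable:
    """Samples x taxa table of non-negative integer read counts.

    Wraps a DataFrame whose index holds sample ids and whose columns hold
    taxon ids.  ``depths`` (per-sample read totals) are always the row sums.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            raise ValidationError("duplicate sample ids in feature table")
        if counts.columns.has_duplicates:
            raise ValidationError("duplicate taxon ids in feature table")
        values = counts.to_numpy()
        if values.size:
            if not np.isfinite(values.astype(float)).all():
                raise ValidationError("non-finite counts in feature table")
            if (values.astype(float) < 0).any():
                raise ValidationError("negative counts in feature table")
            if np.any(values.astype(float) != np.round(values.astype(float))):
                raise ValidationError("non-integer counts in feature table")
        self.counts = counts.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def depths(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        depths = self.depths
        if (depths == 0).any():
            raise ValidationError("zero-depth sample; cannot form relative abundances")
        return self.counts.div(depths, axis=0)

    def subset_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.counts.loc[list(sample_ids)])

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureTable) and self.counts.equals(other.counts)

    def __repr__(self) -> str:
        return f"FeatureTable({self.counts.shape[0]} samples x {self.counts.shape[1]} taxa)"


class TaxonAnnotation(BaseModel):
    """Taxonomic lineage plus physiology flags for one taxon."""

    taxon_id: str
    kingdom: str = "Bacteria"
    phylum: str = "unknown"
    class_: str = Field(default="unknown", alias="class")
    order: str = "unknown"
    family: str = "unknown"
    genus: str = "unknown"
    oxygen_class: Literal["strict_anaerobe", "facultative_anaerobe", "aerobe", "unknown"] = "unknown"
    site_flags: set[Literal["oral", "stool"]] = Field(default_factory=set)

    model_config = {"populate_by_name": True}

    def lineage(self) -> str:
        """Silva-style semicolon lineage string (7 ranks, species blank)."""
        return ";".join(
            [
                f"D_0__{self.kingdom}",
                f"D_1__{self.phylum}",
                f"D_2__{self.class_}",
                f"D_3__{self.order}",
                f"D_4__{self.family}",
                f"D_5__{self.genus}",
                "D_6__",
            ]
        )


class DPCRRecord(BaseModel):
    """One digital-PCR measurement with the dilution/volume bookkeeping
    needed to convert a reaction concentration into copies/mL of sample."""

    sample_id: str
    dpcr_concentration: float = Field(ge=0)  # copies/uL of reaction
    dilution_factor: float = Field(ge=1)
    extract_volume: float = Field(gt=0)  # uL of eluted extract
    collected_sample_volume: Optional[float] = None  # mL; None = missing
    sample_type: Literal["duodenum", "saliva", "blank"]
    volume_imputed: bool = False

    @field_validator("collected_sample_volume")
    @classmethod
    def _volume_positive(cls, v):
        if v is not None and v <= 0:
            raise ValueError("collected_sample_volume must be > 0 when present")
        return v


class QPCRRecord(BaseModel):
    """One taxon-specific qPCR measurement; ``cq`` is None when no
    amplification was observed within the run length."""

    sample_id: str
    cq: Optional[float] = None  # cycles; None = no amplification
    dilution_factor: float = Field(default=1.0, ge=1)
    extract_volume: float = Field(default=100.0, gt=0)  # uL
    collected_sample_volume: Optional[float] = None  # mL

    @field_validator("cq")
    @classmethod
    def _cq_positive(cls, v):
        if v is not None and v <= 0:
            raise ValueError("cq must be > 0 when present")
        return v


class SampleRecord(BaseModel):
    """Clinical metadata for one sample (site, culture, symptoms, cytokines)."""

    sample_id: str
    subject_id: str
    site: Literal["duodenum", "saliva"]
    aerobic_cfu_per_ml: Optional[float] = None
    anaerobic_cfu_per_ml: Optional[float] = None
    symptom_scores: dict[str, float] = Field(default_factory=dict)  # 0-100 each
    cytokines: dict[str, float] = Field(default_factory=dict)
    age: Optional[float] = None
    sex: Optional[str] = None
    ppi: Optional[bool] = None
    antibiotics_current: Optional[bool] = None
    antibiotics_6mo: Optional[bool] = None
    probiotics: Optional[bool] = None
    smoker: Optional[bool] = None

    @field_validator("aerobic_cfu_per_ml", "anaerobic_cfu_per_ml")
    @classmethod
    def _cfu_nonneg(cls, v):
        if v is not None and v < 0:
            raise ValueError("CFU must be >= 0")
        return v

    @model_validator(mode="after")
    def _scores_in_range(self):
        for name, score in self.symptom_scores.items():
            if score is not None and not (0 <= score <= 100):
                raise ValueError(f"symptom score {name}={score} outside [0, 100]")
        return self


class TotalLoad(BaseModel):
    sample_id: str
    copies_per_ml: float = Field(ge=0)

    @field_validator("copies_per_ml")
    @classmethod
    def _finite(cls, v):
        if not np.isfinite(v):
            raise ValueError("total load must be finite")
        return v


class LODRecord(BaseModel):
    """Per-sample limit-of-detection provenance.

    Both LODs are relative-abundance fractions: ``lod_library`` from the
    3-copy rule on the library input, ``lod_depth`` from the read-depth power
    law.  The effective LOD is their minimum.
    """

    sample_id: str
    lod_library: float = Field(gt=0)
    lod_depth: float = Field(gt=0)
    blank_threshold: Optional[float] = None  # copies/mL
    passed_blank_filter: bool = True
    library_input_flagged: bool = False

    @property
    def lod_effective(self) -> float:
        return min(self.lod_library, self.lod_depth)


class AbsoluteAbundanceTable:
    """Samples x taxa absolute loads (16S copies/mL) with per-sample
    total-load and LOD provenance.

    Before LOD zeroing each row sums to the sample's total load (relative
    tolerance 1e-9); after filtering every surviving entry sits at or above
    the sample's effective LOD in relative-abundance terms.
    """

    def __init__(
        self,
        loads: pd.DataFrame,
        total_loads: pd.Series,
        lod_records: Optional[dict[str, LODRecord]] = None,
        filtered: bool = False,
    ):
        if not loads.index.equals(total_loads.index):
            total_loads = total_loads.reindex(loads.index)
        if total_loads.isna().any():
            raise ValidationError("total load missing for some samples")
        if (loads.to_numpy() < 0).any():
            raise ValidationError("negative absolute abundances")
        self.loads = loads.astype(float)
        self.total_loads = total_loads.astype(float)
        self.lod_records = lod_records or {}
        self.filtered = filtered

    @property
    def sample_ids(self) -> list[str]:
        return list(self.loads.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.loads.columns)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.total_loads.replace(0, np.nan)
        return self.loads.div(totals, axis=0).fillna(0.0)

    def presence(self) -> pd.DataFrame:
        """Boolean detection table (nonzero load, post-filtering if applied)."""
        return self.loads > 0

    def subset_samples(self, sample_ids) -> "AbsoluteAbundanceTable":
        ids = list(sample_ids)
        return AbsoluteAbundanceTable(
            self.loads.loc[ids],
            self.total_loads.loc[ids],
            {s: r for s, r in self.lod_records.items() if s in set(ids)},
            filtered=self.filtered,
        )

    def __repr__(self) -> str:
        state = "LOD-filtered" if self.filtered else "unfiltered"
        return (
            f"AbsoluteAbundanceTable({self.loads.shape[0]} samples x "
            f"{self.loads.shape[1]} taxa, {state})"
        )
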