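"""Readers and writers for the pipeline's file formats.

All tabular files are tab-separated UTF-8 with a single header row and "NA"
for missing values (the layout QIIME2 exports use).  Feature tables are
samples x taxa with the sample id in the first column; a ``transpose`` flag
accepts taxa x samples layouts.  BIOM v1 (the JSON flavour) import is
supported for feature tables.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import ValidationError as PydanticValidationError

from .datamodel import (
    CYTOKINE_NAMES,
    SYMPTOM_NAMES,
    DPCRRecord,
    FeatureTable,
    QPCRRecord,
    SampleRecord,
    TaxonAnnotation,
    ValidationError,
)

_NA = "NA"


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValidationError(f"empty or missing file: {path}")
    return pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=False)


# ---------------------------------------------------------------------------
# feature tables


def read_feature_table(path, transpose: bool = False) -> FeatureTable:
    """Read a TSV feature table (first column = sample id, or taxon id when
    ``transpose`` is set)."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ValidationError(f"feature table {path} has no taxon columns")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns.name = None
    if transpose:
        df = df.T
    if df.isna().any().any():
        raise ValidationError("missing values in feature table")
    try:
        numeric = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric counts in feature table: {exc}") from exc
    return FeatureTable(numeric)


def write_feature_table(table: FeatureTable, path) -> None:
    out = table.counts.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep=_NA)


def read_biom_v1(path) -> FeatureTable:
    """Read a BIOM v1 (JSON) feature table into samples x taxa orientation."""
    with open(path) as fh:
        doc = json.load(fh)
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    shape = tuple(doc["shape"])
    dense = np.zeros(shape, dtype=float)
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            dense[i, j] = v
    else:
        dense = np.asarray(doc["data"], dtype=float)
    # BIOM stores observations (taxa) as rows; transpose to samples x taxa
    return FeatureTable(pd.DataFrame(dense.T, index=samples, columns=taxa))


# ---------------------------------------------------------------------------
# taxonomy


def read_taxonomy(path) -> dict[str, TaxonAnnotation]:
    """2-column TSV (taxon id, 7-rank semicolon lineage) -> annotations.

    Oxygen class and site flags are filled from the built-in table keyed by
    genus when available.
    """
    from .annotations import builtin_annotations

    df = _read_tsv(path)
    builtin = builtin_annotations()
    out: dict[str, TaxonAnnotation] = {}
    for _, row in df.iterrows():
        taxon_id = str(row.iloc[0])
        ranks = [r.split("__", 1)[-1] for r in str(row.iloc[1]).split(";")]
        ranks += ["unknown"] * (7 - len(ranks))
        genus = ranks[5] or "unknown"
        base = builtin.get(genus)
        out[taxon_id] = TaxonAnnotation(
            taxon_id=taxon_id,
            kingdom=ranks[0] or "Bacteria",
            phylum=ranks[1] or "unknown",
            **{"class": ranks[2] or "unknown"},
            order=ranks[3] or "unknown",
            family=ranks[4] or "unknown",
            genus=genus,
            oxygen_class=base.oxygen_class if base else "unknown",
            site_flags=base.site_flags if base else set(),
        )
    return out


def write_taxonomy(annotations: dict[str, TaxonAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon_id\tlineage\n")
        for taxon_id, ann in annotations.items():
            fh.write(f"{taxon_id}\t{ann.lineage()}\n")


# ---------------------------------------------------------------------------
# records


def _opt(row, col, cast=float):
    if col not in row or pd.isna(row[col]):
        return None
    value = row[col]
    if cast is bool:
        return bool(int(value)) if not isinstance(value, str) else value.lower() in ("1", "true", "yes")
    return cast(value)


def read_dpcr_records(path) -> list[DPCRRecord]:
    df = _read_tsv(path)
    records = []
    for _, row in df.iterrows():
        try:
            records.append(
                DPCRRecord(
                    sample_id=str(row["sample_id"]),
                    dpcr_concentration=float(row["dpcr_concentration"]),
                    dilution_factor=float(row["dilution_factor"]),
                    extract_volume=float(row["extract_volume"]),
                    collected_sample_volume=_opt(row, "collected_sample_volume"),
                    sample_type=str(row["sample_type"]),
                )
            )
        except (PydanticValidationError, KeyError) as exc:
            raise ValidationError(f"bad dPCR record {dict(row)}: {exc}") from exc
    return records


def write_dpcr_records(records: Sequence[DPCRRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "dpcr_concentration": r.dpcr_concentration,
                "dilution_factor": r.dilution_factor,
                "extract_volume": r.extract_volume,
                "collected_sample_volume": r.collected_sample_volume,
                "sample_type": r.sample_type,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep=_NA)


def read_qpcr_records(path) -> list[QPCRRecord]:
    df = _read_tsv(path)
    records = []
    for _, row in df.iterrows():
        try:
            records.append(
                QPCRRecord(
                    sample_id=str(row["sample_id"]),
                    cq=_opt(row, "cq"),
                    dilution_factor=float(row.get("dilution_factor", 1.0)),
                    extract_volume=float(row.get("extract_volume", 100.0)),
                    collected_sample_volume=_opt(row, "collected_sample_volume"),
                )
            )
        except (PydanticValidationError, KeyError) as exc:
            raise ValidationError(f"bad qPCR record {dict(row)}: {exc}") from exc
    return records


def write_qpcr_records(records: Sequence[QPCRRecord], path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "cq": r.cq,
            "dilution_factor": r.dilution_factor,
            "extract_volume": r.extract_volume,
            "collected_sample_volume": r.collected_sample_volume,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep=_NA)


_BOOL_FLAGS = ("ppi", "antibiotics_current", "antibiotics_6mo", "probiotics", "smoker")


def read_metadata(path) -> list[SampleRecord]:
    """Read sample metadata TSV into typed records; missing values stay None."""
    df = _read_tsv(path)
    records = []
    for _, row in df.iterrows():
        symptoms = {s: row[s] for s in SYMPTOM_NAMES if s in row and not pd.isna(row[s])}
        cytokines = {c: float(row[c]) for c in CYTOKINE_NAMES if c in row and not pd.isna(row[c])}
        try:
            records.append(
                SampleRecord(
                    sample_id=str(row["sample_id"]),
                    subject_id=str(row["subject_id"]),
                    site=str(row["site"]),
                    aerobic_cfu_per_ml=_opt(row, "aerobic_cfu_per_ml"),
                    anaerobic_cfu_per_ml=_opt(row, "anaerobic_cfu_per_ml"),
                    symptom_scores={k: float(v) for k, v in symptoms.items()},
                    cytokines=cytokines,
                    age=_opt(row, "age"),
                    sex=_opt(row, "sex", str),
                    **{f: _opt(row, f, bool) for f in _BOOL_FLAGS},
                )
            )
        except (PydanticValidationError, KeyError) as exc:
            raise ValidationError(f"bad metadata row {dict(row)}: {exc}") from exc
    return records


def write_metadata(records: Sequence[SampleRecord], path) -> None:
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "subject_id": r.subject_id,
            "site": r.site,
            "aerobic_cfu_per_ml": r.aerobic_cfu_per_ml,
            "anaerobic_cfu_per_ml": r.anaerobic_cfu_per_ml,
            "age": r.age,
            "sex": r.sex,
        }
        for f in _BOOL_FLAGS:
            value = getattr(r, f)
            row[f] = None if value is None else int(value)
        for s in SYMPTOM_NAMES:
            row[s] = r.symptom_scores.get(s)
        for c in CYTOKINE_NAMES:
            row[c] = r.cytokines.get(c)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep=_NA)


# ---------------------------------------------------------------------------
# volume imputation


def impute_missing_volumes(dpcr_records: Iterable[DPCRRecord]) -> list[DPCRRecord]:
    """Replace missing collected volumes by the mean of the non-missing
    volumes of the same sample type; imputed records are flagged."""
    records = list(dpcr_records)
    means: dict[str, float] = {}
    for stype in {r.sample_type for r in records}:
        present = [
            r.collected_sample_volume
            for r in records
            if r.sample_type == stype and r.collected_sample_volume is not None
        ]
        if any(r.sample_type == stype and r.collected_sample_volume is None for r in records):
            if not present:
                raise ValidationError(f"all collected volumes missing for sample type {stype!r}")
        if present:
            means[stype] = float(np.mean(present))
    out = []
    for r in records:
        if r.collected_sample_volume is None:
            out.append(
                r.model_copy(
                    update={
                        "collected_sample_volume": means[r.sample_type],
                        "volume_imputed": True,
                    }
                )
            )
        else:
            out.append(r)
    return out
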