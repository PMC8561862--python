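"""End-to-end orchestration: raw inputs -> anchored, LOD-filtered tables ->
analysis outputs, with a reproducible run manifest.

The stage order mirrors the measurement chain: volume imputation, dPCR
total loads, blank filtering, rarefaction, anchoring, LOD filtering, then
the community / disruptor / ordination / clinical / oral-link analyses.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .annotations import DEFAULT_DISRUPTOR_EXCLUSIONS, DISRUPTOR_SIGNATURE, MACCONKEY_SUBSET
from .datamodel import (
    AbsoluteAbundanceTable,
    DPCRRecord,
    FeatureTable,
    SampleRecord,
    TaxonAnnotation,
    ValidationError,
)
from .io import impute_missing_volumes
from .quantload import (
    DEFAULT_TEMPLATE_VOLUME_UL,
    anchor_absolute_abundance,
    apply_lod_filter,
    blank_threshold,
    compute_lod_records,
    rarefy,
    total_load,
    total_loads,
)


@dataclass
class RunManifest:
    """Config snapshot, seeds, and per-stage bookkeeping for one run."""

    seed: int
    software_version: str = __version__
    config: dict = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)
    input_digests: dict = field(default_factory=dict)

    def log(self, stage: str, **info) -> None:
        self.stages.append({"stage": stage, **info})

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "software_version": self.software_version,
                "config": self.config,
                "stages": self.stages,
                "input_digests": self.input_digests,
            },
            indent=2,
            default=str,
        )

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        doc = json.loads(text)
        return cls(
            seed=doc["seed"],
            software_version=doc["software_version"],
            config=doc["config"],
            stages=doc["stages"],
            input_digests=doc["input_digests"],
        )


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class QuantifiedSite:
    """Anchored and LOD-filtered table for one body site."""

    table: AbsoluteAbundanceTable  # LOD-filtered
    unfiltered: AbsoluteAbundanceTable
    counts: FeatureTable  # rarefied counts the anchoring used
    excluded_by_blank: list[str]
    rarefaction_depth: int


def quantify(
    counts: FeatureTable,
    dpcr_records: Sequence[DPCRRecord],
    seed: int,
    template_volume: float = DEFAULT_TEMPLATE_VOLUME_UL,
    rarefy_depth: int | Literal["auto"] | None = "auto",
    lod_depth_units: Literal["percent", "fraction"] = "percent",
    apply_blank_filter: bool = True,
    manifest: Optional[RunManifest] = None,
) -> QuantifiedSite:
    """Run the measurement chain for one site's feature table.

    Blank records are used for the blank threshold and never quantified
    themselves.  ``rarefy_depth="auto"`` rarefies to the minimum sample
    depth; ``None`` skips rarefaction.
    """
    records = impute_missing_volumes(dpcr_records)
    blanks = [r for r in records if r.sample_type == "blank"]
    sample_recs = [r for r in records if r.sample_type != "blank" and r.sample_id in set(counts.sample_ids)]
    if not sample_recs:
        raise ValidationError("no dPCR records match the feature table")

    thresh = None
    if apply_blank_filter and len(blanks) >= 2:
        thresh = blank_threshold([total_load(b).copies_per_ml for b in blanks])

    if rarefy_depth == "auto":
        depth = int(counts.depths.min())
    else:
        depth = rarefy_depth
    if depth is not None:
        counts = rarefy(counts, depth, seed=seed)
    else:
        depth = int(counts.depths.min())

    loads = total_loads(sample_recs)
    lods = compute_lod_records(
        sample_recs,
        counts.depths,
        template_volume=template_volume,
        blank_thresh=thresh,
        lod_depth_units=lod_depth_units,
    )
    excluded = [s for s, rec in lods.items() if not rec.passed_blank_filter]
    kept = [s for s in counts.sample_ids if s in lods and s not in set(excluded)]
    counts = counts.subset_samples(kept)
    unfiltered = anchor_absolute_abundance(counts, loads.loc[kept], lod_records=lods)
    filtered = apply_lod_filter(unfiltered)
    if manifest is not None:
        manifest.log(
            "quantify",
            n_samples_in=len(loads),
            n_excluded_by_blank=len(excluded),
            n_samples_out=len(kept),
            rarefaction_depth=depth,
            blank_threshold=thresh,
        )
    return QuantifiedSite(
        table=filtered,
        unfiltered=unfiltered,
        counts=counts,
        excluded_by_blank=excluded,
        rarefaction_depth=depth,
    )


def run_pipeline(
    duodenum_counts: FeatureTable,
    dpcr_records: Sequence[DPCRRecord],
    sample_records: Sequence[SampleRecord],
    annotations: dict[str, TaxonAnnotation],
    seed: int,
    saliva_counts: Optional[FeatureTable] = None,
    subject_map: Optional[dict[str, tuple[str, str]]] = None,
    qpcr_records: Sequence = (),
    out_dir: Optional[Path] = None,
    culture_threshold: float = 1e3,
    load_threshold: float = 1e4,
    q_volcano_sibo: float = 0.01,
    q_volcano_site: float = 0.1,
    n_components: int = 10,
) -> dict:
    """Execute every analysis stage and (optionally) write TSV outputs plus
    a JSON run manifest.  Returns the in-memory results keyed by stage."""
    from . import clinical, community, disruptors, oral, ordination

    manifest = RunManifest(seed=seed, config={
        "culture_threshold": culture_threshold,
        "load_threshold": load_threshold,
        "q_volcano_sibo": q_volcano_sibo,
        "q_volcano_site": q_volcano_site,
        "n_components": n_components,
    })
    results: dict = {"manifest": manifest}

    duo = quantify(duodenum_counts, dpcr_records, seed=seed, manifest=manifest)
    results["duodenum"] = duo
    table = duo.table

    # community statistics -------------------------------------------------
    fit = community.fit_lognormal(table.total_loads[table.total_loads > 0])
    prev = community.prevalence(table)
    partition = community.anaerobe_partition(table, annotations)
    results["load_fit"] = fit
    results["prevalence"] = prev
    results["partition"] = partition
    manifest.log("community", n_samples=fit.n, mean_log10=fit.mean_log10, sd_log10=fit.sd_log10)

    # disruptor discovery --------------------------------------------------
    k_top = min(20, len(table.taxon_ids))
    top = disruptors.top_abundant_taxa(table, k=k_top)
    cocorr = disruptors.cocorrelation_matrix(table, top)
    motifs = disruptors.classify_motifs(cocorr)
    report = disruptors.disruptor_rank(table)
    report = disruptors.signature_cluster(
        report, table, annotations, exclusions=DEFAULT_DISRUPTOR_EXCLUSIONS
    )
    results["cocorrelation"] = cocorr
    results["motifs"] = motifs
    results["disruptor_report"] = report
    manifest.log("disruptors", candidate_set=report.candidate_set, final_set=report.final_set)

    # ordination -----------------------------------------------------------
    x = ordination.log_pseudo_transform(duo.counts, table.total_loads)
    ord_result = ordination.pca(x, n_components=n_components)
    results["ordination"] = ord_result
    manifest.log("ordination", explained=ord_result.explained_variance_ratio.to_dict())

    # clinical -------------------------------------------------------------
    final_set = report.final_set or [
        t for t in DISRUPTOR_SIGNATURE if t not in DEFAULT_DISRUPTOR_EXCLUSIONS
    ]
    sibo = clinical.classify_sibo(
        sample_records,
        table,
        disruptor_set=final_set,
        culture_threshold=culture_threshold,
        load_threshold=load_threshold,
    )
    results["sibo"] = sibo
    severe, medians = clinical.binarize_symptoms(
        [r for r in sample_records if r.site == "duodenum" and r.symptom_scores]
    )
    results["symptoms"] = (severe, medians)
    d_load = clinical.disruptor_loads(table, final_set)
    shared = severe.index.intersection(d_load.index)
    results["burden"] = clinical.symptom_burden_by_disruptor_bin(
        d_load.loc[shared], severe.loc[shared, "severe_count"]
    )
    counts_series = clinical.disruptor_counts(table, final_set)
    results["count_trend"] = clinical.disruptor_count_load_trend(counts_series, table.total_loads)
    if len(qpcr_records):
        try:
            results["klebsiella"] = clinical.klebsiella_analysis(table, qpcr_records)
        except ValidationError:
            results["klebsiella"] = None
    manifest.log("clinical", agreement=sibo.agreement)

    # oral link ------------------------------------------------------------
    if saliva_counts is not None and subject_map:
        sal = quantify(saliva_counts, dpcr_records, seed=seed, manifest=manifest)
        results["saliva"] = sal
        usable = {
            s: pair
            for s, pair in subject_map.items()
            if pair[0] in set(table.sample_ids) and pair[1] in set(sal.table.sample_ids)
        }
        if len(usable) >= 3:
            results["overlap"] = oral.overlap_cohort(table, sal.table, usable)
            results["site_loads"] = oral.site_load_comparison(
                table.total_loads, sal.table.total_loads, usable
            )
            results["site_volcano"] = oral.site_volcano(
                table, sal.table, usable, alpha=q_volcano_site
            )
            manifest.log(
                "oral_link",
                n_pairs=len(usable),
                mean_paired=results["overlap"].mean_paired,
                mean_nonpaired=results["overlap"].mean_nonpaired,
            )
        else:
            manifest.log("oral_link", skipped=True, reason="fewer than 3 usable pairs")
    else:
        manifest.log("oral_link", skipped=True, reason="no saliva inputs")

    if out_dir is not None:
        _write_outputs(Path(out_dir), results)
    return results


def _write_outputs(out_dir: Path, results: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    duo = results["duodenum"]
    duo.table.loads.to_csv(out_dir / "absolute_abundance.tsv", sep="\t")
    pd.DataFrame(
        [
            {
                "sample_id": s,
                "total_load": duo.table.total_loads[s],
                "lod_library": rec.lod_library,
                "lod_depth": rec.lod_depth,
                "lod_effective": rec.lod_effective,
                "passed_blank_filter": rec.passed_blank_filter,
            }
            for s, rec in duo.table.lod_records.items()
            if s in duo.table.loads.index
        ]
    ).to_csv(out_dir / "lod_records.tsv", sep="\t", index=False)
    results["prevalence"].to_csv(out_dir / "prevalence.tsv", sep="\t")
    results["partition"].per_sample.to_csv(out_dir / "diversity_partition.tsv", sep="\t")
    results["cocorrelation"].rho.to_csv(out_dir / "cocorrelation_rho.tsv", sep="\t")
    results["cocorrelation"].q.to_csv(out_dir / "cocorrelation_q.tsv", sep="\t")
    pd.Series(results["motifs"], name="motif").to_csv(out_dir / "motifs.tsv", sep="\t")
    report = results["disruptor_report"]
    with open(out_dir / "disruptor_report.json", "w") as fh:
        json.dump(
            {
                "scores": report.scores.to_dict(),
                "top_k": report.top_k,
                "signatures": report.signatures,
                "candidate_set": report.candidate_set,
                "exclusions": report.exclusions,
                "final_set": report.final_set,
            },
            fh,
            indent=2,
        )
    ord_result = results["ordination"]
    ord_result.scores.to_csv(out_dir / "pca_scores.tsv", sep="\t")
    ord_result.loadings.to_csv(out_dir / "pca_loadings.tsv", sep="\t")
    ord_result.explained_variance_ratio.to_csv(out_dir / "pca_explained.tsv", sep="\t")
    results["sibo"].frame().to_csv(out_dir / "sibo_calls.tsv", sep="\t")
    results["burden"].to_csv(out_dir / "symptom_burden.tsv", sep="\t")
    if "overlap" in results:
        results["overlap"].frame().to_csv(out_dir / "overlap.tsv", sep="\t")
        results["site_volcano"].to_csv(out_dir / "site_volcano.tsv", sep="\t")
    (out_dir / "manifest.json").write_text(results["manifest"].to_json())
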