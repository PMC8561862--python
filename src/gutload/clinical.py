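"""SIBO classification and concordance, symptom binarization and burden,
and disruptor-load clinical associations.

SIBO (small intestinal bacterial overgrowth) is called clinically from
aerobic culture at >= 1e3 CFU/mL of duodenal aspirate; the sequencing-based
call uses the summed absolute load of the disruptor taxa.  Symptom scores
(0-100) become binary "severe" flags at each symptom's cohort median.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skmetrics
from statsmodels.stats.multitest import multipletests

from .datamodel import (
    SYMPTOM_NAMES,
    AbsoluteAbundanceTable,
    QPCRRecord,
    SampleRecord,
    ValidationError,
)
from .quantload import genome_load, qpcr_load

DEFAULT_CULTURE_THRESHOLD = 1e3  # CFU/mL, aerobic culture
DEFAULT_LOAD_THRESHOLD = 1e4  # copies/mL, summed disruptor load
PER_TAXON_THRESHOLD = 1e4  # copies/mL, strict > rule for disruptor counting
DEFAULT_BURDEN_BIN_EDGES = (1e4, 1e5, 1e6, 1e7)  # log-spaced bin edges; zero is its own bin
ENTEROBACTERIACEAE_16S_COPIES = 8
KLEBSIELLA_QPCR_TRIGGER = 1e5  # copies/mL of Enterobacteriaceae-family 16S
QPCR_RUN_LENGTH_CYCLES = 40.0


@dataclass
class SiboCall:
    sample_id: str
    by_culture: Optional[bool]
    by_disruptor: Optional[bool]
    disruptor_load: float
    disruptor_count: int


@dataclass
class SiboClassification:
    calls: list[SiboCall]
    agreement: Optional[float]
    confusion: Optional[pd.DataFrame]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": c.sample_id,
                    "by_culture": c.by_culture,
                    "by_disruptor": c.by_disruptor,
                    "disruptor_load": c.disruptor_load,
                    "disruptor_count": c.disruptor_count,
                }
                for c in self.calls
            ]
        ).set_index("sample_id")


def disruptor_loads(
    table: AbsoluteAbundanceTable,
    disruptor_set: Sequence[str],
    exclusions: Sequence[str] = (),
) -> pd.Series:
    """Summed disruptor load per sample (copies/mL), exclusions removed."""
    taxa = [t for t in disruptor_set if t in table.loads.columns and t not in set(exclusions)]
    if not taxa:
        return pd.Series(0.0, index=table.loads.index)
    return table.loads[taxa].sum(axis=1)


def disruptor_counts(
    table: AbsoluteAbundanceTable,
    disruptor_set: Sequence[str],
    exclusions: Sequence[str] = (),
    per_taxon_threshold: float = PER_TAXON_THRESHOLD,
) -> pd.Series:
    """Number of disruptor taxa with load strictly above the per-taxon
    threshold (default 1e4 copies/mL), exclusions removed."""
    taxa = [t for t in disruptor_set if t in table.loads.columns and t not in set(exclusions)]
    if not taxa:
        return pd.Series(0, index=table.loads.index)
    return (table.loads[taxa] > per_taxon_threshold).sum(axis=1)


def classify_sibo(
    records: Sequence[SampleRecord],
    table: AbsoluteAbundanceTable,
    disruptor_set: Sequence[str],
    culture_threshold: float = DEFAULT_CULTURE_THRESHOLD,
    load_threshold: float = DEFAULT_LOAD_THRESHOLD,
    exclusions: Sequence[str] = (),
) -> SiboClassification:
    """Culture-based (CFU >= threshold) and sequencing-based (summed
    disruptor load >= threshold) SIBO calls with their agreement."""
    if not list(disruptor_set):
        raise ValidationError("empty disruptor set")
    d_load = disruptor_loads(table, disruptor_set, exclusions)
    d_count = disruptor_counts(table, disruptor_set, exclusions)
    by_id = {r.sample_id: r for r in records}
    calls = []
    for sample_id in table.sample_ids:
        rec = by_id.get(sample_id)
        cfu = rec.aerobic_cfu_per_ml if rec else None
        calls.append(
            SiboCall(
                sample_id=sample_id,
                by_culture=None if cfu is None else bool(cfu >= culture_threshold),
                by_disruptor=bool(d_load[sample_id] >= load_threshold),
                disruptor_load=float(d_load[sample_id]),
                disruptor_count=int(d_count[sample_id]),
            )
        )
    both = [c for c in calls if c.by_culture is not None and c.by_disruptor is not None]
    agreement = confusion = None
    if both:
        agreement = float(np.mean([c.by_culture == c.by_disruptor for c in both]))
        confusion = pd.crosstab(
            pd.Series([c.by_culture for c in both], name="by_culture"),
            pd.Series([c.by_disruptor for c in both], name="by_disruptor"),
        )
    return SiboClassification(calls, agreement, confusion)


def agreement_permutation_p(
    classification: SiboClassification, n_permutations: int = 2000, seed: int = 0
) -> float:
    """Permutation p-value for the culture/sequencing agreement exceeding
    chance (labels shuffled across samples)."""
    both = [c for c in classification.calls if c.by_culture is not None]
    culture = np.array([c.by_culture for c in both])
    seq = np.array([c.by_disruptor for c in both])
    observed = np.mean(culture == seq)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        hits += np.mean(rng.permutation(culture) == seq) >= observed
    return float((hits + 1) / (n_permutations + 1))


def roc_curve(scores: pd.Series, labels: pd.Series) -> tuple[pd.DataFrame, float]:
    """ROC points (all thresholds, tied scores grouped) and trapezoidal AUC."""
    paired = pd.DataFrame({"score": scores, "label": labels}).dropna()
    classes = paired["label"].astype(bool)
    if classes.nunique() < 2:
        raise ValidationError("both classes must be present")
    fpr, tpr, thresh = skmetrics.roc_curve(classes, paired["score"])
    auc = float(skmetrics.auc(fpr, tpr))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresh}), auc


def binarize_symptoms(records: Sequence[SampleRecord]) -> tuple[pd.DataFrame, pd.Series]:
    """Severe flag per symptom = score strictly greater than the cohort
    median for that symptom.  Returns (per-sample frame with severe flags
    and severe_count, per-symptom medians)."""
    scores = pd.DataFrame(
        {r.sample_id: {s: r.symptom_scores.get(s) for s in SYMPTOM_NAMES} for r in records}
    ).T
    medians = scores.median(axis=0, skipna=True)
    severe = scores.gt(medians, axis=1)
    severe[scores.isna()] = False
    out = severe.add_prefix("severe_")
    out["severe_count"] = severe.sum(axis=1).astype(int)
    return out, medians


def symptom_burden_by_disruptor_bin(
    disruptor_load: pd.Series,
    severe_count: pd.Series,
    bin_edges: Sequence[float] = DEFAULT_BURDEN_BIN_EDGES,
) -> pd.DataFrame:
    """Per disruptor-load bin: % of samples with 0 severe symptoms, with 1-4,
    and with 5-6, plus n.  Zero-load samples form their own bin; the last
    bin is open above the final edge."""
    paired = pd.DataFrame({"load": disruptor_load, "count": severe_count}).dropna()
    if paired.empty:
        raise ValidationError("empty cohort")
    edges = sorted(bin_edges)
    labels = ["zero"]
    labels += [f"(0, {edges[0]:g}]"]
    labels += [f"({lo:g}, {hi:g}]" for lo, hi in zip(edges[:-1], edges[1:])]
    labels += [f">{edges[-1]:g}"]

    def assign(load: float) -> str:
        if load == 0:
            return "zero"
        if load <= edges[0]:
            return labels[1]
        for lo, hi, lab in zip(edges[:-1], edges[1:], labels[2:-1]):
            if lo < load <= hi:
                return lab
        return labels[-1]

    paired["bin"] = paired["load"].map(assign)
    rows = []
    for lab in labels:
        sub = paired[paired["bin"] == lab]
        n = len(sub)
        if n == 0:
            rows.append({"bin": lab, "pct_zero": np.nan, "pct_mid": np.nan, "pct_high": np.nan, "n": 0})
            continue
        rows.append(
            {
                "bin": lab,
                "pct_zero": 100.0 * (sub["count"] == 0).mean(),
                "pct_mid": 100.0 * sub["count"].between(1, 4).mean(),
                "pct_high": 100.0 * sub["count"].isin([5, 6]).mean(),
                "n": n,
            }
        )
    return pd.DataFrame(rows).set_index("bin")


def disruptor_count_load_trend(
    disruptor_count: pd.Series, total_loads: pd.Series
) -> tuple[pd.DataFrame, Optional[float]]:
    """Median/quartile total load per disruptor-count group, plus a
    Kruskal-Wallis p comparing zero-disruptor vs >=1-disruptor samples."""
    paired = pd.DataFrame({"count": disruptor_count, "load": total_loads}).dropna()
    summary = (
        paired.groupby("count")["load"]
        .agg(n="size", median="median", q1=lambda x: x.quantile(0.25), q3=lambda x: x.quantile(0.75))
        .reset_index()
        .set_index("count")
    )
    zero = paired.loc[paired["count"] == 0, "load"]
    some = paired.loc[paired["count"] >= 1, "load"]
    p = None
    if len(zero) and len(some):
        _, p = stats.kruskal(zero, some)
        p = float(p)
    return summary, p


@dataclass
class KlebsiellaResult:
    paired: pd.DataFrame  # entero_genomes, klebsiella_genomes per detected sample
    pearson_r: float
    pearson_p: float
    n_tested: int
    n_detected: int
    detection_fraction: float


def klebsiella_analysis(
    table: AbsoluteAbundanceTable,
    qpcr_records: Sequence[QPCRRecord],
    entero_taxa: Sequence[str] = ("Enterobacteriaceae", "Escherichia-Shigella"),
    trigger: float = KLEBSIELLA_QPCR_TRIGGER,
    run_length: float = QPCR_RUN_LENGTH_CYCLES,
) -> KlebsiellaResult:
    """Compare Klebsiella genome loads (single-copy marker-gene qPCR) to
    Enterobacteriaceae genome loads (16S / 8) on the log10 scale, over the
    samples with at least ``trigger`` copies/mL of family-level 16S load.

    Records with cq >= run_length or no amplification count as undetected.
    """
    taxa = [t for t in entero_taxa if t in table.loads.columns]
    entero_16s = table.loads[taxa].sum(axis=1) if taxa else pd.Series(0.0, index=table.loads.index)
    eligible = set(entero_16s.index[entero_16s >= trigger])
    rows, n_tested, n_detected = [], 0, 0
    for rec in qpcr_records:
        if rec.sample_id not in eligible:
            continue
        n_tested += 1
        detected = rec.cq is not None and rec.cq < run_length
        if not detected:
            continue
        n_detected += 1
        kleb = genome_load(qpcr_load(rec), copies_per_genome=1)
        entero = genome_load(float(entero_16s[rec.sample_id]), ENTEROBACTERIACEAE_16S_COPIES)
        rows.append(
            {"sample_id": rec.sample_id, "entero_genomes": entero, "klebsiella_genomes": kleb}
        )
    if not rows:
        raise ValidationError("no detected Klebsiella pairs")
    paired = pd.DataFrame(rows).set_index("sample_id")
    log_e = np.log10(paired["entero_genomes"])
    log_k = np.log10(paired["klebsiella_genomes"])
    if len(paired) >= 3 and log_e.nunique() > 1 and log_k.nunique() > 1:
        r, p = stats.pearsonr(log_e, log_k)
    else:
        r, p = np.nan, np.nan
    return KlebsiellaResult(
        paired=paired,
        pearson_r=float(r),
        pearson_p=float(p),
        n_tested=n_tested,
        n_detected=n_detected,
        detection_fraction=n_detected / n_tested if n_tested else np.nan,
    )


def subgroup_load_tests(
    loads: pd.Series, flags: pd.DataFrame
) -> pd.DataFrame:
    """Kruskal-Wallis of total load between the two levels of each boolean
    metadata flag, BH-corrected across the flag family.  Single-level flags
    are skipped (reported with NaN p)."""
    rows = []
    for col in flags.columns:
        paired = pd.DataFrame({"load": loads, "flag": flags[col]}).dropna()
        levels = paired["flag"].unique()
        if len(levels) < 2:
            rows.append(
                {"flag": col, "p": np.nan, "n_true": int(paired["flag"].sum()), "n_false": 0,
                 "median_true": np.nan, "median_false": np.nan}
            )
            continue
        true_loads = paired.loc[paired["flag"].astype(bool), "load"]
        false_loads = paired.loc[~paired["flag"].astype(bool), "load"]
        _, p = stats.kruskal(true_loads, false_loads)
        rows.append(
            {
                "flag": col,
                "p": float(p),
                "n_true": int(len(true_loads)),
                "n_false": int(len(false_loads)),
                "median_true": float(true_loads.median()),
                "median_false": float(false_loads.median()),
            }
        )
    out = pd.DataFrame(rows).set_index("flag")
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        _, qvals, _, _ = multipletests(out.loc[ok, "p"], method="fdr_bh")
        out.loc[ok, "q"] = qvals
    return out
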