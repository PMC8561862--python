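"""Distributional, diversity, and anaerobe-composition analyses.

Covers the cohort-level descriptions of total microbial load (log-normal
fit, QQ points), taxon prevalence, Shannon diversity, the strict- vs
facultative-anaerobe partition, conditional load ECDFs, and culture vs
sequencing concordance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AbsoluteAbundanceTable, TaxonAnnotation, ValidationError

#: pseudo-load (copies/mL) used when log-transforming loads that may be zero
DEFAULT_PSEUDO_LOAD = 1.0


@dataclass
class LogNormalFit:
    mean_log10: float
    sd_log10: float
    n: int


@dataclass
class AnaerobePartition:
    per_sample: pd.DataFrame  # strict_load, facultative_load, fraction_strict, shannon
    excluded_taxa: list[str]
    r_strict_vs_facultative_log: float
    r_strict_vs_facultative_linear: float
    r_fraction_vs_shannon: float


def fit_lognormal(loads: Sequence[float]) -> LogNormalFit:
    """Sample mean and SD (n-1 denominator) of log10 loads."""
    arr = np.asarray(list(loads), dtype=float)
    if arr.size < 2:
        raise ValidationError("need at least 2 loads to fit")
    if (arr <= 0).any():
        raise ValidationError("loads must be > 0 for a log-normal fit")
    logs = np.log10(arr)
    return LogNormalFit(float(logs.mean()), float(logs.std(ddof=1)), int(arr.size))


def qq_points(loads: Sequence[float]) -> pd.DataFrame:
    """Sorted log10 loads against normal quantiles at positions (i-0.5)/n,
    using the fitted mean/SD (so perfectly normal data sits on y = x)."""
    arr = np.asarray(list(loads), dtype=float)
    if arr.size < 3:
        raise ValidationError("need at least 3 loads for a QQ plot")
    fit = fit_lognormal(arr)
    sample_q = np.sort(np.log10(arr))
    probs = (np.arange(1, arr.size + 1) - 0.5) / arr.size
    theo_q = stats.norm.ppf(probs, loc=fit.mean_log10, scale=max(fit.sd_log10, 1e-12))
    return pd.DataFrame({"theoretical_quantile": theo_q, "sample_quantile": sample_q})


def prevalence(table: AbsoluteAbundanceTable) -> pd.Series:
    """Fraction of samples in which each taxon is detected (nonzero load)."""
    if not table.sample_ids:
        raise ValidationError("empty table")
    return (table.loads > 0).mean(axis=0).rename("prevalence")


def prevalent_taxa(table: AbsoluteAbundanceTable, threshold: float = 0.5) -> list[str]:
    prev = prevalence(table)
    return prev.index[prev >= threshold].tolist()


def shannon(counts_row: Sequence[float], base: Literal["e", "2"] = "e") -> float:
    """Shannon diversity H = -sum p ln p over nonzero proportions (nats by
    default; ``base="2"`` for bits)."""
    arr = np.asarray(list(counts_row), dtype=float)
    if arr.sum() <= 0:
        raise ValidationError("row sum must be > 0")
    if (arr < 0).any():
        raise ValidationError("negative entries")
    h = stats.entropy(arr)  # normalizes and uses natural log
    return float(h / np.log(2)) if base == "2" else float(h)


def shannon_per_sample(table: AbsoluteAbundanceTable, base: Literal["e", "2"] = "e") -> pd.Series:
    return pd.Series(
        {s: shannon(table.loads.loc[s], base=base) for s in table.sample_ids},
        name="shannon",
    )


def anaerobe_partition(
    table: AbsoluteAbundanceTable,
    annotations: dict[str, TaxonAnnotation],
    pseudo_load: float = DEFAULT_PSEUDO_LOAD,
) -> AnaerobePartition:
    """Per-sample strict- and facultative-anaerobe loads with companion
    correlations (log10 strict vs log10 facultative; fraction strict vs
    Shannon).  Taxa without a known oxygen class are excluded and reported.
    """
    strict = [t for t in table.taxon_ids if annotations.get(t) and annotations[t].oxygen_class == "strict_anaerobe"]
    facult = [t for t in table.taxon_ids if annotations.get(t) and annotations[t].oxygen_class == "facultative_anaerobe"]
    excluded = [t for t in table.taxon_ids if t not in set(strict) | set(facult)]
    if not strict and not facult:
        raise ValidationError("no taxa with known oxygen class")
    strict_load = table.loads[strict].sum(axis=1) if strict else pd.Series(0.0, index=table.loads.index)
    facult_load = table.loads[facult].sum(axis=1) if facult else pd.Series(0.0, index=table.loads.index)
    denom = strict_load + facult_load
    fraction = strict_load.div(denom.where(denom > 0))
    sh = shannon_per_sample(table)
    per_sample = pd.DataFrame(
        {
            "strict_load": strict_load,
            "facultative_load": facult_load,
            "fraction_strict": fraction,
            "shannon": sh,
        }
    )
    log_strict = np.log10(strict_load + pseudo_load)
    log_facult = np.log10(facult_load + pseudo_load)
    r_log = stats.pearsonr(log_strict, log_facult)[0] if len(per_sample) > 2 else np.nan
    r_lin = stats.pearsonr(strict_load, facult_load)[0] if len(per_sample) > 2 else np.nan
    ok = fraction.notna()
    r_frac = (
        stats.pearsonr(fraction[ok], sh[ok])[0]
        if ok.sum() > 2 and fraction[ok].nunique() > 1
        else np.nan
    )
    return AnaerobePartition(per_sample, excluded, float(r_log), float(r_lin), float(r_frac))


def conditional_load_ecdf(table: AbsoluteAbundanceTable, taxon: str):
    """ECDF of log10 total load over the samples containing ``taxon``.

    Returns (ecdf callable, points DataFrame, n).  The ECDF is the usual
    right-continuous step function with range [0, 1].
    """
    if taxon not in table.loads.columns:
        raise ValidationError(f"unknown taxon {taxon!r}")
    containing = table.loads.index[table.loads[taxon] > 0]
    if len(containing) == 0:
        raise ValidationError(f"taxon {taxon!r} absent from every sample")
    loads = np.log10(table.total_loads.loc[containing].astype(float))
    from statsmodels.distributions.empirical_distribution import ECDF

    ecdf = ECDF(loads)
    points = pd.DataFrame({"log10_load": np.sort(loads.values)})
    points["ecdf"] = ecdf(points["log10_load"])
    return ecdf, points, int(len(containing))


def culture_concordance(
    table: AbsoluteAbundanceTable,
    culture_cfu: pd.Series,
    taxon_subset: Sequence[str],
) -> tuple[float, float, int]:
    """Spearman rank correlation of the summed subset load vs culture
    CFU/mL over samples with both measurements (zeros kept as ties)."""
    subset = [t for t in taxon_subset if t in table.loads.columns]
    if not subset:
        raise ValidationError("no subset taxa present in table")
    seq_load = table.loads[subset].sum(axis=1)
    paired = pd.DataFrame({"seq": seq_load, "cfu": culture_cfu}).dropna()
    if len(paired) < 3:
        raise ValidationError("need at least 3 paired samples")
    rho, p = stats.spearmanr(paired["seq"], paired["cfu"])
    return float(rho), float(p), int(len(paired))
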