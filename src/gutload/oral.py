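"""Paired saliva-duodenum comparisons: taxon overlap, site load offsets,
and per-taxon site enrichment.

Overlap is computed on detected taxa (nonzero load after LOD filtering):
the paired fraction is the share of a subject's duodenal taxa also present
in their own saliva; the non-paired baseline is the mean of the same
fraction against every other subject's saliva.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AbsoluteAbundanceTable, ValidationError
from .disruptors import differential_volcano


@dataclass
class OverlapResult:
    subject_id: str
    paired_fraction: float
    nonpaired_mean_fraction: float
    n_duodenal_taxa: int


@dataclass
class OverlapCohortResult:
    per_subject: list[OverlapResult]
    mean_paired: float
    mean_nonpaired: float
    kruskal_p: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject_id": r.subject_id,
                    "paired_fraction": r.paired_fraction,
                    "nonpaired_mean_fraction": r.nonpaired_mean_fraction,
                    "n_duodenal_taxa": r.n_duodenal_taxa,
                }
                for r in self.per_subject
            ]
        ).set_index("subject_id")


def paired_overlap(duodenum_taxa: set, saliva_taxa: set) -> float:
    """|D intersect S| / |D|."""
    if not duodenum_taxa:
        raise ValidationError("empty duodenal taxon set")
    return len(duodenum_taxa & saliva_taxa) / len(duodenum_taxa)


def detected_sets(table: AbsoluteAbundanceTable) -> dict[str, set]:
    """Per-sample set of detected (nonzero) taxa."""
    presence = table.presence()
    return {s: set(presence.columns[presence.loc[s]]) for s in table.sample_ids}


def overlap_cohort(
    duodenum: AbsoluteAbundanceTable,
    saliva: AbsoluteAbundanceTable,
    subject_map: dict[str, tuple[str, str]],
) -> OverlapCohortResult:
    """Per-subject paired and non-paired overlap with a Kruskal-Wallis test
    between the two collections.

    ``subject_map`` maps subject id -> (duodenal sample id, saliva sample id).
    """
    if len(subject_map) < 3:
        raise ValidationError("need at least 3 paired subjects")
    duo_sets = detected_sets(duodenum)
    sal_sets = detected_sets(saliva)
    results = []
    subjects = list(subject_map)
    for subj in subjects:
        duo_id, sal_id = subject_map[subj]
        d = duo_sets[duo_id]
        if not d:
            continue
        paired = paired_overlap(d, sal_sets[sal_id])
        others = [
            paired_overlap(d, sal_sets[subject_map[o][1]]) for o in subjects if o != subj
        ]
        results.append(
            OverlapResult(
                subject_id=subj,
                paired_fraction=paired,
                nonpaired_mean_fraction=float(np.mean(others)),
                n_duodenal_taxa=len(d),
            )
        )
    if len(results) < 3:
        raise ValidationError("fewer than 3 subjects with detected duodenal taxa")
    paired_vals = [r.paired_fraction for r in results]
    nonpaired_vals = [r.nonpaired_mean_fraction for r in results]
    if np.allclose(paired_vals, nonpaired_vals):
        p = 1.0
    else:
        _, p = stats.kruskal(paired_vals, nonpaired_vals)
    return OverlapCohortResult(
        per_subject=results,
        mean_paired=float(np.mean(paired_vals)),
        mean_nonpaired=float(np.mean(nonpaired_vals)),
        kruskal_p=float(p),
    )


@dataclass
class SiteLoadComparison:
    delta_mean_log10: float  # saliva - duodenum
    duodenum_range_log10: tuple[float, float]
    saliva_range_log10: tuple[float, float]
    spearman_rho: float
    spearman_p: float
    kruskal_p: float
    n: int


def site_load_comparison(
    duodenum_loads: pd.Series, saliva_loads: pd.Series, subject_map: dict[str, tuple[str, str]]
) -> SiteLoadComparison:
    """Paired site comparison of total loads on the log10 scale."""
    duo = np.array([duodenum_loads[subject_map[s][0]] for s in subject_map], dtype=float)
    sal = np.array([saliva_loads[subject_map[s][1]] for s in subject_map], dtype=float)
    if (duo <= 0).any() or (sal <= 0).any():
        raise ValidationError("loads must be > 0 for log comparison")
    log_duo, log_sal = np.log10(duo), np.log10(sal)
    if np.allclose(log_duo, log_duo[0]) and np.allclose(log_sal, log_sal[0]):
        rho, rho_p = np.nan, np.nan
    else:
        rho, rho_p = stats.spearmanr(log_duo, log_sal)
    if np.array_equal(log_duo, log_sal):
        kw_p = 1.0
    else:
        _, kw_p = stats.kruskal(log_duo, log_sal)
    return SiteLoadComparison(
        delta_mean_log10=float(log_sal.mean() - log_duo.mean()),
        duodenum_range_log10=(float(log_duo.min()), float(log_duo.max())),
        saliva_range_log10=(float(log_sal.min()), float(log_sal.max())),
        spearman_rho=float(rho) if np.isfinite(rho) else (1.0 if np.array_equal(log_duo, log_sal) else np.nan),
        spearman_p=float(rho_p) if np.isfinite(rho_p) else np.nan,
        kruskal_p=float(kw_p),
        n=len(duo),
    )


def site_volcano(
    duodenum: AbsoluteAbundanceTable,
    saliva: AbsoluteAbundanceTable,
    subject_map: dict[str, tuple[str, str]],
    pseudo: float = 1e-6,
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Per-taxon duodenum:saliva enrichment of relative abundances
    (positive effect = duodenum-enriched), via the volcano machinery."""
    duo_ids = [subject_map[s][0] for s in subject_map]
    sal_ids = [subject_map[s][1] for s in subject_map]
    rel_duo = duodenum.relative_abundance().loc[duo_ids]
    rel_sal = saliva.relative_abundance().loc[sal_ids]
    taxa = sorted(set(rel_duo.columns) | set(rel_sal.columns))
    rel = pd.concat(
        [rel_duo.reindex(columns=taxa, fill_value=0.0), rel_sal.reindex(columns=taxa, fill_value=0.0)]
    )
    labels = pd.Series(
        [True] * len(duo_ids) + [False] * len(sal_ids), index=rel.index, name="is_duodenum"
    )
    return differential_volcano(rel, labels, pseudo=pseudo, alpha=alpha)
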