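"""Co-correlation motifs, max-minus-mean disruptor ranking, signature
clustering, and group-difference (volcano) machinery.

"Disruptor" taxa are rare across samples but dominate when present.  The
ranking statistic is max(load) - mean(load) per taxon on linear copies/mL:
a taxon present once at load L in n samples scores L * (1 - 1/n), so
rare-but-dominant taxa rank first.  Hierarchical clustering of the top-16
co-correlation matrix splits them into two taxonomic signatures; the
candidate disruptor signature is anchored by the Enterobacteriaceae-family
taxon with the highest score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .datamodel import AbsoluteAbundanceTable, TaxonAnnotation, ValidationError

TOTAL_LOAD_VARIABLE = "total_load"


@dataclass
class CoCorrelationResult:
    variables: list[str]
    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    significant: pd.DataFrame  # boolean mask at q < alpha
    alpha: float


@dataclass
class DisruptorReport:
    scores: pd.Series  # max - mean per taxon, descending
    top_k: list[str]
    signatures: dict[str, int] = field(default_factory=dict)  # taxon -> 1 or 2
    candidate_set: list[str] = field(default_factory=list)
    exclusions: list[str] = field(default_factory=list)
    final_set: list[str] = field(default_factory=list)


def spearman_bh(matrix: pd.DataFrame, alpha: float = 0.1) -> CoCorrelationResult:
    """Pairwise Spearman correlations with BH correction over the unique
    off-diagonal pairs (one correction family per call).

    Constant variables yield undefined correlations, reported as NaN and
    never significant.
    """
    if matrix.shape[0] < 3:
        raise ValidationError("need at least 3 samples")
    cols = list(matrix.columns)
    k = len(cols)
    rho = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    pmat = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    constant = {c for c in cols if matrix[c].nunique() <= 1}
    pairs, pvals = [], []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = cols[i], cols[j]
            if a in constant or b in constant:
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(matrix[a], matrix[b])
            rho.iloc[i, j] = rho.iloc[j, i] = r
            pmat.iloc[i, j] = pmat.iloc[j, i] = p
            if np.isfinite(p):
                pairs.append((i, j))
                pvals.append(p)
    q = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    np.fill_diagonal(q.values, 0.0)
    if pvals:
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for (i, j), qv in zip(pairs, qvals):
            q.iloc[i, j] = q.iloc[j, i] = qv
    significant = (q < alpha).fillna(False)
    np.fill_diagonal(significant.values, False)
    return CoCorrelationResult(cols, rho, pmat, q, significant, alpha)


def top_abundant_taxa(table: AbsoluteAbundanceTable, k: int = 20) -> list[str]:
    """Taxa ranked by mean absolute load (descending, ties lexicographic)."""
    if k > len(table.taxon_ids):
        raise ValidationError(f"k={k} exceeds taxon count {len(table.taxon_ids)}")
    means = table.loads.mean(axis=0)
    order = sorted(means.index, key=lambda t: (-means[t], t))
    return order[:k]


def cocorrelation_matrix(
    table: AbsoluteAbundanceTable,
    taxa: Sequence[str],
    include_total_load: bool = True,
    alpha: float = 0.1,
) -> CoCorrelationResult:
    """Spearman/BH co-correlation of taxon loads, optionally with the total
    microbial load as a pseudo-variable."""
    data = table.loads[list(taxa)].copy()
    if include_total_load:
        data[TOTAL_LOAD_VARIABLE] = table.total_loads
    return spearman_bh(data, alpha=alpha)


Motif = Literal["total_load_coupled", "pair_coupled", "mutually_exclusive", "unclassified"]


def classify_motifs(
    result: CoCorrelationResult, exclusivity_threshold: float = 0.25
) -> dict[str, Motif]:
    """Assign each taxon a co-correlation motif.

    mutually_exclusive: significant correlations with fewer than
    ``exclusivity_threshold`` of the other taxa; pair_coupled: some
    taxon-taxon correlation is significant and exceeds the taxon's
    correlation with total load; total_load_coupled: a significant positive
    correlation with total load that is also the taxon's largest.
    Precedence: mutually_exclusive > pair_coupled > total_load_coupled.
    """
    if TOTAL_LOAD_VARIABLE not in result.variables:
        raise ValidationError("total-load column required for motif classification")
    taxa = [v for v in result.variables if v != TOTAL_LOAD_VARIABLE]
    out: dict[str, Motif] = {}
    for t in taxa:
        others = [u for u in taxa if u != t]
        sig_others = [u for u in others if result.significant.loc[t, u]]
        rho_total = result.rho.loc[t, TOTAL_LOAD_VARIABLE]
        if not np.isfinite(rho_total):
            rho_total = -np.inf
        sig_total = bool(result.significant.loc[t, TOTAL_LOAD_VARIABLE])
        # the total-load link counts as a significant correlation, so a pure
        # total-load tracker is never called mutually exclusive
        n_sig = len(sig_others) + (1 if sig_total else 0)
        if others and n_sig < exclusivity_threshold * len(others):
            out[t] = "mutually_exclusive"
            continue
        best_sig_partner = max((result.rho.loc[t, u] for u in sig_others), default=-np.inf)
        best_partner = max(
            (result.rho.loc[t, u] for u in others if np.isfinite(result.rho.loc[t, u])),
            default=-np.inf,
        )
        if best_sig_partner > rho_total:
            out[t] = "pair_coupled"
            continue
        if sig_total and rho_total > 0 and rho_total >= best_partner:
            out[t] = "total_load_coupled"
            continue
        out[t] = "unclassified"
    return out


def disruptor_rank(table: AbsoluteAbundanceTable, top_k: int = 16) -> DisruptorReport:
    """Rank taxa by max(load) - mean(load) on linear copies/mL."""
    if not table.sample_ids:
        raise ValidationError("empty table")
    loads = table.loads
    scores = loads.max(axis=0) - loads.mean(axis=0)
    order = sorted(scores.index, key=lambda t: (-scores[t], t))
    ranked = scores.loc[order]
    return DisruptorReport(scores=ranked, top_k=order[: min(top_k, len(order))])


def signature_cluster(
    report: DisruptorReport,
    table: AbsoluteAbundanceTable,
    annotations: dict[str, TaxonAnnotation],
    exclusions: Sequence[str] = ("Lactobacillus",),
    n_signatures: int = 2,
) -> DisruptorReport:
    """Split the top-k taxa into two signatures by average-linkage
    hierarchical clustering on 1 - Spearman rho of their loads.

    The candidate disruptor signature is the cluster containing the
    highest-scored Enterobacteriaceae-family taxon (fallback: the cluster
    with the larger mean score); the final set removes the exclusion list.
    """
    taxa = report.top_k
    if len(taxa) < n_signatures:
        raise ValidationError("fewer top taxa than requested signatures")
    loads = table.loads[list(taxa)]
    rho = loads.corr(method="spearman").to_numpy()
    rho = np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(rho, 1.0)
    dist = 1.0 - rho
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=n_signatures, criterion="maxclust")
    if len(set(labels)) < n_signatures:
        raise ValidationError("could not form two clusters")
    signatures = dict(zip(taxa, (int(l) for l in labels)))

    entero = [
        t
        for t in taxa
        if annotations.get(t) and annotations[t].family == "Enterobacteriaceae"
    ]
    if entero:
        anchor = max(entero, key=lambda t: report.scores[t])
        candidate_label = signatures[anchor]
    else:
        mean_scores = {
            lab: np.mean([report.scores[t] for t in taxa if signatures[t] == lab])
            for lab in set(signatures.values())
        }
        candidate_label = max(mean_scores, key=mean_scores.get)
    # renumber so the candidate signature is 1
    signatures = {t: (1 if lab == candidate_label else 2) for t, lab in signatures.items()}
    candidates = [t for t in taxa if signatures[t] == 1]
    applied = [e for e in exclusions if e in candidates]
    final = [t for t in candidates if t not in set(exclusions)]
    return DisruptorReport(
        scores=report.scores,
        top_k=list(taxa),
        signatures=signatures,
        candidate_set=candidates,
        exclusions=applied,
        final_set=final,
    )


def differential_volcano(
    abundance: pd.DataFrame,
    group_labels: pd.Series,
    pseudo: float = 1.0,
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Per-taxon two-group comparison: effect = log10 ratio of group means
    (with a pseudo value for zero means), p from Kruskal-Wallis, q from BH.

    ``abundance`` may hold absolute loads (pseudo in copies/mL) or relative
    abundances (use a correspondingly small pseudo).
    """
    groups = group_labels.dropna()
    levels = sorted(groups.unique(), key=str)
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 groups, got {levels}")
    idx_a = groups.index[groups == levels[1]]  # "positive" group (e.g. True/SIBO)
    idx_b = groups.index[groups == levels[0]]
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValidationError("both groups must be nonempty")
    rows = []
    for taxon in abundance.columns:
        a = abundance.loc[idx_a, taxon].astype(float)
        b = abundance.loc[idx_b, taxon].astype(float)
        if a.sum() == 0 and b.sum() == 0:
            continue
        effect = float(np.log10((a.mean() + pseudo) / (b.mean() + pseudo)))
        if np.allclose(a, a.iloc[0]) and np.allclose(b, b.iloc[0]) and a.iloc[0] == b.iloc[0]:
            p = 1.0
        else:
            try:
                _, p = stats.kruskal(a, b)
            except ValueError:  # all values identical
                p = 1.0
        rows.append({"taxon": taxon, "effect_log10_ratio": effect, "p": float(p)})
    result = pd.DataFrame(rows).set_index("taxon")
    if len(result):
        _, qvals, _, _ = multipletests(result["p"], method="fdr_bh")
        result["q"] = qvals
        result["significant"] = result["q"] < alpha
    else:
        result["q"] = []
        result["significant"] = []
    return result
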