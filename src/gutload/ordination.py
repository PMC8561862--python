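"""Log pseudo-count transform, PCA, ranked loadings, and axis-metadata
correlations.

The transform adds a pseudo-count of 0.1 reads to every taxon before
forming relative abundances and multiplying by the sample's total load:
X[s, t] = log10(((count[s, t] + 0.1) / depth[s]) * load[s]).  Columns are
mean-centered (not variance-scaled) before PCA.  Component signs follow a
fixed convention: the largest-|loading| taxon on each axis is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .datamodel import AbsoluteAbundanceTable, FeatureTable, ValidationError

PSEUDO_COUNT = 0.1


@dataclass
class OrdinationResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # taxa x components, unit-norm eigenvectors
    explained_variance_ratio: pd.Series
    mean_: pd.Series  # column means removed before the SVD

    @property
    def components(self) -> list[str]:
        return list(self.scores.columns)

    def scaled_loadings(self, component: str) -> pd.Series:
        """Eigenvector scaled by the maximum |score| on that axis."""
        scale = self.scores[component].abs().max()
        return self.loadings[component] * scale

    def reconstruct(self) -> pd.DataFrame:
        x = self.scores.to_numpy() @ self.loadings.to_numpy().T + self.mean_.to_numpy()
        return pd.DataFrame(x, index=self.scores.index, columns=self.loadings.index)


def log_pseudo_transform(
    counts: FeatureTable, loads: pd.Series, pseudo_count: float = PSEUDO_COUNT
) -> pd.DataFrame:
    """X[s, t] = log10(((count + pseudo) / depth) * load); zero-load samples
    are dropped (they carry no quantitative information)."""
    depths = counts.depths
    if (depths == 0).any():
        raise ValidationError("zero-depth samples cannot be transformed")
    loads = loads.loc[counts.sample_ids].astype(float)
    keep = loads.index[loads > 0]
    if len(keep) < len(loads):
        counts = counts.subset_samples(keep)
        loads = loads.loc[keep]
        depths = counts.depths
    rel = counts.counts.add(pseudo_count).div(depths, axis=0)
    return np.log10(rel.mul(loads, axis=0))


def pca(x: pd.DataFrame, n_components: int | None = 10) -> OrdinationResult:
    """Principal axes of the column-centered matrix, deterministic up to the
    fixed sign convention."""
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValidationError("need at least 2 samples and 2 taxa")
    values = x.to_numpy(dtype=float)
    if np.allclose(values, values.mean(axis=0), atol=1e-12):
        raise ValidationError("matrix has rank 0 after centering")
    max_rank = min(x.shape[0] - 1, x.shape[1])
    k = max_rank if n_components is None else min(n_components, max_rank)
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(values)
    loadings = model.components_.T  # taxa x components
    # sign convention: largest-|loading| taxon positive on each axis
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    names = [f"PC{i + 1}" for i in range(k)]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=x.index, columns=names),
        loadings=pd.DataFrame(loadings, index=x.columns, columns=names),
        explained_variance_ratio=pd.Series(model.explained_variance_ratio_, index=names),
        mean_=pd.Series(model.mean_, index=x.columns),
    )


def ranked_loadings(result: OrdinationResult, component: str, top_n: int = 5) -> pd.DataFrame:
    """Taxa ordered by scaled loading on ``component``; the top ``top_n``
    per direction are annotated."""
    if component not in result.components:
        raise ValidationError(f"unknown component {component!r}")
    scaled = result.scaled_loadings(component).sort_values(ascending=False)
    out = pd.DataFrame({"scaled_loading": scaled})
    out["direction"] = np.where(out["scaled_loading"] >= 0, "positive", "negative")
    ranks = np.arange(1, len(out) + 1)
    out["top_positive"] = ranks <= top_n
    out["top_negative"] = ranks > len(out) - top_n
    return out


def axis_metadata_correlation(
    scores: pd.Series, metadata: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Spearman correlation of one ordination axis against each metadata
    column, BH-corrected within this variable family."""
    rows = []
    for col in metadata.columns:
        paired = pd.DataFrame({"axis": scores, "var": metadata[col]}).dropna()
        if len(paired) < 3 or paired["var"].nunique() <= 1:
            rows.append({"variable": col, "rho": np.nan, "p": np.nan, "n": len(paired)})
            continue
        rho, p = stats.spearmanr(paired["axis"], paired["var"])
        rows.append({"variable": col, "rho": float(rho), "p": float(p), "n": len(paired)})
    out = pd.DataFrame(rows).set_index("variable")
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        _, qvals, _, _ = multipletests(out.loc[ok, "p"], method="fdr_bh")
        out.loc[ok, "q"] = qvals
    out["significant"] = out["q"] < alpha
    return out
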