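"""Climate heterogeneity (turnover) per time slice from four climate variables.

Four variables — annual average minimum temperature, annual average maximum
temperature, annual actual evapotranspiration (AET), and total annual
precipitation — are standardized and reduced by PCA; climate turnover for a
time slice is the mean pairwise Euclidean distance among its samples in
(PC1, PC2) score space.  One pooled PCA across all slices is the default so
scores (and hence turnover) are comparable between slices; a per-slice mode
exists for sensitivity checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

CLIMATE_VARS = ("tmin", "tmax", "aet", "precip")


@dataclass
class ClimatePCA:
    """Scores (PC1, PC2 per sample), loadings, and variance fractions."""

    scores: pd.DataFrame  # columns: PC1, PC2 (+ carry-through id/slice columns)
    loadings: np.ndarray  # (4 components, 4 variables)
    variance_fractions: np.ndarray  # length 4, sums to 1


def climate_pca(samples: pd.DataFrame, pooled: bool = True) -> ClimatePCA:
    """Correlation-matrix PCA of the four standardized climate variables.

    ``samples`` needs columns ``tmin, tmax, aet, precip`` and, for turnover,
    ``slice`` (time-slice label).  With ``pooled=False`` a separate PCA is run
    per slice (scores are then not comparable across slices).
    """
    for v in CLIMATE_VARS:
        if v not in samples.columns:
            raise ValueError(f"missing climate variable column {v!r}")
        if np.asarray(samples[v], dtype=float).std() == 0:
            raise ValueError(f"climate variable {v!r} has zero variance")
    if len(samples) < 3:
        raise ValueError("need at least 3 climate samples")

    def _fit(df: pd.DataFrame):
        X = df[list(CLIMATE_VARS)].to_numpy(dtype=float)
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        pca = PCA(n_components=4)
        scores = pca.fit_transform(Z)
        return scores, pca.components_, pca.explained_variance_ratio_

    if pooled or "slice" not in samples.columns:
        scores, loadings, var = _fit(samples)
    else:
        parts = []
        loadings = var = None
        for _, df in samples.groupby("slice", sort=False):
            s, loadings, var = _fit(df)
            parts.append(pd.DataFrame(s[:, :2], index=df.index, columns=["PC1", "PC2"]))
        joined = pd.concat(parts).sort_index()
        out = samples.copy()
        out[["PC1", "PC2"]] = joined
        return ClimatePCA(scores=out, loadings=loadings, variance_fractions=var)

    out = samples.copy()
    out["PC1"] = scores[:, 0]
    out["PC2"] = scores[:, 1]
    return ClimatePCA(scores=out, loadings=loadings, variance_fractions=var)


@dataclass(frozen=True)
class ClimateTurnover:
    """Mean pairwise climate dissimilarity of one time slice."""

    slice_label: object
    mean_dissimilarity: float
    sem: float
    n_samples: int


def climate_turnover(scores: pd.DataFrame, slice_column: str = "slice") -> list:
    """Mean pairwise Euclidean distance in (PC1, PC2) per time slice, +/- SEM."""
    out = []
    for lab, df in scores.groupby(slice_column, sort=False):
        if len(df) < 2:
            warnings.warn(f"slice {lab!r} has a single sample; turnover undefined")
            out.append(ClimateTurnover(lab, float("nan"), float("nan"), len(df)))
            continue
        d = pdist(df[["PC1", "PC2"]].to_numpy(dtype=float))
        sem = float(d.std(ddof=1) / np.sqrt(d.size)) if d.size > 1 else 0.0
        out.append(ClimateTurnover(lab, float(d.mean()), sem, len(df)))
    return out


def average_slices_to_bins(turnovers: list, slice_ages: dict, bin_config) -> pd.DataFrame:
    """Unweighted mean of slice turnovers within each time bin.

    ``slice_ages`` maps slice label -> age in years BP (or None for modern).
    Slices outside the binning scheme are ignored; empty bins get NaN.
    """
    per_bin: dict = {lab: [] for lab in bin_config.labels}
    for t in turnovers:
        age = slice_ages[t.slice_label]
        lab = bin_config.assign(age, modern=age is None)
        if lab is not None and np.isfinite(t.mean_dissimilarity):
            per_bin[lab].append(t.mean_dissimilarity)
    rows = []
    for lab in bin_config.labels:
        vals = per_bin[lab]
        rows.append(
            {
                "bin": lab,
                "mean_turnover": float(np.mean(vals)) if vals else float("nan"),
                "n_slices": len(vals),
            }
        )
    return pd.DataFrame(rows)
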