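"""Latent-trait utilities: PCA projection, pairwise-distance separability
and the descriptor-table preprocessing used before model fitting.

Descriptor tables hold one row per spike and one named numeric column per
descriptor. Principal components of the centered/scaled table act as latent
phenotypes; the mean pairwise Euclidean distance between spikes in PC space
quantifies how well a descriptor set separates samples.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .errors import DegenerateInputError, ValidationError

NZV_VARIANCE = 1e-8
CORR_CUTOFF = 0.85
CURVATURE_SD_CUTOFF = 5.5


@dataclass
class PCAResult:
    """Top-k principal component scores of a descriptor table.

    ``scores`` are min-max standardized to [0, 1] per component (the
    plotting convention); ``raw_scores`` are the unscaled projections of
    the centered/scaled data, on which distances are meaningful.
    """

    scores: np.ndarray
    raw_scores: np.ndarray
    variance_ratio: np.ndarray


def _numeric_matrix(table: pd.DataFrame) -> np.ndarray:
    x = np.asarray(table, dtype=float)
    if np.isnan(x).any():
        raise ValidationError("descriptor table contains missing values")
    return x


def pca_project(table: pd.DataFrame, k: int = 2) -> PCAResult:
    """Project spikes onto the top-k principal components.

    Columns are centered and scaled to unit (population) variance first.
    Scores are additionally min-max standardized to [0, 1] per component
    for plotting; variance-explained fractions are reported.
    """
    x = _numeric_matrix(table)
    if x.shape[0] < 2 or x.shape[1] < k:
        raise ValidationError(f"need >= 2 rows and >= {k} columns")
    sd = x.std(axis=0)
    if (sd == 0).all():
        raise DegenerateInputError("constant descriptor table")
    keep = sd > 0
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    if z.shape[1] < k:
        raise DegenerateInputError("fewer than k varying columns")
    pca = PCA(n_components=k, svd_solver="full")
    raw = pca.fit_transform(z)
    span = raw.max(axis=0) - raw.min(axis=0)
    span[span == 0] = 1.0
    scaled = (raw - raw.min(axis=0)) / span
    return PCAResult(scores=scaled, raw_scores=raw,
                     variance_ratio=pca.explained_variance_ratio_)


def mean_pairwise_ed(scores: np.ndarray, subset=None):
    """Mean and SD of all pairwise Euclidean distances between rows."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    if subset is not None:
        scores = scores[np.asarray(subset)]
    if scores.shape[0] < 2:
        raise ValidationError("need >= 2 rows for pairwise distances")
    d = pdist(scores)
    return float(d.mean()), float(d.std())


def feature_filter(table: pd.DataFrame, curvature: str | None = None):
    """Preprocess a descriptor table for model fitting.

    Steps, in order: drop rows whose ``curvature`` column exceeds
    mean + 5.5 sd (storage-deformed spikes); drop near-zero-variance
    columns; greedily drop one member of every column pair with
    |Pearson r| > 0.85 (the one with the larger mean absolute correlation
    to all other columns); center and scale the survivors. Idempotent.

    Returns ``(filtered_table, removal_log)``.
    """
    df = table.copy()
    log: dict = {"rows_removed": [], "near_zero_variance": [],
                 "correlated": []}

    if curvature is not None:
        if curvature not in df.columns:
            raise ValidationError(f"no curvature column {curvature!r}")
        cv = df[curvature].astype(float)
        cutoff = cv.mean() + CURVATURE_SD_CUTOFF * cv.std(ddof=0)
        drop_rows = df.index[cv > cutoff]
        log["rows_removed"] = list(drop_rows)
        df = df.drop(index=drop_rows)

    x = _numeric_matrix(df)
    variances = x.var(axis=0)
    nunique = df.nunique(axis=0).to_numpy()
    nzv = (variances < NZV_VARIANCE) | (nunique < 2)
    log["near_zero_variance"] = list(df.columns[nzv])
    df = df.loc[:, ~nzv]
    if df.shape[1] == 0:
        raise DegenerateInputError("all columns removed by variance filter")

    while df.shape[1] > 1:
        corr = df.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= CORR_CUTOFF:
            break
        mean_i = corr[i].mean()
        mean_j = corr[j].mean()
        drop = df.columns[i] if mean_i >= mean_j else df.columns[j]
        log["correlated"].append(str(drop))
        df = df.drop(columns=[drop])

    z = (df - df.mean()) / df.std(ddof=0)
    return z, log
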