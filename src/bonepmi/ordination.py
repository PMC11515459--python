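"""Unsupervised ordination of abundance tables.

Standardized PCA with explained-variance ratios and variable loadings,
K-means clustering on the principal components, and multiple
correspondence analysis (MCA) of protein presence/absence.

Missing intensities are zero-filled before standardization: in
label-free quantification an unidentified protein is naturally read as
"below detection", and zero is the conventional stand-in.  The
imputation rule is a named option so alternatives stay visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = ["OrdinationResult", "standardize", "pca", "kmeans_components", "mca"]


@dataclass
class OrdinationResult:
    scores: pd.DataFrame                  # samples x components
    loadings: pd.DataFrame                # variables x components
    explained_variance_ratio: np.ndarray  # per-component fractions
    cluster_labels: pd.Series | None = None
    degenerate: bool = False
    dropped: list[str] = field(default_factory=list)


def standardize(table: pd.DataFrame, imputation: str = "zero_fill",
                log10: bool = False) -> pd.DataFrame:
    """Impute missing entries, optionally log10-transform, then z-score
    each protein column (population standard deviation).

    Constant columns carry no ordination information and are dropped
    with a warning; an all-constant table is an error.
    """
    if table.empty:
        raise ValueError("empty abundance table")
    if imputation != "zero_fill":
        raise ValueError(f"unknown imputation rule: {imputation!r}")
    filled = table.fillna(0.0).astype(float)
    if log10:
        filled = np.log10(filled + 1.0)
    sd = filled.std(axis=0, ddof=0)
    constant = sd.index[sd == 0].tolist()
    if len(constant) == len(filled.columns):
        raise ValueError("all columns are constant; nothing to standardize")
    if constant:
        warnings.warn(f"dropping constant columns: {constant}")
        filled = filled.drop(columns=constant)
        sd = sd.drop(index=constant)
    return (filled - filled.mean(axis=0)) / sd


def pca(z: pd.DataFrame, n_components: int) -> OrdinationResult:
    """Principal component analysis of an already-standardized matrix."""
    max_rank = min(z.shape[0] - 1, z.shape[1])
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds min(rows-1, cols)={max_rank}")
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(z.to_numpy(dtype=float))
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=z.index, columns=comp_names),
        loadings=pd.DataFrame(model.components_.T, index=z.columns,
                              columns=comp_names),
        explained_variance_ratio=model.explained_variance_ratio_,
    )


def kmeans_components(scores: pd.DataFrame, k: int, seed: int,
                      n_init: int = 10) -> pd.Series:
    """K-means (Lloyd + k-means++ seeding, best of ``n_init`` restarts)
    on ordination scores; deterministic given ``seed``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(scores):
        raise ValueError(f"k={k} exceeds the {len(scores)} samples")
    model = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = model.fit_predict(scores.to_numpy(dtype=float))
    return pd.Series(labels, index=scores.index, name="cluster")


def mca(presence: pd.DataFrame, n_components: int) -> OrdinationResult:
    """Multiple correspondence analysis of a binary presence/absence
    matrix, via the complete disjunctive (indicator) table.

    Each protein contributes two indicator columns (present/absent);
    proteins observed in only one state everywhere are uninformative and
    dropped with a warning.  Returns sample coordinates and
    per-dimension inertia fractions from the SVD of the standardized
    residual matrix.
    """
    if presence.empty:
        raise ValueError("empty presence/absence matrix")
    presence = presence.astype(float)
    if not presence.isin([0.0, 1.0]).all().all():
        raise ValueError("presence matrix must be binary")
    varying = presence.columns[presence.nunique(axis=0) > 1].tolist()
    dropped = [c for c in presence.columns if c not in varying]
    if dropped:
        warnings.warn(f"dropping single-state proteins: {dropped}")
    if not varying:
        # every protein constant: zero-inertia, degenerate ordination
        zeros = np.zeros((len(presence), n_components))
        return OrdinationResult(
            scores=pd.DataFrame(zeros, index=presence.index,
                                columns=[f"Dim{i+1}" for i in range(n_components)]),
            loadings=pd.DataFrame(columns=[f"Dim{i+1}" for i in range(n_components)]),
            explained_variance_ratio=np.zeros(n_components),
            degenerate=True, dropped=dropped)
    presence = presence[varying]

    # complete disjunctive table: one column per (protein, state)
    indicator = pd.concat(
        [presence.rename(columns=lambda c: f"{c}=1"),
         (1.0 - presence).rename(columns=lambda c: f"{c}=0")], axis=1)
    Z = indicator.to_numpy(dtype=float)
    P = Z / Z.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    inertia = sv ** 2
    total = inertia.sum()
    degenerate = total < 1e-12
    ratios = inertia / total if not degenerate else np.zeros_like(inertia)

    n_components = min(n_components, len(sv))
    dims = [f"Dim{i + 1}" for i in range(n_components)]
    row_coords = (U[:, :n_components] * sv[:n_components]) / np.sqrt(r)[:, None]
    col_coords = (Vt.T[:, :n_components] * sv[:n_components]) / np.sqrt(c)[:, None]
    return OrdinationResult(
        scores=pd.DataFrame(row_coords, index=presence.index, columns=dims),
        loadings=pd.DataFrame(col_coords, index=indicator.columns, columns=dims),
        explained_variance_ratio=ratios[:n_components],
        degenerate=degenerate,
        dropped=dropped,
    )
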