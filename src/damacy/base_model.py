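"""Stage 2: the cell-level PCA base model.

A PCA over all preprocessed cells describes the dominant directions of
marker co-expression. Fitted naively, the loadings would be dominated
by whichever individuals contributed the most cells, so each
individual's block of X_cs is first divided by its own cell count N_ig;
the loadings are the leading right singular vectors of that
cell-count-normalized stack. Scores for any sample — training or
held-out — are then plain projections T = X_cs P, putting every cell of
every individual in one common low-dimensional space.

Scores and loadings together form a biplot: each dot is a cell, each
vector a marker, and the vector directions explain what the cell cloud's
shape means in terms of marker expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MFCDataset

__all__ = [
    "BaseModel",
    "fit_base_model",
    "project_cells",
    "explained_variance_per_individual",
    "export_biplot_data",
]


@dataclass
class BaseModel:
    """Fitted cell-level PCA.

    ``loadings`` is (J x K_base) with orthonormal columns ordered by
    singular value; the sign of each component is fixed so that its
    largest-magnitude loading element is positive, making repeated fits
    reproducible. ``explained_variance_total`` are per-component
    fractions of the normalized-stack variance.
    """

    loadings: np.ndarray
    k_base: int
    singular_values: np.ndarray
    explained_variance_total: np.ndarray
    marker_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(self.k_base), atol=1e-8):
            raise ValueError("loadings must be orthonormal")


def _normalized_stack(dataset: MFCDataset) -> np.ndarray:
    """X_csn: each individual's block divided by its cell count N_ig."""
    weights = 1.0 / dataset.cell_counts.astype(np.float64)
    return dataset.values * weights[dataset.cell_to_individual, None]


def fit_base_model(dataset: MFCDataset, k_base: int = 2) -> BaseModel:
    """Fit the cell-count-normalized PCA on preprocessed training cells.

    Parameters
    ----------
    dataset : MFCDataset
        Preprocessed cells (X_cs); centring has already happened in
        Stage 1, so the decomposition is about the origin.
    k_base : int
        Number of components to keep (``1 <= k_base <= J``).
    """
    j = dataset.n_markers
    if not 1 <= k_base <= j:
        raise ValueError(f"k_base must be in [1, {j}], got {k_base}")
    if dataset.n_individuals < 2:
        raise ValueError("base model requires at least 2 individuals")
    x_csn = _normalized_stack(dataset)
    # SVD of the stacked normalized matrix: deterministic and full-rank safe.
    _, sing, vt = np.linalg.svd(x_csn, full_matrices=False)
    loadings = vt[:k_base].T.copy()
    for k in range(k_base):
        if loadings[np.argmax(np.abs(loadings[:, k])), k] < 0:
            loadings[:, k] = -loadings[:, k]
    total_ss = float(np.sum(sing**2))
    frac = (sing[:k_base] ** 2) / total_ss if total_ss > 0 else np.zeros(k_base)
    return BaseModel(
        loadings=loadings,
        k_base=k_base,
        singular_values=sing[:k_base].copy(),
        explained_variance_total=frac,
        marker_names=list(dataset.marker_names),
    )


def project_cells(dataset: MFCDataset, model: BaseModel) -> np.ndarray:
    """Scores T_base = X_cs P for training or held-out cells alike."""
    if dataset.n_markers != model.loadings.shape[0]:
        raise ValueError(
            f"panel mismatch: data has {dataset.n_markers} markers, "
            f"model expects {model.loadings.shape[0]}"
        )
    if model.marker_names and list(dataset.marker_names) != list(model.marker_names):
        raise ValueError("marker panel mismatch between data and fitted base model")
    return dataset.values @ model.loadings


def explained_variance_per_individual(
    dataset: MFCDataset, model: BaseModel
) -> np.ndarray:
    """Per-individual, per-component explained-variance fractions (I x K).

    For individual i and component k: variance of the individual's
    scores on k divided by the trace of the individual's own centred
    covariance. With K_base = J the fractions of an individual sum to 1
    exactly (orthonormal basis); single-cell individuals have zero
    variance and return zero fractions.
    """
    scores = project_cells(dataset, model)
    out = np.zeros((dataset.n_individuals, model.k_base))
    for i in range(dataset.n_individuals):
        rows = dataset.cell_to_individual == i
        block = dataset.values[rows]
        total = float(block.var(axis=0, ddof=0).sum())
        if total == 0.0:
            continue  # 1-cell (or constant) individual: flagged as all-zero row
        out[i] = scores[rows].var(axis=0, ddof=0) / total
    return out


def export_biplot_data(
    dataset: MFCDataset,
    model: BaseModel,
    individual: int,
    pc_pair: tuple[int, int] = (0, 1),
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Scores of one individual on a PC pair plus co-plottable loadings.

    Returns (scores table, loadings table, loading scale factor). The
    loading vectors are multiplied by a positive factor so they span the
    same radius as the scores, the usual biplot convention; the factor
    is returned so the plot can state it.
    """
    if model.k_base < 2:
        raise ValueError("biplot requires k_base >= 2")
    a, b = pc_pair
    if not (0 <= a < model.k_base and 0 <= b < model.k_base and a != b):
        raise ValueError(f"pc_pair {pc_pair} out of range for k_base={model.k_base}")
    if not 0 <= individual < dataset.n_individuals:
        raise ValueError(f"no individual with index {individual}")
    scores = project_cells(dataset, model)[dataset.cell_to_individual == individual]
    if scores.shape[0] == 0:
        raise ValueError("individual has no cells")
    score_df = pd.DataFrame(
        {"pc_x": scores[:, a], "pc_y": scores[:, b]},
    )
    load = model.loadings[:, [a, b]]
    score_radius = float(np.max(np.hypot(scores[:, a], scores[:, b])))
    load_radius = float(np.max(np.hypot(load[:, 0], load[:, 1])))
    scale = score_radius / load_radius if load_radius > 0 and score_radius > 0 else 1.0
    load_df = pd.DataFrame(
        {
            "marker": model.marker_names or [f"m{j}" for j in range(load.shape[0])],
            "pc_x": load[:, 0] * scale,
            "pc_y": load[:, 1] * scale,
        }
    )
    return score_df, load_df, scale
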