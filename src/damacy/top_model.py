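"""Stage 3: OPLS-DA on vectorized histograms and the leukocyte map.

Each sample's smoothed histogram is flattened into a row of the design
matrix C (samples x F^K_base bins). Bins whose across-sample variance
is below a threshold carry no between-sample information and are
dropped (the surviving column mask is part of the fitted model and is
re-applied to held-out samples).

The class contrast is then modelled by orthogonal projections to latent
structures discriminant analysis (OPLS-DA): an orthogonal-signal-
correction (OSC) step estimates ``n_ortho`` components of between-
sample histogram variation uncorrelated with the class vector y (coded
control = -1, challenged = +1, centred) and deflates them from C; one
predictive PLS component is then fitted on the deflated matrix. With
``n_ortho = 0`` the model reduces exactly to single-component PLS-DA.

The unit-norm predictive weight vector w_top says, per bin, whether
cells falling there push a sample's score towards the challenged (+) or
the control (-) side. For a 2-component base model, refolding w_top
onto the F x F grid gives the leukocyte map: the picture of which cell
regions are over- or under-represented in either group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .histogram import BinGrid, SampleHistogram

__all__ = [
    "HistogramDesignMatrix",
    "TopModel",
    "LeukocyteMap",
    "DegenerateDesignError",
    "vectorize_histograms",
    "refold_vector",
    "filter_low_variance_bins",
    "fit_oplsda",
    "predict_scores",
    "refold_weights",
]


class DegenerateDesignError(ValueError):
    """The variance filter removed every bin."""


@dataclass
class HistogramDesignMatrix:
    """Vectorized histograms plus the retained-bin mask.

    ``matrix`` holds the masked columns only (n_samples x F*);
    ``bin_mask`` is the boolean vector over all F^K bins marking which
    columns were retained. ``unfold_order`` is the numpy ravel order —
    'C' (row-major): the first base component is the slowest axis.
    """

    matrix: np.ndarray
    bin_mask: np.ndarray
    grid_shape: tuple[int, ...]
    unfold_order: str = "C"
    individual_ids: list[str] = field(default_factory=list)


def vectorize_histograms(histograms: list[SampleHistogram]) -> HistogramDesignMatrix:
    """Stack flattened histograms into the design matrix C (all bins kept)."""
    if not histograms:
        raise ValueError("no histograms given")
    grid = histograms[0].grid
    shape = histograms[0].values.shape
    rows = []
    for h in histograms:
        if h.values.shape != shape or (grid is not None and h.grid != grid):
            raise ValueError("all histograms must share one grid")
        rows.append(h.values.ravel(order="C"))
    return HistogramDesignMatrix(
        matrix=np.vstack(rows),
        bin_mask=np.ones(int(np.prod(shape)), dtype=bool),
        grid_shape=shape,
        individual_ids=[h.individual_id for h in histograms],
    )


def refold_vector(
    vector: np.ndarray, bin_mask: np.ndarray, grid_shape: tuple[int, ...]
) -> np.ndarray:
    """Scatter a masked-space vector back onto the full grid (zeros elsewhere)."""
    full = np.zeros(int(np.prod(grid_shape)))
    full[bin_mask] = vector
    return full.reshape(grid_shape, order="C")


def filter_low_variance_bins(
    design: HistogramDesignMatrix, threshold: float = 1e-6
) -> HistogramDesignMatrix:
    """Drop bins whose across-sample variance is below ``threshold``.

    Near-constant bins contribute nothing to the between-group contrast;
    the mask is computed on training samples only and stored for
    held-out prediction.
    """
    c = design.matrix
    if c.shape[0] < 2:
        raise ValueError("variance filter needs at least 2 samples")
    variances = c.var(axis=0, ddof=0)
    keep_local = variances >= threshold
    if not keep_local.any():
        raise DegenerateDesignError(
            f"all {c.shape[1]} bins have across-sample variance < {threshold}"
        )
    new_mask = design.bin_mask.copy()
    new_mask[np.nonzero(design.bin_mask)[0][~keep_local]] = False
    return HistogramDesignMatrix(
        matrix=c[:, keep_local],
        bin_mask=new_mask,
        grid_shape=design.grid_shape,
        unfold_order=design.unfold_order,
        individual_ids=list(design.individual_ids),
    )


@dataclass
class TopModel:
    """Fitted OPLS-DA: C* = t_top p_top^T + T_o P_o^T + E."""

    w_top: np.ndarray  # predictive weights, unit norm, length F*
    p_top: np.ndarray  # predictive loading, length F*
    t_top: np.ndarray  # predictive scores, length n_samples
    w_ortho: np.ndarray  # (F* x n_ortho) orthogonal weights
    p_ortho: np.ndarray  # (F* x n_ortho) orthogonal loadings
    t_ortho: np.ndarray  # (n_samples x n_ortho) orthogonal scores
    column_center: np.ndarray  # per-bin centring vector of C
    bin_mask: np.ndarray
    grid_shape: tuple[int, ...]
    y: np.ndarray  # +/-1 coded class vector used in the fit
    threshold: float = 0.0

    @property
    def n_ortho(self) -> int:
        return self.w_ortho.shape[1]


def fit_oplsda(design: HistogramDesignMatrix, y: np.ndarray, n_ortho: int = 1) -> TopModel:
    """Fit OSC-filtered single-predictive-component PLS-DA.

    Parameters
    ----------
    design : HistogramDesignMatrix
        Masked design matrix (training samples).
    y : ndarray
        Class labels; anything with exactly two distinct values is
        accepted and coded -1 (first sorted value = control) / +1.
    n_ortho : int
        Number of y-orthogonal components to deflate before the
        predictive component. ``0`` gives plain PLS1-DA.
    """
    c = np.asarray(design.matrix, dtype=np.float64)
    n, _ = c.shape
    if n < 4:
        raise ValueError("OPLS-DA needs at least 4 samples")
    classes = np.unique(np.asarray(y))
    if classes.size != 2:
        raise ValueError(f"y must contain exactly 2 classes, got {classes.size}")
    if n_ortho < 0:
        raise ValueError("n_ortho must be >= 0")
    if n_ortho >= min(n - 1, c.shape[1]):
        raise ValueError(f"n_ortho={n_ortho} too large for a {n}-sample design")
    y_signed = np.where(np.asarray(y) == classes[0], -1.0, 1.0)

    center = c.mean(axis=0)
    xc = c - center
    yc = y_signed - y_signed.mean()

    w_os, p_os, t_os = [], [], []
    for _ in range(n_ortho):
        w = xc.T @ yc
        w /= np.linalg.norm(w)
        t = xc @ w
        p = xc.T @ t / (t @ t)
        w_o = p - (w @ p) * w  # part of the loading not explained by w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            raise np.linalg.LinAlgError(
                "orthogonal component collapsed; reduce n_ortho"
            )
        w_o /= norm
        t_o = xc @ w_o
        p_o = xc.T @ t_o / (t_o @ t_o)
        xc = xc - np.outer(t_o, p_o)
        w_os.append(w_o)
        p_os.append(p_o)
        t_os.append(t_o)

    w_top = xc.T @ yc
    norm = np.linalg.norm(w_top)
    if norm < 1e-15:
        raise np.linalg.LinAlgError("predictive weight vanished; y uncorrelated with C")
    w_top /= norm
    t_top = xc @ w_top
    p_top = xc.T @ t_top / (t_top @ t_top)

    k = len(w_os)
    f_star = c.shape[1]
    return TopModel(
        w_top=w_top,
        p_top=p_top,
        t_top=t_top,
        w_ortho=np.column_stack(w_os) if k else np.zeros((f_star, 0)),
        p_ortho=np.column_stack(p_os) if k else np.zeros((f_star, 0)),
        t_ortho=np.column_stack(t_os) if k else np.zeros((len(t_top), 0)),
        column_center=center,
        bin_mask=design.bin_mask.copy(),
        grid_shape=design.grid_shape,
        y=y_signed,
    )


def predict_scores(model: TopModel, histogram_rows: np.ndarray) -> np.ndarray:
    """Prediction scores for vectorized (full-grid) histogram rows.

    Applies the stored bin mask and column centring, removes the fitted
    orthogonal components, and projects on w_top. Positive scores
    classify as challenged, negative as control.
    """
    rows = np.atleast_2d(np.asarray(histogram_rows, dtype=np.float64))
    if rows.shape[1] == model.bin_mask.size:
        rows = rows[:, model.bin_mask]
    elif rows.shape[1] != model.w_top.size:
        raise ValueError(
            f"histogram rows must have {model.bin_mask.size} (full grid) or "
            f"{model.w_top.size} (masked) columns"
        )
    xc = rows - model.column_center
    for j in range(model.n_ortho):
        t_o = xc @ model.w_ortho[:, j]
        xc = xc - np.outer(t_o, model.p_ortho[:, j])
    return xc @ model.w_top


def predict_classes(model: TopModel, scores: np.ndarray) -> np.ndarray:
    """+1 (challenged) where score exceeds the threshold, else -1."""
    return np.where(np.asarray(scores) > model.threshold, 1, -1)


@dataclass
class LeukocyteMap:
    """Predictive weights refolded onto the 2-D score grid."""

    weights: np.ndarray  # (F x F); zeros at masked-out bins
    grid: BinGrid | None = None
    loadings: np.ndarray | None = None  # (J x 2) base loadings for overlay
    marker_names: list[str] = field(default_factory=list)


def refold_weights(
    model: TopModel,
    grid: BinGrid | None = None,
    loadings: np.ndarray | None = None,
    marker_names: list[str] | None = None,
) -> LeukocyteMap:
    """Refold w_top into the F x F leukocyte map (2-D base models only).

    Axis 0 of the map is the first base component, axis 1 the second
    (matching the design matrix's row-major unfolding); transpose when
    plotting with the first component on x.
    """
    if len(model.grid_shape) != 2:
        raise ValueError(
            f"leukocyte map requires a 2-component base model, got K={len(model.grid_shape)}"
        )
    weights = refold_vector(model.w_top, model.bin_mask, model.grid_shape)
    return LeukocyteMap(
        weights=weights,
        grid=grid,
        loadings=loadings,
        marker_names=list(marker_names or []),
    )
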