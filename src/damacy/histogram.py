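"""Stage 2b: per-sample score histograms on a shared grid.

Single-cell scores cannot be compared across individuals directly —
each score belongs to one cell of one sample. Each sample's score cloud
is therefore converted into a K_base-dimensional histogram of cell
*fractions* on a bin grid shared by every sample of a study.

The grid is anchored to the pooled training scores with the extreme
0.1% trimmed: per component, bin width delta_k spans
(percentile 99.95 - percentile 0.05) / F. Counts are divided by the
sample's cell count so histograms are comparable regardless of how many
cells were acquired, and a separable Gaussian smoothing (sigma in bin
units) absorbs small biological/instrumental shifts that would
otherwise land equivalent cells in adjacent bins of different samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import MFCDataset  # noqa: F401  (typing/doc context)

__all__ = [
    "BinGrid",
    "SampleHistogram",
    "DegenerateAxisError",
    "fit_bin_grid",
    "build_histogram",
    "smooth_histogram",
]


class DegenerateAxisError(ValueError):
    """A score axis has zero trimmed range and cannot be binned."""


@dataclass(frozen=True)
class BinGrid:
    """Shared binning of score space: F bins per component.

    ``anchor`` is the per-component 0.05th percentile of the pooled
    training scores, ``delta`` the per-component bin width (Eq. range /
    F over the trimmed range). ``clip_policy='clip'`` assigns cells
    outside the trimmed range to the boundary bins so every cell counts
    and histogram mass stays exactly 1.
    """

    f_bins: int
    anchor: tuple[float, ...]
    delta: tuple[float, ...]
    clip_policy: str = "clip"

    @property
    def k(self) -> int:
        return len(self.delta)

    @property
    def shape(self) -> tuple[int, ...]:
        return (self.f_bins,) * self.k

    def edges(self, axis: int) -> np.ndarray:
        return self.anchor[axis] + self.delta[axis] * np.arange(self.f_bins + 1)

    def bin_indices(self, scores: np.ndarray) -> np.ndarray:
        """Per-cell bin index along each axis; half-open bins, clipped.

        A cell exactly on an interior edge goes to the upper bin
        (floor of the scaled coordinate); anything outside the trimmed
        range is clipped into the first/last bin.
        """
        scores = np.asarray(scores, dtype=np.float64)
        if scores.ndim != 2 or scores.shape[1] != self.k:
            raise ValueError(f"scores must be (n, {self.k})")
        rel = (scores - np.asarray(self.anchor)) / np.asarray(self.delta)
        idx = np.floor(rel).astype(np.intp)
        if self.clip_policy != "clip":
            raise NotImplementedError(f"clip_policy {self.clip_policy!r}")
        return np.clip(idx, 0, self.f_bins - 1)


@dataclass
class SampleHistogram:
    """One individual's normalized cell-density histogram H_ig."""

    values: np.ndarray  # (F,)*K array of cell fractions, sums to 1
    individual_id: str
    n_cells: int
    smoothed: bool = False
    grid: BinGrid | None = None


def fit_bin_grid(pooled_scores: np.ndarray, f_bins: int = 500) -> BinGrid:
    """Fit the shared grid from the pooled training scores of all cells.

    Per component: delta_k = (P99.95 - P0.05) / F, i.e. the bin width is
    set by the score range excluding the 0.1% most extreme values;
    percentiles use linear interpolation between order statistics.
    """
    pooled_scores = np.atleast_2d(np.asarray(pooled_scores, dtype=np.float64))
    if f_bins < 1:
        raise ValueError("f_bins must be >= 1")
    lo, hi = np.percentile(pooled_scores, [0.05, 99.95], axis=0)
    if np.any(hi <= lo):
        k = int(np.nonzero(hi <= lo)[0][0])
        raise DegenerateAxisError(f"score axis {k} has zero trimmed range")
    return BinGrid(
        f_bins=int(f_bins),
        anchor=tuple(float(v) for v in lo),
        delta=tuple(float(v) for v in (hi - lo) / f_bins),
    )


def build_histogram(
    scores: np.ndarray, grid: BinGrid, individual_id: str = ""
) -> SampleHistogram:
    """Bin one individual's scores and normalize counts to fractions."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 2 or scores.shape[1] != grid.k:
        raise ValueError(f"scores must be (n, {grid.k})")
    n = scores.shape[0]
    if n == 0:
        raise ValueError("cannot build a histogram for an empty individual")
    idx = grid.bin_indices(scores)
    flat = np.ravel_multi_index(tuple(idx.T), grid.shape)  # C order: axis 0 = PC 1
    counts = np.bincount(flat, minlength=int(np.prod(grid.shape))).reshape(grid.shape)
    return SampleHistogram(
        values=counts.astype(np.float64) / n,
        individual_id=individual_id,
        n_cells=n,
        smoothed=False,
        grid=grid,
    )


def smooth_histogram(hist: SampleHistogram, smoothing_factor: float = 5.0) -> SampleHistogram:
    """Separable Gaussian smoothing with sigma = smoothing_factor bins.

    One 1-D Gaussian pass per axis (which equals the full K-D Gaussian
    convolution, for any K_base), kernel truncated at +/- 4 sigma,
    reflective boundaries; the result is renormalized to sum 1 since
    boundary handling can leak a little mass.
    """
    if smoothing_factor < 0:
        raise ValueError("smoothing_factor must be >= 0")
    if smoothing_factor == 0:
        return SampleHistogram(
            values=hist.values.copy(),
            individual_id=hist.individual_id,
            n_cells=hist.n_cells,
            smoothed=True,
            grid=hist.grid,
        )
    smoothed = ndimage.gaussian_filter(
        hist.values, sigma=smoothing_factor, mode="reflect", truncate=4.0
    )
    smoothed = np.maximum(smoothed, 0.0)  # guard against tiny negative round-off
    total = smoothed.sum()
    if total <= 0:
        raise ValueError("smoothing annihilated the histogram")
    return SampleHistogram(
        values=smoothed / total,
        individual_id=hist.individual_id,
        n_cells=hist.n_cells,
        smoothed=True,
        grid=hist.grid,
    )
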