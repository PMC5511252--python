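"""Stage 1: log transform, multiset centring and multiset scaling.

Flow-cytometry intensities are approximately log-normal, so the matrix
is first log10-transformed. Centring and scaling must then respect the
multiset structure: statistics are averaged over *individuals*, never
pooled over cells, so that a sample contributing a million cells weighs
no more than one contributing a thousand.

Centring: per-individual column means m_ig are averaged (unweighted)
over individuals to give the overall centre m, which is subtracted from
every cell. Scaling: each marker's scale is the square root of the mean
over individuals of that individual's column variance; dividing by it
makes every sample contribute equally to the unit-variance convention.

Variants: per-individual or per-group centring/scaling, and a
median-based overall centre (per-individual medians, then the median
across individuals), useful when one dominant cell type should sit at
the origin. All statistics are fitted on training data and can be
applied unchanged to held-out samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MFCDataset

__all__ = [
    "PreprocessModel",
    "DegenerateMarkerError",
    "log_transform",
    "fit_centring",
    "apply_centring",
    "fit_scaling",
    "apply_scaling",
    "fit_preprocess",
    "apply_preprocess",
]

CENTER_MODES = ("overall", "per_individual", "per_group", "median_overall")
SCALE_MODES = ("pooled", "per_individual", "per_group", "none")

# population-variance convention (ddof=0) throughout: it makes the
# equal-weighting property under exact cell replication hold exactly
_DDOF = 0


class DegenerateMarkerError(ValueError):
    """A marker has zero variance and cannot be scaled."""


@dataclass
class PreprocessModel:
    """Fitted Stage-1 parameters, applicable to held-out samples."""

    log_shift: float = 0.0
    center_mode: str = "overall"
    scale_mode: str = "pooled"
    individual_means: np.ndarray | None = None  # (I_train x J), log10 units
    overall_center: np.ndarray | None = None  # m, (J,)
    group_centers: np.ndarray | None = None  # (G x J), per_group mode
    scale_s: np.ndarray | None = None  # s, (J,)
    group_scales: np.ndarray | None = None  # (G x J), per_group mode
    marker_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.center_mode not in CENTER_MODES:
            raise ValueError(f"center_mode must be one of {CENTER_MODES}")
        if self.scale_mode not in SCALE_MODES:
            raise ValueError(f"scale_mode must be one of {SCALE_MODES}")


def _check_finite(values: np.ndarray) -> None:
    if not np.all(np.isfinite(values)):
        raise ValueError("input contains non-finite values")


def log_transform(dataset: MFCDataset) -> tuple[MFCDataset, float]:
    """log10-transform intensities, shifting so the transform is defined.

    If the global minimum v_min is below 1, all values are shifted by
    ``1 - v_min`` first, so the minimum maps to log10(1) = 0; data that
    are already >= 1 everywhere are transformed directly. Returns the
    transformed dataset and the shift used (stored for prediction).
    """
    _check_finite(dataset.values)
    v_min = float(dataset.values.min()) if dataset.n_cells else 1.0
    shift = 1.0 - v_min if v_min < 1.0 else 0.0
    return dataset.with_values(np.log10(dataset.values + shift)), shift


def apply_log_transform(dataset: MFCDataset, shift: float) -> MFCDataset:
    """Apply a previously fitted shift + log10 to held-out data.

    Held-out values below the training shift's reach are clipped to the
    smallest representable positive argument to keep log10 defined.
    """
    _check_finite(dataset.values)
    shifted = np.maximum(dataset.values + shift, np.finfo(np.float64).tiny)
    return dataset.with_values(np.log10(shifted))


def _per_individual_stat(dataset: MFCDataset, stat: str) -> np.ndarray:
    """(I x J) matrix of per-individual column means/medians/variances."""
    out = np.empty((dataset.n_individuals, dataset.n_markers))
    for i in range(dataset.n_individuals):
        block = dataset.cells_of(i)
        if block.shape[0] == 0:
            raise ValueError(f"individual {dataset.individual_ids[i]!r} has no cells")
        if stat == "mean":
            out[i] = block.mean(axis=0)
        elif stat == "median":
            out[i] = np.median(block, axis=0)
        elif stat == "var":
            out[i] = block.var(axis=0, ddof=_DDOF)
        else:  # pragma: no cover
            raise ValueError(stat)
    return out


def fit_centring(dataset: MFCDataset, center_mode: str = "overall") -> PreprocessModel:
    """Fit the centring statistics on (log-transformed) training data.

    ``overall``: m = unweighted mean over individuals of the
    per-individual column means — NOT the grand mean over cells, so
    cell-count imbalance between samples cannot bias the centre.
    ``median_overall``: medians at both levels. ``per_group``: one
    centre per group, each the unweighted mean of its members' means.
    ``per_individual``: no pooled statistic; each sample self-centres.
    """
    model = PreprocessModel(center_mode=center_mode, marker_names=list(dataset.marker_names))
    stat = "median" if center_mode == "median_overall" else "mean"
    m_ig = _per_individual_stat(dataset, stat)
    model.individual_means = m_ig
    if center_mode == "median_overall":
        model.overall_center = np.median(m_ig, axis=0)
    else:
        model.overall_center = m_ig.mean(axis=0)
    if center_mode == "per_group":
        centers = np.empty((dataset.n_groups, dataset.n_markers))
        for g in range(1, dataset.n_groups + 1):
            members = dataset.group_labels == g
            if not members.any():
                raise ValueError(f"group {g} has no individuals")
            centers[g - 1] = m_ig[members].mean(axis=0)
        model.group_centers = centers
    return model


def apply_centring(dataset: MFCDataset, model: PreprocessModel) -> MFCDataset:
    """Subtract the fitted centre (mode-dependent) from every cell."""
    if model.overall_center is None:
        raise ValueError("centring not fitted")
    mode = model.center_mode
    if mode in ("overall", "median_overall"):
        centred = dataset.values - model.overall_center
    elif mode == "per_individual":
        stat = _per_individual_stat(dataset, "mean")
        centred = dataset.values - stat[dataset.cell_to_individual]
    elif mode == "per_group":
        if model.group_centers is None:
            raise ValueError("group centres not fitted")
        if dataset.n_groups > model.group_centers.shape[0] or dataset.group_labels.min() < 1:
            raise ValueError(
                "held-out sample has a group unknown to the fitted per_group centring"
            )
        per_ind = model.group_centers[dataset.group_labels - 1]
        centred = dataset.values - per_ind[dataset.cell_to_individual]
    else:  # pragma: no cover
        raise ValueError(mode)
    return dataset.with_values(centred)


def fit_scaling(
    centred: MFCDataset, scale_mode: str = "pooled", model: PreprocessModel | None = None
) -> PreprocessModel:
    """Fit per-marker scales on centred training data.

    ``pooled``: s_j = sqrt( mean over individuals of the individual's
    column variance ) — each sample determines the scale equally.
    """
    if model is None:
        model = PreprocessModel(scale_mode=scale_mode, marker_names=list(centred.marker_names))
    else:
        model.scale_mode = scale_mode
    if scale_mode == "none":
        model.scale_s = np.ones(centred.n_markers)
        return model
    variances = _per_individual_stat(centred, "var")
    s = np.sqrt(variances.mean(axis=0))
    _raise_if_degenerate(s, centred.marker_names)
    model.scale_s = s
    if scale_mode == "per_group":
        scales = np.empty((centred.n_groups, centred.n_markers))
        for g in range(1, centred.n_groups + 1):
            members = centred.group_labels == g
            scales[g - 1] = np.sqrt(variances[members].mean(axis=0))
        _raise_if_degenerate(scales.ravel(), centred.marker_names * centred.n_groups)
        model.group_scales = scales
    return model


def _raise_if_degenerate(s: np.ndarray, names) -> None:
    bad = np.nonzero(s == 0.0)[0]
    if bad.size:
        raise DegenerateMarkerError(
            f"zero variance for marker(s) {[names[i] for i in bad]}; cannot scale"
        )


def apply_scaling(centred: MFCDataset, model: PreprocessModel) -> MFCDataset:
    """Divide each marker column by its fitted scale (X_cs = D_mc S^-1)."""
    if model.scale_s is None:
        raise ValueError("scaling not fitted")
    if len(model.marker_names) and list(centred.marker_names) != list(model.marker_names):
        raise ValueError("marker panel mismatch between data and fitted model")
    mode = model.scale_mode
    if mode in ("pooled", "none"):
        return centred.with_values(centred.values / model.scale_s)
    if mode == "per_individual":
        variances = _per_individual_stat(centred, "var")
        s_i = np.sqrt(variances)
        _raise_if_degenerate(s_i.ravel(), list(centred.marker_names) * centred.n_individuals)
        return centred.with_values(centred.values / s_i[centred.cell_to_individual])
    if mode == "per_group":
        if model.group_scales is None:
            raise ValueError("group scales not fitted")
        if centred.n_groups > model.group_scales.shape[0]:
            raise ValueError("held-out sample has a group unknown to the fitted per_group scaling")
        per_ind = model.group_scales[centred.group_labels - 1]
        return centred.with_values(centred.values / per_ind[centred.cell_to_individual])
    raise ValueError(mode)  # pragma: no cover


def fit_preprocess(
    dataset: MFCDataset, center_mode: str = "overall", scale_mode: str = "pooled"
) -> tuple[MFCDataset, PreprocessModel]:
    """Fit the whole Stage-1 chain on training data; return X_cs and the model."""
    logged, shift = log_transform(dataset)
    model = fit_centring(logged, center_mode)
    model.log_shift = shift
    centred = apply_centring(logged, model)
    fit_scaling(centred, scale_mode, model=model)
    return apply_scaling(centred, model), model


def apply_preprocess(dataset: MFCDataset, model: PreprocessModel) -> MFCDataset:
    """Apply a fitted Stage-1 chain to held-out data (training statistics only)."""
    logged = apply_log_transform(dataset, model.log_shift)
    centred = apply_centring(logged, model)
    return apply_scaling(centred, model)
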