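"""End-to-end pipeline: fit all stages on training data, score new samples.

A fitted :class:`DamacyModel` bundles every stage's parameters —
preprocessing statistics, base-model loadings, bin grid, retained-bin
mask and OPLS-DA weights — because a new sample cannot be scored
without the complete training state. The bundle serializes to a single
archive file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import base_model as bm
from . import histogram as hg
from . import preprocess as pp
from . import top_model as tm
from .io import MFCDataset, load_archive, save_archive

__all__ = ["PipelineConfig", "DamacyModel", "fit_pipeline"]

logger = logging.getLogger("damacy")


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters of one run.

    Defaults are the method's standard working values: F = 500 bins per
    component, smoothing factor 5, bin-variance threshold 1e-6, a
    2-component base model, and one orthogonal component in the top
    model. ``pc_pair`` selects which base components feed the histogram
    stage (``None`` = the first ``histogram_k``); selection is always
    explicit, never silent.
    """

    center_mode: str = "overall"
    scale_mode: str = "pooled"
    k_base: int = 2
    pc_pair: tuple[int, ...] | None = None
    bins_f: int = 500
    smoothing_factor: float = 5.0
    variance_threshold: float = 1e-6
    n_ortho: int = 1

    def histogram_components(self) -> tuple[int, ...]:
        if self.pc_pair is not None:
            return tuple(self.pc_pair)
        return tuple(range(min(self.k_base, 2)))

    @classmethod
    def for_small_cohorts(cls, **overrides) -> "PipelineConfig":
        """Settings scaled to cohorts of a few thousand cells per sample.

        The standard F=500 / threshold 1e-6 are calibrated to samples of
        ~1e5 cells, where occupied bins hold fractions of order 1e-3.
        With ~1e3-cell samples the same resolution leaves every bin's
        across-sample variance below 1e-6; F=100 with a proportionally
        smaller threshold keeps the design matrix informative. See the
        methods note for the scaling argument.
        """
        defaults = dict(bins_f=100, variance_threshold=1e-10)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class DamacyModel:
    """The complete fitted pipeline."""

    config: PipelineConfig
    preprocess: pp.PreprocessModel
    base: bm.BaseModel
    grid: hg.BinGrid
    top: tm.TopModel
    group_names: list[str] = field(default_factory=list)
    individual_ids: list[str] = field(default_factory=list)

    # ------------------------------------------------------------------
    @property
    def training_scores(self) -> np.ndarray:
        """t_top of the training samples."""
        return self.top.t_top

    def _score_columns(self, scores: np.ndarray) -> np.ndarray:
        return scores[:, list(self.config.histogram_components())]

    def histogram_of(
        self, dataset: MFCDataset, individual: int, smoothed: bool = True
    ) -> hg.SampleHistogram:
        """One individual's histogram under the fitted pipeline."""
        x_cs = pp.apply_preprocess(dataset, self.preprocess)
        scores = self._score_columns(bm.project_cells(x_cs, self.base))
        h = hg.build_histogram(
            scores[dataset.cell_to_individual == individual],
            self.grid,
            individual_id=dataset.individual_ids[individual],
        )
        return hg.smooth_histogram(h, self.config.smoothing_factor) if smoothed else h

    def predict(self, dataset: MFCDataset) -> pd.DataFrame:
        """Score every individual of a (held-out or training) dataset.

        Each sample is pushed through the stored chain: log/centre/scale
        with training statistics, projection on the training loadings,
        binning on the training grid, smoothing, masking, centring and
        projection on w_top. Returns one row per individual with the
        prediction score and the +/-1 class call.
        """
        x_cs = pp.apply_preprocess(dataset, self.preprocess)
        scores = self._score_columns(bm.project_cells(x_cs, self.base))
        rows = []
        for i in range(dataset.n_individuals):
            h = hg.build_histogram(
                scores[dataset.cell_to_individual == i],
                self.grid,
                individual_id=dataset.individual_ids[i],
            )
            h = hg.smooth_histogram(h, self.config.smoothing_factor)
            rows.append(h.values.ravel(order="C"))
        t = tm.predict_scores(self.top, np.vstack(rows))
        calls = tm.predict_classes(self.top, t)
        return pd.DataFrame(
            {
                "individual": dataset.individual_ids,
                "group": [
                    self._group_name(g) for g in dataset.group_labels
                ],
                "score": t,
                "predicted_class": calls,
                "predicted_group": [self._group_name(1 if c < 0 else 2) for c in calls],
            }
        )

    def _group_name(self, g: int) -> str:
        names = self.group_names
        return names[g - 1] if 0 < g <= len(names) else str(g)

    def leukocyte_map(self) -> tm.LeukocyteMap:
        comps = self.config.histogram_components()
        loadings = self.base.loadings[:, list(comps)] if len(comps) == 2 else None
        return tm.refold_weights(
            self.top, grid=self.grid, loadings=loadings, marker_names=self.base.marker_names
        )

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        cfg = asdict(self.config)
        cfg["pc_pair"] = list(self.config.pc_pair) if self.config.pc_pair is not None else None
        meta = {
            "kind": "damacy-model",
            "config": cfg,
            "preprocess": {
                "log_shift": self.preprocess.log_shift,
                "center_mode": self.preprocess.center_mode,
                "scale_mode": self.preprocess.scale_mode,
                "marker_names": self.preprocess.marker_names,
            },
            "grid": {
                "f_bins": self.grid.f_bins,
                "anchor": list(self.grid.anchor),
                "delta": list(self.grid.delta),
                "clip_policy": self.grid.clip_policy,
            },
            "base": {"k_base": self.base.k_base, "marker_names": self.base.marker_names},
            "top": {"grid_shape": list(self.top.grid_shape), "threshold": self.top.threshold},
            "group_names": self.group_names,
            "individual_ids": self.individual_ids,
        }
        arrays = {
            "pre_individual_means": _maybe(self.preprocess.individual_means),
            "pre_overall_center": _maybe(self.preprocess.overall_center),
            "pre_scale_s": _maybe(self.preprocess.scale_s),
            "pre_group_centers": _maybe(self.preprocess.group_centers),
            "pre_group_scales": _maybe(self.preprocess.group_scales),
            "base_loadings": self.base.loadings,
            "base_singular_values": self.base.singular_values,
            "base_explained_variance": self.base.explained_variance_total,
            "top_w": self.top.w_top,
            "top_p": self.top.p_top,
            "top_t": self.top.t_top,
            "top_w_ortho": self.top.w_ortho,
            "top_p_ortho": self.top.p_ortho,
            "top_t_ortho": self.top.t_ortho,
            "top_center": self.top.column_center,
            "top_mask": self.top.bin_mask,
            "top_y": self.top.y,
        }
        save_archive(path, meta, {k: v for k, v in arrays.items() if v is not None})

    @classmethod
    def load(cls, path) -> "DamacyModel":
        meta, arrays = load_archive(path)
        if meta.get("kind") != "damacy-model":
            raise ValueError(f"{path}: not a fitted model archive")
        cfg = dict(meta["config"])
        if cfg.get("pc_pair") is not None:
            cfg["pc_pair"] = tuple(cfg["pc_pair"])
        config = PipelineConfig(**cfg)
        pre = pp.PreprocessModel(
            log_shift=meta["preprocess"]["log_shift"],
            center_mode=meta["preprocess"]["center_mode"],
            scale_mode=meta["preprocess"]["scale_mode"],
            individual_means=arrays.get("pre_individual_means"),
            overall_center=arrays.get("pre_overall_center"),
            group_centers=arrays.get("pre_group_centers"),
            scale_s=arrays.get("pre_scale_s"),
            group_scales=arrays.get("pre_group_scales"),
            marker_names=list(meta["preprocess"]["marker_names"]),
        )
        base = bm.BaseModel(
            loadings=arrays["base_loadings"],
            k_base=meta["base"]["k_base"],
            singular_values=arrays["base_singular_values"],
            explained_variance_total=arrays["base_explained_variance"],
            marker_names=list(meta["base"]["marker_names"]),
        )
        grid = hg.BinGrid(
            f_bins=meta["grid"]["f_bins"],
            anchor=tuple(meta["grid"]["anchor"]),
            delta=tuple(meta["grid"]["delta"]),
            clip_policy=meta["grid"]["clip_policy"],
        )
        top = tm.TopModel(
            w_top=arrays["top_w"],
            p_top=arrays["top_p"],
            t_top=arrays["top_t"],
            w_ortho=arrays["top_w_ortho"],
            p_ortho=arrays["top_p_ortho"],
            t_ortho=arrays["top_t_ortho"],
            column_center=arrays["top_center"],
            bin_mask=arrays["top_mask"].astype(bool),
            grid_shape=tuple(meta["top"]["grid_shape"]),
            y=arrays["top_y"],
            threshold=meta["top"]["threshold"],
        )
        return cls(
            config=config,
            preprocess=pre,
            base=base,
            grid=grid,
            top=top,
            group_names=list(meta["group_names"]),
            individual_ids=list(meta["individual_ids"]),
        )


def _maybe(a):
    return None if a is None else np.asarray(a)


def fit_pipeline(dataset: MFCDataset, config: PipelineConfig | None = None) -> DamacyModel:
    """Fit every stage on ``dataset`` (the training individuals).

    Raises if the dataset has fewer than two groups; all fitted
    statistics derive exclusively from the given individuals.
    """
    config = config or PipelineConfig()
    if dataset.n_groups < 2:
        raise ValueError("supervised fit requires at least 2 groups")
    logger.info(
        "fit: %d individuals, %d cells, %d markers", dataset.n_individuals,
        dataset.n_cells, dataset.n_markers,
    )
    x_cs, pre = pp.fit_preprocess(dataset, config.center_mode, config.scale_mode)
    base = bm.fit_base_model(x_cs, config.k_base)
    comps = config.histogram_components()
    if max(comps) >= base.k_base:
        raise ValueError(f"pc_pair {comps} out of range for k_base={base.k_base}")
    scores = bm.project_cells(x_cs, base)[:, list(comps)]
    grid = hg.fit_bin_grid(scores, config.bins_f)
    hists = []
    for i in range(dataset.n_individuals):
        h = hg.build_histogram(
            scores[dataset.cell_to_individual == i], grid,
            individual_id=dataset.individual_ids[i],
        )
        hists.append(hg.smooth_histogram(h, config.smoothing_factor))
    design = tm.vectorize_histograms(hists)
    design = tm.filter_low_variance_bins(design, config.variance_threshold)
    logger.info("top model: %d of %d bins retained", design.matrix.shape[1], design.bin_mask.size)
    top = tm.fit_oplsda(design, dataset.group_labels, n_ortho=config.n_ortho)
    return DamacyModel(
        config=config,
        preprocess=pre,
        base=base,
        grid=grid,
        top=top,
        group_names=list(dataset.group_names),
        individual_ids=list(dataset.individual_ids),
    )
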