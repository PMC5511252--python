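"""Double (nested) cross-validation with leave-sample-out folds.

Folds partition *individuals*, never cells: a sample's cells are either
all in training or all held out. The outer loop measures prediction
accuracy; an inner loop on each training set selects the number of
orthogonal components (and, via helpers, the preprocessing mode or the
base-component pair). Fold membership is reshuffled every iteration
from a per-iteration seed derived from the master seed, and every
fitted statistic — means, scales, loadings, grid, bin mask, centring
vector, weights — derives from training individuals only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd

from .io import MFCDataset
from .pipeline import DamacyModel, PipelineConfig, fit_pipeline

__all__ = [
    "CVConfig",
    "CVResult",
    "make_folds",
    "double_cross_validate",
    "summarize",
    "rank_pc_pairs",
    "evaluate_preprocess_modes",
    "planted_region_recovery",
]


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings (defaults: 6 outer folds, 20 iterations)."""

    outer_folds: int = 6
    n_iterations: int = 20
    inner_folds: int = 3
    n_ortho_grid: tuple[int, ...] = (0, 1, 2)
    stratified: bool = True
    seed: int = 0
    store_models: bool = False


@dataclass
class CVResult:
    """Held-out scores and accuracies of one double-CV run."""

    individual_ids: list[str]
    group_labels: np.ndarray
    group_names: list[str]
    scores: np.ndarray  # (n_iterations x I) held-out prediction scores
    iteration_accuracy: np.ndarray  # (n_iterations,)
    fold_log: list[dict] = field(default_factory=list)
    models: list[DamacyModel] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(self.iteration_accuracy.mean())

    @property
    def per_sample_mean_score(self) -> np.ndarray:
        return self.scores.mean(axis=0)

    @property
    def per_sample_score_std(self) -> np.ndarray:
        return self.scores.std(axis=0, ddof=0)


def make_folds(
    group_labels: np.ndarray, n_folds: int, rng: np.random.Generator, stratified: bool = True
) -> list[np.ndarray]:
    """Partition individual indices into ``n_folds`` disjoint folds.

    Stratified: each group's members are shuffled and dealt round-robin
    so every fold holds a near-proportional mix of groups. Deterministic
    for a given generator state.
    """
    group_labels = np.asarray(group_labels)
    n = group_labels.size
    if n_folds < 2 or n_folds > n:
        raise ValueError(f"outer_folds must be in [2, {n}], got {n_folds}")
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    if stratified:
        offset = 0
        for g in np.unique(group_labels):
            members = np.nonzero(group_labels == g)[0]
            if members.size < 1:
                raise ValueError(f"group {g} has no members to stratify")
            members = rng.permutation(members)
            for j, idx in enumerate(members):
                folds[(offset + j) % n_folds].append(int(idx))
            offset += members.size  # stagger groups across folds
    else:
        for j, idx in enumerate(rng.permutation(n)):
            folds[j % n_folds].append(int(idx))
    out = [np.sort(np.array(f, dtype=np.intp)) for f in folds]
    if any(f.size == 0 for f in out):
        raise ValueError("a fold came out empty; reduce outer_folds")
    return out


def _accuracy(scores: np.ndarray, y_true_signed: np.ndarray) -> float:
    """Fraction of correct sign calls; a score exactly at 0 counts wrong."""
    calls = np.where(scores > 0, 1, -1)
    correct = (calls == y_true_signed) & (scores != 0)
    return float(np.mean(correct))


def _select_n_ortho(
    train: MFCDataset,
    config: PipelineConfig,
    cv: CVConfig,
    rng: np.random.Generator,
) -> int:
    """Pick n_ortho from the grid by inner leave-sample-out CV accuracy.

    The full pipeline is refitted per inner fold; ties prefer the
    simpler (smaller) n_ortho. A candidate that cannot be fitted on
    some inner fold (rank deficiency) is discarded.
    """
    grid = cv.n_ortho_grid
    if len(grid) == 1:
        return grid[0]
    inner = make_folds(train.group_labels, cv.inner_folds, rng, cv.stratified)
    y_signed = np.where(train.group_labels == 1, -1, 1)
    best, best_acc = grid[0], -np.inf
    for cand in grid:
        hits: list[float] = []
        try:
            for fold in inner:
                tr = np.setdiff1d(np.arange(train.n_individuals), fold)
                model = fit_pipeline(train.subset(tr), replace(config, n_ortho=cand))
                pred = model.predict(train.subset(fold))
                hits.append(_accuracy(pred["score"].to_numpy(), y_signed[fold]))
        except (ValueError, np.linalg.LinAlgError):
            continue
        acc = float(np.mean(hits))
        if acc > best_acc + 1e-12:
            best, best_acc = cand, acc
    return best


def double_cross_validate(
    dataset: MFCDataset, config: PipelineConfig | None = None, cv: CVConfig | None = None
) -> CVResult:
    """Leave-sample-out double CV: outer accuracy folds, inner selection.

    Every iteration reshuffles fold membership under a per-iteration
    seed spawned from ``cv.seed``; per-fold hyperparameters come from
    the inner loop run on that fold's training individuals only. The
    result carries each sample's held-out score per iteration and the
    per-iteration accuracy (fraction of held-out sign calls matching
    the true group; g=1 is coded -1, g=2 coded +1).
    """
    config = config or PipelineConfig()
    cv = cv or CVConfig()
    I = dataset.n_individuals
    if cv.outer_folds > I:
        raise ValueError("outer_folds exceeds the number of individuals")
    y_signed = np.where(dataset.group_labels == 1, -1, 1)
    scores = np.full((cv.n_iterations, I), np.nan)
    accs = np.zeros(cv.n_iterations)
    fold_log: list[dict] = []
    models: list[DamacyModel] = []
    children = np.random.SeedSequence(cv.seed).spawn(cv.n_iterations)
    for it, seq in enumerate(children):
        rng = np.random.default_rng(seq)
        folds = make_folds(dataset.group_labels, cv.outer_folds, rng, cv.stratified)
        for k, fold in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(I), fold)
            train = dataset.subset(train_idx)
            try:
                n_ortho = _select_n_ortho(train, config, cv, rng)
                model = fit_pipeline(train, replace(config, n_ortho=n_ortho))
                pred = model.predict(dataset.subset(fold))
            except (ValueError, np.linalg.LinAlgError) as err:
                raise RuntimeError(
                    f"pipeline fit failed in iteration {it}, fold {k}: {err}"
                ) from err
            scores[it, fold] = pred["score"].to_numpy()
            fold_log.append(
                {
                    "iteration": it,
                    "fold": k,
                    "seed_entropy": int(seq.entropy) if seq.entropy is not None else None,
                    "test_individuals": [dataset.individual_ids[i] for i in fold],
                    "n_ortho": n_ortho,
                }
            )
            if cv.store_models:
                models.append(model)
        accs[it] = _accuracy(scores[it], y_signed)
    assert not np.isnan(scores).any(), "some individual was never held out"
    return CVResult(
        individual_ids=list(dataset.individual_ids),
        group_labels=dataset.group_labels.copy(),
        group_names=list(dataset.group_names),
        scores=scores,
        iteration_accuracy=accs,
        fold_log=fold_log,
        models=models,
    )


def summarize(result: CVResult) -> pd.DataFrame:
    """Per-sample table of averaged held-out scores and the class call."""
    mean_scores = result.per_sample_mean_score
    return pd.DataFrame(
        {
            "individual": result.individual_ids,
            "group": [result.group_names[g - 1] for g in result.group_labels],
            "mean_score": mean_scores,
            "score_std": result.per_sample_score_std,
            "predicted_group": [
                result.group_names[1] if s > 0 else result.group_names[0]
                for s in mean_scores
            ],
        }
    )


def rank_pc_pairs(
    dataset: MFCDataset,
    config: PipelineConfig,
    cv: CVConfig | None = None,
    k_base: int | None = None,
) -> pd.DataFrame:
    """Cross-validated accuracy for every unordered base-component pair.

    Fits nothing silently: the caller reads the ranking and sets
    ``pc_pair`` explicitly for the final model.
    """
    cv = cv or CVConfig()
    k = k_base or config.k_base
    rows = []
    for a, b in combinations(range(k), 2):
        pair_cfg = replace(config, k_base=k, pc_pair=(a, b))
        res = double_cross_validate(dataset, pair_cfg, cv)
        rows.append({"pc_x": a + 1, "pc_y": b + 1, "mean_accuracy": res.mean_accuracy})
    return (
        pd.DataFrame(rows)
        .sort_values("mean_accuracy", ascending=False)
        .reset_index(drop=True)
    )


def evaluate_preprocess_modes(
    dataset: MFCDataset,
    config: PipelineConfig,
    cv: CVConfig | None = None,
    center_modes: tuple[str, ...] = ("overall", "median_overall"),
    scale_modes: tuple[str, ...] = ("pooled",),
) -> pd.DataFrame:
    """CV accuracy over a grid of centring/scaling modes.

    Mode choice is a study-level configuration decided by prediction
    accuracy; this helper makes that evaluation explicit.
    """
    cv = cv or CVConfig()
    rows = []
    for cm in center_modes:
        for sm in scale_modes:
            res = double_cross_validate(
                dataset, replace(config, center_mode=cm, scale_mode=sm), cv
            )
            rows.append({"center_mode": cm, "scale_mode": sm, "mean_accuracy": res.mean_accuracy})
    return (
        pd.DataFrame(rows)
        .sort_values("mean_accuracy", ascending=False)
        .reset_index(drop=True)
    )


def planted_region_recovery(
    dataset: MFCDataset,
    cell_mask: np.ndarray,
    model: DamacyModel,
    region_mass: float = 0.95,
    decile: float = 0.9,
) -> dict:
    """How well the leukocyte map localizes a known cell population.

    ``cell_mask`` marks the cells of the ground-truth population (e.g.
    from a simulated cohort's truth record). The population's region is
    the smallest set of bins holding ``region_mass`` of its smoothed
    density under the fitted grid; the score is the fraction of
    top-decile \\|weight\\| bins (among retained bins) that fall inside
    it. Also reported: the same fraction split by weight sign, and
    whether the single largest \\|weight\\| bin is inside.
    """
    from . import base_model as bm
    from . import histogram as hg
    from . import preprocess as pp

    x_cs = pp.apply_preprocess(dataset, model.preprocess)
    comps = list(model.config.histogram_components())
    scores = bm.project_cells(x_cs, model.base)[:, comps]
    hist = hg.smooth_histogram(
        hg.build_histogram(scores[np.asarray(cell_mask, bool)], model.grid),
        model.config.smoothing_factor,
    )
    dens = hist.values.ravel(order="C")
    order = np.argsort(dens)[::-1]
    cutoff = int(np.searchsorted(np.cumsum(dens[order]), region_mass)) + 1
    region = np.zeros(dens.size, dtype=bool)
    region[order[:cutoff]] = True

    weights = model.leukocyte_map().weights.ravel(order="C")
    retained = model.top.bin_mask
    abs_w = np.abs(weights[retained])
    idx = np.nonzero(retained)[0]
    top = idx[abs_w >= np.quantile(abs_w, decile)]
    pos = weights[top] > 0
    return {
        "fraction_top_decile_in_region": float(region[top].mean()),
        "fraction_positive_top_decile_in_region": float(region[top[pos]].mean())
        if pos.any()
        else float("nan"),
        "max_weight_bin_in_region": bool(region[idx[np.argmax(abs_w)]]),
        "n_top_bins": int(top.size),
        "n_region_bins": int(region.sum()),
    }
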