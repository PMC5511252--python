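"""Synthetic multi-individual cytometry cohorts with known ground truth.

Generates the statistical structure the method assumes: G groups of
individuals, each individual a mixture of Gaussian cell populations on
the log10 intensity scale, with group-dependent mixing fractions and/or
group-dependent population shifts, per-individual jitter of population
means (biological between-individual variability), measurement noise,
and per-individual cell counts drawn from a range so samples are
unbalanced. A population may be a *continuum*: its mean drifts linearly
along a direction across the population, emulating gradient-shaped cell
clouds rather than discrete clusters.

Cells are drawn on the log10 scale and exponentiated, so the pipeline's
log transform recovers the generative scale; the truth record keeps the
per-cell population membership and per-individual realized fractions
for parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import MFCDataset, SampleManifest, write_fcs_sample

__all__ = [
    "PopulationSpec",
    "CohortSpec",
    "CohortTruth",
    "simulate_cohort",
    "write_fixture_fcs",
    "preset_scenarios",
]


@dataclass(frozen=True)
class PopulationSpec:
    """One Gaussian (or gradient) cell population.

    ``mean`` is on the log10 intensity scale. ``fractions[g]`` is the
    population's mixing fraction in group g+1 (fractions of each group
    sum to 1 across populations). ``group_shift[g]`` optionally moves
    the mean per group. A continuum population drifts linearly:
    cell mean = mean + u * continuum_direction with u ~ Uniform(0, 1).
    """

    name: str
    mean: tuple[float, ...]
    cov: tuple[tuple[float, ...], ...]
    fractions: tuple[float, ...]
    group_shift: tuple[tuple[float, ...], ...] | None = None
    continuum_direction: tuple[float, ...] | None = None

    def covariance(self) -> np.ndarray:
        cov = np.asarray(self.cov, dtype=np.float64)
        if cov.ndim == 0:
            cov = np.eye(len(self.mean)) * float(cov)
        if not np.allclose(cov, cov.T):
            raise ValueError(f"population {self.name!r}: covariance not symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() < -1e-12:
            raise ValueError(f"population {self.name!r}: covariance not PSD")
        return cov

    @staticmethod
    def isotropic(
        name: str,
        mean,
        sigma: float,
        fractions,
        group_shift=None,
        continuum_direction=None,
    ) -> "PopulationSpec":
        j = len(mean)
        cov = tuple(
            tuple(sigma**2 if a == b else 0.0 for b in range(j)) for a in range(j)
        )
        return PopulationSpec(
            name=name,
            mean=tuple(float(v) for v in mean),
            cov=cov,
            fractions=tuple(float(v) for v in fractions),
            group_shift=group_shift,
            continuum_direction=continuum_direction,
        )


@dataclass(frozen=True)
class CohortSpec:
    """A two-or-more-group cohort design."""

    populations: tuple[PopulationSpec, ...]
    individuals_per_group: tuple[int, ...] = (8, 8)
    cells_range: tuple[int, int] = (1500, 2500)
    n_markers: int = 6
    jitter_scale: float = 0.08  # sd of per-individual population-mean shifts, log10 units
    noise_floor: float = 0.03  # sd of added measurement noise, log10 units
    seed: int = 0

    def __post_init__(self) -> None:
        g = len(self.individuals_per_group)
        for p in self.populations:
            if len(p.fractions) != g:
                raise ValueError(f"population {p.name!r} needs {g} fractions")
            if len(p.mean) != self.n_markers:
                raise ValueError(f"population {p.name!r} mean has wrong length")
            p.covariance()  # validates symmetry / PSD
        frac = np.array([p.fractions for p in self.populations])
        if not np.allclose(frac.sum(axis=0), 1.0):
            raise ValueError("population fractions must sum to 1 within each group")
        if self.cells_range[0] < 1 or self.cells_range[1] < self.cells_range[0]:
            raise ValueError("invalid cells_range")


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort."""

    cell_population: np.ndarray  # per-cell population index
    realized_fractions: np.ndarray  # (I x n_populations)
    population_names: list[str]
    spec: CohortSpec
    log_means: np.ndarray = field(default=None)  # (I, P, J) jittered means used


def simulate_cohort(spec: CohortSpec, seed: int | None = None) -> tuple[MFCDataset, CohortTruth]:
    """Draw a cohort; identical seeds give identical datasets cell-for-cell."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_pop = len(spec.populations)
    covs = [p.covariance() for p in spec.populations]
    chols = []
    for cov in covs:
        # PSD but possibly singular (e.g. zero covariance): use sqrt via eigh
        vals, vecs = np.linalg.eigh(cov)
        chols.append(vecs * np.sqrt(np.clip(vals, 0.0, None)))

    blocks: list[np.ndarray] = []
    pop_labels: list[np.ndarray] = []
    ids: list[str] = []
    groups: list[int] = []
    realized = []
    means_used = []
    for g, n_ind in enumerate(spec.individuals_per_group, start=1):
        fracs = np.array([p.fractions[g - 1] for p in spec.populations])
        for i in range(n_ind):
            n_cells = int(rng.integers(spec.cells_range[0], spec.cells_range[1] + 1))
            assignment = rng.choice(n_pop, size=n_cells, p=fracs)
            cells = np.empty((n_cells, spec.n_markers))
            ind_means = np.empty((n_pop, spec.n_markers))
            for p_idx, pop in enumerate(spec.populations):
                mean = np.asarray(pop.mean, dtype=np.float64)
                if pop.group_shift is not None:
                    mean = mean + np.asarray(pop.group_shift[g - 1])
                mean = mean + rng.normal(0.0, spec.jitter_scale, spec.n_markers)
                ind_means[p_idx] = mean
                members = np.nonzero(assignment == p_idx)[0]
                if members.size == 0:
                    continue
                z = rng.standard_normal((members.size, spec.n_markers))
                draw = mean + z @ chols[p_idx].T
                if pop.continuum_direction is not None:
                    u = rng.uniform(0.0, 1.0, members.size)
                    draw = draw + u[:, None] * np.asarray(pop.continuum_direction)
                cells[members] = draw
            if spec.noise_floor > 0:
                cells += rng.normal(0.0, spec.noise_floor, cells.shape)
            blocks.append(10.0**cells)
            pop_labels.append(assignment)
            ids.append(f"g{g}_ind{i + 1}")
            groups.append(g)
            realized.append(np.bincount(assignment, minlength=n_pop) / n_cells)
            means_used.append(ind_means)

    counts = [b.shape[0] for b in blocks]
    dataset = MFCDataset(
        values=np.vstack(blocks),
        cell_to_individual=np.repeat(np.arange(len(blocks)), counts),
        individual_ids=ids,
        group_labels=np.array(groups),
        marker_names=[f"M{j + 1}" for j in range(spec.n_markers)],
        group_names=["control", "challenged"][: len(spec.individuals_per_group)]
        or [str(g) for g in sorted(set(groups))],
    )
    truth = CohortTruth(
        cell_population=np.concatenate(pop_labels),
        realized_fractions=np.array(realized),
        population_names=[p.name for p in spec.populations],
        spec=spec,
        log_means=np.array(means_used),
    )
    return dataset, truth


def write_fixture_fcs(dataset: MFCDataset, directory: str | Path) -> SampleManifest:
    """Write one FCS 3.1 file per individual plus a manifest CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for i, ind in enumerate(dataset.individual_ids):
        path = directory / f"{ind}.fcs"
        write_fcs_sample(path, dataset.cells_of(i), dataset.marker_names)
        files.append(str(path))
    manifest = SampleManifest(
        files=files,
        individual_ids=list(dataset.individual_ids),
        group_labels=[
            dataset.group_names[g - 1] for g in dataset.group_labels
        ],
    )
    manifest.to_csv(directory / "manifest.csv")
    return manifest


def preset_scenarios(j: int = 6) -> dict[str, CohortSpec]:
    """Named cohort designs used throughout the test battery.

    ``lps_like``: 8 control + 8 challenged individuals, ~2000 cells
    each; a broad baseline population plus a compact gradient
    (continuum) population present in 5% of control cells and 30% of
    challenged cells — the planted effect a correct analysis must place
    on the leukocyte map.

    ``null``: 20 + 20 individuals, ~1000 cells each, identical mixture
    in both groups; any classifier should sit at chance.

    ``aml_like``: 8 + 8 individuals; same fractions in both groups, but
    one population's mean is shifted along a single marker in the
    challenged group.

    The mixing fractions and effect sizes are test parameters of this
    package's fixtures, not estimates from any clinical cohort.
    """
    base_mean = [2.5, 2.5, 2.2, 2.3, 2.1, 2.4][:j]
    minor_mean = [2.0, 2.9, 2.4, 2.0, 2.5, 2.2][:j]
    planted_mean = [3.3, 1.7, 2.8, 2.3, 2.1, 2.4][:j]
    gradient = [0.35, -0.35, 0.2, 0.0, 0.0, 0.0][:j]

    lps_like = CohortSpec(
        populations=(
            PopulationSpec.isotropic("baseline", base_mean, 0.28, (0.80, 0.55)),
            PopulationSpec.isotropic("minor", minor_mean, 0.20, (0.15, 0.15)),
            PopulationSpec.isotropic(
                "planted_gradient",
                planted_mean,
                0.10,
                (0.05, 0.30),
                continuum_direction=tuple(gradient),
            ),
        ),
        individuals_per_group=(8, 8),
        cells_range=(1500, 2500),
        n_markers=j,
        seed=2017,
    )

    null = CohortSpec(
        populations=(
            PopulationSpec.isotropic("baseline", base_mean, 0.28, (0.75, 0.75)),
            PopulationSpec.isotropic("minor", minor_mean, 0.20, (0.25, 0.25)),
        ),
        individuals_per_group=(20, 20),
        cells_range=(800, 1200),
        n_markers=j,
        seed=2018,
    )

    aml_like = CohortSpec(
        populations=(
            PopulationSpec.isotropic("baseline", base_mean, 0.28, (0.70, 0.70)),
            PopulationSpec.isotropic(
                "blast",
                minor_mean,
                0.18,
                (0.30, 0.30),
                group_shift=(
                    tuple(0.0 for _ in range(j)),
                    tuple(0.6 if m == 0 else 0.0 for m in range(j)),
                ),
            ),
        ),
        individuals_per_group=(8, 8),
        cells_range=(1500, 2500),
        n_markers=j,
        seed=2019,
    )
    return {"lps_like": lps_like, "null": null, "aml_like": aml_like}
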