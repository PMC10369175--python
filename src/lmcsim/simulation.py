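"""Initialization, the generational loop, the treatment grid, and recording.

A treatment is one (inheritance mode, foundress number n, dispersal cost c)
cell run for a fixed number of non-overlapping generations; the reported
statistics — realized sex ratio z and dispersal attempt rate d — are averaged
over the final ``record_window`` generations, yielding one data point per
treatment.  The full study grid crosses three genetic systems with
n in {1, 2, 5, 10} and c in {0.2, 0.4, 0.6, 0.8} (48 cells).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from . import metrics, theory
from .config import TreatmentConfig
from .demography import (
    Mothers,
    dispersal_step,
    mate_within_patch,
    produce_brood,
    regulate,
)
from .genetics import InheritanceMode

__all__ = [
    "GenerationSummary",
    "TreatmentResult",
    "initialize_population",
    "run_generation",
    "run_treatment",
    "run_grid",
    "results_table",
    "cell_seed",
    "GRID_MODES",
    "GRID_NS",
    "GRID_CS",
]

GRID_MODES: tuple[InheritanceMode, ...] = tuple(InheritanceMode)
GRID_NS: tuple[int, ...] = (1, 2, 5, 10)
GRID_CS: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)

#: Columns of a per-generation trajectory frame.
TRAJECTORY_COLUMNS = (
    "generation",
    "son_fraction",
    "attempt_fraction",
    "mean_z_phenotype",
    "mean_p0",
    "mean_p1",
    "occupied_patches",
    "threshold_K",
    "undersized_fraction",
)


@dataclass(frozen=True)
class GenerationSummary:
    """Realized statistics of one generation."""

    generation: int
    son_fraction: float  # sons / all juveniles, forced extras included
    attempt_fraction: float  # dispersal attempts / mated daughters
    mean_z_phenotype: float  # mean expressed sex allocation of the mothers
    mean_p0: float  # genotypic (unclipped) mean reaction-norm endpoints
    mean_p1: float  # of the mated-daughter cohort
    occupied_patches: int
    threshold_K: int
    undersized_fraction: float
    n_mothers: int


@dataclass(frozen=True)
class TreatmentResult:
    """Final-window means and diagnostics of one treatment run."""

    mode: InheritanceMode
    n: int
    c: float
    seed: int
    n_patches: int
    generations: int
    record_window: int
    mean_z: float
    mean_d: float
    undersized_fraction: float
    mean_p0: float
    mean_p1: float
    extinct: bool = False
    extinction_generation: int | None = None
    trajectory: pd.DataFrame | None = None


def initialize_population(config: TreatmentConfig) -> Mothers:
    """Found every patch with ``n`` mated, genetically uniform mothers.

    Dispersal alleles at both reaction-norm loci start at the unbeatable
    density-independent dispersal probability for (n, c); sex-allocation
    alleles start at the classical local-mate-competition value (or
    ``config.z0``).  Founding mates carry the same allelic values.
    """
    d0 = theory.density_independent_dispersal(config.n, config.c)
    z0 = config.z0 if config.z0 is not None else theory.init_sex_allocation(config.n, config.mode)
    m = config.n_patches * config.n
    alleles = np.empty((m, 3, 2), dtype=float)
    alleles[:, 0, :] = z0
    alleles[:, 1, :] = d0
    alleles[:, 2, :] = d0
    return Mothers(
        patch=np.repeat(np.arange(config.n_patches, dtype=np.int64), config.n),
        alleles=alleles,
        mate_alleles=alleles.copy(),
    )


def run_generation(
    mothers: Mothers,
    config: TreatmentConfig,
    rng: np.random.Generator,
    generation: int = 0,
) -> tuple[Mothers, GenerationSummary]:
    """Advance the population one generation.

    Order of events: brood production (mothers die) -> within-patch mating
    (males die) -> density assessment and dispersal (cost applied) ->
    regulation to at most n mothers per patch.  Returns the next generation's
    mothers and this generation's realized summary.  An empty mothers
    container signals global extinction.
    """
    mean_z_phen = (
        float(np.clip(mothers.alleles[:, 0, :].mean(axis=1), 0, 1).mean())
        if len(mothers)
        else float("nan")
    )
    broods = produce_brood(mothers, config, rng)
    son_fraction = (
        broods.n_sons / broods.n_total if broods.n_total else float("nan")
    )
    daughters = mate_within_patch(broods, config, rng)

    # Pre-dispersal (post-mating) daughter census: density diagnostics.
    if len(daughters):
        counts = np.bincount(daughters.patch, minlength=config.n_patches)
        occupied = int((counts > 0).sum())
        mean_p0 = float(daughters.alleles[:, 1, :].mean())
        mean_p1 = float(daughters.alleles[:, 2, :].mean())
        K = metrics.estimate_threshold(mean_p0, mean_p1, config.d_max)
        undersized = metrics.undersized_patch_fraction(counts, K)
    else:
        occupied, mean_p0, mean_p1, K, undersized = 0, float("nan"), float("nan"), 0, float("nan")

    daughters, tally = dispersal_step(daughters, config, rng)
    next_mothers = regulate(daughters, config.n, config.n_patches, rng)
    summary = GenerationSummary(
        generation=generation,
        son_fraction=son_fraction,
        attempt_fraction=tally.attempt_fraction,
        mean_z_phenotype=mean_z_phen,
        mean_p0=mean_p0,
        mean_p1=mean_p1,
        occupied_patches=occupied,
        threshold_K=K,
        undersized_fraction=undersized,
        n_mothers=len(next_mothers),
    )
    return next_mothers, summary


def run_treatment(
    config: TreatmentConfig,
    *,
    keep_trajectory: bool = False,
    progress: Callable[[GenerationSummary], None] | None = None,
    progress_every: int = 0,
) -> TreatmentResult:
    """Run one treatment cell to completion and average the final window.

    Deterministic given ``config`` (including its seed).  If the population
    goes globally extinct the result is flagged and the means are NaN.
    """
    rng = np.random.default_rng(config.seed)
    mothers = initialize_population(config)
    g_total = config.generations
    series = {name: np.full(g_total, np.nan) for name in TRAJECTORY_COLUMNS}
    extinct = False
    extinction_generation: int | None = None

    for g in range(g_total):
        mothers, s = run_generation(mothers, config, rng, generation=g)
        for name in TRAJECTORY_COLUMNS:
            series[name][g] = getattr(s, name)
        if progress is not None and progress_every and (g + 1) % progress_every == 0:
            progress(s)
        if len(mothers) == 0:
            extinct = True
            extinction_generation = g
            break

    if extinct:
        mean_z = mean_d = undersized = mp0 = mp1 = float("nan")
    else:
        w = config.record_window
        mean_z = metrics.final_window_mean(series["son_fraction"], w)
        mean_d = metrics.final_window_mean(series["attempt_fraction"], w)
        undersized = metrics.final_window_mean(series["undersized_fraction"], w)
        mp0 = metrics.final_window_mean(series["mean_p0"], w)
        mp1 = metrics.final_window_mean(series["mean_p1"], w)

    trajectory = None
    if keep_trajectory:
        trajectory = pd.DataFrame({k: series[k] for k in TRAJECTORY_COLUMNS})
        trajectory["generation"] = np.arange(g_total)
        if extinct:
            trajectory = trajectory.iloc[: (extinction_generation or 0) + 1]

    return TreatmentResult(
        mode=config.mode,
        n=config.n,
        c=config.c,
        seed=config.seed,
        n_patches=config.n_patches,
        generations=config.generations,
        record_window=config.record_window,
        mean_z=mean_z,
        mean_d=mean_d,
        undersized_fraction=undersized,
        mean_p0=mp0,
        mean_p1=mp1,
        extinct=extinct,
        extinction_generation=extinction_generation,
        trajectory=trajectory,
    )


def cell_seed(master_seed: int, mode: InheritanceMode, n: int, c: float) -> int:
    """Deterministic per-cell seed, independent of grid composition/order."""
    mode_idx = list(InheritanceMode).index(mode)
    ss = np.random.SeedSequence((int(master_seed), mode_idx, int(n), int(round(c * 1000))))
    return int(ss.generate_state(1)[0] % (2**31))


def run_grid(
    modes: Iterable[InheritanceMode | str],
    ns: Sequence[int],
    cs: Sequence[float],
    base_config: TreatmentConfig,
    master_seed: int,
    *,
    progress: Callable[[TreatmentConfig, TreatmentResult], None] | None = None,
) -> list[TreatmentResult]:
    """Run every (mode, n, c) cell with per-cell derived seeds.

    Two grids sharing a master seed produce identical cells regardless of the
    order or subset of cells requested.
    """
    results = []
    for mode in modes:
        mode = InheritanceMode(mode) if isinstance(mode, str) else mode
        for n in ns:
            for c in cs:
                cfg = base_config.replace(
                    mode=mode, n=n, c=c, seed=cell_seed(master_seed, mode, n, c)
                )
                res = run_treatment(cfg)
                if progress is not None:
                    progress(cfg, res)
                results.append(res)
    return results


def results_table(results: Iterable[TreatmentResult]) -> pd.DataFrame:
    """Flatten treatment results into the study's results table."""
    rows = [
        {
            "mode": r.mode.value,
            "n": r.n,
            "c": r.c,
            "seed": r.seed,
            "mean_z": r.mean_z,
            "mean_d": r.mean_d,
            "undersized_fraction": r.undersized_fraction,
            "n_patches": r.n_patches,
            "generations": r.generations,
            "record_window": r.record_window,
            "extinct": r.extinct,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
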