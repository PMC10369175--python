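"""One lifecycle step on the patch-structured population.

The population lives on ``n_patches`` discrete patches.  Each generation:
mothers produce broods and die; offspring mate at random within their natal
patch (females once, males repeatedly), after which males die; mated daughters
assess local daughter density and either stay or attempt dispersal, dying with
probability ``c`` on an attempt; finally at most ``n`` daughters per patch are
retained as next-generation mothers.

Cohorts are stored as structure-of-arrays: a patch-index vector plus an
``(N, 3, 2)`` allele array.  Haploid individuals store their single allele per
locus duplicated in both slots, so additive expression (mean over the last
axis) and maternal gamete draws are ploidy-agnostic; mutation is applied to
logical genes before duplication.  Patches are implicit — per-patch structure
is recovered from the patch-index vectors with bincount/offset arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import TreatmentConfig
from .genetics import InheritanceMode, MutationParams, mutate_alleles

__all__ = [
    "Mothers",
    "Broods",
    "MatedDaughters",
    "DispersalTally",
    "produce_brood",
    "mate_within_patch",
    "normalized_density",
    "dispersal_step",
    "regulate",
]


@dataclass
class Mothers:
    """Current-generation breeding females, sorted by patch index.

    Every mother is mated: ``mate_alleles`` holds the genetic contribution of
    her (dead) mate, used to fertilize her brood.
    """

    patch: np.ndarray  # (M,) int64, non-decreasing
    alleles: np.ndarray  # (M, 3, 2) float64
    mate_alleles: np.ndarray  # (M, 3, 2) float64

    def __len__(self) -> int:
        return self.patch.shape[0]


@dataclass
class Broods:
    """Juveniles of one generation, before mating."""

    son_patch: np.ndarray
    son_alleles: np.ndarray
    dau_patch: np.ndarray
    dau_alleles: np.ndarray
    n_forced: int  # forced extra offspring included above (2 per occupied patch)

    @property
    def n_sons(self) -> int:
        return self.son_patch.shape[0]

    @property
    def n_daughters(self) -> int:
        return self.dau_patch.shape[0]

    @property
    def n_total(self) -> int:
        return self.n_sons + self.n_daughters


@dataclass
class MatedDaughters:
    """Mated daughters between mating and regulation."""

    patch: np.ndarray  # current patch (natal until a successful dispersal)
    alleles: np.ndarray
    mate_alleles: np.ndarray

    def __len__(self) -> int:
        return self.patch.shape[0]


@dataclass(frozen=True)
class DispersalTally:
    n_daughters: int
    n_attempts: int
    n_deaths: int
    n_migrants: int

    @property
    def attempt_fraction(self) -> float:
        return self.n_attempts / self.n_daughters if self.n_daughters else float("nan")


def _patch_layout(patch_sorted: np.ndarray, n_patches: int):
    """Counts and start offsets per patch for a patch-sorted cohort."""
    counts = np.bincount(patch_sorted, minlength=n_patches)
    starts = np.zeros(n_patches, dtype=np.int64)
    np.cumsum(counts[:-1], out=starts[1:])
    return counts, starts


def _make_offspring(
    mothers: Mothers,
    mom_idx: np.ndarray,
    male: bool,
    mode: InheritanceMode,
    mutation: MutationParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Genotypes of offspring of ``mothers[mom_idx]``, inherited + mutated.

    Returns an (K, 3, 2) allele array in the duplicated-haploid convention.
    Per locus, the maternal gamete is a uniform draw from the mother's pair
    (both slots equal for haploid mothers, so the draw is a no-op there) and
    the paternal gamete likewise from the stored mate contribution.
    """
    k = mom_idx.shape[0]
    mom = mothers.alleles[mom_idx]  # (K, 3, 2)
    pat = mothers.mate_alleles[mom_idx]
    rows = np.arange(k)[:, None]
    cols = np.arange(3)[None, :]
    maternal = mom[rows, cols, rng.integers(0, 2, size=(k, 3))]

    if mode is InheritanceMode.HAPLOID:
        paternal = pat[:, :, 0]
        genes = np.where(rng.random((k, 3)) < 0.5, maternal, paternal)
        mutate_alleles(genes, mutation, rng)
        return np.repeat(genes[:, :, None], 2, axis=2)
    if mode is InheritanceMode.DIPLOID:
        paternal = pat[rows, cols, rng.integers(0, 2, size=(k, 3))]
        genes = np.stack([maternal, paternal], axis=2)
        return mutate_alleles(genes, mutation, rng)
    # haplodiploid
    if male:  # unfertilized: maternal gamete only, haploid
        mutate_alleles(maternal, mutation, rng)
        return np.repeat(maternal[:, :, None], 2, axis=2)
    genes = np.stack([maternal, pat[:, :, 0]], axis=2)
    return mutate_alleles(genes, mutation, rng)


def produce_brood(mothers: Mothers, config: TreatmentConfig, rng: np.random.Generator) -> Broods:
    """Brood production across all patches.

    Each mother bears ``config.brood`` offspring whose sexes are i.i.d.
    Bernoulli draws with her expressed sex-allocation probability; on every
    occupied patch one uniformly chosen mother additionally bears a guaranteed
    son, and one independently chosen mother a guaranteed daughter, so every
    patch with mothers yields at least one of each sex.  Offspring genotypes
    follow the configured inheritance scheme and are then mutated.
    """
    m = len(mothers)
    empty = np.empty(0, dtype=np.int64), np.empty((0, 3, 2))
    if m == 0:
        return Broods(*empty, *empty, n_forced=0)
    if not np.isfinite(mothers.mate_alleles).all():
        raise ValueError("unmated or corrupt mother: mate contribution must be finite")

    z = np.clip(mothers.alleles[:, 0, :].mean(axis=1), 0.0, 1.0)
    mom_of = np.repeat(np.arange(m), config.brood)
    is_son = rng.random(m * config.brood) < z[mom_of]

    counts, starts = _patch_layout(mothers.patch, config.n_patches)
    occ = np.flatnonzero(counts)
    forced_son_mom = starts[occ] + rng.integers(0, counts[occ])
    forced_dau_mom = starts[occ] + rng.integers(0, counts[occ])

    son_moms = np.concatenate([mom_of[is_son], forced_son_mom])
    dau_moms = np.concatenate([mom_of[~is_son], forced_dau_mom])
    return Broods(
        son_patch=mothers.patch[son_moms],
        son_alleles=_make_offspring(mothers, son_moms, True, config.mode, config.mutation, rng),
        dau_patch=mothers.patch[dau_moms],
        dau_alleles=_make_offspring(mothers, dau_moms, False, config.mode, config.mutation, rng),
        n_forced=2 * occ.shape[0],
    )


def mate_within_patch(
    broods: Broods, config: TreatmentConfig, rng: np.random.Generator
) -> MatedDaughters:
    """Random mating within each natal patch.

    Every daughter mates once with an independently, uniformly chosen male of
    her patch (males can mate repeatedly); his genetic contribution is stored
    with her.  All males then die.  A daughter's patch is guaranteed to hold a
    male by the forced-extra-son rule.
    """
    if broods.n_daughters == 0:
        return MatedDaughters(
            np.empty(0, dtype=np.int64), np.empty((0, 3, 2)), np.empty((0, 3, 2))
        )
    order = np.argsort(broods.son_patch, kind="stable")
    counts, starts = _patch_layout(broods.son_patch[order], config.n_patches)
    dpatch = broods.dau_patch
    if not (counts[dpatch] > 0).all():
        raise AssertionError("patch with daughters but no male: forced-son rule violated")
    chosen = starts[dpatch] + rng.integers(0, counts[dpatch])
    return MatedDaughters(
        patch=dpatch.copy(),
        alleles=broods.dau_alleles,
        mate_alleles=broods.son_alleles[order[chosen]],
    )


def normalized_density(D, config: TreatmentConfig):
    """Normalized local daughter density rho = D / D_max, clamped to [0, 1].

    ``D_max = brood * n + 1`` is the largest locally producible daughter
    count; clamping covers counts inflated past it (e.g. by immigration).
    Accepts scalars or arrays.
    """
    D = np.asarray(D)
    if (D < 0).any():
        raise ValueError("daughter count must be non-negative")
    return np.clip(D / config.d_max, 0.0, 1.0)


def dispersal_step(
    daughters: MatedDaughters, config: TreatmentConfig, rng: np.random.Generator
) -> tuple[MatedDaughters, DispersalTally]:
    """Density-dependent dispersal of mated daughters.

    Densities are assessed on the natal patch once, before anyone moves.  Each
    daughter attempts dispersal with her reaction-norm probability at that
    density (or with her flat zero-density value when the control model is
    configured); an attempter dies with probability ``c`` and otherwise
    relocates to a uniformly chosen non-natal patch.
    """
    jd = len(daughters)
    if jd == 0:
        return daughters, DispersalTally(0, 0, 0, 0)
    p0 = daughters.alleles[:, 1, :].mean(axis=1)
    if config.dispersal_model == "flat":
        p = np.clip(p0, 0.0, 1.0)
    else:
        counts = np.bincount(daughters.patch, minlength=config.n_patches)
        rho = normalized_density(counts, config)[daughters.patch]
        p1 = daughters.alleles[:, 2, :].mean(axis=1)
        p = np.clip(p0 + (p1 - p0) * rho, 0.0, 1.0)

    attempt = rng.random(jd) < p
    dies = attempt & (rng.random(jd) < config.c)
    migrates = attempt & ~dies
    new_patch = daughters.patch.copy()
    k = int(migrates.sum())
    if k:
        dest = rng.integers(0, config.n_patches - 1, size=k)
        dest += dest >= daughters.patch[migrates]
        new_patch[migrates] = dest
    survives = ~dies
    out = MatedDaughters(
        patch=new_patch[survives],
        alleles=daughters.alleles[survives],
        mate_alleles=daughters.mate_alleles[survives],
    )
    tally = DispersalTally(jd, int(attempt.sum()), int(dies.sum()), k)
    return out, tally


def regulate(
    daughters: MatedDaughters, n: int, n_patches: int, rng: np.random.Generator
) -> Mothers:
    """Density regulation: at most ``n`` mothers survive per patch.

    On patches holding more than ``n`` mated daughters, ``n`` are sampled
    uniformly without replacement (every subset equally likely); smaller
    patches keep everyone, possibly leaving the patch under-filled or empty.
    """
    jd = len(daughters)
    if jd == 0:
        return Mothers(np.empty(0, dtype=np.int64), np.empty((0, 3, 2)), np.empty((0, 3, 2)))
    order = np.lexsort((rng.random(jd), daughters.patch))
    sp = daughters.patch[order]
    _, starts = _patch_layout(sp, n_patches)
    rank = np.arange(jd) - starts[sp]
    sel = order[rank < n]
    return Mothers(
        patch=daughters.patch[sel],
        alleles=daughters.alleles[sel],
        mate_alleles=daughters.mate_alleles[sel],
    )
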