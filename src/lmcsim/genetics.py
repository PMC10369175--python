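"""Genome representation, phenotype expression, inheritance and mutation.

Each individual carries three real-valued loci:

0. sex allocation — the probability that each of a mother's offspring is a son;
1. dispersal probability at zero local daughter density;
2. dispersal probability at maximum local daughter density.

Allelic values are unbounded reals.  Clipping to [0, 1] happens only when a
phenotype is expressed: a sex-allocation value below zero means an all-daughter
brood, above one an all-son brood, and likewise for dispersal probabilities.
Expression is additive (the mean of an individual's alleles at the locus).

Three genetic systems are supported: haploidy, diploidy, and haplodiploidy
(diploid females from fertilized eggs, haploid males from unfertilized eggs).

This module keeps the per-individual object semantics (:class:`Genotype` and
the scalar operations on it); the simulation engine in :mod:`lmcsim.demography`
applies the same rules to whole cohorts at once, and the two are held together
by the shared array kernels (:func:`mutate_alleles`) and by tests.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InheritanceMode",
    "MutationParams",
    "Genotype",
    "Sex",
    "express_sex_allocation",
    "express_dispersal_prob",
    "inherit",
    "mutate",
    "mutate_alleles",
]

N_LOCI = 3

LOCUS_SEX_ALLOCATION = 0
LOCUS_DISPERSAL_ZERO = 1
LOCUS_DISPERSAL_MAX = 2


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"


class InheritanceMode(enum.Enum):
    """Genetic system of the simulated population."""

    HAPLOID = "haploid"
    DIPLOID = "diploid"
    HAPLODIPLOID = "haplodiploid"

    def ploidy(self, sex: Sex) -> int:
        """Number of alleles carried per locus by an individual of ``sex``."""
        if self is InheritanceMode.HAPLOID:
            return 1
        if self is InheritanceMode.DIPLOID:
            return 2
        return 2 if sex is Sex.FEMALE else 1


@dataclass(frozen=True)
class MutationParams:
    """Per-gene mutation model: with probability ``rate`` an allelic value is
    incremented by a Gaussian deviate of mean zero and standard deviation
    ``sd``."""

    rate: float = 0.01
    sd: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"mutation rate must be in [0, 1], got {self.rate}")
        if not self.sd > 0.0:
            raise ValueError(f"mutation sd must be > 0, got {self.sd}")


@dataclass(frozen=True)
class Genotype:
    """Allelic values at the three loci.

    ``loci`` holds one tuple per locus; each tuple has one allele (haploid
    individuals, haplodiploid males) or two (diploid individuals,
    haplodiploid females).  All loci of one individual share the same ploidy.
    """

    loci: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        if len(self.loci) != N_LOCI:
            raise ValueError(f"genotype must have {N_LOCI} loci, got {len(self.loci)}")
        ploidies = {len(alleles) for alleles in self.loci}
        if not ploidies <= {1, 2} or len(ploidies) != 1:
            raise ValueError(f"each locus must hold 1 or 2 alleles uniformly, got {self.loci}")
        for alleles in self.loci:
            for a in alleles:
                if not math.isfinite(a):
                    raise ValueError(f"allelic values must be finite, got {a}")

    @property
    def ploidy(self) -> int:
        return len(self.loci[0])

    @classmethod
    def haploid(cls, z: float, p0: float, p1: float) -> "Genotype":
        return cls(((z,), (p0,), (p1,)))

    @classmethod
    def diploid(cls, z, p0, p1) -> "Genotype":
        """Build from per-locus pairs; scalars are duplicated (homozygote)."""
        as_pair = lambda v: tuple(v) if isinstance(v, (tuple, list)) else (float(v), float(v))
        return cls((as_pair(z), as_pair(p0), as_pair(p1)))

    def locus_mean(self, locus: int) -> float:
        alleles = self.loci[locus]
        return sum(alleles) / len(alleles)


def _clip01(x: float) -> float:
    return 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)


def express_sex_allocation(genotype: Genotype) -> float:
    """Probability that each of this mother's offspring is a son.

    The mean of her alleles at the sex-allocation locus, clipped to [0, 1]:
    values below zero are expressed as an all-daughter strategy, values above
    one as an all-son strategy.
    """
    return _clip01(genotype.locus_mean(LOCUS_SEX_ALLOCATION))


def express_dispersal_prob(genotype: Genotype, rho: float) -> float:
    """Dispersal probability of a mated daughter at normalized density ``rho``.

    A linear reaction norm connects the expressed values at zero density
    (locus 1) and maximum density (locus 2); the interpolated value is clipped
    to [0, 1].
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"normalized density must be in [0, 1], got {rho}")
    p0 = genotype.locus_mean(LOCUS_DISPERSAL_ZERO)
    p1 = genotype.locus_mean(LOCUS_DISPERSAL_MAX)
    return _clip01(p0 + (p1 - p0) * rho)


def inherit(
    mother: Genotype,
    father: Genotype | None,
    mode: InheritanceMode,
    offspring_sex: Sex,
    rng: np.random.Generator,
) -> Genotype:
    """Transmit alleles from parents to one offspring.

    Loci assort independently (free recombination).  Per locus:

    * haploid — the offspring's single allele is the maternal or the paternal
      allele with equal probability;
    * diploid — one allele drawn uniformly from the mother's pair plus one
      drawn uniformly from the father's pair;
    * haplodiploid — daughters (fertilized) receive one maternal draw plus the
      father's single allele; sons (unfertilized) receive one maternal draw
      only, and must have no father.

    Mutation is a separate step (:func:`mutate`).
    """
    if mother.ploidy != mode.ploidy(Sex.FEMALE):
        raise ValueError(f"mother ploidy {mother.ploidy} inconsistent with {mode}")
    if mode is InheritanceMode.HAPLODIPLOID and offspring_sex is Sex.MALE:
        if father is not None:
            raise ValueError("haplodiploid sons develop from unfertilized eggs: no father allowed")
    else:
        if father is None:
            raise ValueError(f"{mode.value} {offspring_sex.value} offspring requires a father")
        if father.ploidy != mode.ploidy(Sex.MALE):
            raise ValueError(f"father ploidy {father.ploidy} inconsistent with {mode}")

    def mat(locus: int) -> float:
        alleles = mother.loci[locus]
        return alleles[rng.integers(len(alleles))]

    loci: list[tuple[float, ...]] = []
    for locus in range(N_LOCI):
        if mode is InheritanceMode.HAPLOID:
            pat = father.loci[locus][0]
            loci.append((mat(locus),) if rng.random() < 0.5 else ((pat,)))
        elif mode is InheritanceMode.DIPLOID:
            pat_pair = father.loci[locus]
            loci.append((mat(locus), pat_pair[rng.integers(len(pat_pair))]))
        else:  # haplodiploid
            if offspring_sex is Sex.MALE:
                loci.append((mat(locus),))
            else:
                loci.append((mat(locus), father.loci[locus][0]))
    return Genotype(tuple(loci))


def mutate_alleles(
    values: np.ndarray, params: MutationParams, rng: np.random.Generator
) -> np.ndarray:
    """Mutate an array of allelic values in place and return it.

    Each entry independently mutates with probability ``params.rate``, gaining
    a Normal(0, params.sd**2) increment.  The array is modified in place (the
    simulation engine's hot path) — callers owning immutable data must copy.
    """
    if params.rate <= 0.0 or values.size == 0:
        return values
    mask = rng.random(values.shape) < params.rate
    k = int(mask.sum())
    if k:
        values[mask] += rng.standard_normal(k) * params.sd
    return values


def mutate(genotype: Genotype, params: MutationParams, rng: np.random.Generator) -> Genotype:
    """Return a copy of ``genotype`` after one round of mutation."""
    flat = np.array([a for alleles in genotype.loci for a in alleles], dtype=float)
    mutate_alleles(flat, params, rng)
    out, i = [], 0
    for alleles in genotype.loci:
        out.append(tuple(flat[i : i + len(alleles)]))
        i += len(alleles)
    return Genotype(tuple(out))
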