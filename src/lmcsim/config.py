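"""Treatment configuration and named size presets."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .genetics import InheritanceMode, MutationParams

__all__ = ["TreatmentConfig", "preset", "PRESETS"]

#: Named problem-size profiles: (n_patches, generations, record_window).
#: ``paper`` is the full-scale study design; ``scaled`` and ``quick`` are
#: reduced profiles whose equilibria match ``paper`` up to Monte Carlo error
#: and which fit on a single desk CPU (see docs/methods.md).
PRESETS: dict[str, tuple[int, int, int]] = {
    "paper": (1000, 100_000, 50_000),
    "scaled": (250, 20_000, 10_000),
    "quick": (100, 8_000, 4_000),
}


@dataclass(frozen=True)
class TreatmentConfig:
    """Full parameterization of one simulation run.

    Parameters
    ----------
    mode : InheritanceMode
        Genetic system (haploid, diploid or haplodiploid).
    n : int
        Foundresses per patch (the study grid uses 1, 2, 5, 10).
    c : float
        Mortality cost of dispersal, in (0, 1) (grid: 0.2, 0.4, 0.6, 0.8).
    n_patches : int
        Number of discrete patches (>= 2, so a dispersal destination exists).
    brood : int
        Offspring per mother, before the forced extra son/daughter.
    mutation : MutationParams
        Per-gene mutation rate and increment scale.
    generations : int
        Length of the run.
    record_window : int
        Summary statistics are averaged over this many final generations.
    seed : int
        Seed of the run's random generator; identical configs with identical
        seeds reproduce bit-for-bit.
    dispersal_model : str
        ``"density_dependent"`` — evolving linear reaction norm between the
        zero-density and maximum-density loci (the focal model);
        ``"flat"`` — dispersal probability is the zero-density locus
        regardless of density (the density-independent control under which
        the Bulmer-Frank invariant is expected to hold).
    z0 : float or None
        Override for the founding sex-allocation allelic value; ``None``
        uses the classical local-mate-competition value (n-1)/(2n).
    """

    mode: InheritanceMode = InheritanceMode.DIPLOID
    n: int = 1
    c: float = 0.2
    n_patches: int = 1000
    brood: int = 10
    mutation: MutationParams = field(default_factory=MutationParams)
    generations: int = 100_000
    record_window: int = 50_000
    seed: int = 0
    dispersal_model: str = "density_dependent"
    z0: float | None = None

    def __post_init__(self) -> None:
        if isinstance(self.mode, str):  # tolerate CLI/CSV round-trips
            object.__setattr__(self, "mode", InheritanceMode(self.mode))
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not 0.0 < self.c < 1.0:
            raise ValueError(f"c must be in (0, 1), got {self.c}")
        if self.n_patches < 2:
            raise ValueError(f"n_patches must be >= 2, got {self.n_patches}")
        if self.brood < 1:
            raise ValueError(f"brood must be >= 1, got {self.brood}")
        if self.generations < 1:
            raise ValueError(f"generations must be >= 1, got {self.generations}")
        if not 1 <= self.record_window <= self.generations:
            raise ValueError(
                f"record_window must be in [1, generations], got {self.record_window}"
            )
        if self.dispersal_model not in ("density_dependent", "flat"):
            raise ValueError(f"unknown dispersal_model {self.dispersal_model!r}")

    @property
    def d_max(self) -> int:
        """Largest daughter count a patch can produce locally: an all-daughter
        brood from each of ``n`` mothers plus the forced extra daughter,
        capped by the forced extra son."""
        return self.brood * self.n + 1

    def replace(self, **kwargs) -> "TreatmentConfig":
        return dataclasses.replace(self, **kwargs)


def preset(name: str, **overrides) -> TreatmentConfig:
    """Build a :class:`TreatmentConfig` from a named size profile.

    >>> cfg = preset("scaled", mode="haploid", n=2, c=0.4, seed=1)
    """
    try:
        n_patches, generations, window = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    base = dict(n_patches=n_patches, generations=generations, record_window=window)
    base.update(overrides)
    return TreatmentConfig(**base)
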