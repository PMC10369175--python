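"""Closed-form baselines used to initialize and benchmark the simulations.

Both quantities refer to the classical island-model setting in which ``n``
mated foundresses breed per patch and dispersing daughters die with
probability ``c``: the evolutionarily stable (density-independent) dispersal
probability, and the local-mate-competition sex-allocation value that is
invariant with respect to that dispersal rate (the Bulmer-Frank invariant).
"""

from __future__ import annotations

import math

__all__ = ["density_independent_dispersal", "init_sex_allocation"]


def density_independent_dispersal(n: int, c: float) -> float:
    """Unbeatable density-independent dispersal probability.

    d* = 2 / (1 + 2cn + sqrt(1 + 4n(n-1)c^2)),

    which reduces to 1/(1+c) for a single foundress (n = 1).

    Parameters
    ----------
    n : int
        Number of foundresses per patch, >= 1.
    c : float
        Mortality cost of dispersal, in (0, 1] (c = 1 is the lethal limit).

    Returns
    -------
    float
        d* in (0, 1].
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0.0 < c <= 1.0:
        raise ValueError(f"c must be in (0, 1], got {c}")
    return 2.0 / (1.0 + 2.0 * c * n + math.sqrt(1.0 + 4.0 * n * (n - 1) * c * c))


def init_sex_allocation(n: int, mode=None) -> float:
    """Sex-allocation value used to found the population.

    Returns the classical local-mate-competition proportion of sons,
    z0 = (n - 1) / (2n), for every inheritance mode.  This is the value the
    Bulmer-Frank invariant pins for haploidy and diploidy; for haplodiploidy
    it is used as a convenient starting point.  Because the population is
    evolved through a long mutation-selection burn-in, the equilibrium does
    not depend on this choice (checked by an initialization-independence
    test); ``TreatmentConfig.z0`` can override it.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return (n - 1) / (2.0 * n)
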