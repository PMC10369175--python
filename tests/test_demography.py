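"""Lifecycle steps: brood production, mating, dispersal, regulation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_mothers
from lmcsim.config import TreatmentConfig
from lmcsim.demography import (
    MatedDaughters,
    dispersal_step,
    mate_within_patch,
    normalized_density,
    produce_brood,
    regulate,
)
from lmcsim.genetics import InheritanceMode, MutationParams

NO_MUT = MutationParams(rate=0.0, sd=0.1)


def cfg_for(n_patches, n, c=0.4, **kw):
    kw.setdefault("mutation", NO_MUT)
    kw.setdefault("generations", 10)
    kw.setdefault("record_window", 5)
    return TreatmentConfig(n_patches=n_patches, n=n, c=c, **kw)


class TestProduceBrood:
    def test_single_foundress_brood_size_and_sexes(self, rng):
        """n = 1: 10 regular offspring + forced son + forced daughter = 12."""
        cfg = cfg_for(50, 1)
        broods = produce_brood(make_mothers(50, 1, z=0.5), cfg, rng)
        assert broods.n_total == 50 * 12
        son_counts = np.bincount(broods.son_patch, minlength=50)
        dau_counts = np.bincount(broods.dau_patch, minlength=50)
        assert (son_counts >= 1).all() and (dau_counts >= 1).all()
        assert (son_counts + dau_counts == 12).all()

    def test_all_daughter_strategy_keeps_exactly_one_son(self, rng):
        cfg = cfg_for(40, 1)
        broods = produce_brood(make_mothers(40, 1, z=-0.5), cfg, rng)
        assert (np.bincount(broods.son_patch, minlength=40) == 1).all()
        assert (np.bincount(broods.dau_patch, minlength=40) == 11).all()

    def test_son_fraction_binomial_at_half(self, rng):
        cfg = cfg_for(100, 10)
        broods = produce_brood(make_mothers(100, 10, z=0.5), cfg, rng)
        regular = broods.n_total - broods.n_forced  # exclude 2 forced per patch
        sons_regular = broods.n_sons - 100  # one forced son per patch
        sd3 = 3 * np.sqrt(0.25 / regular)
        assert abs(sons_regular / regular - 0.5) < sd3

    def test_unmated_mother_rejected(self, rng):
        cfg = cfg_for(5, 1)
        with pytest.raises(ValueError, match="unmated"):
            produce_brood(make_mothers(5, 1, mate_nan=True), cfg, rng)

    def test_empty_population_produces_nothing(self, rng):
        cfg = cfg_for(5, 1)
        broods = produce_brood(make_mothers(5, 1).__class__(
            patch=np.empty(0, dtype=np.int64),
            alleles=np.empty((0, 3, 2)),
            mate_alleles=np.empty((0, 3, 2)),
        ), cfg, rng)
        assert broods.n_total == 0


class TestMating:
    def test_single_male_fathers_everyone(self, rng):
        cfg = cfg_for(30, 1)
        broods = produce_brood(make_mothers(30, 1, z=-1.0, p0=0.11, p1=0.11), cfg, rng)
        daughters = mate_within_patch(broods, cfg, rng)
        # each patch has exactly one male; every daughter must carry his genome
        assert np.allclose(daughters.mate_alleles[:, 1, :], 0.11)
        assert len(daughters) == broods.n_daughters

    def test_fathers_chosen_uniformly(self, rng):
        """Two males on one patch: each fathers ~half of 10,000 daughters."""
        from lmcsim.demography import Broods

        cfg = cfg_for(2, 2)
        son_alleles = np.zeros((2, 3, 2))
        son_alleles[1] = 1.0  # tag the second male
        broods = Broods(
            son_patch=np.zeros(2, dtype=np.int64),
            son_alleles=son_alleles,
            dau_patch=np.zeros(10_000, dtype=np.int64),
            dau_alleles=np.zeros((10_000, 3, 2)),
            n_forced=0,
        )
        daughters = mate_within_patch(broods, cfg, rng)
        share = daughters.mate_alleles[:, 0, 0].mean()
        assert abs(share - 0.5) < 3 * np.sqrt(0.25 / 10_000)

    def test_no_daughters_is_fine(self, rng):
        cfg = cfg_for(10, 1)
        broods = produce_brood(make_mothers(10, 1, z=2.0), cfg, rng)  # all-son
        daughters = mate_within_patch(broods, cfg, rng)
        assert len(daughters) == 10  # only the forced daughters remain


class TestNormalizedDensity:
    def test_examples(self):
        assert normalized_density(0, cfg_for(10, 1)) == 0.0
        assert normalized_density(11, cfg_for(10, 1)) == 1.0  # D_max = 11 at n=1
        assert normalized_density(10, cfg_for(10, 2)) == pytest.approx(10 / 21)

    def test_clamped_above_dmax_and_negative_rejected(self):
        cfg = cfg_for(10, 1)
        assert normalized_density(25, cfg) == 1.0
        with pytest.raises(ValueError):
            normalized_density(-1, cfg)


def _daughters_on(patches, n_patches, p0=0.0, p1=0.0):
    k = len(patches)
    alleles = np.zeros((k, 3, 2))
    alleles[:, 1, :] = p0
    alleles[:, 2, :] = p1
    return MatedDaughters(
        patch=np.asarray(patches, dtype=np.int64),
        alleles=alleles,
        mate_alleles=np.zeros((k, 3, 2)),
    )


class TestDispersal:
    def test_no_dispersal_genotype_changes_nothing(self, rng):
        cfg = cfg_for(20, 2)
        d = _daughters_on(np.repeat(np.arange(20), 5), 20, p0=-1.0, p1=-1.0)
        out, tally = dispersal_step(d, cfg, rng)
        assert tally.n_attempts == tally.n_deaths == tally.n_migrants == 0
        assert np.array_equal(out.patch, d.patch)

    def test_obligate_dispersal_survival_fraction(self):
        rng = np.random.default_rng(1)
        cfg = cfg_for(50, 2, c=0.4)
        d = _daughters_on(np.repeat(np.arange(50), 200), 50, p0=2.0, p1=2.0)
        out, tally = dispersal_step(d, cfg, rng)
        assert tally.n_attempts == 10_000
        surv = len(out) / 10_000
        assert abs(surv - 0.6) < 3 * np.sqrt(0.6 * 0.4 / 10_000)

    def test_conservation_of_daughters(self, rng):
        cfg = cfg_for(30, 2, c=0.6)
        d = _daughters_on(np.repeat(np.arange(30), 7), 30, p0=0.5, p1=0.5)
        out, tally = dispersal_step(d, cfg, rng)
        stayers = tally.n_daughters - tally.n_attempts
        assert tally.n_attempts == tally.n_deaths + tally.n_migrants
        assert len(out) == stayers + tally.n_migrants

    def test_migrants_avoid_natal_patch(self, rng):
        cfg = cfg_for(3, 2, c=0.2)
        d = _daughters_on(np.zeros(5000, dtype=int), 3, p0=2.0, p1=2.0)
        out, _ = dispersal_step(d, cfg, rng)
        assert (out.patch != 0).all()
        assert set(np.unique(out.patch)) == {1, 2}

    def test_flat_model_ignores_density(self, rng):
        cfg = cfg_for(40, 2, dispersal_model="flat")
        # p0 = 0.3 everywhere; p1 huge would dominate under the reaction norm
        d = _daughters_on(np.repeat(np.arange(40), 21), 40, p0=0.3, p1=50.0)
        _, tally = dispersal_step(d, cfg, rng)
        assert abs(tally.attempt_fraction - 0.3) < 3 * np.sqrt(0.3 * 0.7 / len(d.patch))


class TestRegulate:
    def test_truncates_to_n(self, rng):
        d = _daughters_on(np.zeros(15, dtype=int), 1)
        mothers = regulate(d, 10, 1, rng)
        assert len(mothers) == 10

    def test_underfilled_patch_keeps_everyone(self, rng):
        d = _daughters_on([0, 0, 0], 2)
        mothers = regulate(d, 5, 2, rng)
        assert len(mothers) == 3

    def test_empty_patchset(self, rng):
        d = _daughters_on([], 4)
        assert len(regulate(d, 3, 4, rng)) == 0

    def test_every_pair_equally_likely(self, rng):
        """4 daughters, n = 2: all 6 unordered pairs appear uniformly."""
        counts = {pair: 0 for pair in itertools.combinations(range(4), 2)}
        for _ in range(6000):
            d = _daughters_on(np.zeros(4, dtype=int), 1)
            d.alleles[:, 0, 0] = np.arange(4)  # tag individuals
            kept = regulate(d, 2, 1, rng)
            counts[tuple(sorted(kept.alleles[:, 0, 0].astype(int)))] += 1
        expected = 1000.0
        from scipy import stats as sps

        assert sps.chisquare(list(counts.values())).pvalue > 0.001


@settings(derandomize=True, max_examples=50)
@given(
    counts=st.lists(st.integers(0, 25), min_size=3, max_size=40),
    k1=st.integers(0, 26),
    k2=st.integers(0, 26),
)
def test_undersized_fraction_monotone_in_threshold(counts, k1, k2):
    from lmcsim.metrics import undersized_patch_fraction

    counts = np.asarray(counts)
    if not (counts > 0).any():
        return
    lo, hi = sorted((k1, k2))
    assert undersized_patch_fraction(counts, lo) <= undersized_patch_fraction(counts, hi)
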