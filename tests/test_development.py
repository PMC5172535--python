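"""Development of zygotes into adults: lineage growth, germline, tissues,
ageing, and organism fitness."""

import json
import math

import numpy as np
import pytest

from mitogerm.cells import FitnessParams, MitoCell, MutationRates
from mitogerm.development import (
    LifeCycleParams,
    Organism,
    adult_fitness,
    adult_fitness_cohort,
    age_cohort,
    age_organism,
    develop,
    develop_cohort,
    organism_from_json,
    organism_to_json,
    tissue_fitness,
)
from mitogerm.genotypes import NuclearGenotype, TraitModel, TraitSet

ZERO = MutationRates(0.0, 0.0)


def small_model(L, n_g=None, a=0, q=0):
    t = TraitSet(n_g=L if n_g is None else n_g, a=a, q=q)
    return TraitModel(resident=t, invader=t)


class TestDevelop:
    def test_cell_count_is_two_to_the_L(self, rng):
        lc = LifeCycleParams(L=3, T=0, S=10)
        org = develop(
            MitoCell(0, 50), NuclearGenotype("ZW"), lc, ZERO, rng, small_model(3)
        )
        assert org.soma_m.size == 8
        assert org.age == lc.L

    def test_mutation_free_zygote_stays_clean(self, rng):
        lc = LifeCycleParams(L=4, T=2, S=10)
        org = develop(
            MitoCell(0, 50), NuclearGenotype("ZW"), lc, ZERO, rng, small_model(4)
        )
        assert np.all(org.soma_m == 0)
        assert np.all(org.germ_m == 0)

    def test_oogamous_zygote_restores_baseline_after_q_divisions(self, rng):
        # 800 = 2^4 * 50 mitochondria are partitioned without replication
        # over four divisions until M=50 per cell is restored
        lc = LifeCycleParams(L=4, T=0, S=10)
        soma, _, _ = develop_cohort(
            np.array([0]), np.array([800]), np.array([4]), np.array([0]), lc, ZERO, rng
        )
        assert soma.shape == (1, 16)
        # every cell is at baseline: mutant counts bounded by M and totals
        # implicit — run again with a fully mutant zygote to see totals
        soma_full, _, _ = develop_cohort(
            np.array([800]),
            np.array([800]),
            np.array([4]),
            np.array([0]),
            lc,
            ZERO,
            rng,
        )
        assert np.all(soma_full == 50)

    def test_partition_only_rounds_conserve_mutants(self, rng):
        lc = LifeCycleParams(L=4, T=0, S=10)
        soma, _, _ = develop_cohort(
            np.array([160]),
            np.array([800]),
            np.array([4]),
            np.array([0]),
            lc,
            ZERO,
            rng,
        )
        assert soma.sum() == 160  # purely redistributive, nothing created

    def test_germline_proliferation_yields_2_to_a_cells(self, rng):
        lc = LifeCycleParams(L=6, T=0, S=10)
        org = develop(
            MitoCell(10, 50),
            NuclearGenotype("ZW"),
            lc,
            ZERO,
            rng,
            small_model(6, n_g=3, a=2),
        )
        assert org.germ_m.size == 4

    def test_configuration_errors(self, rng):
        lc = LifeCycleParams(L=4, T=0, S=10)
        with pytest.raises(ValueError):  # n_g > L
            develop_cohort(
                np.array([0]), np.array([50]), np.array([5]), np.array([0]),
                lc, ZERO, rng,
            )
        with pytest.raises(ValueError):  # n_g + a > L
            develop_cohort(
                np.array([0]), np.array([50]), np.array([3]), np.array([2]),
                lc, ZERO, rng,
            )
        with pytest.raises(ValueError):  # sequestration before baseline restored
            develop_cohort(
                np.array([0]), np.array([800]), np.array([2]), np.array([0]),
                lc, ZERO, rng,
            )
        with pytest.raises(ValueError):  # zygote total not M * 2^k
            develop_cohort(
                np.array([0]), np.array([60]), np.array([4]), np.array([0]),
                lc, ZERO, rng,
            )


class TestAgeing:
    def test_no_background_rate_means_no_change(self, rng):
        lc = LifeCycleParams(L=3, T=0, S=20)
        org = develop(
            MitoCell(5, 50), NuclearGenotype("ZW"), lc, ZERO, rng, small_model(3)
        )
        aged = age_organism(org, lc, ZERO, rng)
        assert np.array_equal(aged.soma_m, org.soma_m)
        assert aged.age == 20

    def test_mean_background_accumulation(self, rng):
        # 30 time units at mu_B=0.005 on clean cells: per-copy mutation
        # probability 1-(1-mu_B)^30, so mean mutants ~= 50 * 0.1396 ~= 7.0
        mu_B = 0.005
        units = 30
        n_cells = 10_000
        soma = np.zeros((10, n_cells // 10), dtype=np.int64)
        germ = np.zeros((10, 1), dtype=np.int64)
        lc = LifeCycleParams(L=1, T=0, S=40)
        soma, _ = age_cohort(
            soma, germ, np.ones(10, dtype=np.int64), units,
            lc, MutationRates(0.0, mu_B), rng,
        )
        p = 1 - (1 - mu_B) ** units
        se = math.sqrt(50 * p * (1 - p) / n_cells)
        assert abs(soma.mean() - 50 * p) < 3 * se

    def test_germline_background_exposure_exceeds_soma(self, rng):
        # a germ cell sequestered at division 3 sees S-3 = 37 background
        # units, versus S-L = 30 for soma sequestered at the end of
        # development (L=10)
        lc = LifeCycleParams(L=10, T=0, S=40)
        org = develop(
            MitoCell(0, 50),
            NuclearGenotype("ZW"),
            lc,
            ZERO,
            rng,
            small_model(10, n_g=3),
        )
        org = age_organism(org, lc, ZERO, rng)
        assert org.germ_postsequestration_exposure == 37
        assert org.age - org.lc.L == 30


def _organism_from_counts(counts, lc, rng=None):
    return Organism(
        soma_m=np.asarray(counts, dtype=np.int64),
        germ_m=np.array([0]),
        genotype=NuclearGenotype("ZW"),
        lc=lc,
        age=lc.S,
        n_g=lc.L,
    )


class TestFitness:
    def test_clean_tissue_has_unit_fitness(self):
        lc = LifeCycleParams(L=2, T=1, S=10)
        org = _organism_from_counts([0, 0, 0, 0], lc)
        fp = FitnessParams(s=1.0, xi=2.0)
        assert tissue_fitness(org, 0, fp) == 1.0

    def test_tissue_fitness_is_mean_of_cells(self):
        lc = LifeCycleParams(L=1, T=0, S=10)
        org = _organism_from_counts([0, 50], lc)
        fp = FitnessParams(s=1.0, xi=2.0)
        assert tissue_fitness(org, 0, fp) == pytest.approx(0.5)

    def test_adult_fitness_is_worst_tissue(self, rng):
        lc = LifeCycleParams(L=2, T=2, S=10)
        org = _organism_from_counts([0, 10, 25, 40], lc)
        fp = FitnessParams(s=1.0, xi=2.0)
        per_tissue = [tissue_fitness(org, t, fp) for t in range(4)]
        assert adult_fitness(org, fp) == pytest.approx(min(per_tissue))

    def test_single_tissue_equals_overall_mean(self, rng):
        lc = LifeCycleParams(L=3, T=0, S=10)
        counts = [0, 5, 10, 15, 20, 25, 30, 35]
        org = _organism_from_counts(counts, lc)
        fp = FitnessParams(s=1.0, xi=2.0)
        assert adult_fitness(org, fp) == pytest.approx(tissue_fitness(org, 0, fp))

    def test_epsilon_interpolates_to_mean(self):
        lc = LifeCycleParams(L=2, T=2, S=10)
        org = _organism_from_counts([0, 10, 25, 40], lc)
        fp = FitnessParams(s=1.0, xi=2.0)
        per_tissue = np.array([tissue_fitness(org, t, fp) for t in range(4)])
        assert adult_fitness(org, fp, epsilon=0.0) == pytest.approx(per_tissue.mean())
        mid = adult_fitness(org, fp, epsilon=0.5)
        assert mid == pytest.approx(0.5 * per_tissue.mean() + 0.5 * per_tissue.min())

    def test_empty_tissue_rejected(self):
        lc = LifeCycleParams(L=2, T=1, S=10)
        org = _organism_from_counts([0, 0, 0, 0], lc)
        with pytest.raises(IndexError):
            org.tissue_cells(5)


class TestSegregationalFitnessEffects:
    """Cohort-level consequences of drift during development."""

    RATES = MutationRates(mu_S=0.01, mu_B=0.005)
    FP = FitnessParams(s=1.0, xi=2.0)

    def _mean_fitness(self, rng, T, M=50, q=0, n=2000, L=10):
        lc = LifeCycleParams(L=L, T=T, S=40, baseline_M=M)
        tot = 2**q * M
        zyg = np.full(n, round(0.2 * tot), dtype=np.int64)
        soma, germ, germ_n = develop_cohort(
            zyg, np.full(n, tot), np.full(n, L), np.zeros(n, dtype=np.int64),
            lc, self.RATES, rng,
        )
        soma, _ = age_cohort(soma, germ, germ_n, lc.S - lc.L, lc, self.RATES, rng)
        fit = adult_fitness_cohort(soma, lc, self.FP)
        return fit.mean(), fit.std(ddof=1) / math.sqrt(n), (soma, lc)

    def test_multiple_tissues_depress_mean_adult_fitness(self, rng):
        # with worst-tissue epistasis, segregation into 8 tissues hurts
        one, se1, _ = self._mean_fitness(rng, T=0)
        eight, se8, _ = self._mean_fitness(rng, T=3)
        assert one - eight > 3 * math.hypot(se1, se8)

    def test_oogamy_helps_mainly_with_tissue_differentiation(self, rng):
        # Q=4 suppresses early segregational variance; with worst-tissue
        # epistasis (T=3) that buys a large fitness gain, while with a single
        # tissue only the (much smaller) single-lineage variance channel and
        # the deferred copy-error rounds remain.
        base_T3, se_a, _ = self._mean_fitness(rng, T=3, q=0)
        oog_T3, se_b, _ = self._mean_fitness(rng, T=3, q=4)
        gain_T3 = oog_T3 - base_T3
        assert gain_T3 > 3 * math.hypot(se_a, se_b)
        base_T0, se_c, _ = self._mean_fitness(rng, T=0, q=0)
        oog_T0, se_d, _ = self._mean_fitness(rng, T=0, q=4)
        gain_T0 = oog_T0 - base_T0
        assert gain_T3 > 2.0 * abs(gain_T0)

    def test_more_mitochondria_reduce_between_tissue_variance(self, rng):
        _, _, (soma50, lc50) = self._mean_fitness(rng, T=3, M=50, n=1000)
        _, _, (soma200, lc200) = self._mean_fitness(rng, T=3, M=200, n=1000)

        def tissue_var(soma, lc):
            w = 1.0 - (soma / lc.baseline_M) ** 2
            tis = w.reshape(soma.shape[0], lc.n_tissues, -1).mean(axis=2)
            return tis.var(axis=1, ddof=1).mean()

        assert tissue_var(soma200, lc200) < tissue_var(soma50, lc50)


def test_organism_json_roundtrip(rng):
    lc = LifeCycleParams(L=3, T=1, S=12)
    org = develop(
        MitoCell(8, 50),
        NuclearGenotype("ZW", (0, 1), 0),
        lc,
        MutationRates(0.01, 0.005),
        rng,
        small_model(3),
    )
    text = organism_to_json(org)
    back = organism_from_json(text)
    assert np.array_equal(back.soma_m, org.soma_m)
    assert np.array_equal(back.germ_m, org.germ_m)
    assert back.genotype == org.genotype
    assert back.age == org.age
    json.loads(text)  # valid JSON document
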