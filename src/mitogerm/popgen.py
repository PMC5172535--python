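"""Population layer: selection, gametogenesis, fertilization, generations.

Discrete non-overlapping generations of N individuals (N/2 ZW females, N/2 ZZ
males).  Each generation: zygotes develop and age to the lifespan S; parents
are sampled with replacement, linearly weighted by adult fitness within each
sex; every offspring gets a fresh gametogenesis — the mother's chosen germ
cell is amplified through Q oogamy rounds (copy-error mutation + duplication)
and passed through meiosis (one duplication, two hypergeometric halvings) to
an egg of 2^Q M / 2 mitochondria; fertilization is strictly uniparental
(v=1): the sperm's mitochondria are discarded and the zygote's 2^Q M copies
are resampled binomially from the egg's mutant frequency.  Nuclear
transmission is Mendelian at the autosomal germline locus; the W (with its
oogamy allele) passes mother -> daughter and determines sex.

The whole generation step is vectorized across the population; a fixed seed
makes runs bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .cells import FitnessParams, MitoCell, MutationRates
from .development import (
    LifeCycleParams,
    adult_fitness_cohort,
    age_cohort,
    develop_cohort,
)
from .genotypes import INVADER, NuclearGenotype, TraitModel, phenotype_of

logger = logging.getLogger(__name__)

__all__ = [
    "SimParams",
    "Population",
    "phenotype_of",
    "select_parents",
    "oogamy_amplification",
    "meiosis",
    "fertilize",
    "next_generation",
    "develop_population",
    "invader_frequency",
]


@dataclass(frozen=True)
class SimParams:
    """Everything a generation step needs."""

    N: int = 500
    lc: LifeCycleParams = field(default_factory=LifeCycleParams)
    rates: MutationRates = field(default_factory=MutationRates)
    fp: FitnessParams = field(default_factory=FitnessParams)
    model: TraitModel = field(default_factory=TraitModel)
    epsilon: float = 1.0  # tissue-epistasis strength (1 = worst-tissue rule)

    def __post_init__(self) -> None:
        if self.N < 2 or self.N % 2:
            raise ValueError(f"N must be even and >= 2, got {self.N}")


@dataclass
class Population:
    """Array-backed population state at the zygote stage, plus cached adult
    state once developed.

    ``auto`` holds the two autosomal germline-locus allele ids per
    individual; ``w`` the W-linked allele id (-1 in males); ``female`` the
    sex mask.  Adult caches (soma/germ mutant counts, fitness) are filled by
    :func:`develop_population`.
    """

    zyg_m: np.ndarray
    zyg_tot: np.ndarray
    auto: np.ndarray
    w: np.ndarray
    female: np.ndarray
    generation: int = 0
    soma_m: np.ndarray | None = None
    germ_m: np.ndarray | None = None
    germ_n: np.ndarray | None = None
    fitness: np.ndarray | None = None

    @property
    def size(self) -> int:
        return self.zyg_m.size

    @property
    def developed(self) -> bool:
        return self.fitness is not None

    def copy(self) -> "Population":
        return Population(
            zyg_m=self.zyg_m.copy(),
            zyg_tot=self.zyg_tot.copy(),
            auto=self.auto.copy(),
            w=self.w.copy(),
            female=self.female.copy(),
            generation=self.generation,
            soma_m=None if self.soma_m is None else self.soma_m.copy(),
            germ_m=None if self.germ_m is None else self.germ_m.copy(),
            germ_n=None if self.germ_n is None else self.germ_n.copy(),
            fitness=None if self.fitness is None else self.fitness.copy(),
        )

    def genotype_of(self, i: int) -> NuclearGenotype:
        female = bool(self.female[i])
        return NuclearGenotype(
            sex_chromosomes="ZW" if female else "ZZ",
            germline_alleles=(int(self.auto[i, 0]), int(self.auto[i, 1])),
            w_allele=int(self.w[i]) if female else None,
        )


def _germline_phenotypes(
    auto: np.ndarray, model: TraitModel
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (n_g, a) expression of the autosomal allele pairs."""
    if model.dominance == "invader":
        expressed_invader = (auto == INVADER).any(axis=1)
    else:  # invader recessive: expressed only when homozygous
        expressed_invader = (auto == INVADER).all(axis=1)
    n_g = np.where(expressed_invader, model.invader.n_g, model.resident.n_g)
    a = np.where(expressed_invader, model.invader.a, model.resident.a)
    return n_g.astype(np.int64), a.astype(np.int64)


def _w_q(w: np.ndarray, model: TraitModel) -> np.ndarray:
    """Oogamy level q expressed by each W allele id (males yield resident q,
    never used)."""
    return np.where(w == INVADER, model.invader.q, model.resident.q).astype(np.int64)


def develop_population(
    pop: Population, params: SimParams, rng: np.random.Generator
) -> Population:
    """Develop and age every zygote to an adult; caches somatic and germ
    state and adult fitness on the population."""
    n_g, a = _germline_phenotypes(pop.auto, params.model)
    soma, germ, germ_n = develop_cohort(
        pop.zyg_m, pop.zyg_tot, n_g, a, params.lc, params.rates, rng
    )
    soma, germ = age_cohort(
        soma, germ, germ_n, params.lc.S - params.lc.L, params.lc, params.rates, rng
    )
    pop.soma_m, pop.germ_m, pop.germ_n = soma, germ, germ_n
    pop.fitness = adult_fitness_cohort(soma, params.lc, params.fp, params.epsilon)
    return pop


def _selection_weights(fitness: np.ndarray, label: str) -> np.ndarray:
    total = fitness.sum()
    if total <= 0.0:
        logger.warning(
            "all %s fitnesses are zero; falling back to uniform sampling", label
        )
        return np.full(fitness.size, 1.0 / fitness.size)
    return fitness / total


def select_parents(
    pop: Population,
    params: SimParams,
    rng: np.random.Generator,
    n_per_sex: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample N/2 mothers and N/2 fathers with replacement, probability
    proportional to adult fitness within each sex.  Returns index arrays
    into the population."""
    if not pop.developed:
        raise ValueError("population must be developed before selection")
    n_per_sex = pop.size // 2 if n_per_sex is None else n_per_sex
    fem = np.flatnonzero(pop.female)
    mal = np.flatnonzero(~pop.female)
    mothers = rng.choice(
        fem, size=n_per_sex, p=_selection_weights(pop.fitness[fem], "female")
    )
    fathers = rng.choice(
        mal, size=n_per_sex, p=_selection_weights(pop.fitness[mal], "male")
    )
    return mothers, fathers


def oogamy_amplification(
    germ: MitoCell, Q: int, mu_S: float, rng: np.random.Generator
) -> MitoCell:
    """Q rounds of (copy-error mutation, duplication) on a germ cell at the
    baseline copy number: egg precursor with 2^Q M mitochondria."""
    m, tot = germ.mutants, germ.total
    for _ in range(Q):
        m += int(rng.binomial(tot - m, mu_S))
        m, tot = 2 * m, 2 * tot
    return MitoCell(m, tot)


def meiosis(germ: MitoCell, rng: np.random.Generator) -> MitoCell:
    """Two meiotic divisions with mitochondrial sampling without replacement:
    one duplication (no mutation) then two hypergeometric halvings, leaving a
    gamete with half the germ cell's mitochondria."""
    m, tot = 2 * germ.mutants, 2 * germ.total
    if tot % 4:
        raise ValueError(f"germ cell total {germ.total} not divisible for meiosis")
    m = int(rng.hypergeometric(m, tot - m, tot // 2))
    tot //= 2
    m = int(rng.hypergeometric(m, tot - m, tot // 2))
    return MitoCell(m, tot // 2)


def fertilize(
    egg: MitoCell,
    sperm: MitoCell,
    mother: NuclearGenotype,
    father: NuclearGenotype,
    Q: int,
    baseline_M: int,
    rng: np.random.Generator,
) -> tuple[MitoCell, NuclearGenotype, str]:
    """Fuse gametes under strict uniparental inheritance.

    The sperm's mitochondria are discarded; the zygote's 2^Q M copies are
    resampled with replacement from the egg pool, i.e. Binomial(2^Q M, egg
    frequency).  One autosomal allele comes from each parent; the mother
    transmits W or Z equiprobably (W -> daughter), the father a Z.
    """
    if egg.total != 2**Q * baseline_M // 2:
        raise ValueError(
            f"egg carries {egg.total} mitochondria, expected {2**Q * baseline_M // 2}"
        )
    zyg_tot = 2**Q * baseline_M
    zyg_m = int(rng.binomial(zyg_tot, egg.mutants / egg.total))
    m_allele = mother.germline_alleles[int(rng.integers(2))]
    f_allele = father.germline_alleles[int(rng.integers(2))]
    transmits_w = bool(rng.integers(2))
    if transmits_w:
        genotype = NuclearGenotype(
            "ZW", germline_alleles=(m_allele, f_allele), w_allele=mother.w_allele
        )
        sex = "female"
    else:
        genotype = NuclearGenotype(
            "ZZ", germline_alleles=(m_allele, f_allele), w_allele=None
        )
        sex = "male"
    return MitoCell(zyg_m, zyg_tot), genotype, sex


def _gametogenesis_batch(
    pop: Population,
    params: SimParams,
    mothers: np.ndarray,
    fathers: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-offspring gametogenesis and fertilization.

    Returns zygote mutants/totals, offspring autosomal pairs, W alleles
    (-1 for sons), and the sex mask.
    """
    M = params.lc.baseline_M
    B = mothers.size
    mu_S = params.rates.mu_S

    # mother's germ cell: random atresia among her 2^a germ cells
    gcol = rng.integers(0, pop.germ_n[mothers])
    m = pop.germ_m[mothers, gcol].astype(np.int64)
    tot = np.full(B, M, dtype=np.int64)

    # oogamy amplification, Q from the mother's W allele
    q = _w_q(pop.w[mothers], params.model)
    for r in range(1, int(q.max()) + 1 if B else 0):
        mask = q >= r
        if mu_S > 0:
            m[mask] += rng.binomial(tot[mask] - m[mask], mu_S)
        m[mask] *= 2
        tot[mask] *= 2

    # meiosis: duplicate, then two hypergeometric halvings -> egg of tot/2
    em, et = 2 * m, 2 * tot
    em = rng.hypergeometric(em, et - em, et // 2)
    et //= 2
    em = rng.hypergeometric(em, et - em, et // 2)
    egg_tot = et // 2

    # male meiosis (sperm mitochondria generated, then discarded under v=1)
    pcol = rng.integers(0, pop.germ_n[fathers])
    pm = 2 * pop.germ_m[fathers, pcol].astype(np.int64)
    pm = rng.hypergeometric(pm, 2 * M - pm, M)
    rng.hypergeometric(pm, M - pm, M // 2)

    # uniparental fertilization with binomial resampling to 2^Q M
    zyg_tot = 2**q * M
    zyg_m = rng.binomial(zyg_tot, em / egg_tot)

    auto = np.empty((B, 2), dtype=pop.auto.dtype)
    auto[:, 0] = pop.auto[mothers, rng.integers(0, 2, size=B)]
    auto[:, 1] = pop.auto[fathers, rng.integers(0, 2, size=B)]
    daughters = rng.integers(0, 2, size=B).astype(bool)
    w = np.where(daughters, pop.w[mothers], -1).astype(pop.w.dtype)
    return zyg_m, zyg_tot, auto, w, daughters


def next_generation(
    pop: Population, params: SimParams, rng: np.random.Generator
) -> Population:
    """Advance one full generation.

    Develops/ages the current zygotes if needed, then draws exactly N
    offspring — N/2 of each sex, filled by rejection on offspring sex — each
    from an independently drawn fitness-weighted mother and father with a
    fresh meiosis.  Returns the next population, already developed.
    """
    if not pop.developed:
        develop_population(pop, params, rng)
    N = pop.size
    half = N // 2
    fem = np.flatnonzero(pop.female)
    mal = np.flatnonzero(~pop.female)
    wf = _selection_weights(pop.fitness[fem], "female")
    wm = _selection_weights(pop.fitness[mal], "male")

    out_m = np.empty(N, dtype=np.int64)
    out_tot = np.empty(N, dtype=np.int64)
    out_auto = np.empty((N, 2), dtype=pop.auto.dtype)
    out_w = np.empty(N, dtype=pop.w.dtype)
    out_female = np.zeros(N, dtype=bool)
    need_f, need_m = half, half
    filled = 0
    while need_f + need_m > 0:
        batch = max(need_f + need_m, 8)
        mothers = fem[rng.choice(wf.size, size=batch, p=wf)]
        fathers = mal[rng.choice(wm.size, size=batch, p=wm)]
        zm, zt, auto, w, daughters = _gametogenesis_batch(
            pop, params, mothers, fathers, rng
        )
        for i in range(batch):  # accept into open sex quotas, in draw order
            if daughters[i]:
                if need_f == 0:
                    continue
                need_f -= 1
            else:
                if need_m == 0:
                    continue
                need_m -= 1
            out_m[filled] = zm[i]
            out_tot[filled] = zt[i]
            out_auto[filled] = auto[i]
            out_w[filled] = w[i]
            out_female[filled] = daughters[i]
            filled += 1
            if need_f + need_m == 0:
                break

    child = Population(
        zyg_m=out_m,
        zyg_tot=out_tot,
        auto=out_auto,
        w=out_w,
        female=out_female,
        generation=pop.generation + 1,
    )
    return develop_population(child, params, rng)


def invader_frequency(pop: Population, locus: str) -> float:
    """Frequency of the invading allele: among all 2N autosomal copies, or
    among the N/2 W chromosomes for a W-linked locus."""
    if locus == "autosomal":
        return float((pop.auto == INVADER).mean())
    if locus == "W":
        return float((pop.w[pop.female] == INVADER).mean())
    raise ValueError(f"unknown locus {locus!r}")
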