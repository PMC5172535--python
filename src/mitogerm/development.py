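"""Development: one zygote to one adult, and the vectorized cohort kernel.

A zygote divides L times into 2^L somatic cells.  Every division costs one
time unit and applies background mutation; cells at the baseline copy number
M additionally take copy-error mutation, duplicate, and partition
(segregational drift), while cells still above baseline — the early divisions
after an oogamous fertilization — are partitioned without replication until M
is restored.  At division n_g one randomly chosen cell is copied (the soma is
not depleted) to found the germline, which may proliferate through ``a``
further replicative divisions into 2^a germ cells.  The 2^T cells present at
division T found the tissues; descendants inherit the label.  After
development, background mutation continues in every cell until the lifespan S
is reached, and adult fitness is the worst tissue's mean cell fitness.

The cohort functions operate on whole arrays of organisms at once and are the
computational core of the population engine; the single-``Organism`` API is a
thin N=1 wrapper around the same kernel, so there is exactly one
implementation of the life cycle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cells import (
    FitnessParams,
    MitoCell,
    MutationRates,
    collapsed_background_probability,
)
from .genotypes import NuclearGenotype, TraitModel, phenotype_of

__all__ = [
    "LifeCycleParams",
    "Organism",
    "develop",
    "age_organism",
    "tissue_fitness",
    "adult_fitness",
    "develop_cohort",
    "age_cohort",
    "adult_fitness_cohort",
    "organism_to_json",
    "organism_from_json",
]


@dataclass(frozen=True)
class LifeCycleParams:
    """Life cycle shape.

    L: cell divisions from zygote to adult (2^L cells).
    T: division at which tissues differentiate (2^T tissues; T=0, one tissue).
    S: lifespan in time units; one division = one time unit, so cells age for
       S - L further units after development.
    baseline_M: mitochondria per somatic cell.
    """

    L: int = 10
    T: int = 0
    S: int = 40
    baseline_M: int = 50

    def __post_init__(self) -> None:
        if not 0 <= self.T <= self.L <= self.S:
            raise ValueError(
                f"need 0 <= T <= L <= S, got T={self.T}, L={self.L}, S={self.S}"
            )
        if self.baseline_M < 2 or self.baseline_M % 2:
            raise ValueError(f"baseline_M must be even and >= 2, got {self.baseline_M}")

    @property
    def n_cells(self) -> int:
        return 2**self.L

    @property
    def n_tissues(self) -> int:
        return 2**self.T


@dataclass
class Organism:
    """A developed individual.

    ``soma_m`` holds the mutant count of each of the 2^L somatic cells in
    ancestry order, so cell i belongs to tissue ``i >> (L - T)``.  ``germ_m``
    holds the 2^a sequestered germ cells (all at baseline M copies).
    """

    soma_m: np.ndarray
    germ_m: np.ndarray
    genotype: NuclearGenotype
    lc: LifeCycleParams
    age: int
    n_g: int = 0
    sex: str = "female"
    extra: dict = field(default_factory=dict)

    @property
    def M(self) -> int:
        return self.lc.baseline_M

    def tissue_cells(self, tissue: int) -> np.ndarray:
        per = self.lc.n_cells // self.lc.n_tissues
        if not 0 <= tissue < self.lc.n_tissues:
            raise IndexError(f"tissue index {tissue} out of range")
        return self.soma_m[tissue * per : (tissue + 1) * per]

    @property
    def germ_postsequestration_exposure(self) -> int:
        """Background time units the germline has seen since sequestration."""
        return self.age - self.n_g


def _interleave(d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    """Place daughters adjacent to their parent: cell i -> cells 2i, 2i+1."""
    out = np.empty((d1.shape[0], 2 * d1.shape[1]), dtype=d1.dtype)
    out[:, 0::2] = d1
    out[:, 1::2] = d2
    return out


def develop_cohort(
    zyg_m: np.ndarray,
    zyg_tot: np.ndarray,
    n_g: np.ndarray,
    a_extra: np.ndarray,
    lc: LifeCycleParams,
    rates: MutationRates,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Develop a cohort of zygotes in lockstep.

    Parameters are per-organism arrays: zygote mutant counts and totals
    (totals must be baseline_M * 2^k), germline sequestration divisions and
    extra germline divisions.  Returns ``(soma_m, germ_m, germ_n)``:
    somatic mutant counts (N, 2^L) — all cells at baseline M — a padded germ
    array (N, 2^max(a)), and the germ-cell count 2^a per organism.  On
    return every cell, somatic or germline, has experienced exactly L time
    units of background mutation (organism age = L).
    """
    zyg_m = np.asarray(zyg_m, dtype=np.int64)
    zyg_tot = np.asarray(zyg_tot, dtype=np.int64)
    n_g = np.asarray(n_g, dtype=np.int64)
    a_extra = np.asarray(a_extra, dtype=np.int64)
    N = zyg_m.size
    M = lc.baseline_M

    q_rounds = np.round(np.log2(zyg_tot / M)).astype(np.int64)
    if np.any(M * 2**q_rounds != zyg_tot):
        raise ValueError("zygote totals must equal baseline_M * 2^k")
    if np.any((n_g < 1) | (n_g > lc.L)):
        raise ValueError("n_g must lie in 1..L")
    if np.any(n_g < q_rounds):
        raise ValueError(
            "germline sequestration before copy number returns to baseline "
            "(n_g < Q) is not supported"
        )
    if np.any(n_g + a_extra > lc.L):
        raise ValueError("n_g + a extra germline divisions must not exceed L")
    if np.any((zyg_m < 0) | (zyg_m > zyg_tot)):
        raise ValueError("invalid zygote mutant counts")

    cur = zyg_m[:, None].copy()  # (N, cells-so-far)
    tot = zyg_tot.copy()  # per-organism per-cell copy number
    germ0 = np.zeros(N, dtype=np.int64)
    for d in range(1, lc.L + 1):
        # one time unit of background damage, all cells
        cur = cur + rng.binomial(tot[:, None] - cur, rates.mu_B)
        repl = tot == M  # replicative vs partition-only division
        if repl.any() and rates.mu_S > 0:
            sub = cur[repl]
            cur[repl] = sub + rng.binomial(M - sub, rates.mu_S)
        pool_m = np.where(repl[:, None], 2 * cur, cur)
        pool_t = np.where(repl, 2 * tot, tot)[:, None]
        half = pool_t // 2
        d1 = rng.hypergeometric(pool_m, pool_t - pool_m, half)
        cur = _interleave(d1, pool_m - d1)
        tot = np.where(repl, tot, tot // 2)
        seq = n_g == d
        if seq.any():
            cols = rng.integers(0, cur.shape[1], size=int(seq.sum()))
            germ0[seq] = cur[np.flatnonzero(seq), cols]

    # germline proliferation: a further replicative divisions -> 2^a cells
    a_max = int(a_extra.max()) if N else 0
    germ = np.zeros((N, 2**a_max), dtype=np.int64)
    germ[:, 0] = germ0
    for j in range(1, a_max + 1):
        mask = a_extra >= j
        sub = germ[np.ix_(mask, np.arange(2 ** (j - 1)))]
        sub = sub + rng.binomial(M - sub, rates.mu_B)
        sub = sub + rng.binomial(M - sub, rates.mu_S)
        pool = 2 * sub
        d1 = rng.hypergeometric(pool, 2 * M - pool, M)
        germ[np.ix_(mask, np.arange(2**j))] = _interleave(d1, pool - d1)
    germ_n = 2**a_extra

    # sequestered germ cells age through the rest of development:
    # background for the L - n_g - a units not already spent dividing
    units = lc.L - n_g - a_extra
    p_eff = 1.0 - (1.0 - rates.mu_B) ** units
    if rates.mu_B > 0:
        valid = np.arange(germ.shape[1])[None, :] < germ_n[:, None]
        drawn = rng.binomial(M - germ, p_eff[:, None])
        germ = np.where(valid, germ + drawn, germ)
    return cur, germ, germ_n


def age_cohort(
    soma_m: np.ndarray,
    germ_m: np.ndarray,
    germ_n: np.ndarray,
    units: int,
    lc: LifeCycleParams,
    rates: MutationRates,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply ``units`` further time units of background mutation to every
    somatic and germ cell (collapsed into one exact binomial draw each)."""
    M = lc.baseline_M
    p_eff = collapsed_background_probability(rates.mu_B, units)
    if p_eff == 0.0:
        return soma_m, germ_m
    soma_m = soma_m + rng.binomial(M - soma_m, p_eff)
    valid = np.arange(germ_m.shape[1])[None, :] < germ_n[:, None]
    germ_m = np.where(valid, germ_m + rng.binomial(M - germ_m, p_eff), germ_m)
    return soma_m, germ_m


def adult_fitness_cohort(
    soma_m: np.ndarray,
    lc: LifeCycleParams,
    fp: FitnessParams,
    epsilon: float = 1.0,
) -> np.ndarray:
    """Adult fitness of each organism in a cohort.

    Tissue fitness is the mean cell fitness in each of the 2^T tissues;
    adult fitness interpolates between the tissue mean (epsilon=0) and the
    worst tissue (epsilon=1, the default epistasis rule).
    """
    N = soma_m.shape[0]
    w = 1.0 - fp.s * (soma_m / lc.baseline_M) ** fp.xi
    tis = w.reshape(N, lc.n_tissues, -1).mean(axis=2)
    if epsilon == 1.0:
        return tis.min(axis=1)
    return (1.0 - epsilon) * tis.mean(axis=1) + epsilon * tis.min(axis=1)


def develop(
    zygote: MitoCell,
    genotype: NuclearGenotype,
    lc: LifeCycleParams,
    rates: MutationRates,
    rng: np.random.Generator,
    model: TraitModel | None = None,
) -> Organism:
    """Grow one zygote into an adult at age L (see module docstring)."""
    model = model if model is not None else TraitModel()
    ph = phenotype_of(genotype, model)
    soma, germ, germ_n = develop_cohort(
        np.array([zygote.mutants]),
        np.array([zygote.total]),
        np.array([ph.n_g]),
        np.array([ph.a]),
        lc,
        rates,
        rng,
    )
    return Organism(
        soma_m=soma[0],
        germ_m=germ[0, : germ_n[0]].copy(),
        genotype=genotype,
        lc=lc,
        age=lc.L,
        n_g=ph.n_g,
        sex="female" if genotype.is_female else "male",
    )


def age_organism(
    org: Organism,
    lc: LifeCycleParams,
    rates: MutationRates,
    rng: np.random.Generator,
) -> Organism:
    """Age an organism to the end of its lifespan S, applying background
    mutation to every somatic and germ cell for each remaining time unit."""
    units = lc.S - org.age
    if units < 0:
        raise ValueError(f"organism is already older than S={lc.S}")
    germ2d = org.germ_m[None, :]
    soma2d, germ2d = age_cohort(
        org.soma_m[None, :],
        germ2d,
        np.array([org.germ_m.size]),
        units,
        lc,
        rates,
        rng,
    )
    return Organism(
        soma_m=soma2d[0],
        germ_m=germ2d[0],
        genotype=org.genotype,
        lc=org.lc,
        age=lc.S,
        n_g=org.n_g,
        sex=org.sex,
        extra=dict(org.extra),
    )


def tissue_fitness(org: Organism, tissue: int, fp: FitnessParams) -> float:
    cells = org.tissue_cells(tissue)
    if cells.size == 0:
        raise ValueError(f"tissue {tissue} holds no cells")
    return float(np.mean(1.0 - fp.s * (cells / org.M) ** fp.xi))


def adult_fitness(
    org: Organism, fp: FitnessParams, epsilon: float = 1.0
) -> float:
    """Worst-tissue fitness by default (epsilon=1); epsilon interpolates
    toward the plain tissue mean (epsilon=0), a tunable tissue-epistasis
    strength."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon must be in [0, 1], got {epsilon}")
    return float(adult_fitness_cohort(org.soma_m[None, :], org.lc, fp, epsilon)[0])


def organism_to_json(org: Organism) -> str:
    """Serialize an organism snapshot (cells grouped by tissue) to JSON."""
    payload = {
        "age": org.age,
        "sex": org.sex,
        "n_g": org.n_g,
        "baseline_M": org.M,
        "L": org.lc.L,
        "T": org.lc.T,
        "S": org.lc.S,
        "tissues": [org.tissue_cells(t).tolist() for t in range(org.lc.n_tissues)],
        "germ_cells": org.germ_m.tolist(),
        "genotype": {
            "sex_chromosomes": org.genotype.sex_chromosomes,
            "germline_alleles": list(org.genotype.germline_alleles),
            "w_allele": org.genotype.w_allele,
        },
    }
    return json.dumps(payload)


def organism_from_json(text: str) -> Organism:
    d = json.loads(text)
    lc = LifeCycleParams(L=d["L"], T=d["T"], S=d["S"], baseline_M=d["baseline_M"])
    g = d["genotype"]
    genotype = NuclearGenotype(
        sex_chromosomes=g["sex_chromosomes"],
        germline_alleles=tuple(g["germline_alleles"]),
        w_allele=g["w_allele"],
    )
    return Organism(
        soma_m=np.concatenate([np.asarray(t, dtype=np.int64) for t in d["tissues"]]),
        germ_m=np.asarray(d["germ_cells"], dtype=np.int64),
        genotype=genotype,
        lc=lc,
        age=d["age"],
        n_g=d["n_g"],
        sex=d["sex"],
    )
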