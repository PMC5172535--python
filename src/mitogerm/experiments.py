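"""Experiment drivers: burn-in, allele invasion, fixation probability, sweeps.

The central measurement is the fixation probability of a modifier allele
(germline timing, germline proliferation, or W-linked oogamy level):
introduce it at frequency f0 = 0.05 into a resident population at
mutation-selection equilibrium and track it to fixation or loss, many times
over.  The neutral benchmark is f0 itself — an allele is advantageous when
its fixation probability exceeds the fixation chance of a neutral allele.

Two named profiles ship with the package: ``desk`` (N=100, L=6, 500
replicates), sized for interactive runs and the test suite, and ``paper``
(N=500, L=10, 1000 replicates).  Replicates branch from one shared burn-in
snapshot, each with an independent seed substream and a short decorrelation
run before the allele is introduced; runs are bit-reproducible given a seed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cells import FitnessParams, MutationRates
from .development import LifeCycleParams
from .genotypes import INVADER, RESIDENT, TraitModel, TraitSet
from .popgen import (
    Population,
    SimParams,
    develop_population,
    invader_frequency,
    next_generation,
)

logger = logging.getLogger(__name__)

__all__ = [
    "InvasionConfig",
    "FixationRecord",
    "PROFILES",
    "initialize_population",
    "burn_in",
    "introduce_allele",
    "run_to_fixation",
    "estimate_fixation_probability",
    "sweep",
    "trend_pvalue",
]

PROFILES: dict[str, dict] = {
    "desk": {"N": 100, "L": 6, "n_reps": 500},
    "paper": {"N": 500, "L": 10, "n_reps": 1000},
}


@dataclass(frozen=True)
class InvasionConfig:
    """One invasion experiment: who invades whom, and at what scale."""

    resident: TraitSet = TraitSet(n_g=10)
    invader: TraitSet = TraitSet(n_g=3)
    locus: str = "autosomal"  # or "W"
    dominance: str = "invader"
    f0: float = 0.05
    n_reps: int = 1000
    max_generations: int = 20000
    burn_in_generations: int = 200
    decorrelation_generations: int = 5
    p_init: float = 0.2
    seed: int = 0
    N: int = 500
    lc: LifeCycleParams = field(default_factory=LifeCycleParams)
    rates: MutationRates = field(default_factory=MutationRates)
    fp: FitnessParams = field(default_factory=FitnessParams)
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.f0 < 1.0:
            raise ValueError(f"f0 must lie in (0, 1), got {self.f0}")
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")
        if self.locus not in ("autosomal", "W"):
            raise ValueError(f"locus must be 'autosomal' or 'W', got {self.locus}")

    @property
    def params(self) -> SimParams:
        return SimParams(
            N=self.N,
            lc=self.lc,
            rates=self.rates,
            fp=self.fp,
            model=TraitModel(
                resident=self.resident,
                invader=self.invader,
                dominance=self.dominance,
            ),
            epsilon=self.epsilon,
        )

    @classmethod
    def from_profile(cls, profile: str = "desk", **overrides) -> "InvasionConfig":
        """Build a config from a named scale profile; the resident practices
        somatic gametogenesis (n_g = L) unless overridden."""
        prof = PROFILES[profile]
        lc = overrides.pop("lc", LifeCycleParams(L=prof["L"], T=overrides.pop("T", 0)))
        resident = overrides.pop("resident", TraitSet(n_g=lc.L))
        invader = overrides.pop("invader", TraitSet(n_g=3))
        return cls(
            resident=resident,
            invader=invader,
            N=prof["N"],
            n_reps=overrides.pop("n_reps", prof["n_reps"]),
            lc=lc,
            **overrides,
        )


@dataclass
class FixationRecord:
    """Aggregated outcome of an invasion experiment.

    p_hat is fixed/(fixed+lost); censored replicates (allele still
    segregating at max_generations) are reported separately and never
    counted.  The confidence halfwidth is the Gaussian binomial-proportion
    interval 1.96 sqrt(p(1-p)/n)."""

    n_reps: int
    fixed: int
    lost: int
    censored: int
    p_hat: float
    ci_halfwidth: float
    f0: float
    outcomes: list[str] = field(default_factory=list)
    generations: list[int] = field(default_factory=list)

    @property
    def n_effective(self) -> int:
        return self.fixed + self.lost

    @property
    def advantageous(self) -> bool:
        """Does the measured fixation probability exceed the neutral
        benchmark f0?"""
        return self.p_hat > self.f0


def _aggregate(outcomes: list[str], generations: list[int], f0: float) -> FixationRecord:
    fixed = outcomes.count("fixed")
    lost = outcomes.count("lost")
    censored = outcomes.count("censored")
    n_eff = fixed + lost
    if n_eff == 0:
        raise RuntimeError(
            "all replicates were censored; raise max_generations"
        )
    p_hat = fixed / n_eff
    ci = 1.96 * np.sqrt(p_hat * (1.0 - p_hat) / n_eff)
    if fixed == 0:
        logger.info("no fixations observed; Gaussian CI is degenerate at 0")
    return FixationRecord(
        n_reps=len(outcomes),
        fixed=fixed,
        lost=lost,
        censored=censored,
        p_hat=p_hat,
        ci_halfwidth=float(ci),
        f0=f0,
        outcomes=outcomes,
        generations=generations,
    )


def initialize_population(
    params: SimParams, p_init: float, rng: np.random.Generator
) -> Population:
    """All-resident population of N zygotes in a random mutational state —
    mutant counts Binomial(2^Q M, p_init) — developed and aged to adults."""
    if not 0.0 <= p_init <= 1.0:
        raise ValueError(f"p_init must be in [0, 1], got {p_init}")
    N = params.N
    q = params.model.resident.q
    tot = 2**q * params.lc.baseline_M
    zyg_m = rng.binomial(tot, p_init, size=N).astype(np.int64)
    female = np.zeros(N, dtype=bool)
    female[: N // 2] = True
    pop = Population(
        zyg_m=zyg_m,
        zyg_tot=np.full(N, tot, dtype=np.int64),
        auto=np.full((N, 2), RESIDENT, dtype=np.int8),
        w=np.where(female, RESIDENT, -1).astype(np.int8),
        female=female,
    )
    return develop_population(pop, params, rng)


def burn_in(
    pop: Population,
    generations: int,
    params: SimParams,
    rng: np.random.Generator,
) -> tuple[Population, pd.DataFrame]:
    """Run the resident population to mutation-selection equilibrium.

    Returns the final population and the mean-zygote-load / mean-fitness
    trajectory so stationarity can be inspected (see :func:`trend_pvalue`).
    """
    rows = []
    for _ in range(generations):
        pop = next_generation(pop, params, rng)
        rows.append(
            {
                "generation": pop.generation,
                "mean_zygote_load": float(np.mean(pop.zyg_m / pop.zyg_tot)),
                "mean_fitness": float(pop.fitness.mean()),
                "min_fitness": float(pop.fitness.min()),
            }
        )
    return pop, pd.DataFrame(rows)


def trend_pvalue(series: np.ndarray) -> float:
    """Mann-Kendall trend test p-value (Kendall's tau against time); large
    values mean no detectable monotone trend."""
    series = np.asarray(series, dtype=float)
    if series.size < 3:
        return 1.0
    tau = stats.kendalltau(np.arange(series.size), series)
    return float(tau.pvalue)


def introduce_allele(
    pop: Population, cfg: InvasionConfig, rng: np.random.Generator
) -> Population:
    """Place the invading allele at frequency f0.

    Autosomal: round(2N f0) single copies in distinct, randomly chosen
    individuals (heterozygotes).  W-linked: round(N_female f0) of the
    females' W alleles are replaced.
    """
    def _round_half_up(x: float) -> int:
        return int(np.floor(x + 0.5))

    pop = pop.copy()
    if cfg.locus == "autosomal":
        copies = _round_half_up(2 * pop.size * cfg.f0)
        if copies == 0:
            raise ValueError(f"f0={cfg.f0} yields zero allele copies at N={pop.size}")
        if copies > pop.size:
            raise ValueError("f0 too large for single-copy heterozygote placement")
        chosen = rng.choice(pop.size, size=copies, replace=False)
        pop.auto[chosen, 0] = INVADER
    else:
        fem = np.flatnonzero(pop.female)
        copies = _round_half_up(fem.size * cfg.f0)
        if copies == 0:
            raise ValueError(f"f0={cfg.f0} yields zero W copies at N={pop.size}")
        chosen = rng.choice(fem, size=copies, replace=False)
        pop.w[chosen] = INVADER
    return pop


def run_to_fixation(
    pop: Population,
    cfg: InvasionConfig,
    rng: np.random.Generator,
) -> tuple[str, int]:
    """Track the invading allele to absorption.

    Returns ("fixed" | "lost" | "censored", generations elapsed).
    """
    params = cfg.params
    start = pop.generation
    freq = invader_frequency(pop, cfg.locus)
    while 0.0 < freq < 1.0:
        if pop.generation - start >= cfg.max_generations:
            return "censored", pop.generation - start
        pop = next_generation(pop, params, rng)
        freq = invader_frequency(pop, cfg.locus)
    return ("fixed" if freq == 1.0 else "lost"), pop.generation - start


def estimate_fixation_probability(cfg: InvasionConfig) -> FixationRecord:
    """Estimate the invader's fixation probability.

    One shared burn-in brings the resident population to equilibrium; each
    replicate then branches from that snapshot on its own seed substream,
    runs a short decorrelation stretch, introduces the allele, and iterates
    to absorption.
    """
    ss = np.random.SeedSequence(cfg.seed)
    burn_ss, *rep_ss = ss.spawn(cfg.n_reps + 1)
    params = cfg.params
    rng = np.random.default_rng(burn_ss)
    pop = initialize_population(params, cfg.p_init, rng)
    pop, _ = burn_in(pop, cfg.burn_in_generations, params, rng)

    outcomes: list[str] = []
    generations: list[int] = []
    for i in range(cfg.n_reps):
        rng_i = np.random.default_rng(rep_ss[i])
        pop_i = pop.copy()
        for _ in range(cfg.decorrelation_generations):
            pop_i = next_generation(pop_i, params, rng_i)
        pop_i = introduce_allele(pop_i, cfg, rng_i)
        outcome, gens = run_to_fixation(pop_i, cfg, rng_i)
        outcomes.append(outcome)
        generations.append(gens)
    return _aggregate(outcomes, generations, cfg.f0)


_SWEEPABLE = {
    "mu_S",
    "mu_B",
    "T",
    "M",
    "Q_resident",
    "Q_invader",
    "n_g_invader",
    "a_invader",
    "locus",
    "n_reps",
    "seed",
}


def _apply_point(cfg: InvasionConfig, point: dict) -> InvasionConfig:
    rates = cfg.rates
    lc = cfg.lc
    resident = cfg.resident
    invader = cfg.invader
    if "mu_S" in point or "mu_B" in point:
        rates = MutationRates(
            mu_S=point.get("mu_S", rates.mu_S), mu_B=point.get("mu_B", rates.mu_B)
        )
    if "T" in point or "M" in point:
        lc = LifeCycleParams(
            L=lc.L,
            T=point.get("T", lc.T),
            S=lc.S,
            baseline_M=point.get("M", lc.baseline_M),
        )
    if "Q_resident" in point:
        resident = replace(resident, q=point["Q_resident"])
    if "Q_invader" in point:
        invader = replace(invader, q=point["Q_invader"])
    if "n_g_invader" in point:
        invader = replace(invader, n_g=point["n_g_invader"])
    if "a_invader" in point:
        invader = replace(invader, a=point["a_invader"])
    return replace(
        cfg,
        rates=rates,
        lc=lc,
        resident=resident,
        invader=invader,
        locus=point.get("locus", cfg.locus),
        n_reps=point.get("n_reps", cfg.n_reps),
        seed=point.get("seed", cfg.seed),
    )


def sweep(grid: dict[str, list], template: InvasionConfig) -> pd.DataFrame:
    """Run estimate_fixation_probability over a Cartesian parameter grid.

    ``grid`` maps sweepable names (mu_S, mu_B, T, M, Q_resident, Q_invader,
    n_g_invader, a_invader, locus, n_reps, seed) to value lists.  Each row
    carries the full parameter provenance plus the estimate and its CI.
    """
    unknown = set(grid) - _SWEEPABLE
    if unknown:
        raise ValueError(f"unknown sweep parameters: {sorted(unknown)}")
    keys = list(grid)
    rows = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        point = dict(zip(keys, combo))
        cfg = _apply_point(template, point)
        rec = estimate_fixation_probability(cfg)
        rows.append(
            {
                **point,
                "N": cfg.N,
                "L": cfg.lc.L,
                "S": cfg.lc.S,
                "M": cfg.lc.baseline_M,
                "T": cfg.lc.T,
                "mu_S": cfg.rates.mu_S,
                "mu_B": cfg.rates.mu_B,
                "s": cfg.fp.s,
                "xi": cfg.fp.xi,
                "locus": cfg.locus,
                "f0": cfg.f0,
                "n_reps": cfg.n_reps,
                "seed": cfg.seed,
                "resident_n_g": cfg.resident.n_g,
                "invader_n_g": cfg.invader.n_g,
                "resident_q": cfg.resident.q,
                "invader_q": cfg.invader.q,
                "resident_a": cfg.resident.a,
                "invader_a": cfg.invader.a,
                "p_hat": rec.p_hat,
                "ci_halfwidth": rec.ci_halfwidth,
                "fixed": rec.fixed,
                "lost": rec.lost,
                "censored": rec.censored,
            }
        )
    return pd.DataFrame(rows)
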