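"""Single-cell mitochondrial dynamics: mutation, replication, partition, fitness.

A cell's mitochondrial state is summarised by two integers — the number of
mutant copies ``m`` and the total copy number ``M`` (heteroplasmy as a count
pair).  Mutations are one-way (wild-type -> mutant); all mutants are
interchangeable, so the pair is a sufficient statistic.  At cell division the
mitochondrial population is duplicated and then partitioned between the two
daughters by sampling without replacement, which is the source of
segregational drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np


class MitoCell(NamedTuple):
    """Mitochondrial state of one cell: ``mutants`` of ``total`` copies."""

    mutants: int
    total: int

    @property
    def load(self) -> float:
        """Mutant frequency m/M."""
        return self.mutants / self.total


@dataclass(frozen=True)
class MutationRates:
    """Per-copy mutation probabilities.

    mu_S: replication (copying-error) mutation probability per wild-type copy
        per cell division.
    mu_B: background damage probability per wild-type copy per time unit
        (applies whether or not the cell divides).
    """

    mu_S: float = 0.01
    mu_B: float = 0.005

    def __post_init__(self) -> None:
        for name in ("mu_S", "mu_B"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")


@dataclass(frozen=True)
class FitnessParams:
    """Cell fitness function w(m) = 1 - s * (m/M)**xi.

    ``s`` is the selection strength (fitness of a fully mutant cell is 1-s);
    ``xi`` shapes the curve: concave for xi > 1 (the mitochondrial-disease
    threshold effect), linear at xi = 1, convex below.
    """

    s: float = 1.0
    xi: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"s must be in [0, 1], got {self.s}")
        if self.xi <= 0:
            raise ValueError(f"xi must be positive, got {self.xi}")


def _check_cell(cell: MitoCell) -> None:
    if cell.total < 2:
        raise ValueError(f"cell must hold at least 2 mitochondria, got {cell.total}")
    if not 0 <= cell.mutants <= cell.total:
        raise ValueError(f"invalid cell state {cell}")


def _check_prob(p: float, name: str) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {p}")


def apply_background_mutation(
    cell: MitoCell, mu_B: float, rng: np.random.Generator
) -> MitoCell:
    """One time unit of background damage: each wild-type copy mutates
    independently with probability ``mu_B``; the total is unchanged."""
    _check_cell(cell)
    _check_prob(mu_B, "mu_B")
    new = int(rng.binomial(cell.total - cell.mutants, mu_B))
    return MitoCell(cell.mutants + new, cell.total)


def apply_copy_error_mutation(
    cell: MitoCell, mu_S: float, rng: np.random.Generator
) -> MitoCell:
    """Replication errors: each wild-type copy mutates with probability
    ``mu_S``.  Only meaningful at a replicative division (see divide_cell)."""
    _check_cell(cell)
    _check_prob(mu_S, "mu_S")
    new = int(rng.binomial(cell.total - cell.mutants, mu_S))
    return MitoCell(cell.mutants + new, cell.total)


def replicate_mitochondria(cell: MitoCell) -> MitoCell:
    """Duplicate every copy; mutant frequency is preserved exactly."""
    _check_cell(cell)
    return MitoCell(2 * cell.mutants, 2 * cell.total)


def partition(cell: MitoCell, rng: np.random.Generator) -> tuple[MitoCell, MitoCell]:
    """Split a cell into two daughters of half the size by sampling without
    replacement: daughter 1 receives Hypergeom(total, mutants, total/2)
    mutants, daughter 2 the complement.  Mutant copies are conserved."""
    _check_cell(cell)
    if cell.total % 2:
        raise ValueError(f"cannot halve an odd mitochondrial population ({cell.total})")
    half = cell.total // 2
    d1 = int(rng.hypergeometric(cell.mutants, cell.total - cell.mutants, half))
    return MitoCell(d1, half), MitoCell(cell.mutants - d1, half)


def divide_cell(
    cell: MitoCell,
    baseline_M: int,
    rates: MutationRates,
    rng: np.random.Generator,
) -> tuple[MitoCell, MitoCell]:
    """One cell division.

    Background mutation is applied first (one time unit elapses).  A cell at
    the baseline copy number then undergoes a replicative division:
    copy-error mutation, duplication, and hypergeometric partition into two
    daughters of ``baseline_M``.  A cell still above baseline (early
    development after an oogamous fertilization) is partitioned only — no
    copy-error mutation, no duplication — halving the copy number.
    """
    _check_cell(cell)
    if cell.total < baseline_M:
        raise ValueError(
            f"cell total {cell.total} below baseline {baseline_M}; cannot divide"
        )
    cell = apply_background_mutation(cell, rates.mu_B, rng)
    if cell.total == baseline_M:
        cell = apply_copy_error_mutation(cell, rates.mu_S, rng)
        cell = replicate_mitochondria(cell)
    return partition(cell, rng)


def cell_fitness(cell: MitoCell, fp: FitnessParams) -> float:
    """w(m) = 1 - s*(m/M)^xi, with the cell's own total as denominator."""
    _check_cell(cell)
    return 1.0 - fp.s * (cell.mutants / cell.total) ** fp.xi


def simulate_lineages(
    m0: int,
    total: int,
    baseline_M: int,
    rates: MutationRates,
    n_divisions: int,
    n_lineages: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Follow many independent cell lineages through successive divisions.

    Each lineage starts at (m0, total) and at every division follows one
    uniformly chosen daughter of :func:`divide_cell` (the hypergeometric
    draw *is* a random daughter, so one draw per division suffices).  The
    marginal state of a random lineage equals the state of a random cell in
    the full division tree, which is what the transition-matrix oracle
    propagates.  Returns an (n_divisions + 1, n_lineages) array of mutant
    counts, row n holding the state after n divisions.
    """
    if total < baseline_M or total % baseline_M or (total // baseline_M) & (total // baseline_M - 1):
        raise ValueError("total must be baseline_M * 2^k")
    out = np.empty((n_divisions + 1, n_lineages), dtype=np.int64)
    m = np.full(n_lineages, m0, dtype=np.int64)
    tot = total
    out[0] = m
    for d in range(1, n_divisions + 1):
        if rates.mu_B > 0:
            m = m + rng.binomial(tot - m, rates.mu_B)
        if tot == baseline_M:
            if rates.mu_S > 0:
                m = m + rng.binomial(tot - m, rates.mu_S)
            m = rng.hypergeometric(2 * m, 2 * (tot - m), tot)
        else:
            m = rng.hypergeometric(m, tot - m, tot // 2)
            tot //= 2
        out[d] = m
    return out


def collapsed_background_probability(mu_B: float, units: int) -> float:
    """Probability a wild-type copy has mutated after ``units`` time units of
    background exposure at per-unit rate ``mu_B``: 1 - (1-mu_B)^units.

    Applying Binomial(wild-types, this) in one draw is distributionally
    identical to ``units`` sequential Binomial(., mu_B) draws.
    """
    _check_prob(mu_B, "mu_B")
    if units < 0:
        raise ValueError(f"exposure must be non-negative, got {units}")
    if units == 0 or mu_B == 0.0:
        return 0.0
    return float(-np.expm1(units * np.log1p(-mu_B)))
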