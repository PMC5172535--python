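"""Nuclear genotypes: ZW mating types and the modifier loci under study.

Three heritable traits sit in the (diploid) nuclear genome:

* germline timing — an autosomal locus whose alleles encode the division
  ``n_g`` at which the primordial germ cell is sequestered and the number
  ``a`` of extra proliferative germline divisions (atresia then picks one of
  the 2^a germ cells at gametogenesis).  Expressed in both sexes.
* oogamy — a W-linked allele encoding ``q``, the log2 egg amplification
  factor (zygotes carry 2^q M mitochondria).  Expressed in females only.
* uniparental inheritance — a W-linked allele encoding ``v``; fixed at v=1
  (strict maternal transmission) throughout.

Alleles are stored as integer ids (0 = resident, 1 = invader) and resolved to
trait values through a :class:`TraitModel`, which also fixes the dominance
relation at the autosomal locus (the invading allele is dominant by default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["TraitSet", "TraitModel", "NuclearGenotype", "phenotype_of"]

RESIDENT, INVADER = 0, 1


@dataclass(frozen=True)
class TraitSet:
    """Resolved phenotype: germline timing n_g, extra germline divisions a,
    oogamy level q, uniparental degree v."""

    n_g: int = 10
    a: int = 0
    q: int = 0
    v: float = 1.0

    def __post_init__(self) -> None:
        if self.n_g < 1:
            raise ValueError(f"n_g must be >= 1, got {self.n_g}")
        if self.a < 0 or self.q < 0:
            raise ValueError("a and q must be non-negative")
        if self.v != 1.0:
            raise NotImplementedError(
                "partial uniparental inheritance (v < 1) is not modelled"
            )


@dataclass(frozen=True)
class TraitModel:
    """Maps allele ids to trait values and fixes autosomal dominance."""

    resident: TraitSet = TraitSet()
    invader: TraitSet = TraitSet()
    dominance: str = "invader"  # allele that wins in a heterozygote

    def __post_init__(self) -> None:
        if self.dominance not in ("invader", "resident"):
            raise ValueError(f"dominance must be 'invader' or 'resident'")

    def traits_of(self, allele: int) -> TraitSet:
        return self.invader if allele == INVADER else self.resident

    def germline_phenotype(self, alleles: tuple[int, int]) -> tuple[int, int]:
        """(n_g, a) expressed by an autosomal allele pair under dominance."""
        a1, a2 = alleles
        if a1 == a2:
            t = self.traits_of(a1)
        elif self.dominance == "invader":
            t = self.invader
        else:
            t = self.resident
        return t.n_g, t.a


def neutral_invader(resident: TraitSet) -> TraitSet:
    """An invader phenotypically identical to the resident (calibration)."""
    return replace(resident)


@dataclass(frozen=True)
class NuclearGenotype:
    """One individual's nuclear state.

    Females are heterogametic ZW and carry exactly one W; W-linked loci
    (oogamy, uniparental degree) are expressed and transmitted only through
    the W.  ``germline_alleles`` are the two autosomal allele ids;
    ``w_allele`` is the W haplotype's allele id (None in ZZ males).
    """

    sex_chromosomes: str  # "ZW" or "ZZ"
    germline_alleles: tuple[int, int] = (RESIDENT, RESIDENT)
    w_allele: int | None = RESIDENT

    def __post_init__(self) -> None:
        if self.sex_chromosomes not in ("ZW", "ZZ"):
            raise ValueError("sex_chromosomes must be 'ZW' or 'ZZ'")
        if self.sex_chromosomes == "ZW" and self.w_allele is None:
            raise ValueError("ZW females must carry a W allele")
        if self.sex_chromosomes == "ZZ" and self.w_allele is not None:
            raise ValueError("ZZ males carry no W allele")

    @property
    def is_female(self) -> bool:
        return self.sex_chromosomes == "ZW"


def phenotype_of(genotype: NuclearGenotype, model: TraitModel) -> TraitSet:
    """Resolve a genotype to its expressed traits.

    Germline timing comes from the autosomal pair under the model's
    dominance; q and v are read off the W allele in females.  Males express
    no oogamy (their q is irrelevant); the resident value is reported.
    """
    n_g, a = model.germline_phenotype(genotype.germline_alleles)
    if genotype.is_female:
        w = model.traits_of(genotype.w_allele)
        return TraitSet(n_g=n_g, a=a, q=w.q, v=w.v)
    return TraitSet(n_g=n_g, a=a, q=model.resident.q, v=model.resident.v)
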