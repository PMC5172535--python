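# Model and methods

`mitogerm` simulates the evolution of germline strategies in a multicellular
organism whose fitness is set by the quality of its mitochondria. This note
records the model, its assumptions, the numerical choices, and what the
synthetic experiments do and do not show.

## Cell level

A cell's mitochondrial state is a count pair `(m, M)`: `m` mutant copies out
of `M` total. Two one-way mutation processes act on wild-type copies only
(no back-mutation):

* **copy errors** — at a replicative division each wild-type copy mutates
  with probability `mu_S` (drawn as `Binomial(M - m, mu_S)`);
* **background damage** — each time unit, every wild-type copy mutates with
  probability `mu_B`, dividing or not.

A replicative division applies background mutation, copy-error mutation,
duplication to `2M`, and a hypergeometric partition: one daughter receives
`Hypergeom(2M, 2m, M)` mutants, the other the complement. Partition without
replacement is the sole source of segregational drift: it never moves the
mean mutant frequency but converts heteroplasmy into between-cell variance.
Mutant severity is fixed (all mutants equivalent), and there is no
within-cell selection among mitochondria — both deliberate model
assumptions; within-cell selection acts approximately like a change of
mutation rate and is outside scope.

Cell fitness is the concave load curve

```
w(m) = 1 - s (m/M)^xi,        s in [0,1], xi > 0 (defaults s=1, xi=2),
```

mirroring the clinical threshold effect of heteroplasmic mitochondrial
disease: load barely matters until it is large. `xi` tunes the shape
(1 = linear, <1 convex); `s` the severity of a fully mutant cell.

## Analytic oracle

For an infinite cell population the state is a probability vector `p` over
mutant counts `0..M`. One cell cycle is `p -> K J p` with `J` the binomial
mutation kernel and `K` the hypergeometric segregation kernel (both
column-stochastic `(M+1) x (M+1)` matrices). With `mu = 0` the mutant-
frequency variance has the closed form

```
Var(P_n) = p0 (1 - p0) [1 - (1 - 1/(2M-1))^n],
```

and for an oogamous zygote of `2^Q M` copies whose first `Q` divisions are
partition-only,

```
Var(P_n) = p0(1-p0)/(2^{1+Q-n} M - 1) + Var(P_{n-1}) (1 - 1/(2^{1+Q-n} M - 1)),
```

with the large-pool approximation `p0(1-p0)(2^n - 1)/(2^Q M)`. These exact
results are the package's correctness gate: the stochastic engine must
reproduce the propagated distributions (total-variation distance < 0.01 at
1e5 lineages) and every variance curve within Monte Carlo error. The
matrix power is computed by iterated multiplication (n <= ~60 everywhere),
clipping round-off negatives above -1e-12 and renormalizing columns to keep
the iterate a distribution; binomial pmfs are evaluated in log space so
extreme rates and large `M` (up to `2^Q M`) do not overflow.

## Organism level

Development is `L` synchronous divisions (2^L cells; one division = one time
unit). A `Q`-oogamous zygote starts with `2^Q M` mitochondria; divisions are
partition-only until the baseline `M` is restored, replicative afterwards
(hence the constraint `n_g >= Q`: the germ cell must be at baseline when
sequestered). At division `n_g` one uniformly chosen cell is *copied* (the
soma is not depleted) to found the germline; it divides no further except
for `a` optional proliferative divisions (full replicative divisions taken
immediately after sequestration), yielding `2^a` germ cells of which
gametogenesis later picks one uniformly at random — random atresia. The
2^T cells present at division `T` found the tissues; descendants inherit
the label by ancestry.

Ageing: after development every cell, somatic or germline, continues to take
background mutation until the lifespan `S` (default 40). Bookkeeping is
arranged so each cell experiences exactly `S` background units per
generation regardless of `n_g` and `a`; a germ cell sequestered at division
3 therefore carries `S - 3` post-sequestration units versus `S - L` for
soma — early sequestration limits copy errors, never background damage.
Sequential per-unit background draws are collapsed into a single exact
binomial with per-copy probability `1 - (1 - mu_B)^t` (the per-copy
Bernoulli events compose), which is what makes whole-population simulation
cheap.

Tissue fitness is the mean cell fitness of the tissue; adult fitness is the
**worst** tissue's fitness. An interpolation parameter `epsilon` in [0,1]
(`(1-eps) * mean + eps * min`, default 1) exposes a tunable tissue-epistasis
strength; the strict min rule is the default and the one used everywhere in
the shipped experiments.

## Population level

`N` individuals (default 500), half ZW females, half ZZ males; discrete
non-overlapping generations. Three nuclear loci: an autosomal germline
locus encoding `(n_g, a)`, expressed in both sexes, invader dominant by
default (configurable); and two W-linked loci — oogamy level `Q` and
uniparental degree `v` — expressed in females and transmitted only
mother-to-daughter. `v` is fixed at 1 (strict maternal inheritance); the
evolution of paternal leakage has no defined mixing rule here and is out of
scope.

Each generation: zygotes develop and age; parents are sampled with
replacement, linearly weighted by adult fitness within each sex (uniform
fallback with a logged warning if a sex's fitness sums to zero). Every
offspring draws an independent fitness-weighted mother and father and gets a
fresh gametogenesis: the mother's germ cell (one of her `2^a`, uniformly)
undergoes `Q` oogamy rounds (copy-error mutation then duplication), then
meiosis — one duplication *without* mutation followed by two hypergeometric
halvings, the arithmetic that yields eggs of `2^Q M / 2` and sperm of `M/2`
while injecting two rounds of segregational sampling. Fertilization is
uniparental: sperm mitochondria are generated and discarded; the zygote's
`2^Q M` copies are resampled *with replacement* from the egg frequency
(`Binomial(2^Q M, m_egg / M_egg)`) — the simplest reading of resampling the
fused cell up to its target copy number. Offspring sex follows the
transmitted chromosome (mother passes W or Z equiprobably); exact `N/2`
quotas per sex are filled by rejection on offspring sex. Meiotic
duplication takes no copy-error mutation: replication noise at gametogenesis
enters only through the `Q` oogamy rounds.

A design note on selection: the classical scheme samples `N/2` parents per
sex and then pairs them; here each offspring samples its mother and father
directly from the fitness-weighted population. Both schemes give every
parent the same expected offspring number; the direct draw is simpler and
is what `next_generation` uses (`select_parents` exposes the list-based
operation for callers that want it).

## Invasion experiments

`estimate_fixation_probability` measures the fate of a modifier allele
introduced at `f0 = 0.05` (autosomal: `round(2N f0)` single copies in
distinct heterozygotes; W-linked: `round(N_f f0)` W chromosomes replaced;
half-up rounding) into a resident population at mutation-selection
equilibrium. The neutral benchmark is `f0` itself. Burn-in is a fixed,
configurable 200 generations (reproducibility over adaptive stopping); the
mean-zygote-load trajectory is recorded and a Mann-Kendall trend test is
available as a stationarity diagnostic, reported rather than enforced. All
replicates branch from the single equilibrated snapshot, each on an
independent seed substream (`SeedSequence.spawn`) with a 5-generation
decorrelation run before introduction; per-replicate burn-ins would
multiply the cost ~200-fold for no change in the measured quantity (the
equilibrium is unique and the neutral calibration is insensitive to the
mitochondrial state). Runs are bit-reproducible given a seed. Censored
replicates (allele still segregating at the horizon) are reported and never
counted in `p_hat = fixed / (fixed + lost)`; the interval is the Gaussian
binomial-proportion CI `1.96 sqrt(p(1-p)/n)`.

Two scale profiles ship: **desk** (N=100, L=6, 500 replicates) and
**paper** (N=500, L=10, 1000 replicates). The test suite runs the desk
profile with these problem sizes, chosen as the package's own balance of
statistical power against runtime: 2000 replicates for the neutral
calibration; 150 replicates per point on the 3x3 mutation-rate grid; 400
replicates per arm for the oogamy-suppression and germline-proliferation
comparisons; 300 for the high-`mu_B` threshold check; 1e5 lineages for all
oracle-equivalence checks; cohorts of 2000 organisms for the fitness
comparisons. Fixation-probability *levels* shift with `N` and `L`, so at
desk scale only directions and orderings of effects are asserted, not
absolute values; the paper profile is the configuration for quantitative
heat-map work and is reachable through the same API/CLI.

The extended-lifecycle approximation is available through the oracle:
`expected_fitness_of_distribution` reads an adult's fitness directly off a
propagated distribution (e.g. `p^(60)`), replacing full development when
the division count makes agent-based simulation disproportionate; gamete
loads can likewise be drawn from `p^(n)` at the germline's division count.

## What the generator does and does not emulate

The synthetic populations implement the study conditions exactly as the
model states them: fixed even `N` with enforced equal sex numbers,
synchronous development, a single germline locus pair plus W-linked oogamy,
fixed-severity mutations, no within-cell selection, no paternal leakage, no
overlapping generations, no spatial structure, no cell death outside
atresia. Passing tests therefore validate the model's internal logic and
its agreement with the exact distribution theory — not the biological
realism of any parameter. Mutation rates here are orders of magnitude above
empirical estimates so that evolutionary outcomes resolve within tractable
population sizes; conclusions should be read through relative comparisons
(e.g. `mu_S` vs `mu_B`), which is also how the scientific claims are framed.

## Known numerical/degenerate-input choices

* Odd totals cannot partition; partition-only divisions and meiosis demand
  divisibility and raise structural errors otherwise.
* `n_g + a <= L` and `n_g >= Q` are enforced at development time.
* A fully censored invasion estimate raises rather than reporting a NaN.
* `p_hat = 0` yields the degenerate CI halfwidth 0 (logged).
* Transition matrices tolerate round-off at `1e-12` and are renormalized;
  distribution vectors must sum to 1 within `1e-9` on input.
* All RNG flows through injected `numpy.random.Generator` streams; spawned
  substreams keep sweeps and replicates deterministic and order-independent.
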