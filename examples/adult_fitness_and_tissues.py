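"""Worst-tissue epistasis makes segregation costly for complex organisms.

Develops cohorts of 2000 organisms (L = 10 divisions, lifespan S = 40,
mu_S = 0.01, mu_B = 0.005) from zygotes at 20% mutant load and compares
adult fitness across tissue counts and mitochondrial numbers.
"""

import numpy as np

from mitogerm import FitnessParams, LifeCycleParams, MutationRates
from mitogerm.development import adult_fitness_cohort, age_cohort, develop_cohort

rng = np.random.default_rng(2)
rates, fp = MutationRates(0.01, 0.005), FitnessParams(s=1.0, xi=2.0)
N = 2000


def cohort_fitness(T, M=50):
    lc = LifeCycleParams(L=10, T=T, S=40, baseline_M=M)
    zyg = rng.binomial(M, 0.2, size=N).astype(np.int64)
    soma, germ, germ_n = develop_cohort(
        zyg, np.full(N, M), np.full(N, 10), np.zeros(N, dtype=np.int64),
        lc, rates, rng,
    )
    soma, _ = age_cohort(soma, germ, germ_n, lc.S - lc.L, lc, rates, rng)
    return adult_fitness_cohort(soma, lc, fp)


zygote_fitness = 1.0 - 0.2**2
print(f"zygote fitness at 20% load: {zygote_fitness:.3f}\n")
print("tissues  M    mean_adult_fitness  sd")
for T, M in ((0, 50), (3, 50), (3, 200)):
    fit = cohort_fitness(T, M)
    print(f"{2**T:7d}  {M:3d}  {fit.mean():18.4f}  {fit.std(ddof=1):.4f}")
print(
    "\nWith one tissue, adult fitness tracks the inherited load. With eight\n"
    "tissues the worst tissue governs, so random segregation into tissue\n"
    "precursors depresses the mean and widens the spread; raising M to 200\n"
    "dampens drift and recovers much of the loss."
)
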