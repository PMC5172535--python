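"""Oogamy temporarily suppresses segregational variance.

A Q=4 oogamous zygote holds 2^Q M = 800 mitochondria and spends its first
four divisions partitioning them back down to M = 50 without replication.
This script evaluates the variance recurrence for those divisions, its
large-M approximation, and a 1e5-replicate Monte Carlo partition-only
simulation, then follows both life histories out to 20 divisions.
"""

import numpy as np

from mitogerm import (
    MutationRates,
    oogamy_variance_approx,
    oogamy_variance_recurrence,
    simulate_lineages,
    variance_closed_form,
    variance_profile,
)

M, Q, p0 = 50, 4, 0.5
rng = np.random.default_rng(1)
lin = simulate_lineages(400, 800, M, MutationRates(0.0, 0.0), Q, 100_000, rng)

print("early divisions of the Q=4 zygote (partition-only):")
print("n   recurrence   approximation   monte_carlo   isogamous_closed_form")
for n in range(1, Q + 1):
    tot = 800 >> n
    mc = (lin[n] / tot).var(ddof=1)
    print(
        f"{n}   {oogamy_variance_recurrence(p0, M, Q, n):.6f}"
        f"     {oogamy_variance_approx(p0, M, Q, n):.6f}"
        f"        {mc:.6f}      {variance_closed_form(p0, M, n):.6f}"
    )

print("\nvariance of mutant load out to 20 divisions:")
print("n    Q=0 (isogamy)   Q=4 (oogamy)")
for n in (1, 4, 8, 12, 20):
    print(
        f"{n:2d}   {variance_closed_form(p0, M, n):.5f}"
        f"         {variance_profile(p0, M, Q, n):.5f}"
    )
print(
    "\nThe large zygote suppresses variance ~16-fold in the first division\n"
    "(protecting tissue precursors from unlucky segregation), but the gap\n"
    "closes steadily once the baseline copy number is restored."
)
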