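"""Segregational drift turns heteroplasmy into between-cell variance.

Propagates the exact mutant-load distribution of a cell lineage (M = 50
mitochondria, starting at 24% mutant load) through ten cell divisions at a
copying-error rate of mu_S = 0.01, and compares the mutation-free variance
against the closed form Var(P_n) = p0(1-p0)[1 - (1 - 1/(2M-1))^n].
"""

import numpy as np

from mitogerm import (
    delta_distribution,
    distribution_moments,
    propagate_distribution,
    variance_closed_form,
)

M, m0, mu = 50, 12, 0.01
p = delta_distribution(M, m0)

print("division  mean_load  var_load   mutation_free_var  closed_form")
for n in range(11):
    pn = propagate_distribution(p, mu, n)
    p0n = propagate_distribution(p, 0.0, n)
    mean, var = distribution_moments(pn)
    _, var0 = distribution_moments(p0n)
    cf = variance_closed_form(m0 / M, M, n)
    print(
        f"{n:8d}  {mean / M:9.4f}  {var / M**2:9.5f}  {var0 / M**2:17.5f}"
        f"  {cf:11.5f}"
    )

# mutation slowly raises the mean load, while segregation alone (mu = 0)
# spreads the distribution without moving the mean: the mutation-free
# variance column reproduces the closed form to floating-point accuracy.
pn = propagate_distribution(p, mu, 10)
frac_better = float(pn[:m0].sum())
print(
    f"\nAfter 10 divisions at mu_S={mu}, {frac_better:.1%} of cells carry "
    f"fewer mutants than the zygote did — drift keeps generating\n"
    "high-quality daughters that selection on gametes can exploit."
)
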