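"""Off-time memory and the cyclicity gain from a refractory period.

Shows that refractory off-times (3 h + Exp(3.5 h)) fail an exponentiality
test and carry memory, that removing the refractory shift restores
memorylessness, and that the refractory period makes simulated
transcription cycles more regular (lower ACF first-peak-time variance).
"""

import numpy as np

from txcycle.refractory import (
    exponential_ks_test,
    memory_function,
    shift_by_refractory,
)
from txcycle.workflows import cyclicity_ordering_study

rng = np.random.default_rng(0)
off = 3.0 + rng.exponential(3.5, 1000)

ks = exponential_ks_test(off, seed=1)
print(f"off-times vs exponential: KS = {ks['statistic']:.3f}, p = {ks['p_value']:.3f}")

excess = shift_by_refractory(off, 3.0, "remove")
ks2 = exponential_ks_test(excess[excess > 0], seed=2)
print(f"excess (refractory removed): KS = {ks2['statistic']:.3f}, p = {ks2['p_value']:.3f}")

mc = memory_function(off)
i0 = 0  # s = 0
i2 = np.searchsorted(mc.s_grid, 2.0)
j2 = np.searchsorted(mc.t_values, 2.0)
print(f"P(wait > 2 h more | waited 0 h) = {mc.prob[i0, j2]:.2f}  "
      f"(memoryless reference {mc.exponential_reference[j2]:.2f})")
print(f"P(wait > 2 h more | waited 2 h) = {mc.prob[i2, j2]:.2f}")

res = cyclicity_ordering_study(n_replicates=10, n_cells=500, seed=0)
print(f"first-peak variance, with refractory:    {res['mean_variance_with']:.1f} h^2")
print(f"first-peak variance, without refractory: {res['mean_variance_without']:.1f} h^2")
print(f"ordered (without > with) in {res['wins']}/{res['n_replicates']} replicates")
# The hard 3-h floor makes short waits certain to continue (memory), and
# concentrates the cycle period, so the population cycles more regularly.
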