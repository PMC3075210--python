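"""Windowed rank correlation C(T) between dual-reporter transcription profiles.

Contrasts the unstimulated scenario (independent switch processes at the
two promoters: no correlation) with the stimulated shared-path scenario
(synchronized activation: correlation near 1 at short windows).
"""

import numpy as np

from txcycle.workflows import independence_study, synchronization_study

indep = independence_study(n_cells=40, seed=5, n_boot=1000)
sync = synchronization_study(n_cells=40, seed=5, n_boot=1000)

print("T (h):              ", np.round(indep.T, 1))
print("independent median: ", np.round(indep.median, 2))
print("  CI excludes 0?    ", indep.significant())
print("shared-path median: ", np.round(sync.median, 2))
print("  CI excludes 0?    ", sync.significant())
# Independent promoters: medians hover near 0 and the bootstrap CI for the
# median covers 0 at every window length — transcription cycles at the two
# loci are not coordinated.  After a synchronizing stimulus the shared
# activation drives the short-window median close to 1.
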