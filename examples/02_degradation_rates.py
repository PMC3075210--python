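"""Estimate reporter degradation rates from inhibitor decay experiments.

Simulates a cycloheximide (translation-block) and an actinomycin D
(transcription-block) experiment and fits delta_P and delta_M, the rates
required before transcription can be reconstructed from protein data.
"""

import numpy as np

import txcycle as tx
from txcycle.degradation import fit_delta_m, fit_delta_p

kin = tx.LUC_KINETICS  # truth: delta_M = 0.7 /h, delta_P = 0.35 /h
grid = np.arange(0.0, 10.0 + 1e-9, 0.5)
noise = tx.NoiseParams(sd_additive=0.1, cv_multiplicative=0.03)
m_ss, p_ss = 5.0, 5.0 / 0.35

chx = tx.simulate_decay_experiment(
    "translation-block", kin, m_ss, p_ss, grid, noise=noise, seed=1
)
actd = tx.simulate_decay_experiment(
    "transcription-block", kin, m_ss, p_ss, grid, noise=noise, seed=2
)

fit_p = fit_delta_p(chx)
fit_m = fit_delta_m(actd, fit_p.rate)
print(f"delta_P = {fit_p.rate:.3f} /h (se {fit_p.rate_se:.3f}), truth 0.350")
print(f"delta_M = {fit_m.rate:.3f} /h (se {fit_m.rate_se:.3f}), truth 0.700")
# Protein decays as a single exponential once translation stops; after a
# transcription block the protein follows a double exponential whose second
# rate is the mRNA half-life, recovered here to a few percent at 3% noise.
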