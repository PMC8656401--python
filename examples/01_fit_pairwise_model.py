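"""Fit the pairwise maximum-entropy model to a small binary state series.

Builds a 2-region model with a known interaction (J12 = ln 3, so the all-on
state is exactly three times as likely as each other state), samples from it,
and refits.  The printed moment gap shows the maximum-entropy property: at
convergence the model's state and pairwise activation moments equal the data's.
"""

import numpy as np

from statescape import (
    IsingModel,
    boltzmann_distribution,
    empirical_distribution,
    fit_pmem,
    sample_states,
)

true = IsingModel(h=np.zeros(2), J=np.log(3.0) * (np.ones((2, 2)) - np.eye(2)))
print("true Boltzmann probabilities:", boltzmann_distribution(true).probabilities)

series = sample_states(true, T=50_000, seed=0)
model, report = fit_pmem(empirical_distribution(series))

print(f"fitted h = {model.h.round(4)}  (true 0, 0)")
print(f"fitted J12 = {model.J[0, 1]:.4f}  (true ln 3 = {np.log(3):.4f})")
print(f"converged in {report.iterations} iterations, moment gap {report.max_moment_gap:.1e}")
print("-> h/J are chosen so the model reproduces the data's first and second")
print("   moments exactly; the J12 estimate differs from ln 3 only by sampling noise.")
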