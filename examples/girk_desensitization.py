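"""GIRK current desensitization: residual currents and group comparison.

Simulates 415 s agonist applications at 156 Hz with different planted decay
time constants, measures the residual current fraction, and compares groups
with one-way ANOVA plus Bonferroni-corrected pairwise tests.
"""

import numpy as np

from neurobias import (
    GirkTruth,
    compare_groups,
    fit_monoexponential_decay,
    generate_girk_trace,
    residual_fraction,
)

conditions = {"no_barr2": 2000.0, "barr2_slow": 400.0, "barr2_fast": 120.0}
groups = {}
for label, tau in conditions.items():
    residuals = []
    for rep in range(6):
        truth = GirkTruth(onset_tau=5.0, decay_tau=tau, duration=415.0)
        trace = generate_girk_trace(truth, seed=100 + rep, noise_sd=0.01)
        residuals.append(residual_fraction(trace, t_end=415.0))
    groups[label] = np.array(residuals)
    fit = fit_monoexponential_decay(trace)
    print(f"{label:12s} planted tau {tau:7.0f} s  residual {np.mean(residuals):.3f}  "
          f"fitted tau {fit.decay_tau:7.0f} s")

res = compare_groups(groups)
print(f"\nANOVA: F = {res.f_statistic:.1f}, p = {res.p_value:.2e}")
print(res.pairwise.round(6).to_string(index=False))
print("\nFaster decay (stronger desensitization) leaves a smaller residual")
print("fraction of the peak current after the 415 s application.  A decay")
print("constant much longer than the application window (no_barr2) is only")
print("weakly identified by the monoexponential fit, as expected.")
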