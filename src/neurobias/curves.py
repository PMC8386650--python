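"""Closed-form concentration-response models.

Two response models are used throughout the package:

* the variable-slope (four-parameter) Hill sigmoid, parametrised by pEC50 so
  that potencies read directly in -log10 molar, and
* the Black-Leff operational model of agonism in its transduction-ratio form,
  where each agonist is summarised by log R = log10(tau/KA).

Concentrations are molar everywhere; log transforms are base 10.
"""

from __future__ import annotations

import numpy as np

__all__ = ["hill_response", "operational_response"]


def hill_response(conc, pec50, top, hill_n, basal=0.0):
    """Variable-slope sigmoid response at molar concentration(s) ``conc``.

    Y(c) = basal + top / (1 + 10**(hill_n * (-pec50 - log10 c)))

    ``top`` is the span above ``basal`` (Y -> basal + top as c -> inf and
    Y(EC50) = basal + top/2).  ``conc`` must be strictly positive.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive (molar)")
    x = np.log10(conc)
    expo = np.clip(hill_n * (-pec50 - x) * np.log(10.0), -700.0, 700.0)
    return basal + top / (1.0 + np.exp(expo))


def operational_response(conc, em, basal, n, log_ka, log_r):
    """Operational (Black-Leff) model response.

    E = Basal + (Em - Basal) * tau^n [A]^n / (([A] + KA)^n + tau^n [A]^n)

    with tau = 10**(log_r + log_ka) and KA = 10**log_ka.  Equivalently
    E = Basal + (Em - Basal) / (1 + (([A] + KA) / (tau [A]))^n), the form used
    here for overflow safety.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative (molar)")
    ka = 10.0 ** log_ka
    tau = 10.0 ** (log_r + log_ka)
    with np.errstate(divide="ignore"):
        log_ratio = np.where(conc > 0, np.log(conc + ka) - np.log(tau * conc), np.inf)
    expo = np.clip(n * log_ratio, -700.0, 700.0)
    return basal + (em - basal) / (1.0 + np.exp(expo))
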