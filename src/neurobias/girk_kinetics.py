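"""Desensitization analysis of GIRK current traces.

GIRK (G protein-gated inwardly rectifying K+) currents report Gbetagamma
release downstream of receptor activation.  During sustained agonist
application the current decays as the receptor desensitizes; the residual
current after a long application (415 s in the reference protocol) is the
summary readout, compared across conditions by one-way ANOVA with Bonferroni
pairwise correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GIRKTrace",
    "DecayFit",
    "GroupComparison",
    "normalize_to_peak",
    "residual_fraction",
    "fit_monoexponential_decay",
    "compare_groups",
]


@dataclass(frozen=True)
class GIRKTrace:
    """Current time series on a uniform time grid (seconds, normalized units)."""

    time: np.ndarray
    current: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        c = np.asarray(self.current, dtype=float)
        if t.size != c.size or t.size < 2:
            raise ValueError("time and current must be equal length, >= 2 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "current", c)

    @property
    def peak(self) -> float:
        return float(np.max(self.current))

    @property
    def peak_time(self) -> float:
        return float(self.time[int(np.argmax(self.current))])


@dataclass(frozen=True)
class DecayFit:
    decay_tau: float
    plateau: float
    converged: bool
    decay_tau_stderr: Optional[float] = None
    plateau_stderr: Optional[float] = None


@dataclass(frozen=True)
class GroupComparison:
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, t, p_raw, p_adj


def normalize_to_peak(trace: GIRKTrace, baseline: float = 0.0) -> GIRKTrace:
    """Divide the trace by its peak so max(output) == 1.

    An agonist-independent ``baseline`` current, when known, is subtracted
    before normalization.  Idempotent on an already-normalized trace.
    """
    current = trace.current - baseline
    peak = np.max(current)
    if peak <= 0:
        raise ValueError("trace peak must be positive after baseline subtraction")
    return GIRKTrace(time=trace.time, current=current / peak)


def residual_fraction(trace: GIRKTrace, t_end: float, window: float = 5.0) -> float:
    """Fraction of peak current remaining at ``t_end`` (seconds).

    Mean of the peak-normalized current over the terminal ``window`` seconds
    ending at ``t_end``; the window averages out sampling noise at the 156 Hz
    acquisition rate.  ``t_end = 0`` returns the first sample.
    """
    t = trace.time
    if t_end > t[-1] + 0.5 * (t[1] - t[0]) or t_end < t[0] - 0.5 * (t[1] - t[0]):
        raise ValueError(f"t_end={t_end} outside trace support [{t[0]}, {t[-1]}]")
    normalized = normalize_to_peak(trace)
    mask = (t >= t_end - window) & (t <= t_end)
    if not mask.any():
        mask = np.zeros_like(t, dtype=bool)
        mask[np.argmin(np.abs(t - t_end))] = True
    return float(np.mean(normalized.current[mask]))


def fit_monoexponential_decay(trace: GIRKTrace, from_peak: bool = True) -> DecayFit:
    """Fit plateau + (1 - plateau) * exp(-(t - t_peak)/tau) to the decay phase.

    The trace is peak-normalized first; the fit runs on the post-peak segment
    (or the whole trace if ``from_peak`` is false).  A flat segment leaves tau
    unidentifiable and is reported as an unconverged fit rather than raising.
    """
    norm = normalize_to_peak(trace)
    if from_peak:
        i0 = int(np.argmax(norm.current))
    else:
        i0 = 0
    t = norm.time[i0:] - norm.time[i0]
    y = norm.current[i0:]
    if t.size < 20:
        raise ValueError("need >= 20 samples after the peak")
    span = float(np.max(y) - np.min(y))
    if span < 1e-9:
        return DecayFit(decay_tau=np.nan, plateau=float(np.mean(y)), converged=False)

    def model(params, t):
        p = params["plateau"].value
        tau = params["tau"].value
        return p + (1.0 - p) * np.exp(-t / tau)

    params = lmfit.Parameters()
    params.add("plateau", value=float(y[-1]), min=-0.5, max=1.5)
    params.add("tau", value=max(t[-1] / 3.0, 1e-3), min=1e-6, max=1e6)
    try:
        out = lmfit.minimize(lambda p: model(p, t) - y, params)
    except Exception:
        return DecayFit(decay_tau=np.nan, plateau=np.nan, converged=False)
    tau = float(out.params["tau"].value)
    plateau = float(out.params["plateau"].value)
    # tau pinned at its upper bound means no measurable decay
    converged = bool(out.success) and tau < 0.99e6
    return DecayFit(
        decay_tau=tau,
        plateau=plateau,
        converged=converged,
        decay_tau_stderr=out.params["tau"].stderr,
        plateau_stderr=out.params["plateau"].stderr,
    )


def compare_groups(groups: Mapping[str, np.ndarray]) -> GroupComparison:
    """One-way ANOVA across conditions plus Bonferroni-adjusted pairwise t-tests.

    ``groups`` maps condition label -> residual-fraction observations.  The
    Bonferroni adjustment multiplies each raw two-sided p by the number of
    pairwise comparisons, capped at 1.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for label, arr in zip(labels, arrays):
        if arr.size < 2:
            raise ValueError(f"group {label!r} needs >= 2 observations")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:  # all observations identical: no effect anywhere
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = stats.f_oneway(*arrays)
    pairs = list(combinations(range(len(labels)), 2))
    rows = []
    for i, j in pairs:
        if np.ptp(np.concatenate([arrays[i], arrays[j]])) == 0:
            t, p_raw = 0.0, 1.0
        else:
            t, p_raw = stats.ttest_ind(arrays[i], arrays[j])
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "t": float(t),
                "p_raw": float(p_raw),
                "p_adj": float(min(1.0, p_raw * len(pairs))),
            }
        )
    return GroupComparison(
        f_statistic=float(f_stat), p_value=float(p_val), pairwise=pd.DataFrame(rows)
    )
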