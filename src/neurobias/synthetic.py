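"""Synthetic data generators with known ground truth.

Every input the analysis chain consumes can be generated here: BRET-style
concentration-response tables (Hill or operational-model truths), GIRK current
time series, and per-frame coordinate tables with planted contact frequencies.
Toy potentials for the metadynamics engine live in :mod:`neurobias.metadynamics`.

All generators take an explicit integer seed and are deterministic: the same
seed yields byte-identical output.  Noise is i.i.d. Gaussian on the response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .curves import hill_response, operational_response
from .girk_kinetics import GIRKTrace

__all__ = [
    "BretTruth",
    "OperationalTruth",
    "GirkTruth",
    "DEFAULT_CONC_GRID",
    "generate_bret_dataset",
    "generate_operational_dataset",
    "generate_girk_trace",
    "generate_contact_fixture",
]

#: Default 9-point concentration grid, 1 pM - 100 uM, log-spaced.  Spans the
#: potency range of all ligands considered (pEC50 roughly 4-8).
DEFAULT_CONC_GRID = np.logspace(-12.0, -4.0, 9)


@dataclass(frozen=True)
class BretTruth:
    """Ground-truth Hill parameters for one (agonist, pathway) BRET curve.

    ``emax`` is the response span above ``basal`` in uBRET units; ``pec50`` is
    -log10 of the half-maximal molar concentration.
    """

    agonist: str
    pathway: str
    pec50: float
    emax: float
    hill_n: float = 1.0
    basal: float = 0.0
    noise_sd: float = 0.05

    def __post_init__(self):
        if not math.isfinite(self.pec50):
            raise ValueError("pec50 must be finite")
        if self.emax < 0:
            raise ValueError("emax must be >= 0")
        if self.hill_n <= 0:
            raise ValueError("hill_n must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class OperationalTruth:
    """Ground truth for an operational-model dataset.

    System parameters (``em``, ``basal``, ``n``) are shared by all agonists;
    ``log_ka`` maps agonist -> log10 KA (0 for full agonists) and ``log_r``
    maps agonist -> {pathway -> log10(tau/KA)}.
    """

    em: float
    basal: float
    n: float
    log_ka: Mapping[str, float]
    log_r: Mapping[str, Mapping[str, float]]

    def __post_init__(self):
        if self.em <= self.basal:
            raise ValueError("Em must exceed Basal")
        if self.n <= 0:
            raise ValueError("transducer slope n must be > 0")
        missing = set(self.log_r) - set(self.log_ka)
        if missing:
            raise ValueError(f"log_ka missing for agonists: {sorted(missing)}")


@dataclass(frozen=True)
class GirkTruth:
    """Ground truth for a GIRK current trace.

    ``decay_tau`` may be ``math.inf`` for a non-desensitizing response.
    ``baseline`` is the agonist-independent current level the trace decays
    towards, as a fraction of ``peak``'s units.
    """

    peak: float = 1.0
    onset_tau: float = 5.0
    decay_tau: float = math.inf
    baseline: float = 0.0
    duration: float = 415.0
    sample_rate: float = 156.0

    def __post_init__(self):
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample_rate must be > 0")
        if not 0 <= self.baseline < self.peak:
            raise ValueError("require 0 <= baseline < peak")
        if self.onset_tau < 0 or self.decay_tau <= 0:
            raise ValueError("time constants must be positive")

    @classmethod
    def with_residual(cls, residual: float, t_end: float = 415.0, **kwargs) -> "GirkTruth":
        """Truth whose decay term leaves ``residual`` of peak at ``t_end``.

        Inverts e^(-t_end/tau) = residual (baseline fixed at 0).
        """
        if not 0 < residual < 1:
            raise ValueError("residual must be in (0, 1)")
        tau = t_end / math.log(1.0 / residual)
        return cls(decay_tau=tau, baseline=0.0, duration=max(t_end, kwargs.pop("duration", t_end)), **kwargs)


def _check_grid(conc_grid) -> np.ndarray:
    conc = np.asarray(conc_grid, dtype=float)
    if conc.size == 0:
        raise ValueError("concentration grid is empty")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive (molar)")
    if np.any(np.diff(conc) <= 0):
        raise ValueError("concentration grid must be strictly increasing")
    return conc


def generate_bret_dataset(
    truths: Sequence[BretTruth],
    conc_grid=None,
    n_rep: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format replicate-level concentration-response table.

    One row per (truth, concentration, replicate) with columns
    ``agonist, pathway, conc_M, replicate, response``.  The noise-free mean at
    concentration c is ``basal + emax / (1 + 10**(hill_n*(-pec50 - log10 c)))``.
    """
    conc = _check_grid(DEFAULT_CONC_GRID if conc_grid is None else conc_grid)
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for truth in truths:
        mean = hill_response(conc, truth.pec50, truth.emax, truth.hill_n, truth.basal)
        for rep in range(1, n_rep + 1):
            noise = rng.normal(0.0, truth.noise_sd, size=conc.size) if truth.noise_sd > 0 else 0.0
            rows.append(
                pd.DataFrame(
                    {
                        "agonist": truth.agonist,
                        "pathway": truth.pathway,
                        "conc_M": conc,
                        "replicate": rep,
                        "response": mean + noise,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def generate_operational_dataset(
    truth: OperationalTruth,
    conc_grid=None,
    n_rep: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Concentration-response table drawn from the operational model.

    Rows cover every agonist/pathway combination present in ``truth.log_r``;
    schema matches :func:`generate_bret_dataset`.
    """
    conc = _check_grid(DEFAULT_CONC_GRID if conc_grid is None else conc_grid)
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for agonist, per_pathway in truth.log_r.items():
        for pathway, log_r in per_pathway.items():
            mean = operational_response(
                conc, truth.em, truth.basal, truth.n, truth.log_ka[agonist], log_r
            )
            for rep in range(1, n_rep + 1):
                noise = rng.normal(0.0, noise_sd, size=conc.size) if noise_sd > 0 else 0.0
                rows.append(
                    pd.DataFrame(
                        {
                            "agonist": agonist,
                            "pathway": pathway,
                            "conc_M": conc,
                            "replicate": rep,
                            "response": mean + noise,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


def generate_girk_trace(truth: GirkTruth, seed: int = 0, noise_sd: float = 0.0) -> GIRKTrace:
    """GIRK current trace: exponential onset times exponential decay to baseline.

    current(t) = peak * (1 - e^(-t/onset_tau))
                      * (b + (1 - b) * e^(-t/decay_tau)) + noise,  b = baseline/peak

    sampled at ``truth.sample_rate`` over ``truth.duration`` seconds
    (floor(duration * rate) samples, t_k = (k+1)/rate so the final sample sits
    at the end of the application window).
    """
    n = int(math.floor(truth.duration * truth.sample_rate))
    if n < 2:
        raise ValueError("duration * sample_rate must give at least 2 samples")
    t = (np.arange(n, dtype=float) + 1.0) / truth.sample_rate
    onset = 1.0 - np.exp(-t / truth.onset_tau) if truth.onset_tau > 0 else np.ones_like(t)
    b = truth.baseline / truth.peak
    decay = b + (1.0 - b) * (np.exp(-t / truth.decay_tau) if math.isfinite(truth.decay_tau) else 1.0)
    current = truth.peak * onset * decay
    if noise_sd > 0:
        current = current + np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    return GIRKTrace(time=t, current=current)


def generate_contact_fixture(
    n_frames: int,
    targets: Mapping[tuple, float],
    cutoff: float = 3.5,
    seed: int = 0,
    mediated_fraction: float = 0.0,
    n_decoy_waters: int = 0,
) -> pd.DataFrame:
    """Per-frame coordinate table with planted contact frequencies.

    ``targets`` maps (ligand_atom_id, residue_atom_id) -> Bernoulli contact
    probability per frame.  In contact frames the partner is placed within
    ``cutoff``; with probability ``mediated_fraction`` the contact is realised
    through a bridging water instead (partner outside cutoff, water oxygen
    within cutoff of both).  Columns: frame, atom_id, role, x, y, z (Angstrom).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if n_frames < 1:
        raise ValueError("need at least one frame")
    for pair, p in targets.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"target frequency for {pair} must be in [0, 1]")
    if not 0.0 <= mediated_fraction <= 1.0:
        raise ValueError("mediated_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    # anchor each pair's ligand atom on its own lattice site so pairs do not
    # accidentally bridge through each other's waters
    anchors = {pair: np.array([50.0 * i, 0.0, 0.0]) for i, pair in enumerate(targets)}
    for frame in range(n_frames):
        water_idx = 0
        for pair, p in targets.items():
            lig_id, res_id = pair
            a = anchors[pair]
            records.append((frame, lig_id, "ligand", *a))
            contact = rng.random() < p
            mediated = contact and (rng.random() < mediated_fraction)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            if contact and not mediated:
                d = rng.uniform(0.5 * cutoff, cutoff)
            elif mediated:
                # partner outside cutoff but close enough for a midpoint bridge
                d = rng.uniform(1.5 * cutoff, 1.9 * cutoff)
            else:
                d = rng.uniform(1.5 * cutoff, 3.0 * cutoff)
            b = a + d * direction
            records.append((frame, res_id, "residue", *b))
            if mediated:
                # bridge: water at the midpoint works whenever d < 2*cutoff
                w = (a + b) / 2.0
                records.append((frame, f"W{water_idx}", "water", *w))
                water_idx += 1
        for _ in range(n_decoy_waters):
            w = rng.uniform(-5.0, 5.0, size=3) + np.array([0.0, 4.0 * cutoff, 0.0])
            records.append((frame, f"W{water_idx}", "water", *w))
            water_idx += 1
    return pd.DataFrame(records, columns=["frame", "atom_id", "role", "x", "y", "z"])
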