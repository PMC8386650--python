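"""Shared fixtures.

The metadynamics runs are expensive (hundreds of thousands of Langevin
steps), so each configuration is run once per session and shared between the
unit tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from neurobias import MetadParams, ToyPotential, run_langevin_metadynamics
from neurobias.synthetic import BretTruth

# pEC50/Emax parameter sets for GIRK activation by the four reference agonists
FIG4_TRUTHS = [
    BretTruth("dopamine", "GIRK", pec50=7.88, emax=1.07, hill_n=1.0, basal=0.0, noise_sd=0.0),
    BretTruth("(S)-5-OH-DPAT", "GIRK", pec50=7.94, emax=1.99, hill_n=1.0, basal=0.0, noise_sd=0.0),
    BretTruth("(R)-5-OH-DPAT", "GIRK", pec50=6.02, emax=0.78, hill_n=1.0, basal=0.0, noise_sd=0.0),
    BretTruth("p-tyramine", "GIRK", pec50=4.06, emax=0.66, hill_n=1.0, basal=0.0, noise_sd=0.0),
]

CV_GRID = np.arange(-2.0, 2.0 + 0.02, 0.02)
DW_BARRIER = 1.3


@pytest.fixture(scope="session")
def fig4_truths():
    return FIG4_TRUTHS


@pytest.fixture(scope="session")
def cv_grid():
    return CV_GRID


@pytest.fixture(scope="session")
def double_well_potential():
    return ToyPotential.double_well(barrier=DW_BARRIER, half_separation=1.0)


@pytest.fixture(scope="session")
def double_well_run(double_well_potential):
    """6-walker well-tempered run on the 1.3 kcal/mol double well (7500 hills)."""
    traj, hills = run_langevin_metadynamics(
        double_well_potential, MetadParams(), n_steps=500_000, seed=3, grid_range=(-4, 4)
    )
    return traj, hills


@pytest.fixture(scope="session")
def harmonic_run():
    pot = ToyPotential.harmonic(k=2.0)
    traj, hills = run_langevin_metadynamics(
        pot, MetadParams(), n_steps=400_000, seed=5, grid_range=(-4, 4)
    )
    return pot, traj, hills


@pytest.fixture(scope="session")
def tilted_double_well_run():
    pot = ToyPotential.double_well(barrier=DW_BARRIER, tilt=0.3)
    traj, hills = run_langevin_metadynamics(
        pot, MetadParams(), n_steps=400_000, seed=7, grid_range=(-4, 4)
    )
    return pot, traj, hills
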