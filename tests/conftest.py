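import numpy as np
import pandas as pd
import pytest

from enantiodyn import synthgen
from enantiodyn.core_io import SpeciesMap, Trajectory


@pytest.fixture(scope="session")
def bias_run():
    """A short run with heterochiral-biased kinetics (k_off hetero < homo),
    shared by detection/lifetime/census tests."""
    spec = synthgen.preset("hetero-bias-kinetic", seed=7, n_steps=2000, save_interval=2)
    traj, smap, truth = synthgen.simulate(spec)
    return spec, traj, smap, truth


@pytest.fixture(scope="session")
def free_run():
    """One replicate of free (non-associating) tracers with known D."""
    spec = synthgen.preset("free-tracers", seed=21)
    traj, smap, truth = synthgen.simulate(spec)
    return spec, traj, smap, truth


def make_trajectory(frames, box=10.0, dt_ps=1.0, wrapped=False):
    frames = np.asarray(frames, dtype=float)
    return Trajectory(
        times=np.arange(frames.shape[0], dtype=float) * dt_ps,
        frames=frames,
        box=np.full(3, float(box)),
        wrapped=wrapped,
    )


def make_species_map(rows):
    return SpeciesMap(
        pd.DataFrame(rows, columns=["particle", "molecule_id", "species", "chirality", "role"])
    )


@pytest.fixture
def two_molecule_map():
    """1 R-MA (bead + chiral_H) and 1 R-CRA bead."""
    return make_species_map(
        [
            (0, 0, "MA", "R", "heavy"),
            (1, 0, "MA", "R", "chiral_H"),
            (2, 1, "CRA", "R", "heavy"),
        ]
    )
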