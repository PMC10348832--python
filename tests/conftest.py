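"""Shared fixtures: tiny in-memory ensembles and on-disk synthetic files."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mdsieve as m

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_ensemble(frames, names=None, resids=None, resnames=None):
    """Build a TrajectoryEnsemble from a list of (n_atoms, 3) arrays."""
    coords = np.asarray(frames, dtype=np.float64)
    n_atoms = coords.shape[1]
    table = pd.DataFrame(
        {
            "name": names if names is not None else ["CA"] * n_atoms,
            "resname": resnames if resnames is not None else ["ALA"] * n_atoms,
            "resid": resids if resids is not None else np.arange(1, n_atoms + 1),
            "chain": ["A"] * n_atoms,
        }
    )
    return m.TrajectoryEnsemble(coords, table)


@pytest.fixture
def peptide():
    """A 5-residue peptide with N/CA/C atoms per residue, one static frame."""
    names, resids, coords = [], [], []
    for r in range(5):
        for j, atom in enumerate(("N", "CA", "C")):
            names.append(atom)
            resids.append(r + 1)
            coords.append([3.8 * r + j, float(r % 2), 0.0])
    return make_ensemble([coords], names=names, resids=resids)


@pytest.fixture(scope="session")
def two_state():
    """A small two-state trajectory: 200 frames, 50 residues, lid 20-35."""
    spec = m.TwoStateSpec(
        n_frames=200, n_residues=50, open_fraction=0.5,
        displacement=5.0, noise_sd=0.3, lid_range=(20, 35), seed=11,
    )
    return m.generate_two_state_trajectory(spec)


@pytest.fixture(scope="session")
def fixture_files(tmp_path_factory, two_state):
    """The small two-state trajectory written to disk as PDB + DCD."""
    prefix = tmp_path_factory.mktemp("fixtures") / "twostate"
    return m.write_fixture_files(two_state, prefix)


@pytest.fixture(scope="session")
def bimodal_90_10():
    """A 90/10 two-mode property series: 4000 frames, modes at 1.0 and 5.0."""
    return m.generate_property_series(
        "mixture",
        {"mu1": 1.0, "sigma1": 0.1, "mu2": 5.0, "sigma2": 0.1, "pi": 0.9},
        n_frames=4000, seed=7,
    )
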