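import numpy as np
import pytest

from pladpd.builder import Configuration
from pladpd.parameters import load_interaction_matrix
from pladpd.topology import default_bead_registry
from pladpd.units import SimulationUnits


@pytest.fixture(scope="session")
def registry():
    return default_bead_registry()


@pytest.fixture(scope="session")
def table1():
    return load_interaction_matrix("table1")


@pytest.fixture(scope="session")
def table2():
    return load_interaction_matrix("table2")


def make_config(
    positions,
    species,
    box,
    molecule_id=None,
    molecule_templates=None,
    bonds=None,
    velocities=None,
    masses=None,
    units=None,
):
    """Assemble a Configuration from raw arrays (analysis-test helper)."""
    positions = np.asarray(positions, float)
    n = len(positions)
    box = np.asarray(box, float)
    species = np.asarray(species, dtype="U4")
    if molecule_id is None:
        molecule_id = np.zeros(n, np.int64)
    else:
        molecule_id = np.asarray(molecule_id, np.int64)
    n_mol = int(molecule_id.max()) + 1 if n else 0
    if molecule_templates is None:
        molecule_templates = np.array(["synthetic"] * n_mol, dtype="U16")
    else:
        molecule_templates = np.asarray(molecule_templates, dtype="U16")
    return Configuration(
        box=box,
        positions=positions % box,
        velocities=(
            np.zeros((n, 3)) if velocities is None else np.asarray(velocities, float)
        ),
        species=species,
        masses=np.ones(n) if masses is None else np.asarray(masses, float),
        molecule_id=molecule_id,
        molecule_templates=molecule_templates,
        bonds=(
            np.empty((0, 2), np.int64)
            if bonds is None
            else np.asarray(bonds, np.int64).reshape(-1, 2)
        ),
        units=units or SimulationUnits(),
    )
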