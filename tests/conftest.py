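import numpy as np
import pytest

from hexreg import (Config, CouplingParams, HeterogeneousModel,
                    build_hex_mesh, build_interface, coarsen_mesh,
                    embed_landmarks)
from hexreg.io import LabeledVolume
from hexreg.phantom import PhantomSpec, generate_phantom, generate_scenarios

# near-critically damped dynamic-relaxation settings used by the
# phantom-scale simulation fixtures (equilibrium is damping-independent)
RELAX = {"solver": {"alpha": "auto", "tol": 3e-4, "ramp_steps": 400}}


@pytest.fixture(scope="session")
def phantom():
    """Default synthetic phantom: labeled volume + 25 landmarks."""
    return generate_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def phantom_mesh(phantom):
    vol, _ = phantom
    return build_hex_mesh(vol)


@pytest.fixture(scope="session")
def phantom_interface(phantom_mesh):
    return build_interface(phantom_mesh)


@pytest.fixture(scope="session")
def relax_config():
    return Config(dict(RELAX))


@pytest.fixture(scope="session")
def hetero_model(phantom_mesh, phantom_interface, relax_config):
    return HeterogeneousModel(phantom_mesh, relax_config,
                              interface=phantom_interface)


@pytest.fixture(scope="session")
def coarse_pair(phantom_mesh):
    return coarsen_mesh(phantom_mesh, (8, 4, 6))


@pytest.fixture(scope="session")
def low_model(coarse_pair, relax_config):
    coarse, _ = coarse_pair
    return HeterogeneousModel(coarse, relax_config)


@pytest.fixture(scope="session")
def embedded_landmarks(phantom_mesh, phantom):
    _, lms = phantom
    return embed_landmarks(phantom_mesh, lms)


@pytest.fixture(scope="session")
def scenarios(phantom):
    """Five compression positions with distinct magnitudes (the emulated
    study protocol: datasets A..E)."""
    vol, _ = phantom
    scns = generate_scenarios(vol, n_positions=5, seed=7)
    for s, mag in zip(scns, (7e-3, 8.5e-3, 1e-2, 8e-3, 9e-3)):
        s.magnitude = mag
    return scns


@pytest.fixture(scope="session")
def true_params():
    return CouplingParams(600.0, 500.0)


def block_volume(nx, ny, nz, spacing=5e-3, label=1):
    """Homogeneous rectangular block volume (all foreground)."""
    return LabeledVolume(labels=np.full((nx, ny, nz), label, np.int16),
                         spacing=np.full(3, spacing))


def embedded_block_volume(n=5, spacing=5e-3, lesion_label=3):
    """n^3 parenchyma block with a single central lesion voxel."""
    labels = np.full((n, n, n), 1, np.int16)
    c = n // 2
    labels[c, c, c] = lesion_label
    return LabeledVolume(labels=labels, spacing=np.full(3, spacing))
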