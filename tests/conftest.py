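from pathlib import Path

import numpy as np
import pytest

from kinasedyn import reference_structure_path
from kinasedyn.structures_io import SegmentSelection, Trajectory, make_atom
from kinasedyn.synthetic_data import (
    ToyDimerSpec,
    ToyKinaseSpec,
    build_helix,
    make_dimer_trajectory,
    make_hinged_trajectory,
)

DATA_DIR = Path(__file__).parent / "data"

# Reference crystal structure (PDB 3alo). The file is looked up in the
# package data directory / KINASEDYN_PDB_DIR; no download is attempted
# during unit tests.
CRYSTAL_PATH = reference_structure_path("3alo", download=False)
needs_crystal = pytest.mark.skipif(
    CRYSTAL_PATH is None,
    reason="reference crystal structure 3alo.pdb not available offline "
    "(place it in src/kinasedyn/data/ or KINASEDYN_PDB_DIR)",
)


@pytest.fixture(scope="session")
def bpti_path() -> Path:
    return DATA_DIR / "1bpi.pdb"


@pytest.fixture(scope="session")
def peptide_path() -> Path:
    return DATA_DIR / "2eqq_model1.pdb"


@pytest.fixture(scope="session")
def helix_trajectory() -> Trajectory:
    atoms, coords = build_helix(20)
    return Trajectory(atoms, coords[None], [0.0])


@pytest.fixture(scope="session")
def hinged():
    spec = ToyKinaseSpec(theta0=40.0, noise_amplitude=1.5, reversion_rate=0.15,
                         n_frames=300, seed=42)
    return make_hinged_trajectory(spec)


@pytest.fixture(scope="session")
def static_dimer():
    spec = ToyDimerSpec(n_frames=5, water_count=3)
    return make_dimer_trajectory(spec)


def toy_points_frame(cog_a, cog_v, cog_b, jitter_rng=None, n_per=4):
    """Three-residue topology whose per-residue cogs sit at given points.

    Residue 1 = ray_a, 2 = vertex, 3 = ray_b (chain A). Each residue has
    ``n_per`` atoms scattered symmetrically so the cog is exact.
    """
    atoms = []
    coords = []
    serial = 1
    rng = jitter_rng or np.random.default_rng(0)
    for resnum, cog in ((1, cog_a), (2, cog_v), (3, cog_b)):
        offsets = rng.normal(0, 1.0, size=(n_per // 2, 3))
        offsets = np.vstack([offsets, -offsets])  # symmetric: mean exactly 0
        for k in range(n_per):
            atoms.append(make_atom(serial, "CA" if k == 0 else f"C{k}", "C",
                                   "GLY", resnum, "A"))
            coords.append(np.asarray(cog, dtype=float) + offsets[k])
            serial += 1
    traj = Trajectory(atoms, np.asarray(coords)[None], [0.0])
    return traj.frame(0)


TOY_ANGLE_DEFN = dict(
    ray_a=SegmentSelection("A", 1, 1),
    vertex=SegmentSelection("A", 2, 2),
    ray_b=SegmentSelection("A", 3, 3),
)
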