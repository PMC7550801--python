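"""Seeded trajectory generators with known ground truth.

Every generator is bit-reproducible given (spec, seed) and returns its
ground truth through a side channel, never embedded in the trajectory
itself.  Pseudo-proteins are poly-alanine backbones built from ideal
internal coordinates, so secondary-structure geometry is exact; the
contact generator adds correctly named pseudo-side-chain atoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, TopologyError
from .structures_io import Atom, Trajectory, make_atom

__all__ = [
    "ToyKinaseSpec",
    "ToyDimerSpec",
    "build_backbone",
    "build_helix",
    "build_extended",
    "ou_series",
    "make_hinged_trajectory",
    "make_dimer_trajectory",
    "make_contact_trajectory",
    "make_jitter_replicas",
]

# ideal backbone internal coordinates (Å / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
OMEGA = 180.0

HELIX_PHI, HELIX_PSI = -57.0, -47.0
EXTENDED_PHI, EXTENDED_PSI = 180.0, 180.0


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF: position D from A-B-C with given C-D bond, B-C-D angle, A-B-C-D torsion."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    phi_psi: list[tuple[float, float]],
    chain_id: str = "A",
    start_residue: int = 1,
    residue_name: str = "ALA",
    start_serial: int = 1,
) -> tuple[list[Atom], np.ndarray]:
    """Backbone (N, CA, C, O) chain with the given per-residue (φ, ψ).

    φ of the first residue is undefined and ignored.  Returns (atoms,
    coordinates in Å).
    """
    n_res = len(phi_psi)
    if n_res < 1:
        raise ConfigurationError("need at least one residue")
    coords: list[np.ndarray] = []
    atoms: list[Atom] = []
    serial = start_serial

    def add(name, element, resnum, xyz):
        nonlocal serial
        atoms.append(make_atom(serial, name, element, residue_name, resnum, chain_id))
        coords.append(np.asarray(xyz, dtype=float))
        serial += 1

    # first residue: canonical placement
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    angle = np.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(angle), np.sin(angle), 0.0])
    o_positions = []

    all_n = [n0]
    all_ca = [ca0]
    all_c = [c0]
    for i in range(1, n_res):
        phi, psi = phi_psi[i]
        _, psi_prev = phi_psi[i - 1]
        n_i = _place_atom(all_n[-1], all_ca[-1], all_c[-1], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_i = _place_atom(all_ca[-1], all_c[-1], n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_i = _place_atom(all_c[-1], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi)
        all_n.append(n_i)
        all_ca.append(ca_i)
        all_c.append(c_i)

    # carbonyl O: anti-periplanar to the next residue's N (torsion psi+180)
    for i in range(n_res):
        if i < n_res - 1:
            o_i = _place_atom(all_n[i], all_ca[i], all_c[i], BOND_C_O, ANGLE_CA_C_O,
                              phi_psi[i][1] + 180.0)
        else:
            o_i = _place_atom(all_n[i], all_ca[i], all_c[i], BOND_C_O, ANGLE_CA_C_O, 0.0)
        o_positions.append(o_i)

    for i in range(n_res):
        resnum = start_residue + i
        add("N", "N", resnum, all_n[i])
        add("CA", "C", resnum, all_ca[i])
        add("C", "C", resnum, all_c[i])
        add("O", "O", resnum, o_positions[i])
    return atoms, np.vstack(coords)


def build_helix(n_residues: int, **kwargs) -> tuple[list[Atom], np.ndarray]:
    """Ideal α-helix (φ=−57°, ψ=−47°)."""
    return build_backbone([(HELIX_PHI, HELIX_PSI)] * n_residues, **kwargs)


def build_extended(n_residues: int, **kwargs) -> tuple[list[Atom], np.ndarray]:
    """Fully extended chain (φ=ψ=180°)."""
    return build_backbone([(EXTENDED_PHI, EXTENDED_PSI)] * n_residues, **kwargs)


def _recentre(coords: np.ndarray, target_cog) -> np.ndarray:
    return coords + (np.asarray(target_cog, dtype=float) - coords.mean(axis=0))


def _rot_z(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    return np.array([
        [np.cos(a), -np.sin(a), 0.0],
        [np.sin(a), np.cos(a), 0.0],
        [0.0, 0.0, 1.0],
    ])


def _rot_x(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    return np.array([
        [1.0, 0.0, 0.0],
        [0.0, np.cos(a), -np.sin(a)],
        [0.0, np.sin(a), np.cos(a)],
    ])


def ou_series(
    mean: float, reversion_rate: float, noise_amplitude: float, n: int, rng
) -> np.ndarray:
    """Discrete Ornstein–Uhlenbeck series started at its mean."""
    values = np.empty(n)
    current = mean
    for i in range(n):
        values[i] = current
        current = current + reversion_rate * (mean - current) + noise_amplitude * rng.standard_normal()
    return values


# ---------------------------------------------------------------------------
# hinged toy kinase
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyKinaseSpec:
    """Three-segment pseudo-kinase whose hinge angle follows an OU process."""

    n_ash: int = 15       # residues 250..  (moving ray)
    n_alpha_c: int = 16   # residues 139..  (static ray)
    n_hinge: int = 4      # residues 179..  (vertex)
    n_scaffold: int = 17  # residues 286..  (static bystander)
    ray_length: float = 25.0  # Å, cog distance of each ray from the vertex
    theta0: float = 40.0      # degrees, stationary mean of the hinge angle
    reversion_rate: float = 0.1
    noise_amplitude: float = 0.0
    n_frames: int = 100
    frame_dt_ns: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames <= 0:
            raise ConfigurationError("n_frames must be positive")


def make_hinged_trajectory(spec: ToyKinaseSpec) -> tuple[Trajectory, np.ndarray]:
    """Toy kinase whose ASH segment rotates rigidly about a hinge axis
    through the hinge-region cog by a per-frame OU angle.

    Returns (trajectory, ground-truth angle series in degrees): the
    cog-apex angle measured on the default intervals equals the ground
    truth exactly in the noiseless case.
    """
    rng = np.random.default_rng(spec.seed)

    atoms_c, coords_c = build_helix(spec.n_alpha_c, start_residue=139, start_serial=1)
    atoms_h, coords_h = build_extended(spec.n_hinge, start_residue=179,
                                       start_serial=1 + len(atoms_c))
    atoms_a, coords_a = build_helix(spec.n_ash, start_residue=250,
                                    start_serial=1 + len(atoms_c) + len(atoms_h))
    atoms_s, coords_s = build_helix(spec.n_scaffold, start_residue=286,
                                    start_serial=1 + len(atoms_c) + len(atoms_h) + len(atoms_a))

    # vertex cog at the origin; both ray cogs start on +x at ray_length
    coords_h = _recentre(coords_h, (0.0, 0.0, 0.0))
    coords_c = _recentre(coords_c, (spec.ray_length, 0.0, 0.0))
    ash_base = _recentre(coords_a, (spec.ray_length, 0.0, 0.0))
    coords_s = _recentre(coords_s, (-20.0, -20.0, -15.0))

    theta = ou_series(spec.theta0, spec.reversion_rate, spec.noise_amplitude,
                      spec.n_frames, rng)

    static = np.vstack([coords_c, coords_h])
    frames = np.empty((spec.n_frames, len(atoms_c) + len(atoms_h) + len(atoms_a) + len(atoms_s), 3))
    for t in range(spec.n_frames):
        rotated = ash_base @ _rot_z(theta[t]).T  # hinge axis = z through origin
        frames[t] = np.vstack([static, rotated, coords_s])

    traj = Trajectory(
        topology=tuple(atoms_c + atoms_h + atoms_a + atoms_s),
        coordinates=frames,
        times_ns=np.arange(spec.n_frames) * spec.frame_dt_ns,
        system_label="toy-hinge",
        replica_index=1,
    )
    return traj, theta


# ---------------------------------------------------------------------------
# toy dimer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyDimerSpec:
    """Two-subunit pseudo-dimer with scripted twist/translation of chain B.

    Chain B is chain A rotated 180° about z (C2 symmetry), so at zero
    schedules the subunits are exact mirror copies of frame 0
    throughout.  The N-lobe and αF cog separations lie along x (the
    interface normal) while the ASH separation is perpendicular to it.
    """

    chain_a: str = "A"
    chain_b: str = "B"
    twist_schedule: tuple = ()        # degrees per frame, about x through B's cog
    translation_schedule: tuple = ()  # nm per frame, along +x
    n_frames: int = 0                 # inferred from schedules when 0
    water_count: int = 0
    frame_dt_ns: float = 1.0
    seed: int = 0
    half_nlobe_gap: float = 15.0  # Å
    half_ash_gap: float = 30.0    # Å
    half_af_gap: float = 10.0     # Å

    def resolved_frames(self) -> int:
        n = max(self.n_frames, len(self.twist_schedule), len(self.translation_schedule))
        if n <= 0:
            raise ConfigurationError("dimer spec defines no frames")
        return n

    def __post_init__(self) -> None:
        if self.chain_a == self.chain_b:
            raise TopologyError("dimer chains must have distinct chain IDs")


def _build_subunit(spec: ToyDimerSpec, chain_id: str, start_serial: int):
    """One subunit with all the standard analysis intervals present."""
    segments = [
        # (builder, n_res, start_resnum, cog position)
        (build_helix, 25, 102, (-spec.half_nlobe_gap, 0.0, 0.0)),    # N-lobe
        (build_helix, 16, 139, (-20.0, -10.0, 10.0)),                # αC
        (build_helix, 5, 164, (-12.0, 3.0, 5.0)),                    # N-lobe strand
        (build_extended, 4, 179, (-15.0, -5.0, 2.0)),                # hinge
        (build_helix, 15, 250, (0.0, -spec.half_ash_gap, 0.0)),      # ASH
        (build_helix, 17, 286, (-spec.half_af_gap, 0.0, -25.0)),     # αF
    ]
    atoms: list[Atom] = []
    blocks = []
    serial = start_serial
    for builder, n_res, start_resnum, cog in segments:
        seg_atoms, seg_coords = builder(
            n_res, chain_id=chain_id, start_residue=start_resnum, start_serial=serial
        )
        serial += len(seg_atoms)
        atoms.extend(seg_atoms)
        blocks.append(_recentre(seg_coords, cog))
    return atoms, np.vstack(blocks), serial


def make_dimer_trajectory(spec: ToyDimerSpec) -> tuple[Trajectory, dict]:
    """Two-chain trajectory with scripted rigid motion of chain B.

    Returns (trajectory, ground truth) where the ground truth dict holds
    the applied per-frame ``twist_deg`` and ``translation_nm`` arrays.
    """
    n_frames = spec.resolved_frames()
    twist = np.zeros(n_frames)
    twist[: len(spec.twist_schedule)] = spec.twist_schedule
    translation = np.zeros(n_frames)
    translation[: len(spec.translation_schedule)] = spec.translation_schedule

    atoms_a, coords_a, serial = _build_subunit(spec, spec.chain_a, 1)
    atoms_b = [
        make_atom(serial + i, a.name, a.element, a.residue_name,
                  a.residue_number, spec.chain_b)
        for i, a in enumerate(atoms_a)
    ]
    serial += len(atoms_b)
    coords_b0 = coords_a @ _rot_z(180.0).T  # C2 copy

    water_atoms = []
    water_coords = []
    for k in range(spec.water_count):
        water_atoms.append(
            make_atom(serial + k, "O", "O", "HOH", 500 + k, "W")
        )
        water_coords.append([0.0, 0.0, 6.0 + 3.0 * k])
    water_coords = np.asarray(water_coords, dtype=float).reshape(-1, 3)

    n_atoms = len(atoms_a) + len(atoms_b) + len(water_atoms)
    frames = np.empty((n_frames, n_atoms, 3))
    b_cog = coords_b0.mean(axis=0)
    for t in range(n_frames):
        rot = _rot_x(twist[t])
        moved_b = (coords_b0 - b_cog) @ rot.T + b_cog
        moved_b = moved_b + np.array([translation[t] * 10.0, 0.0, 0.0])  # nm → Å
        parts = [coords_a, moved_b]
        if spec.water_count:
            parts.append(water_coords)
        frames[t] = np.vstack(parts)

    traj = Trajectory(
        topology=tuple(atoms_a + atoms_b + water_atoms),
        coordinates=frames,
        times_ns=np.arange(n_frames) * spec.frame_dt_ns,
        system_label="toy-dimer",
        replica_index=1,
    )
    return traj, {"twist_deg": twist, "translation_nm": translation}


# ---------------------------------------------------------------------------
# Bernoulli contact pair
# ---------------------------------------------------------------------------

BONDED_DISTANCE = 3.0  # Å, NZ–OE1 when the contact is on
UNBONDED_DISTANCE = 6.0  # Å when off


def make_contact_trajectory(
    occupancy_p: float,
    n_frames: int,
    seed: int = 0,
    frame_dt_ns: float = 1.0,
) -> tuple[Trajectory, np.ndarray]:
    """LYS/GLU pair whose NZ–OE1 distance alternates between 3.0 Å
    (contact) and 6.0 Å (no contact) by seeded Bernoulli draws.

    Returns (trajectory, ground-truth boolean occupancy).
    """
    if not 0.0 <= occupancy_p <= 1.0:
        raise ConfigurationError("occupancy probability must be in [0, 1]")
    if n_frames <= 0:
        raise ConfigurationError("n_frames must be positive")
    rng = np.random.default_rng(seed)
    occupancy = rng.random(n_frames) < occupancy_p

    lys_atoms, lys_bb = build_extended(1, start_residue=10, residue_name="LYS",
                                       start_serial=1)
    lys_bb = _recentre(lys_bb, (-4.0, 0.0, 0.0))
    lys_atoms.append(make_atom(5, "NZ", "N", "LYS", 10, "A"))
    lys_nz = np.array([[0.0, 0.0, 0.0]])

    glu_atoms, glu_bb = build_extended(1, start_residue=20, residue_name="GLU",
                                       start_serial=6)
    glu_atoms.append(make_atom(10, "OE1", "O", "GLU", 20, "A"))
    glu_atoms.append(make_atom(11, "OE2", "O", "GLU", 20, "A"))
    glu_base = np.vstack([_recentre(glu_bb, (4.0, 0.0, 0.0)),
                          [[0.0, 0.0, 0.0]], [[1.0, 0.8, 0.0]]])

    topology = tuple(lys_atoms + glu_atoms)
    lys_coords = np.vstack([lys_bb, lys_nz])
    frames = np.empty((n_frames, len(topology), 3))
    for t in range(n_frames):
        shift = BONDED_DISTANCE if occupancy[t] else UNBONDED_DISTANCE
        frames[t] = np.vstack([lys_coords, glu_base + np.array([shift, 0.0, 0.0])])

    traj = Trajectory(
        topology=topology,
        coordinates=frames,
        times_ns=np.arange(n_frames) * frame_dt_ns,
        system_label="toy-contact",
        replica_index=1,
    )
    return traj, occupancy


# ---------------------------------------------------------------------------
# jitter replicas
# ---------------------------------------------------------------------------

def make_jitter_replicas(
    base_atoms: list[Atom] | None = None,
    base_coords: np.ndarray | None = None,
    sigma: float = 0.5,
    n_replicas: int = 5,
    n_frames: int = 200,
    seed: int = 0,
    frame_dt_ns: float = 1.0,
    system_label: str = "toy-jitter",
) -> list[Trajectory]:
    """Replicas of a rigid body with isotropic Gaussian jitter per
    coordinate (σ in Å); each replica gets an independent child seed.

    The per-atom RMSF of such a trajectory converges to σ·√3.
    """
    if sigma < 0:
        raise ConfigurationError("sigma must be >= 0")
    if base_atoms is None or base_coords is None:
        base_atoms, base_coords = build_helix(125, start_residue=1)
    seeds = np.random.SeedSequence(seed).spawn(n_replicas)
    replicas = []
    for k in range(n_replicas):
        rng = np.random.default_rng(seeds[k])
        noise = rng.normal(0.0, sigma, size=(n_frames, base_coords.shape[0], 3))
        replicas.append(
            Trajectory(
                topology=tuple(base_atoms),
                coordinates=base_coords[None] + noise,
                times_ns=np.arange(n_frames) * frame_dt_ns,
                system_label=system_label,
                replica_index=k + 1,
            )
        )
    return replicas
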