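"""Per-frame interaction detection and replica-aggregated frequencies.

Detectors for salt bridges (4.0 Å default cutoff between charged
side-chain nitrogens and acidic/phosphate oxygens), hydrophobic
side-chain contacts (2.5 Å, hydrogens included), hydrogen bonds, π–π
ring stacking and single-water bridges; plus frequency tables filtered
by cross-system differences and the replica-count heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    AggregationError,
    AtomSetError,
    ConfigurationError,
    EmptySeriesError,
)
from .structures_io import Frame, Trajectory

__all__ = [
    "ResidueRef",
    "ContactSpec",
    "ContactSeries",
    "detect_salt_bridge",
    "detect_hydrophobic",
    "detect_hbond",
    "detect_pi_pi",
    "detect_water_bridge",
    "detect_contact",
    "contact_frequency",
    "replica_heatmap",
    "interaction_table",
]

SALT_BRIDGE_CUTOFF = 4.0  # Å
HYDROPHOBIC_CUTOFF = 2.5  # Å
HBOND_HEAVY_CUTOFF = 3.5  # Å donor–acceptor heavy-atom distance
HBOND_ANGLE_MIN = 110.0  # degrees donor–H–acceptor
PI_PI_CENTROID_CUTOFF = 5.5  # Å
PI_PI_PLANE_ANGLE_MAX = 30.0  # degrees (parallel); 60–90 accepted as T-shaped

BASIC_SIDECHAIN_N = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
    "HID": ("ND1", "NE2"),
    "HIE": ("ND1", "NE2"),
    "HIP": ("ND1", "NE2"),
}
ACIDIC_SIDECHAIN_O = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    # phospho-serine / phospho-threonine: phosphate + bridging oxygen
    "SEP": ("O1P", "O2P", "O3P", "OP1", "OP2", "OP3", "OG"),
    "TPO": ("O1P", "O2P", "O3P", "OP1", "OP2", "OP3", "OG1"),
}
RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "TYR"}
)
CONTACT_KINDS = ("salt_bridge", "hydrophobic", "hbond", "pi_pi", "water_bridge")


@dataclass(frozen=True)
class ResidueRef:
    """Chain-qualified residue identity (author numbering)."""

    chain_id: str
    number: int
    name: str = ""

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.name}{self.number}"


@dataclass(frozen=True)
class ContactSpec:
    residue_a: ResidueRef
    residue_b: ResidueRef
    kind: str
    cutoff: float = 0.0

    def __post_init__(self) -> None:
        if (self.residue_a.chain_id, self.residue_a.number) == (
            self.residue_b.chain_id,
            self.residue_b.number,
        ):
            raise AtomSetError("contact residues must differ (chain-qualified)")
        if self.kind not in CONTACT_KINDS:
            raise AtomSetError(f"unknown contact kind {self.kind!r}")
        if self.kind in ("salt_bridge", "hydrophobic") and self.effective_cutoff <= 0:
            raise AtomSetError("cutoff must be positive")

    @property
    def effective_cutoff(self) -> float:
        if self.cutoff > 0:
            return self.cutoff
        return {"salt_bridge": SALT_BRIDGE_CUTOFF, "hydrophobic": HYDROPHOBIC_CUTOFF}.get(
            self.kind, 0.0
        )

    def label(self) -> str:
        return f"{self.residue_a}-{self.residue_b}:{self.kind}"


@dataclass
class ContactSeries:
    spec: ContactSpec
    occupancy: np.ndarray  # per-frame boolean
    system_label: str = ""
    replica_index: int = 1

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.size == 0:
            raise EmptySeriesError("contact series has no retained frames")

    @property
    def frequency_percent(self) -> float:
        return 100.0 * float(self.occupancy.mean())


# ---------------------------------------------------------------------------
# residue atom lookup
# ---------------------------------------------------------------------------

def _residue_atoms(frame: Frame, ref: ResidueRef) -> list[int]:
    idx = [
        i
        for i, atom in enumerate(frame.topology)
        if atom.chain_id == ref.chain_id and atom.residue_number == ref.number
        and not atom.is_water
    ]
    if not idx:
        raise AtomSetError(f"residue {ref} not found in topology")
    return idx


def _named_atoms(frame: Frame, ref: ResidueRef, names: Sequence[str]) -> np.ndarray:
    idx = [i for i in _residue_atoms(frame, ref) if frame.topology[i].name in names]
    if not idx:
        resname = frame.topology[_residue_atoms(frame, ref)[0]].residue_name
        raise AtomSetError(
            f"residue {ref} ({resname}) lacks required atoms {tuple(names)}"
        )
    return frame.coordinates[idx]


def _sidechain_atoms(frame: Frame, ref: ResidueRef, heavy_only: bool) -> np.ndarray:
    all_idx = _residue_atoms(frame, ref)
    idx = []
    for i in all_idx:
        atom = frame.topology[i]
        if atom.is_sidechain:
            idx.append(i)
        elif atom.is_hydrogen and not heavy_only:
            # keep side-chain hydrogens: anything not amide H / Hα
            if atom.name not in ("H", "HA", "H1", "H2", "H3", "HA2", "HA3", "HN"):
                idx.append(i)
    if not idx:
        resname = frame.topology[all_idx[0]].residue_name
        raise AtomSetError(f"residue {ref} ({resname}) has no side chain")
    return frame.coordinates[idx]


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    diff = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).min())


def _residue_name(frame: Frame, ref: ResidueRef) -> str:
    return frame.topology[_residue_atoms(frame, ref)[0]].residue_name


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------

def detect_salt_bridge(
    frame: Frame,
    res_basic: ResidueRef,
    res_acidic: ResidueRef,
    cutoff: float = SALT_BRIDGE_CUTOFF,
) -> bool:
    """True iff any basic side-chain N is within ``cutoff`` of any
    acidic/phosphate side-chain O.  Residue order is symmetric: the
    roles are resolved from the residue names."""
    name_a = _residue_name(frame, res_basic)
    name_b = _residue_name(frame, res_acidic)
    if name_a not in BASIC_SIDECHAIN_N and name_b in BASIC_SIDECHAIN_N:
        res_basic, res_acidic = res_acidic, res_basic
        name_a, name_b = name_b, name_a
    if name_a not in BASIC_SIDECHAIN_N:
        raise AtomSetError(f"{res_basic} ({name_a}) is not a basic residue")
    if name_b not in ACIDIC_SIDECHAIN_O:
        raise AtomSetError(f"{res_acidic} ({name_b}) is not acidic/phospho")
    nitrogens = _named_atoms(frame, res_basic, BASIC_SIDECHAIN_N[name_a])
    oxygens = _named_atoms(frame, res_acidic, ACIDIC_SIDECHAIN_O[name_b])
    return _min_dist(nitrogens, oxygens) <= cutoff


def detect_hydrophobic(
    frame: Frame,
    res_a: ResidueRef,
    res_b: ResidueRef,
    cutoff: float = HYDROPHOBIC_CUTOFF,
    heavy_only: bool = False,
) -> bool:
    """True iff the minimum side-chain atom distance is below ``cutoff``.

    Hydrogens participate by default (a 2.5 Å heavy-atom contact would
    be a near-clash); pass ``heavy_only=True`` to restrict."""
    a = _sidechain_atoms(frame, res_a, heavy_only)
    b = _sidechain_atoms(frame, res_b, heavy_only)
    return _min_dist(a, b) < cutoff


def _polar_atoms(frame: Frame, ref: ResidueRef) -> np.ndarray:
    idx = [
        i
        for i in _residue_atoms(frame, ref)
        if frame.topology[i].element in ("N", "O")
    ]
    if not idx:
        raise AtomSetError(f"residue {ref} has no polar (N/O) atoms")
    return frame.coordinates[idx]


def detect_hbond(
    frame: Frame,
    res_a: ResidueRef,
    res_b: ResidueRef,
    heavy_cutoff: float = HBOND_HEAVY_CUTOFF,
) -> bool:
    """Distance-criterion hydrogen bond between polar (N/O) atoms."""
    return _min_dist(_polar_atoms(frame, res_a), _polar_atoms(frame, res_b)) <= heavy_cutoff


def _ring(frame: Frame, ref: ResidueRef) -> np.ndarray:
    name = _residue_name(frame, ref)
    key = "HIS" if name in ("HID", "HIE", "HIP") else name
    if key not in RING_ATOMS:
        raise AtomSetError(f"residue {ref} ({name}) has no aromatic ring")
    return _named_atoms(frame, ref, RING_ATOMS[key])


def _plane_normal(points: np.ndarray) -> np.ndarray:
    centred = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centred)
    return vt[2]


def detect_pi_pi(frame: Frame, res_a: ResidueRef, res_b: ResidueRef) -> bool:
    """Ring-centroid distance ≤ 5.5 Å with parallel (≤30°) or T-shaped
    (60–90°) inter-plane angle."""
    ring_a = _ring(frame, res_a)
    ring_b = _ring(frame, res_b)
    centroid_dist = float(np.linalg.norm(ring_a.mean(axis=0) - ring_b.mean(axis=0)))
    if centroid_dist > PI_PI_CENTROID_CUTOFF:
        return False
    cosang = abs(float(np.dot(_plane_normal(ring_a), _plane_normal(ring_b))))
    angle = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
    return angle <= PI_PI_PLANE_ANGLE_MAX or 60.0 <= angle <= 90.0


def _water_oxygens(frame: Frame) -> np.ndarray:
    idx = [
        i
        for i, atom in enumerate(frame.topology)
        if atom.is_water and atom.element == "O"
    ]
    if not idx:
        raise ConfigurationError("topology contains no water molecules")
    return frame.coordinates[idx]


def detect_water_bridge(
    frame: Frame,
    res_a: ResidueRef,
    res_b: ResidueRef,
    heavy_cutoff: float = HBOND_HEAVY_CUTOFF,
) -> bool:
    """True iff one water O is simultaneously H-bonded (heavy-atom
    distance criterion) to polar atoms of both residues."""
    waters = _water_oxygens(frame)
    polar_a = _polar_atoms(frame, res_a)
    polar_b = _polar_atoms(frame, res_b)
    da = np.sqrt(((waters[:, None, :] - polar_a[None]) ** 2).sum(axis=2)).min(axis=1)
    db = np.sqrt(((waters[:, None, :] - polar_b[None]) ** 2).sum(axis=2)).min(axis=1)
    return bool(np.any((da <= heavy_cutoff) & (db <= heavy_cutoff)))


_DETECTORS = {
    "salt_bridge": lambda fr, spec: detect_salt_bridge(
        fr, spec.residue_a, spec.residue_b, spec.effective_cutoff
    ),
    "hydrophobic": lambda fr, spec: detect_hydrophobic(
        fr, spec.residue_a, spec.residue_b, spec.effective_cutoff
    ),
    "hbond": lambda fr, spec: detect_hbond(fr, spec.residue_a, spec.residue_b),
    "pi_pi": lambda fr, spec: detect_pi_pi(fr, spec.residue_a, spec.residue_b),
    "water_bridge": lambda fr, spec: detect_water_bridge(
        fr, spec.residue_a, spec.residue_b
    ),
}


def detect_contact(frame: Frame, spec: ContactSpec) -> bool:
    return _DETECTORS[spec.kind](frame, spec)


# ---------------------------------------------------------------------------
# frequencies and aggregation
# ---------------------------------------------------------------------------

def contact_frequency(
    traj: Trajectory, spec: ContactSpec, exclude_ns: float = 250.0
) -> ContactSeries:
    """Per-frame detection over retained frames (time_ns ≥ exclude_ns)."""
    mask = traj.times_ns >= exclude_ns
    if not mask.any():
        raise EmptySeriesError(f"no frames retained after excluding {exclude_ns} ns")
    retained = traj.with_frames(mask)
    occupancy = np.fromiter(
        (detect_contact(retained.frame(i), spec) for i in range(retained.n_frames)),
        dtype=bool,
        count=retained.n_frames,
    )
    return ContactSeries(
        spec=spec,
        occupancy=occupancy,
        system_label=traj.system_label,
        replica_index=traj.replica_index,
    )


def replica_heatmap(
    series: Sequence[ContactSeries], threshold_percent: float = 30.0
) -> int:
    """Number of replicas whose frequency is strictly above the threshold."""
    if not series:
        raise AggregationError("no replica series supplied")
    specs = {s.spec for s in series}
    if len(specs) != 1:
        raise AggregationError(f"mixed contact specs in aggregation: {specs}")
    return int(sum(s.frequency_percent > threshold_percent for s in series))


def interaction_table(
    frequencies: dict[str, dict[str, float]],
    min_reporting_delta: float = 20.0,
):
    """Cross-system frequency table, keeping specs whose max−min spread
    across systems exceeds ``min_reporting_delta`` percentage points.

    ``frequencies`` maps spec label → {system label → frequency %}.
    Pass ``min_reporting_delta=0`` to disable the filter.
    """
    import pandas as pd

    rows = []
    for label, by_system in frequencies.items():
        values = list(by_system.values())
        spread = max(values) - min(values)
        if min_reporting_delta <= 0 or spread > min_reporting_delta:
            rows.append({"contact": label, **by_system, "delta": spread})
    return pd.DataFrame(rows)
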