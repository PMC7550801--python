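"""Domain model for structures/trajectories plus readers and writers.

The internal length unit is Å (native to PDB); reporting layers convert
to nm where appropriate.  Residue numbering follows the source file's
author numbering throughout — no re-indexing is ever applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    EmptyInputError,
    EmptySelectionError,
    FormatError,
    SelectionError,
    TopologyError,
)

__all__ = [
    "Atom",
    "Frame",
    "Trajectory",
    "SegmentSelection",
    "ATOM_SUBSETS",
    "read_structure",
    "read_trajectory",
    "resolve_selection",
    "write_trajectory_pdb",
    "write_trajectory_dcd",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")
WATER_RESNAMES = frozenset({"HOH", "WAT", "SOL", "TIP3", "TIP4", "H2O", "SPC"})
ATOM_SUBSETS = ("all", "backbone", "ca", "sidechain", "heavy")


@dataclass(frozen=True)
class Atom:
    """One topology entry, carrying author numbering from the source file."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    is_backbone: bool = False
    is_sidechain: bool = False
    is_hydrogen: bool = False
    is_water: bool = False

    def __post_init__(self) -> None:
        if self.is_backbone and self.is_sidechain:
            raise TopologyError(
                f"atom {self.serial} {self.name}: backbone and sidechain flags "
                "are mutually exclusive"
            )


def _classify(name: str, element: str, residue_name: str) -> dict:
    """Derive the boolean atom flags from name/element/residue."""
    is_water = residue_name in WATER_RESNAMES
    is_hydrogen = element == "H" or (not element and name.lstrip("0123456789").startswith("H"))
    is_backbone = (not is_water) and (not is_hydrogen) and name in BACKBONE_NAMES
    is_sidechain = (not is_water) and (not is_hydrogen) and (not is_backbone)
    return dict(
        is_backbone=is_backbone,
        is_sidechain=is_sidechain,
        is_hydrogen=is_hydrogen,
        is_water=is_water,
    )


def make_atom(serial, name, element, residue_name, residue_number, chain_id) -> Atom:
    """Build an :class:`Atom` with flags derived from its identity."""
    return Atom(
        serial=int(serial),
        name=str(name),
        element=str(element),
        residue_name=str(residue_name),
        residue_number=int(residue_number),
        chain_id=str(chain_id),
        **_classify(str(name), str(element), str(residue_name)),
    )


@dataclass(frozen=True)
class Frame:
    """One time point: per-atom coordinates in Å plus the shared topology."""

    coordinates: np.ndarray  # (n_atoms, 3), Å
    time_ns: float
    frame_index: int
    topology: tuple[Atom, ...] = field(repr=False, default=())

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise TopologyError(f"coordinates must be (n, 3); got {coords.shape}")
        if self.topology and coords.shape[0] != len(self.topology):
            raise TopologyError(
                f"coordinate count {coords.shape[0]} != topology atom count "
                f"{len(self.topology)}"
            )
        if not np.all(np.isfinite(coords)):
            raise TopologyError("non-finite coordinates in frame")
        if self.frame_index < 0:
            raise TopologyError("frame_index must be >= 0")


@dataclass
class Trajectory:
    """Time-ordered coordinates over a fixed topology.

    ``coordinates`` has shape (n_frames, n_atoms, 3) in Å and
    ``times_ns`` is strictly increasing.
    """

    topology: tuple[Atom, ...]
    coordinates: np.ndarray
    times_ns: np.ndarray
    system_label: str = ""
    replica_index: int = 1

    def __post_init__(self) -> None:
        self.topology = tuple(self.topology)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise TopologyError(
                f"coordinates must be (n_frames, n_atoms, 3); got {self.coordinates.shape}"
            )
        if self.coordinates.shape[1] != len(self.topology):
            raise TopologyError(
                f"atom count {self.coordinates.shape[1]} != topology size {len(self.topology)}"
            )
        if self.times_ns.shape[0] != self.coordinates.shape[0]:
            raise TopologyError("times_ns length != number of frames")
        if self.n_frames > 1 and not np.all(np.diff(self.times_ns) > 0):
            raise TopologyError("time_ns must be strictly increasing across frames")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    def frame(self, i: int) -> Frame:
        return Frame(
            coordinates=self.coordinates[i],
            time_ns=float(self.times_ns[i]),
            frame_index=i,
            topology=self.topology,
        )

    def __iter__(self) -> Iterable[Frame]:
        return (self.frame(i) for i in range(self.n_frames))

    def with_frames(self, mask_or_indices) -> "Trajectory":
        """Sub-trajectory with a subset of frames (topology shared)."""
        return replace(
            self,
            coordinates=self.coordinates[mask_or_indices],
            times_ns=self.times_ns[mask_or_indices],
        )


@dataclass(frozen=True)
class SegmentSelection:
    """Chain + inclusive author-numbered residue interval + atom-subset rule."""

    chain_id: str
    start_residue: int
    end_residue: int
    atom_subset: str = "all"

    def __post_init__(self) -> None:
        if self.start_residue > self.end_residue:
            raise SelectionError(
                f"start_residue {self.start_residue} > end_residue {self.end_residue}"
            )
        if self.atom_subset not in ATOM_SUBSETS:
            raise SelectionError(
                f"atom_subset must be one of {ATOM_SUBSETS}; got {self.atom_subset!r}"
            )

    @classmethod
    def parse(cls, text: str, atom_subset: str = "all") -> "SegmentSelection":
        """Parse the CLI form ``A:250-264``."""
        try:
            chain, interval = text.split(":")
            lo, hi = interval.split("-")
            return cls(chain, int(lo), int(hi), atom_subset)
        except ValueError as exc:
            raise SelectionError(f"cannot parse selection {text!r}: {exc}") from exc

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.start_residue}-{self.end_residue}[{self.atom_subset}]"


def _subset_ok(atom: Atom, subset: str) -> bool:
    if subset == "all":
        return True
    if subset == "backbone":
        return atom.is_backbone
    if subset == "ca":
        return atom.name == "CA" and not atom.is_hydrogen
    if subset == "sidechain":
        return atom.is_sidechain
    if subset == "heavy":
        return not atom.is_hydrogen
    raise SelectionError(f"unknown atom_subset {subset!r}")


def resolve_selection(
    traj_or_topology, sel: SegmentSelection
) -> np.ndarray:
    """Resolve a selection to topology-ordered atom indices.

    Accepts a :class:`Trajectory`, :class:`Frame` or a bare topology
    sequence.  Raises :class:`EmptySelectionError` when no atom survives
    the interval + subset filter.
    """
    topology = getattr(traj_or_topology, "topology", traj_or_topology)
    indices = [
        i
        for i, atom in enumerate(topology)
        if atom.chain_id == sel.chain_id
        and sel.start_residue <= atom.residue_number <= sel.end_residue
        and not atom.is_water
        and _subset_ok(atom, sel.atom_subset)
    ]
    if not indices:
        raise EmptySelectionError(f"selection {sel} resolves to zero atoms")
    return np.asarray(indices, dtype=int)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _topology_from_atom_array(arr) -> tuple[Atom, ...]:
    """Convert a biotite AtomArray's annotations into our topology."""
    ins = arr.get_annotation("ins_code") if "ins_code" in arr.get_annotation_categories() else None
    if ins is not None and any(code.strip() for code in ins):
        bad = next(i for i, code in enumerate(ins) if code.strip())
        raise FormatError(
            f"insertion code {ins[bad]!r} at atom {int(arr.atom_id[bad])} "
            "not supported (author numbering would be ambiguous)"
        )
    return tuple(
        make_atom(
            serial=int(arr.atom_id[i]),
            name=str(arr.atom_name[i]),
            element=str(arr.element[i]),
            residue_name=str(arr.res_name[i]),
            residue_number=int(arr.res_id[i]),
            chain_id=str(arr.chain_id[i]),
        )
        for i in range(arr.array_length())
    )


def _read_pdb_models(path):
    import biotite.structure.io.pdb as bpdb

    try:
        pdb_file = bpdb.PDBFile.read(str(path))
    except OSError:
        raise
    except Exception as exc:  # parse failure inside biotite
        raise FormatError(f"{path}: not a parsable PDB file: {exc}") from exc
    try:
        n_models = pdb_file.get_model_count()
    except Exception as exc:
        raise FormatError(f"{path}: cannot determine model count: {exc}") from exc
    if n_models == 0:
        raise EmptyInputError(f"{path}: no models in file")
    try:
        # altloc resolution keeps the highest-occupancy location
        if n_models == 1:
            arrs = [pdb_file.get_structure(model=1, altloc="occupancy",
                                           extra_fields=["atom_id", "occupancy"])]
        else:
            stack = pdb_file.get_structure(altloc="occupancy",
                                           extra_fields=["atom_id", "occupancy"])
            arrs = [stack[i] for i in range(stack.stack_depth())]
    except Exception as exc:
        raise FormatError(f"{path}: failed to extract coordinates: {exc}") from exc
    if arrs[0].array_length() == 0:
        raise EmptyInputError(f"{path}: model contains no atoms")
    return arrs


def read_structure(path, format: str = "pdb") -> Trajectory:
    """Read a single-model structure file into a one-frame Trajectory.

    Multi-chain structures keep their chain identifiers; HETATM waters
    are flagged ``is_water``; alternate locations resolve to the highest
    occupancy.  For a multi-model file only the first model is used.
    """
    if format != "pdb":
        raise FormatError(f"read_structure supports 'pdb'; got {format!r}")
    if not Path(path).exists():
        raise FileNotFoundError(path)
    arr = _read_pdb_models(path)[0]
    topology = _topology_from_atom_array(arr)
    return Trajectory(
        topology=topology,
        coordinates=np.asarray(arr.coord, dtype=float)[None, :, :],
        times_ns=np.array([0.0]),
    )


def _times_from_map(frame_time_map, n_frames: int) -> np.ndarray:
    if frame_time_map is None:
        raise ConfigurationError(
            "frame_time_map is required: pass ns-per-frame or an explicit list of times"
        )
    if np.isscalar(frame_time_map):
        return np.arange(n_frames, dtype=float) * float(frame_time_map)
    times = np.asarray(frame_time_map, dtype=float)
    if times.shape[0] != n_frames:
        raise ConfigurationError(
            f"frame_time_map lists {times.shape[0]} times for {n_frames} frames"
        )
    return times


def read_trajectory(
    topology_path,
    traj_path=None,
    format: str | None = None,
    frame_time_map=None,
    system_label: str = "",
    replica_index: int = 1,
) -> Trajectory:
    """Read a trajectory (multi-model PDB, DCD or XTC) with explicit times.

    ``frame_time_map`` is mandatory metadata: either a scalar ns-per-frame
    or an explicit list of times in ns.  For multi-model PDB input,
    ``traj_path`` may be omitted.
    """
    topology_path = Path(topology_path)
    if format is None:
        probe = Path(traj_path) if traj_path is not None else topology_path
        format = probe.suffix.lstrip(".").lower() or "pdb"

    if format == "pdb":
        source = Path(traj_path) if traj_path is not None else topology_path
        arrs = _read_pdb_models(source)
        topology = _topology_from_atom_array(arrs[0])
        coords = np.stack([np.asarray(a.coord, dtype=float) for a in arrs])
    elif format in ("dcd", "xtc"):
        if traj_path is None:
            raise ConfigurationError(f"{format} input requires a separate topology file")
        import MDAnalysis as mda

        topo_traj = read_structure(topology_path, "pdb")
        topology = topo_traj.topology
        try:
            u = mda.Universe(str(topology_path), str(traj_path))
        except ValueError as exc:
            raise TopologyError(
                f"topology/trajectory atom-count mismatch: {exc}"
            ) from exc
        if u.atoms.n_atoms != len(topology):
            raise TopologyError(
                f"topology has {len(topology)} atoms but trajectory frames have "
                f"{u.atoms.n_atoms}"
            )
        coords = np.stack([u.atoms.positions.astype(float).copy() for _ in u.trajectory])
    else:
        raise FormatError(f"unsupported trajectory format {format!r}")

    times = _times_from_map(frame_time_map, coords.shape[0])
    return Trajectory(
        topology=topology,
        coordinates=coords,
        times_ns=times,
        system_label=system_label,
        replica_index=replica_index,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _to_atom_array_stack(traj: Trajectory):
    import biotite.structure as struc

    n = traj.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(traj.coordinates[0], dtype=np.float32)
    arr.chain_id = np.array([a.chain_id for a in traj.topology], dtype="U4")
    arr.res_id = np.array([a.residue_number for a in traj.topology], dtype=int)
    arr.res_name = np.array([a.residue_name for a in traj.topology], dtype="U5")
    arr.atom_name = np.array([a.name for a in traj.topology], dtype="U6")
    arr.element = np.array([a.element for a in traj.topology], dtype="U2")
    arr.hetero = np.array([a.is_water for a in traj.topology], dtype=bool)
    stack = struc.stack([arr] * traj.n_frames)
    stack.coord = np.asarray(traj.coordinates, dtype=np.float32)
    return stack


def write_trajectory_pdb(traj: Trajectory, path) -> None:
    """Write as a multi-model PDB (one MODEL per frame)."""
    import biotite.structure.io.pdb as bpdb

    pdb_file = bpdb.PDBFile()
    pdb_file.set_structure(_to_atom_array_stack(traj))
    pdb_file.write(str(path))


def write_trajectory_dcd(traj: Trajectory, topology_pdb_path, dcd_path) -> None:
    """Write a topology PDB (frame 0) plus a DCD of all frames."""
    import MDAnalysis as mda

    single = replace(traj, coordinates=traj.coordinates[:1], times_ns=traj.times_ns[:1])
    write_trajectory_pdb(single, topology_pdb_path)
    u = mda.Universe(str(topology_pdb_path))
    with mda.Writer(str(dcd_path), n_atoms=traj.n_atoms) as writer:
        for i in range(traj.n_frames):
            u.atoms.positions = traj.coordinates[i].astype(np.float32)
            writer.write(u.atoms)


def write_metric_csv(rows: Sequence[dict], path) -> None:
    """Write the standard long-format table: system,replica,frame,time_ns,value."""
    import pandas as pd

    frame = pd.DataFrame(rows, columns=["system", "replica", "frame", "time_ns", "value"])
    frame.to_csv(path, index=False)
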