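"""Core geometric statistics over trajectories.

Centre-of-geometry (cog) apex angles, interval-shift validation of the
angle definition, cog–cog distances, rigid-body superposition, RMSD and
replica-aggregated per-residue RMSF, equilibration exclusion and
1.5·IQR boxplot summaries.

Angles are reported in degrees, distances and RMSD/RMSF in nm
(coordinates are carried internally in Å).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateGeometryError,
    EmptySelectionError,
    EmptySeriesError,
    TopologyError,
    UnderdeterminedFitError,
)
from .structures_io import Frame, SegmentSelection, Trajectory, resolve_selection

__all__ = [
    "AngleDefinition",
    "MetricSeries",
    "BoxplotSummary",
    "centre_of_geometry",
    "segment_angle",
    "segment_angle_series",
    "interval_shift_validation",
    "shift_interval",
    "cog_distance",
    "cog_distance_series",
    "superpose",
    "kabsch",
    "rmsd_series",
    "rmsf_per_residue",
    "exclude_equilibration",
    "boxplot_summary",
]

ANGSTROM_PER_NM = 10.0

# Default intervals of the apex-angle metric (author numbering, chain A):
# activation-segment helix, hinge region (vertex) and αC helix.
DEFAULT_RAY_A = SegmentSelection("A", 250, 264)  # ASH
DEFAULT_VERTEX = SegmentSelection("A", 179, 182)  # hinge region
DEFAULT_RAY_B = SegmentSelection("A", 139, 154)  # αC helix


@dataclass(frozen=True)
class AngleDefinition:
    """Three selections defining a cog apex angle: ray_a — vertex — ray_b."""

    ray_a: SegmentSelection = DEFAULT_RAY_A
    vertex: SegmentSelection = DEFAULT_VERTEX
    ray_b: SegmentSelection = DEFAULT_RAY_B

    def __post_init__(self) -> None:
        sels = (self.ray_a, self.vertex, self.ray_b)
        if len(set(sels)) != 3:
            raise DegenerateGeometryError(
                "the three angle selections must be pairwise non-identical"
            )

    def for_chain(self, chain_id: str) -> "AngleDefinition":
        """Same intervals re-targeted at another chain (dimer subunits)."""
        return AngleDefinition(
            replace(self.ray_a, chain_id=chain_id),
            replace(self.vertex, chain_id=chain_id),
            replace(self.ray_b, chain_id=chain_id),
        )


@dataclass
class MetricSeries:
    """Per-frame scalar metric with system/replica provenance."""

    values: np.ndarray
    unit: str  # "degrees" or "nm"
    system_label: str = ""
    replica_index: int = 1
    times_ns: np.ndarray | None = None
    equilibration_excluded: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.times_ns is not None:
            self.times_ns = np.asarray(self.times_ns, dtype=float)
            if self.times_ns.shape != self.values.shape:
                raise TopologyError("times_ns and values length mismatch")
        if self.unit == "degrees" and self.values.size:
            if self.values.min() < -1e-9 or self.values.max() > 180 + 1e-9:
                raise DegenerateGeometryError("degree values outside [0, 180]")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class BoxplotSummary:
    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outliers: tuple
    mean: float
    sd: float

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "median", "q1", "q3", "iqr", "whisker_low", "whisker_high", "mean", "sd")}
        d["outliers"] = list(self.outliers)
        return d


# ---------------------------------------------------------------------------
# cog and angles
# ---------------------------------------------------------------------------

def centre_of_geometry(points) -> np.ndarray:
    """Unweighted arithmetic mean of a point set (no mass weighting)."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise EmptySelectionError("centre_of_geometry of an empty point set")
    if pts.ndim == 1:
        pts = pts[None, :]
    if not np.all(np.isfinite(pts)):
        raise DegenerateGeometryError("non-finite point passed to centre_of_geometry")
    return pts.mean(axis=0)


def _angle_from_cogs(cog_a, cog_v, cog_b) -> float:
    ray_a = cog_a - cog_v
    ray_b = cog_b - cog_v
    na = np.linalg.norm(ray_a)
    nb = np.linalg.norm(ray_b)
    if na < 1e-9 or nb < 1e-9:
        raise DegenerateGeometryError("coincident cogs give a zero-length ray")
    cosine = np.clip(np.dot(ray_a, ray_b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosine)))


def segment_angle(frame: Frame, defn: AngleDefinition = AngleDefinition()) -> float:
    """Apex angle (degrees) at the vertex cog between the two ray cogs."""
    coords = frame.coordinates
    topo = frame.topology
    cog_a = centre_of_geometry(coords[resolve_selection(topo, defn.ray_a)])
    cog_v = centre_of_geometry(coords[resolve_selection(topo, defn.vertex)])
    cog_b = centre_of_geometry(coords[resolve_selection(topo, defn.ray_b)])
    return _angle_from_cogs(cog_a, cog_v, cog_b)


def segment_angle_series(
    traj: Trajectory, defn: AngleDefinition = AngleDefinition()
) -> MetricSeries:
    """Per-frame apex angle over a trajectory."""
    idx_a = resolve_selection(traj, defn.ray_a)
    idx_v = resolve_selection(traj, defn.vertex)
    idx_b = resolve_selection(traj, defn.ray_b)
    cogs_a = traj.coordinates[:, idx_a].mean(axis=1)
    cogs_v = traj.coordinates[:, idx_v].mean(axis=1)
    cogs_b = traj.coordinates[:, idx_b].mean(axis=1)
    values = [_angle_from_cogs(a, v, b) for a, v, b in zip(cogs_a, cogs_v, cogs_b)]
    return MetricSeries(
        values=np.array(values),
        unit="degrees",
        system_label=traj.system_label,
        replica_index=traj.replica_index,
        times_ns=traj.times_ns.copy(),
    )


def shift_interval(sel: SegmentSelection, shift: int) -> SegmentSelection:
    """Shifted variant of an interval for the angle-robustness check.

    ``shift < 0`` truncates the C-terminal end (start, end+shift);
    ``shift > 0`` truncates the N-terminal end (start+shift, end);
    ``shift == 0`` is the identity.  With the default ASH interval
    250–264, shift −5 gives 250–259 and +5 gives 255–264.
    """
    if shift == 0:
        return sel
    if shift < 0:
        return replace(sel, end_residue=sel.end_residue + shift)
    return replace(sel, start_residue=sel.start_residue + shift)


def interval_shift_validation(
    traj_or_frame, defn: AngleDefinition, shift: int
) -> np.ndarray:
    """Per-frame deviation angle(shifted ray_a) − angle(reference).

    On the autoinhibited geometry the C-terminal truncation (negative
    shift) gives negative deviations and the N-terminal truncation
    positive ones.
    """
    shifted = AngleDefinition(
        shift_interval(defn.ray_a, shift), defn.vertex, defn.ray_b
    )
    if isinstance(traj_or_frame, Frame):
        return np.array([segment_angle(traj_or_frame, shifted)
                         - segment_angle(traj_or_frame, defn)])
    ref = segment_angle_series(traj_or_frame, defn).values
    alt = segment_angle_series(traj_or_frame, shifted).values
    return alt - ref


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def cog_distance(frame: Frame, sel_a: SegmentSelection, sel_b: SegmentSelection) -> float:
    """Euclidean cog–cog distance in nm."""
    coords = frame.coordinates
    cog_a = centre_of_geometry(coords[resolve_selection(frame.topology, sel_a)])
    cog_b = centre_of_geometry(coords[resolve_selection(frame.topology, sel_b)])
    return float(np.linalg.norm(cog_a - cog_b)) / ANGSTROM_PER_NM


def cog_distance_series(
    traj: Trajectory, sel_a: SegmentSelection, sel_b: SegmentSelection
) -> MetricSeries:
    idx_a = resolve_selection(traj, sel_a)
    idx_b = resolve_selection(traj, sel_b)
    cogs_a = traj.coordinates[:, idx_a].mean(axis=1)
    cogs_b = traj.coordinates[:, idx_b].mean(axis=1)
    values = np.linalg.norm(cogs_a - cogs_b, axis=1) / ANGSTROM_PER_NM
    return MetricSeries(
        values=values,
        unit="nm",
        system_label=traj.system_label,
        replica_index=traj.replica_index,
        times_ns=traj.times_ns.copy(),
    )


# ---------------------------------------------------------------------------
# superposition, RMSD, RMSF
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rotation/translation of ``mobile`` onto ``reference``.

    Returns (rotation 3×3, translation 3,) such that
    ``mobile @ R.T + t`` least-squares matches ``reference``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise TopologyError("fit selections differ in atom count")
    if mobile.shape[0] < 3:
        raise UnderdeterminedFitError("need at least 3 fit atoms")
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    # collinearity check: rank of the centred cloud
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise UnderdeterminedFitError("fit atoms are collinear")
    h = mob_c.T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = reference.mean(axis=0) - rotation @ mobile.mean(axis=0)
    return rotation, translation


def superpose(mobile: Frame, reference: Frame, fit_selection: SegmentSelection):
    """Rigid-body fit of ``mobile`` onto ``reference`` over ``fit_selection``.

    The transform is determined on the fit selection and applied to all
    atoms.  Returns (fitted Frame, rotation, translation).
    """
    idx_m = resolve_selection(mobile.topology, fit_selection)
    idx_r = resolve_selection(reference.topology, fit_selection)
    if idx_m.shape[0] != idx_r.shape[0]:
        raise TopologyError("fit selection resolves differently in mobile and reference")
    rotation, translation = kabsch(
        mobile.coordinates[idx_m], reference.coordinates[idx_r]
    )
    fitted = mobile.coordinates @ rotation.T + translation
    return (
        Frame(fitted, mobile.time_ns, mobile.frame_index, mobile.topology),
        rotation,
        translation,
    )


def _fit_coords(coords: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Kabsch-fit every frame of (F, N, 3) onto ref (N, 3)."""
    out = np.empty_like(coords)
    for i in range(coords.shape[0]):
        rotation, translation = kabsch(coords[i], ref)
        out[i] = coords[i] @ rotation.T + translation
    return out


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def rmsd_series(
    traj: Trajectory,
    reference: Frame,
    selection: SegmentSelection,
    fit: bool = True,
) -> MetricSeries:
    """Per-frame RMSD (nm) of ``selection`` against a reference frame.

    With ``fit=True`` each frame is first superposed on the reference
    over the same selection.
    """
    idx = resolve_selection(traj, selection)
    idx_ref = resolve_selection(reference.topology, selection)
    if idx.shape[0] != idx_ref.shape[0]:
        raise TopologyError("selection resolves differently in trajectory and reference")
    ref = reference.coordinates[idx_ref]
    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        mob = traj.coordinates[i, idx]
        if fit:
            rotation, translation = kabsch(mob, ref)
            mob = mob @ rotation.T + translation
        values[i] = _rmsd(mob, ref) / ANGSTROM_PER_NM
    return MetricSeries(
        values=values,
        unit="nm",
        system_label=traj.system_label,
        replica_index=traj.replica_index,
        times_ns=traj.times_ns.copy(),
    )


def _replica_rmsf(traj: Trajectory, idx: np.ndarray) -> np.ndarray:
    """Per-atom RMSF (Å) for one replica over the selected atoms.

    Frames are fitted to frame 0, a mean structure is computed, frames
    are re-fitted to that mean (one iteration) and the fluctuation is
    taken about the final mean.
    """
    sel_coords = traj.coordinates[:, idx]
    fitted = _fit_coords(sel_coords, sel_coords[0])
    mean = fitted.mean(axis=0)
    fitted = _fit_coords(sel_coords, mean)
    mean = fitted.mean(axis=0)
    return np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))


def rmsf_per_residue(
    replicas: Sequence[Trajectory],
    selection: SegmentSelection,
):
    """Replica-aggregated per-residue backbone RMSF.

    For each replica the per-atom RMSF is computed after superposition
    on the replica mean structure, then averaged over each residue's
    selected atoms.  Across replicas the arithmetic mean and standard
    deviation are returned, in nm.

    Returns a pandas DataFrame with columns
    ``chain_id, residue_number, rmsf_mean_nm, rmsf_sd_nm`` plus one
    ``rmsf_rep{k}_nm`` column per replica.
    """
    import pandas as pd

    if not replicas:
        raise EmptySeriesError("need at least one replica")
    topo0 = replicas[0].topology
    for rep in replicas[1:]:
        if rep.topology != topo0:
            raise TopologyError("replicas do not share a topology")
    idx = resolve_selection(replicas[0], selection)

    residue_keys = []
    residue_of_atom = []
    for i in idx:
        atom = topo0[i]
        key = (atom.chain_id, atom.residue_number)
        if key not in residue_keys:
            residue_keys.append(key)
        residue_of_atom.append(residue_keys.index(key))
    residue_of_atom = np.asarray(residue_of_atom)

    per_replica = []
    for rep in replicas:
        atom_rmsf = _replica_rmsf(rep, idx) / ANGSTROM_PER_NM
        res_rmsf = np.array([
            atom_rmsf[residue_of_atom == r].mean() for r in range(len(residue_keys))
        ])
        per_replica.append(res_rmsf)
    stacked = np.vstack(per_replica)  # (R, n_residues)

    table = pd.DataFrame({
        "chain_id": [c for c, _ in residue_keys],
        "residue_number": [n for _, n in residue_keys],
        "rmsf_mean_nm": stacked.mean(axis=0),
        "rmsf_sd_nm": stacked.std(axis=0, ddof=0),
    })
    for k, row in enumerate(stacked, start=1):
        table[f"rmsf_rep{k}_nm"] = row
    return table


# ---------------------------------------------------------------------------
# equilibration exclusion and summaries
# ---------------------------------------------------------------------------

def exclude_equilibration(obj, cutoff_ns: float = 250.0):
    """Drop frames with time_ns < cutoff (the frame at the cutoff is kept).

    Accepts a :class:`Trajectory` or a :class:`MetricSeries` carrying a
    time map.  Raises :class:`EmptySeriesError` if nothing survives.
    """
    if isinstance(obj, Trajectory):
        mask = obj.times_ns >= cutoff_ns
        if not mask.any():
            raise EmptySeriesError(f"all frames fall before {cutoff_ns} ns")
        return obj.with_frames(mask)
    if isinstance(obj, MetricSeries):
        if obj.times_ns is None:
            raise TopologyError("MetricSeries has no time map; cannot exclude")
        mask = obj.times_ns >= cutoff_ns
        if not mask.any():
            raise EmptySeriesError(f"all values fall before {cutoff_ns} ns")
        return MetricSeries(
            values=obj.values[mask],
            unit=obj.unit,
            system_label=obj.system_label,
            replica_index=obj.replica_index,
            times_ns=obj.times_ns[mask],
            equilibration_excluded=True,
        )
    raise TypeError(f"cannot exclude equilibration from {type(obj).__name__}")


def boxplot_summary(values) -> BoxplotSummary:
    """Tukey summary: quartiles, 1.5·IQR whiskers, outliers, mean and sd.

    Quartiles use linear interpolation between order statistics;
    whiskers sit on the most extreme data points inside
    [q1 − 1.5·IQR, q3 + 1.5·IQR]; outliers lie strictly outside the
    whiskers.
    """
    if isinstance(values, MetricSeries):
        values = values.values
    data = np.asarray(values, dtype=float).ravel()
    if data.size == 0:
        raise EmptySeriesError("boxplot_summary of an empty series")
    q1, median, q3 = np.percentile(data, [25, 50, 75], method="linear")
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = data[(data >= lo_fence) & (data <= hi_fence)]
    whisker_low = float(inside.min())
    whisker_high = float(inside.max())
    outliers = tuple(sorted(data[(data < whisker_low) | (data > whisker_high)]))
    return BoxplotSummary(
        median=float(median),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        whisker_low=whisker_low,
        whisker_high=whisker_high,
        outliers=outliers,
        mean=float(data.mean()),
        sd=float(data.std(ddof=0)),
    )


def pool_replicas(series_list: Sequence[MetricSeries]) -> np.ndarray:
    """Concatenate replica series of one system for pooled summaries."""
    if not series_list:
        raise EmptySeriesError("no series to pool")
    units = {s.unit for s in series_list}
    if len(units) != 1:
        raise TopologyError(f"cannot pool mixed units {units}")
    return np.concatenate([s.values for s in series_list])
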