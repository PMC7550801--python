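"""DSSP-style secondary-structure assignment and %SSE summaries.

Backbone hydrogen bonds are scored with the electrostatic energy
E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) kcal/mol and
accepted below -0.5 kcal/mol.  Two consecutive i→i+4 turns yield helix
(3-10 turns are pooled into the helix label), bridge/ladder patterns
yield strand, everything else is labelled other.

Amide hydrogens are reconstructed at 1.01 Å along the bisector of the
C(prev)→N and CA→N directions when absent from the topology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptySelectionError, EmptySeriesError
from .structures_io import Frame, SegmentSelection, Trajectory

__all__ = ["assign_ss", "percent_sse", "SSEAssignment", "LABELS"]

LABELS = ("helix", "strand", "other")
Q_COUPLING = 0.084 * 332.0  # kcal/mol·Å, dipole-pair coupling constant
HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
NH_BOND_LENGTH = 1.01  # Å


@dataclass
class SSEAssignment:
    """Per-frame, per-residue labels plus interval %SSE summaries."""

    residue_keys: list  # (chain_id, residue_number)
    labels: np.ndarray  # (n_frames, n_residues) of {helix,strand,other}
    interval_summaries: dict


def _collect_backbone(frame: Frame):
    """Group backbone atoms (and any amide H) per protein residue, in order."""
    residues: dict[tuple, dict] = {}
    for i, atom in enumerate(frame.topology):
        if atom.is_water:
            continue
        key = (atom.chain_id, atom.residue_number)
        entry = residues.setdefault(key, {"resname": atom.residue_name})
        if atom.name in ("N", "CA", "C", "O"):
            entry[atom.name] = frame.coordinates[i]
        elif atom.name in ("H", "HN"):
            entry["H"] = frame.coordinates[i]
    return residues


def _reconstruct_h(n, ca, c_prev):
    """Amide H along the bisector of (N−C_prev) and (N−CA)."""
    u = n - c_prev
    v = n - ca
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    bisector = u + v
    norm = np.linalg.norm(bisector)
    if norm < 1e-8:
        return None
    return n + NH_BOND_LENGTH * bisector / norm


def _hbond_energy(n, h, c, o) -> float:
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # clashing geometry, no bond
        return 0.0
    return Q_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _hbond_matrix(residues: dict):
    """Boolean matrix hb[d, a]: backbone N–H of residue d donates to C=O of a."""
    keys = list(residues.keys())
    n_res = len(keys)
    complete = [all(x in residues[k] for x in ("N", "CA", "C", "O")) for k in keys]

    # reconstruct missing amide hydrogens from the previous residue's C
    hydrogens = []
    for i, key in enumerate(keys):
        entry = residues[key]
        if not complete[i]:
            hydrogens.append(None)
            continue
        if "H" in entry:
            hydrogens.append(entry["H"])
            continue
        prev = residues[keys[i - 1]] if i > 0 else None
        same_chain = i > 0 and keys[i - 1][0] == key[0]
        if (
            same_chain
            and prev is not None
            and "C" in prev
            and entry["resname"] != "PRO"
        ):
            hydrogens.append(_reconstruct_h(entry["N"], entry["CA"], prev["C"]))
        else:
            hydrogens.append(None)  # chain start or proline: cannot donate

    hb = np.zeros((n_res, n_res), dtype=bool)
    for d in range(n_res):
        if hydrogens[d] is None or not complete[d]:
            continue
        entry_d = residues[keys[d]]
        for a in range(n_res):
            if a == d or abs(a - d) < 2 or not complete[a]:
                continue
            entry_a = residues[keys[a]]
            energy = _hbond_energy(
                entry_d["N"], hydrogens[d], entry_a["C"], entry_a["O"]
            )
            hb[d, a] = energy < HBOND_ENERGY_CUTOFF
    return keys, complete, hb


def _labels_from_hbonds(keys, complete, hb) -> np.ndarray:
    n_res = len(keys)
    labels = np.array(["other"] * n_res, dtype="U6")

    def same_chain(i, j):
        return keys[i][0] == keys[j][0]

    def turn(i, n):
        return (
            i + n < n_res
            and same_chain(i, i + n)
            and hb[i + n, i]
        )

    # helices: two consecutive n-turns (alpha n=4 first, then 3-10 n=3)
    helix = np.zeros(n_res, dtype=bool)
    for n in (4, 3):
        for i in range(1, n_res - n):
            if turn(i - 1, n) and turn(i, n):
                helix[i : i + n] = True
    labels[helix] = "helix"

    # bridges (parallel / antiparallel), ladders of length >= 1
    strand = np.zeros(n_res, dtype=bool)
    for i in range(1, n_res - 1):
        for j in range(i + 3, n_res - 1):
            parallel = (hb[j, i - 1] and hb[i + 1, j]) or (hb[i, j - 1] and hb[j + 1, i])
            anti = (hb[i, j] and hb[j, i]) or (hb[j - 1, i + 1] and hb[i - 1, j + 1])
            if parallel or anti:
                strand[i] = strand[j] = True
    # strand wins over nothing, helix keeps precedence
    labels[strand & ~helix] = "strand"
    for i in range(n_res):
        if not complete[i]:
            labels[i] = "other"
    return labels


def assign_ss(frame: Frame) -> tuple[list, np.ndarray]:
    """Per-residue labels for one frame.

    Returns (residue keys, labels) where keys are (chain_id,
    residue_number) in topology order.  Residues with incomplete
    backbone are labelled ``other``.
    """
    residues = _collect_backbone(frame)
    if not residues:
        raise EmptySelectionError("no protein residues in frame")
    keys, complete, hb = _hbond_matrix(residues)
    return keys, _labels_from_hbonds(keys, complete, hb)


def assign_ss_trajectory(traj: Trajectory) -> SSEAssignment:
    keys = None
    per_frame = []
    for i in range(traj.n_frames):
        frame_keys, labels = assign_ss(traj.frame(i))
        if keys is None:
            keys = frame_keys
        per_frame.append(labels)
    return SSEAssignment(
        residue_keys=keys,
        labels=np.vstack(per_frame),
        interval_summaries={},
    )


def percent_sse(
    traj: Trajectory,
    interval: SegmentSelection,
    label: str = "helix",
    exclude_ns: float = 0.0,
):
    """Share (%) of interval residues carrying ``label``, per frame.

    Returns (per-frame percentage array, scalar mean over retained
    frames).
    """
    if label not in LABELS:
        raise EmptySeriesError(f"unknown label {label!r}")
    mask = traj.times_ns >= exclude_ns
    if not mask.any():
        raise EmptySeriesError(f"no frames retained after excluding {exclude_ns} ns")
    retained = traj.with_frames(mask)
    assignment = assign_ss_trajectory(retained)
    in_interval = [
        i
        for i, (chain, number) in enumerate(assignment.residue_keys)
        if chain == interval.chain_id
        and interval.start_residue <= number <= interval.end_residue
    ]
    if not in_interval:
        raise EmptySelectionError(f"interval {interval} matches no residues")
    share = 100.0 * (assignment.labels[:, in_interval] == label).mean(axis=1)
    return share, float(share.mean())
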