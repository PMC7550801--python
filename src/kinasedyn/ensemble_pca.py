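"""Cross-system principal component analysis on a shared atom selection.

A single PCA is fitted over the pooled frames of every system so that
per-system score plots are directly comparable.  Coordinates are fitted
to the pooled mean structure (one re-fit iteration), the covariance of
the flattened 3N coordinates uses 1/N normalisation, and no mass
weighting is applied — so the score variance along mode k equals
eigenvalue k exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import IncompatibleEnsemblesError, TopologyError
from .geometry_metrics import _fit_coords, kabsch
from .structures_io import SegmentSelection, Trajectory, resolve_selection

__all__ = ["PCAModel", "fit_pca", "project_scores", "retain_pcs", "mode_endpoints"]


@dataclass
class PCAModel:
    """Result of a pooled-ensemble PCA.

    ``eigenvectors`` has the modes in columns (shape 3N × 3N) and
    ``eigenvalues`` (Å²) is non-increasing.
    """

    selections: tuple[SegmentSelection, ...]
    mean_coordinates: np.ndarray  # (N, 3) Å, pooled mean after fitting
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray

    @property
    def n_atoms(self) -> int:
        return self.mean_coordinates.shape[0]

    def validate(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise TopologyError("eigenvalues are not non-increasing")
        if np.any(self.eigenvalues < -1e-9):
            raise TopologyError("negative eigenvalue beyond tolerance")
        if abs(self.variance_fractions.sum() - 1.0) > 1e-9:
            raise TopologyError("variance fractions do not sum to 1")

    # -- persistence (documented JSON; coordinates inline as lists) --------
    def save(self, path) -> None:
        payload = {
            "selections": [
                [s.chain_id, s.start_residue, s.end_residue, s.atom_subset]
                for s in self.selections
            ],
            "mean_coordinates": self.mean_coordinates.tolist(),
            "eigenvectors": self.eigenvectors.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_fractions": self.variance_fractions.tolist(),
        }
        with open(path, "w") as handle:
            json.dump(payload, handle)

    @classmethod
    def load(cls, path) -> "PCAModel":
        with open(path) as handle:
            payload = json.load(handle)
        return cls(
            selections=tuple(SegmentSelection(*s) for s in payload["selections"]),
            mean_coordinates=np.asarray(payload["mean_coordinates"]),
            eigenvectors=np.asarray(payload["eigenvectors"]),
            eigenvalues=np.asarray(payload["eigenvalues"]),
            variance_fractions=np.asarray(payload["variance_fractions"]),
        )


def _gather(traj: Trajectory, selections: Sequence[SegmentSelection]) -> np.ndarray:
    idx = np.concatenate([resolve_selection(traj, s) for s in selections])
    return traj.coordinates[:, idx]


def fit_pca(
    trajs: Sequence[Trajectory],
    selections: SegmentSelection | Sequence[SegmentSelection],
    fit: bool = True,
) -> PCAModel:
    """Fit one PCA over the pooled frames of all trajectories.

    ``selections`` must resolve to the same atom count in every system
    (residues that differ among systems have to be excluded up front).
    ``fit=False`` skips the rigid-body superposition, for inputs that
    are already aligned.
    """
    if isinstance(selections, SegmentSelection):
        selections = (selections,)
    selections = tuple(selections)
    gathered = [_gather(t, selections) for t in trajs]
    counts = {g.shape[1] for g in gathered}
    if len(counts) != 1:
        raise IncompatibleEnsemblesError(
            f"selection resolves to differing atom counts across systems: {sorted(counts)}"
        )
    pooled = np.concatenate(gathered, axis=0)  # (F_total, N, 3)

    if fit:
        fitted = _fit_coords(pooled, pooled[0])
        mean = fitted.mean(axis=0)
        fitted = _fit_coords(pooled, mean)
    else:
        fitted = pooled
    mean = fitted.mean(axis=0)

    flat = fitted.reshape(fitted.shape[0], -1) - mean.ravel()
    cov = flat.T @ flat / flat.shape[0]  # population (1/N) covariance
    eigenvalues, eigenvectors = np.linalg.eigh(cov)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = np.clip(eigenvalues[order], 0.0, None)
    eigenvectors = eigenvectors[:, order]
    total = eigenvalues.sum()
    fractions = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)

    model = PCAModel(
        selections=selections,
        mean_coordinates=mean,
        eigenvectors=eigenvectors,
        eigenvalues=eigenvalues,
        variance_fractions=fractions,
    )
    model.validate()
    return model


def project_scores(
    model: PCAModel,
    traj: Trajectory,
    n_components: int | None = None,
    fit: bool = True,
):
    """Per-frame PC scores of a trajectory against a fitted model.

    Frames are superposed on the model mean over the model selection,
    mean-centred and dotted with the eigenvectors.  Returns an array of
    shape (n_frames, n_components).
    """
    coords = _gather(traj, model.selections)
    if coords.shape[1] != model.n_atoms:
        raise IncompatibleEnsemblesError(
            f"selection resolves to {coords.shape[1]} atoms; model has {model.n_atoms}"
        )
    fitted = _fit_coords(coords, model.mean_coordinates) if fit else coords
    flat = fitted.reshape(fitted.shape[0], -1) - model.mean_coordinates.ravel()
    k = model.eigenvectors.shape[1] if n_components is None else n_components
    return flat @ model.eigenvectors[:, :k]


def project_frame(model: PCAModel, coordinates: np.ndarray) -> np.ndarray:
    """Scores for a bare (N, 3) coordinate set on the model selection."""
    rotation, translation = kabsch(coordinates, model.mean_coordinates)
    fitted = coordinates @ rotation.T + translation
    return (fitted.ravel() - model.mean_coordinates.ravel()) @ model.eigenvectors


def retain_pcs(model: PCAModel, threshold_fraction: float = 0.09) -> list[int]:
    """Indices (0-based) of PCs with variance fraction strictly above threshold."""
    return [
        i for i, f in enumerate(model.variance_fractions) if f > threshold_fraction
    ]


def mode_endpoints(model: PCAModel, pc: int, amplitude_sd: float = 3.0):
    """Coordinate sets at ±amplitude·sd along one PC, for visualisation.

    Returns (minus, plus), each (N, 3) in Å.
    """
    sd = float(np.sqrt(model.eigenvalues[pc]))
    displacement = (amplitude_sd * sd) * model.eigenvectors[:, pc].reshape(-1, 3)
    return model.mean_coordinates - displacement, model.mean_coordinates + displacement
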