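"""kinasedyn: geometric, contact and secondary-structure analysis of
kinase MD trajectories, plus synthetic ground-truth generators."""

__version__ = "0.1.0"

from . import (  # noqa: F401
    contact_analysis,
    ensemble_pca,
    errors,
    geometry_metrics,
    secondary_structure,
    structures_io,
    synthetic_data,
)
from .structures_io import (  # noqa: F401
    Atom,
    Frame,
    SegmentSelection,
    Trajectory,
    read_structure,
    read_trajectory,
    resolve_selection,
)
from .geometry_metrics import (  # noqa: F401
    AngleDefinition,
    MetricSeries,
    boxplot_summary,
    centre_of_geometry,
    cog_distance,
    exclude_equilibration,
    rmsd_series,
    rmsf_per_residue,
    segment_angle,
    segment_angle_series,
)


def reference_structure_path(accession: str = "3alo", download: bool = True):
    """Path to the bundled reference crystal structure, if available.

    Looks for ``data/<accession>.pdb`` inside the package, then the
    ``KINASEDYN_PDB_DIR`` environment variable, and finally (when
    ``download`` is true and the network is reachable) fetches the entry
    from RCSB into the package data directory.  Returns ``None`` when
    the structure cannot be located.
    """
    import os
    from pathlib import Path

    package_data = Path(__file__).parent / "data" / f"{accession.lower()}.pdb"
    if package_data.exists():
        return package_data
    env_dir = os.environ.get("KINASEDYN_PDB_DIR")
    if env_dir:
        candidate = Path(env_dir) / f"{accession.lower()}.pdb"
        if candidate.exists():
            return candidate
    if download:
        import urllib.request

        url = f"https://files.rcsb.org/download/{accession.upper()}.pdb"
        try:
            package_data.parent.mkdir(parents=True, exist_ok=True)
            with urllib.request.urlopen(url, timeout=30) as response:
                payload = response.read()
            if payload.startswith(b"HEADER") or b"\nATOM" in payload:
                package_data.write_bytes(payload)
                return package_data
        except Exception:
            return None
    return None
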