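"""Trajectory bundles, per-ligand splitting and contact-map featurization.

A *bundle* is a set of simulation runs sharing one receptor, each run a
sequence of coordinate frames for receptor reference atoms, one or more
ligand copies, and optionally ions.  Runs with several ligand copies are
split into independent per-ligand streams — each ligand's encounter with
the receptor is treated as its own trajectory — before featurization.

Features are binary contact maps: one column per receptor reference atom
(typically alpha-carbons), set to 1 in a frame iff that atom lies strictly
within ``cutoff`` (default 8 Å) of any ligand atom.  A parallel boolean
ion-coordination flag marks frames where a ligand phosphate atom sits
strictly within 4 Å of any declared ion; it is used downstream to split
geometric clusters by coordination state.

Two on-disk forms are supported:

* the portable bundle (canonical for tests): plain CSV coordinate or
  feature matrices, one frame per row, plus a JSON sidecar with frame
  spacing and atom roles;
* standard MD formats (PDB topology + XTC/DCD coordinates) through
  mdtraj, converted to Å/ns on read.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTrajectory",
    "CoordinationFlags",
    "LigandStream",
    "TrajectoryBundle",
    "read_bundle",
    "write_bundle",
    "split_ligand_copies",
    "contact_map_features",
    "coordination_flags",
    "write_feature_trajectory",
    "read_feature_trajectory",
]


@dataclass
class FeatureTrajectory:
    """Per-ligand time series of feature vectors.

    frames : (T, F) float array, no missing values
    frame_dt : frame spacing in ns
    feature_names : length-F labels
    source : (run id, ligand id)
    """

    frames: np.ndarray
    frame_dt: float
    feature_names: list[str] = field(default_factory=list)
    source: tuple = ("run0", 0)

    def __post_init__(self) -> None:
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=float))
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be positive")
        if self.frames.shape[0] < 2:
            raise ValueError("a feature trajectory needs at least 2 frames")
        if self.frames.shape[1] < 1:
            raise ValueError("a feature trajectory needs at least 1 feature")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("feature matrix contains non-finite values")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.frames.shape[1])]
        if len(self.feature_names) != self.frames.shape[1]:
            raise ValueError("feature_names length must match column count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_features(self) -> int:
        return self.frames.shape[1]


@dataclass
class CoordinationFlags:
    """Boolean ion-coordination sequence aligned to one feature trajectory."""

    flags: np.ndarray
    source: tuple = ("run0", 0)

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool).ravel()

    def __len__(self) -> int:
        return self.flags.shape[0]


@dataclass
class LigandStream:
    """Coordinates of one ligand copy against the shared receptor.

    All coordinate arrays are in Å: ligand_xyz (T, a, 3), receptor_xyz
    (T, p, 3), optional ion_xyz (T, q, 3) and phosphate_xyz (T, b, 3).
    """

    run_id: str
    ligand_id: int
    ligand_xyz: np.ndarray
    receptor_xyz: np.ndarray
    frame_dt: float
    ion_xyz: np.ndarray | None = None
    phosphate_xyz: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.ligand_xyz.shape[0]


@dataclass
class TrajectoryBundle:
    """A batch of runs with declared atom roles and frame spacing.

    runs : list of (run_id, xyz) with xyz of shape (T, n_atoms, 3) in Å
    receptor_atoms : indices of receptor reference atoms (e.g. CA)
    ligand_groups : disjoint per-ligand atom index lists
    ion_atoms : indices of free ions (may be empty)
    phosphate_atoms : per-ligand indices of the phosphate group (optional)
    """

    runs: list[tuple[str, np.ndarray]]
    frame_dt: float
    receptor_atoms: np.ndarray
    ligand_groups: list[np.ndarray]
    ion_atoms: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    phosphate_atoms: list[np.ndarray] | None = None
    topology: object | None = None

    def __post_init__(self) -> None:
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be positive")
        self.receptor_atoms = np.asarray(self.receptor_atoms, dtype=int)
        self.ligand_groups = [np.asarray(g, dtype=int) for g in self.ligand_groups]
        self.ion_atoms = np.asarray(self.ion_atoms, dtype=int)
        seen: set[int] = set()
        for g in self.ligand_groups:
            if seen & set(g.tolist()):
                raise ValueError("ligand_groups must be disjoint")
            seen |= set(g.tolist())
        if not self.runs:
            warnings.warn("bundle contains no runs", stacklevel=2)
        for rid, xyz in self.runs:
            n_atoms = xyz.shape[1]
            for idx in [self.receptor_atoms, self.ion_atoms, *self.ligand_groups]:
                if idx.size and idx.max() >= n_atoms:
                    raise ValueError(f"atom index out of range in run {rid!r}")

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def n_ligands(self) -> int:
        return len(self.ligand_groups)


# ---------------------------------------------------------------------------
# portable bundle I/O

_BUNDLE_META = "bundle.json"
_REQUIRED_KEYS = {"frame_dt_ns", "runs", "receptor_atoms", "ligand_groups"}


def write_bundle(path, bundle: TrajectoryBundle, provenance: dict | None = None) -> Path:
    """Write a bundle as CSV coordinate matrices plus a JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    run_entries = []
    for rid, xyz in bundle.runs:
        fname = f"{rid}_coords.csv"
        flat = xyz.reshape(xyz.shape[0], -1)
        np.savetxt(path / fname, flat, delimiter=",")
        run_entries.append({"id": rid, "coords": fname, "n_atoms": int(xyz.shape[1])})
    meta = {
        "format": "msmbind-bundle",
        "frame_dt_ns": bundle.frame_dt,
        "runs": run_entries,
        "receptor_atoms": bundle.receptor_atoms.tolist(),
        "ligand_groups": [g.tolist() for g in bundle.ligand_groups],
        "ion_atoms": bundle.ion_atoms.tolist(),
        "phosphate_atoms": (
            [g.tolist() for g in bundle.phosphate_atoms] if bundle.phosphate_atoms is not None else None
        ),
        "provenance": provenance or {},
    }
    (path / _BUNDLE_META).write_text(json.dumps(meta, indent=1))
    return path


def _read_portable(path: Path) -> TrajectoryBundle:
    meta = json.loads((path / _BUNDLE_META).read_text())
    missing = _REQUIRED_KEYS - set(meta)
    if missing:
        raise ValueError(f"bundle metadata missing keys: {sorted(missing)}")
    if meta["frame_dt_ns"] <= 0:
        raise ValueError("frame_dt_ns must be positive")
    runs = []
    for entry in meta["runs"]:
        flat = np.loadtxt(path / entry["coords"], delimiter=",", ndmin=2)
        n_atoms = int(entry["n_atoms"])
        if flat.shape[1] != 3 * n_atoms:
            raise ValueError(f"run {entry['id']!r}: column count does not match n_atoms")
        runs.append((entry["id"], flat.reshape(flat.shape[0], n_atoms, 3)))
    return TrajectoryBundle(
        runs=runs,
        frame_dt=float(meta["frame_dt_ns"]),
        receptor_atoms=np.asarray(meta["receptor_atoms"], int),
        ligand_groups=[np.asarray(g, int) for g in meta["ligand_groups"]],
        ion_atoms=np.asarray(meta.get("ion_atoms", []), int),
        phosphate_atoms=(
            [np.asarray(g, int) for g in meta["phosphate_atoms"]]
            if meta.get("phosphate_atoms") is not None
            else None
        ),
    )


def _read_md(path: Path, metadata: dict) -> TrajectoryBundle:
    import mdtraj as md  # heavy import kept local

    required = {"frame_dt_ns", "topology", "trajectories", "receptor_atoms", "ligand_groups"}
    missing = required - set(metadata)
    if missing:
        raise ValueError(f"MD bundle metadata missing keys: {sorted(missing)}")
    if metadata["frame_dt_ns"] <= 0:
        raise ValueError("frame_dt_ns must be positive")
    top = md.load_topology(str(path / metadata["topology"]))
    runs = []
    for i, traj_file in enumerate(metadata["trajectories"]):
        t = md.load(str(path / traj_file), top=top)
        runs.append((f"run{i}", np.asarray(t.xyz, dtype=float) * 10.0))  # nm -> Å
    return TrajectoryBundle(
        runs=runs,
        frame_dt=float(metadata["frame_dt_ns"]),
        receptor_atoms=np.asarray(metadata["receptor_atoms"], int),
        ligand_groups=[np.asarray(g, int) for g in metadata["ligand_groups"]],
        ion_atoms=np.asarray(metadata.get("ion_atoms", []), int),
        phosphate_atoms=(
            [np.asarray(g, int) for g in metadata["phosphate_atoms"]]
            if metadata.get("phosphate_atoms") is not None
            else None
        ),
        topology=top,
    )


def read_bundle(path, metadata: dict | None = None) -> TrajectoryBundle:
    """Read a trajectory bundle, portable or MD-format.

    A directory containing ``bundle.json`` is read as a portable bundle;
    otherwise ``metadata`` must declare topology / trajectory files and
    atom roles, and coordinates are loaded through mdtraj (converted to Å).
    """
    path = Path(path)
    if (path / _BUNDLE_META).exists():
        return _read_portable(path)
    if metadata is None:
        raise ValueError(f"{path} has no {_BUNDLE_META} and no metadata was supplied")
    return _read_md(path, metadata)


def write_feature_trajectory(path, traj: FeatureTrajectory, extra_meta: dict | None = None) -> None:
    """Write one feature trajectory as CSV plus a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, traj.frames, delimiter=",")
    meta = {
        "frame_dt_ns": traj.frame_dt,
        "feature_names": traj.feature_names,
        "source": list(traj.source),
    }
    meta.update(extra_meta or {})
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_feature_trajectory(path) -> FeatureTrajectory:
    path = Path(path)
    frames = np.loadtxt(path, delimiter=",", ndmin=2)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return FeatureTrajectory(
        frames=frames,
        frame_dt=float(meta["frame_dt_ns"]),
        feature_names=list(meta["feature_names"]),
        source=tuple(meta["source"]),
    )


# ---------------------------------------------------------------------------
# splitting and featurization


def split_ligand_copies(bundle: TrajectoryBundle) -> list[LigandStream]:
    """One independent stream per (run, ligand copy) pair.

    Multi-copy boxes are decomposed so that each ligand's interaction with
    the receptor is analysed as its own trajectory; receptor, ion and
    per-ligand phosphate coordinates are carried along.  The result has
    ``n_runs * n_ligands`` streams.
    """
    if not bundle.ligand_groups:
        raise ValueError("bundle declares no ligand groups")
    for li, g in enumerate(bundle.ligand_groups):
        if g.size == 0:
            raise ValueError(f"ligand group {li} is empty")
    streams = []
    for rid, xyz in bundle.runs:
        rec = xyz[:, bundle.receptor_atoms, :]
        ions = xyz[:, bundle.ion_atoms, :] if bundle.ion_atoms.size else None
        for li, group in enumerate(bundle.ligand_groups):
            phos = None
            if bundle.phosphate_atoms is not None:
                phos = xyz[:, bundle.phosphate_atoms[li], :]
            streams.append(
                LigandStream(
                    run_id=rid,
                    ligand_id=li,
                    ligand_xyz=xyz[:, group, :],
                    receptor_xyz=rec,
                    frame_dt=bundle.frame_dt,
                    ion_xyz=ions,
                    phosphate_xyz=phos,
                )
            )
    return streams


def _min_image(delta: np.ndarray, box_edge: float | None) -> np.ndarray:
    if box_edge is None:
        return delta
    return delta - box_edge * np.round(delta / box_edge)


def _pairwise_min_dist(a: np.ndarray, b: np.ndarray, box_edge: float | None) -> np.ndarray:
    """Min over b-atoms of |a_i - b_j| per frame: (T, n_a)."""
    delta = a[:, :, None, :] - b[:, None, :, :]
    delta = _min_image(delta, box_edge)
    return np.sqrt((delta**2).sum(axis=-1)).min(axis=2)


def contact_map_features(
    stream: LigandStream,
    cutoff: float = 8.0,
    box_edge: float | None = None,
) -> FeatureTrajectory:
    """Binary receptor-ligand contact map, one column per receptor atom.

    Column ``p`` of frame ``t`` is 1 iff the minimum distance from
    receptor atom ``p`` to any ligand atom is strictly below ``cutoff``
    (default 8 Å).  ``box_edge`` enables minimum-image distances for
    periodic cubic boxes; the default is plain Euclidean distance.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if stream.receptor_xyz.shape[1] == 0 or stream.ligand_xyz.shape[1] == 0:
        raise ValueError("empty receptor or ligand atom selection")
    mind = _pairwise_min_dist(stream.receptor_xyz, stream.ligand_xyz, box_edge)
    contacts = (mind < cutoff).astype(float)
    names = [f"contact_rec{p}" for p in range(contacts.shape[1])]
    return FeatureTrajectory(
        frames=contacts,
        frame_dt=stream.frame_dt,
        feature_names=names,
        source=(stream.run_id, stream.ligand_id),
    )


def coordination_flags(
    stream: LigandStream,
    cutoff: float = 4.0,
    box_edge: float | None = None,
) -> CoordinationFlags:
    """Per-frame ion-coordination flag for one ligand stream.

    True at frame ``t`` iff any ligand phosphate atom is strictly within
    ``cutoff`` (default 4 Å) of any declared ion.  Systems without ions
    get an all-false flag sequence (with a warning), so ion-free batches
    flow through the same pipeline.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if stream.ion_xyz is None or stream.ion_xyz.shape[1] == 0:
        warnings.warn("no ion atoms declared; coordination flags all false", stacklevel=2)
        return CoordinationFlags(np.zeros(stream.n_frames, dtype=bool), (stream.run_id, stream.ligand_id))
    phos = stream.phosphate_xyz if stream.phosphate_xyz is not None else stream.ligand_xyz
    mind = _pairwise_min_dist(phos, stream.ion_xyz, box_edge).min(axis=1)
    return CoordinationFlags(mind < cutoff, (stream.run_id, stream.ligand_id))
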