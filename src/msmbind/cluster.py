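"""k-centers discretization and coordination-flag cluster splitting.

The projected trajectories are discretized with the Gonzalez (farthest
point) k-centers algorithm: the first center is a seeded uniform draw
from the pooled frames, and each subsequent center is the frame farthest
from its nearest existing center.  The covering radius (max distance of
any frame to its nearest center) is reported and is non-increasing in k.

Geometric clusters can then be split by a boolean per-frame flag (ion
coordination of the ligand phosphate): every cluster observed with both
flag values becomes two microstates, so the final count is
``k_geometric + (#clusters with both flags)``.  Splitting uses observed
flag values only and never creates empty microstates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .featurize import CoordinationFlags, FeatureTrajectory

__all__ = ["ClusterModel", "DiscreteTrajectory", "kcenters_fit", "assign", "split_by_flag"]


@dataclass
class DiscreteTrajectory:
    """Microstate index sequence for one (run, ligand) trajectory."""

    states: np.ndarray
    frame_dt: float
    source: tuple = ("run0", 0)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64).ravel()
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]


@dataclass
class ClusterModel:
    """Fitted k-centers model, optionally refined by a boolean flag.

    centers : (k, d) geometric cluster centers
    flag_split_map : {(geometric cluster, flag) -> final microstate id};
        empty until :func:`split_by_flag` is applied
    covering_radius : max distance of any training frame to its center
    """

    centers: np.ndarray
    seed: int
    covering_radius: float = np.nan
    flag_split_map: dict[tuple[int, bool], int] = field(default_factory=dict)

    @property
    def k_geometric(self) -> int:
        return self.centers.shape[0]

    @property
    def n_microstates(self) -> int:
        if not self.flag_split_map:
            return self.k_geometric
        return max(self.flag_split_map.values()) + 1

    def to_json(self, path) -> None:
        payload = {
            "centers": self.centers.tolist(),
            "seed": self.seed,
            "covering_radius": self.covering_radius,
            "flag_split_map": [[c, bool(f), m] for (c, f), m in sorted(self.flag_split_map.items())],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "ClusterModel":
        d = json.loads(Path(path).read_text())
        return cls(
            centers=np.asarray(d["centers"], float),
            seed=int(d["seed"]),
            covering_radius=float(d["covering_radius"]),
            flag_split_map={(int(c), bool(f)): int(m) for c, f, m in d["flag_split_map"]},
        )


def _nearest_center(frames: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Index of the nearest center per frame; ties go to the lowest index."""
    d2 = ((frames[:, None, :] - centers[None, :, :]) ** 2).sum(axis=-1)
    return np.argmin(d2, axis=1)


def kcenters_fit(data: list[FeatureTrajectory], k: int, seed: int) -> ClusterModel:
    """Gonzalez farthest-point k-centers over the pooled frames.

    Deterministic for a fixed seed (which selects only the first center);
    subsequent centers are the frames of maximal distance to the nearest
    existing center, ties resolved by the first occurrence in pooled frame
    order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = np.vstack([t.frames for t in data])
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the {X.shape[0]} available frames")
    rng = np.random.default_rng(seed)
    first = int(rng.integers(X.shape[0]))
    centers = [X[first]]
    dmin = np.linalg.norm(X - X[first], axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(dmin))
        centers.append(X[nxt])
        d_new = np.linalg.norm(X - X[nxt], axis=1)
        np.minimum(dmin, d_new, out=dmin)
    return ClusterModel(
        centers=np.asarray(centers),
        seed=seed,
        covering_radius=float(dmin.max()),
    )


def assign(
    model: ClusterModel,
    trajectory: FeatureTrajectory,
    flags: CoordinationFlags | None = None,
) -> DiscreteTrajectory:
    """Nearest-center assignment, flag-refined if the model was split.

    Euclidean nearest center, ties to the lowest center index.  When the
    model carries a flag_split_map, ``flags`` must be given and aligned;
    each (geometric cluster, flag) pair maps to its final microstate id.
    A flag value never observed during splitting falls back to the id of
    the observed value for that cluster.
    """
    if trajectory.n_features != model.centers.shape[1]:
        raise ValueError("trajectory dimensionality does not match cluster centers")
    geo = _nearest_center(trajectory.frames, model.centers)
    if not model.flag_split_map:
        return DiscreteTrajectory(geo, trajectory.frame_dt, trajectory.source)
    if flags is None:
        raise ValueError("model was flag-split; coordination flags are required")
    if len(flags) != trajectory.n_frames:
        raise ValueError("flags length does not match trajectory frame count")
    states = np.empty_like(geo)
    fm = model.flag_split_map
    for t, (c, f) in enumerate(zip(geo.tolist(), flags.flags.tolist())):
        key = (c, f)
        if key not in fm:
            key = (c, not f)  # unseen flag value for this cluster
        states[t] = fm[key]
    return DiscreteTrajectory(states, trajectory.frame_dt, trajectory.source)


def split_by_flag(
    model: ClusterModel,
    assignments: list[DiscreteTrajectory],
    flags: list[CoordinationFlags],
) -> tuple[ClusterModel, list[DiscreteTrajectory]]:
    """Split each geometric cluster observed with both flag values.

    Clusters seen with a single flag value keep their id; clusters seen
    with both get a second microstate (new ids appended after the
    geometric ids), so ``n_microstates = k_geometric + #mixed``.  Returns
    an updated model plus reindexed assignments.
    """
    if len(assignments) != len(flags):
        raise ValueError("need one flag sequence per discrete trajectory")
    k = model.k_geometric
    seen_false = np.zeros(k, dtype=bool)
    seen_true = np.zeros(k, dtype=bool)
    for dtraj, fl in zip(assignments, flags):
        if len(fl) != dtraj.n_frames:
            raise ValueError("flags length does not match assignment length")
        s = dtraj.states
        f = fl.flags
        seen_true[np.unique(s[f])] = True
        seen_false[np.unique(s[~f])] = True
    mixed = np.flatnonzero(seen_true & seen_false)
    split_map: dict[tuple[int, bool], int] = {}
    next_id = k
    for c in range(k):
        if c in set(mixed.tolist()):
            split_map[(c, False)] = c
            split_map[(c, True)] = next_id
            next_id += 1
        elif seen_true[c] and not seen_false[c]:
            split_map[(c, True)] = c
        else:  # only False observed, or never observed at all
            split_map[(c, False)] = c
    new_model = ClusterModel(
        centers=model.centers,
        seed=model.seed,
        covering_radius=model.covering_radius,
        flag_split_map=split_map,
    )
    new_assignments = []
    for dtraj, fl in zip(assignments, flags):
        states = dtraj.states.copy()
        remap_true = fl.flags & np.isin(dtraj.states, mixed)
        for c in mixed:
            states[remap_true & (dtraj.states == c)] = split_map[(int(c), True)]
        new_assignments.append(DiscreteTrajectory(states, dtraj.frame_dt, dtraj.source))
    return new_model, new_assignments
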