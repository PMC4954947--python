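"""Time-lagged independent component analysis (TICA).

TICA finds the linear combinations of input features with the slowest
decorrelation: the generalized eigenproblem ``C(tau) v = lambda C(0) v``
with mean-free instantaneous covariance ``C(0)`` and *symmetrized*
time-lagged covariance ``C(tau) = 1/2 <x_t x_{t+tau}^T + x_{t+tau} x_t^T>``
pooled over all trajectories.  Symmetrization guarantees a real spectrum;
binary contact features are frequently collinear, so ``C(0)`` is ridge
regularized with ``eps = 1e-6 * trace(C(0)) / F`` before solving.

Projections onto the leading eigenvectors are the slow order parameters
on which trajectories are subsequently clustered.  Components are
normalized in the ``C(0)`` metric (unit instantaneous variance); no
kinetic-map eigenvalue rescaling is applied by default.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .featurize import FeatureTrajectory

__all__ = ["TicaModel", "fit_tica", "transform_tica"]

_LAG_TOL = 1e-9


@dataclass
class TicaModel:
    """Fitted TICA projection.

    mean : length-F feature mean over all lagged pairs
    eigenvalues : top-d autocorrelation eigenvalues, descending
    components : (F, d) projection matrix; rows of dropped (constant)
        feature columns are zero
    lag : ns
    kept_columns : indices of non-constant features used in the fit
    """

    mean: np.ndarray
    eigenvalues: np.ndarray
    components: np.ndarray
    lag: float
    regularization: float
    kept_columns: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    kinetic_map: bool = False

    @property
    def dim(self) -> int:
        return self.components.shape[1]

    @property
    def n_features(self) -> int:
        return self.components.shape[0]

    def to_json(self, path) -> None:
        payload = {
            "mean": self.mean.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "components": self.components.tolist(),
            "lag_ns": self.lag,
            "regularization": self.regularization,
            "kept_columns": self.kept_columns.tolist(),
            "kinetic_map": self.kinetic_map,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "TicaModel":
        d = json.loads(Path(path).read_text())
        return cls(
            mean=np.asarray(d["mean"], float),
            eigenvalues=np.asarray(d["eigenvalues"], float),
            components=np.asarray(d["components"], float),
            lag=float(d["lag_ns"]),
            regularization=float(d["regularization"]),
            kept_columns=np.asarray(d["kept_columns"], int),
            kinetic_map=bool(d.get("kinetic_map", False)),
        )


def _lag_frames(lag: float, frame_dt: float) -> int:
    ratio = lag / frame_dt
    if abs(ratio - round(ratio)) > _LAG_TOL * max(1.0, ratio):
        raise ValueError(f"lag {lag} ns is not an integer multiple of frame_dt {frame_dt} ns")
    k = int(round(ratio))
    if k < 1:
        raise ValueError("lag must be at least one frame")
    return k


def fit_tica(
    trajectories: list[FeatureTrajectory],
    lag: float,
    dim: int,
    kinetic_map: bool = False,
) -> TicaModel:
    """Fit TICA at lag ``lag`` (ns) and keep the top ``dim`` components.

    All trajectories must share frame spacing and feature count and be
    longer than the lag.  All-constant feature columns carry no kinetic
    signal and are dropped with a warning; the returned components have
    zero rows there so ``transform_tica`` accepts full-width frames.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    frame_dt = trajectories[0].frame_dt
    F = trajectories[0].n_features
    for t in trajectories:
        if t.frame_dt != frame_dt:
            raise ValueError("trajectories disagree on frame_dt")
        if t.n_features != F:
            raise ValueError("trajectories disagree on feature count")
    if not 1 <= dim <= F:
        raise ValueError("dim must be between 1 and the feature count")
    k = _lag_frames(lag, frame_dt)
    usable = [t for t in trajectories if t.n_frames > k]
    if not usable:
        raise ValueError("no trajectory longer than the lag")

    # pooled moments over all (t, t+k) pairs
    n_pairs = 0
    s0 = np.zeros(F)
    st = np.zeros(F)
    for t in usable:
        X0, Xt = t.frames[:-k], t.frames[k:]
        n_pairs += X0.shape[0]
        s0 += X0.sum(axis=0)
        st += Xt.sum(axis=0)
    mean = (s0 + st) / (2.0 * n_pairs)

    C0 = np.zeros((F, F))
    Ct = np.zeros((F, F))
    for t in usable:
        X0 = t.frames[:-k] - mean
        Xt = t.frames[k:] - mean
        C0 += X0.T @ X0 + Xt.T @ Xt
        Ct += X0.T @ Xt
    C0 /= 2.0 * n_pairs
    Ct = (Ct + Ct.T) / (2.0 * n_pairs)

    keep = np.flatnonzero(np.diag(C0) > 1e-12)
    if keep.size < F:
        warnings.warn(f"dropping {F - keep.size} constant feature column(s)", stacklevel=2)
    if keep.size == 0:
        raise ValueError("all feature columns are constant")
    if dim > keep.size:
        raise ValueError(f"dim={dim} exceeds the {keep.size} non-constant columns")
    C0r = C0[np.ix_(keep, keep)]
    Ctr = Ct[np.ix_(keep, keep)]
    eps = 1e-6 * np.trace(C0r) / keep.size
    C0r = C0r + eps * np.eye(keep.size)

    evals, evecs = scipy.linalg.eigh(Ctr, C0r)  # ascending, C0-orthonormal
    order = np.argsort(evals)[::-1][:dim]
    evals = evals[order]
    evecs = evecs[:, order]
    if np.any(np.abs(evals) > 1.0 + 1e-8):
        warnings.warn("eigenvalues exceed 1; lag may be too short for the data", stacklevel=2)
    if kinetic_map:
        evecs = evecs * evals[None, :]
    components = np.zeros((F, dim))
    components[keep, :] = evecs
    return TicaModel(
        mean=mean,
        eigenvalues=evals,
        components=components,
        lag=lag,
        regularization=eps,
        kept_columns=keep,
        kinetic_map=kinetic_map,
    )


def transform_tica(model: TicaModel, trajectory: FeatureTrajectory) -> FeatureTrajectory:
    """Project a feature trajectory onto the fitted slow components."""
    if trajectory.n_features != model.n_features:
        raise ValueError(
            f"trajectory has {trajectory.n_features} features, model expects {model.n_features}"
        )
    proj = (trajectory.frames - model.mean) @ model.components
    names = [f"tic{i + 1}" for i in range(model.dim)]
    return FeatureTrajectory(
        frames=proj,
        frame_dt=trajectory.frame_dt,
        feature_names=names,
        source=trajectory.source,
    )
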