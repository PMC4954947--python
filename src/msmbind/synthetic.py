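"""Synthetic trajectory generators with analytic kinetic ground truth.

Every downstream stage of the binding-kinetics pipeline (featurization,
TICA, clustering, MSM estimation, macrostate kinetics) can be validated
against the exact quantities of a continuous-time Markov jump process:
its stationary distribution, its lag-``t`` transition matrix ``expm(K t)``
and its mean first passage times.  Two generators are provided:

* :func:`sample_ctmc_trajectories` — exact Gillespie simulation of a rate
  matrix, discretized on a regular frame grid, then optionally embedded
  into a feature space with :func:`embed_states`.  This emulates the
  statistical structure of ligand-binding MD data: many short independent
  trajectories, a bulk state, metastable intermediates and a long-lived
  bound state.
* :func:`brownian_binding_trajectories` — overdamped Brownian dynamics of
  a point ligand in a box with a flat-bottom attractive well, emulating
  free-ligand binding runs at the coordinate level.

All rates are in 1/ns, times in ns, lengths in Å, energies in kcal/mol.
Matrices use the ROW convention throughout: ``K[i, j]`` is the rate from
state ``i`` to state ``j`` and ``T[i, j]`` the conditional probability of
``j`` at lag ``t`` given ``i`` at time 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .featurize import FeatureTrajectory

__all__ = [
    "RateMatrix",
    "StateEmbedding",
    "GroundTruthSystem",
    "BrownianConfig",
    "sample_ctmc_trajectories",
    "embed_states",
    "brownian_binding_trajectories",
    "exact_stationary",
    "exact_transition_matrix",
    "exact_mfpt",
    "preset",
    "PRESET_NAMES",
]

BOLTZMANN_KCAL = 1.9872e-3  # kcal/(mol K)


@dataclass(frozen=True)
class RateMatrix:
    """Generator ``K`` of a continuous-time Markov chain (row convention).

    ``K[i, j] >= 0`` for ``i != j`` is the transition rate (1/ns) from
    state ``i`` to ``j``; diagonal entries make each row sum to zero so
    that probability is conserved under ``dP/dt = P K``.
    """

    K: np.ndarray
    state_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1] or K.shape[0] < 2:
            raise ValueError("K must be a square matrix with n >= 2")
        off = K - np.diag(np.diag(K))
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be non-negative")
        if np.max(np.abs(K.sum(axis=1))) >= 1e-12:
            raise ValueError("each row of K must sum to zero (rate conservation)")
        object.__setattr__(self, "K", K)
        names = tuple(self.state_names) or tuple(f"s{i}" for i in range(K.shape[0]))
        if len(names) != K.shape[0]:
            raise ValueError("state_names length must match K")
        object.__setattr__(self, "state_names", names)

    @property
    def n_states(self) -> int:
        return self.K.shape[0]

    @property
    def absorbing_states(self) -> np.ndarray:
        """Indices of states with zero total exit rate."""
        return np.flatnonzero(np.diag(self.K) == 0.0)


@dataclass(frozen=True)
class StateEmbedding:
    """Placement of discrete states in feature space.

    Each state maps to a centroid; frames are centroids plus isotropic
    Gaussian noise of standard deviation ``noise_sd``.  For benchmark
    presets the minimum pairwise centroid distance exceeds four noise
    standard deviations so every state is resolvable by clustering.
    """

    centroids: np.ndarray
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.centroids, dtype=float))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "centroids", c)

    @property
    def n_states(self) -> int:
        return self.centroids.shape[0]

    @property
    def n_features(self) -> int:
        return self.centroids.shape[1]

    def min_pairwise_distance(self) -> float:
        c = self.centroids
        d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
        return float(d[np.triu_indices(len(c), k=1)].min())


@dataclass(frozen=True)
class GroundTruthSystem:
    """A rate matrix plus its feature-space embedding and box metadata.

    ``bulk_state`` / ``bound_state`` name the unbound and bound ends of
    the binding process; ``box_volume`` (litres) and ``n_ligand_copies``
    define the simulation concentration used for on-rate conversion.
    """

    rate_matrix: RateMatrix
    embedding: StateEmbedding
    bulk_state: int
    bound_state: int
    frame_dt: float  # ns
    box_volume: float | None = None  # L
    n_ligand_copies: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        if self.bulk_state == self.bound_state:
            raise ValueError("bulk_state and bound_state must differ")
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be positive")
        n = self.rate_matrix.n_states
        if not (0 <= self.bulk_state < n and 0 <= self.bound_state < n):
            raise ValueError("bulk/bound state index out of range")

    @property
    def concentration(self) -> float | None:
        """Single-copy simulation concentration in mol/L, if the box is known."""
        if self.box_volume is None:
            return None
        from .kinetics import concentration_from_box

        return concentration_from_box(1, self.box_volume)


def _check_irreducible(K: np.ndarray) -> None:
    adj = csr_matrix((K - np.diag(np.diag(K))) > 0)
    n_comp, _ = connected_components(adj, directed=True, connection="strong")
    if n_comp != 1:
        raise ValueError("rate matrix is reducible; stationary vector not unique")


def exact_stationary(rate_matrix: RateMatrix | np.ndarray) -> np.ndarray:
    """Stationary distribution ``pi`` with ``pi K = 0`` and ``sum(pi) = 1``.

    This is the continuous-time analogue of the eigenvector of the
    transition matrix with eigenvalue one.  Raises for reducible ``K``.
    """
    K = rate_matrix.K if isinstance(rate_matrix, RateMatrix) else np.asarray(rate_matrix)
    _check_irreducible(K)
    n = K.shape[0]
    # solve pi K = 0 with normalization row appended
    A = np.vstack([K.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.any(pi <= 0):
        raise ValueError("stationary distribution not strictly positive")
    return pi / pi.sum()


def exact_transition_matrix(rate_matrix: RateMatrix | np.ndarray, lag: float) -> np.ndarray:
    """Lag-``lag`` transition matrix ``expm(K * lag)`` (row-stochastic)."""
    if lag < 0:
        raise ValueError("lag must be non-negative")
    K = rate_matrix.K if isinstance(rate_matrix, RateMatrix) else np.asarray(rate_matrix)
    return expm(K * lag)


def exact_mfpt(
    rate_matrix: RateMatrix | np.ndarray,
    source: int | list[int] | set[int],
    target: int | list[int] | set[int],
) -> float:
    """Mean first passage time (ns) from ``source`` into ``target``.

    Solves ``K_restricted @ m = -1`` on the non-target states; the
    returned value averages ``m`` over the source states with weights
    proportional to the stationary distribution restricted to the source.
    Sources already inside the target contribute zero.
    """
    K = rate_matrix.K if isinstance(rate_matrix, RateMatrix) else np.asarray(rate_matrix)
    n = K.shape[0]
    src = np.atleast_1d(np.asarray(list(source) if not np.isscalar(source) else [source], int))
    tgt_set = set(np.atleast_1d(np.asarray(list(target) if not np.isscalar(target) else [target], int)).tolist())
    if not tgt_set:
        raise ValueError("target set must be non-empty")
    if set(src.tolist()) <= tgt_set:
        return 0.0
    non_target = np.array([i for i in range(n) if i not in tgt_set])
    Knn = K[np.ix_(non_target, non_target)]
    try:
        m_non = np.linalg.solve(Knn, -np.ones(len(non_target)))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - singular system
        raise ValueError("target unreachable from some source states") from exc
    if np.any(m_non < -1e-9):
        raise ValueError("target unreachable from some source states")
    m = np.zeros(n)
    m[non_target] = m_non
    if src.size == 1:
        return float(m[src[0]])
    try:
        pi = exact_stationary(K)
        w = pi[src]
    except ValueError:
        warnings.warn("reducible K: uniform source weighting used for MFPT", stacklevel=2)
        w = np.ones(src.size)
    w = w / w.sum()
    return float(w @ m[src])


def _resolve_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def sample_ctmc_trajectories(
    system: GroundTruthSystem,
    n_traj: int,
    n_frames: int,
    seed: int,
    start_state: int | None = None,
    with_metadata: bool = False,
):
    """Simulate ``n_traj`` discretized jump-process trajectories.

    Dynamics are exact Gillespie jumps of the rate matrix, recorded on a
    regular grid of spacing ``system.frame_dt``.  Initial states are drawn
    from the exact stationary distribution unless ``start_state`` is given
    (e.g. "start in bulk" for binding-time experiments, mirroring setups
    that place the ligand far from the receptor).  Bit-reproducible for a
    fixed seed.

    Returns a list of integer state sequences of length ``n_frames``; with
    ``with_metadata=True`` also returns a dict flagging trajectories that
    entered an absorbing (zero exit rate) state.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    K = system.rate_matrix.K
    n = K.shape[0]
    exit_rates = -np.diag(K)
    jump_probs = np.where(exit_rates[:, None] > 0, K / np.where(exit_rates[:, None] > 0, exit_rates[:, None], 1.0), 0.0)
    np.fill_diagonal(jump_probs, 0.0)
    absorbing = set(system.rate_matrix.absorbing_states.tolist())
    if start_state is None:
        pi0 = exact_stationary(system.rate_matrix) if not absorbing else None
        if pi0 is None:
            raise ValueError("absorbing states present: an explicit start_state is required")
    dt = system.frame_dt
    horizon = (n_frames - 1) * dt
    frame_times = np.arange(n_frames) * dt
    rngs = _resolve_rngs(seed, n_traj)
    dtrajs: list[np.ndarray] = []
    absorbed_flags: list[bool] = []
    for rng in rngs:
        s = int(start_state) if start_state is not None else int(rng.choice(n, p=pi0))
        times = [0.0]
        states = [s]
        t = 0.0
        hit_absorbing = s in absorbing
        while t < horizon and not hit_absorbing:
            r = exit_rates[s]
            t += rng.exponential(1.0 / r)
            if t >= horizon:
                break
            s = int(rng.choice(n, p=jump_probs[s]))
            times.append(t)
            states.append(s)
            hit_absorbing = s in absorbing
        idx = np.searchsorted(np.asarray(times), frame_times, side="right") - 1
        dtrajs.append(np.asarray(states, dtype=np.int64)[idx])
        absorbed_flags.append(hit_absorbing)
    if any(absorbed_flags):
        warnings.warn("some trajectories entered an absorbing state", stacklevel=2)
    if with_metadata:
        return dtrajs, {"absorbed": absorbed_flags}
    return dtrajs


def embed_states(
    dtraj: np.ndarray,
    embedding: StateEmbedding,
    seed: int,
    frame_dt: float = 1.0,
    source: tuple = ("synthetic", 0),
) -> FeatureTrajectory:
    """Map a discrete state sequence into feature space.

    Frame ``t`` is ``centroids[state_t]`` plus isotropic Gaussian noise of
    standard deviation ``embedding.noise_sd``.
    """
    dtraj = np.asarray(dtraj, dtype=np.int64)
    if dtraj.size and (dtraj.min() < 0 or dtraj.max() >= embedding.n_states):
        raise IndexError("state index out of range for embedding")
    rng = np.random.default_rng(seed)
    frames = embedding.centroids[dtraj].astype(float)
    if embedding.noise_sd > 0:
        frames = frames + rng.normal(0.0, embedding.noise_sd, size=frames.shape)
    names = [f"f{i}" for i in range(embedding.n_features)]
    return FeatureTrajectory(frames=frames, frame_dt=frame_dt, feature_names=names, source=source)


@dataclass(frozen=True)
class BrownianConfig:
    """Parameters of the overdamped ligand-in-a-box binding simulation.

    The potential is a flat-bottom spherical well of depth ``well_depth``
    centred on ``well_center``; the wall of the well is a smooth cosine
    ramp over the outer 20% of ``well_radius`` so forces stay continuous.
    Walls of the cubic box (edge ``box_edge``) are reflecting.
    """

    box_edge: float  # Å
    diffusion_coeff: float  # Å^2/ns
    well_center: np.ndarray  # Å
    well_depth: float  # kcal/mol
    well_radius: float  # Å
    receptor_atoms: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    dt: float = 0.01  # ns
    temperature: float = 298.0  # K
    seed: int = 0

    def __post_init__(self) -> None:
        center = np.asarray(self.well_center, dtype=float).reshape(3)
        rec = np.atleast_2d(np.asarray(self.receptor_atoms, dtype=float))
        if rec.size == 0:
            rec = rec.reshape(0, 3)
        object.__setattr__(self, "well_center", center)
        object.__setattr__(self, "receptor_atoms", rec)
        if self.well_radius <= 0:
            raise ValueError("well_radius must be positive")
        if self.well_depth < 0:
            raise ValueError("well_depth must be >= 0")
        if np.any(center < 0) or np.any(center > self.box_edge):
            raise ValueError("well_center must lie inside the box")
        if rec.size and (np.any(rec < 0) or np.any(rec > self.box_edge)):
            raise ValueError("all receptor atoms must lie inside the box")
        rms_step = np.sqrt(6.0 * self.diffusion_coeff * self.dt)
        if rms_step >= self.well_radius / 4.0:
            raise ValueError(
                f"dt too large: RMS step {rms_step:.3g} Å must be < well_radius/4 = "
                f"{self.well_radius / 4.0:.3g} Å"
            )


def _well_force(x: np.ndarray, cfg: BrownianConfig) -> np.ndarray:
    """Radial force (kcal/mol/Å) of the smoothed flat-bottom well."""
    rvec = x - cfg.well_center
    r = np.linalg.norm(rvec, axis=-1)
    R = cfg.well_radius
    r0 = 0.8 * R
    f = np.zeros_like(x)
    on_ramp = (r > r0) & (r < R) & (r > 0)
    if np.any(on_ramp):
        rr = r[on_ramp]
        # U(r) = -depth/2 * (1 + cos(pi (r - r0)/(R - r0))); F = -dU/dr r_hat
        dUdr = cfg.well_depth * 0.5 * np.pi / (R - r0) * np.sin(np.pi * (rr - r0) / (R - r0))
        f[on_ramp] = -(dUdr / rr)[:, None] * rvec[on_ramp]
    return f


def _reflect(x: np.ndarray, edge: float) -> np.ndarray:
    # fold positions back into [0, edge] (single or multiple reflections)
    y = np.mod(x, 2.0 * edge)
    return np.where(y > edge, 2.0 * edge - y, y)


def brownian_binding_trajectories(
    config: BrownianConfig,
    n_traj: int,
    n_frames: int,
    min_start_distance: float = 0.0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Euler–Maruyama trajectories of a point ligand in the well-in-a-box.

    Position update: ``x <- x + sqrt(2 D dt) xi + D dt / (kB T) * F(x)``
    with reflecting walls.  Ligands start uniformly in the box, at least
    ``min_start_distance`` from the well centre (use this to mimic runs
    that place the free ligand well away from the receptor).

    Returns ``[(ligand_xyz, receptor_xyz), ...]`` with ligand_xyz of shape
    (n_frames, 3) in Å.
    """
    if n_traj < 1 or n_frames < 1:
        raise ValueError("n_traj and n_frames must be >= 1")
    D, dt, kT = config.diffusion_coeff, config.dt, BOLTZMANN_KCAL * config.temperature
    step_sd = np.sqrt(2.0 * D * dt)
    rngs = _resolve_rngs(config.seed, n_traj)
    out = []
    for rng in rngs:
        while True:
            x = rng.uniform(0.0, config.box_edge, size=3)
            if np.linalg.norm(x - config.well_center) >= min_start_distance:
                break
        frames = np.empty((n_frames, 3))
        frames[0] = x
        noise = rng.normal(0.0, step_sd, size=(n_frames - 1, 3))
        for t in range(1, n_frames):
            force = _well_force(x[None, :], config)[0]
            x = x + noise[t - 1] + D * dt / kT * force
            x = _reflect(x, config.box_edge)
            frames[t] = x
        out.append((frames, config.receptor_atoms.copy()))
    return out


# ---------------------------------------------------------------------------
# Benchmark presets: fixed, documented ground truths used throughout the tests.

PRESET_NAMES = ("twostate", "binding5", "metastable-blocks")


def _binding5_rate_matrix() -> RateMatrix:
    # bulk(0) <-> interface(1); bulk <-> inter1(2) <-> inter2(3) <-> bound(4)
    # Tree topology => detailed balance holds by construction. Rates (1/ns)
    # give a dominant bulk population, short-lived intermediates and a bound
    # dwell time (~33 ns) much longer than the bulk dwell (~10 ns).
    n = 5
    K = np.zeros((n, n))
    pairs = {
        (0, 1): (0.05, 0.5),
        (0, 2): (0.05, 2.0),
        (2, 3): (1.0, 0.5),
        (3, 4): (0.5, 0.03),
    }
    for (i, j), (kf, kb) in pairs.items():
        K[i, j] = kf
        K[j, i] = kb
    np.fill_diagonal(K, 0.0)
    np.fill_diagonal(K, -K.sum(axis=1))
    return RateMatrix(K, ("bulk", "interface", "inter1", "inter2", "bound"))


def preset(name: str) -> GroundTruthSystem:
    """Return one of the shipped benchmark systems.

    ``twostate``
        Slow symmetric two-state exchange (dwell 20 ns, frame 0.1 ns) with
        centroids 4 units apart; the slowest TICA component must separate
        the states by sign.
    ``binding5``
        Five states mimicking a ligand-binding state decomposition: a
        dominant bulk state, an off-pathway interface state that only
        exchanges with bulk, two on-pathway intermediates and a long-lived
        bound state.  Centroid coordinates are contact-map-like: near zero
        for bulk and largest in total magnitude for the bound pose, so the
        bulk/bound identification rule applies unchanged.  The box volume
        corresponds to a 12 mM single-ligand concentration.
    ``metastable-blocks``
        Six states in two weakly connected 3-state blocks for macrostate
        lumping tests.
    """
    if name == "twostate":
        K = np.array([[-0.05, 0.05], [0.05, -0.05]])
        emb = StateEmbedding(np.array([[0.0, 0.0], [4.0, 0.0]]), noise_sd=0.8)
        return GroundTruthSystem(RateMatrix(K, ("a", "b")), emb, bulk_state=0, bound_state=1,
                                 frame_dt=0.1, name="twostate")
    if name == "binding5":
        rm = _binding5_rate_matrix()
        centroids = np.array(
            [
                [0.0, 0.0, 0.0],  # bulk: no contacts
                [6.0, 0.0, 0.0],  # interface
                [0.0, 6.0, 0.0],  # inter1
                [4.5, 4.5, 0.0],  # inter2
                [6.0, 6.0, 6.0],  # bound: largest contact count
            ]
        )
        # min pairwise distance 4.74 at noise_sd 0.5 (~9.5 sigma): per-frame
        # misassignment is negligible, as the resolvable-embedding guarantee
        # for downstream clustering requires.
        emb = StateEmbedding(centroids, noise_sd=0.5)
        box_volume = 1.0 / (6.02214e23 * 0.012)  # L, 12 mM for one copy
        return GroundTruthSystem(rm, emb, bulk_state=0, bound_state=4, frame_dt=0.1,
                                 box_volume=box_volume, n_ligand_copies=1, name="binding5")
    if name == "metastable-blocks":
        n = 6
        K = np.zeros((n, n))
        within = 1.0
        between = 0.005
        for block in ((0, 1, 2), (3, 4, 5)):
            for i in block:
                for j in block:
                    if i != j:
                        K[i, j] = within
        K[2, 3] = K[3, 2] = between
        np.fill_diagonal(K, 0.0)
        np.fill_diagonal(K, -K.sum(axis=1))
        centroids = np.array(
            [
                [0.0, 0.0, 0.0],
                [3.0, 0.0, 0.0],
                [0.0, 3.0, 0.0],
                [10.0, 10.0, 0.0],
                [13.0, 10.0, 0.0],
                [10.0, 13.0, 0.0],
            ]
        )
        emb = StateEmbedding(centroids, noise_sd=0.5)
        return GroundTruthSystem(RateMatrix(K), emb, bulk_state=0, bound_state=5,
                                 frame_dt=0.1, name="metastable-blocks")
    raise ValueError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
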