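"""Reversible Markov state model estimation and validation.

From discrete trajectories, transition counts at a lag time are collected
with a sliding window (never across trajectory boundaries), the largest
strongly connected set of states is retained, and the transition matrix is
the maximum-likelihood estimate under detailed balance
``pi_i T_ij = pi_j T_ji``.  The estimator is the classic self-consistent
fixed-point iteration on symmetric auxiliary variables ``x_ij = x_ji``
with ``T_ij = x_ij / sum_k x_ik``; it increases the likelihood
monotonically and its fixed point satisfies the constrained stationarity
conditions.

Model validation follows the implied-timescale test: relaxation times
``tau_s = -lag / ln(lambda_s)`` are computed across a ladder of lags, and
the shortest lag at which they stop depending on the lag is suggested as
the Markovian lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .cluster import DiscreteTrajectory

__all__ = [
    "CountModel",
    "TransitionModel",
    "SpectralResult",
    "count_transitions",
    "largest_connected_set",
    "estimate_reversible",
    "stationary_distribution",
    "implied_timescales",
    "lag_scan",
]


@dataclass
class CountModel:
    """Transition counts at one lag, with its largest connected set."""

    counts: np.ndarray
    lag: float  # ns
    counting_mode: str
    active_set: np.ndarray  # original-state indices, sorted

    @property
    def n_states_total(self) -> int:
        return self.counts.shape[0]

    def active_counts(self) -> np.ndarray:
        return self.counts[np.ix_(self.active_set, self.active_set)]


@dataclass
class TransitionModel:
    """Reversible transition matrix on the active set.

    T : (n_active, n_active) row-stochastic
    pi : stationary distribution of T (all positive)
    active_set : map from active index to original microstate index
    """

    T: np.ndarray
    pi: np.ndarray
    lag: float  # ns
    active_set: np.ndarray
    loglik: float

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    def to_original(self, active_indices) -> np.ndarray:
        return self.active_set[np.asarray(active_indices, int)]

    def to_active(self, original_indices) -> np.ndarray:
        lookup = {int(s): i for i, s in enumerate(self.active_set)}
        out = []
        for s in np.atleast_1d(np.asarray(original_indices, int)):
            if int(s) not in lookup:
                raise KeyError(f"microstate {int(s)} is outside the active set")
            out.append(lookup[int(s)])
        return np.asarray(out, int)


@dataclass
class SpectralResult:
    """Eigenvalues (descending) and implied timescales at one lag.

    ``timescales[s] = -lag / ln(eigenvalues[s])`` for eigenvalues in
    (0, 1); the stationary eigenvalue 1 maps to +inf and non-positive
    eigenvalues (undefined relaxation time) to NaN.
    """

    eigenvalues: np.ndarray
    timescales: np.ndarray
    lag: float


def _lag_in_frames(lag: float, frame_dt: float) -> int:
    ratio = lag / frame_dt
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 * max(1.0, ratio) or k < 1:
        raise ValueError(f"lag {lag} ns must be a positive integer multiple of frame_dt {frame_dt} ns")
    return k


def count_transitions(
    dtrajs: list[DiscreteTrajectory],
    lag: float,
    mode: str = "sliding",
    n_states: int | None = None,
) -> CountModel:
    """Sliding-window transition counts pooled over trajectories.

    ``C_ij = #{t : s_t = i, s_{t+k} = j}`` summed over trajectories with
    ``k = lag / frame_dt`` frames; pairs never straddle a trajectory
    boundary.  ``mode='strided'`` subsamples non-overlapping pairs instead.
    """
    if mode not in ("sliding", "strided"):
        raise ValueError("mode must be 'sliding' or 'strided'")
    if not dtrajs:
        raise ValueError("no discrete trajectories given")
    frame_dt = dtrajs[0].frame_dt
    k = _lag_in_frames(lag, frame_dt)
    n = n_states if n_states is not None else max(int(d.states.max()) for d in dtrajs if d.n_frames) + 1
    C = np.zeros((n, n))
    any_long_enough = False
    for d in dtrajs:
        if d.frame_dt != frame_dt:
            raise ValueError("trajectories disagree on frame_dt")
        s = d.states
        if s.shape[0] <= k:
            continue
        any_long_enough = True
        a, b = (s[:-k], s[k:]) if mode == "sliding" else (s[:-k:k], s[k::k])
        np.add.at(C, (a, b), 1.0)
    if not any_long_enough:
        raise ValueError("all trajectories are shorter than the lag")
    active = largest_connected_set(C)
    return CountModel(counts=C, lag=lag, counting_mode=mode, active_set=active)


def largest_connected_set(counts: np.ndarray) -> np.ndarray:
    """Largest strongly connected component of the count graph.

    Edge ``i -> j`` exists iff ``counts[i, j] > 0``.  Among components of
    maximal size, the one with the largest total counts wins; remaining
    ties go to the component containing the lowest state index.
    """
    C = np.asarray(counts)
    n = C.shape[0]
    n_comp, labels = connected_components(csr_matrix(C > 0), directed=True, connection="strong")
    best_key = None
    best_members = None
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        total = C[np.ix_(members, members)].sum()
        key = (members.size, total, -int(members.min()))
        if best_key is None or key > best_key:
            best_key = key
            best_members = members
    return np.sort(best_members)


def estimate_reversible(
    counts: CountModel,
    tol: float = 1e-12,
    max_iter: int = 1_000_000,
) -> TransitionModel:
    """Maximum-likelihood reversible transition matrix from counts.

    Maximizes ``sum_ij C_ij log T_ij`` over row-stochastic ``T`` subject
    to detailed balance, by fixed-point iteration on the symmetric
    variables ``x_ij``:

        ``x_ij <- (C_ij + C_ji) / (c_i / x_i + c_j / x_j)``

    with ``c_i`` the count row sums and ``x_i = sum_j x_ij``.  Converged
    when the max relative change of ``x`` falls below ``tol``.  Then
    ``T_ij = x_ij / x_i`` and ``pi_i = x_i / sum x``.
    """
    C = counts.active_counts()
    if C.shape[0] == 0:
        raise ValueError("empty active set")
    Csym = C + C.T
    if np.any(Csym.sum(axis=1) == 0):
        raise ValueError("active set contains states with no transitions")
    X = Csym.copy()
    c_i = C.sum(axis=1)
    nonzero = Csym > 0
    for _ in range(max_iter):
        x_i = X.sum(axis=1)
        denom = c_i[:, None] / x_i[:, None] + c_i[None, :] / x_i[None, :]
        X_new = np.where(nonzero, Csym / np.where(denom > 0, denom, 1.0), 0.0)
        delta = np.max(np.abs(X_new - X) / np.maximum(np.abs(X), 1e-300), initial=0.0, where=nonzero)
        X = X_new
        if delta < tol:
            break
    else:
        raise RuntimeError(f"reversible MLE did not converge: residual {delta:.3e} after {max_iter} sweeps")
    x_i = X.sum(axis=1)
    T = X / x_i[:, None]
    pi = x_i / x_i.sum()
    with np.errstate(divide="ignore"):
        loglik = float(np.sum(C[T > 0] * np.log(T[T > 0])))
    return TransitionModel(T=T, pi=pi, lag=counts.lag, active_set=counts.active_set, loglik=loglik)


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Left eigenvector of ``T`` with eigenvalue 1, normalized, positive.

    This is the stationary equilibrium probability of the chain; raises
    for reducible ``T`` (where it is not unique).
    """
    T = np.asarray(T, float)
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("T is not row-stochastic")
    n_comp, _ = connected_components(csr_matrix(T > 0), directed=True, connection="strong")
    if n_comp != 1:
        raise ValueError("T is reducible; stationary distribution not unique")
    n = T.shape[0]
    A = np.vstack([T.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.maximum(pi, 0.0)
    return pi / pi.sum()


def implied_timescales(model_or_T, lag: float | None = None, n_timescales: int | None = None) -> SpectralResult:
    """Relaxation timescales ``-lag / ln(lambda_s)`` of the model.

    Eigenvalues are sorted descending by real part; under a reversible
    ``T`` the spectrum is real (imaginary parts below 1e-10 are dropped).
    Eigenvalues within 1e-12 of 1 give infinite timescales; non-positive
    eigenvalues have no relaxation-time interpretation and give NaN.
    """
    if isinstance(model_or_T, TransitionModel):
        T = model_or_T.T
        lag = model_or_T.lag if lag is None else lag
    else:
        T = np.asarray(model_or_T, float)
        if lag is None:
            raise ValueError("lag required when passing a raw matrix")
    evals = np.linalg.eigvals(T)
    if np.max(np.abs(evals.imag)) > 1e-8:
        raise ValueError("complex eigenvalues beyond tolerance; matrix is far from reversible")
    evals = np.sort(evals.real)[::-1]
    if n_timescales is not None:
        evals = evals[: n_timescales + 1]
    ts = np.full(evals.shape, np.nan)
    near_one = evals >= 1.0 - 1e-12
    interior = (evals > 0) & ~near_one
    ts[near_one] = np.inf
    ts[interior] = -lag / np.log(evals[interior])
    return SpectralResult(eigenvalues=evals, timescales=ts, lag=lag)


def lag_scan(
    dtrajs: list[DiscreteTrajectory],
    lags: list[float],
    n_timescales: int = 3,
    rel_tol: float = 0.10,
) -> tuple[pd.DataFrame, float | None]:
    """Implied-timescale curve over a ladder of lags.

    Counts and estimates are recomputed per lag on the COMMON active set
    (intersection of per-lag largest connected sets, re-trimmed to its
    largest strongly connected component).  Returns the table of
    ``tau_s`` per lag and the suggested Markovian lag: the smallest lag
    whose slowest timescale differs from the next lag's by less than
    ``rel_tol`` (None if the curve never flattens).
    """
    if len(lags) < 2:
        raise ValueError("lag_scan needs at least two lags")
    lags = sorted(lags)
    n = max(int(d.states.max()) for d in dtrajs) + 1
    count_models = [count_transitions(dtrajs, lag, n_states=n) for lag in lags]
    common = count_models[0].active_set
    for cm in count_models[1:]:
        common = np.intersect1d(common, cm.active_set)
    if common.size == 0:
        raise ValueError("no common active set across lags")
    rows = []
    tau2 = []
    for cm in count_models:
        sub = cm.counts[np.ix_(common, common)]
        active_local = largest_connected_set(sub)
        cm_common = CountModel(
            counts=sub, lag=cm.lag, counting_mode=cm.counting_mode, active_set=active_local
        )
        model = estimate_reversible(cm_common)
        spec = implied_timescales(model, n_timescales=n_timescales)
        taus = spec.timescales[1 : n_timescales + 1]
        taus = np.pad(taus, (0, max(0, n_timescales - taus.size)), constant_values=np.nan)
        rows.append({"lag_ns": cm.lag, **{f"tau_{s + 2}_ns": taus[s] for s in range(n_timescales)}})
        tau2.append(taus[0])
    table = pd.DataFrame(rows)
    suggested = None
    for i in range(len(lags) - 1):
        if np.isfinite(tau2[i]) and np.isfinite(tau2[i + 1]):
            if abs(tau2[i + 1] - tau2[i]) / abs(tau2[i]) < rel_tol:
                suggested = lags[i]
                break
    return table, suggested
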