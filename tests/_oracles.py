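"""Independent oracles used to cross-check the implementation.

These deliberately avoid the code paths they validate: a generic
penalized optimizer for the reversible MLE, brute-force Monte-Carlo
samplers for first-passage times and committors, and a textbook
strongly-connected-components routine via networkx.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def reversible_mle_optimizer(C: np.ndarray) -> np.ndarray:
    """Constrained-likelihood optimum by a generic numerical optimizer.

    Parameterizes the symmetric auxiliary matrix ``x_ij = exp(theta_ij)``
    (upper triangle including the diagonal, entries with
    ``C_ij + C_ji = 0`` pinned to zero) and maximizes
    ``sum_ij C_ij log(x_ij / x_i)`` with an analytic gradient.  The
    objective is invariant to a global rescaling of ``x``; a quadratic
    penalty on ``log(sum x)`` removes the flat direction without moving
    the optimum in ``T``.
    """
    C = np.asarray(C, float)
    n = C.shape[0]
    iu, ju = np.triu_indices(n)
    Csym = C + C.T
    free = Csym[iu, ju] > 0
    ii, jj = iu[free], ju[free]
    c_row = C.sum(axis=1)

    def unpack(theta):
        X = np.zeros((n, n))
        X[ii, jj] = np.exp(theta)
        X[jj, ii] = np.exp(theta)
        return X

    def negloglik(theta):
        X = unpack(theta)
        x_i = X.sum(axis=1)
        ll = np.sum(C[X > 0] * np.log(X[X > 0])) - np.sum(c_row * np.log(x_i))
        S = X.sum()
        pen = 1e3 * np.log(S) ** 2
        # dL/dX_ab (symmetric pair as one variable)
        ratio = np.where(X > 0, C / np.where(X > 0, X, 1.0), 0.0)
        dldx = ratio + ratio.T - (c_row / x_i)[:, None] - (c_row / x_i)[None, :]
        diag_dldx = np.diag(ratio) - c_row / x_i
        dpen_dS = 2e3 * np.log(S) / S
        g = np.empty(ii.size)
        for k, (a, b) in enumerate(zip(ii, jj)):
            if a == b:
                g[k] = (-diag_dldx[a] + dpen_dS) * X[a, b]
            else:
                g[k] = (-dldx[a, b] + 2.0 * dpen_dS) * X[a, b]
        return -ll + pen, g

    theta0 = np.log(np.maximum(Csym[ii, jj], 0.5))
    res = minimize(negloglik, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 50000, "maxcor": 50, "ftol": 1e-18, "gtol": 1e-14})
    # polish with a second pass from the solution (still the generic optimizer)
    res = minimize(negloglik, res.x, jac=True, method="CG",
                   options={"maxiter": 20000, "gtol": 1e-13})
    X = unpack(res.x)
    return X / X.sum(axis=1)[:, None]


def mc_mfpt_dtmc(T: np.ndarray, lag: float, start: np.ndarray, target, n_runs: int, rng) -> np.ndarray:
    """First-passage times of the discrete chain by direct simulation.

    ``start`` is a distribution over states; returns the per-run passage
    times (steps * lag).
    """
    n = T.shape[0]
    cum = np.cumsum(T, axis=1)
    target = np.asarray(target, int)
    states = rng.choice(n, size=n_runs, p=start)
    steps = np.zeros(n_runs)
    active = ~np.isin(states, target)
    while active.any():
        s = states[active]
        u = rng.random(s.size)
        nxt = (u[:, None] > cum[s]).sum(axis=1)
        states[active] = nxt
        steps[active] += 1
        active = ~np.isin(states, target)
    return steps * lag


def mc_mfpt_ctmc(K: np.ndarray, start_state: int, target, n_runs: int, rng) -> np.ndarray:
    """Gillespie first-passage times of the jump process (ns per run)."""
    n = K.shape[0]
    exit_rates = -np.diag(K)
    P = K.copy()
    np.fill_diagonal(P, 0.0)
    P = P / np.where(exit_rates[:, None] > 0, exit_rates[:, None], 1.0)
    cum = np.cumsum(P, axis=1)
    target = np.asarray(target, int)
    states = np.full(n_runs, start_state)
    t = np.zeros(n_runs)
    active = ~np.isin(states, target)
    while active.any():
        s = states[active]
        t[active] += rng.exponential(1.0 / exit_rates[s])
        u = rng.random(s.size)
        states[active] = (u[:, None] > cum[s]).sum(axis=1)
        active = ~np.isin(states, target)
    return t


def mc_committor(T: np.ndarray, start_state: int, A, B, n_runs: int, rng) -> float:
    """Fraction of runs hitting B before A, by direct chain simulation."""
    n = T.shape[0]
    cum = np.cumsum(T, axis=1)
    A = np.asarray(A, int)
    B = np.asarray(B, int)
    states = np.full(n_runs, start_state)
    hit_b = np.zeros(n_runs, bool)
    active = ~(np.isin(states, A) | np.isin(states, B))
    hit_b[np.isin(states, B)] = True
    while active.any():
        s = states[active]
        u = rng.random(s.size)
        states[active] = (u[:, None] > cum[s]).sum(axis=1)
        done_b = np.isin(states, B) & active
        hit_b[done_b] = True
        active = ~(np.isin(states, A) | np.isin(states, B))
    return hit_b.mean()


def scc_networkx(counts: np.ndarray):
    """All strongly connected components of the count graph (oracle)."""
    import networkx as nx

    G = nx.from_numpy_array(np.asarray(counts) > 0, create_using=nx.DiGraph)
    return [sorted(c) for c in nx.strongly_connected_components(G)]
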