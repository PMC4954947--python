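"""Bootstrap error estimation over trajectories with full re-clustering.

Errors on every derived observable (rates, free energies, timescales,
populations) come from repeating the whole discretization + estimation
chain on resampled data: in each of ``n_runs`` independent runs (default
7), a fraction ``drop_fraction`` (default 0.2) of the trajectories is
randomly eliminated without replacement, the remaining trajectories are
re-clustered and a new MSM with the same hyper-parameters (k, lag,
dimension, macrostate count) is built, and the observables are recorded.
The reported uncertainty is the sample standard deviation over runs (and
is labelled as such, not as a standard error of the mean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BootstrapSpec", "bootstrap_observables"]


@dataclass(frozen=True)
class BootstrapSpec:
    """Protocol parameters for trajectory-bootstrap error bars."""

    n_runs: int = 7
    drop_fraction: float = 0.2
    seed: int = 0
    observables: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.drop_fraction < 1.0:
            raise ValueError("drop_fraction must be in (0, 1)")
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")


def bootstrap_observables(
    estimator,
    trajectories: list,
    spec: BootstrapSpec,
    point_estimate: dict | None = None,
) -> pd.DataFrame:
    """Run the bootstrap protocol and tabulate per-observable errors.

    ``estimator(subset, run_seed)`` must rebuild the full model on the
    trajectory subset (re-clustering with the run-specific seed) and
    return a mapping observable name -> float.  Each run keeps
    ``N - floor(drop_fraction * N)`` trajectories, chosen without
    replacement by a seeded draw; runs are independent.  Runs whose
    resampled model loses ergodicity (estimator raises) are skipped with
    a warning and counted out of ``n_effective_runs``.

    Returns a DataFrame with columns observable, point, mean, sd,
    n_effective_runs.  Fixed seeds give identical partitions and errors.
    """
    N = len(trajectories)
    n_drop = int(np.floor(spec.drop_fraction * N))
    if N - n_drop < 1:
        raise ValueError("too few trajectories to bootstrap at this drop fraction")
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_runs)
    records: list[dict] = []
    n_skipped = 0
    for r, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        run_seed = int(rng.integers(2**31 - 1))
        keep = np.sort(rng.choice(N, size=N - n_drop, replace=False))
        subset = [trajectories[i] for i in keep]
        try:
            obs = estimator(subset, run_seed)
        except Exception as exc:  # a run losing ergodicity is expected occasionally
            warnings.warn(f"bootstrap run {r} skipped: {exc}", stacklevel=2)
            n_skipped += 1
            continue
        records.append(dict(obs))
    if not records:
        raise RuntimeError("every bootstrap run failed; model too fragile for this protocol")
    frame = pd.DataFrame.from_records(records)
    names = spec.observables or tuple(frame.columns)
    rows = []
    for name in names:
        vals = frame[name].to_numpy(dtype=float)
        rows.append(
            {
                "observable": name,
                "point": (point_estimate or {}).get(name, np.nan),
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                "n_effective_runs": len(vals),
            }
        )
    return pd.DataFrame(rows)
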