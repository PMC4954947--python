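"""Macrostate lumping and binding thermodynamics / kinetics.

Microstates of a reversible MSM are lumped into a few metastable
macrostates with PCCA+ (spectral simplex construction on the leading
right eigenvectors).  The bulk (unbound) macrostate is the one with the
smallest stationary-weighted mean ligand-receptor contact count and the
bound macrostate the one with the largest.  Mean first passage times
between the two, solved from the transition matrix, convert to rate
constants and a standard binding free energy:

    kon  = 1 / (MFPT_on * C_sim)        [1/(M s)]
    koff = 1 / MFPT_off                 [1/s]
    dG0  = R T ln( koff / (kon * C0) )  [kcal/mol],  C0 = 1 M

where ``C_sim`` is the single-ligand simulation concentration (copies
per box volume).  Helper conversions for frequency-based on-rates,
``Kd``-based free energies and turnover times round out the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msm import TransitionModel

__all__ = [
    "MacroModel",
    "BindingKinetics",
    "pcca_lump",
    "identify_bulk_bound",
    "mfpt",
    "committor",
    "rates_from_mfpt",
    "on_rate_from_frequency",
    "free_energy_from_kd",
    "timescale_from_rate",
    "format_timescale",
    "concentration_from_box",
]

GAS_CONSTANT_KCAL = 1.9872e-3  # kcal/(mol K)
AVOGADRO = 6.02214e23  # 1/mol
STANDARD_CONC = 1.0  # M


@dataclass
class MacroModel:
    """PCCA+ macrostate decomposition of a transition model.

    memberships : (n_active, M) fuzzy memberships, rows sum to 1
    crisp_assignment : microstate (active index) -> macrostate
    macro_pi : stationary probability aggregated per macrostate
    labels : macrostate -> 'bulk' | 'bound' | 'intermediate' (set by
        :func:`identify_bulk_bound`)
    """

    memberships: np.ndarray
    crisp_assignment: np.ndarray
    macro_pi: np.ndarray
    labels: dict[int, str] = field(default_factory=dict)

    @property
    def n_macrostates(self) -> int:
        return self.memberships.shape[1]

    def members(self, macro: int) -> np.ndarray:
        return np.flatnonzero(self.crisp_assignment == macro)

    @property
    def bulk(self) -> int:
        return next(m for m, lab in self.labels.items() if lab == "bulk")

    @property
    def bound(self) -> int:
        return next(m for m, lab in self.labels.items() if lab == "bound")


@dataclass
class BindingKinetics:
    """Binding rate constants and standard free energy.

    mfpt_matrix is macrostate-to-macrostate, in seconds, zero diagonal.
    """

    kon: float  # 1/(M s)
    koff: float  # 1/s
    dG0: float  # kcal/mol
    concentration: float  # M (simulation, single ligand copy)
    temperature: float  # K
    mfpt_matrix: np.ndarray | None = None  # s
    standard_conc: float = STANDARD_CONC

    def __post_init__(self) -> None:
        if self.kon <= 0 or self.koff <= 0:
            raise ValueError("kon and koff must be positive")
        expected = (
            GAS_CONSTANT_KCAL
            * self.temperature
            * np.log(self.koff / (self.kon * self.standard_conc))
        )
        if abs(expected - self.dG0) > 1e-9:
            raise ValueError("dG0 inconsistent with kon/koff fields")

    @property
    def kd(self) -> float:
        return self.koff / self.kon


def _right_eigenvectors(model: TransitionModel, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-m real right eigenvectors via the symmetrized reversible form."""
    pi = model.pi
    sqrt_pi = np.sqrt(pi)
    S = sqrt_pi[:, None] * model.T / sqrt_pi[None, :]
    S = 0.5 * (S + S.T)  # reversible => symmetric up to round-off
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1][:m]
    psi = evecs[:, order] / sqrt_pi[:, None]
    psi[:, 0] = 1.0  # stationary right eigenvector, fixed sign and scale
    return evals[order], psi


def pcca_lump(model: TransitionModel, n_macrostates: int) -> MacroModel:
    """PCCA+ lumping of kinetically similar microstates.

    Builds fuzzy memberships from the top-M right eigenvectors by the
    inner-simplex construction: M maximally spread microstates serve as
    simplex vertices, and every microstate's eigenvector coordinates are
    expressed as a convex-like combination of the vertices.  Small
    negative memberships from round-off are clipped and rows renormalized.
    Crisp assignment is by maximal membership, ties to the lower
    macrostate index.
    """
    M = n_macrostates
    if M < 2:
        raise ValueError("need at least 2 macrostates")
    if M > model.n_states:
        raise ValueError("more macrostates than microstates")
    evals, psi = _right_eigenvectors(model, M)
    if np.any(np.abs(np.diff(evals)) < 1e-14):
        raise ValueError("degenerate eigenvalues at the requested number of macrostates")
    # inner-simplex vertex search
    idx = np.zeros(M, dtype=int)
    work = psi.copy()
    norms = np.linalg.norm(work, axis=1)
    idx[0] = int(np.argmax(norms))
    work = work - work[idx[0]]
    for j in range(1, M):
        norms = np.linalg.norm(work, axis=1)
        idx[j] = int(np.argmax(norms))
        v = work[idx[j]]
        nv = np.linalg.norm(v)
        if nv < 1e-14:
            raise ValueError("simplex construction degenerate: too few distinct kinetic centers")
        v = v / nv
        work = work - np.outer(work @ v, v)
    A = np.linalg.inv(psi[idx])
    chi = psi @ A
    chi = np.clip(chi, 0.0, None)
    chi = chi / chi.sum(axis=1, keepdims=True)
    crisp = np.argmax(chi, axis=1)  # argmax takes the first (lowest) index on ties
    macro_pi = np.array([model.pi[crisp == m].sum() for m in range(M)])
    return MacroModel(memberships=chi, crisp_assignment=crisp, macro_pi=macro_pi)


def identify_bulk_bound(macro: MacroModel, contact_counts: np.ndarray, pi: np.ndarray) -> dict[int, str]:
    """Label macrostates as bulk / bound / intermediate.

    ``contact_counts`` is the mean ligand-receptor contact count per
    microstate (active indexing).  The bulk macrostate minimizes and the
    bound macrostate maximizes the stationary-weighted mean contact
    count; labels are attached to the model and returned.
    """
    contact_counts = np.asarray(contact_counts, float)
    M = macro.n_macrostates
    means = np.empty(M)
    for m in range(M):
        mem = macro.members(m)
        if mem.size == 0:
            raise ValueError(f"macrostate {m} has no member microstates")
        w = pi[mem] / pi[mem].sum()
        means[m] = float(w @ contact_counts[mem])
    bulk = int(np.argmin(means))
    bound = int(np.argmax(means))
    if bulk == bound:
        raise ValueError("bulk and bound resolve to the same macrostate (degenerate contacts)")
    labels = {m: "intermediate" for m in range(M)}
    labels[bulk] = "bulk"
    labels[bound] = "bound"
    macro.labels = labels
    return labels


def _as_active_sets(model: TransitionModel, source, target) -> tuple[np.ndarray, np.ndarray]:
    src = np.unique(np.atleast_1d(np.asarray(source, int)))
    tgt = np.unique(np.atleast_1d(np.asarray(target, int)))
    if src.size == 0 or tgt.size == 0:
        raise ValueError("source and target sets must be non-empty")
    if src.max() >= model.n_states or tgt.max() >= model.n_states:
        raise ValueError("state index outside the active set")
    return src, tgt


def mfpt(model: TransitionModel, source, target) -> float:
    """Mean first passage time (ns) from source into target microstates.

    Solves ``m_i = lag + sum_{j not in target} T_ij m_j`` with ``m = 0``
    on the target; the source value averages ``m`` with the stationary
    distribution restricted to (and renormalized over) the source set.
    Indices refer to the model's active set.
    """
    src, tgt = _as_active_sets(model, source, target)
    if np.intersect1d(src, tgt).size:
        if set(src.tolist()) <= set(tgt.tolist()):
            return 0.0
        raise ValueError("source and target sets must be disjoint")
    n = model.n_states
    non_target = np.setdiff1d(np.arange(n), tgt)
    Tnn = model.T[np.ix_(non_target, non_target)]
    A = np.eye(non_target.size) - Tnn
    try:
        m_non = np.linalg.solve(A, np.full(non_target.size, model.lag))
    except np.linalg.LinAlgError as exc:
        raise ValueError("target unreachable from the source set") from exc
    if np.any(m_non < -1e-9) or not np.all(np.isfinite(m_non)):
        raise ValueError("target unreachable from the source set")
    m = np.zeros(n)
    m[non_target] = m_non
    w = model.pi[src] / model.pi[src].sum()
    return float(w @ m[src])


def mfpt_matrix_macro(model: TransitionModel, macro: MacroModel) -> np.ndarray:
    """Macrostate-to-macrostate MFPT matrix in ns (zero diagonal)."""
    M = macro.n_macrostates
    out = np.zeros((M, M))
    for a in range(M):
        for b in range(M):
            if a != b:
                out[a, b] = mfpt(model, macro.members(a), macro.members(b))
    return out


def committor(model: TransitionModel, A, B) -> np.ndarray:
    """Forward committor: probability of reaching B before A.

    ``q = 0`` on A, ``q = 1`` on B, and harmonic with respect to ``T``
    elsewhere (linear solve).  Indices refer to the active set.
    """
    A_set, B_set = _as_active_sets(model, A, B)
    if np.intersect1d(A_set, B_set).size:
        raise ValueError("A and B must be disjoint")
    n = model.n_states
    q = np.zeros(n)
    q[B_set] = 1.0
    C_set = np.setdiff1d(np.arange(n), np.concatenate([A_set, B_set]))
    if C_set.size:
        Tcc = model.T[np.ix_(C_set, C_set)]
        rhs = model.T[np.ix_(C_set, B_set)].sum(axis=1)
        q[C_set] = np.linalg.solve(np.eye(C_set.size) - Tcc, rhs)
    return q


def rates_from_mfpt(
    mfpt_on_ns: float,
    mfpt_off_ns: float,
    concentration: float,
    temperature: float = 298.0,
    mfpt_matrix_ns: np.ndarray | None = None,
) -> BindingKinetics:
    """Convert bulk->bound / bound->bulk MFPTs into kon, koff, dG0.

    ``mfpt_on_ns`` is a single-ligand quantity, so the pseudo-first-order
    on-rate ``1 / MFPT_on`` divides by the single-copy simulation
    concentration (M) to give the bimolecular ``kon``.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if not (mfpt_on_ns > 0 and np.isfinite(mfpt_on_ns)) or not (mfpt_off_ns > 0 and np.isfinite(mfpt_off_ns)):
        raise ValueError("MFPTs must be positive and finite")
    mfpt_on_s = mfpt_on_ns * 1e-9
    mfpt_off_s = mfpt_off_ns * 1e-9
    kon = 1.0 / (mfpt_on_s * concentration)
    koff = 1.0 / mfpt_off_s
    dG0 = GAS_CONSTANT_KCAL * temperature * np.log(koff / (kon * STANDARD_CONC))
    return BindingKinetics(
        kon=kon,
        koff=koff,
        dG0=float(dG0),
        concentration=concentration,
        temperature=temperature,
        mfpt_matrix=None if mfpt_matrix_ns is None else mfpt_matrix_ns * 1e-9,
    )


def on_rate_from_frequency(binding_frequency_per_us: float, concentration: float) -> float:
    """Bimolecular on-rate (1/(M s)) from a binding frequency (1/us).

    Divides the per-second event frequency by the ligand concentration;
    e.g. 0.01 events/us at 54 mM gives 1.85e5 per molar per second.
    """
    if binding_frequency_per_us <= 0:
        raise ValueError("binding frequency must be positive")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    return binding_frequency_per_us * 1e6 / concentration


def free_energy_from_kd(kd: float, temperature: float = 298.0) -> float:
    """Standard binding free energy ``R T ln(Kd / C0)`` in kcal/mol."""
    if kd <= 0:
        raise ValueError("Kd must be positive")
    return GAS_CONSTANT_KCAL * temperature * np.log(kd / STANDARD_CONC)


def timescale_from_rate(rate_per_s: float) -> float:
    """Characteristic time (seconds) of a first-order rate: ``1 / rate``."""
    if rate_per_s <= 0:
        raise ValueError("rate must be positive")
    return 1.0 / rate_per_s


def format_timescale(seconds: float, sig: int = 2) -> str:
    """Human-readable time with SI prefix, e.g. ``1/22 s^-1 -> '45 ms'``."""
    for factor, unit in ((1.0, "s"), (1e-3, "ms"), (1e-6, "us"), (1e-9, "ns")):
        if seconds >= factor:
            val = seconds / factor
            return f"{float(f'%.{sig}g' % val):g} {unit}"
    return f"{seconds:.{sig}g} s"


def concentration_from_box(n_copies: int, box_volume_l: float) -> float:
    """Molar concentration of ``n_copies`` molecules in ``box_volume_l`` litres."""
    if n_copies <= 0 or box_volume_l <= 0:
        raise ValueError("n_copies and box_volume must be positive")
    return n_copies / (AVOGADRO * box_volume_l)


def population_free_energy(
    pi_bound: float,
    pi_unbound: float,
    concentration: float,
    temperature: float = 298.0,
) -> float:
    """dG0 from stationary populations with standard-state correction.

    ``Kd = (pi_unbound / pi_bound) * C_sim`` for a single ligand copy, so
    ``dG0 = R T ln(Kd / C0)``.  Used as an internal consistency check
    against the rate-ratio route.
    """
    if pi_bound <= 0 or pi_unbound <= 0:
        raise ValueError("populations must be positive")
    kd = pi_unbound / pi_bound * concentration
    return free_energy_from_kd(kd, temperature)
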