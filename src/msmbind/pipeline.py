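"""End-to-end orchestration: featurize -> TICA -> cluster -> MSM -> kinetics.

The pipeline runs identically on real trajectory bundles (contact-map
features from coordinates) and on synthetic benchmark presets (embedded
jump-process trajectories with analytic ground truth).  A single
:class:`PipelineConfig` carries every tunable parameter; the same
configuration drives the point estimate and each bootstrap replica, and
its hash is stamped into every output file for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cluster import assign, kcenters_fit, split_by_flag
from .featurize import (
    CoordinationFlags,
    FeatureTrajectory,
    contact_map_features,
    coordination_flags,
    read_bundle,
    split_ligand_copies,
    write_feature_trajectory,
)
from .kinetics import (
    identify_bulk_bound,
    mfpt,
    mfpt_matrix_macro,
    pcca_lump,
    population_free_energy,
    rates_from_mfpt,
)
from .msm import count_transitions, estimate_reversible, implied_timescales, lag_scan
from .synthetic import embed_states, preset, sample_ctmc_trajectories
from .tica import fit_tica, transform_tica
from .uncertainty import BootstrapSpec, bootstrap_observables

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "analyze_trajectories"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the analysis chain.

    Distances in Å, times in ns, temperature in K, concentration in M.
    ``n_clusters`` has no universal default (it is data-set specific) and
    must be set before an analysis runs; the synthetic presets inject a
    suitable value.  ``concentration`` is the single-ligand simulation
    concentration used to convert the on-MFPT into a bimolecular rate;
    presets derive it from their box volume when it is not given.
    """

    contact_cutoff: float = 8.0
    coordination_cutoff: float = 4.0
    tica_lag: float = 2.0
    tica_dim: int = 3
    n_clusters: int | None = None
    msm_lag: float | None = None
    lag_scan: tuple[float, ...] = ()
    n_macrostates: int = 5
    temperature: float = 298.0
    concentration: float | None = None
    bootstrap_runs: int = 7
    bootstrap_drop_fraction: float = 0.2
    seed: int = 1
    n_traj: int = 100
    n_frames: int = 2000

    def __post_init__(self) -> None:
        positive = {
            "contact_cutoff": self.contact_cutoff,
            "coordination_cutoff": self.coordination_cutoff,
            "tica_lag": self.tica_lag,
            "tica_dim": self.tica_dim,
            "n_macrostates": self.n_macrostates,
            "temperature": self.temperature,
            "bootstrap_runs": self.bootstrap_runs,
            "n_traj": self.n_traj,
            "n_frames": self.n_frames,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        for name, value in (("n_clusters", self.n_clusters), ("msm_lag", self.msm_lag),
                            ("concentration", self.concentration)):
            if value is not None and value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not 0 < self.bootstrap_drop_fraction < 1:
            raise ValueError("bootstrap_drop_fraction must be in (0, 1)")
        object.__setattr__(self, "lag_scan", tuple(float(x) for x in self.lag_scan))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def bootstrap_spec(self) -> BootstrapSpec:
        return BootstrapSpec(
            n_runs=self.bootstrap_runs,
            drop_fraction=self.bootstrap_drop_fraction,
            seed=self.seed,
        )


def validate_config(path_or_mapping) -> PipelineConfig:
    """Load and normalize a JSON/YAML config file (or mapping).

    Unknown keys are an error, not a warning; defaults fill the rest.
    Normalization is idempotent.
    """
    if isinstance(path_or_mapping, PipelineConfig):
        return path_or_mapping
    if isinstance(path_or_mapping, dict):
        raw = dict(path_or_mapping)
    else:
        text = Path(path_or_mapping).read_text()
        if str(path_or_mapping).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text) or {}
        else:
            raw = json.loads(text) if text.strip() else {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _contact_counts_per_microstate(
    ftrajs: list[FeatureTrajectory],
    dtrajs,
    n_microstates: int,
) -> np.ndarray:
    """Mean per-frame total feature magnitude for each microstate.

    For binary contact maps this is the mean number of receptor contacts;
    for synthetic embeddings the centroids are contact-map-like, so the
    same statistic orders states from bulk (near zero) to bound (max).
    """
    sums = np.zeros(n_microstates)
    counts = np.zeros(n_microstates)
    for ft, dt in zip(ftrajs, dtrajs):
        per_frame = ft.frames.sum(axis=1)
        np.add.at(sums, dt.states, per_frame)
        np.add.at(counts, dt.states, 1.0)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1.0), 0.0)


def analyze_trajectories(
    ftrajs: list[FeatureTrajectory],
    config: PipelineConfig,
    flags: list[CoordinationFlags] | None = None,
    cluster_seed: int | None = None,
) -> dict:
    """Run TICA -> k-centers -> (flag split) -> reversible MSM -> kinetics.

    Returns a dict with the fitted models and an ``observables`` mapping
    (kon_M_s, koff_s, dG0_kcal_mol, dG0_populations_kcal_mol, tau2_ns,
    mfpt_on_ns, mfpt_off_ns).  ``cluster_seed`` defaults to the config
    seed; the bootstrap passes run-specific seeds here.
    """
    if config.n_clusters is None:
        raise ValueError("config.n_clusters is required for an analysis run")
    if config.msm_lag is None:
        raise ValueError("config.msm_lag is required for an analysis run")
    if config.concentration is None:
        raise ValueError("config.concentration is required for kinetics")
    seed = config.seed if cluster_seed is None else cluster_seed

    tica_model = fit_tica(ftrajs, lag=config.tica_lag, dim=config.tica_dim)
    projected = [transform_tica(tica_model, t) for t in ftrajs]
    cluster_model = kcenters_fit(projected, k=config.n_clusters, seed=seed)
    dtrajs = [assign(cluster_model, t) for t in projected]
    if flags is not None:
        cluster_model, dtrajs = split_by_flag(cluster_model, dtrajs, flags)

    counts = count_transitions(dtrajs, lag=config.msm_lag, n_states=cluster_model.n_microstates)
    model = estimate_reversible(counts)
    spectrum = implied_timescales(model)

    micro_contacts = _contact_counts_per_microstate(ftrajs, dtrajs, cluster_model.n_microstates)
    macro = pcca_lump(model, config.n_macrostates)
    identify_bulk_bound(macro, micro_contacts[model.active_set], model.pi)
    bulk_members = macro.members(macro.bulk)
    bound_members = macro.members(macro.bound)
    mfpt_on = mfpt(model, bulk_members, bound_members)
    mfpt_off = mfpt(model, bound_members, bulk_members)
    kin = rates_from_mfpt(
        mfpt_on,
        mfpt_off,
        concentration=config.concentration,
        temperature=config.temperature,
        mfpt_matrix_ns=mfpt_matrix_macro(model, macro),
    )
    dG0_pop = population_free_energy(
        pi_bound=float(macro.macro_pi[macro.bound]),
        pi_unbound=float(macro.macro_pi[macro.bulk]),
        concentration=config.concentration,
        temperature=config.temperature,
    )
    tau2 = float(spectrum.timescales[1]) if spectrum.timescales.size > 1 else float("nan")
    observables = {
        "kon_M_s": kin.kon,
        "koff_s": kin.koff,
        "dG0_kcal_mol": kin.dG0,
        "dG0_populations_kcal_mol": dG0_pop,
        "tau2_ns": tau2,
        "mfpt_on_ns": mfpt_on,
        "mfpt_off_ns": mfpt_off,
    }
    return {
        "tica": tica_model,
        "clusters": cluster_model,
        "dtrajs": dtrajs,
        "counts": counts,
        "msm": model,
        "spectrum": spectrum,
        "macro": macro,
        "kinetics": kin,
        "observables": observables,
    }


def _synthetic_inputs(preset_name: str, config: PipelineConfig):
    system = preset(preset_name)
    dtrajs_true = sample_ctmc_trajectories(system, config.n_traj, config.n_frames, seed=config.seed)
    embed_seeds = np.random.SeedSequence(config.seed + 1).spawn(len(dtrajs_true))
    ftrajs = [
        embed_states(
            dt,
            system.embedding,
            seed=int(np.random.default_rng(ss).integers(2**31 - 1)),
            frame_dt=system.frame_dt,
            source=("synthetic", i),
        )
        for i, (dt, ss) in enumerate(zip(dtrajs_true, embed_seeds))
    ]
    if config.concentration is None and system.concentration is not None:
        config = config.replace(concentration=system.concentration)
    return system, ftrajs, config


def _featurize_bundle(bundle_path, config: PipelineConfig):
    bundle = read_bundle(bundle_path)
    streams = split_ligand_copies(bundle)
    ftrajs = [contact_map_features(s, cutoff=config.contact_cutoff) for s in streams]
    flags = None
    if bundle.ion_atoms.size:
        flags = [coordination_flags(s, cutoff=config.coordination_cutoff) for s in streams]
    return ftrajs, flags


def run_pipeline(config: PipelineConfig, source: str, outdir) -> Path:
    """Execute the full workflow and write a report directory.

    ``source`` is either a synthetic preset name (``twostate``,
    ``binding5``, ``metastable-blocks``) or a path to a trajectory
    bundle.  Artifacts land under ``outdir`` in features/, tica/,
    clusters/, msm/, kinetics/ and bootstrap/; every JSON output carries
    the config hash, the seed and the package version.  Returns the
    report directory path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = {"config_hash": config.config_hash, "seed": config.seed, "version": __version__}

    from .synthetic import PRESET_NAMES

    flags = None
    if source in PRESET_NAMES:
        logger.info("generating synthetic data from preset %r", source)
        system, ftrajs, config = _synthetic_inputs(source, config)
        if config.n_clusters is None:
            config = config.replace(n_clusters=max(5 * system.rate_matrix.n_states, 25))
        if config.msm_lag is None:
            config = config.replace(msm_lag=10 * system.frame_dt)
    else:
        ftrajs, flags = _featurize_bundle(source, config)

    feat_dir = outdir / "features"
    feat_dir.mkdir(exist_ok=True)
    for i, ft in enumerate(ftrajs[: min(len(ftrajs), 1000)]):
        write_feature_trajectory(feat_dir / f"traj_{i:04d}.csv", ft, extra_meta={"provenance": provenance})

    result = analyze_trajectories(ftrajs, config, flags=flags)

    tica_dir = outdir / "tica"
    tica_dir.mkdir(exist_ok=True)
    result["tica"].to_json(tica_dir / "tica_model.json")

    cl_dir = outdir / "clusters"
    cl_dir.mkdir(exist_ok=True)
    result["clusters"].to_json(cl_dir / "cluster_model.json")
    for i, dt in enumerate(result["dtrajs"]):
        np.savetxt(cl_dir / f"dtraj_{i:04d}.txt", dt.states, fmt="%d")

    msm_dir = outdir / "msm"
    msm_dir.mkdir(exist_ok=True)
    model = result["msm"]
    msm_payload = {
        "T": model.T.tolist(),
        "pi": model.pi.tolist(),
        "lag_ns": model.lag,
        "active_set": model.active_set.tolist(),
        "loglik": model.loglik,
        "provenance": provenance,
    }
    (msm_dir / "transition_model.json").write_text(json.dumps(msm_payload))
    if len(config.lag_scan) >= 2:
        table, suggested = lag_scan(result["dtrajs"], list(config.lag_scan))
        table.to_csv(msm_dir / "lag_scan.csv", index=False)
        (msm_dir / "suggested_lag.json").write_text(
            json.dumps({"suggested_lag_ns": suggested, "provenance": provenance})
        )

    kin_dir = outdir / "kinetics"
    kin_dir.mkdir(exist_ok=True)
    kin = result["kinetics"]
    macro = result["macro"]
    kin_payload = {
        "kon_M_s": kin.kon,
        "koff_s": kin.koff,
        "dG0_kcal_mol": kin.dG0,
        "mfpt_s": kin.mfpt_matrix.tolist() if kin.mfpt_matrix is not None else None,
        "labels": {str(m): lab for m, lab in macro.labels.items()},
        "temperature_K": kin.temperature,
        "concentration_M": kin.concentration,
        "provenance": provenance,
    }
    (kin_dir / "kinetics.json").write_text(json.dumps(kin_payload, indent=1, sort_keys=True))

    boot_dir = outdir / "bootstrap"
    boot_dir.mkdir(exist_ok=True)
    spec = config.bootstrap_spec()

    paired = list(zip(ftrajs, flags)) if flags is not None else [(ft, None) for ft in ftrajs]

    def _estimator(subset, run_seed):
        fts = [ft for ft, _ in subset]
        fls = [fl for _, fl in subset] if flags is not None else None
        return analyze_trajectories(fts, config, flags=fls, cluster_seed=run_seed)["observables"]

    if len(ftrajs) >= 5:
        table = bootstrap_observables(_estimator, paired, spec, point_estimate=result["observables"])
        table.to_csv(boot_dir / "errors.csv", index=False)
        kin_payload["errors"] = {
            row["observable"]: {"mean": row["mean"], "sd": row["sd"]} for _, row in table.iterrows()
        }
        (kin_dir / "kinetics.json").write_text(json.dumps(kin_payload, indent=1, sort_keys=True))

    summary = outdir / "summary.txt"
    lines = [
        f"msmbind {__version__}  config {config.config_hash}  seed {config.seed}",
        f"source: {source}",
        f"trajectories: {len(ftrajs)}   microstates: {result['clusters'].n_microstates}"
        f"   active: {model.n_states}",
        f"macrostates: {macro.n_macrostates}  labels: {macro.labels}",
        f"kon  = {kin.kon:.3e} 1/(M s)",
        f"koff = {kin.koff:.3e} 1/s",
        f"dG0  = {kin.dG0:.2f} kcal/mol (rate ratio)",
        f"tau2 = {result['observables']['tau2_ns']:.1f} ns",
    ]
    summary.write_text("\n".join(lines) + "\n")
    logger.info("report written to %s", outdir)
    return outdir
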