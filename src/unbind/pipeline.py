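"""Orchestration: trajectories -> contacts -> kinetics -> report,
hills -> free-energy profile, structures -> NAC table.

All protocol constants live in :class:`PipelineConfig` with the defaults
the analysis protocol prescribes (5 A contact cutoff, 90th-percentile
pocket, 10 A dissociation threshold, half-ensemble blocks, diffusion-
limited kon of 1e9 /M/s, 300 K, bias factor 35).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import __version__
from . import contacts as ct
from . import kinetics as kn
from . import metad as fes

logger = logging.getLogger("unbind")

__all__ = ["PipelineConfig", "run_unbinding", "run_fes", "run_geometry"]


@dataclass
class PipelineConfig:
    """Resolved parameter registry for a full analysis run."""

    contact_cutoff_A: float = 5.0
    pocket_percentile: float = 90.0
    dissociation_threshold_A: float = 10.0
    bound_criterion: str = "pocket-distance"
    block_size: int | None = None          # None -> half the ensemble
    fit_model: str = "A"
    kon_per_M_s: float = 1e9
    temperature_K: float = 300.0
    gamma: float = 35.0
    grid_min: float = -2.0
    grid_max: float = 2.0
    grid_points: int = 601
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("contact_cutoff_A", "pocket_percentile",
                     "dissociation_threshold_A", "kon_per_M_s",
                     "temperature_K"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gamma <= 1:
            raise ValueError("gamma must exceed 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["version"] = __version__
        return d


def run_unbinding(ensemble: ct.TrajectoryEnsemble,
                  config: PipelineConfig | None = None,
                  outdir=None) -> dict:
    """Contacts -> pocket -> bound series -> block-averaged kinetic fit.

    Returns the full report as a dict; with ``outdir`` the pocket JSON,
    per-trajectory bound CSVs and the fit report are also written.
    """
    config = config or PipelineConfig()
    logger.info("contacts: %d trajectories, cutoff %.1f A",
                ensemble.n_trajectories, config.contact_cutoff_A)
    profile = ct.compute_contacts(ensemble, config.contact_cutoff_A)
    pocket = ct.define_pocket(profile, config.pocket_percentile)
    logger.info("pocket: %s (threshold %.3g)", pocket.labels(),
                pocket.percentile_value)

    series = ct.ligand_pocket_distance_series(ensemble, pocket)
    bound = [
        ct.classify_bound(s, config.dissociation_threshold_A,
                          ensemble.frame_interval_ns,
                          config.bound_criterion)
        for s in series
    ]
    model = kn.DissociationKinetics.from_bound_series(bound)
    results = model.fit(model=config.fit_model, block=True,
                        block_size=config.block_size)
    report = {
        "config": config.to_dict(),
        "pocket": {
            "residues": pocket.labels(),
            "percentile": pocket.percentile,
            "percentile_value": pocket.percentile_value,
        },
        "records": [
            {"trajectory_id": r.trajectory_id,
             "time_ns": None if r.censored else r.time_ns,
             "censored": r.censored,
             "censor_time_ns": r.censor_time_ns}
            for r in model.records
        ],
        "fit": results.to_dict(config.kon_per_M_s, config.temperature_K),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        import pandas as pd
        for i, (s, b) in enumerate(zip(series, bound)):
            pd.DataFrame({
                "time_ns": np.arange(len(s)) * ensemble.frame_interval_ns,
                "pocket_distance_A": s,
                "bound": b.bound,
            }).to_csv(outdir / f"bound_{i:03d}.csv", index=False)
        (outdir / "summary.txt").write_text(
            results.summary(config.kon_per_M_s, config.temperature_K) + "\n")
    return report


def run_fes(hills_paths, config: PipelineConfig | None = None,
            checkpoints=None, reactant_window=None, product_window=None,
            outdir=None) -> dict:
    """Merge walker HILLS files, reconstruct the PMF, extract energetics."""
    config = config or PipelineConfig()
    paths = [Path(p) for p in hills_paths]
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(f"HILLS file not found: {p}")
    walkers = [fes.parse_hills(p) for p in paths]
    merged = fes.merge_walkers(walkers)
    grid = np.linspace(config.grid_min, config.grid_max, config.grid_points)
    profile = fes.pmf(merged, grid, config.gamma)
    report = {
        "config": config.to_dict(),
        "n_walkers": len(walkers),
        "n_hills": int(len(merged)),
        "gamma": config.gamma,
    }
    if reactant_window and product_window:
        barrier, dg = fes.barrier_and_dg(profile, reactant_window,
                                         product_window)
        report["barrier_kcal"] = barrier
        report["dg_rxn_kcal"] = dg
    if checkpoints:
        _, dev = fes.convergence_series(merged, grid, checkpoints,
                                        config.gamma)
        report["convergence_max_dev_kcal"] = dev.tolist()
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        profile.to_frame().to_csv(outdir / "profile.csv", index=False)
        (outdir / "fes.json").write_text(json.dumps(report, indent=2))
    report["profile"] = profile
    return report


def run_geometry(entries, config: PipelineConfig | None = None,
                 outdir=None):
    """NAC geometry table for (label, pdb_path, spec) entries."""
    from . import geometry as geo

    complexes = [(label, geo.read_structure(path), spec)
                 for label, path, spec in entries]
    table = geo.nac_report(complexes)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "nac_report.csv", index=False)
    return table
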