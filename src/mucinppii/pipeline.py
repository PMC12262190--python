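"""End-to-end orchestration of the ensemble-analysis chain.

``run_pipeline`` chains the library modules in the analysis order used for
mucin-domain model peptides: sample (or replica-exchange simulate) ->
discard burn-in -> backbone build, dihedrals and Rg -> convergence check ->
free-energy surface -> per-residue populations with bootstrap CIs ->
glycosylated-vs-non-glycosylated comparison.  Everything is driven by one
:class:`PipelineConfig` with explicit seeds, so reruns are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .convergence import convergence_report
from .ensemble import (DEFAULT_GLYCO_SHIFT, DEFAULT_KAPPA, make_ladder,
                       peptide_ensemble_specs, remd_run, sample_ensemble)
from .peptide import (MUCIN_PEPTIDE_EXCLUDED_SITES, MUCIN_PEPTIDE_FIRST_RESIDUE,
                      MUCIN_PEPTIDE_SEQUENCE, PeptideModel, assign_glyco_sites,
                      build_backbone_frames)
from .rama import (RegionSet, compare_populations, population_ci,
                   surface_from_trajectory)
from .trajectory import BackboneTrajectory, write_dihedral_table

log = logging.getLogger(__name__)

#: Replica-ladder presets: the two protocol-scale ladders plus a desk-scale
#: toy ladder.
LADDER_PRESETS = {
    "full-64": (300.0, 455.95, 64),
    "half-32": (300.0, 452.32, 32),
    "toy-8": (300.0, 455.95, 8),
}


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end synthetic-ensemble analysis run."""

    seed: int | None = None
    sequence: str = MUCIN_PEPTIDE_SEQUENCE
    first_residue_number: int = MUCIN_PEPTIDE_FIRST_RESIDUE
    excluded_glyco_sites: tuple[int, ...] = tuple(
        sorted(MUCIN_PEPTIDE_EXCLUDED_SITES))
    mode: str = "sample"                 # "sample" (i.i.d.) or "remd"
    n_frames: int = 10000                # sample mode frames / remd sweeps
    kappa: float = DEFAULT_KAPPA
    glyco_weight_shift: float = DEFAULT_GLYCO_SHIFT
    ladder_preset: str = "toy-8"
    exchange_interval: int = 10
    proposal_step: float = 25.0
    discard_fraction: float = 0.5        # burn-in: drop the first half
    n_bins_fes: int = 72
    n_bins_rg: int = 50
    overlap_threshold: float = 0.90
    temperature: float = 300.0
    alpha: float = 0.05
    block_length: int = 10
    n_boot: int = 1000

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("config must set an explicit seed")
        if self.mode not in ("sample", "remd"):
            raise ValueError("mode must be 'sample' or 'remd'")
        if self.ladder_preset not in LADDER_PRESETS:
            raise ValueError(f"unknown ladder preset {self.ladder_preset!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if "excluded_glyco_sites" in payload:
            payload["excluded_glyco_sites"] = tuple(
                payload["excluded_glyco_sites"])
        return cls(**payload)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """In-memory results of one pipeline run."""

    config: PipelineConfig
    trajectories: dict
    convergence: dict
    fes: dict
    populations: dict
    comparison: object
    manifest: dict = field(default_factory=dict)


def _generate(config: PipelineConfig, model: PeptideModel, seed: int):
    specs = peptide_ensemble_specs(model, config.kappa,
                                   config.glyco_weight_shift)
    kwargs = dict(residue_numbers=model.residue_numbers,
                  residue_types=list(model.sequence))
    if config.mode == "sample":
        return sample_ensemble(specs, config.n_frames, seed, **kwargs)
    ladder = make_ladder(*LADDER_PRESETS[config.ladder_preset])
    result = remd_run(specs, ladder, config.n_frames,
                      config.exchange_interval, config.proposal_step,
                      seed, **kwargs)
    log.info("remd exchange acceptance: %s",
             {k: round(v, 3) for k, v in result.acceptance_by_pair.items()})
    return result.trajectories[0]        # analysis temperature (ladder base)


def run_pipeline(config: PipelineConfig, outdir=None) -> ReportBundle:
    """Run the full analysis chain for the glycosylated and
    non-glycosylated variants of the configured peptide."""
    root = np.random.SeedSequence(config.seed)
    seeds = {}
    for name, child in zip(
            ("gen_plain", "gen_glyco", "ci_plain", "ci_glyco", "compare"),
            root.spawn(5)):
        seeds[name] = int(child.generate_state(1)[0] % (2 ** 31))

    glyco_sites = assign_glyco_sites(config.sequence,
                                     config.first_residue_number,
                                     config.excluded_glyco_sites)
    variants = {
        "plain": PeptideModel(config.sequence, config.first_residue_number),
        "glyco": PeptideModel(config.sequence, config.first_residue_number,
                              glyco_sites),
    }
    regions = RegionSet()
    trajectories, conv, fes, pops = {}, {}, {}, {}
    for name, model in variants.items():
        log.info("pipeline stage: generate (%s)", name)
        traj = _generate(config, model, seeds[f"gen_{name}"])
        traj = traj.discard_burn_in(config.discard_fraction)
        log.info("stage generate(%s): %d frames x %d residues kept",
                 name, traj.n_frames, traj.n_residues)
        trajectories[name] = traj

        coords = build_backbone_frames(traj.phi, traj.psi)
        backbone = BackboneTrajectory(coords,
                                      residue_numbers=model.residue_numbers,
                                      residue_types=list(model.sequence))
        conv[name] = convergence_report(
            backbone, n_bins=config.n_bins_rg,
            threshold=config.overlap_threshold)
        fes[name] = surface_from_trajectory(
            traj, config.n_bins_fes, config.temperature)
        pops[name] = population_ci(
            traj, regions, config.block_length, config.n_boot,
            seeds[f"ci_{name}"])

    comparison = compare_populations(
        trajectories["plain"], trajectories["glyco"], regions, config.alpha,
        config.block_length, config.n_boot, seeds["compare"])

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "versions": {"mucinppii": __version__,
                     "numpy": np.__version__},
        "stages": {name: {"n_frames": trajectories[name].n_frames,
                          "n_residues": trajectories[name].n_residues}
                   for name in trajectories},
    }
    bundle = ReportBundle(config, trajectories, conv, fes, pops, comparison,
                          manifest)
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _write_bundle(bundle: ReportBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for name, traj in bundle.trajectories.items():
        write_dihedral_table(outdir / f"dihedrals_{name}.tsv", traj)
        bundle.fes[name].write_tsv(outdir / f"fes_{name}.tsv")
        bundle.fes[name].write_json(outdir / f"fes_{name}.json")
        bundle.convergence[name].to_json(outdir / f"convergence_{name}.json")
        bundle.populations[name].to_csv(
            outdir / f"populations_{name}.tsv", sep="\t", index=False,
            float_format="%.10g")
    bundle.comparison.to_csv(outdir / "comparison.tsv", sep="\t",
                             index=False, float_format="%.10g")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, default=str)
    log.info("wrote report bundle to %s", outdir)
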