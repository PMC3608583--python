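"""Configuration-driven orchestration of the full groove analysis.

A :class:`RunConfig` lists systems (each either a structure+trajectory file
pair or a synthetic-generation block), the selection/criteria/SIE settings,
and an output directory.  :func:`run` executes every stage per system
(binding-site RMSD, compartment widths, interaction networks, entropy,
SIE/IC50), writes deterministic CSV/JSON artifacts, and returns an in-memory
:class:`RunReport`; :func:`compare` derives cross-system tables.
"""
from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import structure_io, synthetic_data
from .errors import ConfigurationError
from .groove_geometry import (
    DistributionSummary,
    compartment_distance_series,
    distribution,
    rmsd_series,
)
from .interaction_networks import (
    HBondCriteria,
    HydrophobicCriteria,
    StackCriteria,
    detect_hbonds,
    detect_hydrophobic,
    detect_stacking,
    network_summary,
)
from .system import MolecularSystem, ResidueSelection, TrajectorySeries
from .thermo import (
    BindingResult,
    EntropyResult,
    SIEParams,
    ic50_ratio,
    quasiharmonic_entropy,
    sie_trajectory,
)

logger = logging.getLogger("pmhcgroove")

_FLOAT_FMT = "%.10g"


def load_profile(name: str = "defaults") -> dict:
    """Load a packaged settings profile."""
    source = resources.files("pmhcgroove.data") / f"{name}.yaml"
    return yaml.safe_load(source.read_text())


@dataclass
class SystemConfig:
    label: str
    structure: str | None = None
    trajectory: str | None = None
    synth: dict | None = None  # synthetic-generation block


@dataclass
class RunConfig:
    systems: list[SystemConfig]
    output_dir: str = "pmhcgroove_out"
    seed: int = 0
    profile: dict = field(default_factory=load_profile)
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [s.label for s in self.systems]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("system labels must be unique")
        settings = json.loads(json.dumps(self.profile))
        _deep_update(settings, self.overrides)
        self.settings = settings

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        systems = [SystemConfig(**block) for block in raw.get("systems", [])]
        return RunConfig(
            systems=systems,
            output_dir=raw.get("output_dir", "pmhcgroove_out"),
            seed=int(raw.get("seed", 0)),
            overrides=raw.get("settings", {}),
        )

    def provenance_hash(self) -> str:
        payload = {
            "systems": [
                {"label": s.label, "structure": s.structure, "trajectory": s.trajectory,
                 "synth": s.synth}
                for s in self.systems
            ],
            "seed": self.seed,
            "settings": self.settings,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _deep_update(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


@dataclass
class SystemResult:
    label: str
    rmsd: Any
    rmsd_distribution: DistributionSummary
    compartment_series: list
    compartment_distributions: dict[str, DistributionSummary]
    network: pd.DataFrame
    entropy: EntropyResult
    binding: BindingResult | None


@dataclass
class RunReport:
    config_hash: str
    systems: dict[str, SystemResult]


def _materialize_system(cfg: SystemConfig, seed: int) -> TrajectorySeries:
    if cfg.synth is not None:
        synth = dict(cfg.synth)
        n_frames = int(synth.pop("n_frames", 600))
        frame_interval = float(synth.pop("frame_interval", 20.0))
        fluct = synth.pop("fluctuation", {})
        plants = synth.pop("plants", [])
        system = synthetic_data.make_toy_complex(
            n_alpha=int(synth.get("n_alpha", 80)),
            n_beta=int(synth.get("n_beta", 95)),
            n_pep=int(synth.get("n_pep", 14)),
            with_waters=int(synth.get("with_waters", 0)),
            seed=seed,
            sequences=synth.get("sequences"),
        )
        spec = synthetic_data.FluctuationSpec(seed=seed, **fluct)
        traj = synthetic_data.sample_trajectory(system, spec, n_frames, frame_interval)
        for i, block in enumerate(plants):
            plant = synthetic_data.PlantedInteraction(
                kind=block["kind"],
                partners=(tuple(block["partners"][0]), tuple(block["partners"][1])),
                target_fraction=float(block["target_fraction"]),
                geometry=block.get("geometry", {}),
                seed=seed + i + 1,
            )
            traj = synthetic_data.plant_interaction(traj, plant)
        return traj
    if cfg.structure is None or cfg.trajectory is None:
        raise ConfigurationError(
            f"system '{cfg.label}': needs either a synth block or structure+trajectory paths"
        )
    for path in (cfg.structure, cfg.trajectory):
        if not Path(path).exists():
            raise ConfigurationError(f"system '{cfg.label}': input file not found: {path}")
    system = structure_io.read_structure(cfg.structure)
    return structure_io.read_trajectory(system, cfg.trajectory)


def _distribution_json(dist: DistributionSummary) -> dict:
    return {
        "bin_edges": [round(float(x), 10) for x in dist.bin_edges],
        "probability": [round(float(x), 10) for x in dist.probability],
        "modes": [[round(float(l), 10), round(float(m), 10)] for l, m in dist.modes],
        "bandwidth": dist.bandwidth,
    }


def analyze_system(label: str, traj: TrajectorySeries, settings: dict) -> SystemResult:
    """Run every analysis stage on one trajectory."""
    system = traj.system
    sel_cfg = settings["selections"]
    site = structure_io.binding_site_selection(
        system, {c: tuple(r) for c, r in sel_cfg["binding_site"].items()}
    )
    cmap = structure_io.compartment_selections(
        system, [(n, tuple(a), tuple(b)) for n, a, b in sel_cfg["compartments"]]
    )
    hist = settings["histograms"]

    t0 = time.perf_counter()
    rmsd = rmsd_series(traj, site, label=f"{label}_rmsd")
    rmsd_dist = distribution(rmsd, float(hist["rmsd_bin_width"]))
    logger.info("[%s] rmsd: %d frames in %.2fs", label, traj.n_frames, time.perf_counter() - t0)

    comp_series = compartment_distance_series(traj, cmap)
    comp_dists = {
        s.label: distribution(s, float(hist["distance_bin_width"])) for s in comp_series
    }

    crit = settings["criteria"]
    beta_site = ResidueSelection(
        "beta_site", tuple(m for m in site.members if m[0] == "B")
    )
    pep_members = tuple(
        ("P", int(r)) for r in np.unique(system.resids[system.chain_index["P"]])
    ) if "P" in system.chain_index else ()
    if pep_members:
        peptide = ResidueSelection("peptide", pep_members)
        t0 = time.perf_counter()
        records = [
            detect_hbonds(traj, beta_site, peptide, HBondCriteria(**crit["hbond"])),
            detect_stacking(traj, beta_site, peptide, StackCriteria(**crit["stacking"])),
            detect_hydrophobic(traj, beta_site, peptide, HydrophobicCriteria(**crit["hydrophobic"])),
        ]
        network = network_summary(*records)
        logger.info("[%s] network: %d records in %.2fs", label, len(network),
                    time.perf_counter() - t0)
    else:
        network = network_summary()

    entropy = quasiharmonic_entropy(
        traj, site, temperature=float(settings["entropy"]["temperature"])
    )
    binding = None
    if pep_members:
        sie_cfg = dict(settings["sie"])
        stride = float(sie_cfg.pop("stride_ps", 20.0))
        stride = max(stride, traj.frame_interval)
        binding = sie_trajectory(traj, site, peptide, SIEParams(**sie_cfg), stride)
    return SystemResult(
        label=label, rmsd=rmsd, rmsd_distribution=rmsd_dist,
        compartment_series=comp_series, compartment_distributions=comp_dists,
        network=network, entropy=entropy, binding=binding,
    )


def _write_system_outputs(out: Path, res: SystemResult) -> None:
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"frame": np.arange(res.rmsd.values.size), "rmsd": res.rmsd.values}
    ).to_csv(out / "rmsd.csv", index=False, float_format=_FLOAT_FMT)
    comp = pd.DataFrame({s.label: s.values for s in res.compartment_series})
    comp.insert(0, "frame", np.arange(len(comp)))
    comp.to_csv(out / "compartment_distances.csv", index=False, float_format=_FLOAT_FMT)
    res.network.to_csv(out / "network.csv", index=False, float_format=_FLOAT_FMT)
    dists = {"rmsd": _distribution_json(res.rmsd_distribution)}
    dists.update({k: _distribution_json(v) for k, v in res.compartment_distributions.items()})
    (out / "distributions.json").write_text(json.dumps(dists, indent=2, sort_keys=True))
    summary = {
        "TS_kcal_mol": res.entropy.TS,
        "entropy_temperature_K": res.entropy.temperature,
        "n_frames": res.entropy.n_frames_used,
    }
    if res.binding is not None:
        summary.update(
            dg_mean=res.binding.dg_mean, dg_sd=res.binding.dg_sd,
            ic50_nM=res.binding.ic50_nM, stride_ps=res.binding.stride_ps,
        )
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline for every configured system."""
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    results: dict[str, SystemResult] = {}
    try:
        for syscfg in config.systems:
            try:
                traj = _materialize_system(syscfg, config.seed)
                res = analyze_system(syscfg.label, traj, config.settings)
            except Exception as exc:
                logger.error("[%s] stage failed: %s", syscfg.label, exc)
                raise
            _write_system_outputs(out_root / syscfg.label, res)
            results[syscfg.label] = res
    finally:
        logger.removeHandler(handler)
    report = RunReport(config_hash=config.provenance_hash(), systems=results)
    (out_root / "provenance.json").write_text(
        json.dumps({"config_hash": report.config_hash,
                    "systems": sorted(results)}, indent=2, sort_keys=True)
    )
    return report


def compare(report: RunReport, reference_label: str) -> dict[str, pd.DataFrame]:
    """Cross-system comparison tables relative to a reference system."""
    if reference_label not in report.systems:
        raise ConfigurationError(f"unknown reference label '{reference_label}'")
    labels = list(report.systems)
    rows = []
    with_binding = [l for l in labels if report.systems[l].binding is not None]
    if with_binding:
        if reference_label not in with_binding:
            raise ConfigurationError(
                f"reference '{reference_label}' has no binding result"
            )
        ratios = ic50_ratio(
            [report.systems[l].binding.ic50_nM for l in with_binding],
            with_binding, reference_label,
        )
        ref_dg = report.systems[reference_label].binding.dg_mean
        for l in with_binding:
            b = report.systems[l].binding
            rows.append({"label": l, "dg": b.dg_mean, "ddg_vs_ref": b.dg_mean - ref_dg,
                         "ic50_nM": b.ic50_nM, "ic50_ratio": float(ratios[l])})
    binding_table = pd.DataFrame(rows, columns=["label", "dg", "ddg_vs_ref", "ic50_nM", "ic50_ratio"])

    mode_rows = []
    ref_modes = {
        k: v.modes[0][0]
        for k, v in report.systems[reference_label].compartment_distributions.items()
    }
    for l in labels:
        for comp, dist in report.systems[l].compartment_distributions.items():
            mode_rows.append({
                "label": l, "compartment": comp,
                "primary_mode_A": dist.modes[0][0],
                "mode_shift_vs_ref_A": dist.modes[0][0] - ref_modes[comp],
            })
    modes_table = pd.DataFrame(mode_rows)

    def _keyset(label):
        df = report.systems[label].network
        return {tuple(r) for r in df[["kind", "chain", "res_mhc", "res_pep"]].itertuples(index=False)}

    ref_keys = _keyset(reference_label)
    net_rows = []
    for l in labels:
        keys = _keyset(l)
        net_rows.append({
            "label": l,
            "n_records": len(keys),
            "shared_with_ref": len(keys & ref_keys),
            "unique_vs_ref": len(keys - ref_keys),
            "missing_vs_ref": len(ref_keys - keys),
        })
    network_table = pd.DataFrame(net_rows)
    return {"binding": binding_table, "compartment_modes": modes_table,
            "network": network_table}
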