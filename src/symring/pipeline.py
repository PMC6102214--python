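"""End-to-end orchestration: monomer -> dimer -> landscape scan -> reports.

One config object drives the whole analysis and every tabular output is
byte-deterministic for a fixed config, so diffing two runs detects any
change in inputs or code. A machine-readable manifest (JSON) records the
resolved config and outputs; re-running from the manifest reproduces the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import warnings
from dataclasses import dataclass, field

import yaml

from . import __version__
from .assembly import (
    EnergyLandscape,
    build_decamer,
    build_dimer,
    default_D_grid,
    default_R_grid,
    find_minima,
    junction_chain_pair,
    scan_landscape,
)
from .energy import EnergySettings
from .interface import burial_class, interface_residues
from .kinetics import fit_michaelis_menten, RateDataset
from .structio import Structure, read_pdb, write_pdb

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    monomer_pdb: str
    dimer_template_pdb: str | None = None
    rates_csv: str | None = None
    R_grid: list[float] = field(default_factory=lambda: list(default_R_grid()))
    D_grid: list[float] = field(default_factory=lambda: list(default_D_grid()))
    energy: dict = field(default_factory=dict)
    rotation_axis_choice: str = "first"
    interface_cutoff: float = 5.0
    burial_residues: list[int] = field(default_factory=lambda: [213, 289, 356])
    max_minima_models: int = 2
    enzyme_conc: float | None = None
    out_dir: str = "symring_run"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        # plain python floats so configs round-trip through YAML/JSON exactly
        self.R_grid = [float(r) for r in self.R_grid]
        self.D_grid = [float(d) for d in self.D_grid]
        self.burial_residues = [int(r) for r in self.burial_residues]
        if not self.R_grid or not self.D_grid:
            raise ValueError("R and D grids must be non-empty")

    def validate_inputs(self) -> None:
        for path in (self.monomer_pdb, self.dimer_template_pdb, self.rates_csv):
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(f"configured input does not exist: {path}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _resolve_dimer(config: PipelineConfig, monomer: Structure) -> Structure:
    if config.dimer_template_pdb is not None:
        template = read_pdb(config.dimer_template_pdb)
        return build_dimer(monomer, template)
    if len(monomer.chains) == 2:
        logger.info("monomer input already has 2 chains; using it as the dimer")
        return monomer
    raise ValueError(
        "no dimer template configured and the monomer input is not a 2-chain structure"
    )


def _write_minima_tsv(path, minima) -> None:
    with open(path, "w") as fh:
        fh.write("R_deg\tD_ang\tenergy_kcal_mol\n")
        for r, d, e in minima:
            fh.write(f"{r:.6f}\t{d:.6f}\t{e:.8f}\n")


def run_decamer_analysis(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest dict (also written to disk)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate_inputs()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "version": __version__,
        "seed": config.seed,
        "outputs": [],
        "status": "running",
    }

    def record(name: str) -> str:
        path = os.path.join(out, name)
        manifest["outputs"].append(name)
        return path

    stage = "setup"
    try:
        stage = "dimer"
        monomer = read_pdb(config.monomer_pdb)
        dimer = _resolve_dimer(config, monomer)
        write_pdb(dimer, record("dimer.pdb"))

        stage = "scan"
        settings = EnergySettings(**config.energy)
        landscape = scan_landscape(
            dimer,
            R_grid=config.R_grid,
            D_grid=config.D_grid,
            energy_settings=settings,
            rotation_axis_choice=config.rotation_axis_choice,
        )
        landscape.to_csv(record("landscape.csv"))
        landscape.plot_heatmap(record("landscape.png"))

        stage = "minima"
        minima = find_minima(landscape)
        _write_minima_tsv(record("minima.tsv"), minima)

        stage = "decamer_models"
        best_decamer: Structure | None = None
        for rank, (r, d, _e) in enumerate(minima[: config.max_minima_models]):
            decamer = build_decamer(
                dimer, r, d, rotation_axis_choice=config.rotation_axis_choice
            )
            if best_decamer is None:
                best_decamer = decamer
            write_pdb(decamer, record(f"decamer_min{rank + 1}_R{r:g}_D{d:g}.pdb"))
        assert best_decamer is not None

        stage = "interface"
        dimer_report = interface_residues(
            dimer, *dimer.chains[:2], cutoff=config.interface_cutoff
        )
        dimer_report.to_tsv(record("interface_dimer.tsv"))
        # one dimer-dimer junction: the closest chain pair across adjacent dimers
        junction = junction_chain_pair(best_decamer)
        junction_report = interface_residues(
            best_decamer, *junction, cutoff=config.interface_cutoff
        )
        junction_report.to_tsv(record("interface_junction.tsv"))

        stage = "burial"
        with open(record("burial.tsv"), "w") as fh:
            fh.write(
                "# CA-neighbour burial proxy: buried >= 28, exposed <= 18 "
                "neighbours within 10 A (package convention)\n"
            )
            fh.write("chain\tresnum\tclass\tneighbour_count\n")
            chain = best_decamer.chains[0]
            for resnum in config.burial_residues:
                try:
                    cls, count = burial_class(best_decamer, chain, resnum)
                    fh.write(f"{chain}\t{resnum}\t{cls.value}\t{count}\n")
                except KeyError:
                    fh.write(f"{chain}\t{resnum}\tabsent\t-1\n")

        stage = "kinetics"
        if config.rates_csv is not None:
            import pandas as pd

            df = pd.read_csv(config.rates_csv)
            dataset = RateDataset(
                substrate_conc=df["conc_mM"].to_numpy(),
                initial_rate=df["rate"].to_numpy(),
                enzyme_conc=config.enzyme_conc,
            )
            fit = fit_michaelis_menten(dataset)
            with open(record("kinetics.tsv"), "w") as fh:
                fh.write("Km_mM\tVmax\tkcat_per_hr\tkcat_over_Km\tconverged\n")
                kcat = "" if fit.kcat is None else f"{fit.kcat:.6f}"
                eff = "" if fit.efficiency is None else f"{fit.efficiency:.6f}"
                fh.write(
                    f"{fit.Km:.6f}\t{fit.Vmax:.6f}\t{kcat}\t{eff}\t{fit.converged}\n"
                )

        manifest["status"] = "ok"
        manifest["n_minima"] = len(minima)
        manifest["global_minimum"] = (
            {"R_deg": minima[0][0], "D_ang": minima[0][1], "energy": minima[0][2]}
            if minima
            else None
        )
    except Exception:
        manifest["status"] = f"failed at stage: {stage}"
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def rerun_from_manifest(manifest_path, out_dir: str | None = None) -> dict:
    """Re-execute a run from its manifest; the manifest alone defines the run."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    config = PipelineConfig.from_dict(manifest["config"])
    if out_dir is not None:
        config.out_dir = out_dir
    return run_decamer_analysis(config)
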