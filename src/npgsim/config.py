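"""Run configuration, serialization and the end-to-end pipeline.

The config file is YAML (or JSON, a YAML subset) with three optional
blocks — ``energy``, ``sim`` and ``sweep`` — whose keys mirror
:class:`npgsim.energy.EnergyParams`, :class:`npgsim.engine.SimConfig`
and the sweep arguments.  Every omitted key takes the model's default
(E_a=3, A=3.5, B=-12, C=5.2, r_max=150, dt=0.01, 1000 integrins on a
100x100 grid); unknown keys are rejected by name.  ``run_pipeline``
executes substrate generation (field mode only), the scenario sweep and
the report, and writes a manifest with per-file checksums so a run can
be verified byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .energy import EnergyParams, SCENARIOS
from .engine import MembraneLattice, SimConfig

__all__ = [
    "FullConfig",
    "SweepConfig",
    "ConfigError",
    "load_config",
    "write_config",
    "run_pipeline",
    "RunManifest",
]

log = logging.getLogger("npgsim")


class ConfigError(ValueError):
    """Malformed or invalid configuration file."""


@dataclass(frozen=True)
class SweepConfig:
    """Parameters of the scenario x pore-size sweep."""

    scenarios: tuple[str, ...] = ("fig5b", "fig5c", "fig5d", "fig5e")
    pore_sizes_nm: tuple[float, ...] = (20.0, 50.0, 75.0, 100.0, 150.0)
    include_flat: bool = True
    n_replicates: int = 3
    base_seed: int = 0

    def __post_init__(self) -> None:
        for s in self.scenarios:
            if s not in SCENARIOS:
                raise ConfigError(f"unknown scenario {s!r} in sweep.scenarios")
        if self.n_replicates < 1:
            raise ConfigError("sweep.n_replicates must be >= 1")


@dataclass(frozen=True)
class FullConfig:
    """Validated union of the energy, simulation and sweep blocks."""

    energy: EnergyParams = field(default_factory=EnergyParams)
    sim: SimConfig = field(default_factory=SimConfig)
    sweep: SweepConfig = field(default_factory=SweepConfig)


_SIM_SIMPLE_KEYS = {
    f.name for f in dataclasses.fields(SimConfig)
    if f.name not in ("lattice", "substrate")
}
_LATTICE_KEYS = {f.name for f in dataclasses.fields(MembraneLattice)}


def _build(cls, block: dict[str, Any], where: str, allowed: set[str] | None = None):
    allowed = allowed if allowed is not None else {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where!r} block")
    try:
        return cls(**block)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid value in {where!r} block: {exc}") from exc


def load_config(path: str | Path) -> FullConfig:
    """Parse and validate a YAML/JSON config file.

    An empty file yields the full default configuration.  Unknown keys and
    invalid values raise :class:`ConfigError` naming the offending key.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - {"energy", "sim", "sweep"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")

    energy = _build(EnergyParams, dict(raw.get("energy") or {}), "energy")

    sim_block = dict(raw.get("sim") or {})
    unknown = set(sim_block) - _SIM_SIMPLE_KEYS - _LATTICE_KEYS
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in 'sim' block")
    lat_kwargs = {k: sim_block.pop(k) for k in list(sim_block) if k in _LATTICE_KEYS}
    lattice = _build(MembraneLattice, lat_kwargs, "sim")
    try:
        sim = SimConfig(lattice=lattice, **sim_block)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid value in 'sim' block: {exc}") from exc

    sweep_block = dict(raw.get("sweep") or {})
    for key in ("scenarios", "pore_sizes_nm"):
        if key in sweep_block and isinstance(sweep_block[key], list):
            sweep_block[key] = tuple(sweep_block[key])
    sweep = _build(SweepConfig, sweep_block, "sweep")
    return FullConfig(energy=energy, sim=sim, sweep=sweep)


def write_config(cfg: FullConfig, path: str | Path) -> None:
    """Serialize a config so that ``load_config`` round-trips it exactly."""
    sim_d = dataclasses.asdict(cfg.sim)
    lattice = sim_d.pop("lattice")
    sim_d.pop("substrate", None)
    sim_d.update(lattice)
    doc = {
        "energy": dataclasses.asdict(cfg.energy),
        "sim": sim_d,
        "sweep": {
            "scenarios": list(cfg.sweep.scenarios),
            "pore_sizes_nm": list(cfg.sweep.pore_sizes_nm),
            "include_flat": cfg.sweep.include_flat,
            "n_replicates": cfg.sweep.n_replicates,
            "base_seed": cfg.sweep.base_seed,
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


@dataclass(frozen=True)
class RunManifest:
    """Inventory of one pipeline run: config echo, seeds, outputs, checksums."""

    config: dict[str, Any]
    seeds: tuple[int, ...]
    version: str
    files: dict[str, str]        # path -> sha256
    all_equilibrated: bool

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: FullConfig, out_dir: str | Path, progress: bool = False) -> RunManifest:
    """Substrate generation (field mode), sweep, aggregate report, manifest.

    Writes ``sweep_replicates.csv``, ``sweep_aggregate.csv`` and
    ``manifest.json`` under ``out_dir``; re-running with the same config
    yields identical CSV checksums.  The manifest's ``all_equilibrated``
    flag (and the CLI exit status) reflects any run that hit ``max_steps``
    before passing the equilibrium test.
    """
    from . import __version__
    from .clusters import aggregate_sweep, sweep_fig5
    from .substrate import generate_npg_field, save_field

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc

    base_sim = cfg.sim
    written: dict[str, str] = {}
    if base_sim.c_mode == "field" and base_sim.substrate is None:
        log.info("generating parent substrate field (seed=%d)", base_sim.seed)
        parent = generate_npg_field(seed=base_sim.seed)
        files = save_field(parent, out, name="substrate_20nm", png=False)
        written.update({v: "" for v in files.values()})
        base_sim = dataclasses.replace(base_sim, substrate=parent)

    sw = cfg.sweep
    log.info(
        "sweep: scenarios=%s pores=%s flat=%s replicates=%d base_seed=%d",
        sw.scenarios, sw.pore_sizes_nm, sw.include_flat, sw.n_replicates, sw.base_seed,
    )
    df = sweep_fig5(
        scenarios=sw.scenarios,
        pore_sizes_nm=sw.pore_sizes_nm,
        include_flat=sw.include_flat,
        n_replicates=sw.n_replicates,
        base_seed=sw.base_seed,
        base_config=base_sim,
        base_params=cfg.energy,
        progress=progress,
    )
    for _, row in df.iterrows():
        log.info(
            "run scenario=%s pore=%s seed=%d equilibrated=%s step=%d",
            row["scenario"], row["pore_nm"], row["seed"],
            row["equilibrated"], row["equil_step"],
        )
    rep_path = out / "sweep_replicates.csv"
    agg_path = out / "sweep_aggregate.csv"
    df.to_csv(rep_path, index=False)
    aggregate_sweep(df).to_csv(agg_path, index=False)
    written[str(rep_path)] = ""
    written[str(agg_path)] = ""

    sim_echo = dataclasses.asdict(dataclasses.replace(base_sim, substrate=None))
    manifest = RunManifest(
        config={
            "energy": dataclasses.asdict(cfg.energy),
            "sim": sim_echo,
            "sweep": dataclasses.asdict(cfg.sweep),
        },
        seeds=tuple(int(s) for s in sorted(df["seed"].unique())),
        version=__version__,
        files={p: _sha256(Path(p)) for p in written},
        all_equilibrated=bool(df["equilibrated"].all()),
    )
    manifest.write(out / "manifest.json")
    return manifest
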