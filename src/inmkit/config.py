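"""Run configuration (TOML) and the end-to-end analysis pipeline."""

from __future__ import annotations

import json
import os
import tomllib
from dataclasses import dataclass, field, fields

from inmkit.observables import region_entropy, sasa_profile, backbone_dihedrals
from inmkit.similarity import (
    Template, classify_trajectory, similarity_trace, tabulate_transitions,
)
from inmkit.structures import (
    ResidueMapping, map_residues, parse_ranges, read_structure,
    read_trajectory, select_atoms,
)

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "parse_template_spec"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated pipeline parameters; defaults follow the package Methods
    conventions (13 Å cutoff, 2 modes, 10 ps stride, 0.95/0.85 thresholds,
    300 K, 1.4 Å probe)."""

    trajectory: str = ""
    topology: str = ""
    dt_ps: float = 10.0
    open_template: str = ""         # "path.pdb[:CHAIN[:RANGES]]"
    closed_template: str = ""
    mapping: str = "offset:0"       # "offset:K" | path to 2-column file
    cutoff: float = 13.0
    n_modes: int = 2
    stride_ps: float | None = 10.0
    high: float = 0.95
    low: float = 0.85
    dwell: int = 5
    temperature: float = 300.0
    probe: float = 1.4
    seed: int = 0
    protein_tag: str = "protein"
    start_state: str = "open"
    regions: dict = field(default_factory=dict)
    sasa_range: list = field(default_factory=list)   # [lo, hi]
    dihedral_residues: list = field(default_factory=list)
    n_blocks: int = 3
    entropy_units: str = "J/mol/K"

    def validate(self) -> None:
        if self.cutoff <= 0:
            raise ConfigError(f"cutoff must be positive, got {self.cutoff}")
        if self.n_modes < 1:
            raise ConfigError("n_modes must be >= 1")
        if not (0 <= self.low < self.high <= 1):
            raise ConfigError(
                f"thresholds must satisfy 0 <= low < high <= 1, got "
                f"low={self.low} high={self.high}")
        if self.dwell < 1:
            raise ConfigError("dwell must be >= 1")
        if self.temperature <= 0:
            raise ConfigError("temperature must be positive")
        if self.probe < 0:
            raise ConfigError("probe radius must be nonnegative")
        if self.stride_ps is not None and self.stride_ps <= 0:
            raise ConfigError("stride_ps must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_toml(cls, path: str) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        flat: dict = {}
        for key, val in data.items():
            if isinstance(val, dict) and key not in ("regions",):
                flat.update(val)
            else:
                flat[key] = val
        return cls.from_dict(flat)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def parse_template_spec(spec: str, atom_name: str = "CA"):
    """Load ``path.pdb[:CHAIN[:RANGES]]`` into a Structure."""
    parts = spec.split(":")
    path = parts[0]
    chain = parts[1] if len(parts) > 1 and parts[1] else None
    s = read_structure(path, chain_id=chain)
    if len(parts) > 2 and parts[2]:
        s = select_atoms(s, parse_ranges(parts[2]))
    return s


def _load_mapping(spec: str, a, b) -> ResidueMapping | None:
    if spec is None or spec == "":
        return None
    if spec.startswith("offset"):
        return map_residues(a, b, spec.replace(":", " "))
    if spec == "align":
        return map_residues(a, b, "align")
    if os.path.exists(spec):
        return ResidueMapping.read(spec)
    raise ConfigError(f"unrecognized mapping spec {spec!r}")


def run_pipeline(config: RunConfig, outdir: str) -> dict:
    """Execute the configured stages in dependency order.

    Produces (as applicable) trace.tsv, calls.json, table.tsv,
    entropy.tsv, sasa.tsv and dihedrals.tsv under ``outdir``; every output
    embeds the resolved configuration.  Deterministic for a fixed config
    and seed.
    """
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    outputs: dict = {}

    def stage(name):
        def deco(fn):
            try:
                fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return deco

    topo = read_structure(config.topology) if config.topology else None
    traj = read_trajectory(config.trajectory, topology=topo,
                           dt_ps=config.dt_ps)

    if config.open_template and config.closed_template:
        @stage("trace")
        def _trace():
            open_s = parse_template_spec(config.open_template)
            closed_s = parse_template_spec(config.closed_template)
            open_map = _load_mapping(config.mapping, traj.topology, open_s)
            closed_map = _load_mapping(config.mapping, traj.topology,
                                       closed_s)
            trace = similarity_trace(
                traj, Template(open_s, open_map, name="open"),
                Template(closed_s, closed_map, name="closed"),
                n=config.n_modes, cutoff=config.cutoff,
                stride_ps=config.stride_ps)
            path = os.path.join(outdir, "trace.tsv")
            trace.to_tsv(path)
            outputs["trace"] = path
            outputs["_trace_obj"] = trace

        @stage("classify")
        def _classify():
            call = classify_trajectory(outputs["_trace_obj"],
                                       high=config.high, low=config.low,
                                       dwell=config.dwell)
            path = os.path.join(outdir, "calls.json")
            with open(path, "w") as fh:
                json.dump({
                    "config": {"high": config.high, "low": config.low,
                               "dwell": config.dwell},
                    "labels": call.labels,
                    "segments": call.segments,
                    "transitions": call.transitions,
                    "n_transitions": call.n_transitions,
                    "start_state": call.start_state,
                }, fh, indent=1, sort_keys=True)
            outputs["calls"] = path
            outputs["_call_obj"] = call

        @stage("table")
        def _table():
            call = outputs["_call_obj"]
            df = tabulate_transitions(
                [(config.protein_tag, config.start_state, call)])
            path = os.path.join(outdir, "table.tsv")
            with open(path, "w") as fh:
                fh.write(f"# seed={config.seed} high={config.high} "
                         f"low={config.low} dwell={config.dwell}\n")
                df.to_csv(fh, sep="\t", index=False)
            outputs["table"] = path

    if config.regions:
        @stage("entropy")
        def _entropy():
            regions = {name: [tuple(iv) for iv in ivs]
                       for name, ivs in config.regions.items()}
            rep = region_entropy(traj, regions, n_blocks=config.n_blocks,
                                 temperature=config.temperature,
                                 units=config.entropy_units)
            path = os.path.join(outdir, "entropy.tsv")
            with open(path, "w") as fh:
                fh.write(f"# temperature={config.temperature} "
                         f"units={config.entropy_units} "
                         f"blocks={config.n_blocks}\n")
                rep.to_frame().drop(columns=["blocks"]).to_csv(
                    fh, sep="\t", index=False)
            outputs["entropy"] = path

    if config.sasa_range:
        @stage("sasa")
        def _sasa():
            lo, hi = config.sasa_range
            prof = sasa_profile(traj, (int(lo), int(hi)), probe=config.probe)
            path = os.path.join(outdir, "sasa.tsv")
            with open(path, "w") as fh:
                fh.write(f"# probe={config.probe} n_points={prof.n_points}\n")
                fh.write("resid\tmean_A2\tstd_A2\n")
                for r, m, s in zip(prof.resids, prof.mean, prof.std):
                    fh.write(f"{r}\t{float(m)!r}\t{float(s)!r}\n")
            outputs["sasa"] = path

    if config.dihedral_residues:
        @stage("dihedrals")
        def _dihedrals():
            series = backbone_dihedrals(traj, config.dihedral_residues)
            path = os.path.join(outdir, "dihedrals.tsv")
            with open(path, "w") as fh:
                fh.write("# phi/psi in degrees, NaN where undefined\n")
                fh.write("frame\tresid\tphi\tpsi\n")
                for f in range(series.phi.shape[0]):
                    for k, r in enumerate(series.resids):
                        fh.write(f"{f}\t{r}\t{float(series.phi[f, k])!r}\t"
                                 f"{float(series.psi[f, k])!r}\n")
            outputs["dihedrals"] = path

    for k in list(outputs):
        if k.startswith("_"):
            del outputs[k]
    return outputs
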