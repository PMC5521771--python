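"""Run configuration, output files and provenance.

The run configuration is a flat YAML document whose keys mirror
:class:`chitosim.mc.SimulationConfig` plus force-field and output
options.  Unknown keys are rejected, defaults are filled in, and a
configuration hash is stamped into every output so a run can be
reproduced byte-for-byte from its provenance record.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field, fields

import yaml

from . import __version__
from .energetics import ForceFieldParams
from .mc import ObservableLog, SimulationConfig
from .pmf_maps import MapLibrary


@dataclass
class RunConfig:
    # sequence / conditions
    dp: int = 50
    dd: float = 1.0
    pattern: str = "random"
    pH: float = 4.5
    c_s: float = 0.1
    temperature: float = 298.0
    # force field
    sigma_lj: float = 0.65
    eps_lj_kjmol: float = 0.6276
    pk_i: float = 6.6
    map_cutoff: float = 7.0
    include_bonded_in_titration: bool = False
    # maps
    map_manifest: str | None = None  # None -> bundled synthetic library
    map_grid: int = 200
    # schedule
    n_steps: int = 10_000
    titration_per_step: int | None = None
    seed: int = 0
    log_stride: int = 100
    frame_stride: int | None = None
    burn_in_fraction: float = 0.2
    electrostatics: bool = True
    sterics: bool = True
    titration: bool = True
    map_swapping: bool = True
    # outputs
    out_dir: str = "out"
    write_frames: bool = False

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown configuration keys: {', '.join(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def force_field(self) -> ForceFieldParams:
        return ForceFieldParams(
            sigma_lj=self.sigma_lj,
            eps_lj_kjmol=self.eps_lj_kjmol,
            pk_i=self.pk_i,
            map_cutoff=self.map_cutoff,
            include_bonded_in_titration=self.include_bonded_in_titration,
        )

    def library(self) -> MapLibrary:
        if self.map_manifest:
            return MapLibrary.from_manifest(
                self.map_manifest, cutoff=self.map_cutoff, grid_spec=self.map_grid
            )
        return MapLibrary.synthetic(cutoff=self.map_cutoff, grid_spec=self.map_grid)

    def simulation_config(self, library: MapLibrary | None = None) -> SimulationConfig:
        return SimulationConfig(
            dp=self.dp,
            dd=self.dd,
            pattern=self.pattern,
            pH=self.pH,
            c_s=self.c_s,
            temperature=self.temperature,
            params=self.force_field(),
            library=library or self.library(),
            n_steps=self.n_steps,
            titration_per_step=self.titration_per_step,
            seed=self.seed,
            log_stride=self.log_stride,
            frame_stride=self.frame_stride
            if self.frame_stride
            else (self.log_stride if self.write_frames else None),
            burn_in_fraction=self.burn_in_fraction,
            electrostatics=self.electrostatics,
            sterics=self.sterics,
            titration=self.titration,
            map_swapping=self.map_swapping,
        )


def parse_config(path: str) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(data)


def write_config(cfg: RunConfig, path: str):
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


@dataclass
class ProvenanceRecord:
    config_hash: str
    seed: int
    package_version: str
    map_checksums: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def map_checksums(library: MapLibrary) -> dict:
    out = {}
    for key, dmap in sorted(library.maps.items()):
        h = hashlib.sha256(dmap.grid.tobytes()).hexdigest()[:16]
        out[" ".join(key)] = h
    return out


def write_outputs(
    log: ObservableLog, cfg: RunConfig, library: MapLibrary | None = None
):
    """Write observables/energies CSV, acceptance and provenance JSON and
    optional XYZ frames into ``cfg.out_dir``; returns the paths written."""
    from .mc import acceptance_report

    os.makedirs(cfg.out_dir, exist_ok=True)
    chash = cfg.config_hash()
    paths = {}

    obs_cols = ["step", "r_g", "r_ee", "alpha"]
    en_cols = ["step", "e_map", "e_lj", "e_dh", "f_prot"]
    obs_path = os.path.join(cfg.out_dir, "observables.csv")
    en_path = os.path.join(cfg.out_dir, "energies.csv")
    header = f"# config_hash={chash}\n"
    for path, cols in ((obs_path, obs_cols), (en_path, en_cols)):
        with open(path, "w") as fh:
            fh.write(header)
            if len(log.records):
                df = log.records[cols].copy()
                if "e_map" in cols:
                    df = df.assign(
                        total=df[["e_map", "e_lj", "e_dh", "f_prot"]].sum(axis=1)
                    )
                df.to_csv(fh, index=False)
            else:
                fh.write(",".join(cols) + "\n")
        paths[os.path.basename(path)] = path

    acc_path = os.path.join(cfg.out_dir, "acceptance.json")
    with open(acc_path, "w") as fh:
        payload = {"config_hash": chash}
        if len(log.records):
            payload.update(acceptance_report(log))
        json.dump(payload, fh, indent=2)
    paths["acceptance.json"] = acc_path

    prov = ProvenanceRecord(
        config_hash=chash,
        seed=cfg.seed,
        package_version=__version__,
        map_checksums=map_checksums(library) if library else {},
    )
    prov_path = os.path.join(cfg.out_dir, "provenance.json")
    with open(prov_path, "w") as fh:
        json.dump(prov.to_dict(), fh, indent=2)
    paths["provenance.json"] = prov_path

    if log.frames:
        xyz_path = os.path.join(cfg.out_dir, "frames.xyz")
        with open(xyz_path, "w") as fh:
            for step, sites in zip(log.frame_steps, log.frames):
                fh.write(f"{len(sites)}\n")
                fh.write(f"step={step} config_hash={chash}\n")
                for x, y, z in sites:
                    fh.write(f"S {x:.6f} {y:.6f} {z:.6f}\n")
        paths["frames.xyz"] = xyz_path
    return paths


def read_xyz_frames(path: str):
    """Read site frames back from a standard XYZ file."""
    import numpy as np

    frames = []
    with open(path) as fh:
        while True:
            head = fh.readline()
            if not head.strip():
                break
            n = int(head)
            fh.readline()
            pts = []
            for _ in range(n):
                parts = fh.readline().split()
                pts.append([float(p) for p in parts[1:4]])
            frames.append(np.array(pts))
    return frames
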