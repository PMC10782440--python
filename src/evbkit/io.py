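"""File formats: energy-log CSVs, profile TSVs, JSON reports, TOML configs.

Energy logs are one CSV per (temperature, replicate) with columns
``step, lambda, T, replicate, eps1, eps2s, Eg, eps_m, w1,
bond1..vdw1, bond2..vdw2, kinT`` plus the full group-resolved component
columns ``{rr,rs,ss}_{term}{state}`` needed for re-analysis by the
decomposition stage.  Provenance (config, seed, coupling) is echoed as
``# key = value`` comment lines at the top of every file.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .evb_core import GROUPS, TERMS
from .free_energy import FreeEnergyProfile
from .sampler import SimulationConfig, WindowTrajectory


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Runtime parameters of a full pipeline run (echoed into every output)."""

    system_file: str
    out_dir: str
    seed: int = 0
    n_windows: int = 51
    n_replicates: int = 10
    temperatures: tuple[float, ...] = (298.0,)
    n_prod_steps: int = 3000
    n_window_equil_steps: int = 300
    timestep_fs: float = 1.0
    friction_ps: float = 25.0
    sample_stride: int = 3

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            timestep_fs=self.timestep_fs, friction_ps=self.friction_ps,
            n_window_equil_steps=self.n_window_equil_steps,
            n_prod_steps=self.n_prod_steps, sample_stride=self.sample_stride,
            seed=self.seed)

    def provenance(self) -> dict:
        return dataclasses.asdict(self)


def read_run_config(path: str | Path, **overrides) -> RunConfig:
    """Load a RunConfig from a TOML key-value file."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    if "temperatures" in data:
        data["temperatures"] = tuple(float(t) for t in data["temperatures"])
    data.update(overrides)
    return RunConfig(**data)


def _component_columns(state: int) -> list[str]:
    return [f"{g}_{t}{state}" for g in GROUPS for t in TERMS]


def energy_log_frame(trajs: Sequence[WindowTrajectory]) -> pd.DataFrame:
    """Stack window trajectories (one T, one replicate) into a long table."""
    rows = []
    for w in sorted(trajs, key=lambda w: w.lam):
        n = w.n_frames
        rec = {
            "step": w.step, "lambda": np.full(n, w.lam),
            "T": np.full(n, w.T), "replicate": np.full(n, w.replicate, int),
            "eps1": w.e1, "eps2s": w.e2s, "Eg": w.eg, "eps_m": w.em,
            "w1": w.w1, "kinT": w.kin_t,
        }
        for state, bd in ((1, w.bd1), (2, w.bd2)):
            if bd is None:
                continue
            for gi, g in enumerate(GROUPS):
                for ti, t in enumerate(TERMS):
                    rec[f"{g}_{t}{state}"] = bd[:, gi, ti]
            for ti, t in enumerate(TERMS):
                rec[f"{t}{state}"] = bd[:, :, ti].sum(axis=1)
        rows.append(pd.DataFrame(rec))
    return pd.concat(rows, ignore_index=True)


def write_energy_logs(trajs: Sequence[WindowTrajectory], out_dir: str | Path,
                      provenance: dict | None = None) -> list[Path]:
    """One CSV per (T, replicate) under ``out_dir``; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    keys = sorted({(w.T, w.replicate) for w in trajs})
    written = []
    for T, rep in keys:
        sel = [w for w in trajs if w.T == T and w.replicate == rep]
        df = energy_log_frame(sel)
        path = out_dir / f"energy_T{T:.2f}_rep{rep}.csv"
        with open(path, "w") as fh:
            for k, v in (provenance or {}).items():
                fh.write(f"# {k} = {v}\n")
            df.to_csv(fh, index=False)
        written.append(path)
    return written


def read_energy_logs(paths: Sequence[str | Path] | str | Path
                     ) -> list[WindowTrajectory]:
    """Rebuild window trajectories (no coordinates) from energy-log CSVs."""
    if isinstance(paths, (str, Path)):
        p = Path(paths)
        paths = sorted(p.glob("energy_*.csv")) if p.is_dir() else [p]
    if not paths:
        raise FileNotFoundError("no energy logs found")
    out: list[WindowTrajectory] = []
    for path in paths:
        df = pd.read_csv(path, comment="#")
        has_bd = all(c in df.columns for c in _component_columns(1))
        for (lam, T, rep), g in df.groupby(["lambda", "T", "replicate"]):
            n = len(g)
            bd = {}
            if has_bd:
                for state in (1, 2):
                    m = np.empty((n, 3, 6))
                    for gi, grp in enumerate(GROUPS):
                        for ti, t in enumerate(TERMS):
                            m[:, gi, ti] = g[f"{grp}_{t}{state}"].to_numpy()
                    bd[state] = m
            out.append(WindowTrajectory(
                lam=float(lam), T=float(T), replicate=int(rep),
                step=g["step"].to_numpy(int),
                e1=g["eps1"].to_numpy(), e2s=g["eps2s"].to_numpy(),
                eg=g["Eg"].to_numpy(), em=g["eps_m"].to_numpy(),
                w1=g["w1"].to_numpy(), kin_t=g["kinT"].to_numpy(),
                bd1=bd.get(1), bd2=bd.get(2)))
    return out


def write_profiles_tsv(profiles: Sequence[FreeEnergyProfile],
                       path: str | Path) -> None:
    """Profiles as TSV: columns de_center, dg, n_frames, replicate, T."""
    rows = []
    for p in profiles:
        rows.append(pd.DataFrame({
            "de_center": p.centers, "dg": p.dg, "n_frames": p.counts,
            "replicate": -1 if p.replicate is None else p.replicate,
            "T": p.T}))
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_json(obj: dict, path: str | Path,
               provenance: dict | None = None) -> None:
    doc = dict(obj)
    if provenance is not None:
        doc["provenance"] = provenance
    Path(path).write_text(json.dumps(doc, indent=2, default=_jsonify) + "\n")


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def read_minimal_pdb(path: str | Path) -> np.ndarray:
    """Coordinates (A) from ATOM/HETATM records of a minimal PDB file.

    Only the coordinate fields are interpreted; no connectivity is inferred.
    """
    coords = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("ATOM", "HETATM")):
                coords.append([float(line[30:38]), float(line[38:46]),
                               float(line[46:54])])
    if not coords:
        raise ValueError(f"no ATOM records in {path}")
    return np.array(coords)
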