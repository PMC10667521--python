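"""Readers and writers for the package's file dialects.

Formats: YAML simulation configs, CSV phase-boundary tables
(protein_conc, rna_conc, phase in {P, N}), CSV spot and nucleus tables,
CSV FRAP traces (time_s, bleached, unbleached, background,
acquisition_id), FASTA sequences, and an .npz + JSON-sidecar trajectory
container.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .boundary import BoundaryDataset
from .config import SimulationConfig, Species
from .imaging import DEFAULT_SPOT_RADIUS_PX, FRAPTraces, NucleusSet, SpotField
from .simulate import TrajectorySample

__version__ = "0.1.0"


# -- simulation configs -------------------------------------------------

def save_config(config: SimulationConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["species"] = [dataclasses.asdict(sp) for sp in config.species]
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_config(path) -> SimulationConfig:
    d = yaml.safe_load(Path(path).read_text())
    d["species"] = [Species(**sp) for sp in d["species"]]
    return SimulationConfig(**d)


# -- phase boundary tables ----------------------------------------------

def save_boundary_csv(data: BoundaryDataset, path) -> None:
    rows = [{"protein_conc": x, "rna_conc": y, "phase": "P"}
            for x, y in data.two_phase]
    rows += [{"protein_conc": x, "rna_conc": y, "phase": "N"}
             for x, y in data.one_phase]
    df = pd.DataFrame(rows)
    df.attrs["units"] = data.units
    with open(path, "w") as fh:
        fh.write(f"# units: {data.units}\n")
        df.to_csv(fh, index=False)


def load_boundary_csv(path) -> BoundaryDataset:
    units = "uM"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "units:" in first:
                units = first.split("units:")[1].strip()
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    bad = set(df["phase"]) - {"P", "N"}
    if bad:
        raise ValueError(f"phase labels must be P or N, found {sorted(bad)}")
    P = df[df["phase"] == "P"][["protein_conc", "rna_conc"]].to_numpy(float)
    N = df[df["phase"] == "N"][["protein_conc", "rna_conc"]].to_numpy(float)
    return BoundaryDataset(two_phase=P, one_phase=N, units=units)


# -- spot / nucleus tables ----------------------------------------------

def save_spots_csv(field: SpotField, path) -> None:
    pd.DataFrame({"x_px": field.centers[:, 0], "y_px": field.centers[:, 1],
                  "channel": field.channel}).to_csv(path, index=False)


def load_spots_csv(path, channel: str | None = None,
                   spot_radius: float = DEFAULT_SPOT_RADIUS_PX) -> SpotField:
    df = pd.read_csv(path)
    if channel is not None and "channel" in df:
        df = df[df["channel"] == channel]
    return SpotField(df[["x_px", "y_px"]].to_numpy(float),
                     spot_radius=spot_radius, channel=channel or "")


def save_nuclei_csv(nuclei: NucleusSet, path) -> None:
    pd.DataFrame({"x_px": nuclei.centroids[:, 0],
                  "y_px": nuclei.centroids[:, 1],
                  "area_px2": nuclei.areas}).to_csv(path, index=False)


def load_nuclei_csv(path) -> NucleusSet:
    df = pd.read_csv(path)
    return NucleusSet(df[["x_px", "y_px"]].to_numpy(float),
                      df["area_px2"].to_numpy(float))


# -- FRAP traces ---------------------------------------------------------

def save_frap_csv(traces: FRAPTraces, path) -> None:
    rows = []
    for a in range(traces.n_acquisitions):
        for t in range(len(traces.time)):
            rows.append({"time_s": traces.time[t],
                         "bleached": traces.bleached[a, t],
                         "unbleached": traces.unbleached[a, t],
                         "background": traces.background[a, t],
                         "acquisition_id": a,
                         "pre_bleach_index": traces.pre_bleach_index})
    pd.DataFrame(rows).to_csv(path, index=False)


def load_frap_csv(path) -> FRAPTraces:
    df = pd.read_csv(path)
    acqs = sorted(df["acquisition_id"].unique())
    t0 = df[df["acquisition_id"] == acqs[0]]["time_s"].to_numpy(float)
    b, u, g = [], [], []
    for a in acqs:
        sub = df[df["acquisition_id"] == a].sort_values("time_s")
        b.append(sub["bleached"].to_numpy(float))
        u.append(sub["unbleached"].to_numpy(float))
        g.append(sub["background"].to_numpy(float))
    pre = int(df["pre_bleach_index"].iloc[0]) if "pre_bleach_index" in df else 1
    return FRAPTraces(time=t0, bleached=np.array(b), unbleached=np.array(u),
                      background=np.array(g), pre_bleach_index=pre)


# -- sequences -----------------------------------------------------------

def save_fasta(records: dict[str, str], path) -> None:
    SeqIO.write([SeqRecord(Seq(s), id=name, description="")
                 for name, s in records.items()], path, "fasta")


def load_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def load_reactivity_csv(path) -> dict[int, float]:
    """CSV of (position, value); positions 1-based in the file."""
    df = pd.read_csv(path)
    pos_col, val_col = df.columns[:2]
    return {int(p) - 1: float(v) for p, v in zip(df[pos_col], df[val_col])}


# -- trajectories --------------------------------------------------------

def save_trajectory(samples: list[TrajectorySample], config: SimulationConfig,
                    path, seed: int | None = None) -> None:
    """Write samples to <path>.npz with a JSON metadata sidecar <path>.json."""
    path = Path(path)
    np.savez_compressed(
        path.with_suffix(".npz"),
        mc_step=np.array([s.mc_step for s in samples]),
        temperature=np.array([s.temperature for s in samples]),
        total_energy=np.array([s.total_energy for s in samples]),
        positions=np.array([s.positions for s in samples]),
        bonds=np.array([s.bonds for s in samples]))
    meta = dataclasses.asdict(config)
    meta["species"] = [dataclasses.asdict(sp) for sp in config.species]
    sidecar = {"config": meta, "seed": seed, "version": __version__,
               "n_samples": len(samples)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_trajectory(path) -> list[TrajectorySample]:
    z = np.load(Path(path).with_suffix(".npz"))
    return [TrajectorySample(int(z["mc_step"][k]), float(z["temperature"][k]),
                             z["positions"][k], z["bonds"][k],
                             float(z["total_energy"][k]))
            for k in range(len(z["mc_step"]))]
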