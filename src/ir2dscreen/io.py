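"""File formats: grid text maps, manifests, model serialisation.

Maps use a bespoke plain-text grid format (there is no community standard
for 2D-IR maps): a comment header carrying the waiting time, sample id and
config hash; a tab-separated probe axis line; then one line per pump value,
the pump wavenumber followed by that row's amplitudes.  Values are written
with 12 significant digits so a write/read round trip is faithful to 1e-10
at unit scale.
"""

from __future__ import annotations

import os
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .gridmap import AxisGrid, SpectrumMap2D
from .pls import PLSModel
from .synth import Dataset, SampleRecord

__all__ = [
    "write_map",
    "read_map",
    "write_dataset",
    "read_dataset",
    "write_model",
    "read_model",
]

_FMT = "%.12g"


def write_map(map_: SpectrumMap2D, path: str | os.PathLike, config_hash: str = "") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            f"# waiting_time_ps={_FMT % map_.waiting_time} "
            f"sample_id={map_.sample_id or 'unknown'} config_hash={config_hash or 'none'}\n"
        )
        fh.write("\t".join(_FMT % v for v in map_.grid.probe_axis) + "\n")
        for pump, row in zip(map_.grid.pump_axis, map_.amplitudes):
            fh.write(_FMT % pump + "\t" + "\t".join(_FMT % v for v in row) + "\n")


class MapParseError(ValueError):
    pass


def read_map(path: str | os.PathLike) -> SpectrumMap2D:
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 4:
        raise MapParseError(f"{path}: too short for a 2x2 map")
    header = lines[0]
    if not header.startswith("#"):
        raise MapParseError(f"{path}:1: missing comment header")
    m = re.search(r"waiting_time_ps=(\S+)", header)
    wt = float(m.group(1)) if m else 0.0
    m = re.search(r"sample_id=(\S+)", header)
    sid = m.group(1) if m else ""

    def parse(line: str, lineno: int) -> np.ndarray:
        try:
            return np.array([float(x) for x in line.split("\t")])
        except ValueError as e:
            raise MapParseError(f"{path}:{lineno}: non-numeric cell ({e})") from None

    probe = parse(lines[1], 2)
    pump_vals, rows = [], []
    for k, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        vals = parse(line, k)
        if vals.size != probe.size + 1:
            raise MapParseError(
                f"{path}:{k}: ragged row ({vals.size - 1} cells, expected {probe.size})"
            )
        pump_vals.append(vals[0])
        rows.append(vals[1:])
    try:
        grid = AxisGrid(np.array(pump_vals), probe)
    except ValueError as e:
        raise MapParseError(f"{path}: invalid axes: {e}") from None
    return SpectrumMap2D(
        grid=grid, amplitudes=np.vstack(rows), waiting_time=wt,
        sample_id="" if sid == "unknown" else sid,
    )


def write_dataset(dataset: Dataset, out_dir: str | os.PathLike, config_hash: str = "") -> Path:
    """Write every map pair plus the manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    maps_dir = out_dir / "maps"
    maps_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec, m250, m5 in zip(dataset.records, dataset.maps_250fs, dataset.maps_5ps):
        p250 = maps_dir / f"{rec.sample_id}_250fs.tsv"
        p5 = maps_dir / f"{rec.sample_id}_5ps.tsv"
        write_map(m250, p250, config_hash)
        write_map(m5, p5, config_hash)
        rows.append(
            dict(
                sample_id=rec.sample_id,
                class_label=rec.class_label,
                drug_conc_mM=rec.drug_conc,
                replicate=rec.replicate_index,
                path_length_factor=rec.path_length_factor,
                map_250fs=os.path.relpath(p250, out_dir),
                map_5ps=os.path.relpath(p5, out_dir),
            )
        )
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w") as fh:
        fh.write(f"# config_hash={config_hash or 'none'}\n")
        pd.DataFrame(rows).to_csv(fh, index=False, float_format=_FMT)
    return manifest


def read_dataset(manifest_path: str | os.PathLike, config=None) -> Dataset:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, comment="#")
    if df["sample_id"].duplicated().any():
        raise ValueError("manifest sample_ids must be unique")
    base = manifest_path.parent
    records, m250s, m5s = [], [], []
    for _, row in df.iterrows():
        for col in ("map_250fs", "map_5ps"):
            if not (base / row[col]).exists():
                raise FileNotFoundError(f"manifest references missing file {row[col]}")
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                class_label=str(row["class_label"]),
                drug_conc=float(row["drug_conc_mM"]),
                replicate_index=int(row["replicate"]),
                path_length_factor=float(row.get("path_length_factor", 1.0)),
            )
        )
        m250s.append(read_map(base / row["map_250fs"]))
        m5s.append(read_map(base / row["map_5ps"]))
    return Dataset(records=records, maps_250fs=m250s, maps_5ps=m5s, config=config)


def write_model(model: PLSModel, path: str | os.PathLike) -> None:
    """Serialise a PLS model to a key-value text container (arrays as
    flattened 12-significant-digit rows)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"n_lv={model.n_lv}\n")
        fh.write(f"centered={int(model.centered)}\n")
        fh.write("class_names=" + ",".join(model.class_names) + "\n")
        for name in ("W", "P", "Q", "T", "B", "x_mean", "y_mean"):
            arr = getattr(model, name)
            if arr is None:
                continue
            arr = np.atleast_2d(arr)
            fh.write(f"array {name} {arr.shape[0]} {arr.shape[1]}\n")
            for row in arr:
                fh.write("\t".join(_FMT % v for v in row) + "\n")


def read_model(path: str | os.PathLike) -> PLSModel:
    with open(path) as fh:
        lines = fh.read().splitlines()
    meta: dict = {}
    arrays: dict = {}
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("array "):
            _, name, r, c = line.split()
            r, c = int(r), int(c)
            block = [
                [float(x) for x in lines[i + 1 + j].split("\t")] for j in range(r)
            ]
            arrays[name] = np.array(block).reshape(r, c)
            i += 1 + r
        else:
            k, _, v = line.partition("=")
            meta[k] = v
            i += 1
    names = [c for c in meta.get("class_names", "").split(",") if c]
    return PLSModel(
        W=arrays["W"], P=arrays["P"], Q=arrays["Q"], T=arrays["T"], B=arrays["B"],
        n_lv=int(meta["n_lv"]), centered=bool(int(meta["centered"])),
        x_mean=arrays.get("x_mean", [None])[0] if "x_mean" in arrays else None,
        y_mean=arrays.get("y_mean", [None])[0] if "y_mean" in arrays else None,
        class_names=names,
    )
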