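"""Plain-text persistence for recordings: one CSV per sweep plus a JSON manifest.

Sweep files carry comment-prefixed metadata lines (``# cell_id``,
``# condition``, ``# capacitance_pF``, ``# protocol``, ``# seed``) followed by
``time_ms,voltage_mV,current_pA`` columns.  Floats are written with ``repr``
precision so a write/read cycle is lossless up to float formatting.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import InvalidInputError
from .synthetic_recordings import CellRecording, Sweep

__all__ = ["write_recording", "read_recording", "write_group", "read_group"]


def _sweep_filename(rec: CellRecording, sweep: Sweep) -> str:
    sign = "m" if sweep.test_voltage < 0 else "p"
    return f"{rec.cell_id}_{sweep.protocol_name}_{sign}{abs(sweep.test_voltage):g}mV.csv"


def write_recording(rec: CellRecording, directory: str | Path) -> list[str]:
    """Write each sweep of a recording as a CSV file; returns the file names."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for sweep in rec.sweeps:
        name = _sweep_filename(rec, sweep)
        with open(directory / name, "w") as fh:
            fh.write(f"# cell_id = {rec.cell_id}\n")
            fh.write(f"# condition = {rec.condition}\n")
            fh.write(f"# capacitance_pF = {rec.capacitance!r}\n")
            fh.write(f"# protocol = {sweep.protocol_name}\n")
            fh.write(f"# seed = {rec.seed}\n")
            fh.write("time_ms,voltage_mV,current_pA\n")
            v_txt = repr(float(sweep.test_voltage))
            for t, i in zip(sweep.time, sweep.current):
                fh.write(f"{float(t)!r},{v_txt},{float(i)!r}\n")
        names.append(name)
    return names


def _read_sweep_file(path: Path) -> tuple[dict, Sweep]:
    meta = {}
    with open(path) as fh:
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = value.strip()
        df = pd.read_csv(fh, float_precision="round_trip")
    required = {"cell_id", "condition", "capacitance_pF", "protocol", "seed"}
    missing = required - meta.keys()
    if missing:
        raise InvalidInputError(f"{path.name}: missing metadata {sorted(missing)}")
    voltages = df["voltage_mV"].unique()
    if len(voltages) != 1:
        raise InvalidInputError(f"{path.name}: mixed test voltages in one sweep")
    sweep = Sweep(
        test_voltage=float(voltages[0]),
        time=df["time_ms"].to_numpy(dtype=float),
        current=df["current_pA"].to_numpy(dtype=float),
        protocol_name=meta["protocol"],
    )
    return meta, sweep


def read_recording(paths: list[str | Path]) -> CellRecording:
    """Assemble a recording from its sweep CSV files (same cell throughout)."""
    if not paths:
        raise InvalidInputError("no sweep files given")
    metas, sweeps = zip(*(_read_sweep_file(Path(p)) for p in paths))
    ids = {m["cell_id"] for m in metas}
    if len(ids) != 1:
        raise InvalidInputError(f"sweep files from different cells: {sorted(ids)}")
    meta = metas[0]
    return CellRecording(
        cell_id=meta["cell_id"],
        condition=meta["condition"],
        capacitance=float(meta["capacitance_pF"]),
        seed=int(meta["seed"]),
        sweeps=tuple(sweeps),
    )


def write_group(
    recordings: list[CellRecording], manifest: dict, directory: str | Path
) -> Path:
    """Write a condition group and its manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {rec.cell_id: write_recording(rec, directory) for rec in recordings}
    manifest = dict(manifest)
    manifest["files"] = files
    manifest_path = directory / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest_path


def read_group(manifest_path: str | Path) -> tuple[list[CellRecording], dict]:
    """Load all recordings referenced by a group manifest."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    directory = manifest_path.parent
    recordings = [
        read_recording([directory / name for name in names])
        for names in manifest["files"].values()
    ]
    return recordings, manifest
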