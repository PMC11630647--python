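"""Dataset and result serialization.

Dataset layout (one directory per run, diff-able plain text):

    dataset/
      manifest.json            # run ids, seed, generator settings
      run00_center/
        offline.csv            # t, X, P, G   (G empty where censored)
        online.csv             # t, f, T
        manifest.json          # V0, X0, Gf, events, design point, base feed

Kinetic parameter sets round-trip through a flat YAML mapping with an
explicit mask section.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import KineticParameterSet
from .process_model import BaseFeedParams, SamplingEvent
from .records import ProcessRecord

__all__ = [
    "save_params",
    "load_params",
    "save_record",
    "load_record",
    "save_dataset",
    "load_dataset",
]


def save_params(params: KineticParameterSet, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=True)


def load_params(path) -> KineticParameterSet:
    with open(path) as fh:
        return KineticParameterSet.from_dict(yaml.safe_load(fh))


def _record_manifest(record: ProcessRecord) -> dict:
    return {
        "run_id": record.run_id,
        "V0": record.V0,
        "X0": record.X0,
        "Gf": record.Gf,
        "G_loq": record.G_loq,
        "design_point": {"mu_f": record.design_point[0],
                         "T": record.design_point[1]},
        "sampling_events": [
            {"t_sample": e.t_sample, "volume_removed": e.volume_removed}
            for e in record.sampling_events
        ],
        "base_params": (None if record.base_params is None else
                        {"a": record.base_params.a, "b": record.base_params.b}),
    }


def save_record(record: ProcessRecord, run_dir) -> None:
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    record.offline_frame().to_csv(run_dir / "offline.csv", index=False)
    record.online_frame().to_csv(run_dir / "online.csv", index=False)
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(_record_manifest(record), fh, indent=1)


def load_record(run_dir) -> ProcessRecord:
    run_dir = Path(run_dir)
    off = pd.read_csv(run_dir / "offline.csv")
    on = pd.read_csv(run_dir / "online.csv")
    with open(run_dir / "manifest.json") as fh:
        man = json.load(fh)
    base = man.get("base_params")
    return ProcessRecord(
        run_id=man["run_id"],
        sample_times=off["t"].to_numpy(float),
        X_meas=off["X"].to_numpy(float),
        P_meas=off["P"].to_numpy(float),
        G_meas=off["G"].to_numpy(float),
        t_online=on["t"].to_numpy(float),
        f_online=on["f"].to_numpy(float),
        T_online=on["T"].to_numpy(float),
        V0=float(man["V0"]),
        X0=float(man["X0"]),
        Gf=float(man["Gf"]),
        sampling_events=[SamplingEvent(e["t_sample"], e["volume_removed"])
                         for e in man["sampling_events"]],
        design_point=(man["design_point"]["mu_f"], man["design_point"]["T"]),
        base_params=None if base is None else BaseFeedParams(**base),
        G_loq=float(man.get("G_loq", 0.1)),
    )


def save_dataset(records: list, out_dir, seed=None, meta: dict | None = None
                 ) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for r in records:
        save_record(r, out_dir / r.run_id)
    manifest = {"runs": [r.run_id for r in records], "seed": seed}
    manifest.update(meta or {})
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_dataset(path) -> list:
    path = Path(path)
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    return [load_record(path / rid) for rid in manifest["runs"]]
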