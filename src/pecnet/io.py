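"""File I/O: HDF5 cohort containers with JSON sidecars, lead fields, and
delimited-text result tables."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import SensorEpochs
from .synthetic import (Cohort, GroundTruth, LeadField, SimulationConfig,
                        SubjectRecord)


def save_subject(path: Path, rec: SubjectRecord) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("continuous", data=rec.continuous)
        f.create_dataset("onsets", data=rec.onsets)
        f.create_dataset("epochs/data", data=rec.epochs.data)
        f.create_dataset("epochs/times", data=rec.epochs.epoch_times)
        f.attrs["fs"] = rec.fs
        f.attrs["subject_id"] = rec.subject_id
        f.attrs["group"] = rec.group
        f.attrs["seed"] = rec.seed
    sidecar = {
        "subject_id": rec.subject_id, "group": rec.group, "seed": rec.seed,
        "coupled_pairs": [[int(i), int(j), float(r), float(rr)]
                          for i, j, r, rr in rec.ground_truth.coupled_pairs],
        "subject_seeds": rec.ground_truth.subject_seeds,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_subject(path: Path) -> SubjectRecord:
    path = Path(path)
    with h5py.File(path, "r") as f:
        continuous = f["continuous"][()]
        onsets = f["onsets"][()]
        epochs = SensorEpochs(data=f["epochs/data"][()], fs=float(f.attrs["fs"]),
                              epoch_times=f["epochs/times"][()])
        fs = float(f.attrs["fs"])
        sid = str(f.attrs["subject_id"])
        group = str(f.attrs["group"])
        seed = int(f.attrs["seed"])
    side = json.loads(path.with_suffix(".json").read_text())
    gt = GroundTruth(
        coupled_pairs=[(int(i), int(j), float(r), float(rr))
                       for i, j, r, rr in side["coupled_pairs"]],
        subject_seeds={k: int(v) for k, v in side["subject_seeds"].items()})
    return SubjectRecord(subject_id=sid, group=group, seed=seed,
                         continuous=continuous, onsets=onsets, epochs=epochs,
                         ground_truth=gt, fs=fs)


def save_leadfield(path: Path, lf: LeadField) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("gain", data=lf.gain)


def load_leadfield(path: Path) -> LeadField:
    with h5py.File(path, "r") as f:
        return LeadField(gain=f["gain"][()])


def save_cohort(outdir: Path, cohort: Cohort) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_leadfield(outdir / "leadfield.h5", cohort.leadfield)
    paths = []
    for rec in cohort.subjects:
        p = outdir / f"{rec.subject_id}.h5"
        save_subject(p, rec)
        paths.append(p)
    return paths


def load_cohort_subjects(outdir: Path) -> tuple[list[SubjectRecord], LeadField]:
    outdir = Path(outdir)
    subs = [load_subject(p) for p in sorted(outdir.glob("*.h5"))
            if p.name != "leadfield.h5"]
    return subs, load_leadfield(outdir / "leadfield.h5")


def save_matrix_txt(path: Path, matrix: np.ndarray) -> None:
    np.savetxt(path, np.asarray(matrix), fmt="%.8g", delimiter="\t")


def save_features_csv(path: Path, features: np.ndarray,
                      subject_ids: list[str], groups: list[str]) -> None:
    df = pd.DataFrame(features,
                      columns=[f"edge{k}" for k in range(features.shape[1])])
    df.insert(0, "group", groups)
    df.insert(0, "subject", subject_ids)
    df.to_csv(path, index=False)
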