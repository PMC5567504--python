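"""Readers and writers for the pipeline's plain-text formats.

Phenotype tables are CSV; ROI time courses are TSV with a header row of ROI
names; FD series are one float per line; connectivity matrices are CSV with
ROI names as both header row and index column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix, TimeCourse
from .mapper import ClinicalMatrix

PHENOTYPE_COLUMNS = [
    "subject_id", "group", "adhd_index", "inattentive", "hyper_impulsive",
    "fsiq", "viq", "piq", "age",
]


def write_phenotype_csv(M: ClinicalMatrix, path, ages=None) -> None:
    df = M.to_frame()
    if ages is None:
        ages = getattr(M, "ages", None)
    if ages is not None:
        df["age"] = np.asarray(ages, dtype=float)
    df.to_csv(path, index=False)


def read_phenotype_csv(path) -> ClinicalMatrix:
    df = pd.read_csv(path)
    M = ClinicalMatrix.from_phenotype(df)
    if "age" in df.columns:
        M.ages = df["age"].to_numpy(dtype=float)
    return M


def write_timecourse_tsv(data: np.ndarray, roi_names, path) -> None:
    pd.DataFrame(np.asarray(data), columns=list(roi_names)).to_csv(
        path, sep="\t", index=False
    )


def write_fd(fd, path) -> None:
    np.savetxt(path, np.asarray(fd, dtype=float), fmt="%.6f")


def read_timecourse(tc_path, fd_path) -> TimeCourse:
    df = pd.read_csv(tc_path, sep="\t")
    fd = np.loadtxt(fd_path, ndmin=1)
    return TimeCourse(df.to_numpy(dtype=float), list(df.columns), fd)


def write_connectivity_csv(R: ConnectivityMatrix, path) -> None:
    pd.DataFrame(R.values, index=R.roi_names, columns=R.roi_names).to_csv(path)


def read_connectivity_csv(path) -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0)
    return ConnectivityMatrix(df.to_numpy(dtype=float), list(df.columns))


def write_partition_csv(assignment: dict, path) -> None:
    pd.DataFrame(
        sorted(assignment.items()), columns=["roi", "module"]
    ).to_csv(path, index=False)


def read_partition_csv(path) -> dict:
    df = pd.read_csv(path)
    return dict(zip(df["roi"], df["module"]))


def write_flares_csv(flares, path) -> None:
    rows = []
    for i, fl in enumerate(flares):
        for s in sorted(fl.subjects):
            rows.append((i, fl.majority_label, s, s in fl.peripheral))
    pd.DataFrame(
        rows, columns=["flare", "majority_label", "subject_id", "peripheral"]
    ).to_csv(path, index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
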