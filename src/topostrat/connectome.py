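"""Functional connectivity matrices from ROI time courses.

Consumes preprocessed, band-pass-filtered regional time courses (one frames
x ROI matrix per subject) plus a per-frame framewise-displacement (FD)
series.  High-motion frames are scrubbed, Pearson correlation networks are
computed per subject, and group-representative matrices are obtained by
elementwise averaging.  Negative weights are zeroed only when building the
graph used by centrality and modularity analyses; the signed matrices are
kept for connectivity-density statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np


@dataclass
class TimeCourse:
    """Frames x ROI signal matrix with per-frame head-motion magnitude."""

    data: np.ndarray
    roi_names: list[str]
    fd: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.fd = np.asarray(self.fd, dtype=float)
        self.roi_names = list(self.roi_names)
        if self.data.ndim != 2:
            raise ValueError("data must be frames x ROI")
        if len(self.roi_names) != self.data.shape[1]:
            raise ValueError("roi_names length must match ROI count")
        if self.fd.shape[0] != self.data.shape[0]:
            raise ValueError("fd length must match frame count")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass
class ConnectivityMatrix:
    """ROI x ROI Pearson correlation matrix (symmetric, unit diagonal)."""

    values: np.ndarray
    roi_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.roi_names = list(self.roi_names)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or len(self.roi_names) != n:
            raise ValueError("values must be square and match roi_names")


def scrub(tc: TimeCourse, threshold: float = 1.0) -> TimeCourse:
    """Drop frames whose framewise displacement exceeds the threshold (mm).

    Strictly greater-than: a frame at exactly the threshold is kept.  Only
    offending frames are removed — no neighbour augmentation.  Fewer than
    two surviving frames is an error (correlation would be undefined).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    keep = tc.fd <= threshold
    if keep.sum() < 2:
        raise ValueError(
            f"scrubbing at {threshold} mm leaves {int(keep.sum())} frames "
            "(need >= 2)"
        )
    return TimeCourse(tc.data[keep], tc.roi_names, tc.fd[keep])


def correlation_network(tc: TimeCourse) -> ConnectivityMatrix:
    """Pearson correlations between all ROI pairs of (scrubbed) series."""
    if tc.n_frames < 2:
        raise ValueError("need at least 2 frames")
    sds = tc.data.std(axis=0)
    dead = np.flatnonzero(sds == 0)
    if dead.size:
        raise ValueError(
            f"ROI {tc.roi_names[dead[0]]!r} has zero variance"
        )
    R = np.corrcoef(tc.data, rowvar=False)
    np.fill_diagonal(R, 1.0)
    return ConnectivityMatrix(R, tc.roi_names)


def positive_adjacency(R: ConnectivityMatrix) -> np.ndarray:
    """Off-diagonal non-negative part of R: negatives to 0, zero diagonal."""
    A = np.maximum(R.values, 0.0)
    np.fill_diagonal(A, 0.0)
    return A


def positive_graph(R: ConnectivityMatrix) -> nx.Graph:
    """Weighted undirected graph on the positive correlations.

    Negative off-diagonal entries become absent edges (weight zero) and
    self-loops are removed; all ROIs are present as nodes even if isolated.
    This adjacency is the substrate for all centrality and modularity
    computations.
    """
    A = positive_adjacency(R)
    g = nx.Graph()
    g.add_nodes_from(R.roi_names)
    rows, cols = np.nonzero(np.triu(A, k=1))
    g.add_weighted_edges_from(
        (R.roi_names[i], R.roi_names[j], float(A[i, j]))
        for i, j in zip(rows, cols)
    )
    return g


def group_mean_network(
    matrices: list[ConnectivityMatrix], fisher: bool = False
) -> ConnectivityMatrix:
    """Elementwise mean of subject matrices (the group-representative net).

    Plain arithmetic mean of raw r values by default; ``fisher=True``
    averages on the z scale (arctanh) and transforms back.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    names = matrices[0].roi_names
    for m in matrices[1:]:
        if m.roi_names != names:
            raise ValueError("matrices have heterogeneous ROI sets")
    stack = np.stack([m.values for m in matrices])
    if fisher:
        with np.errstate(divide="ignore"):
            mean = np.tanh(np.arctanh(np.clip(stack, -1, 1)).mean(axis=0))
        np.fill_diagonal(mean, 1.0)
    else:
        mean = stack.mean(axis=0)
    return ConnectivityMatrix(mean, names)


def power_fd(motion_params: np.ndarray, head_radius_mm: float = 50.0) -> np.ndarray:
    """Framewise displacement from six realignment parameters.

    Columns: three translations (mm) and three rotations (radians); FD is
    the sum of absolute backward differences with rotations converted to arc
    length on a sphere of ``head_radius_mm``.  First frame gets FD 0.
    Optional helper — the pipeline normally consumes FD files as given.
    """
    mp = np.asarray(motion_params, dtype=float)
    if mp.ndim != 2 or mp.shape[1] != 6:
        raise ValueError("motion_params must be frames x 6")
    diffs = np.abs(np.diff(mp, axis=0))
    diffs[:, 3:] *= head_radius_mm
    fd = np.zeros(mp.shape[0])
    fd[1:] = diffs.sum(axis=1)
    return fd
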