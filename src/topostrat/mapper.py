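"""Patient-patient network construction via Mapper.

The stratification pipeline: z-score clinical features against a reference
(control) group, compute Euclidean distances between subjects, use
L-infinity centrality as a one-dimensional lens, and build the Mapper nerve
graph — overlapping intervals over the lens range, single-linkage clustering
of each interval's preimage, one node per cluster, an edge wherever two
clusters share a subject.  Subgroups appear as flares (branches) of the
graph; subjects at flare tips carry the most extreme lens values.

Everything here is deterministic: no randomness enters the pipeline.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter, deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster
from scipy.cluster.hierarchy import single as single_linkage
from scipy.spatial.distance import pdist, squareform

#: canonical clinical feature order: three symptom scores, three IQ scores
CLINICAL_FEATURES = (
    "adhd_index",
    "inattentive",
    "hyper_impulsive",
    "fsiq",
    "viq",
    "piq",
)


@dataclass
class ClinicalMatrix:
    """Subjects x features matrix of clinical scores with group labels.

    Parameters
    ----------
    values : (n_subjects, n_features) array
        One row per subject, one column per clinical variable.
    subject_ids, feature_names, group_labels : sequences
        Row identifiers, column names, and per-subject group membership.
    """

    values: np.ndarray
    subject_ids: list[str]
    feature_names: list[str]
    group_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_ids = list(self.subject_ids)
        self.feature_names = list(self.feature_names)
        self.group_labels = list(self.group_labels)
        n, p = self.values.shape
        if n < 2:
            raise ValueError("need at least 2 subjects")
        if p < 1:
            raise ValueError("need at least 1 feature")
        if len(self.subject_ids) != n or len(self.group_labels) != n:
            raise ValueError("subject_ids/group_labels length mismatch")
        if len(self.feature_names) != p:
            raise ValueError("feature_names length mismatch")
        if np.isnan(self.values).any():
            raise ValueError("missing entries are not allowed")

    @classmethod
    def from_phenotype(
        cls,
        pheno: pd.DataFrame,
        feature_names: tuple[str, ...] = CLINICAL_FEATURES,
    ) -> "ClinicalMatrix":
        """Build from a phenotype table with subject_id and group columns."""
        return cls(
            values=pheno.loc[:, list(feature_names)].to_numpy(dtype=float),
            subject_ids=[str(s) for s in pheno["subject_id"]],
            feature_names=list(feature_names),
            group_labels=[str(g) for g in pheno["group"]],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "group", self.group_labels)
        df.insert(0, "subject_id", self.subject_ids)
        return df


@dataclass
class NormalizationParams:
    """Reference-group feature means and population SDs used for z-scoring."""

    ref_means: np.ndarray
    ref_sds: np.ndarray
    feature_names: list[str]
    reference_ids: list[str]


def fit_reference_normalization(
    M: ClinicalMatrix, reference_ids: list[str]
) -> NormalizationParams:
    """Estimate per-feature mean and population SD from reference subjects.

    The SD divides by the number of reference subjects (population SD), so a
    single reference subject — or any constant reference column — is an
    error: the scale would be zero.
    """
    ref_set = set(reference_ids)
    unknown = ref_set - set(M.subject_ids)
    if unknown:
        raise ValueError(f"reference ids not in matrix: {sorted(unknown)}")
    rows = [i for i, s in enumerate(M.subject_ids) if s in ref_set]
    ref = M.values[rows]
    means = ref.mean(axis=0)
    sds = ref.std(axis=0, ddof=0)
    for j, sd in enumerate(sds):
        if sd == 0:
            raise ValueError(
                f"reference feature {M.feature_names[j]!r} has zero spread"
            )
    return NormalizationParams(
        ref_means=means,
        ref_sds=sds,
        feature_names=list(M.feature_names),
        reference_ids=[M.subject_ids[i] for i in rows],
    )


def normalize(M: ClinicalMatrix, params: NormalizationParams) -> ClinicalMatrix:
    """z-score every subject against the reference mean/SD, per feature."""
    if list(M.feature_names) != list(params.feature_names):
        raise ValueError("feature names do not match normalization params")
    values = (M.values - params.ref_means) / params.ref_sds
    return ClinicalMatrix(values, M.subject_ids, M.feature_names, M.group_labels)


def denormalize(M: ClinicalMatrix, params: NormalizationParams) -> ClinicalMatrix:
    """Invert :func:`normalize` with the same parameters."""
    if list(M.feature_names) != list(params.feature_names):
        raise ValueError("feature names do not match normalization params")
    values = M.values * params.ref_sds + params.ref_means
    return ClinicalMatrix(values, M.subject_ids, M.feature_names, M.group_labels)


def euclidean_distances(M: ClinicalMatrix) -> np.ndarray:
    """Full symmetric subject-by-subject Euclidean distance matrix."""
    return squareform(pdist(M.values, metric="euclidean"))


def linf_centrality(D: np.ndarray) -> np.ndarray:
    """L-infinity centrality lens: f_a = max_b D_ab.

    The maximal distance from each subject to any other subject; extreme
    values of this lens land at the tips of flares in the Mapper graph.
    """
    D = np.asarray(D, dtype=float)
    return D.max(axis=1)


@dataclass
class CoverConfig:
    """Mapper cover and in-interval clustering parameters.

    n_intervals uniform-width intervals span the lens range; each is widened
    symmetrically so that adjacent intervals overlap by ``overlap_frac`` of
    their (widened) width.  Within each interval's preimage, single-linkage
    merge heights are histogrammed into ``cluster_bins`` bins and the tree is
    cut at the first gap — the first empty bin after the populated region
    begins (one cluster if there is no gap); singleton clusters produced by
    the cut are reattached to the nearest multi-member cluster.

    Few wide intervals and a coarse height histogram are deliberate: the cut
    should fire only on order-of-magnitude jumps in merge height (distinct
    subject blobs sharing an interval), not on the tail of within-blob merge
    heights, and wide intervals give adjacent blobs enough co-presence to
    form the junction node where branches meet.
    """

    n_intervals: int = 4
    overlap_frac: float = 0.45
    cluster_bins: int = 3

    def __post_init__(self) -> None:
        if self.n_intervals < 1:
            raise ValueError("n_intervals must be >= 1")
        if not 0 < self.overlap_frac < 1:
            raise ValueError("overlap_frac must be in (0, 1)")
        if self.cluster_bins < 1:
            raise ValueError("cluster_bins must be >= 1")


class MapperGraph:
    """Nerve graph over subject clusters (the patient-patient network).

    Wraps a :class:`networkx.Graph` whose nodes are ``(interval, cluster)``
    pairs carrying a ``members`` attribute (frozenset of subject ids) and
    whose edges carry ``weight`` = number of shared subjects.
    """

    def __init__(
        self,
        graph: nx.Graph,
        subject_ids: list[str],
        group_labels: list[str] | None = None,
    ) -> None:
        self.graph = graph
        self.subject_ids = list(subject_ids)
        self.group_labels = list(group_labels) if group_labels is not None else None

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def members(self, node) -> frozenset:
        return self.graph.nodes[node]["members"]

    def covered_subjects(self) -> set:
        out: set = set()
        for n in self.graph.nodes:
            out |= self.members(n)
        return out

    def to_graphml(self, path) -> None:
        g = nx.Graph()
        for n, data in self.graph.nodes(data=True):
            attrs = {
                "size": len(data["members"]),
                "members": ";".join(sorted(data["members"])),
                "interval": n[0],
                "cluster": n[1],
            }
            for key, val in data.items():
                if key != "members":
                    attrs[key] = val
            g.add_node(f"{n[0]}_{n[1]}", **attrs)
        for u, v, data in self.graph.edges(data=True):
            g.add_edge(f"{u[0]}_{u[1]}", f"{v[0]}_{v[1]}", weight=data["weight"])
        nx.write_graphml(g, path)

    def to_json(self, path) -> None:
        payload = {
            "nodes": [
                {
                    "id": f"{n[0]}_{n[1]}",
                    "interval": n[0],
                    "cluster": n[1],
                    "members": sorted(data["members"]),
                    **{
                        k: v
                        for k, v in data.items()
                        if k != "members"
                    },
                }
                for n, data in self.graph.nodes(data=True)
            ],
            "edges": [
                {"source": f"{u[0]}_{u[1]}", "target": f"{v[0]}_{v[1]}",
                 "weight": d["weight"]}
                for u, v, d in self.graph.edges(data=True)
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _cover_intervals(f: np.ndarray, cover: CoverConfig) -> list[tuple[float, float]]:
    lo, hi = float(f.min()), float(f.max())
    if hi == lo:
        return [(lo, hi)]
    step = (hi - lo) / cover.n_intervals
    width = step / (1.0 - cover.overlap_frac)
    pad = (width - step) / 2.0
    return [
        (lo + i * step - pad, lo + (i + 1) * step + pad)
        for i in range(cover.n_intervals)
    ]


def _cluster_interval(subD: np.ndarray, bins: int) -> np.ndarray:
    """Single linkage cut at the first gap in the merge-height histogram.

    The gap is the first empty bin after the populated region begins;
    leading empty bins only say the smallest merge is not tiny and must not
    trigger a cut.  Singletons split off by the cut are reattached to the
    nearest multi-member cluster: a lone subject is an outlier of its blob,
    not a blob of its own.
    """
    n = subD.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int)
    Z = single_linkage(squareform(subD, checks=False))
    heights = Z[:, 2]
    hmax = heights.max()
    if hmax == 0:
        return np.zeros(n, dtype=int)
    counts, edges = np.histogram(heights, bins=bins, range=(0.0, hmax))
    first_used = np.argmax(counts > 0)
    gaps = np.flatnonzero(counts[first_used:] == 0)
    if gaps.size == 0:
        return np.zeros(n, dtype=int)
    cut = edges[first_used + gaps[0]]
    labels = fcluster(Z, t=cut, criterion="distance") - 1
    sizes = np.bincount(labels)
    anchors = np.flatnonzero(sizes >= 2)
    if anchors.size == 0:
        return np.zeros(n, dtype=int)
    for c in np.flatnonzero(sizes == 1):
        i = int(np.flatnonzero(labels == c)[0])
        labels[i] = min((subD[i, labels == a].min(), a) for a in anchors)[1]
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def build_mapper(
    D: np.ndarray,
    f: np.ndarray,
    cover: CoverConfig | None = None,
    subject_ids: list[str] | None = None,
    group_labels: list[str] | None = None,
) -> MapperGraph:
    """Construct the Mapper nerve graph from distances and a 1-D lens.

    Intervals with empty preimage are skipped; an edge joins two nodes iff
    their subject sets intersect, weighted by the intersection size.
    """
    D = np.asarray(D, dtype=float)
    f = np.asarray(f, dtype=float)
    if D.size == 0 or f.size == 0:
        raise ValueError("empty input")
    if D.shape[0] != D.shape[1] or D.shape[0] != f.shape[0]:
        raise ValueError("D and f must cover the same subjects")
    cover = cover or CoverConfig()
    ids = list(subject_ids) if subject_ids is not None else [
        str(i) for i in range(len(f))
    ]

    g = nx.Graph()
    node_members: dict[tuple[int, int], frozenset] = {}
    for i, (lo, hi) in enumerate(_cover_intervals(f, cover)):
        idx = np.flatnonzero((f >= lo) & (f <= hi))
        if idx.size == 0:
            continue
        labels = _cluster_interval(D[np.ix_(idx, idx)], cover.cluster_bins)
        for c in np.unique(labels):
            members = frozenset(ids[j] for j in idx[labels == c])
            node = (i, int(c))
            node_members[node] = members
            g.add_node(node, members=members)
    nodes = list(node_members)
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            shared = node_members[nodes[a]] & node_members[nodes[b]]
            if shared:
                g.add_edge(nodes[a], nodes[b], weight=len(shared))
    return MapperGraph(g, ids, group_labels)


def map_attribute(graph: MapperGraph, values) -> dict:
    """Per-node arithmetic mean of a per-subject attribute.

    ``values`` is a mapping subject id -> number (or a sequence aligned with
    the graph's subject order).  Every covered subject must have a value.
    """
    if not isinstance(values, dict):
        seq = np.asarray(values, dtype=float)
        if seq.shape[0] != len(graph.subject_ids):
            raise ValueError("attribute length does not match subjects")
        values = dict(zip(graph.subject_ids, seq))
    missing = graph.covered_subjects() - set(values)
    if missing:
        raise ValueError(f"missing attribute values for: {sorted(missing)[:5]}")
    return {
        n: float(np.mean([values[s] for s in graph.members(n)]))
        for n in graph.graph.nodes
    }


@dataclass
class Flare:
    """A branch of the patient-patient network.

    Nodes are ordered outward from the junction they attach to (breadth
    first); ``subjects`` is the union of node memberships; the majority
    group label breaks ties alphabetically.
    """

    nodes: list
    subjects: set
    majority_label: str | None
    node_members: list = field(default_factory=list)
    peripheral: list = field(default_factory=list)


def extract_flares(graph: MapperGraph) -> list[Flare]:
    """Split the graph into flares: junctions are nodes of degree >= 3,
    flares are the connected components left after removing junctions.

    A connected component containing no junction is a single flare.
    """
    g = graph.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    junctions = {n for n in g.nodes if g.degree(n) >= 3}
    rest = g.subgraph(n for n in g.nodes if n not in junctions)
    flares = []
    for comp in nx.connected_components(rest):
        ordered = _order_from_junction(g, comp, junctions)
        subjects: set = set()
        for n in ordered:
            subjects |= graph.members(n)
        label = None
        if graph.group_labels is not None:
            lab = dict(zip(graph.subject_ids, graph.group_labels))
            counts = Counter(lab[s] for s in subjects)
            top = max(counts.values())
            label = sorted(l for l, c in counts.items() if c == top)[0]
        flares.append(
            Flare(
                nodes=ordered,
                subjects=subjects,
                majority_label=label,
                node_members=[graph.members(n) for n in ordered],
            )
        )
    return flares


def _order_from_junction(g: nx.Graph, comp: set, junctions: set) -> list:
    """BFS order starting at nodes adjacent to a junction (attachment end)."""
    roots = sorted(
        n for n in comp if any(nb in junctions for nb in g.neighbors(n))
    )
    if not roots:
        roots = [sorted(comp)[0]]
    seen = dict.fromkeys(roots)
    queue = deque(roots)
    while queue:
        n = queue.popleft()
        for nb in sorted(g.neighbors(n)):
            if nb in comp and nb not in seen:
                seen[nb] = None
                queue.append(nb)
    return list(seen)


def select_peripheral(flare: Flare, f, k: int = 15, direction: str = "high") -> list:
    """The k flare members at the extreme peripheral end of the branch.

    Branch tips carry extreme lens values — highest for a branch that climbs
    away from its junction, lowest for one that descends.  ``direction``
    selects which end: "high" (default) ranks by largest lens value, "low"
    by smallest, and "auto" compares the branch's tip nodes (last in the
    outward ordering) with its attachment nodes and picks the outward end.

    ``f`` maps subject id -> lens value (or is a sequence when subject ids
    are stringified indices).  Ties break by subject id; if the flare has
    fewer than k members, all are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if direction not in ("high", "low", "auto"):
        raise ValueError("direction must be 'high', 'low' or 'auto'")
    if not isinstance(f, dict):
        f = {str(i): float(v) for i, v in enumerate(np.asarray(f, dtype=float))}
    if direction == "auto":
        direction = _outward_direction(flare, f)
    sign = -1.0 if direction == "high" else 1.0
    ranked = sorted(sorted(flare.subjects), key=lambda s: (sign * f[s], s))
    if len(ranked) < k:
        warnings.warn(
            f"flare has only {len(ranked)} members (< k={k}); returning all",
            stacklevel=2,
        )
        return ranked
    return ranked[:k]


def _outward_direction(flare: Flare, f: dict) -> str:
    """Does the branch climb or descend in lens value, junction to tip?"""
    if len(flare.node_members) < 2:
        return "high"
    root = float(np.mean([f[s] for s in flare.node_members[0]]))
    tip = float(np.mean([f[s] for s in flare.node_members[-1]]))
    return "high" if tip >= root else "low"


@dataclass
class StratificationResult:
    """Output bundle of the end-to-end stratification pipeline."""

    matrix: ClinicalMatrix
    params: NormalizationParams
    distances: np.ndarray
    lens: np.ndarray
    graph: MapperGraph
    flares: list[Flare]


def stratify_cohort(
    M: ClinicalMatrix,
    reference_group: str = "TDC",
    cover: CoverConfig | None = None,
    k_peripheral: int = 15,
) -> StratificationResult:
    """Run the full pipeline: reference z-scoring, distances, L-infinity
    lens, Mapper graph, flare extraction and peripheral selection."""
    reference_ids = [
        s for s, g in zip(M.subject_ids, M.group_labels) if g == reference_group
    ]
    if not reference_ids:
        raise ValueError(f"no subjects in reference group {reference_group!r}")
    params = fit_reference_normalization(M, reference_ids)
    Mhat = normalize(M, params)
    D = euclidean_distances(Mhat)
    f = linf_centrality(D)
    graph = build_mapper(D, f, cover, M.subject_ids, M.group_labels)
    flares = extract_flares(graph)
    fmap = dict(zip(M.subject_ids, f))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for fl in flares:
            fl.peripheral = select_peripheral(fl, fmap, k=k_peripheral,
                                              direction="auto")
    return StratificationResult(M, params, D, f, graph, flares)
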