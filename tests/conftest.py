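import networkx as nx
import numpy as np
import pytest

from topostrat import (
    ClinicalMatrix,
    MapperGraph,
    gen_clinical_cohort,
    principal_cohort_specs,
)


@pytest.fixture(scope="session")
def small_cohort() -> ClinicalMatrix:
    """15/15/15 cohort from the default group presets, fixed seed."""
    return gen_clinical_cohort(principal_cohort_specs(15, 15, 15), seed=11)


@pytest.fixture(scope="session")
def topology_cohort() -> ClinicalMatrix:
    """60/30/30 cohort sized for topology-recovery checks, fixed seed."""
    return gen_clinical_cohort(principal_cohort_specs(60, 30, 30), seed=5)


def make_mapper_graph(edges, members, labels=None) -> MapperGraph:
    """Assemble a MapperGraph by hand for flare-extraction tests."""
    g = nx.Graph()
    for node, mem in members.items():
        g.add_node(node, members=frozenset(mem))
    for u, v in edges:
        shared = g.nodes[u]["members"] & g.nodes[v]["members"]
        g.add_edge(u, v, weight=max(len(shared), 1))
    ids = sorted(set().union(*[set(m) for m in members.values()]))
    group_labels = [labels[s] for s in ids] if labels else None
    return MapperGraph(g, ids, group_labels)


def exact_summary_sample(mean: float, sd: float, n: int, rng) -> np.ndarray:
    """A sample of size n whose mean and sample SD (ddof=1) are exact."""
    z = rng.standard_normal(n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z
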