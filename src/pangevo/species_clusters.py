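"""Genomic-species delineation: thresholded ANI graph + Markov clustering.

Genomes whose average nucleotide identity (ANI) meets the classical 95%
intra-species boundary are linked in an undirected weighted graph; Markov
clustering (MCL) of that graph yields genomic-species clusters.  Because ANI
programs report each direction of a comparison separately and the two values
can differ slightly, an edge is kept when *either* direction passes the
threshold, with the edge weight set to the mean of the available directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import AniPairList


@dataclass
class MclConfig:
    """Markov-clustering parameters.

    inflation > 1 sharpens the random-walk matrix (higher -> finer
    clusters); expansion is the matrix-power step; entries below
    ``prune_epsilon`` are zeroed each round for sparsity and determinism.
    """

    inflation: float = 2.0
    expansion: int = 2
    prune_epsilon: float = 1e-6
    max_iterations: int = 200
    tolerance: float = 1e-6
    binary_edges: bool = False

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be an integer >= 2")


@dataclass
class SpeciesClustering:
    """genome -> cluster-label partition.

    Labels are assigned in order of descending cluster size, ties broken by
    the lexicographically smallest member, so the labelling is deterministic
    under any input permutation.
    """

    assignments: dict[str, str]
    converged: bool = True
    n_iterations: int = 0

    @property
    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for genome, label in self.assignments.items():
            out.setdefault(label, []).append(genome)
        return {k: sorted(v) for k, v in out.items()}

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignments.values()))


def build_ani_graph(
    pairs: AniPairList,
    threshold: float = 95.0,
    roster: Optional[Sequence[str]] = None,
) -> nx.Graph:
    """Build the thresholded undirected ANI graph.

    Every genome mentioned in ``pairs`` (either direction) is a node;
    ``roster`` adds genomes with no surviving comparisons as isolated
    nodes.  Self-comparisons are dropped.  An unordered pair becomes an
    edge iff max(ANI(A->B), ANI(B->A)) >= threshold; the edge weight is the
    mean of the available directions.
    """
    if not (0 < threshold <= 100):
        raise ValueError("threshold must lie in (0, 100]")
    graph = nx.Graph(threshold=threshold)
    directional: dict[tuple[str, str], list[float]] = {}
    for rec in pairs:
        graph.add_node(rec.query)
        graph.add_node(rec.reference)
        if rec.query == rec.reference:
            continue
        key = tuple(sorted((rec.query, rec.reference)))
        directional.setdefault(key, []).append(rec.ani)
    if roster is not None:
        graph.add_nodes_from(roster)
    if graph.number_of_nodes() == 0:
        raise ValueError("empty ANI pair list and no genome roster supplied")
    for (a, b), values in directional.items():
        if max(values) >= threshold:
            graph.add_edge(a, b, weight=float(np.mean(values)))
    return graph


def _stochastic(matrix: np.ndarray) -> np.ndarray:
    colsum = matrix.sum(axis=0)
    colsum[colsum == 0] = 1.0
    return matrix / colsum


def mcl(graph: nx.Graph, config: Optional[MclConfig] = None) -> SpeciesClustering:
    """Markov clustering of the ANI graph.

    The transition matrix is built from edge weights (or 0/1 with
    ``binary_edges``) with a self-loop on each node equal to its maximum
    incident edge weight (1 for isolated nodes), guaranteeing aperiodicity.
    Expansion (matrix power) and inflation (elementwise power + column
    renormalization) alternate, pruning entries below ``prune_epsilon``,
    until the largest column change falls under ``tolerance``.  Clusters are
    the connected components of the converged matrix's nonzero structure —
    the attractor basins — so nodes from different components of the input
    graph are never merged.
    """
    config = config or MclConfig()
    nodes = sorted(graph.nodes)
    if not nodes:
        raise ValueError("MCL requires a non-empty node set")
    n = len(nodes)
    index = {g: i for i, g in enumerate(nodes)}
    mat = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = 1.0 if config.binary_edges else float(data.get("weight", 1.0))
        mat[index[a], index[b]] = w
        mat[index[b], index[a]] = w
    loops = mat.max(axis=0)
    loops[loops == 0] = 1.0
    mat[np.diag_indices(n)] = loops
    mat = _stochastic(mat)

    converged = False
    iteration = 0
    for iteration in range(1, config.max_iterations + 1):
        expanded = np.linalg.matrix_power(mat, config.expansion)
        inflated = _stochastic(np.power(expanded, config.inflation))
        inflated[inflated < config.prune_epsilon] = 0.0
        inflated = _stochastic(inflated)
        change = np.abs(inflated - mat).max()
        mat = inflated
        if change < config.tolerance:
            converged = True
            break
    if not converged:
        import warnings

        warnings.warn(
            f"MCL did not converge in {config.max_iterations} iterations; "
            "returning current clustering",
            stacklevel=2,
        )

    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(mat)
    support.add_edges_from(zip(rows.tolist(), cols.tolist()))
    components = [sorted(nodes[i] for i in comp) for comp in nx.connected_components(support)]
    components.sort(key=lambda members: (-len(members), members[0]))

    assignments = {
        genome: f"C{rank}" for rank, members in enumerate(components, 1) for genome in members
    }
    return SpeciesClustering(assignments=assignments, converged=converged, n_iterations=iteration)


def cluster_summary(clustering: SpeciesClustering) -> pd.DataFrame:
    """Per-cluster summary table sorted by descending size (then smallest
    member), mirroring the "most prevalent clusters first" convention."""
    rows = [
        {"cluster": label, "size": len(members), "members": ",".join(members)}
        for label, members in clustering.clusters.items()
    ]
    if not rows:
        return pd.DataFrame(columns=["cluster", "size", "members"])
    df = pd.DataFrame(rows)
    df["_first"] = [m.split(",")[0] for m in df["members"]]
    df = df.sort_values(["size", "_first"], ascending=[False, True]).drop(columns="_first")
    return df.reset_index(drop=True)
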