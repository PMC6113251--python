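"""Correlation-weighted residue interaction networks.

Nodes are residues (one marker atom each, Cα by default). An edge joins two
nonconsecutive residues whose marker atoms stay within a distance cutoff
(default 4.5 Å) for at least a threshold fraction of frames (default 75%).
Edges are weighted w_ij = -log(|C_ij|) from the dynamic cross-correlation,
so highly correlated residues are "close" in the information-transfer sense.
All-pairs shortest paths come from Floyd–Warshall; the mean of the finite
off-diagonal path lengths is the critical path length (CPL). Communities are
found by Girvan–Newman edge-betweenness removal, with the partition chosen
to maximize Newman–Girvan modularity Q.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from networkx.algorithms.community import modularity as _nx_modularity

from .corr_pca import CorrelationMatrix
from .trajio import AtomSelection, Trajectory

logger = logging.getLogger(__name__)

CORRELATION_FLOOR = 1e-6  # |C| below this is capped so weights stay finite


@dataclass
class ContactOccupancy:
    """Fraction of frames each nonconsecutive residue pair is in contact."""

    pairs: dict  # (pos_i, pos_j) i<j -> occupancy in [0, 1]
    nodes: list  # residue ids, one per selected marker atom (selection order)
    chain_of: dict  # node -> chain id
    cutoff: float
    window: tuple[int, int]


@dataclass
class ResidueNetwork:
    graph: nx.Graph  # nodes: positions 0..n-1; edges carry weight/correlation/occupancy
    nodes: list  # residue ids in position order
    chain_of: dict


@dataclass
class PathMatrix:
    D: np.ndarray  # node x node shortest path lengths (inf if unreachable)
    predecessors: np.ndarray
    cpl: float  # mean of finite off-diagonal entries
    n_unreachable_pairs: int
    nodes: list


@dataclass
class CommunityPartition:
    assignment: dict  # node position -> community id
    n_communities: int
    modularity: float
    removal_step: int = 0


def contact_occupancy(
    traj: Trajectory,
    node_selection: AtomSelection,
    cutoff: float = 4.5,
    window: tuple[int, int] | None = None,
) -> ContactOccupancy:
    """Contact occupancy of every nonconsecutive residue pair.

    ``node_selection`` must contain exactly one marker atom per residue
    (Cα by default usage). Consecutive residues of the same chain are
    excluded — they are covalently linked, and their correlation carries no
    contact information. The cutoff test is inclusive (distance <= cutoff).
    """
    if window is None:
        window = (0, traj.n_frames)
    a, b = window
    if not (0 <= a < b <= traj.n_frames):
        raise ValueError(f"window [{a}, {b}) invalid for {traj.n_frames} frames")

    atoms = [traj.structure.atoms[i] for i in node_selection.indices]
    res_ids = [at.residue_index for at in atoms]
    if len(set(res_ids)) != len(res_ids):
        dup = [r for r in set(res_ids) if res_ids.count(r) > 1]
        raise ValueError(
            f"node selection has multiple atoms for residue(s) {sorted(dup)}; "
            "one marker atom per residue required"
        )
    chain_of = {r: at.chain_id for r, at in zip(res_ids, atoms)}

    coords = traj.frames[a:b][:, node_selection.indices, :]
    n = len(res_ids)
    pairs: dict = {}
    # pairwise distances per frame, vectorized over frames
    for i, j in combinations(range(n), 2):
        if chain_of[res_ids[i]] == chain_of[res_ids[j]] and abs(res_ids[i] - res_ids[j]) == 1:
            continue  # consecutive residues of one chain
        d = np.linalg.norm(coords[:, i, :] - coords[:, j, :], axis=1)
        pairs[(i, j)] = float((d <= cutoff).mean())
    return ContactOccupancy(
        pairs=pairs, nodes=res_ids, chain_of=chain_of, cutoff=cutoff, window=(a, b)
    )


def edge_weight(correlation: float, floor: float = CORRELATION_FLOOR) -> float:
    """w = -log|C|, capped at -log(floor) so a near-zero correlation stays finite."""
    c = abs(correlation)
    if c < floor:
        return float(-np.log(floor))
    return float(-np.log(min(c, 1.0)))


def build_network(
    occupancy: ContactOccupancy,
    correlation: CorrelationMatrix,
    occupancy_threshold: float = 0.75,
) -> ResidueNetwork:
    """Edges where occupancy >= threshold, weighted by -log|C_ij|.

    The correlation matrix must be over the same marker-atom selection, in
    the same order, as the occupancy's nodes. |C| below the floor (1e-6) is
    capped with a warning rather than dropped: an infinite weight would
    silently delete topology.
    """
    n = len(occupancy.nodes)
    if correlation.matrix.shape[0] != n:
        raise ValueError(
            f"correlation is {correlation.matrix.shape[0]} nodes, "
            f"occupancy has {n}"
        )
    g = nx.Graph()
    for pos, res in enumerate(occupancy.nodes):
        g.add_node(pos, residue=res, chain=occupancy.chain_of[res])
    n_capped = 0
    for (i, j), occ in sorted(occupancy.pairs.items()):
        if occ >= occupancy_threshold:
            c = float(correlation.matrix[i, j])
            if abs(c) < CORRELATION_FLOOR:
                n_capped += 1
            g.add_edge(i, j, weight=edge_weight(c), correlation=c, occupancy=occ)
    if n_capped:
        logger.warning(
            "capped %d edge weight(s) at -log(%g): |C| below floor", n_capped,
            CORRELATION_FLOOR,
        )
    return ResidueNetwork(graph=g, nodes=occupancy.nodes, chain_of=occupancy.chain_of)


def shortest_paths(network: ResidueNetwork) -> PathMatrix:
    """All-pairs shortest path lengths (Floyd–Warshall) and the CPL.

    Unreachable pairs are infinite and excluded from the CPL; their count is
    reported separately.
    """
    from scipy.sparse.csgraph import floyd_warshall

    g = network.graph
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("path analysis needs at least 2 nodes")
    w = np.full((n, n), np.inf)
    np.fill_diagonal(w, 0.0)
    for i, j, data in g.edges(data=True):
        w[i, j] = w[j, i] = data["weight"]
    d, pred = floyd_warshall(w, directed=False, return_predecessors=True)
    iu = np.triu_indices(n, k=1)
    finite = np.isfinite(d[iu])
    cpl = float(d[iu][finite].mean()) if finite.any() else float("nan")
    return PathMatrix(
        D=d,
        predecessors=pred,
        cpl=cpl,
        n_unreachable_pairs=int((~finite).sum()),
        nodes=network.nodes,
    )


def reconstruct_path(paths: PathMatrix, source: int, sink: int) -> list[int]:
    """One optimal node sequence from the predecessor table."""
    if not np.isfinite(paths.D[source, sink]):
        return []
    seq = [sink]
    while seq[-1] != source:
        seq.append(int(paths.predecessors[source, seq[-1]]))
    return seq[::-1]


def suboptimal_paths(
    network: ResidueNetwork,
    source: int,
    sink: int,
    tolerance: float,
    max_paths: int = 100_000,
) -> dict:
    """All simple paths with length <= optimal + tolerance.

    Bounded depth-first enumeration, pruning any partial path whose length
    plus the remaining shortest distance to the sink exceeds the bound.
    Returns paths sorted by length (ties by node sequence) and a truncation
    flag if the path cap was hit.
    """
    if source == sink:
        raise ValueError("source and sink must differ")
    g = network.graph
    if source not in g or sink not in g:
        raise ValueError("source/sink not in network")
    # shortest distance from every node to the sink, for pruning
    dist_to_sink = nx.single_source_dijkstra_path_length(g, sink, weight="weight")
    if source not in dist_to_sink:
        return {"paths": [], "lengths": [], "optimal": float("inf"), "truncated": False}
    bound = dist_to_sink[source] + tolerance
    eps = 1e-12 * max(1.0, bound)

    found: list[tuple[float, tuple[int, ...]]] = []
    truncated = False
    stack = [(source, (source,), 0.0)]
    while stack:
        node, path, length = stack.pop()
        if node == sink:
            found.append((length, path))
            if len(found) >= max_paths:
                truncated = True
                break
            continue
        for nb in sorted(g.neighbors(node), reverse=True):
            if nb in path:
                continue
            nl = length + g[node][nb]["weight"]
            if nl + dist_to_sink.get(nb, np.inf) <= bound + eps:
                stack.append((nb, path + (nb,), nl))
    found.sort(key=lambda t: (t[0], t[1]))
    return {
        "paths": [list(p) for _, p in found],
        "lengths": [l for l, _ in found],
        "optimal": dist_to_sink[source],
        "truncated": truncated,
    }


def _partition_from_components(g: nx.Graph) -> list[set]:
    comps = [set(c) for c in nx.connected_components(g)]
    return sorted(comps, key=min)


def _modularity(orig: nx.Graph, communities: list[set], weighted: bool) -> float:
    if orig.number_of_edges() == 0:
        return 0.0
    return float(
        _nx_modularity(orig, communities, weight="weight" if weighted else None)
    )


def girvan_newman(
    network: ResidueNetwork, weighted_modularity: bool = False
) -> CommunityPartition:
    """Girvan–Newman community detection, best-modularity partition.

    Repeatedly removes the edge of highest betweenness (computed on the
    weighted graph, w as length, recomputed after every removal) and scores
    each distinct partition by modularity Q on the original edge set
    (unweighted by default, matching the classical formulation). Ties are
    deterministic: among equal-betweenness edges the lexicographically
    smallest (i, j) is removed; among equal-Q partitions the earliest in the
    removal sequence wins.
    """
    orig = network.graph
    n = orig.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    if n == 1:
        return CommunityPartition(
            assignment={next(iter(orig.nodes)): 0}, n_communities=1, modularity=0.0
        )

    work = orig.copy()
    best_comms = _partition_from_components(work)
    best_q = _modularity(orig, best_comms, weighted_modularity)
    best_step = 0
    step = 0
    while work.number_of_edges() > 0:
        bc = nx.edge_betweenness_centrality(work, weight="weight")
        max_b = max(bc.values())
        candidates = [
            tuple(sorted(e)) for e, v in bc.items() if v == max_b
        ]
        edge = min(candidates)
        work.remove_edge(*edge)
        step += 1
        comms = _partition_from_components(work)
        if len(comms) == len(best_comms) and step > 1:
            # component count unchanged: same partition, skip rescoring
            pass
        q = _modularity(orig, comms, weighted_modularity)
        if q > best_q + 1e-15:
            best_q, best_comms, best_step = q, comms, step

    assignment = {}
    for cid, comm in enumerate(sorted(best_comms, key=min)):
        for node in comm:
            assignment[node] = cid
    return CommunityPartition(
        assignment=assignment,
        n_communities=len(best_comms),
        modularity=best_q,
        removal_step=best_step,
    )


def interface_communities(
    partition: CommunityPartition, chain_map: dict
) -> list[int]:
    """Community ids whose nodes span more than one chain.

    ``chain_map`` maps every node of the partition to its chain id; a node
    missing from the map is an error.
    """
    by_comm: dict[int, set] = {}
    for node, cid in partition.assignment.items():
        if node not in chain_map:
            raise ValueError(f"node {node!r} missing from chain map")
        by_comm.setdefault(cid, set()).add(chain_map[node])
    return sorted(cid for cid, chains in by_comm.items() if len(chains) > 1)


def write_edge_list(network: ResidueNetwork, path) -> None:
    """Weighted edge list: res_i res_j weight correlation occupancy."""
    with open(path, "w") as fh:
        fh.write("# res_i res_j weight correlation occupancy\n")
        for i, j, data in sorted(network.graph.edges(data=True)):
            fh.write(
                f"{network.nodes[i]} {network.nodes[j]} "
                f"{data['weight']:.10g} {data['correlation']:.10g} "
                f"{data['occupancy']:.10g}\n"
            )


def write_gml(network: ResidueNetwork, partition: CommunityPartition | None, path) -> None:
    g = network.graph.copy()
    if partition is not None:
        nx.set_node_attributes(g, partition.assignment, "community")
    nx.write_gml(g, path)


def write_partition(partition: CommunityPartition, nodes: list, path) -> None:
    with open(path, "w") as fh:
        fh.write("# node community\n")
        for pos in sorted(partition.assignment):
            fh.write(f"{nodes[pos]} {partition.assignment[pos]}\n")
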