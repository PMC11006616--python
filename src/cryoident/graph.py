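"""Residue graph construction and chain post-processing.

Predicted residues form a graph in which each residue is a node with edges
to its k nearest neighbours (k = 20 by default). Chains are traced from that
graph by greedily linking nearest candidate pairs under a bond-length
cutoff, then post-processed: fragments assigned to the same sequence are
connected when their spatial gap is compatible with the number of missing
residues, and chains shorter than four residues are pruned.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .model import AtomicModel, Chain, Residue, Atom, ResiduePrediction

__all__ = ["ResidueGraph", "build_graph", "trace_fragments", "trace_chains",
           "fragments_to_model", "prune_short_chains", "connect_chains",
           "BOND_CUTOFF"]

log = logging.getLogger(__name__)

DEFAULT_K = 20

# Maximum inter-residue link distance when tracing: Cα-Cα for protein
# (peptide bond ~3.8 Å plus slack), P-P for nucleic acids.
BOND_CUTOFF = {"amino": 4.2, "nucleotide": 7.5}


@dataclass
class ResidueGraph:
    """k-nearest-neighbour graph over predicted residue positions.

    ``neighbors[i]`` holds the indices of node i's k nearest neighbours in
    order of increasing distance (ties broken by lower index);
    ``distances[i]`` the matching Euclidean distances (Å)."""

    nodes: list
    neighbors: np.ndarray
    distances: np.ndarray

    @property
    def k(self) -> int:
        return self.neighbors.shape[1]

    def edges(self):
        """Iterate directed edges as (i, j, distance)."""
        for i in range(len(self.nodes)):
            for j, d in zip(self.neighbors[i], self.distances[i]):
                yield i, int(j), float(d)

    def edge_table(self):
        """Edge list as rows (i, j, distance) for TSV dumping."""
        return [(i, j, d) for i, j, d in self.edges()]


def _positions(nodes) -> np.ndarray:
    return np.array([
        n.position if isinstance(n, ResiduePrediction) else np.asarray(n)
        for n in nodes
    ], dtype=float)


def build_graph(nodes, k: int = DEFAULT_K) -> ResidueGraph:
    """Build the k-nearest-neighbour residue graph (k clamped to n-1).

    Ties in distance are broken by lower node index, so the graph is a
    deterministic function of the input.
    """
    nodes = list(nodes)
    n = len(nodes)
    if n < 1:
        raise ValueError("graph needs at least one node")
    k = min(k, n - 1)
    pts = _positions(nodes)
    if k == 0:
        return ResidueGraph(nodes, np.zeros((n, 0), int),
                            np.zeros((n, 0)))
    if n <= 512:
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        order = np.lexsort((np.arange(n)[None, :].repeat(n, 0), d), axis=1)
        nb = order[:, :k]
        dist = np.take_along_axis(d, nb, axis=1)
    else:
        tree = cKDTree(pts)
        dist, nb = tree.query(pts, k=k + 1)
        keep = np.empty((n, k), dtype=int)
        kd = np.empty((n, k))
        for i in range(n):
            cand = [(dist[i, m], int(nb[i, m])) for m in range(k + 1)
                    if int(nb[i, m]) != i][:k]
            cand.sort()
            kd[i] = [c[0] for c in cand]
            keep[i] = [c[1] for c in cand]
        nb, dist = keep, kd
    return ResidueGraph(nodes, nb.astype(int), dist)


def trace_fragments(graph: ResidueGraph,
                    bond_cutoff: float | None = None,
                    polymer: str = "amino") -> list[list[int]]:
    """Partition graph nodes into linear fragments.

    Candidate links are graph edges no longer than ``bond_cutoff``;
    links are accepted shortest-first provided neither endpoint already has
    two links and no cycle forms. Every node ends up in exactly one
    fragment (isolated nodes become singletons); fragments are returned in
    order of their smallest node index, each traversed from its
    lower-indexed endpoint.
    """
    if bond_cutoff is None:
        bond_cutoff = BOND_CUTOFF[polymer]
    n = len(graph.nodes)
    cand = sorted(
        {(d, min(i, j), max(i, j))
         for i, j, d in graph.edges() if d <= bond_cutoff}
    )
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    degree = [0] * n
    links: dict[int, list[int]] = {i: [] for i in range(n)}
    for d, i, j in cand:
        if degree[i] >= 2 or degree[j] >= 2:
            continue
        ri, rj = find(i), find(j)
        if ri == rj:
            continue  # would close a cycle
        parent[ri] = rj
        degree[i] += 1
        degree[j] += 1
        links[i].append(j)
        links[j].append(i)

    seen = [False] * n
    fragments = []
    # endpoints (degree <= 1) first so each path is walked end-to-end
    for start in sorted(range(n), key=lambda x: (degree[x] > 1, x)):
        if seen[start]:
            continue
        frag = [start]
        seen[start] = True
        prev, cur = None, start
        while True:
            nxt = [m for m in links[cur] if m != prev and not seen[m]]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            seen[cur] = True
            frag.append(cur)
        fragments.append(frag)
    fragments.sort(key=lambda f: min(f))
    return [f if f[0] <= f[-1] else f[::-1] for f in fragments]


def _chain_id(i: int) -> str:
    letters = string.ascii_uppercase
    out = ""
    i += 1
    while i > 0:
        i, r = divmod(i - 1, 26)
        out = letters[r] + out
    return out


def fragments_to_model(preds, fragments: list[list[int]],
                       polymer: str = "amino") -> AtomicModel:
    """Turn traced fragments into a model of anchor-atom (CA/P) residues,
    identities set to each prediction's argmax, confidence in the B-factor
    column."""
    anchor = "CA" if polymer == "amino" else "P"
    element = "C" if polymer == "amino" else "P"
    chains = []
    for ci, frag in enumerate(fragments):
        residues = []
        for ri, node in enumerate(frag, start=1):
            p = preds[node]
            residues.append(Residue(ri, p.argmax_identity, [
                Atom(anchor, element, p.position, b_factor=p.confidence)
            ]))
        chains.append(Chain(_chain_id(ci), polymer, residues))
    return AtomicModel(chains)


def trace_chains(graph: ResidueGraph, bond_cutoff: float | None = None,
                 polymer: str = "amino") -> AtomicModel:
    """Trace fragments and return them as an AtomicModel (see
    :func:`trace_fragments` for the linking rule)."""
    frags = trace_fragments(graph, bond_cutoff, polymer)
    return fragments_to_model(graph.nodes, frags, polymer)


def prune_short_chains(model: AtomicModel, min_length: int = 4
                       ) -> AtomicModel:
    """Drop chains with fewer than ``min_length`` residues (default 4).
    Surviving residues are returned unchanged; the operation is
    idempotent."""
    return AtomicModel([c for c in model.chains if len(c) >= min_length])


def connect_chains(fragments: AtomicModel, assignments: dict,
                   max_gap_per_residue: float = 3.8) -> AtomicModel:
    """Merge fragments assigned to the same sequence.

    ``assignments`` maps chain id to ``(sequence_id, start, end)`` (1-based
    inclusive residue range on the sequence) or ``None`` for unassigned
    fragments. Two fragments on the same sequence with order-compatible,
    non-overlapping ranges are merged when the distance between their
    facing ends is at most ``(missing_residues + 1) * max_gap_per_residue``
    — i.e. a fully extended linker could span the gap. Fragments with
    overlapping ranges are kept separate and the conflict is logged.
    Coordinates are never modified; only chain topology and numbering
    change.
    """
    assigned: dict[str, list] = {}
    out_chains = []
    for chain in fragments.chains:
        a = assignments.get(chain.chain_id)
        if a is None:
            out_chains.append(chain)
            continue
        seq_id, start, end = a
        assigned.setdefault(seq_id, []).append((start, end, chain))

    for seq_id, frags in sorted(assigned.items()):
        frags.sort(key=lambda t: (t[0], t[1], t[2].chain_id))
        groups: list[list] = [[frags[0]]]
        for start, end, chain in frags[1:]:
            p_start, p_end, p_chain = groups[-1][-1]
            if start <= p_end:
                log.warning(
                    "sequence %s: fragments %s (%d-%d) and %s (%d-%d) "
                    "overlap; kept separate", seq_id, p_chain.chain_id,
                    p_start, p_end, chain.chain_id, start, end)
                groups.append([(start, end, chain)])
                continue
            missing = start - p_end - 1
            gap = float(np.linalg.norm(
                chain.residues[0].anchor - p_chain.residues[-1].anchor))
            if gap <= (missing + 1) * max_gap_per_residue:
                groups[-1].append((start, end, chain))
            else:
                groups.append([(start, end, chain)])
        for group in groups:
            first = group[0][2]
            residues = []
            for start, end, chain in group:
                already_numbered = (chain.residues[0].seq_id == start
                                    and chain.residues[-1].seq_id == end)
                for off, res in enumerate(chain.residues):
                    num = res.seq_id if already_numbered else start + off
                    residues.append(Residue(num, res.identity, res.atoms))
            out_chains.append(Chain(first.chain_id, first.polymer, residues))

    out_chains.sort(key=lambda c: c.chain_id)
    return AtomicModel(out_chains)
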