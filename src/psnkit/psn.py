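"""PSN construction: side-chain centers of mass, contact persistence, graph.

The network is built in three steps:

1. For each frame, the center of mass (COM) of every residue side chain:
   ``com = Σ m_a r_a / Σ m_a`` over the node's selected atoms.
2. For every unordered node pair, the *persistence*: the fraction of frames
   in which the Euclidean COM–COM distance is within the distance cutoff
   (inclusive, ``d <= cutoff``).
3. The weighted graph: an edge for every pair whose persistence, expressed
   as a percentage, is at least ``p_crit`` (default 20%); the edge weight is
   the persistence percentage. All nodes are kept even when isolated.

No periodic-boundary minimum-image convention is applied: inputs are
assumed whole-molecule/PBC-corrected. Sequence-adjacent pairs are not
excluded by default; ``min_seq_separation`` is available for users who
want an i,i+k exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .ensemble_io import (
    MassTable,
    Residue,
    SideChainSelection,
    StructuralEnsemble,
)
from .errors import MassLookupError

__all__ = [
    "ComSeries",
    "PersistenceMatrix",
    "PSNGraph",
    "compute_com_series",
    "compute_persistence",
    "build_graph",
    "write_edge_list",
    "write_adjacency_matrix",
]


@dataclass
class ComSeries:
    """Per-frame side-chain COM positions: ``positions[frame, node]`` (Å)."""

    nodes: list[Residue]
    positions: np.ndarray  # (n_frames, n_nodes, 3)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def slice_frames(self, indices) -> "ComSeries":
        return ComSeries(self.nodes, self.positions[np.asarray(indices, dtype=int)])


@dataclass
class PersistenceMatrix:
    """Symmetric matrix of contact fractions in [0, 1] at a given cutoff."""

    nodes: list[Residue]
    values: np.ndarray  # (n_nodes, n_nodes), diagonal 0
    cutoff: float
    n_frames_used: int


@dataclass
class PSNGraph:
    """The filtered weighted network plus its construction parameters.

    ``graph`` is a :class:`networkx.Graph` whose nodes are :class:`Residue`
    tuples and whose edges carry ``weight`` = persistence × 100 (%).
    """

    graph: nx.Graph
    nodes: list[Residue]
    cutoff: float
    p_crit: float
    min_seq_separation: int = 0

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def compute_com_series(
    ensemble: StructuralEnsemble,
    selection: SideChainSelection,
    masses: MassTable,
) -> ComSeries:
    """Mass-weighted side-chain center of mass for every (frame, node)."""
    atoms = ensemble.atoms
    positions = np.empty((ensemble.n_frames, len(selection.nodes), 3))
    for k, node in enumerate(selection.nodes):
        idx = selection.atom_indices[node]
        try:
            m = np.array(
                [
                    masses.mass_of(
                        atoms["resname"].values[i],
                        atoms["name"].values[i],
                        atoms["element"].values[i],
                    )
                    for i in idx
                ]
            )
        except MassLookupError as exc:
            raise MassLookupError(f"node {node.label}: {exc}") from exc
        coords = ensemble.coordinates[:, idx, :]  # (F, n_atoms, 3)
        if len(idx) == 1:
            positions[:, k, :] = coords[:, 0, :]  # exact identity
        else:
            positions[:, k, :] = np.einsum("fai,a->fi", coords, m) / m.sum()
    return ComSeries(nodes=list(selection.nodes), positions=positions)


def compute_persistence(coms: ComSeries, cutoff: float) -> PersistenceMatrix:
    """Fraction of frames with COM distance <= cutoff, per node pair.

    Exact rational fractions k/N: the count of in-contact frames is integer
    and divided once by the frame count.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    n_frames, n_nodes = coms.positions.shape[:2]
    counts = np.zeros((n_nodes, n_nodes), dtype=np.int64)
    for f in range(n_frames):
        p = coms.positions[f]
        d2 = np.sum((p[:, None, :] - p[None, :, :]) ** 2, axis=-1)
        counts += d2 <= cutoff * cutoff
    values = counts / n_frames
    np.fill_diagonal(values, 0.0)
    return PersistenceMatrix(
        nodes=list(coms.nodes),
        values=values,
        cutoff=cutoff,
        n_frames_used=n_frames,
    )


def build_graph(
    persistence: PersistenceMatrix,
    p_crit: float = 20.0,
    min_seq_separation: int = 0,
) -> PSNGraph:
    """Filter the persistence matrix into the weighted PSN.

    An edge (i, j) is included iff ``persistence * 100 >= p_crit`` and the
    persistence is non-zero; its weight is the persistence percentage. With
    ``min_seq_separation = s > 0``, same-chain pairs closer than ``s`` in
    sequence are dropped regardless of persistence.
    """
    if not 0 <= p_crit <= 100:
        raise ValueError(f"p_crit must be in [0, 100], got {p_crit}")
    nodes = list(persistence.nodes)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    n = len(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            v = persistence.values[i, j]
            if v <= 0:
                continue
            weight = v * 100.0
            if weight < p_crit:
                continue
            a, b = nodes[i], nodes[j]
            if (
                min_seq_separation > 0
                and a.chain == b.chain
                and abs(a.resid - b.resid) < min_seq_separation
            ):
                continue
            g.add_edge(a, b, weight=weight)
    return PSNGraph(
        graph=g,
        nodes=nodes,
        cutoff=persistence.cutoff,
        p_crit=p_crit,
        min_seq_separation=min_seq_separation,
    )


def write_edge_list(psn: PSNGraph, path: str | Path) -> Path:
    """Tab-separated edge list ``node1  node2  weight%``, sorted by nodes."""
    path = Path(path)
    rows = []
    for a, b, data in psn.graph.edges(data=True):
        a, b = sorted((a, b))
        rows.append((a, b, data["weight"]))
    rows.sort(key=lambda r: (r[0], r[1]))
    with path.open("w") as fh:
        for a, b, w in rows:
            fh.write(f"{a.label}\t{b.label}\t{w:.4f}\n")
    return path


def write_adjacency_matrix(psn: PSNGraph, path: str | Path) -> Path:
    """Square weight matrix as text; row/column order = node order."""
    path = Path(path)
    n = len(psn.nodes)
    mat = np.zeros((n, n))
    index = {node: i for i, node in enumerate(psn.nodes)}
    for a, b, data in psn.graph.edges(data=True):
        i, j = index[a], index[b]
        mat[i, j] = mat[j, i] = data["weight"]
    header = "# " + " ".join(node.label for node in psn.nodes)
    with path.open("w") as fh:
        fh.write(header + "\n")
        for row in mat:
            fh.write(" ".join(f"{v:.4f}" for v in row) + "\n")
    return path
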