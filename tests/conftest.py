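"""Shared fixtures: hand-written PDB ensembles and graph builders."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from psnkit.ensemble_io import Residue
from psnkit.psn import PSNGraph


def _pdb_atom(serial, name, resname, chain, resid, x, y, z, element):
    padded = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (
        f"ATOM  {serial:5d} {padded} {resname:<3s} {chain}{resid:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
    )


def make_multimodel_pdb(models: list[list[tuple]]) -> str:
    """Build multi-model PDB text from per-model atom tuples.

    Each atom tuple is (name, resname, chain, resid, x, y, z, element).
    """
    lines = []
    for m, atoms in enumerate(models, 1):
        lines.append(f"MODEL     {m:4d}")
        for serial, atom in enumerate(atoms, 1):
            lines.append(_pdb_atom(serial, *atom))
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


TRIPEPTIDE_ATOMS = [
    # ALA 1: backbone + CB
    ("N", "ALA", "A", 1, 0.0, 0.0, 0.0, "N"),
    ("CA", "ALA", "A", 1, 1.5, 0.0, 0.0, "C"),
    ("C", "ALA", "A", 1, 2.2, 1.3, 0.0, "C"),
    ("O", "ALA", "A", 1, 1.6, 2.4, 0.0, "O"),
    ("CB", "ALA", "A", 1, 2.2, -1.3, 0.2, "C"),
    # GLY 2: backbone only
    ("N", "GLY", "A", 2, 3.5, 1.2, 0.0, "N"),
    ("CA", "GLY", "A", 2, 4.3, 2.4, 0.1, "C"),
    ("C", "GLY", "A", 2, 5.8, 2.2, 0.0, "C"),
    ("O", "GLY", "A", 2, 6.4, 1.1, 0.0, "O"),
    # SER 3: backbone + CB OG
    ("N", "SER", "A", 3, 6.4, 3.4, 0.0, "N"),
    ("CA", "SER", "A", 3, 7.9, 3.4, 0.1, "C"),
    ("C", "SER", "A", 3, 8.5, 4.8, 0.0, "C"),
    ("O", "SER", "A", 3, 7.8, 5.8, 0.0, "O"),
    ("CB", "SER", "A", 3, 8.5, 2.6, 1.2, "C"),
    ("OG", "SER", "A", 3, 8.3, 1.2, 1.1, "O"),
]


def _shift(atoms, dx):
    return [
        (n, rn, ch, ri, x + dx, y, z, e) for (n, rn, ch, ri, x, y, z, e) in atoms
    ]


@pytest.fixture
def tripeptide_pdb(tmp_path):
    """3-model PDB of ALA-GLY-SER, models rigidly shifted along x."""
    text = make_multimodel_pdb(
        [TRIPEPTIDE_ATOMS, _shift(TRIPEPTIDE_ATOMS, 0.5), _shift(TRIPEPTIDE_ATOMS, 1.0)]
    )
    path = tmp_path / "tripeptide.pdb"
    path.write_text(text)
    return path


def residue(i: int, resname: str = "ALA", chain: str = "A") -> Residue:
    return Residue(chain, i, "", resname)


def psn_from_edges(
    n_nodes: int,
    edges: list[tuple[int, int]],
    cutoff: float = 5.0,
    p_crit: float = 20.0,
) -> PSNGraph:
    """PSNGraph over n_nodes pseudo-residues with the given 1-based edges."""
    nodes = [residue(i) for i in range(1, n_nodes + 1)]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a, b in edges:
        g.add_edge(nodes[a - 1], nodes[b - 1], weight=100.0)
    return PSNGraph(graph=g, nodes=nodes, cutoff=cutoff, p_crit=p_crit)


def bfs_components_oracle(nodes, edges) -> set[frozenset]:
    """Independent flood-fill connected-components oracle."""
    adjacency = {node: set() for node in nodes}
    for a, b in edges:
        adjacency[a].add(b)
        adjacency[b].add(a)
    unvisited = set(nodes)
    components = set()
    while unvisited:
        start = unvisited.pop()
        comp = {start}
        queue = [start]
        while queue:
            current = queue.pop()
            for neighbor in adjacency[current]:
                if neighbor not in comp:
                    comp.add(neighbor)
                    queue.append(neighbor)
        unvisited -= comp
        components.add(frozenset(comp))
    return components


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation matrix via QR."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
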