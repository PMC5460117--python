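"""Hubs and connected components — the two fundamental PSN properties.

A *hub* is a node whose degree (number of incident edges, weights ignored)
is at least ``min_hub_degree``; the conventional threshold is 3. The
*connected components* (clusters) partition the node set into maximal sets
of mutually reachable nodes, ranked by size with rank 1 the largest;
singleton components are counted so the partition covers every node.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .ensemble_io import Residue
from .psn import PSNGraph

__all__ = [
    "HubTable",
    "ComponentPartition",
    "node_degrees",
    "find_hubs",
    "connected_components",
    "hubs_to_dataframe",
    "components_to_dataframe",
    "summary_dict",
]


@dataclass
class HubTable:
    """All hub nodes with their degrees, plus the degree histogram."""

    records: list[tuple[Residue, int]]  # sorted by (-degree, node)
    min_hub_degree: int
    histogram: dict[int, int] = field(default_factory=dict)

    @property
    def n_hubs(self) -> int:
        return len(self.records)

    def count_at_degree(self, degree: int) -> int:
        return self.histogram.get(degree, 0)


@dataclass
class ComponentPartition:
    """Connected components ranked by size (rank 1 = largest).

    Ties in size are broken by the smallest member (chain, resid, icode),
    so ranks are reproducible across runs — a requirement for rank-matched
    jackknife error bars.
    """

    components: list[list[Residue]]  # members sorted within each component
    sizes: list[int]
    rank_of: dict[Residue, int]  # 1-based

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def n_nonsingleton(self) -> int:
        return sum(1 for s in self.sizes if s > 1)

    def size_at_rank(self, rank: int) -> int:
        """Size of the rank-th largest component; 0 when absent."""
        return self.sizes[rank - 1] if 1 <= rank <= len(self.sizes) else 0

    @property
    def largest_fraction(self) -> float:
        total = sum(self.sizes)
        return self.sizes[0] / total if total else 0.0


def node_degrees(psn: PSNGraph) -> dict[Residue, int]:
    """Number of incident edges per node (weights ignored)."""
    return {node: int(deg) for node, deg in psn.graph.degree()}


def find_hubs(
    psn: PSNGraph,
    min_hub_degree: int = 3,
    mode: str = "fixed",
) -> HubTable:
    """Nodes with degree >= threshold.

    ``mode="fixed"`` uses ``min_hub_degree`` (default 3, the conventional
    definition). ``mode="average"`` instead takes nodes whose degree is
    strictly greater than the network's mean degree.
    """
    if mode not in ("fixed", "average"):
        raise ValueError(f"mode must be 'fixed' or 'average', got {mode!r}")
    degrees = node_degrees(psn)
    if mode == "average":
        mean_degree = sum(degrees.values()) / len(degrees) if degrees else 0.0
        threshold = math.floor(mean_degree) + 1  # smallest integer > mean
    else:
        if min_hub_degree < 1:
            raise ValueError(f"min_hub_degree must be >= 1, got {min_hub_degree}")
        threshold = min_hub_degree
    records = sorted(
        ((node, deg) for node, deg in degrees.items() if deg >= threshold),
        key=lambda r: (-r[1], r[0]),
    )
    histogram: dict[int, int] = {}
    for _, deg in records:
        histogram[deg] = histogram.get(deg, 0) + 1
    return HubTable(
        records=records,
        min_hub_degree=threshold,
        histogram=dict(sorted(histogram.items())),
    )


def connected_components(psn: PSNGraph) -> ComponentPartition:
    """Partition into maximal connected clusters, largest first.

    Singletons are included; equal-size components are ordered by their
    smallest member.
    """
    comps = [sorted(c) for c in nx.connected_components(psn.graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    rank_of = {node: rank for rank, comp in enumerate(comps, 1) for node in comp}
    return ComponentPartition(
        components=comps,
        sizes=[len(c) for c in comps],
        rank_of=rank_of,
    )


def hubs_to_dataframe(hubs: HubTable) -> pd.DataFrame:
    """Hub table as rows of node, chain, resid, resname, degree."""
    return pd.DataFrame(
        [
            {
                "node": node.label,
                "chain": node.chain,
                "resid": node.resid,
                "resname": node.resname,
                "degree": deg,
            }
            for node, deg in hubs.records
        ],
        columns=["node", "chain", "resid", "resname", "degree"],
    )


def components_to_dataframe(partition: ComponentPartition) -> pd.DataFrame:
    """One row per node: node, component_rank, component_size."""
    rows = [
        {
            "node": node.label,
            "component_rank": rank,
            "component_size": len(comp),
        }
        for rank, comp in enumerate(partition.components, 1)
        for node in comp
    ]
    return pd.DataFrame(rows, columns=["node", "component_rank", "component_size"])


def summary_dict(
    hubs: HubTable,
    partition: ComponentPartition,
    top_k: int = 5,
) -> dict:
    """JSON-serializable summary: hub histogram and top-k component sizes."""
    return {
        "n_hubs": hubs.n_hubs,
        "min_hub_degree": hubs.min_hub_degree,
        "hub_histogram": {str(d): c for d, c in hubs.histogram.items()},
        "n_components": partition.n_components,
        "n_nonsingleton_components": partition.n_nonsingleton,
        "top_component_sizes": [
            partition.size_at_rank(k) for k in range(1, top_k + 1)
        ],
        "largest_component_fraction": partition.largest_fraction,
    }


def write_summary_json(
    hubs: HubTable, partition: ComponentPartition, path: str | Path, top_k: int = 5
) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps(summary_dict(hubs, partition, top_k), indent=2, sort_keys=True)
        + "\n"
    )
    return path
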