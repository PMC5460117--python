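"""Cutoff scan: the full pipeline over a grid of distance cutoffs.

For each cutoff the pipeline computes persistence, builds the filtered
graph, extracts hubs and connected components on the full ensemble, and
attaches jackknife standard errors from the leave-block-out subsets. The
default grid 4.0–6.0 Å in 0.5 Å steps brackets the fragmentation-to-
percolation transition of side-chain COM contact networks.

The whole analysis path is deterministic: identical inputs produce
byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .ensemble_io import (
    MassTable,
    SideChainSelection,
    StructuralEnsemble,
    select_sidechains,
)
from .graph_analysis import (
    components_to_dataframe,
    connected_components,
    find_hubs,
    hubs_to_dataframe,
)
from .jackknife import (
    JackknifeEstimate,
    ResampleScheme,
    jackknife_observables_from_coms,
)
from .psn import build_graph, compute_com_series, compute_persistence, write_edge_list

logger = logging.getLogger(__name__)

__all__ = ["ScanConfig", "CutoffSlice", "CutoffScanResult", "run_scan", "write_report"]

DEFAULT_CUTOFFS = (4.0, 4.5, 5.0, 5.5, 6.0)


@dataclass
class ScanConfig:
    """Parameters of a cutoff scan.

    Defaults follow the standard protocol: 4–6 Å grid in 0.5 Å steps,
    p_crit 20%, 10 jackknife subsets, hub threshold 3, top-5 components,
    glycine excluded from the node set.
    """

    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    p_crit: float = 20.0
    n_subsets: int = 10
    min_hub_degree: int = 3
    top_k_components: int = 5
    excluded_resnames: tuple[str, ...] = ("GLY",)
    min_seq_separation: int = 0

    def __post_init__(self) -> None:
        self.cutoffs = tuple(float(c) for c in self.cutoffs)
        if not self.cutoffs:
            raise ValueError("at least one cutoff is required")
        if any(c <= 0 for c in self.cutoffs):
            raise ValueError("cutoffs must be strictly positive")
        if any(b <= a for a, b in zip(self.cutoffs, self.cutoffs[1:])):
            raise ValueError("cutoffs must be strictly increasing")
        if not 0 <= self.p_crit <= 100:
            raise ValueError(f"p_crit must be in [0, 100], got {self.p_crit}")


@dataclass
class CutoffSlice:
    """Everything the scan records for one cutoff."""

    cutoff: float
    n_edges: int
    n_components: int
    n_nonsingleton_components: int
    largest_component_fraction: float
    hub_histogram: dict[int, int]
    top_component_sizes: list[int]
    hubs: list[tuple[str, int]]  # (node label, degree)
    component_rank_of: dict[str, int]  # node label -> 1-based rank
    component_sizes: list[int]  # all sizes, rank order
    estimates: list[JackknifeEstimate]


@dataclass
class CutoffScanResult:
    """Per-cutoff results plus the configuration and node set used."""

    config: ScanConfig
    n_frames: int
    nodes: list[str]  # node labels, canonical order
    slices: list[CutoffSlice] = field(default_factory=list)

    def slice_at(self, cutoff: float) -> CutoffSlice:
        for s in self.slices:
            if s.cutoff == cutoff:
                return s
        raise KeyError(f"no slice at cutoff {cutoff}")

    def to_dict(self) -> dict:
        """Plain-data form, JSON-serializable; inverse of :meth:`from_dict`."""
        return {
            "config": dataclasses.asdict(self.config)
            | {
                "cutoffs": list(self.config.cutoffs),
                "excluded_resnames": list(self.config.excluded_resnames),
            },
            "n_frames": self.n_frames,
            "nodes": list(self.nodes),
            "slices": [
                {
                    "cutoff": s.cutoff,
                    "n_edges": s.n_edges,
                    "n_components": s.n_components,
                    "n_nonsingleton_components": s.n_nonsingleton_components,
                    "largest_component_fraction": s.largest_component_fraction,
                    "hub_histogram": {str(d): c for d, c in s.hub_histogram.items()},
                    "top_component_sizes": list(s.top_component_sizes),
                    "hubs": [[label, deg] for label, deg in s.hubs],
                    "component_rank_of": dict(s.component_rank_of),
                    "component_sizes": list(s.component_sizes),
                    "estimates": [dataclasses.asdict(e) for e in s.estimates],
                }
                for s in self.slices
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CutoffScanResult":
        cfg = dict(data["config"])
        cfg["cutoffs"] = tuple(cfg["cutoffs"])
        cfg["excluded_resnames"] = tuple(cfg["excluded_resnames"])
        slices = [
            CutoffSlice(
                cutoff=s["cutoff"],
                n_edges=s["n_edges"],
                n_components=s["n_components"],
                n_nonsingleton_components=s["n_nonsingleton_components"],
                largest_component_fraction=s["largest_component_fraction"],
                hub_histogram={int(d): c for d, c in s["hub_histogram"].items()},
                top_component_sizes=list(s["top_component_sizes"]),
                hubs=[(label, deg) for label, deg in s["hubs"]],
                component_rank_of=dict(s["component_rank_of"]),
                component_sizes=list(s["component_sizes"]),
                estimates=[JackknifeEstimate(**e) for e in s["estimates"]],
            )
            for s in data["slices"]
        ]
        return cls(
            config=ScanConfig(**cfg),
            n_frames=data["n_frames"],
            nodes=list(data["nodes"]),
            slices=slices,
        )


def run_scan(
    ensemble: StructuralEnsemble,
    config: ScanConfig | None = None,
    selection: SideChainSelection | None = None,
    masses: MassTable | None = None,
) -> CutoffScanResult:
    """Run persistence → graph → hubs/components (+ jackknife) per cutoff.

    The COM series is computed once and shared across cutoffs and jackknife
    subsets; subsets are frame slices.
    """
    config = config or ScanConfig()
    masses = masses or MassTable()
    if selection is None:
        selection = select_sidechains(ensemble, config.excluded_resnames)
    for res, reason in selection.excluded:
        logger.info("excluded residue %s: %s", res.label, reason)

    coms = compute_com_series(ensemble, selection, masses)
    scheme = ResampleScheme.build(ensemble.n_frames, config.n_subsets)
    result = CutoffScanResult(
        config=config,
        n_frames=ensemble.n_frames,
        nodes=[node.label for node in selection.nodes],
    )
    for cutoff in config.cutoffs:
        logger.info("cutoff %.2f Å: building PSN", cutoff)
        try:
            persistence = compute_persistence(coms, cutoff)
            psn = build_graph(persistence, config.p_crit, config.min_seq_separation)
            hubs = find_hubs(psn, config.min_hub_degree)
            partition = connected_components(psn)
            estimates = jackknife_observables_from_coms(
                coms,
                scheme,
                cutoff,
                config.p_crit,
                config.min_hub_degree,
                config.top_k_components,
                config.min_seq_separation,
            )
        except Exception as exc:
            raise type(exc)(f"cutoff {cutoff} Å: {exc}") from exc
        result.slices.append(
            CutoffSlice(
                cutoff=cutoff,
                n_edges=psn.n_edges,
                n_components=partition.n_components,
                n_nonsingleton_components=partition.n_nonsingleton,
                largest_component_fraction=partition.largest_fraction,
                hub_histogram=dict(hubs.histogram),
                top_component_sizes=[
                    partition.size_at_rank(k)
                    for k in range(1, config.top_k_components + 1)
                ],
                hubs=[(node.label, deg) for node, deg in hubs.records],
                component_rank_of={
                    node.label: rank for node, rank in partition.rank_of.items()
                },
                component_sizes=list(partition.sizes),
                estimates=estimates,
            )
        )
    return result


def _estimates_to_dataframe(estimates: list[JackknifeEstimate]) -> pd.DataFrame:
    n = max((e.n for e in estimates), default=0)
    rows = []
    for e in estimates:
        row = {
            "observable": e.label,
            "full_value": e.full_value,
            "theta_dot": e.theta_dot,
            "se": e.se,
            "n": e.n,
        }
        for i, theta in enumerate(e.theta_i, 1):
            row[f"theta_{i}"] = theta
        rows.append(row)
    columns = ["observable", "full_value", "theta_dot", "se", "n"] + [
        f"theta_{i}" for i in range(1, n + 1)
    ]
    return pd.DataFrame(rows, columns=columns)


def write_report(
    result: CutoffScanResult,
    outdir: str | Path,
    ensemble: StructuralEnsemble | None = None,
    selection: SideChainSelection | None = None,
    masses: MassTable | None = None,
) -> list[Path]:
    """Write per-cutoff edge lists, hub/component/jackknife CSVs, summary JSON.

    File names embed cutoff and p_crit. Re-running on identical inputs
    produces byte-identical files. When ``ensemble`` (with selection and
    masses) is passed, edge lists are regenerated from it; otherwise only
    the tables and summary are written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    p_crit = result.config.p_crit

    coms = None
    if ensemble is not None:
        masses = masses or MassTable()
        if selection is None:
            selection = select_sidechains(ensemble, result.config.excluded_resnames)
        coms = compute_com_series(ensemble, selection, masses)

    for s in result.slices:
        tag = f"cutoff{s.cutoff:g}_pcrit{p_crit:g}"
        if coms is not None:
            psn = build_graph(
                compute_persistence(coms, s.cutoff),
                p_crit,
                result.config.min_seq_separation,
            )
            written.append(write_edge_list(psn, outdir / f"edges_{tag}.tsv"))

        hub_df = pd.DataFrame(
            [
                {
                    "node": label,
                    "chain": label.split(":")[0],
                    "resid": label.split(":")[1],
                    "resname": label.split(":")[2],
                    "degree": deg,
                }
                for label, deg in s.hubs
            ],
            columns=["node", "chain", "resid", "resname", "degree"],
        )
        hub_path = outdir / f"hubs_{tag}.csv"
        hub_df.to_csv(hub_path, index=False)
        written.append(hub_path)

        comp_df = pd.DataFrame(
            sorted(
                (
                    {
                        "node": label,
                        "component_rank": rank,
                        "component_size": s.component_sizes[rank - 1],
                    }
                    for label, rank in s.component_rank_of.items()
                ),
                key=lambda r: (r["component_rank"], r["node"]),
            ),
            columns=["node", "component_rank", "component_size"],
        )
        comp_path = outdir / f"components_{tag}.csv"
        comp_df.to_csv(comp_path, index=False)
        written.append(comp_path)

        jk_path = outdir / f"jackknife_{tag}.csv"
        _estimates_to_dataframe(s.estimates).to_csv(jk_path, index=False)
        written.append(jk_path)

    summary_path = outdir / "summary.json"
    summary_path.write_text(
        json.dumps(result.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    written.append(summary_path)
    return written
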