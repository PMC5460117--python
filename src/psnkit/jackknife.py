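"""Jackknife resampling of trajectory frames for PSN observables.

The trajectory is tiled into ``n`` contiguous blocks of ``B = floor(F/n)``
frames; subset *i* is the trajectory with block *i* removed, so each subset
retains ``F - B`` frames (90% at the default ``n = 10``). Remainder frames
(``F mod n``, at the tail) belong to no block and are kept in every subset.

For an observable x̂ with per-subset estimates θ̂(i), the jackknife mean and
standard error are

    θ̂(.)        = (1/n) Σ θ̂(i)
    SE(x̂)_jack  = { (n−1)/n · Σ (θ̂(i) − θ̂(.))² }^(1/2)

The observables with error bars are the hub count at each degree and the
size of the k-th largest component, matched across subsets by *rank* (size
order), not by member identity. An observable absent in a subset (no hub of
that degree, fewer than k components) contributes θ̂(i) = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ensemble_io import MassTable, SideChainSelection, StructuralEnsemble
from .errors import InsufficientFramesError
from .graph_analysis import HubTable, ComponentPartition, connected_components, find_hubs
from .psn import ComSeries, PSNGraph, build_graph, compute_com_series, compute_persistence

__all__ = [
    "ResampleScheme",
    "JackknifeEstimate",
    "make_jackknife_subsets",
    "jackknife_mean",
    "jackknife_se",
    "jackknife_observables",
    "observable_values",
]


@dataclass
class ResampleScheme:
    """Leave-block-out frame bookkeeping.

    ``kept[i]`` are the frame positions subset *i* retains (order
    preserved); ``discarded[i] = (start, stop)`` is its removed block,
    half-open.
    """

    n_frames: int
    n_subsets: int
    block_size: int
    kept: list[np.ndarray]
    discarded: list[tuple[int, int]]

    @classmethod
    def build(cls, n_frames: int, n_subsets: int = 10) -> "ResampleScheme":
        if n_subsets < 2:
            raise ValueError(f"n_subsets must be >= 2, got {n_subsets}")
        if n_frames < n_subsets:
            raise InsufficientFramesError(
                f"{n_frames} frames cannot be split into {n_subsets} subsets"
            )
        block = n_frames // n_subsets
        all_frames = np.arange(n_frames)
        kept, discarded = [], []
        for i in range(n_subsets):
            start, stop = i * block, (i + 1) * block
            kept.append(np.concatenate([all_frames[:start], all_frames[stop:]]))
            discarded.append((start, stop))
        return cls(
            n_frames=n_frames,
            n_subsets=n_subsets,
            block_size=block,
            kept=kept,
            discarded=discarded,
        )


@dataclass
class JackknifeEstimate:
    """Full-trajectory value plus jackknife mean and standard error."""

    label: str
    full_value: float
    theta_i: list[float]
    theta_dot: float
    se: float
    n: int


def make_jackknife_subsets(
    ensemble: StructuralEnsemble, n_subsets: int = 10
) -> tuple[list[StructuralEnsemble], ResampleScheme]:
    """The n leave-block-out sub-ensembles, each retaining ~90% of frames."""
    scheme = ResampleScheme.build(ensemble.n_frames, n_subsets)
    subsets = [ensemble.slice_frames(kept) for kept in scheme.kept]
    return subsets, scheme


def jackknife_mean(theta_i: Sequence[float]) -> float:
    """Arithmetic mean θ̂(.) of the per-subset estimates."""
    if len(theta_i) == 0:
        raise ValueError("jackknife_mean of an empty sequence")
    return float(np.mean(theta_i))


def jackknife_se(theta_i: Sequence[float]) -> float:
    """Jackknife standard error {(n−1)/n · Σ(θ̂(i) − θ̂(.))²}^(1/2)."""
    n = len(theta_i)
    if n < 2:
        raise ValueError(f"jackknife SE needs n >= 2 subsets, got {n}")
    theta = np.asarray(theta_i, dtype=float)
    if (theta == theta[0]).all():
        return 0.0  # exact: all deviations are zero by definition
    dev = theta - theta.mean()
    return float(np.sqrt((n - 1) / n * np.sum(dev * dev)))


def observable_values(
    hubs: HubTable,
    partition: ComponentPartition,
    degrees: Sequence[int],
    ranks: Sequence[int],
) -> dict[str, float]:
    """Hub-count-per-degree and rank-k component-size observables."""
    values: dict[str, float] = {}
    for d in degrees:
        values[f"hub_count_degree_{d}"] = float(hubs.count_at_degree(d))
    for k in ranks:
        values[f"component_size_rank_{k}"] = float(partition.size_at_rank(k))
    return values


def _estimates_from_graphs(
    full_psn: PSNGraph,
    subset_psns: list[PSNGraph],
    min_hub_degree: int,
    top_k: int,
) -> list[JackknifeEstimate]:
    full_hubs = find_hubs(full_psn, min_hub_degree)
    full_parts = connected_components(full_psn)
    sub_hubs = [find_hubs(p, min_hub_degree) for p in subset_psns]
    sub_parts = [connected_components(p) for p in subset_psns]

    max_degree = max(
        [min_hub_degree]
        + [max(h.histogram, default=0) for h in [full_hubs] + sub_hubs]
    )
    degrees = range(min_hub_degree, max_degree + 1)
    ranks = range(1, top_k + 1)

    full_values = observable_values(full_hubs, full_parts, degrees, ranks)
    per_subset = [
        observable_values(h, p, degrees, ranks)
        for h, p in zip(sub_hubs, sub_parts)
    ]
    estimates = []
    for label, full_value in full_values.items():
        theta = [vals[label] for vals in per_subset]
        estimates.append(
            JackknifeEstimate(
                label=label,
                full_value=full_value,
                theta_i=theta,
                theta_dot=jackknife_mean(theta),
                se=jackknife_se(theta),
                n=len(theta),
            )
        )
    return estimates


def jackknife_observables_from_coms(
    coms: ComSeries,
    scheme: ResampleScheme,
    cutoff: float,
    p_crit: float = 20.0,
    min_hub_degree: int = 3,
    top_k: int = 5,
    min_seq_separation: int = 0,
) -> list[JackknifeEstimate]:
    """Jackknife estimates at one cutoff, from a precomputed COM series.

    COM positions are per-frame quantities, so subset trajectories are frame
    slices of the full COM series — the expensive COM step runs once.
    """

    def psn_of(series: ComSeries) -> PSNGraph:
        return build_graph(
            compute_persistence(series, cutoff), p_crit, min_seq_separation
        )

    full_psn = psn_of(coms)
    subset_psns = [psn_of(coms.slice_frames(kept)) for kept in scheme.kept]
    return _estimates_from_graphs(full_psn, subset_psns, min_hub_degree, top_k)


def jackknife_observables(
    ensemble: StructuralEnsemble,
    selection: SideChainSelection,
    masses: MassTable,
    cutoff: float,
    p_crit: float = 20.0,
    n_subsets: int = 10,
    min_hub_degree: int = 3,
    top_k: int = 5,
    min_seq_separation: int = 0,
) -> list[JackknifeEstimate]:
    """Full pipeline: jackknife mean and SE for every PSN observable.

    Observables: hub count at each degree from ``min_hub_degree`` up to the
    largest degree observed (full ensemble or any subset), and the size of
    the k-th largest component for k = 1..``top_k``.
    """
    coms = compute_com_series(ensemble, selection, masses)
    scheme = ResampleScheme.build(ensemble.n_frames, n_subsets)
    return jackknife_observables_from_coms(
        coms, scheme, cutoff, p_crit, min_hub_degree, top_k, min_seq_separation
    )
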