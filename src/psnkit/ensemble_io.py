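"""Ensemble input/output, atomic masses, and side-chain node selection.

A *structural ensemble* is an ordered set of conformations (frames) of the
same molecule — a multi-model PDB, or a binary trajectory (XTC/TRR/DCD)
paired with a topology file. Reading goes through MDAnalysis; in memory the
ensemble is a frames × atoms coordinate array plus a per-atom metadata
table, which makes frame slicing (jackknife subsets, strides) cheap.

The network nodes are residues represented by their side chains: every atom
of a residue except the backbone names ``N, CA, C, O, OXT`` and the backbone
hydrogens ``H, H1, H2, H3, HA, HA2, HA3``. Glycine has no side chain beyond
HA2/HA3 and is excluded by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    EmptyNetworkError,
    EnsembleFormatError,
    MalformedEnsembleError,
    MassLookupError,
    MassTableError,
)

__all__ = [
    "Residue",
    "StructuralEnsemble",
    "MassTable",
    "SideChainSelection",
    "load_ensemble",
    "write_ensemble_pdb",
    "load_mass_table",
    "select_sidechains",
    "BACKBONE_ATOM_NAMES",
    "DEFAULT_ELEMENT_MASSES",
]

#: Atom names treated as backbone (never part of a side chain): the peptide
#: unit, terminal oxygen, and the backbone hydrogens.
BACKBONE_ATOM_NAMES = frozenset(
    {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HA", "HA2", "HA3"}
)

#: Standard atomic masses (amu) used when no mass file is supplied.
DEFAULT_ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
}


class Residue(NamedTuple):
    """Identity of a residue: (chain, resid, insertion code, residue name).

    Ordering follows the tuple, i.e. by chain, then resid, then insertion
    code — the deterministic order used for nodes throughout the package.
    """

    chain: str
    resid: int
    icode: str
    resname: str

    @property
    def label(self) -> str:
        """Compact ``chain:resid[icode]:resname`` label, e.g. ``A:42:LEU``."""
        return f"{self.chain}:{self.resid}{self.icode}:{self.resname}"


def _infer_element(atom_name: str) -> str:
    """Infer the chemical element from a PDB atom name.

    Handles the common protein cases: names starting with a digit or with
    ``H`` are hydrogens (1HB2, HG21, ...), two-letter ``SE`` (selenium in
    MSE), otherwise the first alphabetic character.
    """
    stripped = atom_name.strip()
    if not stripped:
        return ""
    bare = stripped.lstrip("0123456789")
    if not bare:
        return ""
    if bare.upper().startswith("SE") and stripped.upper() not in ("S", "SD", "SG"):
        return "SE"
    first = bare[0].upper()
    return first


@dataclass
class StructuralEnsemble:
    """frames × atoms coordinates (Å) plus per-atom metadata.

    Attributes
    ----------
    atoms:
        DataFrame with one row per atom and columns ``name``, ``element``,
        ``chain``, ``resid``, ``icode``, ``resname``. Identical for every
        frame (all frames share atom count and ordering).
    coordinates:
        float array of shape ``(n_frames, n_atoms, 3)`` in Å.
    frame_indices:
        Original frame numbers of each stored frame, for subset provenance.
    """

    atoms: pd.DataFrame
    coordinates: np.ndarray
    frame_indices: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise MalformedEnsembleError(
                f"coordinates must have shape (n_frames, n_atoms, 3), "
                f"got {self.coordinates.shape}"
            )
        if self.coordinates.shape[0] == 0:
            raise EmptyInputError("ensemble has zero frames")
        if self.coordinates.shape[1] != len(self.atoms):
            raise MalformedEnsembleError(
                f"{len(self.atoms)} atom records but coordinate frames carry "
                f"{self.coordinates.shape[1]} atoms"
            )
        if len(self.frame_indices) != self.coordinates.shape[0]:
            raise MalformedEnsembleError("frame_indices length != n_frames")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def slice_frames(self, indices: Sequence[int]) -> "StructuralEnsemble":
        """Sub-ensemble containing the given frame positions, order kept."""
        idx = np.asarray(indices, dtype=int)
        return StructuralEnsemble(
            atoms=self.atoms,
            coordinates=self.coordinates[idx],
            frame_indices=self.frame_indices[idx],
        )

    def residues(self) -> list[Residue]:
        """All residues present, sorted by (chain, resid, icode)."""
        seen: dict[Residue, None] = {}
        for row in self.atoms.itertuples(index=False):
            seen.setdefault(Residue(row.chain, int(row.resid), row.icode, row.resname))
        return sorted(seen)


def load_ensemble(
    path: str | Path,
    topology: str | Path | None = None,
    frame_stride: int = 1,
) -> StructuralEnsemble:
    """Read a structural ensemble from disk.

    Parameters
    ----------
    path:
        Multi-model PDB (readable standalone) or a binary trajectory
        (XTC/TRR/DCD), in which case ``topology`` is required.
    topology:
        Topology structure file (PDB/GRO) for binary trajectories.
    frame_stride:
        Keep every ``frame_stride``-th frame; original frame numbers are
        recorded in ``frame_indices``.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise EnsembleFormatError(f"no such file: {path}")
    if frame_stride < 1:
        raise ValueError(f"frame_stride must be >= 1, got {frame_stride}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if topology is not None:
                universe = mda.Universe(str(topology), str(path))
            else:
                universe = mda.Universe(str(path))
        except EmptyInputError:
            raise
        except Exception as exc:  # MDAnalysis raises many types here
            raise EnsembleFormatError(f"cannot read {path}: {exc}") from exc

        ag = universe.atoms
        if len(ag) == 0:
            raise EmptyInputError(f"{path} contains no atoms")

        names = [a.strip() for a in ag.names]
        try:
            elements = [str(e).strip().upper() for e in ag.elements]
        except Exception:
            elements = [""] * len(ag)
        elements = [
            e if e else _infer_element(n) for e, n in zip(elements, names)
        ]
        try:
            chains = [str(c).strip() or "A" for c in ag.chainIDs]
        except Exception:
            chains = [str(s).strip() or "A" for s in ag.segids]
        try:
            icodes = [str(i).strip() for i in ag.icodes]
        except Exception:
            icodes = [""] * len(ag)

        atoms = pd.DataFrame(
            {
                "name": names,
                "element": elements,
                "chain": chains,
                "resid": ag.resids.astype(int),
                "icode": icodes,
                "resname": [r.strip() for r in ag.resnames],
            }
        )

        frames: list[np.ndarray] = []
        indices: list[int] = []
        try:
            for i, _ts in enumerate(universe.trajectory):
                if i % frame_stride == 0:
                    frames.append(ag.positions.astype(float).copy())
                    indices.append(i)
        except EOFError:
            pass  # ragged trailing data: keep complete frames
        except Exception as exc:
            raise MalformedEnsembleError(
                f"frame {len(frames)} of {path} is inconsistent with the "
                f"first frame: {exc}"
            ) from exc

    if not frames:
        raise EmptyInputError(f"{path} contains no frames")
    return StructuralEnsemble(
        atoms=atoms,
        coordinates=np.stack(frames),
        frame_indices=np.array(indices),
    )


def write_ensemble_pdb(ensemble: StructuralEnsemble, path: str | Path) -> Path:
    """Write the ensemble as a multi-model PDB (MODEL/ENDMDL records).

    Coordinates are written at the format's 3-decimal precision; re-reading
    with :func:`load_ensemble` reproduces them to that precision. Output is
    deterministic: identical ensembles give byte-identical files.
    """
    path = Path(path)
    atoms = ensemble.atoms
    lines: list[str] = []
    for f in range(ensemble.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        serial = 1
        for j, row in enumerate(atoms.itertuples(index=False)):
            x, y, z = ensemble.coordinates[f, j]
            name = row.name
            # PDB atom-name column convention: 1-letter elements start in
            # column 14, longer names in column 13.
            padded = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
            element = (row.element or _infer_element(name))[:2]
            lines.append(
                f"ATOM  {serial:5d} {padded} {row.resname:<3s} "
                f"{(row.chain or 'A')[:1]}{row.resid:4d}{row.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {element:>2s}"
            )
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


@dataclass
class MassTable:
    """Atomic masses for COM weighting.

    Lookup resolves ``(residue_name, atom_name)`` entries first, then falls
    back to the element mass. Every side-chain atom must resolve one way or
    the other.
    """

    entries: dict[tuple[str, str], float] = field(default_factory=dict)
    element_masses: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ELEMENT_MASSES)
    )
    provenance: str = "default element masses"

    def __post_init__(self) -> None:
        for key, mass in list(self.entries.items()) + list(
            self.element_masses.items()
        ):
            if not mass > 0:
                raise MassTableError(f"non-positive mass {mass} for {key}")

    def mass_of(self, resname: str, atom_name: str, element: str = "") -> float:
        specific = self.entries.get((resname.upper(), atom_name.upper()))
        if specific is not None:
            return specific
        elem = (element or _infer_element(atom_name)).upper()
        fallback = self.element_masses.get(elem)
        if fallback is None:
            raise MassLookupError(
                f"no mass for atom {atom_name!r} (residue {resname!r}, "
                f"element {elem!r}) in table [{self.provenance}]"
            )
        return fallback


def load_mass_table(path: str | Path | None = None) -> MassTable:
    """Load a mass table, or the default element-mass table when ``path`` is None.

    File format: whitespace-separated lines, ``#`` comments. Three tokens
    ``RESNAME ATOMNAME MASS`` define a residue-specific entry; two tokens
    ``ELEMENT MASS`` override/extend the element fallback.
    """
    if path is None:
        return MassTable()
    path = Path(path)
    entries: dict[tuple[str, str], float] = {}
    element_masses = dict(DEFAULT_ELEMENT_MASSES)
    seen_elements: set[str] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        try:
            mass = float(tokens[-1])
        except ValueError as exc:
            raise MassTableError(
                f"{path}:{lineno}: mass {tokens[-1]!r} is not a number"
            ) from exc
        if not mass > 0:
            raise MassTableError(f"{path}:{lineno}: non-positive mass {mass}")
        if len(tokens) == 3:
            key = (tokens[0].upper(), tokens[1].upper())
            if key in entries:
                raise MassTableError(f"{path}:{lineno}: duplicate entry {key}")
            entries[key] = mass
        elif len(tokens) == 2:
            elem = tokens[0].upper()
            if elem in seen_elements:
                raise MassTableError(
                    f"{path}:{lineno}: duplicate element entry {elem}"
                )
            seen_elements.add(elem)
            element_masses[elem] = mass
        else:
            raise MassTableError(
                f"{path}:{lineno}: expected 2 or 3 tokens, got {len(tokens)}"
            )
    return MassTable(
        entries=entries, element_masses=element_masses, provenance=str(path)
    )


@dataclass
class SideChainSelection:
    """The node set of the network and the atoms behind each node.

    ``nodes`` are ordered by (chain, resid, icode); ``atom_indices[node]``
    are row indices into the ensemble's atom table; ``excluded`` records
    every residue dropped, with the reason (``excluded_resname`` or
    ``no_sidechain_atoms``).
    """

    nodes: list[Residue]
    atom_indices: dict[Residue, np.ndarray]
    excluded: list[tuple[Residue, str]]

    def __post_init__(self) -> None:
        for node in self.nodes:
            if len(self.atom_indices[node]) == 0:
                raise EmptyNetworkError(f"node {node.label} has no atoms")


def select_sidechains(
    ensemble: StructuralEnsemble,
    excluded_resnames: Iterable[str] = ("GLY",),
) -> SideChainSelection:
    """Select side-chain atoms and define the residue node set.

    Every residue whose name is not in ``excluded_resnames`` contributes a
    node carrying all its atoms except the backbone names
    (:data:`BACKBONE_ATOM_NAMES`); residues left with no atoms (e.g. only a
    backbone was resolved) are excluded with reason ``no_sidechain_atoms``.
    """
    excluded_set = {r.upper() for r in excluded_resnames}
    groups: dict[Residue, list[int]] = {}
    for i, row in enumerate(ensemble.atoms.itertuples(index=False)):
        res = Residue(row.chain, int(row.resid), row.icode, row.resname)
        groups.setdefault(res, []).append(i)

    nodes: list[Residue] = []
    atom_indices: dict[Residue, np.ndarray] = {}
    excluded: list[tuple[Residue, str]] = []
    for res in sorted(groups):
        if res.resname.upper() in excluded_set:
            excluded.append((res, "excluded_resname"))
            continue
        names = ensemble.atoms["name"].values
        side = np.array(
            [i for i in groups[res] if names[i].upper() not in BACKBONE_ATOM_NAMES],
            dtype=int,
        )
        if len(side) == 0:
            excluded.append((res, "no_sidechain_atoms"))
            continue
        nodes.append(res)
        atom_indices[res] = side

    if not nodes:
        raise EmptyNetworkError(
            "side-chain selection produced an empty node set "
            f"({len(excluded)} residues excluded)"
        )
    return SideChainSelection(nodes=nodes, atom_indices=atom_indices, excluded=excluded)
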