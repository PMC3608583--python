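"""Core in-memory containers: atoms, systems, trajectories, selections.

A :class:`MolecularSystem` couples an ordered atom table (with force-field
parameters attached) to reference coordinates; a :class:`TrajectorySeries`
adds a stack of frames.  Residue selections are plain (chain, residue_index)
member lists; the groove compartment map pairs an alpha-side and a beta-side
selection per compartment.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .constants import WATER_RESNAMES
from .errors import ConfigurationError, ShapeError


@dataclass(frozen=True)
class AtomRecord:
    """One atom with its per-atom force-field parameters.

    Units: mass amu, partial_charge e, lj_epsilon kcal/mol, lj_rmin_half and
    born_radius_seed Angstrom.  ``residue_index`` is 1-based per chain, taken
    verbatim from the structure file (no renumbering).
    """

    atom_name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    mass: float
    partial_charge: float = 0.0
    lj_epsilon: float = 0.0
    lj_rmin_half: float = 0.0
    born_radius_seed: float = 1.5

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.atom_name}: mass must be > 0, got {self.mass}")
        if self.residue_index <= 0:
            raise ValueError(
                f"atom {self.atom_name}: residue_index must be positive, got {self.residue_index}"
            )

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


class MolecularSystem:
    """Topology + parameters + reference coordinates.

    Parameters
    ----------
    atoms
        Ordered atom records.
    reference_coords
        (N, 3) array in Angstrom; N must equal ``len(atoms)``.
    """

    def __init__(self, atoms: Sequence[AtomRecord], reference_coords: np.ndarray):
        self.atoms: tuple[AtomRecord, ...] = tuple(atoms)
        coords = np.asarray(reference_coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ShapeError(f"reference_coords must be (N, 3), got {coords.shape}")
        if coords.shape[0] != len(self.atoms):
            raise ShapeError(
                f"reference_coords has {coords.shape[0]} rows for {len(self.atoms)} atoms"
            )
        self.reference_coords = coords.copy()
        # cached column arrays
        self.names = np.array([a.atom_name for a in self.atoms])
        self.elements = np.array([a.element for a in self.atoms])
        self.resids = np.array([a.residue_index for a in self.atoms], dtype=int)
        self.resnames = np.array([a.residue_name for a in self.atoms])
        self.chains = np.array([a.chain_id for a in self.atoms])
        self.masses = np.array([a.mass for a in self.atoms], dtype=float)
        self.charges = np.array([a.partial_charge for a in self.atoms], dtype=float)
        self.lj_epsilon = np.array([a.lj_epsilon for a in self.atoms], dtype=float)
        self.lj_rmin_half = np.array([a.lj_rmin_half for a in self.atoms], dtype=float)
        self.radii = np.array([a.born_radius_seed for a in self.atoms], dtype=float)
        self.heavy = np.array([a.is_heavy for a in self.atoms], dtype=bool)
        self.chain_index: dict[str, np.ndarray] = {
            c: np.flatnonzero(self.chains == c) for c in dict.fromkeys(self.chains)
        }

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residues(self, chain_id: str | None = None) -> Iterator[tuple[str, int, str, np.ndarray]]:
        """Yield (chain_id, residue_index, residue_name, atom_indices) in file order."""
        seen: dict[tuple[str, int], list[int]] = {}
        order: list[tuple[str, int]] = []
        for i, a in enumerate(self.atoms):
            key = (a.chain_id, a.residue_index)
            if key not in seen:
                seen[key] = []
                order.append(key)
            seen[key].append(i)
        for chain, resid in order:
            if chain_id is not None and chain != chain_id:
                continue
            idx = np.asarray(seen[(chain, resid)], dtype=int)
            yield chain, resid, self.resnames[idx[0]], idx

    def residue_atoms(self, chain_id: str, residue_index: int) -> np.ndarray:
        idx = np.flatnonzero((self.chains == chain_id) & (self.resids == residue_index))
        if idx.size == 0:
            raise ConfigurationError(f"residue {chain_id}:{residue_index} not present in system")
        return idx

    def has_residue(self, chain_id: str, residue_index: int) -> bool:
        return bool(np.any((self.chains == chain_id) & (self.resids == residue_index)))

    def select_atoms(
        self,
        members: Iterable[tuple[str, int]],
        atom_names: Sequence[str] | None = None,
        heavy_only: bool = False,
    ) -> np.ndarray:
        """Atom indices of the given (chain, residue) members, optionally filtered."""
        keys = {(c, int(r)) for c, r in members}
        mask = np.array(
            [(c, r) in keys for c, r in zip(self.chains, self.resids)], dtype=bool
        )
        if atom_names is not None:
            mask &= np.isin(self.names, list(atom_names))
        if heavy_only:
            mask &= self.heavy
        return np.flatnonzero(mask)

    def water_oxygen_indices(self) -> np.ndarray:
        return np.flatnonzero(
            np.isin(self.resnames, list(WATER_RESNAMES)) & (self.elements == "O")
        )

    def with_charges(self, charges: np.ndarray | float) -> "MolecularSystem":
        """Copy of the system with replaced partial charges (used in what-if scoring)."""
        charges = np.broadcast_to(np.asarray(charges, dtype=float), (self.n_atoms,))
        atoms = [
            AtomRecord(
                a.atom_name, a.element, a.residue_index, a.residue_name, a.chain_id,
                a.mass, float(q), a.lj_epsilon, a.lj_rmin_half, a.born_radius_seed,
            )
            for a, q in zip(self.atoms, charges)
        ]
        return MolecularSystem(atoms, self.reference_coords)

    def subset(self, keep: np.ndarray) -> "MolecularSystem":
        """System restricted to the given atom indices (order preserved)."""
        keep = np.asarray(keep, dtype=int)
        return MolecularSystem([self.atoms[i] for i in keep], self.reference_coords[keep])


@dataclass
class TrajectorySeries:
    """Ordered frames of Cartesian coordinates for a system.

    ``frames`` is (T, N, 3) in Angstrom; ``frame_interval`` in ps.
    """

    system: MolecularSystem
    frames: np.ndarray
    frame_interval: float = 20.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ShapeError(f"frames must be (T, N, 3), got {self.frames.shape}")
        if self.frames.shape[1] != self.system.n_atoms:
            raise ShapeError(
                f"trajectory has {self.frames.shape[1]} atoms, system has "
                f"{self.system.n_atoms}"
            )
        if self.frames.shape[0] < 1:
            raise ShapeError("trajectory must contain at least one frame")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


@dataclass(frozen=True)
class ResidueSelection:
    """A named list of (chain_id, residue_index) members."""

    label: str
    members: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ConfigurationError(f"selection '{self.label}' is empty")
        if len(set(self.members)) != len(self.members):
            raise ConfigurationError(f"selection '{self.label}' has duplicate members")

    @staticmethod
    def from_ranges(label: str, ranges: Iterable[tuple[str, int, int]]) -> "ResidueSelection":
        members = []
        for chain, lo, hi in ranges:
            members.extend((chain, r) for r in range(lo, hi + 1))
        return ResidueSelection(label, tuple(members))

    def to_json(self) -> str:
        return json.dumps(
            {"label": self.label, "members": [[c, r] for c, r in self.members]},
            sort_keys=True,
        )


@dataclass(frozen=True)
class Compartment:
    name: str
    alpha_selection: ResidueSelection
    beta_selection: ResidueSelection

    def __post_init__(self) -> None:
        overlap = set(self.alpha_selection.members) & set(self.beta_selection.members)
        if overlap:
            raise ConfigurationError(
                f"compartment {self.name}: alpha/beta selections overlap on {sorted(overlap)}"
            )


@dataclass(frozen=True)
class CompartmentMap:
    """Ordered groove compartments, each an alpha-side + beta-side residue pair."""

    compartments: tuple[Compartment, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.compartments)

    def __iter__(self) -> Iterator[Compartment]:
        return iter(self.compartments)

    def get(self, name: str) -> Compartment:
        for c in self.compartments:
            if c.name == name:
                return c
        raise ConfigurationError(f"no compartment named '{name}'")

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "name": c.name,
                    "alpha": [[ch, r] for ch, r in c.alpha_selection.members],
                    "beta": [[ch, r] for ch, r in c.beta_selection.members],
                }
                for c in self.compartments
            ],
            sort_keys=True,
        )
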