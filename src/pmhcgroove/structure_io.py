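"""Structure/trajectory I/O and the groove selection conventions.

Reading goes through MDAnalysis (PDB structures; DCD or multi-model PDB
trajectories); per-atom charges, Lennard-Jones parameters, radii and masses
come from a packaged tab-separated parameter table keyed on
(residue_name, atom_name).

Chain conventions: chain ``A`` is the MHC alpha chain, ``B`` the beta chain,
water residues (HOH/WAT/TIP3) map to chain class ``W``, and any remaining
chain is treated as the bound peptide ``P``.  Residue numbering is taken
verbatim from the file (1-based per chain, mature-protein convention);
insertion codes are ignored.
"""
from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import WATER_RESNAMES
from .errors import ConfigurationError, ParameterizationError, ParseError, ShapeError
from .system import (
    AtomRecord,
    Compartment,
    CompartmentMap,
    MolecularSystem,
    ResidueSelection,
    TrajectorySeries,
)

#: Binding-site residue ranges: alpha1 domain 5-76, beta1 domain 5-90.
DEFAULT_BINDING_SITE = {"A": (5, 76), "B": (5, 90)}

#: Groove compartments D1-D4 as (alpha range, beta range) residue pairs.
DEFAULT_COMPARTMENTS: tuple[tuple[str, tuple[int, int], tuple[int, int]], ...] = (
    ("D1", (50, 51), (85, 86)),
    ("D2", (53, 55), (78, 83)),
    ("D3", (60, 65), (65, 70)),
    ("D4", (68, 73), (56, 61)),
)

ParamTable = Mapping[tuple[str, str], tuple[float, float, float, float, float]]


def load_parameter_table(path: str | Path | None = None) -> dict:
    """Load the per-(residue, atom) parameter table.

    Returns a dict mapping (residue_name, atom_name) to
    (element, charge, epsilon, rmin_half, radius, mass).
    """
    if path is None:
        source = resources.files("pmhcgroove.data") / "parameters.tsv"
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"residue", "atom", "element", "charge", "epsilon", "rmin_half", "radius", "mass"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"parameter table missing columns: {sorted(missing)}")
    return {
        (row.residue, row.atom): (
            row.element, float(row.charge), float(row.epsilon),
            float(row.rmin_half), float(row.radius), float(row.mass),
        )
        for row in df.itertuples()
    }


def _classify_chain(chain_id: str, residue_name: str) -> str:
    if residue_name in WATER_RESNAMES:
        return "W"
    if chain_id in ("A", "B"):
        return chain_id
    return "P"


def _atom_record(name: str, resid: int, resname: str, chain: str, table: ParamTable) -> AtomRecord:
    try:
        element, charge, eps, rmin_half, radius, mass = table[(resname, name)]
    except KeyError:
        raise ParameterizationError(
            f"no parameters for atom '{name}' of residue '{resname}' "
            f"(chain {chain}, residue {resid})"
        ) from None
    return AtomRecord(
        atom_name=name, element=element, residue_index=int(resid), residue_name=resname,
        chain_id=chain, mass=mass, partial_charge=charge, lj_epsilon=eps,
        lj_rmin_half=rmin_half, born_radius_seed=radius,
    )


def read_structure(path: str | Path, param_table: str | Path | ParamTable | None = None) -> MolecularSystem:
    """Read a PDB structure and attach force-field parameters to every atom."""
    import MDAnalysis as mda

    table = (
        param_table
        if isinstance(param_table, Mapping)
        else load_parameter_table(param_table)
    )
    path = Path(path)
    if not path.exists():
        raise ParseError(f"structure file not found: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            universe = mda.Universe(str(path))
    except Exception as exc:  # MDAnalysis raises assorted types on bad input
        raise ParseError(f"could not parse structure '{path}': {exc}") from exc
    atoms = []
    for a in universe.atoms:
        chain = _classify_chain(getattr(a, "chainID", "") or a.segid, a.resname)
        atoms.append(_atom_record(a.name, a.resid, a.resname, chain, table))
    if not atoms:
        raise ParseError(f"structure '{path}' contains no atoms")
    return MolecularSystem(atoms, universe.atoms.positions.astype(float))


def to_mdanalysis(system: MolecularSystem, frames: np.ndarray | None = None):
    """Build an MDAnalysis Universe mirroring the system (helper for writers)."""
    import MDAnalysis as mda

    n = system.n_atoms
    residue_keys: list[tuple[str, int]] = []
    res_of_atom = np.empty(n, dtype=int)
    for i in range(n):
        key = (system.chains[i], int(system.resids[i]))
        if not residue_keys or residue_keys[-1] != key:
            residue_keys.append(key)
        res_of_atom[i] = len(residue_keys) - 1
    seg_ids = list(dict.fromkeys(c for c, _ in residue_keys))
    seg_of_res = np.array([seg_ids.index(c) for c, _ in residue_keys], dtype=int)
    u = mda.Universe.empty(
        n_atoms=n, n_residues=len(residue_keys), n_segments=len(seg_ids),
        atom_resindex=res_of_atom, residue_segindex=seg_of_res, trajectory=True,
    )
    u.add_TopologyAttr("names", system.names)
    u.add_TopologyAttr("elements", system.elements)
    u.add_TopologyAttr("masses", system.masses)
    u.add_TopologyAttr("chainIDs", system.chains)
    u.add_TopologyAttr("resids", np.array([r for _, r in residue_keys], dtype=int))
    first_atom = np.searchsorted(res_of_atom, np.arange(len(residue_keys)))
    u.add_TopologyAttr("resnames", system.resnames[first_atom])
    u.add_TopologyAttr("segids", np.array(seg_ids))
    if frames is None:
        u.atoms.positions = system.reference_coords.astype(np.float32)
    else:
        frames = np.asarray(frames, dtype=np.float32)
        u.load_new(frames, order="fac")
    return u


def write_structure(system: MolecularSystem, path: str | Path) -> None:
    """Write the reference coordinates as a single-model PDB."""
    u = to_mdanalysis(system)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(traj: TrajectorySeries, path: str | Path) -> None:
    """Write frames as DCD (binary) or multi-model PDB (text), by extension."""
    import MDAnalysis as mda

    path = Path(path)
    u = to_mdanalysis(traj.system, frames=traj.frames)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.system.n_atoms) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def read_trajectory(
    system: MolecularSystem,
    path: str | Path,
    frame_interval: float | None = None,
) -> TrajectorySeries:
    """Read a trajectory (DCD or multi-model PDB) onto an existing system.

    The file's atom count must match the system; ``frame_interval`` (ps)
    overrides whatever the file header carries.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ParseError(f"trajectory file missing or empty: {path}")
    u = to_mdanalysis(system)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u.load_new(str(path))
    except Exception as exc:
        n_file = _trajectory_atom_count(path)
        if n_file is not None and n_file != system.n_atoms:
            raise ShapeError(
                f"trajectory '{path}' has {n_file} atoms, system has {system.n_atoms}"
            ) from exc
        raise ParseError(f"could not parse trajectory '{path}': {exc}") from exc
    if u.trajectory.n_atoms != system.n_atoms:
        raise ShapeError(
            f"trajectory has {u.trajectory.n_atoms} atoms, system has {system.n_atoms}"
        )
    frames = np.stack([u.atoms.positions.astype(float) for _ in u.trajectory])
    if frame_interval is None:
        dt = float(getattr(u.trajectory, "dt", 0.0) or 0.0)
        frame_interval = dt if dt > 0 else 20.0
    return TrajectorySeries(system=system, frames=frames, frame_interval=frame_interval)


def _trajectory_atom_count(path: Path) -> int | None:
    """Atom count stated by the file itself (first PDB model / DCD header)."""
    try:
        if path.suffix.lower() == ".dcd":
            from MDAnalysis.lib.formats.libdcd import DCDFile

            with DCDFile(str(path)) as f:
                return int(f.header["natoms"])
        count = 0
        with open(path) as fh:
            for line in fh:
                if line.startswith(("ATOM", "HETATM")):
                    count += 1
                elif line.startswith(("ENDMDL", "END")):
                    break
        return count or None
    except Exception:
        return None


def binding_site_selection(
    system: MolecularSystem,
    ranges: Mapping[str, tuple[int, int]] | None = None,
    label: str = "binding_site",
) -> ResidueSelection:
    """Binding-site residues (alpha1 5-76 and beta1 5-90 by default),
    intersected with the residues actually present in the system."""
    ranges = dict(DEFAULT_BINDING_SITE if ranges is None else ranges)
    for chain in ranges:
        if chain not in system.chain_index:
            raise ConfigurationError(f"binding-site chain '{chain}' absent from system")
    members = []
    for chain, (lo, hi) in ranges.items():
        present = np.unique(system.resids[system.chain_index[chain]])
        members.extend((chain, int(r)) for r in present if lo <= r <= hi)
    if not members:
        raise ConfigurationError("binding-site selection is empty for this system")
    return ResidueSelection(label, tuple(members))


def compartment_selections(
    system: MolecularSystem,
    compartments: Sequence[tuple[str, tuple[int, int], tuple[int, int]]] | None = None,
) -> CompartmentMap:
    """The groove compartment map (default D1-D4); every listed residue must exist."""
    compartments = DEFAULT_COMPARTMENTS if compartments is None else tuple(compartments)
    built = []
    for name, (alo, ahi), (blo, bhi) in compartments:
        for chain, lo, hi in (("A", alo, ahi), ("B", blo, bhi)):
            for r in range(lo, hi + 1):
                if not system.has_residue(chain, r):
                    raise ConfigurationError(
                        f"compartment {name}: residue {chain}:{r} not present in system"
                    )
        built.append(
            Compartment(
                name=name,
                alpha_selection=ResidueSelection.from_ranges(f"{name}_alpha", [("A", alo, ahi)]),
                beta_selection=ResidueSelection.from_ranges(f"{name}_beta", [("B", blo, bhi)]),
            )
        )
    return CompartmentMap(tuple(built))
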