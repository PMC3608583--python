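"""Per-frame interaction detectors and persistence networks.

Three residue-pair interaction types between a receptor-side and a
peptide-side selection are detected frame by frame:

* hydrogen bonds — donor-acceptor heavy-atom distance <= 3.1 A and
  donor-H-acceptor angle >= 130 deg (near-linear bonds pass);
* planar/aromatic stacking — acute angle between least-squares ring planes
  <= 30 deg and ring-centroid distance <= 5.0 A;
* hydrophobic contacts — minimum side-chain heavy-atom distance <= 4.0 A
  with no water oxygen within 4.0 A of any contact-forming atom.

Atom-level hits are OR-combined into one record per residue pair; a record
is reported when its persistence (fraction of frames present) reaches the
threshold, 20% by default.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import BACKBONE_ATOMS
from .errors import ConfigurationError, InternalError
from .system import MolecularSystem, ResidueSelection, TrajectorySeries

#: Residues carrying a planar/ring side-chain group, with the atoms defining
#: the plane.  Arg's guanidinium is included: it behaves as a planar stacking
#: partner for aromatic rings in grooves.
RING_ATOMS: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "ARG": ("NE", "CZ", "NH1", "NH2"),
}

PLANAR_RESIDUES = frozenset(RING_ATOMS)

#: Residues counted as hydrophobic for the water-excluded contact detector.
HYDROPHOBIC_RESIDUES = frozenset({"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP"})

#: Maximum covalent donor-H bond length used to associate hydrogens with
#: their donor heavy atom (geometric bond inference on the reference frame).
_DONOR_H_BOND = 1.25


@dataclass(frozen=True)
class HBondCriteria:
    da_cutoff: float = 3.1
    angle_cutoff: float = 130.0
    persistence_threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.da_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ConfigurationError("H-bond cutoffs must be positive")
        if not 0 <= self.persistence_threshold <= 1:
            raise ConfigurationError("persistence_threshold must lie in [0, 1]")


@dataclass(frozen=True)
class StackCriteria:
    dihedral_cutoff: float = 30.0
    centroid_cutoff: float = 5.0
    persistence_threshold: float = 0.2
    planar_residues: frozenset = PLANAR_RESIDUES

    def __post_init__(self) -> None:
        if self.dihedral_cutoff <= 0 or self.centroid_cutoff <= 0:
            raise ConfigurationError("stacking cutoffs must be positive")
        if not 0 <= self.persistence_threshold <= 1:
            raise ConfigurationError("persistence_threshold must lie in [0, 1]")


@dataclass(frozen=True)
class HydrophobicCriteria:
    contact_cutoff: float = 4.0
    water_exclusion_radius: float = 4.0
    persistence_threshold: float = 0.2
    hydrophobic_residues: frozenset = HYDROPHOBIC_RESIDUES

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0 or self.water_exclusion_radius <= 0:
            raise ConfigurationError("hydrophobic cutoffs must be positive")
        if not 0 <= self.persistence_threshold <= 1:
            raise ConfigurationError("persistence_threshold must lie in [0, 1]")


@dataclass
class InteractionRecord:
    """One residue-pair interaction with its per-frame presence trace."""

    kind: str
    mhc_partner: tuple[str, int, str]  # (chain, residue_index, residue_name)
    pep_partner: tuple[int, str]  # (residue_index, residue_name)
    presence: np.ndarray = field(repr=False)
    persistence: float = 0.0

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        self.persistence = float(self.presence.mean())


def _residues_of(system: MolecularSystem, sel: ResidueSelection):
    out = []
    for chain, resid in sel.members:
        if system.has_residue(chain, resid):
            idx = system.residue_atoms(chain, resid)
            out.append((chain, resid, str(system.resnames[idx[0]]), idx))
    return out


def _donors_with_h(system: MolecularSystem, idx: np.ndarray):
    """(donor_heavy, [h, ...]) pairs within one residue, bond-inferred on the
    reference coordinates."""
    heavies = [i for i in idx if system.elements[i] in ("N", "O", "S")]
    hydrogens = [i for i in idx if system.elements[i] == "H"]
    ref = system.reference_coords
    donors = []
    for d in heavies:
        hs = [h for h in hydrogens if np.linalg.norm(ref[h] - ref[d]) <= _DONOR_H_BOND]
        if hs:
            donors.append((d, hs))
    return donors


def _acceptors(system: MolecularSystem, idx: np.ndarray):
    return [i for i in idx if system.elements[i] in ("N", "O")]


def _pair_presence_hbond(frames, donors, acceptors, criteria) -> np.ndarray:
    present = np.zeros(frames.shape[0], dtype=bool)
    cos_cut = np.cos(np.deg2rad(criteria.angle_cutoff))
    for d, hs in donors:
        for a in acceptors:
            if a == d:
                continue
            vd = frames[:, a, :] - frames[:, d, :]
            dist = np.linalg.norm(vd, axis=1)
            ok_dist = dist <= criteria.da_cutoff
            if not ok_dist.any():
                continue
            hit = np.zeros_like(present)
            for h in hs:
                v1 = frames[:, d, :] - frames[:, h, :]
                v2 = frames[:, a, :] - frames[:, h, :]
                denom = np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    cosang = np.einsum("ij,ij->i", v1, v2) / denom
                # angle >= cutoff  <=>  cos(angle) <= cos(cutoff)
                hit |= cosang <= cos_cut
            present |= ok_dist & hit
    return present


def detect_hbonds(
    traj: TrajectorySeries,
    group_a: ResidueSelection,
    group_b: ResidueSelection,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[InteractionRecord]:
    """Hydrogen bonds between group_a (receptor side) and group_b (peptide side).

    Both donor->acceptor directions are searched; residue pairs without any
    donor/acceptor atoms simply yield no records.
    """
    system = traj.system
    records = []
    for chain, resid, resname, idx_a in _residues_of(system, group_a):
        don_a, acc_a = _donors_with_h(system, idx_a), _acceptors(system, idx_a)
        for _, resid_b, resname_b, idx_b in _residues_of(system, group_b):
            don_b, acc_b = _donors_with_h(system, idx_b), _acceptors(system, idx_b)
            present = _pair_presence_hbond(traj.frames, don_a, acc_b, criteria)
            present |= _pair_presence_hbond(traj.frames, don_b, acc_a, criteria)
            rec = InteractionRecord(
                "hbond", (chain, resid, resname), (resid_b, resname_b), present
            )
            if rec.persistence >= criteria.persistence_threshold and rec.persistence > 0:
                records.append(rec)
    return records


def ring_indices(system: MolecularSystem, chain: str, resid: int) -> np.ndarray:
    """Atom indices of the planar group of a ring-bearing residue."""
    idx = system.residue_atoms(chain, resid)
    resname = str(system.resnames[idx[0]])
    if resname not in RING_ATOMS:
        raise ConfigurationError(f"residue {chain}:{resid} ({resname}) has no planar group")
    wanted = RING_ATOMS[resname]
    names = system.names[idx]
    out = [idx[list(names).index(n)] for n in wanted if n in names]
    if len(out) != len(wanted):
        missing = sorted(set(wanted) - set(names))
        raise ConfigurationError(
            f"residue {chain}:{resid} ({resname}) missing ring atoms {missing}"
        )
    return np.asarray(out, dtype=int)


def _plane_normals(coords: np.ndarray) -> np.ndarray:
    """Least-squares plane normals for (T, k, 3) ring coordinates."""
    centered = coords - coords.mean(axis=1, keepdims=True)
    # smallest right-singular vector of each frame's centered ring
    _, _, vt = np.linalg.svd(centered)
    return vt[:, -1, :]


def detect_stacking(
    traj: TrajectorySeries,
    group_a: ResidueSelection,
    group_b: ResidueSelection,
    criteria: StackCriteria = StackCriteria(),
) -> list[InteractionRecord]:
    """Planar stacking between ring-bearing residues of the two groups."""
    system = traj.system
    res_a = [r for r in _residues_of(system, group_a) if r[2] in criteria.planar_residues]
    res_b = [r for r in _residues_of(system, group_b) if r[2] in criteria.planar_residues]
    cos_cut = np.cos(np.deg2rad(criteria.dihedral_cutoff))
    records = []
    for chain, resid, resname, _ in res_a:
        ring_a = ring_indices(system, chain, resid)
        coords_a = traj.frames[:, ring_a, :]
        cent_a, norm_a = coords_a.mean(axis=1), _plane_normals(coords_a)
        for chain_b, resid_b, resname_b, _ in res_b:
            ring_b = ring_indices(system, chain_b, resid_b)
            coords_b = traj.frames[:, ring_b, :]
            cent_b, norm_b = coords_b.mean(axis=1), _plane_normals(coords_b)
            dist = np.linalg.norm(cent_a - cent_b, axis=1)
            # acute angle between normals: |cos| >= cos(cutoff)
            cosang = np.abs(np.einsum("ij,ij->i", norm_a, norm_b))
            present = (dist <= criteria.centroid_cutoff) & (cosang >= cos_cut)
            rec = InteractionRecord(
                "stacking", (chain, resid, resname), (resid_b, resname_b), present
            )
            if rec.persistence >= criteria.persistence_threshold and rec.persistence > 0:
                records.append(rec)
    return records


def sidechain_heavy_indices(system: MolecularSystem, chain: str, resid: int) -> np.ndarray:
    idx = system.residue_atoms(chain, resid)
    mask = system.heavy[idx] & ~np.isin(system.names[idx], list(BACKBONE_ATOMS))
    return idx[mask]


def detect_hydrophobic(
    traj: TrajectorySeries,
    group_a: ResidueSelection,
    group_b: ResidueSelection,
    criteria: HydrophobicCriteria = HydrophobicCriteria(),
) -> list[InteractionRecord]:
    """Water-excluded hydrophobic contacts between the two groups.

    A frame counts when some side-chain heavy-atom pair is within the contact
    cutoff and no water oxygen lies within the exclusion radius of any atom
    participating in such a pair.
    """
    system = traj.system
    res_a = [r for r in _residues_of(system, group_a) if r[2] in criteria.hydrophobic_residues]
    res_b = [r for r in _residues_of(system, group_b) if r[2] in criteria.hydrophobic_residues]
    waters = system.water_oxygen_indices()
    records = []
    for chain, resid, resname, _ in res_a:
        side_a = sidechain_heavy_indices(system, chain, resid)
        if side_a.size == 0:
            continue
        for chain_b, resid_b, resname_b, _ in res_b:
            side_b = sidechain_heavy_indices(system, chain_b, resid_b)
            if side_b.size == 0:
                continue
            # (T, na, nb) pairwise distances
            diff = traj.frames[:, side_a, None, :] - traj.frames[:, None, side_b, :]
            dist = np.linalg.norm(diff, axis=-1)
            contact_pairs = dist <= criteria.contact_cutoff
            present = contact_pairs.any(axis=(1, 2))
            if waters.size and present.any():
                for t in np.flatnonzero(present):
                    ia, ib = np.nonzero(contact_pairs[t])
                    contact_atoms = np.concatenate([side_a[np.unique(ia)], side_b[np.unique(ib)]])
                    wpos = traj.frames[t][waters]
                    cpos = traj.frames[t][contact_atoms]
                    wdist = np.linalg.norm(wpos[:, None, :] - cpos[None, :, :], axis=-1)
                    if (wdist <= criteria.water_exclusion_radius).any():
                        present[t] = False
            rec = InteractionRecord(
                "hydrophobic", (chain, resid, resname), (resid_b, resname_b), present
            )
            if rec.persistence >= criteria.persistence_threshold and rec.persistence > 0:
                records.append(rec)
    return records


def network_summary(*record_lists: list[InteractionRecord]) -> pd.DataFrame:
    """Merge detector outputs into one network table keyed by
    (kind, receptor residue, peptide residue)."""
    rows = []
    seen = set()
    for rec in itertools.chain.from_iterable(record_lists):
        key = (rec.kind, rec.mhc_partner, rec.pep_partner)
        if key in seen:
            raise InternalError(f"duplicate network key {key}; detectors must pre-aggregate")
        seen.add(key)
        chain, resid, resname = rec.mhc_partner
        resid_p, resname_p = rec.pep_partner
        rows.append(
            {
                "kind": rec.kind, "chain": chain, "res_mhc": resid, "resname_mhc": resname,
                "res_pep": resid_p, "resname_pep": resname_p,
                "persistence": rec.persistence,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["kind", "chain", "res_mhc", "resname_mhc", "res_pep", "resname_pep", "persistence"],
    )
    return df.sort_values(["kind", "chain", "res_mhc", "res_pep"], ignore_index=True)
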