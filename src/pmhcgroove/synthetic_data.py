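"""Toy peptide-MHC-like systems and trajectories with planted ground truth.

The generator builds a coarse two-chain receptor (chains A and B, roughly
parallel backbones) flanking an extended peptide (chain P), with minimal
side-chain atoms — just enough for each detector (backbone N-H/O for
hydrogen bonds, ring atoms for stacking, side-chain heavies for hydrophobic
contacts).  Geometry is deliberately non-physical: chains are spaced so that
no interaction criterion is satisfied by accident, and interactions are then
*planted* frame-by-frame with explicit margins (>= 0.2 A / 10 deg) relative
to the default detector cutoffs, so that persistence fractions are known
exactly.

Fluctuation modes for trajectories:

* ``isotropic_gaussian`` — i.i.d. Gaussian displacement of every coordinate;
* ``full_covariance`` — displacements drawn from a supplied 3N x 3N PSD
  covariance (Cholesky sampling);
* ``two_state`` — the beta-side wall of one groove compartment is rigidly
  translated between two target cross-groove widths with a fixed occupancy,
  emulating an open/closed groove.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, NumericError
from .interaction_networks import HYDROPHOBIC_RESIDUES, RING_ATOMS
from .structure_io import compartment_selections, load_parameter_table
from .system import AtomRecord, MolecularSystem, TrajectorySeries

# ---------------------------------------------------------------------------
# toy geometry tables
# ---------------------------------------------------------------------------

#: chain placement: (y offset of CA line, side-chain direction in (ex,ey,ez))
_CHAIN_LAYOUT = {"A": (8.0, "y+"), "B": (-8.0, "y-"), "P": (0.0, "z+")}
_RESIDUE_SPACING = 3.8
_WATER_Z = 25.0

#: backbone offsets relative to CA in the local (along-chain, sidechain, normal)
#: frame; the N-H vector is what hydrogen-bond planting aligns against.
_BACKBONE = {
    "N": (-1.20, -0.60, 0.0),
    "H": (-1.80, -1.40, 0.0),  # 1.0 A from N
    "C": (1.20, -0.60, 0.0),
    "O": (1.63, -1.75, 0.0),  # 1.23 A from C
}

def _hexagon(center_s: float, radius: float = 1.39):
    """Six ring positions in the (along, side) plane, first vertex pointing
    back toward CB."""
    order = (-90.0, -30.0, 30.0, 90.0, 150.0, 210.0)
    return [
        (radius * np.cos(np.deg2rad(a)), center_s + radius * np.sin(np.deg2rad(a)), 0.0)
        for a in order
    ]

def _pentagon(center_s: float, radius: float = 1.17):
    order = (-90.0, -18.0, 54.0, 126.0, 198.0)
    return [
        (radius * np.cos(np.deg2rad(a)), center_s + radius * np.sin(np.deg2rad(a)), 0.0)
        for a in order
    ]

def _side_chain(resname: str) -> dict[str, tuple[float, float, float]]:
    cb = {"CB": (0.0, 1.53, 0.0)}
    if resname == "GLY":
        return {}
    if resname == "ALA":
        return cb
    if resname == "VAL":
        return cb | {"CG1": (0.9, 2.6, 0.0), "CG2": (-0.9, 2.6, 0.0)}
    if resname == "LEU":
        return cb | {"CG": (0.0, 3.0, 0.0), "CD1": (0.9, 4.0, 0.0), "CD2": (-0.9, 4.0, 0.0)}
    if resname == "ILE":
        return cb | {"CG1": (0.9, 2.6, 0.0), "CG2": (-0.9, 2.6, 0.0), "CD1": (0.9, 4.0, 0.0)}
    if resname == "PRO":
        return cb | {"CG": (0.8, 2.7, 0.0), "CD": (-0.5, 2.9, 0.0)}
    if resname == "MET":
        return cb | {"CG": (0.0, 3.0, 0.0), "SD": (0.0, 4.6, 0.0), "CE": (1.2, 5.4, 0.0)}
    if resname == "SER":
        return cb | {"OG": (0.0, 2.9, 0.0), "HG": (0.8, 3.4, 0.0)}
    if resname == "THR":
        return cb | {"OG1": (0.7, 2.7, 0.0), "HG1": (0.7, 3.7, 0.0), "CG2": (-0.9, 2.6, 0.0)}
    if resname == "ASN":
        return cb | {
            "CG": (0.0, 3.0, 0.0), "OD1": (1.1, 3.6, 0.0), "ND2": (-1.1, 3.6, 0.0),
            "HD21": (-1.1, 4.6, 0.0), "HD22": (-2.0, 3.1, 0.0),
        }
    if resname == "GLN":
        return cb | {
            "CG": (0.0, 3.0, 0.0), "CD": (0.0, 4.5, 0.0), "OE1": (1.1, 5.1, 0.0),
            "NE2": (-1.1, 5.1, 0.0), "HE21": (-1.1, 6.1, 0.0), "HE22": (-2.0, 4.6, 0.0),
        }
    if resname == "ASP":
        return cb | {"CG": (0.0, 3.0, 0.0), "OD1": (1.1, 3.6, 0.0), "OD2": (-1.1, 3.6, 0.0)}
    if resname == "GLU":
        return cb | {
            "CG": (0.0, 3.0, 0.0), "CD": (0.0, 4.5, 0.0),
            "OE1": (1.1, 5.1, 0.0), "OE2": (-1.1, 5.1, 0.0),
        }
    if resname == "LYS":
        return cb | {
            "CG": (0.0, 3.0, 0.0), "CD": (0.0, 4.5, 0.0), "CE": (0.0, 6.0, 0.0),
            "NZ": (0.0, 7.4, 0.0), "HZ1": (0.9, 7.9, 0.0), "HZ2": (-0.9, 7.9, 0.0),
            "HZ3": (0.0, 8.4, 0.0),
        }
    if resname == "ARG":
        return cb | {
            "CG": (0.0, 3.0, 0.0), "CD": (0.0, 4.5, 0.0), "NE": (0.0, 5.9, 0.0),
            "HE": (0.9, 6.3, 0.0), "CZ": (0.0, 7.2, 0.0),
            "NH1": (1.1, 7.9, 0.0), "NH2": (-1.1, 7.9, 0.0),
            "HH11": (1.9, 7.5, 0.0), "HH12": (1.1, 8.9, 0.0),
            "HH21": (-1.9, 7.5, 0.0), "HH22": (-1.1, 8.9, 0.0),
        }
    if resname == "PHE":
        ring = _hexagon(4.29)
        return cb | dict(zip(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"), ring))
    if resname == "TYR":
        ring = _hexagon(4.29)
        out = cb | dict(zip(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"), ring))
        return out | {"OH": (0.0, 7.04, 0.0), "HH": (0.0, 8.0, 0.0)}
    if resname == "HIS":
        ring = _pentagon(4.07)
        out = cb | dict(zip(("CG", "CD2", "NE2", "ND1", "CE1"), ring))
        # rough but planar; add the NE2 proton in-plane
        ne2 = out["NE2"]
        return out | {"HE2": (ne2[0] + 0.9, ne2[1] + 0.45, 0.0)}
    if resname == "TRP":
        ring5 = _pentagon(4.07)
        out = cb | dict(zip(("CG", "CD1", "NE1", "CE2", "CD2"), ring5))
        ne1 = out["NE1"]
        out |= {"HE1": (ne1[0] + 0.9, ne1[1] + 0.45, 0.0)}
        # fused six-ring carbons, kept in the same plane
        out |= {
            "CE3": (-1.2, 5.4, 0.0), "CZ2": (1.4, 6.3, 0.0),
            "CZ3": (-1.0, 6.8, 0.0), "CH2": (0.4, 7.2, 0.0),
        }
        return out
    raise ConfigurationError(f"toy builder does not know residue type '{resname}'")


_DEFAULT_CYCLE = ("ALA", "VAL", "SER", "LEU", "ASN", "ILE", "GLU", "PHE", "LYS", "THR")


def _local_frame(direction: str) -> np.ndarray:
    ex = np.array([1.0, 0.0, 0.0])
    ey = {"y+": [0.0, 1.0, 0.0], "y-": [0.0, -1.0, 0.0], "z+": [0.0, 0.0, 1.0]}[direction]
    ey = np.asarray(ey)
    ez = np.cross(ex, ey)
    return np.stack([ex, ey, ez])


def make_toy_complex(
    n_alpha: int,
    n_beta: int,
    n_pep: int,
    with_waters: int = 0,
    seed: int = 0,
    sequences: Mapping[str, Mapping[int, str]] | None = None,
    param_table=None,
) -> MolecularSystem:
    """Build a deterministic toy receptor/peptide complex.

    Parameters
    ----------
    n_alpha, n_beta, n_pep
        Residue counts of chains A, B and P.
    with_waters
        Number of explicit water residues (chain class W), parked on a grid
        well away from the complex.
    seed
        Accepted for API symmetry; the geometry is fully deterministic.
    sequences
        Optional per-chain residue-name overrides, e.g.
        ``{"B": {26: "PHE"}, "P": {3: "PHE"}}``; unspecified positions cycle
        through a fixed mix of residue types.
    """
    if min(n_alpha, n_beta, n_pep) < 1:
        raise ConfigurationError("chain residue counts must be >= 1")
    table = param_table if isinstance(param_table, Mapping) else load_parameter_table(param_table)
    sequences = sequences or {}
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    pep_offset = _RESIDUE_SPACING * max(0, (min(n_alpha, n_beta) - n_pep) // 2)
    for chain, n_res in (("A", n_alpha), ("B", n_beta), ("P", n_pep)):
        y0, direction = _CHAIN_LAYOUT[chain]
        frame = _local_frame(direction)
        overrides = {int(k): v for k, v in sequences.get(chain, {}).items()}
        x0 = pep_offset if chain == "P" else 0.0
        for resid in range(1, n_res + 1):
            resname = overrides.get(resid, _DEFAULT_CYCLE[(resid - 1) % len(_DEFAULT_CYCLE)])
            ca = np.array([x0 + _RESIDUE_SPACING * (resid - 1), y0, 0.0])
            placed = {"CA": (0.0, 0.0, 0.0)} | _BACKBONE | _side_chain(resname)
            if resname == "PRO":
                placed.pop("H", None)
            for name, local in placed.items():
                pos = ca + np.asarray(local) @ frame
                _append_atom(atoms, coords, name, resid, resname, chain, pos, table)
    side = max(1, int(np.ceil(np.sqrt(max(with_waters, 1)))))
    for w in range(with_waters):
        ix, iy = divmod(w, side)
        o = np.array([4.0 * ix, 4.0 * iy, _WATER_Z])
        for name, off in (("O", (0, 0, 0)), ("H1", (0.76, 0.59, 0)), ("H2", (-0.76, 0.59, 0))):
            _append_atom(atoms, coords, name, w + 1, "HOH", "W", o + np.asarray(off), table)
    return MolecularSystem(atoms, np.asarray(coords))


def _append_atom(atoms, coords, name, resid, resname, chain, pos, table):
    try:
        element, charge, eps, rmin_half, radius, mass = table[(resname, name)]
    except KeyError:
        raise ConfigurationError(
            f"toy builder produced unparameterized atom {resname}.{name}"
        ) from None
    atoms.append(
        AtomRecord(
            atom_name=name, element=element, residue_index=resid, residue_name=resname,
            chain_id=chain, mass=mass, partial_charge=charge, lj_epsilon=eps,
            lj_rmin_half=rmin_half, born_radius_seed=radius,
        )
    )
    coords.append(pos)


# ---------------------------------------------------------------------------
# trajectory sampling
# ---------------------------------------------------------------------------


@dataclass
class FluctuationSpec:
    """How the toy trajectory fluctuates about the reference structure."""

    mode: str = "isotropic_gaussian"
    amplitude: float = 0.0  # A, isotropic std (also jitter in two_state mode)
    covariance: np.ndarray | None = None  # 3N x 3N, A^2
    state_means: tuple[float, float] | None = None  # target widths, A
    state_occupancy: float | None = None  # fraction of frames in state 1
    state_compartment: str = "D1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ConfigurationError("amplitude must be >= 0")
        if self.state_occupancy is not None and not 0 <= self.state_occupancy <= 1:
            raise ConfigurationError("state_occupancy must lie in [0, 1]")


def sample_trajectory(
    system: MolecularSystem,
    spec: FluctuationSpec,
    n_frames: int,
    frame_interval: float = 20.0,
) -> TrajectorySeries:
    """Draw frames about the reference according to the fluctuation spec."""
    if n_frames < 1:
        raise ConfigurationError("n_frames must be >= 1")
    rng = np.random.default_rng(spec.seed)
    base = system.reference_coords
    n = system.n_atoms
    if spec.mode == "isotropic_gaussian":
        frames = base[None] + rng.normal(0.0, spec.amplitude, size=(n_frames, n, 3))
    elif spec.mode == "full_covariance":
        cov = np.asarray(spec.covariance, dtype=float)
        if cov.shape != (3 * n, 3 * n):
            raise ConfigurationError(f"covariance must be {(3 * n, 3 * n)}, got {cov.shape}")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise NumericError("covariance matrix is not symmetric")
        # eigendecomposition sampling tolerates PSD-with-zero-modes input
        evals, evecs = np.linalg.eigh(cov)
        if evals.min() < -1e-8 * max(evals.max(), 1.0):
            raise NumericError(f"covariance is not PSD (min eigenvalue {evals.min():.3g})")
        root = evecs * np.sqrt(np.clip(evals, 0.0, None))
        disp = rng.standard_normal(size=(n_frames, 3 * n)) @ root.T
        frames = base[None] + disp.reshape(n_frames, n, 3)
    elif spec.mode == "two_state":
        if spec.state_means is None or spec.state_occupancy is None:
            raise ConfigurationError("two_state mode needs state_means and state_occupancy")
        frames = base[None] + rng.normal(0.0, spec.amplitude, size=(n_frames, n, 3))
        comp = compartment_selections(system).get(spec.state_compartment)
        idx_a = system.select_atoms(comp.alpha_selection.members, heavy_only=True)
        idx_b = system.select_atoms(comp.beta_selection.members, heavy_only=True)
        wall = system.select_atoms(comp.beta_selection.members)  # move all wall atoms
        com_a = np.average(base[idx_a], axis=0, weights=system.masses[idx_a])
        com_b = np.average(base[idx_b], axis=0, weights=system.masses[idx_b])
        d0 = float(np.linalg.norm(com_b - com_a))
        unit = (com_b - com_a) / d0
        n_state1 = int(round(spec.state_occupancy * n_frames))
        state1 = np.zeros(n_frames, dtype=bool)
        state1[rng.choice(n_frames, size=n_state1, replace=False)] = True
        widths = np.where(state1, spec.state_means[0], spec.state_means[1])
        frames[:, wall, :] += (widths - d0)[:, None, None] * unit[None, None, :]
    else:
        raise ConfigurationError(f"unknown fluctuation mode '{spec.mode}'")
    return TrajectorySeries(system=system, frames=frames, frame_interval=frame_interval)


# ---------------------------------------------------------------------------
# interaction planting
# ---------------------------------------------------------------------------


@dataclass
class PlantedInteraction:
    """A ground-truth interaction realised in an exact fraction of frames.

    ``partners`` is (fixed residue, moved residue); the second residue is
    rigidly repositioned each frame so the corresponding detector criterion
    is satisfied with margin in exactly ``round(target_fraction * T)`` frames
    and violated with margin in the rest.  ``geometry`` tunes distances and,
    for hydrophobic plants, an optional ``water_fraction`` of satisfying
    frames in which a water oxygen vetoes the contact.
    """

    kind: str
    partners: tuple[tuple[str, int], tuple[str, int]]
    target_fraction: float
    geometry: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("hbond", "stacking", "hydrophobic"):
            raise ConfigurationError(f"unknown planted interaction kind '{self.kind}'")
        if not 0 <= self.target_fraction <= 1:
            raise ConfigurationError("target_fraction must lie in [0, 1]")

    def n_on(self, n_frames: int) -> int:
        return int(round(self.target_fraction * n_frames))

    def expected_persistence(self, n_frames: int) -> float:
        """Persistence the detector will report, accounting for water vetoes."""
        n_on = self.n_on(n_frames)
        n_veto = int(round(float(self.geometry.get("water_fraction", 0.0)) * n_on))
        return (n_on - n_veto) / n_frames


def _resname_of(system: MolecularSystem, chain: str, resid: int) -> str:
    return str(system.resnames[system.residue_atoms(chain, resid)[0]])


def _atom_of(system: MolecularSystem, chain: str, resid: int, name: str) -> int:
    idx = system.residue_atoms(chain, resid)
    hits = idx[system.names[idx] == name]
    if hits.size == 0:
        raise ConfigurationError(f"residue {chain}:{resid} lacks required atom '{name}'")
    return int(hits[0])


def plant_interaction(traj: TrajectorySeries, plant: PlantedInteraction) -> TrajectorySeries:
    """Return a copy of the trajectory with the interaction planted."""
    system = traj.system
    (chain_a, res_a), (chain_b, res_b) = plant.partners
    idx_b = system.residue_atoms(chain_b, res_b)
    frames = traj.frames.copy()
    n_frames = frames.shape[0]
    rng = np.random.default_rng(plant.seed)
    on = np.zeros(n_frames, dtype=bool)
    on[rng.choice(n_frames, size=plant.n_on(n_frames), replace=False)] = True

    ref_b = system.reference_coords[idx_b]
    if plant.kind == "hbond":
        d_on = float(plant.geometry.get("distance", 2.8))
        from scipy.spatial.transform import Rotation

        i_n = _atom_of(system, chain_a, res_a, "N")
        i_h = _atom_of(system, chain_a, res_a, "H")
        i_o = _atom_of(system, chain_b, res_b, "O")
        i_ca_b = _atom_of(system, chain_b, res_b, "CA")
        for t in range(n_frames):
            if on[t]:
                nh = frames[t, i_h] - frames[t, i_n]
                u = nh / np.linalg.norm(nh)
                target = frames[t, i_n] + d_on * u
                # orient the moved residue so its body points away from the
                # fixed chain (O -> CA along u), then pin O on the N-H axis
                body = frames[t, i_ca_b] - frames[t, i_o]
                rot, _ = Rotation.align_vectors([u], [body / np.linalg.norm(body)])
                frames[t, idx_b] = rot.apply(frames[t, idx_b] - frames[t, i_o]) + target
            else:
                frames[t, idx_b] = ref_b
    elif plant.kind == "stacking":
        from scipy.spatial.transform import Rotation

        d_on = float(plant.geometry.get("distance", 4.0))
        from .interaction_networks import ring_indices

        for chain, resid in plant.partners:
            if _resname_of(system, chain, resid) not in RING_ATOMS:
                raise ConfigurationError(
                    f"stacking plant partner {chain}:{resid} has no planar side chain"
                )
        ring_a = ring_indices(system, chain_a, res_a)
        ring_b = ring_indices(system, chain_b, res_b)
        for t in range(n_frames):
            if on[t]:
                cent_a = frames[t, ring_a].mean(axis=0)
                norm_a = _normal(frames[t, ring_a])
                cent_b = frames[t, ring_b].mean(axis=0)
                norm_b = _normal(frames[t, ring_b])
                rot, _ = Rotation.align_vectors([norm_a], [norm_b])
                frames[t, idx_b] = (
                    rot.apply(frames[t, idx_b] - cent_b) + cent_a + d_on * norm_a
                )
            else:
                frames[t, idx_b] = ref_b
    elif plant.kind == "hydrophobic":
        d_on = float(plant.geometry.get("distance", 3.5))
        water_frac = float(plant.geometry.get("water_fraction", 0.0))
        water_dist = float(plant.geometry.get("water_distance", 3.0))
        for chain, resid in plant.partners:
            if _resname_of(system, chain, resid) not in HYDROPHOBIC_RESIDUES:
                raise ConfigurationError(
                    f"hydrophobic plant partner {chain}:{resid} is not hydrophobic-class"
                )
        i_ca = _atom_of(system, chain_a, res_a, "CA")
        i_cba = _atom_of(system, chain_a, res_a, "CB")
        i_cbb = _atom_of(system, chain_b, res_b, "CB")
        veto_frames = np.zeros(n_frames, dtype=bool)
        if water_frac > 0:
            waters = system.water_oxygen_indices()
            if waters.size == 0:
                raise ConfigurationError("water veto requested but system has no waters")
            on_idx = np.flatnonzero(on)
            chosen = rng.choice(on_idx, size=int(round(water_frac * on_idx.size)), replace=False)
            veto_frames[chosen] = True
            i_wo = int(waters[0])
            water_res = system.residue_atoms(system.chains[i_wo], int(system.resids[i_wo]))
            water_ref = system.reference_coords[water_res]
        for t in range(n_frames):
            if on[t]:
                v = frames[t, i_cba] - frames[t, i_ca]
                v /= np.linalg.norm(v)
                target = frames[t, i_cba] + d_on * v
                frames[t, idx_b] += target - frames[t, i_cbb]
                if veto_frames[t]:
                    w = np.cross(v, [1.0, 0.0, 0.0])
                    if np.linalg.norm(w) < 1e-8:
                        w = np.cross(v, [0.0, 1.0, 0.0])
                    w /= np.linalg.norm(w)
                    w_target = frames[t, i_cba] + water_dist * w
                    frames[t, water_res] = water_ref + (w_target - frames[t, i_wo])
            else:
                frames[t, idx_b] = ref_b
    return TrajectorySeries(system=system, frames=frames, frame_interval=traj.frame_interval)


def _normal(ring: np.ndarray) -> np.ndarray:
    centered = ring - ring.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[-1]


def write_truth_file(
    path: str | Path,
    plants: Sequence[PlantedInteraction],
    n_frames: int,
    spec: FluctuationSpec | None = None,
) -> None:
    """Emit a JSON file describing the planted ground truth."""
    payload = {
        "n_frames": n_frames,
        "plants": [
            {
                "kind": p.kind,
                "partners": [list(p.partners[0]), list(p.partners[1])],
                "target_fraction": p.target_fraction,
                "expected_persistence": p.expected_persistence(n_frames),
                "geometry": {k: float(v) for k, v in p.geometry.items()},
            }
            for p in plants
        ],
    }
    if spec is not None:
        payload["fluctuation"] = {
            "mode": spec.mode,
            "amplitude": spec.amplitude,
            "state_means": list(spec.state_means) if spec.state_means else None,
            "state_occupancy": spec.state_occupancy,
            "seed": spec.seed,
        }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
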