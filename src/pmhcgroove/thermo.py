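"""Configurational entropy and end-point binding free energies.

Quasi-harmonic entropy: frames are superposed on their mean structure over
the selection's C-alpha atoms, the 3n x 3n mass-weighted covariance of the
Cartesian fluctuations is diagonalized, each eigenvalue lambda_i is mapped to
a quantum harmonic oscillator of frequency omega_i = sqrt(kB T / lambda_i),
and the entropy is

    S = kB * sum_i [ x_i / (exp(x_i) - 1) - ln(1 - exp(-x_i)) ],
    x_i = hbar * omega_i / (kB T).

Solvated interaction energy (SIE): an end-point score over trajectory frames,

    dG = alpha * (E_coul + dG_RF + E_vdw + gamma * dMSA) + C,

with intermolecular Coulomb screened by the interior dielectric,
intermolecular Lennard-Jones, a generalized-Born continuum estimate of the
reaction-field change upon binding, and the buried surface area.  The default
coefficients are the published AMBER-trained SIE set (alpha = 0.1048,
D_in = 2.25, gamma = 0.0129 kcal/(mol A^2), C = -2.89 kcal/mol).
Binding affinity follows from dG ~ kB T ln(IC50) with IC50 in mol/L.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import COULOMB_K, DEFAULT_TEMPERATURE, HBAR, KB, PROBE_RADIUS, SOLVENT_DIELECTRIC
from .errors import ConfigurationError, GeometryError, NumericError
from .system import AtomRecord, MolecularSystem, ResidueSelection, TrajectorySeries

#: eigenvalues below this (amu A^2) are rigid-body/rank-deficiency artifacts
EIGENVALUE_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# quasi-harmonic entropy
# ---------------------------------------------------------------------------


@dataclass
class EntropyResult:
    TS: float  # kcal/mol
    temperature: float
    eigenvalues: np.ndarray  # mass-weighted spectrum, amu A^2
    n_frames_used: int


def harmonic_entropy_from_eigenvalues(
    eigenvalues: np.ndarray, temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """T*S (kcal/mol) of independent quantum harmonic oscillators whose
    mass-weighted covariance eigenvalues (amu A^2) are given.

    This closed form doubles as the analytic oracle for Gaussian data."""
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > EIGENVALUE_FLOOR]
    if lam.size == 0:
        return 0.0
    kT = KB * temperature
    x = HBAR / np.sqrt(kT * lam)  # = hbar * omega / kB T
    with np.errstate(over="ignore"):
        s_over_kb = x / np.expm1(x) - np.log1p(-np.exp(-x))
    return float(kT * np.sum(s_over_kb))


def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Proper-rotation least-squares fit of mobile onto ref (both centered)."""
    h = mobile.T @ ref
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


def quasiharmonic_entropy(
    traj: TrajectorySeries,
    selection: ResidueSelection,
    temperature: float = DEFAULT_TEMPERATURE,
    atoms: Sequence[str] = ("CA",),
    n_align_iterations: int = 3,
) -> EntropyResult:
    """Quasi-harmonic configurational entropy of the selection's C-alpha
    fluctuations over the whole frame ensemble."""
    system = traj.system
    idx = system.select_atoms(selection.members, atom_names=atoms)
    if idx.size == 0:
        raise ConfigurationError(f"selection '{selection.label}' has no {atoms} atoms")
    if traj.n_frames < 2:
        raise ConfigurationError("entropy needs at least 2 frames")
    coords = traj.frames[:, idx, :].copy()
    masses = system.masses[idx]
    # iterative superposition on the (mass-uniform C-alpha) mean structure
    mean = coords[0]
    for _ in range(n_align_iterations):
        mean_c = mean - mean.mean(axis=0)
        for t in range(coords.shape[0]):
            x = coords[t] - coords[t].mean(axis=0)
            coords[t] = x @ _kabsch(x, mean_c)
        mean = coords.mean(axis=0)
    fluct = (coords - mean).reshape(coords.shape[0], -1)
    cov = fluct.T @ fluct / coords.shape[0]
    w = np.sqrt(np.repeat(masses, 3))
    cov_mw = cov * np.outer(w, w)
    eigenvalues = np.linalg.eigvalsh(cov_mw)
    eigenvalues = np.clip(eigenvalues, 0.0, None)
    ts = harmonic_entropy_from_eigenvalues(eigenvalues, temperature)
    return EntropyResult(
        TS=ts, temperature=temperature, eigenvalues=eigenvalues,
        n_frames_used=traj.n_frames,
    )


# ---------------------------------------------------------------------------
# SIE
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SIEParams:
    """Coefficients of the scaled SIE functional."""

    alpha: float = 0.1048
    d_in: float = 2.25
    gamma: float = 0.0129  # kcal/(mol A^2)
    constant: float = -2.89  # kcal/mol
    temperature: float = DEFAULT_TEMPERATURE
    d_out: float = SOLVENT_DIELECTRIC
    sasa_points: int = 300  # sphere sampling density for the area term

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ConfigurationError("alpha must be positive")
        if self.d_in < 1:
            raise ConfigurationError("interior dielectric must be >= 1")


@dataclass
class EnergyBreakdown:
    e_coulomb: float
    dg_reaction_field: float
    e_vdw: float
    surface_term: float
    total: float


@dataclass
class BindingResult:
    dg_mean: float
    dg_sd: float
    per_frame: list[EnergyBreakdown]
    ic50_nM: float
    stride_ps: float


def _sasa(coords: np.ndarray, radii: np.ndarray, n_points: int) -> float:
    """Total solvent-accessible surface area (Shrake-Rupley via biotite)."""
    import biotite.structure as struc

    arr = struc.AtomArray(coords.shape[0])
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.element = np.array(["C"] * coords.shape[0])  # radii supplied explicitly
    areas = struc.sasa(
        arr, probe_radius=PROBE_RADIUS, vdw_radii=np.asarray(radii, dtype=float),
        point_number=n_points,
    )
    return float(np.nansum(areas))


def sie_components(
    frame: np.ndarray,
    system: MolecularSystem,
    receptor: ResidueSelection,
    ligand: ResidueSelection,
    params: SIEParams = SIEParams(),
    frame_index: int | None = None,
) -> EnergyBreakdown:
    """SIE energy components for one frame.

    Coulomb and Lennard-Jones run over all receptor-ligand atom pairs; the
    reaction-field change uses a generalized-Born cross term with fixed Born
    radii; the cavity term is gamma times the interface-buried area of the
    heavy atoms.
    """
    idx_r = system.select_atoms(receptor.members)
    idx_l = system.select_atoms(ligand.members)
    if idx_r.size == 0 or idx_l.size == 0:
        raise ConfigurationError("receptor/ligand selections must be non-empty")
    if np.intersect1d(idx_r, idx_l).size:
        raise ConfigurationError("receptor and ligand selections overlap")
    frame = np.asarray(frame, dtype=float)
    xr, xl = frame[idx_r], frame[idx_l]
    diff = xr[:, None, :] - xl[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    if (r < 0.5).any():
        warnings.warn(
            f"atomic clash (< 0.5 A) between receptor and ligand"
            + (f" in frame {frame_index}" if frame_index is not None else ""),
            RuntimeWarning,
            stacklevel=2,
        )
    qq = np.outer(system.charges[idx_r], system.charges[idx_l])
    with np.errstate(divide="ignore"):
        e_coul = float(COULOMB_K / params.d_in * np.sum(qq / r))
    eps = np.sqrt(np.outer(system.lj_epsilon[idx_r], system.lj_epsilon[idx_l]))
    rmin = system.lj_rmin_half[idx_r][:, None] + system.lj_rmin_half[idx_l][None, :]
    with np.errstate(divide="ignore"):
        sr6 = (rmin / r) ** 6
    e_vdw = float(np.sum(eps * (sr6 ** 2 - 2.0 * sr6)))
    # generalized-Born cross term: change in reaction-field energy on binding
    rb = np.outer(system.radii[idx_r], system.radii[idx_l])
    f_gb = np.sqrt(r ** 2 + rb * np.exp(-(r ** 2) / (4.0 * rb)))
    dg_rf = float(-COULOMB_K * (1.0 / params.d_in - 1.0 / params.d_out) * np.sum(qq / f_gb))
    # buried interface area (negative upon burial)
    heavy_r = idx_r[system.heavy[idx_r]]
    heavy_l = idx_l[system.heavy[idx_l]]
    if params.gamma != 0.0:
        heavy_rl = np.concatenate([heavy_r, heavy_l])
        area_c = _sasa(frame[heavy_rl], system.radii[heavy_rl], params.sasa_points)
        area_r = _sasa(frame[heavy_r], system.radii[heavy_r], params.sasa_points)
        area_l = _sasa(frame[heavy_l], system.radii[heavy_l], params.sasa_points)
        surface = params.gamma * (area_c - area_r - area_l)
    else:
        surface = 0.0
    total = params.alpha * (e_coul + dg_rf + e_vdw + surface) + params.constant
    return EnergyBreakdown(e_coul, dg_rf, e_vdw, surface, total)


def sie_trajectory(
    traj: TrajectorySeries,
    receptor: ResidueSelection,
    ligand: ResidueSelection,
    params: SIEParams = SIEParams(),
    stride_ps: float = 20.0,
) -> BindingResult:
    """SIE score averaged over frames taken at the given stride (ps)."""
    if stride_ps < traj.frame_interval:
        raise ConfigurationError(
            f"stride_ps ({stride_ps}) must be >= frame_interval ({traj.frame_interval})"
        )
    step = int(round(stride_ps / traj.frame_interval))
    frames = range(0, traj.n_frames, step)
    per_frame = [
        sie_components(traj.frames[t], traj.system, receptor, ligand, params, frame_index=t)
        for t in frames
    ]
    if not per_frame:
        raise ConfigurationError("stride yields zero evaluated frames")
    totals = np.array([b.total for b in per_frame])
    dg_mean = float(totals.mean())
    dg_sd = float(totals.std(ddof=1)) if totals.size > 1 else 0.0
    return BindingResult(
        dg_mean=dg_mean, dg_sd=dg_sd, per_frame=per_frame,
        ic50_nM=ic50_from_dg(dg_mean, params.temperature), stride_ps=stride_ps,
    )


# ---------------------------------------------------------------------------
# alanine scanning
# ---------------------------------------------------------------------------

#: side-chain atoms retained by the truncation (everything else beyond CB goes)
_ALA_KEEP = frozenset({"N", "H", "CA", "C", "O", "OXT", "CB"})


def _truncate_to_alanine(
    system: MolecularSystem, frames: np.ndarray, chain: str, resid: int, table
) -> tuple[MolecularSystem, np.ndarray]:
    idx = system.residue_atoms(chain, resid)
    resname = str(system.resnames[idx[0]])
    if resname == "GLY":
        raise ConfigurationError(f"cannot alanine-scan {chain}:{resid}: glycine has no CB")
    drop = {int(i) for i in idx if system.names[i] not in _ALA_KEEP}
    keep = np.array([i for i in range(system.n_atoms) if i not in drop], dtype=int)
    atoms = []
    for i in keep:
        a = system.atoms[i]
        if i in set(idx):
            key = (a.atom_name if ("ALA", a.atom_name) in table else None)
            if key is None:
                raise ConfigurationError(
                    f"no alanine parameters for atom {a.atom_name} at {chain}:{resid}"
                )
            element, charge, eps, rmin_half, radius, mass = table[("ALA", a.atom_name)]
            a = AtomRecord(
                a.atom_name, element, a.residue_index, "ALA", a.chain_id,
                mass, charge, eps, rmin_half, radius,
            )
        atoms.append(a)
    mutant = MolecularSystem(atoms, system.reference_coords[keep])
    return mutant, frames[:, keep, :]


def alanine_scan(
    traj: TrajectorySeries,
    positions: Sequence[tuple[str, int]],
    receptor: ResidueSelection,
    ligand: ResidueSelection,
    params: SIEParams = SIEParams(),
    stride_ps: float = 20.0,
    param_table=None,
) -> pd.DataFrame:
    """Single-trajectory virtual alanine scan.

    Each position is truncated to alanine independently (side-chain atoms
    beyond CB deleted, CB re-typed to alanine) on the *same* frames, the SIE
    score recomputed, and ddG = dG_mut - dG_wt reported.
    """
    from .structure_io import load_parameter_table

    table = param_table if isinstance(param_table, dict) else load_parameter_table(param_table)
    wt = sie_trajectory(traj, receptor, ligand, params, stride_ps)
    rows = []
    for chain, resid in positions:
        idx = traj.system.residue_atoms(chain, resid)
        resname = str(traj.system.resnames[idx[0]])
        if resname == "ALA":
            warnings.warn(
                f"position {chain}:{resid} is already alanine; ddG = 0", stacklevel=2
            )
            rows.append({"chain": chain, "residue_index": resid, "resname_wt": resname,
                         "dg_wt": wt.dg_mean, "dg_mut": wt.dg_mean, "ddg": 0.0})
            continue
        mutant, mut_frames = _truncate_to_alanine(traj.system, traj.frames, chain, resid, table)
        mut_traj = TrajectorySeries(mutant, mut_frames, traj.frame_interval)
        mut = sie_trajectory(mut_traj, receptor, ligand, params, stride_ps)
        rows.append({"chain": chain, "residue_index": resid, "resname_wt": resname,
                     "dg_wt": wt.dg_mean, "dg_mut": mut.dg_mean,
                     "ddg": mut.dg_mean - wt.dg_mean})
    return pd.DataFrame(rows, columns=["chain", "residue_index", "resname_wt",
                                       "dg_wt", "dg_mut", "ddg"])


# ---------------------------------------------------------------------------
# IC50 conversion and classification
# ---------------------------------------------------------------------------


def ic50_from_dg(dg: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """IC50 (nM) from a binding free energy via dG ~ kB T ln(IC50 [mol/L])."""
    if temperature <= 0:
        raise NumericError("temperature must be positive")
    with np.errstate(over="ignore"):
        return float(np.exp(dg / (KB * temperature)) * 1e9)


def dg_from_ic50(ic50_nM: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Inverse of :func:`ic50_from_dg`."""
    if ic50_nM <= 0:
        raise NumericError("IC50 must be positive")
    return float(KB * temperature * np.log(ic50_nM * 1e-9))


def ic50_ratio(values: Sequence[float], labels: Sequence[str], reference_label: str) -> pd.Series:
    """Each IC50 divided by the IC50 of the reference label."""
    s = pd.Series(np.asarray(values, dtype=float), index=list(labels))
    if (s <= 0).any():
        raise NumericError("IC50 values must be positive for ratio computation")
    if reference_label not in s.index:
        raise ConfigurationError(f"reference label '{reference_label}' not present")
    return s / s[reference_label]


def classify_binder(ic50_nM: float, threshold_nM: float = 1000.0) -> str:
    """Binder iff IC50 <= 1000 nM (boundary inclusive)."""
    if ic50_nM <= 0:
        raise NumericError("IC50 must be positive")
    return "binder" if ic50_nM <= threshold_nM else "non-binder"
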