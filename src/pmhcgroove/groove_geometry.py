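"""Superposition-based RMSD statistics and groove-width dissection.

RMSD is computed on C-alpha atoms of a residue selection after least-squares
rigid superposition (Kabsch, proper rotation only) onto a fixed reference —
by default the first frame of the trajectory.  Groove width per compartment
is the Euclidean distance between the mass-weighted centers of the heavy
atoms of the alpha-side and beta-side residue selections, an internal
coordinate invariant to rigid motion of the whole frame.

Distributions are normalized histograms; mode locations come from a Gaussian
kernel density (bandwidth = 2x bin width) whose local maxima are filtered by
a minimum prominence of 5% of the peak mass.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial.transform import Rotation
from scipy.stats import gaussian_kde

from .errors import ConfigurationError, GeometryError
from .system import CompartmentMap, MolecularSystem, ResidueSelection, TrajectorySeries


@dataclass
class ScalarSeries:
    """A per-frame scalar observable (A) with frame timing metadata."""

    values: np.ndarray
    frame_interval: float
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(self.values.size) * self.frame_interval


@dataclass
class DistributionSummary:
    """Normalized histogram plus smoothed mode list for a scalar series."""

    bin_edges: np.ndarray
    probability: np.ndarray
    modes: list[tuple[float, float]] = field(default_factory=list)
    bandwidth: float = 0.0


def _ca_indices(system: MolecularSystem, selection: ResidueSelection,
                atoms: Sequence[str]) -> np.ndarray:
    idx = system.select_atoms(selection.members, atom_names=atoms)
    if idx.size < 3:
        raise GeometryError(
            f"selection '{selection.label}' maps to {idx.size} fit atoms; need >= 3"
        )
    return idx


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    system: MolecularSystem,
    selection: ResidueSelection,
    atoms: Sequence[str] = ("CA",),
) -> tuple[np.ndarray, float]:
    """Optimal rigid superposition of a mobile frame onto a reference.

    The rotation/translation is fitted on the selection's C-alpha atoms
    (configurable via ``atoms``; pass ("N", "CA", "C", "O") for a full
    backbone fit) and applied to the whole frame.  Returns the transformed
    frame and the post-fit RMSD over the fit atoms.
    """
    idx = _ca_indices(system, selection, atoms)
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    mob_sel, ref_sel = mob[idx], ref[idx]
    mob_c, ref_c = mob_sel.mean(axis=0), ref_sel.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_sel - ref_c, mob_sel - mob_c)
    transformed = rot.apply(mob - mob_c) + ref_c
    rmsd = float(np.sqrt(np.mean(np.sum((transformed[idx] - ref_sel) ** 2, axis=1))))
    return transformed, rmsd


def rmsd_series(
    traj: TrajectorySeries,
    selection: ResidueSelection,
    reference: np.ndarray | None = None,
    atoms: Sequence[str] = ("CA",),
    label: str = "rmsd",
) -> ScalarSeries:
    """Per-frame post-superposition RMSD versus a fixed reference frame
    (default: the first frame of the trajectory)."""
    ref = traj.frames[0] if reference is None else np.asarray(reference, dtype=float)
    values = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        _, values[t] = superpose(traj.frames[t], ref, traj.system, selection, atoms)
    return ScalarSeries(values, traj.frame_interval, label)


def distribution(
    series: ScalarSeries | np.ndarray,
    bin_width: float,
    min_prominence: float = 0.05,
) -> DistributionSummary:
    """Normalized histogram and KDE-smoothed modes of a scalar series."""
    values = series.values if isinstance(series, ScalarSeries) else np.asarray(series, float)
    if values.size == 0:
        raise ConfigurationError("cannot build a distribution from an empty series")
    if bin_width <= 0:
        raise ConfigurationError("bin_width must be positive")
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    prob = counts / counts.sum()
    bandwidth = 2.0 * bin_width
    std = values.std()
    if std < 1e-12:
        modes = [(float(values[0]), 1.0)]
        return DistributionSummary(edges, prob, modes, bandwidth)
    kde = gaussian_kde(values, bw_method=bandwidth / std)
    grid = np.linspace(values.min(), values.max(), max(512, edges.size * 16))
    density = kde(grid)
    peaks, _ = find_peaks(density, prominence=min_prominence * density.max())
    # interior maxima plus possible boundary maxima
    locations = list(grid[peaks])
    if density[0] > density[1]:
        locations.insert(0, grid[0])
    if density[-1] > density[-2]:
        locations.append(grid[-1])
    if not locations:
        locations = [float(grid[np.argmax(density)])]
    locations = sorted(locations)
    # mass per mode: split samples at KDE minima between adjacent modes
    boundaries = []
    for left, right in zip(locations[:-1], locations[1:]):
        seg = (grid >= left) & (grid <= right)
        boundaries.append(float(grid[seg][np.argmin(density[seg])]))
    cuts = [-np.inf] + boundaries + [np.inf]
    modes = []
    for loc, lo_c, hi_c in zip(locations, cuts[:-1], cuts[1:]):
        mass = float(np.mean((values > lo_c) & (values <= hi_c)))
        modes.append((float(loc), mass))
    return DistributionSummary(edges, prob, modes, bandwidth)


def compartment_distance_series(
    traj: TrajectorySeries,
    cmap: CompartmentMap,
) -> list[ScalarSeries]:
    """Per-compartment cross-groove width: distance between mass-weighted
    heavy-atom centers of the alpha and beta walls, per frame."""
    system = traj.system
    out = []
    for comp in cmap:
        idx_a = system.select_atoms(comp.alpha_selection.members, heavy_only=True)
        idx_b = system.select_atoms(comp.beta_selection.members, heavy_only=True)
        if idx_a.size == 0 or idx_b.size == 0:
            raise GeometryError(
                f"compartment {comp.name}: a wall has no heavy atoms "
                f"(alpha {idx_a.size}, beta {idx_b.size})"
            )
        w_a = system.masses[idx_a]
        w_b = system.masses[idx_b]
        com_a = (traj.frames[:, idx_a, :] * w_a[None, :, None]).sum(axis=1) / w_a.sum()
        com_b = (traj.frames[:, idx_b, :] * w_b[None, :, None]).sum(axis=1) / w_b.sum()
        values = np.linalg.norm(com_a - com_b, axis=1)
        out.append(ScalarSeries(values, traj.frame_interval, comp.name))
    return out
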