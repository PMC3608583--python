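"""Detector correctness: planted geometries, the 20% persistence filter,
monotonicity in the cutoffs, and full agreement with an independent
brute-force re-implementation."""
import math

import numpy as np
import pytest

import pmhcgroove as pg
from pmhcgroove.errors import InternalError
from pmhcgroove.interaction_networks import (
    BACKBONE_ATOMS,
    HYDROPHOBIC_RESIDUES,
    RING_ATOMS,
)
from pmhcgroove.system import AtomRecord, MolecularSystem, ResidueSelection, TrajectorySeries


def _make(atoms, coords, n_frames=1):
    system = MolecularSystem(atoms, coords)
    frames = np.broadcast_to(system.reference_coords, (n_frames, system.n_atoms, 3)).copy()
    return system, TrajectorySeries(system, frames, 20.0)


def _nho(d_no=2.8, angle_deg=180.0):
    """N-H donor on chain B residue 1 and an acceptor O on chain P residue 1,
    with the requested N...O distance and N-H...O angle."""
    n = np.array([0.0, 0.0, 0.0])
    h = np.array([1.0, 0.0, 0.0])
    theta = math.radians(180.0 - angle_deg)
    o = h + (d_no - 1.0) * np.array([math.cos(theta), math.sin(theta), 0.0])
    atoms = [
        AtomRecord("N", "N", 1, "ALA", "B", 14.007),
        AtomRecord("H", "H", 1, "ALA", "B", 1.008),
        AtomRecord("O", "O", 1, "ALA", "P", 15.999),
    ]
    return _make(atoms, [n, h, o], n_frames=3)


SEL_B = ResidueSelection("b", (("B", 1),))
SEL_P = ResidueSelection("p", (("P", 1),))


def test_hbond_linear_geometry_always_present():
    _, traj = _nho(2.8, 180.0)
    records = pg.detect_hbonds(traj, SEL_B, SEL_P)
    assert len(records) == 1 and records[0].persistence == 1.0


def test_hbond_distance_and_angle_cutoffs():
    _, far = _nho(3.5, 180.0)
    assert pg.detect_hbonds(far, SEL_B, SEL_P) == []
    _, bent = _nho(2.8, 100.0)
    assert pg.detect_hbonds(bent, SEL_B, SEL_P) == []
    # exactly at the angle cutoff counts (>= convention)
    _, edge = _nho(2.8, 130.0)
    assert len(pg.detect_hbonds(edge, SEL_B, SEL_P)) == 1


def _two_rings(angle_deg=0.0, centroid_dist=4.0):
    """Two PHE rings: one in the xy-plane at origin, the other rotated about
    x by angle_deg with centroid displaced along z."""
    ring_local = np.array(
        [[math.cos(math.radians(a)), math.sin(math.radians(a)), 0.0]
         for a in range(0, 360, 60)]
    ) * 1.39
    rot = np.array([
        [1, 0, 0],
        [0, math.cos(math.radians(angle_deg)), -math.sin(math.radians(angle_deg))],
        [0, math.sin(math.radians(angle_deg)), math.cos(math.radians(angle_deg))],
    ])
    ring_b = ring_local @ rot.T + np.array([0.0, 0.0, centroid_dist])
    names = RING_ATOMS["PHE"]
    atoms = [AtomRecord(n, "C", 1, "PHE", "B", 12.011) for n in names]
    atoms += [AtomRecord(n, "C", 1, "PHE", "P", 12.011) for n in names]
    return _make(atoms, np.vstack([ring_local, ring_b]), n_frames=2)


def test_stacking_parallel_and_perpendicular():
    _, coplanar = _two_rings(0.0, 4.0)
    records = pg.detect_stacking(coplanar, SEL_B, SEL_P)
    assert len(records) == 1 and records[0].persistence == 1.0
    _, perp = _two_rings(90.0, 4.0)
    assert pg.detect_stacking(perp, SEL_B, SEL_P) == []
    _, far = _two_rings(0.0, 6.0)
    assert pg.detect_stacking(far, SEL_B, SEL_P) == []


def test_stacking_missing_ring_atoms_is_an_error():
    names = RING_ATOMS["PHE"][:-1]  # drop CZ
    atoms = [AtomRecord(n, "C", 1, "PHE", "B", 12.011) for n in names]
    atoms += [AtomRecord(n, "C", 1, "PHE", "P", 12.011) for n in RING_ATOMS["PHE"]]
    system, traj = _make(atoms, np.random.default_rng(0).normal(size=(len(atoms), 3)))
    with pytest.raises(pg.errors.ConfigurationError, match="CZ"):
        pg.detect_stacking(traj, SEL_B, SEL_P)


def _val_val(dist=3.8, water_dist=None):
    atoms = [
        AtomRecord("CA", "C", 1, "VAL", "B", 12.011),
        AtomRecord("CB", "C", 1, "VAL", "B", 12.011),
        AtomRecord("CA", "C", 1, "VAL", "P", 12.011),
        AtomRecord("CB", "C", 1, "VAL", "P", 12.011),
    ]
    coords = [[-1.5, 0, 0], [0, 0, 0], [dist + 1.5, 0, 0], [dist, 0, 0]]
    if water_dist is not None:
        atoms.append(AtomRecord("O", "O", 1, "HOH", "W", 15.999))
        coords.append([0.0, water_dist, 0.0])
    return _make(atoms, coords, n_frames=4)


def test_hydrophobic_contact_and_water_veto():
    _, contact = _val_val(3.8)
    records = pg.detect_hydrophobic(contact, SEL_B, SEL_P)
    assert len(records) == 1 and records[0].persistence == 1.0
    _, vetoed = _val_val(3.8, water_dist=3.0)
    assert pg.detect_hydrophobic(vetoed, SEL_B, SEL_P) == []
    _, distant_water = _val_val(3.8, water_dist=10.0)
    assert len(pg.detect_hydrophobic(distant_water, SEL_B, SEL_P)) == 1


def test_persistence_filter_keeps_025_drops_015(toy_complex, beta_site, peptide):
    """The 20% persistence filter keeps a 0.25 plant and excludes a 0.15
    plant of the same geometry."""
    base = pg.sample_trajectory(toy_complex, pg.FluctuationSpec(amplitude=0.05, seed=2), 200)
    kept = pg.plant_interaction(
        base, pg.PlantedInteraction("stacking", (("B", 26), ("P", 3)), 0.25, seed=5)
    )
    assert len(pg.detect_stacking(kept, beta_site, peptide)) == 1
    dropped = pg.plant_interaction(
        base, pg.PlantedInteraction("stacking", (("B", 26), ("P", 3)), 0.15, seed=5)
    )
    assert pg.detect_stacking(dropped, beta_site, peptide) == []
    # threshold 0 still reports the sub-threshold plant
    low = pg.detect_stacking(dropped, beta_site, peptide,
                             pg.StackCriteria(persistence_threshold=0.0))
    assert len(low) == 1 and low[0].persistence == pytest.approx(0.15)


def _planted_traj(toy_complex):
    base = pg.sample_trajectory(toy_complex, pg.FluctuationSpec(amplitude=0.1, seed=3), 50)
    traj = pg.plant_interaction(
        base, pg.PlantedInteraction("hbond", (("B", 82), ("P", 8)), 0.5, seed=6)
    )
    traj = pg.plant_interaction(
        traj, pg.PlantedInteraction("stacking", (("B", 26), ("P", 3)), 0.5, seed=7)
    )
    return pg.plant_interaction(
        traj, pg.PlantedInteraction("hydrophobic", (("B", 85), ("P", 5)), 0.5, seed=8)
    )


@pytest.mark.parametrize("loosen", [
    ("hbond", pg.HBondCriteria(), pg.HBondCriteria(da_cutoff=3.5, angle_cutoff=120.0)),
    ("stacking", pg.StackCriteria(), pg.StackCriteria(dihedral_cutoff=45.0, centroid_cutoff=6.0)),
    ("hydrophobic", pg.HydrophobicCriteria(), pg.HydrophobicCriteria(contact_cutoff=4.5)),
])
def test_loosening_cutoffs_is_monotone(toy_complex, beta_site, peptide, loosen):
    """Loosening any geometric cutoff never removes a record and never
    decreases any persistence."""
    kind, tight, loose = loosen
    traj = _planted_traj(toy_complex)
    detect = {"hbond": pg.detect_hbonds, "stacking": pg.detect_stacking,
              "hydrophobic": pg.detect_hydrophobic}[kind]
    tight_recs = {(r.mhc_partner, r.pep_partner): r.persistence
                  for r in detect(traj, beta_site, peptide, tight)}
    loose_recs = {(r.mhc_partner, r.pep_partner): r.persistence
                  for r in detect(traj, beta_site, peptide, loose)}
    for key, pers in tight_recs.items():
        assert key in loose_recs
        assert loose_recs[key] >= pers - 1e-12


def test_network_summary_merges_and_rejects_duplicates(toy_complex, beta_site, peptide):
    traj = _planted_traj(toy_complex)
    hb = pg.detect_hbonds(traj, beta_site, peptide)
    st = pg.detect_stacking(traj, beta_site, peptide)
    table = pg.network_summary(hb, st)
    assert set(table["kind"]) == {"hbond", "stacking"}
    assert len(table) == len(hb) + len(st)
    assert pg.network_summary().empty
    with pytest.raises(InternalError):
        pg.network_summary(hb, hb)


def test_identical_planted_systems_give_identical_tables(toy_complex, beta_site, peptide):
    a = _planted_traj(toy_complex)
    b = _planted_traj(toy_complex)
    ta = pg.network_summary(pg.detect_hbonds(a, beta_site, peptide))
    tb = pg.network_summary(pg.detect_hbonds(b, beta_site, peptide))
    assert ta.equals(tb)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def _brute_force_frame(system, frame, res_a, res_b, h_criteria, s_criteria, p_criteria):
    """Independent per-frame decisions for one residue pair, written as plain
    loops over atoms with math-library trigonometry."""
    ref = system.reference_coords

    def atoms_of(chain, resid):
        return [i for i in range(system.n_atoms)
                if system.chains[i] == chain and system.resids[i] == resid]

    def dist(i, j):
        return math.dist(tuple(frame[i]), tuple(frame[j]))

    ia, ib = atoms_of(*res_a), atoms_of(*res_b)
    resname_a = system.resnames[ia[0]]
    resname_b = system.resnames[ib[0]]

    # --- hydrogen bond ---
    def donors(idx):
        out = []
        for d in idx:
            if system.elements[d] not in ("N", "O", "S"):
                continue
            hs = [h for h in idx if system.elements[h] == "H"
                  and math.dist(tuple(ref[h]), tuple(ref[d])) <= 1.25]
            if hs:
                out.append((d, hs))
        return out

    def acceptors(idx):
        return [i for i in idx if system.elements[i] in ("N", "O")]

    hbond = False
    for d_idx, a_idx in ((ia, ib), (ib, ia)):
        for d, hs in donors(d_idx):
            for a in acceptors(a_idx):
                if a == d or dist(d, a) > h_criteria.da_cutoff:
                    continue
                for h in hs:
                    v1 = frame[d] - frame[h]
                    v2 = frame[a] - frame[h]
                    cosang = float(np.dot(v1, v2) /
                                   (np.linalg.norm(v1) * np.linalg.norm(v2)))
                    angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                    if angle >= h_criteria.angle_cutoff:
                        hbond = True

    # --- stacking ---
    stacking = False
    if resname_a in RING_ATOMS and resname_b in RING_ATOMS:
        def plane(idx, names):
            pts = np.array([frame[i] for i in idx if system.names[i] in names])
            centered = pts - pts.mean(axis=0)
            w, v = np.linalg.eigh(centered.T @ centered)
            return pts.mean(axis=0), v[:, 0]

        ca, na = plane(ia, RING_ATOMS[resname_a])
        cb, nb = plane(ib, RING_ATOMS[resname_b])
        angle = math.degrees(math.acos(min(1.0, abs(float(np.dot(na, nb))))))
        if (np.linalg.norm(ca - cb) <= s_criteria.centroid_cutoff
                and angle <= s_criteria.dihedral_cutoff):
            stacking = True

    # --- hydrophobic ---
    hydrophobic = False
    if resname_a in HYDROPHOBIC_RESIDUES and resname_b in HYDROPHOBIC_RESIDUES:
        side_a = [i for i in ia if system.heavy[i] and system.names[i] not in BACKBONE_ATOMS]
        side_b = [i for i in ib if system.heavy[i] and system.names[i] not in BACKBONE_ATOMS]
        contact_atoms = set()
        for i in side_a:
            for j in side_b:
                if dist(i, j) <= p_criteria.contact_cutoff:
                    contact_atoms.update((i, j))
        if contact_atoms:
            hydrophobic = True
            for w in range(system.n_atoms):
                if system.chains[w] == "W" and system.elements[w] == "O":
                    if any(dist(w, c) <= p_criteria.water_exclusion_radius
                           for c in contact_atoms):
                        hydrophobic = False
    return hbond, stacking, hydrophobic


def test_detectors_agree_with_brute_force_on_random_frames():
    """Frame-level decisions match a loop-based re-implementation on every
    frame of a small noisy planted system (all three detectors)."""
    system = pg.make_toy_complex(
        4, 4, 3, with_waters=2, seed=1,
        sequences={"B": {1: "ASN", 2: "PHE", 3: "VAL", 4: "SER"},
                   "P": {1: "PHE", 2: "VAL", 3: "SER"}},
    )
    assert system.n_atoms <= 200
    base = pg.sample_trajectory(system, pg.FluctuationSpec(amplitude=0.35, seed=4), 50)
    traj = pg.plant_interaction(
        base, pg.PlantedInteraction("hbond", (("B", 1), ("P", 3)), 0.5, seed=1)
    )
    traj = pg.plant_interaction(
        traj, pg.PlantedInteraction("stacking", (("B", 2), ("P", 1)), 0.5, seed=2)
    )
    traj = pg.plant_interaction(
        traj, pg.PlantedInteraction(
            "hydrophobic", (("B", 3), ("P", 2)), 0.5,
            geometry={"water_fraction": 0.4}, seed=3,
        )
    )
    group_b = ResidueSelection("bs", tuple(("B", r) for r in range(1, 5)))
    group_p = ResidueSelection("ps", tuple(("P", r) for r in range(1, 4)))
    hc, sc, pc = pg.HBondCriteria(persistence_threshold=0.0), \
        pg.StackCriteria(persistence_threshold=0.0), \
        pg.HydrophobicCriteria(persistence_threshold=0.0)
    presence = {}
    for rec in pg.detect_hbonds(traj, group_b, group_p, hc):
        presence[("hbond", rec.mhc_partner[1], rec.pep_partner[0])] = rec.presence
    for rec in pg.detect_stacking(traj, group_b, group_p, sc):
        presence[("stacking", rec.mhc_partner[1], rec.pep_partner[0])] = rec.presence
    for rec in pg.detect_hydrophobic(traj, group_b, group_p, pc):
        presence[("hydrophobic", rec.mhc_partner[1], rec.pep_partner[0])] = rec.presence
    for t in range(traj.n_frames):
        for rb in range(1, 5):
            for rp in range(1, 4):
                bf = _brute_force_frame(
                    system, traj.frames[t], ("B", rb), ("P", rp), hc, sc, pc
                )
                for kind, expected in zip(("hbond", "stacking", "hydrophobic"), bf):
                    trace = presence.get((kind, rb, rp))
                    got = bool(trace[t]) if trace is not None else False
                    assert got == expected, (kind, rb, rp, t)
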