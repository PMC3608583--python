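"""Shared fixtures: parameter table, toy complexes, selections."""
import numpy as np
import pytest

import pmhcgroove as pg


@pytest.fixture(scope="session")
def param_table():
    return pg.load_parameter_table()


@pytest.fixture(scope="session")
def toy_complex(param_table):
    """Paper-scale toy: chains A(80)/B(95)/P(14), detector-relevant residue
    types planted at known positions, a few waters."""
    return pg.make_toy_complex(
        80, 95, 14, with_waters=4, seed=1,
        sequences={
            "B": {26: "PHE", 81: "HIS", 82: "ASN", 84: "SER", 85: "VAL", 86: "SER"},
            "P": {3: "PHE", 4: "SER", 5: "VAL", 6: "SER", 8: "SER", 10: "HIS"},
        },
        param_table=param_table,
    )


@pytest.fixture(scope="session")
def binding_site(toy_complex):
    return pg.binding_site_selection(toy_complex)


@pytest.fixture(scope="session")
def beta_site(binding_site):
    return pg.ResidueSelection(
        "beta_site", tuple(m for m in binding_site.members if m[0] == "B")
    )


@pytest.fixture(scope="session")
def peptide(toy_complex):
    resids = np.unique(toy_complex.resids[toy_complex.chain_index["P"]])
    return pg.ResidueSelection("peptide", tuple(("P", int(r)) for r in resids))


def rigid_free_covariance(system, scale=0.5, ridge=0.3, seed=0):
    """Random PSD covariance supported on the subspace orthogonal to rigid-body
    motion of the reference coordinates (translations + infinitesimal
    rotations).  Ground truth for the entropy estimator, which superposes
    frames before building the covariance."""
    n = system.n_atoms
    x0 = system.reference_coords - system.reference_coords.mean(axis=0)
    basis = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = 1.0
        basis.append(t.ravel())
    for k in range(3):
        e = np.zeros(3)
        e[k] = 1.0
        basis.append(np.cross(np.tile(e, (n, 1)), x0).ravel())
    q = np.linalg.qr(np.asarray(basis).T)[0]
    proj = np.eye(3 * n) - q @ q.T
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(3 * n, 3 * n))
    dense = a @ a.T / (3 * n) * scale + ridge * np.eye(3 * n)
    return proj @ dense @ proj.T
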