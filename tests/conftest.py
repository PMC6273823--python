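import numpy as np
import pytest
from hypothesis import settings

from cdftkit.records import AtomRecord

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_wavefunction(rng, n_basis=6, n_atoms=3, open_shell=False):
    """Random small wavefunction with exact S-orthonormal MOs.

    Returns (density dict, S, basis_to_atom, C dict, occupations dict).
    """
    A = rng.uniform(-0.2, 0.2, (n_basis, n_basis))
    S = (A + A.T) / 2
    np.fill_diagonal(S, 1.0)
    # keep S positive definite
    w = np.linalg.eigvalsh(S)
    if w.min() <= 0.05:
        S += (0.05 - w.min() + 0.05) * np.eye(n_basis)
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
    w, V = np.linalg.eigh(S)
    S_mhalf = V @ np.diag(w**-0.5) @ V.T
    basis_to_atom = [int(rng.integers(1, n_atoms + 1)) for _ in range(n_basis)]
    # make sure every atom owns at least one basis function
    for a in range(1, n_atoms + 1):
        if a not in basis_to_atom:
            basis_to_atom[a % n_basis] = a

    def channel(n_occ, occ_value):
        Q, _ = np.linalg.qr(rng.normal(size=(n_basis, n_basis)))
        C = S_mhalf @ Q
        occ = np.array([occ_value] * n_occ + [0.0] * (n_basis - n_occ))
        P = (C * occ) @ C.T
        return C, occ, P

    if open_shell:
        Ca, occa, Pa = channel(min(3, n_basis), 1.0)
        Cb, occb, Pb = channel(min(2, n_basis - 1), 1.0)
        density = {"alpha": Pa, "beta": Pb}
        coeffs = {"alpha": Ca, "beta": Cb}
        occupations = {"alpha": occa, "beta": occb}
    else:
        Ca, occa, Pa = channel(2, 2.0)
        density = {"alpha": Pa}
        coeffs = {"alpha": Ca}
        occupations = {"alpha": occa}
    return density, S, basis_to_atom, coeffs, occupations


@pytest.fixture
def butane_like_chain():
    """Four-atom chain with a 60-degree a-b-c-d dihedral."""
    theta = np.radians(60.0)
    return [
        AtomRecord(index=1, element="C", z=6,
                   xyz=(-0.7, 1.2, 0.0)),
        AtomRecord(index=2, element="C", z=6, xyz=(0.0, 0.0, 0.0)),
        AtomRecord(index=3, element="C", z=6, xyz=(1.5, 0.0, 0.0)),
        AtomRecord(index=4, element="C", z=6,
                   xyz=(1.5 + 0.7, float(1.2 * np.cos(theta)), float(1.2 * np.sin(theta)))),
    ]
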