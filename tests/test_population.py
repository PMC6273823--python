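"""Mulliken populations, fragment composition, SOMO classification.

The independent oracle for every Mulliken quantity is the brute-force
double loop over basis-function pairs, never the vectorized diagonal of
P*S used by the implementation.
"""

import numpy as np
import pytest

from cdftkit.population import (
    FragmentComposition,
    classify_anion,
    delocalization_ratio,
    mo_fragment_composition,
    mulliken_populations,
)
from conftest import random_wavefunction


def brute_force_populations(density, S, basis_to_atom, n_atoms):
    """Elementwise oracle: pop_A = sum_{mu in A} sum_nu P_{mu nu} S_{nu mu}."""
    if set(density) == {"alpha"}:
        P_total, P_spin = density["alpha"], np.zeros_like(density["alpha"])
    else:
        P_total = density["alpha"] + density["beta"]
        P_spin = density["alpha"] - density["beta"]
    pop = np.zeros(n_atoms)
    spin = np.zeros(n_atoms)
    n = S.shape[0]
    for mu in range(n):
        for nu in range(n):
            pop[basis_to_atom[mu] - 1] += P_total[mu, nu] * S[nu, mu]
            spin[basis_to_atom[mu] - 1] += P_spin[mu, nu] * S[nu, mu]
    return pop, spin


def test_single_atom_neutral():
    charges, spins = mulliken_populations(
        {"alpha": np.array([[2.0]])}, np.array([[1.0]]), [1], [2]
    )
    assert charges[0] == pytest.approx(0.0, abs=1e-12)
    assert spins[0] == pytest.approx(0.0, abs=1e-12)


def test_homonuclear_symmetry():
    S = np.array([[1.0, 0.4], [0.4, 1.0]])
    P = np.array([[0.9, 0.3], [0.3, 0.9]])  # symmetric across the two atoms
    charges, _ = mulliken_populations({"alpha": P}, S, [1, 2], [1, 1])
    assert charges[0] == pytest.approx(charges[1], abs=1e-12)


@pytest.mark.parametrize("open_shell", [False, True])
def test_matches_brute_force_oracle(rng, open_shell):
    for _ in range(100):
        n_basis = int(rng.integers(2, 10))
        n_atoms = int(rng.integers(1, min(n_basis, 4) + 1))
        density, S, b2a, _, occ = random_wavefunction(
            rng, n_basis=n_basis, n_atoms=n_atoms, open_shell=open_shell
        )
        z = [int(rng.integers(1, 9)) for _ in range(n_atoms)]
        charges, spins = mulliken_populations(density, S, b2a, z)
        pop_ref, spin_ref = brute_force_populations(density, S, b2a, n_atoms)
        assert np.allclose(np.array(z) - charges, pop_ref, atol=1e-10)
        assert np.allclose(spins, spin_ref, atol=1e-10)
        # conservation: total charge and total spin
        n_elec = sum(np.sum(o) for o in occ.values())
        assert np.sum(charges) == pytest.approx(sum(z) - n_elec, abs=1e-8)
        if open_shell:
            assert np.sum(spins) == pytest.approx(
                np.sum(occ["alpha"]) - np.sum(occ["beta"]), abs=1e-8
            )


def test_dimension_mismatch_and_asymmetry_rejected():
    S = np.eye(2)
    with pytest.raises(ValueError):
        mulliken_populations({"alpha": np.eye(3)}, S, [1, 2], [1, 1])
    S_bad = np.array([[1.0, 0.3], [0.1, 1.0]])
    with pytest.raises(ValueError, match="symmetric"):
        mulliken_populations({"alpha": np.eye(2)}, S_bad, [1, 2], [1, 1])


# ---------------------------------------------------------------------------
# fragment composition
# ---------------------------------------------------------------------------

def test_concentrated_mo_single_fragment():
    S = np.eye(3)
    c = np.array([1.0, 0.0, 0.0])
    comp = mo_fragment_composition(c, S, [1, 2, 3], {1: "A", 2: "B", 3: "B"})
    assert comp.weights["A"] == pytest.approx(1.0, abs=1e-12)
    assert comp.weights["B"] == pytest.approx(0.0, abs=1e-12)


def test_symmetric_split_with_overlap():
    S = np.array([[1.0, 0.5], [0.5, 1.0]])
    c = np.array([1.0, 1.0]) / np.sqrt(3.0)  # c^T S c = 1
    comp = mo_fragment_composition(c, S, [1, 2], {1: "A", 2: "B"})
    assert comp.weights["A"] == pytest.approx(0.5, abs=1e-12)
    assert comp.weights["B"] == pytest.approx(0.5, abs=1e-12)


def test_fragment_weights_match_brute_force(rng):
    for _ in range(100):
        density, S, b2a, coeffs, _ = random_wavefunction(rng, n_basis=7, n_atoms=3)
        frag_map = {1: "A", 2: "B", 3: "C"}
        c = coeffs["alpha"][:, 0]
        comp = mo_fragment_composition(c, S, b2a, frag_map)
        ref = {f: 0.0 for f in "ABC"}
        n = S.shape[0]
        for mu in range(n):
            for nu in range(n):
                ref[frag_map[b2a[mu]]] += c[mu] * S[mu, nu] * c[nu]
        for f in "ABC":
            assert comp.weights.get(f, 0.0) == pytest.approx(ref[f], abs=1e-10)
        assert sum(comp.weights.values()) == pytest.approx(1.0, abs=1e-8)


def test_weights_invariant_under_basis_relabeling_within_atom(rng):
    density, S, b2a, coeffs, _ = random_wavefunction(rng, n_basis=6, n_atoms=2)
    c = coeffs["alpha"][:, 1]
    frag_map = {1: "A", 2: "B"}
    comp = mo_fragment_composition(c, S, b2a, frag_map)
    # permute two basis functions belonging to the same atom
    idx = [i for i, a in enumerate(b2a) if a == b2a[0]]
    perm = list(range(len(b2a)))
    if len(idx) >= 2:
        perm[idx[0]], perm[idx[1]] = perm[idx[1]], perm[idx[0]]
    Sp = S[np.ix_(perm, perm)]
    cp = c[perm]
    b2ap = [b2a[i] for i in perm]
    comp_p = mo_fragment_composition(cp, Sp, b2ap, frag_map)
    for f in comp.weights:
        assert comp_p.weights[f] == pytest.approx(comp.weights[f], abs=1e-12)


def test_unnormalized_mo_rejected():
    with pytest.raises(ValueError, match="normalized"):
        mo_fragment_composition(np.array([2.0, 0.0]), np.eye(2), [1, 2], {1: "A", 2: "B"})


def test_unmapped_atom_rejected():
    with pytest.raises(KeyError, match="fragment"):
        mo_fragment_composition(np.array([1.0, 0.0]), np.eye(2), [1, 2], {1: "A"})


# ---------------------------------------------------------------------------
# delocalization and classification
# ---------------------------------------------------------------------------

def comp(weights):
    return FragmentComposition(mo_index=0, spin="alpha", weights=weights)


@pytest.mark.parametrize(
    "weights, expected",
    [
        ({"A": 1.0, "B": 0.0, "C": 0.0, "D": 0.0}, 0.25),
        ({f: 0.2 for f in "ABCDE"}, 1.0),
        ({"A": 0.5, "B": 0.3, "C": 0.2}, (1.0 / 0.38) / 3.0),  # 0.87719...
    ],
)
def test_delocalization_ratio(weights, expected):
    assert delocalization_ratio(comp(weights)) == pytest.approx(expected, abs=1e-12)


def test_delocalization_rejects_empty():
    with pytest.raises(ValueError):
        delocalization_ratio(comp({}))


@pytest.mark.parametrize(
    "weights, expected",
    [
        ({"A": 0.95, "B": 0.05}, "dipole_bound"),
        ({"A": 0.25, "B": 0.25, "C": 0.25, "D": 0.25}, "valence_bound"),
        ({"A": 0.5, "B": 0.3, "C": 0.2}, "valence_bound"),
        ({"A": 0.86, "B": 0.12, "C": 0.02}, "valence_bound"),  # second weight too large
    ],
)
def test_classify_anion(weights, expected):
    assert classify_anion(comp(weights)) == expected


def test_classify_thresholds_configurable():
    w = comp({"A": 0.8, "B": 0.2})
    assert classify_anion(w) == "valence_bound"
    assert classify_anion(w, max_weight_threshold=0.75,
                          second_weight_threshold=0.25) == "dipole_bound"
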