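"""Mulliken population analysis and fragment-resolved MO composition.

The gross Mulliken population of atom A is the sum over its basis functions
of the diagonal of P·S (P the total density matrix, S the AO overlap);
charges follow as Z_A minus the population, spin populations from the
spin-density matrix P_alpha - P_beta. Fragment weights of a normalized MO
column c are w_F = sum_{mu in F} c_mu (S c)_mu, the Mulliken gross orbital
population aggregated over fragments.

The delocalization diagnostics at the bottom classify a radical-anion SOMO
as valence-bound (spread over the molecular frame) or dipole-bound
(concentrated on one fragment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import RecordValidationError, WavefunctionData

#: Fragment weight above which (together with DIPOLE_SECOND_MAX) a SOMO
#: counts as dipole-bound. Heuristic; configurable at the call site.
DIPOLE_MAX_WEIGHT = 0.85
DIPOLE_SECOND_MAX = 0.10


@dataclass
class FragmentComposition:
    """Per-fragment weights of one molecular orbital."""

    mo_index: int
    spin: str
    weights: dict[str, float]

    def validate(self) -> "FragmentComposition":
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-8:
            raise RecordValidationError(
                "fragment_weights_sum", f"sum {total} != 1 for normalized MO"
            )
        if any(w < -1e-8 for w in self.weights.values()):
            # genuinely negative beyond the Mulliken-artifact band
            raise RecordValidationError("fragment_weight_negative", str(self.weights))
        return self


def _check_overlap(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"overlap must be square, got {S.shape}")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("overlap matrix is not symmetric")
    return S


def mulliken_populations(
    density: dict[str, np.ndarray],
    overlap: np.ndarray,
    basis_to_atom: list[int],
    z: list[int],
) -> tuple[np.ndarray, np.ndarray]:
    """Gross Mulliken atomic charges and spin populations.

    Parameters
    ----------
    density : dict
        Per-spin density matrices. A single "alpha" channel is taken as the
        total (closed-shell) density; with both channels present the total
        is their sum and the spin density their difference.
    overlap : ndarray
        AO overlap matrix S.
    basis_to_atom : list of int
        0-based basis index -> 1-based atom index.
    z : list of int
        Nuclear charges, one per atom in index order.

    Returns
    -------
    charges, spin_populations : ndarray
        Both of length n_atoms; charges sum to the net molecular charge,
        spin populations to N_alpha - N_beta.
    """
    S = _check_overlap(overlap)
    n = S.shape[0]
    if len(basis_to_atom) != n:
        raise ValueError(f"basis_to_atom length {len(basis_to_atom)} != {n}")
    for spin, P in density.items():
        P = np.asarray(P)
        if P.shape != (n, n):
            raise ValueError(f"density[{spin}] shape {P.shape} != {(n, n)}")

    if set(density) == {"alpha"}:
        P_total = np.asarray(density["alpha"], float)
        P_spin = np.zeros_like(P_total)
    else:
        Pa = np.asarray(density["alpha"], float)
        Pb = np.asarray(density["beta"], float)
        P_total = Pa + Pb
        P_spin = Pa - Pb

    diag_total = np.einsum("ij,ji->i", P_total, S)
    diag_spin = np.einsum("ij,ji->i", P_spin, S)

    n_atoms = len(z)
    populations = np.zeros(n_atoms)
    spin_populations = np.zeros(n_atoms)
    for mu, atom in enumerate(basis_to_atom):
        populations[atom - 1] += diag_total[mu]
        spin_populations[atom - 1] += diag_spin[mu]
    charges = np.asarray(z, dtype=float) - populations
    return charges, spin_populations


def mulliken_from_wavefunction(
    wf: WavefunctionData, z: list[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Convenience wrapper taking a validated :class:`WavefunctionData`."""
    return mulliken_populations(wf.density, wf.overlap, wf.basis_to_atom, z)


def mo_fragment_composition(
    c: np.ndarray,
    overlap: np.ndarray,
    basis_to_atom: list[int],
    atom_to_fragment: dict[int, str],
    mo_index: int = 0,
    spin: str = "alpha",
) -> FragmentComposition:
    """Mulliken fragment weights of one normalized MO column."""
    S = _check_overlap(overlap)
    c = np.asarray(c, dtype=float).ravel()
    if c.shape[0] != S.shape[0]:
        raise ValueError(f"MO length {c.shape[0]} != basis size {S.shape[0]}")
    norm = float(c @ S @ c)
    if abs(norm - 1.0) > 1e-6:
        raise ValueError(f"MO not normalized: c^T S c = {norm}")
    contrib = c * (S @ c)  # Mulliken gross orbital population per basis fn
    weights: dict[str, float] = {}
    for mu, atom in enumerate(basis_to_atom):
        try:
            frag = atom_to_fragment[atom]
        except KeyError:
            raise KeyError(f"atom {atom} has no fragment assignment") from None
        weights[frag] = weights.get(frag, 0.0) + float(contrib[mu])
    return FragmentComposition(mo_index=mo_index, spin=spin, weights=weights)


def delocalization_ratio(comp: FragmentComposition) -> float:
    """Participation ratio over fragments, normalized to (0, 1].

    PR = 1 / sum_F w_F^2 counts the effective number of fragments the
    orbital occupies; dividing by the fragment count gives 1.0 for a
    perfectly uniform spread and 1/F for a single-fragment orbital.
    Small negative Mulliken weights are clipped to zero first.
    """
    if not comp.weights:
        raise ValueError("empty fragment weights")
    w = np.clip(np.array(list(comp.weights.values()), dtype=float), 0.0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError("all fragment weights vanish")
    w = w / total
    pr = 1.0 / float(np.sum(w**2))
    return pr / len(w)


def classify_anion(
    comp: FragmentComposition,
    max_weight_threshold: float = DIPOLE_MAX_WEIGHT,
    second_weight_threshold: float = DIPOLE_SECOND_MAX,
) -> str:
    """Classify a SOMO as ``"valence_bound"`` or ``"dipole_bound"``.

    Dipole-bound means the orbital is essentially confined to one fragment:
    largest clipped weight >= `max_weight_threshold` and second-largest
    < `second_weight_threshold`. Everything else is valence-bound.
    """
    w = sorted(
        (max(v, 0.0) for v in comp.weights.values()),
        reverse=True,
    )
    if not w:
        raise ValueError("empty fragment weights")
    largest = w[0]
    second = w[1] if len(w) > 1 else 0.0
    if largest >= max_weight_threshold and second < second_weight_threshold:
        return "dipole_bound"
    return "valence_bound"
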