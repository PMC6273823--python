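"""Frontier-orbital extraction and global conceptual-DFT reactivity indices.

Within the frozen-orbital (Koopmans-like) approximation the electronic
chemical potential, chemical hardness and electrophilicity index are

    mu    = (eps_HOMO + eps_LUMO) / 2
    eta   = (eps_LUMO - eps_HOMO) / 2
    omega = mu**2 / (2 * eta)

with the one-half hardness convention. omega is computed from unrounded
mu and eta; rounding happens only at the reporting boundary.
"""

from __future__ import annotations

from .records import ElectronicStructureRecord, GlobalIndices
from .units import hartree_to_ev

#: A spin orbital with occupation above this counts as occupied.
OCCUPATION_THRESHOLD = 0.5

#: omega values closer than this (eV) are reported as tied ranks.
OMEGA_TIE_TOL = 0.005


def frontier_orbitals(
    rec: ElectronicStructureRecord, spin: str = "alpha"
) -> tuple[float, float]:
    """HOMO and LUMO energies in eV from a validated record.

    The HOMO is the highest-energy orbital with occupation above 0.5 per
    spin orbital, the LUMO the lowest-energy orbital below it. For
    open-shell records the requested spin channel (default alpha, which
    holds the SOMO of a radical anion) defines the frontier.
    """
    if spin not in rec.orbital_energies:
        raise ValueError(f"record has no spin channel {spin!r}")
    eps = rec.orbital_energies[spin]
    occ = rec.occupations[spin]
    if not eps:
        raise ValueError("empty orbital list")
    occupied = [e for e, o in zip(eps, occ) if o > OCCUPATION_THRESHOLD]
    virtual = [e for e, o in zip(eps, occ) if o <= OCCUPATION_THRESHOLD]
    if not occupied:
        raise ValueError("no occupied orbitals above threshold")
    if not virtual:
        raise ValueError("all orbitals occupied: no virtual orbital for LUMO")
    return hartree_to_ev(max(occupied)), hartree_to_ev(min(virtual))


def global_reactivity(eps_homo: float, eps_lumo: float) -> GlobalIndices:
    """Global indices from frontier energies (eV in, eV out)."""
    gap = eps_lumo - eps_homo
    if gap <= 0:
        raise ValueError(
            f"hardness undefined: gap = {gap} <= 0 (HOMO {eps_homo}, LUMO {eps_lumo})"
        )
    mu = (eps_homo + eps_lumo) / 2.0
    eta = gap / 2.0
    omega = mu * mu / (2.0 * eta)
    return GlobalIndices(
        eps_homo=eps_homo, eps_lumo=eps_lumo, gap=gap, mu=mu, eta=eta, omega=omega
    )


def record_global_indices(rec: ElectronicStructureRecord) -> GlobalIndices:
    """Frontier extraction and index computation in one step."""
    return global_reactivity(*frontier_orbitals(rec))


def rank_by_omega(
    indices: dict[str, GlobalIndices], tie_tol: float = OMEGA_TIE_TOL
) -> list[tuple[int, list[str]]]:
    """Rank compounds by descending electrophilicity index.

    Returns ``[(rank, [compound, ...]), ...]`` with 1-based dense ranks;
    compounds whose omega values differ by less than `tie_tol` share a rank.
    """
    if len(indices) < 2:
        return [(1, list(indices))]
    ordered = sorted(indices.items(), key=lambda kv: -kv[1].omega)
    ranks: list[tuple[int, list[str]]] = []
    current: list[str] = [ordered[0][0]]
    current_omega = ordered[0][1].omega
    rank = 1
    for cid, gi in ordered[1:]:
        if abs(gi.omega - current_omega) < tie_tol:
            current.append(cid)
        else:
            ranks.append((rank, current))
            rank += 1
            current = [cid]
        current_omega = gi.omega
    ranks.append((rank, current))
    return ranks
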