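"""Rigid-rotor dihedral driving and two-dihedral conformational grid scans.

The scan machinery mirrors the usual semi-empirical rotational analysis of
flexible substituents (e.g. an N-benzyl arm): two dihedral angles are
driven over a regular grid, a pluggable callback supplies the energy of
each rigid-rotated geometry, and the grid argmin is returned. The energy
callback may wrap an external engine (PM6, xtb, a force field) or one of
the packaged analytic surfaces; the package owns the scan, not the
energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .records import AtomRecord

#: Covalent radii (Angstrom) for bond perception; pairwise cutoff is
#: 1.2 * (r_a + r_b).
COVALENT_RADII = {
    "H": 0.31, "He": 0.28, "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76,
    "N": 0.71, "O": 0.66, "F": 0.57, "Na": 1.66, "Mg": 1.41, "Al": 1.21,
    "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "K": 2.03, "Ca": 1.76,
    "Br": 1.20, "I": 1.39,
}
BOND_SCALE = 1.2


@dataclass
class DihedralSpec:
    """Four 1-based atom indices a-b-c-d plus the grid of target angles."""

    atoms: tuple[int, int, int, int]
    grid: Sequence[float] = field(default_factory=lambda: default_grid())

    def __post_init__(self):
        if len(set(self.atoms)) != 4:
            raise ValueError(f"dihedral atoms must be distinct: {self.atoms}")
        for theta in self.grid:
            if not (-180.0 <= theta < 180.0):
                raise ValueError(f"grid angle {theta} outside [-180, 180)")


@dataclass
class TorsionScanResult:
    """Grid energies and the located minimum of a two-dihedral scan."""

    theta1: np.ndarray          # grid of first dihedral, degrees
    theta2: np.ndarray          # grid of second dihedral, degrees
    energies: np.ndarray        # shape (len(theta1), len(theta2)), callback units
    minimum: tuple[float, float, float]  # (theta1*, theta2*, E*)


def default_grid(step: float = 15.0) -> list[float]:
    """Regular grid over [-180, 180) with the given step in degrees."""
    n = int(round(360.0 / step))
    return [-180.0 + i * step for i in range(n)]


def _coords(geometry: Sequence[AtomRecord]) -> np.ndarray:
    return np.array([a.xyz for a in sorted(geometry, key=lambda a: a.index)])


def measure_dihedral(geometry: Sequence[AtomRecord], atoms: tuple[int, int, int, int]) -> float:
    """Signed a-b-c-d dihedral in degrees, IUPAC sign convention."""
    xyz = _coords(geometry)
    a, b, c, d = (xyz[i - 1] for i in atoms)
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    angle = np.degrees(np.arctan2(m @ n2, n1 @ n2))
    return float(angle)


def connectivity(geometry: Sequence[AtomRecord]) -> dict[int, set[int]]:
    """Bond graph from covalent radii; 1-based adjacency sets."""
    atoms = sorted(geometry, key=lambda a: a.index)
    xyz = _coords(geometry)
    adj: dict[int, set[int]] = {a.index: set() for a in atoms}
    for i, ai in enumerate(atoms):
        for j in range(i + 1, len(atoms)):
            aj = atoms[j]
            ri = COVALENT_RADII.get(ai.element, 0.76)
            rj = COVALENT_RADII.get(aj.element, 0.76)
            if np.linalg.norm(xyz[i] - xyz[j]) <= BOND_SCALE * (ri + rj):
                adj[ai.index].add(aj.index)
                adj[aj.index].add(ai.index)
    return adj


def _distal_component(adj: dict[int, set[int]], b: int, c: int) -> set[int]:
    """Atoms on the c-side after deleting bond b-c; error if b-c is in a ring."""
    if c not in adj[b]:
        raise ValueError(f"atoms {b} and {c} are not bonded")
    seen = {c}
    stack = [c]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if u == c and v == b:
                continue
            if v not in seen:
                seen.add(v)
                stack.append(v)
    if b in seen:
        raise ValueError(
            f"bond {b}-{c} lies in a ring: rotation does not partition the molecule"
        )
    return seen


def set_dihedral(
    geometry: Sequence[AtomRecord], spec: DihedralSpec, angle: float
) -> list[AtomRecord]:
    """Return a copy of the geometry with the a-b-c-d dihedral set to `angle`.

    The component distal to the b-c bond is rotated rigidly about the b-c
    axis; all bond lengths (and every distance within each rigid body) are
    preserved.
    """
    a_i, b_i, c_i, d_i = spec.atoms
    atoms = sorted(geometry, key=lambda a: a.index)
    xyz = _coords(geometry)
    adj = connectivity(geometry)
    distal = _distal_component(adj, b_i, c_i)

    current = measure_dihedral(geometry, spec.atoms)
    # rotating the distal body by +delta about b->c decreases the measured
    # dihedral by delta (sign convention of the atan2 form)
    delta = np.radians(current - angle)
    pos = {a.index: i for i, a in enumerate(atoms)}
    b = xyz[pos[b_i]]
    c = xyz[pos[c_i]]
    axis = c - b
    axis = axis / np.linalg.norm(axis)
    # Rodrigues rotation about the b-c axis through point b
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(delta) * K + (1 - np.cos(delta)) * (K @ K)

    out = []
    for atom in atoms:
        p = np.array(atom.xyz)
        if atom.index in distal:
            p = b + R @ (p - b)
        out.append(
            AtomRecord(
                index=atom.index, element=atom.element, z=atom.z,
                xyz=(float(p[0]), float(p[1]), float(p[2])),
                label=atom.label, fragment=atom.fragment,
            )
        )
    return out


class ScanPointError(RuntimeError):
    """The energy callback failed at a named grid point."""

    def __init__(self, theta1: float, theta2: float, cause: Exception):
        self.point = (theta1, theta2)
        super().__init__(f"energy callback failed at ({theta1}, {theta2}): {cause}")


def grid_scan(
    geometry: Sequence[AtomRecord],
    specs: tuple[DihedralSpec, DihedralSpec],
    energy_fn: Callable[[Sequence[AtomRecord]], float],
) -> TorsionScanResult:
    """Evaluate the full cross-product grid of two dihedrals.

    The geometry at each point has both dihedrals driven rigidly; ties in
    the minimum are broken by smallest (theta1, theta2) lexicographically
    (grids are traversed in their given order, strictly-smaller wins).
    """
    spec1, spec2 = specs
    t1 = np.array(sorted(spec1.grid), dtype=float)
    t2 = np.array(sorted(spec2.grid), dtype=float)
    energies = np.empty((t1.size, t2.size))
    best: tuple[float, float, float] | None = None
    for i, th1 in enumerate(t1):
        g1 = set_dihedral(geometry, spec1, float(th1))
        for j, th2 in enumerate(t2):
            g2 = set_dihedral(g1, spec2, float(th2))
            try:
                e = float(energy_fn(g2))
            except Exception as exc:  # noqa: BLE001 — re-raised with the grid point
                raise ScanPointError(float(th1), float(th2), exc) from exc
            if not np.isfinite(e):
                raise ScanPointError(
                    float(th1), float(th2), ValueError(f"non-finite energy {e}")
                )
            energies[i, j] = e
            if best is None or e < best[2]:
                best = (float(th1), float(th2), e)
    assert best is not None
    return TorsionScanResult(theta1=t1, theta2=t2, energies=energies, minimum=best)


def scan_on_surface(
    surface: Callable[[float, float], float],
    grid1: Sequence[float],
    grid2: Sequence[float],
) -> TorsionScanResult:
    """Grid scan of an analytic two-angle surface (no geometry needed).

    Same argmin and tie-break semantics as :func:`grid_scan`; used for
    validating scan logic against closed-form minima.
    """
    t1 = np.array(sorted(grid1), dtype=float)
    t2 = np.array(sorted(grid2), dtype=float)
    energies = np.empty((t1.size, t2.size))
    best: tuple[float, float, float] | None = None
    for i, th1 in enumerate(t1):
        for j, th2 in enumerate(t2):
            e = float(surface(float(th1), float(th2)))
            if not np.isfinite(e):
                raise ScanPointError(float(th1), float(th2), ValueError("non-finite"))
            energies[i, j] = e
            if best is None or e < best[2]:
                best = (float(th1), float(th2), e)
    assert best is not None
    return TorsionScanResult(theta1=t1, theta2=t2, energies=energies, minimum=best)


def cosine_surface(
    min1_deg: float = 60.0, min2_deg: float = 0.0, amp1: float = 1.0, amp2: float = 1.0
) -> Callable[[float, float], float]:
    """Packaged analytic surface with a single global minimum.

    V(t1, t2) = amp1*(1 - cos(t1 - min1)) + amp2*(1 - cos(t2 - min2)),
    minimum V = 0 at (min1, min2).
    """

    def surface(t1: float, t2: float) -> float:
        return amp1 * (1.0 - np.cos(np.radians(t1 - min1_deg))) + amp2 * (
            1.0 - np.cos(np.radians(t2 - min2_deg))
        )

    return surface
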