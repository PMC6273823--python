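"""Domain types for electronic-structure records and derived reactivity data.

The central container is :class:`ElectronicStructureRecord`: one chemical
species (neutral molecule or radical anion) at one geometry and one level of
theory, carrying the total electronic energy, ZPVE, per-spin orbital energies
and occupations, and optionally the wavefunction matrices and pre-condensed
atomic populations needed for population analysis.

Validation is total: every invariant violation raises
:class:`RecordValidationError` with a named violation code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

OCC_SUM_TOL = 1e-6
OVERLAP_DIAG_TOL = 1e-8
MO_NORM_TOL = 1e-6

STATES = ("neutral", "anion")
GEOMETRY_TAGS = ("opt_neutral", "opt_anion", "vertical_at_neutral", "vertical_at_anion")
LEVEL_TAGS = ("basis1", "basis2_composite", "other")


class RecordValidationError(ValueError):
    """An invariant of a record was violated.

    Attributes
    ----------
    violation : str
        Machine-readable name of the violated invariant.
    """

    def __init__(self, violation: str, message: str):
        self.violation = violation
        super().__init__(f"[{violation}] {message}")


@dataclass
class AtomRecord:
    """One atom in a molecular geometry (1-based indexing throughout)."""

    index: int
    element: str
    z: int
    xyz: tuple[float, float, float]
    label: Optional[str] = None        # site label, e.g. "C7", "C9", "O9", "N11"
    fragment: Optional[str] = None     # e.g. "piperidone_ring", "exo_alkene", "aryl_1"


@dataclass
class WavefunctionData:
    """MO coefficients, overlap and density matrices in the AO basis.

    ``mo_coefficients`` and ``density`` are per-spin dicts keyed "alpha" /
    "beta"; a closed-shell record stores a single "alpha" channel whose
    density is the *total* density (trace PS = N electrons).
    ``basis_to_atom`` maps 0-based basis-function index to 1-based atom index.
    """

    mo_coefficients: dict[str, np.ndarray]
    overlap: np.ndarray
    density: dict[str, np.ndarray]
    basis_to_atom: list[int]

    def validate(self) -> None:
        S = np.asarray(self.overlap, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise RecordValidationError("overlap_not_square", f"shape {S.shape}")
        if not np.allclose(S, S.T, atol=OVERLAP_DIAG_TOL):
            raise RecordValidationError("overlap_not_symmetric", "S != S^T")
        if not np.allclose(np.diag(S), 1.0, atol=OVERLAP_DIAG_TOL):
            raise RecordValidationError("overlap_diagonal", "diag(S) != 1")
        n = S.shape[0]
        if len(self.basis_to_atom) != n:
            raise RecordValidationError(
                "basis_map_length", f"{len(self.basis_to_atom)} != {n} basis functions"
            )
        for spin, C in self.mo_coefficients.items():
            C = np.asarray(C, dtype=float)
            if C.shape[0] != n:
                raise RecordValidationError("mo_matrix_shape", f"spin {spin}: {C.shape}")
            norms = np.einsum("ij,ik,kj->j", C, S, C)
            if not np.allclose(norms, 1.0, atol=MO_NORM_TOL):
                worst = float(np.max(np.abs(norms - 1.0)))
                raise RecordValidationError(
                    "mo_not_normalized", f"spin {spin}: max |c^T S c - 1| = {worst:.2e}"
                )
        for spin, P in self.density.items():
            P = np.asarray(P, dtype=float)
            if P.shape != (n, n):
                raise RecordValidationError("density_shape", f"spin {spin}: {P.shape}")


@dataclass
class ElectronicStructureRecord:
    """One species at one geometry and one level of theory.

    Occupation dialect: a record with both "alpha" and "beta" orbital
    channels stores per-spin occupations in [0, 1]; a record with a single
    "alpha" channel is closed-shell and stores occupations in [0, 2].
    """

    species_id: str
    charge: int
    multiplicity: int
    state: str
    geometry_tag: str
    level_tag: str
    e_elec_hartree: float
    orbital_energies: dict[str, list[float]]
    occupations: dict[str, list[float]]
    zpve_hartree: Optional[float] = None
    n_imaginary_freq: Optional[int] = None
    geometry: list[AtomRecord] = field(default_factory=list)
    wavefunction: Optional[WavefunctionData] = None
    atomic_charges: Optional[list[float]] = None
    atomic_spin_populations: Optional[list[float]] = None

    @property
    def closed_shell(self) -> bool:
        """True for the single-channel dialect (occupations in [0, 2])."""
        return set(self.orbital_energies) == {"alpha"}

    @property
    def n_electrons(self) -> float:
        return float(sum(sum(o) for o in self.occupations.values()))

    def site_index(self, label: str) -> int:
        """1-based atom index for a site label such as "C7"."""
        for atom in self.geometry:
            if atom.label == label:
                return atom.index
        raise KeyError(f"no atom labelled {label!r}")

    def validate(self) -> "ElectronicStructureRecord":
        if self.state not in STATES:
            raise RecordValidationError("bad_state", f"{self.state!r} not in {STATES}")
        if self.geometry_tag not in GEOMETRY_TAGS:
            raise RecordValidationError(
                "bad_geometry_tag", f"{self.geometry_tag!r} not in {GEOMETRY_TAGS}"
            )
        if self.level_tag not in LEVEL_TAGS:
            raise RecordValidationError("bad_level_tag", f"{self.level_tag!r}")
        if self.multiplicity < 1:
            raise RecordValidationError("bad_multiplicity", f"{self.multiplicity}")
        # The molecules modelled here are neutral closed-shell parents and
        # their radical anions; anion records must sit one electron up.
        if self.state == "anion" and self.charge != -1:
            raise RecordValidationError(
                "anion_charge", f"anion must have charge -1, got {self.charge}"
            )
        if self.state == "neutral" and self.charge != 0:
            raise RecordValidationError(
                "neutral_charge", f"neutral must have charge 0, got {self.charge}"
            )
        if self.zpve_hartree is not None and self.zpve_hartree < 0:
            raise RecordValidationError("negative_zpve", f"{self.zpve_hartree}")
        if set(self.orbital_energies) != set(self.occupations):
            raise RecordValidationError("spin_channel_mismatch", "energies vs occupations")
        if not self.orbital_energies:
            raise RecordValidationError("no_orbitals", "empty orbital list")
        occ_max = 2.0 if self.closed_shell else 1.0
        for spin, eps in self.orbital_energies.items():
            occ = self.occupations[spin]
            if len(eps) != len(occ):
                raise RecordValidationError("orbital_length_mismatch", f"spin {spin}")
            if any(b < a - 1e-12 for a, b in zip(eps, eps[1:])):
                raise RecordValidationError(
                    "orbital_energies_unsorted", f"spin {spin} not ascending"
                )
            if any(o < -1e-12 or o > occ_max + 1e-12 for o in occ):
                raise RecordValidationError(
                    "occupation_range", f"spin {spin}: outside [0, {occ_max}]"
                )
        if self.geometry:
            indices = [a.index for a in self.geometry]
            if len(set(indices)) != len(indices):
                raise RecordValidationError("duplicate_atom_index", str(indices))
            labels = [a.label for a in self.geometry if a.label is not None]
            if len(set(labels)) != len(labels):
                raise RecordValidationError("duplicate_atom_label", str(labels))
            if any(a.z < 1 for a in self.geometry):
                raise RecordValidationError("bad_nuclear_charge", "Z < 1")
            expected = sum(a.z for a in self.geometry) - self.charge
            if abs(self.n_electrons - expected) > OCC_SUM_TOL:
                raise RecordValidationError(
                    "electron_count",
                    f"occupations sum to {self.n_electrons}, expected {expected}",
                )
        if self.wavefunction is not None:
            self.wavefunction.validate()
            if self.geometry:
                atoms = {a.index for a in self.geometry}
                bad = set(self.wavefunction.basis_to_atom) - atoms
                if bad:
                    raise RecordValidationError("basis_map_atoms", f"unknown atoms {bad}")
        if self.atomic_charges is not None and self.geometry:
            if len(self.atomic_charges) != len(self.geometry):
                raise RecordValidationError("atomic_charges_length", "vs geometry")
        if self.atomic_spin_populations is not None and self.geometry:
            if len(self.atomic_spin_populations) != len(self.geometry):
                raise RecordValidationError("spin_populations_length", "vs geometry")
        return self


@dataclass
class GlobalIndices:
    """Global conceptual-DFT reactivity indices, all in eV.

    mu = (eps_HOMO + eps_LUMO)/2, eta = (eps_LUMO - eps_HOMO)/2,
    omega = mu^2 / (2 eta).
    """

    eps_homo: float
    eps_lumo: float
    gap: float
    mu: float
    eta: float
    omega: float


@dataclass
class AttachmentEnergies:
    """Adiabatic/vertical electron affinities and detachment energy, eV.

    The physical ordering vea <= aea <= vde is *checked*, not enforced,
    so that inconsistent literature values can be flagged rather than
    silently rejected.
    """

    aea: float
    vea: float
    vde: float
    level_tag: str = "other"


@dataclass
class CondensedSiteIndices:
    """Per-atom condensed Fukui f+ and Parr P+ vectors with site labels."""

    fukui_plus: np.ndarray
    parr_plus: Optional[np.ndarray]
    site_map: dict[str, int]  # label -> 1-based atom index

    def value(self, which: str, label: str) -> float:
        vec = self.fukui_plus if which == "fukui_plus" else self.parr_plus
        if vec is None:
            raise ValueError(f"{which} not available")
        try:
            idx = self.site_map[label]
        except KeyError:
            raise KeyError(f"unknown site label {label!r}") from None
        return float(vec[idx - 1])


@dataclass
class HammettFit:
    """Ordinary least-squares fit of a descriptor against sigma_p."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    compounds: list[str] = field(default_factory=list)


#: Default sigma_p substituent constants (Hansch-Leo-Taft compilation).
DEFAULT_SIGMA_P: dict[str, float] = {
    "H": 0.00,
    "4-Cl": 0.23,
    "4-Br": 0.23,
    "4-NMe2": -0.83,
    "4-CN": 0.66,
    "4-CF3": 0.54,
}
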