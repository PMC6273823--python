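"""Synthetic record generators and packaged fixtures.

The generators invert each analysis stage: given the quantity a stage
should report (a frontier-orbital pair, an AEA/VEA/VDE triple, a condensed
Fukui vector, a Hammett line), they construct valid input records that
reproduce it exactly through the pipeline. This gives every stage a
ground-truth input at zero quantum-chemistry cost; absolute energies are
randomized per seed so nothing can pass by matching hard-coded totals.

``load_fixture`` exposes the packaged reference tables (transcribed
printed values for the twelve compounds), a toy enone geometry and a mock
wavefunction for population-analysis smoke tests.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from .attachment import SpeciesQuadruple
from .records import (
    DEFAULT_SIGMA_P,
    AtomRecord,
    ElectronicStructureRecord,
    WavefunctionData,
)
from .io import read_xyz
from .units import ev_to_hartree

_FIXTURES = ("table1", "table2", "table3", "table4", "toy_enone_xyz", "mock_wavefunction")


def _rng(seed: Optional[int]) -> np.random.Generator:
    return np.random.default_rng(seed)


def make_orbital_record(
    eps_homo: float,
    eps_lumo: float,
    n_occupied: int = 5,
    species_id: str = "synthetic",
    seed: Optional[int] = None,
) -> ElectronicStructureRecord:
    """Closed-shell record whose frontier orbitals are exactly (HOMO, LUMO) in eV.

    Filler occupied orbitals are placed strictly below the HOMO and one
    filler virtual strictly above the LUMO, at seed-randomized spacings.
    """
    if eps_lumo <= eps_homo:
        raise ValueError(f"LUMO {eps_lumo} must lie above HOMO {eps_homo}")
    if n_occupied < 1:
        raise ValueError("need at least one occupied orbital")
    rng = _rng(seed)
    homo_ha = ev_to_hartree(eps_homo)
    lumo_ha = ev_to_hartree(eps_lumo)
    fillers = sorted(homo_ha - np.abs(rng.uniform(0.05, 2.0, n_occupied - 1)))
    energies = [float(e) for e in fillers] + [homo_ha, lumo_ha]
    energies.append(lumo_ha + float(rng.uniform(0.05, 2.0)))
    occupations = [2.0] * n_occupied + [0.0, 0.0]
    return ElectronicStructureRecord(
        species_id=species_id,
        charge=0,
        multiplicity=1,
        state="neutral",
        geometry_tag="opt_neutral",
        level_tag="basis1",
        e_elec_hartree=float(rng.uniform(-600.0, -100.0)),
        orbital_energies={"alpha": energies},
        occupations={"alpha": occupations},
    ).validate()


def _minimal_orbitals(state: str) -> tuple[dict, dict, int]:
    """Tiny consistent orbital block for energy-bookkeeping records."""
    if state == "neutral":
        return {"alpha": [-0.5, 0.1]}, {"alpha": [2.0, 0.0]}, 1
    return (
        {"alpha": [-0.5, -0.1], "beta": [-0.5, 0.1]},
        {"alpha": [1.0, 1.0], "beta": [1.0, 0.0]},
        2,
    )


def make_species_quadruple(
    aea: float,
    vea: float,
    vde: float,
    zpve_neutral: float = 0.30,
    zpve_anion: float = 0.29,
    species_id: str = "synthetic",
    level_tag: str = "basis1",
    seed: Optional[int] = None,
) -> SpeciesQuadruple:
    """Four records whose attachment energies are exactly (aea, vea, vde) eV.

    Requires the physical ordering vea <= aea <= vde; the absolute energy
    origin is drawn from the seed so only differences are meaningful.
    """
    if not (vea <= aea <= vde):
        raise ValueError(f"need VEA <= AEA <= VDE, got ({aea}, {vea}, {vde})")
    if zpve_neutral < 0 or zpve_anion < 0:
        raise ValueError("ZPVE must be non-negative")
    rng = _rng(seed)
    e_neutral = float(rng.uniform(-900.0, -300.0))
    aea_ha, vea_ha, vde_ha = (ev_to_hartree(x) for x in (aea, vea, vde))
    # Invert the defining differences (E = E_elec + ZPVE at stationary points)
    e_anion = e_neutral + zpve_neutral - zpve_anion - aea_ha
    e_anion_vert = e_neutral - vea_ha
    e_neutral_vert = e_anion + vde_ha

    def rec(state: str, tag: str, e_elec: float, zpve: Optional[float]):
        energies, occupations, mult = _minimal_orbitals(state)
        return ElectronicStructureRecord(
            species_id=species_id,
            charge=0 if state == "neutral" else -1,
            multiplicity=mult,
            state=state,
            geometry_tag=tag,
            level_tag=level_tag,
            e_elec_hartree=e_elec,
            orbital_energies=energies,
            occupations=occupations,
            zpve_hartree=zpve,
            n_imaginary_freq=0 if zpve is not None else None,
        ).validate()

    return SpeciesQuadruple(
        neutral_opt=rec("neutral", "opt_neutral", e_neutral, zpve_neutral),
        anion_opt=rec("anion", "opt_anion", e_anion, zpve_anion),
        anion_vertical=rec("anion", "vertical_at_neutral", e_anion_vert, None),
        neutral_vertical=rec("neutral", "vertical_at_anion", e_neutral_vert, None),
    ).validate()


def make_population_pair(f_plus: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Charge vectors for the N- and (N+1)-electron systems realizing f+.

    The neutral system is given zero atomic charges; the anion carries
    charge -f+_k on atom k, so the finite difference recovers f+ exactly.
    """
    f = np.asarray(f_plus, dtype=float)
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"f+ must sum to 1, got {f.sum()}")
    charges_n = np.zeros_like(f)
    return charges_n, charges_n - f


def make_spin_populations(
    p_plus: np.ndarray, seed: Optional[int] = None, jitter: float = 0.0
) -> np.ndarray:
    """Doublet-anion spin populations realizing a target Parr vector.

    Optional seeded jitter perturbs entries while preserving the unit sum,
    emulating population-analysis round-off.
    """
    p = np.asarray(p_plus, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"P+ must sum to 1, got {p.sum()}")
    if jitter > 0:
        rng = _rng(seed)
        noise = rng.normal(0.0, jitter, p.size)
        noise -= noise.mean()  # keep the sum exactly
        p = p + noise
    return p


def make_hammett_series(
    slope: float,
    intercept: float,
    noise_sd: float = 0.0,
    sigma_table: Optional[dict[str, float]] = None,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(sigma, y) points with y = slope*sigma + intercept + N(0, noise_sd)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    table = DEFAULT_SIGMA_P if sigma_table is None else sigma_table
    sigma = np.array(list(table.values()), dtype=float)
    rng = _rng(seed)
    y = slope * sigma + intercept
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, sigma.size)
    return sigma, y


def _data_path(name: str):
    return resources.files("cdftkit.data").joinpath(name)


def load_fixture(name: str):
    """Load a packaged fixture by name.

    ``table1``..``table4`` return DataFrames of the transcribed printed
    values; ``toy_enone_xyz`` returns (geometry, comment) with C7/C8/C9/O9
    site labels applied; ``mock_wavefunction`` returns a validated
    :class:`WavefunctionData`.
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {_FIXTURES}")
    if name.startswith("table"):
        df = pd.read_csv(_data_path(f"{name}.csv"), dtype={"compound": str})
        return df
    if name == "toy_enone_xyz":
        with resources.as_file(_data_path("toy_enone.xyz")) as p:
            geometry, comment = read_xyz(p)
        for atom, label in zip(geometry[:4], ("C7", "C8", "C9", "O9")):
            atom.label = label
        return geometry, comment
    payload = json.loads(_data_path("mock_wavefunction.json").read_text())
    wf = WavefunctionData(
        mo_coefficients={k: np.asarray(v, float) for k, v in payload["mo_coefficients"].items()},
        overlap=np.asarray(payload["overlap"], float),
        density={k: np.asarray(v, float) for k, v in payload["density"].items()},
        basis_to_atom=[int(x) for x in payload["basis_to_atom"]],
    )
    wf.validate()
    return wf


def fixture_digest(name: str) -> str:
    """SHA-256 of a packaged fixture file (pins table transcriptions)."""
    import hashlib

    fname = {"toy_enone_xyz": "toy_enone.xyz", "mock_wavefunction": "mock_wavefunction.json"}.get(
        name, f"{name}.csv"
    )
    return hashlib.sha256(_data_path(fname).read_bytes()).hexdigest()
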