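"""Readers and writers: record JSON, report-table CSV dialects, XYZ.

Three CSV dialects mirror the three report tables of the analysis:

* ``table2`` — frontier-orbital energies and global indices, 2 decimals;
* ``table3`` — attachment energies in tidy form (one row per compound and
  level of theory), 3 decimals;
* ``table4`` — condensed site indices at the two electrophilic carbons,
  3 decimals.

Absent optional fields serialize as JSON nulls, never as zeros: zero is a
meaningful population or energy value.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any, Iterable, Mapping, Union

import numpy as np
import pandas as pd

from .records import (
    AtomRecord,
    ElectronicStructureRecord,
    RecordValidationError,
    WavefunctionData,
)
from .units import report_round

PathLike = Union[str, Path]

TABLE_DIALECTS: dict[str, tuple[tuple[str, ...], int]] = {
    "table2": (
        ("compound", "homo_ev", "lumo_ev", "gap_ev", "mu_ev", "eta_ev", "omega_ev"),
        2,
    ),
    "table3": (("compound", "level_tag", "aea_ev", "vea_ev", "vde_ev"), 3),
    "table4": (
        ("compound", "f_plus_c7", "f_plus_c9", "p_plus_c7", "p_plus_c9"),
        3,
    ),
}


class RecordParseError(ValueError):
    """The JSON payload does not conform to the record schema."""


# ---------------------------------------------------------------------------
# record JSON
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = (
    "species_id",
    "charge",
    "multiplicity",
    "state",
    "geometry_tag",
    "level_tag",
    "e_elec_hartree",
    "orbitals",
)


def record_to_dict(rec: ElectronicStructureRecord) -> dict[str, Any]:
    d: dict[str, Any] = {
        "species_id": rec.species_id,
        "charge": rec.charge,
        "multiplicity": rec.multiplicity,
        "state": rec.state,
        "geometry_tag": rec.geometry_tag,
        "level_tag": rec.level_tag,
        "e_elec_hartree": rec.e_elec_hartree,
        "zpve_hartree": rec.zpve_hartree,
        "orbitals": {
            spin: {
                "energies_hartree": list(map(float, rec.orbital_energies[spin])),
                "occupations": list(map(float, rec.occupations[spin])),
            }
            for spin in rec.orbital_energies
        },
        "n_imaginary_freq": rec.n_imaginary_freq,
        "geometry": [
            {
                "index": a.index,
                "element": a.element,
                "z": a.z,
                "xyz_angstrom": list(a.xyz),
                "label": a.label,
                "fragment": a.fragment,
            }
            for a in rec.geometry
        ],
        "wavefunction": None,
        "atomic_charges": rec.atomic_charges,
        "atomic_spin_populations": rec.atomic_spin_populations,
    }
    if rec.wavefunction is not None:
        wf = rec.wavefunction
        d["wavefunction"] = {
            "mo_coefficients": {k: np.asarray(v).tolist() for k, v in wf.mo_coefficients.items()},
            "overlap": np.asarray(wf.overlap).tolist(),
            "density": {k: np.asarray(v).tolist() for k, v in wf.density.items()},
            "basis_to_atom": list(wf.basis_to_atom),
        }
    return d


def record_from_dict(d: Mapping[str, Any]) -> ElectronicStructureRecord:
    missing = [k for k in _REQUIRED_KEYS if k not in d]
    if missing:
        raise RecordParseError(f"missing required keys: {missing}")
    orbitals = d["orbitals"]
    if not isinstance(orbitals, Mapping) or not orbitals:
        raise RecordParseError("'orbitals' must be a non-empty spin->channel map")
    energies: dict[str, list[float]] = {}
    occupations: dict[str, list[float]] = {}
    for spin, chan in orbitals.items():
        try:
            energies[spin] = [float(x) for x in chan["energies_hartree"]]
            occupations[spin] = [float(x) for x in chan["occupations"]]
        except (KeyError, TypeError) as exc:
            raise RecordParseError(f"malformed orbital channel {spin!r}: {exc}") from exc
    geometry = []
    for g in d.get("geometry") or []:
        try:
            geometry.append(
                AtomRecord(
                    index=int(g["index"]),
                    element=str(g["element"]),
                    z=int(g["z"]),
                    xyz=tuple(float(x) for x in g["xyz_angstrom"]),
                    label=g.get("label"),
                    fragment=g.get("fragment"),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise RecordParseError(f"malformed geometry entry: {exc}") from exc
    wavefunction = None
    wf = d.get("wavefunction")
    if wf is not None:
        try:
            wavefunction = WavefunctionData(
                mo_coefficients={k: np.asarray(v, float) for k, v in wf["mo_coefficients"].items()},
                overlap=np.asarray(wf["overlap"], float),
                density={k: np.asarray(v, float) for k, v in wf["density"].items()},
                basis_to_atom=[int(x) for x in wf["basis_to_atom"]],
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise RecordParseError(f"malformed wavefunction block: {exc}") from exc
    try:
        rec = ElectronicStructureRecord(
            species_id=str(d["species_id"]),
            charge=int(d["charge"]),
            multiplicity=int(d["multiplicity"]),
            state=str(d["state"]),
            geometry_tag=str(d["geometry_tag"]),
            level_tag=str(d["level_tag"]),
            e_elec_hartree=float(d["e_elec_hartree"]),
            orbital_energies=energies,
            occupations=occupations,
            zpve_hartree=None if d.get("zpve_hartree") is None else float(d["zpve_hartree"]),
            n_imaginary_freq=(
                None if d.get("n_imaginary_freq") is None else int(d["n_imaginary_freq"])
            ),
            geometry=geometry,
            wavefunction=wavefunction,
            atomic_charges=(
                None if d.get("atomic_charges") is None
                else [float(x) for x in d["atomic_charges"]]
            ),
            atomic_spin_populations=(
                None if d.get("atomic_spin_populations") is None
                else [float(x) for x in d["atomic_spin_populations"]]
            ),
        )
    except (TypeError, ValueError) as exc:
        raise RecordParseError(str(exc)) from exc
    return rec.validate()


def read_record(path: PathLike) -> ElectronicStructureRecord:
    """Read and validate one record JSON file."""
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise RecordParseError(f"{path}: invalid JSON: {exc}") from exc
    return record_from_dict(payload)


def write_record(rec: ElectronicStructureRecord, path: PathLike) -> None:
    rec.validate()
    with open(path, "w") as fh:
        json.dump(record_to_dict(rec), fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def write_table(rows: Iterable[Mapping[str, Any]], dialect: str, path: PathLike) -> None:
    """Write report rows as CSV in a fixed table dialect.

    Every row must carry exactly the dialect's columns; numeric columns are
    formatted at the dialect's reporting precision with ties rounded away
    from zero.
    """
    if dialect not in TABLE_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    columns, digits = TABLE_DIALECTS[dialect]
    lines = [",".join(columns)]
    for row in rows:
        if set(row) != set(columns):
            raise ValueError(
                f"row columns {sorted(row)} do not match dialect {dialect}: {columns}"
            )
        cells = []
        for col in columns:
            v = row[col]
            if isinstance(v, (int, float)) and not isinstance(v, bool) and col not in (
                "compound",
            ):
                if math.isfinite(v):
                    cells.append(f"{report_round(float(v), digits):.{digits}f}")
                else:
                    cells.append("")  # absent value, never fabricated as zero
            else:
                cells.append(str(v))
        lines.append(",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def read_table(path: PathLike, dialect: str) -> pd.DataFrame:
    """Read a dialect CSV back into a DataFrame, checking the header."""
    if dialect not in TABLE_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    columns, _ = TABLE_DIALECTS[dialect]
    df = pd.read_csv(path, dtype={"compound": str, "level_tag": str})
    if tuple(df.columns) != columns:
        raise ValueError(f"header {tuple(df.columns)} != {columns}")
    return df


# ---------------------------------------------------------------------------
# XYZ geometries
# ---------------------------------------------------------------------------

_ELEMENT_Z = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Br": 35, "I": 53,
}


def write_xyz(geometry: list[AtomRecord], path: PathLike, comment: str = "") -> None:
    lines = [str(len(geometry)), comment]
    for a in sorted(geometry, key=lambda a: a.index):
        x, y, z = a.xyz
        lines.append(f"{a.element:2s} {x:18.10f} {y:18.10f} {z:18.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path: PathLike) -> tuple[list[AtomRecord], str]:
    """Read an XYZ file; returns (geometry, comment line)."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2:
        raise RecordParseError(f"{path}: truncated XYZ")
    try:
        n = int(lines[0].strip())
    except ValueError as exc:
        raise RecordParseError(f"{path}: bad atom count line") from exc
    comment = lines[1]
    atoms = []
    for i, line in enumerate(lines[2 : 2 + n], start=1):
        parts = line.split()
        if len(parts) < 4:
            raise RecordParseError(f"{path}: short XYZ line {i}")
        el = parts[0]
        atoms.append(
            AtomRecord(
                index=i,
                element=el,
                z=_ELEMENT_Z.get(el, 1),
                xyz=(float(parts[1]), float(parts[2]), float(parts[3])),
            )
        )
    if len(atoms) != n:
        raise RecordParseError(f"{path}: expected {n} atoms, found {len(atoms)}")
    return atoms, comment


# ---------------------------------------------------------------------------
# adapter from parsed quantum-chemistry output
# ---------------------------------------------------------------------------

def ingest_parsed_output(parsed: Any, **overrides: Any) -> ElectronicStructureRecord:
    """Build a record from a cclib-style parsed payload.

    The payload may be any object (or mapping) exposing the usual parsed
    attributes: ``scfenergies`` (eV, last point used), ``moenergies``
    (per-spin, eV), ``homos`` (per-spin index of highest occupied MO),
    optionally ``zpve`` (Hartree), ``atomnos``, ``atomcoords`` and
    ``mocoeffs``/``aooverlaps``. Fields absent in the payload are left
    absent in the record — never fabricated as zeros.

    Keyword overrides supply bookkeeping the log file cannot know
    (``species_id``, ``state``, ``geometry_tag``, ``level_tag`` ...).
    """
    from .units import ev_to_hartree

    def get(name: str, default: Any = None) -> Any:
        if isinstance(parsed, Mapping):
            return parsed.get(name, default)
        return getattr(parsed, name, default)

    moenergies = get("moenergies")
    if moenergies is None:
        raise RecordParseError("payload lacks orbital energies ('moenergies')")
    homos = get("homos")
    if homos is None:
        raise RecordParseError("payload lacks occupation information ('homos')")
    scf = get("scfenergies")
    if scf is None:
        raise RecordParseError("payload lacks SCF energy ('scfenergies')")
    e_elec = ev_to_hartree(float(np.atleast_1d(scf)[-1]))

    spins = ["alpha", "beta"][: len(moenergies)]
    energies: dict[str, list[float]] = {}
    occupations: dict[str, list[float]] = {}
    occ_per_orbital = 2.0 if len(spins) == 1 else 1.0
    for spin, eps, homo in zip(spins, moenergies, np.atleast_1d(homos)):
        eps_h = [ev_to_hartree(float(e)) for e in eps]
        energies[spin] = eps_h
        occupations[spin] = [
            occ_per_orbital if i <= int(homo) else 0.0 for i in range(len(eps_h))
        ]

    geometry: list[AtomRecord] = []
    atomnos = get("atomnos")
    atomcoords = get("atomcoords")
    if atomnos is not None and atomcoords is not None:
        coords = np.asarray(atomcoords)[-1]
        z_to_el = {z: el for el, z in _ELEMENT_Z.items()}
        for i, (z, xyz) in enumerate(zip(atomnos, coords), start=1):
            geometry.append(
                AtomRecord(
                    index=i,
                    element=z_to_el.get(int(z), "X"),
                    z=int(z),
                    xyz=tuple(float(c) for c in xyz),
                )
            )

    wavefunction = None
    mocoeffs = get("mocoeffs")
    aooverlaps = get("aooverlaps")
    basis_to_atom = get("basis_to_atom")
    if mocoeffs is not None and aooverlaps is not None and basis_to_atom is not None:
        # cclib stores MO coefficients as rows; transpose to columns.
        coeffs = {s: np.asarray(c, float).T for s, c in zip(spins, mocoeffs)}
        density = {}
        for spin in spins:
            occ = np.asarray(occupations[spin])
            C = coeffs[spin]
            density[spin] = (C * occ) @ C.T
        wavefunction = WavefunctionData(
            mo_coefficients=coeffs,
            overlap=np.asarray(aooverlaps, float),
            density=density,
            basis_to_atom=[int(x) for x in basis_to_atom],
        )

    zpve = get("zpve")
    fields: dict[str, Any] = dict(
        species_id=str(get("species_id", "unknown")),
        charge=int(get("charge", 0)),
        multiplicity=int(get("mult", get("multiplicity", 1))),
        state="neutral",
        geometry_tag="opt_neutral",
        level_tag="other",
        e_elec_hartree=e_elec,
        orbital_energies=energies,
        occupations=occupations,
        zpve_hartree=None if zpve is None else float(zpve),
        geometry=geometry,
        wavefunction=wavefunction,
    )
    fields.update(overrides)
    return ElectronicStructureRecord(**fields).validate()
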