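"""Record schema validation, JSON/CSV/XYZ round-trips, parsed-output ingestion."""

import json

import numpy as np
import pytest

from cdftkit.io import (
    RecordParseError,
    ingest_parsed_output,
    read_record,
    read_table,
    read_xyz,
    record_from_dict,
    record_to_dict,
    write_record,
    write_table,
    write_xyz,
)
from cdftkit.records import AtomRecord, ElectronicStructureRecord, RecordValidationError
from cdftkit.synthetic import make_orbital_record


def minimal_record(**overrides):
    fields = dict(
        species_id="1",
        charge=0,
        multiplicity=1,
        state="neutral",
        geometry_tag="opt_neutral",
        level_tag="basis1",
        e_elec_hartree=-100.0,
        orbital_energies={"alpha": [-0.5, 0.1]},
        occupations={"alpha": [2.0, 0.0]},
    )
    fields.update(overrides)
    return ElectronicStructureRecord(**fields)


def test_minimal_record_validates():
    rec = minimal_record().validate()
    assert rec.closed_shell
    assert rec.n_electrons == 2.0


@pytest.mark.parametrize(
    "overrides, violation",
    [
        (dict(state="cation"), "bad_state"),
        (dict(geometry_tag="somewhere"), "bad_geometry_tag"),
        (dict(state="anion", geometry_tag="opt_anion"), "anion_charge"),
        (dict(charge=-1), "neutral_charge"),
        (dict(zpve_hartree=-0.1), "negative_zpve"),
        (dict(orbital_energies={"alpha": [0.1, -0.5]}), "orbital_energies_unsorted"),
        (dict(occupations={"alpha": [2.5, 0.0]}), "occupation_range"),
        (dict(occupations={"alpha": [2.0]}), "orbital_length_mismatch"),
        (dict(orbital_energies={}, occupations={}), "no_orbitals"),
        (
            dict(geometry=[AtomRecord(1, "He", 2, (0, 0, 0)),
                           AtomRecord(1, "He", 2, (1, 0, 0))]),
            "duplicate_atom_index",
        ),
        (
            dict(geometry=[AtomRecord(1, "C", 6, (0, 0, 0))]),
            "electron_count",  # 2 electrons in occupations vs Z=6
        ),
    ],
)
def test_named_validation_failures(overrides, violation):
    with pytest.raises(RecordValidationError) as err:
        minimal_record(**overrides).validate()
    assert err.value.violation == violation


def test_open_shell_occupation_range():
    rec = minimal_record(
        state="anion", charge=-1, geometry_tag="opt_anion", multiplicity=2,
        orbital_energies={"alpha": [-0.5, -0.1], "beta": [-0.5, 0.1]},
        occupations={"alpha": [1.0, 1.0], "beta": [2.0, 0.0]},
    )
    with pytest.raises(RecordValidationError) as err:
        rec.validate()
    assert err.value.violation == "occupation_range"  # per-spin limit is 1


def test_record_json_round_trip(tmp_path):
    rec = make_orbital_record(-6.01, -2.09, n_occupied=4, seed=3)
    rec.geometry = [
        AtomRecord(1, "He", 2, (0.0, 0.0, 0.0), label="C7", fragment="exo_alkene"),
        AtomRecord(2, "He", 2, (1.1, 0.0, 0.0), label="C9", fragment="exo_alkene"),
        AtomRecord(3, "He", 2, (2.2, 0.0, 0.0)),
        AtomRecord(4, "He", 2, (3.3, 0.0, 0.0)),
    ]
    path = tmp_path / "rec.json"
    write_record(rec, path)
    back = read_record(path)
    assert record_to_dict(back) == record_to_dict(rec)


def test_read_record_missing_energy_is_parse_error(tmp_path):
    payload = record_to_dict(minimal_record())
    del payload["e_elec_hartree"]
    path = tmp_path / "broken.json"
    path.write_text(json.dumps(payload))
    with pytest.raises(RecordParseError):
        read_record(path)


def test_absent_fields_stay_null_not_zero():
    d = record_to_dict(minimal_record())
    assert d["zpve_hartree"] is None
    assert d["wavefunction"] is None
    assert d["atomic_charges"] is None
    rec = record_from_dict(d)
    assert rec.zpve_hartree is None


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def test_table2_row_formatting(tmp_path):
    row = {
        "compound": "1", "homo_ev": -6.01, "lumo_ev": -2.09, "gap_ev": 3.92,
        "mu_ev": -4.05, "eta_ev": 1.96, "omega_ev": 4.1843,
    }
    path = tmp_path / "t2.csv"
    write_table([row], "table2", path)
    lines = path.read_text().splitlines()
    assert lines[0] == "compound,homo_ev,lumo_ev,gap_ev,mu_ev,eta_ev,omega_ev"
    assert lines[1] == "1,-6.01,-2.09,3.92,-4.05,1.96,4.18"


def test_empty_table_is_header_only(tmp_path):
    path = tmp_path / "t3.csv"
    write_table([], "table3", path)
    assert path.read_text() == "compound,level_tag,aea_ev,vea_ev,vde_ev\n"


def test_table3_round_trip(tmp_path, rng):
    rows = [
        {
            "compound": str(i + 1), "level_tag": "basis1",
            "aea_ev": round(float(rng.uniform(0, 2)), 3),
            "vea_ev": round(float(rng.uniform(0, 2)), 3),
            "vde_ev": round(float(rng.uniform(0, 2)), 3),
        }
        for i in range(12)
    ]
    path = tmp_path / "t3.csv"
    write_table(rows, "table3", path)
    df = read_table(path, "table3")
    for row, (_, got) in zip(rows, df.iterrows()):
        assert got["aea_ev"] == pytest.approx(row["aea_ev"], abs=5e-4)
        assert got["vea_ev"] == pytest.approx(row["vea_ev"], abs=5e-4)


def test_column_mismatch_rejected(tmp_path):
    with pytest.raises(ValueError, match="columns"):
        write_table([{"compound": "1", "bogus": 1.0}], "table4", tmp_path / "x.csv")


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def test_xyz_round_trip(tmp_path):
    atoms = [
        AtomRecord(1, "C", 6, (0.0, 0.0, 0.0)),
        AtomRecord(2, "O", 8, (1.22, 0.0, 0.0)),
        AtomRecord(3, "H", 1, (-0.6, 0.9, 0.0)),
    ]
    path = tmp_path / "geom.xyz"
    write_xyz(atoms, path, comment="species_id=1 geometry_tag=opt_neutral")
    back, comment = read_xyz(path)
    assert comment == "species_id=1 geometry_tag=opt_neutral"
    assert [a.element for a in back] == ["C", "O", "H"]
    for a, b in zip(atoms, back):
        assert np.allclose(a.xyz, b.xyz, atol=1e-9)


# ---------------------------------------------------------------------------
# parsed-output ingestion
# ---------------------------------------------------------------------------

def test_ingest_energies_only():
    payload = {
        "scfenergies": [-2721.1386245988],  # eV, = -100 Hartree
        "moenergies": [[-13.6, 2.7]],
        "homos": [0],
    }
    rec = ingest_parsed_output(payload, species_id="x")
    assert rec.wavefunction is None
    assert rec.zpve_hartree is None
    assert rec.e_elec_hartree == pytest.approx(-100.0, abs=1e-9)
    assert rec.closed_shell
    assert rec.occupations["alpha"] == [2.0, 0.0]


def test_ingest_two_spin_channels():
    payload = {
        "scfenergies": [-27.211386245988],
        "moenergies": [[-13.6, -2.7, 2.7], [-13.0, 2.0, 3.0]],
        "homos": [1, 0],
        "charge": -1,
        "mult": 2,
    }
    rec = ingest_parsed_output(payload, species_id="y", state="anion",
                               geometry_tag="vertical_at_neutral")
    assert set(rec.orbital_energies) == {"alpha", "beta"}
    assert rec.occupations["alpha"] == [1.0, 1.0, 0.0]
    assert rec.occupations["beta"] == [1.0, 0.0, 0.0]


def test_ingest_requires_orbitals():
    with pytest.raises(RecordParseError, match="orbital energies"):
        ingest_parsed_output({"scfenergies": [-1.0], "homos": [0]})


def test_ingest_matches_hand_built_reference():
    payload = {
        "scfenergies": [-2721.1386245988],
        "moenergies": [[-16.32683174759280, -13.60569312299400, 2.72113862459880]],
        "homos": [1],
        "species_id": "ref",
    }
    rec = ingest_parsed_output(payload)
    ref = ElectronicStructureRecord(
        species_id="ref", charge=0, multiplicity=1, state="neutral",
        geometry_tag="opt_neutral", level_tag="other", e_elec_hartree=-100.0,
        orbital_energies={"alpha": [-0.6, -0.5, 0.1]},
        occupations={"alpha": [2.0, 2.0, 0.0]},
    )
    assert rec.occupations == ref.occupations
    assert np.allclose(rec.orbital_energies["alpha"],
                       ref.orbital_energies["alpha"], atol=1e-12)
    assert rec.e_elec_hartree == pytest.approx(ref.e_elec_hartree, abs=1e-9)
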