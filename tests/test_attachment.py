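"""Attachment-energy bookkeeping: ZPVE handling, bounds, sign flags, round-trips."""

import numpy as np
import pytest

from cdftkit.attachment import (
    attachment_energies,
    check_bounds,
    composite_energy,
    corrected_energy,
    sign_interpretation,
)
from cdftkit.records import AttachmentEnergies, ElectronicStructureRecord
from cdftkit.synthetic import load_fixture, make_species_quadruple
from cdftkit.units import ev_to_hartree


def bare_record(state, tag, e_elec, zpve=None, level="basis1", sid="q"):
    if state == "neutral":
        orbitals = {"alpha": [-0.5, 0.1]}
        occ = {"alpha": [2.0, 0.0]}
        charge, mult = 0, 1
    else:
        orbitals = {"alpha": [-0.5, -0.1], "beta": [-0.5, 0.1]}
        occ = {"alpha": [1.0, 1.0], "beta": [1.0, 0.0]}
        charge, mult = -1, 2
    return ElectronicStructureRecord(
        species_id=sid, charge=charge, multiplicity=mult, state=state,
        geometry_tag=tag, level_tag=level, e_elec_hartree=e_elec,
        orbital_energies=orbitals, occupations=occ, zpve_hartree=zpve,
        n_imaginary_freq=0 if zpve is not None else None,
    ).validate()


def quadruple(en, ea, eav, env, zn=0.1, za=0.098):
    from cdftkit.attachment import SpeciesQuadruple

    return SpeciesQuadruple(
        neutral_opt=bare_record("neutral", "opt_neutral", en, zn),
        anion_opt=bare_record("anion", "opt_anion", ea, za),
        anion_vertical=bare_record("anion", "vertical_at_neutral", eav),
        neutral_vertical=bare_record("neutral", "vertical_at_anion", env),
    )


def test_corrected_energy_stationary_and_vertical():
    assert corrected_energy(bare_record("neutral", "opt_neutral", -100.0, 0.1)) == -99.9
    assert corrected_energy(
        bare_record("anion", "vertical_at_neutral", -100.04)
    ) == -100.04


def test_corrected_energy_requires_zpve_at_stationary_points():
    rec = bare_record("neutral", "opt_neutral", -100.0, 0.1)
    rec.zpve_hartree = None
    with pytest.raises(ValueError, match="ZPVE"):
        corrected_energy(rec)


def test_composite_energy():
    assert composite_energy(-100.5, 0.1) == pytest.approx(-100.4, abs=1e-12)
    assert composite_energy(0.0, 0.0) == 0.0


def test_hand_arithmetic_quadruple():
    """AEA 0.042 Ha, VEA 0.030 Ha, VDE 0.045 Ha, converted by hand."""
    q = quadruple(-100.0, -100.04, -100.03, -99.995, zn=0.1, za=0.098)
    ae = attachment_energies(q)
    assert ae.aea == pytest.approx(0.042 * 27.211386245988, abs=1e-9)   # 1.142878...
    assert ae.vea == pytest.approx(0.030 * 27.211386245988, abs=1e-9)   # 0.816342...
    assert ae.vde == pytest.approx(0.045 * 27.211386245988, abs=1e-9)   # 1.224512...


def test_identical_energies_give_zero():
    q = quadruple(-100.0, -100.0, -100.0, -100.0, zn=0.1, za=0.1)
    ae = attachment_energies(q)
    assert (ae.aea, ae.vea, ae.vde) == (0.0, 0.0, 0.0)


def test_quadruple_consistency_enforced():
    q = quadruple(-100.0, -100.04, -100.03, -99.995)
    q.anion_opt.species_id = "other"
    with pytest.raises(ValueError, match="mismatch"):
        attachment_energies(q)


def test_vertical_records_must_not_carry_zpve():
    q = quadruple(-100.0, -100.04, -100.03, -99.995)
    q.anion_vertical.zpve_hartree = 0.05
    with pytest.raises(ValueError, match="vertical"):
        q.validate()


def test_imaginary_frequencies_rejected():
    q = quadruple(-100.0, -100.04, -100.03, -99.995)
    q.neutral_opt.n_imaginary_freq = 1
    with pytest.raises(ValueError, match="imaginary"):
        q.validate()


def test_aea_invariant_under_common_energy_shift():
    q1 = quadruple(-100.0, -100.04, -100.03, -99.995)
    q2 = quadruple(-150.0, -150.04, -150.03, -149.995)
    a1, a2 = attachment_energies(q1), attachment_energies(q2)
    assert a1.aea == pytest.approx(a2.aea, abs=1e-9)
    assert a1.vea == pytest.approx(a2.vea, abs=1e-9)
    assert a1.vde == pytest.approx(a2.vde, abs=1e-9)


def test_generator_round_trip_recovers_targets(rng):
    """100 seeded synthetic quadruples recover prescribed (AEA, VEA, VDE) to 1e-9 eV."""
    for k in range(100):
        vea = float(rng.uniform(-0.5, 2.0))
        aea = vea + float(rng.uniform(0.0, 0.5))
        vde = aea + float(rng.uniform(0.0, 0.5))
        q = make_species_quadruple(
            aea, vea, vde,
            zpve_neutral=float(rng.uniform(0.05, 0.4)),
            zpve_anion=float(rng.uniform(0.05, 0.4)),
            seed=k,
        )
        ae = attachment_energies(q)
        assert ae.aea == pytest.approx(aea, abs=1e-9)
        assert ae.vea == pytest.approx(vea, abs=1e-9)
        assert ae.vde == pytest.approx(vde, abs=1e-9)
        assert check_bounds(ae) == "holds"


def test_composite_level_shift_recovered():
    """A prescribed basis-2 vs basis-1 AEA shift survives the bookkeeping."""
    shift = 0.466  # eV
    q1 = make_species_quadruple(0.932, 0.791, 1.059, seed=5, level_tag="basis1")
    q2 = make_species_quadruple(0.932 + shift, 0.791, 1.059 + shift,
                                seed=6, level_tag="basis2_composite")
    d = attachment_energies(q2).aea - attachment_energies(q1).aea
    assert d == pytest.approx(shift, abs=1e-9)


# ---------------------------------------------------------------------------
# bounds and signs
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "triple, expected",
    [
        ((0.932, 0.791, 1.059), "holds"),       # reference compound values
        ((1.0, 1.0, 1.0), "holds"),             # degenerate
        ((0.5, 0.6, 0.7), "violated_lower"),
        ((0.8, 0.6, 0.7), "violated_upper"),
    ],
)
def test_check_bounds(triple, expected):
    aea, vea, vde = triple
    assert check_bounds(AttachmentEnergies(aea=aea, vea=vea, vde=vde)) == expected


def test_fixture_bounds_flags_only_documented_misprint():
    t3 = load_fixture("table3")
    flagged = []
    for row in t3.itertuples(index=False):
        ae = AttachmentEnergies(aea=float(row.aea_ev), vea=float(row.vea_ev),
                                vde=float(row.vde_ev), level_tag=str(row.level_tag))
        if check_bounds(ae) != "holds":
            flagged.append((str(row.compound), str(row.level_tag)))
    assert flagged == [("5", "basis2_composite")]


@pytest.mark.parametrize(
    "triple, flags",
    [
        ((0.932, 0.791, 1.059), (True, True, True)),
        ((-0.1, -0.2, 0.05), (False, False, True)),
        ((0.0, 0.0, 0.0), (False, False, False)),  # strict positivity
    ],
)
def test_sign_interpretation(triple, flags):
    aea, vea, vde = triple
    out = sign_interpretation(AttachmentEnergies(aea=aea, vea=vea, vde=vde))
    assert (
        out["stable_anion"],
        out["favorable_vertical_attachment"],
        out["autodetachment_unlikely"],
    ) == flags
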