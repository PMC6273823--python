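"""Small shared builders for test records."""

from cdftkit.records import ElectronicStructureRecord
from cdftkit.units import ev_to_hartree


def minimal_closed_shell(energies_ev, occupations, **overrides):
    fields = dict(
        species_id="test",
        charge=0,
        multiplicity=1,
        state="neutral",
        geometry_tag="opt_neutral",
        level_tag="basis1",
        e_elec_hartree=-100.0,
        orbital_energies={"alpha": [ev_to_hartree(e) for e in energies_ev]},
        occupations={"alpha": list(occupations)},
    )
    fields.update(overrides)
    return ElectronicStructureRecord(**fields).validate()
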