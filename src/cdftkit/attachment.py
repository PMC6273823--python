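"""Electron attachment and detachment energetics.

From four electronic-structure records per species — optimized neutral,
optimized radical anion, and the two vertical cross points — the three
standard quantities are

    AEA = E(optimized neutral) - E(optimized anion)          (adiabatic)
    VEA = E(neutral) - E(anion at the neutral's geometry)    (vertical)
    VDE = E(neutral at the anion's geometry) - E(anion)      (vertical)

where E = E_elec + ZPVE at stationary points. Vertical points are not
stationary (no vibrational frequencies exist there), so vertical
differences use electronic energies only; this is equivalent to assigning
each vertical species the ZPVE of its stationary parent, which then
cancels.

Positive AEA means the relaxed anion lies below the neutral; positive VDE
means vertical electron autodetachment from the anion is uphill. VEA and
VDE bracket AEA whenever neutral and anion geometries are similar — the
bound is checked, not assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import AttachmentEnergies, ElectronicStructureRecord
from .units import hartree_to_ev

#: Slack (eV) on the VEA <= AEA <= VDE check; pure float noise, three
#: orders of magnitude below the 1e-3 eV reporting precision.
BOUNDS_SLACK_EV = 1e-9


@dataclass
class SpeciesQuadruple:
    """The four records feeding one compound's attachment energies."""

    neutral_opt: ElectronicStructureRecord
    anion_opt: ElectronicStructureRecord
    anion_vertical: ElectronicStructureRecord
    neutral_vertical: ElectronicStructureRecord

    def validate(self) -> "SpeciesQuadruple":
        members = {
            "neutral_opt": (self.neutral_opt, "neutral", "opt_neutral"),
            "anion_opt": (self.anion_opt, "anion", "opt_anion"),
            "anion_vertical": (self.anion_vertical, "anion", "vertical_at_neutral"),
            "neutral_vertical": (self.neutral_vertical, "neutral", "vertical_at_anion"),
        }
        sid = self.neutral_opt.species_id
        level = self.neutral_opt.level_tag
        for name, (rec, state, tag) in members.items():
            if rec.species_id != sid or rec.level_tag != level:
                raise ValueError(
                    f"{name}: species/level mismatch "
                    f"({rec.species_id}/{rec.level_tag} vs {sid}/{level})"
                )
            if rec.state != state or rec.geometry_tag != tag:
                raise ValueError(
                    f"{name}: expected state={state}, geometry_tag={tag}, "
                    f"got {rec.state}/{rec.geometry_tag}"
                )
        for name in ("neutral_opt", "anion_opt"):
            rec = members[name][0]
            if rec.zpve_hartree is None:
                raise ValueError(f"{name}: stationary record lacks ZPVE")
            if rec.n_imaginary_freq not in (None, 0):
                raise ValueError(
                    f"{name}: {rec.n_imaginary_freq} imaginary frequencies — not a minimum"
                )
        for name in ("anion_vertical", "neutral_vertical"):
            if members[name][0].zpve_hartree is not None:
                raise ValueError(f"{name}: vertical record must not carry ZPVE")
        return self


def corrected_energy(rec: ElectronicStructureRecord) -> float:
    """E = E_elec + ZPVE at stationary points, E_elec at vertical points (Hartree)."""
    if rec.geometry_tag in ("opt_neutral", "opt_anion"):
        if rec.zpve_hartree is None:
            raise ValueError(
                f"stationary record {rec.species_id}/{rec.geometry_tag} lacks ZPVE"
            )
        return rec.e_elec_hartree + rec.zpve_hartree
    return rec.e_elec_hartree


def composite_energy(e_elec_big: float, zpve_small: float) -> float:
    """Large-basis single-point energy corrected by a small-basis ZPVE (Hartree)."""
    return e_elec_big + zpve_small


def attachment_energies(q: SpeciesQuadruple) -> AttachmentEnergies:
    """AEA, VEA, VDE in eV from a validated quadruple."""
    q.validate()
    aea_ha = corrected_energy(q.neutral_opt) - corrected_energy(q.anion_opt)
    vea_ha = q.neutral_opt.e_elec_hartree - q.anion_vertical.e_elec_hartree
    vde_ha = q.neutral_vertical.e_elec_hartree - q.anion_opt.e_elec_hartree
    return AttachmentEnergies(
        aea=hartree_to_ev(aea_ha),
        vea=hartree_to_ev(vea_ha),
        vde=hartree_to_ev(vde_ha),
        level_tag=q.neutral_opt.level_tag,
    )


def check_bounds(ae: AttachmentEnergies, slack: float = BOUNDS_SLACK_EV) -> str:
    """Check VEA <= AEA <= VDE.

    Returns ``"holds"``, ``"violated_lower"`` (VEA > AEA) or
    ``"violated_upper"`` (AEA > VDE); a lower violation is reported first
    if both fail.
    """
    if ae.vea > ae.aea + slack:
        return "violated_lower"
    if ae.aea > ae.vde + slack:
        return "violated_upper"
    return "holds"


def sign_interpretation(ae: AttachmentEnergies) -> dict[str, bool]:
    """Qualitative stability flags from the signs (strict positivity)."""
    return {
        "stable_anion": ae.aea > 0,
        "favorable_vertical_attachment": ae.vea > 0,
        "autodetachment_unlikely": ae.vde > 0,
    }
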