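"""Condensed local reactivity indices and electrophilic site selectivity.

The condensed Fukui function for nucleophilic attack on atom k is the
finite difference of condensed atomic charges between the N- and
(N+1)-electron systems at the neutral geometry,

    f+_k = q_k(N) - q_k(N+1),

equivalently the gross-population gain on atom k when an electron is
added; it sums to 1 over atoms. The Parr function for nucleophilic attack
P+_k is the atomic spin density of the radical anion, which also sums to
1 for a doublet.

In an alpha,beta-unsaturated ketone C7=C8-C9=O9 the beta-carbon C7 hosts
conjugate (1,4) addition and the carbonyl carbon C9 direct (1,2) addition;
comparing f+ and P+ at the two sites predicts the preferred mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import CondensedSiteIndices

FUKUI_SUM_TOL = 1e-6
SPIN_SUM_TOL = 1e-3

#: |delta| below this counts as a tie (matches 3-decimal reporting).
SITE_TIE_TOL = 5e-4


def fukui_plus(
    charges_n: np.ndarray, charges_n_plus_1: np.ndarray
) -> np.ndarray:
    """Condensed f+ from atomic charges of the N- and (N+1)-electron systems.

    Both charge sets must be evaluated at the same (neutral) geometry; their
    totals must differ by exactly the one added electron.
    """
    qn = np.asarray(charges_n, dtype=float)
    qn1 = np.asarray(charges_n_plus_1, dtype=float)
    if qn.shape != qn1.shape:
        raise ValueError(f"length mismatch: {qn.shape} vs {qn1.shape}")
    dq = float(qn.sum() - qn1.sum())
    if abs(dq - 1.0) > FUKUI_SUM_TOL:
        raise ValueError(
            f"total charge difference {dq} != 1: not an (N, N+1) electron pair"
        )
    return qn - qn1


def parr_plus(
    spin_populations_anion: np.ndarray, renormalize: bool = True
) -> np.ndarray:
    """Condensed P+ from atomic spin populations of the doublet radical anion.

    The populations must sum to the one unpaired electron (tolerance 1e-3,
    absorbing population-analysis round-off); with ``renormalize`` they are
    rescaled to sum to exactly 1.
    """
    s = np.asarray(spin_populations_anion, dtype=float)
    total = float(s.sum())
    if abs(total - 1.0) > SPIN_SUM_TOL:
        raise ValueError(
            f"spin populations sum to {total}, expected 1 (doublet anion)"
        )
    return s / total if renormalize else s


@dataclass
class SiteSelectivity:
    """Outcome of comparing two electrophilic sites."""

    site_a: str
    site_b: str
    ordering: str          # "a_preferred" | "b_preferred" | "tie"
    delta_f: float         # f+(a) - f+(b)
    delta_p: float | None  # P+(a) - P+(b), None when P+ absent


def site_selectivity(
    idx: CondensedSiteIndices,
    site_a: str = "C7",
    site_b: str = "C9",
    tie_tol: float = SITE_TIE_TOL,
) -> SiteSelectivity:
    """Compare two labelled sites; the Fukui difference decides the ordering."""
    fa = idx.value("fukui_plus", site_a)
    fb = idx.value("fukui_plus", site_b)
    delta_f = fa - fb
    delta_p = None
    if idx.parr_plus is not None:
        delta_p = idx.value("parr_plus", site_a) - idx.value("parr_plus", site_b)
    if abs(delta_f) < tie_tol:
        ordering = "tie"
    elif delta_f > 0:
        ordering = "a_preferred"
    else:
        ordering = "b_preferred"
    return SiteSelectivity(
        site_a=site_a, site_b=site_b, ordering=ordering,
        delta_f=delta_f, delta_p=delta_p,
    )


def addition_mode_report(sel: SiteSelectivity) -> str:
    """Map C7-vs-C9 preference to a Michael addition mode.

    Preference for the beta-carbon (C7) means conjugate 1,4-addition;
    preference for the carbonyl carbon (C9) means direct 1,2-addition.
    """
    if {sel.site_a, sel.site_b} != {"C7", "C9"}:
        raise ValueError(
            f"addition modes defined for sites C7/C9, got {sel.site_a}/{sel.site_b}"
        )
    if sel.ordering == "tie":
        return "undetermined"
    preferred = sel.site_a if sel.ordering == "a_preferred" else sel.site_b
    return "mode_1_4" if preferred == "C7" else "mode_1_2"
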