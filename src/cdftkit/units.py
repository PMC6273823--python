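"""Unit conversion and reporting-precision policy.

All energies are carried in Hartree internally and converted to eV only at
the reporting boundary, so repeated conversions never accumulate error.
"""

from __future__ import annotations

import math
from decimal import Decimal, ROUND_HALF_UP

#: CODATA 2018 Hartree-to-electronvolt conversion factor (eV / E_h).
EV_PER_HARTREE: float = 27.211386245988


def hartree_to_ev(x: float) -> float:
    """Convert an energy from Hartree to electronvolt.

    Parameters
    ----------
    x : float
        Energy in Hartree. Must be finite.

    Returns
    -------
    float
        Energy in eV, ``x * 27.211386245988``.
    """
    if not math.isfinite(x):
        raise ValueError(f"non-finite energy: {x!r}")
    return x * EV_PER_HARTREE


def ev_to_hartree(x: float) -> float:
    """Inverse of :func:`hartree_to_ev`; round-trips within 1e-12 relative."""
    if not math.isfinite(x):
        raise ValueError(f"non-finite energy: {x!r}")
    return x / EV_PER_HARTREE


def report_round(x: float, digits: int) -> float:
    """Round to `digits` decimals, ties away from zero.

    Report tables print 2 decimals (global indices) or 3 decimals
    (attachment energies, condensed site indices); this is the single
    rounding rule used at every reporting boundary.
    """
    if digits not in (2, 3):
        raise ValueError(f"digits must be 2 or 3, got {digits}")
    q = Decimal(1).scaleb(-digits)
    # Decimal ROUND_HALF_UP rounds ties away from zero.
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
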