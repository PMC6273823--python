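"""Hammett linear free-energy relationships.

A descriptor (AEA, VEA, VDE, omega, ...) is regressed on the Hammett
substituent constant sigma_p by ordinary least squares,

    y = rho * sigma + c,        R^2 = Sxy^2 / (Sxx * Syy),

a positive slope rho meaning electron-withdrawing substituents raise the
descriptor. The model/results pair follows the statsmodels idiom:
``HammettModel(sigma, y).fit()`` returns :class:`HammettResults` with
coefficient standard errors and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .records import DEFAULT_SIGMA_P, HammettFit


class HammettModel:
    """OLS of one descriptor against sigma_p.

    Parameters
    ----------
    sigma : array-like
        Substituent constants (the regressor).
    y : array-like
        Descriptor values, same length.
    compounds : sequence of str, optional
        Identifiers carried through to the results for reporting.
    """

    def __init__(
        self,
        sigma: Sequence[float],
        y: Sequence[float],
        compounds: Optional[Sequence[str]] = None,
    ):
        self.sigma = np.asarray(sigma, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.sigma.shape != self.y.shape or self.sigma.ndim != 1:
            raise ValueError("sigma and y must be 1-D arrays of equal length")
        if self.sigma.size < 3:
            raise ValueError(f"need n >= 3 points, got {self.sigma.size}")
        if np.ptp(self.sigma) == 0:
            raise ValueError("degenerate regressor: all sigma values equal")
        self.compounds = list(compounds) if compounds is not None else [
            str(i + 1) for i in range(self.sigma.size)
        ]

    @classmethod
    def from_descriptors(
        cls,
        descriptors: Mapping[str, float],
        substituents: Mapping[str, str],
        sigma_table: Optional[Mapping[str, float]] = None,
        series: Optional[Sequence[str]] = None,
    ) -> "HammettModel":
        """Join per-compound descriptor values to sigma_p by substituent.

        `substituents` maps compound id -> substituent key; `series`
        restricts and orders the compounds entering the fit.
        """
        table = DEFAULT_SIGMA_P if sigma_table is None else sigma_table
        ids = list(series) if series is not None else list(descriptors)
        sig, y = [], []
        for cid in ids:
            if cid not in descriptors:
                raise KeyError(f"no descriptor value for compound {cid!r}")
            sub = substituents.get(cid)
            if sub is None:
                raise KeyError(f"no substituent assignment for compound {cid!r}")
            if sub not in table:
                raise KeyError(f"substituent {sub!r} missing from sigma table")
            sig.append(table[sub])
            y.append(descriptors[cid])
        return cls(sig, y, compounds=ids)

    def fit(self) -> "HammettResults":
        x, y = self.sigma, self.y
        n = x.size
        xbar, ybar = x.mean(), y.mean()
        sxx = float(np.sum((x - xbar) ** 2))
        sxy = float(np.sum((x - xbar) * (y - ybar)))
        syy = float(np.sum((y - ybar) ** 2))
        slope = sxy / sxx
        intercept = ybar - slope * xbar
        r_squared = 0.0 if syy == 0 else sxy * sxy / (sxx * syy)
        resid = y - (intercept + slope * x)
        ssr = float(resid @ resid)
        dof = n - 2
        s2 = ssr / dof if dof > 0 else np.nan
        slope_se = float(np.sqrt(s2 / sxx))
        intercept_se = float(np.sqrt(s2 * (1.0 / n + xbar**2 / sxx)))
        return HammettResults(
            model=self,
            slope=slope,
            intercept=intercept,
            r_squared=r_squared,
            slope_se=slope_se,
            intercept_se=intercept_se,
            residuals=resid,
            n=n,
        )


@dataclass
class HammettResults:
    """Fitted Hammett regression with uncertainties and diagnostics."""

    model: HammettModel
    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    intercept_se: float
    residuals: np.ndarray
    n: int

    def as_fit(self) -> HammettFit:
        return HammettFit(
            slope=self.slope,
            intercept=self.intercept,
            r_squared=self.r_squared,
            n=self.n,
            compounds=list(self.model.compounds),
        )

    def predict(self, sigma: Sequence[float]) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(sigma, dtype=float)

    def summary(self) -> str:
        lines = [
            "Hammett linear free-energy relationship (OLS)",
            f"  n            : {self.n}",
            f"  slope (rho)  : {self.slope:+.4f}  (se {self.slope_se:.4f})",
            f"  intercept    : {self.intercept:+.4f}  (se {self.intercept_se:.4f})",
            f"  R^2          : {self.r_squared:.4f}",
            f"  compounds    : {', '.join(self.model.compounds)}",
        ]
        return "\n".join(lines)


def linear_fit(x: Sequence[float], y: Sequence[float]) -> HammettFit:
    """Plain OLS of y on x; closed-form slope, intercept and R^2."""
    return HammettModel(x, y).fit().as_fit()


def hammett_screen(
    descriptors: Mapping[str, float],
    substituents: Mapping[str, str],
    sigma_table: Optional[Mapping[str, float]] = None,
    series: Optional[Sequence[str]] = None,
) -> HammettFit:
    """Fit one descriptor series against sigma_p; reports entered compounds."""
    model = HammettModel.from_descriptors(
        descriptors, substituents, sigma_table=sigma_table, series=series
    )
    return model.fit().as_fit()
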