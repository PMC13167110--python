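"""GRIN-lens chromatic models: axial focal shift, transmission, power planning.

Gradient-index relay lenses shift the focal plane with wavelength (well
described by a second-order polynomial over the visible range) and transmit
light with a strong wavelength dependence (peaking near 550-600 nm and falling
sharply in the violet).  The transmission fit is used to pre-adjust excitation
laser powers so that each line delivers comparable power at the sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PolynomialFit",
    "PowerPlan",
    "fit_axial_shift",
    "fit_transmission",
    "plan_powers",
]


@dataclass(frozen=True)
class PolynomialFit:
    """Least-squares polynomial fit with its goodness of fit and valid domain.

    Coefficients are ordered lowest degree first; ``r_squared`` is
    1 - SS_res/SS_tot on the fitted points; ``domain`` is the wavelength
    interval spanned by the data, outside which evaluation warns.
    """

    coefficients: tuple[float, ...]
    r_squared: float
    domain: tuple[float, float]
    clip: tuple[float, float] | None = None

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, wavelength, extrapolation_warning: bool = True):
        lam = np.asarray(wavelength, dtype=float)
        if extrapolation_warning and (
            np.any(lam < self.domain[0]) or np.any(lam > self.domain[1])
        ):
            warnings.warn(
                f"evaluating polynomial fit outside fitted domain {self.domain}",
                stacklevel=2,
            )
        val = np.polynomial.polynomial.polyval(lam, self.coefficients)
        if self.clip is not None:
            val = np.clip(val, self.clip[0], self.clip[1])
        return val if np.ndim(wavelength) else float(val)


def _polyfit(x, y, degree, clip=None) -> PolynomialFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if x.size < degree + 1:
        raise ValueError(f"need at least {degree + 1} points for degree {degree}")
    coeffs = np.polynomial.polynomial.polyfit(x, y, degree)
    pred = np.polynomial.polynomial.polyval(x, coeffs)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PolynomialFit(
        tuple(coeffs), r2, (float(x.min()), float(x.max())), clip=clip
    )


def fit_axial_shift(wavelengths, focal_z, degree: int = 2) -> PolynomialFit:
    """Fit the axial (z) focal-plane shift versus excitation wavelength.

    The chromatic focal shift of a GRIN lens follows a second-order polynomial
    over the visible range; the fit is informational (acquisition planning) -
    the computational correction is the summed z-projection downstream.
    """
    return _polyfit(wavelengths, focal_z, degree)


def fit_transmission(wavelengths, transmission, degree: int = 6) -> PolynomialFit:
    """Fit fractional lens transmission versus wavelength.

    Degree 6 by default; evaluation clips to (0, 1] so that planning code never
    sees a non-physical transmission.
    """
    t = np.asarray(transmission, dtype=float)
    if np.any(t <= 0) or np.any(t > 1):
        raise ValueError("transmission values must lie in (0, 1]")
    return _polyfit(wavelengths, t, degree, clip=(1e-9, 1.0))


@dataclass(frozen=True)
class PowerPlan:
    """Per-laser excitation power plan derived from a transmission fit.

    ``multipliers`` holds T(reference)/T(laser) for each corrected laser (1 for
    the reference); ``fixed_overrides`` holds absolute power fractions for
    lasers that bypass the correction (e.g. the 639 nm line pinned to 40%).
    """

    reference_laser: float
    multipliers: dict[float, float]
    fixed_overrides: dict[float, float] = field(default_factory=dict)

    def power(self, laser: float) -> float:
        if laser in self.fixed_overrides:
            return self.fixed_overrides[laser]
        return self.multipliers[laser]


def plan_powers(
    fit: PolynomialFit,
    reference_laser: float,
    lasers,
    overrides: dict[float, float] | None = None,
) -> PowerPlan:
    """Scale laser powers so transmitted power matches the reference line.

    multiplier(l) = T(reference)/T(l); lasers in ``overrides`` instead carry
    the given absolute power fraction.  Scale-free in T: rescaling all
    transmissions by a constant leaves the plan unchanged.
    """
    overrides = dict(overrides or {})
    t_ref = fit(reference_laser)
    if t_ref <= 0:
        raise ValueError("transmission at reference laser is not positive")
    multipliers = {}
    for l in lasers:
        if l in overrides:
            continue
        t_l = fit(l)
        if t_l <= 0:
            raise ValueError(f"transmission at {l} nm is not positive")
        multipliers[float(l)] = float(t_ref / t_l)
    multipliers[float(reference_laser)] = 1.0
    return PowerPlan(float(reference_laser), multipliers, overrides)
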