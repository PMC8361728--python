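"""Water-background removal by first-derivative minimization.

Liquid-sample FTIR spectra are dominated by the water background, especially
around the 1600-1700 cm^-1 bending band.  After each sample, a water-filled
cuvette is measured; the background is removed by subtracting a scaled copy of
that reference, with the scale chosen so that the first derivative of the
corrected spectrum is minimal (in the least-squares sense) over a
signal-quiet window, 1800-2200 cm^-1 by default.

Minimizing ``sum_w (d/dnu [sample - a * water])^2`` over the window is a
scalar linear least-squares problem with the closed-form solution

    a = <D_s, D_w> / <D_w, D_w>,

where D_s and D_w are the windowed first-derivative vectors of sample and
reference.  No iterative optimizer, hence no tolerance to tune.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateReferenceError,
    NegativeScaleWarning,
    RangeError,
    ValidationError,
)
from .spectra import Spectrum

DEFAULT_WINDOW = (1800.0, 2200.0)


@dataclass(frozen=True, eq=False)
class WaterSubtractionResult:
    """Outcome of one water subtraction.

    Attributes
    ----------
    corrected : Spectrum
        ``sample - scale * water_ref`` on the sample grid.
    scale : float
        The optimal scale applied to the water reference.
    objective : float
        Residual sum of squared first-derivative values over the window
        (AU^2 cm^2) at the returned scale.
    window : (float, float)
        The fitting window in cm^-1, endpoints inclusive.
    """

    corrected: Spectrum
    scale: float
    objective: float
    window: tuple[float, float]


def first_derivative(s: Spectrum) -> Spectrum:
    """First derivative d(absorbance)/d(wavenumber), units AU per cm^-1.

    Central finite differences on interior points, one-sided at the two ends;
    output grid equals the input grid.  Exact for affine spectra.
    """
    if s.n_points < 3:
        raise ValidationError(f"derivative needs >= 3 points, got {s.n_points}")
    deriv = np.gradient(s.values, s.grid, edge_order=1)
    return s.with_values(deriv)


def subtract_water(
    sample: Spectrum,
    water_ref: Spectrum,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> WaterSubtractionResult:
    """Remove the water background from `sample` using `water_ref`.

    Both spectra must be on identical grids covering the window.  A negative
    optimal scale is mathematically possible and is returned, but triggers a
    :class:`NegativeScaleWarning` since it usually means a corrupted reference.
    """
    if not np.array_equal(sample.grid, water_ref.grid):
        raise ValidationError("sample and water reference must share one grid")
    lo, hi = float(window[0]), float(window[1])
    if lo >= hi:
        raise RangeError(f"empty window ({lo:g}, {hi:g})")
    mask = sample.window_mask(lo, hi)
    if mask.sum() < 2:
        raise RangeError(
            f"window [{lo:g}, {hi:g}] covers {int(mask.sum())} grid points; need >= 2"
        )
    ds = first_derivative(sample).values[mask]
    dw = first_derivative(water_ref).values[mask]
    denom = float(dw @ dw)
    if denom == 0.0:
        raise DegenerateReferenceError(
            "water reference derivative is identically zero in the window; "
            "subtraction scale is undefined"
        )
    scale = float(ds @ dw) / denom
    if scale < 0:
        warnings.warn(
            f"optimal water scale is negative ({scale:.3g}); "
            "check the reference measurement",
            NegativeScaleWarning,
            stacklevel=2,
        )
    corrected = sample.with_values(sample.values - scale * water_ref.values)
    resid = ds - scale * dw
    objective = float(resid @ resid)
    return WaterSubtractionResult(corrected, scale, objective, (lo, hi))
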