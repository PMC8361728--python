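"""Spectral unmixing: recover component concentrations from a spectrum.

The inverse of the linear absorption model: given a measured spectrum and a
library of unit-concentration component spectra, solve

    min_C || y - S C ||^2    subject to C >= 0  (default)

by active-set non-negative least squares, or by unconstrained least squares
(minimum-norm on rank deficiency).  Concentrations are physical, hence the
non-negativity default; serum protein spectra are mutually similar, so near
collinearity is detected via the library Gram-matrix condition number and
reported as a warning rather than silently returning unstable estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

from .errors import CollinearLibraryWarning, ValidationError
from .spectra import SpectralLibrary, Spectrum

#: Gram-matrix condition number above which the library is flagged collinear.
COLLINEARITY_THRESHOLD = 1e8


@dataclass(frozen=True, eq=False)
class UnmixResult:
    """Estimated concentrations (mg/mL) with fit diagnostics."""

    concentrations: pd.Series
    rss: float
    converged: bool
    condition_number: float
    collinear: bool


def estimate_concentrations(
    experiment: Spectrum,
    lib: SpectralLibrary,
    nonneg: bool = True,
    ridge: float = 0.0,
    components: tuple[str, ...] | None = None,
) -> UnmixResult:
    """Least-squares unmixing of `experiment` against `lib`.

    Parameters
    ----------
    nonneg : bool
        Constrain concentrations to be >= 0 (default).  With ``nonneg=False``
        the unconstrained normal equations are solved (minimum-norm solution
        on rank deficiency).
    ridge : float
        Optional Tikhonov penalty ``ridge * ||C||^2``; off by default since
        the design has few components and thousands of grid points.
    """
    names = tuple(components) if components is not None else lib.names
    S = lib.matrix(names)
    if not np.array_equal(experiment.grid, lib.grid):
        raise ValidationError("experiment must be on the library grid")
    if S.shape[0] <= S.shape[1]:
        raise ValidationError(
            f"need more grid points ({S.shape[0]}) than components ({S.shape[1]})"
        )
    if ridge < 0:
        raise ValidationError("ridge penalty must be >= 0")
    y = experiment.values
    gram = S.T @ S
    cond = float(np.linalg.cond(gram))
    collinear = bool(cond > COLLINEARITY_THRESHOLD)
    if collinear:
        warnings.warn(
            f"library Gram condition number {cond:.3g} exceeds "
            f"{COLLINEARITY_THRESHOLD:.0e}; concentration estimates are unstable",
            CollinearLibraryWarning,
            stacklevel=2,
        )
    if ridge > 0:
        A = np.vstack([S, np.sqrt(ridge) * np.eye(S.shape[1])])
        b = np.concatenate([y, np.zeros(S.shape[1])])
    else:
        A, b = S, y
    converged = True
    if nonneg:
        try:
            c, _ = scipy.optimize.nnls(A, b)
        except RuntimeError:
            # active set failed to settle; fall back to the clipped
            # unconstrained solution and say so
            converged = False
            c, *_ = np.linalg.lstsq(A, b, rcond=None)
            c = np.clip(c, 0.0, None)
    else:
        c, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = y - S @ c
    rss = float(resid @ resid)
    return UnmixResult(pd.Series(c, index=list(names)), rss, converged, cond, collinear)
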