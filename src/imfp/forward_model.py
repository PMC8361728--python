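"""The linear serum-absorption model and its goodness of fit.

Each sample's infrared molecular fingerprint is reconstructed as a
concentration-weighted sum of unit-concentration component spectra,

    IMF(nu) = sum_i C_i * S_i(nu),

with no intercept and no interaction terms: absorbance is additive in
concentration (Beer-Lambert) over the dynamic range of interest.  Agreement
with experiment is summarized by the vector distance — the Euclidean norm of
the pointwise model-minus-experiment difference over the working range — and
by the residual sum of squares (RSS), and tracked as components are added one
by one in order of abundance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import RangeError, ValidationError
from .spectra import SpectralLibrary, Spectrum


@dataclass(frozen=True, eq=False)
class ModelFit:
    """Model-experiment agreement over a wavenumber range.

    ``vector_distance = sqrt(rss)`` on the same point set.  When
    ``normalized`` is set, both are divided by sqrt(n_points) so the figure
    is invariant to grid resolution.
    """

    modeled: Spectrum
    rss: float
    vector_distance: float
    n_components: int
    n_points: int
    normalized: bool = False


@dataclass(frozen=True, eq=False)
class DistanceCurve:
    """Mean model-experiment distance as the component count K grows."""

    n_components: np.ndarray
    mean_distance: np.ndarray
    ordering: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.n_components) != len(self.mean_distance):
            raise ValidationError("curve arrays must have equal length")
        if len(self.n_components) != len(self.ordering):
            raise ValidationError("curve length must equal the ordering length")


def _lookup(concentrations: Mapping[str, float] | pd.Series, name: str) -> float:
    try:
        c = concentrations[name]
    except KeyError:
        raise ValidationError(f"no concentration for component {name!r}") from None
    c = float(c)
    if not np.isfinite(c):
        raise ValidationError(f"non-finite concentration for component {name!r}")
    return c


def model_spectrum(
    concentrations: Mapping[str, float] | pd.Series,
    lib: SpectralLibrary,
    subset: Sequence[str] | None = None,
    sample_id: str = "",
    cohort: str = "none",
    kind: str = "serum",
) -> Spectrum:
    """Evaluate ``sum_i C_i * S_i`` over `subset` (the whole library by default).

    Purely linear, no intercept.  Signed concentrations are accepted: the same
    machinery evaluates difference spectra from concentration differences.
    """
    names = tuple(subset) if subset is not None else lib.names
    if not names:
        raise ValidationError("empty component subset")
    S = lib.matrix(names)
    c = np.asarray([_lookup(concentrations, n) for n in names])
    return Spectrum(lib.grid, S @ c, sample_id=sample_id, cohort=cohort, kind=kind)


def fit_distance(
    experiment: Spectrum,
    modeled: Spectrum,
    window: tuple[float, float] | None = None,
    n_components: int = 1,
    normalize: bool = False,
) -> ModelFit:
    """RSS and Euclidean vector distance between model and experiment.

    `window` restricts the comparison to grid points in [lo, hi] inclusive;
    by default the full shared grid is used.
    """
    if not np.array_equal(experiment.grid, modeled.grid):
        raise ValidationError("experiment and model must share one grid")
    if window is None:
        mask = np.ones(experiment.n_points, dtype=bool)
    else:
        mask = experiment.window_mask(*window)
        if not mask.any():
            raise RangeError(f"window {window} contains no grid points")
    diff = modeled.values[mask] - experiment.values[mask]
    rss = float(diff @ diff)
    n = int(mask.sum())
    distance = float(np.sqrt(rss))
    if normalize:
        rss /= n
        distance /= np.sqrt(n)
    return ModelFit(modeled, rss, distance, n_components, n, normalize)


def order_by_abundance(panel: Mapping[str, float] | pd.Series) -> list[str]:
    """Component names in descending mean-concentration order (ties by name)."""
    s = pd.Series(dict(panel), dtype=float)
    return s.sort_values(ascending=False, kind="stable").index.tolist()


def incremental_model(
    experiments: Sequence[Spectrum],
    concentrations: pd.DataFrame,
    lib: SpectralLibrary,
    ordering: Sequence[str],
    window: tuple[float, float] | None = None,
    normalize: bool = False,
) -> DistanceCurve:
    """Mean vector distance across a cohort as components are added one by one.

    For K = 1..len(ordering), every sample is modeled with the first K
    components of `ordering` using its own concentrations, and the per-sample
    vector distances are averaged.
    """
    ordering = list(ordering)
    if not ordering:
        raise ValidationError("ordering must be non-empty")
    if not experiments:
        raise ValidationError("need at least one experimental spectrum")
    for name in ordering:
        if name not in lib:
            raise ValidationError(f"component {name!r} not in the library")
        if name not in concentrations.columns:
            raise ValidationError(f"no concentration column for component {name!r}")
    grid = lib.grid
    for s in experiments:
        if not np.array_equal(s.grid, grid):
            raise ValidationError("experimental spectra must be on the library grid")
    if window is None:
        mask = np.ones(grid.size, dtype=bool)
    else:
        mask = experiments[0].window_mask(*window)
        if not mask.any():
            raise RangeError(f"window {window} contains no grid points")
    E = np.vstack([s.values[mask] for s in experiments])  # samples x points
    S = lib.matrix(ordering)[mask]  # points x K
    C = concentrations[ordering].to_numpy(dtype=float)  # samples x K
    if not np.all(np.isfinite(C)):
        raise ValidationError("missing or non-finite concentrations in the ordering")
    mean_distance = np.empty(len(ordering))
    modeled = np.zeros_like(E)
    for k, name in enumerate(ordering):
        modeled = modeled + np.outer(C[:, k], S[:, k])
        diff = modeled - E
        dist = np.sqrt(np.sum(diff * diff, axis=1))
        if normalize:
            dist = dist / np.sqrt(mask.sum())
        mean_distance[k] = float(dist.mean())
    return DistanceCurve(
        np.arange(1, len(ordering) + 1), mean_distance, tuple(ordering)
    )
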