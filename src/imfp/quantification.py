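"""From relative protein intensities to absolute concentrations.

Label-free quantification (LFQ) intensities from MS proteomics characterize
*relative* differences between samples but are not proportional to absolute
concentrations.  To feed the linear absorption model they are rescaled
per protein against the average intensity of a reference cohort, anchored to
a reference concentration panel (mg/mL):

    C[s, i] = intensity[s, i] / mean_ref(intensity[., i]) * panel[i]

Tables are plain pandas DataFrames: rows = samples, columns = proteins,
``NaN`` = missing (never zero-coded).  The module also provides the
coefficient-of-variation reproducibility summaries and fraction-partition
bookkeeping used when modeling biochemical fractions of serum.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DegenerateNormalizationError, RangeError, ValidationError
from .spectra import Spectrum

#: Fraction vocabulary for partition maps.
FRACTIONS = ("metabolite", "hsa-depleted", "hsa-enriched")

_PARTITION_SUM_TOL = 1e-9


def validate_intensity_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check an intensity table: numeric, no negative entries (NaN = missing)."""
    t = table.astype(float)
    if (t.to_numpy() < 0).any():
        bad = t.columns[(t < 0).any(axis=0)].tolist()
        raise ValidationError(f"negative intensities for protein(s) {bad}")
    return t


def rescale_lfq(
    intensities: pd.DataFrame,
    panel: Mapping[str, float] | pd.Series,
    reference_ids: Sequence[str],
) -> pd.DataFrame:
    """Rescale LFQ intensities to mg/mL using reference-cohort averages.

    Parameters
    ----------
    intensities : DataFrame
        Samples x proteins, relative units, NaN = missing.
    panel : mapping protein -> mg/mL
        Average reference concentrations in healthy subjects; all > 0.
    reference_ids : sequence of sample ids
        The reference cohort whose mean intensity anchors the rescaling.

    Returns
    -------
    DataFrame of concentrations (mg/mL) for the panel proteins, in panel
    order; missing intensities propagate as missing concentrations.
    """
    panel = pd.Series(dict(panel), dtype=float)
    if (panel <= 0).any():
        bad = panel.index[panel <= 0].tolist()
        raise ValidationError(f"panel concentrations must be > 0; offending: {bad}")
    reference_ids = list(reference_ids)
    if not reference_ids:
        raise ValidationError("reference_ids must be non-empty")
    missing_ids = [s for s in reference_ids if s not in intensities.index]
    if missing_ids:
        raise ValidationError(f"reference ids absent from table: {missing_ids[:5]}")
    missing_prot = [p for p in panel.index if p not in intensities.columns]
    if missing_prot:
        raise ValidationError(f"panel protein(s) absent from table: {missing_prot}")
    t = validate_intensity_table(intensities[panel.index])
    ref = t.loc[reference_ids]
    out = {}
    for protein in panel.index:
        ref_vals = ref[protein].dropna()
        if ref_vals.empty:
            raise DegenerateNormalizationError(
                f"protein {protein!r}: all reference intensities missing"
            )
        m = float(ref_vals.mean())
        if m == 0.0:
            raise DegenerateNormalizationError(
                f"protein {protein!r}: zero reference mean intensity"
            )
        out[protein] = t[protein] / m * panel[protein]
    return pd.DataFrame(out, index=t.index)[panel.index.tolist()]


def coefficient_of_variation(
    table: pd.DataFrame, ids: Sequence[str] | None = None
) -> pd.Series:
    """Per-protein coefficient of variation, in percent.

    CV = 100 * sd / mean with the n-1 (sample) standard deviation, computed
    over the rows in `ids` (all rows when omitted), ignoring missing values.
    Requires >= 2 non-missing values and a strictly positive mean per protein.
    """
    sub = table.loc[list(ids)] if ids is not None else table
    out = {}
    for protein in sub.columns:
        x = sub[protein].dropna()
        if len(x) < 2:
            raise ValidationError(
                f"protein {protein!r}: need >= 2 non-missing values for a CV"
            )
        m = float(x.mean())
        if m <= 0:
            raise ValidationError(f"protein {protein!r}: CV undefined for mean <= 0")
        out[protein] = 100.0 * float(x.std(ddof=1)) / m
    return pd.Series(out, name="cv_percent")


def spectral_cv(
    spectra: Sequence[Spectrum], window: tuple[float, float] | None = None
) -> float:
    """Average per-wavenumber CV (%) of a set of spectra over a range.

    The spectral analogue of the per-protein CV: at each wavenumber the CV of
    absorbance across spectra is computed (n-1 sd), then averaged across the
    stated range (full shared grid when omitted).
    """
    if len(spectra) < 2:
        raise ValidationError("need >= 2 spectra for a spectral CV")
    grid = spectra[0].grid
    for s in spectra[1:]:
        if not np.array_equal(s.grid, grid):
            raise ValidationError("spectra must share one grid")
    mat = np.vstack([s.values for s in spectra])
    if window is not None:
        mask = spectra[0].window_mask(*window)
        if not mask.any():
            raise RangeError(f"window {window} outside the shared grid")
        mat = mat[:, mask]
    mean = mat.mean(axis=0)
    if np.any(mean <= 0):
        raise ValidationError("spectral CV undefined where the mean absorbance <= 0")
    sd = mat.std(axis=0, ddof=1)
    return float(np.mean(100.0 * sd / mean))


def validate_partition_map(partition: pd.DataFrame) -> pd.DataFrame:
    """Validate a proteins x fractions partition table.

    Each entry is the proportion of the protein's serum amount retained in
    that fraction, in [0, 1]; per protein the fractions sum to <= 1 (within
    1e-9).
    """
    p = partition.astype(float)
    unknown = [c for c in p.columns if c not in FRACTIONS]
    if unknown:
        raise ValidationError(f"unknown fraction(s) {unknown}; expected {FRACTIONS}")
    vals = p.to_numpy()
    if np.any(~np.isfinite(vals)) or np.any(vals < 0) or np.any(vals > 1):
        raise ValidationError("partition values must be finite and within [0, 1]")
    sums = p.sum(axis=1)
    if (sums > 1 + _PARTITION_SUM_TOL).any():
        bad = sums.index[sums > 1 + _PARTITION_SUM_TOL].tolist()
        raise ValidationError(f"partition fractions sum above 1 for {bad}")
    return p


def apply_partition(
    concentrations: pd.DataFrame, partition: pd.DataFrame, fraction: str
) -> pd.DataFrame:
    """Scale serum concentrations by each protein's share in a fraction.

    A missing partition entry is an error, never a silent 1.0: partition
    tables are measured quantities and must be supplied explicitly.
    """
    if fraction not in FRACTIONS:
        raise ValidationError(f"unknown fraction {fraction!r}; expected one of {FRACTIONS}")
    p = validate_partition_map(partition)
    if fraction not in p.columns:
        raise ValidationError(f"partition map has no column for fraction {fraction!r}")
    missing = [c for c in concentrations.columns if c not in p.index]
    if missing:
        raise ValidationError(f"no partition value for protein(s) {missing}")
    weights = p.loc[list(concentrations.columns), fraction]
    return concentrations * weights


# ---------------------------------------------------------------------------
# Plain-text config I/O (YAML key/value)


def read_panel(path: str | Path) -> pd.Series:
    """Read a protein -> mg/mL reference panel from a YAML mapping."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or not data:
        raise ValidationError(f"{path}: expected a non-empty mapping")
    panel = pd.Series({str(k): float(v) for k, v in data.items()})
    if (panel <= 0).any():
        raise ValidationError(f"{path}: panel concentrations must be > 0")
    return panel


def write_panel(panel: Mapping[str, float] | pd.Series, path: str | Path) -> None:
    data = {str(k): float(v) for k, v in dict(pd.Series(panel)).items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_partition_map(path: str | Path) -> pd.DataFrame:
    """Read a nested protein -> {fraction: share} YAML mapping."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or not data:
        raise ValidationError(f"{path}: expected a non-empty mapping")
    df = pd.DataFrame.from_dict(data, orient="index").fillna(0.0)
    return validate_partition_map(df)


def write_partition_map(partition: pd.DataFrame, path: str | Path) -> None:
    p = validate_partition_map(partition)
    data = {str(i): {str(c): float(p.loc[i, c]) for c in p.columns} for i in p.index}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
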