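"""Case-vs-reference differential fingerprints and protein-level rankings.

The *differential fingerprint* is the per-wavenumber difference between the
average spectrum of a case cohort and that of a reference cohort, reported
together with the reference cohort's per-wavenumber spread.  Because the
absorption model is linear, the differential fingerprint predicted from
chemistry is simply the concentration-difference-weighted sum of component
spectra — the same machinery as the forward model applied to signed
concentration differences.

Per-wavenumber and per-protein significance uses the two-sided Welch
(unequal-variance) t-test; star labels follow strict thresholds
(* p < 0.05, ** p < 0.0005, *** p < 1e-6).  No multiple-testing correction
is applied by default (raw per-peak p-values are reported);
Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ValidationError
from .forward_model import model_spectrum
from .spectra import SpectralLibrary, Spectrum

#: Strict star thresholds on the p-value, most significant first.
STAR_THRESHOLDS = ((1e-6, "***"), (5e-4, "**"), (0.05, "*"))


@dataclass(frozen=True, eq=False)
class DifferentialFingerprint:
    """Per-wavenumber mean(case) - mean(reference) with reference spread."""

    grid: np.ndarray
    delta: np.ndarray
    ref_std: np.ndarray
    pvalues: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (len(self.grid) == len(self.delta) == len(self.ref_std)):
            raise ValidationError("fingerprint arrays must share one length")
        if self.pvalues is not None and len(self.pvalues) != len(self.grid):
            raise ValidationError("pvalues length mismatch")

    def to_frame(self) -> pd.DataFrame:
        data = {"wavenumber": self.grid, "delta": self.delta, "ref_std": self.ref_std}
        if self.pvalues is not None:
            data["pvalue"] = self.pvalues
        return pd.DataFrame(data)


def significance_stars(p: float) -> str:
    """Star label for a p-value; strict inequalities, '' above 0.05."""
    if not np.isfinite(p) or p < 0 or p > 1:
        raise ValidationError(f"p-value {p!r} outside [0, 1]")
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return ""


def g_per_dl_to_mg_per_ml(x: float) -> float:
    """Unit conversion: clinical g/dL to the package's mg/mL (x10)."""
    return 10.0 * x


def _cohort_matrix(spectra: Sequence[Spectrum], grid: np.ndarray) -> np.ndarray:
    for s in spectra:
        if not np.array_equal(s.grid, grid):
            raise ValidationError("all spectra must share one grid")
    return np.vstack([s.values for s in spectra])


def differential_fingerprint(
    case: Sequence[Spectrum],
    reference: Sequence[Spectrum],
    with_pvalues: bool = False,
) -> DifferentialFingerprint:
    """mean(case) - mean(reference) per wavenumber, with reference-cohort sd.

    Requires >= 2 spectra per cohort on a shared grid.  With `with_pvalues`,
    a two-sided Welch t-test is run at every wavenumber.
    """
    if len(case) < 2 or len(reference) < 2:
        raise ValidationError("need >= 2 spectra per cohort")
    grid = case[0].grid
    cm = _cohort_matrix(case, grid)
    rm = _cohort_matrix(reference, grid)
    delta = cm.mean(axis=0) - rm.mean(axis=0)
    ref_std = rm.std(axis=0, ddof=1)
    pvalues = None
    if with_pvalues:
        pvalues = scipy.stats.ttest_ind(cm, rm, axis=0, equal_var=False).pvalue
    return DifferentialFingerprint(grid, delta, ref_std, pvalues)


def rank_proteins(
    case: pd.DataFrame,
    reference: pd.DataFrame,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Rank proteins by the absolute case-vs-reference concentration change.

    Both tables are samples x proteins in mg/mL and must share a protein set.
    Returns a DataFrame ordered by descending ``abs_diff`` with columns
    ``mean_case, mean_reference, abs_diff, rel_diff_pct, pvalue, stars``;
    the relative difference is against the reference mean.  Proteins missing
    in every sample of either cohort are excluded with a warning.
    """
    proteins = [p for p in case.columns if p in reference.columns]
    if set(case.columns) != set(reference.columns):
        raise ValidationError("case and reference tables must share one protein set")
    if len(case) < 2 or len(reference) < 2:
        raise ValidationError("need >= 2 samples per cohort")
    rows = []
    for protein in proteins:
        x = case[protein].dropna().to_numpy(dtype=float)
        y = reference[protein].dropna().to_numpy(dtype=float)
        if x.size == 0 or y.size == 0:
            warnings.warn(
                f"protein {protein!r} has no data in one cohort; excluded",
                UserWarning,
                stacklevel=2,
            )
            continue
        mc, mr = float(x.mean()), float(y.mean())
        if x.size >= 2 and y.size >= 2:
            p = float(scipy.stats.ttest_ind(x, y, equal_var=False).pvalue)
        else:
            p = float("nan")
        rows.append(
            {
                "protein": protein,
                "mean_case": mc,
                "mean_reference": mr,
                "abs_diff": abs(mc - mr),
                "rel_diff_pct": 100.0 * (mc - mr) / mr if mr != 0 else float("nan"),
                "pvalue": p,
            }
        )
    out = pd.DataFrame(rows).set_index("protein")
    if bh_correct and len(out):
        out["pvalue_bh"] = _benjamini_hochberg(out["pvalue"].to_numpy())
    star_source = "pvalue_bh" if bh_correct else "pvalue"
    out["stars"] = [
        significance_stars(p) if np.isfinite(p) else "" for p in out[star_source]
    ]
    return out.sort_values("abs_diff", ascending=False, kind="stable")


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def modeled_differential(
    delta_concentrations: Mapping[str, float] | pd.Series,
    lib: SpectralLibrary,
) -> Spectrum:
    """The linear model's prediction of a differential fingerprint.

    ``sum_i dC_i * S_i(nu)`` for signed per-protein mean concentration
    differences (mg/mL).
    """
    names = tuple(pd.Series(dict(delta_concentrations)).index)
    return model_spectrum(delta_concentrations, lib, subset=names, kind="serum")
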