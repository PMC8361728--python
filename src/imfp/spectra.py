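"""Containers and plain-text I/O for mid-infrared absorption spectra.

The atomic object is :class:`Spectrum`: absorbance (in absorbance units, AU)
sampled on a strictly ascending wavenumber grid (cm^-1), together with sample
metadata.  :class:`SpectralLibrary` collects named component spectra, each
normalized to unit concentration (1 mg/mL), all on one common grid; these are
the S_i(nu) of the linear serum-absorption model

    IMF(nu) = sum_i C_i * S_i(nu),

where C_i is the concentration of component i in mg/mL.

Two text dialects are supported: a two-column table (one spectrum per file,
``# key: value`` metadata comments, then ``wavenumber<delim>absorbance`` rows)
and a wide matrix (header row of wavenumbers, one row per sample with a
leading sample-id column).  Floats are written with 17 significant digits so
that write -> read round-trips bit-exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import ParseError, RangeError, ValidationError

#: Hard physical bounds on the mid-IR wavenumber axis accepted by validation.
WAVENUMBER_MIN = 400.0
WAVENUMBER_MAX = 4000.0

#: Default working range of the serum fingerprint, cm^-1.
DEFAULT_RANGE = (1000.0, 3000.0)

COHORTS = ("reference", "case", "none")
KINDS = (
    "serum",
    "fraction-metabolite",
    "fraction-hsa-depleted",
    "fraction-hsa-enriched",
    "water",
    "component",
)

_DELIMITERS = (",", "\t", ";")


def default_grid(lo: float = 1000.0, hi: float = 3000.0, step: float = 1.0) -> np.ndarray:
    """The default working grid: 1000-3000 cm^-1 at 1 cm^-1 spacing (2001 points)."""
    return np.arange(lo, hi + step / 2.0, step, dtype=np.float64)


@dataclass(frozen=True, eq=False)
class Spectrum:
    """A single absorption spectrum on a strictly ascending wavenumber grid.

    Parameters
    ----------
    grid : array-like
        Wavenumbers in cm^-1, strictly ascending, within [400, 4000].
    values : array-like
        Absorbance in AU, same length as `grid`, all finite.
    sample_id : str
        Sample identifier (may be empty).
    cohort : {"reference", "case", "none"}
        Cohort label for case/control analyses.
    kind : str
        Material kind, one of :data:`KINDS`.
    """

    grid: np.ndarray
    values: np.ndarray
    sample_id: str = ""
    cohort: str = "none"
    kind: str = "serum"

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=np.float64)
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)
        if grid.ndim != 1 or values.ndim != 1:
            raise ValidationError("grid and values must be one-dimensional")
        if grid.size < 2:
            raise ValidationError(f"a spectrum needs >= 2 points, got {grid.size}")
        if grid.size != values.size:
            raise ValidationError(
                f"grid ({grid.size}) and values ({values.size}) length mismatch"
            )
        if not np.all(np.isfinite(grid)):
            raise ValidationError("grid contains non-finite wavenumbers")
        diffs = np.diff(grid)
        if np.any(diffs <= 0):
            if np.any(diffs == 0):
                dup = grid[:-1][diffs == 0][0]
                raise ValidationError(f"duplicate wavenumber {dup:g} cm^-1")
            raise ValidationError("grid must be strictly ascending")
        if grid[0] < WAVENUMBER_MIN or grid[-1] > WAVENUMBER_MAX:
            raise ValidationError(
                f"grid [{grid[0]:g}, {grid[-1]:g}] outside "
                f"[{WAVENUMBER_MIN:g}, {WAVENUMBER_MAX:g}] cm^-1"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError("values contain NaN or Inf")
        if self.cohort not in COHORTS:
            raise ValidationError(f"unknown cohort label {self.cohort!r}")
        if self.kind not in KINDS:
            raise ValidationError(f"unknown material kind {self.kind!r}")

    # -- conveniences -----------------------------------------------------

    @property
    def n_points(self) -> int:
        return int(self.grid.size)

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of grid points inside [lo, hi], endpoints inclusive."""
        if lo > hi:
            raise RangeError(f"empty window ({lo:g}, {hi:g})")
        return (self.grid >= lo) & (self.grid <= hi)

    def with_values(self, values: np.ndarray, **meta: str) -> "Spectrum":
        """A copy of this spectrum with new absorbance values (same grid)."""
        return dataclasses.replace(self, values=values, **meta)

    def allclose(self, other: "Spectrum", rtol: float = 0.0, atol: float = 0.0) -> bool:
        return np.array_equal(self.grid, other.grid) and np.allclose(
            self.values, other.values, rtol=rtol, atol=atol
        )


def resample(s: Spectrum, target_grid: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto `target_grid`.

    The target grid must be strictly ascending and contained within the
    spectrum's own range; extrapolation is never performed.
    """
    target = np.asarray(target_grid, dtype=np.float64)
    if target.ndim != 1 or target.size < 2:
        raise ValidationError("target grid must be 1-D with >= 2 points")
    if np.any(np.diff(target) <= 0):
        raise ValidationError("target grid must be strictly ascending")
    if target[0] < s.grid[0] or target[-1] > s.grid[-1]:
        raise RangeError(
            f"target grid [{target[0]:g}, {target[-1]:g}] requires extrapolation "
            f"outside [{s.grid[0]:g}, {s.grid[-1]:g}]"
        )
    values = np.interp(target, s.grid, s.values)
    return Spectrum(target, values, s.sample_id, s.cohort, s.kind)


# ---------------------------------------------------------------------------
# Two-column dialect


def write_spectrum(s: Spectrum, path: str | Path, delimiter: str = ",") -> None:
    lines = [
        f"# sample_id: {s.sample_id}",
        f"# cohort: {s.cohort}",
        f"# kind: {s.kind}",
    ]
    for w, v in zip(s.grid, s.values):
        lines.append(f"{w:.17g}{delimiter}{v:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def _sniff_delimiter(line: str) -> str:
    for d in _DELIMITERS:
        if d in line:
            return d
    return ","


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a two-column spectral table.

    Comment lines start with ``#``; ``# key: value`` comments populate the
    sample metadata.  Rows are sorted into ascending grid order if needed.
    """
    path = Path(path)
    meta = {"sample_id": "", "cohort": "none", "kind": "serum"}
    grid: list[float] = []
    values: list[float] = []
    delimiter: str | None = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                key = key.strip()
                if key in meta:
                    meta[key] = val.strip()
            continue
        if delimiter is None:
            delimiter = _sniff_delimiter(line)
        fields = [f for f in line.split(delimiter)]
        if len(fields) != 2:
            raise ParseError(f"{path.name} line {lineno}: expected 2 fields, got {len(fields)}")
        try:
            w = float(fields[0])
            v = float(fields[1])
        except ValueError:
            raise ParseError(f"{path.name} line {lineno}: non-numeric cell in {line!r}") from None
        grid.append(w)
        values.append(v)
    if len(grid) < 2:
        raise ValidationError(f"{path.name}: a spectrum needs >= 2 points, got {len(grid)}")
    g = np.asarray(grid)
    v = np.asarray(values)
    order = np.argsort(g, kind="stable")
    g, v = g[order], v[order]
    if np.any(np.diff(g) == 0):
        dup = g[:-1][np.diff(g) == 0][0]
        raise ValidationError(f"{path.name}: duplicate wavenumber {dup:g} cm^-1")
    return Spectrum(g, v, **meta)


# ---------------------------------------------------------------------------
# Wide-matrix dialect


def write_spectra_matrix(
    spectra: Sequence[Spectrum], path: str | Path, delimiter: str = "\t"
) -> None:
    """Write a cohort of spectra sharing one grid as a wide matrix."""
    if not spectra:
        raise ValidationError("no spectra to write")
    grid = spectra[0].grid
    for s in spectra[1:]:
        if not np.array_equal(s.grid, grid):
            raise ValidationError("all spectra in a matrix must share one grid")
    header = delimiter.join(["sample_id"] + [f"{w:.17g}" for w in grid])
    rows = [header]
    for s in spectra:
        rows.append(delimiter.join([s.sample_id] + [f"{v:.17g}" for v in s.values]))
    Path(path).write_text("\n".join(rows) + "\n")


def read_spectra_matrix(
    path: str | Path,
    cohorts: Mapping[str, str] | None = None,
    kind: str = "serum",
) -> list[Spectrum]:
    """Read a wide-matrix spectral table into a list of spectra.

    `cohorts` optionally maps sample ids to cohort labels.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise ParseError(f"{path.name}: need a header and at least one sample row")
    delimiter = _sniff_delimiter(lines[0])
    header = lines[0].split(delimiter)
    try:
        grid = np.asarray([float(w) for w in header[1:]])
    except ValueError:
        raise ParseError(f"{path.name} line 1: non-numeric wavenumber in header") from None
    out: list[Spectrum] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split(delimiter)
        if len(fields) != len(header):
            raise ParseError(
                f"{path.name} line {lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        sid = fields[0]
        try:
            vals = np.asarray([float(x) for x in fields[1:]])
        except ValueError:
            raise ParseError(f"{path.name} line {lineno}: non-numeric cell") from None
        cohort = cohorts.get(sid, "none") if cohorts else "none"
        out.append(Spectrum(grid, vals, sample_id=sid, cohort=cohort, kind=kind))
    return out


# ---------------------------------------------------------------------------
# Component libraries


@dataclass(frozen=True, eq=False)
class SpectralLibrary:
    """Named component spectra at unit concentration (1 mg/mL) on one grid.

    All member spectra must share a bitwise-identical grid and be everywhere
    non-negative.  Component order is the insertion order of `spectra`.
    """

    names: tuple[str, ...]
    spectra: Mapping[str, Spectrum]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValidationError("component names must be unique")
        if not self.names:
            raise ValidationError("a library needs at least one component")
        if set(self.names) != set(self.spectra):
            raise ValidationError("names and spectra keys disagree")
        grid = self.spectra[self.names[0]].grid
        for name in self.names:
            s = self.spectra[name]
            if not np.array_equal(s.grid, grid):
                raise ValidationError(f"component {name!r} is not on the common grid")
            if np.any(s.values < 0):
                raise ValidationError(f"component {name!r} has negative absorbance")

    @classmethod
    def from_components(cls, components: Mapping[str, Spectrum]) -> "SpectralLibrary":
        return cls(tuple(components), dict(components))

    @property
    def grid(self) -> np.ndarray:
        return self.spectra[self.names[0]].grid

    def matrix(self, subset: Sequence[str] | None = None) -> np.ndarray:
        """Stack component spectra into an (n_points, n_components) array."""
        names = tuple(subset) if subset is not None else self.names
        for n in names:
            if n not in self.spectra:
                raise ValidationError(f"unknown component {n!r}")
        return np.column_stack([self.spectra[n].values for n in names])

    def __getitem__(self, name: str) -> Spectrum:
        return self.spectra[name]

    def __contains__(self, name: str) -> bool:
        return name in self.spectra

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[str]:
        return iter(self.names)


def write_library(lib: SpectralLibrary, directory: str | Path) -> None:
    """One two-column file per component; filename = component name."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in lib.names:
        write_spectrum(lib[name], directory / f"{name}.csv")


def read_library(directory: str | Path) -> SpectralLibrary:
    """Read a library directory written by :func:`write_library`.

    Components are ordered by sorted filename (the on-disk format does not
    record insertion order).
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.csv"))
    if not files:
        raise ValidationError(f"no component files in {directory}")
    comps: dict[str, Spectrum] = {}
    for f in files:
        s = read_spectrum(f)
        comps[f.stem] = dataclasses.replace(s, sample_id=f.stem, kind="component")
    return SpectralLibrary.from_components(comps)
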