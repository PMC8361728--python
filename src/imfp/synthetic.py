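"""Synthetic serum cohorts with known ground truth.

Everything the pipeline consumes can be generated here: a component spectral
library built from band models, a water background, cohort concentration
tables with disease effects, LFQ-style relative intensity tables with
instrument noise, and the resulting measured spectra.  The generator's
defaults emulate the design of a 148-sample lung-cancer case-control study:

* 93 reference and 55 case samples;
* a 12-protein panel dominated by albumin (ALB, ~45 mg/mL), with the ten
  most abundant serum proteins plus ORM1 and SERPINA3;
* between-person concentration variability of 33% CV (log-normal), and
  instrument (proteomic measurement) variability of 9% CV;
* a case effect of -9% on albumin (-0.4 g/dL) and moderate acute-phase
  rises for haptoglobin, C3, alpha-1-antitrypsin, alpha-1-acid glycoprotein
  and alpha-1-antichymotrypsin;
* component spectra with amide I (1600-1700 cm^-1), amide II, strong
  carbohydrate-region absorption (1000-1200 cm^-1) for the glycosylated
  ORM1, lipid ester/CH bands at 1735, 2852 and 2926 cm^-1, and a metabolite
  pseudo-component overlapping amide I;
* a strong water background dominating the 1600-1700 cm^-1 region, scaled
  per sample.

The default library deliberately keeps 1800-2200 cm^-1 free of bands, so the
signal-quiet assumption behind derivative-minimization water subtraction
holds by construction.  For the same reason the shipped bands are pure
Gaussians: Lorentzian tails decay only polynomially and would leak into the
subtraction window.  Everything is reproducible bitwise from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .forward_model import model_spectrum
from .spectra import SpectralLibrary, Spectrum, default_grid

# ---------------------------------------------------------------------------
# Band models

BAND_SHAPES = ("gaussian", "lorentzian", "pseudo-voigt")

#: Allowed slack for band centers beyond the grid ends, cm^-1.
BAND_CENTER_SLACK = 200.0


@dataclass(frozen=True)
class BandSpec:
    """One absorption band of a component spectrum.

    ``center`` and ``width`` (Gaussian sigma / Lorentzian half-width) are in
    cm^-1; ``amplitude`` is the peak absorbance at 1 mg/mL.  ``eta`` is the
    Lorentzian mixing fraction of the pseudo-Voigt profile (eta = 0 is pure
    Gaussian, eta = 1 pure Lorentzian).
    """

    center: float
    width: float
    amplitude: float
    shape: str = "gaussian"
    eta: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError(f"band width must be > 0, got {self.width}")
        if self.amplitude < 0:
            raise ValidationError(f"band amplitude must be >= 0, got {self.amplitude}")
        if self.shape not in BAND_SHAPES:
            raise ValidationError(f"unknown band shape {self.shape!r}")
        if not 0.0 <= self.eta <= 1.0:
            raise ValidationError(f"pseudo-Voigt eta must be in [0, 1], got {self.eta}")

    def profile(self, grid: np.ndarray) -> np.ndarray:
        x = (np.asarray(grid, dtype=float) - self.center) / self.width
        gauss = np.exp(-0.5 * x * x)
        if self.shape == "gaussian":
            return self.amplitude * gauss
        lorentz = 1.0 / (1.0 + x * x)
        if self.shape == "lorentzian":
            return self.amplitude * lorentz
        return self.amplitude * ((1.0 - self.eta) * gauss + self.eta * lorentz)


# Band tables for the default components.  Centers/widths follow the usual
# mid-IR assignments (amide I 1600-1700, amide II ~1545, CH deformations
# 1400-1470, glycan C-O 1000-1200, lipid ester 1735 and CH stretches
# 2852/2926); amplitudes are chosen so 45 mg/mL albumin gives an amide I
# absorbance of ~0.4 AU.  All bands below 1800 cm^-1 use sigma <= 42 and sit
# at or below 1735 cm^-1, keeping the 1800-2200 cm^-1 window band-free.
DEFAULT_BANDS: dict[str, tuple[BandSpec, ...]] = {
    "ALB": (
        BandSpec(1654, 22, 0.0095),
        BandSpec(1546, 20, 0.0062),
        BandSpec(1515, 10, 0.0013),
        BandSpec(1451, 18, 0.0020),
        BandSpec(1398, 16, 0.0016),
        BandSpec(1302, 20, 0.0013),
        BandSpec(2935, 24, 0.0013),
    ),
    "IGHG1": (
        BandSpec(1638, 16, 0.0082),
        BandSpec(1690, 11, 0.0026),
        BandSpec(1543, 17, 0.0055),
        BandSpec(1448, 16, 0.0017),
        BandSpec(1368, 14, 0.0013),
        BandSpec(1310, 14, 0.0014),
        BandSpec(1082, 40, 0.0011),
        BandSpec(2935, 24, 0.0011),
    ),
    "TF": (
        BandSpec(1650, 21, 0.0088),
        BandSpec(1542, 20, 0.0056),
        BandSpec(1450, 18, 0.0017),
        BandSpec(1248, 18, 0.0013),
        BandSpec(1070, 38, 0.0014),
        BandSpec(2933, 24, 0.0011),
    ),
    "IGHA1": (
        BandSpec(1643, 21, 0.0080),
        BandSpec(1596, 14, 0.0012),
        BandSpec(1552, 19, 0.0053),
        BandSpec(1285, 18, 0.0011),
        BandSpec(1062, 34, 0.0019),
        BandSpec(1132, 30, 0.0013),
        BandSpec(2934, 24, 0.0011),
    ),
    "A2M": (
        BandSpec(1645, 24, 0.0086),
        BandSpec(1544, 22, 0.0055),
        BandSpec(1449, 18, 0.0016),
        BandSpec(1234, 20, 0.0012),
        BandSpec(1078, 40, 0.0012),
        BandSpec(2935, 24, 0.0011),
    ),
    "HP": (
        BandSpec(1639, 20, 0.0083),
        BandSpec(1549, 19, 0.0055),
        BandSpec(1452, 18, 0.0016),
        BandSpec(1270, 16, 0.0012),
        BandSpec(1046, 30, 0.0021),
        BandSpec(1118, 32, 0.0017),
        BandSpec(2934, 24, 0.0011),
    ),
    "SERPINA1": (
        BandSpec(1651, 19, 0.0087),
        BandSpec(1547, 18, 0.0056),
        BandSpec(1449, 18, 0.0016),
        BandSpec(1318, 14, 0.0013),
        BandSpec(1088, 36, 0.0013),
        BandSpec(2935, 24, 0.0011),
    ),
    "APOA1": (
        BandSpec(1656, 18, 0.0093),
        BandSpec(1548, 20, 0.0059),
        BandSpec(1452, 18, 0.0018),
        BandSpec(1222, 16, 0.0012),
        BandSpec(2933, 24, 0.0012),
    ),
    "C3": (
        BandSpec(1648, 25, 0.0085),
        BandSpec(1545, 22, 0.0055),
        BandSpec(1450, 18, 0.0016),
        BandSpec(1258, 16, 0.0012),
        BandSpec(1080, 42, 0.0010),
        BandSpec(2934, 24, 0.0011),
    ),
    "IGHM": (
        BandSpec(1628, 17, 0.0081),
        BandSpec(1684, 11, 0.0024),
        BandSpec(1534, 17, 0.0054),
        BandSpec(1340, 14, 0.0013),
        BandSpec(1072, 36, 0.0016),
        BandSpec(2936, 24, 0.0011),
    ),
    "ORM1": (
        # heavily glycosylated: ~45% of dry mass is carbohydrate, so the
        # 1000-1200 cm^-1 region rivals the amide bands at equal mass
        BandSpec(1644, 22, 0.0052),
        BandSpec(1550, 20, 0.0034),
        BandSpec(1041, 28, 0.0046),
        BandSpec(1076, 26, 0.0041),
        BandSpec(1121, 30, 0.0036),
        BandSpec(1155, 26, 0.0024),
        BandSpec(2934, 24, 0.0009),
    ),
    "SERPINA3": (
        BandSpec(1649, 21, 0.0085),
        BandSpec(1546, 20, 0.0054),
        BandSpec(1330, 14, 0.0012),
        BandSpec(1085, 38, 0.0015),
        BandSpec(2935, 24, 0.0011),
    ),
    "LIPID": (
        BandSpec(1735, 10, 0.016),
        BandSpec(1466, 14, 0.0042),
        BandSpec(2852, 15, 0.012),
        BandSpec(2926, 17, 0.017),
    ),
    "METABOLITE": (
        # small molecules: a band overlapping amide I plus sugar/urea bands
        BandSpec(1652, 24, 0.0115),
        BandSpec(1035, 24, 0.0080),
        BandSpec(1079, 24, 0.0058),
        BandSpec(1124, 22, 0.0040),
        BandSpec(1455, 20, 0.0058),
    ),
}

WATER_BANDS: tuple[BandSpec, ...] = (
    BandSpec(1643, 48, 1.22),   # H-O-H bending
    BandSpec(2127, 115, 0.105),  # association band
    BandSpec(3200, 190, 0.92),  # O-H stretch edge
    BandSpec(980, 60, 0.25),    # libration shoulder
)

#: Reference panel, mg/mL: the ten most abundant serum proteins plus the two
#: disease-relevant additions (ORM1, SERPINA3).  Literature-style placeholder
#: values; users supply their own panel for real data.
DEFAULT_PANEL: dict[str, float] = {
    "ALB": 45.0,
    "IGHG1": 11.0,
    "TF": 2.5,
    "IGHA1": 2.2,
    "A2M": 1.6,
    "HP": 1.5,
    "SERPINA1": 1.4,
    "APOA1": 1.3,
    "C3": 1.2,
    "IGHM": 1.0,
    "ORM1": 0.8,
    "SERPINA3": 0.45,
}

#: Multiplicative case-vs-reference concentration shifts.  ALB x0.91 (-9%) is
#: the anchoring clinical observation; the remaining entries are synthetic
#: magnitudes at the strong end of the acute-phase responses documented for
#: symptomatic stage II/III disease (positive acute-phase rises for HP, C3,
#: SERPINA1, ORM1, SERPINA3; negative acute-phase drops for TF and APOA1),
#: chosen so the 12-protein disease pattern is clearly expressed in both the
#: concentration and the spectral feature space.
DEFAULT_EFFECTS: dict[str, float] = {
    "ALB": 0.91,
    "HP": 1.8,
    "C3": 1.35,
    "SERPINA1": 1.5,
    "ORM1": 1.8,
    "SERPINA3": 2.0,
    "TF": 0.8,
    "APOA1": 0.8,
}

#: Non-protein components with fixed concentrations (mg/mL equivalents).
DEFAULT_FIXED_COMPONENTS: dict[str, float] = {"LIPID": 2.0, "METABOLITE": 3.0}

#: Default partition of each protein's serum amount across the three
#: biochemical fractions.  ALB, HP and ORM1 remain predominantly in the
#: HSA-enriched fraction; other proteins precipitate into the depleted one.
DEFAULT_PARTITION: dict[str, dict[str, float]] = {
    **{
        name: {"metabolite": 0.0, "hsa-depleted": 0.85, "hsa-enriched": 0.15}
        for name in DEFAULT_PANEL
    },
    "ALB": {"metabolite": 0.0, "hsa-depleted": 0.1, "hsa-enriched": 0.9},
    "HP": {"metabolite": 0.0, "hsa-depleted": 0.25, "hsa-enriched": 0.75},
    "ORM1": {"metabolite": 0.0, "hsa-depleted": 0.3, "hsa-enriched": 0.7},
}


def make_library(
    bands: Mapping[str, Sequence[BandSpec]] | None = None,
    grid: np.ndarray | None = None,
) -> SpectralLibrary:
    """Build a unit-concentration component library from band tables."""
    bands = dict(bands) if bands is not None else DEFAULT_BANDS
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    lo, hi = grid[0] - BAND_CENTER_SLACK, grid[-1] + BAND_CENTER_SLACK
    components: dict[str, Spectrum] = {}
    for name, bandlist in bands.items():
        if not bandlist:
            raise ValidationError(f"component {name!r} needs >= 1 band")
        values = np.zeros_like(grid)
        for b in bandlist:
            if not lo <= b.center <= hi:
                raise ValidationError(
                    f"component {name!r}: band center {b.center:g} cm^-1 is beyond "
                    f"the grid range +- {BAND_CENTER_SLACK:g}"
                )
            values = values + b.profile(grid)
        components[name] = Spectrum(grid, values, sample_id=name, kind="component")
    return SpectralLibrary.from_components(components)


def water_reference(grid: np.ndarray | None = None) -> Spectrum:
    """The default water-background reference spectrum."""
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    values = np.zeros_like(grid)
    for b in WATER_BANDS:
        values = values + b.profile(grid)
    return Spectrum(grid, values, sample_id="water", kind="water")


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters for a simulated case-control cohort."""

    n_reference: int = 93
    n_case: int = 55
    panel: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PANEL))
    between_person_cv: float = 0.33
    instrument_cv: float = 0.09
    effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    spectral_noise_sd: float = 2e-4
    water_scale_range: tuple[float, float] = (0.5, 1.5)
    fixed_components: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FIXED_COMPONENTS)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_reference < 2 or self.n_case < 2:
            raise ValidationError("need >= 2 samples per cohort")
        if not self.panel:
            raise ValidationError("panel must be non-empty")
        if any(v <= 0 for v in self.panel.values()):
            raise ValidationError("panel concentrations must be > 0")
        if self.between_person_cv < 0 or self.instrument_cv < 0:
            raise ValidationError("CVs must be >= 0")
        if any(e <= 0 for e in self.effects.values()):
            raise ValidationError("effects must be multiplicative and > 0")
        if any(p not in self.panel for p in self.effects):
            raise ValidationError("every effect must name a panel protein")
        if self.spectral_noise_sd < 0:
            raise ValidationError("spectral noise sd must be >= 0")
        lo, hi = self.water_scale_range
        if lo < 0 or hi < lo:
            raise ValidationError("water scale range must satisfy 0 <= lo <= hi")
        if any(v < 0 for v in self.fixed_components.values()):
            raise ValidationError("fixed component concentrations must be >= 0")


@dataclass(frozen=True, eq=False)
class GroundTruth:
    """Everything the generator drew, for recovery checks."""

    concentrations: pd.DataFrame  # samples x (panel + fixed components), mg/mL
    water_scales: pd.Series
    intensity_scales: pd.Series  # per-protein arbitrary LFQ scale factors
    effects: dict[str, float]


@dataclass(frozen=True, eq=False)
class SimulatedCohort:
    """A complete simulated study: spectra, intensities and ground truth."""

    spectra: list[Spectrum]  # measured spectra (protein sum + water + noise)
    intensities: pd.DataFrame  # samples x panel proteins, LFQ-style
    labels: pd.Series  # sample_id -> cohort
    truth: GroundTruth
    library: SpectralLibrary
    water: Spectrum
    config: CohortConfig

    @property
    def reference_ids(self) -> list[str]:
        return self.labels.index[self.labels == "reference"].tolist()

    @property
    def case_ids(self) -> list[str]:
        return self.labels.index[self.labels == "case"].tolist()


def _lognormal_sigma(cv: float) -> float:
    """Log-space sigma giving an exact coefficient of variation `cv`."""
    return float(np.sqrt(np.log1p(cv * cv)))


def draw_concentrations(
    cfg: CohortConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw true per-sample panel concentrations and cohort labels.

    Concentrations are log-normal with mean = panel value (times the case
    effect) and CV = `between_person_cv`; the log-normal keeps them positive
    and makes the CV parameterization exact.
    """
    ids = [f"REF{i + 1:03d}" for i in range(cfg.n_reference)] + [
        f"LC{i + 1:03d}" for i in range(cfg.n_case)
    ]
    labels = pd.Series(
        ["reference"] * cfg.n_reference + ["case"] * cfg.n_case, index=ids, name="cohort"
    )
    sigma = _lognormal_sigma(cfg.between_person_cv)
    n = len(ids)
    is_case = (labels == "case").to_numpy()
    cols = {}
    for protein, mean_ref in cfg.panel.items():
        effect = cfg.effects.get(protein, 1.0)
        means = np.where(is_case, mean_ref * effect, mean_ref)
        mu = np.log(means) - 0.5 * sigma * sigma
        cols[protein] = rng.lognormal(mean=mu, sigma=sigma) if sigma > 0 else means
    return pd.DataFrame(cols, index=ids), labels


def simulate_cohort(
    cfg: CohortConfig | None = None,
    lib: SpectralLibrary | None = None,
    water: Spectrum | None = None,
) -> SimulatedCohort:
    """Simulate a full case-control study with known ground truth.

    Per sample: true panel concentrations are drawn log-normal; the LFQ
    intensity is the true concentration times a protein-specific arbitrary
    scale times log-normal instrument noise (so intensities are relative,
    not absolute); the measured spectrum is the linear component sum plus a
    per-sample scaled water background plus additive Gaussian noise.
    """
    cfg = cfg if cfg is not None else CohortConfig()
    cfg.validate()
    lib = lib if lib is not None else make_library()
    water = water if water is not None else water_reference(lib.grid)
    if not np.array_equal(water.grid, lib.grid):
        raise ValidationError("water reference must be on the library grid")
    missing = [p for p in cfg.panel if p not in lib]
    missing += [c for c in cfg.fixed_components if c not in lib]
    if missing:
        raise ValidationError(f"library lacks component(s) {missing}")

    rng = np.random.default_rng(cfg.seed)
    # draw order is fixed and documented: intensity scales, concentrations,
    # instrument noise, water scales, spectral noise
    proteins = list(cfg.panel)
    scales = pd.Series(
        10.0 ** rng.uniform(6.0, 9.0, size=len(proteins)), index=proteins
    )
    conc, labels = draw_concentrations(cfg, rng)
    sigma_i = _lognormal_sigma(cfg.instrument_cv)
    if sigma_i > 0:
        noise = rng.lognormal(
            mean=-0.5 * sigma_i * sigma_i, sigma=sigma_i, size=conc.shape
        )
    else:
        noise = np.ones(conc.shape)
    intensities = conc * scales * noise
    lo, hi = cfg.water_scale_range
    water_scales = pd.Series(
        rng.uniform(lo, hi, size=len(conc)), index=conc.index, name="water_scale"
    )
    full_conc = conc.copy()
    for comp, value in cfg.fixed_components.items():
        full_conc[comp] = value

    spectra: list[Spectrum] = []
    n_points = lib.grid.size
    for sid in conc.index:
        modeled = model_spectrum(
            full_conc.loc[sid],
            lib,
            sample_id=sid,
            cohort=str(labels[sid]),
            kind="serum",
        )
        values = modeled.values + water_scales[sid] * water.values
        if cfg.spectral_noise_sd > 0:
            values = values + cfg.spectral_noise_sd * rng.standard_normal(n_points)
        spectra.append(modeled.with_values(values))
    truth = GroundTruth(full_conc, water_scales, scales, dict(cfg.effects))
    return SimulatedCohort(spectra, intensities, labels, truth, lib, water, cfg)


def simulate_replicate_intensities(
    cfg: CohortConfig | None = None, n_replicates: int = 8, seed: int | None = None
) -> pd.DataFrame:
    """Repeated LFQ measurements of one sample at the panel concentrations.

    Emulates the instrument-reproducibility assessment: the same sample
    measured `n_replicates` times, so the per-protein CV estimates the
    measurement (not biological) variability.
    """
    cfg = cfg if cfg is not None else CohortConfig()
    cfg.validate()
    if n_replicates < 2:
        raise ValidationError("need >= 2 replicates")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    proteins = list(cfg.panel)
    scales = 10.0 ** rng.uniform(6.0, 9.0, size=len(proteins))
    sigma_i = _lognormal_sigma(cfg.instrument_cv)
    base = np.asarray([cfg.panel[p] for p in proteins]) * scales
    noise = rng.lognormal(
        mean=-0.5 * sigma_i * sigma_i, sigma=sigma_i, size=(n_replicates, len(proteins))
    )
    return pd.DataFrame(
        base * noise,
        index=[f"REP{i + 1:02d}" for i in range(n_replicates)],
        columns=proteins,
    )


# ---------------------------------------------------------------------------
# Config I/O


def cohort_config_to_yaml(cfg: CohortConfig, path: str | Path) -> None:
    data = {
        "n_reference": cfg.n_reference,
        "n_case": cfg.n_case,
        "panel": {k: float(v) for k, v in cfg.panel.items()},
        "between_person_cv": cfg.between_person_cv,
        "instrument_cv": cfg.instrument_cv,
        "effects": {k: float(v) for k, v in cfg.effects.items()},
        "spectral_noise_sd": cfg.spectral_noise_sd,
        "water_scale_range": list(cfg.water_scale_range),
        "fixed_components": {k: float(v) for k, v in cfg.fixed_components.items()},
        "seed": cfg.seed,
    }
    # insertion order is semantic: it fixes the random-draw order per protein
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def cohort_config_from_yaml(path: str | Path) -> CohortConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a mapping")
    if "water_scale_range" in data:
        data["water_scale_range"] = tuple(data["water_scale_range"])
    cfg = CohortConfig(**data)
    cfg.validate()
    return cfg


def with_seed(cfg: CohortConfig, seed: int) -> CohortConfig:
    """A copy of `cfg` with a new seed."""
    return replace(cfg, seed=seed)
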