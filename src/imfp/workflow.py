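"""End-to-end orchestration: simulate -> preprocess -> rescale -> model ->
differential -> classify, with an auditable artifact manifest.

Every stage reads and writes declared plain-text artifacts only, so the run
can be resumed or re-executed from any intermediate.  The manifest lists
every output with a SHA-256 content hash; together with the logged
parameters and seed it fully determines the run, which is what the
double-run reproducibility test audits.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential as diff
from . import synthetic
from .classification import repeated_cv_classify
from .errors import ImfError
from .forward_model import incremental_model, order_by_abundance
from .preprocessing import DEFAULT_WINDOW, subtract_water
from .quantification import rescale_lfq
from .spectra import (
    Spectrum,
    read_spectra_matrix,
    write_library,
    write_spectra_matrix,
    write_spectrum,
)

log = logging.getLogger("imfp")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: Path
    seed: int = 0
    cohort: synthetic.CohortConfig | None = None
    window: tuple[float, float] = DEFAULT_WINDOW
    folds: int = 10
    repeats: int = 10
    stages: tuple[str, ...] = (
        "simulate",
        "preprocess",
        "rescale",
        "model",
        "differential",
        "classify",
    )

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.cohort is None:
            self.cohort = synthetic.with_seed(synthetic.CohortConfig(), self.seed)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_table(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", float_format="%.17g")


def run_full_workflow(cfg: RunConfig) -> dict:
    """Execute the whole workflow; returns the manifest dictionary.

    Any stage failure is re-raised annotated with the stage name; artifacts
    written so far stay on disk and are flagged in the partial manifest.
    """
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    completed: list[str] = []
    manifest = {
        "artifacts": artifacts,
        "stages_completed": completed,
        "seed": cfg.seed,
        "window": list(cfg.window),
        "folds": cfg.folds,
        "repeats": cfg.repeats,
    }

    def register(*paths: Path) -> None:
        for p in paths:
            artifacts[p.name] = _sha256(p)

    state: dict = {}
    try:
        for stage in cfg.stages:
            log.info("stage %s starting", stage)
            _STAGES[stage](cfg, out, state, register)
            completed.append(stage)
            log.info("stage %s done", stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
        raise ImfError(f"stage {stage!r} failed: {exc}") from exc
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest


def _stage_simulate(cfg: RunConfig, out: Path, state: dict, register) -> None:
    cohort = synthetic.simulate_cohort(cfg.cohort)
    state["cohort"] = cohort
    write_spectra_matrix(cohort.spectra, out / "spectra_raw.tsv")
    write_spectrum(cohort.water, out / "water.csv")
    write_library(cohort.library, out / "library")
    _write_table(cohort.intensities, out / "intensities.tsv")
    _write_table(cohort.truth.concentrations, out / "true_concentrations.tsv")
    cohort.labels.to_frame().to_csv(out / "labels.tsv", sep="\t")
    synthetic.cohort_config_to_yaml(cfg.cohort, out / "cohort_config.yaml")
    register(
        out / "spectra_raw.tsv",
        out / "water.csv",
        out / "intensities.tsv",
        out / "true_concentrations.tsv",
        out / "labels.tsv",
        out / "cohort_config.yaml",
    )


def _stage_preprocess(cfg: RunConfig, out: Path, state: dict, register) -> None:
    cohort = state["cohort"]
    water = cohort.water
    corrected: list[Spectrum] = []
    rows = []
    for s in cohort.spectra:
        res = subtract_water(s, water, cfg.window)
        corrected.append(res.corrected)
        rows.append(
            {"sample_id": s.sample_id, "scale": res.scale, "objective": res.objective}
        )
    state["corrected"] = corrected
    write_spectra_matrix(corrected, out / "spectra_corrected.tsv")
    _write_table(pd.DataFrame(rows).set_index("sample_id"), out / "water_scales.tsv")
    register(out / "spectra_corrected.tsv", out / "water_scales.tsv")


def _stage_rescale(cfg: RunConfig, out: Path, state: dict, register) -> None:
    cohort = state["cohort"]
    conc = rescale_lfq(cohort.intensities, cfg.cohort.panel, cohort.reference_ids)
    state["concentrations"] = conc
    _write_table(conc, out / "concentrations.tsv")
    register(out / "concentrations.tsv")


def _stage_model(cfg: RunConfig, out: Path, state: dict, register) -> None:
    cohort = state["cohort"]
    ordering = order_by_abundance(cfg.cohort.panel)
    curve = incremental_model(
        state["corrected"], state["concentrations"], cohort.library, ordering
    )
    frame = pd.DataFrame(
        {
            "n_components": curve.n_components,
            "component_added": list(curve.ordering),
            "mean_vector_distance": curve.mean_distance,
        }
    ).set_index("n_components")
    _write_table(frame, out / "distance_curve.tsv")
    register(out / "distance_curve.tsv")


def _stage_differential(cfg: RunConfig, out: Path, state: dict, register) -> None:
    cohort = state["cohort"]
    corrected = state["corrected"]
    case = [s for s in corrected if s.cohort == "case"]
    ref = [s for s in corrected if s.cohort == "reference"]
    fp = diff.differential_fingerprint(case, ref, with_pvalues=True)
    fp.to_frame().to_csv(out / "differential_fingerprint.tsv", sep="\t", index=False,
                         float_format="%.17g")
    conc = state["concentrations"]
    ranking = diff.rank_proteins(
        conc.loc[cohort.case_ids], conc.loc[cohort.reference_ids]
    )
    _write_table(ranking, out / "protein_ranking.tsv")
    delta_conc = ranking["mean_case"] - ranking["mean_reference"]
    modeled = diff.modeled_differential(delta_conc, cohort.library)
    write_spectrum(modeled, out / "differential_modeled.csv")
    register(
        out / "differential_fingerprint.tsv",
        out / "protein_ranking.tsv",
        out / "differential_modeled.csv",
    )


def _stage_classify(cfg: RunConfig, out: Path, state: dict, register) -> None:
    cohort = state["cohort"]
    labels = cohort.labels.to_numpy()
    spectra_features = np.vstack([s.values for s in state["corrected"]])
    for name, feats in (
        ("spectra", spectra_features),
        ("concentrations", state["concentrations"].to_numpy()),
    ):
        res = repeated_cv_classify(
            feats, labels, folds=cfg.folds, repeats=cfg.repeats, seed=cfg.seed
        )
        path = out / f"cv_{name}.json"
        path.write_text(json.dumps(res.to_dict(), sort_keys=True, indent=1))
        register(path)


_STAGES = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "rescale": _stage_rescale,
    "model": _stage_model,
    "differential": _stage_differential,
    "classify": _stage_classify,
}


def load_labels(path: str | Path) -> pd.Series:
    """Read a sample_id -> cohort table written by the simulate stage."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return frame.iloc[:, 0]


def load_corrected_spectra(path: str | Path, labels: pd.Series) -> list[Spectrum]:
    return read_spectra_matrix(path, cohorts=dict(labels))
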