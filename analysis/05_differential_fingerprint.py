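#!/usr/bin/env python
"""Case-vs-reference differential fingerprint, measured and modeled.

Computes the per-wavenumber difference between the average water-corrected
spectra of the two cohorts, ranks the panel proteins by absolute
concentration change (with Welch p-values and significance stars), and
compares the measured differential fingerprint with the one predicted from
the 12 mean concentration differences alone.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from imfp import (
    differential_fingerprint,
    modeled_differential,
    rank_proteins,
    read_spectra_matrix,
)
from imfp import synthetic as syn

SEED = 7
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort_dir = ROOT / "scratch" / "cohort"
    cohort = syn.simulate_cohort(syn.with_seed(syn.CohortConfig(), SEED))
    corrected = read_spectra_matrix(
        cohort_dir / "spectra_corrected.tsv", cohorts=dict(cohort.labels)
    )
    conc = pd.read_csv(cohort_dir / "concentrations.tsv", sep="\t", index_col=0)

    case = [s for s in corrected if s.cohort == "case"]
    ref = [s for s in corrected if s.cohort == "reference"]
    fp = differential_fingerprint(case, ref, with_pvalues=True)
    fp.to_frame().to_csv(cohort_dir / "differential_fingerprint.tsv", sep="\t",
                         index=False, float_format="%.17g")

    ranking = rank_proteins(conc.loc[cohort.case_ids], conc.loc[cohort.reference_ids])
    ranking.to_csv(ROOT / "results" / "protein_ranking.tsv", sep="\t",
                   float_format="%.4g")

    delta = ranking["mean_case"] - ranking["mean_reference"]
    modeled = modeled_differential(delta, cohort.library)
    r = float(np.corrcoef(fp.delta, modeled.values)[0, 1])
    summary = pd.DataFrame(
        {
            "value": {
                "pearson_r_measured_vs_modeled": r,
                "max_abs_delta_au": float(np.max(np.abs(fp.delta))),
                "n_wavenumbers_p_below_1e6": int(np.sum(fp.pvalues < 1e-6)),
            }
        }
    )
    summary.to_csv(ROOT / "results" / "differential_summary.tsv", sep="\t",
                   float_format="%.6g")
    print("protein ranking by |mean case - mean reference| (mg/mL):")
    print(ranking.round(4).to_string())
    print(f"\nmeasured vs 12-protein-modeled differential fingerprint: r = {r:.4f}")


if __name__ == "__main__":
    main()
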