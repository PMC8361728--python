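"""LFQ rescaling, coefficients of variation and fraction partitions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imfp.errors import DegenerateNormalizationError, ValidationError
from imfp.quantification import (
    apply_partition,
    coefficient_of_variation,
    read_panel,
    read_partition_map,
    rescale_lfq,
    spectral_cv,
    validate_partition_map,
    write_panel,
    write_partition_map,
)
from imfp import synthetic as syn


@pytest.fixture
def simple_table():
    return pd.DataFrame(
        {"ALB": [10.0, 10.0, 20.0], "HP": [4.0, 4.0, 4.0]},
        index=["r1", "r2", "c1"],
    )


class TestRescaleLfq:
    def test_reference_mean_maps_to_panel_value(self, simple_table):
        conc = rescale_lfq(simple_table, {"ALB": 45.0, "HP": 1.5}, ["r1", "r2"])
        assert conc.loc["r1", "ALB"] == pytest.approx(45.0)
        assert conc.loc["r2", "HP"] == pytest.approx(1.5)

    def test_double_intensity_doubles_concentration(self, simple_table):
        conc = rescale_lfq(simple_table, {"ALB": 45.0, "HP": 1.5}, ["r1", "r2"])
        assert conc.loc["c1", "ALB"] == pytest.approx(90.0)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=30, deadline=None, database=None)
    def test_scale_invariance_per_protein(self, k):
        t = pd.DataFrame({"ALB": [3.0, 5.0, 9.0]}, index=["a", "b", "c"])
        base = rescale_lfq(t, {"ALB": 45.0}, ["a", "b"])
        scaled = rescale_lfq(t * k, {"ALB": 45.0}, ["a", "b"])
        assert np.allclose(base.to_numpy(), scaled.to_numpy(), rtol=1e-10)

    def test_missing_intensity_propagates_as_missing(self):
        t = pd.DataFrame({"ALB": [10.0, np.nan, 12.0]}, index=["a", "b", "c"])
        conc = rescale_lfq(t, {"ALB": 45.0}, ["a", "c"])
        assert np.isnan(conc.loc["b", "ALB"])
        assert conc.loc["a", "ALB"] == pytest.approx(45.0 * 10 / 11)

    def test_all_missing_reference_is_degenerate(self):
        t = pd.DataFrame({"ALB": [np.nan, np.nan, 12.0]}, index=["a", "b", "c"])
        with pytest.raises(DegenerateNormalizationError, match="ALB"):
            rescale_lfq(t, {"ALB": 45.0}, ["a", "b"])

    def test_zero_reference_mean_is_reported_per_protein(self):
        t = pd.DataFrame({"ALB": [0.0, 0.0]}, index=["a", "b"])
        with pytest.raises(DegenerateNormalizationError, match="ALB"):
            rescale_lfq(t, {"ALB": 45.0}, ["a", "b"])

    def test_unknown_reference_id_and_protein_rejected(self, simple_table):
        with pytest.raises(ValidationError, match="absent"):
            rescale_lfq(simple_table, {"ALB": 45.0}, ["nope"])
        with pytest.raises(ValidationError, match="absent"):
            rescale_lfq(simple_table, {"TF": 2.5}, ["r1"])

    def test_negative_intensity_rejected(self):
        t = pd.DataFrame({"ALB": [-1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValidationError, match="negative"):
            rescale_lfq(t, {"ALB": 45.0}, ["a", "b"])

    def test_recovers_truth_through_origin_slope_near_one(self):
        """Generator closure: rescaled intensities track true concentrations."""
        cohort = syn.simulate_cohort(syn.CohortConfig(seed=13))
        ref = cohort.reference_ids
        proteins = list(cohort.config.panel)
        panel = cohort.truth.concentrations.loc[ref, proteins].mean()
        conc = rescale_lfq(cohort.intensities, panel, ref)
        for p in proteins:
            x = cohort.truth.concentrations.loc[ref, p].to_numpy()
            y = conc.loc[ref, p].to_numpy()
            slope = float(x @ y / (x @ x))
            assert 0.95 < slope < 1.05, p


class TestCoefficientOfVariation:
    def test_identical_replicates_have_zero_cv(self):
        t = pd.DataFrame({"ALB": [5.0, 5.0, 5.0], "HP": [2.0, 2.0, 2.0]})
        assert (coefficient_of_variation(t) == 0).all()

    def test_two_values_hand_computed(self):
        t = pd.DataFrame({"ALB": [90.0, 110.0]})
        cv = coefficient_of_variation(t)["ALB"]
        assert cv == pytest.approx(100.0 * np.sqrt(200.0) / 100.0)  # 14.1421...

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=30, deadline=None, database=None)
    def test_cv_is_unit_free(self, k):
        t = pd.DataFrame({"ALB": [3.0, 4.0, 6.0]})
        assert coefficient_of_variation(t * k)["ALB"] == pytest.approx(
            coefficient_of_variation(t)["ALB"], rel=1e-9
        )

    def test_fewer_than_two_values_rejected(self):
        t = pd.DataFrame({"ALB": [5.0, np.nan]})
        with pytest.raises(ValidationError, match=">= 2"):
            coefficient_of_variation(t)

    def test_nonpositive_mean_rejected(self):
        t = pd.DataFrame({"ALB": [0.0, 0.0, 0.0]})
        with pytest.raises(ValidationError, match="mean"):
            coefficient_of_variation(t)

    def test_lognormal_draws_realize_the_target_cv(self):
        """50 seeded reference cohorts: realized CVs scatter around 33% within
        the analytic sampling band (sd ~2.7 points at n = 93)."""
        cfg = syn.CohortConfig()
        realized = []
        for seed in range(50):
            rng = np.random.default_rng(40_000 + seed)
            conc, labels = syn.draw_concentrations(cfg, rng)
            cvs = coefficient_of_variation(conc, labels.index[labels == "reference"])
            realized.append(cvs)
        stacked = pd.concat(realized, axis=1)
        assert ((stacked > 22.0) & (stacked < 44.0)).all().all()
        per_protein_mean = stacked.mean(axis=1)
        assert ((per_protein_mean > 30.0) & (per_protein_mean < 36.0)).all()

    def test_replicate_intensities_realize_instrument_cv(self):
        reps = syn.simulate_replicate_intensities(n_replicates=8, seed=21)
        mean_cv = coefficient_of_variation(reps).mean()
        # 9% target; CV estimate at n = 8 has sd ~2.4 points per protein
        assert 5.0 < mean_cv < 13.0


class TestSpectralCv:
    def test_replicated_spectra_with_noise_have_small_cv(self, grid):
        from imfp.spectra import Spectrum

        rng = np.random.default_rng(2)
        base = 0.5 + 0.3 * np.exp(-0.5 * ((grid - 1650) / 30.0) ** 2)
        spectra = [
            Spectrum(grid, base * (1 + 0.02 * rng.standard_normal(grid.size)))
            for _ in range(20)
        ]
        cv = spectral_cv(spectra, window=(1400, 1800))
        assert 1.0 < cv < 3.0


class TestApplyPartition:
    @pytest.fixture
    def conc(self):
        return pd.DataFrame({"ALB": [45.0, 40.0], "HP": [1.5, 2.0]}, index=["a", "b"])

    def test_unit_partition_is_identity(self, conc):
        p = pd.DataFrame(
            {"hsa-enriched": [1.0, 1.0]}, index=["ALB", "HP"]
        )
        out = apply_partition(conc, p, "hsa-enriched")
        assert np.array_equal(out.to_numpy(), conc.to_numpy())

    def test_zero_partition_annihilates(self, conc):
        p = pd.DataFrame({"metabolite": [0.0, 0.0]}, index=["ALB", "HP"])
        assert (apply_partition(conc, p, "metabolite") == 0).all().all()

    def test_fractions_conserve_the_serum_table(self, conc):
        p = pd.DataFrame(
            {
                "hsa-enriched": [0.9, 0.75],
                "hsa-depleted": [0.1, 0.25],
            },
            index=["ALB", "HP"],
        )
        total = apply_partition(conc, p, "hsa-enriched") + apply_partition(
            conc, p, "hsa-depleted"
        )
        assert np.allclose(total.to_numpy(), conc.to_numpy(), rtol=0, atol=1e-12)

    def test_partition_value_outside_unit_interval_rejected(self, conc):
        p = pd.DataFrame({"hsa-enriched": [1.2, 0.5]}, index=["ALB", "HP"])
        with pytest.raises(ValidationError, match=r"\[0, 1\]"):
            apply_partition(conc, p, "hsa-enriched")

    def test_oversubscribed_protein_rejected(self):
        p = pd.DataFrame(
            {"hsa-enriched": [0.7], "hsa-depleted": [0.4]}, index=["ALB"]
        )
        with pytest.raises(ValidationError, match="sum above 1"):
            validate_partition_map(p)

    def test_missing_partition_entry_is_an_error_not_a_default(self, conc):
        p = pd.DataFrame({"hsa-enriched": [0.9]}, index=["ALB"])
        with pytest.raises(ValidationError, match="HP"):
            apply_partition(conc, p, "hsa-enriched")

    def test_default_partition_map_is_valid_and_roundtrips(self, tmp_path):
        p = pd.DataFrame.from_dict(syn.DEFAULT_PARTITION, orient="index")
        validate_partition_map(p)
        write_partition_map(p, tmp_path / "p.yaml")
        back = read_partition_map(tmp_path / "p.yaml")
        assert np.allclose(
            back.loc[p.index, p.columns].to_numpy(), p.to_numpy(), atol=1e-12
        )


class TestPanelIo:
    def test_panel_roundtrip(self, tmp_path):
        write_panel(syn.DEFAULT_PANEL, tmp_path / "panel.yaml")
        back = read_panel(tmp_path / "panel.yaml")
        assert dict(back) == pytest.approx(syn.DEFAULT_PANEL)

    def test_nonpositive_panel_rejected(self, tmp_path):
        (tmp_path / "panel.yaml").write_text("ALB: -1.0\n")
        with pytest.raises(ValidationError):
            read_panel(tmp_path / "panel.yaml")
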