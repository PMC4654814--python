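"""Generative-model checks: determinism, the c/2 signal law, artifact
mechanics, and the marginal frequencies the sample sheet encodes."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rctcnv import (
    SimulationConfig,
    simulate_cohort,
    simulate_count_table,
    simulate_expression,
    simulate_mlpa_peaks,
    simulate_multicopy_controls,
    simulate_sample_sheet,
    simulate_truth,
)
from rctcnv.types import ProbeRole


def replace(cfg, **kw):
    return dataclasses.replace(cfg, **kw)


class TestTruth:
    def test_no_variation_when_frequencies_zero(self, noiseless_config):
        truth = simulate_truth(noiseless_config)
        assert (truth.copies.to_numpy() == 2).all()
        assert truth.snp_artifact == {}
        assert truth.denaturation_failure == set()

    def test_nondiploid_count_in_poisson_band(self):
        # E[non-diploid] = n * g * loss_freq = 320 * 16 * 0.003 = 15.36
        cfg = SimulationConfig(loss_freq=0.003, seed=42)
        truth = simulate_truth(cfg)
        n_nd = len(truth.non_diploid())
        mean = 320 * 16 * 0.003
        lo, hi = stats.poisson.ppf([0.005, 0.995], mean)
        assert lo <= n_nd <= hi

    def test_same_seed_reproduces_everything(self, manifest):
        cfg = SimulationConfig(seed=7, loss_freq=0.01, snp_artifact_freq=0.02)
        a, b = simulate_cohort(cfg, manifest), simulate_cohort(cfg, manifest)
        pd.testing.assert_frame_equal(a.truth.copies, b.truth.copies)
        assert a.truth.snp_artifact == b.truth.snp_artifact
        pd.testing.assert_frame_equal(a.mlpa_peaks.values, b.mlpa_peaks.values)
        pd.testing.assert_frame_equal(a.count_table.values, b.count_table.values)
        pd.testing.assert_frame_equal(a.expression, b.expression)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_samples=5)
        with pytest.raises(ValueError):
            SimulationConfig(loss_freq=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(sigma_mlpa=-0.1)


class TestMlpaPeaks:
    def test_noiseless_diploid_targets_equal_references(self, manifest, noiseless_config):
        truth = simulate_truth(noiseless_config)
        peaks = simulate_mlpa_peaks(truth, manifest, noiseless_config)
        targets = [p.probe_id for p in manifest.target_probes]
        refs = [p.probe_id for p in manifest.reference_probes]
        t = peaks.values[targets].to_numpy()
        r = peaks.values[refs].to_numpy()
        assert np.allclose(t, t[0, 0]) and np.isclose(t[0, 0], r[0, 0])

    def test_single_copy_halves_the_peak(self, manifest, noiseless_config):
        truth = simulate_truth(noiseless_config)
        s = truth.samples[3]
        truth.copies.at[s, "CETP"] = 1
        peaks = simulate_mlpa_peaks(truth, manifest, noiseless_config)
        row = peaks.values.loc[s]
        assert row["CETP_P1"] == pytest.approx(0.5 * row["Ref_1"])

    def test_ligation_site_artifact_is_platform_specific(self, manifest, noiseless_config):
        truth = simulate_truth(noiseless_config)
        s = truth.samples[0]
        truth.snp_artifact[s] = {"APOA4"}
        peaks = simulate_mlpa_peaks(truth, manifest, noiseless_config)
        counts = simulate_count_table(truth, manifest, noiseless_config)
        assert peaks.values.at[s, "APOA4_P1"] == pytest.approx(
            0.5 * peaks.values.at[s, "Ref_1"])
        # the counting probe binds elsewhere in the gene: unaffected
        assert counts.values.at[s, "APOA4_P1"] == pytest.approx(
            counts.values.at[s, "Ref_1"])

    def test_denaturation_controls_silent_unless_failure(self, manifest, noiseless_config):
        truth = simulate_truth(noiseless_config)
        fail = truth.samples[5]
        truth.denaturation_failure.add(fail)
        peaks = simulate_mlpa_peaks(truth, manifest, noiseless_config)
        denat = [p.probe_id for p in manifest.probes
                 if p.role is ProbeRole.DENATURATION_CONTROL]
        ok = [s for s in truth.samples if s != fail]
        assert (peaks.values.loc[ok, denat].to_numpy() == 0).all()
        assert (peaks.values.loc[fail, denat] > 0).all()
        # genomic signal is globally depressed in the failure sample
        assert peaks.values.at[fail, "Ref_1"] == pytest.approx(
            0.5 * peaks.values.at[ok[0], "Ref_1"])

    def test_unknown_gene_in_truth_rejected(self, manifest, noiseless_config):
        truth = simulate_truth(noiseless_config)
        truth.copies["NOT_A_GENE"] = 2
        with pytest.raises(ValueError, match="NOT_A_GENE"):
            simulate_mlpa_peaks(truth, manifest, noiseless_config)


class TestCountTable:
    def test_noiseless_single_copy_gives_half_ratio(self, manifest, noiseless_config):
        truth = simulate_truth(noiseless_config)
        s = truth.samples[1]
        truth.copies.at[s, "ABCA1"] = 1
        counts = simulate_count_table(truth, manifest, noiseless_config)
        other = truth.samples[0]
        ratio = (counts.values.at[s, "ABCA1_P1"] / counts.values.at[s, "Ref_1"]) / (
            counts.values.at[other, "ABCA1_P1"] / counts.values.at[other, "Ref_1"])
        assert ratio == pytest.approx(0.5)


class TestExpression:
    def test_dosage_slope_on_log2_copies(self, manifest, noiseless_config):
        cfg = replace(noiseless_config, beta_expr=1.0)
        truth = simulate_truth(cfg)
        s1, s4 = truth.samples[0], truth.samples[1]
        truth.copies.at[s1, "LCAT"] = 1
        truth.copies.at[s4, "LCAT"] = 4
        expr = simulate_expression(truth, cfg)
        mu = expr.loc[truth.samples[2], "LCAT"]  # diploid baseline = mu_g
        assert expr.at[s4, "LCAT"] == pytest.approx(mu + 1.0)
        assert expr.at[s1, "LCAT"] == pytest.approx(mu - 1.0)

    def test_zero_beta_expression_independent_of_copies(self, noiseless_config):
        cfg = replace(noiseless_config, beta_expr=0.0)
        truth = simulate_truth(cfg)
        truth.copies.iloc[0, :] = 1
        expr = simulate_expression(truth, cfg)
        # with expr_sd = 0 and beta = 0 every sample sits at mu_g
        assert np.allclose(expr.iloc[0], expr.iloc[1])

    def test_homozygous_deletion_floored(self, noiseless_config):
        cfg = replace(noiseless_config, beta_expr=1.0)
        truth = simulate_truth(cfg)
        truth.copies.iat[0, 0] = 0
        expr = simulate_expression(truth, cfg)
        assert np.isfinite(expr.iat[0, 0])
        assert expr.iat[0, 0] == pytest.approx(expr.iat[1, 0] - 5.0)


class TestSampleSheet:
    def test_mixture_support_and_positivity(self):
        cfg = SimulationConfig(seed=3)
        records = simulate_sample_sheet(cfg, simulate_truth(cfg))
        hdl = [r.hdl for r in records]
        assert min(hdl) <= 40 and max(hdl) >= 60
        for r in records:
            assert r.hdl > 0 and r.tchol > 0 and r.trig > 0
            assert r.ldl is None or r.ldl > 0
        assert any(r.ldl is None for r in records)

    def test_therapy_fraction_in_binomial_band(self):
        cfg = SimulationConfig(seed=5)
        records = simulate_sample_sheet(cfg, simulate_truth(cfg))
        from rctcnv import Therapy
        pos = [r for r in records if r.hiv_positive]
        treated = [r for r in pos if r.therapy not in (Therapy.NONE, Therapy.NA)]
        lo, hi = stats.binom.ppf([0.005, 0.995], len(pos), 0.70)
        assert lo <= len(treated) <= hi


class TestMulticopyControls:
    def test_noiseless_panel_follows_half_copy_law(self, manifest_mc, noiseless_config):
        cfg = replace(noiseless_config, multicopy_panel=(2, 3, 4, 5, 6, 7))
        peaks, truth = simulate_multicopy_controls(cfg, manifest_mc)
        raw = peaks.values["DEFB103A_P1"] / peaks.values["Ref_1"]
        assert np.allclose(sorted(raw), [1.0, 1.5, 2.0, 2.5, 3.0, 3.5])

    def test_single_entry_panel(self, manifest_mc, noiseless_config):
        cfg = replace(noiseless_config, multicopy_panel=(2,))
        peaks, truth = simulate_multicopy_controls(cfg, manifest_mc)
        assert len(truth.samples) == 1
        assert (truth.copies.to_numpy() == 2).all()

    def test_missing_multicopy_probe_rejected(self, manifest, noiseless_config):
        with pytest.raises(ValueError, match="DEFB103A"):
            simulate_multicopy_controls(noiseless_config, manifest)
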