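"""Normalization, reference-sample selection, ratio computation and QC."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rctcnv import (
    PeakTable,
    RatioMatrix,
    Thresholds,
    apply_exclusions,
    compute_ratios,
    intra_sample_normalize,
    normalize_pipeline,
    probe_iqr_qc,
    replicate_sd,
    sample_qc,
    select_reference_samples,
    simulate_cohort,
    simulate_mlpa_peaks,
    simulate_truth,
)
from rctcnv.normalize import NormalizedTable
from rctcnv.types import Assay, ProbeDef, ProbeManifest, ProbeRole


def tiny_manifest():
    return ProbeManifest([
        ProbeDef("T1", "CETP", ProbeRole.TARGET, "16", 100, 160),
        ProbeDef("R1", "REF1", ProbeRole.REFERENCE, "1", 200, 260),
        ProbeDef("R2", "REF2", ProbeRole.REFERENCE, "2", 300, 360),
        ProbeDef("R3", "REF3", ProbeRole.REFERENCE, "3", 400, 460),
    ])


def peaks_from(rows: dict) -> PeakTable:
    return PeakTable(assay=Assay.MLPA,
                     values=pd.DataFrame(rows).T.astype(float))


class TestIntraSampleNormalize:
    @pytest.mark.parametrize("target,refs,expected", [
        (100.0, (100.0, 100.0, 100.0), 1.0),
        (50.0, (100.0, 100.0, 100.0), 0.5),
        (200.0, (100.0, 100.0, 100.0), 2.0),
    ])
    def test_geometric_mean_reference_normalization(self, target, refs, expected):
        peaks = peaks_from({"s1": {"T1": target, "R1": refs[0],
                                   "R2": refs[1], "R3": refs[2]}})
        out = intra_sample_normalize(peaks, tiny_manifest())
        assert out.values.at["s1", "T1"] == pytest.approx(expected)
        # references normalize to their own geometric mean
        assert out.values.at["s1", "R1"] == pytest.approx(refs[0] / np.exp(
            np.mean(np.log(refs))))

    def test_zero_reference_probe_flags_sample_unnormalizable(self):
        peaks = peaks_from({
            "good": {"T1": 100.0, "R1": 100.0, "R2": 100.0, "R3": 100.0},
            "bad": {"T1": 100.0, "R1": 0.0, "R2": 100.0, "R3": 100.0},
        })
        out = intra_sample_normalize(peaks, tiny_manifest())
        assert out.excluded_samples == {"bad": "unnormalizable"}
        assert list(out.values.index) == ["good"]

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_invariance(self, scale):
        # multiplying one sample's entire peak vector by any positive
        # constant leaves its normalized row (hence its ratios) unchanged
        base = {"T1": 80.0, "R1": 90.0, "R2": 110.0, "R3": 130.0}
        peaks = peaks_from({"a": base, "b": {k: v * scale for k, v in base.items()}})
        out = intra_sample_normalize(peaks, tiny_manifest())
        assert np.allclose(out.values.loc["a"], out.values.loc["b"],
                           rtol=1e-9, atol=1e-9)


class TestSampleQC:
    def test_simulated_failure_modes_are_caught(self, manifest):
        import rctcnv
        cfg = rctcnv.SimulationConfig(seed=21, denat_fail_freq=0.05,
                                      loss_freq=0.0, snp_artifact_freq=0.0)
        truth = simulate_truth(cfg)
        peaks = simulate_mlpa_peaks(truth, manifest, cfg)
        normalized = intra_sample_normalize(peaks, manifest)
        excluded = sample_qc(peaks, normalized, manifest)
        assert set(excluded) == truth.denaturation_failure
        assert all(reason == "denaturation" for reason in excluded.values())

    def test_clean_cohort_passes(self, manifest, noisy_config):
        truth = simulate_truth(noisy_config)
        peaks = simulate_mlpa_peaks(truth, manifest, noisy_config)
        normalized = intra_sample_normalize(peaks, manifest)
        assert sample_qc(peaks, normalized, manifest) == {}

    def test_attrition_below_input_cohort(self, manifest):
        # a 366-sample run with failure modes yields fewer analyzable samples
        import rctcnv
        cfg = rctcnv.SimulationConfig(n_samples=366, seed=9,
                                      denat_fail_freq=0.03)
        truth = simulate_truth(cfg)
        peaks = simulate_mlpa_peaks(truth, manifest, cfg)
        normalized = intra_sample_normalize(peaks, manifest)
        excluded = sample_qc(peaks, normalized, manifest)
        survivors = apply_exclusions(normalized, excluded)
        assert 0 < len(survivors.samples) < 366


class TestReferenceSelection:
    def test_tie_break_by_sample_id(self, manifest, noiseless_config):
        truth = simulate_truth(noiseless_config)
        peaks = simulate_mlpa_peaks(truth, manifest, noiseless_config)
        normalized = intra_sample_normalize(peaks, manifest)
        refs = select_reference_samples(normalized, 5, manifest)
        assert refs == sorted(normalized.samples)[:5]

    def test_single_copy_sample_never_a_reference(self, manifest, noisy_config):
        truth = simulate_truth(noisy_config)
        outlier = truth.samples[10]
        truth.copies.at[outlier, "CETP"] = 1
        peaks = simulate_mlpa_peaks(truth, manifest, noisy_config)
        normalized = intra_sample_normalize(peaks, manifest)
        for k in (5, 32, 100):
            assert outlier not in select_reference_samples(normalized, k, manifest)

    def test_permutation_invariance(self, manifest, noisy_config):
        truth = simulate_truth(noisy_config)
        peaks = simulate_mlpa_peaks(truth, manifest, noisy_config)
        normalized = intra_sample_normalize(peaks, manifest)
        shuffled = NormalizedTable(values=normalized.values.iloc[::-1])
        assert (select_reference_samples(normalized, 10, manifest)
                == select_reference_samples(shuffled, 10, manifest))

    @pytest.mark.parametrize("k", [0, 1, 320, 1000])
    def test_k_out_of_range_rejected(self, manifest, noisy_config, k):
        truth = simulate_truth(noisy_config)
        peaks = simulate_mlpa_peaks(truth, manifest, noisy_config)
        normalized = intra_sample_normalize(peaks, manifest)
        with pytest.raises(ValueError):
            select_reference_samples(normalized, k, manifest)


class TestComputeRatios:
    def test_noiseless_single_copy_gives_exact_half(self, manifest, noiseless_config):
        truth = simulate_truth(noiseless_config)
        s = truth.samples[7]
        truth.copies.at[s, "CETP"] = 1
        peaks = simulate_mlpa_peaks(truth, manifest, noiseless_config)
        normalized = intra_sample_normalize(peaks, manifest)
        refs = select_reference_samples(normalized, 5, manifest)
        ratios = compute_ratios(normalized, refs)
        assert ratios.values.at[s, "CETP_P1"] == pytest.approx(0.5, abs=1e-12)
        others = [x for x in truth.samples if x != s]
        assert np.allclose(ratios.values.loc[others, "CETP_P1"], 1.0, atol=1e-12)

    def test_reference_samples_average_to_unity(self, manifest, noisy_config):
        truth = simulate_truth(noisy_config)
        peaks = simulate_mlpa_peaks(truth, manifest, noisy_config)
        normalized = intra_sample_normalize(peaks, manifest)
        refs = select_reference_samples(normalized, 12, manifest)
        ratios = compute_ratios(normalized, refs)
        ref_means = ratios.values.loc[refs].mean(axis=0).dropna()
        assert np.allclose(ref_means, 1.0, atol=1e-12)

    def test_diploid_ratios_within_lognormal_band(self, manifest, noisy_config):
        # sigma = 0.05 per platform: ~99% of diploid target ratios in [0.85, 1.15]
        truth = simulate_truth(noisy_config)
        ratios = normalize_pipeline(
            simulate_mlpa_peaks(truth, manifest, noisy_config), manifest)
        targets = [p.probe_id for p in manifest.target_probes]
        vals = ratios.values[targets].to_numpy().ravel()
        assert np.mean((vals > 0.85) & (vals < 1.15)) > 0.98

    def test_renormalization_is_idempotent(self, manifest, noisy_config):
        truth = simulate_truth(noisy_config)
        peaks = simulate_mlpa_peaks(truth, manifest, noisy_config)
        normalized = intra_sample_normalize(peaks, manifest)
        refs = select_reference_samples(normalized, 10, manifest)
        ratios = compute_ratios(normalized, refs)
        again = compute_ratios(NormalizedTable(values=ratios.values), refs)
        pd.testing.assert_frame_equal(ratios.values, again.values)

    def test_unknown_reference_sample_rejected(self, manifest, noiseless_config):
        truth = simulate_truth(noiseless_config)
        peaks = simulate_mlpa_peaks(truth, manifest, noiseless_config)
        normalized = intra_sample_normalize(peaks, manifest)
        with pytest.raises(ValueError, match="absent"):
            compute_ratios(normalized, ["NOPE"])


class TestProbeIqrQC:
    def test_noiseless_iqrs_all_zero(self, manifest, noiseless_config):
        truth = simulate_truth(noiseless_config)
        ratios = normalize_pipeline(
            simulate_mlpa_peaks(truth, manifest, noiseless_config), manifest)
        qc = probe_iqr_qc(ratios, manifest)
        # denaturation controls are silent in a healthy cohort (0/0 -> NaN)
        assert (qc["iqr"].dropna() == 0).all()
        assert not qc["over_dispersed"].any()

    def test_target_iqrs_within_reference_envelope(self, manifest, noisy_config):
        truth = simulate_truth(noisy_config)
        ratios = normalize_pipeline(
            simulate_mlpa_peaks(truth, manifest, noisy_config), manifest)
        qc = probe_iqr_qc(ratios, manifest)
        assert not qc["over_dispersed"].any()

    def test_overdispersed_probe_flagged(self, manifest, noisy_config):
        truth = simulate_truth(noisy_config)
        ratios = normalize_pipeline(
            simulate_mlpa_peaks(truth, manifest, noisy_config), manifest)
        rng = np.random.default_rng(0)
        # inject 3x assay noise into one target probe's ratios
        ratios.values["CETP_P1"] *= np.exp(rng.normal(0, 0.15, len(ratios.samples)))
        qc = probe_iqr_qc(ratios, manifest)
        assert qc.at["CETP_P1", "over_dispersed"]


class TestReplicateSD:
    def _ratio(self, df):
        return RatioMatrix(values=df, reference_samples=[])

    def test_identical_runs_are_consistent(self):
        df = pd.DataFrame({"P1": [1.0, 0.5], "P2": [1.0, 1.0]}, index=["a", "b"])
        sd, ok = replicate_sd([self._ratio(df), self._ratio(df.copy())])
        assert (sd.to_numpy() == 0).all()
        assert ok.all().all()

    def test_divergent_cell_flagged_inconsistent(self):
        df1 = pd.DataFrame({"P1": [1.0, 0.60]}, index=["a", "b"])
        df2 = pd.DataFrame({"P1": [1.0, 0.70]}, index=["a", "b"])
        sd, ok = replicate_sd([self._ratio(df1), self._ratio(df2)])
        # two points 0.1 apart: sd = 0.1 / sqrt(2) ~ 0.0707 > 0.05
        assert sd.at["b", "P1"] == pytest.approx(0.1 / np.sqrt(2))
        assert not ok.at["b", "P1"] and ok.at["a", "P1"]

    def test_replicate_run_confirms_flagged_losses(self, manifest):
        # an independent noise stream reproduces the losses consistently
        import rctcnv
        cfg = rctcnv.SimulationConfig(seed=13, loss_freq=0.0,
                                      snp_artifact_freq=0.0, denat_fail_freq=0.0)
        truth = simulate_truth(cfg)
        lost = truth.samples[4]
        truth.copies.at[lost, "ABCA1"] = 1
        runs = []
        for stream in (1, 50):
            peaks = simulate_mlpa_peaks(truth, manifest, cfg, stream=stream)
            runs.append(normalize_pipeline(peaks, manifest))
        sd, ok = replicate_sd(runs)
        assert ok.at[lost, "ABCA1_P1"]
        assert runs[0].values.at[lost, "ABCA1_P1"] < 0.7

    def test_single_run_rejected(self):
        df = pd.DataFrame({"P1": [1.0]}, index=["a"])
        with pytest.raises(ValueError):
            replicate_sd([self._ratio(df)])
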