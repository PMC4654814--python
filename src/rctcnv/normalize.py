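"""Reference-probe normalization, reference-sample selection, ratio
computation and QC for targeted dosage assays.

The two-step normalization mirrors standard MLPA practice:

1. *Intra-sample*: each probe's signal is divided by the geometric mean
   of the sample's reference-probe signals, removing per-sample
   amplification and input differences.  The geometric mean is the
   natural choice under multiplicative noise.
2. *Inter-sample*: normalized signals are divided by the mean normalized
   signal of a set of *reference samples* — experimental samples whose
   probe profile sits closest to the cohort mean, standing in for true
   two-copy calibrators which are unavailable for these loci.  The
   implicit assumption is that the modal state of every locus in the
   cohort is two copies, so a ratio of 1.0 means diploid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import PeakTable, ProbeManifest, ProbeRole, RatioMatrix, Thresholds


@dataclass
class NormalizedTable:
    """Samples x probes matrix after intra-sample normalization.

    Control probes are carried through (divided by the same reference
    geometric mean, i.e. expressed relative to the sample's reference
    level) so that sample QC can inspect them; they are excluded from
    the geometric mean itself.  ``excluded_samples`` maps samples that
    could not be normalized, or failed QC, to a reason code.
    """

    values: pd.DataFrame
    excluded_samples: dict[str, str] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def probes(self) -> list[str]:
        return list(self.values.columns)


def intra_sample_normalize(peaks: PeakTable, manifest: ProbeManifest) -> NormalizedTable:
    """Divide every probe signal by the geometric mean of the sample's
    reference-probe signals.

    Samples in which any reference probe has non-positive signal cannot
    be normalized; they are dropped from the matrix and recorded with
    reason ``unnormalizable``.
    """
    ref_ids = [p.probe_id for p in manifest.reference_probes if p.probe_id in peaks.values.columns]
    if len(ref_ids) < 2:
        raise ValueError("need >=2 reference probes present in the peak table")
    vals = peaks.values
    ref = vals[ref_ids]
    ok = (ref > 0).all(axis=1)
    excluded = {s: "unnormalizable" for s in vals.index[~ok]}
    good = vals.loc[ok]
    geo = np.exp(np.log(good[ref_ids]).mean(axis=1))
    normalized = good.div(geo, axis=0)
    return NormalizedTable(values=normalized, excluded_samples=excluded)


def sample_qc(peaks: PeakTable, normalized: NormalizedTable,
              manifest: ProbeManifest,
              thresholds: Thresholds = Thresholds()) -> dict[str, str]:
    """Per-sample QC on raw signals; returns {sample_id: reason}.

    A sample is excluded when (a) the coefficient of variation of its
    reference-probe signals exceeds ``ref_cv_max`` (noisy/degraded
    reference behaviour), (b) denaturation-control signal exceeds
    ``control_signal_frac`` of the mean reference signal (incomplete
    denaturation: these probes only find their hairpin template when
    genomic DNA failed to denature), or (c) ligation-control signal falls
    below that same fraction of the reference mean (failed ligation
    reaction).  The first matching reason is recorded.
    """
    ref_ids = [p.probe_id for p in manifest.reference_probes if p.probe_id in peaks.values.columns]
    denat_ids = [p.probe_id for p in manifest.probes
                 if p.role is ProbeRole.DENATURATION_CONTROL and p.probe_id in peaks.values.columns]
    lig_ids = [p.probe_id for p in manifest.probes
               if p.role is ProbeRole.LIGATION_CONTROL and p.probe_id in peaks.values.columns]
    excluded: dict[str, str] = {}
    for s in normalized.samples:
        row = peaks.values.loc[s]
        ref = row[ref_ids]
        ref_mean = float(ref.mean())
        if ref_mean <= 0:
            excluded[s] = "reference_signal_zero"
            continue
        cv = float(ref.std(ddof=1) / ref_mean)
        if cv > thresholds.ref_cv_max:
            excluded[s] = "reference_cv"
            continue
        if denat_ids and float(row[denat_ids].mean()) > thresholds.control_signal_frac * ref_mean:
            excluded[s] = "denaturation"
            continue
        if lig_ids and float(row[lig_ids].mean()) < thresholds.control_signal_frac * ref_mean:
            excluded[s] = "ligation"
    return excluded


def apply_exclusions(normalized: NormalizedTable, excluded: dict[str, str]) -> NormalizedTable:
    """Drop QC-failed samples from the matrix, keeping the reasons."""
    keep = [s for s in normalized.samples if s not in excluded]
    merged = dict(normalized.excluded_samples)
    merged.update(excluded)
    return NormalizedTable(values=normalized.values.loc[keep], excluded_samples=merged)


def select_reference_samples(normalized: NormalizedTable, k: int,
                             manifest: Optional[ProbeManifest] = None) -> list[str]:
    """Pick the k samples whose normalized profile is closest to the
    cohort mean, to serve as two-copy calibrators.

    score(s) = mean over probes p of |n(s,p) - m(p)| / m(p) where m(p) is
    the cohort mean of probe p.  Target and reference probes enter the
    score jointly; control probes are excluded when a manifest is given
    (their near-zero means would dominate the relative deviation).  Ties
    are broken by sample id so the selection is order-independent.
    """
    n = len(normalized.samples)
    if not (2 <= k < n):
        raise ValueError(f"k must satisfy 2 <= k < n_samples ({n}), got {k}")
    vals = normalized.values
    if manifest is not None:
        cols = [p.probe_id for p in manifest.probes
                if p.role in (ProbeRole.TARGET, ProbeRole.REFERENCE)
                and p.probe_id in vals.columns]
        vals = vals[cols]
    m = vals.mean(axis=0)
    usable = m > 0
    rel_dev = (vals.loc[:, usable] - m[usable]).abs().div(m[usable], axis=1)
    score = rel_dev.mean(axis=1)
    order = sorted(score.index, key=lambda s: (score[s], s))
    return order[:k]


def compute_ratios(normalized: NormalizedTable, reference_ids: Sequence[str]) -> RatioMatrix:
    """Copy-number ratios: each sample's normalized signal divided by the
    reference samples' mean normalized signal, per probe.

    Probes whose reference mean is zero are uncallable: their column is
    set to NaN and listed in ``uncallable_probes``.  By construction the
    reference samples' mean ratio is exactly 1 for every callable probe.
    """
    missing = [s for s in reference_ids if s not in normalized.values.index]
    if missing:
        raise ValueError(f"reference samples absent from table: {missing}")
    ref_mean = normalized.values.loc[list(reference_ids)].mean(axis=0)
    uncallable = list(ref_mean.index[ref_mean <= 0])
    safe = ref_mean.replace(0, np.nan)
    ratios = normalized.values.div(safe, axis=1)
    ratios[uncallable] = np.nan
    return RatioMatrix(values=ratios, reference_samples=list(reference_ids),
                       uncallable_probes=uncallable)


def probe_iqr_qc(ratios: RatioMatrix, manifest: ProbeManifest,
                 thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Per-probe dispersion QC.

    Computes each probe's ratio interquartile range and flags target
    probes whose IQR exceeds ``ref_iqr_inflation`` times the median
    reference-probe IQR — dispersion beyond what properly functioning
    two-copy probes show in the same run, suggesting either common CNV
    at the locus or a misbehaving probe.
    """
    if len(ratios.samples) < 8:
        raise ValueError("need >=8 samples for a meaningful IQR")
    roles = {p.probe_id: p.role for p in manifest.probes}
    q3 = ratios.values.quantile(0.75)
    q1 = ratios.values.quantile(0.25)
    iqr = q3 - q1
    ref_iqrs = [iqr[p] for p in ratios.probes
                if roles.get(p) is ProbeRole.REFERENCE and np.isfinite(iqr[p])]
    ref_median = float(np.median(ref_iqrs)) if ref_iqrs else np.nan
    rows = []
    for p in ratios.probes:
        role = roles.get(p)
        flagged = bool(
            role is ProbeRole.TARGET
            and np.isfinite(ref_median)
            and np.isfinite(iqr[p])
            and iqr[p] > thresholds.ref_iqr_inflation * ref_median
        )
        rows.append({"probe_id": p, "role": role.value if role else "unknown",
                     "iqr": float(iqr[p]), "over_dispersed": flagged})
    out = pd.DataFrame(rows).set_index("probe_id")
    out.attrs["median_reference_iqr"] = ref_median
    return out


def replicate_sd(runs: Sequence[RatioMatrix],
                 thresholds: Thresholds = Thresholds()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Across-run standard deviation per (sample, probe) and a boolean
    consistency matrix (sd below ``sd_genuine``).

    A flagged ratio that reproduces across independent runs with small
    SD is likely a genuine dosage change rather than a one-off assay
    fluctuation.  Only samples and probes shared by all runs are
    compared.
    """
    if len(runs) < 2:
        raise ValueError("replicate SD needs at least 2 runs")
    common_samples = runs[0].values.index
    common_probes = runs[0].values.columns
    for r in runs[1:]:
        common_samples = common_samples.intersection(r.values.index)
        common_probes = common_probes.intersection(r.values.columns)
    if len(common_samples) == 0 or len(common_probes) == 0:
        raise ValueError("runs share no samples/probes")
    stack = np.stack([r.values.loc[common_samples, common_probes].to_numpy() for r in runs])
    sd = pd.DataFrame(np.std(stack, axis=0, ddof=1),
                      index=common_samples, columns=common_probes)
    consistent = sd < thresholds.sd_genuine
    return sd, consistent


def normalize_pipeline(peaks: PeakTable, manifest: ProbeManifest,
                       k_reference: Optional[int] = None,
                       thresholds: Thresholds = Thresholds()) -> RatioMatrix:
    """Full two-pass normalization: provisional normalize -> sample QC ->
    re-select references among survivors -> ratios.

    ``k_reference`` defaults to max(5, 10% of surviving cohort).  The
    two-pass structure means a denaturation-failure or otherwise failed
    sample can neither become a reference nor receive a ratio.
    """
    normalized = intra_sample_normalize(peaks, manifest)
    excluded = sample_qc(peaks, normalized, manifest, thresholds)
    normalized = apply_exclusions(normalized, excluded)
    n = len(normalized.samples)
    if n < 3:
        raise ValueError("too few samples survive QC to normalize")
    k = k_reference if k_reference is not None else max(5, int(np.ceil(0.10 * n)))
    k = min(k, n - 1)
    refs = select_reference_samples(normalized, k, manifest)
    ratios = compute_ratios(normalized, refs)
    ratios.values.attrs["excluded_samples"] = dict(normalized.excluded_samples)
    return ratios
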