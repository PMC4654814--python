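"""Copy-number calling from ratio matrices.

Two callers are provided, matching how targeted dosage assays are read
out in practice:

* **Threshold calling** for loci without known-copy calibrators: the
  conventional dosage-quotient cut-offs (loss below 0.7, gain above 1.3)
  classify each ratio, with an explicit *borderline* class for ratios
  sitting on a cut-off — those indicate a possible change and are still
  flagged for orthogonal follow-up.
* **Anchored cluster calling** for loci where control samples of known
  copy number exist: cluster centers at (c/2) x scale are calibrated on
  the anchors, each sample is assigned to the nearest center on the log
  scale, and integer copies beyond the anchored range are extrapolated
  by rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import CallStatus, CopyCall, ProbeManifest, RatioMatrix, Thresholds

#: Hard cap for extrapolated copy numbers, beyond the multicopy range the
#: QC panel is designed to resolve.
MAX_COPIES = 12


def threshold_call(ratio: float, thresholds: Thresholds = Thresholds()) -> CallStatus:
    """Classify a single copy-number ratio against the dosage cut-offs.

    Ratios within ``boundary_tol`` of a cut-off are borderline: a ratio
    exactly on the loss threshold is treated as a possible loss (flagged),
    not as normal.
    """
    if not np.isfinite(ratio) or ratio < 0:
        raise ValueError(f"ratio must be finite and >= 0, got {ratio}")
    t = thresholds
    if abs(ratio - t.loss_cut) <= t.boundary_tol:
        return CallStatus.BORDERLINE_LOSS
    if ratio < t.loss_cut:
        return CallStatus.LOSS
    if abs(ratio - t.gain_cut) <= t.boundary_tol:
        return CallStatus.BORDERLINE_GAIN
    if ratio > t.gain_cut:
        return CallStatus.GAIN
    return CallStatus.NORMAL


def call_matrix(ratios: RatioMatrix, manifest: ProbeManifest,
                thresholds: Thresholds = Thresholds()) -> list[CopyCall]:
    """One CopyCall per (sample, target gene).

    When the ratio matrix carries replicate SDs, flagged calls get a
    ``replicate_consistent`` annotation (SD below ``sd_genuine``).
    Probes marked uncallable, or NaN cells, are skipped.
    """
    calls: list[CopyCall] = []
    for probe in manifest.target_probes:
        # ratio matrices may be keyed by probe id or (pre-aggregated) by gene
        key = probe.probe_id if probe.probe_id in ratios.values.columns else probe.gene
        if key not in ratios.values.columns or key in ratios.uncallable_probes:
            continue
        col = ratios.values[key]
        sd_col = ratios.sd[key] if ratios.sd is not None and key in ratios.sd.columns else None
        for sample, r in col.items():
            if not np.isfinite(r):
                continue
            status = threshold_call(float(r), thresholds)
            consistent: Optional[bool] = None
            if status.flagged and sd_col is not None and np.isfinite(sd_col[sample]):
                consistent = bool(sd_col[sample] < thresholds.sd_genuine)
            calls.append(CopyCall(sample_id=str(sample), gene=probe.gene,
                                  ratio=float(r), status=status,
                                  replicate_consistent=consistent))
    return calls


def flagged_calls(calls: Sequence[CopyCall]) -> list[CopyCall]:
    """Calls departing from the two-copy normal range."""
    return [c for c in calls if c.flagged]


class AnchorError(ValueError):
    """Anchors imply mutually inconsistent ratio scales."""


@dataclass
class ClusterModel:
    """Anchored 1-D cluster model for discrete copy calling.

    ``scale`` maps ratio space to copy space: a sample with ratio r has
    estimated copies 2r/scale.  ``centers`` holds the per-copy expected
    ratios after one mean-refinement pass; ``assignment`` the integer
    copies per sample; ``dispersion`` the pooled within-cluster SD of
    ratios.
    """

    anchor_copies: list[int]
    scale: float
    centers: dict[int, float]
    assignment: pd.Series
    dispersion: float = 0.0

    def __post_init__(self) -> None:
        cs = sorted(self.centers)
        vals = [self.centers[c] for c in cs]
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("cluster centers must be strictly increasing in copies")
        if (self.assignment < 0).any():
            raise ValueError("assignments must be >= 0")


def _assign(ratios: np.ndarray, scale: float) -> np.ndarray:
    """Nearest-center assignment on the log scale over copies 0..MAX_COPIES.

    Copy 0 has no log-scale center; a ratio below half the one-copy
    center (the linear midpoint between 0 and scale/2) is called 0.
    """
    centers = np.array([(c / 2.0) * scale for c in range(1, MAX_COPIES + 1)])
    out = np.empty(len(ratios), dtype=int)
    zero_cut = 0.25 * scale  # midpoint between copies 0 and 1 in ratio space
    for i, r in enumerate(ratios):
        if r <= zero_cut:
            out[i] = 0
        else:
            out[i] = 1 + int(np.argmin(np.abs(np.log(r) - np.log(centers))))
    return out


def cluster_call(raw_ratios: pd.Series,
                 anchors: Sequence[tuple[str, int]],
                 max_scale_disagreement: float = 0.25,
                 max_iter: int = 25) -> ClusterModel:
    """Discrete copy numbers from raw ratios, anchored on samples of
    known copy number.

    The anchors calibrate a single multiplicative scale (geometric mean
    of ratio / (copies/2) across anchors); anchors whose implied scales
    disagree by more than ``max_scale_disagreement`` raise
    :class:`AnchorError`.  Samples are assigned to the nearest center
    (c/2) x scale on the log scale; the scale is then re-estimated from
    *all* assigned samples (geometric mean of ratio / (copies/2)) and
    assignment repeated until a fixed point.  Refining the shared scale
    rather than per-cluster means exploits the structural constraint
    that centers are proportional to copy number: it corrects a
    miscalibrated anchor scale, which free mean updates cannot, and is
    well defined even for singleton clusters.  The iteration is
    deterministic and converges in a handful of passes.
    """
    if len(anchors) == 0:
        raise AnchorError("at least one anchor sample is required")
    scales = []
    for sample, copies in anchors:
        if sample not in raw_ratios.index:
            raise AnchorError(f"anchor sample {sample!r} absent from ratios")
        if copies <= 0:
            raise AnchorError("anchor copies must be positive to calibrate scale")
        scales.append(raw_ratios[sample] / (copies / 2.0))
    scales = np.asarray(scales, dtype=float)
    if scales.max() / scales.min() - 1.0 > max_scale_disagreement:
        raise AnchorError(
            f"anchor-implied scales disagree by more than {max_scale_disagreement:.0%}: "
            f"{scales.round(3).tolist()}"
        )
    scale = float(np.exp(np.mean(np.log(scales))))

    vals = raw_ratios.to_numpy(dtype=float)
    assign = _assign(vals, scale)
    for _ in range(max_iter):
        nonzero = assign > 0
        if not nonzero.any():
            break
        new_scale = float(np.exp(np.mean(
            np.log(vals[nonzero] / (assign[nonzero] / 2.0)))))
        new_assign = _assign(vals, new_scale)
        converged = (new_assign == assign).all()
        assign, scale = new_assign, new_scale
        if converged:
            break
    assignment = pd.Series(assign, index=raw_ratios.index, name="copies")

    disp = []
    for c in np.unique(assign):
        members = vals[assign == c]
        if len(members) > 1:
            disp.append(np.std(members, ddof=1))
    dispersion = float(np.mean(disp)) if disp else 0.0

    centers = {int(c): (c / 2.0) * scale for c in np.unique(assign)}
    return ClusterModel(anchor_copies=sorted({c for _, c in anchors}),
                        scale=scale, centers=centers,
                        assignment=assignment, dispersion=dispersion)
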