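"""Orthogonal confirmation of flagged copy-number calls.

A dosage change that is real should replicate on an independent platform
whose probes bind a different region of the gene.  A loss seen by MLPA
but not by the counting assay is the signature of a *ligation-site
artifact*: a sequence variant under the MLPA probe's ligation site that
halves that probe's signal in heterozygotes without any change in copy
number.  (The alternative explanation — a small CNV covering the MLPA
probe but not the counting probe — cannot be excluded without
sequencing; each artifact verdict carries that caveat.)
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import CallStatus, CopyCall, ProbeManifest, RatioMatrix, Thresholds
from .simulate import TruthTable


class Verdict(str, enum.Enum):
    CONFIRMED_LOSS = "confirmed_loss"
    CONFIRMED_GAIN = "confirmed_gain"
    ARTIFACT_SUSPECTED = "artifact_suspected"
    UNCONFIRMED_BORDERLINE = "unconfirmed_borderline"
    DISCORDANT_UNEXPLAINED = "discordant_unexplained"
    UNTESTED = "untested"


ARTIFACT_CAVEAT = (
    "platform-specific loss; consistent with a ligation-site variant under "
    "the MLPA probe, but a small CNV missed by the orthogonal probe cannot "
    "be excluded without sequencing"
)


@dataclass
class ConfirmedCall:
    """Cross-platform verdict for one flagged call."""

    sample_id: str
    gene: str
    mlpa_ratio: float
    ortho_ratio: Optional[float]
    verdict: Verdict
    caveat: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.ortho_ratio is None) != (self.verdict is Verdict.UNTESTED):
            raise ValueError("verdict is untested iff the orthogonal ratio is missing")


def _gene_ratio_lookup(ortho: Union[RatioMatrix, pd.DataFrame],
                       manifest: Optional[ProbeManifest]) -> pd.DataFrame:
    """Orthogonal ratios as a samples x genes frame.

    Accepts either a gene-keyed DataFrame or a probe-keyed RatioMatrix
    plus the manifest to map target probes to genes.
    """
    if isinstance(ortho, pd.DataFrame):
        return ortho
    df = ortho.values
    if manifest is None:
        return df
    mapping = {p.probe_id: p.gene for p in manifest.target_probes
               if p.probe_id in df.columns}
    return df[list(mapping)].rename(columns=mapping)


def confirm_calls(mlpa_calls: Sequence[CopyCall],
                  ortho_ratios: Union[RatioMatrix, pd.DataFrame],
                  thresholds: Thresholds = Thresholds(),
                  manifest: Optional[ProbeManifest] = None) -> list[ConfirmedCall]:
    """Assign one verdict to every flagged MLPA call.

    * loss on both platforms -> ``confirmed_loss``; gain on both ->
      ``confirmed_gain``
    * unambiguous MLPA loss, orthogonal normal -> ``artifact_suspected``
      (binding-site artifacts are platform-specific by nature, so this
      verdict is deliberately asymmetric)
    * borderline MLPA loss, orthogonal normal -> ``unconfirmed_borderline``
    * any other combination -> ``discordant_unexplained``
    * no orthogonal measurement for that (sample, gene) -> ``untested``

    Non-flagged calls are ignored; the verdicts partition the flagged set.
    """
    gene_ratios = _gene_ratio_lookup(ortho_ratios, manifest)
    t = thresholds
    out: list[ConfirmedCall] = []
    for call in mlpa_calls:
        if not call.flagged:
            continue
        o: Optional[float] = None
        if call.sample_id in gene_ratios.index and call.gene in gene_ratios.columns:
            v = gene_ratios.at[call.sample_id, call.gene]
            if np.isfinite(v):
                o = float(v)
        if o is None:
            out.append(ConfirmedCall(call.sample_id, call.gene, call.ratio,
                                     None, Verdict.UNTESTED))
            continue
        o_status = _ortho_status(o, t)
        if call.status in (CallStatus.LOSS, CallStatus.BORDERLINE_LOSS):
            if o_status is CallStatus.LOSS:
                verdict, caveat = Verdict.CONFIRMED_LOSS, None
            elif o_status is CallStatus.NORMAL:
                if call.status is CallStatus.LOSS:
                    verdict, caveat = Verdict.ARTIFACT_SUSPECTED, ARTIFACT_CAVEAT
                else:
                    verdict, caveat = Verdict.UNCONFIRMED_BORDERLINE, None
            else:
                verdict, caveat = Verdict.DISCORDANT_UNEXPLAINED, None
        else:  # gain side
            if o_status is CallStatus.GAIN:
                verdict, caveat = Verdict.CONFIRMED_GAIN, None
            else:
                verdict, caveat = Verdict.DISCORDANT_UNEXPLAINED, None
        out.append(ConfirmedCall(call.sample_id, call.gene, call.ratio, o,
                                 verdict, caveat))
    return out


def _ortho_status(ratio: float, t: Thresholds) -> CallStatus:
    """Three-way status for the confirmation platform: borderline bands
    collapse to the side they sit on (a confirmation at the threshold is
    still not a clear loss/gain)."""
    if ratio < t.loss_cut - t.boundary_tol:
        return CallStatus.LOSS
    if ratio > t.gain_cut + t.boundary_tol:
        return CallStatus.GAIN
    return CallStatus.NORMAL


def confirmation_summary(confirmed: Sequence[ConfirmedCall],
                         cohort_size: int) -> dict:
    """Verdict counts and the confirmed-CNV fraction of the cohort.

    ``confirmed_fraction_percent`` is 100 x (confirmed losses + gains) /
    cohort_size, rounded to one decimal place — the headline rate of
    orthogonally validated CNV in the screen.
    """
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    counts = {v.value: 0 for v in Verdict}
    for c in confirmed:
        counts[c.verdict.value] += 1
    n_confirmed = counts[Verdict.CONFIRMED_LOSS.value] + counts[Verdict.CONFIRMED_GAIN.value]
    return {
        "cohort_size": int(cohort_size),
        "n_flagged": len(confirmed),
        "verdict_counts": counts,
        "confirmed_losses": counts[Verdict.CONFIRMED_LOSS.value],
        "confirmed_gains": counts[Verdict.CONFIRMED_GAIN.value],
        "confirmed_fraction_percent": round(100.0 * n_confirmed / cohort_size, 1),
    }


def artifact_sensitivity(confirmed: Sequence[ConfirmedCall],
                         truth: TruthTable) -> dict:
    """Sensitivity/specificity of the artifact verdict against simulated
    ground truth (simulation-only diagnostic).

    Positives are (sample, gene) pairs carrying a ligation-site variant
    in the truth table; a positive counts as detected only if it was
    flagged by MLPA *and* received the ``artifact_suspected`` verdict.
    Specificity is computed over flagged calls without a true artifact.
    Undefined rates (no positives / no negatives) are reported as None.
    """
    truth_pairs = {(s, g) for s, gs in truth.snp_artifact.items() for g in gs}
    truth_samples = set(truth.samples)
    for c in confirmed:
        if c.sample_id not in truth_samples:
            raise ValueError(f"confirmed call for sample {c.sample_id!r} absent from truth")
    suspected = {(c.sample_id, c.gene) for c in confirmed
                 if c.verdict is Verdict.ARTIFACT_SUSPECTED}
    flagged_pairs = {(c.sample_id, c.gene) for c in confirmed}
    tp = len(truth_pairs & suspected)
    fn = len(truth_pairs - suspected)
    negatives = flagged_pairs - truth_pairs
    fp = len(suspected - truth_pairs)
    tn = len(negatives) - fp
    return {
        "tp": tp, "fn": fn, "fp": fp, "tn": tn,
        "sensitivity": tp / (tp + fn) if (tp + fn) else None,
        "specificity": tn / (tn + fp) if (tn + fp) else None,
    }
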