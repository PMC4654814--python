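"""Shared domain types for the targeted CNV screening pipeline.

The pipeline operates on three kinds of tabular objects: raw signal tables
(fluorescence peak heights from capillary electrophoresis, or molecule
counts from a hybridization counting assay), reference-normalized signal
tables, and copy-number ratio matrices in which 1.0 corresponds to two
copies per diploid genome. All of them are thin dataclasses around pandas
DataFrames indexed by sample id with probe ids as columns.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd


class ProbeRole(str, enum.Enum):
    """Role of a multiplexed probe in the assay."""

    TARGET = "target"
    REFERENCE = "reference"
    LIGATION_CONTROL = "ligation_control"
    DENATURATION_CONTROL = "denaturation_control"


class Assay(str, enum.Enum):
    """Signal-generating platform: MLPA peak heights or molecular counts."""

    MLPA = "mlpa"
    COUNT = "count"


class CallStatus(str, enum.Enum):
    """Threshold classification of a copy-number ratio.

    Ordered from most deleted to most amplified.  Ratios sitting exactly on
    a threshold (within a tolerance) get a borderline status: a ratio on
    the loss cut-off indicates a *possible* loss and is still flagged for
    orthogonal follow-up, but is distinguished from an unambiguous loss.
    """

    LOSS = "loss"
    BORDERLINE_LOSS = "borderline_loss"
    NORMAL = "normal"
    BORDERLINE_GAIN = "borderline_gain"
    GAIN = "gain"

    @property
    def rank(self) -> int:
        return _STATUS_ORDER[self]

    @property
    def flagged(self) -> bool:
        """True for any status that departs from the two-copy normal range."""
        return self is not CallStatus.NORMAL


_STATUS_ORDER = {
    CallStatus.LOSS: 0,
    CallStatus.BORDERLINE_LOSS: 1,
    CallStatus.NORMAL: 2,
    CallStatus.BORDERLINE_GAIN: 3,
    CallStatus.GAIN: 4,
}


class Therapy(str, enum.Enum):
    NONE = "none"
    MONO = "mono"
    COMBINATION = "combination"
    POTENT_ART = "potent_art"
    NA = "na"


@dataclass(frozen=True)
class ProbeDef:
    """One multiplexed probe: its genomic locus, role and, for control
    samples, the known copy number of the locus per diploid genome."""

    probe_id: str
    gene: str
    role: ProbeRole
    chrom: str
    start: int
    end: int
    known_copies: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"probe {self.probe_id}: start > end")
        if self.known_copies is not None and self.known_copies < 0:
            raise ValueError(f"probe {self.probe_id}: negative known_copies")


class ManifestError(ValueError):
    """Raised when a probe manifest violates its invariants."""


@dataclass
class ProbeManifest:
    """An ordered collection of probes with integrity checks.

    A valid MLPA-style manifest needs at least two reference probes (the
    intra-sample normalizer is a geometric mean over them) and at most one
    target probe per gene, since calling is done per gene.
    """

    probes: list[ProbeDef]

    def __post_init__(self) -> None:
        ids = [p.probe_id for p in self.probes]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ManifestError(f"duplicate probe ids: {dupes}")
        n_ref = sum(p.role is ProbeRole.REFERENCE for p in self.probes)
        if n_ref < 2:
            raise ManifestError(
                f"manifest needs >=2 reference probes, found {n_ref}"
            )
        genes = [p.gene for p in self.probes if p.role is ProbeRole.TARGET]
        if len(genes) != len(set(genes)):
            dupes = sorted({g for g in genes if genes.count(g) > 1})
            raise ManifestError(f"multiple target probes for gene(s): {dupes}")

    def __iter__(self):
        return iter(self.probes)

    def __len__(self) -> int:
        return len(self.probes)

    def probe_ids(self, role: Optional[ProbeRole] = None) -> list[str]:
        return [p.probe_id for p in self.probes if role is None or p.role is role]

    @property
    def target_probes(self) -> list[ProbeDef]:
        return [p for p in self.probes if p.role is ProbeRole.TARGET]

    @property
    def reference_probes(self) -> list[ProbeDef]:
        return [p for p in self.probes if p.role is ProbeRole.REFERENCE]

    @property
    def control_probes(self) -> list[ProbeDef]:
        return [
            p
            for p in self.probes
            if p.role in (ProbeRole.LIGATION_CONTROL, ProbeRole.DENATURATION_CONTROL)
        ]

    @property
    def target_genes(self) -> list[str]:
        return [p.gene for p in self.target_probes]

    def probe_for_gene(self, gene: str) -> ProbeDef:
        for p in self.target_probes:
            if p.gene == gene:
                return p
        raise KeyError(f"no target probe for gene {gene!r}")

    def gene_of_probe(self, probe_id: str) -> str:
        for p in self.probes:
            if p.probe_id == probe_id:
                return p.gene
        raise KeyError(f"unknown probe {probe_id!r}")


@dataclass
class PeakTable:
    """Raw samples x probes signal matrix from one assay run.

    ``values`` holds fluorescence peak heights (MLPA) or molecule counts
    (counting assay); both are non-negative by construction of the
    instruments.
    """

    assay: Assay
    values: pd.DataFrame  # samples x probes, non-negative
    run_id: str = "run1"

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("peak table contains negative values")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def probes(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class RatioMatrix:
    """Copy-number ratios relative to a set of in-run reference samples.

    A ratio of 1.0 corresponds to two copies per diploid genome, 0.5 to a
    heterozygous loss.  ``sd`` optionally carries per-cell standard
    deviations across replicate runs.  ``uncallable_probes`` lists probes
    whose reference-sample mean signal was zero.
    """

    values: pd.DataFrame
    reference_samples: list[str]
    sd: Optional[pd.DataFrame] = None
    uncallable_probes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = self.values.to_numpy()
        if (vals[~pd.isna(vals)] < 0).any():
            raise ValueError("ratios must be non-negative")
        if self.sd is not None:
            if not self.sd.index.equals(self.values.index) or not self.sd.columns.equals(
                self.values.columns
            ):
                raise ValueError("sd matrix must align with ratio matrix")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def probes(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CopyCall:
    """Per (sample, gene) copy-number call."""

    sample_id: str
    gene: str
    ratio: float
    status: CallStatus
    discrete_copies: Optional[int] = None
    replicate_consistent: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.discrete_copies is not None and self.discrete_copies < 0:
            raise ValueError("discrete_copies must be >= 0")

    @property
    def flagged(self) -> bool:
        return self.status.flagged


@dataclass
class SampleRecord:
    """One cohort member's serum lipid panel and covariates.

    Lipids are in mg/dL.  LDL-C may be missing (encoded None): direct LDL
    measurement is skipped when triglycerides are too high for the
    Friedewald estimate, and the phenotype classifier treats those samples
    as unclassifiable unless HDL alone settles eligibility.
    """

    sample_id: str
    hiv_positive: bool
    hdl: float
    tchol: float
    trig: float
    ldl: Optional[float] = None
    therapy: Therapy = Therapy.NA
    adherence: Optional[str] = None
    ancestry: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("hdl", "tchol", "trig"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v <= 0):
                raise ValueError(f"{name} must be positive, got {v}")
        if self.ldl is not None and (not math.isfinite(self.ldl) or self.ldl <= 0):
            raise ValueError(f"ldl must be positive or missing, got {self.ldl}")


@dataclass(frozen=True)
class Thresholds:
    """Ratio cut-offs and QC tolerances.

    ``loss_cut``/``gain_cut`` are the conventional MLPA dosage-quotient
    bounds: ratios strictly between them are consistent with two copies.
    ``boundary_tol`` defines the width of the borderline band around each
    cut-off.  ``sd_genuine`` is the replicate-SD limit below which a
    flagged ratio is considered reproducible.  ``ref_iqr_inflation``
    flags a target probe whose ratio IQR exceeds that multiple of the
    median reference-probe IQR.  ``ref_cv_max`` and
    ``control_signal_frac`` parameterize per-sample QC (coefficient of
    variation of reference-probe signals; control-probe signal expressed
    as a fraction of mean reference signal).
    """

    loss_cut: float = 0.7
    gain_cut: float = 1.3
    boundary_tol: float = 1e-9
    sd_genuine: float = 0.05
    ref_iqr_inflation: float = 1.5
    ref_cv_max: float = 0.30
    control_signal_frac: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.loss_cut < 1 < self.gain_cut):
            raise ValueError("need 0 < loss_cut < 1 < gain_cut")
        for name in (
            "boundary_tol",
            "sd_genuine",
            "ref_iqr_inflation",
            "ref_cv_max",
            "control_signal_frac",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


# The 16 reverse-cholesterol-transport pathway genes screened by the assay.
RCT_GENES: tuple[str, ...] = (
    "SRBI",
    "APOC3",
    "APOA1",
    "APOE",
    "PLTP",
    "LIPC",
    "LCAT",
    "APOA4",
    "LPL",
    "LIPG",
    "LDLR",
    "CETP",
    "APOA5",
    "APOB",
    "ABCA1",
    "APOC2",
)
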