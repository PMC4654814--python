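"""Synthetic cohort generator for the targeted CNV screen.

Emulates the statistical structure the downstream analysis assumes: a
cohort of ~320 samples assayed with a 35-probe MLPA-style panel (16 target
genes, 16 two-copy reference probes, 1 ligation control, 2 denaturation
controls), an orthogonal molecule-counting assay on the same genes, a
log2 expression matrix with a configurable gene-dosage slope, and a lipid
sample sheet with extreme HDL/LDL strata.

Generative model for a raw MLPA peak of probe p in sample s::

    value = BASE * A_s * E_p * (c / 2) * b * d * exp(eps)

where ``A_s`` is a per-sample amplification factor (lognormal), ``E_p`` a
per-probe efficiency (lognormal, shared across samples), ``c`` the true
copy number of the probe's locus (2 for reference probes), ``b`` a binding
factor that is 0.5 when the sample is heterozygous for a ligation-site
variant under that probe and 1 otherwise, ``d`` a denaturation factor
(0.5 on genomic probes in denaturation-failure samples), and ``eps``
zero-mean Gaussian noise on the natural-log scale.  The counting assay
follows the same law with its own amplification/efficiency draws and no
ligation-site term: its probes bind elsewhere in the gene, which is
exactly what makes the ligation-site artifact detectable by platform
comparison.

Multiplicative lognormal noise is used throughout because signals are
positive and instrument noise scales with signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    Assay,
    PeakTable,
    ProbeDef,
    ProbeManifest,
    ProbeRole,
    RCT_GENES,
    SampleRecord,
    Therapy,
)

#: Nominal diploid peak height / molecule count before per-sample and
#: per-probe factors; arbitrary instrument units.
BASE_SIGNAL = 1000.0

#: Floor for log2(c/2) when c = 0, so homozygous deletions do not produce
#: -inf expression; corresponds to ~3% of diploid expression.
LOG2_DOSAGE_FLOOR = -5.0

_GENE_CHROM = {
    "SRBI": "12", "APOC3": "11", "APOA1": "11", "APOE": "19", "PLTP": "20",
    "LIPC": "15", "LCAT": "16", "APOA4": "11", "LPL": "8", "LIPG": "18",
    "LDLR": "19", "CETP": "16", "APOA5": "11", "APOB": "2", "ABCA1": "9",
    "APOC2": "19",
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generative model.

    Defaults encode the regime the screen was designed for: whole-gene
    CNV that is rare (well under 1% per gene), a rare heterozygous
    ligation-site variant at the APOA4 probe, ~5% multiplicative assay
    noise, and no true expression dosage effect.
    """

    n_samples: int = 320
    genes: tuple[str, ...] = RCT_GENES
    loss_freq: float = 0.003
    gain_freq: float = 0.0
    snp_artifact_freq: float = 0.006
    artifact_gene: str = "APOA4"
    sigma_mlpa: float = 0.05
    sigma_count: float = 0.05
    amp_sd: float = 0.3
    probe_eff_sd: float = 0.2
    denat_fail_freq: float = 0.01
    ligation_fail_freq: float = 0.0
    beta_expr: float = 0.0
    expr_sd: float = 0.2
    multicopy_panel: tuple[int, ...] = (2, 3, 4, 5, 6, 7)
    multicopy_gene: str = "DEFB103A"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        for name in (
            "loss_freq", "gain_freq", "snp_artifact_freq",
            "denat_fail_freq", "ligation_fail_freq",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("sigma_mlpa", "sigma_count", "amp_sd", "probe_eff_sd", "expr_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.artifact_gene not in self.genes:
            raise ValueError(
                f"artifact_gene {self.artifact_gene!r} not among simulated genes"
            )
        if any(c < 0 for c in self.multicopy_panel):
            raise ValueError("multicopy_panel copies must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["genes"] = list(self.genes)
        d["multicopy_panel"] = list(self.multicopy_panel)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "genes" in d:
            d["genes"] = tuple(d["genes"])
        if "multicopy_panel" in d:
            d["multicopy_panel"] = tuple(d["multicopy_panel"])
        return cls(**d)


@dataclass
class TruthTable:
    """Ground truth behind one simulated cohort.

    ``copies`` is samples x genes (integer, 2 = diploid normal).
    ``snp_artifact`` maps sample id -> set of gene symbols whose MLPA
    probe is hit by a heterozygous ligation-site variant in that sample.
    ``denaturation_failure`` lists samples whose DNA denatured
    incompletely.  ``amplification`` holds the per-sample log-amplification
    factors actually drawn for each platform.
    """

    copies: pd.DataFrame
    snp_artifact: dict[str, set[str]] = field(default_factory=dict)
    denaturation_failure: set[str] = field(default_factory=set)
    ligation_failure: set[str] = field(default_factory=set)
    amplification: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if (self.copies.to_numpy() < 0).any():
            raise ValueError("true copies must be >= 0")
        genes = set(self.copies.columns)
        for s, gs in self.snp_artifact.items():
            bad = gs - genes
            if bad:
                raise ValueError(f"artifact flags for unknown genes {bad} in {s}")

    @property
    def samples(self) -> list[str]:
        return list(self.copies.index)

    @property
    def genes(self) -> list[str]:
        return list(self.copies.columns)

    def non_diploid(self) -> list[tuple[str, str, int]]:
        """(sample, gene, copies) triples where copies != 2."""
        out = []
        for s in self.copies.index:
            row = self.copies.loc[s]
            for g, c in row.items():
                if c != 2:
                    out.append((s, g, int(c)))
        return out


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generator stage
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def default_manifest(include_multicopy: bool = False,
                     genes: Sequence[str] = RCT_GENES) -> ProbeManifest:
    """The 35-probe screening panel: one target probe per gene, 16
    reference probes, one ligation control and two denaturation controls.

    With ``include_multicopy`` an extra target probe for the DEFB103A
    multicopy locus is appended, mirroring the extended QC panel used to
    validate multi-copy calling against samples of known copy number.
    """
    probes: list[ProbeDef] = []
    for i, g in enumerate(genes):
        chrom = _GENE_CHROM.get(g, str((i % 22) + 1))
        start = 1_000_000 + 50_000 * i
        probes.append(ProbeDef(f"{g}_P1", g, ProbeRole.TARGET, chrom, start, start + 60))
    for i in range(1, 17):
        start = 2_000_000 + 50_000 * i
        probes.append(
            ProbeDef(f"Ref_{i}", f"REF{i}", ProbeRole.REFERENCE,
                     str((i % 22) + 1), start, start + 60, known_copies=2)
        )
    probes.append(ProbeDef("Ref_17", "DCTRL1", ProbeRole.DENATURATION_CONTROL,
                           "5", 3_000_000, 3_000_060))
    probes.append(ProbeDef("Ref_18", "LCTRL1", ProbeRole.LIGATION_CONTROL,
                           "6", 3_100_000, 3_100_060))
    probes.append(ProbeDef("Ref_19", "DCTRL2", ProbeRole.DENATURATION_CONTROL,
                           "7", 3_200_000, 3_200_060))
    if include_multicopy:
        probes.append(ProbeDef("DEFB103A_P1", "DEFB103A", ProbeRole.TARGET,
                               "8", 7_000_000, 7_000_060))
    return ProbeManifest(probes)


def simulate_truth(config: SimulationConfig) -> TruthTable:
    """Draw per-(sample, gene) copy states and per-sample artifact flags.

    Copy states are independent across samples and genes: 1 copy with
    probability ``loss_freq``, 3 copies with ``gain_freq``, else 2.  The
    ligation-site variant is drawn per sample at the designated artifact
    gene; denaturation failures are drawn per sample.
    """
    rng = _child_rng(config.seed, 0)
    sample_ids = [f"S{i:04d}" for i in range(1, config.n_samples + 1)]
    u = rng.random((config.n_samples, len(config.genes)))
    copies = np.full(u.shape, 2, dtype=int)
    copies[u < config.loss_freq] = 1
    copies[(u >= config.loss_freq) & (u < config.loss_freq + config.gain_freq)] = 3
    copies_df = pd.DataFrame(copies, index=sample_ids, columns=list(config.genes))

    art = rng.random(config.n_samples) < config.snp_artifact_freq
    snp_artifact = {
        s: {config.artifact_gene} for s, a in zip(sample_ids, art) if a
    }
    denat = rng.random(config.n_samples) < config.denat_fail_freq
    lig = rng.random(config.n_samples) < config.ligation_fail_freq
    amp = pd.DataFrame(
        {
            "log_amp_mlpa": rng.normal(0.0, config.amp_sd, config.n_samples),
            "log_amp_count": rng.normal(0.0, config.amp_sd, config.n_samples),
        },
        index=sample_ids,
    )
    return TruthTable(
        copies=copies_df,
        snp_artifact=snp_artifact,
        denaturation_failure={s for s, d in zip(sample_ids, denat) if d},
        ligation_failure={s for s, l in zip(sample_ids, lig) if l},
        amplification=amp,
    )


def _probe_efficiencies(manifest: ProbeManifest, sd: float,
                        rng: np.random.Generator) -> pd.Series:
    eff = np.exp(rng.normal(0.0, sd, len(manifest)))
    return pd.Series(eff, index=[p.probe_id for p in manifest])


def simulate_mlpa_peaks(truth: TruthTable, manifest: ProbeManifest,
                        config: SimulationConfig, run_id: str = "mlpa_run1",
                        stream: int = 1) -> PeakTable:
    """Raw MLPA peak-height table under the multiplicative signal model.

    Reference probes and the ligation control behave as two-copy loci;
    denaturation controls are silent except in denaturation-failure
    samples, where they light up while all genomic probes drop to half
    signal.  The ligation control drops to ~0 in ligation-failure
    samples.  ``stream`` selects an independent noise stream so repeated
    runs of the same truth are genuine replicates.
    """
    for g in truth.genes:
        if g not in {p.gene for p in manifest.target_probes}:
            raise ValueError(f"gene {g!r} in truth has no target probe in manifest")
    rng = _child_rng(config.seed, stream)
    eff = _probe_efficiencies(manifest, config.probe_eff_sd, rng)
    samples = truth.samples
    amp = (
        np.exp(truth.amplification["log_amp_mlpa"].to_numpy())
        if truth.amplification is not None
        else np.ones(len(samples))
    )
    values = np.zeros((len(samples), len(manifest)))
    probe_list = list(manifest)
    eps = rng.normal(0.0, config.sigma_mlpa, values.shape) if config.sigma_mlpa > 0 else np.zeros(values.shape)
    for j, probe in enumerate(probe_list):
        for i, s in enumerate(samples):
            denat_fail = s in truth.denaturation_failure
            d = 0.5 if denat_fail else 1.0
            if probe.role is ProbeRole.TARGET:
                c = truth.copies.at[s, probe.gene] if probe.gene in truth.copies.columns else 2
                b = 0.5 if probe.gene in truth.snp_artifact.get(s, ()) else 1.0
                signal = (c / 2.0) * b * d
            elif probe.role is ProbeRole.REFERENCE:
                signal = d
            elif probe.role is ProbeRole.LIGATION_CONTROL:
                signal = 1e-3 if s in truth.ligation_failure else d
            else:  # denaturation control: signal only when denaturation failed
                signal = 1.0 if denat_fail else 0.0
            values[i, j] = BASE_SIGNAL * amp[i] * eff[probe.probe_id] * signal * np.exp(eps[i, j])
    df = pd.DataFrame(values, index=samples, columns=[p.probe_id for p in probe_list])
    return PeakTable(assay=Assay.MLPA, values=df, run_id=run_id)


def simulate_count_table(truth: TruthTable, manifest: ProbeManifest,
                         config: SimulationConfig, run_id: str = "count_run1",
                         stream: int = 2) -> PeakTable:
    """Orthogonal molecule-count table for target + reference probes.

    The counting probes bind different regions of each gene, so the
    ligation-site variant has no effect here; nor do MLPA-specific
    denaturation/ligation failure modes.
    """
    for g in truth.genes:
        if g not in {p.gene for p in manifest.target_probes}:
            raise ValueError(f"gene {g!r} in truth has no target probe in manifest")
    rng = _child_rng(config.seed, stream)
    probes = [p for p in manifest if p.role in (ProbeRole.TARGET, ProbeRole.REFERENCE)]
    eff = np.exp(rng.normal(0.0, config.probe_eff_sd, len(probes)))
    samples = truth.samples
    amp = (
        np.exp(truth.amplification["log_amp_count"].to_numpy())
        if truth.amplification is not None
        else np.ones(len(samples))
    )
    values = np.zeros((len(samples), len(probes)))
    eps = rng.normal(0.0, config.sigma_count, values.shape) if config.sigma_count > 0 else np.zeros(values.shape)
    for j, probe in enumerate(probes):
        if probe.role is ProbeRole.TARGET and probe.gene in truth.copies.columns:
            c = truth.copies[probe.gene].to_numpy()
        else:
            c = np.full(len(samples), 2)
        values[:, j] = BASE_SIGNAL * amp * eff[j] * (c / 2.0) * np.exp(eps[:, j])
    df = pd.DataFrame(values, index=samples, columns=[p.probe_id for p in probes])
    return PeakTable(assay=Assay.COUNT, values=df, run_id=run_id)


def simulate_expression(truth: TruthTable, config: SimulationConfig,
                        stream: int = 3) -> pd.DataFrame:
    """log2 expression matrix (samples x genes) with a dosage effect.

    x(s, g) = mu_g + beta_expr * log2(c/2) + N(0, expr_sd^2), with mu_g
    drawn once per gene around a typical microarray intensity and the
    dosage term floored at ``LOG2_DOSAGE_FLOOR`` for homozygous losses.
    """
    rng = _child_rng(config.seed, stream)
    genes = truth.genes
    mu = rng.normal(8.0, 1.0, len(genes))
    c = truth.copies.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        dosage = np.log2(c / 2.0)
    dosage = np.maximum(dosage, LOG2_DOSAGE_FLOOR)
    noise = rng.normal(0.0, config.expr_sd, c.shape) if config.expr_sd > 0 else 0.0
    x = mu[None, :] + config.beta_expr * dosage + noise
    return pd.DataFrame(x, index=truth.samples, columns=genes)


def simulate_sample_sheet(config: SimulationConfig, truth: TruthTable,
                          stream: int = 4) -> list[SampleRecord]:
    """Lipid panel and covariates for each simulated sample.

    HDL-C ~ N(45, 12) and LDL-C ~ N(125, 25) truncated positive, wide
    enough that a ~320-sample cohort contains both protective (HDL >= 60)
    and at-risk (HDL <= 40) strata; ~10% of LDL values are missing.
    About 65% of samples are HIV-positive and, of those, ~70% receive
    antiretroviral therapy.
    """
    rng = _child_rng(config.seed, stream)
    n = len(truth.samples)

    def _trunc_normal(mean: float, sd: float, size: int) -> np.ndarray:
        out = rng.normal(mean, sd, size)
        bad = out <= 1.0
        while bad.any():
            out[bad] = rng.normal(mean, sd, int(bad.sum()))
            bad = out <= 1.0
        return out

    hdl = _trunc_normal(45.0, 12.0, n)
    ldl = _trunc_normal(125.0, 25.0, n)
    ldl_missing = rng.random(n) < 0.10
    trig = np.exp(rng.normal(np.log(130.0), 0.4, n))
    tchol = np.maximum(ldl + hdl + trig / 5.0 + rng.normal(0.0, 10.0, n), 40.0)
    hiv = rng.random(n) < 0.65
    on_therapy = rng.random(n) < 0.70
    therapy_kind = rng.choice(
        ["potent_art", "combination", "mono"], size=n, p=[0.75, 0.15, 0.10],
    )
    adherence = rng.choice(["100%", "95-99%", "<75%", "NA"], size=n,
                           p=[0.30, 0.45, 0.08, 0.17])
    ancestry = rng.choice(["EA", "AEA", "AsEA", "NA"], size=n,
                          p=[0.70, 0.25, 0.04, 0.01])

    records = []
    for i, s in enumerate(truth.samples):
        if hiv[i]:
            therapy = Therapy(str(therapy_kind[i])) if on_therapy[i] else Therapy.NONE
            adh = str(adherence[i]) if therapy is not Therapy.NONE else None
        else:
            therapy, adh = Therapy.NA, None
        records.append(
            SampleRecord(
                sample_id=s,
                hiv_positive=bool(hiv[i]),
                hdl=float(hdl[i]),
                ldl=None if ldl_missing[i] else float(ldl[i]),
                tchol=float(tchol[i]),
                trig=float(trig[i]),
                therapy=therapy,
                adherence=adh,
                ancestry=str(ancestry[i]),
            )
        )
    return records


def simulate_multicopy_controls(config: SimulationConfig, manifest: ProbeManifest,
                                stream: int = 5) -> tuple[PeakTable, TruthTable]:
    """Control samples of known copy number at the multicopy QC locus.

    One control sample per entry of ``config.multicopy_panel`` carries
    that many copies at the multicopy gene (DEFB103A-like) and two copies
    everywhere else; used to validate that anchored cluster calling
    recovers a range of copy numbers.
    """
    genes = [p.gene for p in manifest.target_probes]
    if config.multicopy_gene not in genes:
        raise ValueError(
            f"manifest has no target probe for multicopy gene {config.multicopy_gene!r}"
        )
    rng = _child_rng(config.seed, stream)
    sample_ids = [f"CTRL{c}_{i}" for i, c in enumerate(config.multicopy_panel)]
    copies = pd.DataFrame(2, index=sample_ids, columns=genes, dtype=int)
    for s, c in zip(sample_ids, config.multicopy_panel):
        copies.at[s, config.multicopy_gene] = int(c)
    amp = pd.DataFrame(
        {
            "log_amp_mlpa": rng.normal(0.0, config.amp_sd, len(sample_ids)),
            "log_amp_count": np.zeros(len(sample_ids)),
        },
        index=sample_ids,
    )
    truth = TruthTable(copies=copies, amplification=amp)
    peaks = simulate_mlpa_peaks(truth, manifest, config,
                                run_id="multicopy_qc", stream=stream + 100)
    return peaks, truth


@dataclass
class SimulatedCohort:
    """Bundle of everything one simulation run produces."""

    config: SimulationConfig
    manifest: ProbeManifest
    truth: TruthTable
    mlpa_peaks: PeakTable
    count_table: PeakTable
    expression: pd.DataFrame
    sample_sheet: list[SampleRecord]


def simulate_cohort(config: Optional[SimulationConfig] = None,
                    manifest: Optional[ProbeManifest] = None) -> SimulatedCohort:
    """Generate a complete cohort: truth, both assay tables, expression
    and sample sheet, all deterministic given ``config.seed``."""
    config = config or SimulationConfig()
    manifest = manifest or default_manifest()
    truth = simulate_truth(config)
    return SimulatedCohort(
        config=config,
        manifest=manifest,
        truth=truth,
        mlpa_peaks=simulate_mlpa_peaks(truth, manifest, config),
        count_table=simulate_count_table(truth, manifest, config),
        expression=simulate_expression(truth, config),
        sample_sheet=simulate_sample_sheet(config, truth),
    )
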