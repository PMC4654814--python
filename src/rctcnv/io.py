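"""Readers and writers for the pipeline's plain-text formats.

All tables are CSV/TSV with header rows: probe manifests as TSV, signal
tables and sample sheets as CSV (first column ``sample_id``), reports as
TSV plus a JSON summary.  Output is deterministic — fixed column order,
fixed float formatting, sorted JSON keys — so identical inputs produce
identical bytes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .simulate import SimulationConfig, TruthTable
from .types import (
    Assay,
    CopyCall,
    ManifestError,
    PeakTable,
    ProbeDef,
    ProbeManifest,
    ProbeRole,
    RatioMatrix,
    SampleRecord,
    Therapy,
    Thresholds,
)

PathLike = Union[str, Path]

_MANIFEST_COLS = ["probe_id", "gene", "role", "chrom", "start", "end", "known_copies"]


class FormatError(ValueError):
    """Malformed input table."""


class ReportError(ValueError):
    """Invalid report request (e.g. empty call list)."""


# ---------------------------------------------------------------- manifest

def read_probe_manifest(path: PathLike) -> ProbeManifest:
    """Parse a TSV probe manifest; validates roles, id uniqueness and the
    two-reference-probe minimum via :class:`ProbeManifest`."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene": str,
                                            "role": str, "chrom": str})
    missing = [c for c in _MANIFEST_COLS[:-1] if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest missing columns: {missing}")
    probes = []
    for _, row in df.iterrows():
        try:
            role = ProbeRole(row["role"])
        except ValueError as exc:
            raise ManifestError(f"unknown probe role {row['role']!r}") from exc
        kc = row.get("known_copies")
        known = None if kc is None or pd.isna(kc) else int(kc)
        probes.append(ProbeDef(str(row["probe_id"]), str(row["gene"]), role,
                               str(row["chrom"]), int(row["start"]), int(row["end"]),
                               known_copies=known))
    return ProbeManifest(probes)


def write_probe_manifest(manifest: ProbeManifest, path: PathLike) -> None:
    rows = [
        {
            "probe_id": p.probe_id, "gene": p.gene, "role": p.role.value,
            "chrom": p.chrom, "start": p.start, "end": p.end,
            "known_copies": "" if p.known_copies is None else p.known_copies,
        }
        for p in manifest
    ]
    pd.DataFrame(rows, columns=_MANIFEST_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- signal tables

def read_peak_table(path: PathLike, assay: Union[Assay, str],
                    manifest: Optional[ProbeManifest] = None,
                    run_id: Optional[str] = None) -> PeakTable:
    """Read a samples x probes signal CSV (first column ``sample_id``).

    Negative values raise :class:`FormatError`; probe columns not present
    in the supplied manifest raise :class:`ManifestError`.
    """
    assay = Assay(assay)
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    if df.isna().any().any():
        raise FormatError(f"{path}: missing values in signal table")
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative signal values")
    if manifest is not None:
        known = set(p.probe_id for p in manifest)
        unknown = [c for c in df.columns if c not in known]
        if unknown:
            raise ManifestError(f"probes absent from manifest: {unknown}")
    return PeakTable(assay=assay, values=df,
                     run_id=run_id or Path(path).stem)


def write_peak_table(table: PeakTable, path: PathLike) -> None:
    out = table.values.copy()
    out.index.name = "sample_id"
    out.to_csv(path, float_format="%.6g")


def read_matrix(path: PathLike) -> pd.DataFrame:
    """Generic samples x columns CSV (ratios, expression)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path: PathLike, float_format: str = "%.6g") -> None:
    out = df.copy()
    out.index.name = "sample_id"
    out.to_csv(path, float_format=float_format)


def write_ratio_matrix(ratios: RatioMatrix, path: PathLike) -> None:
    write_matrix(ratios.values, path)


# ---------------------------------------------------------------- sample sheet

_SHEET_COLS = ["sample_id", "hiv_positive", "hdl", "ldl", "tchol", "trig",
               "therapy", "adherence", "ancestry"]


def write_sample_sheet(records: Sequence[SampleRecord], path: PathLike) -> None:
    rows = []
    for r in records:
        rows.append({
            "sample_id": r.sample_id,
            "hiv_positive": int(r.hiv_positive),
            "hdl": f"{r.hdl:.2f}",
            "ldl": "" if r.ldl is None else f"{r.ldl:.2f}",
            "tchol": f"{r.tchol:.2f}",
            "trig": f"{r.trig:.2f}",
            "therapy": r.therapy.value,
            "adherence": r.adherence or "",
            "ancestry": r.ancestry or "",
        })
    pd.DataFrame(rows, columns=_SHEET_COLS).to_csv(path, index=False)


def read_sample_sheet(path: PathLike) -> list[SampleRecord]:
    """Read a cohort sample sheet; empty LDL fields become missing."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    records = []
    for _, row in df.iterrows():
        ldl = row.get("ldl")
        records.append(SampleRecord(
            sample_id=str(row["sample_id"]),
            hiv_positive=bool(int(row["hiv_positive"])),
            hdl=float(row["hdl"]),
            ldl=None if pd.isna(ldl) else float(ldl),
            tchol=float(row["tchol"]),
            trig=float(row["trig"]),
            therapy=Therapy(row["therapy"]) if not pd.isna(row.get("therapy")) else Therapy.NA,
            adherence=None if pd.isna(row.get("adherence")) else str(row["adherence"]),
            ancestry=None if pd.isna(row.get("ancestry")) else str(row["ancestry"]),
        ))
    return records


# ---------------------------------------------------------------- truth table

def write_truth_table(truth: TruthTable, path: PathLike) -> None:
    """Ground truth as tidy TSV: one row per sample with per-gene copies
    and artifact flags."""
    out = truth.copies.copy()
    out.index.name = "sample_id"
    out["snp_artifact_genes"] = [
        ";".join(sorted(truth.snp_artifact.get(s, ()))) for s in out.index
    ]
    out["denaturation_failure"] = [int(s in truth.denaturation_failure) for s in out.index]
    out.to_csv(path, sep="\t")


def read_truth_table(path: PathLike) -> TruthTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    art_col = df.pop("snp_artifact_genes") if "snp_artifact_genes" in df else None
    denat_col = df.pop("denaturation_failure") if "denaturation_failure" in df else None
    snp = {}
    if art_col is not None:
        for s, v in art_col.items():
            if isinstance(v, str) and v:
                snp[str(s)] = set(v.split(";"))
    denat = set()
    if denat_col is not None:
        denat = {str(s) for s, v in denat_col.items() if int(v)}
    return TruthTable(copies=df.astype(int), snp_artifact=snp,
                      denaturation_failure=denat)


# ---------------------------------------------------------------- config

def save_config(config: SimulationConfig, path: PathLike,
                thresholds: Optional[Thresholds] = None) -> None:
    doc: dict = {"simulation": config.to_dict()}
    if thresholds is not None:
        doc["thresholds"] = {k: getattr(thresholds, k)
                             for k in Thresholds.__dataclass_fields__}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_config(path: PathLike) -> tuple[SimulationConfig, Thresholds]:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    config = SimulationConfig.from_dict(doc.get("simulation", {}))
    thresholds = Thresholds(**doc.get("thresholds", {}))
    return config, thresholds


# ---------------------------------------------------------------- call report

def write_call_report(calls: Sequence[CopyCall], summary: dict,
                      out_dir: PathLike, prefix: str = "cnv") -> tuple[Path, Path]:
    """Write the call table (TSV, ratios at 2 dp) and a JSON summary.

    The JSON carries per-status call counts plus whatever confirmation
    summary is supplied.  Output bytes are a pure function of the inputs.
    """
    if not calls:
        raise ReportError("cannot write a report for an empty call list")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for c in sorted(calls, key=lambda c: (c.sample_id, c.gene)):
        rows.append({
            "sample_id": c.sample_id,
            "gene": c.gene,
            "ratio": f"{c.ratio:.2f}",
            "status": c.status.value,
            "discrete_copies": "" if c.discrete_copies is None else c.discrete_copies,
            "replicate_consistent": "" if c.replicate_consistent is None
            else int(c.replicate_consistent),
        })
    tsv_path = out_dir / f"{prefix}_calls.tsv"
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)

    status_counts: dict[str, int] = {}
    for c in calls:
        status_counts[c.status.value] = status_counts.get(c.status.value, 0) + 1
    doc = {
        "n_calls": len(calls),
        "n_flagged": sum(c.flagged for c in calls),
        "status_counts": dict(sorted(status_counts.items())),
        "confirmation": summary,
    }
    json_path = out_dir / f"{prefix}_summary.json"
    json_path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return tsv_path, json_path
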