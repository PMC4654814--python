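"""Lipid phenotype classification and CNV-dosage association analyses.

Phenotype groups follow the NCEP ATP III extreme-lipid strata used to
enrich the screen: *atheroprotective* (HDL-C >= 60 mg/dL and LDL-C <=
100 mg/dL) and *atherogenic* (HDL-C <= 40 mg/dL and LDL-C >= 160 mg/dL),
with eligibility for the screen granted by any single extreme criterion
(HDL-C <= 40 or >= 60; LDL-C <= 100 or >= 130).  Bounds are inclusive.

Association analyses deliberately stay descriptive where power is
absent: with fewer than three carriers of a CNV no test is reported,
only medians and IQRs, mirroring how rare-variant screens should refuse
to over-interpret.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import CopyCall, ProbeManifest, RatioMatrix, SampleRecord


class PhenotypeGroup(str, enum.Enum):
    ATHEROPROTECTIVE = "atheroprotective"
    ATHEROGENIC = "atherogenic"
    INTERMEDIATE = "intermediate"
    UNCLASSIFIED = "unclassified"


# inclusive NCEP ATP III cut-offs, mg/dL
HDL_LOW, HDL_HIGH = 40.0, 60.0
LDL_LOW, LDL_ELEVATED, LDL_HIGH = 100.0, 130.0, 160.0

MIN_CARRIERS_FOR_TEST = 3


@dataclass(frozen=True)
class PhenotypeClass:
    sample_id: str
    eligible: bool
    group: PhenotypeGroup


def classify_phenotype(hdl: float, ldl: Optional[float],
                       sample_id: str = "") -> PhenotypeClass:
    """NCEP-based extreme-lipid classification of one sample.

    ``eligible`` is True if any single criterion is met (HDL <= 40 or
    >= 60; LDL <= 100 or >= 130).  The group requires both lipids: with
    LDL missing the group is ``unclassified`` even when HDL alone makes
    the sample eligible.
    """
    if not np.isfinite(hdl) or hdl <= 0:
        raise ValueError(f"HDL must be positive, got {hdl}")
    if ldl is not None and (not np.isfinite(ldl) or ldl <= 0):
        raise ValueError(f"LDL must be positive or missing, got {ldl}")
    eligible = hdl <= HDL_LOW or hdl >= HDL_HIGH
    if ldl is not None:
        eligible = eligible or ldl <= LDL_LOW or ldl >= LDL_ELEVATED
        if hdl >= HDL_HIGH and ldl <= LDL_LOW:
            group = PhenotypeGroup.ATHEROPROTECTIVE
        elif hdl <= HDL_LOW and ldl >= LDL_HIGH:
            group = PhenotypeGroup.ATHEROGENIC
        else:
            group = PhenotypeGroup.INTERMEDIATE
    else:
        group = PhenotypeGroup.UNCLASSIFIED
    return PhenotypeClass(sample_id=sample_id, eligible=eligible, group=group)


def _hdl_stratum(hdl: float) -> str:
    if hdl <= HDL_LOW:
        return "<=40"
    if hdl < HDL_HIGH:
        return "40-60"
    return ">=60"


def _ldl_stratum(ldl: Optional[float]) -> str:
    if ldl is None:
        return "not_measured"
    if ldl <= LDL_LOW:
        return "<=100"
    if ldl < LDL_ELEVATED:
        return "100-130"
    if ldl < LDL_HIGH:
        return "130-160"
    return ">=160"


def phenotype_group_counts(records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Cross-tabulate the cohort by HDL stratum x LDL stratum x HIV status.

    Returns a tidy frame (hdl_stratum, ldl_stratum, hiv_positive, n)
    covering every stratum combination, with empty strata reported as 0.
    Phenotype-group totals (counts of atheroprotective / atherogenic /
    intermediate / unclassified samples) are attached in
    ``.attrs["group_totals"]``; counts always partition the cohort.
    """
    if not records:
        raise ValueError("no sample records supplied")
    rows = []
    group_totals = {g.value: 0 for g in PhenotypeGroup}
    for r in records:
        cls = classify_phenotype(r.hdl, r.ldl, r.sample_id)
        group_totals[cls.group.value] += 1
        rows.append({
            "hdl_stratum": _hdl_stratum(r.hdl),
            "ldl_stratum": _ldl_stratum(r.ldl),
            "hiv_positive": r.hiv_positive,
        })
    df = pd.DataFrame(rows)
    hdl_levels = ["<=40", "40-60", ">=60"]
    ldl_levels = ["<=100", "100-130", "130-160", ">=160", "not_measured"]
    idx = pd.MultiIndex.from_product(
        [hdl_levels, ldl_levels, [False, True]],
        names=["hdl_stratum", "ldl_stratum", "hiv_positive"],
    )
    counts = (
        df.groupby(["hdl_stratum", "ldl_stratum", "hiv_positive"])
        .size()
        .reindex(idx, fill_value=0)
        .rename("n")
        .reset_index()
    )
    counts.attrs["group_totals"] = group_totals
    return counts


def cnv_lipid_comparison(calls: Sequence[CopyCall],
                         records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Per-gene lipid comparison between CNV carriers and non-carriers.

    Carriers are samples flagged at the gene.  Reports median (IQR)
    HDL and LDL for both groups; a two-sided rank-sum (Mann-Whitney)
    test is reported only with >= 3 carriers, otherwise the row is
    marked underpowered and no p-value is emitted.
    """
    by_sample = {r.sample_id: r for r in records}
    overlap = {c.sample_id for c in calls} & set(by_sample)
    if not overlap:
        raise ValueError("calls and lipid records share no samples")

    def _summ(vals: list[float]) -> str:
        if not vals:
            return "NA"
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        return f"{med:.1f} ({q1:.1f}-{q3:.1f})"

    genes = sorted({c.gene for c in calls})
    rows = []
    for gene in genes:
        carriers = {c.sample_id for c in calls if c.gene == gene and c.flagged}
        carriers &= set(by_sample)
        non = overlap - carriers
        hdl_c = [by_sample[s].hdl for s in sorted(carriers)]
        hdl_n = [by_sample[s].hdl for s in sorted(non)]
        ldl_c = [by_sample[s].ldl for s in sorted(carriers) if by_sample[s].ldl is not None]
        ldl_n = [by_sample[s].ldl for s in sorted(non) if by_sample[s].ldl is not None]
        row = {
            "gene": gene,
            "n_carriers": len(carriers),
            "n_noncarriers": len(non),
            "hdl_carriers": _summ(hdl_c),
            "hdl_noncarriers": _summ(hdl_n),
            "ldl_carriers": _summ(ldl_c),
            "ldl_noncarriers": _summ(ldl_n),
            "underpowered": len(carriers) < MIN_CARRIERS_FOR_TEST,
            "hdl_p": np.nan,
            "ldl_p": np.nan,
        }
        if len(carriers) >= MIN_CARRIERS_FOR_TEST and len(non) >= MIN_CARRIERS_FOR_TEST:
            row["hdl_p"] = float(stats.mannwhitneyu(hdl_c, hdl_n,
                                                    alternative="two-sided").pvalue)
            if len(ldl_c) >= MIN_CARRIERS_FOR_TEST and len(ldl_n) >= MIN_CARRIERS_FOR_TEST:
                row["ldl_p"] = float(stats.mannwhitneyu(ldl_c, ldl_n,
                                                        alternative="two-sided").pvalue)
        rows.append(row)
    return pd.DataFrame(rows)


#: Floor applied to log2(ratio) so a homozygous-deletion ratio of 0 does
#: not produce -inf in the dosage regressor.
LOG2_RATIO_FLOOR = -5.0


def cnv_expression_association(ratios: Union[RatioMatrix, pd.DataFrame],
                               expression: pd.DataFrame,
                               manifest: Optional[ProbeManifest] = None,
                               dosage_scale: bool = True) -> pd.DataFrame:
    """Least-squares association of log expression on copy-number ratio.

    One row per expression column; columns named ``GENE`` or
    ``GENE_k`` (transcript variant k) are matched to the gene's ratio.
    With ``dosage_scale`` (default) the regressor is log2(ratio), so
    under a proportional dosage model the slope is the change in log2
    expression per doubling of copy number and directly estimates the
    generative dosage coefficient; with ``dosage_scale=False`` the raw
    ratio is the regressor (the plotting convention for these data).
    Reports Pearson r, slope, the two-sided p-value, and a
    Benjamini-Hochberg adjusted p across assessable rows.  Genes whose
    ratios have (numerically) zero variance are reported as not
    assessable — the expected situation when CNV is essentially absent.
    """
    if isinstance(ratios, RatioMatrix):
        if manifest is not None:
            mapping = {p.probe_id: p.gene for p in manifest.target_probes
                       if p.probe_id in ratios.values.columns}
            gene_ratios = ratios.values[list(mapping)].rename(columns=mapping)
        else:
            gene_ratios = ratios.values
    else:
        gene_ratios = ratios

    rows = []
    for col in expression.columns:
        gene = str(col).rsplit("_", 1)[0] if "_" in str(col) else str(col)
        if gene not in gene_ratios.columns:
            continue
        merged = pd.concat(
            [gene_ratios[gene].rename("ratio"), expression[col].rename("expr")],
            axis=1, join="inner",
        ).dropna()
        n = len(merged)
        row = {"gene": gene, "variant": str(col), "n": n,
               "r": np.nan, "slope": np.nan, "p": np.nan,
               "assessable": False}
        if dosage_scale:
            with np.errstate(divide="ignore"):
                x = np.log2(merged["ratio"].to_numpy(dtype=float))
            x = np.maximum(x, LOG2_RATIO_FLOOR)
        else:
            x = merged["ratio"].to_numpy(dtype=float)
        if n >= 3 and np.std(x, ddof=1) > 1e-12:
            fit = stats.linregress(x, merged["expr"])
            row.update(r=float(fit.rvalue), slope=float(fit.slope),
                       p=float(fit.pvalue), assessable=True)
        rows.append(row)
    if not rows:
        raise ValueError("expression columns share no genes with the ratio matrix")
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    mask = out["assessable"] & out["p"].notna()
    if mask.any():
        out.loc[mask, "p_adj"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    return out
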