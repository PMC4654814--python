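"""Miniature worked-example dataset for the cross-platform workflow.

This is the published-style endpoint of a 320-sample screen of 16
reverse-cholesterol-transport genes: the four individuals whose MLPA
ratios departed from unity at any probe, the four genes involved in
those departures, and the confirmation-assay ratios subsequently
measured for the flagged calls.  It exercises every verdict class the
confirmation logic produces — a replicated loss, a borderline call that
does not confirm, and two platform-specific losses caused by a
heterozygous ligation-site SNP under one MLPA probe — without needing a
full cohort simulation.
"""

from __future__ import annotations

import pandas as pd

from .types import ProbeDef, ProbeManifest, ProbeRole

#: Cohort size the screen's headline percentage is quoted against.
DEMO_COHORT_SIZE = 320

# MLPA copy-number ratios for the four samples with any flagged probe.
# Sample 157 carries a real heterozygous CETP loss; samples 123 and 367
# are heterozygous for a ligation-site SNP under the APOA4 MLPA probe;
# sample 209's ABCA1 ratio sits exactly on the loss threshold.
_MLPA_RATIOS = {
    "ABCA1": {"123": 1.00, "157": 0.75, "209": 0.70, "367": 0.95},
    "APOA4": {"123": 0.56, "157": 0.98, "209": 1.12, "367": 0.55},
    "CETP": {"123": 0.99, "157": 0.65, "209": 0.92, "367": 0.93},
    "SRBI": {"123": 1.06, "157": 0.98, "209": 0.77, "367": 1.00},
}

# Molecule-count (orthogonal) ratios for the flagged (sample, gene) pairs.
_ORTHO_RATIOS = {
    "ABCA1": {"209": 1.06},
    "APOA4": {"123": 1.10, "367": 1.04},
    "CETP": {"157": 0.58},
}

# Median (serum) lipid levels of the four samples, mg/dL.
_LIPIDS = {
    "123": {"hdl": 55.0, "ldl": 147.0},
    "157": {"hdl": 30.0, "ldl": 114.0},
    "209": {"hdl": 38.0, "ldl": 136.5},
    "367": {"hdl": 39.2, "ldl": 69.0},
}


def demo_flagged_ratios() -> pd.DataFrame:
    """4 samples x 4 genes MLPA ratio block (samples as rows)."""
    return pd.DataFrame(_MLPA_RATIOS).astype(float)


def demo_ortho_ratios() -> pd.DataFrame:
    """Confirmation-assay ratios for the flagged calls (NaN elsewhere)."""
    df = pd.DataFrame(_ORTHO_RATIOS, index=sorted(_LIPIDS)).astype(float)
    return df


def demo_lipids() -> pd.DataFrame:
    """Median HDL-C / LDL-C (mg/dL) of the four flagged samples."""
    return pd.DataFrame(_LIPIDS).T.astype(float)


# Cohort composition of the 319 successfully assayed samples, cross-
# tabulated by HDL stratum x LDL stratum x HIV status (counts per
# (HIV-negative, HIV-positive) pair).  "NM" = LDL not measured.
_STRATUM_COUNTS: dict[tuple[str, str], tuple[int, int]] = {
    ("<=40", "<=100"): (17, 46),
    ("<=40", "100-130"): (12, 27),
    ("<=40", "130-160"): (19, 7),
    ("<=40", ">=160"): (3, 4),
    ("<=40", "not_measured"): (17, 23),
    ("40-60", "<=100"): (15, 19),
    ("40-60", "100-130"): (11, 17),
    ("40-60", "130-160"): (1, 2),
    ("40-60", ">=160"): (13, 4),
    ("40-60", "not_measured"): (1, 1),
    (">=60", "<=100"): (8, 15),
    (">=60", "100-130"): (8, 7),
    (">=60", "130-160"): (2, 6),
    (">=60", ">=160"): (3, 6),
    (">=60", "not_measured"): (1, 4),
}

# Representative in-stratum lipid values (mg/dL) used when expanding the
# stratum counts into individual records; any value inside the stratum
# bounds yields the same classification.
_HDL_REP = {"<=40": 35.0, "40-60": 50.0, ">=60": 65.0}
_LDL_REP = {"<=100": 90.0, "100-130": 115.0, "130-160": 145.0,
            ">=160": 175.0, "not_measured": None}


def demo_stratum_counts() -> pd.DataFrame:
    """Published cohort composition as a tidy frame
    (hdl_stratum, ldl_stratum, hiv_positive, n); sums to 319."""
    rows = []
    for (hdl_s, ldl_s), (n_neg, n_pos) in _STRATUM_COUNTS.items():
        rows.append({"hdl_stratum": hdl_s, "ldl_stratum": ldl_s,
                     "hiv_positive": False, "n": n_neg})
        rows.append({"hdl_stratum": hdl_s, "ldl_stratum": ldl_s,
                     "hiv_positive": True, "n": n_pos})
    return pd.DataFrame(rows)


def demo_cohort_records() -> list:
    """Expand the stratum counts into individual SampleRecord objects
    with representative in-stratum lipid values."""
    from .types import SampleRecord

    records = []
    i = 0
    for (hdl_s, ldl_s), (n_neg, n_pos) in sorted(_STRATUM_COUNTS.items()):
        for hiv, n in ((False, n_neg), (True, n_pos)):
            for _ in range(n):
                i += 1
                records.append(SampleRecord(
                    sample_id=f"D{i:03d}", hiv_positive=hiv,
                    hdl=_HDL_REP[hdl_s], ldl=_LDL_REP[ldl_s],
                    tchol=180.0, trig=130.0,
                ))
    return records


def demo_manifest() -> ProbeManifest:
    """Minimal manifest covering the four genes of the worked example."""
    probes = [
        ProbeDef("ABCA1_P1", "ABCA1", ProbeRole.TARGET, "9", 1_000_000, 1_000_060),
        ProbeDef("APOA4_P1", "APOA4", ProbeRole.TARGET, "11", 1_100_000, 1_100_060),
        ProbeDef("CETP_P1", "CETP", ProbeRole.TARGET, "16", 1_200_000, 1_200_060),
        ProbeDef("SRBI_P1", "SRBI", ProbeRole.TARGET, "12", 1_300_000, 1_300_060),
        ProbeDef("Ref_1", "REF1", ProbeRole.REFERENCE, "1", 2_000_000, 2_000_060,
                 known_copies=2),
        ProbeDef("Ref_2", "REF2", ProbeRole.REFERENCE, "2", 2_100_000, 2_100_060,
                 known_copies=2),
    ]
    return ProbeManifest(probes)
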