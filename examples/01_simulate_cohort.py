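"""Generate a synthetic screening cohort and inspect its ground truth.

The generator emulates a ~320-sample targeted CNV screen: raw MLPA peak
heights for 16 target genes plus reference/control probes, an orthogonal
molecule-count table, a log2 expression matrix and a lipid sample sheet,
together with the truth table recording which samples really carry a
copy-number change, a ligation-site variant, or a failed assay.
"""

from rctcnv import SimulationConfig, simulate_cohort

config = SimulationConfig(seed=42, loss_freq=0.003, snp_artifact_freq=0.006)
cohort = simulate_cohort(config)

print(f"cohort: {config.n_samples} samples, {len(config.genes)} target genes")
print(f"MLPA peak table:   {cohort.mlpa_peaks.values.shape} (samples x probes)")
print(f"count table:       {cohort.count_table.values.shape}")
print(f"expression matrix: {cohort.expression.shape}")

print("\ntrue non-diploid states (sample, gene, copies):")
for s, g, c in cohort.truth.non_diploid():
    print(f"  {s}  {g}  {c}")
print("\nligation-site heterozygotes (halve one MLPA probe's signal only):")
for s, genes in sorted(cohort.truth.snp_artifact.items()):
    print(f"  {s}  {sorted(genes)}")
print(f"denaturation failures: {sorted(cohort.truth.denaturation_failure)}")
# Expect a handful of single-copy losses (n*genes*0.003 ~ 15), a couple of
# artifact carriers, and ~1% failed samples -- the regime where whole-gene
# CNV in these genes is rare and every flagged call needs confirmation.
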