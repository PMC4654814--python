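"""Confirm flagged MLPA calls on an orthogonal platform.

Uses the bundled worked example: the four samples of a 320-sample
screen whose MLPA ratios departed from unity, and the molecule-count
ratios later measured for those calls.  A real loss replicates on both
platforms; a loss seen only by MLPA is the signature of a ligation-site
variant under that probe; a borderline call that does not replicate is
left unconfirmed.
"""

from rctcnv import (
    DEMO_COHORT_SIZE, RatioMatrix, call_matrix, confirm_calls,
    confirmation_summary, demo_flagged_ratios, demo_manifest,
    demo_ortho_ratios, flagged_calls,
)

mlpa = demo_flagged_ratios()
print("MLPA copy-number ratios (flagged entries outside 0.7-1.3 or on 0.7):")
print(mlpa.to_string(float_format="%.2f"))

ratio_matrix = RatioMatrix(values=mlpa, reference_samples=[])
flagged = flagged_calls(call_matrix(ratio_matrix, demo_manifest()))
confirmed = confirm_calls(flagged, demo_ortho_ratios())

print("\ncross-platform verdicts:")
for c in confirmed:
    print(f"  sample {c.sample_id}  {c.gene:6s} "
          f"mlpa={c.mlpa_ratio:.2f} ortho={c.ortho_ratio:.2f}  {c.verdict.value}")

summary = confirmation_summary(confirmed, DEMO_COHORT_SIZE)
print(f"\nconfirmed losses: {summary['confirmed_losses']} of "
      f"{summary['n_flagged']} flagged calls "
      f"= {summary['confirmed_fraction_percent']}% of the "
      f"{summary['cohort_size']}-sample cohort")
# Only the CETP loss (0.65 by MLPA, 0.58 by counting) is real: 0.3% of
# the cohort.  The two APOA4 "losses" are platform artifacts and the
# borderline ABCA1 call does not replicate.
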