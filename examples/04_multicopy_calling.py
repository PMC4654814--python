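"""Discrete copy-number calling on a multicopy control panel.

Threshold calling only separates loss/normal/gain.  Where control
samples of known copy number exist (here a DEFB103A-like multicopy
locus spanning 2-7 copies), anchored cluster analysis assigns integer
copies: anchor samples calibrate the ratio scale, every sample goes to
the nearest center (copies/2 x scale) on the log scale, and the scale
is refined from all assignments to a fixed point.
"""

import numpy as np

from rctcnv import (
    SimulationConfig, cluster_call, default_manifest,
    simulate_multicopy_controls,
)

manifest = default_manifest(include_multicopy=True)
panel = tuple(c for c in range(2, 8) for _ in range(20))  # 20 samples per state
config = SimulationConfig(seed=0, multicopy_panel=panel,
                          loss_freq=0.0, snp_artifact_freq=0.0,
                          denat_fail_freq=0.0)
peaks, truth = simulate_multicopy_controls(config, manifest)

ref_ids = [p.probe_id for p in manifest.reference_probes]
geo = np.exp(np.log(peaks.values[ref_ids]).mean(axis=1))
raw = peaks.values["DEFB103A_P1"] / geo

anchors = [(truth.samples[i * 20], int(truth.copies.iloc[i * 20]["DEFB103A"]))
           for i in range(6)]
model = cluster_call(raw, anchors)

accuracy = (model.assignment == truth.copies["DEFB103A"]).mean()
print(f"panel: {len(raw)} control samples, copies 2-7, assay noise 5%")
print(f"calibrated scale: {model.scale:.3f} "
      "(ratio units per two copies; absorbs probe efficiency)")
print("refined cluster centers (copies -> expected ratio):")
for c, center in sorted(model.centers.items()):
    n = int((model.assignment == c).sum())
    print(f"  {c} copies -> {center:.2f}  ({n} samples)")
print(f"assignment accuracy vs truth: {accuracy:.1%}")
# ~95% is the intrinsic limit at 5% multiplicative noise: adjacent
# high-copy states (6 vs 7) differ by only ~15% in ratio.
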