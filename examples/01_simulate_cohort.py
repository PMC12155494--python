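"""Simulate a small paired non-AC / CT-AC cohort and inspect one artifact.

Builds six training subjects (two with corrupted references) plus one test
subject, prints the cohort roster and the survival-factor range of the first
case, and shows how strongly each artifact corrupts its reference.
"""

import numpy as np

from petacpurify import simulate_dataset, survival_map, auto_body_mask
from petacpurify.metrics import EvaluationMask, compute_case_metrics

cases = simulate_dataset(
    n_train=6, n_test=1, artifact_fraction=1 / 3, seed=42,
    grid_shape=(32, 32, 40),
)

print("case roster:")
for c in cases:
    print(f"  {c.case_id}  split={c.split:5s}  artifact={c.artifact_label}")

first = cases[0]
# non_ac / clean_ref recovers the survival factor exactly (the noise is
# shared); restrict to voxels that registered counts
body = auto_body_mask(first.clean_ref)
counted = body & (first.non_ac.data > 0)
S_range = first.non_ac.data[counted] / first.clean_ref.data[counted]
print(f"\nin-body survival factor of {first.case_id}: "
      f"{S_range.min():.2f}..{S_range.max():.2f}")
print("(fraction of coincidence counts surviving attenuation: deep voxels lose most)")

print("\nreference corruption, MAE(ct_ac vs artifact-free ideal), in SUV-like units:")
for c in cases:
    if c.split != "train":
        continue
    mask = EvaluationMask(auto_body_mask(c.non_ac))
    cm = compute_case_metrics(c.ct_ac, c.clean_ref, mask, include_ssim=False)
    print(f"  {c.case_id}  {c.artifact_label:10s}  MAE={cm.mae:.4f}")
print("artifact cases show clearly elevated MAE: their references are corrupted,")
print("which is exactly what the purification stage must detect.")
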