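"""Train on synthetic fixtures and evaluate per-type segmentation quality.

A desk-scale run: 8 fixtures at 32x64 input, MobileNetV2 encoder, Adam with
batch 8 / lr 0.001 (the reference recipe), up to 200 steps with early stop
once training-set F1 reaches 80 for Types I and II. Takes a few minutes on
one CPU.
"""

from dcdnet.training import overfit_fixtures

report, steps, history = overfit_fixtures(seed=1, input_hw=(32, 64),
                                          max_steps=200, check_every=20)

print(f"stopped after {steps} steps; loss {history[0]['loss']:.4f} -> "
      f"{history[-1]['loss']:.4f}")
for tname, vals in report.round(2).per_type.items():
    print(f"  {tname}: " + ", ".join(f"{k}={v}" for k, v in vals.items()))
print(f"  weighted F1 = {report.round(2).weighted_f1} "
      f"(weights = per-type lesion counts {report.weights})")
print("-> the three-head model memorises occlusal (I) and proximal (II)")
print("   lesions quickly; cervical (III) is rarer and smaller, so it is")
print("   consistently the weakest class.")
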