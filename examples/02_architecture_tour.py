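"""Walk the network architecture: encoder taps, decoder ledger, output heads.

Builds the model on a ResNet50 encoder, traces one forward pass and prints
the spatial/channel shape of every decoder layer against the static ledger,
demonstrating the 1/32 -> 1/2 upsampling path and the three independent
sigmoid heads.
"""

import numpy as np

from dcdnet import DCDNet, DCDNetConfig, shape_ledger
from dcdnet.nn import no_grad

cfg = DCDNetConfig(backbone="resnet50", input_h=64, input_w=128, seed=0)
model = DCDNet(cfg).eval()
print(f"backbone: {cfg.backbone.name}; parameters: {model.n_parameters():,}")
print(f"encoder taps (Sc0..Sc4): {model.taps.tap_names}")

x = np.random.default_rng(0).random((1, 3, 64, 128), dtype=np.float32)
with no_grad():
    outs, acts = model.forward(x, trace=True)

ledger = shape_ledger(cfg)
print(f"{'layer':>6} {'traced (C,H,W)':>20} {'ledger':>20}")
for layer_id in ledger:
    got = tuple(acts[layer_id].shape[1:])
    print(f"{layer_id:>6} {str(got):>20} {str(ledger[layer_id]):>20}"
          + ("  <- mismatch!" if got != ledger[layer_id] else ""))

print(f"\n{len(outs)} output maps, each {outs[0].shape[2:]}, values in "
      f"[{min(float(o.data.min()) for o in outs):.3f}, "
      f"{max(float(o.data.max()) for o in outs):.3f}]")
print("-> one sigmoid probability map per caries type, at input resolution.")
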