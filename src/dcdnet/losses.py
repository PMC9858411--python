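"""Multi-head binary cross-entropy.

Each caries type k has its own sigmoid output; its loss L_k is the binary
cross-entropy of that map against the type's binary mask, averaged over all
pixels and samples (an unnormalised per-pixel sum is available via
``reduction='sum'``). The total loss is the plain mean over the N=3 types:

    L_k = mean_{i,j,samples} -[ y_ij log P_ij + (1 - y_ij) log(1 - P_ij) ]
    L   = (1/N) sum_k L_k
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ShapeError, ValidationError
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = ["LossValue", "bce_type_loss", "total_loss", "EPS"]

EPS = 1e-7


@dataclass
class LossValue:
    per_type: tuple[float, float, float]
    total: float
    n_types: int = 3
    n_samples: int = 1


def _validate_binary(y: np.ndarray):
    if not np.isin(y, (0, 1)).all():
        raise ValidationError("ground-truth mask must be binary (0/1)")


def bce_type_loss(y, p, reduction: str = "mean"):
    """BCE of one type's probability map against its binary mask.

    Accepts NumPy arrays (returns float) or an autodiff Tensor prediction
    (returns a scalar Tensor for backprop). Probabilities are clipped to
    [EPS, 1-EPS] before the logarithms.
    """
    y = np.asarray(y, dtype=np.float32)
    _validate_binary(y)
    if reduction not in ("mean", "sum"):
        raise ValueError("reduction must be 'mean' or 'sum'")
    if isinstance(p, Tensor):
        if p.shape != y.shape:
            raise ShapeError(f"shape mismatch: y {y.shape} vs p {p.shape}")
        return F.bce_mean(p, y, EPS, reduction)
    p = np.asarray(p, dtype=np.float64)
    if p.shape != y.shape:
        raise ShapeError(f"shape mismatch: y {y.shape} vs p {p.shape}")
    if p.min() < 0 or p.max() > 1:
        raise ValidationError("predictions must lie in [0, 1]")
    pc = np.clip(p, EPS, 1.0 - EPS)
    ll = -(y * np.log(pc) + (1.0 - y) * np.log1p(-pc))
    return float(ll.mean()) if reduction == "mean" else float(ll.sum())


def total_loss(masks, preds, reduction: str = "mean"):
    """Mean-over-types BCE for a (B,3,H,W) mask batch vs prediction batch.

    `preds` may be a (B,3,H,W) array, or the list of three (B,1,H,W) head
    Tensors a DCDNet forward returns (then the result is a scalar Tensor
    suitable for .backward(), alongside the LossValue report).
    """
    masks = np.asarray(masks, dtype=np.float32)
    if masks.ndim != 4 or masks.shape[1] != 3:
        raise ShapeError(f"masks must be (B,3,H,W), got {masks.shape}")
    if isinstance(preds, (list, tuple)):
        if len(preds) != 3:
            raise ShapeError(f"need 3 prediction heads, got {len(preds)}")
        per = [bce_type_loss(masks[:, k:k + 1], preds[k], reduction)
               for k in range(3)]
        third = Tensor(np.float32(1.0 / 3.0))
        tot = F.mul(F.add(F.add(per[0], per[1]), per[2]), third)
        report = LossValue(per_type=tuple(float(p.data) for p in per),
                           total=float(tot.data), n_samples=masks.shape[0])
        return tot, report
    preds = np.asarray(preds)
    if preds.shape != masks.shape:
        raise ShapeError(f"shape mismatch: masks {masks.shape} vs preds {preds.shape}")
    per = tuple(bce_type_loss(masks[:, k], preds[:, k], reduction) for k in range(3))
    return LossValue(per_type=per, total=sum(per) / 3.0, n_samples=masks.shape[0])
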