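"""Architecture audit: exact trainable-parameter and multiply-accumulate
counts, per-layer tables, and a human-readable report.

Parameters are the sizes of every trainable tensor (convolution kernels,
biases, normalisation shifts/scales, excitation weights).  MACs follow the
usual GMac convention: one multiply-accumulate per kernel tap per output
element, depthwise cost divided by the group count, and zero cost for
normalisation, activations, resizes and element-wise products.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .model import PlutoNet


@dataclass
class ModelSummary:
    trainable_parameters: int
    macs: int                      # main-branch multiply-accumulates
    input_size: int
    per_layer: list = field(default_factory=list)   # (name, params)

    @property
    def gmacs(self) -> float:
        return self.macs / 1e9

    def to_json(self) -> str:
        return json.dumps({
            "trainable_parameters": self.trainable_parameters,
            "macs": self.macs,
            "gmacs": self.gmacs,
            "input_size": self.input_size,
            "per_layer": [{"layer": n, "parameters": p} for n, p in self.per_layer],
        }, indent=2)

    def __str__(self) -> str:
        lines = [f"{'layer':<40}{'params':>12}", "-" * 52]
        for name, p in self.per_layer:
            lines.append(f"{name:<40}{p:>12,}")
        lines.append("-" * 52)
        lines.append(f"{'total trainable':<40}{self.trainable_parameters:>12,}")
        lines.append(f"MACs @ {self.input_size}x{self.input_size}x3: "
                     f"{self.gmacs:.3f} GMac")
        return "\n".join(lines)


def count_parameters(model: PlutoNet, include_aux: bool = True) -> int:
    """Sum of sizes of all trainable tensors."""
    return model.count_parameters(include_aux)


def count_parameters_oracle(model: PlutoNet, include_aux: bool = True) -> int:
    """Independent brute-force count: walk every trainable tensor and multiply
    its dimensions explicitly (no reliance on ndarray.size)."""
    total = 0
    for p in model.trainable_parameters(include_aux):
        n = 1
        for d in p.data.shape:
            n *= int(d)
        total += n
    return total


def count_macs(model: PlutoNet, input_size: int | None = None) -> int:
    """Multiply-accumulates of one main-branch (inference) forward pass.

    Measured by metering an actual forward pass on a zero image, so the
    count reflects the graph exactly as executed.
    """
    size = input_size or model.encoder_config.input_size
    if size != model.encoder_config.input_size:
        from dataclasses import replace
        model = PlutoNet(replace(model.encoder_config, input_size=size),
                         model.decoder_config, with_aux=False)
    x = np.zeros((1, size, size, 3), dtype=np.float32)
    with nn.mac_meter() as meter:
        model.forward(x, training=False, with_aux=False)
    return meter.total


def _layer_rows(module, include_aux: bool):
    rows = []
    for sub in module.submodules():
        own = [v for v in vars(sub).values() if isinstance(v, nn.Parameter)]
        if own:
            rows.append((sub.name or sub.__class__.__name__,
                         int(sum(p.data.size for p in own))))
    return rows


def summarize(model: PlutoNet, input_size: int | None = None,
              include_aux: bool = False) -> ModelSummary:
    """Assemble parameter and MAC totals plus the per-layer table.

    With ``include_aux=False`` (inference graph) no auxiliary-branch rows
    appear and the parameter total is the deployable model's.
    """
    size = input_size or model.encoder_config.input_size
    rows = _layer_rows(model.encoder, include_aux)
    rows += _layer_rows(model.decoder, include_aux)
    if include_aux and model.aux is not None:
        rows += _layer_rows(model.aux, include_aux)
    total = count_parameters(model, include_aux)
    assert total == sum(p for _, p in rows)
    return ModelSummary(trainable_parameters=total,
                        macs=count_macs(model, size),
                        input_size=size, per_layer=rows)
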