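"""Backbone feature blocks.

Two block families live here:

* :class:`C3K2Block` — the split–bottleneck–merge block used throughout
  recent YOLO backbones: a 1x1 conv splits the channels, a chain of residual
  bottlenecks enriches one half while every intermediate output is retained,
  and a final 1x1 conv merges them.
* :class:`BBMM` — the block-based mixed mechanism: three parallel branches
  over the same input (the C3K2 path, a 1x1 channel-mixing convolution, and
  a 3x3 deformable convolution whose predicted offsets adapt the receptive
  field to non-rigid cell morphology), fused either by channel concatenation
  followed by a 1x1 projection (default) or by summation.

All blocks are stride 1: spatial size in equals spatial size out.
"""
from __future__ import annotations

from dataclasses import dataclass

from .autodiff import concat, silu
from .layers import Conv2d, ConvBNAct, DeformableConv2d, Module


@dataclass
class BBMMConfig:
    """Configuration of a BBMM block.

    branch_fusion: "concat+project" (default) or "sum".
    n_bottlenecks: bottlenecks inside the C3K2 branch.
    kernel: deformable-branch kernel size (odd).
    """
    in_channels: int
    out_channels: int
    branch_fusion: str = "concat+project"
    n_bottlenecks: int = 1
    kernel: int = 3

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be positive")
        if self.kernel % 2 != 1 or self.kernel < 1:
            raise ValueError("kernel must be a positive odd size")
        if self.branch_fusion not in ("concat+project", "sum"):
            raise ValueError(
                f"unknown branch_fusion {self.branch_fusion!r}; "
                "expected 'concat+project' or 'sum'")


class Bottleneck(Module):
    """Two 3x3 convs with a residual skip when shapes allow."""

    def __init__(self, rng, c_in, c_out):
        super().__init__()
        self.cv1 = ConvBNAct(rng, c_in, c_out, k=3)
        self.cv2 = ConvBNAct(rng, c_out, c_out, k=3)
        self.add = c_in == c_out

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3K2Block(Module):
    """Split–bottleneck–merge transform (C2f-style)."""

    def __init__(self, rng, c_in, c_out, n=1):
        super().__init__()
        c_h = max(c_out // 2, 1)
        self.cv1 = ConvBNAct(rng, c_in, 2 * c_h, k=1)
        self.bottlenecks = [Bottleneck(rng, c_h, c_h) for _ in range(n)]
        self.cv2 = ConvBNAct(rng, (2 + n) * c_h, c_out, k=1)
        self.c_h = c_h

    def forward(self, x):
        y = self.cv1(x)
        a = y[:, : self.c_h]
        b = y[:, self.c_h:]
        outs = [a, b]
        for m in self.bottlenecks:
            outs.append(m(outs[-1]))
        return self.cv2(concat(outs, axis=1))


class BBMM(Module):
    """Block-based mixed mechanism: C3K2 ∥ 1x1 conv ∥ deformable conv."""

    N_BRANCHES = 3

    def __init__(self, rng, cfg: BBMMConfig):
        super().__init__()
        self.cfg = cfg
        ci, co = cfg.in_channels, cfg.out_channels
        self.c3k2 = C3K2Block(rng, ci, co, n=cfg.n_bottlenecks)
        self.pointwise = ConvBNAct(rng, ci, co, k=1)
        self.deform = DeformableConv2d(rng, ci, co, k=cfg.kernel)
        if cfg.branch_fusion == "concat+project":
            self.project = Conv2d(rng, 3 * co, co, k=1)
        else:
            self.project = None

    def forward(self, x):
        branches = [self.c3k2(x), self.pointwise(x), silu(self.deform(x))]
        if self.project is not None:
            return self.project(concat(branches, axis=1))
        return branches[0] + branches[1] + branches[2]


def c3k2_block(rng, x, cfg: BBMMConfig):
    """Functional form: run a freshly initialised C3K2 block on `x`."""
    return C3K2Block(rng, cfg.in_channels, cfg.out_channels,
                     n=cfg.n_bottlenecks)(x)


def bbmm_block(rng, x, cfg: BBMMConfig):
    """Functional form: run a freshly initialised BBMM block on `x`."""
    return BBMM(rng, cfg)(x)
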