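"""The fusion expert network.

Pipeline (one forward pass):

1. *Shallow extraction* — two depthwise-separable 3x3 convolutions with
   disjoint parameters map the color image (3 channels) and the depth
   map (1 channel) to C-channel feature maps at the input resolution.
2. *Concatenation* — ``F_RGBD = [F_RGB, F_D]`` along channels (2C).
3. *Spatial attention* — channel-wise average- and max-pooled maps are
   concatenated (2 channels), passed through a single 7x7 convolution to
   one channel and a sigmoid, giving a mask ``W_S`` in (0,1) that
   reweights every pixel of the fused map.
4. *Channel split* — the masked map yields three branch inputs: the
   first C channels (masked RGB), all 2C channels (masked RGB-D), and
   the last C channels (masked depth).
5. *Three experts* — each branch feeds an independent ResNet18-style
   backbone (7x7/s2 stem, 3x3/s2 max pool, four residual stages at
   64/64/128/256/512 channels scaled by a width multiplier) ending in
   global average pooling: the "father" (RGB), "child" (fused) and
   "mother" (depth) embeddings.
6. *Gated heads* — per task, a nonnegative (softplus) gate per expert
   forms a weighted sum of embeddings which a linear head maps to one
   scalar; the 3x3 gate matrix is the reported expert-contribution
   matrix.

Ablation switches: ``ablate_attention`` forces ``W_S = 1``;
``ablate_experts`` replaces the three experts by a single general
network on the full 2C-channel branch (all three embeddings then
coincide and the heritable loss is unavailable).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

#: the expert backbone layer contract: (name, kernel, stride, padding, out_channels)
TABLE1_SPEC = (
    ("conv1", 7, 2, 3, 64),
    ("maxpool", 3, 2, 1, 64),
    ("conv2", 3, 1, 1, 64),
    ("conv3", 3, 2, 1, 128),
    ("conv4", 3, 2, 1, 256),
    ("conv5", 3, 2, 1, 512),
)

MIN_INPUT_SIZE = 32  # below this the five stride-2 stages collapse to nothing

TASKS = ("weight", "uniformity", "count")
EXPERTS = ("father", "child", "mother")


@dataclasses.dataclass
class FusionConfig:
    shallow_channels: int = 8
    width_multiplier: float = 1.0
    attention_kernel: int = 7
    head_gate_type: str = "softplus"
    ablate_attention: bool = False
    ablate_experts: bool = False

    def __post_init__(self):
        if self.attention_kernel % 2 == 0:
            raise ValueError("attention_kernel must be odd")
        if not 0.0 < self.width_multiplier <= 1.0:
            raise ValueError("width_multiplier must lie in (0, 1]")
        if self.head_gate_type != "softplus":
            raise ValueError("only the softplus gate family is implemented")

    def scaled(self, channels: int) -> int:
        return max(1, int(round(channels * self.width_multiplier)))

    @property
    def embedding_dim(self) -> int:
        return self.scaled(TABLE1_SPEC[-1][4])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FusionConfig":
        return cls(**d)


@dataclasses.dataclass
class FeatureBundle:
    """Intermediates of one forward pass (autodiff tensors)."""

    f_rgb: Tensor
    f_d: Tensor
    f_rgbd: Tensor
    w_s: Tensor
    f_rgbd_masked: Tensor
    m_rgb: Tensor
    m_rgbd: Tensor
    m_d: Tensor


@dataclasses.dataclass
class ExpertEmbeddings:
    """Pooled expert feature vectors, (n, embedding_dim) each."""

    father: Tensor
    mother: Tensor
    child: Tensor
    experts_ablated: bool = False


@dataclasses.dataclass
class TraitPredictions:
    """De-standardized per-scene predictions; count is rounded only here."""

    weight_hat: np.ndarray
    uniformity_hat: np.ndarray
    count_hat: np.ndarray

    def rounded_counts(self) -> np.ndarray:
        return np.clip(np.round(self.count_hat), 0, None)


class ShallowExtractor(nn.Module):
    """Per-modality depthwise-separable 3x3 conv (stride 1) + ReLU."""

    def __init__(self, in_channels: int, out_channels: int, rng):
        super().__init__()
        self.conv = nn.DepthwiseSeparableConv(in_channels, out_channels, 3, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(x).relu()


class SpatialAttention(nn.Module):
    """Channel avg/max pooling -> kxk conv to 1 channel -> sigmoid mask."""

    def __init__(self, kernel: int, rng):
        super().__init__()
        self.conv = nn.Conv2d(2, 1, kernel, stride=1, padding=kernel // 2,
                              bias=True, rng=rng)

    def __call__(self, f_rgbd: Tensor) -> Tensor:
        avg = f_rgbd.mean(axis=1, keepdims=True)
        mx = f_rgbd.max(axis=1, keepdims=True)
        return self.conv(ad.concat([avg, mx], axis=1)).sigmoid()


class BasicBlock(nn.Module):
    """Two 3x3 conv/BN layers with an identity (or 1x1 projected) skip."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=1,
                               bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, stride=1, padding=1,
                               bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.proj = nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng)
            self.proj_bn = nn.BatchNorm2d(out_ch)
        else:
            self.proj = None

    def __call__(self, x: Tensor) -> Tensor:
        out = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        skip = self.proj_bn(self.proj(x)) if self.proj is not None else x
        return (out + skip).relu()


class ExpertNetwork(nn.Module):
    """One ResNet18-style backbone ending in a global-average-pooled embedding."""

    def __init__(self, in_channels: int, config: FusionConfig, rng):
        super().__init__()
        c1 = config.scaled(TABLE1_SPEC[0][4])
        self.stem = nn.Conv2d(in_channels, c1, 7, stride=2, padding=3,
                              bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(c1)
        self.stages = []
        in_ch = c1
        for name, _, stride, _, channels in TABLE1_SPEC[2:]:
            out_ch = config.scaled(channels)
            self.stages.append(BasicBlock(in_ch, out_ch, stride, rng))
            self.stages.append(BasicBlock(out_ch, out_ch, 1, rng))
            in_ch = out_ch
        self.embedding_dim = in_ch

    def __call__(self, x: Tensor) -> Tensor:
        if min(x.shape[2], x.shape[3]) < MIN_INPUT_SIZE:
            raise ValueError(f"expert input must be at least "
                             f"{MIN_INPUT_SIZE}x{MIN_INPUT_SIZE}, got {x.shape[2:]}")
        out = ad.max_pool2d(self.stem_bn(self.stem(x)).relu(), 3, 2, 1)
        for block in self.stages:
            out = block(out)
        return ad.global_avg_pool(out)

    def shape_trace(self, input_hw: int = 224):
        """(layer name, spatial size, channels) after each backbone layer."""
        with ad.no_grad():
            self.eval()
            x = Tensor(np.zeros((1, self.stem.weight.shape[1], input_hw, input_hw),
                                np.float32))
            rows = []
            out = self.stem_bn(self.stem(x)).relu()
            rows.append(("conv1", out.shape[2], out.shape[1]))
            out = ad.max_pool2d(out, 3, 2, 1)
            rows.append(("maxpool", out.shape[2], out.shape[1]))
            for i in range(0, len(self.stages), 2):
                out = self.stages[i + 1](self.stages[i](out))
                rows.append((f"conv{2 + i // 2}", out.shape[2], out.shape[1]))
            self.train()
        return rows


def shallow_extract(rgb: Tensor, depth: Tensor, extractor_rgb: ShallowExtractor,
                    extractor_depth: ShallowExtractor) -> tuple[Tensor, Tensor]:
    if rgb.shape[2:] != depth.shape[2:]:
        raise ValueError(f"modalities must share spatial size, got "
                         f"{rgb.shape[2:]} vs {depth.shape[2:]}")
    return extractor_rgb(rgb), extractor_depth(depth)


def split_masked(f_rgbd_masked: Tensor) -> tuple[Tensor, Tensor, Tensor]:
    """First C channels (RGB branch), all 2C (fusion branch), last C (depth)."""
    channels = f_rgbd_masked.shape[1]
    if channels % 2:
        raise ValueError(f"channel count must be even, got {channels}")
    c = channels // 2
    return (f_rgbd_masked[:, :c], f_rgbd_masked, f_rgbd_masked[:, c:])


def softplus_inverse(y: float) -> float:
    return float(np.log(np.expm1(y))) if y > 0 else -1e4


class FusionExpertNet(nn.Module):
    """The full model; see the module docstring for the pipeline."""

    GATE_INIT = 1.0 / 3.0  # each expert starts contributing equally

    def __init__(self, config: FusionConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB3]))
        c = config.shallow_channels
        self.shallow_rgb = ShallowExtractor(3, c, rng)
        self.shallow_depth = ShallowExtractor(1, c, rng)
        self.attention = SpatialAttention(config.attention_kernel, rng)
        if config.ablate_experts:
            self.general = ExpertNetwork(2 * c, config, rng)
            self.experts = []
        else:
            self.general = None
            # father (RGB, C ch), child (fused, 2C ch), mother (depth, C ch)
            self.experts = [ExpertNetwork(c, config, rng),
                            ExpertNetwork(2 * c, config, rng),
                            ExpertNetwork(c, config, rng)]
        emb = config.embedding_dim
        raw0 = softplus_inverse(self.GATE_INIT)
        self.gate_raw = Tensor(np.full((3, 3), raw0, np.float32), requires_grad=True)
        self.heads = [nn.Linear(emb, 1, rng=rng) for _ in TASKS]

    # -- pieces -----------------------------------------------------------
    def attention_fuse(self, f_rgbd: Tensor) -> tuple[Tensor, Tensor]:
        if self.config.ablate_attention:
            w_s = Tensor(np.ones((f_rgbd.shape[0], 1) + f_rgbd.shape[2:],
                                 f_rgbd.data.dtype))
            return w_s, f_rgbd
        w_s = self.attention(f_rgbd)
        return w_s, w_s * f_rgbd

    def gates(self) -> Tensor:
        """(tasks x experts) nonnegative contribution matrix."""
        return self.gate_raw.softplus()

    def predict_traits(self, embeddings: ExpertEmbeddings) -> tuple[Tensor, np.ndarray]:
        """Gated sum of expert embeddings per task -> linear head -> scalar.

        Returns the (n, 3) standardized prediction tensor and the gate
        matrix as the per-task expert contribution report.
        """
        gates = self.gates()
        exp_vecs = [embeddings.father, embeddings.child, embeddings.mother]
        outs = []
        for t in range(len(TASKS)):
            mixed = None
            for e, vec in enumerate(exp_vecs):
                term = gates[t, e].reshape(1, 1) * vec
                mixed = term if mixed is None else mixed + term
            outs.append(self.heads[t](mixed))
        preds = ad.concat(outs, axis=1)
        return preds, gates.data.copy()

    # -- full forward -----------------------------------------------------
    def __call__(self, rgb: Tensor, depth: Tensor):
        """rgb (n,3,H,W), depth (n,1,H,W) -> (predictions (n,3) Tensor,
        ExpertEmbeddings, FeatureBundle)."""
        if rgb.shape[0] == 0:
            raise ValueError("empty batch")
        f_rgb, f_d = shallow_extract(rgb, depth, self.shallow_rgb, self.shallow_depth)
        f_rgbd = ad.concat([f_rgb, f_d], axis=1)
        w_s, masked = self.attention_fuse(f_rgbd)
        m_rgb, m_rgbd, m_d = split_masked(masked)
        bundle = FeatureBundle(f_rgb=f_rgb, f_d=f_d, f_rgbd=f_rgbd, w_s=w_s,
                               f_rgbd_masked=masked, m_rgb=m_rgb,
                               m_rgbd=m_rgbd, m_d=m_d)
        if self.config.ablate_experts:
            shared = self.general(m_rgbd)
            embeddings = ExpertEmbeddings(father=shared, mother=shared,
                                          child=shared, experts_ablated=True)
        else:
            embeddings = ExpertEmbeddings(
                father=self.experts[0](m_rgb),
                child=self.experts[1](m_rgbd),
                mother=self.experts[2](m_d),
            )
        preds, _ = self.predict_traits(embeddings)
        return preds, embeddings, bundle
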