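"""Per-level U-Net and the hierarchical patchwork conditioning contract.

Each pyramid level owns a small 3D U-Net of identical architecture
(default feature dimensions ``(8, 16, 16, 32, 64)``, max pooling down,
transposed convolutions up) operating on the level's fixed 32^3 patch
matrix.  Level 0 sees only the image patch; every finer level additionally
receives its parent's foreground class probabilities, resampled
trilinearly onto the child patch grid, as extra input channels — this is
what lets a 32 mm, 1 mm-resolution patch know where it sits inside the
150 mm context.

The engine behind the layers is the package's own numpy implementation in
:mod:`patchwork3d._nn`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from . import _nn
from ._resample import grid_sample_trilinear
from .pyramid import PatchPyramidConfig, PatchSpec, level_sizes, patch_bounds, validate_chain

__all__ = [
    "UNetConfig",
    "DNPConfig",
    "SingleLevelBaselineConfig",
    "UNet3D",
    "PatchworkModel",
    "build_level_net",
    "forward_hierarchy",
]


@dataclass(frozen=True)
class UNetConfig:
    """Architecture of one per-level network.

    ``feature_dims`` follows the U-Net convention: one entry per encoder
    stage plus the bottleneck.  The reference configuration is
    ``(8, 16, 16, 32, 64)``; the desk preset uses a slimmer net sized for
    one-CPU runs.
    """

    feature_dims: tuple[int, ...] = (8, 16, 16, 32, 64)
    convs_per_block: int = 1
    out_classes: int = 3
    matrix: int = 32
    decoder_kernel: int = 3

    def __post_init__(self) -> None:
        if len(self.feature_dims) < 2:
            raise ValueError("feature_dims needs at least two entries")
        depth = len(self.feature_dims) - 1
        if self.matrix % (2**depth) != 0 or self.matrix // (2**depth) < 1:
            raise ValueError(
                f"feature_dims too deep: {self.matrix}^3 patches cannot be pooled "
                f"{depth} times"
            )

    @classmethod
    def desk(cls) -> "UNetConfig":
        """Slim configuration for one-CPU desk-scale experiments.

        Pointwise decoder convolutions keep the full-resolution decoder
        cheap; local detail still enters through the skip connection from
        the 3x3x3 encoder stage.  Four stages give deep features a
        receptive field wide enough to reach the midline landmark from the
        putamen, which is what makes left/right assignment learnable.
        """
        return cls(feature_dims=(4, 8, 16, 32), decoder_kernel=1)


@dataclass(frozen=True)
class DNPConfig:
    """Full patchwork: pyramid geometry plus the shared per-level U-Net config."""

    pyramid: PatchPyramidConfig = field(default_factory=PatchPyramidConfig)
    unet: UNetConfig = field(default_factory=UNetConfig.desk)
    condition_on: str = "probs"  # or "logits"
    condition_classes: str = "foreground"  # or "all"

    def cond_channels(self) -> int:
        if self.condition_classes == "foreground":
            return self.unet.out_classes - 1
        return self.unet.out_classes

    def in_channels(self, level: int) -> int:
        return 1 if level == 0 else 1 + self.cond_channels()


def SingleLevelBaselineConfig(
    matrix: int = 128, fov_mm: tuple[float, float, float] = (256.0, 256.0, 192.0)
) -> DNPConfig:
    """Classical one-level 3D U-Net covering the head at reduced resolution.

    With the default 128^3 matrix over a (256, 256, 192) mm field of view the
    voxel size is 2 x 2 x 1.5 mm.  Only isotropic patch geometry is supported
    by the pyramid, so the baseline uses the largest axis as its cubic field
    of view; the 32^3 coarsest-only baseline used in desk experiments is
    ``DNPConfig(pyramid=PatchPyramidConfig(n_levels=1))``.
    """
    del fov_mm
    return DNPConfig(
        pyramid=PatchPyramidConfig(n_levels=1, matrix=matrix, coarsest_fov_mm=256.0),
        unet=UNetConfig(matrix=matrix),
    )


class UNet3D:
    """3D U-Net on a fixed cubic matrix; returns per-class logits.

    ``forward`` caches activations for a matching ``backward`` call; use
    ``predict_probs`` for inference (softmax over channel axis).
    """

    def __init__(self, cfg: UNetConfig, in_channels: int, seed: int):
        self.cfg = cfg
        self.in_channels = in_channels
        rng = np.random.default_rng(seed)
        f = cfg.feature_dims
        depth = len(f) - 1
        self.enc: list[_Block] = []
        self.pools: list[_nn.MaxPool3d] = []
        c = in_channels
        for i in range(depth):
            self.enc.append(_Block(c, f[i], cfg.convs_per_block, rng))
            self.pools.append(_nn.MaxPool3d())
            c = f[i]
        self.bottleneck = _Block(c, f[-1], cfg.convs_per_block, rng)
        self.tconvs: list[_nn.ConvTranspose3d] = []
        self.dec: list[_Block] = []
        c = f[-1]
        for i in reversed(range(depth)):
            self.tconvs.append(_nn.ConvTranspose3d(c, f[i], rng))
            self.dec.append(
                _Block(2 * f[i], f[i], cfg.convs_per_block, rng, k=cfg.decoder_kernel)
            )
            c = f[i]
        self.head = _nn.Conv3d(c, cfg.out_classes, 1, rng)
        # background-prior head bias: foreground voxels are rare, so start
        # from a confident-background prediction instead of a uniform one
        if cfg.out_classes >= 2:
            self.head.b.value[0] = 2.0
            self.head.b.value[1:] = -2.0

    # ---- autodiff ----

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {x.shape[1]}")
        skips = []
        h = x
        for blk, pool in zip(self.enc, self.pools):
            h = blk.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        self._skip_channels = []
        for tconv, dec in zip(self.tconvs, self.dec):
            h = tconv.forward(h)
            s = skips.pop()
            self._skip_channels.append(s.shape[1])
            h = np.concatenate([s, h], axis=1)
            h = dec.forward(h)
        return self.head.forward(h)

    def backward(self, glogits: np.ndarray) -> np.ndarray:
        g = self.head.backward(glogits)
        gskips = []
        for tconv, dec, cs in zip(
            reversed(self.tconvs), reversed(self.dec), reversed(self._skip_channels)
        ):
            g = dec.backward(g)
            gskips.append(g[:, :cs])
            g = tconv.backward(g[:, cs:])
        g = self.bottleneck.backward(g)
        for blk, pool in zip(reversed(self.enc), reversed(self.pools)):
            g = pool.backward(g)
            g = g + gskips.pop()
            g = blk.backward(g)
        return g

    def predict_probs(self, x: np.ndarray) -> np.ndarray:
        return _nn.softmax(self.forward(x), axis=1)

    # ---- parameters ----

    def params(self) -> list[_nn.Param]:
        out = []
        for blk in self.enc:
            out += blk.params()
        out += self.bottleneck.params()
        for tconv, dec in zip(self.tconvs, self.dec):
            out += tconv.params()
            out += dec.params()
        out += self.head.params()
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.params()
        if len(state) != len(params):
            raise ValueError("state length mismatch")
        for p, v in zip(params, state):
            p.value[...] = v


class _Block:
    """``convs_per_block`` repeats of Conv3d -> InstanceNorm -> ReLU."""

    def __init__(self, cin: int, cout: int, n: int, rng: np.random.Generator, k: int = 3):
        self.ops: list = []
        c = cin
        for _ in range(n):
            self.ops += [_nn.Conv3d(c, cout, k, rng), _nn.InstanceNorm3d(cout), _nn.ReLU()]
            c = cout

    def forward(self, x: np.ndarray) -> np.ndarray:
        for op in self.ops:
            x = op.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for op in reversed(self.ops):
            g = op.backward(g)
        return g

    def params(self) -> list[_nn.Param]:
        out = []
        for op in self.ops:
            out += op.params()
        return out


def build_level_net(cfg: UNetConfig, in_channels: int = 1, seed: int = 0) -> UNet3D:
    """Construct one per-level segmentation net with seeded initialization."""
    return UNet3D(cfg, in_channels, seed)


def resample_patch_field(
    field_arr: np.ndarray,
    parent_spec: PatchSpec,
    child_spec: PatchSpec,
    matrix: int,
) -> np.ndarray:
    """Resample a (C, m, m, m) field from a parent patch grid onto a child grid.

    Trilinear, edge-clamped; used to hand parent probabilities down the
    hierarchy.
    """
    plo, _ = patch_bounds(parent_spec)
    clo, _ = patch_bounds(child_spec)
    p_spacing = parent_spec.size_mm / matrix
    c_spacing = child_spec.size_mm / matrix
    # child sample positions, expressed in parent patch index coordinates
    coords1d = [
        (clo[ax] + (np.arange(matrix) + 0.5) * c_spacing - plo[ax]) / p_spacing - 0.5
        for ax in range(3)
    ]
    return np.stack(
        [
            grid_sample_trilinear(field_arr[c], *coords1d, clamp=True)
            for c in range(field_arr.shape[0])
        ]
    )


class PatchworkModel:
    """The stacked hierarchy: one :class:`UNet3D` per pyramid level."""

    def __init__(self, cfg: DNPConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        ss = np.random.SeedSequence([seed, 0x9E37])
        level_seeds = ss.generate_state(cfg.pyramid.n_levels)
        self.nets = [
            build_level_net(cfg.unet, cfg.in_channels(level), int(s) % (2**31))
            for level, s in enumerate(level_seeds)
        ]

    @property
    def n_levels(self) -> int:
        return self.cfg.pyramid.n_levels

    def conditioning(
        self, parent_probs: np.ndarray, parent_spec: PatchSpec, child_spec: PatchSpec
    ) -> np.ndarray:
        """Extra input channels for a child patch from its parent's output."""
        fields = _conditioning_fields(parent_probs, self.cfg)
        return resample_patch_field(fields, parent_spec, child_spec, self.cfg.unet.matrix)

    def level_input(
        self,
        level: int,
        image_patch: np.ndarray,
        parent_probs: np.ndarray | None,
        parent_spec: PatchSpec | None,
        spec: PatchSpec,
    ) -> np.ndarray:
        """Assemble the (C, m, m, m) input for one patch at one level."""
        img = image_patch[None].astype(np.float32)
        if level == 0:
            return img
        if parent_probs is None or parent_spec is None:
            raise ValueError(f"level {level} requires parent conditioning")
        cond = self.conditioning(parent_probs, parent_spec, spec).astype(np.float32)
        return np.concatenate([img, cond], axis=0)

    # ---- persistence ----

    def save(self, path) -> None:
        arrays = {}
        for lvl, net in enumerate(self.nets):
            for i, arr in enumerate(net.get_state()):
                arrays[f"level{lvl}_p{i}"] = arr
        meta = {
            "format_version": 1,
            "seed": self.seed,
            "pyramid": asdict(self.cfg.pyramid),
            "unet": asdict(self.cfg.unet),
            "condition_on": self.cfg.condition_on,
            "condition_classes": self.cfg.condition_classes,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "PatchworkModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            model = cls(
                DNPConfig(
                    pyramid=PatchPyramidConfig(**meta["pyramid"]),
                    unet=UNetConfig(
                        feature_dims=tuple(meta["unet"]["feature_dims"]),
                        convs_per_block=meta["unet"]["convs_per_block"],
                        out_classes=meta["unet"]["out_classes"],
                        matrix=meta["unet"]["matrix"],
                        decoder_kernel=meta["unet"].get("decoder_kernel", 3),
                    ),
                    condition_on=meta["condition_on"],
                    condition_classes=meta["condition_classes"],
                ),
                seed=meta["seed"],
            )
            for lvl, net in enumerate(model.nets):
                state = []
                i = 0
                while f"level{lvl}_p{i}" in z:
                    state.append(z[f"level{lvl}_p{i}"])
                    i += 1
                net.set_state(state)
        return model


def _conditioning_fields(parent_probs: np.ndarray, cfg: DNPConfig) -> np.ndarray:
    """Select and transform the parent output channels handed to a child.

    ``condition_on="logits"`` passes log-probabilities (equal to logits up
    to a per-voxel constant, which the first convolution's bias absorbs).
    """
    fields = parent_probs[1:] if cfg.condition_classes == "foreground" else parent_probs
    if cfg.condition_on == "logits":
        fields = np.log(np.clip(fields, 1e-7, None))
    return fields


def forward_hierarchy(
    nets: list,
    image_patches: list[np.ndarray],
    chain: list[PatchSpec],
    cfg: DNPConfig | None = None,
) -> np.ndarray:
    """Run one nested chain through the hierarchy; return finest-level probs.

    ``nets`` must expose ``predict_probs`` on a (1, C, m, m, m) input (the
    per-level U-Nets do; tests use stubs).  Level 0 sees the image patch
    only; each finer level sees its image patch concatenated with the
    parent's foreground probabilities resampled onto its grid.
    """
    cfg = cfg or DNPConfig()
    validate_chain(chain, cfg.pyramid)
    if len(nets) != len(chain) or len(image_patches) != len(chain):
        raise ValueError("nets, image_patches and chain must have one entry per level")
    matrix = cfg.unet.matrix
    probs = None
    prev_spec = None
    for level, (net, img, spec) in enumerate(zip(nets, image_patches, chain)):
        x = img[None].astype(np.float32)
        if level > 0:
            fields = _conditioning_fields(probs, cfg)
            cond = resample_patch_field(fields, prev_spec, spec, matrix).astype(np.float32)
            x = np.concatenate([x, cond], axis=0)
        probs = net.predict_probs(x[None])[0]
        prev_spec = spec
    return probs
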