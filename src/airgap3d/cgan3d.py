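"""3D pix2pix conditional GAN for volumetric artifact inpainting.

The generator is a 3D U-Net whose encoder halves the cube edge at every
block until a 1-voxel bottleneck, with skip connections at matching
resolutions; the discriminator is a 3D PatchGAN that scores overlapping
patches of a (source, candidate) pair concatenated along the channel axis.
At the default cube edge of 256 the architecture reproduces the canonical
pix2pix layer strings

* encoder  C64-C128-C256-C512-C512-C512-C512-C512
* decoder  T512-T512-T512-T512-T256-T128-T64 (+ output transpose conv, tanh)
* PatchGAN C64-C128-C256-C512 (+ 1-filter scoring conv, sigmoid)

with 4x4x4 kernels, stride 2 (the last two discriminator convolutions use
stride 1, giving a 70-voxel receptive field per score).  The cube edge is
configurable — the depth rule ``len(encoder_filters) == log2(edge)``
generalises the printed architecture, and the test/desk scale uses edges
16-32.

Training alternates one discriminator update (real pair vs. fake pair, BCE
halved per the original pix2pix convention) with one generator update
(BCE toward "real" plus an L1 term weighted by ``lambda_l1 = 100``), batch
size 1, Adam(lr=2e-4, beta1=0, beta2=0.999).  Intensities are mapped to
[-1, 1] before the network (tanh output head) and back to 8-bit afterwards.
Inference is deterministic: dropout and normalisation run in eval mode.

Checkpoints are written every ``checkpoint_interval_epochs`` epochs as
``generator_epoch{N}.npz`` plus a JSON manifest; per-iteration losses go to
``losses.csv``.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .pair_factory import TrainingPair
from .volume_io import Volume3D, _round_half_away

__all__ = [
    "GeneratorSpec", "DiscriminatorSpec", "TrainConfig",
    "GeneratorModel", "DiscriminatorModel", "CheckpointSeries",
    "build_generator", "build_discriminator", "receptive_field",
    "generator_loss", "discriminator_loss",
    "train", "generate", "load_generator",
    "normalize_intensities", "denormalize_intensities",
]

_FULL_ENCODER = (64, 128, 256, 512, 512, 512, 512, 512)


# ---------------------------------------------------------------------------
# specs


@dataclass
class GeneratorSpec:
    """3D U-Net architecture parameters.

    ``encoder_filters`` must have exactly ``log2(cube_edge)`` entries so the
    bottleneck is 1 voxel; the decoder mirrors the encoder minus the
    bottleneck.  Dropout (rate 0.5) acts on the first ``n_dropout_blocks``
    decoder blocks.
    """

    cube_edge: int = 256
    encoder_filters: tuple[int, ...] | None = None
    kernel: int = 4
    stride: int = 2
    dropout_rate: float = 0.5
    n_dropout_blocks: int = 3
    leaky_slope: float = 0.2

    def __post_init__(self) -> None:
        e = self.cube_edge
        if e < 8 or e & (e - 1):
            raise ValueError(f"cube_edge must be a power of two >= 8, got {e}")
        depth = int(math.log2(e))
        if self.encoder_filters is None:
            self.encoder_filters = _FULL_ENCODER[:depth]
        self.encoder_filters = tuple(self.encoder_filters)
        if len(self.encoder_filters) != depth:
            raise ValueError(
                f"need log2({e}) = {depth} encoder filters for a 1-voxel "
                f"bottleneck, got {len(self.encoder_filters)}"
            )

    @property
    def decoder_filters(self) -> tuple[int, ...]:
        return tuple(reversed(self.encoder_filters[:-1]))


@dataclass
class DiscriminatorSpec:
    """3D PatchGAN architecture parameters.

    The final listed block and the 1-filter scoring convolution both use
    stride 1 ("the final two convolutions have stride 1").
    """

    filters: tuple[int, ...] = (64, 128, 256, 512)
    strides: tuple[int, ...] = (2, 2, 2, 1)
    kernel: int = 4
    leaky_slope: float = 0.2

    def __post_init__(self) -> None:
        self.filters = tuple(self.filters)
        self.strides = tuple(self.strides)
        if len(self.filters) != len(self.strides):
            raise ValueError("filters and strides must have equal length")
        if self.strides[-1] != 1:
            raise ValueError("the final two convolutions must have stride 1")


@dataclass
class TrainConfig:
    """Optimisation hyper-parameters of the alternating GAN training."""

    lambda_l1: float = 100.0
    learning_rate: float = 0.0002
    beta1: float = 0.0
    beta2: float = 0.999
    batch_size: int = 1
    epochs: int = 30
    checkpoint_interval_epochs: int = 10
    save_initial: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_l1 <= 0:
            raise ValueError("lambda_l1 must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


# ---------------------------------------------------------------------------
# intensity normalisation


def normalize_intensities(data: np.ndarray) -> np.ndarray:
    """8-bit [0, 255] -> float32 [-1, 1] (tanh range)."""
    return (np.asarray(data, dtype=np.float32) / 127.5) - 1.0


def denormalize_intensities(data: np.ndarray) -> np.ndarray:
    """float [-1, 1] -> uint8 [0, 255]; inverts :func:`normalize_intensities`
    exactly on 8-bit inputs (round half away from zero, then clip)."""
    out = (np.asarray(data, dtype=np.float64) + 1.0) * 127.5
    return np.clip(_round_half_away(out), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# networks


class _UNet3d(nn.Module):
    """Encoder/decoder with skip connections; input/output (1, E, E, E)."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator,
                 dtype=np.float32):
        self.spec = spec
        k, s = spec.kernel, spec.stride
        filters = spec.encoder_filters
        depth = len(filters)

        self.enc: list[nn.Sequential] = []
        in_ch = 1
        for i, f in enumerate(filters):
            layers: list[nn.Module] = [nn.Conv3d(in_ch, f, k, s, rng, dtype)]
            if 0 < i < depth - 1:           # no norm on first block or bottleneck
                layers.append(nn.BatchNorm3d(f, rng=rng, dtype=dtype))
            layers.append(nn.ReLU() if i == depth - 1 else nn.LeakyReLU(spec.leaky_slope))
            self.enc.append(nn.Sequential(*layers))
            in_ch = f

        self.dec: list[nn.Sequential] = []
        in_ch = filters[-1]
        for j, f in enumerate(spec.decoder_filters):
            layers = [nn.ConvTranspose3d(in_ch, f, k, s, rng, dtype),
                      nn.BatchNorm3d(f, rng=rng, dtype=dtype)]
            if j < spec.n_dropout_blocks and spec.dropout_rate > 0:
                layers.append(nn.Dropout(spec.dropout_rate, rng))
            layers.append(nn.ReLU())
            self.dec.append(nn.Sequential(*layers))
            # next block consumes the concat with the matching encoder output
            in_ch = f + filters[depth - 2 - j]
        self.final = nn.Sequential(nn.ConvTranspose3d(in_ch, 1, k, s, rng, dtype), nn.Tanh())

    def params(self):
        blocks = self.enc + self.dec + [self.final]
        return [p for b in blocks for p in b.params()]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        skips = []
        h = x
        for blk in self.enc:
            h = blk.forward(h, training)
            skips.append(h)
        self._split_sizes = []
        for j, blk in enumerate(self.dec):
            h = blk.forward(h, training)
            skip = skips[len(self.enc) - 2 - j]
            self._split_sizes.append(h.shape[0])
            h = np.concatenate([h, skip], axis=0)
        return self.final.forward(h, training)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.final.backward(gy)
        skip_grads: list[np.ndarray] = []
        for j in reversed(range(len(self.dec))):
            n = self._split_sizes[j]
            g_dec, g_skip = g[:n], g[n:]
            skip_grads.append(g_skip)  # grad into encoder output len(enc)-2-j
            g = self.dec[j].backward(g_dec)
        # g is now the grad into the bottleneck output (skips[-1])
        for i in reversed(range(len(self.enc))):
            if i < len(self.enc) - 1:
                # skip_grads recorded for j descending -> encoder index ascending
                g = g + skip_grads[i]  # index i corresponds to enc output i
            g = self.enc[i].backward(g)
        return g


class _PatchGAN3d(nn.Module):
    """Conditioned patch classifier; input (2, E, E, E), output scores in (0,1)."""

    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator,
                 dtype=np.float32):
        self.spec = spec
        k = spec.kernel
        layers: list[nn.Module] = []
        in_ch = 2
        for i, (f, s) in enumerate(zip(spec.filters, spec.strides)):
            layers.append(nn.Conv3d(in_ch, f, k, s, rng, dtype))
            if i > 0:
                layers.append(nn.BatchNorm3d(f, rng=rng, dtype=dtype))
            layers.append(nn.LeakyReLU(spec.leaky_slope))
            in_ch = f
        layers.append(nn.Conv3d(in_ch, 1, k, 1, rng, dtype))
        layers.append(nn.Sigmoid())
        self.net = nn.Sequential(*layers)

    def params(self):
        return self.net.params()

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        return self.net.forward(x, training)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return self.net.backward(gy)


@dataclass
class GeneratorModel:
    spec: GeneratorSpec
    net: _UNet3d
    epoch: int = 0
    seed: int = 0

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.net.params()))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.net.params())}
        meta = json.dumps({"spec": asdict(self.spec), "epoch": self.epoch,
                           "seed": self.seed})
        np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    def copy(self) -> "GeneratorModel":
        clone = build_generator(self.spec, seed=self.seed)
        for src, dst in zip(self.net.params(), clone.net.params()):
            dst.value[...] = src.value
        # carry the normalisation statistics as well
        for a, b in zip(_iter_batchnorms(self.net), _iter_batchnorms(clone.net)):
            b.running_mean = a.running_mean.copy()
            b.running_var = a.running_var.copy()
        clone.epoch = self.epoch
        return clone


@dataclass
class DiscriminatorModel:
    spec: DiscriminatorSpec
    net: _PatchGAN3d
    seed: int = 0

    def score(self, source: np.ndarray, candidate: np.ndarray,
              training: bool = True) -> np.ndarray:
        """Patch scores for a conditioned (source, candidate) pair in [-1,1] space."""
        return self.net.forward(np.stack([source, candidate]), training)


def _iter_batchnorms(net: nn.Module):
    stack = [net]
    while stack:
        m = stack.pop()
        if isinstance(m, nn.BatchNorm3d):
            yield m
        for attr in ("layers",):
            stack.extend(getattr(m, attr, []))
        for attr in ("enc", "dec"):
            stack.extend(getattr(m, attr, []))
        if hasattr(m, "final"):
            stack.append(m.final)
        if hasattr(m, "net") and isinstance(getattr(m, "net"), nn.Module):
            stack.append(m.net)


def build_generator(spec: GeneratorSpec, seed: int = 0,
                    dtype=np.float32) -> GeneratorModel:
    rng = np.random.default_rng(seed)
    return GeneratorModel(spec=spec, net=_UNet3d(spec, rng, dtype), epoch=0, seed=seed)


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0,
                        dtype=np.float32) -> DiscriminatorModel:
    rng = np.random.default_rng(seed)
    return DiscriminatorModel(spec=spec, net=_PatchGAN3d(spec, rng, dtype), seed=seed)


def load_generator(path: str | Path) -> GeneratorModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        spec = GeneratorSpec(**{**meta["spec"],
                                "encoder_filters": tuple(meta["spec"]["encoder_filters"])})
        model = build_generator(spec, seed=meta["seed"])
        for i, p in enumerate(model.net.params()):
            p.value[...] = data[f"p{i}"]
        model.epoch = meta["epoch"]
    return model


# ---------------------------------------------------------------------------
# losses


def receptive_field(spec: DiscriminatorSpec) -> int:
    """Voxels per axis of input seen by one output score.

    Standard recurrence over the layer stack (including the stride-1
    scoring convolution): ``rf += (k - 1) * jump; jump *= stride``.
    """
    rf, jump = 1, 1
    for s in (*spec.strides, 1):
        rf += (spec.kernel - 1) * jump
        jump *= s
    return rf


_EPS = 1e-7


def _bce(scores: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy against a constant target, with gradient."""
    p = np.clip(scores, _EPS, 1.0 - _EPS)
    loss = float(-(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)).mean())
    grad = ((1.0 - target) / (1.0 - p) - target / p) / p.size
    return loss, grad.astype(scores.dtype)


def generator_loss(d_scores_fake: np.ndarray, generated: np.ndarray,
                   target: np.ndarray, lambda_l1: float = 100.0) -> float:
    """Adversarial BCE (fool the discriminator) plus ``lambda_l1`` x mean |error|."""
    if generated.shape != target.shape:
        raise ValueError(f"shape mismatch: {generated.shape} vs {target.shape}")
    adv, _ = _bce(d_scores_fake, 1.0)
    return adv + lambda_l1 * float(np.abs(generated - target).mean())


def discriminator_loss(d_scores_real: np.ndarray, d_scores_fake: np.ndarray) -> float:
    """Halved sum of BCE(real -> 1) and BCE(fake -> 0) (pix2pix convention)."""
    real, _ = _bce(d_scores_real, 1.0)
    fake, _ = _bce(d_scores_fake, 0.0)
    return 0.5 * (real + fake)


# ---------------------------------------------------------------------------
# training / inference


@dataclass
class CheckpointEntry:
    epoch: int
    path: Path | None
    model: GeneratorModel


@dataclass
class CheckpointSeries:
    entries: list[CheckpointEntry] = field(default_factory=list)
    loss_trace: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def last(self) -> CheckpointEntry:
        return self.entries[-1]


def train(pairs: list[TrainingPair], cfg: TrainConfig,
          checkpoint_dir: str | Path | None = None,
          gen_spec: GeneratorSpec | None = None,
          disc_spec: DiscriminatorSpec | None = None) -> CheckpointSeries:
    """Alternating adversarial training; returns the saved generator series.

    Per iteration: one discriminator update on the (real, fake) pair, then
    one generator update through the refreshed discriminator.  Fully seeded;
    identical config and seed reproduce the loss trace exactly.
    """
    if not pairs:
        raise ValueError("pairs must be non-empty")
    edges = {p.source.shape for p in pairs}
    if len(edges) != 1:
        raise ValueError(f"inconsistent cube shapes across pairs: {sorted(edges)}")
    edge = pairs[0].source.shape[0]
    if gen_spec is None:
        gen_spec = GeneratorSpec(cube_edge=edge)
    if gen_spec.cube_edge != edge:
        raise ValueError(f"pairs have edge {edge}, generator spec edge {gen_spec.cube_edge}")
    if disc_spec is None:
        disc_spec = DiscriminatorSpec()

    rng = np.random.default_rng(cfg.seed)
    gen = build_generator(gen_spec, seed=int(rng.integers(2 ** 31)))
    disc = build_discriminator(disc_spec, seed=int(rng.integers(2 ** 31)))
    opt_g = nn.Adam(gen.net.params(), cfg.learning_rate, cfg.beta1, cfg.beta2)
    opt_d = nn.Adam(disc.net.params(), cfg.learning_rate, cfg.beta1, cfg.beta2)

    ckpt_dir = Path(checkpoint_dir) if checkpoint_dir is not None else None
    if ckpt_dir is not None:
        ckpt_dir.mkdir(parents=True, exist_ok=True)
    series = CheckpointSeries()

    def save_checkpoint(epoch: int) -> None:
        gen.epoch = epoch
        path = None
        if ckpt_dir is not None:
            path = ckpt_dir / f"generator_epoch{epoch}.npz"
            gen.save(path)
        series.entries.append(CheckpointEntry(epoch=epoch, path=path, model=gen.copy()))

    if cfg.save_initial:
        save_checkpoint(0)

    a_vols = [normalize_intensities(p.source.data)[None] for p in pairs]
    b_vols = [normalize_intensities(p.target.data)[None] for p in pairs]

    it = 0
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(pairs))
        for idx in order:
            a, b = a_vols[idx], b_vols[idx]
            fake = gen.net.forward(a, training=True)

            # --- discriminator update ---
            disc.net.zero_grad()
            s_real = disc.score(a[0], b[0], training=True)
            l_real, g_real = _bce(s_real, 1.0)
            disc.net.backward(0.5 * g_real)
            s_fake = disc.score(a[0], fake[0], training=True)
            l_fake, g_fake = _bce(s_fake, 0.0)
            disc.net.backward(0.5 * g_fake)
            opt_d.step()
            d_loss = 0.5 * (l_real + l_fake)

            # --- generator update (through the refreshed discriminator) ---
            disc.net.zero_grad()
            s_fake2 = disc.score(a[0], fake[0], training=True)
            l_adv, g_adv = _bce(s_fake2, 1.0)
            g_into_pair = disc.net.backward(g_adv)  # grad wrt (source, fake)
            l1 = float(np.abs(fake - b).mean())
            g_l1 = (cfg.lambda_l1 * np.sign(fake - b) / fake.size).astype(fake.dtype)
            gen.net.zero_grad()
            gen.net.backward(g_into_pair[1:2] + g_l1)
            opt_g.step()
            disc.net.zero_grad()

            it += 1
            series.loss_trace.append({
                "iteration": it, "epoch": epoch,
                "d_loss": d_loss, "g_adv": l_adv, "g_l1": l1,
            })

        if epoch % cfg.checkpoint_interval_epochs == 0:
            save_checkpoint(epoch)

    if ckpt_dir is not None:
        with open(ckpt_dir / "losses.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["iteration", "epoch", "d_loss",
                                                    "g_adv", "g_l1"])
            writer.writeheader()
            writer.writerows(series.loss_trace)
        manifest = {
            "generator_spec": asdict(gen_spec),
            "discriminator_spec": asdict(disc_spec),
            "train_config": asdict(cfg),
            "checkpoints": [{"epoch": e.epoch, "path": str(e.path)} for e in series],
            "loss_trace": "losses.csv",
        }
        (ckpt_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return series


def generate(model: GeneratorModel, cube: Volume3D) -> Volume3D:
    """Deterministic inference: 8-bit cube in, 8-bit artifact-suppressed cube out."""
    e = model.spec.cube_edge
    if cube.shape != (e, e, e):
        raise ValueError(f"expected a cube of edge {e}, got shape {cube.shape}")
    x = normalize_intensities(cube.data)[None]
    y = model.net.forward(x, training=False)
    return Volume3D(denormalize_intensities(y[0]), cube.voxel_size_um, cube.origin)
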