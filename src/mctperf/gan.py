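"""Conditional GAN mapping a 3-phase mCTP stack to a single perfusion map.

Generator: a temporal 3D-convolution block collapses the depth-3 phase axis
to one channel stack, followed by a 2D U-Net encoder/decoder with skip
connections and a tanh-bounded single-channel output.  Discriminator: a
conditional PatchGAN scoring local patches of (mCTP stack, map) pairs.
Objective: least-squares adversarial loss plus masked L1 pixel loss plus an
"extreme" L1 term restricted to the lowest/highest quantiles of the target
map inside the brain (steering capacity toward infarct and high-flow
tissue).  One model is trained per target map type (CBF or Tmax).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .containers import MCTPTriplet, PerfusionMaps
from .preprocess import denormalize, normalize


@dataclass
class GanConfig:
    """Architecture, optimizer and loss settings.

    Clinical-scale defaults (N=512, batch 15, Adam(0.5, 0.999) at 1e-4,
    85 epochs for CBF / 80 for Tmax); desk-scale experiments use
    ``image_size=64`` with a small ``base_channels``.
    """

    image_size: int = 512
    depth: int = 3
    base_channels: int = 8
    unet_levels: int = 3
    lr_g: float = 1e-4
    lr_d: float = 1e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    batch_size: int = 15
    epochs: int = 85
    epochs_tmax: int = 80
    w_pix: float = 100.0
    w_adv: float = 1.0
    w_ext: float = 50.0
    extreme_low_q: float = 0.10
    extreme_high_q: float = 0.90
    input_bounds: tuple[float, float] = (0.0, 100.0)
    target_bounds: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth != 3:
            raise ValueError("depth is fixed at 3 (the three mCTP phases)")
        if min(self.w_pix, self.w_adv, self.w_ext) < 0:
            raise ValueError("loss weights must be >= 0")
        if not (0 < self.extreme_low_q < self.extreme_high_q < 1):
            raise ValueError("extreme quantiles must satisfy 0 < low < high < 1")
        if self.image_size % (2**self.unet_levels) != 0:
            raise ValueError(
                f"image_size {self.image_size} not divisible by 2^{self.unet_levels}"
            )


@dataclass
class TrainingRecord:
    """Per-epoch training trace; serializable and replayable."""

    g_losses: list[float] = field(default_factory=list)
    d_losses: list[float] = field(default_factory=list)
    g_components: list[dict] = field(default_factory=list)
    val_ssim: list[float] = field(default_factory=list)
    val_nrmse: list[float] = field(default_factory=list)
    seed: int = 0
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


class Generator:
    """Temporal 3D-conv block + 2D U-Net, output bounded in [-1, 1]."""

    def __init__(self, cfg: GanConfig, rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        c = cfg.base_channels
        self.cfg = cfg
        # two 3x3x3 convolutions over the depth-3 phase axis: the first is
        # depth-padded (3 -> 3), the second valid (3 -> 1)
        self.t1 = [nn.Conv2d(1, c, 3, rng=rng) for _ in range(3)]
        self.t2 = [nn.Conv2d(c, c, 3, rng=rng) for _ in range(3)]
        self.downs = []
        ch = c
        for _ in range(cfg.unet_levels):
            self.downs.append(nn.Conv2d(ch, ch * 2, 4, stride=2, pad=1, rng=rng))
            ch *= 2
        self.bottleneck = nn.Conv2d(ch, ch, 3, rng=rng)
        self.ups, self.fuses = [], []
        for _ in range(cfg.unet_levels):
            self.ups.append(nn.Conv2d(ch, ch // 2, 3, rng=rng))
            self.fuses.append(nn.Conv2d(ch, ch // 2, 3, rng=rng))
            ch //= 2
        self.final = nn.Conv2d(ch, 1, 3, rng=rng)

    def parameters(self):
        layers = self.t1 + self.t2 + self.downs + [self.bottleneck]
        layers += self.ups + self.fuses + [self.final]
        return [p for layer in layers for p in layer.parameters()]

    def __call__(self, phases: list[nn.Var]) -> nn.Var:
        # depth-padded temporal conv: h_d = sum_j t1[j](x_{d+j-1})
        h = []
        for d in range(3):
            acc = None
            for j in range(3):
                src = d + j - 1
                if 0 <= src < 3:
                    term = self.t1[j](phases[src])
                    acc = term if acc is None else acc + term
            h.append(nn.leaky_relu(acc))
        # depth-valid temporal conv collapsing 3 -> 1
        y = self.t2[0](h[0]) + self.t2[1](h[1]) + self.t2[2](h[2])
        y = nn.leaky_relu(y)

        skips = []
        for down in self.downs:
            skips.append(y)
            y = nn.leaky_relu(down(y))
        y = nn.leaky_relu(self.bottleneck(y))
        for up, fuse, skip in zip(self.ups, self.fuses, reversed(skips)):
            y = nn.leaky_relu(up(nn.upsample_nearest(y)))
            y = nn.leaky_relu(fuse(nn.concat([y, skip], axis=1)))
        return nn.tanh(self.final(y))

    def forward_array(self, phase_stack: np.ndarray) -> np.ndarray:
        """Inference on a normalized (B, 3, H, W) or (3, H, W) stack."""
        x = np.asarray(phase_stack, dtype=np.float32)
        squeeze = x.ndim == 3
        if squeeze:
            x = x[None]
        phases = [nn.Var(x[:, d : d + 1]) for d in range(3)]
        out = self(phases).data[:, 0]
        return out[0] if squeeze else out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data[...] = state[f"p{i}"]

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    @classmethod
    def load(cls, path, cfg: GanConfig) -> "Generator":
        gen = cls(cfg)
        with np.load(path) as state:
            gen.load_state_dict(dict(state))
        return gen


def build_generator(cfg: GanConfig) -> Generator:
    return Generator(cfg)


class PatchDiscriminator:
    """Conditional PatchGAN: (3-phase stack, map) -> grid of patch scores.

    Two stride-2 convolutions give a 4x architectural downsampling of the
    patch-score grid relative to the input.
    """

    downsampling_factor = 4

    def __init__(self, cfg: GanConfig, rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng(cfg.seed + 1)
        c = cfg.base_channels
        self.c1 = nn.Conv2d(4, c, 4, stride=2, pad=1, rng=rng)
        self.c2 = nn.Conv2d(c, 2 * c, 4, stride=2, pad=1, rng=rng)
        self.c3 = nn.Conv2d(2 * c, 1, 3, rng=rng)

    def parameters(self):
        return [p for layer in (self.c1, self.c2, self.c3) for p in layer.parameters()]

    def __call__(self, condition: nn.Var, map_img: nn.Var) -> nn.Var:
        x = nn.concat([condition, map_img], axis=1)
        x = nn.leaky_relu(self.c1(x))
        x = nn.leaky_relu(self.c2(x))
        return self.c3(x)


def build_discriminator(cfg: GanConfig) -> PatchDiscriminator:
    return PatchDiscriminator(cfg)


def _masked_l1(pred: nn.Var, true: np.ndarray, weight: np.ndarray) -> nn.Var:
    w = weight.astype(np.float32)
    total = float(w.sum())
    if total == 0:
        return nn.Var(np.array(0.0))
    diff = nn.absolute(pred - nn.Var(true)) * nn.Var(w)
    return nn.mean(diff) * (w.size / total)


def generator_loss(
    pred_map: nn.Var,
    true_map: np.ndarray,
    disc_scores: nn.Var | None,
    brain_mask: np.ndarray,
    cfg: GanConfig,
) -> tuple[nn.Var, dict[str, float]]:
    """Total generator loss and its components.

    L = w_pix * L1(pred, true | mask) + w_adv * LSGAN(scores)
      + w_ext * L1 restricted to mask voxels where the target lies below the
        extreme_low_q or above the extreme_high_q in-mask quantile.
    An empty extreme region contributes 0.
    """
    true_map = np.asarray(true_map, dtype=np.float32)
    mask = np.broadcast_to(np.asarray(brain_mask, dtype=bool), true_map.shape)
    if not mask.any():
        raise ValueError("empty brain mask")
    if pred_map.data.shape != true_map.shape:
        raise ValueError("shape mismatch between prediction and target")

    pix = _masked_l1(pred_map, true_map, mask)

    vals = true_map[mask]
    lo = np.quantile(vals, cfg.extreme_low_q)
    hi = np.quantile(vals, cfg.extreme_high_q)
    extreme = mask & ((true_map < lo) | (true_map > hi))
    ext = _masked_l1(pred_map, true_map, extreme)

    if disc_scores is not None:
        adv = nn.mean((disc_scores - 1.0) * (disc_scores - 1.0))
    else:
        adv = nn.Var(np.array(0.0))

    total = cfg.w_pix * pix + cfg.w_adv * adv + cfg.w_ext * ext
    components = {
        "pixel": float(pix.data),
        "adversarial": float(adv.data),
        "extreme": float(ext.data),
        "total": float(total.data),
    }
    return total, components


def discriminator_loss(real_scores: nn.Var, fake_scores: nn.Var) -> nn.Var:
    """Least-squares GAN discriminator objective."""
    real = nn.mean((real_scores - 1.0) * (real_scores - 1.0))
    fake = nn.mean(fake_scores * fake_scores)
    return 0.5 * (real + fake)


def _as_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def train(
    dataset: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    cfg: GanConfig,
    epochs: int | None = None,
    val_dataset: list | None = None,
    checkpoint_path=None,
) -> tuple[Generator, TrainingRecord]:
    """Adversarial training of the map generator.

    ``dataset`` holds (phase_stack (3,H,W), target_map (H,W), brain_mask
    (H,W)) triples, all already normalized to [-1, 1] with one shared affine
    map per modality.  Returns the trained generator and the training
    record; fully deterministic for a fixed ``cfg.seed``.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if epochs is None:
        epochs = cfg.epochs
    rng = np.random.default_rng(cfg.seed)
    gen = Generator(cfg, rng=np.random.default_rng(cfg.seed + 10))
    disc = PatchDiscriminator(cfg, rng=np.random.default_rng(cfg.seed + 11))
    opt_g = nn.Adam(gen.parameters(), lr=cfg.lr_g, beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
    opt_d = nn.Adam(disc.parameters(), lr=cfg.lr_d, beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)

    phases_all = np.stack([d[0] for d in dataset]).astype(np.float32)
    targets_all = np.stack([d[1] for d in dataset]).astype(np.float32)
    masks_all = np.stack([d[2] for d in dataset]).astype(bool)

    cfg_snapshot = {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.__dict__.items()}
    cfg_snapshot["epochs_run"] = epochs
    record = TrainingRecord(seed=cfg.seed, config=cfg_snapshot)

    for _epoch in range(epochs):
        g_ep, d_ep, comp_ep = [], [], []
        for batch in _as_batches(len(dataset), cfg.batch_size, rng):
            xb = phases_all[batch]
            yb = targets_all[batch][:, None]
            mb = masks_all[batch][:, None]
            phase_vars = [nn.Var(xb[:, d : d + 1]) for d in range(3)]
            cond = nn.concat(phase_vars, axis=1)

            # --- discriminator step (generator output detached) ---
            fake_detached = nn.Var(gen(phase_vars).data)
            opt_d.zero_grad()
            d_loss = discriminator_loss(
                disc(cond, nn.Var(yb)), disc(cond, fake_detached)
            )
            d_loss.backward()
            opt_d.step()

            # --- generator step ---
            opt_g.zero_grad()
            opt_d.zero_grad()  # D participates in the graph but is not stepped
            fake = gen(phase_vars)
            scores = disc(cond, fake)
            g_loss, comps = generator_loss(fake, yb, scores, mb, cfg)
            g_loss.backward()
            opt_g.step()

            g_ep.append(float(g_loss.data))
            d_ep.append(float(d_loss.data))
            comp_ep.append(comps)

        record.g_losses.append(float(np.mean(g_ep)))
        record.d_losses.append(float(np.mean(d_ep)))
        record.g_components.append(
            {k: float(np.mean([c[k] for c in comp_ep])) for k in comp_ep[0]}
        )
        if val_dataset:
            s, e = _validate(gen, val_dataset)
            record.val_ssim.append(s)
            record.val_nrmse.append(e)

    if checkpoint_path is not None:
        gen.save(checkpoint_path)
    return gen, record


def _validate(gen: Generator, val_dataset) -> tuple[float, float]:
    from .evaluation import nrmse as _nrmse
    from .evaluation import ssim as _ssim

    ssims, errs = [], []
    for phases, target, mask in val_dataset:
        pred = gen.forward_array(phases)
        ssims.append(_ssim(pred, target, mask=mask, data_range=2.0))
        if target[mask].max() > target[mask].min():
            errs.append(_nrmse(pred, target, mask))
    return float(np.mean(ssims)), float(np.mean(errs)) if errs else float("nan")


def predict(
    generator: Generator,
    triplet: MCTPTriplet,
    input_bounds: tuple[float, float],
    target_bounds: tuple[float, float],
    brain_mask: np.ndarray,
    provenance: str = "gan",
    map_type: str = "cbf",
    voxel_spacing: tuple[float, float, float] = (5.0, 1.0, 1.0),
) -> PerfusionMaps:
    """Run the generator slice-by-slice on an mCTP triplet.

    Phases are normalized with the training input bounds, the output is
    denormalized with the training target bounds, clamped at 0 and brain
    masked.  Deterministic: repeated calls give identical maps.
    """
    phases = normalize(triplet.phase_images, *input_bounds)
    n_slices = phases.shape[1]
    out = np.zeros(phases.shape[1:], dtype=float)
    stack = np.transpose(phases, (1, 0, 2, 3)).astype(np.float32)  # (Z, 3, H, W)
    pred = generator.forward_array(stack)  # (Z, H, W)
    out[:n_slices] = denormalize(pred, *target_bounds)
    out = np.clip(out, 0.0, None)
    out[~brain_mask] = 0.0
    zeros = np.zeros_like(out)
    if map_type == "cbf":
        return PerfusionMaps(cbf=out, tmax=zeros, brain_mask=brain_mask, provenance=provenance, voxel_spacing=voxel_spacing)
    return PerfusionMaps(cbf=zeros, tmax=out, brain_mask=brain_mask, provenance=provenance, voxel_spacing=voxel_spacing)
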