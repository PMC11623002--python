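"""Label-conditioned GAN for minority-class image synthesis.

Generator: the class label is embedded and projected to a one-channel
(s/4, s/4) map; the latent vector is projected (with leaky-ReLU) to a
second such map; the two channels are upsampled 2x, passed through a
stride-2 transposed convolution (4x4, 64 filters by default) and a final
stride-1 transposed convolution to a single tanh channel of size (s, s).

Discriminator: the embedded label is projected to a full-resolution
one-channel map, concatenated with the image, and reduced by five stride-2
3x3 convolutions (128 filters by default) with leaky-ReLU, then flattened
through dropout to a single sigmoid unit.

Training alternates discriminator updates on separate real and fake
half-batches with a generator update through the frozen discriminator,
using the standard non-saturating generator loss (the saturating
log(1 - D(G(z))) form is available via ``saturating=True``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field

import numpy as np

from . import nn
from .nn import Tensor
from .data import LabeledImageSet, DatasetError, SYNTHETIC, DEFAULT_CLASS_NAMES


@dataclass
class GanSpec:
    latent_dim: int = 100
    embed_dim: int = 50
    n_classes: int = 3
    image_size: int = 256
    base_channels: int = 128   # discriminator filters; generator uses half

    def __post_init__(self):
        if self.image_size % 4 != 0:
            raise DatasetError("image_size must be divisible by 4")
        if min(self.latent_dim, self.embed_dim, self.n_classes,
               self.base_channels) < 1:
            raise DatasetError("all GanSpec dimensions must be positive")

    @property
    def gen_channels(self) -> int:
        return max(1, self.base_channels // 2)


@dataclass
class GanTrainLog:
    """Per-epoch discriminator/generator statistics."""
    d_loss_real: list = field(default_factory=list)
    d_loss_fake: list = field(default_factory=list)
    d_acc_real: list = field(default_factory=list)
    d_acc_fake: list = field(default_factory=list)
    g_loss: list = field(default_factory=list)

    def __len__(self):
        return len(self.g_loss)


class Generator(nn.Module):
    def __init__(self, spec: GanSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        ss = np.random.SeedSequence(seed).spawn(4)
        s4 = spec.image_size // 4
        self.embed = nn.Embedding(spec.n_classes, spec.embed_dim, ss[0])
        self.dense_label = nn.Dense(spec.embed_dim, s4 * s4, ss[1])
        self.dense_latent = nn.Dense(spec.latent_dim, s4 * s4, ss[2])
        self.up = nn.Upsample2x()
        ss3 = ss[3].spawn(2)
        self.convt1 = nn.ConvTranspose2d(2, spec.gen_channels, 4, stride=2, rng=ss3[0])
        self.convt2 = nn.ConvTranspose2d(spec.gen_channels, 1, 4, stride=1, rng=ss3[1])

    def forward(self, z, labels) -> Tensor:
        z = z if isinstance(z, Tensor) else Tensor(z)
        s4 = self.spec.image_size // 4
        n = z.shape[0]
        lab = self.dense_label(self.embed(np.asarray(labels)).reshape(n, self.spec.embed_dim))
        lab = lab.reshape(n, 1, s4, s4)
        lat = self.dense_latent(z).leaky_relu(0.2).reshape(n, 1, s4, s4)
        x = nn.concat([lat, lab], axis=1)
        x = self.up(x)
        x = self.convt1(x).leaky_relu(0.2)
        return self.convt2(x).tanh()


class Discriminator(nn.Module):
    def __init__(self, spec: GanSpec, seed: int = 0, dropout: float = 0.4):
        super().__init__()
        self.spec = spec
        ss = np.random.SeedSequence(seed).spawn(8)
        s = spec.image_size
        c = spec.base_channels
        self.embed = nn.Embedding(spec.n_classes, spec.embed_dim, ss[0])
        self.dense_label = nn.Dense(spec.embed_dim, s * s, ss[1])
        self.convs = nn.Sequential(*[
            nn.Conv2d(2 if i == 0 else c, c, 3, stride=2, padding="same", rng=ss[2 + i])
            for i in range(5)
        ])
        self.drop = nn.Dropout(dropout, seed=int(ss[7].generate_state(1)[0] % (2 ** 31)))
        feat = c * max(1, s // 32) ** 2
        self.dense_out = nn.Dense(feat, 1, ss[2 + 5])

    def forward(self, images, labels) -> Tensor:
        x = images if isinstance(images, Tensor) else Tensor(images)
        n = x.shape[0]
        s = self.spec.image_size
        lab = self.dense_label(self.embed(np.asarray(labels)).reshape(n, self.spec.embed_dim))
        lab = lab.reshape(n, 1, s, s)
        h = nn.concat([x, lab], axis=1)
        for conv in self.convs._order:
            h = conv(h).leaky_relu(0.2)
        h = self.drop(h.reshape(n, -1))
        return self.dense_out(h).sigmoid()


@dataclass
class GanWeights:
    spec: GanSpec
    generator: dict
    discriminator: dict

    def param_table(self):
        return {"generator": generator_param_table(self.spec),
                "discriminator": discriminator_param_table(self.spec)}


# ------------------------------------------------------------ conformance
def generator_param_table(spec: GanSpec) -> dict:
    """Per-layer trainable parameter counts, derivable from the spec alone."""
    s4 = (spec.image_size // 4) ** 2
    g = spec.gen_channels
    return {
        "embedding": spec.n_classes * spec.embed_dim,
        "dense_label": spec.embed_dim * s4 + s4,
        "dense_latent": spec.latent_dim * s4 + s4,
        "convtranspose_1": 4 * 4 * 2 * g + g,
        "convtranspose_2": 4 * 4 * g * 1 + 1,
    }


def discriminator_param_table(spec: GanSpec) -> dict:
    s2 = spec.image_size ** 2
    c = spec.base_channels
    feat = c * max(1, spec.image_size // 32) ** 2
    table = {
        "embedding": spec.n_classes * spec.embed_dim,
        "dense_label": spec.embed_dim * s2 + s2,
        "conv_1": 3 * 3 * 2 * c + c,
    }
    for i in range(2, 6):
        table[f"conv_{i}"] = 3 * 3 * c * c + c
    table["dense_out"] = feat + 1
    return table


def _actual_counts(module: nn.Module, groups: dict) -> dict:
    named = dict(module.named_parameters())
    return {g: sum(named[n].data.size for n in names)
            for g, names in groups.items()}


def generator_actual_counts(gen: Generator) -> dict:
    return _actual_counts(gen, {
        "embedding": ["embed.weight"],
        "dense_label": ["dense_label.weight", "dense_label.bias"],
        "dense_latent": ["dense_latent.weight", "dense_latent.bias"],
        "convtranspose_1": ["convt1.weight", "convt1.bias"],
        "convtranspose_2": ["convt2.weight", "convt2.bias"],
    })


def discriminator_actual_counts(disc: Discriminator) -> dict:
    groups = {
        "embedding": ["embed.weight"],
        "dense_label": ["dense_label.weight", "dense_label.bias"],
        "dense_out": ["dense_out.weight", "dense_out.bias"],
    }
    for i in range(5):
        groups[f"conv_{i + 1}"] = [f"convs.m{i}.weight", f"convs.m{i}.bias"]
    return _actual_counts(disc, groups)


# ------------------------------------------------------------- objectives
def build_generator(spec: GanSpec, seed: int = 0) -> Generator:
    return Generator(spec, seed)


def build_discriminator(spec: GanSpec, seed: int = 0) -> Discriminator:
    return Discriminator(spec, seed)


def gan_objective(d_real, d_fake, eps: float = 1e-7) -> float:
    """Value function E[log D(x)] + E[log(1 - D(G(z)))].

    The discriminator ascends this; the generator descends it.
    """
    d_real = np.clip(np.asarray(d_real, dtype=np.float64), eps, 1 - eps)
    d_fake = np.clip(np.asarray(d_fake, dtype=np.float64), eps, 1 - eps)
    if d_real.size == 0 or d_fake.size == 0:
        raise DatasetError("empty probability vectors")
    return float(np.mean(np.log(d_real)) + np.mean(np.log(1.0 - d_fake)))


def generator_loss(d_fake, saturating: bool = False, eps: float = 1e-7) -> float:
    """Generator loss: non-saturating -E[log D(G(z))] by default, or the
    original saturating E[log(1 - D(G(z)))]."""
    d_fake = np.clip(np.asarray(d_fake, dtype=np.float64), eps, 1 - eps)
    if saturating:
        return float(np.mean(np.log(1.0 - d_fake)))
    return float(-np.mean(np.log(d_fake)))


def generate_latent_points(latent_dim: int, n: int, n_classes: int, seed,
                           fixed_class: int | None = None):
    """Standard-normal latent draws plus uniform (or fixed) class labels."""
    if n < 1:
        raise DatasetError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal((n, latent_dim)).astype(np.float32)
    if fixed_class is None:
        labels = rng.integers(0, n_classes, size=n)
    else:
        if not (0 <= fixed_class < n_classes):
            raise DatasetError("class label out of range")
        labels = np.full(n, fixed_class, dtype=np.int64)
    return z, labels.astype(np.int64)


# ---------------------------------------------------------------- training
def train_cgan(dataset: LabeledImageSet, spec: GanSpec, n_epochs: int,
               n_batch: int, seed: int, checkpoint_dir=None,
               checkpoint_every: int = 10, lr: float = 2e-4,
               balance_classes: bool = True,
               real_label_smoothing: float = 0.9,
               retry_on_collapse: int = 2):
    """Adversarial training loop; returns (GanWeights, GanTrainLog).

    Each batch: the discriminator is fitted on a real half-batch then a
    fake half-batch separately; the generator is then updated through the
    combined model with the discriminator's weights frozen.

    Stability/imbalance policy (each is a keyword, so the textbook loop is
    one call away): real half-batches are drawn with equal per-class
    probability so rare classes are not starved of discriminator feedback;
    one-sided label smoothing (real target 0.9) damps discriminator
    overshoot; and if a run still ends in the degenerate state where the
    discriminator rejects essentially all *real* data, training restarts
    from a derived seed (at most ``retry_on_collapse`` times — adversarial
    dynamics are chaotic and an occasional trajectory diverges).
    """
    for im in dataset.images[:1]:
        if im.shape != (spec.image_size, spec.image_size):
            raise DatasetError(
                f"dataset images {im.shape} do not match spec size {spec.image_size}")
    if n_batch > len(dataset):
        raise DatasetError("n_batch exceeds the dataset size")

    weights = log = None
    for attempt in range(retry_on_collapse + 1):
        run_seed = (seed + 1000003 * attempt) % (2 ** 31)
        weights, log = _train_cgan_once(
            dataset, spec, n_epochs, n_batch, run_seed, checkpoint_dir,
            checkpoint_every, lr, balance_classes, real_label_smoothing)
        tail = log.d_acc_real[-min(10, len(log)):]
        if not tail or float(np.mean(tail)) >= 0.2:
            break
        warnings.warn("cGAN run ended with the discriminator rejecting real "
                      "data; restarting from a derived seed")
    return weights, log


def _train_cgan_once(dataset, spec, n_epochs, n_batch, seed, checkpoint_dir,
                     checkpoint_every, lr, balance_classes,
                     real_label_smoothing):
    ss = np.random.SeedSequence(seed).spawn(3)
    gen = Generator(spec, seed=int(ss[0].generate_state(1)[0] % (2 ** 31)))
    disc = Discriminator(spec, seed=int(ss[1].generate_state(1)[0] % (2 ** 31)))
    rng = np.random.default_rng(ss[2])

    opt_d = nn.Adam(disc.parameters(), lr=lr, betas=(0.5, 0.999))
    opt_g = nn.Adam(gen.parameters(), lr=lr, betas=(0.5, 0.999))

    x_all = dataset.stack() * 2.0 - 1.0          # tanh range
    y_all = dataset.labels
    half = max(1, n_batch // 2)
    batches = max(1, len(dataset) // n_batch)
    log = GanTrainLog()

    if balance_classes:
        counts = np.bincount(y_all, minlength=spec.n_classes).astype(np.float64)
        weights = np.where(counts[y_all] > 0, 1.0 / np.maximum(counts[y_all], 1), 0.0)
        weights /= weights.sum()
    else:
        weights = None

    present = np.unique(y_all)   # fake labels only for classes the GAN can learn

    def latent(n):
        z = rng.standard_normal((n, spec.latent_dim)).astype(np.float32)
        return z, rng.choice(present, size=n)

    for epoch in range(n_epochs):
        stats = np.zeros(5)
        for _ in range(batches):
            # --- discriminator, real half-batch
            idx = rng.choice(len(x_all), size=half, replace=False, p=weights)
            xr = x_all[idx][:, None, :, :]
            pr = disc(xr, y_all[idx])
            loss_r = nn.binary_cross_entropy(
                pr, np.full((half, 1), real_label_smoothing))
            disc.zero_grad()
            loss_r.backward()
            opt_d.step()
            # --- discriminator, fake half-batch
            z, zl = latent(half)
            fake = gen(z, zl).detach()
            pf = disc(fake, zl)
            loss_f = nn.binary_cross_entropy(pf, np.zeros((half, 1)))
            disc.zero_grad()
            loss_f.backward()
            opt_d.step()
            # --- generator through frozen discriminator
            z2, zl2 = latent(n_batch)
            pg = disc(gen(z2, zl2), zl2)
            loss_g = nn.binary_cross_entropy(pg, np.ones((n_batch, 1)))
            gen.zero_grad()
            disc.zero_grad()        # grads flow through D but are discarded
            loss_g.backward()
            opt_g.step()
            disc.zero_grad()
            stats += [loss_r.item(), loss_f.item(),
                      float((pr.data > 0.5).mean()), float((pf.data < 0.5).mean()),
                      loss_g.item()]
        stats /= batches
        log.d_loss_real.append(float(stats[0]))
        log.d_loss_fake.append(float(stats[1]))
        log.d_acc_real.append(float(stats[2]))
        log.d_acc_fake.append(float(stats[3]))
        log.g_loss.append(float(stats[4]))
        if checkpoint_dir is not None and (epoch + 1) % checkpoint_every == 0:
            save_gan(GanWeights(spec, gen.state_dict(), disc.state_dict()),
                     f"{checkpoint_dir}/cgan_epoch{epoch + 1:04d}.npz")

    return GanWeights(spec, gen.state_dict(), disc.state_dict()), log


def synthesize(weights: GanWeights, class_label: int, n: int, seed: int,
               class_names=None) -> LabeledImageSet:
    """Sample ``n`` images of one class; output rescaled from tanh to [0,1]."""
    spec = weights.spec
    if not (0 <= class_label < spec.n_classes):
        raise DatasetError("class label out of range")
    gen = Generator(spec, seed=0)
    gen.load_state_dict(weights.generator)
    gen.eval()
    z, labels = generate_latent_points(spec.latent_dim, n, spec.n_classes,
                                       seed, fixed_class=class_label)
    out = gen(z, labels).data[:, 0]
    images = [np.clip((im + 1.0) / 2.0, 0.0, 1.0).astype(np.float32) for im in out]
    names = (list(class_names) if class_names is not None
             else (DEFAULT_CLASS_NAMES if spec.n_classes == 3
                   else [f"class_{i}" for i in range(spec.n_classes)]))
    return LabeledImageSet(images, np.full(n, class_label, dtype=np.int64),
                           names, [SYNTHETIC] * n)


# ------------------------------------------------------------- persistence
def save_gan(weights: GanWeights, path) -> None:
    arrays = {f"gen:{k}": v for k, v in weights.generator.items()}
    arrays.update({f"disc:{k}": v for k, v in weights.discriminator.items()})
    arrays["spec_json"] = np.frombuffer(
        json.dumps(asdict(weights.spec)).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_gan(path) -> GanWeights:
    with np.load(path) as z:
        spec = GanSpec(**json.loads(bytes(z["spec_json"].tolist()).decode()))
        gen = {k[4:]: z[k] for k in z.files if k.startswith("gen:")}
        disc = {k[5:]: z[k] for k in z.files if k.startswith("disc:")}
    return GanWeights(spec, gen, disc)
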