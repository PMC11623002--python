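"""Desk-scale replication of the study workflow on phantom data.

``scaled_study`` runs the full pipeline — phantom generation, 80/20 split,
IID sharding, conditional-GAN pre-training on the minority classes,
CLAHE-enhanced minority augmentation, and split-federated training with
and without the synthetic images — at sizes chosen for a single CPU:
64x64 phantoms with the study's 0.28/0.02 class ratios, a half-width
split ResNet, and a 32x32 reduced GAN whose outputs are enhanced and
resized to the classifier input (mirroring the synthesize-then-resize
order of the full-size pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import federation as fed
from .cgan import GanSpec, GanTrainLog, GanWeights, train_cgan
from .data import LabeledImageSet, partition_clients, stratified_split
from .enhance import resize_image
from .phantom import PhantomSpec, generate_phantom_dataset


@dataclass
class StudyResult:
    """Outcome of one scaled study run.

    ``minority_recall`` is the unweighted mean recall over the minority
    classes (every class below the majority count) — the desk-scale
    reading of a single reported recall for an imbalanced multi-class
    task. ``rarest_recall`` is the recall of the single rarest class
    alone; at this problem size it rests on very few test images and is
    reported for transparency rather than asserted on.
    """
    plain_accuracy: list = field(default_factory=list)       # per seed
    plain_minority_recall: list = field(default_factory=list)
    plain_rarest_recall: list = field(default_factory=list)
    augmented_accuracy: list = field(default_factory=list)
    augmented_minority_recall: list = field(default_factory=list)
    augmented_rarest_recall: list = field(default_factory=list)
    gan_log: GanTrainLog | None = None
    gan_weights: GanWeights | None = None

    @property
    def median_plain_recall(self) -> float:
        return float(np.median(self.plain_minority_recall))

    @property
    def median_augmented_recall(self) -> float:
        return float(np.median(self.augmented_minority_recall))


def pretrain_minority_gan(train_set: LabeledImageSet, seed: int,
                          gan_image_size: int = 32, base_channels: int = 32,
                          n_epochs: int = 200, n_batch: int = 32):
    """Train the cGAN on the minority classes of the training pool."""
    counts = np.bincount(train_set.labels, minlength=train_set.n_classes)
    majority = int(counts.argmax())
    minor = train_set.subset(np.flatnonzero(train_set.labels != majority))
    minor_small = LabeledImageSet(
        [resize_image(im, gan_image_size) for im in minor.images],
        minor.labels, minor.class_names, minor.provenance)
    spec = GanSpec(image_size=gan_image_size, base_channels=base_channels,
                   n_classes=train_set.n_classes)
    return train_cgan(minor_small, spec, n_epochs,
                      min(n_batch, len(minor_small)), seed)


def scaled_study(seed: int = 0, image_size: int = 64,
                 n_per_class: tuple = (800, 224, 16), width: float = 0.5,
                 epochs: int = 5, n_clients: int = 2, n_seeds: int = 3,
                 target_ratio: float = 0.5, gan_epochs: int = 200,
                 run_augmented: bool = True) -> StudyResult:
    """Phantom pipeline with and without cGAN augmentation.

    The ``n_seeds`` repetitions re-shard and re-train with seeds
    ``seed .. seed+n_seeds-1``; the GAN is pre-trained once on the minority
    classes of the shared training pool.
    """
    spec = PhantomSpec(image_size=image_size, n_per_class=n_per_class,
                       seed=seed)
    dataset = generate_phantom_dataset(spec)
    train_set, test_set = stratified_split(dataset, 0.8, seed)
    counts = np.bincount(train_set.labels, minlength=train_set.n_classes)
    minority = np.flatnonzero(counts < counts.max())
    rarest = int(counts.argmin())

    result = StudyResult()
    if run_augmented:
        weights, log = pretrain_minority_gan(train_set, seed + 17,
                                             n_epochs=gan_epochs)
        result.gan_weights, result.gan_log = weights, log

    for s in range(seed, seed + n_seeds):
        shards = partition_clients(train_set, n_clients, s)
        config = fed.TrainingConfig(mode="sfl", n_clients=n_clients,
                                    epochs=epochs, width=width, seed=s)
        plain = fed.run_sfl(config, shards, test_set)
        rep = plain.rows[-1]["test"]
        result.plain_accuracy.append(rep.accuracy)
        result.plain_minority_recall.append(float(rep.recall[minority].mean()))
        result.plain_rarest_recall.append(float(rep.recall[rarest]))
        if run_augmented:
            aug_shards = fed.augment_minority(shards, result.gan_weights,
                                              target_ratio, s)
            augmented = fed.run_sfl(config, aug_shards, test_set)
            rep_a = augmented.rows[-1]["test"]
            result.augmented_accuracy.append(rep_a.accuracy)
            result.augmented_minority_recall.append(
                float(rep_a.recall[minority].mean()))
            result.augmented_rarest_recall.append(float(rep_a.recall[rarest]))
    return result
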