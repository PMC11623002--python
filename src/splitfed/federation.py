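"""Training protocols: split federated learning plus FL and SL baselines.

One global round (epoch) of SFL: a fraction of clients is selected; each
selected client runs its shard through the split pipeline (client forward
-> server step -> client backward) against a single shared server half
that is updated sequentially across clients; afterwards the client-side
weights of the participants are federated-averaged and installed as the
new global client model, which is also used (with the server half) for
evaluation.

FL: each client trains a full composed copy locally for one epoch and all
weights are averaged. SL: clients train sequentially against the shared
server, the client half being relayed from client to client without
averaging. ``run_centralized`` trains the composed model on pooled data
and is the degenerate-case oracle: with one client and full participation
all three protocols collapse to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .cgan import GanWeights, synthesize
from .data import (AugmentationConfig, LabeledImageSet, DatasetError,
                   build_augmentation, class_distribution)
from .enhance import EnhanceConfig, apply_clahe, resize_image
from .metrics import History, MetricsReport, compute_metrics
from .models import (ClientNet, ServerNet, compose, forward_client,
                     server_step, client_backward)


@dataclass
class TrainingConfig:
    """Run settings; the defaults are the reference training configuration
    (Adam, batch 64, learning rate 1e-4, 50 epochs, 3 classes, 2 clients)."""

    mode: str = "sfl"               # fl | sl | sfl
    optimizer: str = "adam"
    batch_size: int = 64
    learning_rate: float = 1e-4
    epochs: int = 50
    n_classes: int = 3
    n_clients: int = 2
    frac: float = 1.0
    model: str = "resnet18-split"
    loss: str = "categorical_cross_entropy"
    seed: int = 0
    width: float = 1.0              # channel multiplier for reduced-size runs
    dropout: float = 0.5
    #: apply the stochastic training augmentation (random resized crop,
    #: flips, rotation, intensity jitter) to every training batch; besides
    #: regularizing, this suppresses the low-level real-vs-synthetic cues
    #: (sharpness, noise texture) a CNN would otherwise exploit when GAN
    #: images join a shard
    train_augment: bool = False

    def __post_init__(self):
        if self.mode not in ("fl", "sl", "sfl"):
            raise DatasetError("mode must be one of fl, sl, sfl")
        if not (0 < self.frac <= 1):
            raise DatasetError("frac must be in (0, 1]")
        if self.frac * self.n_clients < 1:
            raise DatasetError("frac * n_clients must be >= 1")


# ------------------------------------------------------------------ fedavg
def fedavg(weight_sets: list) -> dict:
    """Unweighted elementwise mean of congruent parameter collections."""
    if not weight_sets:
        raise DatasetError("fedavg needs at least one weight set")
    keys = list(weight_sets[0].keys())
    for ws in weight_sets[1:]:
        if list(ws.keys()) != keys:
            raise DatasetError("weight sets have mismatched entries")
    out = {}
    for k in keys:
        arrs = [ws[k] for ws in weight_sets]
        if any(a.shape != arrs[0].shape for a in arrs):
            raise DatasetError(f"shape mismatch for {k!r}")
        # accumulate in float64 so averaging identical sets is exact
        out[k] = np.mean(np.stack(arrs), axis=0,
                         dtype=np.float64).astype(arrs[0].dtype)
    return out


def select_clients(n_clients: int, frac: float, seed) -> list:
    """m = max(1, round(frac * n_clients)) distinct indices, uniform."""
    if not (0 < frac <= 1):
        raise DatasetError("frac must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = max(1, int(round(frac * n_clients)))
    return sorted(rng.choice(n_clients, size=m, replace=False).tolist())


# ----------------------------------------------------------------- helpers
def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _derive_seeds(config: TrainingConfig):
    ss = np.random.SeedSequence(config.seed)
    s_client, s_server, s_select, s_data, s_aug = ss.spawn(5)
    data_children = s_data.spawn(max(config.n_clients, 1))
    aug_children = s_aug.spawn(max(config.n_clients, 1))
    return {
        "client_model": _seed_int(s_client),
        "server_model": _seed_int(s_server),
        "select": np.random.default_rng(s_select),
        "data_rngs": [np.random.default_rng(c) for c in data_children],
        "aug_seeds": [_seed_int(c) for c in aug_children],
    }


def _make_augmenters(config: TrainingConfig, shards: list, seeds: dict) -> list:
    """Per-client training-batch transforms (or Nones when disabled)."""
    if not config.train_augment:
        return [None] * len(shards)
    out = []
    for shard, seed in zip(shards, seeds["aug_seeds"]):
        size = shard.images[0].shape[0]
        cfg = AugmentationConfig(output_size=size, normalize_mean=0.0,
                                 normalize_std=1.0)
        out.append(build_augmentation(cfg, seed))
    return out


def _iter_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _batch_arrays(dataset: LabeledImageSet, idx: np.ndarray, transform=None):
    if transform is None:
        x = np.stack([dataset.images[i] for i in idx])[:, None]
    else:
        x = np.stack([transform(dataset.images[i]) for i in idx])[:, None]
    y = dataset.labels[idx]
    return x.astype(np.float32), y


def _predict(client: ClientNet, server: ServerNet, dataset: LabeledImageSet,
             batch_size: int) -> np.ndarray:
    """Eval-mode class probabilities via the split path (deterministic order)."""
    client.eval()
    server.eval()
    probs = []
    for start in range(0, len(dataset), batch_size):
        idx = np.arange(start, min(start + batch_size, len(dataset)))
        x, y = _batch_arrays(dataset, idx)
        smashed = forward_client(client, x, y)
        packet = server_step(server, smashed, train=False)
        probs.append(packet.predictions)
    client.train()
    server.train()
    return np.concatenate(probs)


def evaluate_model(client: ClientNet, server: ServerNet,
                   dataset: LabeledImageSet, batch_size: int) -> MetricsReport:
    """Eval-mode metrics via the split path."""
    return compute_metrics(_predict(client, server, dataset, batch_size),
                           dataset.labels, n_classes=server.n_classes)


def _check_shards(config: TrainingConfig, shards: list) -> None:
    if len(shards) != config.n_clients:
        raise DatasetError("number of shards must equal n_clients")
    for i, s in enumerate(shards):
        if len(s) == 0:
            raise DatasetError(f"client {i} has an empty shard")


def _record_epoch(history: History, epoch: int, client: ClientNet,
                  server: ServerNet, shards, test, batch_size: int) -> None:
    # each shard is scored once; the global train report reuses those
    # predictions, so evaluation costs one pass over train + test per epoch
    shard_probs = [_predict(client, server, shard, batch_size)
                   for shard in shards]
    per_client = {i: compute_metrics(p, shard.labels, n_classes=server.n_classes)
                  for i, (p, shard) in enumerate(zip(shard_probs, shards))}
    train_rep = compute_metrics(
        np.concatenate(shard_probs),
        np.concatenate([s.labels for s in shards]),
        n_classes=server.n_classes)
    test_rep = evaluate_model(client, server, test, batch_size)
    history.append(epoch, train_rep, test_rep, per_client)


# -------------------------------------------------------------------- SFL
def run_sfl(config: TrainingConfig, shards: list,
            test: LabeledImageSet) -> History:
    """Algorithm: per round select clients, run local split training against
    the shared server half, then FedAvg the participating client fronts."""
    _check_shards(config, shards)
    seeds = _derive_seeds(config)
    server = ServerNet(config.width, config.n_classes, seeds["server_model"])
    opt_server = nn.make_optimizer(config.optimizer, server.parameters(),
                                   config.learning_rate)
    # persistent per-client trainer modules; weights are overwritten by the
    # global state each round, dropout streams advance across rounds
    trainers = [ClientNet(config.width, config.dropout, seeds["client_model"])
                for _ in range(config.n_clients)]
    opts = [nn.make_optimizer(config.optimizer, t.parameters(),
                              config.learning_rate) for t in trainers]
    global_client = ClientNet(config.width, config.dropout, seeds["client_model"])
    global_state = global_client.state_dict()
    augmenters = _make_augmenters(config, shards, seeds)

    history = History()
    for epoch in range(1, config.epochs + 1):
        selected = select_clients(config.n_clients, config.frac, seeds["select"])
        w_locals = []
        for idx in selected:
            trainers[idx].load_state_dict(global_state)
            if len(selected) > 1:
                # installed weights came from averaging over several clients:
                # stale local optimizer moments would be ill-defined
                opts[idx].reset_state()
            shard = shards[idx]
            for bidx in _iter_batches(len(shard), config.batch_size,
                                      seeds["data_rngs"][idx]):
                x, y = _batch_arrays(shard, bidx, augmenters[idx])
                smashed = forward_client(trainers[idx], x, y)
                packet = server_step(server, smashed, train=True,
                                     optimizer=opt_server)
                client_backward(trainers[idx], smashed, packet, opts[idx])
            w_locals.append(trainers[idx].state_dict())
        global_state = fedavg(w_locals)
        global_client.load_state_dict(global_state)
        _record_epoch(history, epoch, global_client, server, shards, test,
                      config.batch_size)
    return history


# --------------------------------------------------------------------- FL
def run_fl(config: TrainingConfig, shards: list,
           test: LabeledImageSet) -> History:
    """Federated averaging of complete (composed) models."""
    _check_shards(config, shards)
    seeds = _derive_seeds(config)
    trainers = []
    opts = []
    for _ in range(config.n_clients):
        c = ClientNet(config.width, config.dropout, seeds["client_model"])
        s = ServerNet(config.width, config.n_classes, seeds["server_model"])
        m = compose(c, s)
        trainers.append(m)
        opts.append(nn.make_optimizer(config.optimizer, m.parameters(),
                                      config.learning_rate))
    eval_model = compose(
        ClientNet(config.width, config.dropout, seeds["client_model"]),
        ServerNet(config.width, config.n_classes, seeds["server_model"]))
    global_state = eval_model.state_dict()
    augmenters = _make_augmenters(config, shards, seeds)

    history = History()
    for epoch in range(1, config.epochs + 1):
        selected = select_clients(config.n_clients, config.frac, seeds["select"])
        w_locals = []
        for idx in selected:
            trainers[idx].load_state_dict(global_state)
            if len(selected) > 1:
                opts[idx].reset_state()
            shard = shards[idx]
            for bidx in _iter_batches(len(shard), config.batch_size,
                                      seeds["data_rngs"][idx]):
                x, y = _batch_arrays(shard, bidx, augmenters[idx])
                logits = trainers[idx](x)
                loss, _ = nn.softmax_cross_entropy(logits, y)
                trainers[idx].zero_grad()
                loss.backward()
                opts[idx].step()
            w_locals.append(trainers[idx].state_dict())
        global_state = fedavg(w_locals)
        eval_model.load_state_dict(global_state)
        _record_epoch(history, epoch, eval_model.client, eval_model.server,
                      shards, test, config.batch_size)
    return history


# --------------------------------------------------------------------- SL
def run_sl(config: TrainingConfig, shards: list,
           test: LabeledImageSet) -> History:
    """Sequential split learning: the client half is relayed from client to
    client within each epoch; one shared server half; no averaging."""
    _check_shards(config, shards)
    seeds = _derive_seeds(config)
    server = ServerNet(config.width, config.n_classes, seeds["server_model"])
    opt_server = nn.make_optimizer(config.optimizer, server.parameters(),
                                   config.learning_rate)
    trainers = [ClientNet(config.width, config.dropout, seeds["client_model"])
                for _ in range(config.n_clients)]
    opts = [nn.make_optimizer(config.optimizer, t.parameters(),
                              config.learning_rate) for t in trainers]
    eval_client = ClientNet(config.width, config.dropout, seeds["client_model"])
    relay_state = eval_client.state_dict()
    augmenters = _make_augmenters(config, shards, seeds)

    history = History()
    for epoch in range(1, config.epochs + 1):
        for idx in range(config.n_clients):
            trainers[idx].load_state_dict(relay_state)
            if config.n_clients > 1:
                opts[idx].reset_state()   # weights arrived from another client
            shard = shards[idx]
            for bidx in _iter_batches(len(shard), config.batch_size,
                                      seeds["data_rngs"][idx]):
                x, y = _batch_arrays(shard, bidx, augmenters[idx])
                smashed = forward_client(trainers[idx], x, y)
                packet = server_step(server, smashed, train=True,
                                     optimizer=opt_server)
                client_backward(trainers[idx], smashed, packet, opts[idx])
            relay_state = trainers[idx].state_dict()
        eval_client.load_state_dict(relay_state)
        _record_epoch(history, epoch, eval_client, server, shards, test,
                      config.batch_size)
    return history


# -------------------------------------------------------------- centralized
def run_centralized(config: TrainingConfig, dataset: LabeledImageSet,
                    test: LabeledImageSet) -> History:
    """Composed-model training on pooled data — the degenerate-case oracle."""
    seeds = _derive_seeds(config)
    model = compose(
        ClientNet(config.width, config.dropout, seeds["client_model"]),
        ServerNet(config.width, config.n_classes, seeds["server_model"]))
    opt = nn.make_optimizer(config.optimizer, model.parameters(),
                            config.learning_rate)
    augmenters = _make_augmenters(config, [dataset], seeds)
    history = History()
    for epoch in range(1, config.epochs + 1):
        for bidx in _iter_batches(len(dataset), config.batch_size,
                                  seeds["data_rngs"][0]):
            x, y = _batch_arrays(dataset, bidx, augmenters[0])
            loss, _ = nn.softmax_cross_entropy(model(x), y)
            model.zero_grad()
            loss.backward()
            opt.step()
        _record_epoch(history, epoch, model.client, model.server, [dataset],
                      test, config.batch_size)
    return history


def run(config: TrainingConfig, shards: list, test: LabeledImageSet) -> History:
    fn = {"sfl": run_sfl, "fl": run_fl, "sl": run_sl}[config.mode]
    return fn(config, shards, test)


# ------------------------------------------------------------ augmentation
def augment_minority(shards: list, gan_weights: GanWeights,
                     target_ratio: float = 0.5, seed: int = 0,
                     enhance_config: EnhanceConfig | None = None) -> list:
    """Raise each client's minority-class ratios to ``target_ratio`` with
    enhanced GAN images (CLAHE then resize to the shard's image size).

    The needed count per class is ceil(target_ratio x majority) minus the
    current count. Test data must never pass through here.
    """
    if not (0 < target_ratio <= 1):
        raise DatasetError("target_ratio must be in (0, 1]")
    ss = np.random.SeedSequence(seed).spawn(len(shards))
    out = []
    any_added = False
    for shard, shard_ss in zip(shards, ss):
        dist = class_distribution(shard)
        majority = int(dist.counts.max())
        size = shard.images[0].shape[0]
        cfg = enhance_config or EnhanceConfig(target_size=size)
        pieces = [shard]
        for c in range(shard.n_classes):
            target = int(np.ceil(target_ratio * majority))
            need = target - int(dist.counts[c])
            if need <= 0:
                continue
            any_added = True
            synth = synthesize(gan_weights, c, need,
                               _seed_int(shard_ss.spawn(1)[0]) + c,
                               class_names=shard.class_names)
            images = [resize_image(apply_clahe(im, cfg), size)
                      for im in synth.images]
            pieces.append(LabeledImageSet(images, synth.labels,
                                          list(shard.class_names),
                                          list(synth.provenance)))
        out.append(LabeledImageSet.concatenate(pieces))
    if not any_added:
        warnings.warn("target_ratio does not exceed any current class ratio; "
                      "shards returned unchanged")
    return out
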