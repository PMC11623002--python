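"""ResNet18-style classifier partitioned at the cut layer.

Client front: 7x7/2 conv - BN - ReLU - 3x3/2 max pool (the stem), then a
3x3 conv - BN - ReLU refinement and dropout. Its output — the "smashed
data" — is a 64-channel map at 1/4 the input resolution (56x56 for 224
inputs).

Server back: a conv-BN-ReLU-conv-BN refinement, three basic residual
blocks (128/256/512 channels, first conv of each stride 2, projection
shortcuts), global average pooling and a linear head to ``n_classes``.

A ``width`` multiplier scales every channel count for reduced-size runs;
``width=1`` is the full architecture. ``compose`` wires the two halves
into one model sharing the same weight tensors, used as the centralized
oracle and the federated-learning baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .data import DatasetError


def _ch(base: int, width: float) -> int:
    return max(1, int(round(base * width)))


@dataclass
class SmashedBatch:
    """Cut-layer activations plus the shared true labels.

    ``graph`` retains the client-side autograd graph so the client can
    backpropagate once the server returns the cut gradient; the numeric
    ``activations`` array is what would travel over the wire.
    """
    activations: np.ndarray
    labels: np.ndarray
    graph: Tensor | None = None

    def __post_init__(self):
        if self.activations.shape[0] != len(self.labels):
            raise DatasetError("activation/label batch sizes differ")


@dataclass
class GradientPacket:
    """Loss gradient at the cut layer, with the loss and predictions."""
    grad: np.ndarray | None
    loss: float
    predictions: np.ndarray


class ClientNet(nn.Module):
    """Client-side front of the split network."""

    def __init__(self, width: float = 1.0, dropout: float = 0.5, seed: int = 0,
                 in_channels: int = 1):
        super().__init__()
        ss = np.random.SeedSequence(seed).spawn(3)
        c = _ch(64, width)
        self.conv1 = nn.Conv2d(in_channels, c, 7, stride=2, padding=3, rng=ss[0], init="he")
        self.bn1 = nn.BatchNorm2d(c)
        self.pool = nn.MaxPool2d(3, stride=2, padding=1)
        self.conv2 = nn.Conv2d(c, c, 3, stride=1, padding=1, rng=ss[1], init="he")
        self.bn2 = nn.BatchNorm2d(c)
        self.drop = nn.Dropout(dropout, seed=int(ss[2].generate_state(1)[0] % (2 ** 31)))
        self.out_channels = c

    def forward(self, x) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.shape[2] % 4 or x.shape[3] % 4:
            raise DatasetError("input spatial size must be divisible by 4")
        h = self.pool(self.bn1(self.conv1(x)).relu())
        h = self.bn2(self.conv2(h)).relu()
        return self.drop(h)


class BasicBlock(nn.Module):
    """Two 3x3 conv-BN pairs with a (projection) shortcut."""

    def __init__(self, c_in: int, c_out: int, stride: int, seed: int = 0):
        super().__init__()
        ss = np.random.SeedSequence(seed).spawn(3)
        self.conv1 = nn.Conv2d(c_in, c_out, 3, stride=stride, padding=1, rng=ss[0], init="he")
        self.bn1 = nn.BatchNorm2d(c_out)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, stride=1, padding=1, rng=ss[1], init="he")
        self.bn2 = nn.BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.proj = nn.Conv2d(c_in, c_out, 1, stride=stride, padding=0, rng=ss[2], init="he")
            self.bn_proj = nn.BatchNorm2d(c_out)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        sc = self.bn_proj(self.proj(x)) if self.proj is not None else x
        return (h + sc).relu()


class ServerNet(nn.Module):
    """Server-side back of the split network."""

    def __init__(self, width: float = 1.0, n_classes: int = 3, seed: int = 0):
        super().__init__()
        ss = np.random.SeedSequence(seed).spawn(6)
        c64 = _ch(64, width)
        self.conv3a = nn.Conv2d(c64, c64, 3, stride=1, padding=1, rng=ss[0], init="he")
        self.bn3a = nn.BatchNorm2d(c64)
        self.conv3b = nn.Conv2d(c64, c64, 3, stride=1, padding=1, rng=ss[1], init="he")
        self.bn3b = nn.BatchNorm2d(c64)
        self.block4 = BasicBlock(c64, _ch(128, width), 2,
                                 int(ss[2].generate_state(1)[0] % (2 ** 31)))
        self.block5 = BasicBlock(_ch(128, width), _ch(256, width), 2,
                                 int(ss[3].generate_state(1)[0] % (2 ** 31)))
        self.block6 = BasicBlock(_ch(256, width), _ch(512, width), 2,
                                 int(ss[4].generate_state(1)[0] % (2 ** 31)))
        self.gap = nn.GlobalAvgPool()
        self.fc = nn.Dense(_ch(512, width), n_classes, ss[5], init="he")
        self.n_classes = n_classes

    def forward(self, x) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        h = self.bn3a(self.conv3a(x)).relu()
        h = self.bn3b(self.conv3b(h))
        h = self.block4(h)
        h = self.block5(h)
        h = self.block6(h)
        return self.fc(self.gap(h))     # logits


class ComposedModel(nn.Module):
    """Client front and server back sharing the same weight tensors."""

    def __init__(self, client: ClientNet, server: ServerNet):
        super().__init__()
        if client.out_channels != server.conv3a.weight.data.shape[1]:
            raise DatasetError("client/server channel widths are incompatible")
        self.client = client
        self.server = server

    def forward(self, x) -> Tensor:
        return self.server(self.client(x))


def compose(client: ClientNet, server: ServerNet) -> ComposedModel:
    return ComposedModel(client, server)


# ----------------------------------------------------------- split protocol
def forward_client(net: ClientNet, images, labels) -> SmashedBatch:
    """Client forward pass: images -> smashed activations (+ shared labels)."""
    labels = np.asarray(labels, dtype=np.int64)
    out = net(images)
    return SmashedBatch(activations=out.data, labels=labels, graph=out)


def server_step(net: ServerNet, smashed: SmashedBatch, train: bool = True,
                optimizer=None) -> GradientPacket:
    """One server step on a smashed batch.

    Training mode: forward from a leaf tensor at the cut, categorical
    cross-entropy against the shared labels, backward, one optimizer step
    on the server weights, and the gradient at the cut returned.
    Eval mode: loss and predictions only; no gradient.
    """
    cut = Tensor(smashed.activations, requires_grad=train)
    logits = net(cut)
    loss, probs = nn.softmax_cross_entropy(logits, smashed.labels)
    if not train:
        return GradientPacket(grad=None, loss=loss.item(), predictions=probs)
    net.zero_grad()
    loss.backward()
    if optimizer is not None:
        optimizer.step()
    return GradientPacket(grad=cut.grad, loss=loss.item(), predictions=probs)


def client_backward(net: ClientNet, smashed: SmashedBatch,
                    packet: GradientPacket, optimizer=None) -> None:
    """Backpropagate the received cut gradient through the client graph and
    apply one optimizer step."""
    if smashed.graph is None:
        raise DatasetError("smashed batch carries no client-side graph")
    if packet.grad is None or packet.grad.shape != smashed.activations.shape:
        raise DatasetError("gradient shape does not match the smashed activations")
    net.zero_grad()
    smashed.graph.backward(packet.grad)
    if optimizer is not None:
        optimizer.step()
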