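"""Classification metrics and per-epoch history reporting.

Conventions: predicted class is the argmax of the probability row with
ties broken to the lowest index; per-class precision/recall come from the
confusion matrix with 0/0 defined as 0; macro averages are unweighted
means over classes; loss is mean categorical cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DatasetError


@dataclass
class MetricsReport:
    accuracy: float
    loss: float
    precision: np.ndarray          # per class
    recall: np.ndarray             # per class
    macro_precision: float
    macro_recall: float
    confusion: np.ndarray          # rows = true class, cols = predicted


def compute_metrics(pred_probs: np.ndarray, labels: np.ndarray,
                    n_classes: int | None = None) -> MetricsReport:
    pred_probs = np.asarray(pred_probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if pred_probs.ndim != 2 or len(pred_probs) != len(labels) or len(labels) == 0:
        raise DatasetError("pred_probs must be (batch, n_classes) with matching labels")
    if (pred_probs < 0).any():
        raise DatasetError("probabilities must be nonnegative")
    k = n_classes or pred_probs.shape[1]
    if labels.min() < 0 or labels.max() >= k:
        raise DatasetError("label out of range")

    pred = pred_probs.argmax(axis=1)       # numpy argmax ties -> lowest index
    confusion = np.zeros((k, k), dtype=np.int64)
    np.add.at(confusion, (labels, pred), 1)

    diag = np.diag(confusion).astype(np.float64)
    col = confusion.sum(axis=0).astype(np.float64)
    row = confusion.sum(axis=1).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / np.maximum(col, 1), 0.0)
        recall = np.where(row > 0, diag / np.maximum(row, 1), 0.0)

    rowsum = pred_probs.sum(axis=1, keepdims=True)
    probs = pred_probs / np.maximum(rowsum, np.finfo(np.float64).tiny)
    eps = np.finfo(np.float64).tiny
    loss = float(-np.log(probs[np.arange(len(labels)), labels] + eps).mean())

    return MetricsReport(
        accuracy=float(diag.sum() / confusion.sum()),
        loss=loss,
        precision=precision,
        recall=recall,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        confusion=confusion,
    )


# ------------------------------------------------------------------ history
@dataclass
class History:
    """Per-global-epoch training record, one row per epoch."""
    rows: list = field(default_factory=list)

    def append(self, epoch: int, train: MetricsReport, test: MetricsReport,
               per_client: dict) -> None:
        self.rows.append({"epoch": epoch, "train": train, "test": test,
                          "per_client": per_client})

    def __len__(self):
        return len(self.rows)

    def final_test_accuracy(self) -> float:
        return self.rows[-1]["test"].accuracy

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: epoch, split, client, metric, value."""
        records = []

        def emit(epoch, split, client, rep: MetricsReport):
            records.append((epoch, split, client, "accuracy", rep.accuracy))
            records.append((epoch, split, client, "loss", rep.loss))
            records.append((epoch, split, client, "macro_precision", rep.macro_precision))
            records.append((epoch, split, client, "macro_recall", rep.macro_recall))
            for c, (p, r) in enumerate(zip(rep.precision, rep.recall)):
                records.append((epoch, split, client, f"precision_class{c}", float(p)))
                records.append((epoch, split, client, f"recall_class{c}", float(r)))

        for row in self.rows:
            emit(row["epoch"], "train", "global", row["train"])
            emit(row["epoch"], "test", "global", row["test"])
            for cid, rep in sorted(row["per_client"].items()):
                emit(row["epoch"], "train", f"client{cid}", rep)
        return pd.DataFrame(records,
                            columns=["epoch", "split", "client", "metric", "value"])


def write_history_csv(history: History, path) -> None:
    if len(history) == 0:
        raise DatasetError("empty history")
    df = history.to_frame()
    df["value"] = df["value"].map(lambda v: format(float(v), ".10g"))
    df.to_csv(path, index=False)


def read_history_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def per_client_table(history: History) -> pd.DataFrame:
    """Final-epoch per-client metrics, one row per client per metric."""
    if len(history) == 0:
        raise DatasetError("empty history")
    df = history.to_frame()
    last = df[df.epoch == df.epoch.max()]
    return last[last.client != "global"].reset_index(drop=True)


def plot_history(history: History, out_path) -> None:
    """Train/test accuracy and loss versus epoch (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = history.to_frame()
    g = df[df.client == "global"]
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for split in ("train", "test"):
        sub = g[(g.split == split) & (g.metric == "accuracy")]
        axes[0].plot(sub.epoch, sub.value, label=split)
        sub = g[(g.split == split) & (g.metric == "loss")]
        axes[1].plot(sub.epoch, sub.value, label=split)
    axes[0].set_xlabel("epoch"); axes[0].set_ylabel("accuracy"); axes[0].legend()
    axes[1].set_xlabel("epoch"); axes[1].set_ylabel("loss"); axes[1].legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
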