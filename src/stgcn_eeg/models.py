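"""ST-GCN and T-CNN classifiers, statsmodels-style.

A model object is built from data (mini-epoch tensors, per-sample adjacency
matrices, binary labels) plus a :class:`ModelConfig`; ``fit`` trains with
Adam on binary cross-entropy, checkpointing the parameters whenever the
validation loss improves, and returns a results object carrying the best
parameters, the per-epoch history, and evaluation helpers.

The two variants share everything except the spatial unit: the ST-GCN's
ST-Conv blocks interleave a first-order graph convolution (driven by the
renormalised propagation matrix of each sample's functional-connectivity
adjacency) between the two temporal convolutions; the T-CNN baseline drops
the graph convolution and ignores the adjacency input entirely.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn

VARIANTS = ("ST-GCN", "T-CNN")


class TrainingError(RuntimeError):
    pass


@dataclass
class ModelConfig:
    """Architecture and optimisation hyperparameters.

    ``channels`` gives the width of each ST-Conv block; each block shortens
    the sequence by ``2 (Kt - 1)`` so ``in_len - n_blocks * 2 * (Kt - 1)``
    must stay >= 1.
    """

    Kt: int = 3
    n_blocks: int = 2
    channels: tuple[int, ...] = (16, 32)
    n_nodes: int = 23
    in_len: int = 25
    cheb_K: int = 1
    variant: str = "ST-GCN"
    seed: int = 0
    lr: float = 1e-3
    batch_size: int = 64
    epochs: int = 100
    weight_decay: float = 0.0

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.Kt < 1:
            raise ValueError("Kt must be >= 1")
        if self.in_len - self.n_blocks * 2 * (self.Kt - 1) < 1:
            raise ValueError("blocks consume the whole sequence")
        if self.cheb_K != 1:
            raise ValueError(
                "network layers use the first-order renormalised propagation "
                "(cheb_K=1); higher orders live in stgcn_eeg.graphops"
            )

    @property
    def out_len(self) -> int:
        return self.in_len - self.n_blocks * 2 * (self.Kt - 1)

    @property
    def flat_dim(self) -> int:
        return self.out_len * self.n_nodes * self.channels[-1]


@dataclass
class TrainReport:
    """Per-epoch history plus the checkpoint bookkeeping."""

    history: list[dict] = field(default_factory=list)
    best_val_loss: float = np.inf
    checkpoint_epoch: int = -1
    test_accuracy: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)


def propagation_from_adjacency(W: np.ndarray) -> np.ndarray:
    """Batched renormalised propagation ``S = D~^{-1/2} (W + I) D~^{-1/2}``."""
    W = np.asarray(W, dtype=float)
    single = W.ndim == 2
    if single:
        W = W[None]
    n = W.shape[-1]
    Wt = W + np.eye(n)
    d = Wt.sum(axis=-1) ** -0.5
    S = d[:, :, None] * Wt * d[:, None, :]
    return S[0] if single else S


class GraphEEGClassifier:
    """Base model: data + config -> fit() -> results.

    Parameters
    ----------
    X
        Mini-epoch tensor, [N, in_len, n_nodes] or [N, in_len, n_nodes, 1].
    W
        Per-sample adjacency matrices [N, n_nodes, n_nodes] (may be omitted
        for the T-CNN variant).
    y
        Binary labels, 1 for the patient-like class.
    """

    variant = "ST-GCN"

    def __init__(self, X: np.ndarray, y: np.ndarray,
                 W: np.ndarray | None = None,
                 config: ModelConfig | None = None):
        config = config or ModelConfig()
        if config.variant != self.variant:
            config = ModelConfig(**{**asdict(config), "variant": self.variant})
        self.config = config
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            X = X[..., None]
        if X.ndim != 4 or X.shape[1] != config.in_len \
                or X.shape[2] != config.n_nodes:
            raise ValueError(
                f"X must be [N, {config.in_len}, {config.n_nodes}, 1], "
                f"got {X.shape}"
            )
        self.X = X
        self.y = np.asarray(y, dtype=float).ravel()
        if self.y.size != X.shape[0]:
            raise ValueError("label count mismatch")
        if self.needs_graph:
            if W is None:
                raise ValueError(f"{self.variant} requires adjacency matrices")
            self.S = propagation_from_adjacency(W)
            if self.S.shape != (X.shape[0], config.n_nodes, config.n_nodes):
                raise ValueError("W must be [N, n_nodes, n_nodes]")
        else:
            self.S = None

    @property
    def needs_graph(self) -> bool:
        return self.variant == "ST-GCN"

    @classmethod
    def from_dataset(cls, X, y, W=None, **config_kwargs):
        """Convenience constructor with config fields as keyword arguments."""
        cfg = ModelConfig(variant=cls.variant, **config_kwargs)
        return cls(X, y, W=W, config=cfg)

    def _build(self) -> nn.Network:
        c = self.config
        return nn.Network(Kt=c.Kt, n_blocks=c.n_blocks, channels=c.channels,
                          n_nodes=c.n_nodes, in_len=c.in_len, seed=c.seed,
                          use_graph=self.needs_graph)

    def _batch(self, idx: np.ndarray):
        S = None if self.S is None else self.S[idx]
        return self.X[idx], S, self.y[idx]

    def _eval_loss_acc(self, net: nn.Network, idx: np.ndarray,
                       batch_size: int) -> tuple[float, float]:
        losses, correct = [], 0
        for lo in range(0, idx.size, batch_size):
            bidx = idx[lo:lo + batch_size]
            Xb, Sb, yb = self._batch(bidx)
            logits = net.forward_logits(Xb, Sb)
            loss, _ = nn.bce_with_logits(logits, yb)
            losses.append(loss * bidx.size)
            correct += int(np.sum((logits > 0) == (yb > 0.5)))
        return float(np.sum(losses) / idx.size), correct / idx.size

    def fit(self, train_idx=None, val_idx=None, *, epochs: int | None = None,
            verbose: bool = False) -> "GraphEEGResults":
        """Train with Adam/BCE; keep the parameters of the best-validation
        epoch.

        If no indices are given, a seeded 85/15 shuffle of all samples is
        used for train/validation.
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        N = self.X.shape[0]
        if train_idx is None or val_idx is None:
            perm = rng.permutation(N)
            n_val = max(1, int(0.15 * N))
            val_idx = perm[:n_val]
            train_idx = perm[n_val:]
        train_idx = np.asarray(train_idx, dtype=int)
        val_idx = np.asarray(val_idx, dtype=int)
        if train_idx.size == 0 or val_idx.size == 0:
            raise ValueError("train and validation sets must be non-empty")

        net = self._build()
        opt = nn.Adam(net.params(), lr=cfg.lr,
                      weight_decay=cfg.weight_decay)
        report = TrainReport()
        best_state = net.get_state()
        n_epochs = cfg.epochs if epochs is None else epochs

        for epoch in range(n_epochs):
            order = rng.permutation(train_idx.size)
            ep_loss, ep_correct = 0.0, 0
            for lo in range(0, train_idx.size, cfg.batch_size):
                bidx = train_idx[order[lo:lo + cfg.batch_size]]
                Xb, Sb, yb = self._batch(bidx)
                net.zero_grad()
                logits = net.forward_logits(Xb, Sb)
                loss, dlogit = nn.bce_with_logits(logits, yb)
                if not np.isfinite(loss):
                    raise TrainingError(
                        f"loss diverged at epoch {epoch} "
                        f"(lr={cfg.lr}, batch={cfg.batch_size})"
                    )
                net.backward(dlogit)
                opt.step()
                ep_loss += loss * bidx.size
                ep_correct += int(np.sum((logits > 0) == (yb > 0.5)))
            val_loss, val_acc = self._eval_loss_acc(net, val_idx,
                                                    cfg.batch_size)
            row = {
                "epoch": epoch,
                "train_loss": ep_loss / train_idx.size,
                "train_acc": ep_correct / train_idx.size,
                "val_loss": val_loss,
                "val_acc": val_acc,
            }
            report.history.append(row)
            if val_loss < report.best_val_loss:
                report.best_val_loss = val_loss
                report.checkpoint_epoch = epoch
                best_state = net.get_state()
            if verbose:
                print(f"epoch {epoch:3d}  train {row['train_loss']:.4f}/"
                      f"{row['train_acc']:.3f}  val {val_loss:.4f}/{val_acc:.3f}")

        net.set_state(best_state)
        return GraphEEGResults(self, net, report, train_idx, val_idx)


class STGCN(GraphEEGClassifier):
    """Spatial-temporal graph convolutional classifier."""

    variant = "ST-GCN"


class TCNN(GraphEEGClassifier):
    """Temporal-only convolutional baseline (no graph unit, W unused)."""

    variant = "T-CNN"

    def __init__(self, X, y, W=None, config=None):
        # the baseline deliberately ignores W
        super().__init__(X, y, W=None, config=config)


class GraphEEGResults:
    """Fitted-model results: best checkpoint, history, evaluation."""

    def __init__(self, model: GraphEEGClassifier, net: nn.Network,
                 report: TrainReport, train_idx, val_idx):
        self.model = model
        self.net = net
        self.report = report
        self.train_idx = np.asarray(train_idx)
        self.val_idx = np.asarray(val_idx)

    @property
    def history(self) -> pd.DataFrame:
        return self.report.to_frame()

    def predict_proba(self, X: np.ndarray | None = None,
                      W: np.ndarray | None = None,
                      idx=None) -> np.ndarray:
        """Class-1 probabilities, batched through the checkpointed net."""
        if X is None:
            idx = np.arange(self.model.X.shape[0]) if idx is None \
                else np.asarray(idx, dtype=int)
            X = self.model.X[idx]
            S = None if self.model.S is None else self.model.S[idx]
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim == 3:
                X = X[..., None]
            S = None
            if self.model.needs_graph:
                if W is None:
                    raise ValueError("graph variant requires W for new data")
                S = propagation_from_adjacency(W)
        out = []
        bs = self.model.config.batch_size
        for lo in range(0, X.shape[0], bs):
            Sb = None if S is None else S[lo:lo + bs]
            out.append(nn.sigmoid(self.net.forward_logits(X[lo:lo + bs], Sb)))
        return np.concatenate(out)

    def evaluate(self, idx) -> dict:
        """Accuracy and confusion counts on an index set (threshold 0.5)."""
        idx = np.asarray(idx, dtype=int)
        if idx.size == 0:
            raise ValueError("empty evaluation set")
        p = self.predict_proba(idx=idx)
        y = self.model.y[idx]
        pred = p >= 0.5
        truth = y > 0.5
        tp = int(np.sum(pred & truth))
        tn = int(np.sum(~pred & ~truth))
        fp = int(np.sum(pred & ~truth))
        fn = int(np.sum(~pred & truth))
        acc = (tp + tn) / idx.size
        self.report.test_accuracy = acc
        return {"accuracy": acc, "tp": tp, "tn": tn, "fp": fp, "fn": fn,
                "n": int(idx.size)}

    def summary(self) -> str:
        cfg = self.model.config
        h = self.history
        lines = [
            f"{cfg.variant} classification results",
            "=" * 40,
            f"blocks: {cfg.n_blocks}  Kt: {cfg.Kt}  widths: {cfg.channels}",
            f"nodes: {cfg.n_nodes}  window: {cfg.in_len}  "
            f"flatten dim: {cfg.flat_dim}",
            f"train/val sizes: {self.train_idx.size}/{self.val_idx.size}",
            f"epochs run: {len(h)}  checkpoint epoch: "
            f"{self.report.checkpoint_epoch}",
            f"best val loss: {self.report.best_val_loss:.4f}",
        ]
        if len(h):
            lines.append(f"final train acc: {h['train_acc'].iloc[-1]:.3f}  "
                         f"val acc at checkpoint: "
                         f"{h['val_acc'].iloc[self.report.checkpoint_epoch]:.3f}")
        if self.report.test_accuracy is not None:
            lines.append(f"test accuracy: {self.report.test_accuracy:.3f}")
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Write checkpoint as ``<path>.npz`` + ``<path>.json`` config."""
        path = Path(path)
        base = path.with_suffix("") if path.suffix in {".npz", ".json"} else path
        state = self.net.get_state()
        np.savez_compressed(base.with_suffix(".npz"),
                            **{f"p{i}": v for i, v in enumerate(state)})
        payload = {
            "config": asdict(self.model.config),
            "checkpoint_epoch": self.report.checkpoint_epoch,
            "best_val_loss": self.report.best_val_loss,
            "history": self.report.history,
        }
        base.with_suffix(".json").write_text(json.dumps(payload, indent=1))
        return base.with_suffix(".npz")


def load_results(path: str | Path, X, y, W=None) -> GraphEEGResults:
    """Rebuild a results object from a saved checkpoint and a dataset."""
    base = Path(path)
    base = base.with_suffix("") if base.suffix in {".npz", ".json"} else base
    payload = json.loads(base.with_suffix(".json").read_text())
    cfg = ModelConfig(**{**payload["config"],
                         "channels": tuple(payload["config"]["channels"])})
    cls = STGCN if cfg.variant == "ST-GCN" else TCNN
    model = cls(X, y, W=W, config=cfg)
    net = model._build()
    with np.load(base.with_suffix(".npz")) as archive:
        state = [archive[f"p{i}"] for i in range(len(archive.files))]
    net.set_state(state)
    report = TrainReport(history=payload["history"],
                         best_val_loss=payload["best_val_loss"],
                         checkpoint_epoch=payload["checkpoint_epoch"])
    return GraphEEGResults(model, net, report, np.array([], dtype=int),
                           np.array([], dtype=int))
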