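"""Residual convolutional denoising autoencoder for genotype windows.

The network maps a one-hot corrupted genotype window (n x 3 x p) to
per-position 3-class scores for the codes {1, 2, 3}. Eight same-padded
1-D convolutions form a symmetric hourglass: input channels
3-32-64-64-128-64-64-32, kernel 15, stride 1, padding 7, max-pooling
(factor 2) after the second and fourth convolutions and repeat-upsampling
before the sixth and eighth, identity residual skips around the two
channel-preserving 64->64 convolutions, ReLU then layer normalization
after each convolution except the final score layer.

Training minimizes cross-entropy between predicted scores and the clean
genotype classes at every position whose clean genotype is known
(originally missing truth is excluded), with Adam (lr 1e-3, eps 1e-8,
weight decay 1e-5), batch size 64, at most 150 epochs, a
reduce-on-plateau learning-rate schedule (factor 0.9, patience 0) active
after epoch 100, and best-loss checkpointing.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .genotype_io import encode_onehot

__all__ = [
    "NetworkConfig",
    "TrainedWindowModel",
    "dropout_rate",
    "build_network",
    "train_window",
    "predict_window",
]

CHANNELS = (3, 32, 64, 64, 128, 64, 64, 32)


@dataclass
class NetworkConfig:
    """Hyperparameters of the imputation network and its training loop.

    Ablation flags reproduce the published component-removal variants:
    ``residual`` (identity skips), ``layernorm``/``batchnorm`` (normalization
    choice; batchnorm=True substitutes batch for layer normalization),
    ``dynamic_lr`` (reduce-on-plateau schedule), ``matching`` (automatic
    sample matching vs random masks) and ``augmentation`` (KNN-imputed
    testing rows stacked into the training set).
    """

    channels: tuple[int, ...] = CHANNELS
    kernel: int = 15
    stride: int = 1
    window: int = 1000
    batch: int = 64
    max_epochs: int = 150
    lr0: float = 1e-3
    adam_eps: float = 1e-8
    weight_decay: float = 1e-5
    sched_factor: float = 0.9
    sched_patience: int = 0
    sched_start_epoch: int = 100
    dropout: float = 0.3
    knn_k: int = 5
    seed: int = 0
    # ablation flags
    residual: bool = True
    layernorm: bool = True
    batchnorm: bool = False
    dynamic_lr: bool = True
    matching: bool = True
    augmentation: bool = True
    # training-loss support: all known positions, or masked positions only
    loss_on_masked_only: bool = False
    remask_each_epoch: bool = False

    @property
    def padding(self) -> int:
        return self.kernel // 2

    def __post_init__(self) -> None:
        if len(self.channels) != 8:
            raise ValueError("channels must list the 8 convolution input widths")
        if self.kernel % 2 != 1:
            raise ValueError("kernel must be odd")

    def with_dropout_for(self, mr: float) -> "NetworkConfig":
        """Copy with the dropout rate set from the window's missing rate."""
        return replace(self, dropout=dropout_rate(mr))


def dropout_rate(mr: float) -> float:
    """Missing-rate-adaptive dropout: 0.3 - (mr - 0.1) / 8, clamped to [0, 1).

    Higher missingness already regularizes the denoising task, so the
    dropout rate decreases linearly (slope -1/8) with the genotype missing
    rate mr.
    """
    if not 0.0 <= mr <= 1.0:
        raise ValueError(f"missing rate must be in [0, 1], got {mr}")
    rate = 0.3 - (mr - 0.1) / 8.0
    return float(min(max(rate, 0.0), 1.0 - 1e-12))


class ImputationNetwork:
    """The hourglass autoencoder with explicit skip bookkeeping."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator) -> None:
        if cfg.window < 4:
            raise ValueError("window must be at least 4 markers")
        self.cfg = cfg
        self.rng = rng
        c = cfg.channels
        k = cfg.kernel

        def norm(width: int):
            if cfg.batchnorm:
                return nn.BatchNorm(width)
            if cfg.layernorm:
                return nn.LayerNorm(width)
            return None

        # conv i maps c[i] -> c[i+1]; the final conv maps c[7] -> 3 scores
        outs = [c[1], c[2], c[3], c[4], c[5], c[6], c[7], 3]
        self.convs = [nn.Conv1D(c[i], outs[i], k, rng) for i in range(8)]
        self.norms = [norm(outs[i]) for i in range(7)]  # no norm on the score layer
        self.relus = [nn.ReLU() for _ in range(7)]
        self.pools = [nn.MaxPool2(), nn.MaxPool2()]
        self.ups = [nn.Upsample2(), nn.Upsample2()]
        self.drops = [nn.Dropout(cfg.dropout, rng), nn.Dropout(cfg.dropout, rng)]

    # -- parameter plumbing -------------------------------------------
    def _layers(self):
        for lyr in (*self.convs, *[x for x in self.norms if x is not None]):
            yield lyr

    def parameters(self) -> list[np.ndarray]:
        return [p for lyr in self._layers() for p in lyr.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for lyr in self._layers() for g in lyr.grads]

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p[...] = s

    # -- forward / backward -------------------------------------------
    def _stage(self, i: int, x: np.ndarray, training: bool) -> np.ndarray:
        y = self.convs[i].forward(x, training)
        if i == 7:
            return y  # raw scores
        y = self.relus[i].forward(y, training)
        if self.norms[i] is not None:
            y = self.norms[i].forward(y, training)
        return y

    def _stage_back(self, i: int, gy: np.ndarray) -> np.ndarray:
        if i != 7:
            if self.norms[i] is not None:
                gy = self.norms[i].backward(gy)
            gy = self.relus[i].backward(gy)
        return self.convs[i].backward(gy)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """x: (n, 3, p) one-hot corrupted window -> (n, 3, p) class scores."""
        n, c, p = x.shape
        pad = (-p) % 4  # two pooling stages need a multiple of 4
        self._out_len = p
        if pad:
            x = np.pad(x, ((0, 0), (0, 0), (0, pad)))
        res = self.cfg.residual

        h = self._stage(0, x, training)
        h = self._stage(1, h, training)
        h = self.pools[0].forward(h, training)
        h = self.drops[0].forward(h, training)
        skip1 = h
        h = self._stage(2, h, training)
        if res:
            h = h + skip1
        h = self._stage(3, h, training)
        h = self.pools[1].forward(h, training)
        h = self.drops[1].forward(h, training)
        h = self._stage(4, h, training)
        h = self.ups[0].forward(h, training)
        skip2 = h
        h = self._stage(5, h, training)
        if res:
            h = h + skip2
        h = self._stage(6, h, training)
        h = self.ups[1].forward(h, training)
        h = self._stage(7, h, training)
        return h[:, :, : self._out_len]

    def backward(self, gy: np.ndarray) -> None:
        pad = (-self._out_len) % 4
        if pad:
            gy = np.pad(gy, ((0, 0), (0, 0), (0, pad)))
        res = self.cfg.residual

        g = self._stage_back(7, gy)
        g = self.ups[1].backward(g)
        g = self._stage_back(6, g)
        if res:
            g_skip2 = g
            g = self._stage_back(5, g) + g_skip2
        else:
            g = self._stage_back(5, g)
        g = self.ups[0].backward(g)
        g = self._stage_back(4, g)
        g = self.drops[1].backward(g)
        g = self.pools[1].backward(g)
        g = self._stage_back(3, g)
        if res:
            g_skip1 = g
            g = self._stage_back(2, g) + g_skip1
        else:
            g = self._stage_back(2, g)
        g = self.drops[0].backward(g)
        g = self.pools[0].backward(g)
        g = self._stage_back(1, g)
        self._stage_back(0, g)


def build_network(cfg: NetworkConfig, rng: np.random.Generator | None = None) -> ImputationNetwork:
    """Construct an untrained imputation network from its configuration."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    return ImputationNetwork(cfg, rng)


@dataclass
class TrainedWindowModel:
    """A fitted per-window model: best-checkpoint weights plus training history."""

    network: ImputationNetwork
    cfg: NetworkConfig
    best_loss: float
    best_epoch: int
    epochs_run: int
    history: "list[dict]" = field(default_factory=list)
    window = None  # WindowSpec, attached by the orchestrator

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history)

    def save(self, path: str) -> None:
        """Persist the checkpointed weights, config and history to one
        .npz container."""
        import dataclasses
        import json

        meta = {
            "cfg": dataclasses.asdict(self.cfg),
            "best_loss": self.best_loss,
            "best_epoch": self.best_epoch,
            "epochs_run": self.epochs_run,
            "history": self.history,
        }
        state = self.network.get_state()
        np.savez(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **{f"p{i}": p for i, p in enumerate(state)},
        )


def load_window_model(path: str) -> TrainedWindowModel:
    """Restore a TrainedWindowModel written by TrainedWindowModel.save."""
    import json

    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        state = [z[f"p{i}"] for i in range(len(z.files) - 1)]
    cfg_d = meta["cfg"]
    cfg_d["channels"] = tuple(cfg_d["channels"])
    cfg = NetworkConfig(**cfg_d)
    net = build_network(cfg, np.random.default_rng(cfg.seed))
    net.set_state(state)
    return TrainedWindowModel(
        network=net,
        cfg=cfg,
        best_loss=meta["best_loss"],
        best_epoch=meta["best_epoch"],
        epochs_run=meta["epochs_run"],
        history=meta["history"],
    )


def _codes_to_input(codes: np.ndarray) -> np.ndarray:
    """(n, p) integer codes -> (n, 3, p) channels-first one-hot float32."""
    return np.ascontiguousarray(encode_onehot(codes).transpose(0, 2, 1))


def _full_loss(net: ImputationNetwork, x: np.ndarray, targets: np.ndarray, batch: int) -> float:
    """Evaluation-mode cross-entropy over the whole training set, batched."""
    total, weight = 0.0, 0
    for s in range(0, x.shape[0], batch):
        xb, tb = x[s : s + batch], targets[s : s + batch]
        n_known = int((tb > 0).sum())
        if n_known == 0:
            continue
        logits = net.forward(xb, training=False)
        loss, _ = nn.softmax_cross_entropy(logits, tb)
        total += loss * n_known
        weight += n_known
    if weight == 0:
        raise ValueError("no known genotypes to train on in this window")
    return total / weight


def train_window(
    clean_codes: np.ndarray,
    corrupted_codes: np.ndarray,
    cfg: NetworkConfig,
    max_epochs: int | None = None,
) -> TrainedWindowModel:
    """Fit the denoising autoencoder on one marker window.

    clean_codes and corrupted_codes are (n, p) integer code matrices; the
    corrupted copy differs from the clean one only at masked positions
    (set to 0, one-hot [0,0,0]). The loss is computed where the clean
    genotype is known; with cfg.loss_on_masked_only, only at positions
    masked in the corrupted input. The monitored quantity for scheduling
    and checkpointing is the full training-set loss recomputed each epoch
    in evaluation mode.
    """
    clean_codes = np.asarray(clean_codes)
    corrupted_codes = np.asarray(corrupted_codes)
    if clean_codes.shape != corrupted_codes.shape:
        raise ValueError("clean and corrupted shapes differ")
    n, p = clean_codes.shape
    epochs = cfg.max_epochs if max_epochs is None else max_epochs

    rng = np.random.default_rng(cfg.seed)
    net = build_network(cfg, rng)
    x = _codes_to_input(corrupted_codes)
    targets = clean_codes.astype(np.int64)
    if cfg.loss_on_masked_only:
        masked = (corrupted_codes == 0) & (clean_codes != 0)
        targets = np.where(masked, targets, 0)
    if int((targets > 0).sum()) == 0:
        raise ValueError("no known genotypes to train on in this window")

    opt = nn.Adam(
        net.parameters(),
        net.gradients(),
        lr=cfg.lr0,
        eps=cfg.adam_eps,
        weight_decay=cfg.weight_decay,
    )

    best_loss = np.inf
    best_epoch = -1
    best_state = net.get_state()
    sched_best = np.inf
    sched_wait = 0
    history: list[dict] = []

    for epoch in range(1, epochs + 1):
        order = rng.permutation(n)
        for s in range(0, n, cfg.batch):
            idx = order[s : s + cfg.batch]
            tb = targets[idx]
            if int((tb > 0).sum()) == 0:
                continue
            logits = net.forward(x[idx], training=True)
            _, grad = nn.softmax_cross_entropy(logits, tb)
            net.backward(grad)
            opt.step()

        monitored = _full_loss(net, x, targets, cfg.batch)
        history.append({"epoch": epoch, "loss": monitored, "lr": opt.lr})

        if monitored < best_loss:
            best_loss = monitored
            best_epoch = epoch
            best_state = net.get_state()

        if cfg.dynamic_lr and epoch > cfg.sched_start_epoch:
            if monitored < sched_best:
                sched_best = monitored
                sched_wait = 0
            else:
                sched_wait += 1
                if sched_wait > cfg.sched_patience:
                    opt.lr *= cfg.sched_factor
                    sched_wait = 0
        elif cfg.dynamic_lr:
            sched_best = min(sched_best, monitored)

    net.set_state(best_state)
    return TrainedWindowModel(
        network=net,
        cfg=cfg,
        best_loss=float(best_loss),
        best_epoch=best_epoch,
        epochs_run=epochs,
        history=history,
    )


def predict_window(model: TrainedWindowModel, corrupted_codes: np.ndarray) -> np.ndarray:
    """Impute a corrupted window: argmax class at missing positions, observed
    codes passed through unchanged."""
    corrupted_codes = np.asarray(corrupted_codes)
    x = _codes_to_input(corrupted_codes)
    out = np.empty_like(corrupted_codes, dtype=np.int8)
    batch = model.cfg.batch
    for s in range(0, corrupted_codes.shape[0], batch):
        logits = model.network.forward(x[s : s + batch], training=False)
        out[s : s + batch] = (logits.argmax(axis=1) + 1).astype(np.int8)
    observed = corrupted_codes != 0
    out[observed] = corrupted_codes[observed]
    return out
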