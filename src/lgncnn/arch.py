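"""The LGN-inspired CNN: prefilter layer, lateral connectivity, training.

The network is a standard convolutional image classifier with two
biologically motivated modifications:

* a prefiltering layer ``l0`` with a *single* learned filter applied to the
  grayscale input — an analogue of the LGN stage, expected to converge to a
  center-surround (Laplacian-of-Gaussian-like) profile;
* lateral connections on the first convolutional layer ``l1``, implemented
  as a linear diffusion step ``h~ = (h + K * h) / 2`` driven by a learned
  4-D connectivity kernel ``K(i, j, f, g)`` that couples filters f and g at
  spatial displacement (i, j).

Training is two-phase: all weights except ``K`` are pre-trained with the
lateral step disabled, then ``K`` is initialized randomly and the whole
network is trained jointly, with DropConnect-style dropout on the lateral
kernel entries.  Early stopping monitors validation accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nnet
from .nnet import (
    BatchNorm2D,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    LateralMix,
    MaxPool2,
    Param,
    ReLU,
    SGD,
    softmax_cross_entropy,
)

__all__ = [
    "ArchitectureConfig",
    "TrainingConfig",
    "Network",
    "build_network",
    "lateral_update",
    "self_replicate",
    "train",
    "evaluate",
    "save_bundle",
    "load_bundle",
]

# (filters, kernel size, max-pool after) for conv layers l1..l10
_DEFAULT_CONV_TABLE: tuple[tuple[int, int, bool], ...] = (
    (64, 7, True),
    (64, 5, False),
    (64, 3, False),
    (64, 3, True),
    (64, 3, False),
    (64, 3, False),
    (128, 3, True),
    (128, 3, False),
    (128, 3, False),
    (128, 3, True),
)


@dataclass
class ArchitectureConfig:
    """Structural hyper-parameters of the network.

    ``unit_fraction`` scales every filter count and hidden fully-connected
    width (used for the capacity-comparison experiment); ``depth`` keeps
    only the first ``depth`` convolutional layers, for the depth sweep and
    for fast smoke-scale training.
    """

    l0_size: int = 11
    lateral_size: int = 13
    conv_table: tuple[tuple[int, int, bool], ...] = _DEFAULT_CONV_TABLE
    fc_widths: tuple[int, ...] = (1000, 200)
    n_classes: int = 10
    use_l0: bool = True
    use_lateral: bool = True
    unit_fraction: float = 1.0
    depth: int | None = None

    def __post_init__(self) -> None:
        if self.l0_size % 2 == 0 or self.lateral_size % 2 == 0:
            raise ValueError("l0_size and lateral_size must be odd")
        if not 0.0 < self.unit_fraction <= 1.0:
            raise ValueError("unit_fraction must be in (0, 1]")
        for nf, ks, _ in self.conv_table:
            if ks % 2 == 0 or nf < 1:
                raise ValueError("conv layers need odd kernels, >=1 filters")

    def scaled_conv_table(self) -> list[tuple[int, int, bool]]:
        table = list(self.conv_table)
        if self.depth is not None:
            table = table[: self.depth]
        return [
            (max(1, round(nf * self.unit_fraction)), ks, pool) for nf, ks, pool in table
        ]

    def scaled_fc_widths(self) -> list[int]:
        return [max(2, round(w * self.unit_fraction)) for w in self.fc_widths]

    @property
    def n_l1_filters(self) -> int:
        return self.scaled_conv_table()[0][0]


@dataclass
class TrainingConfig:
    """Optimization protocol; defaults follow the two-phase scheme."""

    max_epochs: int = 800
    patience: int = 80
    dropout_final: float = 0.5
    dropout_lateral: float = 0.2
    lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 128
    val_fraction: float = 0.1
    seed: int = 0
    phase: str = "both"  # "pretrain_feedforward", "joint_with_lateral" or "both"
    restore_best: bool = False  # early stopping is a stopping rule only by
    # default; set True to reload the best-validation weights afterwards

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_final < 1.0 and 0.0 <= self.dropout_lateral < 1.0):
            raise ValueError("dropout rates must be in [0, 1)")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.phase not in ("both", "pretrain_feedforward", "joint_with_lateral"):
            raise ValueError(f"unknown training phase {self.phase!r}")


class Network:
    """An ordered stack of layers plus handles to the analyzable pieces."""

    def __init__(self, layers, cfg: ArchitectureConfig, rng: np.random.Generator):
        self.layers = layers
        self.cfg = cfg
        self.rng = rng
        convs = [l for l in layers if isinstance(l, Conv2D)]
        self.l0_conv: Conv2D | None = convs[0] if cfg.use_l0 else None
        self.l1_conv: Conv2D = convs[1] if cfg.use_l0 else convs[0]
        self.lateral: LateralMix | None = next(
            (l for l in layers if isinstance(l, LateralMix)), None
        )

    # -- weight views used by the analysis half ---------------------------
    @property
    def psi0(self) -> np.ndarray | None:
        return None if self.l0_conv is None else self.l0_conv.W.value[0, 0].copy()

    @property
    def l1_filters(self) -> np.ndarray:
        return self.l1_conv.W.value[:, 0].copy()

    @property
    def K1(self) -> np.ndarray | None:
        return None if self.lateral is None else self.lateral.K.value.copy()

    # -- execution ---------------------------------------------------------
    def set_mode(self, train: bool) -> None:
        for l in self.layers:
            l.train_mode = train

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for l in reversed(self.layers):
            dy = l.backward(dy)

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for l in self.layers for p in l.params()] + [
            arr.copy()
            for l in self.layers
            if isinstance(l, BatchNorm2D)
            for arr in (l.running_mean, l.running_var)
        ]

    def load_state(self, state: list[np.ndarray]) -> None:
        ps = [p for l in self.layers for p in l.params()]
        for p, v in zip(ps, state[: len(ps)]):
            p.value = v.copy()
        bns = [l for l in self.layers if isinstance(l, BatchNorm2D)]
        rest = state[len(ps) :]
        for bn, (m, v) in zip(bns, zip(rest[0::2], rest[1::2])):
            bn.running_mean, bn.running_var = m.copy(), v.copy()


def build_network(
    cfg: ArchitectureConfig, image_size: int = 32, seed: int = 0
) -> Network:
    """Assemble the network for a given square grayscale input size.

    Every convolution is zero-padded to preserve spatial size; max pooling
    (2x2) follows the layers flagged in the table.  The lateral mixing step
    sits right after l1's batch-norm + ReLU.  Fully-connected head widths
    come from the config, with a final ``n_classes`` output layer.
    """
    rng = np.random.default_rng(seed)
    layers: list[nnet.Layer] = []
    in_ch, size = 1, image_size
    if cfg.use_l0:
        layers += [Conv2D(1, 1, cfg.l0_size, rng), BatchNorm2D(1), ReLU()]
    table = cfg.scaled_conv_table()
    for li, (nf, ks, pool) in enumerate(table):
        layers += [Conv2D(in_ch, nf, ks, rng), BatchNorm2D(nf), ReLU()]
        if li == 0 and cfg.use_lateral:
            layers.append(LateralMix(nf, cfg.lateral_size, rng))
        if pool and size >= 2:
            layers.append(MaxPool2())
            size //= 2
        in_ch = nf
    if size < 1:
        raise ValueError("too many poolings for this image size")
    layers.append(Dropout(0.0, rng))  # rate set from TrainingConfig at train time
    layers.append(Flatten())
    n_in = in_ch * size * size
    for w in cfg.scaled_fc_widths():
        layers += [Dense(n_in, w, rng), ReLU()]
        n_in = w
    layers.append(Dense(n_in, cfg.n_classes, rng))
    return Network(layers, cfg, rng)


# ---------------------------------------------------------------------------
# Functional forms of the lateral operator (used by analysis and tests)
# ---------------------------------------------------------------------------

def _kernel_conv(h: np.ndarray, K: np.ndarray) -> np.ndarray:
    """(K * h)(g, y, x) = sum_f sum_ij K(i, j, f, g) h(f, y - i, x - j).

    Zero padding at the borders; ``h`` has shape (n, H, W) and ``K`` shape
    (S, S, n, n).
    """
    W = np.ascontiguousarray(K[::-1, ::-1].transpose(3, 2, 0, 1))
    return nnet._conv_same(h[None].astype(np.float64, copy=False), W.astype(np.float64))[0]


def lateral_update(h: np.ndarray, K: np.ndarray) -> np.ndarray:
    """One lateral propagation step: h~ = (h + K * h) / 2.

    Averages the feedforward activation with the activation propagated
    through the connectivity kernel.  Linear in ``h``.
    """
    h = np.asarray(h, dtype=float)
    K = np.asarray(K, dtype=float)
    if h.ndim != 3 or K.ndim != 4 or K.shape[2] != h.shape[0] or K.shape[2] != K.shape[3]:
        raise ValueError(
            f"shape mismatch: h {h.shape} vs K {K.shape} (need h (n,H,W), K (S,S,n,n))"
        )
    return 0.5 * (h + _kernel_conv(h, K))


def self_replicate(K: np.ndarray) -> np.ndarray:
    """Long-range kernel from one extra diffusion step: 2K + K * K.

    Two applications of the lateral update compose, by linearity, into a
    single step driven by this kernel on the enlarged spatial support
    (4r + 1 per side); the kernel-kernel convolution contracts the shared
    filter index:

        (h + K*h)/2 applied twice  =  (h + (2K + K*K) * h) / 4.

    With zero padding the equivalence is exact on the interior of the
    activation map (further than r from the border); nearer the edge the
    two-step form truncates diffusion paths whose intermediate position
    falls outside the map.
    """
    K = np.asarray(K, dtype=float)
    S, _, n, _ = K.shape
    S2 = 2 * S - 1
    Kf = np.fft.rfft2(K, s=(S2, S2), axes=(0, 1))
    KKf = np.einsum("xyfm,xymg->xyfg", Kf, Kf)
    KK = np.fft.irfft2(KKf, s=(S2, S2), axes=(0, 1))
    out = KK
    pad = (S - 1) // 2
    out[pad : pad + S, pad : pad + S] += 2.0 * K
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _iterate_batches(n: int, batch: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    for i in range(0, n, batch):
        yield idx[i : i + batch]


def _accuracy(net: Network, X: np.ndarray, y: np.ndarray, batch: int = 256) -> float:
    net.set_mode(False)
    correct = 0
    for i in range(0, len(X), batch):
        logits = net.forward(X[i : i + batch])
        correct += int(np.sum(np.argmax(logits, axis=1) == y[i : i + batch]))
    return correct / len(X)


def evaluate(net: Network, dataset) -> float:
    """Top-1 accuracy of the network on a (X, y) dataset."""
    X, y = _as_arrays(dataset)
    if len(X) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    return _accuracy(net, X, y)


def _as_arrays(dataset) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(dataset, tuple):
        X, y = dataset
    else:
        X, y = dataset.images, dataset.labels
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 3:
        X = X[:, None]
    return X, np.asarray(y, dtype=np.int64)


def _run_phase(
    net: Network,
    Xtr, ytr, Xva, yva,
    cfg: TrainingConfig,
    max_epochs: int,
    rng: np.random.Generator,
    history: dict,
    phase: str,
) -> None:
    opt = SGD(net.params(), cfg.lr, cfg.momentum, cfg.weight_decay)
    best_acc, best_state, since_best = -1.0, None, 0
    for epoch in range(max_epochs):
        net.set_mode(True)
        for bidx in _iterate_batches(len(Xtr), cfg.batch_size, rng):
            opt.zero_grad()
            logits = net.forward(Xtr[bidx])
            loss, dlogits = softmax_cross_entropy(logits, ytr[bidx])
            net.backward(dlogits)
            opt.step()
        tr_acc = _accuracy(net, Xtr, ytr)
        va_acc = _accuracy(net, Xva, yva)
        history["phase"].append(phase)
        history["train_acc"].append(tr_acc)
        history["val_acc"].append(va_acc)
        history["psi0"].append(net.psi0)
        if va_acc > best_acc:
            best_acc = va_acc
            since_best = 0
            if cfg.restore_best:
                best_state = net.state()
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    if cfg.restore_best and best_state is not None:
        net.load_state(best_state)


def train(net: Network, dataset, cfg: TrainingConfig) -> dict:
    """Two-phase training of the network on a labeled grayscale dataset.

    Phase 1 trains every weight with the lateral step disabled (the update
    is skipped entirely, ``h~ = h``).  Phase 2 initializes the connectivity
    kernel randomly, enables the lateral step with dropout on the kernel
    entries, and re-trains all weights jointly.  Both phases early-stop on
    validation accuracy and restore the best weights seen.

    Returns a history dict with per-epoch ``phase``, ``train_acc``,
    ``val_acc`` and snapshots of the prefilter ``psi0``.
    """
    X, y = _as_arrays(dataset)
    if len(X) == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(cfg.seed)
    n_val = max(1, int(round(len(X) * cfg.val_fraction)))
    if n_val >= len(X):
        raise ValueError("validation split leaves no training data")
    perm = rng.permutation(len(X))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr, Xva, yva = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]

    # wire the configured dropout rates into the layers
    for l in net.layers:
        if isinstance(l, Dropout):
            l.rate = cfg.dropout_final
            l.rng = rng
        if isinstance(l, LateralMix):
            l.drop_rate = cfg.dropout_lateral
            l.rng = rng

    history: dict = {"phase": [], "train_acc": [], "val_acc": [], "psi0": []}

    lateral = net.lateral
    if cfg.phase in ("both", "pretrain_feedforward"):
        if lateral is not None:
            lateral.enabled = False
        _run_phase(
            net, Xtr, ytr, Xva, yva, cfg, cfg.max_epochs, rng, history,
            "pretrain_feedforward",
        )
    if lateral is not None and cfg.phase in ("both", "joint_with_lateral"):
        lateral.init_random(rng)
        lateral.enabled = True
        _run_phase(
            net, Xtr, ytr, Xva, yva, cfg, cfg.max_epochs, rng, history,
            "joint_with_lateral",
        )
    return history


# ---------------------------------------------------------------------------
# Weight bundles
# ---------------------------------------------------------------------------

def save_bundle(path: str | Path, net: Network, meta: dict | None = None) -> None:
    """Save the analyzable weights as a compressed array container + JSON sidecar."""
    path = Path(path)
    entries: dict[str, np.ndarray] = {"l1_filters": net.l1_filters}
    if net.psi0 is not None:
        entries["psi0"] = net.psi0
    if net.K1 is not None:
        entries["K1"] = net.K1
    np.savez_compressed(path, **entries)
    sidecar = {
        "shapes": {k: list(v.shape) for k, v in entries.items()},
        "config": {
            "l0_size": net.cfg.l0_size,
            "lateral_size": net.cfg.lateral_size,
            "use_l0": net.cfg.use_l0,
            "use_lateral": net.cfg.use_lateral,
            "unit_fraction": net.cfg.unit_fraction,
        },
        **(meta or {}),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_bundle(path: str | Path) -> dict:
    """Load a weight bundle saved by :func:`save_bundle` (or hand-assembled)."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path) as z:
        bundle = {k: z[k].astype(float) for k in z.files}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        bundle["meta"] = json.loads(sidecar.read_text())
    return bundle
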