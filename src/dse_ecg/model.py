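"""DSE-ResNet: residual CNN with a detached squeeze-and-excitation module.

The trunk is 10 residual blocks (1 block-1 + 9 block-2), each holding two
Conv2D layers with kernel (32, 1) — 20 trunk convolutions in all. The first
four convolutions carry 12 kernels, the last four 192, doubling every four
layers (channel schedule 12→24→48→96→192, two blocks per stage). Each
block-2 halves the time axis (nine halvings: 8192 → 16); shortcut
connections use (2, 1) max pooling for the temporal adjustment and
zero-padding for channel growth. The lead axis is never downsampled, so
inter-lead structure is available to every layer.

The detached SE module sits outside all blocks: a 2D global average pool
squeezes the trunk output to a 192-vector, four dense layers (bottleneck
192/r) re-excite it through a sigmoid gate, and the gate rescales the trunk
output channel-wise. The gated features are then averaged over time only and
flattened lead-by-lead — the head's weights are lead-specific, so the
network is sensitive to which lead occupies which column — concatenated
with the age/sex auxiliary scalars, and classified by a two-layer softmax
head over the 9 rhythm classes. Training minimizes mean softmax
cross-entropy.

`DseResNetClassifier` wraps the network as an sklearn-style estimator.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .nn import (
    SGD,
    BatchNorm,
    ChannelPad,
    Conv2dTime,
    Dense,
    Dropout,
    GlobalAvgPool,
    MaxPoolTime,
    ReLU,
    Sequential,
    Sigmoid,
    softmax,
    softmax_cross_entropy,
)
from .nn.layers import DTYPE, Layer, Parameter
from .records import CLASSES, N_LEADS


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The default reproduces the full-size network; tests use reduced
    configurations (shorter input, narrower channel schedule) with the same
    wiring.
    """

    input_len: int = 8192
    n_leads: int = N_LEADS
    n_classes: int = 9
    kernel: int = 32
    channels: tuple[int, ...] = (12, 24, 48, 96, 192)
    blocks_per_stage: int = 2
    dropout: float = 0.5
    use_age_sex: bool = True
    dse_reduction: int = 4
    dse_n_dense: int = 4
    head_width: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        for a, b in zip(self.channels, self.channels[1:]):
            if b != 2 * a:
                raise ValueError(
                    f"channel schedule must double stage-to-stage, got {self.channels}"
                )
        if self.n_blocks < 1:
            raise ValueError("need at least one residual block")
        down = self.downsample_factor
        if self.input_len % down:
            raise ValueError(
                f"input length {self.input_len} must be divisible by the "
                f"cumulative downsampling factor {down}"
            )
        if self.dse_n_dense < 2:
            raise ValueError("the SE stack needs at least 2 dense layers")

    @property
    def n_blocks(self) -> int:
        return len(self.channels) * self.blocks_per_stage

    @property
    def downsample_factor(self) -> int:
        # every block after the first halves the time axis
        return 2 ** (self.n_blocks - 1)


@dataclass
class ArchitectureDescription:
    """Inspectable summary of a built network, for structural verification."""

    layers: list[dict] = field(default_factory=list)
    total_conv2d: int = 0
    kernel: tuple[int, int] = (32, 1)
    residual_blocks: int = 0
    block1_count: int = 0
    block2_count: int = 0
    channel_schedule: tuple[int, ...] = ()
    dse_dense_layers: int = 0
    aux_inputs: bool = False
    output_dim: int = 0
    downsample_factor: int = 1
    n_parameters: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureDescription":
        d = json.loads(text)
        d["kernel"] = tuple(d["kernel"])
        d["channel_schedule"] = tuple(d["channel_schedule"])
        return cls(**d)


class ResidualBlock(Layer):
    """Two Conv→BatchNorm→ReLU→Dropout stacks plus a shortcut.

    Block-1 keeps dimensions (identity shortcut beyond any channel pad);
    block-2 halves time (stride-2 first conv; (2,1) max-pool shortcut).
    """

    def __init__(
        self, k: int, c_in: int, c_out: int, downsample: bool,
        dropout: float, rng: np.random.Generator, drop_rng: np.random.Generator,
        name: str,
    ):
        stride = 2 if downsample else 1
        self.branch = Sequential([
            Conv2dTime(k, c_in, c_out, stride=stride, rng=rng, name=f"{name}.conv1"),
            BatchNorm(c_out, name=f"{name}.bn1"),
            ReLU(),
            Dropout(dropout, drop_rng),
            Conv2dTime(k, c_out, c_out, stride=1, rng=rng, name=f"{name}.conv2"),
            BatchNorm(c_out, name=f"{name}.bn2"),
            ReLU(),
            Dropout(dropout, drop_rng),
        ])
        shortcut: list[Layer] = []
        if downsample:
            shortcut.append(MaxPoolTime(2))
        if c_in != c_out:
            shortcut.append(ChannelPad(c_in, c_out))
        self.shortcut = Sequential(shortcut)
        self.downsample = downsample

    def parameters(self) -> list[Parameter]:
        return self.branch.parameters()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.branch.forward(x, training) + self.shortcut.forward(x, training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.branch.backward(dy) + self.shortcut.backward(dy)


class DseModule(Layer):
    """Detached squeeze-and-excitation over the trunk output.

    Squeeze: global average pool over (time, lead) → channel vector.
    Excite: `n_dense` dense layers (ReLU bottlenecks of width c/r, sigmoid
    output of width c). The gate rescales the trunk output channel-wise.
    """

    def __init__(self, c: int, reduction: int, n_dense: int,
                 rng: np.random.Generator, name: str = "dse"):
        hidden = max(1, c // reduction)
        widths = [hidden] * (n_dense - 1) + [c]
        layers: list[Layer] = []
        prev = c
        for i, width in enumerate(widths):
            layers.append(Dense(prev, width, rng=rng, name=f"{name}.fc{i + 1}"))
            layers.append(Sigmoid() if i == n_dense - 1 else ReLU())
            prev = width
        self.gap = GlobalAvgPool()
        self.stack = Sequential(layers)
        self.n_dense = n_dense

    def parameters(self) -> list[Parameter]:
        return self.stack.parameters()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        squeezed = self.gap.forward(x, training)
        gate = self.stack.forward(squeezed, training)
        self._x, self._gate = x, gate
        return (x * gate[:, None, None, :]).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._gate[:, None, None, :]
        dgate = (dy * self._x).sum(axis=(1, 2))
        dsqueezed = self.stack.backward(dgate.astype(DTYPE))
        return (dx + self.gap.backward(dsqueezed)).astype(DTYPE)


class TimeAvgFlatten(Layer):
    """Average over time, flatten (lead, channel): (n,t,w,c) → (n, w·c).

    Pooling over time only keeps lead identity alive into the head, whose
    weights are therefore lead-specific — the network is NOT invariant to
    permutations of the lead columns.
    """

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        n, t, w, c = x.shape
        return x.mean(axis=1).reshape(n, w * c)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, t, w, c = self._shape
        dx = dy.reshape(n, 1, w, c) / t
        return np.broadcast_to(dx, self._shape).astype(DTYPE)


class DseResNet:
    """The assembled network: trunk blocks → DSE → time-pooled lead-wise
    features with auxiliary age/sex scalars → 9-way logits."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        drop_rng = np.random.default_rng(config.seed + 1)
        self.blocks: list[ResidualBlock] = []
        c_in = 1
        idx = 0
        for c_out in config.channels:
            for _ in range(config.blocks_per_stage):
                self.blocks.append(
                    ResidualBlock(
                        config.kernel, c_in, c_out,
                        downsample=idx > 0, dropout=config.dropout,
                        rng=rng, drop_rng=drop_rng, name=f"block{idx + 1}",
                    )
                )
                c_in = c_out
                idx += 1
        c_top = config.channels[-1]
        self.dse = DseModule(c_top, config.dse_reduction, config.dse_n_dense, rng)
        self.pool = TimeAvgFlatten()
        n_aux = 2 if config.use_age_sex else 0
        self.head = Sequential([
            Dense(config.n_leads * c_top + n_aux, config.head_width,
                  rng=rng, name="head.fc1"),
            ReLU(),
            Dense(config.head_width, config.n_classes, rng=rng, name="head.fc2"),
        ])
        self._n_aux = n_aux

    # -- plumbing ----------------------------------------------------------
    def _batchnorms(self) -> list[BatchNorm]:
        return [
            layer
            for block in self.blocks
            for layer in block.branch.layers
            if isinstance(layer, BatchNorm)
        ]

    def state(self) -> list[np.ndarray]:
        """Copy of all learnable values plus batchnorm running statistics."""
        out = [p.value.copy() for p in self.parameters()]
        for bn in self._batchnorms():
            out.extend([bn.running_mean.copy(), bn.running_var.copy()])
        return out

    def load_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, saved in zip(params, state):
            p.value[...] = saved
        rest = state[len(params):]
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean[...] = rest[2 * i]
            bn.running_var[...] = rest[2 * i + 1]

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for block in self.blocks:
            params.extend(block.parameters())
        params.extend(self.dse.parameters())
        params.extend(self.head.parameters())
        return params

    def _dropouts(self) -> list[Dropout]:
        return [
            layer
            for block in self.blocks
            for layer in block.branch.layers
            if isinstance(layer, Dropout)
        ]

    def recalibrate_batchnorm(
        self, x: np.ndarray, aux: np.ndarray | None = None, batch_size: int = 256
    ) -> None:
        """Re-estimate batchnorm running statistics with frozen weights.

        Mini-batch statistics drift during training; replacing the
        exponential averages with the arithmetic mean of batch statistics
        over the data (dropout disabled) aligns eval-mode behaviour with
        the trained network.
        """
        dropouts = self._dropouts()
        rates = [d.rate for d in dropouts]
        bns = self._batchnorms()
        for d in dropouts:
            d.rate = 0.0
        try:
            for i, start in enumerate(range(0, x.shape[0], batch_size)):
                for bn in bns:
                    bn.momentum = i / (i + 1)
                sl = slice(start, start + batch_size)
                self.forward_logits(
                    x[sl], None if aux is None else aux[sl], training=True
                )
        finally:
            for d, r in zip(dropouts, rates):
                d.rate = r
            for bn in bns:
                bn.momentum = 0.9

    def forward_logits(
        self, x: np.ndarray, aux: np.ndarray | None = None, training: bool = False
    ) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim != 4 or x.shape[1] != self.config.input_len or x.shape[2:] != (
            self.config.n_leads, 1,
        ):
            raise ValueError(
                f"expected input of shape (batch, {self.config.input_len}, "
                f"{self.config.n_leads}, 1), got {x.shape}"
            )
        h = x
        for block in self.blocks:
            h = block.forward(h, training)
        h = self.dse.forward(h, training)
        pooled = self.pool.forward(h, training)
        if self._n_aux:
            if aux is None:
                aux = np.full((x.shape[0], 2), 0.5, dtype=DTYPE)
            z = np.concatenate([pooled, np.asarray(aux, dtype=DTYPE)], axis=1)
        else:
            z = pooled
        return self.head.forward(z, training)

    def backward(self, dlogits: np.ndarray) -> None:
        dz = self.head.backward(dlogits)
        dpooled = dz[:, : dz.shape[1] - self._n_aux] if self._n_aux else dz
        dh = self.pool.backward(dpooled)
        dh = self.dse.backward(dh)
        for block in reversed(self.blocks):
            dh = block.backward(dh)


# ---------------------------------------------------------------------------
# Module-level operations
# ---------------------------------------------------------------------------

def build(config: ModelConfig = ModelConfig()) -> tuple[DseResNet, ArchitectureDescription]:
    """Build the network and its structural description."""
    net = DseResNet(config)
    return net, describe(net)


def describe(net: DseResNet) -> ArchitectureDescription:
    config = net.config
    layers = []
    for i, block in enumerate(net.blocks):
        kind = "residual-block-1" if not block.downsample else "residual-block-2"
        convs = [l for l in block.branch.layers if isinstance(l, Conv2dTime)]
        for conv in convs:
            layers.append({
                "kind": "conv2d", "block": i + 1, "block_kind": kind,
                "kernel": [conv.k, 1], "channels_in": conv.c_in,
                "channels_out": conv.c_out, "temporal_stride": conv.stride,
            })
        layers.append({
            "kind": "shortcut", "block": i + 1,
            "pooling": "maxpool(2,1)" if block.downsample else "identity",
        })
    layers.append({"kind": "dse", "dense_layers": net.dse.n_dense,
                   "channels": config.channels[-1]})
    layers.append({"kind": "time-average-flatten",
                   "features": config.n_leads * config.channels[-1]})
    if config.use_age_sex:
        layers.append({"kind": "aux-concat", "inputs": ["age", "sex"]})
    layers.append({"kind": "dense-head", "output_dim": config.n_classes})
    return ArchitectureDescription(
        layers=layers,
        total_conv2d=sum(1 for l in layers if l["kind"] == "conv2d"),
        kernel=(config.kernel, 1),
        residual_blocks=len(net.blocks),
        block1_count=sum(1 for b in net.blocks if not b.downsample),
        block2_count=sum(1 for b in net.blocks if b.downsample),
        channel_schedule=config.channels,
        dse_dense_layers=net.dse.n_dense,
        aux_inputs=config.use_age_sex,
        output_dim=config.n_classes,
        downsample_factor=config.downsample_factor,
        n_parameters=count_parameters(net),
    )


def count_parameters(net: DseResNet) -> int:
    return int(sum(p.value.size for p in net.parameters()))


def forward(
    net: DseResNet, x: np.ndarray, aux: np.ndarray | None = None
) -> np.ndarray:
    """Class probabilities for a batch (eval mode); rows sum to 1."""
    return softmax(net.forward_logits(x, aux, training=False).astype(np.float64))


# ---------------------------------------------------------------------------
# Sklearn-style estimator
# ---------------------------------------------------------------------------

def encode_aux(
    ages: np.ndarray, sexes: np.ndarray, age_mean: float | None = None
) -> tuple[np.ndarray, float]:
    """Encode age/sex covariates for the network.

    Age is divided by 100 (unitless); missing ages take the training-set
    mean. Sex is 0 (female) / 1 (male); missing is 0.5.
    """
    ages = np.array(
        [np.nan if a is None else float(a) for a in ages], dtype=np.float64
    )
    if age_mean is None:
        age_mean = float(np.nanmean(ages)) if np.isfinite(ages).any() else 60.0
    ages = np.where(np.isnan(ages), age_mean, ages) / 100.0
    sex_codes = np.array(
        [0.5 if s is None else (1.0 if s == "Male" else 0.0) for s in sexes]
    )
    return np.stack([ages, sex_codes], axis=1).astype(DTYPE), age_mean


class DseResNetClassifier(ClassifierMixin, BaseEstimator):
    """Sklearn-style wrapper: fit on slices, predict class probabilities.

    Parameters mirror `ModelConfig` plus the training hyperparameters tuned
    by the orthogonal experiment (learning rate, dropout, momentum).

    Attributes set by `fit` (trailing underscore): ``network_``,
    ``architecture_``, ``classes_``, ``loss_curve_``, ``val_loss_curve_``,
    ``val_acc_curve_``, ``age_mean_``, ``n_features_in_``.
    """

    def __init__(
        self,
        input_len: int = 8192,
        kernel: int = 32,
        channels: tuple[int, ...] = (12, 24, 48, 96, 192),
        blocks_per_stage: int = 2,
        dropout: float = 0.5,
        use_age_sex: bool = True,
        dse_reduction: int = 4,
        dse_n_dense: int = 4,
        head_width: int = 32,
        learning_rate: float = 0.1,
        momentum: float = 0.9,
        epochs: int = 50,
        batch_size: int = 32,
        random_state: int = 0,
        restore_best: bool = False,
    ):
        self.input_len = input_len
        self.kernel = kernel
        self.channels = channels
        self.blocks_per_stage = blocks_per_stage
        self.dropout = dropout
        self.use_age_sex = use_age_sex
        self.dse_reduction = dse_reduction
        self.dse_n_dense = dse_n_dense
        self.head_width = head_width
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state
        self.restore_best = restore_best

    # -- helpers -----------------------------------------------------------
    def _config(self, n_classes: int) -> ModelConfig:
        return ModelConfig(
            input_len=self.input_len,
            n_classes=n_classes,
            kernel=self.kernel,
            channels=tuple(self.channels),
            blocks_per_stage=self.blocks_per_stage,
            dropout=self.dropout,
            use_age_sex=self.use_age_sex,
            dse_reduction=self.dse_reduction,
            dse_n_dense=self.dse_n_dense,
            head_width=self.head_width,
            seed=self.random_state,
        )

    def _encode_y(self, y) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.classes_)}
        return np.array([lookup[v] for v in y], dtype=np.int64)

    def fit(
        self,
        X: np.ndarray,
        y,
        aux: np.ndarray | None = None,
        validation_data: tuple | None = None,
        classes: tuple[str, ...] | None = None,
    ) -> "DseResNetClassifier":
        """Train with SGD+momentum on mean softmax cross-entropy.

        `X` has shape (n, input_len, 12, 1); `aux` the encoded (age, sex)
        pairs; `validation_data` an optional (X, y, aux) triple logged per
        epoch (loss and accuracy curves).
        """
        X = np.asarray(X, dtype=DTYPE)
        if classes is not None:
            self.classes_ = np.asarray(classes)
        else:
            present = set(y)
            self.classes_ = np.array(
                [c for c in CLASSES if c in present]
                or sorted(present)
            )
        y_idx = self._encode_y(y)
        self.n_features_in_ = X.shape[1]
        net = DseResNet(self._config(len(self.classes_)))
        params = net.parameters()
        opt = SGD(params, lr=self.learning_rate, momentum=self.momentum)
        rng = np.random.default_rng(self.random_state + 7)
        n = X.shape[0]
        self.loss_curve_, self.val_loss_curve_, self.val_acc_curve_ = [], [], []
        self.network_ = net
        best_val, best_snapshot, best_epoch = np.inf, None, -1
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                opt.zero_grad()
                with np.errstate(over="ignore", invalid="ignore"):
                    logits = net.forward_logits(
                        X[idx], None if aux is None else aux[idx], training=True
                    )
                    loss, dlogits = softmax_cross_entropy(logits, y_idx[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged (loss={loss}) at epoch {_epoch}"
                    )
                with np.errstate(over="ignore", invalid="ignore"):
                    net.backward(dlogits)
                    opt.step()
                epoch_loss += loss
                n_batches += 1
            self.loss_curve_.append(epoch_loss / max(n_batches, 1))
            if validation_data is not None:
                net.recalibrate_batchnorm(X, aux)
                vl, va = self.evaluate(*validation_data)
                self.val_loss_curve_.append(vl)
                self.val_acc_curve_.append(va)
                if self.restore_best and vl < best_val:
                    best_val, best_epoch = vl, _epoch
                    best_snapshot = net.state()
        if best_snapshot is not None:
            # early stopping: no checkpoint beyond the best-validation epoch
            net.load_state(best_snapshot)
            self.best_epoch_ = best_epoch
        if validation_data is None:
            net.recalibrate_batchnorm(X, aux)
        self.architecture_ = describe(net)
        return self

    def evaluate(self, X, y, aux=None) -> tuple[float, float]:
        """(mean cross-entropy, accuracy) on a labelled set, eval mode."""
        logits = self.network_.forward_logits(
            np.asarray(X, dtype=DTYPE), aux, training=False
        )
        y_idx = self._encode_y(y)
        loss, _ = softmax_cross_entropy(logits, y_idx)
        acc = float((logits.argmax(axis=1) == y_idx).mean())
        return loss, acc

    def predict_proba(self, X, aux: np.ndarray | None = None) -> np.ndarray:
        check_is_fitted(self, "network_")
        out = []
        X = np.asarray(X, dtype=DTYPE)
        for start in range(0, X.shape[0], self.batch_size):
            sl = slice(start, start + self.batch_size)
            out.append(forward(
                self.network_, X[sl], None if aux is None else aux[sl]
            ))
        return np.concatenate(out, axis=0)

    def predict(self, X, aux: np.ndarray | None = None) -> np.ndarray:
        proba = self.predict_proba(X, aux)
        return self.classes_[proba.argmax(axis=1)]
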