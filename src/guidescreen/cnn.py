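"""Convolutional model for guide effect prediction.

The network reads the one-hot encoded 20-mer through four parallel valid
convolutions resembling an inception module — 50, 100, 70 and 40 filters
for kernels of 2, 3, 5 and 7 nt. The 2-nt group uses stride 2 and no
pooling; the other groups are followed by max-pooling of size 2. Every
group ends in dropout 0.4. The flattened, concatenated maps (2240 values
for the full variant) pass through an 80-node fully connected layer
(dropout 0.3) giving the sequence embedding. A parallel size-1 kernel with
a single filter extracts the 20-dimensional mononucleotide path. Embedding,
mononucleotide path and the functional-annotation vector are concatenated
and fed to fully connected layers of 80, 60 and 40 nodes (dropout 0.4
each) and a single output node. All hidden layers use ReLU.

Binary targets (cell fitness, nearby gene expression) train with binary
cross-entropy and predict probabilities through a sigmoid; the continuous
wild-type-count target trains with mean squared error and predicts on the
linear scale. Ablation variants drop the long-kernel groups: ``no57``
removes the 5- and 7-nt groups, ``no357`` also removes the 3-nt group.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from ._nn import Adam, Conv1d, Dense, Dropout, MaxPool1d, ReLU, bce_with_logits, mse_loss, sigmoid
from .sequence import BASES, PROTOSPACER_LENGTH

FULL_KERNEL_GROUPS = ((2, 50), (3, 100), (5, 70), (7, 40))

ABLATIONS = {
    "full": FULL_KERNEL_GROUPS,
    "no57": ((2, 50), (3, 100)),
    "no357": ((2, 50),),
}


@dataclass(frozen=True)
class CnnSpec:
    """Architecture hyperparameters; defaults mirror the published network."""

    ablation: str = "full"
    kernel2_stride: int = 2
    pool_size: int = 2
    conv_dropout: float = 0.4
    seq_fc_nodes: int = 80
    seq_fc_dropout: float = 0.3
    mono_path_filters: int = 1  # one size-1 filter -> a 20-dim mononucleotide path
    head_fc_nodes: tuple[int, ...] = (80, 60, 40)
    head_dropout: float = 0.4
    binary: bool = True

    @property
    def kernel_groups(self) -> tuple[tuple[int, int], ...]:
        try:
            return ABLATIONS[self.ablation]
        except KeyError:
            raise ValueError(f"unknown ablation {self.ablation!r}; choose from {list(ABLATIONS)}") from None


@dataclass(frozen=True)
class TrainSpec:
    """Optimization settings; per-task defaults via :meth:`for_task`."""

    learning_rate: float = 1e-4
    batch_size: int = 256
    loss: str = "bce"  # "bce" or "mse"
    max_epochs: int = 100
    patience: int = 10
    valid_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss not in ("bce", "mse"):
            raise ValueError("loss must be 'bce' or 'mse'")

    @classmethod
    def for_task(cls, task: str, **overrides) -> "TrainSpec":
        """Published per-task settings.

        fitness: lr 1e-4, batch 256, binary cross-entropy.
        wt_abundance: lr 1e-4, batch 512, mean squared error.
        expression: lr 5e-5, batch 512, binary cross-entropy.
        """
        defaults = {
            "fitness": dict(learning_rate=1e-4, batch_size=256, loss="bce"),
            "wt_abundance": dict(learning_rate=1e-4, batch_size=512, loss="mse"),
            "expression": dict(learning_rate=5e-5, batch_size=512, loss="bce"),
        }
        if task not in defaults:
            raise ValueError(f"unknown task {task!r}")
        kw = defaults[task]
        kw.update(overrides)
        return cls(**kw)


def conv_group_output_length(kernel: int, spec: CnnSpec) -> int:
    """Positions left after valid convolution (and pooling for kernels > 2)."""
    if kernel == 2:
        return Conv1d.out_length(PROTOSPACER_LENGTH, kernel, spec.kernel2_stride)
    return Conv1d.out_length(PROTOSPACER_LENGTH, kernel, 1) // spec.pool_size


def flattened_conv_dim(spec: CnnSpec) -> int:
    """Size of the flattened concatenation of all convolution groups.

    Full variant: 10*50 + 9*100 + 8*70 + 7*40 = 2240.
    """
    return sum(conv_group_output_length(k, spec) * f for k, f in spec.kernel_groups)


class CnnModel:
    """The wired network. Build with :func:`build_cnn`."""

    def __init__(self, spec: CnnSpec, n_annotations: int, seed: int = 0):
        if n_annotations < 0:
            raise ValueError("n_annotations must be >= 0")
        self.spec = spec
        self.n_annotations = n_annotations
        rng = np.random.default_rng(seed)
        c = len(BASES)

        self.conv_groups = []
        for kernel, filters in spec.kernel_groups:
            stride = spec.kernel2_stride if kernel == 2 else 1
            conv = Conv1d(c, filters, kernel, stride=stride, rng=rng)
            pool = None if kernel == 2 else MaxPool1d(spec.pool_size)
            self.conv_groups.append(
                {"conv": conv, "relu": ReLU(), "pool": pool, "drop": Dropout(spec.conv_dropout)}
            )

        flat = flattened_conv_dim(spec)
        self.seq_fc = Dense(flat, spec.seq_fc_nodes, rng=rng)
        self.seq_relu = ReLU()
        self.seq_drop = Dropout(spec.seq_fc_dropout)

        self.mono_conv = Conv1d(c, spec.mono_path_filters, 1, stride=1, rng=rng)
        self.mono_relu = ReLU()
        self.mono_dim = spec.mono_path_filters * PROTOSPACER_LENGTH

        head_in = spec.seq_fc_nodes + self.mono_dim + n_annotations
        self.head = []
        for nodes in spec.head_fc_nodes:
            self.head.append({"fc": Dense(head_in, nodes, rng=rng), "relu": ReLU(),
                              "drop": Dropout(spec.head_dropout)})
            head_in = nodes
        self.out_fc = Dense(head_in, 1, rng=rng)

    # -- parameter plumbing ------------------------------------------------
    def _layers(self):
        for g in self.conv_groups:
            yield g["conv"]
        yield self.seq_fc
        yield self.mono_conv
        for h in self.head:
            yield h["fc"]
        yield self.out_fc

    def params(self) -> list[np.ndarray]:
        return [p for layer in self._layers() for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self._layers() for g in layer.grads()]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights):
            p[...] = w

    # -- forward / backward ------------------------------------------------
    def forward(self, x_seq: np.ndarray, x_ann: np.ndarray | None = None,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Logits (binary) or raw predictions (regression), shape (N,).

        ``rng`` enables dropout (training mode); omit it for evaluation.
        """
        x_seq = np.asarray(x_seq, dtype=float)
        if x_seq.ndim != 3 or x_seq.shape[1:] != (len(BASES), PROTOSPACER_LENGTH):
            raise ValueError(f"sequence input must be (N, 4, 20), got {x_seq.shape}")
        if self.n_annotations:
            if x_ann is None:
                raise ValueError(f"model expects {self.n_annotations} annotation features")
            x_ann = np.asarray(x_ann, dtype=float)
            if x_ann.ndim != 2 or x_ann.shape[1] != self.n_annotations:
                raise ValueError(
                    f"annotation input must be (N, {self.n_annotations}), got "
                    f"{None if x_ann is None else x_ann.shape}"
                )
        n = x_seq.shape[0]

        flats = []
        self._group_shapes = []
        for g in self.conv_groups:
            h = g["conv"].forward(x_seq)
            h = g["relu"].forward(h)
            if g["pool"] is not None:
                h = g["pool"].forward(h)
            h = g["drop"].forward(h, rng)
            self._group_shapes.append(h.shape)
            flats.append(h.reshape(n, -1))
        z = np.concatenate(flats, axis=1)

        e = self.seq_drop.forward(self.seq_relu.forward(self.seq_fc.forward(z)), rng)

        m = self.mono_relu.forward(self.mono_conv.forward(x_seq)).reshape(n, -1)

        parts = [e, m] + ([x_ann] if self.n_annotations else [])
        h = np.concatenate(parts, axis=1)
        self._head_in_dim = h.shape[1]
        for layer in self.head:
            h = layer["drop"].forward(layer["relu"].forward(layer["fc"].forward(h)), rng)
        return self.out_fc.forward(h)[:, 0]

    def backward(self, dout: np.ndarray, input_only: bool = False
                 ) -> tuple[np.ndarray, np.ndarray | None]:
        """Backpropagate d(loss)/d(output); returns input gradients.

        ``input_only`` skips parameter-gradient accumulation (used when only
        input attributions are needed)."""
        dh = self.out_fc.backward(dout[:, None], input_only)
        for layer in reversed(self.head):
            dh = layer["fc"].backward(layer["relu"].backward(layer["drop"].backward(dh)), input_only)
        emb = self.spec.seq_fc_nodes
        de = dh[:, :emb]
        dm = dh[:, emb : emb + self.mono_dim]
        dann = dh[:, emb + self.mono_dim :] if self.n_annotations else None

        dz = self.seq_fc.backward(self.seq_relu.backward(self.seq_drop.backward(de)), input_only)

        n = dz.shape[0]
        dx = self.mono_conv.backward(
            self.mono_relu.backward(dm.reshape(n, -1, self.spec.mono_path_filters)), input_only)

        offset = 0
        for g, shape in zip(self.conv_groups, self._group_shapes):
            size = shape[1] * shape[2]
            dgroup = dz[:, offset : offset + size].reshape(shape)
            offset += size
            dgroup = g["drop"].backward(dgroup)
            if g["pool"] is not None:
                dgroup = g["pool"].backward(dgroup)
            dx += g["conv"].backward(g["relu"].backward(dgroup), input_only)
        return dx, dann

    def input_gradient(self, x_seq: np.ndarray, x_ann: np.ndarray | None = None
                       ) -> tuple[np.ndarray, np.ndarray | None]:
        """Per-instance gradient of the linear output w.r.t. both inputs (eval mode)."""
        out = self.forward(x_seq, x_ann, rng=None)
        return self.backward(np.ones_like(out), input_only=True)

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint weights together with an architecture manifest."""
        manifest = json.dumps({"spec": asdict(self.spec), "n_annotations": self.n_annotations})
        arrays = {f"w{i}": w for i, w in enumerate(self.get_weights())}
        np.savez(path, manifest=np.array(manifest), **arrays)

    @classmethod
    def load(cls, path) -> "CnnModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["manifest"]))
        meta["spec"]["head_fc_nodes"] = tuple(meta["spec"]["head_fc_nodes"])
        model = cls(CnnSpec(**meta["spec"]), meta["n_annotations"])
        model.set_weights([data[f"w{i}"] for i in range(len(model.params()))])
        return model


def build_cnn(spec: CnnSpec, n_annotations: int, seed: int = 0) -> CnnModel:
    """Construct and initialize the network for a given annotation width.

    ``n_annotations = 0`` yields the sequence-only ablation."""
    return CnnModel(spec, n_annotations, seed=seed)


def train_cnn(
    model: CnnModel,
    train_data: tuple[np.ndarray, np.ndarray | None, np.ndarray],
    valid_data: tuple[np.ndarray, np.ndarray | None, np.ndarray] | None,
    spec: TrainSpec,
) -> pd.DataFrame:
    """Train in place with Adam and early stopping on validation loss.

    ``train_data`` / ``valid_data`` are ``(one_hot, annotations_or_None,
    targets)`` triples. The best-validation-loss weights are restored at the
    end. Fully reproducible for a fixed ``spec.seed``. Returns the per-epoch
    loss history as a DataFrame (columns epoch, train_loss, valid_loss).
    """
    x_seq, x_ann, y = train_data
    y = np.asarray(y, dtype=float)
    if len(y) == 0:
        raise ValueError("training set is empty")
    if spec.loss == "bce" and len(np.unique(y)) < 2:
        raise ValueError("binary training set contains a single class")
    loss_fn = bce_with_logits if spec.loss == "bce" else mse_loss

    rng = np.random.default_rng(spec.seed)
    optimizer = Adam(model.params(), lr=spec.learning_rate)
    n = len(y)
    history = []
    best_loss, best_weights, best_epoch = np.inf, model.get_weights(), -1

    def eval_loss(data):
        xs, xa, yy = data
        losses, total = 0.0, 0
        for lo in range(0, len(yy), 4096):
            hi = min(lo + 4096, len(yy))
            out = model.forward(xs[lo:hi], None if xa is None else xa[lo:hi], rng=None)
            l, _ = loss_fn(out, np.asarray(yy[lo:hi], dtype=float))
            losses += l * (hi - lo)
            total += hi - lo
        return losses / total

    for epoch in range(spec.max_epochs):
        order = rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for lo in range(0, n, spec.batch_size):
            idx = order[lo : lo + spec.batch_size]
            out = model.forward(x_seq[idx], None if x_ann is None else x_ann[idx], rng=rng)
            loss, dout = loss_fn(out, y[idx])
            model.backward(dout)
            optimizer.step(model.grads())
            epoch_loss += loss * len(idx)
            seen += len(idx)
        train_loss = epoch_loss / seen
        valid_loss = eval_loss(valid_data) if valid_data is not None else np.nan
        history.append((epoch, train_loss, valid_loss))

        monitor = valid_loss if valid_data is not None else train_loss
        if monitor < best_loss - 1e-9:
            best_loss, best_weights, best_epoch = monitor, model.get_weights(), epoch
        elif epoch - best_epoch >= spec.patience:
            break
    model.set_weights(best_weights)
    return pd.DataFrame(history, columns=["epoch", "train_loss", "valid_loss"])


def train_cnn_restarts(
    spec_fn,
    train_data: tuple[np.ndarray, np.ndarray | None, np.ndarray],
    valid_data: tuple[np.ndarray, np.ndarray | None, np.ndarray],
    train_spec: TrainSpec,
    restarts: int = 3,
) -> tuple[CnnModel, pd.DataFrame]:
    """Train with multiple restarts and keep the best validation loss.

    Adam on this loss surface occasionally stalls on the initial plateau
    (especially for motif-detection tasks); restarting from different
    initializations and selecting on validation loss — never on test
    metrics — makes the outcome robust. ``spec_fn(seed) -> CnnModel``
    builds a fresh model; restart r uses seed ``train_spec.seed + 1000*r``
    for both initialization and the optimizer.

    Returns the selected model and its training history.
    """
    best = None
    for r in range(restarts):
        seed = train_spec.seed + 1000 * r
        from dataclasses import replace
        spec_r = replace(train_spec, seed=seed)
        model = spec_fn(seed)
        history = train_cnn(model, train_data, valid_data, spec_r)
        vloss = history["valid_loss"].min()
        if best is None or vloss < best[0]:
            best = (vloss, model, history)
    return best[1], best[2]


def predict(model: CnnModel, x_seq: np.ndarray, x_ann: np.ndarray | None = None) -> np.ndarray:
    """Scores in input order: probabilities for binary models, raw values otherwise."""
    if len(x_seq) == 0:
        return np.empty(0)
    outs = []
    for lo in range(0, len(x_seq), 4096):
        hi = min(lo + 4096, len(x_seq))
        out = model.forward(x_seq[lo:hi], None if x_ann is None else x_ann[lo:hi], rng=None)
        outs.append(out)
    out = np.concatenate(outs)
    return sigmoid(out) if model.spec.binary else out
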