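"""The strain-regression CNN: architecture, training regime, model object.

The network maps a 3 x 201 encoded rotational-velocity image to a single
non-negative strain scalar.  Architecture (valid, i.e. un-padded,
convolutions throughout):

====================  ==============  ===========  ==================
layer                 kernel          stride       output (H x W x C)
====================  ==============  ===========  ==================
conv-1 (32 filters)   3 x 10          1 x 2        1 x 96 x 32
conv-2 (32 filters)   1 x 10          1 x 2        1 x 44 x 32
conv-3 (32 filters)   1 x 5           1 x 1        1 x 40 x 32
flatten + dropout     rate 0.2                     1280
dense                                              64
dense (output)                                     1
====================  ==============  ===========  ==================

ReLU activations are used throughout, including on the output: strains are
non-negative, so a rectified output head is a natural inductive bias.
Training minimises mean squared error with Adam (initial learning rate
1e-6), batch size 64, at most 250 epochs, with validation-based early
stopping that restores the best-validation weights.

The user-facing surface follows the model/results idiom: build a
:class:`StrainCNN` from encoded inputs and labels, call :meth:`StrainCNN.fit`
and receive a :class:`StrainCNNResults` carrying the trained weights, the
loss history and diagnostics.
"""

from __future__ import annotations

import enum
import json
import math
import pathlib
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .encode import N_TIME


class StrainMeasure(str, enum.Enum):
    """The three regional strain measures, each at the 95th percentile.

    MPS_WB_95 : maximum principal strain, whole brain
    MPS_CC_95 : maximum principal strain, corpus callosum
    FS_CC_95  : fiber strain (stretch along white-matter tracts), corpus callosum
    """

    MPS_WB_95 = "MPS_WB_95"
    MPS_CC_95 = "MPS_CC_95"
    FS_CC_95 = "FS_CC_95"


@dataclass(frozen=True)
class CNNSpec:
    """Architecture hyperparameters.

    ``conv_layers`` entries are (n_filters, (kernel_h, kernel_w),
    (stride_h, stride_w)); convolutions are valid (no padding).  The first
    kernel spans all three input rows, collapsing the component axis, so
    later kernels have height 1.  ``fc_sizes`` ends with the width-1
    regression head.
    """

    conv_layers: tuple = (
        (32, (3, 10), (1, 2)),
        (32, (1, 10), (1, 2)),
        (32, (1, 5), (1, 1)),
    )
    dropout_rate: float = 0.2
    fc_sizes: tuple = (64, 1)
    init_gain: float = 1.0
    first_fc_init_scale: float = 7e-6
    hidden_bias_init: float = 0.5

    def __post_init__(self) -> None:
        if self.init_gain <= 0:
            raise ValueError("init_gain must be positive")
        if self.first_fc_init_scale <= 0:
            raise ValueError("first_fc_init_scale must be positive")
        for nf, (kh, kw), (sh, sw) in self.conv_layers:
            if min(nf, kh, kw, sh, sw) < 1:
                raise ValueError("conv kernel/stride dims must be positive")
        if not self.fc_sizes or self.fc_sizes[-1] != 1:
            raise ValueError("final fully connected layer must have width 1")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation hyperparameters."""

    epochs: int = 250
    learning_rate: float = 1e-6
    batch_size: int = 64
    validation_fraction: float = 0.1
    patience: int = 25
    head_init_scale: float = 120.0
    standardize_labels: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")


def feature_map_shapes(spec: CNNSpec,
                       input_shape: tuple[int, int] = (3, N_TIME)) -> list[tuple[int, int, int]]:
    """(height, width, channels) after each convolution, by valid-conv
    arithmetic ``floor((d - k) / s) + 1`` applied per dimension."""
    h, w = input_shape
    c = 1
    shapes = []
    for nf, (kh, kw), (sh, sw) in spec.conv_layers:
        if kh > h or kw > w:
            raise ValueError(
                f"kernel {kh}x{kw} exceeds feature map {h}x{w}")
        h = (h - kh) // sh + 1
        w = (w - kw) // sw + 1
        c = nf
        shapes.append((h, w, c))
    return shapes


def flattened_width(spec: CNNSpec,
                    input_shape: tuple[int, int] = (3, N_TIME)) -> int:
    h, w, c = feature_map_shapes(spec, input_shape)[-1]
    return h * w * c


def build(spec: CNNSpec, rng: np.random.Generator,
          input_shape: tuple[int, int] = (3, N_TIME)) -> nn.Sequential:
    """Instantiate the network with freshly initialised weights.

    The 3 x W image with a full-height first kernel is realised as a 1-D
    convolution treating the three velocity components as input channels;
    this is exactly equivalent and keeps the arithmetic fast.  Kernels that
    do not collapse the height axis on the first layer are rejected.
    """
    shapes = feature_map_shapes(spec, input_shape)
    for i, (h, _, _) in enumerate(shapes):
        if h != 1:
            raise ValueError(
                f"conv layer {i + 1} leaves feature-map height {h}; the "
                "first kernel must span the full component axis")
    layers: list[nn.Layer] = []
    in_ch = input_shape[0]
    for nf, (_, kw), (_, sw) in spec.conv_layers:
        layers += [nn.Conv1D(in_ch, nf, kw, sw, rng, gain=spec.init_gain),
                   nn.ReLU()]
        in_ch = nf
    layers.append(nn.Flatten())
    layers.append(nn.Dropout(spec.dropout_rate))
    d_in = flattened_width(spec, input_shape)
    for i, d_out in enumerate(spec.fc_sizes):
        is_hidden = i < len(spec.fc_sizes) - 1
        gain = spec.init_gain if is_hidden else 1.0
        dense = nn.Dense(d_in, d_out, rng, gain=gain)
        if is_hidden:
            # Feature-learning initialisation for the tiny-learning-rate
            # regime: hidden fully connected weights start near zero (so the
            # initial network function is almost flat and nothing has to be
            # "unlearned"), while the hidden biases start well inside the
            # active region of the ReLU so that no unit can be trapped dead
            # by the bounded per-weight movement of the optimiser.
            dense.params["W"] = (dense.params["W"] *
                                 spec.first_fc_init_scale).astype(nn.DTYPE)
            dense.params["b"][:] = nn.DTYPE(spec.hidden_bias_init)
        layers += [dense, nn.ReLU()]
        d_in = d_out
    return nn.Sequential(layers)


def predict(net: nn.Sequential, inputs: np.ndarray) -> np.ndarray:
    """Deterministic inference (dropout disabled); returns (M,) non-negative."""
    x = np.asarray(inputs, dtype=nn.DTYPE)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3 or x.shape[1:] != (3, N_TIME):
        raise ValueError(
            f"expected inputs of shape (M, 3, {N_TIME}), got {x.shape}")
    return net.forward(x, train=False).ravel().astype(float)


def train(net: nn.Sequential, inputs: np.ndarray, labels: np.ndarray,
          config: TrainingConfig) -> dict:
    """Train in place; returns the history dict.

    A ``validation_fraction`` split (taken after a seeded shuffle) drives
    early stopping: training halts once the validation loss has not improved
    for ``patience`` epochs, and the best-validation weights are restored.

    Initialisation is designed for the very small learning rate, which caps
    the total distance any weight can move during training at roughly
    ``learning_rate * n_steps``:

    * labels are standardised to unit scale internally (the inverse scale is
      folded back into the head weights afterwards, which is exact because
      ``relu(z)/c == relu(z/c)`` for positive ``c``);
    * the head weights are scaled up by ``head_init_scale`` so that the
      gradient signal reaching the hidden layers is strong from the first
      step — in this regime the hidden fully connected layer, whose weights
      start near zero (see :func:`build`), performs nearly all the learning;
    * the head bias is centred so the rectified output starts active at the
      training-label mean.  A mis-centred head can otherwise start with a
      negative pre-activation for every sample, where the output ReLU blocks
      all gradients and the small learning rate cannot recover.
    """
    x = np.asarray(inputs, dtype=nn.DTYPE)
    y = np.asarray(labels, dtype=nn.DTYPE).ravel()
    if x.shape[0] != y.shape[0]:
        raise ValueError("inputs and labels disagree in length")
    rng = np.random.default_rng(config.seed)
    n = x.shape[0]
    order = rng.permutation(n)
    n_val = max(1, int(round(config.validation_fraction * n)))
    val_idx, train_idx = order[:n_val], order[n_val:]
    xt, yt = x[train_idx], y[train_idx]
    xv, yv = x[val_idx], y[val_idx]

    y_scale = 1.0
    if config.standardize_labels:
        spread = float(yt.std())
        if spread > 0:
            y_scale = spread
    yt = (yt / y_scale).astype(nn.DTYPE)
    yv = (yv / y_scale).astype(nn.DTYPE)

    head = [l for l in net.layers if isinstance(l, nn.Dense)][-1]
    head.params["W"] = (head.params["W"] * config.head_init_scale).astype(nn.DTYPE)
    z0 = xt
    for layer in net.layers[:-1]:  # up to the head's pre-activation
        z0 = layer.forward(z0, False, None)
    head.params["b"] += np.asarray(yt.mean() - z0.mean(), dtype=nn.DTYPE)

    opt = nn.Adam(net, lr=config.learning_rate)
    history = {"train_loss": [], "val_loss": []}
    # The untrained (centred) network is a legitimate restore candidate:
    # epochs that fail to beat it are not restored.  It does not take part
    # in the patience count, which compares epochs among themselves.
    best_val = nn.mse(net.forward(xv, train=False).ravel(), yv)
    history["init_val_loss"] = best_val
    best_weights = net.get_weights()
    best_epoch = -1
    best_epoch_val = math.inf
    since_best = 0
    for epoch in range(config.epochs):
        perm = rng.permutation(len(xt))
        epoch_loss = 0.0
        for start in range(0, len(xt), config.batch_size):
            idx = perm[start:start + config.batch_size]
            xb, yb = xt[idx], yt[idx]
            pred = net.forward(xb, train=True, rng=rng).ravel()
            resid = pred - yb
            loss = float(np.mean(resid ** 2))
            if not math.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            epoch_loss += loss * len(idx)
            net.backward((2.0 * resid / len(idx)).astype(nn.DTYPE)[:, None])
            opt.step()
        val_pred = net.forward(xv, train=False).ravel()
        if np.all(val_pred == 0) and float(yt.mean()) > 0:
            # The rectified output has collapsed to zero for every sample
            # (possible when a batch of near-identical residuals makes all
            # hidden-weight gradients coherent and the first optimiser steps
            # overshoot).  The gradient is then identically zero and the
            # state is absorbing, so re-centre the head bias on the labels.
            z = xt
            for layer in net.layers[:-1]:
                z = layer.forward(z, False, None)
            head.params["b"] += np.asarray(yt.mean() - z.mean(),
                                           dtype=nn.DTYPE)
            val_pred = net.forward(xv, train=False).ravel()
        val_loss = nn.mse(val_pred, yv)
        history["train_loss"].append(epoch_loss / len(xt))
        history["val_loss"].append(val_loss)
        if val_loss < best_epoch_val:
            best_epoch_val, since_best = val_loss, 0
            if val_loss < best_val:
                best_val, best_epoch = val_loss, epoch
                best_weights = net.get_weights()
        else:
            since_best += 1
            if since_best > config.patience:
                break
    net.set_weights(best_weights)
    if y_scale != 1.0:
        # Fold the label scale back into the head so the network predicts in
        # raw strain units; exact because relu(z) * c == relu(z * c), c > 0.
        head.params["W"] = (head.params["W"] * y_scale).astype(nn.DTYPE)
        head.params["b"] = (head.params["b"] * y_scale).astype(nn.DTYPE)
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = best_val
    history["label_scale"] = y_scale
    return history


class StrainCNN:
    """Surrogate strain-regression model over encoded impacts.

    Parameters
    ----------
    inputs : ndarray, shape (N, 3, 201)
        Encoded rotational-velocity images.
    labels : ndarray, shape (N,)
        Strain scalars for one measure.
    measure : StrainMeasure, optional
        Which strain measure the labels describe (metadata only; one model
        is trained per measure).
    spec, config : CNNSpec, TrainingConfig
        Architecture and optimisation hyperparameters.
    """

    def __init__(self, inputs: np.ndarray, labels: np.ndarray,
                 measure: StrainMeasure | None = None,
                 spec: CNNSpec | None = None,
                 config: TrainingConfig | None = None) -> None:
        self.inputs = np.asarray(inputs, dtype=float)
        self.labels = np.asarray(labels, dtype=float).ravel()
        if self.inputs.ndim != 3 or self.inputs.shape[1:] != (3, N_TIME):
            raise ValueError(
                f"inputs must be (N, 3, {N_TIME}), got {self.inputs.shape}")
        if len(self.labels) != len(self.inputs):
            raise ValueError("inputs and labels disagree in length")
        if np.any(self.labels < 0):
            raise ValueError("strain labels must be non-negative")
        self.measure = StrainMeasure(measure) if measure is not None else None
        self.spec = spec or CNNSpec()
        self.config = config or TrainingConfig()

    @classmethod
    def from_encoded_file(cls, path, measure: StrainMeasure,
                          **kwargs) -> "StrainCNN":
        """Build from an HDF5 container written by the encoding module."""
        from .encode import load_encoded
        inputs, labels, _, measures = load_encoded(path)
        col = measures.index(StrainMeasure(measure).value)
        return cls(inputs, labels[:, col], measure=measure, **kwargs)

    def fit(self, seed: int | None = None) -> "StrainCNNResults":
        """Train the network and return a results object.

        ``seed`` overrides the config seed for weight initialisation,
        shuffling and dropout.
        """
        cfg = self.config
        if seed is not None:
            cfg = TrainingConfig(**{**asdict(cfg), "seed": int(seed)})
        rng = np.random.default_rng(cfg.seed)
        net = build(self.spec, rng)
        history = train(net, self.inputs, self.labels, cfg)
        return StrainCNNResults(self, net, history, cfg)


class StrainCNNResults:
    """Fit results: trained weights, loss history and diagnostics."""

    def __init__(self, model: StrainCNN, net: nn.Sequential,
                 history: dict, config: TrainingConfig) -> None:
        self.model = model
        self.net = net
        self.history = history
        self.config = config

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        """Strain predictions (non-negative, dropout disabled)."""
        return predict(self.net, inputs)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.inputs)

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters()

    def rsquared(self, inputs=None, labels=None) -> float:
        from .evaluation import r_squared
        if inputs is None:
            inputs, labels = self.model.inputs, self.model.labels
        return r_squared(self.predict(inputs), labels)

    def rmse(self, inputs=None, labels=None) -> float:
        from .evaluation import rmse
        if inputs is None:
            inputs, labels = self.model.inputs, self.model.labels
        return rmse(self.predict(inputs), labels)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        meas = self.model.measure.value if self.model.measure else "unspecified"
        lines = [
            "Strain-regression CNN fit",
            "=" * 45,
            f"{'strain measure':<28}{meas}",
            f"{'training samples':<28}{len(self.model.labels)}",
            f"{'parameters':<28}{self.n_parameters}",
            f"{'epochs run':<28}{len(self.history['train_loss'])}",
            f"{'best epoch (validation)':<28}{self.history['best_epoch']}",
            f"{'best validation MSE':<28}{self.history['best_val_loss']:.3e}",
            f"{'training R^2':<28}{self.rsquared():.4f}",
            f"{'training RMSE':<28}{self.rmse():.4f}",
            "=" * 45,
        ]
        return "\n".join(lines)

    def save(self, directory) -> None:
        """Persist weights plus a JSON manifest (spec, config, measure)."""
        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        weights = self.net.get_weights()
        np.savez(d / "weights.npz",
                 **{f"w{i}": w for i, w in enumerate(weights)})
        manifest = {
            "measure": self.model.measure.value if self.model.measure else None,
            "spec": asdict(self.model.spec),
            "config": asdict(self.config),
            "n_parameters": self.n_parameters,
            "history": {k: v for k, v in self.history.items()},
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @staticmethod
    def load_network(directory) -> tuple[nn.Sequential, dict]:
        """Rebuild a saved network; returns (net, manifest)."""
        d = pathlib.Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        spec_d = manifest["spec"]
        spec = CNNSpec(
            conv_layers=tuple((nf, tuple(k), tuple(s))
                              for nf, k, s in spec_d["conv_layers"]),
            dropout_rate=spec_d["dropout_rate"],
            fc_sizes=tuple(spec_d["fc_sizes"]),
            init_gain=spec_d.get("init_gain", 1.0),
            first_fc_init_scale=spec_d.get("first_fc_init_scale", 7e-6),
            hidden_bias_init=spec_d.get("hidden_bias_init", 0.5))
        net = build(spec, np.random.default_rng(0))
        data = np.load(d / "weights.npz")
        net.set_weights([data[f"w{i}"] for i in range(len(data.files))])
        return net, manifest
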