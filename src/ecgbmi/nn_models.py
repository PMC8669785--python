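"""Conv / GRU / attention networks for BMI estimation from STFT tensors.

Two architectures share one topology: per-window convolution blocks (one
block for model 1, three for model 2) applied to each STFT window's
frequency x lead image, a GRU over the window axis, additive attention
pooling of the GRU states, concatenation of the pooled state with the 36
band-power features (a residual-style shortcut past the recurrent stack),
and a final fully connected layer. Heads: softmax over 2 or 3 classes, or
a single linear unit for continuous BMI or VAT estimation.

Training uses Adam, class-weighted cross-entropy (weights proportional to
inverse class frequency in the training folds) for classification and mean
squared error for regression. Inputs are standardized per feature with
statistics computed on the training folds only; spectral power and band
power are log1p-transformed first, because adiposity scales amplitude
multiplicatively. A simple logistic-regression baseline on the 12 per-lead
maximum absolute amplitudes is provided for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._autograd import Adam, Tensor, concat, conv3x3, maxpool2x2, time_slice
from .ecg_preprocessing import AVERAGED_BEAT, FULL_TRACE

__all__ = [
    "ModelConfig",
    "NNModel",
    "build_model",
    "train",
    "predict",
    "baseline_max_abs_logistic",
    "binary_labels",
    "three_class_labels",
    "inverse_frequency_weights",
]

_TASK_OUT = {"binary": 2, "three_class": 3, "regression_bmi": 1, "regression_vat": 1}


def binary_labels(bmi: np.ndarray) -> np.ndarray:
    """0 = normal weight (BMI < 25), 1 = overweight/obese (BMI >= 25)."""
    return (np.asarray(bmi) >= 25.0).astype(int)


def three_class_labels(bmi: np.ndarray) -> np.ndarray:
    """0: BMI < 25; 1: 25 <= BMI < 30; 2: BMI >= 30."""
    bmi = np.asarray(bmi)
    return np.where(bmi >= 30.0, 2, np.where(bmi >= 25.0, 1, 0))


def inverse_frequency_weights(y: np.ndarray, n_classes: int) -> np.ndarray:
    """Class weights proportional to inverse training-class frequency.

    Normalized so the average weight over training samples is 1 (e.g. a
    75%/25% split yields a 1:3 weight ratio).
    """
    counts = np.bincount(y, minlength=n_classes)
    if np.any(counts == 0):
        raise ValueError(f"class(es) {np.where(counts == 0)[0].tolist()} absent from training data")
    w = len(y) / (n_classes * counts)
    return w / np.average(w, weights=counts)


@dataclass
class ModelConfig:
    architecture: str = "model1"  # "model1" | "model2"
    task: str = "binary"  # binary | three_class | regression_bmi | regression_vat
    input_form: str = FULL_TRACE
    batch_size: int = 50
    n_epochs: int = 100
    learning_rate: float = 0.005
    seed: int = 0
    conv_filters: tuple = ()  # () -> architecture default
    gru_hidden: int = 64
    attention_dim: int = 32

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.n_epochs < 1 or self.batch_size < 1:
            raise ValueError("n_epochs and batch_size must be >= 1")
        if self.architecture not in ("model1", "model2"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.task not in _TASK_OUT:
            raise ValueError(f"unknown task {self.task!r}")
        if not self.conv_filters:
            self.conv_filters = (16,) if self.architecture == "model1" else (16, 32, 32)

    @property
    def tensor_shape(self) -> tuple:
        return (100, 50, 12) if self.input_form == FULL_TRACE else (100, 10, 12)


class NNModel:
    """A (possibly trained) network: parameters, config and normalizer."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.normalizer: dict | None = None  # fitted on training folds only
        self.validation_accuracy: float | None = None
        self.validation_rmse: float | None = None
        self.final_training_loss: float | None = None
        self.params: dict[str, Tensor] = {}
        self._init_params()

    # -- construction -----------------------------------------------------
    def _glorot(self, rng, fan_in, fan_out, shape):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return Tensor(rng.uniform(-lim, lim, size=shape), requires_grad=True)

    def _init_params(self):
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        _, nf, nc = cfg.tensor_shape
        p = self.params
        cin, h, w = 1, nf, nc
        for i, cout in enumerate(cfg.conv_filters):
            p[f"conv{i}_w"] = self._glorot(rng, 9 * cin, cout, (3, 3, cin, cout))
            p[f"conv{i}_b"] = Tensor(np.zeros(cout), requires_grad=True)
            h, w, cin = h // 2, w // 2, cout
        if h < 1 or w < 1:
            raise ValueError("too many conv blocks for this input_form: feature map vanished")
        self._conv_out = (h, w, cin)
        d = h * w * cin
        hid = cfg.gru_hidden
        for gate in ("z", "r", "n"):
            p[f"W{gate}"] = self._glorot(rng, d, hid, (d, hid))
            p[f"U{gate}"] = self._glorot(rng, hid, hid, (hid, hid))
            p[f"b{gate}"] = Tensor(np.zeros(hid), requires_grad=True)
        p["att_W"] = self._glorot(rng, hid, cfg.attention_dim, (hid, cfg.attention_dim))
        p["att_b"] = Tensor(np.zeros(cfg.attention_dim), requires_grad=True)
        p["att_v"] = self._glorot(rng, cfg.attention_dim, 1, (cfg.attention_dim, 1))
        out_dim = _TASK_OUT[cfg.task]
        p["fc_W"] = self._glorot(rng, hid + 36, out_dim, (hid + 36, out_dim))
        p["fc_b"] = Tensor(np.zeros(out_dim), requires_grad=True)

    @property
    def n_parameters(self) -> int:
        return sum(t.data.size for t in self.params.values())

    # -- forward ----------------------------------------------------------
    def forward(self, x: np.ndarray, bp: np.ndarray, return_attention: bool = False):
        """Map normalized inputs (B,T,F,C) and (B,36) to head outputs (B,K)."""
        cfg = self.config
        if x.shape[1:] != cfg.tensor_shape:
            raise ValueError(
                f"input_form {cfg.input_form!r} expects tensors of shape "
                f"{cfg.tensor_shape}, got {x.shape[1:]}"
            )
        p = self.params
        b, t_len, nf, nc = x.shape
        h = Tensor(x.reshape(b * t_len, nf, nc, 1))
        for i in range(len(cfg.conv_filters)):
            h = maxpool2x2(conv3x3(h, p[f"conv{i}_w"], p[f"conv{i}_b"]).relu())
        d = int(np.prod(self._conv_out))
        seq = h.reshape(b, t_len, d)

        hid = cfg.gru_hidden
        h_t = Tensor(np.zeros((b, hid)))
        states = []
        for t in range(t_len):
            xt = time_slice(seq, t)
            z = (xt @ p["Wz"] + h_t @ p["Uz"] + p["bz"]).sigmoid()
            r = (xt @ p["Wr"] + h_t @ p["Ur"] + p["br"]).sigmoid()
            n = (xt @ p["Wn"] + (r * h_t) @ p["Un"] + p["bn"]).tanh()
            h_t = (1.0 - z) * n + z * h_t
            states.append(h_t)

        # additive attention over windows, normalized with a max shift
        scores = [(s @ p["att_W"] + p["att_b"]).tanh() @ p["att_v"] for s in states]
        m = np.max([s.data for s in scores], axis=0)  # constant shift
        expd = [(s - m).exp() for s in scores]
        total = expd[0]
        for e in expd[1:]:
            total = total + e
        alphas = [e / total for e in expd]
        pooled = alphas[0] * states[0]
        for a, s in zip(alphas[1:], states[1:]):
            pooled = pooled + a * s

        out = concat([pooled, Tensor(bp)], axis=1) @ p["fc_W"] + p["fc_b"]
        if return_attention:
            return out, np.concatenate([a.data for a in alphas], axis=1)
        return out

    def predict_proba(self, x: np.ndarray, bp: np.ndarray) -> np.ndarray:
        logits = self.forward(x, bp).data
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    # -- normalization ----------------------------------------------------
    def fit_normalizer(self, x: np.ndarray, bp: np.ndarray, y: np.ndarray | None = None):
        lx, lbp = np.log1p(np.maximum(x, 0)), np.log1p(np.maximum(bp, 0))
        norm = {
            "x_mean": lx.mean(axis=(0, 1)),
            "x_sd": np.maximum(lx.std(axis=(0, 1)), 1e-8),
            "bp_mean": lbp.mean(axis=0),
            "bp_sd": np.maximum(lbp.std(axis=0), 1e-8),
        }
        if y is not None and self.config.task.startswith("regression"):
            norm["y_mean"] = float(np.mean(y))
            norm["y_sd"] = float(max(np.std(y), 1e-8))
        self.normalizer = norm

    def normalize(self, x: np.ndarray, bp: np.ndarray):
        if self.normalizer is None:
            raise ValueError("model has no fitted normalizer; train it first")
        n = self.normalizer
        return (
            (np.log1p(np.maximum(x, 0)) - n["x_mean"]) / n["x_sd"],
            (np.log1p(np.maximum(bp, 0)) - n["bp_mean"]) / n["bp_sd"],
        )


def build_model(config: ModelConfig) -> NNModel:
    """Instantiate an untrained network for `config`."""
    return NNModel(config)


def _classification_loss(logits: Tensor, y: np.ndarray, sample_w: np.ndarray) -> Tensor:
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(y)), y] = 1.0
    m = logits.data.max(axis=1, keepdims=True)  # constant shift
    logz = ((logits - m).exp().sum(axis=1, keepdims=True)).log() + m
    logp = (logits * onehot).sum(axis=1, keepdims=True) - logz
    w = sample_w[:, None]
    return -(logp * w).sum() * (1.0 / w.sum())


def train(
    model: NNModel,
    x: np.ndarray,
    bp: np.ndarray,
    y: np.ndarray,
    class_weights: np.ndarray | None = None,
    validation: tuple | None = None,
) -> NNModel:
    """Train in place and return the model.

    `x` is the raw (N, T, F, C) power tensor stack, `bp` the raw (N, 36)
    band powers, `y` integer class labels or continuous targets. The
    normalizer is fitted here, on this training data only. `validation`,
    if given, is an (x, bp, y) triple used only to record validation
    accuracy (classification) or RMSE (regression). Deterministic given
    `model.config.seed`.
    """
    cfg = model.config
    is_clf = not cfg.task.startswith("regression")
    y = np.asarray(y)
    if is_clf:
        y = y.astype(int)
        if class_weights is None:
            class_weights = inverse_frequency_weights(y, _TASK_OUT[cfg.task])
        sample_w = np.asarray(class_weights)[y]
    model.fit_normalizer(x, bp, y)
    xn, bpn = model.normalize(x, bp)
    if not is_clf:
        yz = (y - model.normalizer["y_mean"]) / model.normalizer["y_sd"]

    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(list(model.params.values()), lr=cfg.learning_rate)
    n = len(y)
    for _ in range(cfg.n_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            out = model.forward(xn[idx], bpn[idx])
            if is_clf:
                loss = _classification_loss(out, y[idx], sample_w[idx])
            else:
                err = out.reshape(len(idx)) - Tensor(yz[idx])
                loss = (err * err).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
    model.final_training_loss = float(loss.data)

    if validation is not None:
        table = predict(model, validation[0], validation[1])
        yv = np.asarray(validation[2])
        if is_clf:
            model.validation_accuracy = float(np.mean(table["pred_class"].to_numpy() == yv))
        else:
            est = table["estimate"].to_numpy()
            model.validation_rmse = float(np.sqrt(np.mean((est - yv) ** 2)))
    return model


def predict(
    model: NNModel,
    x: np.ndarray,
    bp: np.ndarray,
    subject_ids=None,
    ablate_band_power: bool = False,
    chunk: int = 256,
) -> pd.DataFrame:
    """Per-subject predictions as a table.

    Classification rows carry `prob` (probability of the positive class
    for the binary task, max-class probability for 3 classes) and
    `pred_class` (binary threshold 0.5, equivalently argmax; argmax for 3
    classes). Regression rows carry `estimate` in the target's units.
    `ablate_band_power` zeroes the normalized band-power shortcut inputs
    at inference (for shortcut-usefulness analyses).
    """
    cfg = model.config
    xn, bpn = model.normalize(x, bp)
    if ablate_band_power:
        bpn = np.zeros_like(bpn)
    rows = []
    for start in range(0, len(xn), chunk):
        xs, bs = xn[start : start + chunk], bpn[start : start + chunk]
        if cfg.task.startswith("regression"):
            out = model.forward(xs, bs).data[:, 0]
            est = out * model.normalizer["y_sd"] + model.normalizer["y_mean"]
            rows.append(pd.DataFrame({"estimate": est}))
        else:
            proba = model.predict_proba(xs, bs)
            if cfg.task == "binary":
                p1 = proba[:, 1]
                rows.append(pd.DataFrame({"prob": p1, "pred_class": (p1 >= 0.5).astype(int)}))
            else:
                rows.append(
                    pd.DataFrame(
                        {"prob": proba.max(axis=1), "pred_class": proba.argmax(axis=1)}
                    )
                )
    table = pd.concat(rows, ignore_index=True)
    if subject_ids is not None:
        table.insert(0, "subject_id", np.asarray(subject_ids))
    return table


def save_model(model: NNModel, path) -> None:
    """Checkpoint parameters, config and normalizer to one .npz archive."""
    import dataclasses
    import json

    payload = {f"param_{k}": v.data for k, v in model.params.items()}
    payload["config_json"] = np.array(json.dumps(dataclasses.asdict(model.config)))
    if model.normalizer is not None:
        for k, v in model.normalizer.items():
            payload[f"norm_{k}"] = np.asarray(v)
    np.savez(path, **payload)


def load_model(path) -> NNModel:
    import json

    with np.load(path, allow_pickle=False) as data:
        cfg_raw = json.loads(str(data["config_json"]))
        cfg_raw["conv_filters"] = tuple(cfg_raw["conv_filters"])
        model = NNModel(ModelConfig(**cfg_raw))
        for k in model.params:
            model.params[k].data = data[f"param_{k}"]
        norm = {
            k[len("norm_") :]: data[k] for k in data.files if k.startswith("norm_")
        }
        if norm:
            model.normalizer = {
                k: (float(v) if v.ndim == 0 else v) for k, v in norm.items()
            }
    return model


def max_abs_amplitudes(signals: np.ndarray) -> np.ndarray:
    """Per-lead maximum absolute amplitude features, (N, 12)."""
    return np.max(np.abs(signals), axis=2)


def baseline_max_abs_logistic(
    train_signals: np.ndarray,
    train_labels: np.ndarray,
    test_signals: np.ndarray,
    test_labels: np.ndarray,
) -> float:
    """Logistic regression on the 12 per-lead max absolute amplitudes.

    The simple amplitude-only comparator for the networks. Signals are
    (N, 12, L) raw traces in mV. Returns held-out accuracy. Perfect
    separation is flagged and refitted with an ordinary L2 penalty.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.preprocessing import StandardScaler

    y_tr = np.asarray(train_labels).astype(int)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("baseline needs at least 2 classes in the training data")
    scaler = StandardScaler().fit(max_abs_amplitudes(train_signals))
    f_tr = scaler.transform(max_abs_amplitudes(train_signals))
    f_te = scaler.transform(max_abs_amplitudes(test_signals))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf = LogisticRegression(C=1e6, max_iter=5000).fit(f_tr, y_tr)
    if np.max(np.abs(clf.coef_)) > 50.0:  # (near-)separation: unbounded MLE
        warnings.warn("perfect separation detected; refitting with L2 penalty", stacklevel=2)
        clf = LogisticRegression(C=1.0, max_iter=5000).fit(f_tr, y_tr)
    return float(clf.score(f_te, np.asarray(test_labels).astype(int)))
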