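"""LSTM sequence classifier in pure NumPy.

Implements the gated recurrence

    i_t = sigmoid(W_i x_t + b_ii + R_i h_{t-1} + b_hi)
    f_t = sigmoid(W_f x_t + b_if + R_f h_{t-1} + b_hf)
    z_t =     act(W_z x_t + b_ig + R_z h_{t-1} + b_hg)   act: sigmoid | tanh
    o_t = sigmoid(W_o x_t + b_io + R_o h_{t-1} + b_ho)
    c_t = f_t * c_{t-1} + i_t * z_t
    h_t = o_t * tanh(c_t)

with a sigmoid readout on the final hidden state, orthogonal recurrent /
xavier input initialization, zero biases except a forget-gate bias of 1,
Adam training with class-weighted cross-entropy and validation-loss early
stopping, and subject-level cross-validated grid search.

The cell-input activation defaults to sigmoid (see ``Hyperparams``); the
classical tanh variant is available via ``cell_input_activation="tanh"``.

Backpropagation is written out by hand (backpropagation-through-time) and
also yields gradients with respect to the *input* sequence, which the
attribution module reuses.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .preprocess import WindowedDataset

__all__ = [
    "LSTMParams",
    "LSTMState",
    "Hyperparams",
    "TrainedClassifier",
    "init_params",
    "lstm_step",
    "forward",
    "input_gradients",
    "loss_and_grads",
    "train",
    "save_classifier",
    "load_classifier",
    "grid_search_cv",
    "subject_level_folds",
    "subject_level_split",
]

GATES = ("i", "f", "z", "o")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class LSTMParams:
    """All weight matrices, bias vectors, and the sigmoid readout."""

    W: dict[str, np.ndarray]  # gate -> (hidden, input)
    R: dict[str, np.ndarray]  # gate -> (hidden, hidden)
    b_input: dict[str, np.ndarray]  # gate -> (hidden,)  [b_ii, b_if, b_ig, b_io]
    b_hidden: dict[str, np.ndarray]  # gate -> (hidden,)  [b_hi, b_hf, b_hg, b_ho]
    readout_w: np.ndarray  # (hidden,)
    readout_b: float
    cell_input_activation: str = "sigmoid"

    @property
    def hidden_size(self) -> int:
        return self.W["i"].shape[0]

    @property
    def input_size(self) -> int:
        return self.W["i"].shape[1]

    def copy(self) -> "LSTMParams":
        return LSTMParams(
            {g: self.W[g].copy() for g in GATES},
            {g: self.R[g].copy() for g in GATES},
            {g: self.b_input[g].copy() for g in GATES},
            {g: self.b_hidden[g].copy() for g in GATES},
            self.readout_w.copy(),
            float(self.readout_b),
            self.cell_input_activation,
        )

    def flat_arrays(self) -> list[tuple[str, np.ndarray]]:
        """Named views of every parameter array (readout_b as a 0-d array)."""
        out = []
        for g in GATES:
            out.append((f"W_{g}", self.W[g]))
            out.append((f"R_{g}", self.R[g]))
            out.append((f"b_input_{g}", self.b_input[g]))
            out.append((f"b_hidden_{g}", self.b_hidden[g]))
        out.append(("readout_w", self.readout_w))
        return out

    def n_parameters(self) -> int:
        return sum(a.size for _, a in self.flat_arrays()) + 1


@dataclass(frozen=True)
class LSTMState:
    """Per-step gate activations, memory cell and hidden state."""

    i_t: np.ndarray
    f_t: np.ndarray
    z_t: np.ndarray
    o_t: np.ndarray
    c_t: np.ndarray
    h_t: np.ndarray


def _orthogonal(n: int, rng: np.random.Generator) -> np.ndarray:
    a = rng.normal(size=(n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


def _xavier(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    fan_out, fan_in = shape
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_params(
    input_size: int,
    hidden_size: int,
    rng_seed: int | np.random.Generator = 0,
    cell_input_activation: str = "sigmoid",
) -> LSTMParams:
    """Fresh parameters: orthogonal R, xavier W, zero biases, forget bias 1."""
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed
    if cell_input_activation not in ("sigmoid", "tanh"):
        raise ValueError("cell_input_activation must be 'sigmoid' or 'tanh'")
    W = {g: _xavier((hidden_size, input_size), rng) for g in GATES}
    R = {g: _orthogonal(hidden_size, rng) for g in GATES}
    b_input = {g: np.zeros(hidden_size) for g in GATES}
    b_hidden = {g: np.zeros(hidden_size) for g in GATES}
    b_input["f"] = np.ones(hidden_size)  # forget-gate bias 1
    readout_w = _xavier((1, hidden_size), rng)[0]
    return LSTMParams(W, R, b_input, b_hidden, readout_w, 0.0,
                      cell_input_activation)


def lstm_step(
    params: LSTMParams,
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
) -> LSTMState:
    """One recurrence step. Accepts (input,) vectors or (batch, input) arrays."""
    x_t = np.asarray(x_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    c_prev = np.asarray(c_prev, dtype=float)
    if x_t.shape[-1] != params.input_size or h_prev.shape[-1] != params.hidden_size:
        raise ValueError(
            f"dimension mismatch: x {x_t.shape}, h {h_prev.shape}, "
            f"expected input={params.input_size}, hidden={params.hidden_size}"
        )
    pre = {
        g: x_t @ params.W[g].T + params.b_input[g]
        + h_prev @ params.R[g].T + params.b_hidden[g]
        for g in GATES
    }
    i_t = _sigmoid(pre["i"])
    f_t = _sigmoid(pre["f"])
    z_t = np.tanh(pre["z"]) if params.cell_input_activation == "tanh" else _sigmoid(pre["z"])
    o_t = _sigmoid(pre["o"])
    c_t = f_t * c_prev + i_t * z_t
    h_t = o_t * np.tanh(c_t)
    return LSTMState(i_t, f_t, z_t, o_t, c_t, h_t)


def _forward_cached(params: LSTMParams, x: np.ndarray):
    """Unroll over time from zero state; keep per-step caches for backprop.

    x: (batch, T, input). Returns (probabilities, logits, caches).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        x = x[None]
    batch, T, _ = x.shape
    h = np.zeros((batch, params.hidden_size))
    c = np.zeros((batch, params.hidden_size))
    caches = []
    for t in range(T):
        state = lstm_step(params, x[:, t, :], h, c)
        caches.append((x[:, t, :], h, c, state))
        h, c = state.h_t, state.c_t
    logits = h @ params.readout_w + params.readout_b
    return _sigmoid(logits), logits, caches


def forward(params: LSTMParams, windows: np.ndarray,
            expected_len: int | None = 16) -> np.ndarray:
    """Class probabilities for one window (T, C) or a batch (B, T, C)."""
    windows = np.asarray(windows, dtype=float)
    single = windows.ndim == 2
    if single:
        windows = windows[None]
    if expected_len is not None and windows.shape[1] != expected_len:
        raise ValueError(
            f"window length {windows.shape[1]} != expected {expected_len}"
        )
    probs, _, _ = _forward_cached(params, windows)
    return probs[0] if single else probs


def _zero_grads(params: LSTMParams) -> dict:
    return {
        "W": {g: np.zeros_like(params.W[g]) for g in GATES},
        "R": {g: np.zeros_like(params.R[g]) for g in GATES},
        "b_input": {g: np.zeros_like(params.b_input[g]) for g in GATES},
        "b_hidden": {g: np.zeros_like(params.b_hidden[g]) for g in GATES},
        "readout_w": np.zeros_like(params.readout_w),
        "readout_b": 0.0,
    }


def _backward(params: LSTMParams, caches, dlogits: np.ndarray):
    """BPTT given d(loss)/d(logit) per sample.

    Returns (param_grads, input_grads) with input_grads of shape (B, T, C).
    """
    grads = _zero_grads(params)
    batch = dlogits.shape[0]
    T = len(caches)
    h_last = caches[-1][3].h_t
    grads["readout_w"] += dlogits @ h_last
    grads["readout_b"] += float(dlogits.sum())

    dh = dlogits[:, None] * params.readout_w[None, :]
    dc = np.zeros((batch, params.hidden_size))
    dX = np.zeros((batch, T, params.input_size))

    for t in range(T - 1, -1, -1):
        x_t, h_prev, c_prev, st = caches[t]
        tanh_c = np.tanh(st.c_t)
        do = dh * tanh_c
        dc = dc + dh * st.o_t * (1.0 - tanh_c**2)
        df = dc * c_prev
        di = dc * st.z_t
        dz = dc * st.i_t
        dc = dc * st.f_t  # becomes dc_{t-1}

        da = {
            "i": di * st.i_t * (1.0 - st.i_t),
            "f": df * st.f_t * (1.0 - st.f_t),
            "o": do * st.o_t * (1.0 - st.o_t),
        }
        if params.cell_input_activation == "tanh":
            da["z"] = dz * (1.0 - st.z_t**2)
        else:
            da["z"] = dz * st.z_t * (1.0 - st.z_t)

        dh = np.zeros_like(dh)
        for g in GATES:
            grads["W"][g] += da[g].T @ x_t
            grads["R"][g] += da[g].T @ h_prev
            s = da[g].sum(axis=0)
            grads["b_input"][g] += s
            grads["b_hidden"][g] += s
            dX[:, t, :] += da[g] @ params.W[g]
            dh += da[g] @ params.R[g]
    return grads, dX


def input_gradients(params: LSTMParams, windows: np.ndarray,
                    of: str = "logit") -> np.ndarray:
    """Gradient of the scalar output w.r.t. every input sample point.

    ``of="logit"`` differentiates the pre-sigmoid score; ``of="probability"``
    the sigmoid output. Shape matches ``windows``.
    """
    windows = np.asarray(windows, dtype=float)
    single = windows.ndim == 2
    if single:
        windows = windows[None]
    probs, _, caches = _forward_cached(params, windows)
    dlogits = np.ones(len(windows))
    if of == "probability":
        dlogits = probs * (1.0 - probs)
    elif of != "logit":
        raise ValueError("of must be 'logit' or 'probability'")
    _, dX = _backward(params, caches, dlogits)
    return dX[0] if single else dX


def loss_and_grads(
    params: LSTMParams,
    x: np.ndarray,
    y: np.ndarray,
    sample_weights: np.ndarray | None = None,
):
    """Weighted binary cross-entropy (mean) and its parameter gradients."""
    y = np.asarray(y, dtype=float)
    probs, logits, caches = _forward_cached(params, x)
    w = np.ones_like(y) if sample_weights is None else sample_weights
    # stable BCE on logits: max(l,0) - l*y + log(1 + exp(-|l|))
    per = np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits)))
    loss = float(np.mean(w * per))
    dlogits = w * (probs - y) / len(y)
    grads, _ = _backward(params, caches, dlogits)
    return loss, grads


@dataclass(frozen=True)
class Hyperparams:
    hidden_size: int = 32
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    validation_split: float = 0.2
    class_weighting: bool = True
    cell_input_activation: str = "sigmoid"
    threshold: float = 0.5

    def fingerprint(self, seed: int) -> str:
        payload = json.dumps({**dataclasses.asdict(self), "seed": seed},
                             sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class TrainedClassifier:
    params: LSTMParams
    threshold: float
    training_log: list[tuple[int, float, float]]  # (epoch, train_loss, val_loss)
    config_fingerprint: str
    hyperparams: Hyperparams

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        return forward(self.params, windows, expected_len=None)

    def predict(self, windows: np.ndarray) -> np.ndarray:
        return (self.predict_proba(windows) >= self.threshold).astype(int)


def save_classifier(clf: TrainedClassifier, path) -> None:
    """Single-file NPZ checkpoint: parameter arrays + JSON metadata blob."""
    meta = json.dumps({
        "threshold": clf.threshold,
        "config_fingerprint": clf.config_fingerprint,
        "hyperparams": dataclasses.asdict(clf.hyperparams),
        "training_log": clf.training_log,
        "cell_input_activation": clf.params.cell_input_activation,
        "readout_b": clf.params.readout_b,
    })
    arrays = {name: arr for name, arr in clf.params.flat_arrays()}
    np.savez(path, meta=np.array(meta), **arrays)


def load_classifier(path) -> TrainedClassifier:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        params = LSTMParams(
            W={g: data[f"W_{g}"] for g in GATES},
            R={g: data[f"R_{g}"] for g in GATES},
            b_input={g: data[f"b_input_{g}"] for g in GATES},
            b_hidden={g: data[f"b_hidden_{g}"] for g in GATES},
            readout_w=data["readout_w"],
            readout_b=float(meta["readout_b"]),
            cell_input_activation=meta["cell_input_activation"],
        )
    return TrainedClassifier(
        params=params,
        threshold=float(meta["threshold"]),
        training_log=[tuple(row) for row in meta["training_log"]],
        config_fingerprint=meta["config_fingerprint"],
        hyperparams=Hyperparams(**meta["hyperparams"]),
    )


class _Adam:
    def __init__(self, params: LSTMParams, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = _zero_grads(params)
        self.v = _zero_grads(params)

    def _upd(self, m, v, g):
        m *= self.b1
        m += (1 - self.b1) * g
        v *= self.b2
        v += (1 - self.b2) * g * g
        mh = m / (1 - self.b1**self.t)
        vh = v / (1 - self.b2**self.t)
        return self.lr * mh / (np.sqrt(vh) + self.eps)

    def step(self, params: LSTMParams, grads: dict) -> None:
        self.t += 1
        for key in ("W", "R", "b_input", "b_hidden"):
            for g in GATES:
                getattr(params, key)[g] -= self._upd(
                    self.m[key][g], self.v[key][g], grads[key][g])
        params.readout_w -= self._upd(self.m["readout_w"], self.v["readout_w"],
                                      grads["readout_w"])
        self.m["readout_b"] = self.b1 * self.m["readout_b"] \
            + (1 - self.b1) * grads["readout_b"]
        self.v["readout_b"] = self.b2 * self.v["readout_b"] \
            + (1 - self.b2) * grads["readout_b"] ** 2
        mh = self.m["readout_b"] / (1 - self.b1**self.t)
        vh = self.v["readout_b"] / (1 - self.b2**self.t)
        params.readout_b -= self.lr * mh / (np.sqrt(vh) + self.eps)


def train(
    dataset: WindowedDataset,
    hyperparams: Hyperparams | None = None,
    validation_split: float | None = None,
    rng_seed: int = 0,
) -> TrainedClassifier:
    """Adam on weighted BCE with validation-loss early stopping.

    The validation split is a random stratified subset of windows; early
    stopping restores the parameters of the best validation epoch.
    Deterministic given ``rng_seed``.
    """
    hp = hyperparams or Hyperparams()
    val_frac = hp.validation_split if validation_split is None else validation_split
    y = dataset.labels
    if len(np.unique(y)) < 2:
        raise ValueError("training dataset must contain both classes")
    rng = np.random.default_rng(rng_seed)

    # stratified validation split so both subsets keep both classes
    val_mask = np.zeros(len(y), dtype=bool)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(val_frac * len(idx)))) if len(idx) > 1 else 0
        val_mask[idx[:n_val]] = True
    x_tr, y_tr = dataset.windows[~val_mask], y[~val_mask]
    x_va, y_va = dataset.windows[val_mask], y[val_mask]

    if hp.class_weighting:
        n_pos = max(int(y_tr.sum()), 1)
        w_pos = (len(y_tr) - n_pos) / n_pos
    else:
        w_pos = 1.0
    weights_tr = np.where(y_tr == 1, w_pos, 1.0)
    weights_va = np.where(y_va == 1, w_pos, 1.0)

    params = init_params(dataset.n_channels, hp.hidden_size, rng,
                         hp.cell_input_activation)
    opt = _Adam(params, hp.learning_rate)

    best_val = np.inf
    best_params = params.copy()
    best_epoch = -1
    log: list[tuple[int, float, float]] = []
    for epoch in range(hp.max_epochs):
        order = rng.permutation(len(y_tr))
        epoch_loss = 0.0
        for start in range(0, len(order), hp.batch_size):
            sel = order[start : start + hp.batch_size]
            loss, grads = loss_and_grads(params, x_tr[sel], y_tr[sel],
                                         weights_tr[sel])
            if hp.learning_rate > 0:
                opt.step(params, grads)
            epoch_loss += loss * len(sel)
        epoch_loss /= len(y_tr)
        if len(y_va):
            val_loss, _ = loss_and_grads(params, x_va, y_va, weights_va)
        else:
            val_loss = epoch_loss
        log.append((epoch, float(epoch_loss), float(val_loss)))
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_params = params.copy()
            best_epoch = epoch
        elif epoch - best_epoch >= hp.patience:
            break

    return TrainedClassifier(
        params=best_params,
        threshold=hp.threshold,
        training_log=log,
        config_fingerprint=hp.fingerprint(rng_seed),
        hyperparams=hp,
    )


def subject_level_folds(
    subject_ids: np.ndarray, k_folds: int, rng_seed: int = 0
) -> list[np.ndarray]:
    """Partition unique subjects into k folds (sizes differ by at most 1)."""
    unique = np.array(sorted(set(map(str, subject_ids))))
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if k_folds > len(unique):
        raise ValueError("more folds than subjects")
    rng = np.random.default_rng(rng_seed)
    return list(np.array_split(rng.permutation(unique), k_folds))


def subject_level_split(
    subject_ids: np.ndarray, n_test: int, rng_seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test partition at the subject level."""
    unique = np.array(sorted(set(map(str, subject_ids))))
    if not 0 < n_test < len(unique):
        raise ValueError("n_test must be in (0, n_subjects)")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(unique)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def _f1_recall(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return f1, recall


def grid_search_cv(
    dataset: WindowedDataset,
    grid: list[Hyperparams],
    k_folds: int = 5,
    rng_seed: int = 0,
) -> tuple[Hyperparams, list[dict]]:
    """Pick the grid point with the best mean window-level F1 across folds.

    Folds are split at the subject level (no subject in two folds). Ties are
    broken by higher mean recall, then by smaller model (parameter count).
    Returns ``(best, results)`` with per-point fold scores in ``results``.
    """
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    folds = subject_level_folds(dataset.subject_ids, k_folds, rng_seed)
    subject_strs = dataset.subject_ids.astype(str)
    results = []
    for point_idx, hp in enumerate(grid):
        f1s, recalls = [], []
        for fold_idx, fold_subjects in enumerate(folds):
            test_mask = np.isin(subject_strs, fold_subjects)
            train_ds = dataset.subset(~test_mask)
            test_ds = dataset.subset(test_mask)
            if len(np.unique(train_ds.labels)) < 2 or len(test_ds) == 0:
                continue
            clf = train(train_ds, hp, rng_seed=rng_seed * 1000 + fold_idx)
            f1, rec = _f1_recall(test_ds.labels, clf.predict(test_ds.windows))
            f1s.append(f1)
            recalls.append(rec)
        results.append({
            "point": point_idx,
            "hyperparams": hp,
            "mean_f1": float(np.mean(f1s)) if f1s else 0.0,
            "mean_recall": float(np.mean(recalls)) if recalls else 0.0,
            "fold_f1": f1s,
        })
    n_params = [init_params(dataset.n_channels, r["hyperparams"].hidden_size,
                            0).n_parameters() for r in results]
    best = max(
        range(len(results)),
        key=lambda k: (results[k]["mean_f1"], results[k]["mean_recall"],
                       -n_params[k]),
    )
    return results[best]["hyperparams"], results
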