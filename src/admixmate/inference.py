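"""Branched fully-connected regression of mating parameters from profiles.

The network: a shared trunk of 512/256/128/64 rectified-linear layers on
the 132-value flattened profile, dropout 0.2 after the last shared layer,
then one branch per target parameter (32-unit rectified-linear hidden
layer, dropout 0.2, single sigmoid output). Five branches for the
one-pulse parameter set (AM1-3, SB1-2), eight with gene-flow rates.
251,141 trainable weights for the one-pulse spec.

Training: Adam, mean-squared-error loss on [0, 1]-scaled targets, 40
epochs, batch 64, a 0.2 validation split of the 0.8 training portion.
Implemented directly on NumPy (forward + backprop) so the package has no
deep-learning framework dependency; runs are deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .mating_model import MatingParams

__all__ = [
    "ONE_PULSE_TARGETS",
    "TWO_PULSES_TARGETS",
    "NetworkSpec",
    "TrainingConfig",
    "BranchedRegressor",
    "EnsemblePrediction",
    "Ensemble",
    "scale_targets",
    "unscale_targets",
    "scale_target_matrix",
    "unscale_target_matrix",
    "build_network",
    "train_network",
    "evaluate",
    "train_ensemble",
    "predict_with_ci",
]

ONE_PULSE_TARGETS = ("am1", "am2", "am3", "sb1", "sb2")
TWO_PULSES_TARGETS = ONE_PULSE_TARGETS + ("gfr1", "gfr2", "gfr3")

_SB_RANGE = (-1.0, 1.0)


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyper-parameters of the branched regressor."""

    input_size: int = 132
    shared_layers: tuple[int, ...] = (512, 256, 128, 64)
    branch_hidden: int = 32
    dropout: float = 0.2
    targets: tuple[str, ...] = ONE_PULSE_TARGETS

    @classmethod
    def one_pulse(cls, input_size: int = 132) -> "NetworkSpec":
        return cls(input_size=input_size, targets=ONE_PULSE_TARGETS)

    @classmethod
    def two_pulses(cls, input_size: int = 132) -> "NetworkSpec":
        return cls(input_size=input_size, targets=TWO_PULSES_TARGETS)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    def weight_count(self) -> int:
        """Trainable parameters (weight matrices plus biases)."""
        total = 0
        prev = self.input_size
        for width in self.shared_layers:
            total += prev * width + width
            prev = width
        per_branch = prev * self.branch_hidden + self.branch_hidden
        per_branch += self.branch_hidden * 1 + 1
        return total + self.n_targets * per_branch


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation regime (Adam + MSE)."""

    epochs: int = 40
    batch_size: int = 64
    validation_split: float = 0.2
    test_split: float = 0.2
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7
    seed: Optional[int] = None

    def __post_init__(self):
        for name in ("validation_split", "test_split"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Target scaling
# ---------------------------------------------------------------------------

def _scale_one(name: str, value: float) -> float:
    if name.startswith("sb"):
        lo, hi = _SB_RANGE
        if not lo - 1e-12 <= value <= hi + 1e-12:
            raise ValueError(f"{name}={value} outside natural range [{lo}, {hi}]")
        return (value - lo) / (hi - lo)
    if not -1e-12 <= value <= 1 + 1e-12:
        raise ValueError(f"{name}={value} outside [0, 1]")
    return float(value)


def _unscale_one(name: str, value: float) -> float:
    if name.startswith("sb"):
        lo, hi = _SB_RANGE
        return lo + value * (hi - lo)
    return float(value)


def scale_targets(params: MatingParams, targets: Sequence[str] = ONE_PULSE_TARGETS) -> np.ndarray:
    """Map a parameter set to the unit-interval training targets.

    AM and GFR pass through (already in [0, 1]); SB is mapped linearly
    from [-1, 1] so all parameters are weighted equally by the loss.
    """
    d = params.to_dict()
    return np.array([_scale_one(t, d[t]) for t in targets])


def unscale_targets(
    scaled: np.ndarray, targets: Sequence[str] = ONE_PULSE_TARGETS
) -> dict[str, float]:
    """Exact inverse of :func:`scale_targets`, keyed by parameter name."""
    scaled = np.asarray(scaled, dtype=float)
    return {t: _unscale_one(t, v) for t, v in zip(targets, scaled)}


def scale_target_matrix(natural: np.ndarray, targets: Sequence[str]) -> np.ndarray:
    out = np.asarray(natural, dtype=float).copy()
    for j, t in enumerate(targets):
        if t.startswith("sb"):
            lo, hi = _SB_RANGE
            out[:, j] = (out[:, j] - lo) / (hi - lo)
    return out


def unscale_target_matrix(scaled: np.ndarray, targets: Sequence[str]) -> np.ndarray:
    out = np.asarray(scaled, dtype=float).copy()
    for j, t in enumerate(targets):
        if t.startswith("sb"):
            lo, hi = _SB_RANGE
            out[:, j] = lo + out[:, j] * (hi - lo)
    return out


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class BranchedRegressor:
    """Shared-trunk multi-branch MLP with manual backprop and Adam."""

    def __init__(self, spec: NetworkSpec, rng: Optional[np.random.Generator] = None):
        rng = np.random.default_rng() if rng is None else rng
        self.spec = spec
        self.trunk: list[tuple[np.ndarray, np.ndarray]] = []
        prev = spec.input_size
        for width in spec.shared_layers:
            self.trunk.append((_glorot(rng, prev, width), np.zeros(width)))
            prev = width
        self.branches: list[list[tuple[np.ndarray, np.ndarray]]] = []
        for _ in spec.targets:
            w1 = _glorot(rng, prev, spec.branch_hidden)
            w2 = _glorot(rng, spec.branch_hidden, 1)
            self.branches.append(
                [(w1, np.zeros(spec.branch_hidden)), (w2, np.zeros(1))]
            )
        self._adam_state = None
        self._adam_t = 0

    # -- parameter bookkeeping ------------------------------------------------

    def _params(self) -> list[np.ndarray]:
        flat = []
        for w, b in self.trunk:
            flat += [w, b]
        for branch in self.branches:
            for w, b in branch:
                flat += [w, b]
        return flat

    def weight_count(self) -> int:
        return sum(p.size for p in self._params())

    # -- forward --------------------------------------------------------------

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic forward pass (dropout disabled); output (n, P)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.spec.input_size:
            raise ValueError(
                f"feature size {X.shape[1]} != network input {self.spec.input_size}"
            )
        a = X
        for w, b in self.trunk:
            a = np.maximum(a @ w + b, 0.0)
        outs = []
        for (w1, b1), (w2, b2) in self.branches:
            h = np.maximum(a @ w1 + b1, 0.0)
            outs.append(_sigmoid(h @ w2 + b2))
        return np.concatenate(outs, axis=1)

    # -- training -------------------------------------------------------------

    def _forward_train(self, X, rng, dropout):
        acts = [X]
        a = X
        for w, b in self.trunk:
            a = np.maximum(a @ w + b, 0.0)
            acts.append(a)
        keep = 1.0 - dropout
        trunk_mask = (rng.random(a.shape) < keep) / keep
        a_drop = a * trunk_mask
        branch_cache = []
        preds = np.empty((X.shape[0], len(self.branches)))
        for p, ((w1, b1), (w2, b2)) in enumerate(self.branches):
            h = np.maximum(a_drop @ w1 + b1, 0.0)
            mask = (rng.random(h.shape) < keep) / keep
            h_drop = h * mask
            y = _sigmoid(h_drop @ w2 + b2)
            preds[:, p] = y[:, 0]
            branch_cache.append((h, mask, h_drop, y))
        return acts, trunk_mask, a_drop, branch_cache, preds

    def _backward(self, X, Y, acts, trunk_mask, a_drop, branch_cache, preds):
        n, P = Y.shape
        grads_trunk = [(np.zeros_like(w), np.zeros_like(b)) for w, b in self.trunk]
        grads_branches = []
        d_adrop = np.zeros_like(a_drop)
        # total loss = sum over targets of per-target batch-mean MSE
        # (the multi-output default of common DL frameworks)
        dL = 2.0 * (preds - Y) / n
        for p, ((w1, b1), (w2, b2)) in enumerate(self.branches):
            h, mask, h_drop, y = branch_cache[p]
            dz2 = (dL[:, p : p + 1]) * y * (1.0 - y)
            gw2 = h_drop.T @ dz2
            gb2 = dz2.sum(axis=0)
            dh = (dz2 @ w2.T) * mask
            dh[h <= 0.0] = 0.0
            gw1 = a_drop.T @ dh
            gb1 = dh.sum(axis=0)
            d_adrop += dh @ w1.T
            grads_branches.append([(gw1, gb1), (gw2, gb2)])
        da = d_adrop * trunk_mask
        for layer in range(len(self.trunk) - 1, -1, -1):
            w, b = self.trunk[layer]
            a_out = acts[layer + 1]
            da[a_out <= 0.0] = 0.0
            grads_trunk[layer] = (acts[layer].T @ da, da.sum(axis=0))
            da = da @ w.T
        flat = []
        for g in grads_trunk:
            flat += [g[0], g[1]]
        for branch in grads_branches:
            for g in branch:
                flat += [g[0], g[1]]
        return flat

    def _adam_step(self, grads, cfg: TrainingConfig):
        params = self._params()
        if self._adam_state is None:
            self._adam_state = [
                (np.zeros_like(p), np.zeros_like(p)) for p in params
            ]
        self._adam_t += 1
        t = self._adam_t
        lr_t = cfg.learning_rate * np.sqrt(1 - cfg.beta2**t) / (1 - cfg.beta1**t)
        for p, g, (m, v) in zip(params, grads, self._adam_state):
            m *= cfg.beta1
            m += (1 - cfg.beta1) * g
            v *= cfg.beta2
            v += (1 - cfg.beta2) * g * g
            p -= lr_t * m / (np.sqrt(v) + cfg.eps)

    def fit(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        config: TrainingConfig,
        rng: np.random.Generator,
        X_val: Optional[np.ndarray] = None,
        Y_val: Optional[np.ndarray] = None,
    ) -> dict:
        """Mini-batch Adam training; returns per-epoch loss history."""
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.shape[1] != self.spec.input_size:
            raise ValueError(
                f"feature size {X.shape[1]} != network input {self.spec.input_size}"
            )
        history = {"loss": [], "val_loss": []}
        n = X.shape[0]
        for _epoch in range(config.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                xb, yb = X[idx], Y[idx]
                acts, tm, ad, bc, preds = self._forward_train(
                    xb, rng, self.spec.dropout
                )
                grads = self._backward(xb, yb, acts, tm, ad, bc, preds)
                self._adam_step(grads, config)
                epoch_loss += float(np.mean((preds - yb) ** 2)) * len(idx)
            history["loss"].append(epoch_loss / n)
            if X_val is not None and len(X_val):
                pv = self.predict(X_val)
                history["val_loss"].append(float(np.mean((pv - Y_val) ** 2)))
        return history

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self._params())}
        np.savez(path, **arrays)

    def load_weights(self, path) -> None:
        data = np.load(path)
        for i, p in enumerate(self._params()):
            p[...] = data[f"p{i}"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def build_network(
    spec: NetworkSpec, rng: Optional[np.random.Generator] = None
) -> tuple[BranchedRegressor, int]:
    """Instantiate the network; returns (model, trainable weight count)."""
    model = BranchedRegressor(spec, rng)
    count = model.weight_count()
    assert count == spec.weight_count()
    return model, count


def train_network(
    model: BranchedRegressor,
    features: np.ndarray,
    targets: np.ndarray,
    config: TrainingConfig,
    rng: np.random.Generator,
) -> tuple[BranchedRegressor, dict]:
    """Train with an internal validation split of the given data."""
    n = features.shape[0]
    order = rng.permutation(n)
    n_val = int(round(n * config.validation_split))
    val_idx, train_idx = order[:n_val], order[n_val:]
    history = model.fit(
        features[train_idx],
        targets[train_idx],
        config,
        rng,
        X_val=features[val_idx],
        Y_val=targets[val_idx],
    )
    return model, history


def evaluate(
    model: BranchedRegressor,
    features: np.ndarray,
    targets: np.ndarray,
    n_confusion_bins: int = 5,
) -> dict:
    """Held-out metrics on scaled targets.

    Returns per-parameter MSE and R^2 plus a true-vs-predicted confusion
    matrix over equal-width bins of [0, 1].
    """
    if len(features) == 0:
        raise ValueError("empty test set")
    preds = model.predict(features)
    targets = np.asarray(targets, dtype=float)
    mse = np.mean((preds - targets) ** 2, axis=0)
    ss_res = np.sum((preds - targets) ** 2, axis=0)
    ss_tot = np.sum((targets - targets.mean(axis=0)) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, np.nan)
    edges = np.linspace(0.0, 1.0, n_confusion_bins + 1)[1:-1]
    confusion = np.zeros(
        (len(model.spec.targets), n_confusion_bins, n_confusion_bins), dtype=int
    )
    tb = np.searchsorted(edges, targets, side="right")
    pb = np.searchsorted(edges, preds, side="right")
    for j in range(targets.shape[1]):
        np.add.at(confusion[j], (tb[:, j], pb[:, j]), 1)
    return {
        "mse": {t: float(m) for t, m in zip(model.spec.targets, mse)},
        "r2": {t: float(r) for t, r in zip(model.spec.targets, r2)},
        "confusion": confusion,
        "predictions": preds,
    }


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsemblePrediction:
    """Per-parameter mean and 95% interval on the natural scale."""

    targets: tuple[str, ...]
    mean: dict[str, float]
    lower: dict[str, float]
    upper: dict[str, float]

    def __post_init__(self):
        for t in self.targets:
            if not self.lower[t] - 1e-12 <= self.mean[t] <= self.upper[t] + 1e-12:
                raise ValueError(f"{t}: interval does not bracket the mean")


@dataclass
class Ensemble:
    """K independently trained networks sharing one spec."""

    spec: NetworkSpec
    models: list[BranchedRegressor]
    test_metrics: list[dict] = field(default_factory=list)
    normalization: str = "divided_by_total"
    windows: str = "all_windows"

    def __len__(self):
        return len(self.models)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "n_models": len(self.models),
            "targets": list(self.spec.targets),
            "input_size": self.spec.input_size,
            "shared_layers": list(self.spec.shared_layers),
            "branch_hidden": self.spec.branch_hidden,
            "dropout": self.spec.dropout,
            "normalization": self.normalization,
            "windows": self.windows,
            "test_mse": [m.get("mse") for m in self.test_metrics] or None,
        }
        (directory / "ensemble.json").write_text(json.dumps(manifest, indent=2))
        for i, model in enumerate(self.models):
            model.save(directory / f"model_{i:04d}.npz")

    @classmethod
    def load(cls, directory) -> "Ensemble":
        directory = Path(directory)
        manifest = json.loads((directory / "ensemble.json").read_text())
        spec = NetworkSpec(
            input_size=manifest["input_size"],
            shared_layers=tuple(manifest["shared_layers"]),
            branch_hidden=manifest["branch_hidden"],
            dropout=manifest["dropout"],
            targets=tuple(manifest["targets"]),
        )
        models = []
        rng = np.random.default_rng(0)
        for i in range(manifest["n_models"]):
            m = BranchedRegressor(spec, rng)
            m.load_weights(directory / f"model_{i:04d}.npz")
            models.append(m)
        return cls(
            spec,
            models,
            normalization=manifest["normalization"],
            windows=manifest["windows"],
        )


def train_ensemble(
    features: np.ndarray,
    targets: np.ndarray,
    K: int,
    config: TrainingConfig,
    rng: np.random.Generator,
    spec: Optional[NetworkSpec] = None,
    normalization: str = "divided_by_total",
    windows: str = "all_windows",
) -> Ensemble:
    """Train K networks on independent random 0.8/0.2 train/test splits."""
    if K < 2:
        raise ValueError("an ensemble needs K >= 2 networks")
    features = np.asarray(features, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if spec is None:
        spec = NetworkSpec(
            input_size=features.shape[1],
            targets=ONE_PULSE_TARGETS
            if targets.shape[1] == 5
            else TWO_PULSES_TARGETS,
        )
    n = features.shape[0]
    models, metrics = [], []
    for k in range(K):
        sub_rng = np.random.default_rng(rng.integers(2**63))
        order = sub_rng.permutation(n)
        n_test = int(round(n * config.test_split))
        test_idx, train_idx = order[:n_test], order[n_test:]
        model = BranchedRegressor(spec, sub_rng)
        train_network(model, features[train_idx], targets[train_idx], config, sub_rng)
        metrics.append(evaluate(model, features[test_idx], targets[test_idx]))
        models.append(model)
    return Ensemble(spec, models, metrics, normalization, windows)


def predict_with_ci(
    ensemble: Ensemble,
    features: np.ndarray,
    normalization: Optional[str] = None,
) -> EnsemblePrediction:
    """Mean and 2.5/97.5 percentiles across the ensemble, unscaled.

    ``normalization`` (if given) must match the mode the ensemble was
    trained with; a mismatch is an error, not a warning.
    """
    if normalization is not None and normalization != ensemble.normalization:
        raise ValueError(
            f"profile normalization {normalization!r} does not match the "
            f"ensemble's training mode {ensemble.normalization!r}"
        )
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[None, :]
    preds = np.stack([m.predict(features)[0] for m in ensemble.models])
    natural = unscale_target_matrix(preds, ensemble.spec.targets)
    mean = natural.mean(axis=0)
    lo = np.percentile(natural, 2.5, axis=0)
    hi = np.percentile(natural, 97.5, axis=0)
    t = ensemble.spec.targets
    return EnsemblePrediction(
        targets=t,
        mean={k: float(v) for k, v in zip(t, mean)},
        lower={k: float(v) for k, v in zip(t, np.minimum(lo, mean))},
        upper={k: float(v) for k, v in zip(t, np.maximum(hi, mean))},
    )
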