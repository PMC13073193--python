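"""Feed-forward risk classifier, resampling protocol and AUC inference.

The classifier is a fully connected network (67-feature input; hidden layers
of 256, 128 and 64 ReLU units with inverted dropout at rates 0.40/0.30/0.20;
a single sigmoid output) trained with binary cross-entropy by mini-batch SGD
or Adam, Glorot-uniform initialisation, and early stopping on an internal
validation split with best-weight restoration.  Class imbalance is handled by
nested control undersampling (1:1 within 1:2 within 1:3); hyperparameters are
chosen by stratified five-fold cross-validation over an optimizer x
learning-rate grid.  AUC uncertainty uses DeLong's nonparametric variance.

All stochastic steps (initialisation, dropout, batching, splits,
undersampling) consume explicit integer seeds, so every run is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.model_selection import StratifiedKFold

from .panel import FeatureMatrix, SubjectTable

# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class NetworkConfig:
    hidden_sizes: tuple[int, ...] = (256, 128, 64)
    dropout_rates: tuple[float, ...] = (0.40, 0.30, 0.20)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_sizes) != len(self.dropout_rates):
            raise ValueError("one dropout rate per hidden layer")
        if any(not 0 <= p < 1 for p in self.dropout_rates):
            raise ValueError("dropout rates must lie in [0, 1)")
        if any(b > a for a, b in zip(self.dropout_rates, self.dropout_rates[1:])):
            raise ValueError("dropout schedule must be non-increasing")


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "sgd"          # the most stable grid point
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 1000
    patience: int = 20              # early-stopping patience on validation loss
    validation_fraction: float = 0.10
    class_weighted: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.patience < 1:
            raise ValueError("batch_size and patience must be >= 1")


GRID_OPTIMIZERS = ("sgd", "adam")
GRID_LEARNING_RATES = (0.1, 0.01, 0.001)


# ---------------------------------------------------------------------------
# Network internals


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class _MLP:
    """Minimal dense network with inverted dropout; weights as numpy arrays."""

    def __init__(self, n_features: int, net: NetworkConfig):
        rng = np.random.default_rng(net.seed)
        sizes = (n_features, *net.hidden_sizes, 1)
        self.W = [_glorot_uniform(rng, a, b) for a, b in zip(sizes, sizes[1:])]
        self.b = [np.zeros(b) for b in sizes[1:]]
        self.dropout = net.dropout_rates

    def forward(
        self, X: np.ndarray, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, list]:
        """Probabilities plus the cache needed for backprop; rng enables dropout."""
        a = X
        cache = []
        n_hidden = len(self.W) - 1
        for l in range(n_hidden):
            z = a @ self.W[l] + self.b[l]
            h = np.maximum(z, 0.0)
            mask = None
            if rng is not None and self.dropout[l] > 0:
                keep = 1.0 - self.dropout[l]
                mask = (rng.random(h.shape) < keep) / keep
                h = h * mask
            cache.append((a, z, mask))
            a = h
        z_out = a @ self.W[-1] + self.b[-1]
        p = _sigmoid(z_out)[:, 0]
        cache.append((a, z_out, None))
        return p, cache

    def gradients(
        self, p: np.ndarray, y: np.ndarray, w: np.ndarray, cache: list
    ) -> tuple[list, list]:
        B = len(y)
        delta = ((p - y) * w / B)[:, np.newaxis]  # d loss / d z_out
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        a_last = cache[-1][0]
        gW[-1] = a_last.T @ delta
        gb[-1] = delta.sum(axis=0)
        da = delta @ self.W[-1].T
        for l in range(len(self.W) - 2, -1, -1):
            a_in, z, mask = cache[l]
            if mask is not None:
                da = da * mask
            dz = da * (z > 0)
            gW[l] = a_in.T @ dz
            gb[l] = dz.sum(axis=0)
            if l > 0:
                da = dz @ self.W[l].T
        return gW, gb

    def snapshot(self) -> tuple[list, list]:
        return [w.copy() for w in self.W], [b.copy() for b in self.b]

    def restore(self, snap: tuple[list, list]) -> None:
        self.W = [w.copy() for w in snap[0]]
        self.b = [b.copy() for b in snap[1]]


class _Optimizer:
    def __init__(self, mlp: _MLP, kind: str, lr: float):
        self.kind, self.lr, self.mlp = kind, lr, mlp
        if kind == "adam":
            self.t = 0
            self.mW = [np.zeros_like(w) for w in mlp.W]
            self.vW = [np.zeros_like(w) for w in mlp.W]
            self.mb = [np.zeros_like(b) for b in mlp.b]
            self.vb = [np.zeros_like(b) for b in mlp.b]

    def step(self, gW: list, gb: list) -> None:
        if self.kind == "sgd":
            for l in range(len(gW)):
                self.mlp.W[l] -= self.lr * gW[l]
                self.mlp.b[l] -= self.lr * gb[l]
            return
        b1, b2, eps = 0.9, 0.999, 1e-8
        self.t += 1
        c1 = 1 - b1**self.t
        c2 = 1 - b2**self.t
        for l in range(len(gW)):
            for g, m, v, param in (
                (gW[l], self.mW, self.vW, self.mlp.W),
                (gb[l], self.mb, self.vb, self.mlp.b),
            ):
                m[l] = b1 * m[l] + (1 - b1) * g
                v[l] = b2 * v[l] + (1 - b2) * g**2
                param[l] -= self.lr * (m[l] / c1) / (np.sqrt(v[l] / c2) + eps)


def _bce(p: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    p = np.clip(p, 1e-7, 1 - 1e-7)
    return float(-np.mean(w * (y * np.log(p) + (1 - y) * np.log(1 - p))))


def _stratified_holdout(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Indices for (train, validation), stratified by class."""
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        k = max(1, int(round(fraction * len(idx))))
        val_idx.append(idx[:k])
        train_idx.append(idx[k:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


# ---------------------------------------------------------------------------
# The fitted model


@dataclass
class RiskModel:
    """Trained classifier emitting per-subject case probabilities."""

    mlp: _MLP
    feature_names: list[str]
    net: NetworkConfig
    train_config: TrainConfig
    scale_columns: list[int] = field(default_factory=list)
    scale_mean: np.ndarray | None = None
    scale_std: np.ndarray | None = None
    history: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def _prepare(self, features: FeatureMatrix | np.ndarray) -> np.ndarray:
        X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"feature width {X.shape[-1] if X.ndim == 2 else '?'} does not match "
                f"training width {self.n_features}"
            )
        if self.scale_columns:
            X = X.copy()
            X[:, self.scale_columns] = (
                X[:, self.scale_columns] - self.scale_mean
            ) / self.scale_std
        return X

    def predict_proba(self, features: FeatureMatrix | np.ndarray) -> np.ndarray:
        X = self._prepare(features)
        p, _ = self.mlp.forward(X, rng=None)
        return np.clip(p, 1e-12, 1 - 1e-12)


def predict_proba(model: RiskModel, features: FeatureMatrix | np.ndarray) -> np.ndarray:
    return model.predict_proba(features)


def fit(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    net: NetworkConfig | None = None,
    train: TrainConfig | None = None,
) -> RiskModel:
    """Train the network with early stopping; reproducible given the config seeds.

    Entropy columns (names prefixed ``H_``) are z-scored with statistics of
    the training data; dosage/beta-weighted columns are fed raw, their scale
    being small and bounded.
    """
    net = net or NetworkConfig()
    train = train or TrainConfig()
    if isinstance(features, FeatureMatrix):
        names = list(features.feature_names)
        X = features.values
    else:
        X = np.asarray(features, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(labels, dtype=float).ravel()
    if X.ndim != 2 or len(y) != len(X):
        raise ValueError("features and labels must align")
    if np.isnan(X).any():
        raise ValueError("features contain missing values; impute first")

    scale_cols = [j for j, nm in enumerate(names) if nm.startswith("H_")]
    scale_mean = scale_std = None
    if scale_cols:
        scale_mean = X[:, scale_cols].mean(axis=0)
        scale_std = X[:, scale_cols].std(axis=0)
        scale_std = np.where(scale_std > 0, scale_std, 1.0)
        X = X.copy()
        X[:, scale_cols] = (X[:, scale_cols] - scale_mean) / scale_std

    rng = np.random.default_rng(train.seed)
    if train.validation_fraction > 0 and len(y) >= 20 and len(np.unique(y)) == 2:
        tr_idx, val_idx = _stratified_holdout(y, train.validation_fraction, rng)
    else:
        tr_idx = np.arange(len(y))
        val_idx = np.arange(len(y))  # degenerate: monitor training loss
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]

    w_tr = np.ones(len(ytr))
    w_val = np.ones(len(yval))
    if train.class_weighted:
        for arr, yy in ((w_tr, ytr), (w_val, yval)):
            for cls in (0.0, 1.0):
                m = yy == cls
                if m.any():
                    arr[m] = len(yy) / (2.0 * m.sum())

    mlp = _MLP(X.shape[1], net)
    opt = _Optimizer(mlp, train.optimizer, train.learning_rate)
    best_loss = np.inf
    best_snap = mlp.snapshot()
    best_epoch = 0
    since_best = 0
    n = len(ytr)
    val_losses: list[float] = []
    for epoch in range(train.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, train.batch_size):
            batch = order[start : start + train.batch_size]
            p, cache = mlp.forward(Xtr[batch], rng=rng)
            gW, gb = mlp.gradients(p, ytr[batch], w_tr[batch], cache)
            opt.step(gW, gb)
        p_val, _ = mlp.forward(Xval, rng=None)
        loss = _bce(p_val, yval, w_val)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite validation loss at epoch {epoch} "
                f"(optimizer={train.optimizer}, lr={train.learning_rate})"
            )
        val_losses.append(loss)
        if loss < best_loss - 1e-9:
            best_loss = loss
            best_snap = mlp.snapshot()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= train.patience:
                break
    mlp.restore(best_snap)
    return RiskModel(
        mlp=mlp,
        feature_names=names,
        net=net,
        train_config=train,
        scale_columns=scale_cols,
        scale_mean=scale_mean,
        scale_std=scale_std,
        history={
            "val_loss": val_losses,
            "best_epoch": best_epoch,
            "best_val_loss": best_loss,
            "epochs_run": len(val_losses),
        },
    )


def save_model(model: RiskModel, prefix: str | Path) -> tuple[Path, Path]:
    """Serialize a RiskModel to <prefix>.json (config) + <prefix>.npz (weights)."""
    import json

    prefix = Path(prefix)
    weights = {}
    for l, (w, b) in enumerate(zip(model.mlp.W, model.mlp.b)):
        weights[f"W{l}"] = w
        weights[f"b{l}"] = b
    if model.scale_columns:
        weights["scale_mean"] = model.scale_mean
        weights["scale_std"] = model.scale_std
    npz_path = prefix.with_suffix(".npz")
    json_path = prefix.with_suffix(".json")
    np.savez(npz_path, **weights)
    cfg = {
        "feature_names": model.feature_names,
        "hidden_sizes": list(model.net.hidden_sizes),
        "dropout_rates": list(model.net.dropout_rates),
        "net_seed": model.net.seed,
        "train": {
            "optimizer": model.train_config.optimizer,
            "learning_rate": model.train_config.learning_rate,
            "batch_size": model.train_config.batch_size,
            "max_epochs": model.train_config.max_epochs,
            "patience": model.train_config.patience,
            "seed": model.train_config.seed,
        },
        "scale_columns": model.scale_columns,
        "history": {k: v for k, v in model.history.items() if k != "val_loss"},
    }
    json_path.write_text(json.dumps(cfg, indent=2))
    return json_path, npz_path


def load_model(prefix: str | Path) -> RiskModel:
    import json

    prefix = Path(prefix)
    cfg = json.loads(prefix.with_suffix(".json").read_text())
    data = np.load(prefix.with_suffix(".npz"))
    net = NetworkConfig(
        hidden_sizes=tuple(cfg["hidden_sizes"]),
        dropout_rates=tuple(cfg["dropout_rates"]),
        seed=cfg["net_seed"],
    )
    train = TrainConfig(**cfg["train"])
    mlp = _MLP(len(cfg["feature_names"]), net)
    n_layers = len(mlp.W)
    mlp.W = [data[f"W{l}"] for l in range(n_layers)]
    mlp.b = [data[f"b{l}"] for l in range(n_layers)]
    return RiskModel(
        mlp=mlp,
        feature_names=cfg["feature_names"],
        net=net,
        train_config=train,
        scale_columns=cfg["scale_columns"],
        scale_mean=data["scale_mean"] if "scale_mean" in data else None,
        scale_std=data["scale_std"] if "scale_std" in data else None,
        history=cfg.get("history", {}),
    )


# ---------------------------------------------------------------------------
# Resampling protocol


RATIOS = {"1:1": 1, "1:2": 2, "1:3": 3}


def undersample(subjects: SubjectTable, ratio: str, seed: int = 0) -> SubjectTable:
    """Keep all cases and a seeded random subset of controls at the given ratio.

    Control subsets are nested across ratios for a fixed seed: the 1:1
    controls are a prefix of the 1:2 controls, which are a prefix of the 1:3
    controls (a single seeded permutation, taken by prefix).  ``ratio='all'``
    returns the input unchanged.
    """
    if ratio == "all":
        return subjects
    if ratio not in RATIOS:
        raise ValueError(f"ratio must be one of {list(RATIOS) + ['all']}")
    k = RATIOS[ratio]
    cases = [s for s, l in zip(subjects.subject_ids, subjects.labels) if l == "case"]
    controls = [s for s, l in zip(subjects.subject_ids, subjects.labels) if l == "control"]
    need = k * len(cases)
    if need > len(controls):
        max_k = len(controls) // max(len(cases), 1)
        raise ValueError(
            f"not enough controls for ratio {ratio}: need {need}, have {len(controls)} "
            f"(achievable up to 1:{max_k})"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(controls))
    chosen = [controls[i] for i in order[:need]]
    return subjects.subset(cases + chosen)


def split_train_test(
    subjects: SubjectTable,
    test_fraction: float = 0.20,
    test_controls_per_case: int = 9,
    seed: int = 0,
) -> tuple[SubjectTable, SubjectTable]:
    """Disjoint train/test split with a fixed test-set case:control ratio.

    The test set holds ``test_fraction`` of the case/control subjects at a
    1:``test_controls_per_case`` case:control ratio (up to one-subject
    rounding); remaining cases and controls form the training set.  Auxiliary
    controls (e.g. a type 2 diabetes negative-control group) are never
    trained on and are appended to the test set.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    cases = [s for s, l in zip(subjects.subject_ids, subjects.labels) if l == "case"]
    controls = [s for s, l in zip(subjects.subject_ids, subjects.labels) if l == "control"]
    aux = [s for s, l in zip(subjects.subject_ids, subjects.labels) if l == "aux_control"]
    n = len(cases) + len(controls)
    n_test = int(round(test_fraction * n))
    n_test_cases = int(round(n_test / (1 + test_controls_per_case)))
    n_test_controls = n_test - n_test_cases
    if n_test_cases < 1 or n_test_cases > len(cases) or n_test_controls > len(controls):
        raise ValueError(
            f"cannot form a test set of {n_test} at 1:{test_controls_per_case} "
            f"from {len(cases)} cases and {len(controls)} controls"
        )
    case_order = rng.permutation(len(cases))
    control_order = rng.permutation(len(controls))
    test_ids = [cases[i] for i in case_order[:n_test_cases]] + [
        controls[i] for i in control_order[:n_test_controls]
    ]
    train_ids = [cases[i] for i in case_order[n_test_cases:]] + [
        controls[i] for i in control_order[n_test_controls:]
    ]
    return subjects.subset(train_ids), subjects.subset(test_ids + aux)


# ---------------------------------------------------------------------------
# Grid search


@dataclass
class CVResult:
    fold_aucs: list[float]
    mean_auc: float
    best_optimizer: str
    best_learning_rate: float
    fold_assignments: np.ndarray
    all_results: list[dict]


def grid_search_cv(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    net: NetworkConfig | None = None,
    train: TrainConfig | None = None,
    optimizers: Sequence[str] = GRID_OPTIMIZERS,
    learning_rates: Sequence[float] = GRID_LEARNING_RATES,
    n_folds: int = 5,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold grid search over optimizer x learning rate by mean AUC.

    Ties break deterministically: lower learning rate first, then sgd before
    adam.  Never touches any held-out test data.
    """
    net = net or NetworkConfig()
    train = train or TrainConfig()
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    y = np.asarray(labels, int).ravel()
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"need at least {n_folds} subjects per class for stratified {n_folds}-fold CV"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    assignments = np.empty(len(y), dtype=int)
    for f, (_, va) in enumerate(folds):
        assignments[va] = f
    for _, va in folds:
        if len(np.unique(y[va])) < 2:
            raise ValueError("degenerate single-class fold")

    results = []
    for lr in learning_rates:
        for opt in optimizers:
            fold_aucs = []
            for f, (tr, va) in enumerate(folds):
                cfg = replace(train, optimizer=opt, learning_rate=lr, seed=train.seed + f)
                sub_feat = (
                    FeatureMatrix(
                        X[tr], list(features.feature_names), features.encoding,
                        [features.subject_ids[i] for i in tr],
                    )
                    if isinstance(features, FeatureMatrix)
                    else X[tr]
                )
                model = fit(sub_feat, y[tr], net=replace(net, seed=net.seed + f), train=cfg)
                p = model.predict_proba(X[va])
                fold_aucs.append(auc(p, y[va]))
            results.append(
                {
                    "optimizer": opt,
                    "learning_rate": lr,
                    "fold_aucs": fold_aucs,
                    "mean_auc": float(np.mean(fold_aucs)),
                }
            )
    opt_rank = {"sgd": 0, "adam": 1}
    best = sorted(
        results, key=lambda r: (-r["mean_auc"], r["learning_rate"], opt_rank[r["optimizer"]])
    )[0]
    return CVResult(
        fold_aucs=best["fold_aucs"],
        mean_auc=best["mean_auc"],
        best_optimizer=best["optimizer"],
        best_learning_rate=best["learning_rate"],
        fold_assignments=assignments,
        all_results=results,
    )


# ---------------------------------------------------------------------------
# AUC and DeLong confidence intervals


@dataclass(frozen=True)
class AUCEstimate:
    auc: float
    ci_low: float
    ci_high: float
    variance: float


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted half."""
    scores = np.asarray(scores, float)
    y = np.asarray(labels, int).ravel()
    pos = scores[y == 1]
    neg = scores[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))


def auc_with_delong_ci(
    scores: np.ndarray, labels: np.ndarray, alpha: float = 0.05
) -> AUCEstimate:
    """AUC with a DeLong nonparametric variance and normal-approximation CI.

    Structural components: V10_i = P(X_i > Y) (over negatives, ties half) for
    each positive i, V01_j likewise per negative; the AUC variance is
    var(V10)/m + var(V01)/n, and the CI is clipped to [0, 1].
    """
    scores = np.asarray(scores, float)
    y = np.asarray(labels, int).ravel()
    x = scores[y == 1]
    yneg = scores[y == 0]
    m, n = len(x), len(yneg)
    if m == 0 or n == 0:
        raise ValueError("DeLong CI needs both classes present")
    tz = rankdata(np.concatenate([x, yneg]))
    tx = rankdata(x)
    ty = rankdata(yneg)
    v10 = (tz[:m] - tx) / n               # per-positive placement values
    v01 = 1.0 - (tz[m:] - ty) / m         # per-negative placement values
    a = float(v10.mean())
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    z = norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return AUCEstimate(
        auc=a,
        ci_low=float(max(0.0, a - half)),
        ci_high=float(min(1.0, a + half)),
        variance=float(var),
    )
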