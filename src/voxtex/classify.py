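"""Nested cross-validated two-class discrimination from voxel feature maps.

The classifier is a small feed-forward network — 5 tanh hidden layers of 2
units and a linear output — trained full-batch by Levenberg–Marquardt on a
mean-squared-error objective with an L2 weight penalty.  Feature selection
(top-k by Welch two-sample t magnitude) runs inside the inner cycle only;
the outer-fold model is refit on the full outer-training set with the
inner-cycle consensus feature set.  Labels are coded +1/−1; the decision
threshold is 0 and a score of exactly 0 goes to the positive class.

No training function ever receives hold-out labels: metrics come solely
from outer hold-out predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CVConfig",
    "TrainedMLP",
    "CVResult",
    "FoldOutcome",
    "select_features",
    "welch_t",
    "train_mlp",
    "predict",
    "nested_cv",
    "external_validate",
    "metrics",
    "count_planned_fits",
    "stratified_folds",
]

HIDDEN_LAYERS = 5
HIDDEN_WIDTH = 2


@dataclass
class CVConfig:
    outer_folds: int = 10
    inner_folds: int = 10
    outer_reps: int = 10
    inner_reps: int = 10
    k_features: int = 200
    epochs_max: int = 1000
    l2_lambda: float = 0.01
    n_restarts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if self.outer_reps < 1 or self.inner_reps < 1:
            raise ValueError("repetitions must be >= 1")
        if self.k_features < 1:
            raise ValueError("k_features must be >= 1")


def count_planned_fits(config: CVConfig) -> int:
    """Dry-run count of inner model-fitting events: one per inner
    train/validation split, across all inner and outer repetitions."""
    return (
        config.outer_reps
        * config.outer_folds
        * config.inner_reps
        * config.inner_folds
    )


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def welch_t(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-column Welch two-sample t statistic (+1 class minus −1 class).

    Columns with zero variance in both classes get t = 0.
    """
    X = np.asarray(X, dtype=np.float64)
    pos = X[y > 0]
    neg = X[y < 0]
    n1, n2 = len(pos), len(neg)
    if n1 < 2 or n2 < 2:
        raise ValueError("both classes need >= 2 samples")
    m1, m2 = pos.mean(axis=0), neg.mean(axis=0)
    v1, v2 = pos.var(axis=0, ddof=1), neg.var(axis=0, ddof=1)
    denom = np.sqrt(v1 / n1 + v2 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m1 - m2) / denom, 0.0)
    return t


def select_features(X: np.ndarray, y: np.ndarray, k: int = 200) -> np.ndarray:
    """Top-k columns by |Welch t|, descending; ties break toward lower index."""
    t = welch_t(X, y)
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds {X.shape[1]} columns")
    order = np.lexsort((np.arange(X.shape[1]), -np.abs(t)))
    return order[:k]


# ---------------------------------------------------------------------------
# MLP + Levenberg–Marquardt
# ---------------------------------------------------------------------------

@dataclass
class TrainedMLP:
    weights: list  # per layer, shape (n_in, n_out)
    biases: list   # per layer, shape (n_out,)
    selected_features: np.ndarray
    feature_mean: np.ndarray
    feature_std: np.ndarray
    l2_lambda: float
    loss_history: list = field(default_factory=list)  # accepted-step losses
    epochs_run: int = 0

    @property
    def layer_sizes(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]


def _init_layers(n_in: int, rng: np.random.Generator):
    sizes = [n_in] + [HIDDEN_WIDTH] * HIDDEN_LAYERS + [1]
    weights, biases = [], []
    for a, b in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.standard_normal((a, b)) / np.sqrt(a))
        biases.append(np.zeros(b))
    return weights, biases


def _forward(weights, biases, X):
    """Return activations per layer; hidden tanh, linear output."""
    acts = [X]
    a = X
    last = len(weights) - 1
    for i, (W, b) in enumerate(zip(weights, biases)):
        z = a @ W + b
        a = z if i == last else np.tanh(z)
        acts.append(a)
    return acts


def _pack(weights, biases) -> np.ndarray:
    return np.concatenate([w.ravel() for w in weights] + [b.ravel() for b in biases])


def _unpack(theta, templates_w, templates_b):
    ws, bs, pos = [], [], 0
    for w in templates_w:
        ws.append(theta[pos : pos + w.size].reshape(w.shape))
        pos += w.size
    for b in templates_b:
        bs.append(theta[pos : pos + b.size].reshape(b.shape))
        pos += b.size
    return ws, bs


def _jacobian(weights, biases, X):
    """d f(x_n) / d theta for all samples, shape (N, P); theta packs weights
    then biases in layer order."""
    acts = _forward(weights, biases, X)
    N = X.shape[0]
    L = len(weights)
    delta = np.ones((N, 1))  # d out / d z_last (linear output)
    grads_w = [None] * L
    grads_b = [None] * L
    for l in range(L - 1, -1, -1):
        a_prev = acts[l]
        # d out / d W_l[i,j] = a_prev[:, i] * delta[:, j]
        grads_w[l] = a_prev[:, :, None] * delta[:, None, :]
        grads_b[l] = delta
        if l > 0:
            delta = (delta @ weights[l].T) * (1.0 - acts[l] ** 2)
    cols = [g.reshape(N, -1) for g in grads_w] + [g.reshape(N, -1) for g in grads_b]
    return np.concatenate(cols, axis=1), acts[-1][:, 0]


def _loss(weights, biases, X, y, l2):
    r = y - _forward(weights, biases, X)[-1][:, 0]
    w2 = sum(float(np.sum(w * w)) for w in weights)
    return float(np.mean(r * r) + l2 * w2), r


def train_mlp(
    X: np.ndarray,
    y: np.ndarray,
    config: CVConfig | None = None,
    rng: np.random.Generator | None = None,
    selected_features: np.ndarray | None = None,
) -> TrainedMLP:
    """Levenberg–Marquardt batch training of the 5×2 tanh network.

    Damping schedule: λ₀ = 1e−3, ×10 on a rejected step, ÷10 on an accepted
    one; training stops after ``epochs_max`` accepted steps, on damping
    overflow (λ > 1e10) or when the step no longer improves the regularized
    loss.  The recorded accepted-step loss sequence is non-increasing.

    LM on a tiny tanh net can stall in a flat region from an unlucky init,
    so up to ``config.n_restarts`` inits are tried and the lowest final
    regularized loss wins; the draw order from ``rng`` keeps this
    deterministic.
    """
    config = config or CVConfig()
    rng = rng or np.random.default_rng(config.seed)
    best = None
    for _ in range(max(1, config.n_restarts)):
        model = _train_mlp_once(X, y, config, rng, selected_features)
        if best is None or model.loss_history[-1] < best.loss_history[-1]:
            best = model
    return best


def _train_mlp_once(X, y, config, rng, selected_features):
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if not np.isfinite(X).all():
        raise ValueError("X must be finite")
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise ValueError("labels must be coded +1/−1")

    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    Xz = (X - mean) / std

    weights, biases = _init_layers(X.shape[1], rng)
    l2 = config.l2_lambda
    n = len(y)
    n_wparams = sum(w.size for w in weights)

    loss, r = _loss(weights, biases, Xz, y, l2)
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite initial loss")
    history = [loss]
    lam = 1e-3
    epochs = 0
    while epochs < config.epochs_max and lam <= 1e10:
        J, _ = _jacobian(weights, biases, Xz)
        theta = _pack(weights, biases)
        # normal equations for the augmented residual [r/√n ; √l2·θ_w]
        JtJ = J.T @ J / n
        g = J.T @ r / n
        reg = np.zeros_like(theta)
        reg[:n_wparams] = l2
        A_base = JtJ + np.diag(reg)
        g = g - reg * theta
        stepped = False
        while lam <= 1e10:
            try:
                delta = np.linalg.solve(
                    A_base + lam * np.eye(len(theta)), g
                )
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            cand = theta + delta
            ws, bs = _unpack(cand, weights, biases)
            new_loss, new_r = _loss(ws, bs, Xz, y, l2)
            if not np.isfinite(new_loss):
                raise FloatingPointError("non-finite loss during training")
            if new_loss < loss:
                weights, biases = ws, bs
                loss, r = new_loss, new_r
                history.append(loss)
                lam = max(lam / 10, 1e-12)
                epochs += 1
                stepped = True
                break
            lam *= 10
        if not stepped:
            break

    return TrainedMLP(
        weights=weights,
        biases=biases,
        selected_features=(
            np.arange(X.shape[1]) if selected_features is None
            else np.asarray(selected_features)
        ),
        feature_mean=mean,
        feature_std=std,
        l2_lambda=l2,
        loss_history=history,
        epochs_run=epochs,
    )


def predict(model: TrainedMLP, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward pass on raw (unstandardized) selected-feature columns.

    Returns (scores, labels); label = sign(score), score 0 → +1.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != model.weights[0].shape[0]:
        raise ValueError(
            f"expected {model.weights[0].shape[0]} columns, got {X.shape[1]}"
        )
    Xz = (X - model.feature_mean) / model.feature_std
    scores = _forward(model.weights, model.biases, Xz)[-1][:, 0]
    labels = np.where(scores >= 0, 1, -1)
    return scores, labels


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator):
    """Shuffled stratified k-fold; every fold must contain both classes."""
    y = np.asarray(y)
    folds = [[] for _ in range(n_folds)]
    for cls in (1, -1):
        idx = np.flatnonzero(y == cls)
        if len(idx) < n_folds:
            raise ValueError(
                f"class {cls:+d} has {len(idx)} samples < {n_folds} folds"
            )
        idx = rng.permutation(idx)
        for i, j in enumerate(idx):
            folds[i % n_folds].append(j)
    return [np.sort(np.array(f)) for f in folds]


@dataclass
class FoldOutcome:
    rep: int
    fold: int
    test_indices: np.ndarray
    scores: np.ndarray
    predicted: np.ndarray
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def balanced_accuracy(self) -> float:
        return metrics(self.tp, self.fn, self.tn, self.fp)[0]


@dataclass
class CVResult:
    folds: list            # FoldOutcome per outer fold × repetition
    models: list           # TrainedMLP per outer fold × repetition
    inner_val_acc: list    # balanced accuracy per inner fit (diagnostics)
    config: CVConfig
    n_subjects: int

    @property
    def balanced_accuracy(self) -> float:
        return float(np.nanmean([f.balanced_accuracy for f in self.folds]))

    @property
    def sensitivity(self) -> float:
        return float(np.nanmean(
            [metrics(f.tp, f.fn, f.tn, f.fp)[1] for f in self.folds]
        ))

    @property
    def specificity(self) -> float:
        return float(np.nanmean(
            [metrics(f.tp, f.fn, f.tn, f.fp)[2] for f in self.folds]
        ))

    def holdout_models_for(self, subject: int):
        """Models that held this subject out, with their predictions."""
        out = []
        for fold, model in zip(self.folds, self.models):
            pos = np.flatnonzero(fold.test_indices == subject)
            if pos.size:
                out.append((model, int(fold.predicted[pos[0]])))
        return out

    def subject_correctness(self, y: np.ndarray) -> np.ndarray:
        """True where the majority of hold-out predictions match the label."""
        ok = np.zeros(self.n_subjects, dtype=bool)
        for s in range(self.n_subjects):
            votes = [pred == y[s] for _, pred in self.holdout_models_for(s)]
            if votes:
                ok[s] = sum(votes) * 2 >= len(votes)
        return ok

    def to_jsonable(self) -> dict:
        return {
            "balanced_accuracy": self.balanced_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "folds": [
                {
                    "rep": f.rep,
                    "fold": f.fold,
                    "tp": f.tp,
                    "fn": f.fn,
                    "tn": f.tn,
                    "fp": f.fp,
                }
                for f in self.folds
            ],
        }


def metrics(tp: int, fn: int, tn: int, fp: int):
    """(balanced accuracy, sensitivity, specificity); NaN when a class is absent."""
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fn + tn + fp == 0:
        raise ValueError("confusion counts are all zero")
    sens = tp / (tp + fn) if tp + fn > 0 else float("nan")
    spec = tn / (tn + fp) if tn + fp > 0 else float("nan")
    return (sens + spec) / 2.0, sens, spec


def _consensus_features(selections: list[np.ndarray], n_cols: int, k: int) -> np.ndarray:
    """Majority-vote consensus across inner folds, quota-filled by mean rank."""
    freq = np.zeros(n_cols)
    rank_sum = np.full(n_cols, float(n_cols))  # unselected → worst rank
    rank_cnt = np.zeros(n_cols)
    for sel in selections:
        freq[sel] += 1
        for r, c in enumerate(sel):
            rank_sum[c] = rank_sum[c] + r if rank_cnt[c] else float(r)
            rank_cnt[c] += 1
    mean_rank = np.where(rank_cnt > 0, rank_sum / np.maximum(rank_cnt, 1), np.inf)
    order = np.lexsort((np.arange(n_cols), mean_rank, -freq))
    return np.sort(order[:k])


def nested_cv(X: np.ndarray, y: np.ndarray, config: CVConfig) -> CVResult:
    """Repeated stratified nested cross-validation.

    Inner cycle: feature selection + one fit per inner train/validation
    split, evaluated on the inner validation fold (diagnostics only).
    Outer model: refit on the full outer-training set using the consensus
    feature set of its inner cycle; scored on the outer hold-out only.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    n, n_cols = X.shape
    k = min(config.k_features, n_cols)

    folds_out: list[FoldOutcome] = []
    models: list[TrainedMLP] = []
    inner_val = []

    for rep in range(config.outer_reps):
        rep_rng = np.random.default_rng(np.random.SeedSequence([config.seed, rep]))
        outer = stratified_folds(y, config.outer_folds, rep_rng)
        for fold_id, test_idx in enumerate(outer):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            Xtr, ytr = X[train_idx], y[train_idx]

            selections = []
            for irep in range(config.inner_reps):
                irng = np.random.default_rng(
                    np.random.SeedSequence([config.seed, rep, fold_id, irep])
                )
                inner = stratified_folds(ytr, config.inner_folds, irng)
                for ifold_id, ival_idx in enumerate(inner):
                    itr_idx = np.setdiff1d(np.arange(len(ytr)), ival_idx)
                    sel = select_features(Xtr[itr_idx], ytr[itr_idx], k)
                    selections.append(sel)
                    fit_rng = np.random.default_rng(
                        np.random.SeedSequence(
                            [config.seed, rep, fold_id, irep, ifold_id]
                        )
                    )
                    m = train_mlp(
                        Xtr[np.ix_(itr_idx, sel)], ytr[itr_idx], config, fit_rng,
                        selected_features=sel,
                    )
                    _, pred = predict(m, Xtr[np.ix_(ival_idx, sel)])
                    yv = ytr[ival_idx]
                    bacc, _, _ = metrics(
                        int(np.sum((pred > 0) & (yv > 0))),
                        int(np.sum((pred < 0) & (yv > 0))),
                        int(np.sum((pred < 0) & (yv < 0))),
                        int(np.sum((pred > 0) & (yv < 0))),
                    )
                    inner_val.append(bacc)

            consensus = _consensus_features(selections, n_cols, k)
            refit_rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, rep, fold_id, 10_007])
            )
            model = train_mlp(
                Xtr[:, consensus], ytr, config, refit_rng,
                selected_features=consensus,
            )
            models.append(model)

            _, pred = predict(model, X[np.ix_(test_idx, consensus)])
            yt = y[test_idx]
            folds_out.append(
                FoldOutcome(
                    rep=rep,
                    fold=fold_id,
                    test_indices=test_idx,
                    scores=predict(model, X[np.ix_(test_idx, consensus)])[0],
                    predicted=pred,
                    tp=int(np.sum((pred > 0) & (yt > 0))),
                    fn=int(np.sum((pred < 0) & (yt > 0))),
                    tn=int(np.sum((pred < 0) & (yt < 0))),
                    fp=int(np.sum((pred > 0) & (yt < 0))),
                )
            )

    return CVResult(
        folds=folds_out,
        models=models,
        inner_val_acc=inner_val,
        config=config,
        n_subjects=n,
    )


def external_validate(result: CVResult, X_ext: np.ndarray) -> dict:
    """Score external subjects with every stored outer model; majority vote.

    Ties go to the positive class.  Returns per-class counts and per-subject
    positive-vote fractions.
    """
    X_ext = np.asarray(X_ext, dtype=np.float64)
    n = X_ext.shape[0]
    votes_pos = np.zeros(n)
    for model in result.models:
        _, pred = predict(model, X_ext[:, model.selected_features])
        votes_pos += pred > 0
    frac = votes_pos / len(result.models)
    calls = np.where(frac >= 0.5, 1, -1)
    return {
        "n_positive": int(np.sum(calls > 0)),
        "n_negative": int(np.sum(calls < 0)),
        "vote_fraction_positive": frac,
        "calls": calls,
    }
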