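"""Cross-validated training, metrics, baselines, and brain-age-gap reports.

The regressor is trained on healthy controls only with 10-fold
cross-validation: MSE loss, Adam (lr 1e-3, weight decay 1e-3, batch size 16)
and cosine-annealed learning rate. Held-out performance is summarized as
MAE, RMSE and the Pearson correlation (PCC) between predicted and
chronological age, mean +- SD across folds. Each diagnostic group is then
scored by all fold models, and the brain age gap (BAG = predicted minus
chronological age) is averaged within group.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .graphs import BrainGraph, stack_graphs
from .nn import Adam, BrainAgeGNN, ModelConfig

__all__ = [
    "TrainingConfig",
    "FoldResult",
    "GroupReport",
    "kfold_split",
    "compute_metrics",
    "cosine_lr",
    "train_fold",
    "cross_validate",
    "evaluate_group",
    "run_baselines",
]


@dataclass
class TrainingConfig:
    batch_size: int = 16
    lr: float = 1e-3
    lr_min: float = 1e-5
    weight_decay: float = 1e-3
    n_epochs: int = 150
    k_folds: int = 10
    split_seed: int = 0

    def validate(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be > 0")


@dataclass
class FoldResult:
    fold_index: int
    model: BrainAgeGNN
    test_ids: list[str]
    predictions: pd.DataFrame  # subject_id, age, predicted
    mae: float
    rmse: float
    pcc: float
    loss_history: list[float] = field(default_factory=list)

    def test_id_hash(self) -> str:
        """Fingerprint of the held-out set, for cross-method protocol audits."""
        joined = ",".join(sorted(self.test_ids))
        return hashlib.sha256(joined.encode()).hexdigest()[:16]


@dataclass
class GroupReport:
    group: str
    per_model: pd.DataFrame  # fold, mae, rmse, pcc, mean_bag
    mae: tuple[float, float]
    rmse: tuple[float, float]
    pcc: tuple[float, float]
    bag: tuple[float, float]


def kfold_split(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Random partition of 0..n-1 into k folds with sizes differing by <= 1."""
    if n < k:
        raise ValueError(f"cannot split {n} subjects into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def compute_metrics(pred, true) -> tuple[float, float, float]:
    """(MAE, RMSE, PCC) between predicted and true ages.

    PCC is NaN (not 0) when either vector is constant.
    """
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("pred and true must be equal-length, nonempty")
    err = pred - true
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err**2).mean()))
    if pred.std() == 0 or true.std() == 0:
        pcc = float("nan")
    else:
        pcc = float(np.corrcoef(pred, true)[0, 1])
    return mae, rmse, pcc


def cosine_lr(epoch: int, cfg: TrainingConfig) -> float:
    """Cosine annealing from lr to lr_min over n_epochs (lr at epoch 0)."""
    if cfg.n_epochs <= 1:
        return cfg.lr
    t = epoch / (cfg.n_epochs - 1)
    return cfg.lr_min + 0.5 * (cfg.lr - cfg.lr_min) * (1.0 + np.cos(np.pi * t))


def _train_on_arrays(
    X: np.ndarray,
    E: np.ndarray,
    mask: np.ndarray,
    ages: np.ndarray,
    model_cfg: ModelConfig,
    cfg: TrainingConfig,
    rng: np.random.Generator,
) -> tuple[BrainAgeGNN, list[float]]:
    model = BrainAgeGNN(model_cfg)
    # standardize the output scale to the training ages (see BrainAgeGNN)
    model.out_loc = float(ages.mean())
    model.out_scale = float(ages.std()) or 1.0
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    n = len(ages)
    history: list[float] = []
    model.train()
    for epoch in range(cfg.n_epochs):
        opt.lr = cosine_lr(epoch, cfg)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, eb, mb = Tensor(X[idx]), Tensor(E[idx]), mask[idx]
            pred = model(xb, eb, mb)
            diff = pred - Tensor(ages[idx])
            loss = (diff * diff).mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged (loss={loss.data}) at epoch {epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        history.append(epoch_loss / n)
    model.eval()
    return model, history


def _predict_batched(model: BrainAgeGNN, X, E, mask, batch: int = 64) -> np.ndarray:
    out = []
    for start in range(0, len(X), batch):
        sl = slice(start, start + batch)
        out.append(model.predict(X[sl], E[sl], mask[sl]))
    return np.concatenate(out)


def train_fold(
    graphs: list[BrainGraph],
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    model_cfg: ModelConfig,
    cfg: TrainingConfig,
    fold_index: int = 0,
) -> FoldResult:
    """Train on one fold's training set and evaluate on its held-out set."""
    cfg.validate()
    if len(train_idx) < 2:
        raise ValueError("need at least 2 training subjects")
    X, E, mask, ages = stack_graphs(graphs)
    rng = np.random.default_rng([cfg.split_seed, model_cfg.seed, fold_index, 2])
    fold_model_cfg = ModelConfig(**{**model_cfg.__dict__, "seed": model_cfg.seed + fold_index})
    model, history = _train_on_arrays(
        X[train_idx], E[train_idx], mask[train_idx], ages[train_idx], fold_model_cfg, cfg, rng
    )
    preds = _predict_batched(model, X[test_idx], E[test_idx], mask[test_idx])
    mae, rmse, pcc = compute_metrics(preds, ages[test_idx])
    test_ids = [graphs[i].subject_id for i in test_idx]
    pred_df = pd.DataFrame(
        {"subject_id": test_ids, "age": ages[test_idx], "predicted": preds}
    )
    return FoldResult(fold_index, model, test_ids, pred_df, mae, rmse, pcc, history)


def _summarize(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def cross_validate(
    graphs: list[BrainGraph],
    model_cfg: ModelConfig,
    cfg: TrainingConfig,
) -> tuple[list[FoldResult], dict]:
    """k-fold cross-validation; summary is mean +- SD of held-out metrics."""
    cfg.validate()
    n = len(graphs)
    folds = kfold_split(n, cfg.k_folds, cfg.split_seed)
    all_idx = np.arange(n)
    results: list[FoldResult] = []
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        results.append(train_fold(graphs, train_idx, test_idx, model_cfg, cfg, fi))
    summary = {
        "mae": _summarize([r.mae for r in results]),
        "rmse": _summarize([r.rmse for r in results]),
        "pcc": _summarize([r.pcc for r in results]),
    }
    return results, summary


def evaluate_group(
    fold_results: list[FoldResult],
    graphs: list[BrainGraph],
    group_label: str,
) -> GroupReport:
    """Score one diagnostic group with every fold model; mean +- SD across models.

    BAG (brain age gap) is predicted minus chronological age, averaged over
    the group's subjects.
    """
    if not graphs:
        raise ValueError(f"group {group_label}: no subjects")
    X, E, mask, ages = stack_graphs(graphs)
    rows = []
    for r in fold_results:
        preds = _predict_batched(r.model, X, E, mask)
        mae, rmse, pcc = compute_metrics(preds, ages)
        rows.append(
            {
                "fold": r.fold_index,
                "mae": mae,
                "rmse": rmse,
                "pcc": pcc,
                "mean_bag": float((preds - ages).mean()),
            }
        )
    per_model = pd.DataFrame(rows)
    return GroupReport(
        group=group_label,
        per_model=per_model,
        mae=_summarize(per_model["mae"].tolist()),
        rmse=_summarize(per_model["rmse"].tolist()),
        pcc=_summarize(per_model["pcc"].tolist()),
        bag=_summarize(per_model["mean_bag"].tolist()),
    )


# -- baseline regressors on flattened edge vectors -----------------------------


def _alexnet_style(n_features: int, seed: int):
    """Deep fully-connected regressor with staged widths (1-D adaptation)."""
    from sklearn.neural_network import MLPRegressor

    return MLPRegressor(
        hidden_layer_sizes=(256, 128, 64),
        activation="relu",
        solver="adam",
        max_iter=300,
        random_state=seed,
    )


class _AutoencoderRegressor:
    """Reconstruction-pretrained encoder with a linear regression head.

    The encoder is the first layer of an MLP autoencoder trained on
    reconstruction loss; a ridge head is then fit on the encoded features.
    """

    def __init__(self, hidden: int = 64, seed: int = 0, max_iter: int = 200):
        self.hidden = hidden
        self.seed = seed
        self.max_iter = max_iter

    def fit(self, X, y):
        from sklearn.linear_model import Ridge
        from sklearn.neural_network import MLPRegressor

        self._ae = MLPRegressor(
            hidden_layer_sizes=(self.hidden,),
            activation="relu",
            solver="adam",
            max_iter=self.max_iter,
            random_state=self.seed,
        )
        self._ae.fit(X, X)  # reconstruction pretraining
        Z = self._encode(X)
        self._head = Ridge(alpha=1.0)
        self._head.fit(Z, y)
        return self

    def _encode(self, X):
        W, b = self._ae.coefs_[0], self._ae.intercepts_[0]
        return np.maximum(X @ W + b, 0.0)

    def predict(self, X):
        return self._head.predict(self._encode(X))


def baseline_estimators(n_features: int, seed: int = 0) -> dict:
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.linear_model import LassoCV
    from sklearn.svm import SVR

    return {
        "SVR": SVR(),
        "GPR": GaussianProcessRegressor(normalize_y=True, random_state=seed),
        "RFR": RandomForestRegressor(n_estimators=100, random_state=seed),
        "LASSO": LassoCV(cv=3, max_iter=5000),  # regularization path by inner CV
        "AlexNet": _alexnet_style(n_features, seed),
        "AE": _AutoencoderRegressor(seed=seed),
    }


def run_baselines(
    edge_vectors: np.ndarray,
    ages: np.ndarray,
    folds: list[np.ndarray],
    seed: int = 0,
    methods: list[str] | None = None,
) -> pd.DataFrame:
    """Fit the comparison regressors on the same fold partition as the GNN.

    Returns one row per method with mean +- SD of MAE/RMSE/PCC across folds
    plus the fold test-id hash audit column.
    """
    X = np.asarray(edge_vectors, dtype=float)
    y = np.asarray(ages, dtype=float)
    all_idx = np.arange(len(y))
    estimators = baseline_estimators(X.shape[1], seed)
    if methods is not None:
        estimators = {k: v for k, v in estimators.items() if k in methods}
    rows = []
    for name, proto in estimators.items():
        fold_metrics = []
        failed = False
        for test_idx in folds:
            train_idx = np.setdiff1d(all_idx, test_idx)
            try:
                import copy

                est = copy.deepcopy(proto)
                est.fit(X[train_idx], y[train_idx])
                preds = np.asarray(est.predict(X[test_idx]), dtype=float)
                fold_metrics.append(compute_metrics(preds, y[test_idx]))
            except Exception:
                failed = True
                break
        if failed or not fold_metrics:
            rows.append({"method": name, "failed": True})
            continue
        arr = np.asarray(fold_metrics)
        mae_m, mae_s = _summarize(arr[:, 0].tolist())
        rmse_m, rmse_s = _summarize(arr[:, 1].tolist())
        pcc_m, pcc_s = _summarize(arr[:, 2].tolist())
        rows.append(
            {
                "method": name,
                "failed": False,
                "mae_mean": mae_m,
                "mae_sd": mae_s,
                "rmse_mean": rmse_m,
                "rmse_sd": rmse_s,
                "pcc_mean": pcc_m,
                "pcc_sd": pcc_s,
            }
        )
    return pd.DataFrame(rows)
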