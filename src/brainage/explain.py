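"""Perturbation-based explanation of the trained graph regressor.

A soft node-feature mask M in (0,1)^{R x R} (one value per vertex-feature
entry) is optimized so that the frozen model's prediction on the masked graph
stays close to its prediction on the original graph, with a small sparsity
penalty:

    loss(M) = ( f(G) - f(G * M) )^2 + lambda * mean(M),   M = sigmoid(L)

High mask values mark connectivity-profile entries the prediction relies on.
Per-region weights are row means of the mask; group-level importance ranks
the mean weights across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .graphs import BrainGraph
from .nn import Adam, BrainAgeGNN

__all__ = [
    "ExplanationResult",
    "GroupRanking",
    "EnsemblePredictor",
    "explain_subject",
    "explain_cohort",
    "group_region_ranking",
    "top_fraction",
    "shared_distinct",
]


@dataclass
class ExplanationResult:
    subject_id: str
    mask_logits: np.ndarray  # (R, R)
    mask: np.ndarray  # sigmoid(mask_logits), entries in (0, 1)
    region_weights: np.ndarray  # (R,) row means of the mask
    loss_history: list[float]
    region_labels: list[str] = field(default_factory=list)


@dataclass
class GroupRanking:
    group: str
    mean_weights: np.ndarray  # (R,) mean region weight across subjects
    order: np.ndarray  # region indices, descending weight (ties: lower index)
    region_labels: list[str] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        labels = self.region_labels or [f"ROI{i + 1}" for i in range(len(self.mean_weights))]
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.order) + 1),
                "region": [labels[i] for i in self.order],
                "region_index": self.order,
                "weight": self.mean_weights[self.order],
            }
        )


class EnsemblePredictor:
    """Mean prediction over fold models, differentiable through each."""

    def __init__(self, models: list[BrainAgeGNN]):
        if not models:
            raise ValueError("need at least one model")
        self.models = models
        for m in models:
            m.eval()

    def __call__(self, x: Tensor, e: Tensor, mask: np.ndarray) -> Tensor:
        total = self.models[0](x, e, mask)
        for m in self.models[1:]:
            total = total + m(x, e, mask)
        return total * (1.0 / len(self.models))


def explain_subject(
    model: BrainAgeGNN | EnsemblePredictor,
    graph: BrainGraph,
    n_steps: int = 100,
    lr_mask: float = 0.01,
    lambda_size: float = 0.005,
    seed: int = 0,
) -> ExplanationResult:
    """Learn the node-feature mask for one subject; model parameters frozen.

    The mask starts at 0.5 everywhere (logits 0). Only the mask logits carry
    gradients; optimization uses the Adam update rule. ``seed`` is accepted
    for interface stability; with logits initialized at zero the procedure is
    deterministic.
    """
    predict = model if isinstance(model, EnsemblePredictor) else EnsemblePredictor([model])
    R = graph.n_vertices
    X = graph.vertex_features[None]  # (1, R, R)
    E = graph.dense_edge_features()[None]
    A = graph.adjacency_mask()[None]

    with np.errstate(all="ignore"):
        original = predict(Tensor(X), Tensor(E), A).data.copy()

    logits = Tensor(np.zeros((R, R)), requires_grad=True)
    opt = Adam([logits], lr=lr_mask)
    history: list[float] = []
    for _ in range(n_steps):
        mask_t = logits.sigmoid()
        masked = Tensor(X) * mask_t.reshape(1, R, R)
        pred = predict(masked, Tensor(E), A)
        diff = pred - Tensor(original)
        loss = (diff * diff).mean() + lambda_size * mask_t.mean()
        if not np.isfinite(loss.data):
            raise RuntimeError(
                f"subject {graph.subject_id}: non-finite explainer loss; "
                f"history={history[-5:]}"
            )
        history.append(float(loss.data))
        opt.zero_grad()
        loss.backward()
        opt.step()

    final_mask = 1.0 / (1.0 + np.exp(-logits.data))
    return ExplanationResult(
        subject_id=graph.subject_id,
        mask_logits=logits.data.copy(),
        mask=final_mask,
        region_weights=final_mask.mean(axis=1),
        loss_history=history,
        region_labels=list(graph.region_labels),
    )


def explain_cohort(
    model: BrainAgeGNN | EnsemblePredictor,
    graphs: list[BrainGraph],
    n_steps: int = 100,
    lr_mask: float = 0.01,
    lambda_size: float = 0.005,
) -> list[ExplanationResult]:
    """Optimize all subjects' masks jointly in one batched pass.

    The total loss is the sum of the per-subject losses; each subject's mask
    logits receive gradients only from that subject's term, and Adam updates
    are elementwise, so this matches running ``explain_subject`` per subject.
    """
    if not graphs:
        raise ValueError("no graphs to explain")
    predict = model if isinstance(model, EnsemblePredictor) else EnsemblePredictor([model])
    from .graphs import stack_graphs

    X, E, A, _ = stack_graphs(graphs)
    N, R, _ = X.shape
    original = predict(Tensor(X), Tensor(E), A).data.copy()

    logits = Tensor(np.zeros((N, R, R)), requires_grad=True)
    opt = Adam([logits], lr=lr_mask)
    histories: list[list[float]] = [[] for _ in range(N)]
    for _ in range(n_steps):
        mask_t = logits.sigmoid()
        pred = predict(Tensor(X) * mask_t, Tensor(E), A)
        diff = pred - Tensor(original)
        per_subject = diff * diff + lambda_size * mask_t.mean(axis=-1).mean(axis=-1)
        loss = per_subject.sum()
        if not np.isfinite(loss.data):
            raise RuntimeError("non-finite explainer loss in batched optimization")
        for i in range(N):
            histories[i].append(float(per_subject.data[i]))
        opt.zero_grad()
        loss.backward()
        opt.step()

    results = []
    for i, g in enumerate(graphs):
        final_mask = 1.0 / (1.0 + np.exp(-logits.data[i]))
        results.append(
            ExplanationResult(
                subject_id=g.subject_id,
                mask_logits=logits.data[i].copy(),
                mask=final_mask,
                region_weights=final_mask.mean(axis=1),
                loss_history=histories[i],
                region_labels=list(g.region_labels),
            )
        )
    return results


def group_region_ranking(results: list[ExplanationResult], group: str = "") -> GroupRanking:
    """Average region weights across subjects and rank them (descending).

    Ties are broken by region index (lower index first).
    """
    if not results:
        raise ValueError("no explanation results")
    R = len(results[0].region_weights)
    for res in results:
        if len(res.region_weights) != R:
            raise ValueError("inconsistent region count across results")
    mean_w = np.mean([res.region_weights for res in results], axis=0)
    # stable sort on negated weights -> descending with index tie-break
    order = np.argsort(-mean_w, kind="stable")
    return GroupRanking(group, mean_w, order, list(results[0].region_labels))


def top_fraction(ranking: GroupRanking, fraction: float = 0.30) -> list[int]:
    """Indices of the top round(fraction * R) regions (round-half-up)."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    R = len(ranking.mean_weights)
    n_keep = int(np.floor(fraction * R + 0.5))
    return ranking.order[:n_keep].tolist()


def shared_distinct(
    ranking_a: GroupRanking,
    ranking_b: GroupRanking,
    fraction: float = 0.30,
) -> tuple[set[int], set[int], set[int]]:
    """Shared and group-specific regions among the two top-fraction sets."""
    if ranking_a.region_labels != ranking_b.region_labels:
        raise ValueError("rankings use different region labels")
    top_a = set(top_fraction(ranking_a, fraction))
    top_b = set(top_fraction(ranking_b, fraction))
    return top_a & top_b, top_a - top_b, top_b - top_a
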