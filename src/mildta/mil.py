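"""Multiple-instance regression head: per-instance scoring and fusion.

Each instance vector is scored by its own MLP (independent parameters,
because the late-fusion concatenation instance is twice as wide as the
others), and the bag-level affinity is a learned weighted linear
combination of the instance scores:

    ŷ = w₁·s(public_dp) + w₂·s(public_pd) + w₃·s(public_concat) + w₄·s(private_d)

The fusion weights are unconstrained reals learned jointly with the rest of
the network (initialized symmetrically at 0.25 each); there is no intercept
unless explicitly enabled.  Training minimizes the mean squared error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat
from ._nn import Linear, Module

__all__ = [
    "INSTANCE_ORDER",
    "Prediction",
    "MlpScorer",
    "MilHead",
    "score_instances",
    "fuse_scores",
    "mse_loss",
]

# fixed instance roles, in fusion-weight order (w1..w4)
INSTANCE_ORDER = ("public_dp", "public_pd", "public_concat", "private_d")


@dataclass(frozen=True)
class Prediction:
    """One bag-level prediction with its per-instance scores."""

    y_hat: float
    instance_scores: np.ndarray

    def recompute(self, weights: np.ndarray, intercept: float = 0.0) -> float:
        return float(np.dot(weights, self.instance_scores) + intercept)


class MlpScorer(Module):
    """Feed-forward scorer: ReLU hidden layers, linear scalar output."""

    def __init__(
        self, in_dim: int, hidden: tuple[int, ...], rng: np.random.Generator
    ):
        dims = [in_dim, *hidden, 1]
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.in_dim = in_dim

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_dim:
            raise ValueError(
                f"scorer expects width {self.in_dim}, got {x.shape[-1]}"
            )
        for layer in self.layers[:-1]:
            x = layer(x).relu()
        return self.layers[-1](x)[..., 0]


class MilHead(Module):
    """Scorers plus fusion weights, restricted to the enabled instances.

    ``enabled`` preserves the canonical order of :data:`INSTANCE_ORDER`;
    ablation configurations simply instantiate a head with fewer roles, and
    the remaining fusion weights are learned from scratch.
    """

    def __init__(
        self,
        feature_width: int,
        hidden: tuple[int, ...],
        rng: np.random.Generator,
        enabled: tuple[str, ...] = INSTANCE_ORDER,
        intercept: bool = False,
    ):
        unknown = set(enabled) - set(INSTANCE_ORDER)
        if unknown:
            raise ValueError(f"unknown instance roles: {sorted(unknown)}")
        if not enabled:
            raise ValueError("at least one instance role must be enabled")
        self.enabled = tuple(r for r in INSTANCE_ORDER if r in enabled)
        widths = {
            "public_dp": feature_width,
            "public_pd": feature_width,
            "public_concat": 2 * feature_width,
            "private_d": feature_width,
        }
        self.scorers = [MlpScorer(widths[r], hidden, rng) for r in self.enabled]
        self.fusion_weights = Tensor(
            np.full(len(self.enabled), 0.25), requires_grad=True
        )
        self.intercept = (
            Tensor(np.zeros(1), requires_grad=True) if intercept else None
        )

    def scores(self, instances: dict[str, Tensor]) -> Tensor:
        """Stacked per-instance scores, shape (..., n_enabled)."""
        cols = [
            self.scorers[i](instances[r]).reshape(-1, 1)
            for i, r in enumerate(self.enabled)
        ]
        return concat(cols, axis=-1)

    def __call__(self, instances: dict[str, Tensor]) -> tuple[Tensor, Tensor]:
        s = self.scores(instances)
        y_hat = (s * self.fusion_weights).sum(axis=-1)
        if self.intercept is not None:
            y_hat = y_hat + self.intercept[0]
        return y_hat, s


def score_instances(instance_set, head: MilHead) -> np.ndarray:
    """Score one bag's instances; returns the per-instance score vector."""
    tensors = {
        r: Tensor(np.asarray(v)[None])
        for r, v in zip(
            INSTANCE_ORDER,
            (
                instance_set.public_dp,
                instance_set.public_pd,
                instance_set.public_concat,
                instance_set.private_d,
            ),
        )
        if r in head.enabled
    }
    return head.scores(tensors).data[0]


def fuse_scores(scores, weights) -> float:
    """ŷ = Σ wᵢ·scoreᵢ (no intercept)."""
    scores = np.asarray(scores, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if scores.shape != weights.shape:
        raise ValueError(f"length mismatch: {scores.shape} vs {weights.shape}")
    return float(np.dot(weights, scores))


def mse_loss(y_hat, y) -> float:
    """Mean of squared residuals."""
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if y_hat.shape != y.shape:
        raise ValueError(f"length mismatch: {y_hat.shape} vs {y.shape}")
    if y.size == 0:
        raise ValueError("mse_loss of empty input")
    return float(np.mean((y - y_hat) ** 2))


def mse_loss_tensor(y_hat: Tensor, y: np.ndarray) -> Tensor:
    """Differentiable mean-squared-error for training."""
    diff = y_hat - np.asarray(y, dtype=float)
    return (diff**2).mean()
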