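"""Integrated-Gradients attribution for window classifiers.

attribution_j = (x_j - baseline_j) * mean_{k=1..n} dF/dx_j evaluated at
baseline + (k/n) * (x - baseline)  (right Riemann sum along the straight
line from the baseline, by default the zero vector in standardized space).

``F`` is the model's stress probability.  For ensembles the attribution is
the mean of member attributions, which matches the attribution of the
probability-averaged ensemble because averaging commutes with the gradient.
Cohort-level relevance is the arithmetic mean of per-window maps over the
selected class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .augment import DGEnsemble, OuterEnsemble
from .model import TrainedClassifier, forward, input_gradients
from .preprocess import WindowedDataset

__all__ = [
    "AttributionMap",
    "GlobalAttribution",
    "integrated_gradients",
    "global_attribution",
]


@dataclass
class AttributionMap:
    """Signed per-time-step, per-channel relevance for one window."""

    values: np.ndarray  # (T, channels)
    window: np.ndarray
    baseline_type: str
    n_steps: int
    completeness_gap: float  # |sum(values) - (F(x) - F(baseline))|

    def to_frame(self, channel_names=None) -> pd.DataFrame:
        T, C = self.values.shape
        names = channel_names or [f"ch{c}" for c in range(C)]
        rows = [
            {"time_step": t, "channel": names[c], "relevance": self.values[t, c]}
            for t in range(T)
            for c in range(C)
        ]
        return pd.DataFrame(rows)


@dataclass
class GlobalAttribution:
    """Cohort-averaged relevance over one class of windows."""

    mean_values: np.ndarray  # (T, channels)
    n_windows_averaged: int
    class_condition: int
    n_steps: int


def _as_value_grad(model):
    """Normalize a model into ``(value(x_batch), grad(x_batch))`` callables.

    Supported: TrainedClassifier, DGEnsemble, OuterEnsemble (stress
    probability as the attributed output), or any object exposing ``value``
    and ``grad`` methods over batched windows.
    """
    if hasattr(model, "value") and hasattr(model, "grad"):
        return model.value, model.grad
    if isinstance(model, TrainedClassifier):
        clfs = [model]
    elif isinstance(model, DGEnsemble):
        clfs = [clf for _, clf in model.members]
    elif isinstance(model, OuterEnsemble):
        clfs = [clf for dge in model.members for _, clf in dge.members]
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")

    def value(x: np.ndarray) -> np.ndarray:
        return np.stack(
            [forward(c.params, x, expected_len=None) for c in clfs]
        ).mean(axis=0)

    def grad(x: np.ndarray) -> np.ndarray:
        return np.stack(
            [input_gradients(c.params, x, of="probability") for c in clfs]
        ).mean(axis=0)

    return value, grad


def integrated_gradients(
    model,
    window: np.ndarray,
    baseline: np.ndarray | None = None,
    n_steps: int = 128,
) -> AttributionMap:
    """IG attribution of the stress probability for a single window."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    window = np.asarray(window, dtype=float)
    if baseline is None:
        baseline = np.zeros_like(window)
        baseline_type = "zero"
    else:
        baseline = np.asarray(baseline, dtype=float)
        baseline_type = "custom"
    if baseline.shape != window.shape:
        raise ValueError("baseline must have the same shape as the window")

    value, grad = _as_value_grad(model)
    alphas = np.arange(1, n_steps + 1) / n_steps  # right Riemann sum
    points = baseline[None] + alphas[:, None, None] * (window - baseline)[None]
    mean_grad = grad(points).mean(axis=0)
    values = (window - baseline) * mean_grad

    f_x = float(value(window[None])[0])
    f_b = float(value(baseline[None])[0])
    gap = abs(values.sum() - (f_x - f_b))
    return AttributionMap(values, window, baseline_type, n_steps, gap)


def global_attribution(
    model,
    dataset: WindowedDataset,
    class_condition: int = 1,
    n_steps: int = 128,
    baseline: np.ndarray | None = None,
) -> GlobalAttribution:
    """Average per-window attributions over all windows of one class."""
    mask = dataset.labels == class_condition
    if not mask.any():
        raise ValueError(f"no windows with label {class_condition}")
    selected = dataset.windows[mask]
    total = np.zeros(selected.shape[1:])
    for w in selected:
        total += integrated_gradients(model, w, baseline, n_steps).values
    return GlobalAttribution(
        mean_values=total / len(selected),
        n_windows_averaged=int(len(selected)),
        class_condition=class_condition,
        n_steps=n_steps,
    )
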