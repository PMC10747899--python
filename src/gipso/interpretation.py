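"""Shapley-style per-lag attribution for trained anomaly classifiers.

Each lag's contribution to a prediction is estimated game-theoretically:
features enter in random order and the attribution of lag k is the average
change in model output when k joins the coalition of already-present lags,
with absent lags imputed from a background window set.  Averaged over many
random orders (and background draws) this converges to the Shapley value,
whose additivity makes the per-sample attributions sum to the difference
between the sample's output and the background mean output.

An exact enumeration mode (all 2^D coalitions, Shapley-weighted) is provided
for small window sizes and serves as the reference in tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .data import WindowedDataset
from .recurrent_classifier import RNNParameters, forward

__all__ = ["AttributionSummary", "feature_importance", "write_importance_csv"]


@dataclass
class AttributionSummary:
    """Per-sample attribution matrix and its per-lag mean-|value| summary."""

    per_lag: np.ndarray        # (D,) mean absolute attribution per lag
    attributions: np.ndarray   # (n_samples, D)
    expected_value: float      # background mean model output
    background_id: str = "background"

    @property
    def n_lags(self) -> int:
        return self.attributions.shape[1]


def _predict_fn(model) -> Callable[[np.ndarray], np.ndarray]:
    if isinstance(model, RNNParameters):
        return lambda X: np.asarray(forward(model, X), dtype=float)
    if callable(model):
        return lambda X: np.asarray(model(X), dtype=float)
    raise TypeError("model must be an RNNParameters or a callable on windows")


def feature_importance(
    model,
    background: WindowedDataset | np.ndarray,
    samples: WindowedDataset | np.ndarray,
    n_coalitions: int = 128,
    seed: int = 0,
    exact: bool = False,
) -> AttributionSummary:
    """Estimate per-lag Shapley attributions for each sample window.

    ``n_coalitions`` random feature orderings are sampled per window (each
    paired with a background draw for imputation); ``exact=True`` switches to
    full coalition enumeration against the whole background set (cost grows
    as 2^D — intended for small windows).
    """
    f = _predict_fn(model)
    bg = background.X if isinstance(background, WindowedDataset) else np.asarray(background, dtype=float)
    Xs = samples.X if isinstance(samples, WindowedDataset) else np.asarray(samples, dtype=float)
    if bg.ndim != 2 or bg.shape[0] == 0:
        raise ValueError("background set must be a non-empty window matrix")
    rng = np.random.default_rng(seed)
    D = Xs.shape[1]
    expected = float(np.mean(f(bg)))

    if exact:
        attr = np.array([_exact_shapley(f, x, bg) for x in Xs])
    else:
        attr = np.array(
            [_sampled_shapley(f, x, bg, D, n_coalitions, rng) for x in Xs]
        )
    return AttributionSummary(
        per_lag=np.abs(attr).mean(axis=0),
        attributions=attr,
        expected_value=expected,
    )


def _sampled_shapley(
    f: Callable,
    x: np.ndarray,
    bg: np.ndarray,
    D: int,
    n_coalitions: int,
    rng: np.random.Generator,
) -> np.ndarray:
    phi = np.zeros(D)
    for _ in range(n_coalitions):
        order = rng.permutation(D)
        base = bg[rng.integers(len(bg))]
        # states[j] = base with x substituted at the first j features in order
        states = np.tile(base, (D + 1, 1))
        for j, k in enumerate(order):
            states[j + 1 :, k] = x[k]
        out = f(states)
        phi[order] += np.diff(out)
    return phi / n_coalitions


def _exact_shapley(f: Callable, x: np.ndarray, bg: np.ndarray) -> np.ndarray:
    """Shapley values by full coalition enumeration, imputing absent lags
    with every background row (coalition value = mean model output)."""
    D = x.shape[0]
    value: dict[frozenset, float] = {}
    for size in range(D + 1):
        for S in combinations(range(D), size):
            states = bg.copy()
            if S:
                states[:, list(S)] = x[list(S)]
            value[frozenset(S)] = float(np.mean(f(states)))
    phi = np.zeros(D)
    fact = [factorial(i) for i in range(D + 1)]
    for k in range(D):
        for size in range(D):
            weight = fact[size] * fact[D - size - 1] / fact[D]
            for S in combinations([j for j in range(D) if j != k], size):
                fs = frozenset(S)
                phi[k] += weight * (value[fs | {k}] - value[fs])
    return phi


def write_importance_csv(summary: AttributionSummary, path: str | Path) -> None:
    pd.DataFrame(
        {
            "lag": np.arange(1, summary.n_lags + 1),
            "mean_abs_attribution": summary.per_lag,
        }
    ).to_csv(path, index=False)


def plot_importance(summary: AttributionSummary, path: str | Path) -> None:
    """Beeswarm-style scatter of per-sample attributions by lag, with the
    mean-|attribution| bar behind it."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    D = summary.n_lags
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(np.arange(1, D + 1), summary.per_lag, color="0.85", label="mean |attribution|")
    rng = np.random.default_rng(0)
    for k in range(D):
        jitter = rng.uniform(-0.25, 0.25, size=summary.attributions.shape[0])
        ax.scatter(
            np.full_like(jitter, k + 1) + jitter,
            summary.attributions[:, k],
            s=8, alpha=0.6, color="tab:red",
        )
    ax.axhline(0.0, lw=0.5, color="k")
    ax.set_xlabel("lag (steps before prediction)")
    ax.set_ylabel("attribution to anomaly probability")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
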