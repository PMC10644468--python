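"""Bootstrap accuracy and stability diagnostics for estimated networks.

Two resampling schemes:

* nonparametric edge-weight bootstrap — resample subjects with replacement,
  re-run the whole Gaussianize-and-select pipeline, and summarize each
  edge's sampling distribution with percentile 95% intervals; pairs of
  edges can be compared with a bootstrapped difference test;
* case-dropping bootstrap — re-estimate centrality on progressively smaller
  subsamples and track its correlation with the full-sample centrality;
  the correlation-stability (CS) coefficient is the largest drop proportion
  at which that correlation stays >= 0.7 in at least 95% of subsamples
  (above 0.25 is considered acceptable stability, above 0.5 preferable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ggm import select_network
from .preprocess import npn_transform

__all__ = ["EdgeBootstrap", "CaseDropResult", "edge_bootstrap", "case_dropping"]

DEFAULT_DROP_GRID = np.round(np.arange(0.05, 0.751, 0.05), 2)

CS_CORRELATION_THRESHOLD = 0.7
CS_PROBABILITY = 0.95


def _estimate_weights(values, labels, gamma, n_lambda, lambda_min_ratio):
    data = npn_transform(values, labels)
    net, _ = select_network(data, gamma=gamma, n_lambda=n_lambda,
                            lambda_min_ratio=lambda_min_ratio)
    return net


def _upper(mat: np.ndarray, iu) -> np.ndarray:
    return mat[iu]


@dataclass
class EdgeBootstrap:
    node_labels: list[str]
    edge_index: list[tuple[str, str]]
    point_estimates: np.ndarray        # (n_edges,)
    samples: np.ndarray                # (B, n_edges)
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_redrawn: int
    seed: int

    @property
    def B(self) -> int:
        return self.samples.shape[0]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_a": [a for a, _ in self.edge_index],
                "node_b": [b for _, b in self.edge_index],
                "estimate": self.point_estimates,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )

    def _edge_pos(self, edge: tuple[str, str]) -> int:
        a, b = edge
        for key in ((a, b), (b, a)):
            if key in self.edge_index:
                return self.edge_index.index(key)
        raise KeyError(f"edge {edge} not found")

    def difference_test(self, edge1: tuple[str, str], edge2: tuple[str, str],
                        level: float = 0.95) -> bool:
        """True when the percentile CI of the bootstrap difference excludes 0."""
        i, j = self._edge_pos(edge1), self._edge_pos(edge2)
        if i == j:
            return False
        diff = self.samples[:, i] - self.samples[:, j]
        alpha = 1 - level
        lo, hi = np.quantile(diff, [alpha / 2, 1 - alpha / 2])
        return bool(lo > 0 or hi < 0)


@dataclass
class CaseDropResult:
    drop_proportions: np.ndarray
    correlations: dict = field(default_factory=dict)  # proportion -> array of correlations
    cs_coefficient: float = 0.0
    seed: int = 0

    def summary(self) -> pd.DataFrame:
        rows = []
        for q in self.drop_proportions:
            c = np.asarray(self.correlations[float(q)])
            rows.append((q, c.mean(), np.quantile(c, 0.05),
                         float(np.mean(c >= CS_CORRELATION_THRESHOLD))))
        return pd.DataFrame(rows, columns=["drop_proportion", "mean_correlation",
                                           "q05_correlation", "prop_above_0.7"])


def edge_bootstrap(
    items: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    level: float = 0.95,
) -> EdgeBootstrap:
    """Nonparametric bootstrap of all edge weights.

    Subjects are resampled with replacement ``B`` times and the full
    estimation pipeline is re-run on each resample.  Resamples in which an
    item collapses to a constant cannot be Gaussianized and are redrawn;
    the redraw count is reported.
    """
    if B < 200:
        raise ValueError("B must be >= 200 for stable percentile intervals")
    values = np.asarray(items, dtype=float)
    labels = [str(c) for c in items.columns]
    n, p = values.shape
    net = _estimate_weights(values, labels, gamma, n_lambda, lambda_min_ratio)
    iu = np.triu_indices(p, k=1)
    edge_index = [(labels[i], labels[j]) for i, j in zip(*iu)]
    point = net.weights[iu]

    rng = np.random.default_rng(seed)
    samples = np.empty((B, len(edge_index)))
    n_redrawn = 0
    for b in range(B):
        for _attempt in range(1000):
            idx = rng.integers(0, n, size=n)
            sub = values[idx]
            if all(np.unique(sub[:, j]).size >= 2 for j in range(p)):
                break
            n_redrawn += 1
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap resample")
        bnet = _estimate_weights(sub, labels, gamma, n_lambda, lambda_min_ratio)
        samples[b] = bnet.weights[iu]
    alpha = 1 - level
    lo = np.quantile(samples, alpha / 2, axis=0)
    hi = np.quantile(samples, 1 - alpha / 2, axis=0)
    return EdgeBootstrap(labels, edge_index, point, samples, lo, hi, n_redrawn, seed)


def case_dropping(
    items: pd.DataFrame,
    drop_proportions=None,
    B: int = 50,
    seed: int = 0,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
) -> CaseDropResult:
    """Case-dropping bootstrap of expected-influence stability.

    For each drop proportion q, draws ``B`` subsamples of size
    ceil((1-q) n) without replacement, recomputes EI, and correlates it
    (Pearson) with the full-sample EI.  Zero-variance EI vectors contribute
    correlation 0 by convention.  The CS coefficient is the largest q in
    the grid at which >= 95% of correlations are >= 0.7 (0 if none).
    """
    if drop_proportions is None:
        drop_proportions = DEFAULT_DROP_GRID
    grid = np.asarray(drop_proportions, dtype=float)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("drop proportions must lie strictly inside (0, 1)")
    values = np.asarray(items, dtype=float)
    labels = [str(c) for c in items.columns]
    n, p = values.shape
    smallest = int(np.ceil((1 - grid.max()) * n))
    if smallest < 3 * p:
        raise ValueError(
            f"smallest retained subsample ({smallest}) must be >= 3x node count ({3 * p})"
        )
    full_net = _estimate_weights(values, labels, gamma, n_lambda, lambda_min_ratio)
    full_ei = full_net.weights.sum(axis=1)

    rng = np.random.default_rng(seed)
    correlations: dict = {}
    for q in grid:
        m = int(np.ceil((1 - q) * n))
        cors = np.empty(B)
        for b in range(B):
            for _attempt in range(1000):
                idx = rng.choice(n, size=m, replace=False)
                sub = values[idx]
                if all(np.unique(sub[:, j]).size >= 2 for j in range(p)):
                    break
            else:
                raise RuntimeError("could not draw a non-degenerate subsample")
            sub_net = _estimate_weights(sub, labels, gamma, n_lambda, lambda_min_ratio)
            sub_ei = sub_net.weights.sum(axis=1)
            if np.std(sub_ei) == 0 or np.std(full_ei) == 0:
                cors[b] = 0.0
            else:
                cors[b] = float(np.corrcoef(full_ei, sub_ei)[0, 1])
        correlations[float(q)] = cors

    cs = 0.0
    for q in sorted(grid):
        frac = float(np.mean(correlations[float(q)] >= CS_CORRELATION_THRESHOLD))
        if frac >= CS_PROBABILITY:
            cs = max(cs, float(q))
    return CaseDropResult(grid, correlations, cs, seed)
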