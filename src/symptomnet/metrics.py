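"""Node-level network indices: expected influence, strength, predictability.

Expected influence is the signed one-step sum of a node's edge weights —
the centrality of choice for networks whose edges can be negative, since
strength (the absolute sum) conflates activating and protective ties.
Predictability is the share of a node's variance explained by its
neighbors, computed here as the nodewise linear R-squared on the
Gaussianized data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ggm import SymptomNetwork
from .preprocess import TransformedMatrix

__all__ = [
    "CentralityTable",
    "expected_influence",
    "two_step_expected_influence",
    "strength",
    "predictability",
    "centrality_table",
    "centrality_similarity",
]

_DEGENERATE_R2 = 1.0 - 1e-10


@dataclass
class SimilarityResult:
    correlation: float
    p_value: float


@dataclass
class CentralityTable:
    frame: pd.DataFrame  # index: node; columns: expected_influence, strength, predictability, ei_z

    @property
    def mean_predictability(self) -> float:
        return float(self.frame["predictability"].mean())

    def top_nodes(self, k: int = 3) -> list[str]:
        return list(self.frame["expected_influence"].nlargest(k).index)


def expected_influence(network: SymptomNetwork) -> pd.Series:
    """One-step expected influence EI(i) = sum_j w_ij (signed)."""
    ei = network.weights.sum(axis=1)
    return pd.Series(ei, index=network.node_labels, name="expected_influence")


def two_step_expected_influence(network: SymptomNetwork) -> pd.Series:
    """EI2(i) = EI1(i) + sum_j w_ij EI1(j): influence through one intermediary."""
    ei1 = network.weights.sum(axis=1)
    ei2 = ei1 + network.weights @ ei1
    return pd.Series(ei2, index=network.node_labels, name="expected_influence_2step")


def strength(network: SymptomNetwork) -> pd.Series:
    """Strength centrality: sum of absolute incident edge weights."""
    s = np.abs(network.weights).sum(axis=1)
    return pd.Series(s, index=network.node_labels, name="strength")


def predictability(data: TransformedMatrix, network: SymptomNetwork) -> pd.Series:
    """Nodewise R-squared: variance of each node explained by all others.

    Exact linear combinations (R^2 ~ 1) are reported but flagged via the
    returned Series' ``attrs['degenerate']`` list.
    """
    if list(data.variable_labels) != list(network.node_labels):
        raise ValueError("data columns must match network nodes")
    V = data.values
    n, p = V.shape
    r2 = np.empty(p)
    degenerate = []
    for j in range(p):
        others = np.delete(np.arange(p), j)
        X = np.column_stack([np.ones(n), V[:, others]])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                f"regressors for node {network.node_labels[j]!r} are rank deficient"
            )
        beta, *_ = np.linalg.lstsq(X, V[:, j], rcond=None)
        resid = V[:, j] - X @ beta
        tss = float(((V[:, j] - V[:, j].mean()) ** 2).sum())
        r2[j] = 1.0 - float((resid**2).sum()) / tss
        if r2[j] >= _DEGENERATE_R2:
            degenerate.append(network.node_labels[j])
    out = pd.Series(r2, index=network.node_labels, name="predictability")
    out.attrs["degenerate"] = degenerate
    return out


def centrality_table(
    data: TransformedMatrix | None, network: SymptomNetwork
) -> CentralityTable:
    """Assemble EI, strength and (if data given) predictability per node."""
    ei = expected_influence(network)
    frame = pd.DataFrame({
        "expected_influence": ei,
        "strength": strength(network),
    })
    if data is not None:
        frame["predictability"] = predictability(data, network)
    sd = ei.std(ddof=1)
    frame["ei_z"] = 0.0 if sd == 0 else (ei - ei.mean()) / sd
    return CentralityTable(frame)


def centrality_similarity(ei_a, ei_b) -> "SimilarityResult":
    """Spearman rank correlation between two networks' EI vectors."""
    a = np.asarray(ei_a, dtype=float).ravel()
    b = np.asarray(ei_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("EI vectors must cover the same node set")
    if a.size < 3:
        raise ValueError("need at least 3 nodes for a rank correlation")
    r, p = stats.spearmanr(a, b)
    return SimilarityResult(float(r), float(p))
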