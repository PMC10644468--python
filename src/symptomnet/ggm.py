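"""EBIC-selected regularized partial-correlation networks.

The estimator follows the standard psychometric-network recipe: compute the
(copula-scale) correlation matrix, solve the graphical lasso along a
log-spaced penalty path, score every solution with the extended BIC, keep
the minimizer, and report the selected precision matrix as partial
correlations rho_ij = -K_ij / sqrt(K_ii K_jj).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glasso import ebic_score, glasso_path
from .preprocess import TransformedMatrix, correlation_matrix

__all__ = [
    "SymptomNetwork",
    "LambdaPath",
    "precision_to_partials",
    "select_network",
    "flow_edges",
]

_ZERO_TOL = 1e-8


@dataclass
class SymptomNetwork:
    """A weighted symptom network: nodes plus regularized partial correlations.

    ``weights`` is symmetric with exact zero diagonal; entries with
    |rho| <= 1e-8 after conversion are stored as exact zeros so that edge
    counts are well-defined.
    """

    node_labels: list[str]
    weights: np.ndarray
    lambda_selected: float
    gamma: float
    ebic_value: float
    n_subjects: int

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def edge_count(self) -> int:
        iu = np.triu_indices(self.n_nodes, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    def edge_list(self) -> pd.DataFrame:
        """Nonzero edges as a (node_a, node_b, weight) table."""
        rows = []
        for i in range(self.n_nodes):
            for j in range(i + 1, self.n_nodes):
                w = self.weights[i, j]
                if w != 0.0:
                    rows.append((self.node_labels[i], self.node_labels[j], w))
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])

    def to_json(self) -> str:
        return json.dumps(
            {
                "node_labels": self.node_labels,
                "weights": self.weights.tolist(),
                "lambda_selected": self.lambda_selected,
                "gamma": self.gamma,
                "ebic_value": self.ebic_value,
                "n_subjects": self.n_subjects,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SymptomNetwork":
        d = json.loads(text)
        return cls(
            node_labels=list(d["node_labels"]),
            weights=np.asarray(d["weights"], dtype=float),
            lambda_selected=float(d["lambda_selected"]),
            gamma=float(d["gamma"]),
            ebic_value=float(d["ebic_value"]),
            n_subjects=int(d["n_subjects"]),
        )


@dataclass
class LambdaPath:
    """Penalty path diagnostics: one row per lambda value (decreasing order)."""

    lambda_values: np.ndarray
    edge_counts: np.ndarray
    ebic_values: np.ndarray
    log_likelihoods: np.ndarray
    selected_index: int = field(default=-1)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda": self.lambda_values,
                "edges": self.edge_counts,
                "log_likelihood": self.log_likelihoods,
                "ebic": self.ebic_values,
            }
        )


def precision_to_partials(K: np.ndarray, zero_tol: float = _ZERO_TOL) -> np.ndarray:
    """Partial correlations rho_ij = -K_ij / sqrt(K_ii K_jj), zero diagonal."""
    K = np.asarray(K, dtype=float)
    d = np.sqrt(np.diag(K))
    if np.any(d <= 0):
        raise ValueError("precision matrix must have positive diagonal")
    P = -K / np.outer(d, d)
    P = (P + P.T) / 2.0
    P[np.abs(P) <= zero_tol] = 0.0
    np.fill_diagonal(P, 0.0)
    return P


def select_network(
    data: TransformedMatrix,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
) -> tuple[SymptomNetwork, LambdaPath]:
    """Estimate the EBIC-selected regularized partial-correlation network.

    The penalty path is log-spaced over ``n_lambda`` values from
    lambda_max (the largest absolute off-diagonal correlation, at which the
    graph is empty) down to lambda_max * lambda_min_ratio.  Exact EBIC ties
    are broken toward the larger penalty, i.e. the sparser model.
    """
    S = correlation_matrix(data)
    n, p = data.values.shape
    iu = np.triu_indices(p, k=1)
    lam_max = float(np.max(np.abs(S[iu])))
    if lam_max <= 0:
        lam_max = 1e-3  # diagonal correlation matrix; any path selects the empty graph
    lambdas = np.exp(
        np.linspace(np.log(lam_max), np.log(lam_max * lambda_min_ratio), n_lambda)
    )
    precisions = glasso_path(S, lambdas)

    edge_counts = np.empty(n_lambda, dtype=int)
    ebics = np.empty(n_lambda)
    logliks = np.empty(n_lambda)
    log_n, log_p = np.log(n), np.log(p)
    for i, K in enumerate(precisions):
        sign, logdet = np.linalg.slogdet(K)
        logliks[i] = 0.5 * n * (logdet - float(np.sum(S * K)))
        E = int(np.count_nonzero(np.abs(K[iu]) > _ZERO_TOL))
        edge_counts[i] = E
        ebics[i] = -2.0 * logliks[i] + E * log_n + 4.0 * gamma * E * log_p
    # path is in decreasing lambda order, so argmin lands on the largest
    # penalty among exact ties
    best = int(np.argmin(ebics))
    weights = precision_to_partials(precisions[best])
    net = SymptomNetwork(
        node_labels=list(data.variable_labels),
        weights=weights,
        lambda_selected=float(lambdas[best]),
        gamma=float(gamma),
        ebic_value=float(ebics[best]),
        n_subjects=n,
    )
    path = LambdaPath(lambdas, edge_counts, ebics, logliks, selected_index=best)
    return net, path


def flow_edges(network: SymptomNetwork, target_label: str) -> list[tuple[str, float]]:
    """Direct edges incident to one node, most negative first.

    This is the "flow" view of a network: only the edges touching the
    target (here typically the quality-of-life node) are kept, ranking the
    symptoms by their direct conditional association with it.  Nodes with a
    zero edge are omitted; positive edges are kept (sign is not filtered).
    """
    if target_label not in network.node_labels:
        raise KeyError(f"node {target_label!r} not in network")
    t = network.node_labels.index(target_label)
    pairs = [
        (lab, float(network.weights[i, t]))
        for i, lab in enumerate(network.node_labels)
        if i != t and network.weights[i, t] != 0.0
    ]
    return sorted(pairs, key=lambda kv: kv[1])
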