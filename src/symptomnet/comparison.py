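"""Permutation test for differences between two group networks.

Both groups' networks are estimated with the identical pipeline, then
subjects are pooled and group labels reassigned at random (preserving group
sizes) to build the null distribution of

* M — the maximum absolute edge-weight difference (structure invariance),
* S — the absolute difference of global strengths, where global strength
  is the sum of absolute upper-triangle weights (global strength
  invariance),
* per-edge absolute differences and per-node expected-influence
  differences, Holm-adjusted across their respective families.

p-values use the add-one convention p = (1 + #{perm >= obs}) / (1 + n_perm)
and hence are never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .ggm import select_network
from .preprocess import npn_transform

__all__ = ["NCTResult", "nct"]


@dataclass
class NCTResult:
    m_statistic: float
    s_statistic: float
    p_m: float
    p_s: float
    edge_table: pd.DataFrame     # node_a, node_b, diff, p_raw, p_holm
    node_table: pd.DataFrame     # node, ei_diff, p_raw, p_holm
    n_permutations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "m_statistic": self.m_statistic,
            "p_m": self.p_m,
            "s_statistic": self.s_statistic,
            "p_s": self.p_s,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def _fit_weights(values, labels, gamma, n_lambda, lambda_min_ratio):
    data = npn_transform(values, labels)
    net, _ = select_network(data, gamma=gamma, n_lambda=n_lambda,
                            lambda_min_ratio=lambda_min_ratio)
    return net.weights


def _stats_from_weights(wa, wb, iu):
    edge_diff = np.abs(wa - wb)[iu]
    m = float(edge_diff.max())
    s = float(abs(np.abs(wa[iu]).sum() - np.abs(wb[iu]).sum()))
    ei_diff = np.abs(wa.sum(axis=1) - wb.sum(axis=1))
    return m, s, edge_diff, ei_diff


def nct(
    data_a: pd.DataFrame,
    data_b: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int = 0,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
) -> NCTResult:
    """Network comparison test between two groups of subjects.

    ``data_a`` and ``data_b`` must share the same item columns.  Each group
    must contain at least 3x as many subjects as there are nodes.
    """
    labels = [str(c) for c in data_a.columns]
    if [str(c) for c in data_b.columns] != labels:
        raise ValueError("both groups must have the same variables in the same order")
    A = np.asarray(data_a, dtype=float)
    Bv = np.asarray(data_b, dtype=float)
    na, nb = A.shape[0], Bv.shape[0]
    p = A.shape[1]
    if min(na, nb) < 3 * p:
        raise ValueError(f"each group needs >= {3 * p} subjects (3x node count)")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")

    iu = np.triu_indices(p, k=1)
    wa = _fit_weights(A, labels, gamma, n_lambda, lambda_min_ratio)
    wb = _fit_weights(Bv, labels, gamma, n_lambda, lambda_min_ratio)
    m_obs, s_obs, edge_obs, ei_obs = _stats_from_weights(wa, wb, iu)

    pooled = np.vstack([A, Bv])
    n = na + nb
    rng = np.random.default_rng(seed)
    count_m = 0
    count_s = 0
    count_edge = np.zeros_like(edge_obs)
    count_ei = np.zeros_like(ei_obs)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        pa = pooled[perm[:na]]
        pb = pooled[perm[na:]]
        if any(np.unique(pa[:, j]).size < 2 for j in range(p)) or any(
            np.unique(pb[:, j]).size < 2 for j in range(p)
        ):
            # degenerate relabeling: count as extreme (conservative)
            count_m += 1
            count_s += 1
            count_edge += 1
            count_ei += 1
            continue
        wpa = _fit_weights(pa, labels, gamma, n_lambda, lambda_min_ratio)
        wpb = _fit_weights(pb, labels, gamma, n_lambda, lambda_min_ratio)
        m_p, s_p, edge_p, ei_p = _stats_from_weights(wpa, wpb, iu)
        count_m += m_p >= m_obs
        count_s += s_p >= s_obs
        count_edge += edge_p >= edge_obs
        count_ei += ei_p >= ei_obs

    denom = 1.0 + n_permutations
    p_m = (1.0 + count_m) / denom
    p_s = (1.0 + count_s) / denom
    p_edge = (1.0 + count_edge) / denom
    p_ei = (1.0 + count_ei) / denom
    edge_holm = multipletests(p_edge, method="holm")[1]
    ei_holm = multipletests(p_ei, method="holm")[1]

    edge_table = pd.DataFrame(
        {
            "node_a": [labels[i] for i in iu[0]],
            "node_b": [labels[j] for j in iu[1]],
            "abs_diff": edge_obs,
            "p_raw": p_edge,
            "p_holm": edge_holm,
        }
    )
    node_table = pd.DataFrame(
        {"node": labels, "ei_abs_diff": ei_obs, "p_raw": p_ei, "p_holm": ei_holm}
    )
    return NCTResult(m_obs, s_obs, float(p_m), float(p_s), edge_table, node_table,
                     n_permutations, seed)
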