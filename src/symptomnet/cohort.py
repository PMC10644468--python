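"""Synthetic questionnaire cohorts with known network ground truth.

The generator implements a latent Gaussian copula: a zero-mean multivariate
normal whose inverse covariance (precision) carries a sparse
partial-correlation graph, discretized item-by-item through fixed
thresholds into ordinal 0..4 scores.  Because the latent graph is known
exactly, every downstream stage — Gaussianization, graphical-lasso
estimation, centrality, stability, comparison — can be tested against
ground truth.  A one-parameter threshold shift is calibrated by bisection
so that the fraction of subjects crossing the clinical sum-score cut-off
matches a requested prevalence.

Covariates are drawn from simple marginal families (their rates default to
a published caregiver cohort's marginals) and symptom-linked outcomes
(depression, anxiety, fatigue, quality of life) are linear-Gaussian
functions of the latent severity, rounded and clamped into their legal
questionnaire ranges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GroundTruthModel",
    "ground_truth_from_partials",
    "make_ground_truth",
    "default_model",
    "sample_items",
    "generate_cohort",
    "ISI_LABELS",
]

ISI_LABELS = [f"ISI{i}" for i in range(1, 8)]
QOL_LABEL = "QOL"

#: latent cut points (standard-normal scale) shared by all ISI items;
#: chosen so that most subjects score 0-1 per item, as in community samples
_DEFAULT_CUTS = np.array([0.55, 1.25, 1.95, 2.60])

#: the default 7-item graph is derived from a one-factor marginal structure
#: (strongly intercorrelated items, as questionnaire sum-scales show) with
#: extra residual dependence inside a nocturnal cluster (items 1-2-3) and a
#: dissatisfaction/daytime cluster (items 4-7, 5-6-7); factor loadings and
#: residual boosts are assumptions of the generator, not estimates from any
#: dataset.  Partials below 0.02 in magnitude are zeroed so the true edge
#: set is well-defined.
_DEFAULT_LOADINGS = np.array([0.86, 0.90, 0.82, 0.85, 0.84, 0.78, 0.88])
_DEFAULT_CLUSTER_RESID = {
    (0, 1): 0.06, (1, 2): 0.05, (0, 2): 0.04,
    (3, 6): 0.06, (4, 5): 0.06, (4, 6): 0.04, (5, 6): 0.04, (3, 4): 0.03,
}
_SPARSIFY_TOL = 0.02


def _default_item_partials() -> np.ndarray:
    R = np.outer(_DEFAULT_LOADINGS, _DEFAULT_LOADINGS)
    for (i, j), w in _DEFAULT_CLUSTER_RESID.items():
        R[i, j] += w
        R[j, i] += w
    np.fill_diagonal(R, 1.0)
    K = np.linalg.inv(R)
    d = np.sqrt(np.diag(K))
    P = -K / np.outer(d, d)
    np.fill_diagonal(P, 0.0)
    P[np.abs(P) < _SPARSIFY_TOL] = 0.0
    return (P + P.T) / 2.0

#: direct item-QoL partials concentrated on dissatisfaction (ISI4),
#: distress (ISI7) and daytime interference (ISI5)
_DEFAULT_QOL_EDGES = {3: -0.18, 6: -0.12, 4: -0.07}

_DEFAULT_COVARIATES = {
    "gender": ("bernoulli", 0.401),          # 1 = male
    "married": ("bernoulli", 0.820),
    "employed": ("bernoulli", 0.812),
    "education_high": ("bernoulli", 0.615),
    "rural": ("bernoulli", 0.425),
    "physical_disease": ("bernoulli", 0.047),
    "access_difficulty": ("bernoulli", 0.297),
    "adherence": ("bernoulli", 0.704),
    "financial_status": ("categorical", [0.213, 0.690, 0.097]),  # poor/fair/good
    "social_media": ("categorical", [0.077, 0.323, 0.600]),      # none/some/often
    "diagnosis": ("categorical", [0.363, 0.147, 0.202, 0.288]),  # MDD/BP/SCZ/other
    "site": ("categorical", [1.0 / 7.0] * 7),
    "age": ("normal", 43.06, 11.6, (18.0, 90.0)),
}

#: outcome totals as linear-Gaussian functions of latent severity (the mean
#: of the latent item values; QoL instead loads on the items that carry its
#: network edges).  Intercepts sit at the cohort means, slopes produce
#: realistic insomnia-vs-none contrasts.
_DEFAULT_OUTCOMES = {
    "phq9_total": {"intercept": 3.5, "coef": 6.5, "noise_sd": 3.0,
                   "range": (0, 27), "integer": True, "item_weights": None},
    "gad7_total": {"intercept": 2.7, "coef": 5.5, "noise_sd": 2.8,
                   "range": (0, 21), "integer": True, "item_weights": None},
    "fatigue": {"intercept": 3.07, "coef": 2.5, "noise_sd": 1.9,
                "range": (0, 10), "integer": True, "item_weights": None},
    "qol": {"intercept": 6.56, "coef": -1.6, "noise_sd": 1.2,
            "range": (2.0, 10.0), "integer": False,
            "item_weights": [0.0, 0.0, 0.0, 0.5, 0.2, 0.0, 0.3]},
}

_PD_MARGIN = 1e-6


@dataclass
class GroundTruthModel:
    """Latent Gaussian copula model: precision graph + discretization thresholds.

    ``item_thresholds[label]`` is a strictly increasing vector of latent cut
    points for an ordinal node, or ``None`` for a node observed on the
    continuous latent scale (e.g. QoL).
    """

    node_labels: list[str]
    precision: np.ndarray
    item_thresholds: dict
    covariate_spec: dict = field(default_factory=lambda: dict(_DEFAULT_COVARIATES))
    outcome_spec: dict = field(default_factory=lambda: json.loads(json.dumps(_DEFAULT_OUTCOMES)))
    seed: int = 0

    def __post_init__(self):
        K = np.asarray(self.precision, dtype=float)
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("precision must be symmetric")
        if np.linalg.eigvalsh(K).min() <= 0:
            raise ValueError("precision must be positive definite")
        self.precision = (K + K.T) / 2.0
        for lab, thr in self.item_thresholds.items():
            if thr is None:
                continue
            thr = np.asarray(thr, dtype=float)
            if np.any(np.diff(thr) <= 0):
                raise ValueError(f"thresholds for {lab!r} are not strictly increasing")
            self.item_thresholds[lab] = thr

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def partials_true(self) -> np.ndarray:
        """Partial correlations implied by the precision matrix."""
        d = np.sqrt(np.diag(self.precision))
        P = -self.precision / np.outer(d, d)
        P = (P + P.T) / 2.0
        np.fill_diagonal(P, 0.0)
        return P

    @property
    def latent_correlation(self) -> np.ndarray:
        """Correlation matrix of the latent Gaussian (inverse precision, rescaled)."""
        Sigma = np.linalg.inv(self.precision)
        d = 1.0 / np.sqrt(np.diag(Sigma))
        return Sigma * np.outer(d, d)

    def to_json(self) -> str:
        return json.dumps(
            {
                "node_labels": self.node_labels,
                "precision": self.precision.tolist(),
                "item_thresholds": {
                    k: (None if v is None else np.asarray(v).tolist())
                    for k, v in self.item_thresholds.items()
                },
                "covariate_spec": self.covariate_spec,
                "outcome_spec": self.outcome_spec,
                "seed": self.seed,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthModel":
        d = json.loads(text)
        return cls(
            node_labels=list(d["node_labels"]),
            precision=np.asarray(d["precision"], dtype=float),
            item_thresholds={
                k: (None if v is None else np.asarray(v, dtype=float))
                for k, v in d["item_thresholds"].items()
            },
            covariate_spec=d["covariate_spec"],
            outcome_spec=d["outcome_spec"],
            seed=int(d["seed"]),
        )


def ground_truth_from_partials(
    partials,
    node_labels: list[str] | None = None,
    item_thresholds: dict | None = None,
    seed: int = 0,
    **kwargs,
) -> GroundTruthModel:
    """Build a model with unit-diagonal precision realizing the given partials.

    With K_ii = 1 the precision is K_ij = -rho_ij, so the requested partial
    correlations are realized exactly whenever I - P is positive definite.
    """
    P = np.asarray(partials, dtype=float)
    p = P.shape[0]
    if not np.allclose(P, P.T, atol=1e-10) or np.any(np.diag(P) != 0):
        raise ValueError("partials must be symmetric with zero diagonal")
    K = np.eye(p) - P
    eigmin = np.linalg.eigvalsh(K).min()
    if eigmin <= _PD_MARGIN:
        raise ValueError(
            f"requested partial correlations are infeasible: I - P has "
            f"minimum eigenvalue {eigmin:.4g} <= 0; reduce edge weights"
        )
    if node_labels is None:
        node_labels = [f"V{i + 1}" for i in range(p)]
    if item_thresholds is None:
        item_thresholds = {lab: _DEFAULT_CUTS.copy() for lab in node_labels}
    return GroundTruthModel(
        node_labels=list(node_labels),
        precision=K,
        item_thresholds=item_thresholds,
        seed=seed,
        **kwargs,
    )


def make_ground_truth(
    p: int,
    density: float,
    weight_range: tuple[float, float],
    seed: int,
) -> GroundTruthModel:
    """Random sparse ground-truth graph with requested edge weights.

    ``round(density * p(p-1)/2)`` edges are placed uniformly at random and
    given partial correlations drawn uniformly from ``weight_range``.  If
    the resulting unit-diagonal precision is not positive definite, all
    weights are shrunk by the single closed-form factor that restores a
    positive spectral margin; when that shrink would move any realized
    partial more than 0.01 away from its requested value the combination is
    rejected as infeasible.
    """
    if not (2 <= p <= 30):
        raise ValueError("p must be between 2 and 30")
    if not (0.0 <= density <= 1.0):
        raise ValueError("density must be in [0, 1]")
    lo, hi = weight_range
    if not (-1.0 < lo <= hi < 1.0):
        raise ValueError("weight_range must lie within (-1, 1)")
    rng = np.random.default_rng(seed)
    n_possible = p * (p - 1) // 2
    n_edges = int(round(density * n_possible))
    iu = np.transpose(np.triu_indices(p, k=1))
    chosen = rng.choice(n_possible, size=n_edges, replace=False)
    P = np.zeros((p, p))
    for e in chosen:
        i, j = iu[e]
        w = rng.uniform(lo, hi)
        P[i, j] = P[j, i] = w
    if n_edges:
        eigmax = np.linalg.eigvalsh(P).max()
        if 1.0 - eigmax <= _PD_MARGIN:
            # shrink uniformly so that min eig of I - sP equals the margin
            s = (1.0 - 2 * _PD_MARGIN) / eigmax
            max_dev = (1.0 - s) * np.abs(P).max()
            if max_dev > 0.01:
                raise ValueError(
                    "infeasible weight_range/density combination: achieving "
                    f"positive definiteness requires shrinking weights by "
                    f"{max_dev:.3f} > 0.01 tolerance (spectral radius of the "
                    f"partial matrix is {eigmax:.3f} >= 1)"
                )
            P *= s
    model = ground_truth_from_partials(
        P, node_labels=[f"V{i + 1}" for i in range(p)], seed=seed
    )
    model.seed = seed
    return model


def default_model(include_qol: bool = False, seed: int = 0) -> GroundTruthModel:
    """The package's reference insomnia model: 7 ISI items, optionally + QoL.

    The 7-node graph is a positive manifold with nocturnal, satisfaction and
    daytime clusters; with ``include_qol`` an eighth continuous node is
    attached through negative partials concentrated on ISI4, ISI7 and ISI5.
    """
    p = 8 if include_qol else 7
    P = np.zeros((p, p))
    P[:7, :7] = _default_item_partials()
    labels = list(ISI_LABELS)
    thresholds: dict = {lab: _DEFAULT_CUTS.copy() for lab in ISI_LABELS}
    if include_qol:
        labels.append(QOL_LABEL)
        thresholds[QOL_LABEL] = None
        for i, w in _DEFAULT_QOL_EDGES.items():
            P[i, 7] = P[7, i] = w
    return ground_truth_from_partials(P, labels, thresholds, seed=seed)


def _sample_latent(model: GroundTruthModel, n: int, rng: np.random.Generator) -> np.ndarray:
    R = model.latent_correlation
    L = np.linalg.cholesky(R)
    return rng.standard_normal((n, model.n_nodes)) @ L.T


def _discretize(model: GroundTruthModel, Z: np.ndarray, shift: float = 0.0) -> pd.DataFrame:
    cols = {}
    for j, lab in enumerate(model.node_labels):
        thr = model.item_thresholds.get(lab)
        if thr is None:
            cols[lab] = Z[:, j]
        else:
            cols[lab] = np.searchsorted(thr - shift, Z[:, j]).astype(int)
    return pd.DataFrame(cols)


def sample_items(model: GroundTruthModel, n: int, seed: int) -> pd.DataFrame:
    """Draw n subjects' item scores from the latent copula model.

    Latents come from the zero-mean Gaussian whose covariance is the inverse
    precision rescaled to unit variances; each thresholded node is cut into
    ordinal categories, nodes without thresholds are returned on the latent
    scale.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    Z = _sample_latent(model, n, rng)
    return _discretize(model, Z, shift=0.0)


def _prevalence_at_shift(model, Zcal, shift, item_idx, cutoff=8):
    total = np.zeros(Zcal.shape[0], dtype=int)
    for j in item_idx:
        thr = model.item_thresholds[model.node_labels[j]]
        total += np.searchsorted(thr - shift, Zcal[:, j])
    return float(np.mean(total >= cutoff))


def calibrate_threshold_shift(
    model: GroundTruthModel,
    target_prevalence: float,
    seed: int,
    n_calibration: int = 20_000,
    tol: float = 0.005,
    cutoff: int = 8,
) -> float:
    """Common threshold shift s such that P(sum of item scores >= cutoff) hits target.

    All item thresholds are moved by the same amount (preserving the
    relative item-difficulty profile); the shift is found by bisection on a
    fixed internal calibration sample of latent draws.
    """
    if not (0.0 < target_prevalence < 1.0):
        raise ValueError("target_prevalence must be in (0, 1)")
    rng = np.random.default_rng(seed)
    Zcal = _sample_latent(model, n_calibration, rng)
    item_idx = [
        j for j, lab in enumerate(model.node_labels)
        if model.item_thresholds.get(lab) is not None
    ]
    lo, hi = -4.0, 4.0
    p_lo = _prevalence_at_shift(model, Zcal, lo, item_idx, cutoff)
    p_hi = _prevalence_at_shift(model, Zcal, hi, item_idx, cutoff)
    if not (p_lo <= target_prevalence <= p_hi):
        raise ValueError(
            f"target prevalence {target_prevalence} unattainable; achievable "
            f"range on this model is [{p_lo:.4f}, {p_hi:.4f}]"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        p_mid = _prevalence_at_shift(model, Zcal, mid, item_idx, cutoff)
        if abs(p_mid - target_prevalence) <= tol:
            return mid
        if p_mid < target_prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _draw_covariates(spec: dict, n: int, rng: np.random.Generator) -> dict:
    cols = {}
    for name, entry in spec.items():
        family = entry[0]
        if family == "bernoulli":
            cols[name] = (rng.random(n) < entry[1]).astype(int)
        elif family == "categorical":
            probs = np.asarray(entry[1], dtype=float)
            cols[name] = rng.choice(len(probs), size=n, p=probs / probs.sum())
        elif family == "normal":
            _, mean, sd, clip = entry
            x = rng.normal(mean, sd, size=n)
            x = np.clip(x, clip[0], clip[1])
            cols[name] = np.round(x).astype(int) if name == "age" else x
        else:
            raise ValueError(f"unknown covariate family {family!r} for {name!r}")
    return cols


def generate_cohort(
    n: int,
    model: GroundTruthModel | None = None,
    target_prevalence: float = 0.189,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a full synthetic cohort table.

    Calibrates the common threshold shift to the target prevalence of
    insomnia symptoms (item-sum >= 8), draws item scores, covariates and
    symptom-linked outcome totals, and returns the subject-level table.
    The calibrated shift and the seed are recorded in ``DataFrame.attrs``.
    """
    if model is None:
        model = default_model()
    shift = calibrate_threshold_shift(model, target_prevalence, seed=seed + 1)
    rng = np.random.default_rng(seed)
    Z = _sample_latent(model, n, rng)
    items = _discretize(model, Z, shift=shift)

    item_idx = [model.node_labels.index(lab) for lab in ISI_LABELS]
    item_cols = [c.lower() for c in ISI_LABELS]
    df = pd.DataFrame({c: items[lab].to_numpy() for c, lab in zip(item_cols, ISI_LABELS)})
    df["isi_total"] = df[item_cols].sum(axis=1)

    severity = Z[:, item_idx].mean(axis=1)
    R = model.latent_correlation
    for name, sp in model.outcome_spec.items():
        w = sp.get("item_weights")
        if w is None:
            drive = severity
        else:
            w = np.asarray(w, dtype=float)
            var = float(w @ R[np.ix_(item_idx, item_idx)] @ w)
            drive = (Z[:, item_idx] @ w) / np.sqrt(var)
        x = sp["intercept"] + sp["coef"] * drive + rng.normal(0.0, sp["noise_sd"], size=n)
        lo, hi = sp["range"]
        x = np.clip(x, lo, hi)
        df[name] = np.rint(x).astype(int) if sp["integer"] else np.round(x, 3)

    for name, col in _draw_covariates(model.covariate_spec, n, rng).items():
        df[name] = col

    df.attrs["meta"] = {
        "seed": int(seed),
        "target_prevalence": float(target_prevalence),
        "calibrated_shift": float(shift),
        "n": int(n),
    }
    return df
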