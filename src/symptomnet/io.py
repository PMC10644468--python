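"""Cohort table I/O, run configuration, and the end-to-end pipeline.

The interchange format for cohorts is a plain CSV with a fixed documented
header; all model/result metadata is JSON.  ``run_pipeline`` chains the
stages in the study's order — descriptives, symptom network (plus the
age-adjusted variant), centrality/predictability, the quality-of-life flow
network, bootstrap accuracy/stability, and the gender network comparison —
and writes a manifest tying every output file to the seeds and settings
that produced it.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import ISI_LABELS, default_model, generate_cohort
from .comparison import nct
from .descriptives import (
    ancova_group_effect,
    isi_category,
    logistic_insomnia,
    mann_whitney_u,
    pearson_chi2,
    pooled_t,
    prevalence_with_ci,
    welch_t,
    ISI_CUTOFF,
)
from .ggm import flow_edges, select_network
from .metrics import centrality_similarity, centrality_table, expected_influence
from .preprocess import npn_transform, residualize
from .stability import case_dropping, edge_bootstrap

log = logging.getLogger("symptomnet")

__all__ = ["COHORT_SCHEMA", "read_cohort", "write_cohort", "RunConfig", "run_pipeline"]

#: column name -> (kind, legal range or levels)
COHORT_SCHEMA = {
    **{f"isi{i}": ("ordinal", (0, 4)) for i in range(1, 8)},
    "isi_total": ("ordinal", (0, 28)),
    "phq9_total": ("ordinal", (0, 27)),
    "gad7_total": ("ordinal", (0, 21)),
    "fatigue": ("ordinal", (0, 10)),
    "qol": ("numeric", (2.0, 10.0)),
    "age": ("numeric", (18.0, 120.0)),
    "gender": ("binary", (0, 1)),
    "married": ("binary", (0, 1)),
    "employed": ("binary", (0, 1)),
    "education_high": ("binary", (0, 1)),
    "rural": ("binary", (0, 1)),
    "physical_disease": ("binary", (0, 1)),
    "access_difficulty": ("binary", (0, 1)),
    "adherence": ("binary", (0, 1)),
    "financial_status": ("ordinal", (0, 2)),
    "social_media": ("ordinal", (0, 2)),
    "diagnosis": ("ordinal", (0, 3)),
    "site": ("ordinal", (0, 50)),
}

ITEM_COLUMNS = [f"isi{i}" for i in range(1, 8)]


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Every schema column must be present and within range; ``isi_total``
    must equal the item sum row-wise.  Unknown extra columns are kept and
    reported with a warning.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_SCHEMA if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file is missing required columns: {missing}")
    extras = [c for c in df.columns if c not in COHORT_SCHEMA]
    if extras:
        warnings.warn(f"unknown columns carried through untouched: {extras}", stacklevel=2)
    if df[list(COHORT_SCHEMA)].isna().any().any():
        bad = df[list(COHORT_SCHEMA)].isna().any()
        raise ValueError(f"missing values in columns: {list(bad[bad].index)}")
    for col, (kind, rng) in COHORT_SCHEMA.items():
        vals = df[col]
        if kind in ("ordinal", "binary"):
            as_int = vals.astype(float)
            if not np.allclose(as_int, np.rint(as_int)):
                raise ValueError(f"column {col!r} must be integer-valued")
        lo, hi = rng
        out = (vals < lo) | (vals > hi)
        if out.any():
            row = int(np.flatnonzero(out.to_numpy())[0])
            raise ValueError(
                f"column {col!r} out of range [{lo}, {hi}] at row {row} "
                f"(value {vals.iloc[row]})"
            )
    sums = df[ITEM_COLUMNS].sum(axis=1)
    bad = sums != df["isi_total"]
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"isi_total does not equal the item sum at row {row}")
    log.info("read cohort: %d rows from %s", len(df), path)
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV with the documented column order."""
    ordered = [c for c in COHORT_SCHEMA if c in df.columns]
    extras = [c for c in df.columns if c not in COHORT_SCHEMA]
    df[ordered + extras].to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run; every stochastic stage gets a seed."""

    # simulation block (ignored when input_path is given)
    input_path: str | None = None
    n: int = 1101
    target_prevalence: float = 0.189
    seed: int = 0
    # analysis block
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    bootstrap_B: int = 1000
    casedrop_B: int = 50
    nct_permutations: int = 1000
    age_adjust: bool = True
    qol_flow: bool = True
    run_bootstrap: bool = True
    run_casedrop: bool = True
    run_nct: bool = True
    # output
    output_dir: str = "symptomnet_out"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _descriptives_block(df: pd.DataFrame) -> dict:
    insomnia = (df["isi_total"] >= ISI_CUTOFF).astype(int)
    n = len(df)
    out: dict = {"n": n}
    prev = prevalence_with_ci(int(insomnia.sum()), n)
    out["prevalence"] = {
        "count": prev.positive_count,
        "percent": round(100 * prev.proportion, 1),
        "ci_percent": [round(100 * prev.ci_low, 1), round(100 * prev.ci_high, 1)],
    }
    cats = df["isi_total"].map(isi_category)
    out["severity_counts"] = cats.value_counts().to_dict()

    tests = {}
    for col in ["gender", "married", "employed", "education_high", "rural",
                "physical_disease", "access_difficulty", "adherence",
                "financial_status", "social_media", "diagnosis"]:
        tab = pd.crosstab(insomnia, df[col]).to_numpy()
        if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
            continue
        r = pearson_chi2(tab)
        tests[col] = {"chi2": r.statistic, "df": r.df, "p": r.p_value}
    g0, g1 = df[insomnia == 0], df[insomnia == 1]
    r = welch_t(g0["age"].mean(), g0["age"].std(ddof=1), len(g0),
                g1["age"].mean(), g1["age"].std(ddof=1), len(g1))
    tests["age"] = {"t": r.statistic, "df": r.df, "p": r.p_value}
    for col in ["phq9_total", "gad7_total", "fatigue"]:
        r = mann_whitney_u(g0[col], g1[col])
        tests[col] = {"z": r.statistic, "p": r.p_value}
    r = pooled_t(g0["qol"].mean(), g0["qol"].std(ddof=1), len(g0),
                 g1["qol"].mean(), g1["qol"].std(ddof=1), len(g1))
    tests["qol"] = {"t": r.statistic, "df": r.df, "p": r.p_value}
    out["group_tests"] = tests

    # ANCOVA of QoL controlling for the covariates with significant contrasts
    sig_bin = [c for c in ["gender", "physical_disease", "access_difficulty"]
               if tests.get(c, {}).get("p", 1) < 0.05]
    covs = [pd.get_dummies(df["financial_status"], prefix="fin", drop_first=True,
                           dtype=float)]
    covs.extend([df[c].astype(float) for c in sig_bin])
    covs.extend([df[c].astype(float) for c in ["phq9_total", "gad7_total", "fatigue"]])
    C = pd.concat(covs, axis=1).to_numpy()
    r = ancova_group_effect(df["qol"].to_numpy(), insomnia.to_numpy(), C)
    out["ancova_qol"] = {"F": r.statistic, "df": list(r.df), "p": r.p_value}

    predictors = pd.DataFrame(
        {
            "male": df["gender"].astype(float),
            "physical_disease": df["physical_disease"].astype(float),
            "financial_fair": (df["financial_status"] == 1).astype(float),
            "financial_good": (df["financial_status"] == 2).astype(float),
            "access_difficulty": df["access_difficulty"].astype(float),
            "phq9_total": df["phq9_total"].astype(float),
            "gad7_total": df["gad7_total"].astype(float),
            "fatigue": df["fatigue"].astype(float),
        }
    )
    try:
        fit = logistic_insomnia(insomnia.to_numpy(), predictors, site=df["site"])
        out["logistic"] = json.loads(fit.table.to_json(orient="index"))
        out["logistic_converged"] = fit.converged
    except RuntimeError as err:
        out["logistic_error"] = str(err)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages; returns the manifest (also written to disk)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": asdict(config),
        "outputs": {},
        "timings_s": {},
        "seeds": {"master": config.seed},
    }

    def _stage(name):
        t0 = time.perf_counter()

        def _done():
            manifest["timings_s"][name] = round(time.perf_counter() - t0, 3)

        return _done

    # --- cohort ---------------------------------------------------------
    done = _stage("cohort")
    if config.input_path:
        df = read_cohort(config.input_path)
        manifest["input"] = str(config.input_path)
    else:
        df = generate_cohort(config.n, target_prevalence=config.target_prevalence,
                             seed=config.seed)
        manifest["simulation"] = df.attrs["meta"]
        log.info("calibrated threshold shift: %.4f", df.attrs["meta"]["calibrated_shift"])
    cohort_path = outdir / "cohort.csv"
    write_cohort(df, cohort_path)
    manifest["outputs"]["cohort"] = cohort_path.name
    done()

    # --- descriptives ---------------------------------------------------
    done = _stage("descriptives")
    desc = _descriptives_block(df)
    (outdir / "descriptives.json").write_text(json.dumps(desc, indent=2, default=float))
    manifest["outputs"]["descriptives"] = "descriptives.json"
    done()

    # --- symptom network ------------------------------------------------
    done = _stage("network")
    items = df[ITEM_COLUMNS]
    data = npn_transform(items, variable_labels=list(ISI_LABELS))
    net, path = select_network(data, gamma=config.gamma, n_lambda=config.n_lambda,
                               lambda_min_ratio=config.lambda_min_ratio)
    log.info("selected lambda=%.4f with %d edges", net.lambda_selected, net.edge_count)
    net.edge_list().to_csv(outdir / "network_edges.csv", index=False)
    (outdir / "network.json").write_text(net.to_json())
    pd.DataFrame(net.weights, index=net.node_labels, columns=net.node_labels).to_csv(
        outdir / "network_adjacency.csv"
    )
    manifest["outputs"]["network"] = "network.json"
    manifest["network"] = {
        "lambda": net.lambda_selected, "gamma": net.gamma,
        "ebic": net.ebic_value, "edges": net.edge_count,
    }

    adj_net = None
    if config.age_adjust:
        adj_data = residualize(data, df["age"].to_numpy())
        adj_net, _ = select_network(adj_data, gamma=config.gamma,
                                    n_lambda=config.n_lambda,
                                    lambda_min_ratio=config.lambda_min_ratio)
        adj_net.edge_list().to_csv(outdir / "network_edges_age_adjusted.csv", index=False)
        (outdir / "network_age_adjusted.json").write_text(adj_net.to_json())
        manifest["outputs"]["network_age_adjusted"] = "network_age_adjusted.json"
    done()

    # --- centrality -----------------------------------------------------
    done = _stage("centrality")
    cent = centrality_table(data, net)
    cent.frame.to_csv(outdir / "centrality.csv")
    manifest["outputs"]["centrality"] = "centrality.csv"
    manifest["centrality"] = {
        "top_nodes": cent.top_nodes(3),
        "mean_predictability": cent.mean_predictability,
    }
    if adj_net is not None:
        sim = centrality_similarity(expected_influence(net), expected_influence(adj_net))
        manifest["ei_similarity"] = {"spearman_r": sim.correlation, "p": sim.p_value}
    done()

    # --- QoL flow network -----------------------------------------------
    if config.qol_flow:
        done = _stage("flow")
        flow_items = df[ITEM_COLUMNS + ["qol"]]
        flow_data = npn_transform(flow_items, variable_labels=list(ISI_LABELS) + ["QOL"])
        flow_net, _ = select_network(flow_data, gamma=config.gamma,
                                     n_lambda=config.n_lambda,
                                     lambda_min_ratio=config.lambda_min_ratio)
        edges = flow_edges(flow_net, "QOL")
        pd.DataFrame(edges, columns=["node", "weight"]).to_csv(
            outdir / "qol_flow_edges.csv", index=False
        )
        manifest["outputs"]["qol_flow"] = "qol_flow_edges.csv"
        manifest["qol_flow"] = [[n_, round(w, 4)] for n_, w in edges]
        done()

    # --- stability ------------------------------------------------------
    if config.run_bootstrap:
        done = _stage("edge_bootstrap")
        boot = edge_bootstrap(items, B=config.bootstrap_B, seed=config.seed + 101,
                              gamma=config.gamma, n_lambda=config.n_lambda,
                              lambda_min_ratio=config.lambda_min_ratio)
        boot.summary().to_csv(outdir / "edge_bootstrap.csv", index=False)
        manifest["outputs"]["edge_bootstrap"] = "edge_bootstrap.csv"
        manifest["seeds"]["edge_bootstrap"] = config.seed + 101
        manifest["edge_bootstrap"] = {"B": boot.B, "redrawn": boot.n_redrawn}
        done()
    if config.run_casedrop:
        done = _stage("case_dropping")
        cd = case_dropping(items, B=config.casedrop_B, seed=config.seed + 202,
                           gamma=config.gamma, n_lambda=config.n_lambda,
                           lambda_min_ratio=config.lambda_min_ratio)
        cd.summary().to_csv(outdir / "case_dropping.csv", index=False)
        manifest["outputs"]["case_dropping"] = "case_dropping.csv"
        manifest["seeds"]["case_dropping"] = config.seed + 202
        manifest["cs_coefficient"] = cd.cs_coefficient
        log.info("CS coefficient (EI): %.2f", cd.cs_coefficient)
        done()

    # --- gender comparison ----------------------------------------------
    if config.run_nct:
        done = _stage("nct")
        male = df[df["gender"] == 1][ITEM_COLUMNS]
        female = df[df["gender"] == 0][ITEM_COLUMNS]
        res = nct(male, female, n_permutations=config.nct_permutations,
                  seed=config.seed + 303, gamma=config.gamma,
                  n_lambda=config.n_lambda, lambda_min_ratio=config.lambda_min_ratio)
        res.edge_table.to_csv(outdir / "nct_edges.csv", index=False)
        res.node_table.to_csv(outdir / "nct_nodes.csv", index=False)
        (outdir / "nct.json").write_text(json.dumps(res.to_dict(), indent=2))
        manifest["outputs"]["nct"] = "nct.json"
        manifest["seeds"]["nct"] = config.seed + 303
        manifest["nct"] = res.to_dict()
        done()

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
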