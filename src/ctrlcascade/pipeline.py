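"""End-to-end orchestration: simulate -> controllability -> factors ->
associate -> mediate -> clpm, from one config, with spawned per-stage seeds
and a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ctrlcascade import __version__
from ctrlcascade.associations import apply_fdr, fit_site_adjusted
from ctrlcascade.clpm import fdr_crosslagged, fit_clpm, residualize
from ctrlcascade.connectome import ModalControllability, NetworkPartition, read_connectome
from ctrlcascade.factors import (
    PrincipalAxisFactorAnalysis,
    apply_mad_filter,
    crossval_scores,
    factor_scores,
    impute_and_average,
    kmo_bartlett,
    map_criterion,
    qc_items,
    retain_loadings,
    vss_criterion,
)
from ctrlcascade.mediation import mediate
from ctrlcascade.synthgen import default_ground_truth, simulate_cohort, write_cohort

log = logging.getLogger("ctrlcascade")

STAGES = ("simulate", "controllability", "factors", "associate", "mediate", "clpm")

_DEFAULTS: dict = {
    "seed": 0,
    "outdir": "ctrlcascade_run",
    "stages": list(STAGES),
    "n_subjects": 500,
    "n_nodes": 50,
    "density": 0.3,
    "missing_rate": 0.05,
    "binarize_fraction": 0.4,
    "n_sites": 22,
    "qa_threshold": 0.001,
    "n_factors": 5,
    "k_max": 9,
    "loading_cut": 0.45,
    "mad_c": 4.0,
    "missing_threshold": 0.5,
    "n_imputations": 3,
    "impute_iter": 3,
    "n_folds": 10,
    "n_boot": 1000,
    "partition_file": None,
    "connectome_dir": None,
    "items_file": None,
    "phenotypes_file": None,
}

_COVARIATES = ["age", "sex", "race", "handedness", "pubertal", "pc1", "pc2", "pc3", "pc4", "pc5"]


@dataclass
class RunConfig:
    values: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.values[key]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        return cls.from_dict(user)

    @classmethod
    def from_dict(cls, user: dict) -> "RunConfig":
        merged = dict(_DEFAULTS)
        merged.update(user)
        return cls(merged)

    def canonical(self) -> str:
        return yaml.safe_dump(self.values, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of findings; an empty list means the config is valid.

    Warnings are prefixed ``warning:`` and do not block a run.
    """
    findings: list[str] = []
    v = config.values
    for key in v:
        if key not in _DEFAULTS:
            findings.append(f"unknown key: {key}")
    for stage in v.get("stages", []):
        if stage not in STAGES:
            findings.append(f"unknown stage: {stage}")
    if v.get("qa_threshold", 0) < 0:
        findings.append("qa_threshold: threshold must be >= 0")
    if not 0 < v.get("density", 0.3) <= 1:
        findings.append("density must lie in (0, 1]")
    if not 0 <= v.get("missing_rate", 0) < 0.5:
        findings.append("missing_rate must lie in [0, 0.5)")
    if v.get("n_subjects", 1) < 50:
        findings.append("n_subjects must be >= 50")
    for key in ("partition_file", "items_file", "phenotypes_file", "connectome_dir"):
        path = v.get(key)
        if path is not None and not Path(path).exists():
            findings.append(f"{key}: file not found: {path}")
    if v.get("n_boot", 1000) < 1000:
        findings.append(f"warning: n_boot={v.get('n_boot')} is below the recommended 1000")
    return findings


def _stage_seeds(master: int) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(len(STAGES))
    return {
        stage: int(s.generate_state(1)[0] % 2**31) for stage, s in zip(STAGES, children)
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages in dependency order; returns the manifest dict.

    Rerunning with an identical config reproduces identical result CSVs. A
    failing stage aborts the run with a ``.failed`` marker naming the stage;
    artifacts from completed stages are retained.
    """
    findings = [f for f in validate_config(config) if not f.startswith("warning:")]
    if findings:
        raise ValueError("invalid config: " + "; ".join(findings))
    v = config.values
    outdir = Path(v["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(v["seed"])
    manifest: dict = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "seeds": seeds,
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    enabled = [s for s in STAGES if s in v["stages"]]
    current = None
    try:
        for stage in enabled:
            current = stage
            log.info("stage %s starting", stage)
            counts = _STAGE_FUNCS[stage](v, outdir, seeds[stage])
            manifest["stages"][stage] = counts
            log.info("stage %s done: %s", stage, counts)
    except Exception as exc:
        (outdir / ".failed").write_text(f"stage {current} failed: {exc}\n")
        raise RuntimeError(f"stage {current} failed: {exc}") from exc
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(v: dict, outdir: Path, seed: int) -> dict:
    truth = default_ground_truth(seed=seed)
    cohort = simulate_cohort(
        v["n_subjects"],
        truth=truth,
        n_nodes=v["n_nodes"],
        density=v["density"],
        missing_rate=v["missing_rate"],
        binarize_fraction=v["binarize_fraction"],
        n_sites=v["n_sites"],
        seed=seed,
    )
    write_cohort(cohort, outdir / "cohort")
    return {
        "n_subjects": len(cohort.items),
        "n_items": cohort.items.shape[1],
        "n_connectomes": len(cohort.connectomes),
    }


def _stage_controllability(v: dict, outdir: Path, seed: int) -> dict:
    conn_dir = Path(v["connectome_dir"] or outdir / "cohort" / "connectomes")
    part_file = Path(v["partition_file"] or outdir / "cohort" / "partition.csv")
    partition = NetworkPartition.from_csv(part_file)
    manifest = pd.read_csv(conn_dir / "manifest.csv")
    conns = [
        read_connectome(conn_dir / row.file, subject_id=row.subject_id)
        for row in manifest.itertuples()
    ]
    mc = ModalControllability(qa_threshold=v["qa_threshold"], partition=partition)
    node_phi = mc.transform(conns)
    node_df = pd.DataFrame(
        node_phi,
        index=[c.subject_id for c in conns],
        columns=[f"node{j + 1}" for j in range(node_phi.shape[1])],
    )
    node_df.to_csv(outdir / "controllability_nodes.csv", index_label="subject_id")
    net_df = mc.network_table(conns)
    net_df.to_csv(outdir / "controllability_networks.csv", index=False)
    return {"n_subjects": len(net_df), "n_networks": net_df.shape[1] - 1}


def _stage_factors(v: dict, outdir: Path, seed: int) -> dict:
    items_file = Path(v["items_file"] or outdir / "cohort" / "items.csv")
    items = pd.read_csv(items_file, index_col="subject_id")
    clean, report = qc_items(items, missing_threshold=v["missing_threshold"])
    clean, n_outliers = apply_mad_filter(clean, c=v["mad_c"])
    report.outlier_cells = n_outliers
    complete = impute_and_average(
        clean, n_imputations=v["n_imputations"], n_iter=v["impute_iter"], seed=seed
    )
    kmo, chi2, pval = kmo_bartlett(complete)
    r = np.corrcoef(complete.to_numpy(), rowvar=False)
    k_max = min(v["k_max"], complete.shape[1] - 1)
    map_curve = map_criterion(r, k_max)
    vss1 = vss_criterion(r, k_max, complexity=1)
    vss2 = vss_criterion(r, k_max, complexity=2)
    pd.DataFrame(
        {
            "k": np.arange(k_max + 1),
            "map": map_curve,
            "vss1": np.concatenate([[np.nan], vss1]),
            "vss2": np.concatenate([[np.nan], vss2]),
        }
    ).to_csv(outdir / "factor_criteria.csv", index=False)
    model = PrincipalAxisFactorAnalysis(n_factors=v["n_factors"]).fit(complete)
    loadings = pd.DataFrame(
        model.loadings_,
        index=complete.columns,
        columns=[f"factor{j + 1}" for j in range(v["n_factors"])],
    )
    loadings.to_csv(outdir / "factor_loadings.csv", index_label="item")
    scores = factor_scores(model, complete)
    scores_df = pd.DataFrame(
        scores, index=complete.index, columns=[f"F{j + 1}" for j in range(v["n_factors"])]
    )
    scores_df.to_csv(outdir / "factor_scores.csv", index_label="subject_id")
    _, rho = crossval_scores(
        complete.to_numpy(), k=v["n_factors"], n_folds=v["n_folds"], seed=seed
    )
    qc_json = {
        "removed": report.removed,
        "outlier_cells": report.outlier_cells,
        "n_retained": len(report.retained),
        "kmo": kmo,
        "bartlett_chi2": chi2,
        "bartlett_p": pval,
        "map_argmin": int(np.nanargmin(map_curve)),
        "crossval_spearman": rho.tolist(),
        "assignments": {
            complete.columns[i]: (None if f is None else f + 1)
            for i, f in retain_loadings(model.solution_, cut=v["loading_cut"]).items()
        },
    }
    (outdir / "factor_qc.json").write_text(json.dumps(qc_json, indent=2))
    return {"n_items_retained": len(report.retained), "kmo": round(kmo, 3)}


def _merged_cohort(v: dict, outdir: Path) -> pd.DataFrame:
    pheno_file = Path(v["phenotypes_file"] or outdir / "cohort" / "phenotypes.csv")
    pheno = pd.read_csv(pheno_file, index_col="subject_id")
    scores = pd.read_csv(outdir / "factor_scores.csv", index_col="subject_id")
    scores.columns = [f"score_{c}" for c in scores.columns]
    return pheno.join(scores)


def _stage_associate(v: dict, outdir: Path, seed: int) -> dict:
    df = _merged_cohort(v, outdir)
    score_cols = [c for c in df.columns if c.startswith("score_F")]
    ctrl_cols = [c for c in df.columns if c.startswith("ctrl_") and not c.endswith("_t2")]
    outcome_cols = [c for c in df.columns if c.endswith("_t1")]
    cov = df[_COVARIATES]
    site = df["site"]
    rows = []
    for family, (preds, outs) in {
        "ela-controllability": (score_cols, ctrl_cols),
        "ela-behavior": (score_cols, outcome_cols),
        "controllability-behavior": (ctrl_cols, outcome_cols),
    }.items():
        results = []
        for pred in preds:
            for out in outs:
                results.append(
                    fit_site_adjusted(
                        df[out], df[pred], covariates=cov, site=site,
                        outcome_label=out, predictor_label=pred,
                    )
                )
        apply_fdr(results)
        for r in results:
            rows.append(
                {
                    "family": family, "outcome": r.outcome, "predictor": r.predictor,
                    "beta": r.beta, "se": r.se, "p": r.p, "q": r.q, "n": r.n,
                    "site_variance": r.site_variance,
                }
            )
    out_df = pd.DataFrame(rows)
    out_df.to_csv(outdir / "associations.csv", index=False)
    return {"n_models": len(out_df)}


def _stage_mediate(v: dict, outdir: Path, seed: int) -> dict:
    df = _merged_cohort(v, outdir)
    score_cols = [c for c in df.columns if c.startswith("score_F")]
    ctrl_cols = [c for c in df.columns if c.startswith("ctrl_") and not c.endswith("_t2")]
    outcome_cols = [c for c in df.columns if c.endswith("_t1")]
    cov = pd.get_dummies(df[_COVARIATES], drop_first=True, dtype=float)
    rows = []
    for i, x_col in enumerate(score_cols):
        for m_col in ctrl_cols:
            for y_col in outcome_cols:
                res = mediate(
                    df[x_col], df[m_col], df[y_col], covariates=cov,
                    n_boot=v["n_boot"], seed=seed + i,
                )
                rows.append(
                    {
                        "x": x_col, "m": m_col, "y": y_col,
                        "a": res.a, "b": res.b, "c": res.c, "c_prime": res.c_prime,
                        "indirect": res.indirect, "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "proportion_mediated": res.proportion_mediated,
                        "inconsistent": res.inconsistent,
                        "significant": res.significant, "n": res.n,
                    }
                )
    pd.DataFrame(rows).to_csv(outdir / "mediation.csv", index=False)
    return {"n_models": len(rows)}


def _stage_clpm(v: dict, outdir: Path, seed: int) -> dict:
    df = _merged_cohort(v, outdir)
    brain_cols = [c[: -len("_t2")] for c in df.columns if c.startswith("ctrl_") and c.endswith("_t2")]
    # outcome wave-2 columns are named <outcome>_t2 with wave 1 <outcome>_t1
    behav_cols = [
        c[: -len("_t2")] for c in df.columns
        if c.endswith("_t2") and not c.startswith("ctrl_")
    ]
    cov = df[_COVARIATES]
    results = []
    for brain in brain_cols:
        for behav in behav_cols:
            panel = pd.DataFrame(
                {
                    "brain_t1": residualize(df[brain], cov),
                    "brain_t2": residualize(df[f"{brain}_t2"], cov),
                    "behavior_t1": residualize(df[f"{behav}_t1"], cov),
                    "behavior_t2": residualize(df[f"{behav}_t2"], cov),
                },
                index=df.index,
            )
            results.append(fit_clpm(panel, model=f"{brain}~{behav}"))
    fdr_crosslagged(results)
    rows = []
    for r in results:
        for path in ("ar_brain", "ar_behavior", "cl_brain_to_behavior", "cl_behavior_to_brain"):
            rows.append(
                {
                    "model": r.model, "path": path, "beta": getattr(r, path),
                    "robust_se": r.se[path], "p": r.p[path],
                    "q": r.q.get(path, np.nan), "n": r.n,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "clpm.csv", index=False)
    return {"n_models": len(results)}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "controllability": _stage_controllability,
    "factors": _stage_factors,
    "associate": _stage_associate,
    "mediate": _stage_mediate,
    "clpm": _stage_clpm,
}
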