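"""End-to-end orchestration: simulate -> connect -> metrics -> analyze -> validate.

Each stage persists its artifacts as text tables under the run directory and
appends to a line-oriented log; a provenance block (config echo, seed,
threshold, software version) makes every run reproducible.  The whole
pipeline is deterministic under the config seed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    generate_beliefs,
    generate_covariates,
    generate_task_scores,
    generate_timeseries,
    generate_true_topology,
    mediator_column,
    parcellation_map,
)
from .config import CohortConfig
from .connectivity import (
    AdjacencyMatrix,
    ConnectivityMatrix,
    apply_threshold,
    peak_crosscorr,
    population_threshold,
    select_run,
)
from .graph_metrics import compute_all_scales
from .io import write_cohort, write_map, write_matrix
from .stats import (
    DEFAULT_COVARIATES,
    ModelSpec,
    fdr_adjust,
    run_mediation,
    run_moderation,
    site_adjustment,
    split_sample_validate,
)


def demo_config(n_subjects: int = 200, seed: int = 0) -> CohortConfig:
    """Desk-scale configuration: 40 parcels, 8 networks per hemisphere."""
    per_hemi = [
        ("salience_ventral_attention", 3),
        ("dorsal_attention", 3),
        ("frontoparietal_control", 3),
        ("default_mode", 3),
        ("temporoparietal", 2),
        ("somatomotor", 3),
        ("reward", 2),
        ("other", 1),
    ]
    layout = [[n, h, c] for h in ("left", "right") for n, c in per_hemi]
    return CohortConfig(
        n_subjects=n_subjects,
        n_parcels=40,
        n_timepoints=150,
        network_layout=layout,
        seed=seed,
    ).validate()


class _Log:
    def __init__(self, path: Path):
        self.path = path
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self._fh = open(path, "a")

    def write(self, msg: str) -> None:
        stamp = _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")
        self._fh.write(f"{stamp} {msg}\n")
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()


@dataclass
class PipelineResult:
    outdir: Path
    cohort: pd.DataFrame
    global_metrics: pd.DataFrame
    node_metrics: pd.DataFrame
    threshold: float
    mediation_table: pd.DataFrame
    moderation_table: pd.DataFrame
    validation_table: pd.DataFrame


def run_pipeline(
    config: CohortConfig,
    outdir,
    max_lag: int = 5,
    n_nulls: int = 10,
    threshold_method: str = "normal",
    fdr_mode: str = "independent_BH",
    save_adjacency: bool = False,
    save_timeseries: bool = False,
    n_validation_repeats: int = 100,
) -> PipelineResult:
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _Log(outdir / "run.log")

    # ---- simulate --------------------------------------------------------
    log.write(f"stage=simulate n={config.n_subjects} seed={config.seed}")
    df = generate_covariates(config)
    df = generate_beliefs(df, config)
    df = generate_true_topology(df, config)
    pmap = parcellation_map(config)
    write_map(pmap, outdir / "parcel_map.tsv")

    # ---- connect ---------------------------------------------------------
    log.write(f"stage=connect max_lag={max_lag} threshold_method={threshold_method}")
    selected: list[ConnectivityMatrix] = []
    for i in range(len(df)):
        runs_ts = generate_timeseries(df.iloc[i], config, i)
        if save_timeseries:
            tsdir = outdir / "timeseries"
            tsdir.mkdir(exist_ok=True)
            for r, ts in enumerate(runs_ts):
                write_matrix(
                    ts.data,
                    tsdir / f"{df.iloc[i]['subject_id']}_run-{r}.tsv",
                    ts.parcel_ids,
                )
        runs = [peak_crosscorr(ts, max_lag=max_lag) for ts in runs_ts]
        selected.append(runs[select_run(runs)])
    thr = population_threshold(selected, method=threshold_method)
    log.write(f"population_threshold={thr:.6f}")
    adjacencies: list[AdjacencyMatrix] = [apply_threshold(c, thr) for c in selected]
    if save_adjacency:
        adir = outdir / "adjacency"
        adir.mkdir(exist_ok=True)
        for sid, adj in zip(df["subject_id"], adjacencies):
            write_matrix(adj.weights, adir / f"{sid}_adjacency.tsv", adj.parcel_ids)

    # ---- metrics ---------------------------------------------------------
    log.write(f"stage=metrics n_nulls={n_nulls}")
    g_rows, n_rows = [], []
    for sid, conn, adj in zip(df["subject_id"], selected, adjacencies):
        gdf, ndf = compute_all_scales(
            adj, conn, pmap, n_nulls=n_nulls, seed=config.seed, with_small_world=True
        )
        gdf.insert(0, "subject_id", sid)
        ndf.insert(0, "subject_id", sid)
        g_rows.append(gdf)
        n_rows.append(ndf)
    global_metrics = pd.concat(g_rows, ignore_index=True)
    node_metrics = pd.concat(n_rows, ignore_index=True)

    # measured mediator: targeted network's within-network median connectivity
    scope = f"{config.target_network}/{config.target_hemisphere}"
    med = (
        global_metrics.loc[global_metrics["scope"] == scope]
        .set_index("subject_id")["median_conn_in"]
        .reindex(df["subject_id"])
        .to_numpy()
    )
    med_col = mediator_column(config)
    df[med_col] = med
    df = generate_task_scores(df, df["true_within_rho"].to_numpy(), config)
    write_cohort(df, outdir / "cohort.csv")
    global_metrics.to_csv(outdir / "metrics_global.csv", index=False)
    node_metrics.to_csv(outdir / "metrics_nodes.csv", index=False)

    # ---- analyze ---------------------------------------------------------
    log.write(f"stage=analyze fdr_mode={fdr_mode}")
    df_adj, small_sites = site_adjustment(df)
    if small_sites:
        log.write(f"warning: sites with <20 subjects: {small_sites}")
    covs = DEFAULT_COVARIATES + ["site_propensity"]

    med_res = run_mediation(
        df_adj, config.target_belief, med_col, "flanker_score", covariates=covs
    )
    fam_p = np.array(
        [
            med_res.path_a.p(config.target_belief),
            med_res.path_b.p(config.target_belief),
            med_res.path_d.p(config.target_belief),
        ]
    )
    fam_fdr = fdr_adjust(fam_p, mode=fdr_mode)
    rows = []
    for path, fit in (
        ("A", med_res.path_a),
        ("B", med_res.path_b),
        ("C", med_res.path_c),
        ("D", med_res.path_d),
    ):
        for term in fit.terms.index:
            rows.append(
                {
                    "path": path,
                    "term": term,
                    "beta": fit.terms.loc[term, "beta"],
                    "se": fit.terms.loc[term, "se"],
                    "p": fit.terms.loc[term, "p"],
                    "adj_r2": fit.adj_r2,
                    "aic": fit.aic,
                    "n_used": fit.n_used,
                }
            )
    mediation_table = pd.DataFrame(rows)
    summary = pd.DataFrame(
        [
            {"path": "sobel", "term": "indirect_ab", "beta": med_res.indirect_ab,
             "se": np.nan, "p": med_res.sobel_p, "adj_r2": np.nan,
             "aic": np.nan, "n_used": med_res.path_d.n_used},
            {"path": "class", "term": med_res.mediation_class, "beta": np.nan,
             "se": np.nan, "p": np.nan, "adj_r2": np.nan, "aic": np.nan,
             "n_used": med_res.path_d.n_used},
        ]
    )
    mediation_table = pd.concat([mediation_table, summary], ignore_index=True)
    fdr_block = pd.DataFrame(
        {
            "path": ["A", "B", "D"],
            "term": [f"{config.target_belief}:p_fdr"] * 3,
            "beta": np.nan,
            "se": np.nan,
            "p": fam_fdr,
            "adj_r2": np.nan,
            "aic": np.nan,
            "n_used": med_res.path_d.n_used,
        }
    )
    mediation_table = pd.concat([mediation_table, fdr_block], ignore_index=True)
    mediation_table.to_csv(outdir / "analysis_mediation.csv", index=False)

    mod_res = run_moderation(
        df_adj, med_col, "flanker_score", config.target_belief, covariates=covs
    )
    mod_rows = mod_res.simple_slopes.reset_index()
    mod_rows["interaction_p"] = mod_res.interaction_p
    mod_rows["f_squared"] = mod_res.f_squared
    mod_rows.to_csv(outdir / "analysis_moderation.csv", index=False)

    # ---- validate --------------------------------------------------------
    log.write(f"stage=validate repeats={n_validation_repeats}")
    vspec = ModelSpec("flanker_score", config.target_belief, covariates=covs)
    val = split_sample_validate(
        df_adj, vspec, n_repeats=n_validation_repeats, seed=config.seed
    )
    validation_table = pd.DataFrame(
        {"repeat": np.arange(val.n_repeats), "cv_rmse": val.cv_rmse, "aic": val.aic}
    )
    validation_table.to_csv(outdir / "validation.csv", index=False)
    vsummary = {
        "median_cv_rmse": val.median_cv_rmse,
        "median_aic": val.median_aic,
        "n_train": val.n_train,
        "n_test": val.n_test,
        "n_repeats": val.n_repeats,
        "n_undefined": val.n_undefined,
    }

    provenance = {
        "version": __version__,
        "config": config.to_dict(),
        "max_lag": max_lag,
        "n_nulls": n_nulls,
        "threshold_method": threshold_method,
        "population_threshold": float(thr),
        "fdr_mode": fdr_mode,
        "validation": vsummary,
    }
    with open(outdir / "provenance.yaml", "w") as fh:
        yaml.safe_dump(provenance, fh, sort_keys=False)
    log.write("stage=done")
    log.close()

    return PipelineResult(
        outdir=outdir,
        cohort=df,
        global_metrics=global_metrics,
        node_metrics=node_metrics,
        threshold=float(thr),
        mediation_table=mediation_table,
        moderation_table=mod_rows,
        validation_table=validation_table,
    )
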