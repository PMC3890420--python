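"""End-to-end orchestration: normalize -> z-score -> cluster -> infiltration
-> polarization + bootstrap null -> PCA -> survival (+ random-model
ensemble) -> contingency stats, with every stage's output written to a flat,
stage-prefixed directory and every stochastic step's seed recorded."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as co
from . import expression as ex
from . import inference as inf
from . import panels as pn
from . import stats as st
from . import survival as sv
from .simulate import SyntheticCohortConfig, generate_cohort

logger = logging.getLogger("immunopolar")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Inputs, parameters and output location for one pipeline run."""

    matrix_path: str | None = None  # None -> simulate a synthetic cohort
    clinical_path: str | None = None
    matrix_scale: str = ex.LOG2_MEDIAN_RATIO
    panel: str = "default"  # "default" | "revised-th2"
    amplitude: float = 1.0
    n_boot: int = 1000
    n_cohort: int = 200
    n_groups: int = 2
    ensemble_b: int = 200
    seed: int = 0
    outdir: str = "immunopolar_out"
    synthetic: SyntheticCohortConfig | None = None

    def validate(self) -> None:
        for p in (self.matrix_path, self.clinical_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if self.panel not in ("default", "revised-th2"):
            raise ValueError(f"unknown panel choice {self.panel!r}")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the machine-readable summary.

    All outputs are also written under ``cfg.outdir`` with stage-prefixed
    file names; partial outputs are retained if a later stage fails.
    """
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed}
    logger.info("pipeline seed: %d", cfg.seed)

    # ---- inputs ---------------------------------------------------------
    if cfg.matrix_path is None:
        sim = cfg.synthetic or SyntheticCohortConfig(seed=cfg.seed)
        if sim.seed is None:
            sim.seed = cfg.seed
        expr, clinical, truth = _stage("simulate")(generate_cohort)(sim)
        ex.write_matrix(expr, out / "00_matrix.tsv")
        ex.write_clinical(clinical, out / "00_clinical.tsv")
        truth.to_csv(out / "00_ground_truth.tsv", sep="\t", index=False)
        summary["simulated"] = True
    else:
        expr = _stage("read")(ex.read_matrix)(cfg.matrix_path, scale=cfg.matrix_scale)
        clinical = (
            ex.read_clinical(cfg.clinical_path) if cfg.clinical_path else None
        )
        summary["simulated"] = False

    if expr.scale == ex.RAW:
        expr = _stage("normalize")(ex.log2_median_center)(expr)
    zm = _stage("zscore")(ex.zscore)(expr)

    # ---- cohort structure ----------------------------------------------
    panel_genes = [g for g in pn.panel_gene_union() if g in expr.values.index]
    assign = _stage("cluster")(co.ward_cluster)(expr, cfg.n_groups, genes=panel_genes)
    assign.labels.rename("group").to_csv(out / "10_groups.tsv", sep="\t")
    np.savetxt(out / "10_linkage.tsv", assign.linkage, delimiter="\t")
    summary["group_sizes"] = {
        int(k): int(v) for k, v in assign.group_sizes().items()
    }

    markers = pn.infiltration_markers()
    infil = {
        s.name: _stage("infiltrate")(co.infiltration_score)(expr, s.genes)
        for s in markers.subsets
    }
    pd.DataFrame(infil).to_csv(out / "20_infiltration.tsv", sep="\t")

    # ---- polarization ---------------------------------------------------
    icfg = inf.InferenceConfig(amplitude=cfg.amplitude)
    thelper = (
        pn.revised_th2_family(reduced=True)
        if cfg.panel == "revised-th2"
        else pn.thelper_family()
    )
    membership = assign.labels.astype(str)
    summary["mean_posterior"] = {}
    summary["null_p"] = {}
    for fam in (thelper, pn.macrophage_family()):
        post = _stage("polarize")(inf.posterior_frame)(zm, fam, icfg)
        inf.write_posteriors(post, out / f"30_posterior_{fam.label}.tsv")
        means = inf.cohort_mean_posterior(zm, fam, icfg, membership)
        null = _stage("polarize")(inf.bootstrap_null)(
            zm, fam, icfg, n_cohort=cfg.n_cohort, B=cfg.n_boot, seed=cfg.seed
        )
        obs = means.mean(axis=0)
        inf.write_null(
            null,
            out / f"30_null_{fam.label}.tsv",
            out / f"30_null_{fam.label}.json",
            observed=obs.to_dict(),
        )
        summary["mean_posterior"][fam.label] = {
            str(g): row.to_dict() for g, row in means.iterrows()
        }
        summary["null_p"][fam.label] = {
            k: inf.empirical_pvalue(v, null, k) for k, v in obs.items()
        }

    # ---- PCA ------------------------------------------------------------
    pca = _stage("pca")(co.pca_fit)(expr, genes=panel_genes)
    pca.loadings.iloc[:, :10].to_csv(out / "40_pca_loadings.tsv", sep="\t")
    pca.scores.iloc[:, :10].to_csv(out / "40_pca_scores.tsv", sep="\t")
    summary["pca_variance_fraction"] = [float(v) for v in pca.variance_fraction[:10]]

    # ---- survival -------------------------------------------------------
    if clinical is not None:
        records = clinical.table.rename(
            columns={"os_months": "time", "os_event": "event"}
        )
        records["cluster"] = records["sample"].map(assign.labels).astype("Int64")
        tumors = records[records["pathology"] != "normal"].dropna(subset=["cluster"])
        km = {}
        for g, sub in tumors.groupby("cluster"):
            est = _stage("survive")(sv.km_estimate)(sub)
            est.curve.to_csv(out / f"50_km_group{g}.tsv", sep="\t")
            km[int(g)] = {"n": est.n, "events": est.n_events}
        summary["km"] = km
        if tumors["cluster"].nunique() == 2:
            g1, g2 = sorted(tumors["cluster"].unique())
            z, p = sv.peto_peto_test(
                tumors[tumors["cluster"] == g1], tumors[tumors["cluster"] == g2]
            )
            summary["peto_peto"] = {"z": z, "p": p}

        post_th1 = inf.posterior_frame(zm, thelper, icfg)["Th1"]
        tum = tumors.copy()
        tum["p_th1"] = tum["sample"].map(post_th1)
        try:
            cox = _stage("survive")(sv.cox_fit)(tum, ["p_th1", "pathology"])
            cox.summary.to_csv(out / "50_cox.tsv", sep="\t")
            summary["cox"] = {
                cov: {k: float(v) for k, v in row.items()}
                for cov, row in cox.summary.iterrows()
            }
        except PipelineError as exc:
            logger.warning("%s", exc)
            summary["cox"] = None

        if cfg.ensemble_b > 0:
            ens = _stage("survive")(sv.random_model_hr_ensemble)(
                zm,
                tumors,
                pn.panel_gene_union(),
                pn.thelper_family(reduced=False),
                icfg,
                B=cfg.ensemble_b,
                seed=cfg.seed,
            )
            pd.Series(ens.hrs, name="hr").to_csv(out / "50_ensemble_hrs.tsv", sep="\t")
            summary["ensemble"] = {
                "observed_hr": ens.observed_hr,
                "p": ens.p_value,
                "n_failed": ens.n_failed,
                "B": ens.b,
                "seed": ens.seed,
            }

        # ---- contingency stats -----------------------------------------
        if tumors["cluster"].nunique() >= 1:
            stats_out = {}
            n_cohort_all = len(tumors)
            k_cohort = int((tumors["pathology"] == "TN").sum())
            if 0 < k_cohort < n_cohort_all:
                for g, sub in tumors.groupby("cluster"):
                    k_g = int((sub["pathology"] == "TN").sum())
                    if 0 < k_g < len(sub):
                        r = st.odds_ratio_vs_cohort(k_g, len(sub), k_cohort, n_cohort_all)
                        stats_out[f"tn_or_group{g}"] = {
                            "or": r.odds_ratio, "ci": [r.ci_lower, r.ci_upper],
                            "p": r.p_value,
                        }
            summary["stats"] = stats_out

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
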