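"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a three-subpopulation breast cohort — normal-like
tissue, a large hormone-receptor-like tumor group ("group 1") and a smaller
triple-negative-like tumor group ("group 2") — on the log2 median-ratio
scale:

* planted polarization bias: each group adds its configured amplitude
  (z-units) to the exclusive genes of the biased subsets (defaults: Th2/M2 in
  normals, Th2+Th17/M2 in group 1, Th1/M1 in group 2);
* an infiltration offset on NK / T cell / macrophage marker genes (reduced in
  group 1, elevated in group 2);
* a latent factor inducing the WISP1-GATA3 positive and WISP1-PPARG negative
  correlations, plus elevated WISP1 in tumors;
* an elevated IL12RB2/IL12RB1 log-ratio in group 2;
* exponential survival whose hazard decreases with the planted type-1 level,
  with independent exponential censoring calibrated to a target fraction.

Ground truth (group labels, planted type-1 level, true hazard) is returned
separately so recovery tests never read it through the analysis path.
Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .expression import LOG2_MEDIAN_RATIO, ClinicalTable, ExpressionMatrix
from .ihc import StainMatrix, default_stain_matrix, od_to_rgb
from .panels import (
    SignatureFamily,
    default_panel,
    infiltration_markers,
    macrophage_family,
    panel_gene_union,
    thelper_family,
)

logger = logging.getLogger("immunopolar")

__all__ = ["SyntheticCohortConfig", "generate_cohort", "generate_ihc_image"]


@dataclass
class SyntheticCohortConfig:
    """Study conditions for the synthetic cohort.

    Amplitudes are in z-units on the log2 scale (noise sd 1 means an
    amplitude of 1.5 is a 1.5-sigma shift of each planted gene).  The
    survival log hazard ratio is per unit of the planted type-1 level, so the
    group-2 hazard is ``baseline * exp(log_hr_th1 * th1 amplitude)``.
    """

    n_normal: int = 50
    n_group1: int = 50
    n_group2: int = 50
    #: group -> {(family, subset): amplitude}; planted polarization biases
    amplitudes: Mapping[str, Mapping[tuple[str, str], float]] = field(
        default_factory=lambda: {
            "normal": {("Thelper", "Th2"): 1.0, ("macrophage", "M2"): 1.0},
            "group1": {
                ("Thelper", "Th2"): 1.0,
                ("Thelper", "Th17"): 1.0,
                ("macrophage", "M2"): 1.0,
            },
            "group2": {("Thelper", "Th1"): 1.5, ("macrophage", "M1"): 1.5},
        }
    )
    infiltration_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"normal": 0.0, "group1": -1.0, "group2": 1.0}
    )
    wisp1_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"normal": 0.0, "group1": 1.5, "group2": 0.5}
    )
    latent_loading: float = 1.0  # WISP1/GATA3 +, PPARG - loading on a N(0,1) factor
    il12rb2_offset_group2: float = 1.5
    noise_sd: float = 1.0
    baseline_hazard: float = 0.02  # events per month
    log_hr_th1: float = -0.8  # per unit planted type-1 level
    censoring_rate: float = 0.5  # expected censored fraction
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_normal, self.n_group1, self.n_group2) < 0:
            raise ValueError("group sizes must be >= 0")
        if self.n_normal + self.n_group1 + self.n_group2 < 2:
            raise ValueError("need at least 2 samples in total")
        if not self.noise_sd > 0:
            raise ValueError("noise sd must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring rate must be in [0, 1)")

    @property
    def implied_wisp1_gata3_r(self) -> float:
        """Correlation implied by the latent loading at the configured noise."""
        lam2 = self.latent_loading**2
        return lam2 / (lam2 + self.noise_sd**2)


def _censoring_scale(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean P(C < T) = target.

    For exponential T with hazard h and independent exponential C with rate
    c, P(censored) = c / (c + h); solve the cohort average for c.
    """
    if target == 0:
        return 0.0

    def mean_censored(c: float) -> float:
        return float(np.mean(c / (c + hazards))) - target

    hi = float(hazards.max()) * target / (1 - target) * 10 + 1.0
    while mean_censored(hi) < 0:
        hi *= 10
    return brentq(mean_censored, 1e-12, hi)


def generate_cohort(
    cfg: SyntheticCohortConfig | None = None,
) -> tuple[ExpressionMatrix, ClinicalTable, pd.DataFrame]:
    """Generate (expression, clinical, ground truth) for one synthetic cohort."""
    cfg = cfg or SyntheticCohortConfig()
    rng = np.random.default_rng(cfg.seed)
    genes = list(panel_gene_union(default_panel()))
    gene_ix = {g: i for i, g in enumerate(genes)}

    groups = (
        ["normal"] * cfg.n_normal + ["group1"] * cfg.n_group1 + ["group2"] * cfg.n_group2
    )
    samples = [f"S{i:04d}" for i in range(len(groups))]
    n = len(samples)

    X = rng.normal(0.0, cfg.noise_sd, size=(len(genes), n))

    families = {"Thelper": thelper_family(), "macrophage": macrophage_family()}
    group_arr = np.asarray(groups)
    th1_level = np.zeros(n)
    for gname, amps in cfg.amplitudes.items():
        cols = group_arr == gname
        if not cols.any():
            continue
        for (fam_label, subset), amp in amps.items():
            fam: SignatureFamily = families[fam_label]
            for g in fam.exclusive[subset]:
                if g not in gene_ix:
                    raise ValueError(f"unknown panel gene {g!r}")
                X[gene_ix[g], cols] += amp
            if fam_label == "Thelper" and subset == "Th1":
                th1_level[cols] = amp

    markers = [g for s in infiltration_markers().subsets for g in s.genes]
    for gname, off in cfg.infiltration_offsets.items():
        cols = group_arr == gname
        for g in markers:
            X[gene_ix[g], cols] += off

    factor = rng.normal(0.0, 1.0, size=n)
    lam = cfg.latent_loading
    X[gene_ix["WISP1"]] += lam * factor
    X[gene_ix["GATA3"]] += lam * factor
    X[gene_ix["PPARG"]] -= lam * factor
    for gname, off in cfg.wisp1_offsets.items():
        X[gene_ix["WISP1"], group_arr == gname] += off
    X[gene_ix["IL12RB2"], group_arr == "group2"] += cfg.il12rb2_offset_group2

    hazards = cfg.baseline_hazard * np.exp(cfg.log_hr_th1 * th1_level)
    event_times = rng.exponential(1.0 / hazards)
    c_rate = _censoring_scale(hazards, cfg.censoring_rate)
    if c_rate > 0:
        censor_times = rng.exponential(1.0 / c_rate, size=n)
    else:
        censor_times = np.full(n, np.inf)
    observed = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)
    # the analysis requires strictly positive follow-up
    observed = np.maximum(observed, 1e-6)

    # molecular pathology as a per-group mixture (clusters enrich for, but do
    # not equal, a diagnosis), echoing the real cohort's composition
    pathology = np.empty(n, dtype=object)
    pathology[group_arr == "normal"] = "normal"
    path_probs = {
        "group1": ([300, 48, 26], ("ER+/PR+", "HER2+", "TN")),
        "group2": ([75, 27, 60], ("ER+/PR+", "HER2+", "TN")),
    }
    for gname, (counts, labels) in path_probs.items():
        cols = group_arr == gname
        probs = np.asarray(counts, dtype=float)
        pathology[cols] = rng.choice(labels, size=cols.sum(), p=probs / probs.sum())
    expr = ExpressionMatrix(
        values=pd.DataFrame(X, index=genes, columns=samples), scale=LOG2_MEDIAN_RATIO
    )
    clinical = ClinicalTable(
        table=pd.DataFrame(
            {
                "sample": samples,
                "pathology": pathology,
                "os_months": observed,
                "os_event": event,
                "group": groups,
            }
        )
    )
    truth = pd.DataFrame(
        {
            "sample": samples,
            "group": groups,
            "th1_level": th1_level,
            "hazard": hazards,
            "event_time": event_times,
            "latent_factor": factor,
        }
    )
    return expr, clinical, truth


def generate_ihc_image(
    core_layout: list[tuple[float, float, float]],
    stain_densities: list[tuple[float, float]],
    shape: tuple[int, int] = (128, 128),
    noise_sd: float = 2.0,
    seed: int | None = None,
    stains: StainMatrix | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render circular tissue cores through the forward stain model.

    ``core_layout`` lists (center_row, center_col, radius) per core and
    ``stain_densities`` the (stain1, stain2) OD densities inside each core.
    Pixels are composed as densities x stain matrix -> OD -> 8-bit intensity,
    plus Gaussian pixel noise in intensity units.  Returns the image and the
    ground-truth density map (H x W x 2).
    """
    if len(core_layout) != len(stain_densities):
        raise ValueError("one density pair per core required")
    if any(d1 < 0 or d2 < 0 for d1, d2 in stain_densities):
        raise ValueError("densities must be >= 0")
    stains = stains or default_stain_matrix()
    h, w = shape
    truth = np.zeros((h, w, 2))
    rows, cols = np.ogrid[:h, :w]
    for (cr, cc, radius), (d1, d2) in zip(core_layout, stain_densities):
        inside = (rows - cr) ** 2 + (cols - cc) ** 2 <= radius**2
        truth[inside, 0] = d1
        truth[inside, 1] = d2
    dens3 = np.concatenate([truth, np.zeros((h, w, 1))], axis=-1)
    od = dens3 @ stains.matrix
    img = od_to_rgb(od).astype(float)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), truth
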