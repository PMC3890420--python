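"""Survival analysis: Kaplan-Meier, Peto-Peto test, Cox regression, and the
random-signature hazard-ratio null ensemble.

The survival questions are (i) whether the clustered cohorts differ in
overall survival (Kaplan-Meier curves compared with the Peto & Peto modified
Gehan-Wilcoxon test, which up-weights early differences where at-risk counts
are large), and (ii) whether the inferred type 1 polarization posterior
predicts survival independent of molecular pathology (Cox proportional
hazards, survival ~ p(Th1) + pathology).  Because gene signatures correlate
with outcome embarrassingly often, the observed hazard ratio is additionally
compared against an ensemble of random signatures assembled from the same
gene panel with the same subset sizes.

Estimation is delegated to lifelines (Kaplan-Meier with Greenwood variance,
Cox partial likelihood with Efron tie handling); the Peto-Peto statistic is
computed directly so that its signed form is available, and is cross-checked
against lifelines in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy.stats import chi2

from .expression import ZMatrix
from .inference import InferenceConfig, posterior_frame
from .panels import GeneSignature, SignatureFamily, reduce_to_exclusive

logger = logging.getLogger("immunopolar")

__all__ = [
    "KMEstimate",
    "CoxResult",
    "RandomModelEnsemble",
    "SurvivalError",
    "km_estimate",
    "peto_peto_test",
    "cox_fit",
    "random_model_hr_ensemble",
]


class SurvivalError(ValueError):
    """Invalid or degenerate survival input."""


@dataclass
class KMEstimate:
    """Product-limit survival curve with 95% CI and an at-risk table."""

    curve: pd.DataFrame  # index time; columns survival, lower, upper
    at_risk: pd.Series  # time -> number at risk
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        idx = self.curve.index[self.curve.index <= t]
        return float(self.curve.loc[idx[-1], "survival"]) if len(idx) else 1.0


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with Wald CI/p, plus fit bookkeeping."""

    summary: pd.DataFrame  # index covariate; hr, lower, upper, p
    log_likelihood: float
    n: int
    n_events: int

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


@dataclass
class RandomModelEnsemble:
    """Hazard ratios from random signature families of matched sizes."""

    hrs: np.ndarray  # per successful replicate, HR of the pseudo-type-1 posterior
    observed_hr: float
    p_value: float  # one-sided toward protection (HR < 1), add-one rule
    n_failed: int
    cardinalities: tuple[int, ...]
    seed: int | None

    @property
    def b(self) -> int:
        return len(self.hrs) + self.n_failed


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    df = pd.DataFrame(records)
    if "time" not in df.columns or "event" not in df.columns:
        raise SurvivalError("records need 'time' and 'event' columns")
    if len(df) == 0:
        raise SurvivalError("no survival records")
    if (df["time"] <= 0).any():
        raise SurvivalError("survival times must be positive")
    if not set(df["event"].astype(int).unique()) <= {0, 1}:
        raise SurvivalError("event indicator must be 0/1")
    return df


def km_estimate(
    records: pd.DataFrame,
    horizon: float | None = None,
    at_risk_interval: float = 12.0,
) -> KMEstimate:
    """Kaplan-Meier estimate with Greenwood-based 95% CI.

    ``horizon`` truncates the curve (e.g. 72 months for 6-year survival);
    the at-risk table is evaluated every ``at_risk_interval`` months.
    """
    df = _check_records(records)
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], df["event"].astype(int))
    curve = pd.DataFrame(
        {
            "survival": kmf.survival_function_.iloc[:, 0],
            "lower": kmf.confidence_interval_.iloc[:, 0],
            "upper": kmf.confidence_interval_.iloc[:, 1],
        }
    )
    curve.index.name = "time"
    if horizon is not None:
        curve = curve.loc[curve.index <= horizon]
    tmax = horizon if horizon is not None else float(df["time"].max())
    grid = np.arange(0.0, tmax + at_risk_interval, at_risk_interval)
    at_risk = pd.Series(
        [(df["time"].to_numpy() >= t).sum() for t in grid], index=grid, name="at_risk"
    )
    return KMEstimate(
        curve=curve, at_risk=at_risk, n=len(df), n_events=int(df["event"].sum())
    )


def peto_peto_test(
    records_a: pd.DataFrame, records_b: pd.DataFrame
) -> tuple[float, float]:
    """Peto & Peto modified Gehan-Wilcoxon test between two groups.

    A weighted log-rank test whose weight at each event time is the
    Peto-Peto modified pooled survival estimate
    S~(t_j) = prod_{t_i <= t_j} (1 - d_i / (n_i + 1)), the convention of the
    R survival package (and lifelines).  Returns the signed z statistic
    (negative when group A fares better) and the two-sided chi-square p on
    1 df.  With no events in either group the statistic is 0 and p = 1.
    """
    a = _check_records(records_a)
    b = _check_records(records_b)
    times = np.concatenate([a["time"], b["time"]])
    events = np.concatenate([a["event"], b["event"]]).astype(int)
    group_a = np.concatenate([np.ones(len(a), bool), np.zeros(len(b), bool)])
    if events.sum() == 0:
        return 0.0, 1.0
    event_times = np.unique(times[events == 1])
    u = 0.0  # sum of weighted observed - expected for group A
    v = 0.0  # variance
    s_tilde = 1.0
    for t in event_times:
        at = times >= t
        n_i = at.sum()
        d_i = int(((times == t) & (events == 1)).sum())
        n_a = (at & group_a).sum()
        d_a = int(((times == t) & (events == 1) & group_a).sum())
        s_tilde *= 1 - d_i / (n_i + 1)
        w = s_tilde
        e_a = d_i * n_a / n_i
        u += w * (d_a - e_a)
        if n_i > 1:
            v += w**2 * d_i * (n_a / n_i) * (1 - n_a / n_i) * (n_i - d_i) / (n_i - 1)
    if v == 0:
        return 0.0, 1.0
    z = u / np.sqrt(v)
    p = float(chi2.sf(z**2, df=1))
    return float(z), p


def cox_fit(
    records: pd.DataFrame,
    covariates: list[str] | None = None,
    ties: str = "efron",
) -> CoxResult:
    """Cox proportional hazards fit (partial likelihood, Efron ties).

    ``covariates`` selects columns of ``records``; categorical columns are
    expanded to treatment-coded indicators.  Constant covariates and fits
    with fewer than two events are rejected; non-convergence (e.g. complete
    separation) surfaces as a :class:`SurvivalError`.
    """
    df = _check_records(records)
    if df["event"].astype(int).sum() < 2:
        raise SurvivalError("need at least 2 events to fit a Cox model")
    if covariates is None:
        covariates = [c for c in df.columns if c not in ("time", "event", "sample")]
    if not covariates:
        raise SurvivalError("no covariates to fit")
    X = df[covariates]
    cats = [c for c in covariates if not pd.api.types.is_numeric_dtype(X[c])]
    X = pd.get_dummies(X, columns=cats, drop_first=True, dtype=float)
    for c in X.columns:
        if X[c].nunique() < 2:
            raise SurvivalError(f"covariate {c!r} is constant")
    data = pd.concat(
        [df[["time", "event"]].reset_index(drop=True), X.reset_index(drop=True)],
        axis=1,
    )
    cph = CoxPHFitter()
    try:
        cph.fit(
            data, duration_col="time", event_col="event",
            fit_options={"step_size": 0.5},
        )
    except Exception as exc:
        raise SurvivalError(f"Cox fit failed: {exc}") from exc
    s = cph.summary
    summary = pd.DataFrame(
        {
            "hr": s["exp(coef)"],
            "lower": s["exp(coef) lower 95%"],
            "upper": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    return CoxResult(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        n=len(data),
        n_events=int(data["event"].sum()),
    )


def _random_family(
    pool: tuple[str, ...], cardinalities: tuple[int, ...], rng: np.random.Generator
) -> SignatureFamily:
    take = rng.choice(len(pool), size=sum(cardinalities), replace=False)
    genes = [pool[i] for i in take]
    subsets, start = [], 0
    for i, c in enumerate(cardinalities):
        subsets.append(
            GeneSignature(f"R{i + 1}", tuple(genes[start : start + c]), "random")
        )
        start += c
    return SignatureFamily(label="random", subsets=tuple(subsets))


def random_model_hr_ensemble(
    zm: ZMatrix | pd.DataFrame,
    records: pd.DataFrame,
    panel_genes: tuple[str, ...] | list[str],
    reference_family: SignatureFamily,
    cfg: InferenceConfig | None = None,
    B: int = 1000,
    seed: int | None = None,
    pathology_col: str | None = "pathology",
) -> RandomModelEnsemble:
    """Compare the observed Th1 hazard ratio with random-signature nulls.

    Each replicate draws genes without replacement from the full panel gene
    list into pseudo-subsets with the reference family's subset sizes (so
    pseudo-subsets are disjoint, mirroring the mutual-exclusivity
    assumption), computes the per-sample posterior of pseudo-subset 1, and
    fits the same Cox model (posterior + pathology).  The one-sided p-value
    toward protection is (1 + #{random HR <= observed HR}) / (B_ok + 1).

    ``records`` must be indexable by the z-matrix's samples (a 'sample'
    column) and carry 'time' and 'event'.  Cox failures within replicates are
    logged and excluded; the count is reported.
    """
    cfg = cfg or InferenceConfig()
    z = zm.z if isinstance(zm, ZMatrix) else zm
    df = _check_records(records)
    if "sample" in df.columns:
        df = df.set_index("sample")
    df = df.loc[[s for s in z.columns if s in df.index]]
    pool = tuple(g for g in dict.fromkeys(panel_genes) if g in z.index)
    if not pool:
        raise SurvivalError("no panel genes present in the z-matrix")
    ref = (
        reference_family
        if reference_family.exclusive is not None
        else reduce_to_exclusive(reference_family)
    )
    cards = tuple(len(s.genes) for s in ref.subsets)
    if sum(cards) > len(pool):
        raise SurvivalError(
            f"panel has {len(pool)} genes but the reference needs {sum(cards)}"
        )
    covs = ["posterior"] + ([pathology_col] if pathology_col in df.columns else [])

    def _fit_hr(family: SignatureFamily) -> float:
        post = posterior_frame(z, family, cfg)
        first = family.subset_names[0]
        rec = df.copy()
        rec["posterior"] = post[first].reindex(rec.index)
        res = cox_fit(rec.reset_index(), covariates=covs)
        return res.hr("posterior")

    observed_hr = _fit_hr(ref)
    rng = np.random.default_rng(seed)
    hrs, n_failed = [], 0
    for _ in range(B):
        fam = _random_family(pool, cards, rng)
        try:
            hrs.append(_fit_hr(reduce_to_exclusive(fam)))
        except SurvivalError as exc:
            n_failed += 1
            logger.warning("random-model Cox fit excluded: %s", exc)
    hrs_arr = np.asarray(hrs)
    p = float((1 + np.count_nonzero(hrs_arr <= observed_hr)) / (len(hrs_arr) + 1))
    return RandomModelEnsemble(
        hrs=hrs_arr,
        observed_hr=observed_hr,
        p_value=p,
        n_failed=n_failed,
        cardinalities=cards,
        seed=seed,
    )
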