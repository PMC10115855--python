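"""Clinical translation: site ranking, mutation association, Cox model + cutpoints.

Disease sites are ranked by median shifted signature score and rankings from
different datasets are compared by Spearman concordance. Mutation calls are
tested against a high/low median score split with chi-square tests and
Bonferroni correction. For survival translation, signature genes pass a
variance filter and a univariate proportional-hazards screen, a multivariate
Cox panel is trained on treated patients, and its linear predictor is
thresholded -- at the median, tertiles, or chi-square-optimal cutpoints with
a minimum group size -- to define risk groups compared by Kaplan-Meier /
log-rank analysis.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .core import ExpressionMatrix, SampleAnnotation
from .scoring import SignatureScoreVector

__all__ = [
    "SiteRanking",
    "CoxPanelModel",
    "CutpointResult",
    "survival_frame",
    "rank_disease_sites",
    "rank_concordance",
    "mutation_association",
    "variance_filter",
    "univariate_cox_screen",
    "multivariate_cox_train",
    "linear_predictor",
    "split_by_quantiles",
    "optimal_cutpoints",
    "km_compare",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SiteRanking:
    """Disease sites ranked by median shifted score (rank 1 = highest)."""

    table: pd.DataFrame  # columns: site, n, median_score, rank

    @property
    def ranks(self) -> pd.Series:
        return self.table.set_index("site")["rank"]


@dataclass
class CoxPanelModel:
    genes: list[str]
    coefficients: pd.Series
    standard_errors: pd.Series
    training_cohort: str = ""
    screen_threshold: float = 0.5


@dataclass
class CutpointResult:
    cutpoints: list[float]
    group_sizes: list[int]
    chi_square: float
    p: float


def survival_frame(anns: Sequence[SampleAnnotation],
                   treated: bool | None = None) -> pd.DataFrame:
    """Time/event records (index = sample id), optionally filtered by arm."""
    rows = {}
    for a in anns:
        if a.survival_time is None:
            continue
        if treated is not None and a.treated != treated:
            continue
        rows[a.sample_id] = {"time": a.survival_time, "event": int(bool(a.event))}
    if not rows:
        raise ValueError("no survival records matched")
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# site ranking
# ---------------------------------------------------------------------------

def rank_disease_sites(scores: SignatureScoreVector, anns: Sequence[SampleAnnotation],
                       min_n: int = 25) -> SiteRanking:
    """Rank sites by median shifted score, dropping sites with n < min_n."""
    if scores.shifted_score is None:
        from .scoring import shift_scores_positive
        scores = shift_scores_positive(scores)
    site_of = {a.sample_id: a.disease_site for a in anns}
    missing = [s for s in scores.sample_ids if s not in site_of]
    if missing:
        raise ValueError(f"samples lack site annotation: {missing[:5]}")
    df = pd.DataFrame({
        "site": [site_of[s] for s in scores.sample_ids],
        "score": scores.shifted_score.to_numpy(),
    })
    agg = df.groupby("site").agg(n=("score", "size"), median_score=("score", "median"))
    agg = agg[agg["n"] >= min_n]
    if agg.empty:
        raise ValueError(f"no disease site has >= {min_n} samples")
    agg = agg.sort_values(["median_score", "site"], ascending=[False, True])
    agg["rank"] = np.arange(1, len(agg) + 1)
    return SiteRanking(agg.reset_index()[["site", "n", "median_score", "rank"]])


def rank_concordance(a: SiteRanking, b: SiteRanking) -> tuple[float, float, list[str]]:
    """Spearman correlation of shared sites' ranks between two rankings."""
    shared = sorted(set(a.ranks.index) & set(b.ranks.index))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared sites, got {len(shared)}")
    res = stats.spearmanr(a.ranks.loc[shared], b.ranks.loc[shared])
    return float(res.statistic), float(res.pvalue), shared


# ---------------------------------------------------------------------------
# mutation association
# ---------------------------------------------------------------------------

def mutation_association(scores: SignatureScoreVector, anns: Sequence[SampleAnnotation],
                         genes: Sequence[str]) -> pd.DataFrame:
    """Chi-square association of each gene's mutation calls with a median score split.

    Samples are split at the median score (strictly above = high). Each gene
    gets a 2x2 Pearson chi-square with continuity correction; genes mutated
    in none or all samples are untestable and excluded from the Bonferroni
    factor.
    """
    if len(scores.sample_ids) < 20:
        raise ValueError("need >= 20 samples for mutation association")
    calls = {a.sample_id: (a.mutations or {}) for a in anns}
    for s in scores.sample_ids:
        miss = [g for g in genes if g not in calls.get(s, {})]
        if miss:
            raise ValueError(f"sample {s!r} lacks mutation calls for {miss[:5]}")
    med = float(scores.score.median())
    high = scores.score > med
    rows = []
    testable = []
    for g in genes:
        mut = np.array([bool(calls[s][g]) for s in scores.sample_ids])
        if mut.all() or not mut.any():
            rows.append({"gene": g, "chi_square": np.nan, "p_raw": np.nan,
                         "p_bonferroni": np.nan, "testable": False})
            continue
        table = np.array([
            [np.sum(mut & high), np.sum(mut & ~high)],
            [np.sum(~mut & high), np.sum(~mut & ~high)],
        ])
        chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
        rows.append({"gene": g, "chi_square": float(chi2), "p_raw": float(p),
                     "p_bonferroni": np.nan, "testable": True})
        testable.append(len(rows) - 1)
    m = len(testable)
    for i in testable:
        rows[i]["p_bonferroni"] = min(1.0, rows[i]["p_raw"] * m)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cox panel training
# ---------------------------------------------------------------------------

def variance_filter(m: ExpressionMatrix, genes: set[str],
                    threshold: float = 0.2) -> set[str]:
    """Drop genes whose sample variance (divisor n-1) is strictly below threshold."""
    missing = genes - set(m.gene_ids)
    if missing:
        raise ValueError(f"genes absent from matrix: {sorted(missing)[:5]}")
    var = m.frame.loc[sorted(genes)].var(axis=1, ddof=1)
    kept = set(var[var >= threshold].index)
    if not kept:
        raise ValueError(f"no gene passes the variance filter at {threshold}; "
                         "review the threshold")
    return kept


def _cox_frame(m: ExpressionMatrix, cohort: pd.DataFrame, genes: list[str]) -> pd.DataFrame:
    samples = [s for s in cohort.index if s in m.sample_ids]
    if len(samples) < len(cohort):
        raise ValueError("cohort samples missing from expression matrix")
    df = m.frame.loc[genes, samples].T.copy()
    df["time"] = cohort.loc[samples, "time"]
    df["event"] = cohort.loc[samples, "event"]
    return df


def univariate_cox_screen(m: ExpressionMatrix, cohort: pd.DataFrame, genes: set[str],
                          coef_threshold: float = 0.5,
                          protective_only: bool = False) -> set[str]:
    """Retain genes whose single-covariate Cox coefficient is <= coef_threshold.

    ``protective_only=True`` additionally requires a negative coefficient
    (higher expression, lower hazard). Non-converging genes are dropped with
    a warning.
    """
    if int(cohort["event"].sum()) < 10:
        log.warning("univariate_cox_screen: only %d events", int(cohort["event"].sum()))
    kept = set()
    for g in sorted(genes):
        df = _cox_frame(m, cohort, [g])
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except Exception as exc:
            log.warning("gene %s dropped (fit failed: %s)", g, exc)
            continue
        coef = float(cph.params_[g])
        if coef <= coef_threshold and (not protective_only or coef < 0):
            kept.add(g)
    if not kept:
        raise ValueError("no gene passed the univariate screen")
    return kept


def multivariate_cox_train(m: ExpressionMatrix, cohort: pd.DataFrame,
                           genes: set[str], training_cohort: str = "",
                           penalizer: float = 0.0) -> CoxPanelModel:
    """Joint proportional-hazards fit over the retained genes (Efron ties)."""
    gene_list = sorted(genes)
    n_events = int(cohort["event"].sum())
    if len(gene_list) >= n_events:
        log.warning("fitting %d genes with only %d events; fit may be unstable",
                    len(gene_list), n_events)
    df = _cox_frame(m, cohort, gene_list)
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:
        raise RuntimeError(
            f"multivariate fit failed ({exc}); check collinearity/events"
        ) from exc
    return CoxPanelModel(
        genes=gene_list,
        coefficients=cph.params_.loc[gene_list],
        standard_errors=cph.standard_errors_.loc[gene_list],
        training_cohort=training_cohort,
    )


def linear_predictor(model: CoxPanelModel, m: ExpressionMatrix) -> pd.Series:
    """Risk score eta_j = sum_g beta_g * x_{g,j}; higher = higher predicted hazard."""
    missing = set(model.genes) - set(m.gene_ids)
    if missing:
        raise ValueError(f"model genes absent from matrix: {sorted(missing)[:5]}")
    x = m.frame.loc[model.genes]
    eta = model.coefficients.to_numpy() @ x.to_numpy()
    return pd.Series(eta, index=m.frame.columns, name="risk")


# ---------------------------------------------------------------------------
# risk-group construction and comparison
# ---------------------------------------------------------------------------

def split_by_quantiles(risk: pd.Series, kind: str = "median") -> pd.Series:
    """Fixed median or tertile split; group 0 = lowest risk."""
    if kind == "median":
        qs = [0.5]
    elif kind == "tertile":
        qs = [1 / 3, 2 / 3]
    else:
        raise ValueError(f"unknown split {kind!r}")
    cuts = risk.quantile(qs).to_numpy()
    return pd.Series(np.searchsorted(cuts, risk.to_numpy(), side="right"),
                     index=risk.index, name="group")


def _assign_groups(risk: pd.Series, cutpoints: Sequence[float]) -> pd.Series:
    return pd.Series(np.searchsorted(np.asarray(cutpoints), risk.to_numpy(),
                                     side="right"), index=risk.index, name="group")


def _logrank_groups(groups: pd.Series, cohort: pd.DataFrame) -> tuple[float, float, int]:
    idx = groups.index
    res = multivariate_logrank_test(cohort.loc[idx, "time"], groups,
                                    cohort.loc[idx, "event"])
    df = int(groups.nunique() - 1)
    return float(res.test_statistic), float(res.p_value), df


def optimal_cutpoints(risk: pd.Series, cohort: pd.DataFrame, k: int = 1,
                      min_group: int = 4) -> CutpointResult:
    """Exhaustive chi-square-maximizing cutpoint search on the risk score.

    Candidates are midpoints between consecutive sorted unique scores; every
    resulting group must contain at least ``min_group`` patients. Objective
    ties are broken toward the lowest cutpoint(s).
    """
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    n = len(risk)
    if n < (k + 1) * min_group:
        raise ValueError(f"n={n} cannot satisfy {k + 1} groups of >= {min_group}")
    uniq = np.unique(risk.to_numpy())
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    best: CutpointResult | None = None
    candidates = (
        [(c,) for c in mids] if k == 1 else
        [(a, b) for a, b in itertools.combinations(mids, 2)]
    )
    for cuts in candidates:
        groups = _assign_groups(risk, cuts)
        sizes = groups.value_counts()
        if len(sizes) != k + 1 or (sizes < min_group).any():
            continue
        chi2, p, _ = _logrank_groups(groups, cohort)
        if best is None or chi2 > best.chi_square + 1e-12:
            ordered = [int(sizes[g]) for g in sorted(sizes.index)]
            best = CutpointResult(list(map(float, cuts)), ordered, chi2, p)
    if best is None:
        raise ValueError("no feasible cutpoint satisfies the minimum group size")
    return best


def km_compare(groups: pd.Series, cohort: pd.DataFrame
               ) -> tuple[list[pd.DataFrame], float, float, int]:
    """Kaplan-Meier curves per risk group plus a log-rank comparison.

    Returns (curves, chi_square, p, df); each curve frame has columns
    ``time``, ``survival`` and ``group``.
    """
    if groups.empty:
        raise ValueError("no groups supplied")
    curves = []
    for g in sorted(groups.unique()):
        idx = groups.index[groups == g]
        sub = cohort.loc[idx]
        if int(sub["event"].sum()) == 0:
            log.warning("group %s has no events; curve stays at 1", g)
        km = KaplanMeierFitter()
        km.fit(sub["time"], sub["event"])
        frame = km.survival_function_.reset_index()
        frame.columns = ["time", "survival"]
        frame["group"] = g
        curves.append(frame)
    chi2, p, df = _logrank_groups(groups, cohort)
    return curves, chi2, p, df
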