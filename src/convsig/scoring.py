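"""Signature scoring and signature quality-control metrics.

A sample's signature score is the median of the per-gene z-scored expression
of the signature genes within the dataset at hand. For log-scale plotting
and per-site ranking, scores are shifted by ``|min| + 1`` so the minimum
becomes exactly 1 whenever the minimum is non-positive.

QC metrics summarize how coherently and variably the signature genes behave
in a dataset (intra-signature correlation, agreement of mean/median/first
principal component summaries, score spread, representation among the most
variable genes, skewness) and are combined into a radar-area summary score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, zscore_by_gene

__all__ = [
    "SignatureScoreVector",
    "QCReport",
    "signature_score",
    "shift_scores_positive",
    "qc_metrics",
    "normalize_qc_reports",
    "qc_area_score",
    "radar_plot",
]

log = logging.getLogger(__name__)


@dataclass
class SignatureScoreVector:
    """Per-sample signature scores (median of per-gene z-scores)."""

    score: pd.Series
    shifted_score: pd.Series | None = None
    genes_used: list[str] | None = None

    @property
    def sample_ids(self) -> list[str]:
        return self.score.index.tolist()


@dataclass
class QCReport:
    intra_sig_correlation: float
    rho_mean_median: float
    rho_mean_pc1: float
    score_sd: float
    score_cv: float
    prop_top_var: dict[int, float]
    skewness: float
    area_score: float | None = None

    def as_dict(self) -> dict:
        d = {
            "intra_sig_correlation": self.intra_sig_correlation,
            "rho_mean_median": self.rho_mean_median,
            "rho_mean_pc1": self.rho_mean_pc1,
            "score_sd": self.score_sd,
            "score_cv": self.score_cv,
            "skewness": self.skewness,
        }
        for k, v in self.prop_top_var.items():
            d[f"prop_top_var_{k}"] = v
        if self.area_score is not None:
            d["area_score"] = self.area_score
        return d


def _signature_submatrix(m: ExpressionMatrix, genes: set[str],
                         drop_missing: bool) -> ExpressionMatrix:
    present = [g for g in m.gene_ids if g in genes]
    missing = set(genes) - set(present)
    if missing:
        if not drop_missing:
            raise ValueError(f"signature genes absent from matrix: {sorted(missing)[:10]}")
        log.warning("dropping %d signature genes absent from the matrix", len(missing))
    if not present:
        raise ValueError(f"no signature genes found in matrix; requested {sorted(genes)[:10]}")
    sub = m.frame.loc[present]
    const = sub.std(axis=1, ddof=1) == 0
    if const.any():
        log.warning("excluding %d constant signature genes from scoring", int(const.sum()))
        sub = sub.loc[~const]
    if sub.shape[0] == 0:
        raise ValueError("all signature genes are constant in this matrix")
    return ExpressionMatrix(sub, m.scale_tag) if sub.shape[0] >= 2 else _single_row(sub, m)


def _single_row(sub: pd.DataFrame, m: ExpressionMatrix) -> ExpressionMatrix:
    # ExpressionMatrix requires >=2 genes; duplicate the row to z-score, then
    # callers take the median which is unaffected
    dup = pd.concat([sub, sub])
    return ExpressionMatrix(dup, m.scale_tag)


def signature_score(m: ExpressionMatrix, genes: set[str],
                    drop_missing: bool = True) -> SignatureScoreVector:
    """Median per-gene z-scored expression of the signature genes per sample."""
    sub = _signature_submatrix(m, set(genes), drop_missing)
    z = zscore_by_gene(sub)
    score = pd.Series(np.median(z.values, axis=0), index=m.frame.columns, name="score")
    used = list(dict.fromkeys(sub.gene_ids))
    return SignatureScoreVector(score=score, genes_used=used)


def shift_scores_positive(s: SignatureScoreVector) -> SignatureScoreVector:
    """Add ``|min(score)| + 1`` to every score.

    For non-positive minima this maps the minimum to exactly 1 (the intended
    use, enabling log-scale display); the formula is applied verbatim for
    positive minima too.
    """
    shift = abs(float(s.score.min())) + 1.0
    return SignatureScoreVector(score=s.score, shifted_score=s.score + shift,
                                genes_used=s.genes_used)


def qc_metrics(m: ExpressionMatrix, genes: set[str],
               top_percents: tuple[int, ...] = (10, 25, 50)) -> QCReport:
    """Quality-control metrics for a signature within a dataset."""
    present = [g for g in m.gene_ids if g in genes]
    if len(present) < 2:
        raise ValueError("need at least 2 signature genes present for QC")
    if m.shape[1] < 10:
        raise ValueError("need at least 10 samples for QC")
    sub = m.frame.loc[present]
    nonconst = sub.std(axis=1, ddof=1) > 0
    sub = sub.loc[nonconst]
    if sub.shape[0] < 2:
        raise ValueError("fewer than 2 non-constant signature genes")

    # mean pairwise Spearman among signature genes (off-diagonal)
    rho = stats.spearmanr(sub.to_numpy(), axis=1).statistic
    if np.ndim(rho) == 0:  # exactly two genes
        intra = float(rho)
    else:
        iu = np.triu_indices_from(rho, k=1)
        intra = float(np.mean(rho[iu]))

    z = (sub.to_numpy() - sub.to_numpy().mean(axis=1, keepdims=True)) \
        / sub.to_numpy().std(axis=1, ddof=1, keepdims=True)
    mean_s = z.mean(axis=0)
    median_s = np.median(z, axis=0)
    rho_mm = float(stats.spearmanr(mean_s, median_s).statistic)

    # first principal component of the z-scored signature submatrix
    u, sv, vt = np.linalg.svd(z - z.mean(axis=1, keepdims=True), full_matrices=False)
    pc1 = vt[0]
    if np.corrcoef(pc1, mean_s)[0, 1] < 0:
        pc1 = -pc1
    rho_pc1 = float(stats.spearmanr(mean_s, pc1).statistic)

    score = pd.Series(median_s, index=m.frame.columns)
    sd = float(score.std(ddof=1))
    shifted = score + abs(float(score.min())) + 1.0
    cv = float(shifted.std(ddof=1) / shifted.mean())
    skew = float(stats.skew(score.to_numpy()))

    gvar = m.frame.var(axis=1, ddof=1)
    var_rank = gvar.rank(ascending=False, method="first")  # 1 = most variable
    n_genes = len(gvar)
    prop = {}
    for pct in top_percents:
        cut = n_genes * pct / 100.0
        prop[pct] = float((var_rank.loc[sub.index] <= cut).mean())

    return QCReport(
        intra_sig_correlation=intra,
        rho_mean_median=rho_mm,
        rho_mean_pc1=rho_pc1,
        score_sd=sd,
        score_cv=cv,
        prop_top_var=prop,
        skewness=skew,
    )


DEFAULT_METRIC_ORDER = [
    "intra_sig_correlation", "rho_mean_median", "rho_mean_pc1",
    "score_sd", "score_cv", "prop_top_var_10", "prop_top_var_25",
    "prop_top_var_50", "skewness",
]


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = np.min(values), np.max(values)
    if hi == lo:
        return np.full_like(values, 1.0, dtype=float)
    return (values - lo) / (hi - lo)


def normalize_qc_reports(reports: dict[str, QCReport]) -> dict[str, dict[str, float]]:
    """Map every metric of a set of compared signatures onto [0,1].

    Correlations are clipped at 0, proportions pass through, SD and CV are
    min-max scaled across the compared signatures, and skewness maps to
    ``1 - minmax(|skewness|)`` (less skewed is better).
    """
    names = list(reports)
    flat = {n: reports[n].as_dict() for n in names}
    out = {n: {} for n in names}
    sd = _minmax(np.array([flat[n]["score_sd"] for n in names]))
    cv = _minmax(np.array([flat[n]["score_cv"] for n in names]))
    skew = 1.0 - _minmax(np.abs([flat[n]["skewness"] for n in names]))
    for i, n in enumerate(names):
        for key, val in flat[n].items():
            if key.startswith("rho") or key == "intra_sig_correlation":
                out[n][key] = max(float(val), 0.0)
            elif key.startswith("prop_top_var"):
                out[n][key] = float(val)
        out[n]["score_sd"] = float(sd[i])
        out[n]["score_cv"] = float(cv[i])
        out[n]["skewness"] = float(skew[i])
    return out


def qc_area_score(metrics: dict[str, float],
                  metric_order: list[str] | None = None) -> float:
    """Radar-polygon area of [0,1] metrics relative to the full polygon.

    Metrics sit at equally spaced angles; the polygon area (shoelace) is
    divided by the regular-polygon area with all radii 1. Invariant to
    cyclic rotation of the metric order.
    """
    order = metric_order or [k for k in DEFAULT_METRIC_ORDER if k in metrics]
    if len(order) < 3:
        raise ValueError("need at least 3 metrics for a radar area")
    r = np.array([metrics[k] for k in order], dtype=float)
    if np.any((r < -1e-12) | (r > 1 + 1e-12)):
        raise ValueError("metrics must be normalized to [0,1] first")
    k = len(r)
    nxt = np.roll(r, -1)
    area = 0.5 * np.sum(r * nxt * np.sin(2 * np.pi / k))
    full = 0.5 * k * np.sin(2 * np.pi / k)
    return float(area / full)


def radar_plot(normalized: dict[str, dict[str, float]], path: str,
               metric_order: list[str] | None = None) -> None:
    """Optional radar-plot rendering of normalized QC metrics (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    any_metrics = next(iter(normalized.values()))
    order = metric_order or [k for k in DEFAULT_METRIC_ORDER if k in any_metrics]
    angles = np.linspace(0, 2 * np.pi, len(order), endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    for name, mets in normalized.items():
        vals = [mets[k] for k in order]
        ax.plot(np.r_[angles, angles[:1]], np.r_[vals, vals[:1]], label=name)
    ax.set_xticks(angles)
    ax.set_xticklabels(order, fontsize=7)
    ax.set_ylim(0, 1)
    ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1), fontsize=8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
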