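"""Fold construction, extreme-responder contrasts and the three DE statistics.

Per data partition, cell lines in the lowest and highest IC50 fractions form
the "sensitive" and "resistant" groups. Three differential-expression
procedures are run gene-wise -- an empirical-Bayes moderated t, a
permutation-based d-statistic with a variance-stabilizing fudge factor
(SAM), and a bootstrap single-step minP multiplicity adjustment
(Westfall-Young) -- and the genes called *up in sensitive* by all three form
that fold's seed-gene set.

All three statistics are authored here: the moderated t squeezes per-gene
variances toward a method-of-moments prior; the d-statistic adds a fudge
factor s0 chosen to minimize the coefficient of variation of d across the
spread of per-gene standard errors; minP adjusts each raw p by the bootstrap
distribution of the minimum p over genes under a mean-centered null.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .core import DrugResponseTable, ExpressionMatrix

__all__ = [
    "FoldPlan",
    "SeedGeneSet",
    "split_folds",
    "select_extreme_responders",
    "moderated_t_test",
    "sam_test",
    "minp_test",
    "derive_seed_genes",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# folds and extreme responders
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Seeded uniform partition of samples into folds of near-equal size."""

    fold_assignments: dict[str, int]
    n_folds: int

    def fold_samples(self, fold: int) -> list[str]:
        return [s for s, f in self.fold_assignments.items() if f == fold]

    def retained(self, fold: int) -> list[str]:
        """All samples *not* in the given fold (the fold's working set)."""
        return [s for s, f in self.fold_assignments.items() if f != fold]


def split_folds(samples: list[str], n_folds: int, seed: int) -> FoldPlan:
    """Randomly partition samples into ``n_folds`` folds (sizes differ by <=1)."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > len(samples):
        raise ValueError(f"n_folds={n_folds} exceeds sample count {len(samples)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    assignments: dict[str, int] = {}
    for pos, idx in enumerate(order):
        assignments[samples[idx]] = (pos % n_folds) + 1
    # keep insertion order aligned with the original sample order
    assignments = {s: assignments[s] for s in samples}
    return FoldPlan(assignments, n_folds)


def select_extreme_responders(
    resp: DrugResponseTable, fraction: float
) -> tuple[set[str], set[str]]:
    """Lowest-IC50 (sensitive) and highest-IC50 (resistant) sample fractions.

    Group size is ``floor(fraction * n)``; ties at the boundary are broken by
    ascending sample identifier (stable, documented).
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must lie in (0, 0.5]")
    n = len(resp.sample_ids)
    k = math.floor(fraction * n)
    if k < 2:
        raise ValueError(f"fraction {fraction} of {n} samples leaves <2 per group")
    order = sorted(resp.sample_ids, key=lambda s: (resp.ic50[s], s))
    return set(order[:k]), set(order[-k:])


# ---------------------------------------------------------------------------
# shared two-group machinery
# ---------------------------------------------------------------------------

def _group_arrays(
    m: ExpressionMatrix, sensitive: set[str], resistant: set[str], min_per_group: int = 2
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if sensitive & resistant:
        raise ValueError("sensitive and resistant groups overlap")
    for name, grp in (("sensitive", sensitive), ("resistant", resistant)):
        missing = grp - set(m.sample_ids)
        if missing:
            raise ValueError(f"{name} samples absent from matrix: {sorted(missing)[:5]}")
        if len(grp) < min_per_group:
            raise ValueError(f"{name} group has {len(grp)} samples, need >= {min_per_group}")
    sens = sorted(sensitive)
    res = sorted(resistant)
    x1 = m.frame.loc[:, sens].to_numpy()
    x2 = m.frame.loc[:, res].to_numpy()
    return x1, x2, m.gene_ids


def _pooled_stats(x1: np.ndarray, x2: np.ndarray):
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss1 = ((x1 - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((x2 - m2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    s2 = (ss1 + ss2) / df
    return m1, m2, s2, df, n1, n2


def _result_frame(genes, m1, m2, stat, p_raw, q, method, significant) -> pd.DataFrame:
    return pd.DataFrame({
        "gene_id": genes,
        "mean_sensitive": m1,
        "mean_resistant": m2,
        "lfc": m1 - m2,
        "stat": stat,
        "p_raw": p_raw,
        "q_or_adj": q,
        "method": method,
        "significant": significant,
    })


# ---------------------------------------------------------------------------
# moderated t (empirical-Bayes variance squeezing)
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) / np.maximum(x, 1e-12) < 1e-10):
            break
    return x


def _fit_variance_prior(s2: np.ndarray, df: int,
                        covariate: np.ndarray | None = None,
                        lowess_frac: float = 0.5) -> tuple[float, np.ndarray]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Returns ``(d0, s0_sq)`` where ``s0_sq`` is per-gene when a trend
    covariate (mean expression) is supplied, else constant.
    """
    s2 = np.maximum(s2, 1e-300)
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    if covariate is not None:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        order = np.argsort(covariate)
        sm = lowess(e[order], covariate[order], frac=lowess_frac, return_sorted=False)
        e_trend = np.empty_like(e)
        e_trend[order] = sm
        resid = e - e_trend
        e_mean = e_trend
        evar = resid.var(ddof=1)
    else:
        e_mean = np.full_like(e, e.mean())
        evar = e.var(ddof=1)
    evar = evar - special.polygamma(1, df / 2.0)
    if evar <= 0:
        d0 = np.inf
        s0_sq = np.exp(e_mean)
    else:
        d0 = float(2.0 * _trigamma_inverse(np.array([evar]))[0])
        s0_sq = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return d0, s0_sq


def moderated_t_test(
    m: ExpressionMatrix,
    sensitive: set[str],
    resistant: set[str],
    lfc_cutoff: float = 0.5,
    p_cutoff: float = 0.20,
    trend: bool = False,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-group t-test per gene.

    The pooled per-gene variance is squeezed toward a prior estimated by
    method of moments on the log variances; the moderated t uses
    ``d0 + df`` degrees of freedom. ``prior_df=0`` disables moderation and
    reduces to the classical pooled t (used as an oracle check).
    Significance: unadjusted ``p < p_cutoff`` together with
    ``lfc >= lfc_cutoff`` (up in sensitive only).
    """
    x1, x2, genes = _group_arrays(m, sensitive, resistant)
    m1, m2, s2, df, n1, n2 = _pooled_stats(x1, x2)
    if np.all(s2 == 0):
        raise ValueError("all genes constant within groups; cannot test")

    if prior_df is not None and prior_df == 0:
        d0, s0_sq = 0.0, np.zeros_like(s2)
    else:
        cov = np.concatenate([x1, x2], axis=1).mean(axis=1) if trend else None
        d0, s0_sq = _fit_variance_prior(s2, df, covariate=cov)
        if prior_df is not None:
            d0 = float(prior_df)
    if np.isinf(d0):
        s2_post = s0_sq
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, (m1 - m2) / se, 0.0)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2 * stats.t.sf(np.abs(tstat), df_total)
    lfc = m1 - m2
    significant = (p < p_cutoff) & (lfc >= lfc_cutoff) & (lfc > 0)
    return _result_frame(genes, m1, m2, tstat, p, p, "moderated_t", significant)


# ---------------------------------------------------------------------------
# SAM d-statistic with permutation null
# ---------------------------------------------------------------------------

def _d_statistic(x1, x2, s0):
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2, s2, df, _, _ = _pooled_stats(x1, x2)
    s = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    return (m1 - m2) / (s + s0), s


def _choose_fudge_factor(r: np.ndarray, s: np.ndarray) -> float:
    """Fudge factor s0: the percentile of s minimizing the CV of d across s windows.

    ``r`` is the unpenalized numerator (mean difference), ``s`` the per-gene
    standard error. Candidate s0 values are the 0,5,...,100 percentiles of s;
    for each, genes are binned into 100 quantile windows of s and the
    coefficient of variation of the within-window MADs of d is minimized.
    """
    qs = np.percentile(s, np.arange(0, 101, 5))
    # window edges on s (100 windows)
    edges = np.percentile(s, np.linspace(0, 100, 101))
    which = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, 99)
    best_cv, best_s0 = np.inf, 0.0
    for s0 in qs:
        d = r / (s + s0)
        mads = []
        for w in range(100):
            dw = d[which == w]
            if dw.size >= 2:
                med = np.median(dw)
                mads.append(np.median(np.abs(dw - med)) / 0.64)
        mads = np.asarray(mads)
        if mads.size < 2 or mads.mean() == 0:
            continue
        cv = mads.std(ddof=1) / mads.mean()
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _enumerate_splits(n_total: int, n1: int, n_perm: int):
    """All label splits when feasible, else None."""
    if math.comb(n_total, n1) <= n_perm:
        return list(itertools.combinations(range(n_total), n1))
    return None


def _perm_label_matrix(splits, n_total: int) -> np.ndarray:
    lab = np.zeros((len(splits), n_total))
    for i, comb in enumerate(splits):
        lab[i, list(comb)] = 1.0
    return lab


def sam_test(
    m: ExpressionMatrix,
    sensitive: set[str],
    resistant: set[str],
    n_perm: int = 10000,
    fdr_cutoff: float = 0.20,
    seed: int = 1,
    s0: float | None = None,
) -> pd.DataFrame:
    """Permutation d-statistic test with per-gene q-values.

    ``d_g = lfc_g / (s_g + s0)`` with ``s_g`` the pooled standard error. The
    null is built from ``n_perm`` label permutations (exhaustive enumeration
    of all splits when their count does not exceed ``n_perm``). The per-gene
    q-value is ``pi0 * (median false calls) / (observed calls)`` at the
    gene's own |d| threshold, made monotone in |d|. Significance:
    ``q <= fdr_cutoff`` and ``d > 0``. Pass ``s0=0`` to disable the fudge
    factor (d then ranks genes exactly as the ordinary t).
    """
    if n_perm < 100:
        log.warning("sam_test: n_perm=%d is very small; null will be coarse", n_perm)
    x1, x2, genes = _group_arrays(m, sensitive, resistant, min_per_group=3)
    n1, n2 = x1.shape[1], x2.shape[1]
    n_total = n1 + n2
    x = np.concatenate([x1, x2], axis=1)

    m1, m2, s2, df, _, _ = _pooled_stats(x1, x2)
    r = m1 - m2
    s = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    if s0 is None:
        s0 = _choose_fudge_factor(r, s)
    d_obs = r / (s + s0)

    splits = _enumerate_splits(n_total, n1, n_perm)
    rng = np.random.default_rng(seed)
    if splits is None:
        labels = np.zeros((n_perm, n_total))
        for i in range(n_perm):
            idx = rng.choice(n_total, size=n1, replace=False)
            labels[i, idx] = 1.0
    else:
        labels = _perm_label_matrix(splits, n_total)
    B = labels.shape[0]

    # counts of |d*| >= threshold for every observed threshold, per permutation
    abs_obs = np.abs(d_obs)
    order = np.argsort(abs_obs)           # ascending
    thresh = abs_obs[order]
    n_genes = len(genes)

    row_sum = x.sum(axis=1)
    row_sq = (x ** 2).sum(axis=1)
    false_counts = np.empty((B, n_genes), dtype=np.int64)
    pool_sample: list[np.ndarray] = []
    chunk = max(1, int(2_000_000_000 / (16 * n_genes)))  # ~2GB working cap
    chunk = min(chunk, 2000, B)
    for start in range(0, B, chunk):
        lab = labels[start:start + chunk]          # (b, n_total)
        b = lab.shape[0]
        cnt1 = lab.sum(axis=1)                     # == n1
        sum1 = x @ lab.T                           # (genes, b)
        sq1 = (x ** 2) @ lab.T
        sum2 = row_sum[:, None] - sum1
        sq2 = row_sq[:, None] - sq1
        mu1 = sum1 / n1
        mu2 = sum2 / n2
        ss1 = sq1 - n1 * mu1 ** 2
        ss2 = sq2 - n2 * mu2 ** 2
        s2p = np.maximum((ss1 + ss2) / df, 0.0)
        sp = np.sqrt(s2p * (1.0 / n1 + 1.0 / n2))
        dstar = (mu1 - mu2) / (sp + s0)
        del cnt1
        # per permutation, number of |d*| >= each observed threshold; the
        # thresholds are nudged down by a relative epsilon so exact ties
        # (e.g. the identity and label-swap splits) survive floating-point
        # differences between the two variance formulas
        thresh_adj = thresh - (1e-9 * np.abs(thresh) + 1e-12)
        for j in range(b):
            col = np.sort(np.abs(dstar[:, j]))
            false_counts[start + j] = n_genes - np.searchsorted(col, thresh_adj, side="left")
        # deterministic subsample of the signed null pool for pi0
        flat = dstar.ravel()
        stride = max(1, flat.size * B // (b * 1_000_000))
        pool_sample.append(flat[::stride].copy())

    med_false = np.median(false_counts, axis=0)    # aligned with ascending thresh

    pool = np.concatenate(pool_sample)
    q25, q75 = np.percentile(pool, [25, 75])
    pi0 = min(1.0, np.mean((d_obs > q25) & (d_obs < q75)) / 0.5) if pool.size else 1.0

    observed_calls = n_genes - np.arange(n_genes)  # for ascending thresh
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_at = np.minimum(pi0 * med_false / observed_calls, 1.0)
    # q_g = min FDR over thresholds at or below |d_g| (ascending running min)
    q_sorted = np.minimum.accumulate(fdr_at)
    q = np.empty(n_genes)
    q[order] = q_sorted

    # raw permutation p for reporting
    p_raw = np.empty(n_genes)
    # mean over permutations of fraction |d*| >= |d_g| is med_false-like; use mean
    mean_false = false_counts.mean(axis=0)
    p_raw[order] = np.minimum(mean_false / n_genes, 1.0)

    significant = (q <= fdr_cutoff) & (d_obs > 0)
    return _result_frame(genes, m1, m2, d_obs, p_raw, q, "sam", significant)


# ---------------------------------------------------------------------------
# Westfall-Young single-step minP via bootstrap
# ---------------------------------------------------------------------------

def minp_test(
    m: ExpressionMatrix,
    sensitive: set[str],
    resistant: set[str],
    n_boot: int = 1000,
    adj_p_cutoff: float = 0.20,
    seed: int = 1,
) -> pd.DataFrame:
    """Single-step minP adjusted p-values from a null-enforcing bootstrap.

    Raw p-values come from the pooled two-sample t. Each bootstrap iteration
    resamples, with replacement, within each group after per-gene
    mean-centering (which enforces the complete null), recomputes all raw
    p-values, and records their minimum. The adjusted p of gene g is the
    proportion of iterations whose minimum p is <= p_g, floored at p_g so the
    single-step guarantee ``adj_p >= p_raw`` holds exactly at finite
    bootstrap resolution. Significance: ``adj_p <= adj_p_cutoff`` and
    ``lfc > 0``.
    """
    if n_boot < 100:
        log.warning("minp_test: n_boot=%d is very small; adjustment will be coarse", n_boot)
    x1, x2, genes = _group_arrays(m, sensitive, resistant, min_per_group=3)
    m1, m2, s2, df, n1, n2 = _pooled_stats(x1, x2)
    se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_obs = np.where(se > 0, (m1 - m2) / se, 0.0)
    p_raw = 2 * stats.t.sf(np.abs(t_obs), df)

    # center per gene within group -> complete-null bootstrap population
    c1 = x1 - x1.mean(axis=1, keepdims=True)
    c2 = x2 - x2.mean(axis=1, keepdims=True)
    sq1 = c1 ** 2
    sq2 = c2 ** 2

    rng = np.random.default_rng(seed)
    minp = np.empty(n_boot)
    chunk = min(n_boot, max(1, 400))
    pos = 0
    while pos < n_boot:
        b = min(chunk, n_boot - pos)
        w1 = rng.multinomial(n1, np.full(n1, 1.0 / n1), size=b).T.astype(float)  # (n1,b)
        w2 = rng.multinomial(n2, np.full(n2, 1.0 / n2), size=b).T.astype(float)
        s1 = c1 @ w1
        s2b = c2 @ w2
        mu1 = s1 / n1
        mu2 = s2b / n2
        ssq1 = sq1 @ w1 - n1 * mu1 ** 2
        ssq2 = sq2 @ w2 - n2 * mu2 ** 2
        s2p = np.maximum((ssq1 + ssq2) / df, 0.0)
        sp = np.sqrt(s2p * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            tb = np.where(sp > 0, (mu1 - mu2) / sp, 0.0)
        pb = 2 * stats.t.sf(np.abs(tb), df)
        minp[pos:pos + b] = pb.min(axis=0)
        pos += b

    minp_sorted = np.sort(minp)
    adj = np.searchsorted(minp_sorted, p_raw, side="right") / n_boot
    adj = np.maximum(adj, p_raw)  # finite-resampling monotonicity floor
    lfc = m1 - m2
    significant = (adj <= adj_p_cutoff) & (lfc > 0)
    return _result_frame(genes, m1, m2, t_obs, p_raw, adj, "minp", significant)


# ---------------------------------------------------------------------------
# seed genes
# ---------------------------------------------------------------------------

@dataclass
class SeedGeneSet:
    """Per-fold three-way intersection of up-in-sensitive significant genes."""

    fold: int
    genes: set[str]
    per_method_counts: dict[str, int] = field(default_factory=dict)


def derive_seed_genes(results: list[pd.DataFrame], fold: int = 0) -> SeedGeneSet:
    """Intersect the significant up-in-sensitive gene sets of the three methods."""
    if not results:
        raise ValueError("no DE results supplied")
    universes = [frozenset(r["gene_id"]) for r in results]
    if len(set(universes)) != 1:
        raise ValueError("DE results cover mismatched gene universes")
    sig_sets = []
    counts: dict[str, int] = {}
    for r in results:
        sig = set(r.loc[r["significant"], "gene_id"])
        counts[str(r["method"].iloc[0])] = len(sig)
        sig_sets.append(sig)
    genes = set.intersection(*sig_sets)
    if any(len(s) == 0 for s in sig_sets):
        log.warning("fold %s: at least one method found no significant genes", fold)
    if not genes:
        log.warning("fold %s: empty seed-gene set", fold)
    return SeedGeneSet(fold=fold, genes=genes, per_method_counts=counts)
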