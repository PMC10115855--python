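"""Seed-gene co-expression network, connectivity scoring and consensus signature.

Each fold's seed genes are correlated (Spearman) against every gene in a
clinical cohort, giving an affinity matrix. The largest fraction of signed
affinities is binarized to 1 (positive co-expression only), each gene's
connectivity score is the mean of its binarized affinities to the seeds
(self-pairs excluded), and the seed genes falling in the global top
connectivity fraction become that fold's connectivity genes. Genes present
in at least ``min_folds`` of the per-fold connectivity sets form the
consensus signature.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix

__all__ = [
    "AffinityMatrix",
    "ConnectivityResult",
    "ConsensusSignature",
    "compute_affinity_matrix",
    "binarize_affinity",
    "compute_connectivity_scores",
    "extract_connectivity_genes",
    "consensus_signature",
    "load_reference_signature",
]

log = logging.getLogger(__name__)


@dataclass
class AffinityMatrix:
    """Spearman correlations of each seed gene against every gene.

    ``values`` has shape (n_seeds, n_genes); the (s, s) self-pairs are NaN.
    ``binarized`` is populated by :func:`binarize_affinity`.
    """

    seed_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    binarized: np.ndarray | None = None


@dataclass
class ConnectivityResult:
    """Per-gene connectivity scores and, once thresholded, the fold's genes."""

    connectivity_score: pd.Series
    threshold_value: float | None = None
    connectivity_genes: set[str] = field(default_factory=set)


@dataclass
class ConsensusSignature:
    """Cross-fold consensus gene list with per-gene fold membership."""

    genes: list[str]
    fold_membership: dict[str, set[int]]
    min_folds: int

    def to_json(self, path: str | Path, params: dict | None = None) -> None:
        payload = {
            "genes": self.genes,
            "fold_membership": {g: sorted(f) for g, f in self.fold_membership.items()},
            "min_folds": self.min_folds,
            "params": params or {},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def to_txt(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.genes) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ConsensusSignature":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            genes=list(payload["genes"]),
            fold_membership={g: set(f) for g, f in payload["fold_membership"].items()},
            min_folds=int(payload["min_folds"]),
        )


def compute_affinity_matrix(clinical: ExpressionMatrix, seeds: set[str]) -> AffinityMatrix:
    """Spearman affinity of every seed gene to every gene in the cohort.

    Ties receive average ranks; the (seed, seed) self-pair is NaN. Constant
    genes yield NaN affinities with a warning.
    """
    if clinical.shape[1] < 10:
        raise ValueError("need at least 10 clinical samples for co-expression")
    missing = seeds - set(clinical.gene_ids)
    if missing:
        raise ValueError(f"seed genes absent from cohort: {sorted(missing)[:10]}")
    seed_ids = sorted(seeds)
    genes = clinical.gene_ids

    ranks = stats.rankdata(clinical.values, axis=1)
    sd = ranks.std(axis=1)
    const = sd == 0
    if const.any():
        log.warning("%d constant genes; their affinities recorded as missing",
                    int(const.sum()))
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.where(const, np.nan, np.sqrt((centered ** 2).sum(axis=1)))
    normed = centered / denom[:, None]

    pos = {g: i for i, g in enumerate(genes)}
    seed_idx = [pos[s] for s in seed_ids]
    vals = normed[seed_idx] @ normed.T        # (n_seeds, n_genes) Spearman rho
    vals = np.clip(vals, -1.0, 1.0, out=vals)
    vals[~np.isfinite(vals)] = np.nan
    for i, s in enumerate(seed_ids):
        vals[i, pos[s]] = np.nan
    return AffinityMatrix(seed_ids, list(genes), vals)


def binarize_affinity(a: AffinityMatrix, top_fraction: float,
                      per_seed: bool = False) -> AffinityMatrix:
    """Set the largest ``top_fraction`` of signed affinities to 1, the rest to 0.

    The threshold is the (1 - top_fraction) linear-interpolation quantile of
    the pooled non-missing signed values (strict ``>``, so ties at the
    threshold fall below). ``per_seed=True`` applies the cut within each
    seed's row instead of globally.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must lie in (0,1)")
    vals = a.values
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("affinity matrix has no usable values")
    binar = np.zeros_like(vals)
    if per_seed:
        for i in range(vals.shape[0]):
            row = vals[i][finite[i]]
            thr = np.quantile(row, 1 - top_fraction)
            binar[i] = np.where(finite[i] & (vals[i] > thr), 1.0, 0.0)
    else:
        thr = np.quantile(vals[finite], 1 - top_fraction)
        binar = np.where(finite & (vals > thr), 1.0, 0.0)
        if not binar.any():
            log.warning("binarize_affinity: no entries above the threshold "
                        "(degenerate ties at %g)", thr)
    binar[~finite] = np.nan
    return AffinityMatrix(a.seed_ids, a.gene_ids, a.values, binar)


def compute_connectivity_scores(a: AffinityMatrix) -> ConnectivityResult:
    """Mean binarized affinity of each gene across seeds (self excluded)."""
    if a.binarized is None:
        raise ValueError("binarize the affinity matrix first")
    with np.errstate(invalid="ignore"):
        score = np.nanmean(a.binarized, axis=0)
    score = np.nan_to_num(score, nan=0.0)
    return ConnectivityResult(pd.Series(score, index=a.gene_ids, name="connectivity"))


def extract_connectivity_genes(
    c: ConnectivityResult, seeds: set[str], top_fraction: float = 0.20,
    universe: str = "all",
) -> ConnectivityResult:
    """Intersect the seeds with the global top connectivity fraction.

    The threshold is the (1 - top_fraction) quantile of connectivity scores
    over all genes (``universe='all'``, default) or over the seeds only
    (``universe='seeds'``); membership requires a strictly greater score.
    """
    if not seeds:
        log.warning("extract_connectivity_genes: empty seed set")
        return ConnectivityResult(c.connectivity_score, None, set())
    scores = c.connectivity_score
    if universe == "all":
        ref = scores.to_numpy()
    elif universe == "seeds":
        ref = scores.loc[sorted(seeds)].to_numpy()
    else:
        raise ValueError(f"unknown universe {universe!r}")
    thr = float(np.quantile(ref, 1 - top_fraction))
    keep = {g for g in seeds if scores[g] > thr}
    return ConnectivityResult(scores, thr, keep)


def consensus_signature(per_fold: list[ConnectivityResult], min_folds: int) -> ConsensusSignature:
    """Genes present in at least ``min_folds`` of the per-fold connectivity sets.

    Output order: descending fold-membership count, then lexicographic.
    """
    if min_folds > len(per_fold):
        raise ValueError(f"min_folds={min_folds} exceeds the {len(per_fold)} folds supplied")
    membership: dict[str, set[int]] = {}
    for k, res in enumerate(per_fold, start=1):
        for g in res.connectivity_genes:
            membership.setdefault(g, set()).add(k)
    kept = {g: f for g, f in membership.items() if len(f) >= min_folds}
    if not kept:
        log.warning("consensus_signature: no gene reached %d folds", min_folds)
    ordered = sorted(kept, key=lambda g: (-len(kept[g]), g))
    return ConsensusSignature(ordered, kept, min_folds)


def load_reference_signature() -> list[str]:
    """The published 19-gene pan-cancer cisplatin sensitivity signature.

    Shipped as a packaged gene list so the scoring and translation stages can
    be exercised against a real signature without any extraction run.
    """
    text = resources.files("convsig.data").joinpath("cisplatin_signature_19.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]
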