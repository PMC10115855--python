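"""Shared data model, file IO, identifier hygiene and normalization.

Expression data are log2-scale genes x samples matrices. All downstream
stages (differential expression, co-expression, scoring, survival
translation) consume the containers defined here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExpressionMatrix",
    "DrugResponseTable",
    "SampleAnnotation",
    "PipelineConfig",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_drug_response",
    "write_drug_response",
    "read_annotations",
    "write_annotations",
    "collapse_duplicate_genes",
    "zscore_by_gene",
]

#: significant digits used for all text output
FLOAT_FORMAT = "%.12g"


class FormatError(ValueError):
    """Raised when an input file cannot be parsed into a valid container."""


@dataclass
class ExpressionMatrix:
    """Log-scale expression values, genes in rows.

    Parameters
    ----------
    frame : pandas.DataFrame
        Numeric matrix with gene identifiers as the index and sample
        identifiers as the columns.
    scale_tag : str
        One of ``log2_microarray``, ``log2_rnaseq`` or ``other``; purely
        descriptive.
    """

    frame: pd.DataFrame
    scale_tag: str = "other"

    def __post_init__(self) -> None:
        if self.frame.shape[0] < 2 or self.frame.shape[1] < 2:
            raise FormatError(
                f"expression matrix needs >=2 genes and >=2 samples, got {self.frame.shape}"
            )
        if self.frame.columns.duplicated().any():
            dups = self.frame.columns[self.frame.columns.duplicated()].tolist()
            raise FormatError(f"duplicate sample identifiers: {dups[:5]}")
        vals = self.frame.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise FormatError(
                "non-finite expression value at gene "
                f"{self.frame.index[bad[0]]!r}, sample {self.frame.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return self.frame.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.frame.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.frame.loc[:, list(samples)], self.scale_tag)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.frame.loc[list(genes)], self.scale_tag)


@dataclass
class DrugResponseTable:
    """Per-sample drug response: IC50 on the log2(uM) scale, optional AUC."""

    ic50: pd.Series
    auc: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.ic50.index.duplicated().any():
            raise FormatError("duplicate sample identifiers in drug response table")
        if not np.isfinite(self.ic50.to_numpy(dtype=float)).all():
            bad = self.ic50.index[~np.isfinite(self.ic50.to_numpy(dtype=float))]
            raise FormatError(f"non-finite IC50 for samples: {bad.tolist()[:5]}")
        self.ic50 = self.ic50.astype(float)
        if self.auc is not None:
            self.auc = self.auc.reindex(self.ic50.index).astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return self.ic50.index.tolist()

    def subset(self, samples: Iterable[str]) -> "DrugResponseTable":
        samples = list(samples)
        return DrugResponseTable(
            self.ic50.loc[samples],
            None if self.auc is None else self.auc.loc[samples],
        )


@dataclass
class SampleAnnotation:
    """Per-sample metadata: disease site, treatment flag, survival, mutations."""

    sample_id: str
    disease_site: str = ""
    treated: bool | None = None
    survival_time: float | None = None
    event: bool | None = None
    mutations: dict[str, bool] | None = None

    def __post_init__(self) -> None:
        if (self.survival_time is None) != (self.event is None):
            raise FormatError(
                f"sample {self.sample_id!r}: survival_time and event must be "
                "both present or both absent"
            )
        if self.survival_time is not None and self.survival_time <= 0:
            raise FormatError(f"sample {self.sample_id!r}: survival_time must be positive")


@dataclass
class PipelineConfig:
    """Tunable parameters of the extraction pipeline with their defaults."""

    n_folds: int = 5
    extreme_fraction: float = 0.2
    fdr_cutoff: float = 0.20
    lfc_cutoff: float = 0.5
    n_perm_sam: int = 10000
    n_boot_minp: int = 1000
    affinity_top_fraction: float = 0.05
    connectivity_top_fraction: float = 0.20
    consensus_min_folds: int = 3
    n_null: int = 1000
    rng_seed: int = 1

    def __post_init__(self) -> None:
        if self.consensus_min_folds > self.n_folds:
            raise ValueError("consensus_min_folds must be <= n_folds")
        for name in ("extreme_fraction", "fdr_cutoff", "affinity_top_fraction",
                     "connectivity_top_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1 and not (name == "extreme_fraction" and v == 0.5):
                raise ValueError(f"{name} must lie in (0,1), got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_matrix(
    path: str | Path,
    dialect: str = "genes_in_rows",
    scale_tag: str = "other",
) -> ExpressionMatrix:
    """Read a delimited expression matrix.

    The first column (``genes_in_rows``, default) or first row
    (``genes_in_cols``) holds gene identifiers; the header row/column holds
    sample identifiers. Duplicate gene rows are preserved as-is; collapse
    them explicitly with :func:`collapse_duplicate_genes`.
    """
    path = Path(path)
    if dialect not in ("genes_in_rows", "genes_in_cols"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        frame = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if frame.empty:
        raise FormatError(f"{path}: no data rows")
    if dialect == "genes_in_cols":
        frame = frame.T
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric or missing value for gene "
            f"{frame.index[r]!r}, sample {frame.columns[c]!r}"
        )
    frame = numeric.astype(float)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    # duplicate gene ids are allowed here and collapsed downstream
    return ExpressionMatrix(frame, scale_tag)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    m.frame.to_csv(path, sep=_sniff_sep(path), float_format=FLOAT_FORMAT,
                   index_label="gene")


def read_drug_response(path: str | Path) -> DrugResponseTable:
    """Read a TSV/CSV with columns ``sample_id``, ``ic50_log2uM`` and optional ``auc``."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    for col in ("sample_id", "ic50_log2uM"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return DrugResponseTable(
        df["ic50_log2uM"], df["auc"] if "auc" in df.columns else None
    )


def write_drug_response(resp: DrugResponseTable, path: str | Path) -> None:
    df = pd.DataFrame({"ic50_log2uM": resp.ic50})
    if resp.auc is not None:
        df["auc"] = resp.auc
    df.to_csv(Path(path), sep=_sniff_sep(Path(path)), float_format=FLOAT_FORMAT,
              index_label="sample_id")


_ANN_FIXED = ["sample_id", "disease_site", "treated", "time_months", "event"]


def read_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Read sample annotations; columns after the fixed five are mutation flags."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing column 'sample_id'")
    mut_cols = [c for c in df.columns if c not in _ANN_FIXED]
    out = []
    for _, row in df.iterrows():
        t = row.get("time_months")
        e = row.get("event")
        tr = row.get("treated")
        muts = {c: bool(row[c]) for c in mut_cols} if mut_cols else None
        out.append(SampleAnnotation(
            sample_id=str(row["sample_id"]),
            disease_site=str(row.get("disease_site", "")),
            treated=None if pd.isna(tr) else bool(tr),
            survival_time=None if pd.isna(t) else float(t),
            event=None if pd.isna(e) else bool(e),
            mutations=muts,
        ))
    return out


def write_annotations(anns: Sequence[SampleAnnotation], path: str | Path) -> None:
    mut_genes: list[str] = []
    for a in anns:
        if a.mutations:
            for g in a.mutations:
                if g not in mut_genes:
                    mut_genes.append(g)
    rows = []
    for a in anns:
        row: dict = {
            "sample_id": a.sample_id,
            "disease_site": a.disease_site,
            "treated": "" if a.treated is None else int(a.treated),
            "time_months": "" if a.survival_time is None else a.survival_time,
            "event": "" if a.event is None else int(a.event),
        }
        for g in mut_genes:
            row[g] = int((a.mutations or {}).get(g, False))
        rows.append(row)
    pd.DataFrame(rows).to_csv(Path(path), sep=_sniff_sep(Path(path)), index=False,
                              float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def collapse_duplicate_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Average rows sharing a gene identifier into one row each.

    Row order follows the first occurrence of each identifier. Idempotent.
    """
    if not m.frame.index.duplicated().any():
        return m
    order = m.frame.index.drop_duplicates()
    collapsed = m.frame.groupby(level=0, sort=False).mean().loc[order]
    return ExpressionMatrix(collapsed, m.scale_tag)


def zscore_by_gene(m: ExpressionMatrix, ddof: int = 1) -> ExpressionMatrix:
    """Center and scale each gene to mean 0, SD 1 (divisor n-1).

    Raises ``ValueError`` listing the offending identifiers if any gene is
    constant across samples; callers should drop those first.
    """
    vals = m.values
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=ddof, keepdims=True)
    const = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    if const.any():
        genes = [m.gene_ids[i] for i in np.flatnonzero(const)]
        raise ValueError(f"constant genes cannot be z-scored: {genes[:10]}")
    z = (vals - mu) / sd
    return ExpressionMatrix(pd.DataFrame(z, index=m.frame.index, columns=m.frame.columns),
                            m.scale_tag)
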