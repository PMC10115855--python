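"""Synthetic cell-line panels and clinical cohorts with a planted sensitivity program.

The generator emulates the statistical structure the extraction pipeline
assumes: a latent per-sample sensitivity axis, a block of "program" genes
whose expression tracks that axis (high expression => low IC50, i.e. the
drug-sensitive state), equicorrelated background co-expression blocks that
are independent of drug response, disease-site mean shifts, and -- for the
clinical cohort -- treatment-dependent survival whose hazard depends on the
program score only in the treated arm.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DrugResponseTable, ExpressionMatrix, SampleAnnotation

__all__ = ["SyntheticConfig", "simulate_cellline_panel", "simulate_clinical_cohort"]

#: slope (SD units) linking the latent sensitivity axis to IC50
IC50_SLOPE = 2.0
#: baseline mean IC50 in log2(uM)
IC50_MEAN = 4.0
#: number of simulated mutation-call genes
N_MUTATION_GENES = 10
#: mutation gene whose prevalence rises with the latent score (positive control)
MUTATION_POSITIVE_CONTROL = "MUT01"


@dataclass
class SyntheticConfig:
    """Study conditions for the simulated panel and cohort."""

    n_lines: int = 250
    n_genes: int = 2000
    n_program_genes: int = 25
    program_effect: float = 2.0
    ic50_noise_sd: float = 0.5
    n_blocks: int = 10
    block_rho: float = 0.3
    n_clinical: int = 150
    n_sites: int = 6
    site_shift_sd: float = 0.5
    surv_baseline_hazard: float = 0.03
    surv_effect: float = 1.0
    censor_rate: float = 0.2
    mutation_rate: float = 0.2
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.n_program_genes < self.n_genes:
            raise ValueError("need 0 < n_program_genes < n_genes")
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must lie in [0,1)")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0,1)")
        if not 0 < self.mutation_rate < 1:
            raise ValueError("mutation_rate must lie in (0,1)")
        if self.surv_baseline_hazard <= 0:
            raise ValueError("surv_baseline_hazard must be positive")


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _expression(cfg: SyntheticConfig, latent: np.ndarray,
                rng: np.random.Generator) -> tuple[pd.DataFrame, list[str]]:
    """Draw a genes x samples matrix given the latent sensitivity per sample.

    Program genes: ``program_effect * latent + N(0,1)``. Background genes sit
    in ``n_blocks`` equicorrelated blocks (single shared factor per block,
    pairwise correlation ``block_rho``) independent of the latent axis.
    """
    n = latent.size
    genes = _gene_names(cfg.n_genes)
    program = sorted(rng.choice(cfg.n_genes, size=cfg.n_program_genes, replace=False))
    program_set = [genes[i] for i in program]

    x = np.empty((cfg.n_genes, n))
    is_prog = np.zeros(cfg.n_genes, dtype=bool)
    is_prog[program] = True

    x[is_prog] = cfg.program_effect * latent + rng.standard_normal((cfg.n_program_genes, n))

    bg_idx = np.flatnonzero(~is_prog)
    block_of = np.arange(bg_idx.size) % max(cfg.n_blocks, 1)
    factors = rng.standard_normal((max(cfg.n_blocks, 1), n))
    lam = np.sqrt(cfg.block_rho)
    noise = rng.standard_normal((bg_idx.size, n))
    x[bg_idx] = lam * factors[block_of] + np.sqrt(1 - cfg.block_rho) * noise

    # modest gene-specific baseline, keeps values loosely log2-expression-like
    x += 7.0 + rng.normal(0, 1.0, size=(cfg.n_genes, 1))
    return pd.DataFrame(x, index=genes), program_set


def _sites(cfg: SyntheticConfig, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    labels = rng.integers(0, cfg.n_sites, size=n)
    shifts = rng.normal(0, cfg.site_shift_sd, size=cfg.n_sites)
    return labels, shifts


def _mutations(n: int, latent: np.ndarray, cfg: SyntheticConfig,
               rng: np.random.Generator) -> list[dict[str, bool]]:
    """Bernoulli calls, independent of the latent score except one control gene."""
    names = [f"MUT{i:02d}" for i in range(1, N_MUTATION_GENES + 1)]
    calls = rng.random((N_MUTATION_GENES, n)) < cfg.mutation_rate
    p_ctrl = 1.0 / (1.0 + np.exp(-(1.5 * latent)))
    ctrl = rng.random(n) < p_ctrl
    calls[names.index(MUTATION_POSITIVE_CONTROL)] = ctrl
    return [dict(zip(names, calls[:, j].tolist())) for j in range(n)]


def simulate_cellline_panel(
    cfg: SyntheticConfig,
) -> tuple[ExpressionMatrix, DrugResponseTable, list[SampleAnnotation], set[str]]:
    """Simulate a drug-screened cell-line panel.

    Returns the expression matrix, the drug-response table, per-line
    annotations and the ground-truth program gene set. Higher latent
    sensitivity means higher program-gene expression and *lower* IC50.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_lines
    u = rng.standard_normal(n)
    ic50 = IC50_MEAN - IC50_SLOPE * u + rng.normal(0, cfg.ic50_noise_sd, size=n)

    frame, program = _expression(cfg, u, rng)
    site_labels, site_shifts = _sites(cfg, n, rng)
    frame = frame + site_shifts[site_labels][None, :]

    samples = [f"CL{i:04d}" for i in range(1, n + 1)]
    frame.columns = samples
    muts = _mutations(n, u, cfg, rng)
    anns = [
        SampleAnnotation(sample_id=s, disease_site=f"site{site_labels[j] + 1}",
                         mutations=muts[j])
        for j, s in enumerate(samples)
    ]
    expr = ExpressionMatrix(frame, scale_tag="other")
    resp = DrugResponseTable(pd.Series(ic50, index=samples, name="ic50_log2uM"))
    return expr, resp, anns, set(program)


def _program_score(frame: pd.DataFrame, program: list[str]) -> np.ndarray:
    sub = frame.loc[program].to_numpy()
    z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, ddof=1, keepdims=True)
    return np.median(z, axis=0)


def simulate_clinical_cohort(
    cfg: SyntheticConfig, truth: set[str]
) -> tuple[ExpressionMatrix, list[SampleAnnotation]]:
    """Simulate a clinical cohort sharing the panel's co-expression program.

    Program genes load on a cohort-level latent factor with the same
    loading, so they are mutually co-expressed; background blocks are
    preserved. Each patient gets a treated flag (Bernoulli 0.5); treated
    patients' event times are exponential with hazard
    ``surv_baseline_hazard * exp(-surv_effect * score)`` where ``score`` is
    the median z-scored program-gene expression, while untreated hazard is
    score-independent. Censoring is independent with rate ``censor_rate``.
    """
    if not truth:
        raise ValueError("empty program gene set")
    rng = np.random.default_rng(cfg.seed + 10_007)
    n = cfg.n_clinical
    v = rng.standard_normal(n)

    frame, _ = _expression_with_program(cfg, v, rng, truth)
    site_labels, site_shifts = _sites(cfg, n, rng)
    frame = frame + site_shifts[site_labels][None, :]
    samples = [f"PT{i:04d}" for i in range(1, n + 1)]
    frame.columns = samples

    program = sorted(truth)
    missing = set(program) - set(frame.index)
    if missing:
        raise ValueError(f"truth genes outside simulated universe: {sorted(missing)[:5]}")
    score = _program_score(frame, program)

    treated = rng.random(n) < 0.5
    hazard = np.where(
        treated,
        cfg.surv_baseline_hazard * np.exp(-cfg.surv_effect * score),
        cfg.surv_baseline_hazard,
    )
    event_time = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < cfg.censor_rate
    cens_time = rng.uniform(0, event_time)
    time = np.where(censored, cens_time, event_time)
    time = np.maximum(time, 1e-6)
    event = ~censored

    muts = _mutations(n, score, cfg, rng)
    anns = [
        SampleAnnotation(
            sample_id=s,
            disease_site=f"site{site_labels[j] + 1}",
            treated=bool(treated[j]),
            survival_time=float(time[j]),
            event=bool(event[j]),
            mutations=muts[j],
        )
        for j, s in enumerate(samples)
    ]
    return ExpressionMatrix(frame, scale_tag="other"), anns


def _expression_with_program(cfg: SyntheticConfig, latent: np.ndarray,
                             rng: np.random.Generator,
                             truth: set[str]) -> tuple[pd.DataFrame, list[str]]:
    """Like :func:`_expression` but plants the program on a *given* gene set."""
    n = latent.size
    genes = _gene_names(cfg.n_genes)
    idx = {g: i for i, g in enumerate(genes)}
    program = sorted(idx[g] for g in truth)
    is_prog = np.zeros(cfg.n_genes, dtype=bool)
    is_prog[program] = True

    x = np.empty((cfg.n_genes, n))
    x[is_prog] = cfg.program_effect * latent + rng.standard_normal((len(program), n))
    bg_idx = np.flatnonzero(~is_prog)
    block_of = np.arange(bg_idx.size) % max(cfg.n_blocks, 1)
    factors = rng.standard_normal((max(cfg.n_blocks, 1), n))
    x[bg_idx] = (np.sqrt(cfg.block_rho) * factors[block_of]
                 + np.sqrt(1 - cfg.block_rho) * rng.standard_normal((bg_idx.size, n)))
    x += 7.0 + rng.normal(0, 1.0, size=(cfg.n_genes, 1))
    return pd.DataFrame(x, index=genes), [genes[i] for i in program]


def write_truth(truth: set[str], cfg: SyntheticConfig, path: str | Path) -> None:
    """Emit the ground-truth program and the generating configuration as JSON."""
    with open(path, "w") as fh:
        json.dump({"program_genes": sorted(truth), "config": asdict(cfg)}, fh, indent=2)
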