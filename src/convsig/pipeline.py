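"""End-to-end consensus signature extraction.

Orchestrates: fold partition of the training panel, extreme-responder
selection within each fold's retained lines, the three differential
expression tests, per-fold seed genes, seed-gene co-expression connectivity
filtering on the clinical cohort, and the cross-fold consensus signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .coexpression import (
    ConnectivityResult,
    ConsensusSignature,
    binarize_affinity,
    compute_affinity_matrix,
    compute_connectivity_scores,
    consensus_signature,
    extract_connectivity_genes,
)
from .core import DrugResponseTable, ExpressionMatrix, PipelineConfig
from .diffexpr import (
    SeedGeneSet,
    derive_seed_genes,
    minp_test,
    moderated_t_test,
    sam_test,
    select_extreme_responders,
    split_folds,
)

__all__ = ["ExtractionResult", "extract_signature"]

log = logging.getLogger(__name__)


@dataclass
class ExtractionResult:
    signature: ConsensusSignature
    seed_sets: list[SeedGeneSet] = field(default_factory=list)
    connectivity: list[ConnectivityResult] = field(default_factory=list)
    config: PipelineConfig | None = None


def extract_signature(
    panel: ExpressionMatrix,
    resp: DrugResponseTable,
    clinical: ExpressionMatrix,
    config: PipelineConfig | None = None,
) -> ExtractionResult:
    """Run the full fold-wise extraction pipeline.

    ``panel``/``resp`` form the drug-screened training panel, ``clinical``
    the cohort used for the co-expression connectivity filter. Seeds are
    restricted to genes present in the clinical cohort before connectivity
    scoring.
    """
    cfg = config or PipelineConfig()
    samples = [s for s in resp.sample_ids if s in set(panel.sample_ids)]
    plan = split_folds(samples, cfg.n_folds, cfg.rng_seed)

    seed_sets: list[SeedGeneSet] = []
    connectivity: list[ConnectivityResult] = []
    clinical_genes = set(clinical.gene_ids)
    for fold in range(1, cfg.n_folds + 1):
        retained = plan.retained(fold)
        sub_resp = resp.subset(retained)
        sub_expr = panel.subset_samples(retained)
        sensitive, resistant = select_extreme_responders(sub_resp, cfg.extreme_fraction)

        results = [
            moderated_t_test(sub_expr, sensitive, resistant,
                             lfc_cutoff=cfg.lfc_cutoff, p_cutoff=cfg.fdr_cutoff),
            sam_test(sub_expr, sensitive, resistant, n_perm=cfg.n_perm_sam,
                     fdr_cutoff=cfg.fdr_cutoff, seed=cfg.rng_seed),
            minp_test(sub_expr, sensitive, resistant, n_boot=cfg.n_boot_minp,
                      adj_p_cutoff=cfg.fdr_cutoff, seed=cfg.rng_seed),
        ]
        seeds = derive_seed_genes(results, fold=fold)
        seed_sets.append(seeds)
        log.info("fold %d: %d seed genes %s", fold, len(seeds.genes),
                 seeds.per_method_counts)

        usable = seeds.genes & clinical_genes
        dropped = seeds.genes - usable
        if dropped:
            log.warning("fold %d: %d seed genes absent from clinical cohort",
                        fold, len(dropped))
        if not usable:
            connectivity.append(ConnectivityResult(
                connectivity_score=clinical.frame.iloc[:, 0] * 0.0))
            continue
        aff = compute_affinity_matrix(clinical, usable)
        aff = binarize_affinity(aff, cfg.affinity_top_fraction)
        conn = compute_connectivity_scores(aff)
        conn = extract_connectivity_genes(conn, usable, cfg.connectivity_top_fraction)
        connectivity.append(conn)
        log.info("fold %d: %d connectivity genes", fold, len(conn.connectivity_genes))

    signature = consensus_signature(connectivity, cfg.consensus_min_folds)
    return ExtractionResult(signature=signature, seed_sets=seed_sets,
                            connectivity=connectivity, config=cfg)
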