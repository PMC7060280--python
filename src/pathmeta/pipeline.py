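"""End-to-end orchestration: studies -> gene statistics -> ranked pathways.

The stages run in fixed order: per-study Hedges' g, random-effects REML
pooling with normal-tail effect p-values, per-study moderated tests,
additive cross-study combination, maxP fusion with BH-FDR gene selection,
then topology-aware pathway impact scoring with permutation nulls.  All
randomness flows from a single seed, so a rerun with identical inputs and
seed reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .combine import M_SWITCH, fuse_and_select
from .effect_size import StudyData, pool_studies, study_effects
from .impact import PathwayGraph, run_impact_analysis
from .testing import moderated_test

__all__ = ["RunConfig", "run_genes", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline settings; defaults follow the method's published cutoffs."""

    gene_fdr: float = 0.01
    pathway_fdr: float = 0.05
    n_perm: int = 2000
    seed: int = 0
    universe_mode: str = "pathway"

    def __post_init__(self) -> None:
        for name in ("gene_fdr", "pathway_fdr"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.seed is None:
            raise ValueError("a seed is required for the permutation stage")


def run_genes(studies: list[StudyData], config: RunConfig) -> pd.DataFrame:
    """Stages 1-7: effect pooling, moderated tests, fusion, gene selection."""
    if not studies:
        raise ValueError("need at least one study")
    shared = set(studies[0].gene_ids)
    for s in studies[1:]:
        shared &= set(s.gene_ids)
    if len(studies) > 1 and not shared:
        raise ValueError("no overlapping genes between studies")
    effect_tables = [study_effects(s) for s in studies]
    meta = pool_studies(effect_tables)
    logger.info("pooled %d genes over %d studies", len(meta), len(studies))
    tests = [moderated_test(s)[["bp_l", "bp_r"]] for s in studies]
    gene_stats = fuse_and_select(meta, tests, fdr_threshold=config.gene_fdr)
    logger.info(
        "selected %d impacted genes at FDR <= %g",
        int(gene_stats["selected"].sum()), config.gene_fdr,
    )
    return gene_stats


def run_pipeline(
    studies: list[StudyData],
    pathways: list[PathwayGraph],
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Full pipeline; returns (gene table, pathway table, run manifest)."""
    if not pathways:
        raise ValueError("pathway collection is empty")
    gene_stats = run_genes(studies, config)
    pathway_table = run_impact_analysis(
        pathways,
        gene_stats,
        n_perm=config.n_perm,
        seed=config.seed,
        pathway_fdr=config.pathway_fdr,
        universe_mode=config.universe_mode,
    )
    cfg = asdict(config)
    manifest = {
        "version": __version__,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()[:16],
        "m_switch": M_SWITCH,
        "n_studies": len(studies),
        "n_genes_pooled": int(len(gene_stats)),
        "n_genes_selected": int(gene_stats["selected"].sum()),
        "n_pathways": len(pathway_table),
        "n_pathways_untestable": int((~pathway_table["testable"]).sum()),
        "n_pathways_significant": int(pathway_table["significant"].sum()),
    }
    return gene_stats, pathway_table, manifest


def write_outputs(
    output_dir: str | Path,
    gene_stats: pd.DataFrame,
    pathway_table: pd.DataFrame | None,
    manifest: dict,
) -> None:
    from .io import write_table

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(gene_stats, out / "genes.tsv")
    if pathway_table is not None:
        write_table(pathway_table, out / "pathways.tsv", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
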