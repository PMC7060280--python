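"""Synthetic multi-study expression data and pathway collections.

The generator mirrors the pipeline's own generative assumptions so every
stage can be exercised with known ground truth.  For a differentially
expressed gene, each study draws its study-level true standardized effect
from N(mu_star, tau2_star) — the random-effects law the pooling stage
estimates — and expresses it as a case-group mean shift in noise-sd
units.  Every study additionally receives an additive batch shift applied
to all genes and (by default) both groups equally, perturbing the
expression scale between studies without changing any true standardized
difference; an optional group-confounded mode adds the shift to the case
group only, the failure mode that motivates random-effects pooling in the
first place.

Pathway collections consist of random signed directed decoy graphs over
random gene subsets plus one planted pathway whose nodes are drawn
largely from the true DE set with sign-coherent effects wired so that
activation edges propagate reinforcing perturbation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effect_size import CASE, CONTROL, StudyData
from .impact import PathwayGraph

__all__ = ["SimulationConfig", "simulate_studies", "simulate_pathways"]


@dataclass
class SimulationConfig:
    """Ground-truth configuration for the multi-study generator.

    Defaults describe a moderate five-study design: 2,000 genes of which
    100 are differentially expressed with a pooled standardized effect of
    1.0 and between-study variance 0.05, 20 samples per group per study,
    unit-variance log-scale noise, and per-study batch shifts with SD 0.5.
    Pathways default to 50 graphs of 15-40 nodes with edge density 0.08
    and a 30% repression fraction, one of them planted on the DE set.
    """

    n_genes: int = 2000
    n_studies: int = 5
    samples_per_group: int = 20
    de_fraction: float = 0.05
    effect_mu: float = 1.0
    tau2: float = 0.05
    batch_sd: float = 0.5
    noise_sd: float = 1.0
    confounded_batch: bool = False
    baseline_mean: float = 7.0
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (15, 40)
    edge_density: float = 0.08
    repression_fraction: float = 0.3
    planted_de_nodes: int = 15
    seed: int = 0
    de_genes: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_studies, self.samples_per_group) <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.tau2 < 0 or self.noise_sd <= 0 or self.batch_sd < 0:
            raise ValueError("invalid variance parameters")
        lo, hi = self.pathway_size_range
        if not 2 <= lo <= hi:
            raise ValueError("invalid pathway_size_range")


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def simulate_studies(
    config: SimulationConfig,
) -> tuple[list[StudyData], pd.DataFrame]:
    """Generate the study collection and its ground-truth table.

    Returns ``(studies, truth)`` where ``truth`` is indexed by gene with
    columns ``is_de`` (bool), ``mu_true`` (the planted pooled SMD, signed,
    0 for null genes).  DE genes get alternating signs so both tails are
    exercised.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    if config.de_genes is not None:
        de_set = list(config.de_genes)
        unknown = set(de_set) - set(genes)
        if unknown:
            raise ValueError(f"de_genes not in universe: {sorted(unknown)[:5]}")
    else:
        n_de = int(round(config.de_fraction * config.n_genes))
        de_set = list(rng.choice(genes, size=n_de, replace=False))
    signs = np.where(np.arange(len(de_set)) % 2 == 0, 1.0, -1.0)
    mu_true = pd.Series(0.0, index=genes)
    mu_true.loc[de_set] = signs * config.effect_mu
    truth = pd.DataFrame(
        {"is_de": mu_true != 0.0, "mu_true": mu_true}, index=pd.Index(genes, name="gene")
    )

    n = config.samples_per_group
    studies = []
    baseline = config.baseline_mean + rng.normal(0.0, 1.0, size=config.n_genes)
    for j in range(config.n_studies):
        # study-level true effects: N(mu*, tau2*) per DE gene, in SD units
        study_effect = np.zeros(config.n_genes)
        de_idx = truth.index.get_indexer(de_set)
        study_effect[de_idx] = rng.normal(
            mu_true.loc[de_set].to_numpy(), np.sqrt(config.tau2)
        )
        batch = rng.normal(0.0, config.batch_sd)
        ctrl = (
            baseline[:, None]
            + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n))
        )
        case = (
            baseline[:, None]
            + study_effect[:, None] * config.noise_sd
            + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n))
        )
        if config.confounded_batch:
            case = case + batch
        else:
            ctrl = ctrl + batch
            case = case + batch
        samples = [f"s{j}_{i:03d}" for i in range(2 * n)]
        matrix = pd.DataFrame(
            np.hstack([ctrl, case]), index=genes, columns=samples
        )
        groups = pd.Series(
            [CONTROL] * n + [CASE] * n, index=samples, name="group"
        )
        studies.append(StudyData(f"study{j}", matrix, groups))
    return studies, truth


def _random_signed_graph(
    pathway_id: str,
    name: str,
    nodes: list[str],
    edge_density: float,
    repression_fraction: float,
    rng: np.random.Generator,
) -> PathwayGraph:
    """Random signed directed graph over ``nodes`` at the given density."""
    k = len(nodes)
    edges = []
    mask = rng.random((k, k)) < edge_density
    np.fill_diagonal(mask, False)
    for i, j in zip(*np.nonzero(mask)):
        beta = -1.0 if rng.random() < repression_fraction else 1.0
        edges.append((nodes[i], nodes[j], beta))
    return PathwayGraph(pathway_id, name, nodes, edges)


def simulate_pathways(
    config: SimulationConfig,
    truth: pd.DataFrame,
) -> tuple[list[PathwayGraph], str]:
    """Generate decoy pathways plus one planted pathway.

    Decoys are random signed graphs over gene subsets drawn uniformly
    from the whole universe.  The planted pathway draws
    ``planted_de_nodes`` of its nodes from the up-regulated DE genes and
    wires a chain of activation edges through them (plus random
    background edges), so the coherent signature both over-represents on
    it and propagates reinforcing perturbation.  Returns the pathway list
    and the planted pathway's id.
    """
    rng = np.random.default_rng(None if config.seed is None else config.seed + 1)
    genes = list(truth.index)
    lo, hi = config.pathway_size_range
    pathways = []
    for i in range(config.n_pathways - 1):
        size = int(rng.integers(lo, hi + 1))
        nodes = list(rng.choice(genes, size=size, replace=False))
        pathways.append(
            _random_signed_graph(
                f"pw{i:03d}", f"decoy pathway {i}", nodes,
                config.edge_density, config.repression_fraction, rng,
            )
        )
    # planted pathway: sign-coherent DE core + random fillers
    up_genes = list(truth.index[truth["mu_true"] > 0])
    n_core = min(config.planted_de_nodes, len(up_genes))
    core = list(rng.choice(up_genes, size=n_core, replace=False)) if n_core else []
    size = max(int(rng.integers(lo, hi + 1)), n_core + 2)
    null_genes = list(truth.index[~truth["is_de"]])
    fillers = list(rng.choice(null_genes, size=size - n_core, replace=False))
    nodes = core + fillers
    # overlay an activation chain through the DE core so perturbation
    # accumulates coherently downstream; core nodes keep the chain as
    # their only out-edges so the coherent signal is not diluted across
    # random background targets.  Background edges are resampled if they
    # happen to close a singular feedback loop among the fillers: the
    # planted ground truth must be a testable pathway.
    chain = [(core[i], core[i + 1], 1.0) for i in range(n_core - 1)]
    core_set = set(core)
    for _ in range(50):
        base = _random_signed_graph(
            "pw_planted", "planted pathway", nodes,
            config.edge_density, config.repression_fraction, rng,
        )
        merged: dict[tuple[str, str], float] = {
            (u, g): b for u, g, b in base.edges if u not in core_set
        }
        for u, g, b in chain:
            merged[(u, g)] = b
        planted = PathwayGraph(
            "pw_planted", "planted pathway", nodes,
            [(u, g, b) for (u, g), b in merged.items()],
        )
        if planted.is_testable():
            break
    pathways.append(planted)
    return pathways, "pw_planted"
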