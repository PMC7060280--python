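"""Topology-aware pathway impact scoring.

A pathway is a signed directed gene graph: edges u -> g carry a weight
beta_ug (+1 activation, -1 repression).  The perturbation factor of a
gene is its own pooled expression change plus the out-degree-normalized,
signed perturbation flowing in from its upstream regulators:

    PF(g) = dE(g) + sum_{u in US_g} beta_ug * PF(u) / N_ds(u)

which in matrix form is PF = dE + B.PF with B[g, u] = beta_ug / N_ds(u),
solved exactly as PF = (I - B)^-1 dE (for acyclic graphs this equals
forward propagation in topological order; for cyclic graphs it is the
fixed point whenever I - B is well conditioned).  The pathway score is
the node sum of PF.

Two p-values are attached per pathway: an over-representation p (upper
hypergeometric tail of the impacted-gene count) and a perturbation p from
a permutation null in which the impacted genes' pooled effects are
re-assigned to random measurable pathway nodes; the two are combined by
Fisher's method.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PathwayGraph",
    "PathwayResult",
    "compute_pf",
    "pathway_total_pf",
    "p_de_hypergeometric",
    "p_pert_permutation",
    "fisher_combine",
    "run_impact_analysis",
]

logger = logging.getLogger(__name__)

#: condition number of (I - B) above which a pathway is untestable
COND_THRESHOLD = 1e12

_P_FLOOR = 1e-300


class PathwayGraph:
    """Signed directed gene graph for one pathway.

    Parallel (u, g) edges collapse by summing their signs, so a mixed
    activation/repression pair nets to zero weight.  ``n_ds`` counts a
    node's distinct downstream targets; ``upstream`` maps a node to its
    distinct regulators.
    """

    def __init__(self, pathway_id: str, name: str, nodes, edges) -> None:
        self.pathway_id = pathway_id
        self.name = name
        self.nodes = list(dict.fromkeys(nodes))
        node_set = set(self.nodes)
        collapsed: dict[tuple[str, str], float] = {}
        for u, g, beta in edges:
            if u not in node_set or g not in node_set:
                raise ValueError(
                    f"pathway {pathway_id!r}: edge endpoint not a node: ({u}, {g})"
                )
            collapsed[(u, g)] = collapsed.get((u, g), 0.0) + float(beta)
        self.edges = [(u, g, b) for (u, g), b in collapsed.items()]
        self.n_ds = {n: 0 for n in self.nodes}
        self.upstream: dict[str, list[tuple[str, float]]] = {n: [] for n in self.nodes}
        for u, g, b in self.edges:
            self.n_ds[u] += 1
            self.upstream[g].append((u, b))
        self._index = {n: i for i, n in enumerate(self.nodes)}

    def __len__(self) -> int:
        return len(self.nodes)

    def __repr__(self) -> str:
        return (
            f"PathwayGraph({self.pathway_id!r}, nodes={len(self.nodes)}, "
            f"edges={len(self.edges)})"
        )

    def propagation_matrix(self) -> np.ndarray:
        """B with B[g, u] = beta_ug / N_ds(u) over edges u -> g."""
        n = len(self.nodes)
        b = np.zeros((n, n))
        for u, g, beta in self.edges:
            b[self._index[g], self._index[u]] = beta / self.n_ds[u]
        return b

    def system_matrix(self) -> np.ndarray:
        return np.eye(len(self.nodes)) - self.propagation_matrix()

    def is_testable(self) -> bool:
        """False when I - B is numerically singular (pathway excluded)."""
        a = self.system_matrix()
        return bool(np.linalg.cond(a) <= COND_THRESHOLD)

    def accumulation_weights(self) -> np.ndarray:
        """w with w.dE = total PF, i.e. w = (I - B)^-T 1.

        The pathway total is linear in dE, so permutation nulls only need
        this weight vector, not a solve per permutation.
        """
        a = self.system_matrix()
        return np.linalg.solve(a.T, np.ones(len(self.nodes)))


@dataclass
class PathwayResult:
    pathway_id: str
    name: str
    pathway_size: int
    n_de_on_pathway: int
    pf_total: float
    p_de: float
    p_pert: float
    p_combined: float
    fdr: float = np.nan
    rank: int = 0
    testable: bool = True
    extras: dict = field(default_factory=dict)


def compute_pf(graph: PathwayGraph, delta_e: dict[str, float]) -> dict[str, float]:
    """Per-node perturbation factors: solve (I - B) PF = dE.

    ``delta_e`` must define a value for every node (0 for genes with no
    pooled change).  Raises ValueError for an untestable (numerically
    singular) pathway.
    """
    if len(graph) == 0:
        raise ValueError("empty pathway graph")
    missing = [n for n in graph.nodes if n not in delta_e]
    if missing:
        raise ValueError(f"delta_e missing for nodes {missing[:5]}")
    if not graph.is_testable():
        raise ValueError(
            f"pathway {graph.pathway_id!r} untestable: I - B numerically singular"
        )
    de = np.array([delta_e[n] for n in graph.nodes], float)
    pf = np.linalg.solve(graph.system_matrix(), de)
    return dict(zip(graph.nodes, pf))


def pathway_total_pf(pf: dict[str, float]) -> float:
    """Total pathway perturbation: sum of per-node factors."""
    return float(sum(pf.values()))


def p_de_hypergeometric(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail over-representation probability P(X >= k).

    X ~ Hypergeometric(N, K, n): ``k`` impacted genes observed on a
    pathway of size ``K`` when ``n`` of the ``N`` universe genes are
    impacted.
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def p_pert_permutation(
    graph: PathwayGraph,
    signature_mu: dict[str, float],
    universe,
    n_perm: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float, float]:
    """Permutation p-value for the pathway perturbation total.

    The observed total places each impacted gene's pooled effect on its
    own node (zero elsewhere).  Each permutation re-assigns the same
    multiset of effects to nodes drawn uniformly without replacement from
    the pathway's measurable nodes (nodes present in ``universe``),
    keeping the impacted-on-pathway count fixed.  The null is centered at
    its median and the two-sided tail uses the add-one rule, so the
    smallest attainable p is 1/(n_perm + 1).

    Returns ``(p_pert, observed_total, null_median)``; a pathway carrying
    no impacted gene returns ``(1.0, 0.0, 0.0)`` by convention.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(rng)
    universe = set(universe)
    measurable = [n for n in graph.nodes if n in universe]
    on_path = [n for n in graph.nodes if n in signature_mu]
    if not on_path or not measurable:
        return 1.0, 0.0, 0.0
    w = graph.accumulation_weights()
    idx = {n: i for i, n in enumerate(graph.nodes)}
    observed = float(sum(w[idx[n]] * signature_mu[n] for n in on_path))
    mus = np.array([signature_mu[n] for n in on_path], float)
    k = min(len(mus), len(measurable))
    w_meas = np.array([w[idx[n]] for n in measurable], float)
    # uniform k-subsets of the measurable nodes, vectorized over permutations
    u = rng.random((n_perm, len(measurable)))
    pick = np.argpartition(u, k - 1, axis=1)[:, :k]
    null = (w_meas[pick] * mus[:k]).sum(axis=1)
    med = float(np.median(null))
    exceed = int(np.sum(np.abs(null - med) >= abs(observed - med)))
    p = (exceed + 1) / (n_perm + 1)
    return float(p), observed, med


def fisher_combine(p_de: float, p_pert: float) -> float:
    """Fisher's combination of the two pathway p-values.

    X = -2(ln p_de + ln p_pert) ~ chi-square with 4 df under the joint
    null; zeros are nudged to a tiny positive value first.
    """
    a = max(float(p_de), _P_FLOOR)
    b = max(float(p_pert), _P_FLOOR)
    x = -2.0 * (math.log(a) + math.log(b))
    return float(stats.chi2.sf(x, df=4))


def run_impact_analysis(
    pathways: list[PathwayGraph],
    gene_stats: pd.DataFrame,
    n_perm: int = 2000,
    seed: int | None = None,
    pathway_fdr: float = 0.05,
    universe_mode: str = "pathway",
) -> pd.DataFrame:
    """Score and rank pathways against the impacted-gene signature.

    Parameters
    ----------
    pathways
        Signed directed pathway graphs sharing the gene-id namespace of
        ``gene_stats``.
    gene_stats
        Output of :func:`pathmeta.combine.fuse_and_select`: indexed by
        gene, with ``mu`` and the boolean ``selected`` signature.
    n_perm, seed
        Permutation count and seed for the perturbation null (one
        independent substream per pathway, so results do not depend on
        pathway order).
    universe_mode
        ``"pathway"`` restricts the over-representation universe to
        measured genes annotated to at least one pathway (default);
        ``"measured"`` uses all measured genes.

    Returns the ranked pathway table (ascending combined p, BH-FDR across
    pathways, significance call at ``pathway_fdr``).
    """
    if universe_mode not in ("pathway", "measured"):
        raise ValueError(f"unknown universe_mode {universe_mode!r}")
    measured = set(gene_stats.index)
    on_any_pathway = set()
    for g in pathways:
        on_any_pathway.update(g.nodes)
    if universe_mode == "pathway":
        universe = measured & on_any_pathway
    else:
        universe = measured
    selected = gene_stats.index[gene_stats["selected"].astype(bool)]
    signature_mu = gene_stats.loc[selected, "mu"].to_dict()
    if not signature_mu:
        logger.warning("empty gene signature: all perturbation p-values are 1")
    sig_in_universe = set(selected) & universe
    n_sig = len(sig_in_universe)
    n_universe = len(universe)

    def pathway_rng(pid: str) -> np.random.Generator:
        # seed derived from (run seed, pathway id) so the null stream for a
        # pathway does not depend on collection order
        digest = hashlib.sha256(pid.encode()).digest()
        entropy = [int(seed or 0), int.from_bytes(digest[:8], "little")]
        return np.random.default_rng(np.random.SeedSequence(entropy))

    rows = []
    for graph in pathways:
        measurable = [n for n in graph.nodes if n in universe]
        k_size = len(measurable)
        k_de = len(set(measurable) & sig_in_universe)
        if not graph.is_testable():
            logger.warning(
                "pathway %s (%s) untestable: singular propagation system; excluded",
                graph.pathway_id, graph.name,
            )
            rows.append(
                PathwayResult(graph.pathway_id, graph.name, k_size, k_de,
                              np.nan, np.nan, np.nan, np.nan, testable=False)
            )
            continue
        p_de = p_de_hypergeometric(k_de, k_size, n_sig, n_universe)
        if n_sig == 0 or k_de == 0:
            p_pert, obs, med = 1.0, 0.0, 0.0
        else:
            p_pert, obs, med = p_pert_permutation(
                graph, signature_mu, universe, n_perm=n_perm,
                rng=pathway_rng(graph.pathway_id),
            )
        rows.append(
            PathwayResult(
                graph.pathway_id, graph.name, k_size, k_de,
                obs if (n_sig and k_de) else 0.0,
                p_de, p_pert, fisher_combine(p_de, p_pert),
            )
        )
    df = pd.DataFrame(
        {
            "pathway_id": [r.pathway_id for r in rows],
            "name": [r.name for r in rows],
            "size": [r.pathway_size for r in rows],
            "n_de": [r.n_de_on_pathway for r in rows],
            "pf_total": [r.pf_total for r in rows],
            "p_de": [r.p_de for r in rows],
            "p_pert": [r.p_pert for r in rows],
            "p_combined": [r.p_combined for r in rows],
            "testable": [r.testable for r in rows],
        }
    )
    from .combine import bh_fdr  # local import avoids cycle at module load

    fdr = np.full(len(df), np.nan)
    ok = df["testable"].to_numpy() & np.isfinite(df["p_combined"].to_numpy(float))
    if ok.any():
        fdr[ok] = bh_fdr(df.loc[ok, "p_combined"].to_numpy(float))
    df["fdr"] = fdr
    df["significant"] = np.where(np.isfinite(fdr), fdr <= pathway_fdr, False)
    sort_key = df[["fdr", "p_combined", "pathway_id"]].copy()
    sort_key["fdr"] = sort_key["fdr"].fillna(np.inf)
    sort_key["p_combined"] = sort_key["p_combined"].fillna(np.inf)
    df = df.loc[sort_key.sort_values(["fdr", "p_combined", "pathway_id"]).index]
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)
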