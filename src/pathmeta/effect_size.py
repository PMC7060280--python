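"""Standardized-mean-difference estimation and random-effects pooling.

For each gene, each study contributes a Hedges' g (bias-corrected
standardized mean difference between condition and control) together with
its within-study sampling variance.  Across studies these estimates are
pooled under the random-effects model

    y_i = mu + tau_i + eps_i,     tau_i ~ N(0, tau2),  eps_i ~ N(0, v_i),

where ``mu`` is the central tendency of the effect size and ``tau2`` the
between-study variance absorbing batch effects and heterogeneity.
``(mu, tau2)`` are estimated by iterated REML; the pooled z-score
``z = mu / se`` yields left- and right-tailed effect-size p-values under
the standard normal law.

Direction convention, shared with :mod:`pathmeta.testing`: effects are
condition minus control, so positive g means up-regulation and the
right-tailed p-value is small for up-regulated genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StudyData",
    "EffectEstimate",
    "MetaEffect",
    "hedges_g",
    "study_effects",
    "reml_pool",
    "effect_pvalues",
    "pool_studies",
]

CASE = "case"
CONTROL = "control"


@dataclass
class StudyData:
    """One study: a genes x samples log-scale expression matrix plus groups.

    Parameters
    ----------
    study_id
        Text label for the study.
    matrix
        DataFrame indexed by unique gene identifiers, columns are sample
        identifiers, values are log-scale expression.
    groups
        Series mapping each sample (matrix column) to ``"case"`` or
        ``"control"``.
    """

    study_id: str
    matrix: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.matrix.index.has_duplicates:
            dupes = self.matrix.index[self.matrix.index.duplicated()].unique()
            raise ValueError(
                f"study {self.study_id!r}: duplicate gene ids {list(dupes)[:5]}"
            )
        missing = [s for s in self.matrix.columns if s not in self.groups.index]
        if missing:
            raise ValueError(
                f"study {self.study_id!r}: samples without group label: {missing[:5]}"
            )
        self.groups = self.groups.loc[self.matrix.columns]
        self.matrix.index.name = "gene"
        bad = set(self.groups.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(
                f"study {self.study_id!r}: unknown group labels {sorted(bad)}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.matrix.index

    def group_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (control, case) value arrays, genes x samples."""
        ctrl = self.matrix.loc[:, self.groups == CONTROL].to_numpy(float)
        case = self.matrix.loc[:, self.groups == CASE].to_numpy(float)
        return ctrl, case


@dataclass
class EffectEstimate:
    """Hedges' g and its within-study variance for one gene in one study."""

    g: float
    v: float
    n1: int
    n2: int

    @property
    def missing(self) -> bool:
        return not (math.isfinite(self.g) and math.isfinite(self.v) and self.v > 0)


@dataclass
class MetaEffect:
    """Pooled effect for one gene: REML estimates and normal-tail p-values."""

    mu: float
    se: float
    tau2: float
    n_studies: int
    converged: bool
    z: float = field(init=False)
    ep_l: float = field(init=False)
    ep_r: float = field(init=False)

    def __post_init__(self) -> None:
        self.z = self.mu / self.se
        self.ep_l, self.ep_r = effect_pvalues(self)


def hedges_g(a, b) -> EffectEstimate:
    """Hedges' g of condition ``b`` versus control ``a``.

    g = J * (mean(b) - mean(a)) / s_pooled with the small-sample correction
    J = 1 - 3 / (4*df - 1), df = n1 + n2 - 2, and large-sample variance
    v = (n1 + n2)/(n1*n2) + g^2 / (2*df).

    Groups with fewer than two samples, or zero pooled variance, yield a
    missing estimate (NaN fields) rather than an infinite one.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >= 2 samples per group, got {n1} and {n2}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite expression values")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if sp2 <= 0.0:
        return EffectEstimate(np.nan, np.nan, n1, n2)
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * (b.mean() - a.mean()) / math.sqrt(sp2)
    v = (n1 + n2) / (n1 * n2) + g * g / (2.0 * df)
    return EffectEstimate(g, v, n1, n2)


def study_effects(study: StudyData) -> pd.DataFrame:
    """Per-gene Hedges' g for one study.

    Returns a DataFrame indexed by gene with columns ``g, v, n1, n2``;
    genes with zero pooled variance carry NaN (missing), they are never
    silently dropped.
    """
    ctrl, case = study.group_matrices()
    n1, n2 = ctrl.shape[1], case.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"study {study.study_id!r}: need >= 2 samples per group, "
            f"got {n1} control / {n2} case"
        )
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * ctrl.var(axis=1, ddof=1) + (n2 - 1) * case.var(axis=1, ddof=1)) / df
    diff = case.mean(axis=1) - ctrl.mean(axis=1)
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(sp2 > 0, j * diff / np.sqrt(sp2), np.nan)
    v = np.where(sp2 > 0, (n1 + n2) / (n1 * n2) + g * g / (2.0 * df), np.nan)
    return pd.DataFrame(
        {"g": g, "v": v, "n1": n1, "n2": n2}, index=study.gene_ids
    )


def _reml_tau2(y: np.ndarray, v: np.ndarray, tol: float, max_iter: int):
    """REML fixed-point iteration for (mu, tau2).

    tau2 is initialized at the DerSimonian-Laird moment estimate (clamped
    at zero) and updated by the standard REML estimating equation

        tau2 <- sum(w^2 ((y - mu)^2 - v)) / sum(w^2) + 1 / sum(w)

    with w = 1 / (v + tau2), clamping at zero each step.  Returns
    (mu, tau2, converged).
    """
    m = y.size
    # DerSimonian-Laird start
    w0 = 1.0 / v
    mu_fe = np.sum(w0 * y) / np.sum(w0)
    q = np.sum(w0 * (y - mu_fe) ** 2)
    c = np.sum(w0) - np.sum(w0**2) / np.sum(w0)
    tau2 = max(0.0, (q - (m - 1)) / c) if c > 0 else 0.0
    mu = mu_fe
    converged = False
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        mu_new = np.sum(w * y) / np.sum(w)
        num = np.sum(w**2 * ((y - mu_new) ** 2 - v))
        tau2_new = max(0.0, num / np.sum(w**2) + 1.0 / np.sum(w))
        if max(abs(mu_new - mu), abs(tau2_new - tau2)) < tol:
            mu, tau2 = mu_new, tau2_new
            converged = True
            break
        mu, tau2 = mu_new, tau2_new
    return mu, tau2, converged


def reml_pool(
    estimates: list[EffectEstimate] | pd.DataFrame,
    tol: float = 1e-8,
    max_iter: int = 100,
    tau2_fixed: float | None = None,
) -> MetaEffect | None:
    """Pool per-study effect estimates under the random-effects model.

    Missing estimates are ignored.  With a single contributing study the
    between-study variance is unidentifiable and the result degenerates to
    ``mu = y, se = sqrt(v), tau2 = 0``.  Returns None when no study
    contributes a usable estimate.

    ``tau2_fixed`` pins the between-study variance instead of estimating
    it (0 gives the fixed-effects inverse-variance mean); internal, used
    for limit checks, not part of the pipeline.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if isinstance(estimates, pd.DataFrame):
        y = estimates["g"].to_numpy(float)
        v = estimates["v"].to_numpy(float)
    else:
        y = np.array([e.g for e in estimates], float)
        v = np.array([e.v for e in estimates], float)
    keep = np.isfinite(y) & np.isfinite(v) & (v > 0)
    y, v = y[keep], v[keep]
    m = y.size
    if m == 0:
        return None
    if m == 1:
        return MetaEffect(float(y[0]), math.sqrt(v[0]), 0.0, 1, True)
    if tau2_fixed is not None:
        w = 1.0 / (v + tau2_fixed)
        mu = float(np.sum(w * y) / np.sum(w))
        return MetaEffect(mu, math.sqrt(1.0 / np.sum(w)), tau2_fixed, m, True)
    mu, tau2, converged = _reml_tau2(y, v, tol, max_iter)
    se = math.sqrt(1.0 / np.sum(1.0 / (v + tau2)))
    return MetaEffect(float(mu), se, float(tau2), m, converged)


def effect_pvalues(meta: MetaEffect) -> tuple[float, float]:
    """Left- and right-tailed standard-normal p-values of the pooled z.

    ep_l = Phi(z) is small for down-regulated genes, ep_r = 1 - Phi(z) is
    small for up-regulated genes; the tails sum to one.
    """
    if meta.se <= 0:
        raise ValueError("standard error must be positive")
    ep_l = float(stats.norm.cdf(meta.z))
    return ep_l, 1.0 - ep_l


def pool_studies(
    effect_tables: list[pd.DataFrame],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Pool per-study effect tables (from :func:`study_effects`) over all genes.

    Genes are pooled over whichever studies measured them; genes measured
    in fewer than two studies fall back to the single-study rule and are
    annotated via ``n_studies``.  Returns a DataFrame indexed by gene with
    columns ``mu, se, tau2, z, ep_l, ep_r, n_studies, converged``.
    """
    all_genes = pd.Index([])
    for t in effect_tables:
        all_genes = all_genes.union(t.index)
    ys = np.full((len(all_genes), len(effect_tables)), np.nan)
    vs = np.full_like(ys, np.nan)
    for j, t in enumerate(effect_tables):
        idx = all_genes.get_indexer(t.index)
        ys[idx, j] = t["g"].to_numpy(float)
        vs[idx, j] = t["v"].to_numpy(float)
    rows = []
    for i, gene in enumerate(all_genes):
        y, v = ys[i], vs[i]
        keep = np.isfinite(y) & np.isfinite(v) & (v > 0)
        me = reml_pool(
            pd.DataFrame({"g": y[keep], "v": v[keep]}), tol=tol, max_iter=max_iter
        )
        if me is None:
            rows.append((gene, *([np.nan] * 6), 0, True))
        else:
            rows.append(
                (gene, me.mu, me.se, me.tau2, me.z, me.ep_l, me.ep_r,
                 me.n_studies, me.converged)
            )
    out = pd.DataFrame(
        rows,
        columns=["gene", "mu", "se", "tau2", "z", "ep_l", "ep_r",
                 "n_studies", "converged"],
    ).set_index("gene")
    return out
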