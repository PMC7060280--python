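"""Cross-study p-value combination and impacted-gene selection.

Two evidence streams arrive per gene: effect-size tail p-values from the
random-effects pooling (ep_l, ep_r) and, per study, one-tailed
empirical-Bayes p-values (bp_l, bp_r).  The per-study test p-values are
combined across studies with the additive method: the statistic is the
plain average of the m p-values, whose exact null law is the mean of m
iid Uniform(0,1) variables (a rescaled Irwin-Hall distribution); for many
studies the central limit theorem gives N(1/2, 1/(12m)).  Averaging makes
the combination robust to a single extreme p-value, unlike Fisher's
product rule.

The two streams are then fused conservatively with maxP per tail —
a gene counts as impacted only if it is significant from the hypothesis
testing perspective AND its pooled effect stands well clear of its
standard error — followed by a single Benjamini-Hochberg pass over the
two-sided summaries and a 1% FDR cutoff by default.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "irwin_hall_cdf",
    "addclt",
    "maxp",
    "bh_fdr",
    "fuse_and_select",
    "M_SWITCH",
]

#: study counts at or above this use the normal approximation to the
#: Irwin-Hall law; below it, the exact alternating-sum CDF.
M_SWITCH = 20

_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-16


def _ih_cdf_rational(s: float, m: int) -> float:
    """Alternating-sum CDF on the sum scale in exact rational arithmetic.

    The terms C(m,i)(s-i)^m grow to ~1e19 by m = 50 while the sum stays
    in [0, m!], so float64 cancellation destroys the result; integer
    fractions keep it exact at any m.
    """
    from fractions import Fraction

    sf = Fraction(s)
    total = Fraction(0)
    for i in range(min(int(math.floor(s)), m) + 1):
        total += (-1) ** i * math.comb(m, i) * (sf - i) ** m
    return float(total / math.factorial(m))


def irwin_hall_cdf(x, m: int):
    """Exact CDF of the mean of ``m`` iid Uniform(0,1) variables.

    ``x`` is the average (already divided by m) and is clamped to [0, 1].
    Evaluated on the sum scale s = m*x by the alternating closed form
    F(s) = (1/m!) * sum_{i<=floor(s)} (-1)^i C(m,i) (s-i)^m.  Accepts
    scalars or arrays.  Below ~20 summands the float path is accurate;
    above, each value is evaluated in exact rational arithmetic to avoid
    the catastrophic cancellation of the alternating sum.
    """
    if m <= 0:
        raise ValueError("m must be a positive integer")
    x = np.clip(np.asarray(x, float), 0.0, 1.0)
    scalar = x.ndim == 0
    s = np.atleast_1d(m * x)
    if m >= M_SWITCH:
        out = np.array([_ih_cdf_rational(float(si), m) for si in s.ravel()])
        out = out.reshape(s.shape)
    else:
        out = np.zeros_like(s)
        # alternating sum; term i contributes where s >= i
        for i in range(m + 1):
            mask = s >= i
            if not mask.any():
                break
            coef = ((-1.0) ** i) * math.comb(m, i) / math.factorial(m)
            term = np.zeros_like(s)
            term[mask] = coef * (s[mask] - i) ** m
            out += term
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out


def addclt(pvalues) -> float:
    """Combine p-values by their average (exact Irwin-Hall / CLT null).

    For fewer than ``M_SWITCH`` inputs the exact Irwin-Hall CDF of the
    average is used; at or above, the normal approximation
    N(1/2, 1/(12m)).  Inputs of exactly 0 or 1 are nudged inside (0, 1)
    before averaging to guard the CDF endpoints.  Returns a value in
    (0, 1].
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    p = np.clip(p, _P_FLOOR, _P_CEIL)
    m = p.size
    xbar = p.mean()
    if m < M_SWITCH:
        out = irwin_hall_cdf(xbar, m)
    else:
        out = stats.norm.cdf(xbar, loc=0.5, scale=math.sqrt(1.0 / (12.0 * m)))
    return float(min(max(out, _P_FLOOR), 1.0))


def addclt_rows(p: np.ndarray) -> np.ndarray:
    """Row-wise addclt over a genes x studies array with possible NaNs.

    Each gene is combined over its non-missing studies; a gene with no
    usable study yields NaN.
    """
    p = np.asarray(p, float)
    out = np.full(p.shape[0], np.nan)
    counts = np.isfinite(p).sum(axis=1)
    for m in np.unique(counts):
        if m == 0:
            continue
        rows = np.where(counts == m)[0]
        block = np.clip(p[rows], _P_FLOOR, _P_CEIL)
        xbar = np.nansum(block, axis=1) / m
        if m < M_SWITCH:
            vals = irwin_hall_cdf(xbar, int(m))
        else:
            vals = stats.norm.cdf(xbar, loc=0.5, scale=math.sqrt(1.0 / (12.0 * m)))
        out[rows] = np.clip(vals, _P_FLOOR, 1.0)
    return out


def maxp(a, b):
    """Conservative fusion of two p-values: their maximum.

    Significant only when both component tests are significant, which
    suppresses false positives driven by a single evidence stream.
    """
    return np.maximum(a, b)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p[np.isfinite(p)] < 0) or np.any(p[np.isfinite(p)] > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def fuse_and_select(
    meta_effects: pd.DataFrame,
    study_tests: list[pd.DataFrame],
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Fuse effect-size and test evidence, adjust, and select genes.

    Parameters
    ----------
    meta_effects
        Per-gene pooled effects from :func:`pathmeta.effect_size.pool_studies`
        (columns mu, se, tau2, z, ep_l, ep_r, ...).
    study_tests
        One moderated-test table per study (columns bp_l, bp_r), indexed
        by gene; gene universes may differ between studies but their union
        must equal the meta_effects universe.
    fdr_threshold
        Gene-level FDR cutoff for the impacted set (default 1%).

    Returns the per-gene statistics table with combined bp tails, maxP
    fusion p_l/p_r, the two-sided summary p = min(1, 2*min(p_l, p_r)),
    BH-adjusted fdr, and the boolean ``selected`` signature.
    """
    genes = meta_effects.index
    union = pd.Index([])
    for t in study_tests:
        union = union.union(t.index)
    extra = union.difference(genes)
    missing = genes.difference(union)
    if len(extra) or len(missing):
        raise ValueError(
            "gene universe mismatch between effect and test tables; "
            f"test-only: {list(extra[:5])}, effect-only: {list(missing[:5])}"
        )
    bpl = np.full((len(genes), len(study_tests)), np.nan)
    bpr = np.full_like(bpl, np.nan)
    for j, t in enumerate(study_tests):
        idx = genes.get_indexer(t.index)
        bpl[idx, j] = t["bp_l"].to_numpy(float)
        bpr[idx, j] = t["bp_r"].to_numpy(float)
    out = meta_effects.copy()
    out["bp_l"] = addclt_rows(bpl)
    out["bp_r"] = addclt_rows(bpr)
    out["p_l"] = maxp(out["ep_l"], out["bp_l"])
    out["p_r"] = maxp(out["ep_r"], out["bp_r"])
    out["p"] = np.minimum(1.0, 2.0 * np.minimum(out["p_l"], out["p_r"]))
    p_for_bh = out["p"].to_numpy(float).copy()
    ok = np.isfinite(p_for_bh)
    fdr = np.full(p_for_bh.shape, np.nan)
    if ok.any():
        fdr[ok] = bh_fdr(p_for_bh[ok])
    out["fdr"] = fdr
    out["selected"] = np.where(np.isfinite(fdr), fdr <= fdr_threshold, False)
    return out
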