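"""Pharmacodynamic association statistics.

Simple linear regressions of biomarkers on log10 2-HG, pooled-variance
two-group t-tests, the signed significance rank used to order genes,

    rank = −log10(unadjusted p) × sign(log2 FC),

a preranked gene-set enrichment analysis (weighted Kolmogorov–Smirnov running
sum with a gene-sampling permutation null), Benjamini–Hochberg FDR
adjustment, and the "top split" comparison that cuts a complete-linkage
sample dendrogram at the root into two groups and contrasts an external
variable between them.

The per-gene association is a declared simplification: a per-gene linear
model of log2 expression on the z-scored covariate, sufficient to drive the
rank/GSEA machinery.  It is not a negative-binomial count model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "RegressionResult",
    "GeneStats",
    "EnrichmentResult",
    "simple_linear_regression",
    "two_group_ttest",
    "rank_statistic",
    "per_gene_association",
    "bh_adjust",
    "preranked_gsea",
    "top_split_clusters",
    "DegenerateInputError",
]

# smallest positive normal double; p-values below are clamped before log10
P_FLOOR = np.finfo(float).tiny


class DegenerateInputError(ValueError):
    """Input carries no usable variation (constant x, identical samples, ...)."""


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    stderr: float
    pvalue: float
    r2: float


@dataclass(frozen=True)
class GeneStats:
    gene_id: str
    log2_fc: float      # log2-scale coefficient per z-unit of the covariate
    pvalue: float
    adj_pvalue: float
    rank_score: float


@dataclass(frozen=True)
class EnrichmentResult:
    name: str
    size: int
    es: float
    nes: float
    pvalue: float
    qvalue: float


def simple_linear_regression(x: Sequence[float], y: Sequence[float]
                             ) -> RegressionResult:
    """Ordinary least squares of y on x with the two-sided slope test.

    The p-value comes from the t reference with n−2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0.0:
        raise DegenerateInputError("x is constant")
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    syy = float(((y - y.mean()) ** 2).sum())
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    df = x.size - 2
    rss = syy - slope * sxy
    if syy == 0.0:  # constant y: flat fit, no evidence
        return RegressionResult(0.0, intercept, 0.0, 1.0, 0.0)
    stderr = math.sqrt(max(rss, 0.0) / df / sxx)
    if stderr == 0.0:
        pvalue = 0.0 if slope != 0.0 else 1.0
    else:
        t = slope / stderr
        pvalue = float(2.0 * stats.t.sf(abs(t), df))
    r2 = 1.0 - rss / syy
    return RegressionResult(slope, intercept, stderr, pvalue, min(max(r2, 0.0), 1.0))


def two_group_ttest(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Student's pooled-variance two-sample t-test, two sided.

    Degrees of freedom n_a + n_b − 2.  Zero pooled variance: p = 1 when the
    means agree, otherwise the evidence is unbounded and p → 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = a.size, b.size
    pooled = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    diff = float(a.mean() - b.mean())
    if pooled == 0.0:
        return (0.0, 1.0) if diff == 0.0 else (math.copysign(math.inf, diff), 0.0)
    t = diff / math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    p = float(2.0 * stats.t.sf(abs(t), na + nb - 2))
    return float(t), p


def rank_statistic(p: float, log2fc: float, floor: float = P_FLOOR) -> float:
    """Signed significance score: −log10(p) × sign(log2 FC); sign(0) = 0."""
    if p < 0.0 or p > 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if p == 0.0:
        warnings.warn(f"p = 0 clamped to floor {floor:g}", RuntimeWarning,
                      stacklevel=2)
        p = floor
    sign = 0.0 if log2fc == 0.0 else math.copysign(1.0, log2fc)
    return -math.log10(p) * sign


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def per_gene_association(matrix: np.ndarray, covariate: Sequence[float],
                         gene_ids: Sequence[str] | None = None
                         ) -> list[GeneStats]:
    """Per-gene linear association of log2 expression with the z-scored covariate.

    The covariate (log10 2-HG) is z-scored with the population (n) denominator.
    The per-gene coefficient is therefore log2 expression change per covariate
    s.d. — a fold-change-like quantity.  P-values are BH-adjusted across genes;
    zero-variance genes report p = 1 and coefficient 0.  The output is
    invariant under any joint permutation of samples and covariate.
    """
    matrix = np.asarray(matrix, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if matrix.shape[1] != x.size:
        raise ValueError("covariate length must equal the sample count")
    if gene_ids is None:
        gene_ids = [f"G{i + 1:05d}" for i in range(matrix.shape[0])]
    sd = x.std()  # population denominator
    if sd == 0.0:
        raise DegenerateInputError("covariate is constant")
    z = (x - x.mean()) / sd
    log2m = np.log2(matrix)

    n = z.size
    zc = z - z.mean()
    sxx = float((zc**2).sum())
    yc = log2m - log2m.mean(axis=1, keepdims=True)
    sxy = yc @ zc
    syy = (yc**2).sum(axis=1)
    slopes = sxy / sxx
    rss = np.maximum(syy - slopes * sxy, 0.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = slopes / np.sqrt(rss / df / sxx)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    zero_var = syy == 0.0
    slopes[zero_var] = 0.0
    pvals[zero_var] = 1.0
    pvals = np.nan_to_num(pvals, nan=0.0)  # rss==0 with slope!=0: perfect fit
    adj = bh_adjust(pvals)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return [
            GeneStats(gid, float(b), float(p), float(q),
                      rank_statistic(float(p), float(b)))
            for gid, b, p, q in zip(gene_ids, slopes, pvals, adj)
        ]


# ---------------------------------------------------------------------------
# Preranked GSEA

def _enrichment_score(order_scores: np.ndarray, member_mask: np.ndarray,
                      weight: float = 1.0) -> float:
    """Weighted KS running-sum enrichment score for one gene set.

    ``order_scores`` are the rank scores sorted descending; ``member_mask``
    marks set members in that order.  Hits advance by |score|^weight (share of
    the member total); misses advance by 1/(N − n_set).  The ES is the running
    sum's largest-magnitude excursion.
    """
    weights = np.abs(order_scores) ** weight
    hit_total = weights[member_mask].sum()
    n = order_scores.size
    n_set = int(member_mask.sum())
    if n_set == 0 or n_set == n:
        raise ValueError("gene set must be a proper nonempty subset")
    hit_step = np.where(member_mask, weights / hit_total, 0.0) if hit_total > 0 \
        else np.where(member_mask, 1.0 / n_set, 0.0)
    miss_step = np.where(member_mask, 0.0, 1.0 / (n - n_set))
    running = np.cumsum(hit_step - miss_step)
    return float(running[np.argmax(np.abs(running))])


def preranked_gsea(ranked: Sequence[GeneStats],
                   sets: Mapping[str, Sequence[str]],
                   n_perm: int = 1000,
                   min_size: int = 15,
                   max_size: int = 500,
                   seed: int = 0,
                   weight: float = 1.0) -> list[EnrichmentResult]:
    """Preranked gene-set enrichment with a gene-sampling permutation null.

    Genes are ordered by decreasing rank score; each retained set (size within
    [min_size, max_size] after intersecting with the ranked list) gets a
    weighted-KS ES.  The null re-draws ``n_perm`` random same-size gene sets
    (seeded).  NES divides the ES by the mean |null ES| of matching sign;
    the permutation p uses the matching-sign null with +1 continuity; q-values
    are BH across retained sets.  A positive NES means the set concentrates
    among genes positively associated with 2-HG (down with 2-HG suppression).
    """
    rng = np.random.default_rng(seed)
    ordered = sorted(ranked, key=lambda g: g.rank_score, reverse=True)
    scores = np.array([g.rank_score for g in ordered])
    if not np.all(np.isfinite(scores)):
        raise ValueError("rank scores must be finite")
    index = {g.gene_id: i for i, g in enumerate(ordered)}
    n = scores.size

    results = []
    names, pvals = [], []
    for name, genes in sets.items():
        idx = np.array(sorted({index[g] for g in genes if g in index}), dtype=int)
        if idx.size == 0:
            warnings.warn(f"gene set '{name}' has no overlap with the ranked list; "
                          "skipped", UserWarning, stacklevel=2)
            continue
        size = idx.size
        if not (min_size <= size <= max_size):
            continue
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        es = _enrichment_score(scores, mask, weight)

        null_es = np.empty(n_perm)
        for b in range(n_perm):
            perm_mask = np.zeros(n, dtype=bool)
            perm_mask[rng.choice(n, size=size, replace=False)] = True
            null_es[b] = _enrichment_score(scores, perm_mask, weight)
        same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
        denom = np.abs(same_sign).mean() if same_sign.size else np.abs(null_es).mean()
        nes = es / denom if denom > 0 else 0.0
        p = (np.sum(np.abs(same_sign) >= abs(es)) + 1.0) / (same_sign.size + 1.0)
        results.append((name, size, es, nes))
        names.append(name)
        pvals.append(p)

    qvals = bh_adjust(pvals) if pvals else np.array([])
    return [
        EnrichmentResult(name=name, size=size, es=es, nes=float(nes),
                         pvalue=float(p), qvalue=float(q))
        for (name, size, es, nes), p, q in zip(results, pvals, qvals)
    ]


def top_split_clusters(matrix: np.ndarray, external: Sequence[float],
                       sample_ids: Sequence[str] | None = None
                       ) -> tuple[np.ndarray, tuple[float, float]]:
    """Cut the complete-linkage sample dendrogram at the root into two groups.

    Rows (genes) are z-scored first, columns (samples) are clustered with
    Euclidean distance and complete linkage, and the two topmost column
    clusters are compared on ``external`` (e.g. log10 2-HG) with the
    pooled-variance t-test.  Returns (labels in {1, 2}, (t, p)).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    row_sd = matrix.std(axis=1, keepdims=True)
    if np.all(row_sd == 0):
        raise DegenerateInputError("all genes constant across samples")
    keep = row_sd[:, 0] > 0
    z = (matrix[keep] - matrix[keep].mean(axis=1, keepdims=True)) / row_sd[keep]
    cols = z.T
    if np.allclose(cols, cols[0]):
        raise DegenerateInputError("all samples identical after z-scoring")
    tree = linkage(cols, method="complete", metric="euclidean")
    labels = fcluster(tree, t=2, criterion="maxclust")
    ext = np.asarray(external, dtype=float)
    t, p = two_group_ttest(ext[labels == 1], ext[labels == 2])
    return labels, (t, p)
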