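"""PLS1 association between regional gene expression and an effect-size map.

The first partial-least-squares component (PLS1) is the linear combination
of gene expression profiles whose regional scores maximally covary with the
effect-size map.  With a single response variable the first PLS weight
vector has a closed form: it is the normalized cross-covariance X'y of the
z-scored predictor matrix with the z-scored response, which this module
uses directly instead of an iterative solver.

Inference has two layers:

* **Spatial significance** of the score-map correlation via spin-rotation
  permutation of the response map (one-sided on r, which is non-negative
  by the sign convention).
* **Per-gene significance** via bootstrap resampling of regions: the PLS
  weight of each gene divided by its bootstrap standard error gives a
  z-score, converted to a two-sided normal p-value and BH-FDR corrected.
  Genes with q below alpha split by the sign of z into the positively
  (PLS1+) and negatively (PLS1-) associated lists.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .geometry import NullEnsemble
from .maps import EffectSizeMap, RegionGeneMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PLSResult",
    "cohens_d_map",
    "zscore_columns",
    "pls1_fit",
    "pls_spin_significance",
    "bootstrap_gene_z",
    "fdr_bh",
    "split_signed_gene_lists",
    "intersect_gene_lists",
]


@dataclass
class PLSResult:
    """Container for a PLS1 fit and its inference layers.

    Fields are filled incrementally: :func:`pls1_fit` populates the point
    estimate, :func:`pls_spin_significance` the spin p-value, and
    :func:`bootstrap_gene_z` + :func:`split_signed_gene_lists` the
    per-gene statistics and signed lists.
    """

    gene: list[str]
    gene_weight: np.ndarray
    region_score: np.ndarray
    score_map_r: float
    var_explained: float
    x_var_explained: float | None = None
    p_spin: float | None = None
    boot_se: np.ndarray | None = None
    z: np.ndarray | None = None
    p: np.ndarray | None = None
    q: np.ndarray | None = None
    pls1_plus: list[str] = field(default_factory=list)
    pls1_minus: list[str] = field(default_factory=list)


def cohens_d_map(
    parcel_id: list[str],
    n1: np.ndarray,
    mean1: np.ndarray,
    sd1: np.ndarray,
    n2: np.ndarray,
    mean2: np.ndarray,
    sd2: np.ndarray,
    atlas: str = "unknown",
) -> EffectSizeMap:
    """Per-region Cohen's d from two groups' summary statistics.

    d = (mean1 - mean2) / s_pooled with the pooled standard deviation
    s_pooled = sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2)).
    """
    n1, n2 = np.asarray(n1, float), np.asarray(n2, float)
    mean1, mean2 = np.asarray(mean1, float), np.asarray(mean2, float)
    sd1, sd2 = np.asarray(sd1, float), np.asarray(sd2, float)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("both groups need n >= 2 in every region")
    pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    zero = pooled == 0
    if np.any(zero):
        offenders = [p for p, z_ in zip(parcel_id, zero) if z_]
        raise ValueError(f"pooled SD is zero in regions {offenders[:5]}")
    return EffectSizeMap(parcel_id=list(parcel_id), d=(mean1 - mean2) / pooled, atlas=atlas)


def zscore_columns(values: np.ndarray, drop_constant: bool = False):
    """Z-score columns; optionally drop zero-variance columns.

    Returns ``(z, keep_mask)`` where ``keep_mask`` flags retained columns.
    Uses population (ddof=0) standardization.
    """
    values = np.asarray(values, dtype=float)
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    keep = sd > 0
    if not drop_constant and not keep.all():
        raise ValueError("zero-variance column encountered")
    z = np.zeros_like(values)
    z[:, keep] = (values[:, keep] - mu[keep]) / sd[keep]
    return z[:, keep] if drop_constant else z, keep


def _pls1_weights(Xz: np.ndarray, yz: np.ndarray) -> np.ndarray:
    w = Xz.T @ yz
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("response is orthogonal to every gene column")
    return w / norm


def pls1_fit(X: RegionGeneMatrix, y: EffectSizeMap) -> PLSResult:
    """Fit the first PLS component of a single-response regression.

    Predictor columns and the response are z-scored; the weight vector is
    the normalized cross-covariance X'y.  The component is oriented so
    that its region scores correlate positively with the response
    (weights and scores negate together), hence ``score_map_r >= 0``.
    ``var_explained`` is the squared score-map correlation, i.e. the
    fraction of response variance captured by the PLS1 scores; the
    alternative predictor-variance share is reported as
    ``x_var_explained``.

    Raises
    ------
    ValueError
        If fewer than 3 shared regions remain or the response is
        orthogonal to all gene columns.
    """
    if X.parcel_id != y.parcel_id:
        raise ValueError("expression matrix and effect map parcel orders differ")
    if X.n_regions < 3:
        raise ValueError(f"need >= 3 regions, got {X.n_regions}")
    constant = np.ptp(X.values, axis=0) == 0
    genes = list(X.gene)
    vals = X.values
    if np.any(constant):
        dropped = [g for g, c in zip(genes, constant) if c]
        warnings.warn(
            f"dropping {len(dropped)} zero-variance gene column(s): {dropped[:5]}"
        )
        vals = vals[:, ~constant]
        genes = [g for g, c in zip(genes, constant) if not c]
    Xz, _ = zscore_columns(vals)
    yz, _ = zscore_columns(y.d[:, None])
    yz = yz[:, 0]
    w = _pls1_weights(Xz, yz)
    scores = Xz @ w
    r = float(np.corrcoef(scores, yz)[0, 1])
    if r < 0:
        w, scores, r = -w, -scores, -r
    # share of predictor variance carried by the component (loadings form)
    x_var = float(np.sum((Xz.T @ scores) ** 2) / (scores @ scores)) / Xz.shape[1]
    return PLSResult(
        gene=genes,
        gene_weight=w,
        region_score=scores,
        score_map_r=r,
        var_explained=r**2,
        x_var_explained=x_var,
    )


def pls_spin_significance(
    result: PLSResult,
    X: RegionGeneMatrix,
    y: EffectSizeMap,
    nulls: NullEnsemble,
) -> float:
    """Spin-permutation p-value for the PLS1 score-map correlation.

    The response map is spun, PLS1 is refitted against the fixed
    expression matrix, and the null score-map correlations are compared
    one-sided to the observed one (r is non-negative by convention).
    Updates ``result.p_spin`` in place and returns it.
    """
    if nulls.n_parcels != X.n_regions:
        raise ValueError("null ensemble does not match the expression matrix")
    genes_kept = [g in set(result.gene) for g in X.gene]
    Xz, _ = zscore_columns(X.values[:, np.asarray(genes_kept)])
    # With w = X'y/||X'y||, corr(Xw, y) is computable from K = XX' alone,
    # avoiding a per-permutation matrix product over genes.
    K = Xz @ Xz.T
    yz, _ = zscore_columns(y.d[:, None])
    yz = yz[:, 0]

    # Null score maps for all permutations in two matrix products; each
    # refit orients r >= 0, so |corr| is the null statistic.
    Y = yz[nulls.permutations.T]  # (n_regions, n_perm) spun responses
    Yc = Y - Y.mean(axis=0, keepdims=True)
    S = K @ Yc
    Sc = S - S.mean(axis=0, keepdims=True)
    denom = np.linalg.norm(Sc, axis=0) * np.linalg.norm(Yc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        null_r = np.abs(np.einsum("ij,ij->j", Sc, Yc) / denom)
    null_r = np.nan_to_num(null_r, nan=0.0)
    r_obs = result.score_map_r
    p = (1 + int(np.sum(null_r >= r_obs))) / (1 + nulls.n_perm)
    result.p_spin = float(p)
    return result.p_spin


def bootstrap_gene_z(
    result: PLSResult,
    X: RegionGeneMatrix,
    y: EffectSizeMap,
    n_boot: int = 5000,
    seed: int = 0,
    max_redraws: int = 10,
) -> PLSResult:
    """Bootstrap standard errors, z-scores and p-values for PLS1 weights.

    Regions are resampled with replacement; PLS1 is refitted on each
    replicate (including re-z-scoring within the replicate); replicate
    weight vectors are sign-aligned to the point estimate before the
    per-gene standard deviation is taken.  z = weight / SE, with a
    two-sided standard-normal p-value.

    Updates ``result.boot_se``, ``result.z`` and ``result.p`` in place.
    """
    if n_boot < 100:
        warnings.warn(
            f"n_boot={n_boot} is below 100; inference will be unstable "
            "(allowed for tests only)"
        )
    keep = [g in set(result.gene) for g in X.gene]
    vals = X.values[:, np.asarray(keep)]
    n = vals.shape[0]
    rng = np.random.default_rng(seed)
    w0 = result.gene_weight
    boots = np.empty((n_boot, vals.shape[1]))
    yv = y.d
    for b in range(n_boot):
        for attempt in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            Xb = vals[idx]
            yb = yv[idx]
            sd = Xb.std(axis=0)
            if np.std(yb) == 0:
                continue
            Xbz = np.zeros_like(Xb)
            ok = sd > 0
            Xbz[:, ok] = (Xb[:, ok] - Xb[:, ok].mean(axis=0)) / sd[ok]
            ybz = (yb - yb.mean()) / yb.std()
            wb = Xbz.T @ ybz
            norm = np.linalg.norm(wb)
            if norm > 0:
                wb /= norm
                break
        else:
            raise ValueError(
                f"bootstrap replicate {b} degenerate after {max_redraws} redraws"
            )
        if wb @ w0 < 0:
            wb = -wb
        boots[b] = wb
    se = boots.std(axis=0, ddof=1)
    zero_se = se == 0
    if np.any(zero_se):  # constant weight across replicates: infinite z
        logger.info("%d genes have zero bootstrap SE", int(zero_se.sum()))
    with np.errstate(divide="ignore"):
        z = np.where(zero_se, np.sign(w0) * np.inf, w0 / se)
    p = 2 * stats.norm.sf(np.abs(z))
    result.boot_se = se
    result.z = z
    result.p = p
    return result


def fdr_bh(p: np.ndarray, alpha: float = 0.05):
    """Benjamini-Hochberg step-up FDR: returns (q_values, reject_mask)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values are not allowed")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def split_signed_gene_lists(result: PLSResult, alpha: float = 0.05) -> PLSResult:
    """Split FDR-significant genes by the sign of their bootstrap z.

    PLS1+ collects q < alpha with z > 0, PLS1- collects q < alpha with
    z < 0; each list is sorted by \\|z\\| descending.  A significant gene
    with z exactly 0 (pathological) joins neither list.
    """
    if result.z is None or result.p is None:
        raise ValueError("run bootstrap_gene_z before splitting lists")
    q, _ = fdr_bh(result.p, alpha=alpha)
    result.q = q
    sig = q < alpha
    if np.any(sig & (result.z == 0)):
        warnings.warn("significant gene with z == 0 assigned to neither list")
    order = np.argsort(-np.abs(result.z), kind="stable")
    result.pls1_plus = [
        result.gene[i] for i in order if sig[i] and result.z[i] > 0
    ]
    result.pls1_minus = [
        result.gene[i] for i in order if sig[i] and result.z[i] < 0
    ]
    return result


def intersect_gene_lists(*lists: list[str]) -> list[str]:
    """Intersection of gene lists, preserving the first list's order."""
    if len(lists) < 2:
        raise ValueError("need at least two lists")
    common = set(lists[0])
    for other in lists[1:]:
        common &= set(other)
    return [g for g in lists[0] if g in common]
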