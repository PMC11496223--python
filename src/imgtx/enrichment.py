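"""Gene-list enrichment statistics: ORA, specificity (pSI), marker and
disease-overlap tests.

All tests operate against a declared gene *universe*: the set of genes
actually analyzed (by default the DS-retained set), which defines the
sampling frame of every null model here.  Four statistics are provided:

* **over-representation** (one-sided hypergeometric upper tail) for
  functional gene sets such as GO/KEGG terms;
* **specificity profiles** via a permutation specificity index pSI — a
  per-gene, per-condition p-value that is small when a gene's expression
  is specific to one tissue/cell-type/stage column;
* **marker-set tests** (two-sided Fisher, so depletion is also visible)
  for cell-type and cortical-layer marker panels;
* **disease-gene overlap** (two-sided Fisher on the 2x2 table).

BH-FDR correction is applied within each analysis family (across sets,
or across conditions), never across families.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pls import fdr_bh

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "SpecificityProfile",
    "OverlapTestResult",
    "overrepresentation_test",
    "compute_psi",
    "specificity_enrichment",
    "marker_enrichment",
    "disease_overlap_test",
]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the declared analysis universe.

    Set members need not be a subset of the universe on load; every
    statistic intersects each set with the universe first.
    """

    sets: dict[str, list[str]]
    universe: list[str]
    source: str = ""

    def __post_init__(self) -> None:
        if len(set(self.universe)) != len(self.universe):
            raise ValueError("universe contains duplicate symbols")

    def restricted(self, name: str) -> set[str]:
        return set(self.sets[name]) & set(self.universe)


@dataclass
class SpecificityProfile:
    """Per-gene, per-condition specificity-index p-values.

    ``psi.loc[g, c]`` is small when gene g's expression is specific to
    condition c; ``si_rank`` holds the observed mean fold-change ranks
    the p-values derive from (rank 1 = most specific).
    """

    psi: pd.DataFrame
    si_rank: pd.DataFrame
    n_perm: int
    seed: int


@dataclass
class OverlapTestResult:
    """2x2 overlap table with Fisher's exact statistics."""

    a: int  # in both lists
    b: int  # query only
    c: int  # disease only
    d: int  # neither
    odds_ratio: float
    p: float


def _clean_query(query: list[str], universe: list[str]) -> list[str]:
    uni = set(universe)
    dropped = [g for g in query if g not in uni]
    if dropped:
        warnings.warn(
            f"{len(dropped)} query gene(s) outside the universe dropped "
            f"(e.g. {dropped[:3]})"
        )
    seen = set()
    out = []
    for g in query:
        if g in uni and g not in seen:
            seen.add(g)
            out.append(g)
    return out


def _enrichment_frame(rows: list[dict], alpha: float) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    q, _ = fdr_bh(df["p"].to_numpy(), alpha=alpha)
    df["q"] = q
    return df.sort_values("p", kind="stable").reset_index(drop=True)


def overrepresentation_test(
    query: list[str],
    sets: GeneSetCollection,
    alpha: float = 0.05,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list in each gene set.

    p = P(overlap >= observed) drawing |query| genes without replacement
    from the universe, of which |set ∩ universe| are marked.  With
    ``two_sided=True`` a two-sided Fisher exact test is used instead.
    Returns one row per set with overlap counts, expected overlap, odds
    ratio, p and BH q (across sets), sorted by p.
    """
    if not sets.universe:
        raise ValueError("empty universe")
    query = _clean_query(query, sets.universe)
    if not query:
        raise ValueError("empty query after universe restriction")
    N = len(sets.universe)
    n = len(query)
    qset = set(query)
    rows = []
    for name in sets.sets:
        members = sets.restricted(name)
        K = len(members)
        k = len(qset & members)
        if two_sided:
            table = [[k, n - k], [K - k, N - K - (n - k)]]
            odds, p = stats.fisher_exact(table, alternative="two-sided")
        else:
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            b_, c_, d_ = n - k, K - k, N - K - (n - k)
            odds = math.inf if (b_ * c_ == 0 and k * d_ > 0) else (
                (k * d_) / (b_ * c_) if b_ * c_ else np.nan
            )
        rows.append(
            {
                "set": name,
                "overlap_count": k,
                "set_size_in_universe": K,
                "query_size": n,
                "expected_overlap": n * K / N,
                "odds_ratio": odds,
                "p": p,
            }
        )
    return _enrichment_frame(rows, alpha)


def _fold_change_ranks(expr: np.ndarray, eps: float) -> np.ndarray:
    """Competition rank (1 + # strictly greater) of each gene's fold change.

    Returns ``ranks[g, c, c2]``: rank of gene g's fold change
    ``expr[g, c] / expr[g, c2]`` among all genes, for every ordered
    condition pair; the diagonal c == c2 is undefined (0).
    """
    n_genes, n_cond = expr.shape
    ranks = np.zeros((n_genes, n_cond, n_cond))
    for c in range(n_cond):
        for c2 in range(n_cond):
            if c == c2:
                continue
            fc = (expr[:, c] + eps) / (expr[:, c2] + eps)
            # competition ("min") rank: ties share the best position
            ranks[:, c, c2] = stats.rankdata(-fc, method="min")
    return ranks


def compute_psi(
    expr: pd.DataFrame,
    n_perm: int = 5000,
    seed: int = 0,
    eps: float = 1e-9,
) -> SpecificityProfile:
    """Permutation specificity index for a genes x conditions matrix.

    The observed statistic for gene g in condition c is the mean, over
    the other conditions c', of the rank of the fold change
    expr(g, c) / expr(g, c') among all genes (rank 1 = largest fold
    change, i.e. most specific).  The null distribution is built by
    applying a random permutation of the condition labels to the whole
    matrix and pooling the resulting statistics across genes; pSI(g, c)
    is the add-one-corrected fraction of pooled null statistics at or
    below the observed one.  Zero expression values are handled with a
    pseudo-count.

    Notes
    -----
    This is a reimplementation of the specificity-index construction in
    the permutation form above, not a byte-match of any web tool.
    """
    conds = list(expr.columns)
    genes = list(expr.index)
    n_cond = len(conds)
    if n_cond < 2:
        raise ValueError("need at least 2 conditions")
    vals = expr.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("expression must be non-negative")
    if np.any(vals == 0):
        logger.info("zero expression values: pseudo-count %g applied", eps)
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} below 100: pSI resolution will be poor")
    ranks = _fold_change_ranks(vals, eps)
    off = ~np.eye(n_cond, dtype=bool)
    # observed mean rank per (gene, condition)
    obs = np.stack(
        [ranks[:, c, off[c]].mean(axis=1) for c in range(n_cond)], axis=1
    )
    rng = np.random.default_rng(seed)
    # Under a shared relabeling pi of the columns, the statistic for
    # condition c is the observed statistic at source column pi(c), so
    # nulls are index gymnastics over the precomputed rank tensor.
    null_pool: list[np.ndarray] = []
    for _ in range(n_perm):
        pi = rng.permutation(n_cond)
        null_pool.append(obs[:, pi])
    null = np.stack(null_pool)  # (n_perm, n_genes, n_cond)
    psi = np.empty((len(genes), n_cond))
    for c in range(n_cond):
        pooled = np.sort(null[:, :, c].ravel())
        counts = np.searchsorted(pooled, obs[:, c], side="right")
        psi[:, c] = (1 + counts) / (1 + pooled.size)
    return SpecificityProfile(
        psi=pd.DataFrame(psi, index=genes, columns=conds),
        si_rank=pd.DataFrame(obs, index=genes, columns=conds),
        n_perm=n_perm,
        seed=seed,
    )


def specificity_enrichment(
    query: list[str],
    profile: SpecificityProfile,
    universe: list[str],
    psi_threshold: float = 0.05,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher enrichment of a query in each condition's specificity set.

    The specificity set of condition c is {g : pSI(g, c) < threshold};
    each is tested two-sided against the query within the universe, with
    BH correction across conditions.  An empty specificity set records
    p = 1 rather than erroring.
    """
    query = _clean_query(query, universe)
    qset = set(query)
    uni = set(universe)
    rows = []
    for cond in profile.psi.columns:
        spec = {
            g
            for g in profile.psi.index
            if g in uni and profile.psi.loc[g, cond] < psi_threshold
        }
        k = len(qset & spec)
        K = len(spec)
        n = len(qset)
        N = len(uni)
        if K == 0:
            odds, p = np.nan, 1.0
        else:
            table = [[k, n - k], [K - k, N - K - (n - k)]]
            odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "set": cond,
                "overlap_count": k,
                "set_size_in_universe": K,
                "query_size": n,
                "expected_overlap": n * K / N,
                "odds_ratio": odds,
                "p": p,
            }
        )
    return _enrichment_frame(rows, alpha)


def marker_enrichment(
    query: list[str],
    marker_sets: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Fisher tests of a query against marker gene panels.

    Identical bookkeeping to :func:`overrepresentation_test` but two-sided,
    so marker *depletion* (odds ratio < 1) is detectable; BH across sets.
    """
    return overrepresentation_test(query, marker_sets, alpha=alpha, two_sided=True)


def disease_overlap_test(
    query: list[str], disease_genes: list[str], universe: list[str]
) -> OverlapTestResult:
    """Fisher's exact test of overlap between a query and a disease list."""
    uni = set(universe)
    outside = (set(query) | set(disease_genes)) - uni
    if outside:
        logger.info(
            "%d gene(s) outside the universe dropped before overlap test",
            len(outside),
        )
        query = [g for g in query if g in uni]
        disease_genes = [g for g in disease_genes if g in uni]
    qset, dset = set(query), set(disease_genes)
    a = len(qset & dset)
    b = len(qset - dset)
    c = len(dset - qset)
    d = len(uni) - a - b - c
    if d < 0:
        raise ValueError("universe smaller than the union of the two lists")
    odds = math.inf if (b * c == 0 and a * d > 0) else (
        (a * d) / (b * c) if b * c else np.nan
    )
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return OverlapTestResult(a=a, b=b, c=c, d=d, odds_ratio=odds, p=float(p))
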