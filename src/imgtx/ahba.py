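"""Donor microarray processing into a region x gene expression matrix.

Implements the standard multi-donor microarray workflow for building a
parcellated expression matrix:

1. drop probes below background intensity in over half of all samples
   (pooled across donors);
2. keep, per gene, the probe most correlated (Spearman) with an RNA-seq
   reference;
3. assign tissue samples to the nearest parcel centroid within a
   Euclidean distance cutoff (default 2 mm);
4. normalize each gene within donor with a scaled robust sigmoid (SRS),
   rescaled to [0, 1];
5. average samples within parcels per donor, then average donors;
6. filter genes by differential stability (DS), the mean inter-donor
   Spearman correlation of a gene's regional profile.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr

from .geometry import ParcellationGeometry
from .maps import RegionGeneMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DonorExpression",
    "DifferentialStabilityResult",
    "filter_probes_by_noise",
    "select_probe_per_gene",
    "assign_samples_to_parcels",
    "srs_normalize",
    "aggregate_to_regions",
    "differential_stability",
]


@dataclass
class DonorExpression:
    """One donor's microarray data in the parcellation's coordinate space.

    ``intensity`` and ``above_background`` are samples x probes (rows
    aligned with ``sample_xyz``, columns with ``probe_gene.index``).
    ``rnaseq_ref`` is an optional genes x samples reference used for
    probe selection; its columns must be a subset of this donor's
    samples.  Probes without a gene annotation are dropped on load.
    """

    donor_id: str
    sample_xyz: np.ndarray
    intensity: pd.DataFrame
    above_background: pd.DataFrame
    probe_gene: pd.Series
    rnaseq_ref: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.sample_xyz = np.asarray(self.sample_xyz, dtype=float)
        if self.intensity.shape != self.above_background.shape:
            raise ValueError("intensity and above_background shapes differ")
        if self.sample_xyz.shape != (self.intensity.shape[0], 3):
            raise ValueError("sample_xyz must be (n_samples, 3)")
        unannotated = [
            p for p in self.intensity.columns if p not in self.probe_gene.index
        ]
        if unannotated:
            logger.info(
                "donor %s: dropping %d unannotated probe(s)",
                self.donor_id,
                len(unannotated),
            )
            keep = [p for p in self.intensity.columns if p in self.probe_gene.index]
            self.intensity = self.intensity[keep]
            self.above_background = self.above_background[keep]

    @property
    def probes(self) -> list[str]:
        return list(self.intensity.columns)

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[0]


@dataclass
class DifferentialStabilityResult:
    """Per-gene DS scores plus the retained top fraction."""

    ds: pd.Series
    retained_fraction: float
    retained_genes: list[str]


def filter_probes_by_noise(
    donors: list[DonorExpression], min_above_fraction: float = 0.5
) -> list[str]:
    """Retain probes above background intensity in at least half the samples.

    Samples are pooled across all donors; a probe is filtered out iff it
    falls below background in strictly more than half of the pooled
    samples, i.e. retained iff its above-background fraction is
    >= ``min_above_fraction``.  Order of the first donor's probes is kept.
    """
    if not donors:
        raise ValueError("need at least one donor")
    if not 0 < min_above_fraction <= 1:
        raise ValueError("min_above_fraction must be in (0, 1]")
    probes = donors[0].probes
    probe_set = set(probes)
    for d in donors[1:]:
        if set(d.probes) != probe_set:
            offenders = sorted(probe_set.symmetric_difference(d.probes))
            raise ValueError(
                f"probe sets differ between donors (e.g. {offenders[:5]})"
            )
    above = np.concatenate(
        [d.above_background[probes].to_numpy(dtype=bool) for d in donors], axis=0
    )
    frac = above.mean(axis=0)
    retained = [p for p, f in zip(probes, frac) if f >= min_above_fraction]
    logger.info(
        "probe noise filter: retained %d / %d probes", len(retained), len(probes)
    )
    return retained


def select_probe_per_gene(
    donors: list[DonorExpression],
    retained_probes: list[str],
    fallback_mean_intensity: bool = False,
) -> dict[str, str]:
    """Choose one probe per gene, maximizing Spearman r with RNA-seq.

    Intensities are pooled across the donors that carry an RNA-seq
    reference, on samples matched by position in each donor's reference.
    Genes with a single retained probe take it without computing any
    correlation; exact ties break to the lexicographically smallest probe
    id.  With ``fallback_mean_intensity`` (for data without a reference)
    the probe with the highest mean pooled intensity is taken instead.
    """
    probe_gene = donors[0].probe_gene
    genes: dict[str, list[str]] = {}
    for p in retained_probes:
        genes.setdefault(probe_gene[p], []).append(p)
    n_dropped = len(set(probe_gene.values)) - len(genes)
    if n_dropped:
        logger.info("%d gene(s) lost all probes to filtering", n_dropped)

    ref_donors = [d for d in donors if d.rnaseq_ref is not None]
    if not ref_donors and not fallback_mean_intensity:
        raise ValueError(
            "no donor carries an RNA-seq reference; pass "
            "fallback_mean_intensity=True to select by mean intensity"
        )

    chosen: dict[str, str] = {}
    for gene, ps in sorted(genes.items()):
        ps = sorted(ps)
        if len(ps) == 1:
            chosen[gene] = ps[0]
            continue
        if fallback_mean_intensity or not ref_donors:
            pooled = np.concatenate(
                [d.intensity[ps].to_numpy() for d in donors], axis=0
            )
            means = pooled.mean(axis=0)
            chosen[gene] = ps[int(np.argmax(means))]  # argmax: lowest on tie
            continue
        best_p, best_r = None, -np.inf
        for p in ps:
            xs, ys = [], []
            for d in ref_donors:
                if gene not in d.rnaseq_ref.index:
                    continue
                cols = list(d.rnaseq_ref.columns)
                xs.append(d.intensity.loc[cols, p].to_numpy())
                ys.append(d.rnaseq_ref.loc[gene, cols].to_numpy(dtype=float))
            if not xs:
                continue
            r = spearmanr(np.concatenate(xs), np.concatenate(ys)).statistic
            if np.isnan(r):
                r = -np.inf
            if r > best_r:  # strict: ties keep the earlier (smaller) probe id
                best_p, best_r = p, r
        if best_p is None:  # gene absent from every reference
            pooled = np.concatenate(
                [d.intensity[ps].to_numpy() for d in donors], axis=0
            )
            best_p = ps[int(np.argmax(pooled.mean(axis=0)))]
        chosen[gene] = best_p
    return chosen


def assign_samples_to_parcels(
    donor: DonorExpression,
    geometry: ParcellationGeometry,
    max_dist_mm: float = 2.0,
) -> np.ndarray:
    """Map each sample to its nearest parcel centroid within a cutoff.

    Distances are Euclidean in mm against the raw (pre-projection)
    surface coordinates.  Samples farther than ``max_dist_mm`` from every
    centroid are unassigned (-1).  Equidistant ties break to the lowest
    parcel index.
    """
    xyz = donor.sample_xyz
    if not np.all(np.isfinite(xyz)):
        bad = int(np.flatnonzero(~np.isfinite(xyz).all(axis=1))[0])
        raise ValueError(
            f"donor {donor.donor_id}: non-finite coordinates for sample index {bad}"
        )
    dist = cdist(xyz, geometry.surface_xyz)
    nearest = np.argmin(dist, axis=1)  # first minimum: lowest parcel index
    mind = dist[np.arange(len(nearest)), nearest]
    assignment = np.where(mind <= max_dist_mm, nearest, -1)
    logger.info(
        "donor %s: %d / %d samples assigned within %.1f mm",
        donor.donor_id,
        int((assignment >= 0).sum()),
        len(assignment),
        max_dist_mm,
    )
    return assignment


def srs_normalize(values: np.ndarray) -> np.ndarray:
    """Scaled robust sigmoid, rescaled to [0, 1].

    y = 1 / (1 + exp(-(x - median) / (IQR / 1.35))), then min-max scaled.
    The IQR/1.35 factor makes the scale comparable to a standard
    deviation for Gaussian data.  A zero IQR (degenerate gene) maps every
    value to 0.5 with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    med = np.median(x)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr == 0:
        warnings.warn("zero IQR: degenerate gene normalized to 0.5")
        return np.full_like(x, 0.5)
    y = 1.0 / (1.0 + np.exp(-(x - med) / (iqr / 1.35)))
    return (y - y.min()) / (y.max() - y.min())


def aggregate_to_regions(
    donors: list[DonorExpression],
    probe_map: dict[str, str],
    sample_assignments: dict[str, np.ndarray],
    geometry: ParcellationGeometry,
) -> tuple[list[RegionGeneMatrix], RegionGeneMatrix]:
    """Collapse donor samples into per-donor and pooled region x gene matrices.

    Within each donor, the selected probe's intensities are SRS-normalized
    per gene across that donor's *assigned* samples, then averaged within
    each parcel.  The pooled matrix is the mean across donors with
    coverage of the parcel; parcels no donor covers are NaN rows with
    ``n_donors_per_region == 0`` (flag, not fatal).

    Returns ``(per_donor_matrices, pooled_matrix)``.
    """
    genes = sorted(probe_map)
    n_parcels = geometry.n_parcels
    per_donor: list[RegionGeneMatrix] = []
    for donor in donors:
        assign = sample_assignments[donor.donor_id]
        assigned = assign >= 0
        mat = np.full((n_parcels, len(genes)), np.nan)
        if assigned.sum() >= 2:
            sub = donor.intensity.iloc[np.flatnonzero(assigned)]
            labels = assign[assigned]
            for j, g in enumerate(genes):
                norm = srs_normalize(sub[probe_map[g]].to_numpy())
                for parcel in np.unique(labels):
                    mat[parcel, j] = norm[labels == parcel].mean()
        coverage = np.isfinite(mat).all(axis=1).astype(int)
        per_donor.append(
            RegionGeneMatrix(
                parcel_id=list(geometry.parcel_id),
                gene=genes,
                values=mat,
                n_donors_per_region=coverage,
                normalization="srs01",
            )
        )
    stacked = np.stack([m.values for m in per_donor])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN parcels
        pooled_vals = np.nanmean(stacked, axis=0)
    n_donors_per_region = np.isfinite(stacked).all(axis=2).sum(axis=0)
    uncovered = int((n_donors_per_region == 0).sum())
    if uncovered:
        logger.info("%d parcel(s) have no donor coverage", uncovered)
    pooled = RegionGeneMatrix(
        parcel_id=list(geometry.parcel_id),
        gene=genes,
        values=pooled_vals,
        n_donors_per_region=n_donors_per_region,
        normalization="srs01",
    )
    return per_donor, pooled


def differential_stability(
    per_donor: list[RegionGeneMatrix],
    retained_fraction: float = 0.5,
    method: str = "spearman",
) -> DifferentialStabilityResult:
    """Differential stability: mean pairwise inter-donor profile correlation.

    DS(g) averages, over all donor pairs, the correlation (Spearman by
    default, Pearson via ``method="pearson"``) of gene g's regional
    profile across the parcels both donors cover.  Pairs sharing fewer
    than 2 parcels are skipped with a warning; a gene with no valid pair
    gets DS = NaN and is never retained.  The top ``retained_fraction``
    of genes by DS are kept, with all genes tied at the cutoff retained.
    """
    if len(per_donor) < 2:
        raise ValueError("differential stability needs >= 2 donors")
    genes = per_donor[0].gene
    for m in per_donor[1:]:
        if m.gene != genes or m.parcel_id != per_donor[0].parcel_id:
            raise ValueError("donor matrices must share gene and parcel order")
    if not 0 < retained_fraction <= 1:
        raise ValueError("retained_fraction must be in (0, 1]")
    n_genes = len(genes)
    sums = np.zeros(n_genes)
    counts = np.zeros(n_genes, dtype=int)
    for i in range(len(per_donor)):
        for j in range(i + 1, len(per_donor)):
            a, b = per_donor[i].values, per_donor[j].values
            shared = np.isfinite(a).all(axis=1) & np.isfinite(b).all(axis=1)
            if shared.sum() < 2:
                warnings.warn(
                    f"donor pair ({i}, {j}) shares fewer than 2 regions; skipped"
                )
                continue
            if method == "spearman":
                if n_genes == 1:
                    pair = np.array(
                        [spearmanr(a[shared, 0], b[shared, 0]).statistic]
                    )
                else:
                    r = spearmanr(a[shared], b[shared]).statistic
                    # spearmanr on 2D stacks returns the full correlation matrix
                    pair = np.diag(np.asarray(r)[:n_genes, n_genes:])
            elif method == "pearson":
                az = a[shared] - a[shared].mean(axis=0)
                bz = b[shared] - b[shared].mean(axis=0)
                denom = np.linalg.norm(az, axis=0) * np.linalg.norm(bz, axis=0)
                with np.errstate(invalid="ignore"):
                    pair = (az * bz).sum(axis=0) / denom
            else:
                raise ValueError(f"unknown method {method!r}")
            ok = np.isfinite(pair)
            sums[ok] += pair[ok]
            counts[ok] += 1
    with np.errstate(invalid="ignore"):
        ds_vals = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    ds = pd.Series(ds_vals, index=genes, name="DS")
    n_keep = int(round(retained_fraction * n_genes))
    valid = ds.dropna().sort_values(ascending=False)
    if n_keep >= len(valid):
        retained = list(valid.index)
    else:
        cutoff = valid.iloc[n_keep - 1]
        retained = list(valid[valid >= cutoff].index)
        if len(retained) > n_keep:
            logger.info(
                "DS cutoff tie: retaining %d genes instead of %d",
                len(retained),
                n_keep,
            )
    return DifferentialStabilityResult(
        ds=ds, retained_fraction=retained_fraction, retained_genes=retained
    )
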