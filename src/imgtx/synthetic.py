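"""Synthetic inputs with planted ground truth for every pipeline stage.

Real inputs for this kind of analysis — donor microarray expression with
spatial sample coordinates, a consortium effect-size map, curated gene
sets and a PPI network — are external downloads.  This module generates
structurally faithful stand-ins:

* a spherical two-hemisphere parcellation (Fibonacci lattice, mirrored);
* donor-level probe expression whose regional ground truth is a
  Gaussian-process draw on the sphere (squared-exponential covariance in
  angular distance), with jittered sample positions, designated best
  probes, deliberately noisy background-failing probes, and a correlated
  RNA-seq reference;
* an effect-size map that is a noisy linear combination of a sparse
  planted gene-weight vector;
* gene-set collections with one planted enriched set;
* a PPI edge list of Erdős–Rényi background plus planted cliques.

Every generator is a pure function of its seed. Defaults mirror the
study conditions: 6 donors, 180 parcels per hemisphere, and spatial
autocorrelation strong enough that naive permutation nulls misbehave.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ParcellationGeometry
from .maps import EffectSizeMap, RegionGeneMatrix
from .ahba import DonorExpression
from .enrichment import GeneSetCollection

__all__ = [
    "SyntheticTruth",
    "make_sphere_parcellation",
    "simulate_expression",
    "simulate_effect_map",
    "noise_sd_for_target_r2",
    "simulate_gene_sets",
    "simulate_ppi",
]

SPHERE_RADIUS_MM = 80.0  # roughly a human cortical-surface sphere


@dataclass
class SyntheticTruth:
    """Planted ground truth for an effect-size map."""

    planted_genes: list[str]
    planted_weights: dict[str, float]
    noise_sd: float
    autocorr_length: float
    seeds: dict[str, int] = field(default_factory=dict)


def make_sphere_parcellation(n_per_hemisphere: int, seed: int = 0) -> ParcellationGeometry:
    """Two mirrored Fibonacci lattices on a sphere of cortical radius.

    Left-hemisphere parcels occupy the x < 0 half-sphere; the right
    hemisphere is the mirror image through the x = 0 plane, so mirrored
    pairs share y, z and have opposite x.  ``seed`` is accepted for
    interface uniformity; the lattice itself is deterministic.
    """
    if n_per_hemisphere < 2:
        raise ValueError("need at least 2 parcels per hemisphere")
    n = n_per_hemisphere
    i = np.arange(n)
    # Fibonacci lattice on the upper half-sphere (z in (0, 1)), then
    # rotated so the cap axis points along -x
    z = (i + 0.5) / n
    phi = np.pi * (1 + np.sqrt(5)) * i
    rho = np.sqrt(1 - z**2)
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    left = np.column_stack([-pts[:, 2], pts[:, 1], pts[:, 0]])
    right = left * np.array([-1.0, 1.0, 1.0])
    xyz = np.vstack([left, right]) * SPHERE_RADIUS_MM
    ids = [f"L_{k + 1:03d}" for k in range(n)] + [f"R_{k + 1:03d}" for k in range(n)]
    hemi = np.array(["L"] * n + ["R"] * n, dtype=object)
    return ParcellationGeometry(parcel_id=ids, hemisphere=hemi, surface_xyz=xyz)


def gp_maps_on_sphere(
    geometry: ParcellationGeometry,
    n_maps: int,
    autocorr_length: float,
    seed: int,
) -> np.ndarray:
    """Draw smooth maps from a Gaussian process on the unit sphere.

    Covariance is exp(-angle^2 / (2 l^2)) in great-circle angular
    distance (radians); larger ``autocorr_length`` gives smoother maps.
    Returns an (n_parcels, n_maps) array of independent draws.
    """
    unit = geometry.centroid
    cosang = np.clip(unit @ unit.T, -1.0, 1.0)
    angle = np.arccos(cosang)
    cov = np.exp(-(angle**2) / (2 * autocorr_length**2))
    # eigenfactorization with clipping: long length scales make the
    # covariance numerically rank-deficient, defeating a plain Cholesky
    eigval, eigvec = np.linalg.eigh(cov)
    root = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    rng = np.random.default_rng(seed)
    return root @ rng.standard_normal((len(cov), n_maps))


def simulate_expression(
    geometry: ParcellationGeometry,
    n_genes: int = 200,
    n_donors: int = 6,
    probes_per_gene: int = 2,
    autocorr_length: float = 0.3,
    donor_noise_sd: float = 0.5,
    samples_per_parcel: int = 1,
    offparcel_fraction: float = 0.05,
    background_fail_fraction: float = 0.1,
    rnaseq_donors: int = 2,
    seed: int = 0,
) -> tuple[list[DonorExpression], RegionGeneMatrix]:
    """Generate multi-donor probe-level expression with known truth.

    Each gene's regional ground truth is an independent Gaussian-process
    draw on the sphere (length scale ``autocorr_length`` radians).  Per
    donor, ``samples_per_parcel`` samples sit within 2 mm of each parcel
    centroid plus an ``offparcel_fraction`` of extra samples placed 3-6 mm
    from their centroid to exercise the distance cutoff.  Probe 0 of each
    gene is the designated best probe (lowest noise); later probes get
    double noise, and a ``background_fail_fraction`` of the non-best
    probes is marked below background in ~70% of samples.  The first
    ``rnaseq_donors`` donors carry an RNA-seq reference tightly
    correlated with the best probe.

    Returns the donor list and the ground-truth region x gene matrix.
    """
    rng = np.random.default_rng(seed)
    n_parcels = geometry.n_parcels
    truth_vals = gp_maps_on_sphere(
        geometry, n_genes, autocorr_length, seed=int(rng.integers(2**31))
    )
    genes = [f"G{j + 1:04d}" for j in range(n_genes)]
    truth = RegionGeneMatrix(
        parcel_id=list(geometry.parcel_id),
        gene=genes,
        values=truth_vals,
        n_donors_per_region=np.full(n_parcels, n_donors),
        normalization="raw",
    )
    probe_ids, probe_genes, probe_noise = [], [], []
    fail_flags = []
    for j, g in enumerate(genes):
        for k in range(probes_per_gene):
            probe_ids.append(f"P{j + 1:04d}_{k}")
            probe_genes.append(g)
            probe_noise.append(donor_noise_sd if k == 0 else 2.0 * donor_noise_sd)
            fail_flags.append(
                k > 0 and rng.random() < background_fail_fraction * probes_per_gene
                / max(probes_per_gene - 1, 1)
            )
    probe_noise = np.array(probe_noise)
    fail_flags = np.array(fail_flags)

    donors: list[DonorExpression] = []
    for d in range(n_donors):
        drng = np.random.default_rng(int(rng.integers(2**31)))
        # near samples: uniform jitter in a ball of radius < 2 mm
        positions, parcel_of = [], []
        for p in range(n_parcels):
            for _ in range(samples_per_parcel):
                vec = drng.standard_normal(3)
                vec *= (1.8 * drng.random() ** (1 / 3)) / np.linalg.norm(vec)
                positions.append(geometry.surface_xyz[p] + vec)
                parcel_of.append(p)
        n_off = int(round(offparcel_fraction * len(positions)))
        for _ in range(n_off):
            p = int(drng.integers(n_parcels))
            vec = drng.standard_normal(3)
            vec *= (3.0 + 3.0 * drng.random()) / np.linalg.norm(vec)
            positions.append(geometry.surface_xyz[p] + vec)
            parcel_of.append(p)
        positions = np.asarray(positions)
        sample_ids = [f"D{d + 1}_S{s + 1:04d}" for s in range(len(positions))]
        # per-probe intensities: affine transform of truth + probe noise
        base = truth_vals[parcel_of]  # (n_samples, n_genes)
        gene_idx = np.repeat(np.arange(n_genes), probes_per_gene)
        scale = 1.0 + 0.2 * drng.standard_normal(len(probe_ids))
        offset = 7.0 + drng.standard_normal(len(probe_ids))
        intensity = (
            base[:, gene_idx] * scale
            + offset
            + drng.standard_normal((len(positions), len(probe_ids))) * probe_noise
        )
        above = drng.random(intensity.shape) < 0.95
        above[:, fail_flags] = drng.random((len(positions), int(fail_flags.sum()))) < 0.3
        intensity_df = pd.DataFrame(intensity, index=sample_ids, columns=probe_ids)
        above_df = pd.DataFrame(above, index=sample_ids, columns=probe_ids)
        rnaseq = None
        if d < rnaseq_donors:
            best_cols = [f"P{j + 1:04d}_0" for j in range(n_genes)]
            ref = (
                intensity_df[best_cols].to_numpy()
                + 0.1 * drng.standard_normal((len(positions), n_genes))
            )
            rnaseq = pd.DataFrame(ref.T, index=genes, columns=sample_ids)
        donors.append(
            DonorExpression(
                donor_id=f"D{d + 1}",
                sample_xyz=positions,
                intensity=intensity_df,
                above_background=above_df,
                probe_gene=pd.Series(probe_genes, index=probe_ids),
                rnaseq_ref=rnaseq,
            )
        )
    return donors, truth


def noise_sd_for_target_r2(signal: np.ndarray, r2: float) -> float:
    """Noise SD giving an expected in-sample R^2 of ``r2`` for a signal."""
    if not 0 < r2 < 1:
        raise ValueError("target R^2 must be in (0, 1)")
    return float(np.std(signal) * np.sqrt((1 - r2) / r2))


def simulate_effect_map(
    X: RegionGeneMatrix,
    n_planted: int = 30,
    weight_scale: float = 1.0,
    noise_sd: float | None = None,
    target_r2: float = 0.5,
    seed: int = 0,
    atlas: str = "synthetic-sphere",
    weights: dict[str, float] | None = None,
) -> tuple[EffectSizeMap, SyntheticTruth]:
    """Effect-size map as a noisy sparse linear combination of expression.

    A weight vector with ``n_planted`` nonzero entries (magnitude
    ``weight_scale``, random signs) is applied to the column-z-scored
    expression matrix; Gaussian noise is added.  If ``noise_sd`` is None
    it is set so the expected in-sample R^2 equals ``target_r2``.
    Passing ``weights`` (gene -> weight) reuses an existing planted
    vector — e.g. for a second cohort sharing the truth but with
    independent noise — instead of drawing a new one.
    """
    if weights is None and n_planted > X.n_genes:
        raise ValueError("cannot plant more genes than exist")
    rng = np.random.default_rng(seed)
    sd = X.values.std(axis=0)
    Xz = np.zeros_like(X.values)
    ok = sd > 0
    Xz[:, ok] = (X.values[:, ok] - X.values[:, ok].mean(axis=0)) / sd[ok]
    if weights is not None:
        missing = set(weights) - set(X.gene)
        if missing:
            raise ValueError(f"planted weights name unknown genes {sorted(missing)[:5]}")
        w = np.array([weights.get(g, 0.0) for g in X.gene])
        idx = np.flatnonzero(w)
    else:
        idx = rng.choice(X.n_genes, size=n_planted, replace=False)
        w = np.zeros(X.n_genes)
        w[idx] = weight_scale * rng.choice([-1.0, 1.0], size=n_planted)
    signal = Xz @ w
    if noise_sd is None:
        noise_sd = noise_sd_for_target_r2(signal, target_r2)
    y = signal + noise_sd * rng.standard_normal(X.n_regions)
    planted = [X.gene[i] for i in sorted(idx)]
    truth = SyntheticTruth(
        planted_genes=planted,
        planted_weights={X.gene[i]: float(w[i]) for i in sorted(idx)},
        noise_sd=float(noise_sd),
        autocorr_length=np.nan,
        seeds={"effect_map": seed},
    )
    return EffectSizeMap(parcel_id=list(X.parcel_id), d=y, atlas=atlas), truth


def simulate_gene_sets(
    genes: list[str],
    n_sets: int = 20,
    set_size: int = 25,
    planted_set_from: list[str] | None = None,
    planted_fraction: float = 0.6,
    seed: int = 0,
) -> GeneSetCollection:
    """Gene-set collection with one set enriched for a planted list.

    The first set ("planted_set") draws ``planted_fraction`` of its
    members from ``planted_set_from`` and the rest uniformly; the other
    sets are uniform draws from the universe.
    """
    if set_size > len(genes):
        raise ValueError(
            f"set_size {set_size} exceeds the {len(genes)}-gene universe"
        )
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    if planted_set_from:
        n_from = min(int(round(planted_fraction * set_size)), len(planted_set_from))
        members = list(
            rng.choice(planted_set_from, size=n_from, replace=False)
        )
        rest_pool = [g for g in genes if g not in set(members)]
        members += list(
            rng.choice(rest_pool, size=set_size - n_from, replace=False)
        )
        sets["planted_set"] = members
    while len(sets) < n_sets:
        name = f"random_set_{len(sets):02d}"
        sets[name] = list(rng.choice(genes, size=set_size, replace=False))
    return GeneSetCollection(sets=sets, universe=list(genes), source="synthetic")


def simulate_ppi(
    genes: list[str],
    planted_clique_sizes: list[int] = (5, 4),
    background_edge_prob: float = 0.01,
    clique_score: float = 0.9,
    background_score_range: tuple[float, float] = (0.15, 0.95),
    seed: int = 0,
) -> pd.DataFrame:
    """Edge list: Erdős–Rényi background plus planted high-confidence cliques.

    Clique members are disjoint prefixes of ``genes``; clique edges carry
    ``clique_score`` (above the usual 0.4 confidence threshold) while
    background edges get uniform scores over ``background_score_range``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    start = 0
    for size in planted_clique_sizes:
        members = genes[start : start + size]
        start += size
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                rows.append((members[i], members[j], clique_score))
    planted_pairs = {(a, b) for a, b, _ in rows}
    lo, hi = background_score_range
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            pair = (genes[i], genes[j])
            if pair in planted_pairs:
                continue
            if rng.random() < background_edge_prob:
                rows.append((genes[i], genes[j], lo + (hi - lo) * rng.random()))
    return pd.DataFrame(rows, columns=["node_a", "node_b", "score"])
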