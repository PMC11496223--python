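"""Property-validation experiments for the whole pipeline.

Each function here re-runs one verifiable property of the method on
synthetic data with planted ground truth — closed-form agreement of the
PLS solver, planted-gene recovery, spin-test calibration, cross-cohort
reproducibility, brute-force agreement of the combinatorial statistics,
and byte-level determinism — and returns the measured quantities.  The
test suite asserts on these numbers and the acceptance script reports
them; both call into this module so the experiment definitions live in
exactly one place.
"""
from __future__ import annotations

import itertools
import math
import tempfile
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import comb
from scipy.stats import spearmanr

from .ahba import differential_stability, filter_probes_by_noise, srs_normalize
from .enrichment import GeneSetCollection, compute_psi, overrepresentation_test
from .geometry import (
    generate_naive_permutations,
    generate_spin_permutations,
    map_correlation_pspin,
)
from .maps import EffectSizeMap, RegionGeneMatrix
from .pls import bootstrap_gene_z, fdr_bh, intersect_gene_lists, pls1_fit, split_signed_gene_lists
from .ppi import PPINetwork, mcc_scores
from .synthetic import gp_maps_on_sphere, make_sphere_parcellation, simulate_effect_map

__all__ = [
    "pls_closed_form_deviation",
    "planted_recovery",
    "spin_calibration",
    "cross_cohort_jaccard",
    "stage_oracle_deviations",
    "mcc_bruteforce_agreement",
    "ora_null_uniformity",
    "pipeline_determinism",
]


def pls_closed_form_deviation(
    n_instances: int = 100, n_regions: int = 30, n_genes: int = 50, seed: int = 0
) -> float:
    """Max |PLS1 weight - normalized X'y| over random instances."""
    rng = np.random.default_rng(seed)
    max_dev = 0.0
    for _ in range(n_instances):
        vals = rng.standard_normal((n_regions, n_genes))
        y_vals = rng.standard_normal(n_regions)
        X = RegionGeneMatrix(
            parcel_id=[f"P{i}" for i in range(n_regions)],
            gene=[f"G{j}" for j in range(n_genes)],
            values=vals,
        )
        res = pls1_fit(X, EffectSizeMap(X.parcel_id, y_vals))
        Xz = (vals - vals.mean(0)) / vals.std(0)
        yz = (y_vals - y_vals.mean()) / y_vals.std()
        w = Xz.T @ yz
        w /= np.linalg.norm(w)
        if (Xz @ w) @ yz < 0:
            w = -w
        max_dev = max(max_dev, float(np.max(np.abs(res.gene_weight - w))))
    return max_dev


def _planted_instance(n_regions, n_genes, n_planted, target_r2, seed):
    geo = make_sphere_parcellation(n_regions // 2, seed=0)
    vals = gp_maps_on_sphere(geo, n_genes, autocorr_length=0.3, seed=seed)
    X = RegionGeneMatrix(
        parcel_id=list(geo.parcel_id),
        gene=[f"G{j:04d}" for j in range(n_genes)],
        values=vals,
    )
    y, truth = simulate_effect_map(
        X, n_planted=n_planted, target_r2=target_r2, seed=seed + 1
    )
    return X, y, truth


def planted_recovery(
    n_seeds: int = 10,
    n_regions: int = 200,
    n_genes: int = 1000,
    n_planted: int = 30,
    target_r2: float = 0.5,
    n_boot: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Sensitivity and false-discovery proportion for planted genes.

    Spatially smooth expression maps, a sparse planted weight vector,
    bootstrap z inference and BH-FDR gene selection — measured against
    the planted truth, averaged over seeds.
    """
    sens, fdp = [], []
    for s in range(n_seeds):
        X, y, truth = _planted_instance(
            n_regions, n_genes, n_planted, target_r2, seed=seed + 1000 * s
        )
        res = pls1_fit(X, y)
        bootstrap_gene_z(res, X, y, n_boot=n_boot, seed=seed + 1000 * s + 7)
        split_signed_gene_lists(res, alpha=alpha)
        found = set(res.pls1_plus) | set(res.pls1_minus)
        planted = set(truth.planted_genes)
        sens.append(len(found & planted) / len(planted))
        fdp.append(len(found - planted) / max(len(found), 1))
    return {
        "sensitivity": float(np.mean(sens)),
        "fdp": float(np.mean(fdp)),
        "per_seed_sensitivity": sens,
        "per_seed_fdp": fdp,
    }


def spin_calibration(
    n_replicates: int = 200,
    n_perm: int = 200,
    n_per_hemisphere: int = 50,
    autocorr_length: float = 0.3,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of spin vs naive permutation tests on null map pairs.

    Each replicate draws two independent smooth maps on the same sphere;
    any rejection is a false positive.  The naive (unconstrained shuffle)
    rate quantifies how anti-conservative ignoring autocorrelation is.
    """
    geo = make_sphere_parcellation(n_per_hemisphere, seed=0)
    rej_spin = rej_naive = 0
    for rep in range(n_replicates):
        maps = gp_maps_on_sphere(geo, 2, autocorr_length, seed=seed + 3 * rep)
        spin = generate_spin_permutations(geo, n_perm, seed=seed + 3 * rep + 1)
        naive = generate_naive_permutations(geo, n_perm, seed=seed + 3 * rep + 2)
        rej_spin += map_correlation_pspin(maps[:, 0], maps[:, 1], spin).p_spin < alpha
        rej_naive += (
            map_correlation_pspin(maps[:, 0], maps[:, 1], naive).p_spin < alpha
        )
    return {
        "spin_type1": rej_spin / n_replicates,
        "naive_type1": rej_naive / n_replicates,
    }


def cross_cohort_jaccard(
    n_seeds: int = 10,
    n_regions: int = 200,
    n_genes: int = 1000,
    n_planted: int = 30,
    target_r2: float = 0.5,
    n_boot: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Jaccard overlap of the cross-cohort intersected list with truth.

    Two cohorts share the planted weight vector and expression matrix but
    carry independent response noise; significant signed lists are
    intersected sign-wise, as in a two-dataset replication design.
    """
    jaccards = []
    for s in range(n_seeds):
        X, y1, truth = _planted_instance(
            n_regions, n_genes, n_planted, target_r2, seed=seed + 1000 * s
        )
        y2, _ = simulate_effect_map(
            X,
            weights=truth.planted_weights,
            target_r2=target_r2,
            seed=seed + 1000 * s + 500,
        )
        lists = []
        for k, y in enumerate((y1, y2)):
            res = pls1_fit(X, y)
            bootstrap_gene_z(res, X, y, n_boot=n_boot, seed=seed + 1000 * s + 11 + k)
            split_signed_gene_lists(res, alpha=alpha)
            lists.append(res)
        plus = intersect_gene_lists(lists[0].pls1_plus, lists[1].pls1_plus)
        minus = intersect_gene_lists(lists[0].pls1_minus, lists[1].pls1_minus)
        inter = set(plus) | set(minus)
        planted = set(truth.planted_genes)
        denom = len(inter | planted)
        jaccards.append(len(inter & planted) / denom if denom else 0.0)
    return {"jaccard": float(np.mean(jaccards)), "per_seed": jaccards}


def stage_oracle_deviations(seed: int = 0) -> dict:
    """Each pipeline statistic vs an independent brute-force oracle.

    Returns per-stage maximum absolute deviations (or disagreement
    counts), all of which should be at numerical-precision level.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}

    # probe filtering vs direct counting
    above = rng.random((40, 12)) < rng.uniform(0.2, 0.9, size=12)
    frac = above.mean(axis=0)
    probes = [f"p{i:02d}" for i in range(12)]
    from .ahba import DonorExpression

    donor = DonorExpression(
        donor_id="d1",
        sample_xyz=np.zeros((40, 3)),
        intensity=pd.DataFrame(np.zeros((40, 12)), columns=probes),
        above_background=pd.DataFrame(above, columns=probes),
        probe_gene=pd.Series([f"g{i}" for i in range(12)], index=probes),
    )
    got = filter_probes_by_noise([donor])
    expected = [p for p, f in zip(probes, frac) if f >= 0.5]
    out["probe_filter_disagreements"] = float(got != expected)

    # SRS vs stepwise formula
    x = rng.standard_normal(25) * 3 + 1
    med = np.median(x)
    iqr = np.percentile(x, 75) - np.percentile(x, 25)
    sig = 1 / (1 + np.exp(-(x - med) / (iqr / 1.35)))
    expected_srs = (sig - sig.min()) / (sig.max() - sig.min())
    out["srs_max_dev"] = float(np.max(np.abs(srs_normalize(x) - expected_srs)))

    # DS vs direct mean pairwise Spearman
    vals = [rng.standard_normal((8, 5)) for _ in range(3)]
    ms = [
        RegionGeneMatrix(
            parcel_id=[f"P{i}" for i in range(8)],
            gene=[f"g{j}" for j in range(5)],
            values=v,
        )
        for v in vals
    ]
    ds = differential_stability(ms).ds
    dev = 0.0
    for j in range(5):
        pairwise = [
            spearmanr(vals[a][:, j], vals[b][:, j]).statistic
            for a, b in [(0, 1), (0, 2), (1, 2)]
        ]
        dev = max(dev, abs(ds[f"g{j}"] - np.mean(pairwise)))
    out["ds_max_dev"] = float(dev)

    # BH vs hand-applied step-up rule
    p = rng.uniform(size=20) ** 2
    q, _ = fdr_bh(p)
    order = np.argsort(p)
    m = len(p)
    q_oracle = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q_oracle[i] = running
    out["bh_max_dev"] = float(np.max(np.abs(q - q_oracle)))

    # hypergeometric ORA vs exhaustive subset enumeration, universe <= 15
    uni = [f"u{i}" for i in range(13)]
    gene_set = uni[3:9]
    dev = 0.0
    for _ in range(5):
        query = list(rng.choice(uni, size=5, replace=False))
        res = overrepresentation_test(
            query, GeneSetCollection(sets={"s": gene_set}, universe=uni)
        )
        k_obs = len(set(query) & set(gene_set))
        hits = total = 0
        for draw in itertools.combinations(uni, 5):
            total += 1
            hits += len(set(draw) & set(gene_set)) >= k_obs
        dev = max(dev, abs(res.loc[0, "p"] - hits / total))
    out["ora_max_dev"] = float(dev)

    # Fisher odds ratio and p vs fixed-margin enumeration
    from .enrichment import disease_overlap_test

    a, b, c, d = 8, 2, 10, 80
    universe = [f"g{i}" for i in range(a + b + c + d)]
    res = disease_overlap_test(
        universe[: a + b], universe[:a] + universe[a + b : a + b + c], universe
    )
    row1, col1, N = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            comb(col1, x, exact=True)
            * comb(N - col1, row1 - x, exact=True)
            / comb(N, row1, exact=True)
        )

    p_obs = prob(a)
    p_oracle = sum(
        pr
        for x in range(max(0, row1 + col1 - N), min(row1, col1) + 1)
        if (pr := prob(x)) <= p_obs * (1 + 1e-9)
    )
    out["fisher_p_dev"] = float(abs(res.p - p_oracle))
    out["fisher_or_dev"] = float(abs(res.odds_ratio - a * d / (b * c)))

    # pSI Monte Carlo vs exhaustive shared-relabeling null on a 20x4 fixture
    expr = rng.gamma(2.0, 1.0, size=(20, 4))
    expr[0] = [9.0, 0.1, 0.1, 0.1]
    frame = pd.DataFrame(
        expr, index=[f"g{i}" for i in range(20)], columns=list("ABCD")
    )
    prof = compute_psi(frame, n_perm=2000, seed=seed + 1)
    n_genes, n_cond = expr.shape

    def mean_rank(vals, c):
        res_ = np.empty(n_genes)
        for g in range(n_genes):
            rs = []
            for c2 in range(n_cond):
                if c2 == c:
                    continue
                fc = (vals[:, c] + 1e-9) / (vals[:, c2] + 1e-9)
                rs.append(1 + np.sum(fc > fc[g]))
            res_[g] = np.mean(rs)
        return res_

    dev = 0.0
    for c_idx, cond in enumerate(frame.columns):
        obs = mean_rank(expr, c_idx)
        null = np.concatenate(
            [mean_rank(expr[:, pi], c_idx) for pi in itertools.permutations(range(4))]
        )
        exact = (1 + np.array([(null <= o).sum() for o in obs])) / (1 + null.size)
        dev = max(dev, float(np.max(np.abs(prof.psi[cond].to_numpy() - exact))))
    out["psi_max_dev"] = dev
    # 3 Monte-Carlo SEs at the least favourable p=0.5 with 2000x20 pooled draws
    out["psi_tolerance_3se"] = 3 * math.sqrt(0.25 / (2000 * 20)) + 0.02
    return out


def mcc_bruteforce_agreement(n_graphs: int = 200, seed: int = 0) -> dict:
    """MCC vs exhaustive maximal-clique enumeration on <= 6-node graphs."""

    def brute(g):
        nodes = list(g.nodes)
        scores = {v: 0 for v in nodes}
        for r in range(2, len(nodes) + 1):
            for sub in itertools.combinations(nodes, r):
                if not all(
                    g.has_edge(x, y) for x, y in itertools.combinations(sub, 2)
                ):
                    continue
                if any(
                    all(g.has_edge(v, u) for u in sub)
                    for v in nodes
                    if v not in sub
                ):
                    continue
                for v in sub:
                    scores[v] += math.factorial(r - 1)
        return scores

    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_graphs):
        n = int(rng.integers(2, 7))
        g = nx.gnp_random_graph(n, rng.uniform(0.2, 0.9), seed=int(rng.integers(2**31)))
        g = nx.relabel_nodes(g, str)
        got = mcc_scores(PPINetwork(graph=g, threshold=0.0)).scores.to_dict()
        agree += got == brute(g)
    tri = mcc_scores(
        PPINetwork(graph=nx.complete_graph(3), threshold=0.0)
    ).scores
    path = mcc_scores(PPINetwork(graph=nx.path_graph(3), threshold=0.0)).scores
    return {
        "agreement_fraction": agree / n_graphs,
        "triangle_scores": sorted(tri.tolist()),
        "path_scores": sorted(path.tolist()),
    }


def ora_null_uniformity(n_replicates: int = 500, seed: int = 0) -> float:
    """KS-test p-value for uniformity of ORA p-values under null queries."""
    # sizes chosen so the overlap statistic has wide support: the p-value
    # of a discrete test is only near-uniform when no single table carries
    # appreciable mass
    rng = np.random.default_rng(seed)
    uni = [f"g{i:06d}" for i in range(100000)]
    gene_set = uni[:20000]
    sets = GeneSetCollection(sets={"s": gene_set}, universe=uni)
    pvals = []
    for _ in range(n_replicates):
        query = list(rng.choice(uni, size=10000, replace=False))
        pvals.append(overrepresentation_test(query, sets).loc[0, "p"])
    return float(stats.kstest(pvals, "uniform").pvalue)


def pipeline_determinism(seed: int = 0, workdir: str | None = None) -> dict:
    """Run the full synthetic pipeline twice (second time from the run
    manifest) and compare the gene tables byte for byte."""
    from .pipeline import run_pipeline, run_pipeline_from_manifest
    from . import io as iio
    from .synthetic import simulate_expression, simulate_gene_sets, simulate_ppi

    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        tmp = Path(tmp)
        root = tmp / "in"
        root.mkdir()
        geometry = make_sphere_parcellation(8, seed=seed)
        iio.write_geometry(geometry, root / "geometry.tsv")
        donors, truth = simulate_expression(geometry, n_genes=24, n_donors=3, seed=seed)
        donor_dirs = []
        for donor in donors:
            ddir = root / "donors" / donor.donor_id
            iio.write_donor_dir(donor, ddir)
            donor_dirs.append(str(ddir))
        y1, planted = simulate_effect_map(truth, n_planted=6, seed=seed + 1)
        y2, _ = simulate_effect_map(
            truth, weights=planted.planted_weights, seed=seed + 2
        )
        iio.write_effect_map(y1, root / "map1.tsv")
        iio.write_effect_map(y2, root / "map2.tsv")
        sets = simulate_gene_sets(
            truth.gene, n_sets=5, set_size=6,
            planted_set_from=planted.planted_genes, seed=seed + 3,
        )
        iio.write_gmt(sets, root / "sets.gmt")
        iio.write_edge_list(simulate_ppi(truth.gene, seed=seed + 4), root / "ppi.tsv")
        config = {
            "seed": seed,
            "geometry": str(root / "geometry.tsv"),
            "donor_dirs": donor_dirs,
            "maps": {
                "cohort1": str(root / "map1.tsv"),
                "cohort2": str(root / "map2.tsv"),
            },
            "n_perm": 60,
            "n_boot": 120,
            "ds_fraction": 0.8,
            "gene_sets_gmt": str(root / "sets.gmt"),
            "ppi_edges": str(root / "ppi.tsv"),
        }
        out1 = run_pipeline(config, tmp / "out1")
        out2 = run_pipeline_from_manifest(out1 / "manifest.json", tmp / "out2")
        identical = all(
            (out1 / f).read_bytes() == (out2 / f).read_bytes()
            for f in (
                "pls_genes_cohort1.tsv",
                "pls_genes_cohort2.tsv",
                "overlapped_genes.txt",
                "region_gene_matrix.tsv",
            )
        )
    return {"identical": identical}
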