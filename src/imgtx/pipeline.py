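"""End-to-end pipeline driver: expression assembly -> PLS -> downstream.

The driver consumes a flat configuration mapping (usually loaded from
YAML), runs every stage whose inputs are configured, writes all outputs
as TSV/JSON into one directory, and records a run manifest holding the
full settings, input digests, exclusion lists and per-stage timings.
Re-running from a manifest reproduces all deterministic outputs
byte-identically.
"""
from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as iio
from .ahba import (
    aggregate_to_regions,
    assign_samples_to_parcels,
    differential_stability,
    filter_probes_by_noise,
    select_probe_per_gene,
)
from .enrichment import (
    compute_psi,
    disease_overlap_test,
    marker_enrichment,
    overrepresentation_test,
    specificity_enrichment,
)
from .geometry import generate_spin_permutations
from .maps import RegionGeneMatrix
from .pls import (
    bootstrap_gene_z,
    intersect_gene_lists,
    pls1_fit,
    pls_spin_significance,
    split_signed_gene_lists,
)
from .ppi import build_network, mcc_scores

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "run_pipeline_from_manifest", "DEFAULTS"]

DEFAULTS = {
    "seed": 0,
    "ds_fraction": 0.5,
    "max_dist_mm": 2.0,
    "n_perm": 1000,
    "n_boot": 1000,
    "alpha": 0.05,
    "ppi_threshold": 0.4,
    "top_hubs": 3,
    "psi_threshold": 0.05,
    "psi_n_perm": 1000,
}


def _require(config: dict, key: str):
    if key not in config:
        raise KeyError(f"pipeline config is missing required key {key!r}")
    path = Path(config[key])
    if not path.exists():
        raise FileNotFoundError(f"config key {key!r}: no such input {path}")
    return path


def _pls_table(result) -> pd.DataFrame:
    membership = []
    plus, minus = set(result.pls1_plus), set(result.pls1_minus)
    for g in result.gene:
        membership.append("plus" if g in plus else "minus" if g in minus else "none")
    return pd.DataFrame(
        {
            "gene": result.gene,
            "weight": result.gene_weight,
            "z": result.z,
            "p": result.p,
            "q": result.q,
            "list": membership,
        }
    )


def run_pipeline(config: dict, out_dir) -> Path:
    """Run every configured stage; return the output directory.

    Required config keys: ``geometry``, ``donor_dirs``, ``maps`` (a
    mapping cohort-name -> effect-map TSV).  Optional stages activate on
    presence of their input keys: ``gene_sets_gmt``, ``marker_gmt``,
    ``disease_genes``, ``psi_expression``, ``ppi_edges``.
    """
    cfg = {**DEFAULTS, **config}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "settings": {k: v for k, v in cfg.items()},
        "input_digests": {},
        "exclusions": {},
        "timings": {},
        "stages": [],
    }
    t0 = time.perf_counter()

    def stage_done(name: str) -> None:
        nonlocal t0
        manifest["timings"][name] = round(time.perf_counter() - t0, 3)
        manifest["stages"].append(name)
        t0 = time.perf_counter()

    geometry = iio.read_geometry(_require(cfg, "geometry"))
    manifest["input_digests"]["geometry"] = iio.file_digest(cfg["geometry"])

    # --- expression assembly -------------------------------------------
    if "donor_dirs" not in cfg:
        raise KeyError("pipeline config is missing required key 'donor_dirs'")
    donors = []
    for ddir in cfg["donor_dirs"]:
        if not Path(ddir).exists():
            raise FileNotFoundError(f"config key 'donor_dirs': no such input {ddir}")
        donors.append(iio.read_donor_dir(ddir))
    retained_probes = filter_probes_by_noise(donors)
    probe_map = select_probe_per_gene(donors, retained_probes)
    assignments = {
        d.donor_id: assign_samples_to_parcels(d, geometry, cfg["max_dist_mm"])
        for d in donors
    }
    per_donor, pooled = aggregate_to_regions(donors, probe_map, assignments, geometry)
    ds = differential_stability(per_donor, retained_fraction=cfg["ds_fraction"])
    keep_genes = [g for g in pooled.gene if g in set(ds.retained_genes)]
    gene_idx = [pooled.gene.index(g) for g in keep_genes]
    covered = pooled.covered_mask()
    expr = RegionGeneMatrix(
        parcel_id=[p for p, m in zip(pooled.parcel_id, covered) if m],
        gene=keep_genes,
        values=pooled.values[np.ix_(covered, gene_idx)],
        n_donors_per_region=pooled.n_donors_per_region[covered],
        normalization="srs01",
    )
    manifest["exclusions"]["probes_removed"] = len(donors[0].probes) - len(
        retained_probes
    )
    manifest["exclusions"]["uncovered_parcels"] = [
        p for p, m in zip(pooled.parcel_id, covered) if not m
    ]
    manifest["exclusions"]["genes_below_ds_cutoff"] = pooled.n_genes - len(keep_genes)
    iio.write_region_gene_matrix(expr, out / "region_gene_matrix.tsv")
    ds.ds.rename_axis("gene").to_frame().assign(
        retained=lambda f: f.index.isin(set(ds.retained_genes))
    ).to_csv(out / "ds_scores.tsv", sep="\t", float_format="%.10g")
    stage_done("build_expression")

    # --- PLS per cohort ------------------------------------------------
    if "maps" not in cfg or not cfg["maps"]:
        raise KeyError("pipeline config is missing required key 'maps'")
    sub_geo = _subset_geometry(geometry, expr.parcel_id)
    nulls = generate_spin_permutations(sub_geo, cfg["n_perm"], seed=cfg["seed"])
    per_cohort: dict[str, object] = {}
    for i, (cohort, map_path) in enumerate(sorted(cfg["maps"].items())):
        emap = iio.read_effect_map(_require({"m": map_path}, "m"), atlas=cohort)
        manifest["input_digests"][f"map_{cohort}"] = iio.file_digest(map_path)
        order = {p: k for k, p in enumerate(emap.parcel_id)}
        missing = [p for p in expr.parcel_id if p not in order]
        if missing:
            raise ValueError(
                f"cohort {cohort}: map lacks covered parcels {missing[:5]}"
            )
        aligned = type(emap)(
            parcel_id=list(expr.parcel_id),
            d=emap.d[[order[p] for p in expr.parcel_id]],
            atlas=emap.atlas,
        )
        res = pls1_fit(expr, aligned)
        pls_spin_significance(res, expr, aligned, nulls)
        bootstrap_gene_z(
            res, expr, aligned, n_boot=cfg["n_boot"], seed=cfg["seed"] + 1 + i
        )
        split_signed_gene_lists(res, alpha=cfg["alpha"])
        per_cohort[cohort] = res
        _pls_table(res).to_csv(
            out / f"pls_genes_{cohort}.tsv", sep="\t", index=False,
            float_format="%.10g",
        )
        pd.DataFrame(
            {"parcel_id": expr.parcel_id, "score": res.region_score, "d": aligned.d}
        ).to_csv(out / f"pls_scores_{cohort}.tsv", sep="\t", index=False,
                 float_format="%.10g")
        manifest.setdefault("pls", {})[cohort] = {
            "score_map_r": res.score_map_r,
            "var_explained": res.var_explained,
            "x_var_explained": res.x_var_explained,
            "p_spin": res.p_spin,
            "n_plus": len(res.pls1_plus),
            "n_minus": len(res.pls1_minus),
        }
    stage_done("pls")

    # --- cross-cohort intersection -------------------------------------
    results = [per_cohort[c] for c in sorted(per_cohort)]
    if len(results) >= 2:
        plus = intersect_gene_lists(*[r.pls1_plus for r in results])
        minus = intersect_gene_lists(*[r.pls1_minus for r in results])
        overlapped = plus + minus
    else:
        overlapped = results[0].pls1_plus + results[0].pls1_minus
    iio.write_gene_list(overlapped, out / "overlapped_genes.txt")
    universe = list(expr.gene)
    iio.write_gene_list(universe, out / "universe.txt")
    stage_done("intersect")

    # --- downstream stages ---------------------------------------------
    if "gene_sets_gmt" in cfg:
        sets = iio.read_gmt(_require(cfg, "gene_sets_gmt"), universe=universe)
        if overlapped:
            overrepresentation_test(overlapped, sets, alpha=cfg["alpha"]).to_csv(
                out / "enrichment_ora.tsv", sep="\t", index=False,
                float_format="%.10g",
            )
        stage_done("enrich")
    if "marker_gmt" in cfg:
        markers = iio.read_gmt(_require(cfg, "marker_gmt"), universe=universe)
        if overlapped:
            marker_enrichment(overlapped, markers, alpha=cfg["alpha"]).to_csv(
                out / "enrichment_markers.tsv", sep="\t", index=False,
                float_format="%.10g",
            )
        stage_done("markers")
    if "psi_expression" in cfg:
        profile_expr = pd.read_csv(
            _require(cfg, "psi_expression"), sep="\t", index_col=0
        )
        profile = compute_psi(
            profile_expr, n_perm=cfg["psi_n_perm"], seed=cfg["seed"] + 100
        )
        profile.psi.rename_axis("gene").to_csv(
            out / "psi_values.tsv", sep="\t", float_format="%.10g"
        )
        if overlapped:
            specificity_enrichment(
                overlapped, profile, universe,
                psi_threshold=cfg["psi_threshold"], alpha=cfg["alpha"],
            ).to_csv(out / "enrichment_psi.tsv", sep="\t", index=False,
                     float_format="%.10g")
        stage_done("psi")
    if "disease_genes" in cfg:
        disease = iio.read_gene_list(_require(cfg, "disease_genes"))
        res = disease_overlap_test(overlapped, disease, universe)
        iio.write_manifest(
            {
                "a": res.a, "b": res.b, "c": res.c, "d": res.d,
                "odds_ratio": res.odds_ratio, "p": res.p,
            },
            out / "disease_overlap.json",
        )
        stage_done("overlap")
    if "ppi_edges" in cfg:
        edges = iio.read_edge_list(_require(cfg, "ppi_edges"))
        network = build_network(
            edges, threshold=cfg["ppi_threshold"],
            restrict_to=overlapped if overlapped else None,
        )
        hubs = mcc_scores(network)
        hubs.scores.rename_axis("gene").to_csv(
            out / "hub_scores.tsv", sep="\t"
        )
        manifest["top_hubs"] = hubs.top(cfg["top_hubs"])
        stage_done("hubs")

    iio.write_manifest(manifest, out / "manifest.json")
    return out


def _subset_geometry(geometry, parcel_ids: list[str]):
    from .geometry import ParcellationGeometry

    keep = {p: i for i, p in enumerate(geometry.parcel_id)}
    idx = [keep[p] for p in parcel_ids]
    return ParcellationGeometry(
        parcel_id=list(parcel_ids),
        hemisphere=geometry.hemisphere[idx],
        surface_xyz=geometry.surface_xyz[idx],
    )


def run_pipeline_from_manifest(manifest_path, out_dir) -> Path:
    """Replay a run from its manifest's recorded settings."""
    manifest = iio.read_manifest(manifest_path)
    return run_pipeline(manifest["settings"], out_dir)
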