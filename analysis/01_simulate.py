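#!/usr/bin/env python
"""Generate the synthetic study inputs with planted ground truth.

Writes a complete input bundle — spherical parcellation geometry, six
donors' probe-level expression, two cohort effect-size maps sharing one
planted sparse gene-weight vector, gene sets with one planted enriched
set, and a PPI edge list with planted cliques — under scratch/bundle/,
plus a small truth summary under results/analysis/.
"""
import json
from pathlib import Path

import imgtx.io as iio
from imgtx import (
    make_sphere_parcellation,
    simulate_effect_map,
    simulate_expression,
    simulate_gene_sets,
    simulate_ppi,
)

SEED = 7
ROOT = Path(__file__).resolve().parents[1]
BUNDLE = ROOT / "scratch" / "bundle"
RESULTS = ROOT / "results" / "analysis"


def main() -> None:
    BUNDLE.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    geometry = make_sphere_parcellation(30, seed=SEED)  # 60 parcels
    iio.write_geometry(geometry, BUNDLE / "geometry.tsv")

    donors, truth = simulate_expression(
        geometry, n_genes=120, n_donors=6, seed=SEED
    )
    donor_dirs = []
    for donor in donors:
        ddir = BUNDLE / "donors" / donor.donor_id
        iio.write_donor_dir(donor, ddir)
        donor_dirs.append(str(ddir))

    y1, planted = simulate_effect_map(truth, n_planted=12, seed=SEED + 1)
    y2, _ = simulate_effect_map(
        truth, weights=planted.planted_weights, seed=SEED + 2
    )
    iio.write_effect_map(y1, BUNDLE / "effect_map_cohort1.tsv")
    iio.write_effect_map(y2, BUNDLE / "effect_map_cohort2.tsv")

    sets = simulate_gene_sets(
        truth.gene, n_sets=12, set_size=10,
        planted_set_from=planted.planted_genes, seed=SEED + 3,
    )
    iio.write_gmt(sets, BUNDLE / "gene_sets.gmt")
    iio.write_edge_list(
        simulate_ppi(
            planted.planted_genes + truth.gene[:40],
            planted_clique_sizes=[5, 4],
            background_edge_prob=0.02,
            seed=SEED + 4,
        ),
        BUNDLE / "ppi_edges.tsv",
    )
    iio.write_gene_list(planted.planted_genes, BUNDLE / "disease_genes.txt")

    summary = {
        "seed": SEED,
        "n_parcels": geometry.n_parcels,
        "n_genes": len(truth.gene),
        "n_donors": len(donors),
        "planted_genes": planted.planted_genes,
        "noise_sd": planted.noise_sd,
    }
    (RESULTS / "simulation_truth.json").write_text(json.dumps(summary, indent=2))
    print(
        f"bundle written to {BUNDLE}: {geometry.n_parcels} parcels, "
        f"{len(truth.gene)} genes, {len(donors)} donors, "
        f"{len(planted.planted_genes)} planted genes"
    )


if __name__ == "__main__":
    main()
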