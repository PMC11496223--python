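#!/usr/bin/env python
"""Enrichment of the cross-cohort gene list.

Over-representation against the simulated gene-set collection (with one
planted enriched set), a marker-style two-sided Fisher panel, a
specificity (pSI) analysis on a small synthetic tissue panel, and the
disease-overlap Fisher test against the planted disease list.
"""
from pathlib import Path

import numpy as np
import pandas as pd

import imgtx.io as iio
from imgtx import (
    compute_psi,
    disease_overlap_test,
    marker_enrichment,
    overrepresentation_test,
    specificity_enrichment,
)

SEED = 7
ROOT = Path(__file__).resolve().parents[1]
BUNDLE = ROOT / "scratch" / "bundle"
RESULTS = ROOT / "results" / "analysis"


def main() -> None:
    query = iio.read_gene_list(RESULTS / "overlapped_genes.txt")
    universe = iio.read_gene_list(RESULTS / "ds_retained_genes.txt")
    sets = iio.read_gmt(BUNDLE / "gene_sets.gmt", universe=universe)

    ora = overrepresentation_test(query, sets)
    ora.to_csv(RESULTS / "enrichment_ora.tsv", sep="\t", index=False,
               float_format="%.4g")
    top = ora.iloc[0]
    print(
        f"ORA: top set {top['set']!r} p = {top['p']:.3g} "
        f"(q = {top['q']:.3g}, overlap {top['overlap_count']})"
    )

    markers = marker_enrichment(query, sets)
    markers.to_csv(RESULTS / "enrichment_markers.tsv", sep="\t", index=False,
                   float_format="%.4g")

    # small synthetic tissue panel: condition 'cortex' up-weights the query
    rng = np.random.default_rng(SEED + 10)
    expr = pd.DataFrame(
        rng.gamma(2.0, 1.0, size=(len(universe), 3)),
        index=universe,
        columns=["cortex", "cerebellum", "thalamus"],
    )
    expr.loc[[g for g in query if g in expr.index], "cortex"] *= 5
    profile = compute_psi(expr, n_perm=2000, seed=SEED + 11)
    psi_res = specificity_enrichment(query, profile, universe)
    psi_res.to_csv(RESULTS / "enrichment_psi.tsv", sep="\t", index=False,
                   float_format="%.4g")
    best = psi_res.iloc[0]
    print(f"pSI enrichment: top condition {best['set']!r} p = {best['p']:.3g}")

    disease = iio.read_gene_list(BUNDLE / "disease_genes.txt")
    overlap = disease_overlap_test(query, disease, universe)
    print(
        f"disease overlap: {overlap.a} shared genes, "
        f"odds ratio = {overlap.odds_ratio:.3g}, p = {overlap.p:.3g}"
    )
    pd.DataFrame(
        [{"a": overlap.a, "b": overlap.b, "c": overlap.c, "d": overlap.d,
          "odds_ratio": overlap.odds_ratio, "p": overlap.p}]
    ).to_csv(RESULTS / "disease_overlap.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
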