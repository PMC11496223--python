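"""Readers and writers for the plain-text formats the pipeline exchanges.

All tabular files are UTF-8, tab-delimited, with a header row; gene sets
use the standard GMT layout (name, description, members).  Every reader
validates uniqueness of IDs and row shape and raises with the offending
location; every (write, read) pair is a round-trip identity.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ParcellationGeometry
from .maps import EffectSizeMap, RegionGeneMatrix
from .ahba import DonorExpression
from .enrichment import GeneSetCollection

__all__ = [
    "read_geometry",
    "write_geometry",
    "read_effect_map",
    "write_effect_map",
    "read_region_gene_matrix",
    "write_region_gene_matrix",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "read_edge_list",
    "write_edge_list",
    "read_donor_dir",
    "write_donor_dir",
    "read_manifest",
    "write_manifest",
    "file_digest",
]


def _read_tsv(path: Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    # pandas' C reader tolerates short rows; check raggedness explicitly
    with open(path, encoding="utf-8") as fh:
        widths = [len(line.rstrip("\n").split("\t")) for line in fh if line.strip()]
    if len(set(widths)) > 1:
        bad = next(i for i, w in enumerate(widths) if w != widths[0])
        raise ValueError(f"{path}: ragged row at line {bad + 1}")
    df = pd.read_csv(path, sep="\t", encoding="utf-8")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def read_geometry(path) -> ParcellationGeometry:
    df = _read_tsv(Path(path), ["parcel_id", "hemisphere", "x", "y", "z"])
    if df["parcel_id"].duplicated().any():
        dup = df.loc[df["parcel_id"].duplicated(), "parcel_id"].iloc[0]
        raise ValueError(f"{path}: duplicate parcel_id {dup!r}")
    return ParcellationGeometry(
        parcel_id=[str(p) for p in df["parcel_id"]],
        hemisphere=df["hemisphere"].to_numpy(dtype=object),
        surface_xyz=df[["x", "y", "z"]].to_numpy(dtype=float),
    )


def write_geometry(geometry: ParcellationGeometry, path) -> None:
    pd.DataFrame(
        {
            "parcel_id": geometry.parcel_id,
            "hemisphere": geometry.hemisphere,
            "x": geometry.surface_xyz[:, 0],
            "y": geometry.surface_xyz[:, 1],
            "z": geometry.surface_xyz[:, 2],
        }
    ).to_csv(path, sep="\t", index=False)


def read_effect_map(path, atlas: str = "unknown") -> EffectSizeMap:
    df = _read_tsv(Path(path), ["parcel_id", "value"])
    if df["parcel_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate parcel ids")
    return EffectSizeMap(
        parcel_id=[str(p) for p in df["parcel_id"]],
        d=df["value"].to_numpy(dtype=float),
        atlas=atlas,
    )


def write_effect_map(emap: EffectSizeMap, path) -> None:
    emap.to_frame().to_csv(path, sep="\t", index=False)


def read_region_gene_matrix(path) -> RegionGeneMatrix:
    df = _read_tsv(Path(path), ["parcel_id"])
    if df["parcel_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate parcel ids")
    meta_cols = ["parcel_id"]
    n_donors = None
    if "n_donors" in df.columns:
        n_donors = df["n_donors"].to_numpy(dtype=int)
        meta_cols.append("n_donors")
    genes = [c for c in df.columns if c not in meta_cols]
    return RegionGeneMatrix(
        parcel_id=[str(p) for p in df["parcel_id"]],
        gene=genes,
        values=df[genes].to_numpy(dtype=float),
        n_donors_per_region=n_donors,
        normalization="raw",
    )


def write_region_gene_matrix(matrix: RegionGeneMatrix, path) -> None:
    df = matrix.to_frame().reset_index(names="parcel_id")
    df.insert(1, "n_donors", matrix.n_donors_per_region)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_gmt(path, universe: list[str] | None = None) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    members_union: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {i + 1} has fewer than 3 fields")
            name, _desc, *members = parts
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r} at line {i + 1}")
            sets[name] = members
            members_union += members
    if universe is None:
        universe = list(dict.fromkeys(members_union))
    return GeneSetCollection(sets=sets, universe=universe, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, collection.source or "na", *members]) + "\n")


def read_gene_list(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        genes = [line.strip() for line in fh if line.strip()]
    dupes = {g for g in genes if genes.count(g) > 1} if len(genes) < 10000 else set()
    if len(set(genes)) != len(genes):
        raise ValueError(f"{path}: duplicate symbols {sorted(dupes)[:5]}")
    return genes


def write_gene_list(genes: list[str], path) -> None:
    Path(path).write_text("\n".join(genes) + ("\n" if genes else ""), encoding="utf-8")


def read_edge_list(path) -> pd.DataFrame:
    return _read_tsv(Path(path), ["node_a", "node_b", "score"])


def write_edge_list(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_donor_dir(path) -> DonorExpression:
    """Load one donor directory (samples/expression/pacall/probes[/rnaseq])."""
    path = Path(path)
    samples = _read_tsv(path / "samples.tsv", ["sample_id", "x", "y", "z"])
    expr = pd.read_csv(path / "expression.tsv", sep="\t", index_col=0)
    pacall = pd.read_csv(path / "pacall.tsv", sep="\t", index_col=0)
    probes = _read_tsv(path / "probes.tsv", ["probe_id", "gene_symbol"])
    rnaseq = None
    if (path / "rnaseq.tsv").exists():
        rnaseq = pd.read_csv(path / "rnaseq.tsv", sep="\t", index_col=0)
    sample_ids = [str(s) for s in samples["sample_id"]]
    # expression/pacall files are probes x samples; transpose to samples x probes
    return DonorExpression(
        donor_id=path.name,
        sample_xyz=samples[["x", "y", "z"]].to_numpy(dtype=float),
        intensity=expr[sample_ids].T,
        above_background=pacall[sample_ids].T.astype(bool),
        probe_gene=pd.Series(
            probes["gene_symbol"].to_numpy(), index=probes["probe_id"]
        ),
        rnaseq_ref=rnaseq,
    )


def write_donor_dir(donor: DonorExpression, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "sample_id": donor.intensity.index,
            "x": donor.sample_xyz[:, 0],
            "y": donor.sample_xyz[:, 1],
            "z": donor.sample_xyz[:, 2],
        }
    ).to_csv(path / "samples.tsv", sep="\t", index=False)
    donor.intensity.T.to_csv(path / "expression.tsv", sep="\t", float_format="%.10g")
    donor.above_background.T.astype(int).to_csv(path / "pacall.tsv", sep="\t")
    pd.DataFrame(
        {"probe_id": donor.probe_gene.index, "gene_symbol": donor.probe_gene.values}
    ).to_csv(path / "probes.tsv", sep="\t", index=False)
    if donor.rnaseq_ref is not None:
        donor.rnaseq_ref.to_csv(path / "rnaseq.tsv", sep="\t", float_format="%.10g")


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )
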