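"""Shared parcellated-data containers.

A *parcellated map* assigns one scalar (e.g. a Cohen's d effect size) to
every parcel of a cortical atlas; a *region-by-gene matrix* assigns one
expression value per parcel per gene.  Both carry their parcel labels so
that downstream alignment (spin nulls, PLS) can verify ordering instead
of assuming it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EffectSizeMap", "RegionGeneMatrix"]


@dataclass
class EffectSizeMap:
    """Per-parcel standardized effect sizes (Cohen's d) on a named atlas.

    Parameters
    ----------
    parcel_id
        Ordered parcel labels, matching the geometry used for nulls.
    d
        Cohen's d per parcel; must be finite.
    atlas
        Free-text atlas name, recorded in outputs.
    """

    parcel_id: list[str]
    d: np.ndarray
    atlas: str = "unknown"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if len(self.parcel_id) != self.d.shape[0]:
            raise ValueError(
                f"parcel_id has {len(self.parcel_id)} entries but d has "
                f"{self.d.shape[0]}"
            )
        if not np.all(np.isfinite(self.d)):
            bad = [p for p, v in zip(self.parcel_id, self.d) if not np.isfinite(v)]
            raise ValueError(f"non-finite effect sizes for parcels {bad[:5]}")

    def __len__(self) -> int:
        return len(self.parcel_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"parcel_id": self.parcel_id, "value": self.d})


@dataclass
class RegionGeneMatrix:
    """Region x gene expression with donor-coverage provenance.

    ``values[i, j]`` is the expression of gene ``gene[j]`` in parcel
    ``parcel_id[i]``.  ``n_donors_per_region`` records how many donors
    contributed samples to each parcel; parcels with zero coverage carry
    NaN rows and are excluded by :meth:`drop_uncovered`.
    """

    parcel_id: list[str]
    gene: list[str]
    values: np.ndarray
    n_donors_per_region: np.ndarray = field(default=None)  # type: ignore[assignment]
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.parcel_id), len(self.gene)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.parcel_id)} parcels, {len(self.gene)} genes)"
            )
        if len(set(self.gene)) != len(self.gene):
            raise ValueError("gene symbols must be unique")
        if len(set(self.parcel_id)) != len(self.parcel_id):
            raise ValueError("parcel ids must be unique")
        if self.n_donors_per_region is None:
            self.n_donors_per_region = np.ones(len(self.parcel_id), dtype=int)
        else:
            self.n_donors_per_region = np.asarray(self.n_donors_per_region, dtype=int)
        if self.normalization not in {"srs01", "zscore", "raw"}:
            raise ValueError(f"unknown normalization label {self.normalization!r}")
        if self.normalization == "srs01":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
                raise ValueError("srs01 values must lie in [0, 1]")

    @property
    def n_regions(self) -> int:
        return len(self.parcel_id)

    @property
    def n_genes(self) -> int:
        return len(self.gene)

    def covered_mask(self) -> np.ndarray:
        """Boolean mask of parcels with at least one contributing donor."""
        return self.n_donors_per_region > 0

    def drop_uncovered(self) -> "RegionGeneMatrix":
        """Return a copy restricted to parcels with donor coverage."""
        mask = self.covered_mask()
        return RegionGeneMatrix(
            parcel_id=[p for p, m in zip(self.parcel_id, mask) if m],
            gene=list(self.gene),
            values=self.values[mask],
            n_donors_per_region=self.n_donors_per_region[mask],
            normalization=self.normalization,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.parcel_id, columns=self.gene)
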