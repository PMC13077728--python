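"""Shared in-memory containers for the ctprs toolkit.

Conventions used throughout the package:

* genomic intervals are 0-based half-open (BED convention);
* variant positions are 1-based (VCF convention) — the single place the two
  meet is :func:`ctprs.regions.snps_in_ranges`, which applies ``pos - 1``;
* dosages count the ``a1`` allele of each variant, on the 0–2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: Primary brain cell-type labels used as defaults across the package.
PRIMARY_CELL_TYPES = ("AST", "MIC", "ODC", "OPC", "END", "GLU", "GAB")

#: Columns a cell-metadata table may carry (a subset is fine, but every field
#: referenced by an active control criterion must be present and non-missing).
CELL_COLUMNS = (
    "cell_id",
    "donor_id",
    "cell_type",
    "subtype",
    "tss_enrichment",
    "braak",
    "neuritic_plaque_status",
    "mmse",
    "cognitive_status",
    "control_flag",
)

FEATURE_COLUMNS = ("feature_id", "chrom", "start", "end", "strand")


@dataclass(frozen=True)
class VariantLocus:
    """A single variant: 1-based position plus its two alleles."""

    variant_id: str
    chrom: str
    pos: int  # 1-based, VCF convention
    a1: str
    a2: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.variant_id}: pos must be >= 1")
        if self.a1 == self.a2:
            raise ValueError(f"variant {self.variant_id}: a1 == a2")


@dataclass
class FeatureMatrix:
    """Sparse cells x features raw counts with cell and feature metadata.

    Parameters
    ----------
    counts
        Nonnegative sparse matrix, one row per cell, one column per feature.
    modality
        ``"RNA"`` (gene expression) or ``"ATAC"`` (peak accessibility).
    features
        DataFrame with at least ``feature_id``; genomic columns ``chrom``,
        ``start``, ``end`` (0-based half-open) are required for ATAC peaks
        and for any gene-window arithmetic.
    cells
        DataFrame with at least ``cell_id`` and ``cell_type``.
    """

    counts: sp.spmatrix
    modality: str
    features: pd.DataFrame
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cells = self.cells.reset_index(drop=True)
        self.features = self.features.reset_index(drop=True)
        if self.modality not in ("RNA", "ATAC"):
            raise ValueError(f"unknown modality {self.modality!r}")
        n_cells, n_feat = self.counts.shape
        if len(self.cells) != n_cells:
            raise ValueError(
                f"cell metadata rows ({len(self.cells)}) != matrix rows ({n_cells})"
            )
        if len(self.features) != n_feat:
            raise ValueError(
                f"feature rows ({len(self.features)}) != matrix columns ({n_feat})"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts contain negative entries")
        if self.cells["cell_id"].duplicated().any():
            dup = self.cells["cell_id"][self.cells["cell_id"].duplicated()]
            raise ValueError(f"duplicate cell_ids: {sorted(set(dup))[:5]}")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, cell_ids) -> "FeatureMatrix":
        """Return a new matrix restricted to ``cell_ids`` (order preserved)."""
        wanted = set(cell_ids)
        mask = self.cells["cell_id"].isin(wanted).to_numpy()
        return FeatureMatrix(
            counts=self.counts[mask],
            modality=self.modality,
            features=self.features,
            cells=self.cells.loc[mask].reset_index(drop=True),
        )


@dataclass
class DosageMatrix:
    """Samples x variants dosage matrix; NaN marks a missing genotype.

    ``dosage[i, j]`` counts copies of variant j's ``a1`` allele carried by
    sample i (possibly fractional after imputation).
    """

    sample_ids: list = field(default_factory=list)
    variants: pd.DataFrame = None  # variant_id chrom pos a1 a2
    dosage: np.ndarray = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < -1e-6) | (self.dosage > 2 + 1e-6)
        if np.any(bad & ~np.isnan(self.dosage)):
            raise ValueError("dosages outside [0, 2]")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def eaf(self) -> np.ndarray:
        """In-sample frequency of the counted (a1) allele, ignoring missing."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def column(self, variant_id: str) -> np.ndarray:
        idx = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"variant {variant_id!r} not in dosage matrix")
        return self.dosage[:, idx[0]]
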