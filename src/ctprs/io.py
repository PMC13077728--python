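"""Readers and writers for the plain-text formats the pipeline exchanges.

Single-cell references travel as MatrixMarket counts plus feature/cell TSVs;
range sets as BED; summary statistics, weights, dosages and phenotypes as
whitespace/tab-delimited tables. VCF dosage reading (``DS`` FORMAT field,
``GT`` fallback) uses cyvcf2 when available.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .core import DosageMatrix, FeatureMatrix
from .regions import RangeSet
from .scoring import WEIGHT_COLUMNS


# ---------------------------------------------------------------- single-cell

def read_feature_matrix(
    mtx_path: str, features_path: str, cells_path: str, modality: str
) -> FeatureMatrix:
    """Assemble a FeatureMatrix from MTX counts + feature/cell TSVs.

    The MTX is cells x features; a features x cells file is transposed
    (disambiguated by the metadata row counts).
    """
    counts = sp.csr_matrix(scipy.io.mmread(mtx_path))
    features = pd.read_csv(features_path, sep="\t")
    cells = pd.read_csv(cells_path, sep="\t")
    if counts.shape == (len(features), len(cells)) and counts.shape[0] != counts.shape[1]:
        counts = counts.T.tocsr()
    return FeatureMatrix(counts=counts, modality=modality, features=features, cells=cells)


def write_feature_matrix(matrix: FeatureMatrix, out_dir: str, prefix: str = "ref") -> dict:
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "mtx": os.path.join(out_dir, f"{prefix}.counts.mtx"),
        "features": os.path.join(out_dir, f"{prefix}.features.tsv"),
        "cells": os.path.join(out_dir, f"{prefix}.cells.tsv"),
    }
    scipy.io.mmwrite(paths["mtx"], matrix.counts)
    matrix.features.to_csv(paths["features"], sep="\t", index=False)
    matrix.cells.to_csv(paths["cells"], sep="\t", index=False)
    return paths


# ----------------------------------------------------------------------- BED

def read_bed(path: str, label: str | None = None) -> RangeSet:
    ivs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            ivs.append((parts[0], int(parts[1]), int(parts[2])))
    return RangeSet.from_intervals(
        ivs, label=label or os.path.splitext(os.path.basename(path))[0]
    )


def write_bed(ranges: RangeSet, path: str) -> None:
    with open(path, "w") as fh:
        for iv in ranges.intervals:
            name = f"\t{ranges.label}" if ranges.label else ""
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}{name}\n")


# ----------------------------------------------------------- summary stats

def read_sumstats(path: str) -> pd.DataFrame:
    """Whitespace-delimited summary statistics; strict on required names."""
    df = pd.read_csv(path, sep=r"\s+")
    required = {"CHR", "POS", "ID", "A1", "A2", "BETA", "SE", "P"}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"summary statistics lack columns {sorted(missing)}")
    return df


def write_sumstats(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------- weights

def read_weights(path: str) -> pd.DataFrame:
    """Six-column whitespace-delimited weight table (shrinkage-tool layout).

    Accepts a header line naming the columns, or a headerless file in the
    order CHR, ID, POS, A1, A2, WEIGHT.
    """
    first = pd.read_csv(path, sep=r"\s+", nrows=1, header=None)
    has_header = any(str(v).upper() in WEIGHT_COLUMNS for v in first.iloc[0])
    if has_header:
        df = pd.read_csv(path, sep=r"\s+")
        df.columns = [c.upper() for c in df.columns]
    else:
        df = pd.read_csv(path, sep=r"\s+", header=None, names=WEIGHT_COLUMNS)
    missing = set(WEIGHT_COLUMNS) - set(df.columns)
    if missing:
        raise KeyError(f"weight table lacks columns {sorted(missing)}")
    return df[WEIGHT_COLUMNS]


def write_weights(df: pd.DataFrame, path: str) -> None:
    df[WEIGHT_COLUMNS].to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------- dosages

def read_dosages(path: str) -> DosageMatrix:
    """Dosage matrix from a VCF (DS field, GT fallback) or a TSV.

    The TSV layout is samples x variants with a ``sample_id`` first column;
    variant columns are named ``id@chrom:pos:a1:a2``.
    """
    if path.endswith((".vcf", ".vcf.gz")):
        return _read_dosages_vcf(path)
    df = pd.read_csv(path, sep="\t")
    sample_ids = df["sample_id"].tolist()
    var_rows, cols = [], []
    for c in df.columns:
        if c == "sample_id":
            continue
        vid, locus = c.split("@")
        chrom, pos, a1, a2 = locus.split(":")
        var_rows.append((vid, chrom, int(pos), a1, a2))
        cols.append(c)
    variants = pd.DataFrame(var_rows, columns=["variant_id", "chrom", "pos", "a1", "a2"])
    return DosageMatrix(
        sample_ids=sample_ids,
        variants=variants,
        dosage=df[cols].to_numpy(dtype=float),
    )


def _read_dosages_vcf(path: str) -> DosageMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    var_rows, dosage_cols = [], []
    for rec in vcf:
        alt = rec.ALT[0] if rec.ALT else "."
        var_rows.append(
            (rec.ID or f"{rec.CHROM}:{rec.POS}", rec.CHROM, rec.POS, alt, rec.REF)
        )
        ds = rec.format("DS")
        if ds is not None:
            col = np.asarray(ds, dtype=float).ravel()
        else:
            gt = np.asarray(rec.genotype.array())[:, :2]
            col = np.where((gt < 0).any(axis=1), np.nan, (gt > 0).sum(axis=1)).astype(float)
        dosage_cols.append(col)
    variants = pd.DataFrame(var_rows, columns=["variant_id", "chrom", "pos", "a1", "a2"])
    return DosageMatrix(
        sample_ids=sample_ids,
        variants=variants,
        dosage=np.column_stack(dosage_cols) if dosage_cols else np.empty((len(sample_ids), 0)),
    )


def write_dosages_tsv(dosages: DosageMatrix, path: str) -> None:
    cols = {
        f"{v.variant_id}@{v.chrom}:{v.pos}:{v.a1}:{v.a2}": dosages.dosage[:, i]
        for i, v in enumerate(dosages.variants.itertuples())
    }
    out = pd.DataFrame({"sample_id": dosages.sample_ids, **cols})
    out.to_csv(path, sep="\t", index=False)


# -------------------------------------------------------------- phenotypes

def read_phenotypes(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["", "NA"])


def write_phenotypes(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)
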