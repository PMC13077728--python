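"""Polygenic score computation from per-SNP weights and dosages.

The scorer consumes any per-SNP weight table (raw GWAS betas or shrunk
posterior effects — shrinkage itself is an upstream concern) and computes

    raw_score(s) = sum_j d(s, j) * w(j)

over the weighted variants falling inside a :class:`~ctprs.regions.RangeSet`
mask (or genome-wide when no mask is given). Scores are then standardized to
z-scores within the scored sample. Allele bookkeeping is explicit: when the
dosage matrix counts the non-effect allele, the dosage is re-expressed as
``2 - d``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import DosageMatrix
from .regions import RangeSet, snps_in_ranges

WEIGHT_COLUMNS = ["CHR", "ID", "POS", "A1", "A2", "WEIGHT"]


def harmonize_weights(weights: pd.DataFrame, dosages: DosageMatrix) -> pd.DataFrame:
    """Align a weight table onto the dosage matrix's variants and alleles.

    Variants are matched by id, falling back to (chrom, pos). The returned
    table has one row per matched variant with ``col`` (dosage column
    index), ``weight``, ``flip`` (True when the dosage counts the
    non-effect allele, i.e. the effective dosage is ``2 - d``), and the
    locus columns. Unmatched or allele-incompatible weights are dropped
    with a warning.
    """
    required = set(WEIGHT_COLUMNS)
    if not required <= set(weights.columns):
        raise KeyError(f"weight table lacks columns {sorted(required - set(weights.columns))}")
    by_id = {v: i for i, v in enumerate(dosages.variants["variant_id"])}
    by_locus = {
        (c, int(p)): i
        for i, (c, p) in enumerate(
            zip(dosages.variants["chrom"], dosages.variants["pos"])
        )
    }
    rows, unmatched, mismatched = [], 0, []
    for rec in weights.itertuples():
        col = by_id.get(rec.ID)
        if col is None:
            col = by_locus.get((str(rec.CHR), int(rec.POS)))
        if col is None:
            unmatched += 1
            continue
        v = dosages.variants.iloc[col]
        if rec.A1 == v["a1"] and rec.A2 == v["a2"]:
            flip = False
        elif rec.A1 == v["a2"] and rec.A2 == v["a1"]:
            flip = True
        else:
            mismatched.append(rec.ID)
            continue
        rows.append(
            {
                "variant_id": v["variant_id"],
                "chrom": v["chrom"],
                "pos": int(v["pos"]),
                "col": int(col),
                "weight": float(rec.WEIGHT),
                "flip": flip,
            }
        )
    if unmatched:
        warnings.warn(f"{unmatched} weights had no matching dosage variant", stacklevel=2)
    if mismatched:
        warnings.warn(
            f"{len(mismatched)} weights dropped for allele mismatch, "
            f"e.g. {mismatched[:5]}",
            stacklevel=2,
        )
    return pd.DataFrame(
        rows, columns=["variant_id", "chrom", "pos", "col", "weight", "flip"]
    )


def compute_prs(
    dosages: DosageMatrix,
    harmonized: pd.DataFrame,
    ranges: RangeSet | None = None,
    label: str = "genome",
) -> pd.DataFrame:
    """Raw polygenic scores restricted to a range mask (None = genome-wide).

    Missing dosages are mean-imputed per variant (2 x in-sample EAF).
    Returns a DataFrame with sample_id, raw_score, n_snps_used, label.
    """
    sub = harmonized
    if ranges is not None:
        inside = snps_in_ranges(sub[["variant_id", "chrom", "pos"]], ranges)
        sub = sub[sub["variant_id"].isin(inside)]
    if len(sub) == 0:
        raise ValueError(f"no weighted variants in range for label {label!r}")
    cols = sub["col"].to_numpy()
    w = sub["weight"].to_numpy(dtype=float)
    flip = sub["flip"].to_numpy(dtype=bool)
    D = dosages.dosage[:, cols]
    if np.isnan(D).any():
        eaf = np.nanmean(D, axis=0) / 2.0
        D = np.where(np.isnan(D), 2 * eaf, D)
    D = np.where(flip, 2.0 - D, D)
    raw = D @ w
    return pd.DataFrame(
        {
            "sample_id": dosages.sample_ids,
            "raw_score": raw,
            "n_snps_used": len(sub),
            "label": label,
        }
    )


def standardize(profiles: pd.DataFrame) -> pd.DataFrame:
    """Add z-scores: (raw - mean) / sample SD (n-1 denominator), per label."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 samples to standardize")
    out = profiles.copy().reset_index(drop=True)
    zs = np.empty(len(out))
    for _, idx in out.groupby("label", observed=True).groups.items():
        raw = out.loc[idx, "raw_score"].to_numpy(dtype=float)
        sd = raw.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(
                f"degenerate score distribution for label "
                f"{out.loc[idx, 'label'].iloc[0]!r} (SD = 0)"
            )
        zs[out.index.get_indexer(idx)] = (raw - raw.mean()) / sd
    out["z_score"] = zs
    return out


def score_correlation_matrix(
    profiles_by_label: dict,
    genome_label: str | None = None,
    pairs: list | None = None,
) -> tuple:
    """Pairwise Pearson r between standardized score vectors, plus averages.

    Returns (r matrix as DataFrame, summary dict). The summary's
    ``mean_offdiag`` averages the upper off-diagonal entries, excluding any
    row/column named ``genome_label`` (the genome-wide score does not count
    toward cell-type averages). ``pairs`` adds named entries for specific
    label pairs (e.g. the excitatory/inhibitory neuron pair).
    """
    labels = list(profiles_by_label)
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    lengths = {len(np.asarray(v)) for v in profiles_by_label.values()}
    if len(lengths) != 1:
        raise ValueError(f"score vectors differ in length: {sorted(lengths)}")
    (n,) = lengths
    if n < 3:
        raise ValueError("need at least 3 samples for correlations")
    mat = np.corrcoef(np.vstack([np.asarray(profiles_by_label[l], float) for l in labels]))
    r = pd.DataFrame(mat, index=labels, columns=labels)
    ct_labels = [l for l in labels if l != genome_label]
    sub = r.loc[ct_labels, ct_labels].to_numpy()
    iu = np.triu_indices(len(ct_labels), k=1)
    summary = {"mean_offdiag": float(sub[iu].mean()) if len(iu[0]) else np.nan}
    for a, b in pairs or []:
        summary[f"r_{a}_{b}"] = float(r.loc[a, b])
    return r, summary
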