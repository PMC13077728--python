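"""Cell-type and subtype feature specificity from single-nucleus references.

The pipeline mirrors how cell-type-specific gene and peak sets are derived
from control-donor brain tissue:

1. :func:`select_control_cells` — keep nuclei from neuropathologically
   normal donors (and, for ATAC, nuclei with TSS enrichment > 1);
2. :func:`filter_expressed_features` — keep genes detected in >= 10 % of
   cells of at least one cell type;
3. :func:`normalize_rna` (counts per 10k) or :func:`tfidf_transform`
   (log TF-IDF, the standard LSI form for peak matrices);
4. :func:`mean_activity_by_type` — pseudobulk mean per cell type (E_gc for
   genes, A_pc for peaks);
5. :func:`specificity_scores` — S_gc = E_gc / sum_c' E_gc', a per-feature
   distribution over cell types;
6. :func:`select_top_fraction` — the top-q most specific features per type
   (q = 0.10 for primary types);
7. :func:`hierarchical_subtype_selection` — two-stage selection for neuron
   subtypes (top 20 % parent-specific peaks, then top 20 % subtype-specific
   among those).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import FeatureMatrix

#: Neuritic-plaque labels counted as control-compatible.
CONTROL_PLAQUE_LEVELS = ("none", "possible")


@dataclass
class ControlCriteria:
    """Toggleable conjunction of control-cell predicates.

    RNA references use the donor-level pathology/cognition predicates;
    ATAC references use the pathological-control flag plus a strict
    TSS-enrichment cutoff. Each predicate is active iff its threshold is
    not None.
    """

    max_braak: int | None = 2
    plaque_levels: tuple | None = CONTROL_PLAQUE_LEVELS
    cognitive_status: tuple | None = ("NCI",)
    min_mmse: float | None = 23.0  # strict: mmse > 23
    require_control_flag: bool = False
    min_tss_enrichment: float | None = None  # strict: tss > threshold

    @classmethod
    def rna_default(cls) -> "ControlCriteria":
        return cls()

    @classmethod
    def atac_default(cls) -> "ControlCriteria":
        return cls(
            max_braak=None,
            plaque_levels=None,
            cognitive_status=None,
            min_mmse=None,
            require_control_flag=True,
            min_tss_enrichment=1.0,
        )

    def required_columns(self) -> list:
        cols = []
        if self.max_braak is not None:
            cols.append("braak")
        if self.plaque_levels is not None:
            cols.append("neuritic_plaque_status")
        if self.cognitive_status is not None:
            cols.append("cognitive_status")
        if self.min_mmse is not None:
            cols.append("mmse")
        if self.require_control_flag:
            cols.append("control_flag")
        if self.min_tss_enrichment is not None:
            cols.append("tss_enrichment")
        return cols


def select_control_cells(
    cells: pd.DataFrame,
    criteria: ControlCriteria,
    known_types: tuple | None = None,
) -> set:
    """Return cell_ids satisfying every active control predicate.

    Raises if any referenced field is missing/NaN, if a cell carries an
    unknown cell-type label, or if no cell survives.
    """
    for col in criteria.required_columns():
        if col not in cells.columns:
            raise KeyError(f"criteria require column {col!r}, absent from cells")
        if cells[col].isna().any():
            bad = cells.loc[cells[col].isna(), "cell_id"].tolist()[:5]
            raise ValueError(f"column {col!r} missing for cells {bad}")
    if known_types is not None:
        unknown = set(cells["cell_type"]) - set(known_types)
        if unknown:
            raise ValueError(f"unknown cell_type labels: {sorted(unknown)}")

    mask = np.ones(len(cells), dtype=bool)
    if criteria.max_braak is not None:
        mask &= (cells["braak"] <= criteria.max_braak).to_numpy()
    if criteria.plaque_levels is not None:
        mask &= cells["neuritic_plaque_status"].isin(criteria.plaque_levels).to_numpy()
    if criteria.cognitive_status is not None:
        mask &= cells["cognitive_status"].isin(criteria.cognitive_status).to_numpy()
    if criteria.min_mmse is not None:
        mask &= (cells["mmse"] > criteria.min_mmse).to_numpy()
    if criteria.require_control_flag:
        mask &= cells["control_flag"].astype(bool).to_numpy()
    if criteria.min_tss_enrichment is not None:
        mask &= (cells["tss_enrichment"] > criteria.min_tss_enrichment).to_numpy()

    if not mask.any():
        raise ValueError("no control cells satisfy the criteria")
    return set(cells.loc[mask, "cell_id"])


def filter_expressed_features(matrix: FeatureMatrix, min_frac: float = 0.10) -> list:
    """Features detected (count > 0) in >= ``min_frac`` of cells of >= 1 type.

    Input order is preserved. The matrix should already be restricted to
    control cells.
    """
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must be in (0, 1]")
    types = matrix.cells["cell_type"]
    counts = sp.csr_matrix(matrix.counts)
    keep = np.zeros(matrix.n_features, dtype=bool)
    for ct, idx in types.groupby(types, observed=True).groups.items():
        rows = np.fromiter(idx, dtype=int)
        if len(rows) == 0:
            raise ValueError(f"cell type {ct!r} has zero cells")
        frac = counts[rows].getnnz(axis=0) / len(rows)
        keep |= frac >= min_frac
    return matrix.features.loc[keep, "feature_id"].tolist()


def normalize_rna(matrix: FeatureMatrix, scale: float = 1e4) -> sp.csr_matrix:
    """Counts-per-``scale`` normalization: each cell's values sum to scale.

    No log transform is applied: specificity is a ratio of per-type means,
    which a per-cell proportional rescaling leaves meaningful while a log
    would distort.
    """
    counts = sp.csr_matrix(matrix.counts, dtype=float)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    zero = totals == 0
    if zero.any():
        bad = matrix.cells.loc[zero, "cell_id"].tolist()[:10]
        raise ValueError(f"all-zero cells cannot be normalized: {bad}")
    return sp.diags(scale / totals) @ counts


def tfidf_transform(matrix: FeatureMatrix, scale: float = 1e4) -> sp.csr_matrix:
    """log(1 + scale * TF * IDF), the standard LSI transform for peak counts.

    TF(i,j) is peak j's share of cell i's total counts; IDF(j) = n_cells /
    n_cells carrying peak j. Peaks absent from every cell get IDF 0 by
    convention (an all-zero column stays all-zero).
    """
    if matrix.modality != "ATAC":
        raise ValueError("tfidf_transform expects an ATAC matrix")
    counts = sp.csr_matrix(matrix.counts, dtype=float)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    zero = totals == 0
    if zero.any():
        bad = matrix.cells.loc[zero, "cell_id"].tolist()[:10]
        raise ValueError(f"all-zero cells cannot be transformed: {bad}")
    df = counts.getnnz(axis=0).astype(float)
    idf = np.zeros_like(df)
    nonzero = df > 0
    idf[nonzero] = matrix.n_cells / df[nonzero]
    tf = sp.diags(1.0 / totals) @ counts
    out = (tf @ sp.diags(idf)).tocsr()
    out.data = np.log1p(scale * out.data)
    return out


def mean_activity_by_type(
    values: sp.spmatrix,
    cells: pd.DataFrame,
    feature_ids,
    group_by: str = "cell_type",
    clip_negative: bool = False,
) -> pd.DataFrame:
    """Arithmetic pseudobulk mean per group: features x groups DataFrame.

    ``clip_negative`` floors inputs at 0 before averaging (used for ATAC
    activity so A_pc, hence S_pc, stays nonnegative).
    """
    values = sp.csr_matrix(values)
    groups = cells[group_by]
    if groups.isna().any():
        groups = groups.dropna()
    if clip_negative and values.nnz:
        values = values.copy()
        values.data = np.maximum(values.data, 0.0)
    cols = {}
    for g, idx in groups.groupby(groups, observed=True).groups.items():
        rows = np.fromiter(idx, dtype=int)
        if len(rows) == 0:
            raise ValueError(f"group {g!r} is empty")
        cols[g] = np.asarray(values[rows].mean(axis=0)).ravel()
    out = pd.DataFrame(cols, index=pd.Index(feature_ids, name="feature_id"))
    return out[sorted(out.columns)]


def specificity_scores(means: pd.DataFrame) -> pd.DataFrame:
    """Long-format specificity table from a features x groups mean table.

    specificity(g, c) = means(g, c) / sum_c' means(g, c'). Features whose
    means sum to 0 get specificity 0 everywhere and ``zero_sum=True``.
    Within each group, ``rank_within_type`` orders by descending
    specificity, then descending mean, then feature_id (deterministic).
    """
    if (means.to_numpy() < 0).any():
        raise ValueError("means must be nonnegative")
    totals = means.sum(axis=1)
    zero = totals == 0
    spec = means.div(totals.where(~zero, 1.0), axis=0)
    spec[zero] = 0.0

    long = (
        spec.reset_index()
        .melt(id_vars="feature_id", var_name="cell_type", value_name="specificity")
        .merge(
            means.reset_index().melt(
                id_vars="feature_id", var_name="cell_type", value_name="mean_activity"
            ),
            on=["feature_id", "cell_type"],
        )
    )
    long["zero_sum"] = long["feature_id"].map(zero)
    long = long.sort_values(
        ["cell_type", "specificity", "mean_activity", "feature_id"],
        ascending=[True, False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    long["rank_within_type"] = long.groupby("cell_type", observed=True).cumcount() + 1
    long["selected"] = False
    return long[
        [
            "feature_id",
            "cell_type",
            "mean_activity",
            "specificity",
            "rank_within_type",
            "selected",
            "zero_sum",
        ]
    ]


def select_top_fraction(
    spec: pd.DataFrame, q: float, universe: list | None = None
) -> dict:
    """Top floor(q * |universe|) most specific features per cell type.

    Selection is independent per type, so per-type sets may overlap.
    Zero-sum features carry no signal and are never selected.
    """
    if not (0 < q <= 1):
        raise ValueError("q must be in (0, 1]")
    if universe is None:
        universe = spec["feature_id"].unique().tolist()
    universe = list(universe)
    n_sel = int(np.floor(q * len(universe)))
    if n_sel < 1:
        raise ValueError(
            f"q * |universe| = {q * len(universe):.3g} < 1: nothing to select"
        )
    in_universe = spec["feature_id"].isin(set(universe))
    eligible = spec[in_universe & ~spec["zero_sum"]]
    out = {}
    for ct, grp in eligible.groupby("cell_type", observed=True):
        ranked = grp.sort_values("rank_within_type", kind="mergesort")
        chosen = ranked["feature_id"].head(n_sel)
        if len(chosen) < n_sel:
            warnings.warn(
                f"{ct}: only {len(chosen)} non-degenerate features available "
                f"(wanted {n_sel})",
                stacklevel=2,
            )
        out[ct] = set(chosen)
    return out


def mark_selected(spec: pd.DataFrame, selected: dict) -> pd.DataFrame:
    """Fill the ``selected`` column from a per-type selection map."""
    spec = spec.copy()
    spec["selected"] = [
        fid in selected.get(ct, ())
        for fid, ct in zip(spec["feature_id"], spec["cell_type"])
    ]
    return spec


def hierarchical_subtype_selection(
    primary_spec: pd.DataFrame,
    parent_type: str,
    subtype_means: pd.DataFrame,
    q_parent: float = 0.20,
    q_subtype: float = 0.20,
) -> dict:
    """Two-stage neuron-subtype peak selection.

    Stage 1 takes the top ``q_parent`` fraction of the full universe by
    parent-type specificity; stage 2 recomputes specificity among the
    subtypes only (denominator = sum over subtype means), restricted to the
    stage-1 peaks, and takes the top ``q_subtype`` fraction of that subset
    per subtype.
    """
    if parent_type not in set(primary_spec["cell_type"]):
        raise ValueError(f"parent type {parent_type!r} not in specificity table")
    universe = primary_spec["feature_id"].unique().tolist()
    parent_sets = select_top_fraction(primary_spec, q_parent, universe)
    step1 = parent_sets[parent_type]
    if len(step1) < 1:
        raise ValueError("no features survive the parent-type stage")

    sub_means = subtype_means.loc[sorted(step1)]
    sub_spec = specificity_scores(sub_means)
    out = select_top_fraction(sub_spec, q_subtype, sorted(step1))
    if any(len(s) < 1 for s in out.values()):
        raise ValueError("a subtype ended with zero selected features")
    return out


def specificity_pipeline(
    matrix: FeatureMatrix,
    criteria: ControlCriteria | None = None,
    q: float = 0.10,
    min_frac: float = 0.10,
    group_by: str = "cell_type",
) -> tuple:
    """Run stages 1-6 end to end; returns (specificity table, selected map).

    For RNA: control filter -> expression filter -> counts-per-10k ->
    pseudobulk means -> specificity -> top-q. For ATAC the expression filter
    is skipped and TF-IDF replaces the count normalization.
    """
    if criteria is None:
        criteria = (
            ControlCriteria.rna_default()
            if matrix.modality == "RNA"
            else ControlCriteria.atac_default()
        )
    ctrl = select_control_cells(matrix.cells, criteria)
    sub = matrix.subset_cells(ctrl)
    if matrix.modality == "RNA":
        universe = filter_expressed_features(sub, min_frac=min_frac)
        keep = sub.features["feature_id"].isin(set(universe)).to_numpy()
        sub = FeatureMatrix(
            counts=sub.counts[:, keep],
            modality=sub.modality,
            features=sub.features.loc[keep].reset_index(drop=True),
            cells=sub.cells,
        )
        values = normalize_rna(sub)
        clip = False
    else:
        universe = sub.features["feature_id"].tolist()
        values = tfidf_transform(sub)
        clip = True
    means = mean_activity_by_type(
        values, sub.cells, sub.features["feature_id"], group_by=group_by,
        clip_negative=clip,
    )
    spec = specificity_scores(means)
    selected = select_top_fraction(spec, q, universe)
    return mark_selected(spec, selected), selected
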