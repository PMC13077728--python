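"""Synthetic inputs with planted ground truth for every pipeline stage.

Everything runs on a toy genome (two 10 Mb chromosomes) small enough for
brute-force interval oracles. The generators emulate the statistical shape
of the real inputs — negative-binomial single-cell counts with planted
cell-type markers, binomial genotype dosages, liability-threshold binary
outcomes with a controlled heritability — while recording exactly what was
planted in a :class:`TruthManifest` so recovery can be asserted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .core import DosageMatrix, FeatureMatrix, PRIMARY_CELL_TYPES
from .regions import RangeSet, gene_windows
from .sc_reference import specificity_pipeline
from .sumstats import cohort_association, inverse_variance_meta

#: Toy genome used by all generators.
CHROM_SIZES = {"chr1": 10_000_000, "chr2": 10_000_000}

GENE_WIDTH = 10_000
PEAK_WIDTH = 500

BATTERY_OUTCOMES = (
    "mmse",
    "tangle_density",
    "nft_burden",
    "abeta_burden",
    "diffuse_plaque",
    "neuritic_plaque",
)


@dataclass
class TruthManifest:
    """What was planted: markers per type, causal variants, parameters."""

    marker_map: dict = field(default_factory=dict)
    causal_map: dict = field(default_factory=dict)  # type -> {variant_id: effect}
    h2_target: float = 0.0
    seeds: list = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        return cls(**json.loads(text))


def _feature_layout(n_features: int, width: int) -> pd.DataFrame:
    """Evenly spaced feature spans across the toy genome.

    The stride is the genome length divided by the feature count, so window
    overlap between neighbouring features is controlled by n_features.
    """
    total = sum(CHROM_SIZES.values())
    stride = total // n_features
    if stride < 2:
        raise ValueError(f"{n_features} features do not fit the toy genome")
    # Full-width spans when space allows; shrink on dense layouts.
    width = min(width, stride - 1)
    rows = []
    i = 0
    for chrom, size in CHROM_SIZES.items():
        cap = size // stride
        local = 0
        while i < n_features and local < cap:
            start = local * stride
            rows.append((f"feat{i:05d}", chrom, start, start + width, "+"))
            i += 1
            local += 1
    if i < n_features:
        raise ValueError("feature layout overflow")
    return pd.DataFrame(
        rows, columns=["feature_id", "chrom", "start", "end", "strand"]
    )


def simulate_reference(
    n_types: int = 7,
    n_cells_per_type: int = 50,
    n_features: int = 2000,
    n_markers_per_type: int = 50,
    fold: float = 4.0,
    modality: str = "RNA",
    seed: int = 0,
    background_mean: float = 0.2,
    dispersion: float = 0.5,
    type_labels: tuple | None = None,
    n_donors: int = 12,
    subtype_parent: str | None = None,
    n_subtypes: int = 4,
    n_markers_per_subtype: int = 0,
) -> tuple:
    """Single-cell count matrix with markers planted per cell type.

    Background counts are negative-binomial (mean ``background_mean``,
    dispersion ``dispersion`` so var = m + dispersion * m^2); each type's
    markers have their mean multiplied by ``fold`` in that type only.
    When ``subtype_parent`` is set, cells of that type are split across
    ``n_subtypes`` subtypes and each subtype gets ``n_markers_per_subtype``
    extra markers elevated fold-fold within the parent and a further fold
    within the subtype. Returns (FeatureMatrix, TruthManifest).
    """
    if fold < 1:
        raise ValueError("fold must be >= 1 (1 = null case, no planted signal)")
    labels = list(type_labels or PRIMARY_CELL_TYPES[:n_types])
    if len(labels) != n_types:
        raise ValueError("type_labels length != n_types")
    n_sub_markers = (
        n_subtypes * n_markers_per_subtype if subtype_parent else 0
    )
    n_marked = n_markers_per_type * n_types + n_sub_markers
    if n_marked > n_features:
        raise ValueError("more planted markers than features")
    rng = np.random.default_rng(seed)

    features = _feature_layout(
        n_features, GENE_WIDTH if modality == "RNA" else PEAK_WIDTH
    )
    marked_idx = rng.choice(n_features, size=n_marked, replace=False)
    marker_map: dict = {}
    cursor = 0
    for lab in labels:
        ids = marked_idx[cursor : cursor + n_markers_per_type]
        marker_map[lab] = features.loc[ids, "feature_id"].tolist()
        cursor += n_markers_per_type
    subtype_labels = []
    if subtype_parent:
        if subtype_parent not in labels:
            raise ValueError(f"subtype parent {subtype_parent!r} not a cell type")
        for k in range(n_subtypes):
            sub = f"{subtype_parent}_S{k}"
            subtype_labels.append(sub)
            ids = marked_idx[cursor : cursor + n_markers_per_subtype]
            marker_map[sub] = features.loc[ids, "feature_id"].tolist()
            cursor += n_markers_per_subtype

    fid_to_col = {f: i for i, f in enumerate(features["feature_id"])}
    n_cells = n_types * n_cells_per_type
    counts = np.zeros((n_cells, n_features), dtype=np.int64)
    cell_rows = []
    r = 1.0 / dispersion  # NB "size" parameter
    row = 0
    for t, lab in enumerate(labels):
        mu = np.full(n_features, background_mean)
        for mk in marker_map[lab]:
            mu[fid_to_col[mk]] *= fold
        for c in range(n_cells_per_type):
            cell_mu = mu
            subtype = None
            if subtype_parent == lab:
                subtype = subtype_labels[c % n_subtypes]
                cell_mu = mu.copy()
                for sub in subtype_labels:
                    boost = fold * fold if sub == subtype else fold
                    for mk in marker_map[sub]:
                        cell_mu[fid_to_col[mk]] *= boost
            p = r / (r + cell_mu)
            counts[row] = rng.negative_binomial(r, p)
            if counts[row].sum() == 0:  # keep every cell normalizable
                counts[row, rng.integers(n_features)] = 1
            cell_rows.append(
                {
                    "cell_id": f"cell{row:05d}",
                    "donor_id": f"donor{row % n_donors:02d}",
                    "cell_type": lab,
                    "subtype": subtype,
                    "tss_enrichment": 2.0,
                    "braak": 1,
                    "neuritic_plaque_status": "none",
                    "mmse": 28.0,
                    "cognitive_status": "NCI",
                    "control_flag": True,
                }
            )
            row += 1

    matrix = FeatureMatrix(
        counts=sp.csr_matrix(counts),
        modality=modality,
        features=features,
        cells=pd.DataFrame(cell_rows),
    )
    manifest = TruthManifest(
        marker_map=marker_map,
        seeds=[seed],
        params={
            "n_types": n_types,
            "n_cells_per_type": n_cells_per_type,
            "n_features": n_features,
            "n_markers_per_type": n_markers_per_type,
            "fold": fold,
            "modality": modality,
            "background_mean": background_mean,
            "dispersion": dispersion,
            "subtype_parent": subtype_parent,
            "n_markers_per_subtype": n_markers_per_subtype,
        },
    )
    return matrix, manifest


def simulate_genotypes(
    n_samples: int,
    n_variants: int | None = None,
    seed: int = 0,
    maf_range: tuple = (0.05, 0.5),
    positions: pd.DataFrame | None = None,
    mafs: np.ndarray | None = None,
    sample_prefix: str = "S",
) -> DosageMatrix:
    """Independent binomial dosages on the toy genome.

    Per-variant MAF ~ Uniform(maf_range) unless given; dosages are
    Binomial(2, MAF) independently per variant (no LD). ``positions`` may
    fix the variant loci (columns chrom, pos); otherwise loci are placed
    uniformly at random.
    """
    rng = np.random.default_rng(seed)
    if positions is None:
        if n_variants is None:
            raise ValueError("need n_variants or positions")
        chroms = rng.choice(list(CHROM_SIZES), size=n_variants)
        pos = np.array(
            [rng.integers(1, CHROM_SIZES[c] + 1) for c in chroms], dtype=np.int64
        )
        positions = pd.DataFrame({"chrom": chroms, "pos": pos})
    positions = positions.sort_values(["chrom", "pos"]).reset_index(drop=True)
    n_variants = len(positions)
    if mafs is None:
        mafs = rng.uniform(*maf_range, size=n_variants)
    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{i:06d}" for i in range(n_variants)]
            if "variant_id" not in positions.columns
            else positions["variant_id"],
            "chrom": positions["chrom"],
            "pos": positions["pos"].astype(int),
            "a1": "A",
            "a2": "G",
        }
    )
    dosage = rng.binomial(2, mafs, size=(n_samples, n_variants)).astype(float)
    return DosageMatrix(
        sample_ids=[f"{sample_prefix}{i:05d}" for i in range(n_samples)],
        variants=variants,
        dosage=dosage,
    )


def simulate_phenotypes(
    dosages: DosageMatrix,
    causal_effects: dict,
    h2: float,
    seed: int = 0,
    prevalence: float = 0.35,
    outcome_names: tuple = BATTERY_OUTCOMES,
) -> pd.DataFrame:
    """Outcome battery with genetic value G = sum(effect x dosage).

    Continuous outcomes are G plus Gaussian noise scaled so that
    var(G)/var(outcome) = ``h2``; the binary diagnosis uses a liability
    threshold at the given prevalence. Covariates (age, sex, five PCs,
    APOE dosages, education) are generated independently of G.
    """
    if not (0 < h2 < 1):
        raise ValueError("h2 must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = dosages.n_samples
    ids = list(dosages.variants["variant_id"])
    missing = set(causal_effects) - set(ids)
    if missing:
        raise KeyError(f"causal variants absent from dosages: {sorted(missing)[:5]}")
    col = {v: i for i, v in enumerate(ids)}
    G = np.zeros(n)
    for v, eff in causal_effects.items():
        G += eff * np.nan_to_num(dosages.dosage[:, col[v]])
    var_g = G.var()
    if var_g == 0:
        raise ValueError("h2 unreachable: planted effects give var(G) = 0")
    noise_sd = np.sqrt(var_g * (1 - h2) / h2)

    out = pd.DataFrame({"sample_id": dosages.sample_ids})
    for name in outcome_names:
        out[name] = G + rng.normal(0, noise_sd, size=n)
    liability = G + rng.normal(0, noise_sd, size=n)
    thr = liability.mean() + liability.std() * scipy.stats.norm.ppf(1 - prevalence)
    out["ad_pathdx"] = (liability > thr).astype(int)

    out["age_at_death"] = rng.normal(87, 5, size=n)
    out["sex"] = rng.binomial(1, 0.6, size=n)
    for k in range(1, 6):
        out[f"pc{k}"] = rng.normal(0, 1, size=n)
    e4 = rng.binomial(2, 0.2, size=n)
    e2 = np.minimum(rng.binomial(2, 0.08, size=n), 2 - e4)
    out["apoe_e4_dosage"] = e4
    out["apoe_e2_dosage"] = e2
    out["education_years"] = rng.normal(16, 2, size=n)
    return out


def simulate_cohort_sumstats(
    n_cohorts: int,
    n_per_cohort: int,
    causal_effects: dict,
    variants: pd.DataFrame | None = None,
    n_variants: int = 100,
    h2: float = 0.3,
    prevalence: float = 0.35,
    seed: int = 0,
) -> tuple:
    """Per-cohort logistic GWAS tables plus their fixed-effects meta-analysis.

    Every cohort draws independent genotypes at a shared set of loci (and
    shared MAFs) from the same causal architecture; the per-cohort tables
    come from :func:`ctprs.sumstats.cohort_association` and the combined
    table from :func:`ctprs.sumstats.inverse_variance_meta`.
    """
    if n_cohorts < 1:
        raise ValueError("n_cohorts must be >= 1")
    rng = np.random.default_rng(seed)
    template = simulate_genotypes(
        2, n_variants=n_variants if variants is None else None,
        positions=variants, seed=int(rng.integers(2**31)),
    )
    mafs = np.random.default_rng(seed + 1).uniform(0.05, 0.5, template.n_variants)
    tables = []
    for k in range(n_cohorts):
        geno = simulate_genotypes(
            n_per_cohort,
            positions=template.variants[["variant_id", "chrom", "pos"]],
            mafs=mafs,
            seed=int(rng.integers(2**31)),
            sample_prefix=f"C{k}_",
        )
        ph = simulate_phenotypes(
            geno, causal_effects, h2=h2, prevalence=prevalence,
            seed=int(rng.integers(2**31)),
        )
        covs = ph[["age_at_death", "sex", "pc1", "pc2", "pc3", "pc4", "pc5"]]
        tables.append(cohort_association(geno, ph["ad_pathdx"].to_numpy(), covs))
    meta = inverse_variance_meta(tables)
    return tables, meta


def simulate_study(
    causal_type: str = "AST",
    seed: int = 0,
    n_types: int = 7,
    n_cells_per_type: int = 40,
    n_features: int = 280,
    n_markers_per_type: int = 20,
    fold: float = 4.0,
    n_variants_per_type: int = 10,
    n_background_variants: int = 60,
    n_samples: int = 2000,
    h2: float = 0.3,
    flank_bp: int = 30_000,
    q: float = 0.10,
    effect_sd: float = 1.0,
) -> dict:
    """End-to-end scenario: reference -> ranges -> genotypes -> phenotypes.

    Plants ``n_variants_per_type`` variants inside each cell type's marker
    gene bodies (so they land in that type's windows once the markers are
    selected) plus background variants at random loci; causal effects are
    attached only to the ``causal_type`` variants. The gene stride for the
    default 280 features keeps 30 kb windows of distinct genes disjoint, so
    each type's range set is private to its markers.
    """
    rng = np.random.default_rng(seed)
    reference, manifest = simulate_reference(
        n_types=n_types,
        n_cells_per_type=n_cells_per_type,
        n_features=n_features,
        n_markers_per_type=n_markers_per_type,
        fold=fold,
        seed=int(rng.integers(2**31)),
    )
    spec_table, selected = specificity_pipeline(reference, q=q)
    ann = reference.features.set_index("feature_id")
    ranges = {}
    for ct, feats in selected.items():
        genes = ann.loc[sorted(feats)].reset_index()
        ranges[ct] = gene_windows(genes, flank_bp=flank_bp, label=ct)

    # Variants planted inside each type's marker gene bodies.
    pos_rows = []
    planted: dict = {}
    for ct in selected:
        markers = manifest.marker_map[ct]
        planted[ct] = []
        for _ in range(n_variants_per_type):
            g = ann.loc[markers[int(rng.integers(len(markers)))]]
            pos = int(rng.integers(g["start"] + 1, g["end"] + 1))  # 1-based in-body
            pos_rows.append((g["chrom"], pos, ct))
    for _ in range(n_background_variants):
        chrom = list(CHROM_SIZES)[int(rng.integers(len(CHROM_SIZES)))]
        pos_rows.append((chrom, int(rng.integers(1, CHROM_SIZES[chrom] + 1)), None))
    positions = pd.DataFrame(
        [(c, p) for c, p, _ in pos_rows], columns=["chrom", "pos"]
    ).drop_duplicates()
    dosages = simulate_genotypes(
        n_samples, positions=positions, seed=int(rng.integers(2**31))
    )
    # Recover which planted variant ids belong to which type (by locus).
    locus_to_id = {
        (c, int(p)): vid
        for vid, c, p in zip(
            dosages.variants["variant_id"],
            dosages.variants["chrom"],
            dosages.variants["pos"],
        )
    }
    for c, p, ct in pos_rows:
        if ct is not None and (c, p) in locus_to_id:
            planted[ct].append(locus_to_id[(c, p)])

    causal = {
        vid: float(rng.normal(0, effect_sd))
        for vid in dict.fromkeys(planted[causal_type])
    }
    phenos = simulate_phenotypes(
        dosages, causal, h2=h2, seed=int(rng.integers(2**31))
    )
    manifest.causal_map = {causal_type: causal}
    manifest.h2_target = h2
    manifest.params.update(
        {
            "causal_type": causal_type,
            "n_variants_per_type": n_variants_per_type,
            "n_background_variants": n_background_variants,
            "n_samples": n_samples,
            "flank_bp": flank_bp,
            "q": q,
        }
    )
    return {
        "reference": reference,
        "manifest": manifest,
        "spec_table": spec_table,
        "selected": selected,
        "ranges": ranges,
        "dosages": dosages,
        "phenos": phenos,
        "planted_variants": planted,
    }


def discovery_weights(
    variants: pd.DataFrame,
    causal_effects: dict,
    n_samples: int = 2000,
    h2: float = 0.3,
    prevalence: float = 0.35,
    seed: int = 0,
) -> pd.DataFrame:
    """Raw-beta weight table from one simulated discovery-cohort GWAS.

    Draws an independent cohort at the given loci, runs the logistic
    per-variant association, and returns the estimated betas in the
    six-column weight-table layout consumed by the scorer.
    """
    rng = np.random.default_rng(seed)
    geno = simulate_genotypes(
        n_samples,
        positions=variants[["variant_id", "chrom", "pos"]],
        seed=int(rng.integers(2**31)),
        sample_prefix="D",
    )
    ph = simulate_phenotypes(
        geno, causal_effects, h2=h2, prevalence=prevalence,
        seed=int(rng.integers(2**31)),
    )
    covs = ph[["age_at_death", "sex", "pc1", "pc2", "pc3", "pc4", "pc5"]]
    gwas = cohort_association(geno, ph["ad_pathdx"].to_numpy(), covs)
    return gwas.rename(columns={"BETA": "WEIGHT"})[
        ["CHR", "ID", "POS", "A1", "A2", "WEIGHT"]
    ]
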