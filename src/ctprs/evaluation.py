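"""Self-validation routines: planted-truth recovery and null calibration.

These compose the public pipeline stages into the replicated experiments
used to demonstrate that the toolkit recovers what the generators plant
(markers into top-fraction sets, causal cell types into the association
battery) and that its null statistics are calibrated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assoc import fit_outcome_model, per_snp_association
from .sc_reference import specificity_pipeline
from .scoring import compute_prs, harmonize_weights, standardize
from .sumstats import cohort_association
from .synthdata import (
    discovery_weights,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_reference,
    simulate_study,
)


def marker_recovery_rate(seed: int, fold: float = 4.0, q: float = 0.10, **kwargs) -> float:
    """Fraction of planted markers landing in their own type's top-q set."""
    matrix, manifest = simulate_reference(fold=fold, seed=seed, **kwargs)
    _, selected = specificity_pipeline(matrix, q=q)
    hits = sum(
        len(set(manifest.marker_map[ct]) & selected[ct]) for ct in selected
    )
    planted = sum(len(manifest.marker_map[ct]) for ct in selected)
    return hits / planted


def battery_replicate(
    seed: int,
    causal_type: str = "AST",
    outcome: str = "tangle_density",
    n_samples: int = 2000,
    h2: float = 0.3,
    exclude: tuple = ("END",),
) -> dict:
    """One full-pipeline replicate; returns association p per cell-type label.

    Generates a study (reference, ranges, target cohort), estimates raw-beta
    weights from an independent discovery cohort, scores the target cohort
    per cell-type mask, standardizes, and fits the outcome model for each of
    the primary labels (endothelial excluded by default, matching its low
    representation in brain single-nucleus data).
    """
    study = simulate_study(
        causal_type=causal_type, seed=seed, n_samples=n_samples, h2=h2
    )
    weights = discovery_weights(
        study["dosages"].variants,
        study["manifest"].causal_map[causal_type],
        n_samples=n_samples,
        h2=h2,
        seed=seed + 10_000,
    )
    harmonized = harmonize_weights(weights, study["dosages"])
    labels = [ct for ct in study["ranges"] if ct not in exclude]
    profiles = pd.concat(
        [
            compute_prs(study["dosages"], harmonized, study["ranges"][ct], label=ct)
            for ct in labels
        ],
        ignore_index=True,
    )
    z = standardize(profiles)
    pvals = {}
    for ct in labels:
        zz = (
            z[z["label"] == ct]
            .sort_values("sample_id")["z_score"]
            .to_numpy()
        )
        rec = fit_outcome_model(zz, study["phenos"], outcome, predictor_name=ct)
        pvals[ct] = rec.p
    return pvals


def battery_win_rate(
    n_replicates: int, base_seed: int, causal_type: str = "AST", **kwargs
) -> float:
    """Share of replicates where the causal type has the smallest p."""
    wins = 0
    for rep in range(n_replicates):
        pvals = battery_replicate(base_seed + rep, causal_type=causal_type, **kwargs)
        wins += min(pvals, key=pvals.get) == causal_type
    return wins / n_replicates


def null_snp_pvalues(
    n_snps: int = 1000, n_samples: int = 500, seed: int = 0
) -> np.ndarray:
    """Per-SNP association p-values under the global null."""
    geno = simulate_genotypes(n_samples, n_variants=n_snps, seed=seed)
    # outcome driven by a variant that is then withheld from testing
    rng = np.random.default_rng(seed + 1)
    phenos = simulate_phenotypes(
        geno, {geno.variants["variant_id"].iloc[0]: 1.0}, h2=0.5, seed=seed + 2
    )
    phenos["null_outcome"] = rng.normal(size=n_samples)
    snps = list(geno.variants["variant_id"])
    table, _ = per_snp_association(snps, geno, phenos, "null_outcome")
    return table["p"].to_numpy()


def cohort_type_one_error(
    n_replicates: int = 500,
    n_samples: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Empirical per-variant type-I error of the cohort logistic GWAS."""
    rng = np.random.default_rng(seed)
    block = 50  # variants per simulated cohort; replicates = cohorts x variants
    hits = total = 0
    while total < n_replicates:
        geno = simulate_genotypes(
            n_samples, n_variants=block, seed=int(rng.integers(2**31))
        )
        y = rng.binomial(1, 0.4, size=n_samples)
        tab = cohort_association(geno, y)
        take = min(block, n_replicates - total)
        hits += int((tab["P"].iloc[:take] < alpha).sum())
        total += take
    return hits / n_replicates
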