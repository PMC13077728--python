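"""Variant QC, per-cohort logistic GWAS, and fixed-effects meta-analysis.

QC follows the usual genotype-level gates (minor allele count, Hardy-Weinberg
equilibrium, missingness) and imputation-quality gates (MAF-stratified R^2
thresholds). Per-cohort case/control association is a plain logistic
regression of the binary outcome on dosage plus covariates; cohorts are
combined with the inverse-variance fixed-effects scheme (weights 1/SE^2,
the STDERR scheme of METAL-style tools). Cochran's Q is reported
informationally; no genomic control is applied.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .core import DosageMatrix

SUMSTAT_COLUMNS = [
    "CHR", "POS", "ID", "A1", "A2", "BETA", "SE", "P", "EAF", "R2",
    "N_CASES", "N_CONTROLS",
]


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """1-df chi-square goodness-of-fit p-value for Hardy-Weinberg equilibrium.

    Expected genotype counts come from the estimated allele frequency;
    monomorphic input returns p = 1.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be nonnegative")
    n = counts.sum()
    if n == 0:
        raise ValueError("no genotyped individuals")
    p_A = (2 * n_AA + n_Aa) / (2 * n)
    if p_A in (0.0, 1.0):
        return 1.0
    expected = n * np.array([p_A**2, 2 * p_A * (1 - p_A), (1 - p_A) ** 2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(scipy.stats.chi2.sf(chi2, df=1))


def hwe_chi2(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """The chi-square statistic behind :func:`hwe_test` (for reporting)."""
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    n = counts.sum()
    p_A = (2 * n_AA + n_Aa) / (2 * n)
    if p_A in (0.0, 1.0):
        return 0.0
    expected = n * np.array([p_A**2, 2 * p_A * (1 - p_A), (1 - p_A) ** 2])
    return float(((counts - expected) ** 2 / expected).sum())


def genotype_qc_filter(
    stats: pd.DataFrame,
    mac_min: int = 5,
    hwe_p_min: float = 1e-6,
    missing_max: float = 0.10,
) -> set:
    """Variant ids passing MAC / HWE / missingness gates.

    Exclusion is strict (< mac_min, < hwe_p_min, > missing_max), so a
    variant sitting exactly on any boundary is kept.
    """
    required = {"variant_id", "mac", "hwe_p", "missing_rate"}
    missing_cols = required - set(stats.columns)
    if missing_cols:
        raise KeyError(f"stats table lacks columns: {sorted(missing_cols)}")
    keep = (
        (stats["mac"] >= mac_min)
        & (stats["hwe_p"] >= hwe_p_min)
        & (stats["missing_rate"] <= missing_max)
    )
    return set(stats.loc[keep, "variant_id"])


def imputation_filter(
    records: pd.DataFrame,
    maf_lo: float = 0.01,
    r2_lo_rare: float = 0.8,
    r2_lo_common: float = 0.4,
) -> pd.DataFrame:
    """Drop variants failing the MAF-stratified imputation-quality gate.

    Rare variants (MAF < ``maf_lo``) need R^2 >= ``r2_lo_rare``; common
    variants need R^2 >= ``r2_lo_common``. MAF exactly ``maf_lo`` falls
    under the common (lenient) rule. A missing R^2 is treated as 1
    (directly typed/sequenced) with a warning.
    """
    maf = np.minimum(records["EAF"], 1 - records["EAF"]).to_numpy()
    r2 = records["R2"].to_numpy(dtype=float) if "R2" in records.columns else np.full(
        len(records), np.nan
    )
    n_missing = int(np.isnan(r2).sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} records lack imputation R2; treated as typed (R2=1)",
            stacklevel=2,
        )
        r2 = np.where(np.isnan(r2), 1.0, r2)
    drop = ((maf < maf_lo) & (r2 < r2_lo_rare)) | ((maf >= maf_lo) & (r2 < r2_lo_common))
    return records.loc[~drop].reset_index(drop=True)


def cohort_association(
    dosages: DosageMatrix,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    min_group: int = 5,
    info_r2: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variant logistic regression of a binary outcome on dosage.

    Returns a summary-statistics table (one row per converged variant) with
    the effect (log-odds), SE and Wald p of the dosage term. Cohorts with
    fewer than ``min_group`` cases or controls are refused, mirroring the
    usual cohort-exclusion rule. Variants with separation or non-convergence
    are dropped with a warning, never silently NA.
    """
    y = np.asarray(phenotype, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("phenotype must be binary 0/1")
    n_cases, n_controls = int(y.sum()), int((1 - y).sum())
    if n_cases < min_group or n_controls < min_group:
        raise ValueError(
            f"cohort has {n_cases} cases / {n_controls} controls; "
            f"need >= {min_group} of each"
        )
    if covariates is None:
        cov = np.empty((len(y), 0))
    else:
        cov = np.asarray(covariates, dtype=float)
    eafs = dosages.eaf()
    rows, failed = [], []
    for j in range(dosages.n_variants):
        d = dosages.dosage[:, j]
        d = np.where(np.isnan(d), 2 * eafs[j], d)
        X = sm.add_constant(np.column_stack([d, cov]), has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            if not fit.mle_retvals.get("converged", True) or not np.isfinite(
                fit.bse[1]
            ) or fit.bse[1] > 1e3:
                raise RuntimeError("non-convergence or unstable SE")
        except Exception:
            failed.append(dosages.variants.loc[j, "variant_id"])
            continue
        v = dosages.variants.loc[j]
        rows.append(
            {
                "CHR": v["chrom"],
                "POS": int(v["pos"]),
                "ID": v["variant_id"],
                "A1": v["a1"],
                "A2": v["a2"],
                "BETA": float(fit.params[1]),
                "SE": float(fit.bse[1]),
                "P": float(fit.pvalues[1]),
                "EAF": float(eafs[j]),
                "R2": float(info_r2[j]) if info_r2 is not None else 1.0,
                "N_CASES": n_cases,
                "N_CONTROLS": n_controls,
            }
        )
    if failed:
        warnings.warn(
            f"{len(failed)} variants dropped (separation/non-convergence), "
            f"e.g. {failed[:5]}",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=SUMSTAT_COLUMNS)


def _harmonize(ref: pd.Series, rec: pd.Series):
    """Align a cohort record onto the reference effect allele.

    Returns (beta, se, eaf) or None when the allele pair cannot be matched
    in either orientation.
    """
    if rec["A1"] == ref["A1"] and rec["A2"] == ref["A2"]:
        return rec["BETA"], rec["SE"], rec["EAF"]
    if rec["A1"] == ref["A2"] and rec["A2"] == ref["A1"]:
        return -rec["BETA"], rec["SE"], 1 - rec["EAF"]
    return None


def inverse_variance_meta(records_by_cohort: list) -> pd.DataFrame:
    """Fixed-effects inverse-variance meta-analysis across cohort tables.

    Effect alleles are harmonized to the first cohort carrying each variant
    (sign/EAF flipped when a cohort reports the other allele; unresolvable
    allele pairs are dropped with a warning). Weights are 1/SE^2;
    ``beta = sum(w b) / sum(w)``, ``se = 1/sqrt(sum(w))``, p from the
    two-sided normal. Cochran's Q and its p-value are reported per variant.
    """
    if not records_by_cohort:
        raise ValueError("no cohorts supplied")
    by_variant: dict = {}
    order: list = []
    for tab in records_by_cohort:
        for _, rec in tab.iterrows():
            key = rec["ID"]
            if key not in by_variant:
                by_variant[key] = []
                order.append(key)
            by_variant[key].append(rec)
    rows, dropped = [], []
    for key in order:
        recs = by_variant[key]
        ref = recs[0]
        betas, ses, eafs = [], [], []
        ok = True
        for rec in recs:
            h = _harmonize(ref, rec)
            if h is None:
                ok = False
                break
            betas.append(h[0])
            ses.append(h[1])
            eafs.append(h[2])
        if not ok:
            dropped.append(key)
            continue
        betas, ses = np.asarray(betas, float), np.asarray(ses, float)
        if (ses <= 0).any():
            raise ValueError(f"non-positive SE for variant {key}")
        w = 1.0 / ses**2
        beta = float((w * betas).sum() / w.sum())
        se = float(w.sum() ** -0.5)
        z = beta / se
        q = float((w * (betas - beta) ** 2).sum())
        q_p = float(scipy.stats.chi2.sf(q, df=len(betas) - 1)) if len(betas) > 1 else 1.0
        rows.append(
            {
                "CHR": ref["CHR"],
                "POS": int(ref["POS"]),
                "ID": key,
                "A1": ref["A1"],
                "A2": ref["A2"],
                "BETA": beta,
                "SE": se,
                "P": float(2 * scipy.stats.norm.sf(abs(z))),
                "EAF": float(np.mean(eafs)),
                "R2": float(ref.get("R2", 1.0)),
                "N_CASES": int(sum(r.get("N_CASES", 0) for r in recs)),
                "N_CONTROLS": int(sum(r.get("N_CONTROLS", 0) for r in recs)),
                "Q": q,
                "Q_P": q_p,
                "N_COHORTS": len(recs),
            }
        )
    if dropped:
        warnings.warn(
            f"{len(dropped)} variants dropped for unresolvable alleles, "
            f"e.g. {dropped[:5]}",
            stacklevel=2,
        )
    return pd.DataFrame(rows)
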