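"""Association of standardized scores and single SNPs with AD endophenotypes.

Every model shares one covariate scheme: age at death, sex, the first three
genetic principal components, and APOE e2/e4 allele dosages; years of
education enter only for the MMSE outcome. Binary outcomes (pathological AD
diagnosis) use logistic regression, continuous ones linear regression, with
casewise deletion of missing rows.

The multiplicity adjustment used for score batteries is a Bonferroni-style
multiplication (p x m, capped at 1) with m the number of cell types tested
— deliberately distinct from Benjamini-Hochberg, which is available
separately as :func:`benjamini_hochberg`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

from .core import DosageMatrix, FeatureMatrix
from .sc_reference import normalize_rna

DEFAULT_COVARIATES = (
    "age_at_death",
    "sex",
    "pc1",
    "pc2",
    "pc3",
    "apoe_e2_dosage",
    "apoe_e4_dosage",
)

#: Outcomes that additionally adjust for years of education.
EDUCATION_OUTCOMES = ("mmse",)

#: Outcome -> model kind for the standard endophenotype battery.
DEFAULT_OUTCOME_MODELS = {
    "ad_pathdx": "logistic",
    "mmse": "linear",
    "tangle_density": "linear",
    "nft_burden": "linear",
    "abeta_burden": "linear",
    "diffuse_plaque": "linear",
    "neuritic_plaque": "linear",
}


@dataclass
class AssocRecord:
    predictor: str
    outcome: str
    model: str
    beta: float
    se: float
    p: float
    n: int
    fdr: float | None = None
    covariates: list = field(default_factory=list)
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "outcome": self.outcome,
            "model": self.model,
            "beta": self.beta,
            "se": self.se,
            "p": self.p,
            "fdr": self.fdr,
            "n": self.n,
            "covariates": ",".join(self.covariates),
            "note": self.note,
        }


def covariate_list(outcome_name: str, extra: list | None = None) -> list:
    """Mandated covariates for an outcome (education added for MMSE)."""
    cols = list(DEFAULT_COVARIATES)
    if outcome_name.lower() in EDUCATION_OUTCOMES:
        cols.append("education_years")
    for c in extra or []:
        if c not in cols:
            cols.append(c)
    return cols


def _check_collinear(X: np.ndarray, names: list, tol: float = 1e-8) -> None:
    """Raise if the design matrix is rank-deficient, naming loose columns."""
    norms = np.linalg.norm(X, axis=0)
    norms = np.where(norms == 0, 1.0, norms)
    _, R, piv = scipy.linalg.qr(X / norms, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    ref = diag[0] if diag[0] > 0 else 1.0
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] / ref < tol]
    if bad or X.shape[0] < X.shape[1]:
        raise ValueError(f"collinear design columns: {bad or names}")


def fit_outcome_model(
    predictor: np.ndarray,
    phenos: pd.DataFrame,
    outcome_name: str,
    model: str = "linear",
    predictor_name: str = "score",
    extra_covariates: list | None = None,
) -> AssocRecord:
    """Fit outcome ~ predictor + covariates; report the predictor term.

    ``predictor`` must be aligned row-for-row with ``phenos``. Rows with a
    missing outcome, covariate or predictor value are dropped casewise;
    at least 20 complete cases are required.
    """
    if model not in ("linear", "logistic"):
        raise ValueError(f"unknown model {model!r}")
    covs = covariate_list(outcome_name, extra_covariates)
    missing_cols = [c for c in [outcome_name, *covs] if c not in phenos.columns]
    if missing_cols:
        raise KeyError(f"phenotype table lacks columns {missing_cols}")
    df = phenos[[outcome_name, *covs]].copy()
    df.insert(0, "_pred", np.asarray(predictor, dtype=float))
    df = df.dropna()
    n = len(df)
    if n < 20:
        raise ValueError(f"only {n} complete cases (< 20) for {outcome_name}")
    y = df[outcome_name].to_numpy(dtype=float)
    X = sm.add_constant(
        df[["_pred", *covs]].to_numpy(dtype=float), has_constant="add"
    )
    names = ["const", predictor_name, *covs]
    _check_collinear(X, names)
    if model == "logistic":
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError(f"outcome {outcome_name!r} is not binary 0/1")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            raise RuntimeError(f"logistic model for {outcome_name!r} did not converge")
    else:
        fit = sm.OLS(y, X).fit()
    return AssocRecord(
        predictor=predictor_name,
        outcome=outcome_name,
        model=model,
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        p=float(fit.pvalues[1]),
        n=n,
        covariates=covs,
    )


def adjust_fdr(p: float, m: int) -> float:
    """Multiplicative adjustment min(1, p * m), m = number of tests.

    Monotone in both arguments; always >= p. This is the battery-wide
    correction applied per outcome across the m cell-type scores.
    """
    if not (0 < p <= 1):
        raise ValueError("p must be in (0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p * m)


def benjamini_hochberg(pvals) -> np.ndarray:
    """Standard BH step-up q-values (provided as a clearly separate option)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvals, float), method="fdr_bh")[1]


def score_battery(
    scores_by_label: dict,
    phenos: pd.DataFrame,
    outcomes: dict | None = None,
    m: int | None = None,
) -> pd.DataFrame:
    """Fit every (score label x outcome) model and attach the p x m FDR.

    ``scores_by_label`` maps label -> standardized score vector aligned with
    ``phenos``; ``outcomes`` maps outcome name -> model kind (defaults to
    the standard endophenotype battery restricted to available columns);
    ``m`` defaults to the number of labels.
    """
    if outcomes is None:
        outcomes = {
            k: v for k, v in DEFAULT_OUTCOME_MODELS.items() if k in phenos.columns
        }
    m = m if m is not None else len(scores_by_label)
    rows = []
    for label, z in scores_by_label.items():
        for outcome, model in outcomes.items():
            rec = fit_outcome_model(
                z, phenos, outcome, model=model, predictor_name=label
            )
            rec.fdr = adjust_fdr(rec.p, m)
            rows.append(rec.to_dict())
    return pd.DataFrame(rows)


def per_snp_association(
    snp_set,
    dosages: DosageMatrix,
    phenos: pd.DataFrame,
    outcome_name: str,
    model: str = "linear",
    extra_covariates: list | None = None,
) -> tuple:
    """Per-SNP dosage association with one outcome, plus the study-wide line.

    Returns (table, threshold) where threshold = 0.05 / |snp_set|; per-SNP
    failures are logged and skipped, never fatal.
    """
    snp_set = list(dict.fromkeys(snp_set))
    if not snp_set:
        raise ValueError("empty snp_set")
    known = set(dosages.variants["variant_id"])
    missing = [s for s in snp_set if s not in known]
    if missing:
        raise KeyError(f"SNPs absent from dosages: {missing[:10]}")
    pos_by_id = dict(
        zip(dosages.variants["variant_id"], dosages.variants["pos"])
    )
    rows, failed = [], []
    for snp in snp_set:
        try:
            rec = fit_outcome_model(
                dosages.column(snp),
                phenos,
                outcome_name,
                model=model,
                predictor_name=snp,
                extra_covariates=extra_covariates,
            )
        except Exception as exc:  # noqa: BLE001 - per-SNP failure is non-fatal
            failed.append((snp, str(exc)))
            continue
        d = rec.to_dict()
        d["pos"] = int(pos_by_id[snp])
        rows.append(d)
    if failed:
        warnings.warn(
            f"{len(failed)} SNP models failed, e.g. {failed[:3]}", stacklevel=2
        )
    threshold = 0.05 / len(snp_set)
    return pd.DataFrame(rows), threshold


def conditional_association(
    snp: str,
    dosages: DosageMatrix,
    phenos: pd.DataFrame,
    outcome_name: str,
    extra_covariate_name: str,
    model: str = "linear",
) -> AssocRecord:
    """Per-SNP model with one additional adjustment covariate.

    Used to ask whether an association survives adjustment for a correlated
    pathology measure.
    """
    if extra_covariate_name == outcome_name:
        raise ValueError("conditioning variable equals the outcome")
    if extra_covariate_name not in phenos.columns:
        raise KeyError(f"covariate {extra_covariate_name!r} absent from phenotypes")
    rec = fit_outcome_model(
        dosages.column(snp),
        phenos,
        outcome_name,
        model=model,
        predictor_name=snp,
        extra_covariates=[extra_covariate_name],
    )
    rec.note = f"conditioned on {extra_covariate_name}"
    return rec


def locus_window_scan(
    index_snp: str,
    dosages: DosageMatrix,
    phenos: pd.DataFrame,
    outcome_name: str,
    window_bp: int = 300_000,
    model: str = "linear",
) -> pd.DataFrame:
    """Test every variant within ``window_bp`` of the index SNP (inclusive).

    Scans all available variants on the index chromosome with
    |pos - index_pos| <= window_bp, regardless of any range membership, and
    returns a position-ordered table ready for locus plotting.
    """
    v = dosages.variants
    hit = v.index[v["variant_id"] == index_snp]
    if len(hit) == 0:
        raise KeyError(f"index SNP {index_snp!r} absent from dosages")
    row = v.loc[hit[0]]
    in_window = (v["chrom"] == row["chrom"]) & (
        (v["pos"] - int(row["pos"])).abs() <= window_bp
    )
    snps = v.loc[in_window].sort_values("pos")["variant_id"].tolist()
    table, _ = per_snp_association(snps, dosages, phenos, outcome_name, model=model)
    return table.sort_values("pos").reset_index(drop=True)


def single_cell_eqtl(
    snp: str,
    gene: str,
    cell_group: str,
    expr: FeatureMatrix,
    dosages: DosageMatrix,
    phenos: pd.DataFrame,
    group_by: str = "cell_type",
) -> AssocRecord:
    """Donor-pseudobulk expression of one gene regressed on SNP dosage.

    Expression is counts-per-10k (no log) averaged over each donor's cells
    of ``cell_group``; donors are matched to dosage sample ids and the
    standard covariates apply. Requires >= 20 donors with both data types.
    """
    fid = expr.features["feature_id"]
    if gene not in set(fid):
        raise KeyError(f"gene {gene!r} absent from expression matrix")
    gcol = int(np.flatnonzero((fid == gene).to_numpy())[0])
    in_group = (expr.cells[group_by] == cell_group).to_numpy()
    if not in_group.any():
        raise ValueError(f"no cells in group {cell_group!r}")
    norm = normalize_rna(expr)
    gvals = np.asarray(norm[:, gcol].todense()).ravel()
    donor = expr.cells.loc[in_group, "donor_id"]
    pseudo = (
        pd.Series(gvals[in_group], index=donor.to_numpy())
        .groupby(level=0)
        .mean()
    )
    d = pd.Series(dosages.column(snp), index=dosages.sample_ids)
    ph = phenos.set_index("sample_id")
    donors = sorted(set(pseudo.index) & set(d.index) & set(ph.index))
    if len(donors) < 20:
        raise ValueError(f"only {len(donors)} donors with expression + dosage (< 20)")
    dd = d.loc[donors].to_numpy(dtype=float)
    if np.nanstd(dd) == 0:
        raise ValueError(f"dosage of {snp!r} is constant across donors")
    yv = pseudo.loc[donors].to_numpy(dtype=float)
    sub = ph.loc[donors].reset_index()
    sub["_expr"] = yv
    if np.allclose(yv, 0):
        return AssocRecord(
            predictor=snp,
            outcome=f"{gene}@{cell_group}",
            model="linear",
            beta=0.0,
            se=np.nan,
            p=1.0,
            n=len(donors),
            note="degenerate: gene unexpressed",
        )
    rec = fit_outcome_model(
        dd, sub, "_expr", model="linear", predictor_name=snp
    )
    rec.outcome = f"{gene}@{cell_group}"
    return rec
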