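"""Covariate-adjusted SNP–phenotype association with permutation correction.

Each candidate SNP is tested by ordinary least squares of the quantitative
phenotype on additive allele dosage (0/1/2) plus covariates and an
intercept, with a two-sided t test on the dosage coefficient. Family-wise
correction across the candidate SNPs uses a max-T permutation scheme on
covariate residuals: the phenotype is residualized on the covariates once,
the residuals are permuted B times, all SNPs are refit per permutation,
and each SNP's corrected p-value is the fraction of permutations whose
maximum |t| across the family reaches its observed |t| (with the +1
correction, so corrected p ∈ [1/(B+1), 1]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .diffexon import adjust_bh

__all__ = [
    "AssociationResult",
    "fit_additive_model",
    "permutation_maxT",
    "associate_snps",
    "adjust_fdr",
]


@dataclass(frozen=True)
class AssociationResult:
    variant_id: str
    beta: float
    se: float
    t_statistic: float
    p_nominal: float
    p_perm_corrected: float | None
    n_used: int
    testable: bool = True


def _design(covariates: pd.DataFrame | None, index) -> pd.DataFrame:
    X = pd.DataFrame({"const": 1.0}, index=index)
    if covariates is not None:
        X = pd.concat([X, covariates.astype(float)], axis=1)
    return X


def fit_additive_model(
    phenotype: pd.Series,
    dosage: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> AssociationResult:
    """OLS of phenotype on allele dosage + covariates + intercept.

    Samples with missing dosage or phenotype are dropped pairwise. A
    constant dosage makes the SNP untestable and is flagged rather than
    raising.
    """
    df = pd.DataFrame({"y": phenotype, "dosage": dosage})
    X = _design(covariates, phenotype.index)
    df = pd.concat([df, X], axis=1).dropna()
    n = len(df)
    vid = dosage.name or "dosage"
    if df["dosage"].nunique() < 2 or n < X.shape[1] + 3:
        return AssociationResult(str(vid), np.nan, np.nan, np.nan, np.nan, None, n, False)
    exog = df[list(X.columns) + ["dosage"]]
    fit = sm.OLS(df["y"], exog).fit()
    return AssociationResult(
        variant_id=str(vid),
        beta=float(fit.params["dosage"]),
        se=float(fit.bse["dosage"]),
        t_statistic=float(fit.tvalues["dosage"]),
        p_nominal=float(fit.pvalues["dosage"]),
        p_perm_corrected=None,
        n_used=n,
        testable=True,
    )


def _residualize(M: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of each column of M on the column space of X."""
    coef, *_ = np.linalg.lstsq(X, M, rcond=None)
    return M - X @ coef


def _family_tstats(
    e_y: np.ndarray, e_D: np.ndarray, df_resid: int
) -> np.ndarray:
    """t statistics of each residualized dosage column against e_y.

    By Frisch–Waugh–Lovell these equal the full-model OLS t statistics on
    the dosage coefficient when ``df_resid`` is the full-model residual df.
    e_y: (n,) or (n, B); e_D: (n, m). Returns (m,) or (m, B).
    """
    ssd = (e_D**2).sum(axis=0)  # (m,)
    num = e_D.T @ e_y  # (m,) or (m, B)
    b = (num.T / ssd).T
    ssy = (e_y**2).sum(axis=0)  # scalar or (B,)
    sse = np.maximum(ssy - (b.T**2 * ssd).T * 1.0, 0.0)
    # broadcast: b and sse are (m,) or (m, B); ssd is (m,)
    sigma2 = sse / df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt((sigma2.T / ssd).T)
        t = b / se
    return t


def permutation_maxT(
    phenotype: pd.Series,
    dosages: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Max-T permutation-corrected p-values for a family of SNPs.

    Parameters
    ----------
    phenotype
        Quantitative phenotype indexed by sample.
    dosages
        SNP × sample table of allele dosages (0/1/2); samples with any
        missing value in the family are dropped.
    covariates
        Optional sample × covariate table.
    n_permutations
        Number of permutations B (≥ 100; the corrected p resolution is
        1/(B+1)).
    seed
        Seed for the permutation stream.

    Returns
    -------
    DataFrame indexed by variant id with columns beta, se, t_statistic,
    p_nominal, p_perm_corrected, n_used.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations for a stable correction")
    D = dosages.T  # samples × SNPs
    df = pd.concat([phenotype.rename("y"), _design(covariates, phenotype.index), D], axis=1)
    df = df.dropna()
    n = len(df)
    k = 1 + (0 if covariates is None else covariates.shape[1])  # incl. intercept
    m = D.shape[1]
    df_resid = n - k - 1  # full model: covariates + intercept + dosage
    if df_resid < 3:
        raise ValueError("too few complete samples for the family test")
    X = df.iloc[:, 1 : 1 + k].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    Dm = df.iloc[:, 1 + k :].to_numpy(dtype=float)
    const_mask = np.ptp(Dm, axis=0) == 0

    e_y = _residualize(y[:, None], X)[:, 0]
    e_D = _residualize(Dm, X)
    t_obs = np.full(m, np.nan)
    ok = ~const_mask
    t_obs[ok] = _family_tstats(e_y, e_D[:, ok], df_resid)
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    ssd = (e_D[:, ok] ** 2).sum(axis=0)
    b_ok = (e_D[:, ok].T @ e_y) / ssd
    sse = (e_y**2).sum() - b_ok**2 * ssd
    se_ok = np.sqrt(np.maximum(sse, 0) / df_resid / ssd)
    beta[ok], se[ok] = b_ok, se_ok
    from scipy import stats as _st

    p_nom = np.full(m, np.nan)
    p_nom[ok] = 2 * _st.t.sf(np.abs(t_obs[ok]), df_resid)

    rng = np.random.default_rng(seed)
    B = n_permutations
    perm = np.empty((n, B))
    for b in range(B):
        perm[:, b] = e_y[rng.permutation(n)]
    t_perm = _family_tstats(perm, e_D[:, ok], df_resid)  # (m_ok, B)
    max_t = np.abs(t_perm).max(axis=0)  # (B,)
    p_corr = np.full(m, np.nan)
    p_corr[ok] = (1 + (max_t[None, :] >= np.abs(t_obs[ok])[:, None]).sum(axis=1)) / (B + 1)

    return pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "t_statistic": t_obs,
            "p_nominal": p_nom,
            "p_perm_corrected": p_corr,
            "n_used": n,
        },
        index=D.columns,
    )


def associate_snps(
    phenotype: pd.Series,
    dosages: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> list[AssociationResult]:
    """Per-SNP OLS plus family-wise max-T correction, as result records."""
    fam = permutation_maxT(phenotype, dosages, covariates, n_permutations, seed)
    out = []
    for vid, r in fam.iterrows():
        testable = np.isfinite(r["t_statistic"])
        out.append(
            AssociationResult(
                variant_id=str(vid),
                beta=float(r["beta"]),
                se=float(r["se"]),
                t_statistic=float(r["t_statistic"]),
                p_nominal=float(r["p_nominal"]),
                p_perm_corrected=float(r["p_perm_corrected"]) if testable else None,
                n_used=int(r["n_used"]),
                testable=bool(testable),
            )
        )
    return out


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjustment; identical semantics to diffexon.adjust_bh."""
    return adjust_bh(p_values)
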