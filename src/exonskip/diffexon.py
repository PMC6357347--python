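"""Differential exon usage testing and skipping-event calling.

Per-exon usage is the fraction of a gene's reads falling in one exon bin;
a drop in usage in one condition relative to the other is the count-level
signature of increased exon skipping. Each exon is tested with a
generalized linear model on the paired counts (this exon, rest-of-gene)
per sample: a binomial GLM (logit link) of the exon count out of the
sample's gene total on condition, which conditions on each sample's
sequencing depth and gene expression exactly. Extra-binomial variation
(the count-level footprint of biological overdispersion) is absorbed by a
per-exon moment-based Pearson dispersion factor, floored at 1, with no
information sharing across exons; the Wald statistic on the condition
coefficient is referred to a t distribution with n − 2 df.

Events are called at FDR < 0.05 (Benjamini–Hochberg) and fold change
> 1.5, both strict, with fold change oriented ≥ 1 and the direction
(which condition has lower usage) carried separately.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

PEARSON_DISPERSION_FLOOR = 1.0


@dataclass(frozen=True)
class SkippingEvent:
    """A differentially used exon passing the FDR and fold-change cutoffs."""

    exon_id: str
    gene_id: str
    p_value: float
    fdr: float
    fold_change: float
    direction: str  # lower_in_case | higher_in_case
    mean_usage_case: float
    mean_usage_control: float


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (exon-level), geometric mean 1.

    Ratios are taken to the geometric-mean pseudo-reference over exons
    positive in every sample. If no such exon exists, falls back to
    total-count ratios with a warning.
    """
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if all_pos.any():
        sub = mat[all_pos]
        ref = np.exp(np.log(sub).mean(axis=1))
        sf = np.median(sub / ref[:, None], axis=0)
    else:
        logger.warning(
            "no exon positive in all samples; using total-count size factors"
        )
        totals = mat.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("sample with zero total count")
        sf = totals / totals.mean()
    sf = sf / np.exp(np.log(sf).mean())  # rescale to geometric mean 1
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalized_usage(
    counts: pd.DataFrame,
    gene_of: pd.Series,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-exon relative usage: the exon's share of its gene per sample.

    usage(e, s) = (count(e,s)/sf_s) / Σ_{e' in gene(e)} (count(e',s)/sf_s);
    NaN where the gene total is zero in a sample. Size factors cancel in
    the ratio but are accepted for interface symmetry.
    """
    mat = counts.to_numpy(dtype=float)
    if size_factors is not None:
        mat = mat / size_factors.reindex(counts.columns).to_numpy()
    norm = pd.DataFrame(mat, index=counts.index, columns=counts.columns)
    gene_totals = norm.groupby(gene_of.reindex(counts.index)).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        usage = norm / gene_totals
    return usage.where(gene_totals > 0)


def _fit_exon(
    y_exon: np.ndarray, y_rest: np.ndarray, is_case: np.ndarray
) -> tuple[float, float]:
    """Overdispersion-adjusted Wald p and condition coefficient for one exon.

    Binomial GLM of (exon, rest-of-gene) pairs on condition; the Wald
    statistic is deflated by the square root of the moment-based Pearson
    dispersion (floored at 1) and referred to t with n − 2 df.
    """
    n = y_exon.size
    X = np.column_stack([np.ones(n), is_case.astype(float)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(
            np.column_stack([y_exon, y_rest]), X, family=sm.families.Binomial()
        ).fit()
    phi = max(float(fit.pearson_chi2) / (n - 2), PEARSON_DISPERSION_FLOOR)
    t_stat = float(fit.params[1]) / (float(fit.bse[1]) * np.sqrt(phi))
    p = 2.0 * float(stats.t.sf(abs(t_stat), n - 2))
    return p, float(fit.params[1])


def test_exon_usage(
    counts: pd.DataFrame,
    gene_of: pd.Series,
    sample_table: pd.DataFrame,
    size_factors: pd.Series | None = None,
    fold_change_on: str = "counts",
) -> pd.DataFrame:
    """Test every exon for differential usage between case and control.

    Parameters
    ----------
    counts
        Integer exon × sample count matrix.
    gene_of
        exon_id → gene_id map covering every row of ``counts``.
    sample_table
        Indexed by sample_id with a ``condition`` column in
        {"case", "control"}; both conditions must have ≥ 2 samples.
    size_factors
        Per-sample normalization factors; estimated if omitted.
    fold_change_on
        "counts": fold change from size-factor-normalized exon counts
        (matching fold changes reported on exon expression levels);
        "usage": from relative usage.

    Returns
    -------
    DataFrame indexed by exon_id with columns gene_id, p_value,
    fold_change, direction, mean_usage_case, mean_usage_control. Exons in
    single-bin genes, all-zero exons and non-converged fits carry NaN
    p-values.
    """
    if fold_change_on not in ("counts", "usage"):
        raise ValueError("fold_change_on must be 'counts' or 'usage'")
    samples = [s for s in counts.columns if s in sample_table.index]
    if len(samples) < len(counts.columns):
        missing = set(counts.columns) - set(samples)
        raise ValueError(f"samples missing from sample table: {sorted(missing)}")
    cond = sample_table.loc[samples, "condition"]
    bad = set(cond.unique()) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown conditions: {sorted(bad)}")
    n_case = int((cond == "case").sum())
    n_ctrl = int((cond == "control").sum())
    if n_case < 2 or n_ctrl < 2:
        raise ValueError("need at least 2 samples per condition")
    if size_factors is None:
        size_factors = estimate_size_factors(counts[samples])

    gene_of = gene_of.reindex(counts.index)
    usage = normalized_usage(counts[samples], gene_of)
    is_case = (cond == "case").to_numpy()
    usage_case = usage.loc[:, is_case].mean(axis=1, skipna=True)
    usage_ctrl = usage.loc[:, ~is_case].mean(axis=1, skipna=True)

    sf = size_factors.reindex(samples).to_numpy()
    norm_counts = counts[samples].to_numpy(dtype=float) / sf
    mean_norm_case = norm_counts[:, is_case].mean(axis=1)
    mean_norm_ctrl = norm_counts[:, ~is_case].mean(axis=1)

    mat = counts[samples].to_numpy(dtype=float)
    gene_sums = counts[samples].groupby(gene_of).transform("sum").to_numpy(dtype=float)
    gene_sizes = gene_of.map(gene_of.value_counts())

    records = []
    for i, exon_id in enumerate(counts.index):
        gene_id = gene_of.iloc[i]
        row = dict(exon_id=exon_id, gene_id=gene_id, p_value=np.nan,
                   fold_change=np.nan, direction="",
                   mean_usage_case=float(usage_case.iloc[i]),
                   mean_usage_control=float(usage_ctrl.iloc[i]))
        if gene_sizes.iloc[i] < 2:
            records.append(row)
            continue
        y_exon = mat[i]
        y_rest = gene_sums[i] - y_exon
        keep = gene_sums[i] > 0
        if y_exon[keep].sum() == 0 or y_rest[keep].sum() == 0 or keep.sum() < 4:
            records.append(row)
            continue
        if fold_change_on == "counts":
            r = mean_norm_ctrl[i] / mean_norm_case[i] if mean_norm_case[i] > 0 else np.inf
        else:
            r = (
                usage_ctrl.iloc[i] / usage_case.iloc[i]
                if usage_case.iloc[i] > 0
                else np.inf
            )
        row["fold_change"] = float(max(r, 1 / r)) if np.isfinite(r) and r > 0 else np.inf
        row["direction"] = "lower_in_case" if r >= 1 else "higher_in_case"
        if is_case[keep].sum() < 2 or (~is_case[keep]).sum() < 2:
            records.append(row)
            continue
        try:
            p, _beta = _fit_exon(y_exon[keep], y_rest[keep], is_case[keep])
            row["p_value"] = p
        except Exception as exc:  # non-convergence / separation
            logger.warning("fit failed for exon %s: %s", exon_id, exc)
        records.append(row)
    return pd.DataFrame.from_records(records).set_index("exon_id")


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment.

    Matches R's ``p.adjust(method="BH")`` semantics, including the
    cumulative-minimum monotonicity pass from the largest rank. NaN
    entries are excluded from the number of tests m and stay NaN.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[valid] = res
    return out


def call_skipping_events(
    results: pd.DataFrame, fdr_max: float = 0.05, fc_min: float = 1.5
) -> list[SkippingEvent]:
    """Call skipping events at strict FDR and fold-change cutoffs.

    Adds/uses an ``fdr`` column (computed from ``p_value`` if absent) and
    emits one event per exon with fdr < fdr_max and fold_change > fc_min,
    sorted by fdr then exon_id.
    """
    res = results.copy()
    if "fdr" not in res.columns:
        res["fdr"] = adjust_bh(res["p_value"])
    mask = (res["fdr"] < fdr_max) & (res["fold_change"] > fc_min)
    mask &= res["fdr"].notna() & np.isfinite(res["fold_change"])
    hits = res[mask].sort_index(kind="mergesort").sort_values("fdr", kind="mergesort")
    return [
        SkippingEvent(
            exon_id=str(idx),
            gene_id=str(r["gene_id"]),
            p_value=float(r["p_value"]),
            fdr=float(r["fdr"]),
            fold_change=float(r["fold_change"]),
            direction=str(r["direction"]),
            mean_usage_case=float(r["mean_usage_case"]),
            mean_usage_control=float(r["mean_usage_control"]),
        )
        for idx, r in hits.iterrows()
    ]


def one_way_chisq(
    observed, expected=None
) -> tuple[float, float]:
    """One-way (goodness-of-fit) chi-squared test.

    Expected counts default to equal proportions across categories.
    Returns the Pearson statistic (k − 1 df) and its exact chi-square
    tail probability.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least 2 categories")
    if expected is None:
        expected = np.full(obs.size, obs.sum() / obs.size)
    exp = np.asarray(expected, dtype=float)
    if (exp <= 0).any():
        raise ValueError("expected counts must be positive")
    chi2, p = stats.chisquare(obs, f_exp=exp)
    return float(chi2), float(p)
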