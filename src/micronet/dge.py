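"""Expression filtering and covariate-adjusted negative-binomial differential expression.

The model mirrors the standard count-based workflow: features with an
overall expression of more than ``min_total`` counts across all samples are
retained; per-sample size factors come from median-of-ratios normalization;
each retained feature is fit with a negative-binomial GLM (log link) of

    counts ~ intercept + group[L] + sex + batch,  offset = log(size factor)

with a per-feature method-of-moments dispersion, and the group coefficient
is Wald-tested against the standard normal (two-sided). The H group is the
reference level, so a positive log2 fold change means higher expression in
the L group. Benjamini-Hochberg adjustment is applied across the tested
features of one layer; a feature is called differentially expressed when
p_adj < alpha and |log2FC| exceeds the layer's fold-change threshold
(1.5 for mRNA, 1.2 for miRNA on the linear scale).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix

__all__ = ["filter_expressed", "size_factors", "nb_wald_de", "design_matrix"]

#: floor for the method-of-moments dispersion estimate
MIN_DISPERSION = 1e-8


def filter_expressed(counts: CountMatrix, min_total: int = 20) -> CountMatrix:
    """Keep features whose total count across all samples is strictly > ``min_total``."""
    keep = counts.counts.sum(axis=1) > min_total
    return CountMatrix(counts.counts.loc[keep].copy(), layer=counts.layer)


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    For every feature positive in all samples, each sample's ratio to the
    feature's geometric mean is formed; the per-sample median of those
    ratios is the raw factor. The ratio definition leaves an overall scale
    free; it is fixed by rescaling the factors to geometric mean 1.
    """
    mat = counts.counts.to_numpy(dtype=float)
    all_positive = (mat > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no feature has positive counts in every sample; "
            "filter low-expression features before normalization"
        )
    sub = mat[all_positive]
    log_geo_mean = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_geo_mean)
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def design_matrix(samples: pd.DataFrame) -> pd.DataFrame:
    """Build the design: intercept + group[L] + sex and batch dummies.

    H, and the lexicographically first sex/batch level, are the reference
    levels. Covariates constant across samples are dropped (they are not
    estimable and carry no information).
    """
    X = pd.DataFrame(index=samples.index)
    X["intercept"] = 1.0
    X["group_L"] = (samples["group"] == "L").astype(float)
    for covariate in ("sex", "batch"):
        levels = sorted(samples[covariate].astype(str).unique())
        for level in levels[1:]:
            X[f"{covariate}_{level}"] = (samples[covariate].astype(str) == level).astype(float)
    return X


def _mom_dispersion(y_norm: np.ndarray) -> float:
    """Method-of-moments NB dispersion on normalized counts: (s^2 - m) / m^2, floored."""
    m = y_norm.mean()
    if m <= 0:
        return MIN_DISPERSION
    s2 = y_norm.var(ddof=1)
    return max(MIN_DISPERSION, (s2 - m) / (m * m))


def nb_wald_de(
    counts: CountMatrix,
    samples: pd.DataFrame,
    fc_threshold: float,
    alpha: float = 0.05,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-feature NB Wald differential expression between the H and L groups.

    Parameters
    ----------
    counts
        Filtered count matrix. Sample columns must match ``samples``.
    samples
        Metadata indexed by sample_id with ``group`` in {H, L}, ``sex``,
        ``batch`` columns. Both groups must be present.
    fc_threshold
        Linear-scale fold-change cutoff for the DE call (1.5 or 1.2 in
        pipeline use); the call uses |log2FC| > log2(fc_threshold).
    alpha
        Adjusted-p cutoff for the DE call.
    factors
        Precomputed size factors; computed from ``counts`` if omitted.

    Returns
    -------
    DataFrame indexed by feature_id with columns base_mean, log2fc, se,
    wald_stat, p_value, p_adj, is_de, converged. Non-converged fits are
    reported with p_value 1 and converged=False rather than dropped.
    """
    samples = samples.loc[counts.sample_ids]
    if set(samples["group"]) != {"H", "L"}:
        raise ValueError("both groups H and L must be present for the contrast")
    if factors is None:
        factors = size_factors(counts)
    factors = factors.loc[counts.sample_ids]
    offset = np.log(factors.to_numpy(dtype=float))
    X = design_matrix(samples)
    group_col = X.columns.get_loc("group_L")
    in_L = (samples["group"] == "L").to_numpy()

    mat = counts.counts.to_numpy(dtype=float)
    norm = mat / factors.to_numpy()

    rows = []
    for i, feature in enumerate(counts.feature_ids):
        y = mat[i]
        y_norm = norm[i]
        disp = _mom_dispersion(y_norm)
        coef = se = wald = np.nan
        p = 1.0
        converged = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GLM(
                    y,
                    X.to_numpy(),
                    family=sm.families.NegativeBinomial(alpha=disp),
                    offset=offset,
                )
                fit = model.fit(maxiter=100)
            coef = fit.params[group_col]
            se = fit.bse[group_col]
            converged = bool(getattr(fit, "converged", True)) and np.isfinite(coef) and np.isfinite(se) and se > 0
            if converged:
                wald = coef / se
                p = float(2.0 * stats.norm.sf(abs(wald)))
        except Exception:
            converged = False

        # One group entirely zero gives an unbounded coefficient; report a
        # finite fold change from pseudo-counted group means without
        # altering the test outcome.
        zero_separated = (y[in_L].sum() == 0) or (y[~in_L].sum() == 0)
        if converged and not zero_separated:
            log2fc = coef / np.log(2.0)
        else:
            mean_L = y_norm[in_L].mean()
            mean_H = y_norm[~in_L].mean()
            log2fc = np.log2((mean_L + 0.5) / (mean_H + 0.5))
            if not converged:
                p = 1.0
                wald = np.nan
        rows.append(
            {
                "feature_id": feature,
                "base_mean": float(y_norm.mean()),
                "log2fc": float(log2fc),
                "se": float(se) if np.isfinite(se) else np.nan,
                "wald_stat": float(wald) if np.isfinite(wald) else np.nan,
                "p_value": min(1.0, max(0.0, p)),
                "converged": converged,
            }
        )

    table = pd.DataFrame(rows).set_index("feature_id")
    if len(table):
        table["p_adj"] = multipletests(table["p_value"].to_numpy(), method="fdr_bh")[1]
    else:
        table["p_adj"] = pd.Series(dtype=float)
    lfc_cut = np.log2(fc_threshold)
    table["is_de"] = (table["p_adj"] < alpha) & (table["log2fc"].abs() > lfc_cut)
    return table[["base_mean", "log2fc", "se", "wald_stat", "p_value", "p_adj", "is_de", "converged"]]
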