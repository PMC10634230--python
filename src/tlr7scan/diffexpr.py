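"""Sex-biased differential expression with empirical-Bayes moderation.

A two-group moderated t-test on log expression, in the spirit of the
limma/edgeR family: per-gene pooled variances s^2 (d = n - 2 df) are
shrunk toward a common prior variance s0^2 with prior weight d0, where
(d0, s0^2) are estimated by a closed-form method of moments on the scaled-F
marginal of {s^2}.  Multiple testing uses the Benjamini-Yekutieli step-up
procedure, which controls FDR under arbitrary dependence.

The moderated statistic for gene g is

    t_g = (mean_F - mean_M) / (s_tilde_g * sqrt(1/n_F + 1/n_M)),
    s_tilde_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d),

with a two-sided p-value from Student's t on d0 + d degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class VariancePrior:
    """Shared empirical-Bayes variance hyperparameters."""

    prior_df: float  # d0
    prior_var: float  # s0^2


def estimate_variance_prior(s2: np.ndarray, residual_df: int) -> VariancePrior:
    """Method-of-moments fit of the scaled-F marginal of sample variances.

    Under the hierarchical model, s^2 / s0^2 ~ F(d, d0).  Matching the mean
    and variance of the observed s^2 gives, with r = Var[s^2] / E[s^2]^2,

        d0 = (4 r d + 2 d - 4) / (r d - 2)   (when r d > 2)
        s0^2 = E[s^2] * (d0 - 2) / d0,

    falling back to d0 = inf (no gene-specific variance component
    detectable beyond sampling noise) with s0^2 = E[s^2] otherwise.
    """
    s2 = np.asarray(s2, dtype=float)
    d = float(residual_df)
    m1 = s2.mean()
    if m1 <= 0 or len(s2) < 2:
        return VariancePrior(prior_df=np.inf, prior_var=max(m1, 0.0))
    r = s2.var(ddof=1) / m1**2
    if r * d <= 2:
        return VariancePrior(prior_df=np.inf, prior_var=m1)
    d0 = (4 * r * d + 2 * d - 4) / (r * d - 2)
    return VariancePrior(prior_df=d0, prior_var=m1 * (d0 - 2) / d0)


def moderated_sex_test(
    log_expression: pd.DataFrame,
    sex: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Moderated two-group (female vs male) test per gene.

    Parameters
    ----------
    log_expression : genes x samples matrix on a log2 scale
        (e.g. log2(TPM + pseudocount)).
    sex : per-sample labels, "female" or "male", indexed by sample.
    alpha : significance level for the BY-adjusted q-values.

    Returns a table with log2fc (mean female minus mean male log2
    expression), t_mod, df_total, p_value, q_by and a boolean
    ``significant`` column.  Genes with zero variance in both groups and
    zero mean difference get p = 1.
    """
    sex = sex.loc[log_expression.columns]
    f_cols = sex.index[sex == "female"]
    m_cols = sex.index[sex == "male"]
    n_f, n_m = len(f_cols), len(m_cols)
    if n_f < 2 or n_m < 2:
        raise ValueError(
            f"need >= 2 samples per sex, got {n_f} female / {n_m} male"
        )
    x_f = log_expression[f_cols].to_numpy(dtype=float)
    x_m = log_expression[m_cols].to_numpy(dtype=float)
    diff = x_f.mean(axis=1) - x_m.mean(axis=1)
    ss = ((x_f - x_f.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x_m - x_m.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    d = n_f + n_m - 2
    s2 = ss / d

    prior = estimate_variance_prior(s2, d)
    if np.isinf(prior.prior_df):
        s2_post = np.full_like(s2, prior.prior_var)
        df_total = np.inf
    else:
        s2_post = (prior.prior_df * prior.prior_var + d * s2) / (prior.prior_df + d)
        df_total = prior.prior_df + d

    se = np.sqrt(s2_post * (1.0 / n_f + 1.0 / n_m))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, diff / np.where(se > 0, se, 1.0), np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.where((se == 0) & (diff == 0), 1.0, p)
    p = np.where(np.isinf(t_mod), 0.0, p)

    q = by_adjust(p)
    out = pd.DataFrame(
        {
            "log2fc": diff,
            "t_mod": t_mod,
            "df_total": df_total,
            "p_value": p,
            "q_by": q,
            "significant": q < alpha,
        },
        index=log_expression.index,
    )
    out.attrs["prior_df"] = prior.prior_df
    out.attrs["prior_var"] = prior.prior_var
    return out


def by_adjust(p_values) -> np.ndarray:
    """Benjamini-Yekutieli adjusted q-values, in input order.

    q_(i) = min_{j >= i} min(1, m * c(m) * p_(j) / j) with the harmonic
    factor c(m) = sum_{k=1}^m 1/k.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_by")
    return q
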