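"""Per-probe linear models on M-values with empirical-Bayes moderation.

Each probe is fit by OLS of M on [intercept, case indicator, cell-proportion
covariates]; residual variances are then shrunk toward a pooled prior
(d0, s0^2) estimated by moment matching on the log-variances, and the
moderated t uses the squeezed variance with d0 + d_g degrees of freedom.
Effect sizes for thresholding are computed separately on the beta scale,
since the 10% criterion is stated in methylation-fraction units.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .containers import BetaMatrix, MValueMatrix, SampleSheet, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ModelFit:
    """Per-probe OLS results plus the pooled moderation prior."""

    coef: pd.Series          # case-effect on the M scale
    s2: pd.Series            # residual variance
    df_residual: int
    std_unscaled: float      # sd of the case coefficient per unit sigma
    d0: float | None = None  # prior df (None until moderated; inf allowed)
    s0_sq: float | None = None


def build_design(samples: SampleSheet,
                 covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Design matrix [intercept, case, covariate columns].

    Bi- and mono-allelic cases are pooled into one case indicator; when
    cell proportions are supplied the last column is dropped (they sum to
    one, which would be collinear with the intercept).
    """
    case = samples.table["group"].isin(
        ("case_biallelic", "case_monoallelic")).astype(float)
    design = pd.DataFrame({"intercept": 1.0, "case": case},
                          index=samples.sample_ids)
    if covariates is not None:
        cov = covariates.loc[samples.sample_ids]
        if np.allclose(cov.sum(axis=1), 1.0, atol=1e-6):
            cov = cov.iloc[:, :-1]
        for col in cov.columns:
            design[str(col)] = cov[col].astype(float)
    return design


def fit_probe_models(m: MValueMatrix, samples: SampleSheet,
                     covariates: pd.DataFrame | None = None) -> ModelFit:
    """Vectorised OLS of every probe's M-values on the shared design."""
    design = build_design(samples, covariates)
    x = design.to_numpy(dtype=float)
    n, p = x.shape
    if np.linalg.matrix_rank(x) < p:
        # name the offending columns for the error message
        bad = []
        for j, col in enumerate(design.columns):
            others = np.delete(x, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(x):
                bad.append(col)
        raise ValidationError(f"design matrix is rank deficient "
                              f"(collinear columns: {bad})")
    if n <= p:
        raise ValidationError("no residual degrees of freedom")

    y = m.m[design.index].to_numpy(dtype=float)  # probes x samples
    xtx_inv = np.linalg.inv(x.T @ x)
    coefs = y @ x @ xtx_inv.T                   # probes x p
    resid = y - coefs @ x.T
    df = n - p
    s2 = (resid ** 2).sum(axis=1) / df
    case_idx = design.columns.get_loc("case")
    return ModelFit(
        coef=pd.Series(coefs[:, case_idx], index=m.probe_ids, name="coef"),
        s2=pd.Series(s2, index=m.probe_ids, name="s2"),
        df_residual=df,
        std_unscaled=float(np.sqrt(xtx_inv[case_idx, case_idx])),
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = scipy.special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / scipy.special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-matching fit of the scaled-F prior on residual variances.

    Works on z = log(s2): the excess variance of z over its sampling
    variance trigamma(df/2) identifies the prior df d0 via the trigamma
    inverse; the mean identifies s0^2.  A non-positive excess gives
    d0 = inf (all variances equal a common value).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValidationError("all residual variances are zero")
    z = np.log(s2[ok])
    if np.ptp(z) == 0:
        # degenerate ensemble: no spread to de-bias against, so the common
        # value itself is the prior (the squeeze is then the identity)
        return np.inf, float(s2[ok][0])
    e = z - scipy.special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(scipy.special.polygamma(1, df / 2.0))
    if e_var <= 0:
        logger.warning("no excess variance in log-s2; prior df set to inf")
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = float(np.exp(e_mean + scipy.special.digamma(d0 / 2.0)
                         - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderate_statistics(fit: ModelFit,
                        d0_override: float | None = None) -> pd.DataFrame:
    """Empirical-Bayes variance squeeze and moderated t-statistics.

    s~2_g = (d0*s0^2 + d_g*s2_g) / (d0 + d_g); t = coef / (s~ * std_unscaled)
    with d0 + d_g df (normal when d0 = inf).  ``d0_override`` forces the
    prior df (0 recovers the ordinary t).
    Returns a DataFrame with t_mod, p_raw, s2_post.
    """
    if len(fit.s2) < 10 and d0_override is None:
        raise ValidationError("moderation needs >= 10 probes")
    s2 = fit.s2.to_numpy(dtype=float)
    df = fit.df_residual
    if d0_override is not None:
        d0 = float(d0_override)
        _, s0_sq = estimate_prior(s2, df) if d0 > 0 else (None, 1.0)
        if d0 == 0:
            s0_sq = 1.0  # irrelevant: zero weight
    else:
        d0, s0_sq = estimate_prior(s2, df)
    fit.d0, fit.s0_sq = d0, s0_sq

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        total_df = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        total_df = d0 + df
    t = fit.coef.to_numpy() / (np.sqrt(s2_post) * fit.std_unscaled)
    if np.isinf(total_df):
        p = 2.0 * scipy.stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * scipy.stats.t.sf(np.abs(t), total_df)
    return pd.DataFrame({"t_mod": t, "p_raw": p, "s2_post": s2_post},
                        index=fit.coef.index)


def adjust_bh(p_raw: pd.Series | np.ndarray, method: str = "fdr_bh") -> pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values (Bonferroni/Holm
    selectable via ``method``)."""
    p = np.asarray(p_raw, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values outside [0, 1]")
    adj = multipletests(p, method=method)[1]
    index = p_raw.index if isinstance(p_raw, pd.Series) else None
    return pd.Series(adj, index=index, name="p_adj")


def mean_beta_difference(beta: BetaMatrix, samples: SampleSheet) -> pd.Series:
    """Per-probe mean case beta minus mean control beta (beta scale,
    missing values excluded per group; NaN when a group is empty at a
    probe)."""
    case_ids = samples.case_ids
    ctrl_ids = samples.control_ids
    if not case_ids or not ctrl_ids:
        raise ValidationError("need non-empty case and control groups")
    case_mean = beta.beta[case_ids].mean(axis=1, skipna=True)
    ctrl_mean = beta.beta[ctrl_ids].mean(axis=1, skipna=True)
    return (case_mean - ctrl_mean).rename("delta_beta")


def probe_statistics(beta: BetaMatrix, m: MValueMatrix, samples: SampleSheet,
                     covariates: pd.DataFrame | None = None,
                     adjust_method: str = "fdr_bh") -> pd.DataFrame:
    """Full per-probe table: delta_beta, t_mod, p_raw, p_adj (auc filled by
    the signature cascade)."""
    fit = fit_probe_models(m, samples, covariates)
    mod = moderate_statistics(fit)
    stats = pd.DataFrame({
        "delta_beta": mean_beta_difference(beta, samples),
        "coef_m": fit.coef,
        "t_mod": mod["t_mod"],
        "p_raw": mod["p_raw"],
    })
    stats["p_adj"] = adjust_bh(stats["p_raw"], method=adjust_method)
    stats["auc"] = np.nan
    return stats
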