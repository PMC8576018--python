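"""Probe QC, value transforms, control matching and cohort-level statistics.

The QC filter mirrors standard methylation-array practice: drop probes that
fail detection (p > 0.01) in any retained sample, probes on the sex
chromosomes, probes with a SNP at the interrogation/extension site, and
known cross-reactive probes.  Linear modelling downstream runs on M-values
(log2-odds); the 10% effect threshold stays on the beta scale.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .containers import (
    BetaMatrix,
    CellReference,
    MValueMatrix,
    ProbeManifest,
    SampleSheet,
    SEX_CHROMS,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    """Counts of probes removed per criterion, in application order.

    A probe is counted once, under the first criterion it hits
    (detection -> sex chromosome -> SNP -> cross-reactive)."""

    n_input: int
    n_detection_fail: int
    n_sex_chrom: int
    n_snp: int
    n_cross_reactive: int
    n_kept: int


@dataclass
class GlobalStats:
    """Cohort-level methylation summaries: per-group medians/means, the two
    per-probe difference distributions (bi-ctrl, mono-ctrl), their KS
    comparison, and the case-vs-control correlation."""

    group_median: dict[str, float]
    group_mean: dict[str, float]
    diff_bi_control: pd.Series
    diff_mono_control: pd.Series
    ks_d: float
    ks_p: float
    pearson_r: float
    r_squared: float


def qc_filter_probes(beta: BetaMatrix, manifest: ProbeManifest,
                     detection_threshold: float = 0.01,
                     ) -> tuple[BetaMatrix, QCReport]:
    """Remove probes failing detection in any sample, on chrX/chrY, with a
    SNP flag or a cross-reactivity flag.  Returns the filtered matrix and a
    per-criterion removal report (first-match counting)."""
    probes = beta.probe_ids
    man = manifest.table.reindex(probes)
    if man["chrom"].isna().any():
        missing = probes[man["chrom"].isna()][:5].tolist()
        raise ValidationError(f"manifest does not cover probes: {missing}")

    if beta.detection_p is not None:
        det_fail = (beta.detection_p.to_numpy() > detection_threshold).any(axis=1)
    else:
        det_fail = np.zeros(len(probes), dtype=bool)
    sex = man["chrom"].isin(SEX_CHROMS).to_numpy()
    snp = man["snp_flag"].to_numpy(dtype=bool)
    cross = man["cross_reactive_flag"].to_numpy(dtype=bool)

    report = QCReport(
        n_input=len(probes),
        n_detection_fail=int(det_fail.sum()),
        n_sex_chrom=int((sex & ~det_fail).sum()),
        n_snp=int((snp & ~det_fail & ~sex).sum()),
        n_cross_reactive=int((cross & ~det_fail & ~sex & ~snp).sum()),
        n_kept=int((~(det_fail | sex | snp | cross)).sum()),
    )
    keep = probes[~(det_fail | sex | snp | cross)]
    if len(keep) == 0:
        raise ValidationError("no probes survive QC")
    logger.info("QC: %d -> %d probes (detection %d, sex %d, SNP %d, cross %d)",
                report.n_input, report.n_kept, report.n_detection_fail,
                report.n_sex_chrom, report.n_snp, report.n_cross_reactive)
    return beta.subset_probes(keep), report


def drop_incomplete(beta: BetaMatrix) -> BetaMatrix:
    """Keep only probes measured in every sample (complete cases)."""
    complete = ~beta.beta.isna().any(axis=1)
    if not complete.any():
        logger.warning("all probes have missing values; result is empty")
    return beta.subset_probes(beta.probe_ids[complete])


def beta_to_m(beta: BetaMatrix, clip_eps: float = 0.001) -> MValueMatrix:
    """M = log2(b/(1-b)) with b clipped to [clip_eps, 1-clip_eps].

    Missing betas stay missing; clipping keeps M finite (|M| < ~10 at the
    default eps)."""
    b = beta.beta.to_numpy(dtype=float)
    clipped = np.clip(b, clip_eps, 1.0 - clip_eps)
    m = np.log2(clipped / (1.0 - clipped))
    m[np.isnan(b)] = np.nan
    return MValueMatrix(pd.DataFrame(m, index=beta.probe_ids,
                                     columns=beta.sample_ids))


def m_to_beta(m: MValueMatrix) -> BetaMatrix:
    """Inverse logit: beta = 2^M / (1 + 2^M)."""
    vals = m.m.to_numpy(dtype=float)
    beta = 1.0 / (1.0 + np.exp2(-vals))
    return BetaMatrix(pd.DataFrame(beta, index=m.probe_ids, columns=m.sample_ids))


def match_controls(cases: SampleSheet, pool: SampleSheet, ratio: int = 5,
                   max_age_gap: float = 10.0) -> list[str]:
    """Greedy nearest-age, same-sex control selection without replacement.

    For each case (in sheet order) pick ``ratio`` same-sex controls closest
    in age; ties broken younger-first, then lexicographic sample id.  A gap
    beyond ``max_age_gap`` is allowed with a warning.  Raises when the pool
    runs dry for some case, naming it.
    """
    overlap = set(cases.sample_ids) & set(pool.sample_ids)
    if overlap:
        raise ValidationError(f"pool overlaps cases: {sorted(overlap)[:5]}")
    available = pool.table.copy()
    chosen: list[str] = []
    for case_id, case in cases.table.iterrows():
        cands = available[available["sex"] == case["sex"]]
        if len(cands) < ratio:
            raise ValidationError(
                f"control pool exhausted for case {case_id!r} "
                f"(sex {case['sex']}: {len(cands)} left, need {ratio})")
        order = cands.assign(_gap=(cands["age_years"] - case["age_years"]).abs())
        # lexicographic id as final tie-break: index-sort first, stable sort after
        order = order.sort_index(kind="stable")
        order = order.sort_values(["_gap", "age_years"], kind="stable")
        picks = order.index[:ratio].tolist()
        worst = order["_gap"].iloc[:ratio].max()
        if worst > max_age_gap:
            logger.warning("case %s: age gap %.1f exceeds %.1f years",
                           case_id, worst, max_age_gap)
        chosen.extend(picks)
        available = available.drop(picks)
    return chosen


def pca_outlier_check(m: MValueMatrix, k: int = 2, z_cut: float = 3.0,
                      ) -> pd.Series:
    """Flag samples whose score on any of the top-k principal components is
    beyond ``z_cut`` robust z-scores (median/MAD)."""
    x = m.m.to_numpy(dtype=float).T  # samples x probes
    if x.shape[0] < 3:
        raise ValidationError("PCA outlier check needs >= 3 samples")
    x = x - x.mean(axis=0)
    k = min(k, min(x.shape) - 1)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :k] * s[:k]
    flags = np.zeros(x.shape[0], dtype=bool)
    for j in range(scores.shape[1]):
        col = scores[:, j]
        med = np.median(col)
        mad = np.median(np.abs(col - med)) * 1.4826
        if mad == 0:
            z = np.where(col == med, 0.0, np.inf)
        else:
            z = np.abs(col - med) / mad
        flags |= z > z_cut
    return pd.Series(flags, index=m.sample_ids, name="pca_outlier")


def estimate_cell_proportions(beta: BetaMatrix, ref: CellReference,
                              ) -> tuple[pd.DataFrame, pd.Series]:
    """Reference-based deconvolution: per sample, least squares of the beta
    profile on the reference columns under proportions >= 0 and sum == 1.

    The equality constraint is enforced by augmenting the NNLS system with a
    heavily weighted sum row, then renormalising.  Returns (proportions
    samples x cell-types, residual norms)."""
    common = beta.probe_ids.intersection(ref.probe_ids)
    n_types = len(ref.cell_types)
    if len(common) < n_types:
        raise ValidationError(
            f"only {len(common)} probes shared with reference; "
            f"need >= {n_types}")
    a = ref.ref_beta.loc[common].to_numpy(dtype=float)
    lam = 1000.0
    a_aug = np.vstack([a, lam * np.ones((1, n_types))])
    props = np.zeros((len(beta.sample_ids), n_types))
    resid = np.zeros(len(beta.sample_ids))
    b_all = beta.beta.loc[common].to_numpy(dtype=float)
    for i in range(b_all.shape[1]):
        b = b_all[:, i]
        mask = ~np.isnan(b)
        a_i = np.vstack([a[mask], lam * np.ones((1, n_types))])
        x, _ = scipy.optimize.nnls(a_i, np.append(b[mask], lam))
        total = x.sum()
        if total > 0:
            x = x / total
        props[i] = x
        resid[i] = float(np.linalg.norm(a[mask] @ x - b[mask]))
    props_df = pd.DataFrame(props, index=beta.sample_ids,
                            columns=ref.cell_types)
    return props_df, pd.Series(resid, index=beta.sample_ids, name="residual")


def global_methylation_stats(beta: BetaMatrix, samples: SampleSheet,
                             ) -> GlobalStats:
    """Cohort-wide summaries: group medians/means over all complete-case
    entries, per-probe (bi - control) and (mono - control) mean differences,
    a two-sample KS test between those two difference distributions
    (asymptotic p), and the Pearson correlation of per-probe bi-allelic vs
    control means."""
    complete = drop_incomplete(beta)
    groups = {
        "case_biallelic": samples.ids_in_group("case_biallelic"),
        "case_monoallelic": samples.ids_in_group("case_monoallelic"),
        "control": samples.ids_in_group("control"),
    }
    for g, ids in groups.items():
        if not ids:
            raise ValidationError(f"group {g!r} has no samples")
    vals = {g: complete.beta[ids].to_numpy() for g, ids in groups.items()}
    medians = {g: float(np.median(v)) for g, v in vals.items()}
    means = {g: float(np.mean(v)) for g, v in vals.items()}

    bi_mean = complete.beta[groups["case_biallelic"]].mean(axis=1)
    mono_mean = complete.beta[groups["case_monoallelic"]].mean(axis=1)
    ctrl_mean = complete.beta[groups["control"]].mean(axis=1)
    diff_bi = bi_mean - ctrl_mean
    diff_mono = mono_mean - ctrl_mean

    ks = scipy.stats.ks_2samp(diff_bi.to_numpy(), diff_mono.to_numpy(),
                              method="asymp")
    r = float(scipy.stats.pearsonr(bi_mean.to_numpy(), ctrl_mean.to_numpy())[0])
    return GlobalStats(
        group_median=medians, group_mean=means,
        diff_bi_control=diff_bi, diff_mono_control=diff_mono,
        ks_d=float(ks.statistic), ks_p=float(ks.pvalue),
        pearson_r=r, r_squared=r * r,
    )
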