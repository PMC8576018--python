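"""The four-stage probe-selection cascade producing an episignature.

Stages: (1) effect-size + significance screen (|delta beta| >= 0.10 and
adjusted p < 0.001), (2) ROC filter keeping probes whose case/control AUC
exceeds 0.9 in either direction, (3) greedy correlation pruning (Pearson
|r| > 0.8 within either the case or the control samples removes the
lower-ranked probe), (4) signature assembly with per-probe direction and
group means.  Stage counts are non-increasing by construction.
"""
from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .containers import BetaMatrix, SampleSheet, Signature, ValidationError

logger = logging.getLogger(__name__)


def select_candidates(stats: pd.DataFrame, delta_min: float = 0.10,
                      p_adj_max: float = 0.001,
                      ) -> tuple[list[str], dict[str, int]]:
    """Effect + significance screen.

    Keeps probes with |delta_beta| >= delta_min (inclusive, 'at least 10%')
    AND p_adj < p_adj_max (strict).  Returns the intersection in input
    order plus the triplet of stage cardinalities.
    """
    by_delta = stats.index[stats["delta_beta"].abs() >= delta_min]
    by_p = stats.index[stats["p_adj"] < p_adj_max]
    both = stats.index[(stats["delta_beta"].abs() >= delta_min)
                       & (stats["p_adj"] < p_adj_max)]
    counts = {"n_delta": len(by_delta), "n_padj": len(by_p),
              "n_both": len(both)}
    logger.info("candidate screen: %(n_delta)d by delta, %(n_padj)d by "
                "adjusted p, %(n_both)d by both", counts)
    return both.tolist(), counts


def pairwise_auc(beta: BetaMatrix, samples: SampleSheet,
                 probes: Sequence[str]) -> pd.Series:
    """Directional ROC AUC per probe: the fraction of (case, control) pairs
    with case beta > control beta, ties counting 1/2 (the Mann-Whitney
    U / (n1*n2) identity, computed via midranks)."""
    case_ids = samples.case_ids
    ctrl_ids = samples.control_ids
    if not case_ids or not ctrl_ids:
        raise ValidationError("need non-empty case and control groups")
    cases = beta.beta.loc[probes, case_ids].to_numpy(dtype=float)
    ctrls = beta.beta.loc[probes, ctrl_ids].to_numpy(dtype=float)
    n1, n2 = cases.shape[1], ctrls.shape[1]
    pooled = np.concatenate([cases, ctrls], axis=1)
    ranks = scipy.stats.rankdata(pooled, axis=1)
    u = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    return pd.Series(u / (n1 * n2), index=pd.Index(probes), name="auc")


def roc_filter(beta: BetaMatrix, samples: SampleSheet,
               probes: Sequence[str], auc_min: float = 0.9,
               ) -> tuple[list[str], pd.Series]:
    """Keep probes separating cases from controls with
    max(AUC, 1-AUC) > auc_min; the directional AUC is returned for all
    candidates (two-sided so the rare hypomethylated probes survive)."""
    auc = pairwise_auc(beta, samples, probes)
    keep = auc.index[np.maximum(auc, 1.0 - auc) > auc_min].tolist()
    logger.info("ROC filter: %d -> %d probes at AUC > %g",
                len(probes), len(keep), auc_min)
    return keep, auc


def correlation_filter(beta: BetaMatrix, samples: SampleSheet,
                       probes: Sequence[str], r_max: float = 0.8,
                       rule: str = "both") -> list[str]:
    """Greedy redundancy pruning over probes ordered by significance.

    Correlations are computed separately within the case-only and the
    control-only samples.  Sweeping the candidate list in order, a probe is
    removed when its Pearson |r| with an already-kept probe exceeds
    ``r_max`` in both groups (``rule='both'``, default) or in either group
    (``rule='either'``).  The default targets genuine redundancy:
    co-methylated probes track each other in cases AND controls, whereas
    the disorder signal itself correlates all signature probes within the
    case group alone, and pruning on that would discard independent
    signature probes.  Zero-variance probes (undefined r) are kept with a
    warning.
    """
    if rule not in ("both", "either"):
        raise ValueError(f"unknown correlation rule {rule!r}")
    probes = list(probes)
    if not probes:
        return []
    case_ids = samples.case_ids
    ctrl_ids = samples.control_ids

    def corr_matrix(ids: list[str]) -> np.ndarray:
        x = beta.beta.loc[probes, ids].to_numpy(dtype=float)
        sd = x.std(axis=1)
        degenerate = sd == 0
        if degenerate.any():
            logger.warning("%d probes have zero variance within a group; "
                           "correlation treated as undefined (kept)",
                           int(degenerate.sum()))
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(x)
        c = np.atleast_2d(c)
        c[np.isnan(c)] = 0.0  # undefined correlation never excludes
        return np.abs(c)

    r_case = corr_matrix(case_ids)
    r_ctrl = corr_matrix(ctrl_ids)
    kept_idx: list[int] = []
    for i in range(len(probes)):
        if rule == "both":
            ok = all(r_case[i, j] <= r_max or r_ctrl[i, j] <= r_max
                     for j in kept_idx)
        else:
            ok = all(r_case[i, j] <= r_max and r_ctrl[i, j] <= r_max
                     for j in kept_idx)
        if ok:
            kept_idx.append(i)
    kept = [probes[i] for i in kept_idx]
    logger.info("correlation filter: %d -> %d probes at |r| <= %g",
                len(probes), len(kept), r_max)
    return kept


def build_signature(beta: BetaMatrix, samples: SampleSheet,
                    probes: Sequence[str], stats: pd.DataFrame | None = None,
                    provenance: dict | None = None) -> Signature:
    """Assemble the episignature: per-probe direction (sign of the
    case-control beta difference), group mean betas and full provenance."""
    probes = list(probes)
    if not probes:
        raise ValidationError("no signature probes")
    if len(set(probes)) != len(probes):
        raise ValidationError("duplicate probes in signature")
    case_mean = beta.beta.loc[probes, samples.case_ids].mean(axis=1)
    ctrl_mean = beta.beta.loc[probes, samples.control_ids].mean(axis=1)
    delta = case_mean - ctrl_mean
    table = pd.DataFrame({
        "direction": np.where(delta >= 0, "hyper", "hypo"),
        "mean_beta_case": case_mean,
        "mean_beta_control": ctrl_mean,
        "delta_beta": delta,
    }, index=pd.Index(probes, name="probe_id"))
    if stats is not None:
        table["p_adj"] = stats.loc[probes, "p_adj"]
        table["auc"] = stats.loc[probes, "auc"]
        table = table.sort_values("p_adj", kind="stable")
    prov = dict(provenance or {})
    prov.setdefault("n_cases", len(samples.case_ids))
    prov.setdefault("n_controls", len(samples.control_ids))
    prov["n_probes"] = len(probes)
    return Signature(table, prov)


def signature_overlap(a: Signature, b: Signature) -> int:
    """Number of probes shared between two signatures (e.g. across
    re-discovery rounds on enlarged cohorts)."""
    return len(set(a.probe_ids) & set(b.probe_ids))


def discover_signature(beta: BetaMatrix, samples: SampleSheet,
                       stats: pd.DataFrame, delta_min: float = 0.10,
                       p_adj_max: float = 0.001, auc_min: float = 0.9,
                       r_max: float = 0.8, corr_rule: str = "both") -> Signature:
    """Run the full cascade on a QC'd cohort and its probe statistics."""
    candidates, counts = select_candidates(stats, delta_min, p_adj_max)
    # rank candidates by ascending adjusted p before the greedy stages
    candidates = (stats.loc[candidates, "p_adj"]
                  .sort_values(kind="stable").index.tolist())
    after_roc, auc = roc_filter(beta, samples, candidates, auc_min)
    stats = stats.copy()
    stats.loc[auc.index, "auc"] = auc
    final = correlation_filter(beta, samples, after_roc, r_max, rule=corr_rule)
    provenance = {
        "delta_min": delta_min, "p_adj_max": p_adj_max,
        "auc_min": auc_min, "r_max": r_max, "corr_rule": corr_rule,
        "stage_counts": {**counts, "n_after_roc": len(after_roc),
                         "n_final": len(final)},
    }
    return build_signature(beta, samples, final, stats, provenance)
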