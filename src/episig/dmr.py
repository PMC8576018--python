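"""Rule-based differentially methylated region (DMR) calling.

Per chromosome, significant CpGs (adjusted p below ``sig_p``) are chained:
consecutive significant CpGs at most ``max_gap`` bp apart join one cluster.
A cluster with at least ``min_cpgs`` significant CpGs becomes a candidate
region spanning its first to last significant CpG; it is reported when the
regional mean beta difference over ALL array CpGs inside the span reaches
``delta_min`` in magnitude and Fisher's combined p over the raw p-values of
all span CpGs is below ``fisher_p_max``.  Clusters are disjoint by
construction, so candidate regions never overlap.
"""
from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .containers import BetaMatrix, DMRSet, ProbeManifest, SampleSheet, ValidationError

logger = logging.getLogger(__name__)


def fisher_combine(p: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's method: X2 = -2 * sum(ln p_i) ~ chi-square with 2k df.

    Zero p-values are clipped to 1e-300 with a warning."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValidationError("cannot combine zero p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values outside [0, 1]")
    if (p == 0).any():
        logger.warning("p-value of 0 clipped to 1e-300 in Fisher combination")
        p = np.clip(p, 1e-300, 1.0)
    chi2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return chi2, df, float(scipy.stats.chi2.sf(chi2, df))


def find_dmrs(stats: pd.DataFrame, manifest: ProbeManifest,
              sig_p: float = 0.01, min_cpgs: int = 5, max_gap: int = 1000,
              delta_min: float = 0.10, fisher_p_max: float = 0.01,
              window_mode: str = "chain") -> DMRSet:
    """Call DMRs from per-probe statistics (columns delta_beta, p_raw,
    p_adj) and manifest positions.

    ``window_mode='chain'`` (default) joins consecutive significant CpGs
    whose gap is <= max_gap; ``'strict'`` additionally requires the whole
    significant-CpG span to fit within max_gap.  Output is sorted by
    combined p and is invariant to manifest row order.
    """
    if window_mode not in ("chain", "strict"):
        raise ValueError(f"unknown window_mode {window_mode!r}")
    probes = stats.index
    man = manifest.table.reindex(probes)
    if man["pos"].isna().any():
        missing = probes[man["pos"].isna()][:5].tolist()
        raise ValidationError(f"manifest lacks positions for: {missing}")

    df = pd.DataFrame({
        "chrom": man["chrom"], "pos": man["pos"].astype(int),
        "delta_beta": stats["delta_beta"], "p_raw": stats["p_raw"],
        "p_adj": stats["p_adj"],
    }).sort_values(["chrom", "pos"], kind="stable")

    records = []
    for chrom, chrom_df in df.groupby("chrom", sort=True):
        sig = chrom_df[chrom_df["p_adj"] < sig_p]
        if len(sig) < min_cpgs:
            continue
        pos = sig["pos"].to_numpy()
        breaks = np.where(np.diff(pos) > max_gap)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for s, e in zip(starts, ends):
            n_sig = e - s + 1
            if n_sig < min_cpgs:
                continue
            lo, hi = int(pos[s]), int(pos[e])
            if window_mode == "strict" and hi - lo > max_gap:
                continue
            span = chrom_df[(chrom_df["pos"] >= lo) & (chrom_df["pos"] <= hi)]
            mean_delta = float(span["delta_beta"].mean())
            chi2, fdf, comb_p = fisher_combine(span["p_raw"].to_numpy())
            if abs(mean_delta) < delta_min or comb_p >= fisher_p_max:
                continue
            records.append({
                "chrom": chrom, "start": lo, "end": hi,
                "n_cpgs_total": len(span), "n_cpgs_significant": int(n_sig),
                "mean_delta_beta": mean_delta, "fisher_chi2": chi2,
                "fisher_df": fdf, "combined_p": comb_p,
                "direction": "hyper" if mean_delta >= 0 else "hypo",
                "probe_ids": span.index.tolist(),
            })
    table = pd.DataFrame(records, columns=[
        "chrom", "start", "end", "n_cpgs_total", "n_cpgs_significant",
        "mean_delta_beta", "fisher_chi2", "fisher_df", "combined_p",
        "direction", "probe_ids"])
    if len(table):
        table = table.sort_values("combined_p", kind="stable").reset_index(drop=True)
    logger.info("DMR calling: %d regions", len(table))
    return DMRSet(table)


def annotate_dmrs(dmrs: DMRSet, manifest: ProbeManifest) -> DMRSet:
    """Attach the union of gene annotations of all CpGs in each span and a
    TSS-overlap flag; unannotated regions are labelled intergenic."""
    table = dmrs.table.copy()
    genes_col, tss_col = [], []
    for _, row in table.iterrows():
        seen: dict[tuple[str, str], None] = {}
        for probe in row["probe_ids"]:
            if probe in manifest.table.index:
                for pair in manifest.table.loc[probe, "genes"]:
                    seen.setdefault(tuple(pair))
        genes = list(seen)
        genes_col.append(genes)
        tss_col.append(any(region == "TSS" for _, region in genes))
    table["genes"] = genes_col
    table["tss_overlap"] = tss_col
    return DMRSet(table)


def dmr_cohort_compare(dmrs: DMRSet, beta_other: BetaMatrix,
                       samples_other: SampleSheet,
                       ) -> tuple[pd.DataFrame, int]:
    """Directional agreement of another cohort at each DMR.

    Per DMR, the sign of (case mean - control mean) regional beta in the
    other cohort is compared with the DMR's own direction; DMRs with no
    covered CpGs in the other cohort are excluded and logged.  Returns the
    per-DMR table and the count of agreeing DMRs (the 'x of n' statistic).
    """
    case_ids = samples_other.case_ids or samples_other.ids_in_group("query")
    ctrl_ids = samples_other.control_ids
    if not case_ids or not ctrl_ids:
        raise ValidationError("other cohort needs case/query and control samples")
    rows = []
    for idx, row in dmrs.table.iterrows():
        covered = [p for p in row["probe_ids"] if p in beta_other.beta.index]
        if not covered:
            logger.info("DMR %s:%d-%d has no covered CpGs in other cohort",
                        row["chrom"], row["start"], row["end"])
            continue
        sub = beta_other.beta.loc[covered]
        delta = float(sub[case_ids].mean(axis=1).mean()
                      - sub[ctrl_ids].mean(axis=1).mean())
        other_dir = "hyper" if delta >= 0 else "hypo"
        rows.append({
            "chrom": row["chrom"], "start": row["start"], "end": row["end"],
            "direction": row["direction"], "other_delta_beta": delta,
            "other_direction": other_dir,
            "agrees": other_dir == row["direction"],
        })
    out = pd.DataFrame(rows)
    n_agree = int(out["agrees"].sum()) if len(out) else 0
    return out, n_agree
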