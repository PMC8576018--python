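"""End-to-end drivers tying the stages together.

`run_discovery` takes a raw beta matrix + sample sheet + manifest to a
Signature and the per-probe statistics table; `evaluate_recovery` scores a
signature against a simulation's ground truth.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import diffmeth, preprocess, signature as sig
from .config import PipelineConfig
from .containers import (BetaMatrix, CellReference, ProbeManifest,
                         SampleSheet, Signature)
from .simulate import TruthSet

logger = logging.getLogger(__name__)


@dataclass
class DiscoveryResult:
    signature: Signature
    stats: pd.DataFrame
    beta_qc: BetaMatrix
    qc_report: preprocess.QCReport
    cell_proportions: pd.DataFrame | None


def run_discovery(beta: BetaMatrix, samples: SampleSheet,
                  manifest: ProbeManifest,
                  cell_reference: CellReference | None = None,
                  config: PipelineConfig | None = None) -> DiscoveryResult:
    """QC -> complete cases -> M transform -> (optional deconvolution
    covariates) -> moderated per-probe models -> selection cascade."""
    cfg = config or PipelineConfig()
    beta_qc, report = preprocess.qc_filter_probes(
        beta, manifest, detection_threshold=cfg.detection_threshold)
    beta_qc = preprocess.drop_incomplete(beta_qc)
    m = preprocess.beta_to_m(beta_qc, clip_eps=cfg.clip_eps)

    covariates = None
    if cell_reference is not None:
        covariates, _ = preprocess.estimate_cell_proportions(beta_qc,
                                                             cell_reference)
    stats = diffmeth.probe_statistics(beta_qc, m, samples,
                                      covariates=covariates,
                                      adjust_method=cfg.adjust_method)
    signature = sig.discover_signature(
        beta_qc, samples, stats, delta_min=cfg.delta_min,
        p_adj_max=cfg.p_adj_max, auc_min=cfg.auc_min, r_max=cfg.r_max,
        corr_rule=cfg.corr_rule)
    return DiscoveryResult(signature=signature, stats=stats,
                           beta_qc=beta_qc, qc_report=report,
                           cell_proportions=covariates)


def evaluate_recovery(signature: Signature, truth: TruthSet,
                      ) -> dict[str, float]:
    """Sensitivity and precision of a discovered signature against the
    planted probe set."""
    selected = set(signature.probe_ids)
    planted = truth.signature_probe_ids
    tp = len(selected & planted)
    sensitivity = tp / len(planted) if planted else float("nan")
    precision = tp / len(selected) if selected else float("nan")
    return {"n_selected": len(selected), "n_planted": len(planted),
            "n_true_positive": tp, "sensitivity": sensitivity,
            "precision": precision}
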