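"""Discover an episignature and check it against the planted truth.

Runs the full discovery pipeline — probe QC, logit (M-value) transform,
cell-composition deconvolution, moderated per-probe linear models, then the
four-stage selection cascade (|delta beta| >= 0.10 & adjusted p < 0.001,
ROC AUC > 0.9, correlation pruning at r > 0.8).
"""
from episig import SimulationConfig, evaluate_recovery, run_discovery
from episig.simulate import _build_manifest, simulate_cohort

cfg = SimulationConfig(seed=7)  # 16 cases vs 64 controls, 20,000 probes
manifest, _, _ = _build_manifest(cfg)
beta, samples, truth, cell_ref = simulate_cohort(cfg, manifest)

result = run_discovery(beta, samples, manifest, cell_reference=cell_ref)
counts = result.signature.provenance["stage_counts"]
print("cascade: "
      f"{counts['n_delta']} probes pass |delta beta| >= 0.10, "
      f"{counts['n_padj']} pass adjusted p < 0.001, "
      f"{counts['n_both']} pass both;")
print(f"         {counts['n_after_roc']} survive ROC AUC > 0.9, "
      f"{counts['n_final']} survive correlation pruning "
      "(the episignature)")

rec = evaluate_recovery(result.signature, truth)
print(f"\nrecovery vs planted truth: sensitivity {rec['sensitivity']:.2f}, "
      f"precision {rec['precision']:.2f}")
print("-> most planted probes are recovered and essentially nothing else; "
      "misses are planted probes whose sampled effect fell under the 10% "
      "threshold")
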