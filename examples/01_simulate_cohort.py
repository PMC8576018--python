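"""Simulate a methylation cohort with a planted episignature.

Builds a small EPIC-like cohort (8 bi-allelic + 8 mono-allelic cases vs 32
controls) in which 120 probes carry a hypermethylation signature — a 0.15
beta shift in bi-allelic carriers, halved in mono-allelic carriers — partly
arranged in tight CpG clusters that a DMR caller should find.
"""
import numpy as np

from episig import SimulationConfig, simulate_cohort

cfg = SimulationConfig(n_probes=5000, n_signature_probes=120,
                       n_clusters=6, cluster_size=6,
                       n_case_bi=8, n_case_mono=8, n_control_pool=32,
                       seed=1)
beta, samples, truth, cell_ref = simulate_cohort(cfg)

print(f"cohort: {beta.shape[0]} probes x {beta.shape[1]} samples")
print(samples.table["group"].value_counts().to_string())

planted = sorted(truth.signature_probe_ids)
bi = samples.ids_in_group("case_biallelic")
mono = samples.ids_in_group("case_monoallelic")
ctrl = samples.control_ids
d_bi = (beta.beta.loc[planted, bi].mean(axis=1)
        - beta.beta.loc[planted, ctrl].mean(axis=1)).mean()
d_mono = (beta.beta.loc[planted, mono].mean(axis=1)
          - beta.beta.loc[planted, ctrl].mean(axis=1)).mean()
print(f"\nrealised beta shift at planted probes: "
      f"bi-allelic {d_bi:.3f}, mono-allelic {d_mono:.3f}")
print("-> the dose effect: bi-allelic carriers shift ~2x further than "
      "mono-allelic, both hypermethylated")
print(f"planted DMR clusters: {len(truth.dmr_truth)} "
      f"(first: {truth.dmr_truth[0]})")
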