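"""Cohort-level methylation summaries: medians, difference distributions,
KS test and the case/control correlation.

These are the genome-wide statistics one inspects before any signature
work: the global methylation shift is tiny (group medians nearly equal,
per-probe case and control means correlate almost perfectly), yet the two
difference distributions (bi-allelic minus control vs mono-allelic minus
control) differ detectably — the dose effect at genome scale.
"""
from episig import SimulationConfig
from episig.preprocess import global_methylation_stats
from episig.simulate import simulate_cohort

cfg = SimulationConfig(seed=7)
beta, samples, truth, _ = simulate_cohort(cfg)

stats = global_methylation_stats(beta, samples)
for g in ("control", "case_monoallelic", "case_biallelic"):
    print(f"{g:17s} median beta {stats.group_median[g]:.3f}  "
          f"mean beta {stats.group_mean[g]:.3f}")
print(f"\nKS test bi-vs-mono difference distributions: "
      f"D = {stats.ks_d:.3f}, p = {stats.ks_p:.3g}")
print(f"bi-allelic vs control per-probe means: r^2 = {stats.r_squared:.4f}")
print("-> a small D yet p < 0.05: the genome-wide shift is subtle but "
      "systematic, while r^2 near 1 says the methylation landscapes are "
      "otherwise almost identical")
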