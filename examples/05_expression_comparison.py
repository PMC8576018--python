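"""Compare DMR-associated gene expression to background genes.

Each DMR contributes its highest-expressed annotated gene; the set is then
tested against all other genes with a one-tailed Wilcoxon rank-sum test
(alternative: DMR genes expressed higher), per cell type.
"""
from episig import SimulationConfig, run_discovery
from episig.dmr import annotate_dmrs, find_dmrs
from episig.expression import compare_expression, map_dmr_genes
from episig.simulate import (_build_manifest, simulate_cohort,
                             simulate_expression)

cfg = SimulationConfig(seed=7)
manifest, _, _ = _build_manifest(cfg)
beta, samples, truth, cell_ref = simulate_cohort(cfg, manifest)
result = run_discovery(beta, samples, manifest, cell_reference=cell_ref)
dmrs = annotate_dmrs(find_dmrs(result.stats, manifest), manifest)

expr = simulate_expression([f"GENE{k:03d}" for k in range(cfg.n_clusters)],
                           n_background=2000, enrichment=1.0, seed=7)
for cell_type in ("excitatory_neurons", "inhibitory_neurons"):
    genes = map_dmr_genes(dmrs, expr, cell_type)
    background = [g for g in expr.gene_ids if g not in set(genes)]
    res = compare_expression(genes, background, expr, cell_type)
    print(f"{cell_type}: {res.n_dmr_genes} DMR genes vs "
          f"{res.n_background_genes} background, one-tailed p = "
          f"{res.p_one_tailed:.3g}")
print("-> p near the 0.05 level: the generator plants a one-log-unit "
      "enrichment, but with only ~10 DMR genes the rank test has modest "
      "power; more regions sharpen it")
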