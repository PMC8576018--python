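"""Synthetic methylation cohorts with planted episignatures.

The generator works on the M scale (logit-normal on beta): per probe *p* and
sample *s*,

    M(p, s) = mu_p + delta_p * g(s) + gamma_p . c(s) + eps,   eps ~ N(0, noise_sd)
    beta    = 2^M / (1 + 2^M)

where ``g(s)`` is 1 for bi-allelic cases, ``dose_factor`` encodes the weaker
mono-allelic effect, ``c(s)`` is the sample's leukocyte composition and
``gamma_p`` a per-probe composition loading (the confounder the linear model
must absorb).  ``delta_p`` is chosen so the *beta-scale* mean shift at the
probe's baseline equals ``effect_bi`` (bi-allelic) or
``effect_bi * dose_factor`` (mono-allelic).

Planted signature probes emulate CpG-island promoter probes that gain
methylation: their baseline beta is drawn from a low, unmethylated range,
while background probes follow a broad blood-like M-scale baseline.
A subset of the planted probes is laid out as tight genomic clusters so the
DMR caller has recoverable regions; the rest are scattered.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (
    BetaMatrix,
    CellReference,
    ExpressionMatrix,
    ProbeManifest,
    SampleSheet,
    ValidationError,
)

#: declared genome: 22 autosomes + sex chromosomes, toy 50 Mb lengths
GENOME = {f"chr{i}": 50_000_000 for i in range(1, 23)}
GENOME["chrX"] = 50_000_000
GENOME["chrY"] = 10_000_000

CELL_TYPES = ("neutrophils", "cd4t", "cd8t", "bcells", "nk", "monocytes")
_BASE_PROPS = np.array([0.55, 0.15, 0.10, 0.05, 0.05, 0.10])


def _logit2(b: np.ndarray | float) -> np.ndarray | float:
    return np.log2(b / (1.0 - b))


def _expit2(m: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp2(-m))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the final discovery design: 8 bi-allelic + 8 mono-allelic
    cases against a pool of 64 matched controls, 20,000 probes of which 300
    carry a planted hypermethylation signature with a 0.15 beta shift in
    bi-allelic cases, halved in mono-allelic cases.
    """

    n_probes: int = 20_000
    n_signature_probes: int = 300
    n_case_bi: int = 8
    n_case_mono: int = 8
    n_control_pool: int = 64
    effect_bi: float = 0.15
    dose_factor: float = 0.5
    baseline_mu: float = 1.9     # M-scale background mean (beta ~ 0.79)
    baseline_sd: float = 1.5     # M-scale background spread
    sig_baseline_range: tuple[float, float] = (0.03, 0.10)  # beta, island-like
    noise_sd: float = 0.5        # per-sample M-scale noise
    n_clusters: int = 10
    cluster_size: int = 6
    cluster_gap: int = 150       # bp between consecutive clustered CpGs
    n_cell_types: int = 6
    dirichlet_conc: float = 60.0
    confounding_strength: float = 1.0
    confounded_fraction: float = 0.10
    detection_fail_rate: float = 1e-4
    frac_on_450k: float = 0.5
    frac_snp: float = 0.02
    frac_cross: float = 0.03
    frac_sex_chrom: float = 0.03
    age_range: tuple[float, float] = (2.0, 65.0)
    sex_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.effect_bi < 1.0):
            raise ValidationError("effect_bi must be in (0, 1)")
        if not (0.0 < self.dose_factor <= 1.0):
            raise ValidationError("dose_factor must be in (0, 1]")
        for name in ("n_probes", "n_signature_probes", "n_case_bi",
                     "n_case_mono", "n_control_pool", "n_clusters",
                     "cluster_size"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (1 <= self.n_cell_types <= len(CELL_TYPES)):
            raise ValidationError("n_cell_types must be between 1 and 6")
        if self.n_signature_probes > self.n_probes:
            raise ValidationError("more signature probes than probes")
        if self.n_clusters * self.cluster_size > self.n_signature_probes:
            raise ValidationError("clusters exceed signature probe budget")


@dataclass
class TruthSet:
    """Ground truth of a simulated cohort, for recovery scoring."""

    signature_probe_ids: set[str]
    dmr_truth: list[tuple[str, int, int]]  # (chrom, start, end) 1-based incl.
    true_delta_beta: pd.DataFrame  # probes x {case_biallelic, case_monoallelic}


def _place_clusters(cfg: SimulationConfig, rng: np.random.Generator,
                    autosomes: list[str]) -> list[tuple[str, np.ndarray]]:
    """Place non-overlapping CpG clusters; bounded retries on collision."""
    placed: list[tuple[str, np.ndarray]] = []
    span = (cfg.cluster_size - 1) * cfg.cluster_gap
    for _ in range(cfg.n_clusters):
        for attempt in itertools.count():
            if attempt >= 100:
                raise ValidationError("could not place non-overlapping clusters")
            chrom = autosomes[rng.integers(len(autosomes))]
            if GENOME[chrom] <= span + 2:
                continue
            start = int(rng.integers(1, GENOME[chrom] - span))
            ok = all(c != chrom or start > s + span + 2000 or s > start + span + 2000
                     for c, s in ((c, int(pos[0])) for c, pos in placed))
            if ok:
                pos = start + cfg.cluster_gap * np.arange(cfg.cluster_size)
                placed.append((chrom, pos))
                break
    return placed


def _build_manifest(cfg: SimulationConfig) -> tuple[ProbeManifest, list[str],
                                                    list[tuple[str, int, int]]]:
    """Deterministic manifest + planted probe ids + true cluster intervals."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    autosomes = [c for c in GENOME if c not in ("chrX", "chrY")]

    clusters = _place_clusters(cfg, rng, autosomes)
    n_clustered = cfg.n_clusters * cfg.cluster_size
    n_scatter_sig = cfg.n_signature_probes - n_clustered
    n_background = cfg.n_probes - cfg.n_signature_probes

    chroms: list[str] = []
    positions: list[int] = []
    is_sig: list[bool] = []
    genes: list[list[tuple[str, str]]] = []
    dmr_truth: list[tuple[str, int, int]] = []

    for k, (chrom, pos) in enumerate(clusters):
        dmr_truth.append((chrom, int(pos[0]), int(pos[-1])))
        for p in pos:
            chroms.append(chrom)
            positions.append(int(p))
            is_sig.append(True)
            genes.append([(f"GENE{k:03d}", "TSS")])

    for _ in range(n_scatter_sig):
        chrom = autosomes[rng.integers(len(autosomes))]
        chroms.append(chrom)
        positions.append(int(rng.integers(1, GENOME[chrom])))
        is_sig.append(True)
        genes.append([])

    n_sex = int(round(cfg.frac_sex_chrom * n_background))
    for i in range(n_background):
        if i < n_sex:
            chrom = "chrX" if rng.random() < 0.8 else "chrY"
        else:
            chrom = autosomes[rng.integers(len(autosomes))]
        chroms.append(chrom)
        positions.append(int(rng.integers(1, GENOME[chrom])))
        is_sig.append(False)
        if rng.random() < 0.05:
            genes.append([(f"BG{rng.integers(5000):04d}",
                           "body" if rng.random() < 0.6 else "TSS")])
        else:
            genes.append([])

    n = len(chroms)
    order = rng.permutation(n)
    probe_ids = [f"cg{i:07d}" for i in range(n)]
    sig_flags = np.asarray(is_sig)[order]
    # planted probes are clean autosomal probes; QC flags only on background
    snp = (rng.random(n) < cfg.frac_snp) & ~sig_flags
    cross = (rng.random(n) < cfg.frac_cross) & ~sig_flags & ~snp
    table = pd.DataFrame({
        "chrom": np.asarray(chroms)[order],
        "pos": np.asarray(positions)[order],
        "on_450k": rng.random(n) < cfg.frac_on_450k,
        "snp_flag": snp,
        "cross_reactive_flag": cross,
        "genes": [genes[i] for i in order],
    }, index=pd.Index(probe_ids, name="probe_id"))
    planted = [probe_ids[i] for i in range(n) if sig_flags[i]]
    return ProbeManifest(table), planted, dmr_truth


def simulate_manifest(cfg: SimulationConfig) -> ProbeManifest:
    """Synthetic probe manifest: background probes uniform over the genome,
    planted clusters of closely spaced CpGs, ~``frac_on_450k`` probes shared
    with the 450K platform."""
    manifest, _, _ = _build_manifest(cfg)
    return manifest


def _delta_m_for_beta_shift(beta0: np.ndarray, shift: float) -> np.ndarray:
    """M-scale offset giving a beta-scale shift of `shift` at baseline beta0."""
    target = np.clip(beta0 + shift, 1e-6, 1.0 - 1e-6)
    return _logit2(target) - _logit2(np.clip(beta0, 1e-6, 1.0 - 1e-6))


def _sample_sheet(cfg: SimulationConfig, rng: np.random.Generator) -> SampleSheet:
    rows = []
    for i in range(cfg.n_case_bi):
        rows.append((f"bi{i + 1:02d}", "case_biallelic"))
    for i in range(cfg.n_case_mono):
        rows.append((f"mono{i + 1:02d}", "case_monoallelic"))
    for i in range(cfg.n_control_pool):
        rows.append((f"ctl{i + 1:03d}", "control"))
    ids = [r[0] for r in rows]
    lo, hi = cfg.age_range
    table = pd.DataFrame({
        "group": [r[1] for r in rows],
        "age_years": np.round(rng.uniform(lo, hi, len(rows)), 1),
        "sex": np.where(rng.random(len(rows)) < cfg.sex_ratio, "F", "M"),
        "batch": "b1",
    }, index=pd.Index(ids, name="sample_id"))
    return SampleSheet(table)


def simulate_cohort(cfg: SimulationConfig,
                    manifest: ProbeManifest | None = None,
                    ) -> tuple[BetaMatrix, SampleSheet, TruthSet, CellReference]:
    """Simulate a case/control cohort with a planted dose-dependent
    hypermethylation signature, composition confounding and detection-p
    failures.  Pure function of the config (including its seed)."""
    built_manifest, planted, dmr_truth = _build_manifest(cfg)
    if manifest is None:
        manifest = built_manifest
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))

    probe_ids = manifest.probe_ids
    n_probes = len(probe_ids)
    planted_mask = probe_ids.isin(planted).astype(bool)

    samples = _sample_sheet(cfg, rng)
    n_samples = len(samples.table)
    group = samples.table["group"].to_numpy()
    dose = np.where(group == "case_biallelic", 1.0,
                    np.where(group == "case_monoallelic", cfg.dose_factor, 0.0))

    # baselines: broad blood-like M for background, low beta for planted
    mu = rng.normal(cfg.baseline_mu, cfg.baseline_sd, n_probes)
    lo, hi = cfg.sig_baseline_range
    sig_beta0 = rng.uniform(lo, hi, int(planted_mask.sum()))
    mu[planted_mask] = _logit2(sig_beta0)
    beta0 = _expit2(mu)

    # planted beta-scale shifts -> per-probe, per-group M offsets
    delta_bi = np.zeros(n_probes)
    delta_mono = np.zeros(n_probes)
    delta_bi[planted_mask] = _delta_m_for_beta_shift(beta0[planted_mask],
                                                     cfg.effect_bi)
    delta_mono[planted_mask] = _delta_m_for_beta_shift(
        beta0[planted_mask], cfg.effect_bi * cfg.dose_factor)

    # cell composition and per-probe composition loadings
    base_props = _BASE_PROPS[:cfg.n_cell_types]
    base_props = base_props / base_props.sum()
    comp = rng.dirichlet(cfg.dirichlet_conc * base_props, size=n_samples)
    gamma = np.zeros((n_probes, cfg.n_cell_types))
    conf_mask = (rng.random(n_probes) < cfg.confounded_fraction) & ~planted_mask
    gamma[conf_mask] = rng.normal(0.0, cfg.confounding_strength,
                                  (int(conf_mask.sum()), cfg.n_cell_types))
    comp_effect = gamma @ (comp - base_props).T  # centred: zero at mean comp

    eps = rng.normal(0.0, cfg.noise_sd, (n_probes, n_samples))
    is_bi = group == "case_biallelic"
    is_mono = group == "case_monoallelic"
    m = (mu[:, None] + delta_bi[:, None] * is_bi[None, :]
         + delta_mono[:, None] * is_mono[None, :] + comp_effect + eps)
    beta = _expit2(m)

    det = rng.uniform(0.0, 0.005, (n_probes, n_samples))
    fails = rng.random((n_probes, n_samples)) < cfg.detection_fail_rate
    det[fails] = rng.uniform(0.011, 0.2, int(fails.sum()))

    beta_df = pd.DataFrame(beta, index=probe_ids, columns=samples.sample_ids)
    det_df = pd.DataFrame(det, index=probe_ids, columns=samples.sample_ids)

    ref_beta = _expit2(mu[:, None] + gamma)
    ref = CellReference(pd.DataFrame(ref_beta, index=probe_ids,
                                     columns=list(CELL_TYPES[:cfg.n_cell_types])))

    truth = TruthSet(
        signature_probe_ids=set(planted),
        dmr_truth=dmr_truth,
        true_delta_beta=pd.DataFrame(
            {"case_biallelic": np.where(planted_mask, cfg.effect_bi, 0.0),
             "case_monoallelic": np.where(planted_mask,
                                          cfg.effect_bi * cfg.dose_factor, 0.0)},
            index=probe_ids),
    )
    return BetaMatrix(beta_df, det_df), samples, truth, ref


def simulate_disorder_cohort(cfg: SimulationConfig,
                             manifest: ProbeManifest,
                             planted_ids: set[str],
                             n_cases: int,
                             effect: float,
                             seed: int,
                             prefix: str = "oth") -> tuple[BetaMatrix, SampleSheet]:
    """Cases from a *different* disorder: same background process, its own
    planted hypermethylation set ``planted_ids`` (which may partially overlap
    another signature).  Used for cross-disorder specificity studies."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, seed, 303]))
    base_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))

    _, tet3_planted, _ = _build_manifest(cfg)
    probe_ids = manifest.probe_ids
    n_probes = len(probe_ids)

    # reproduce the same per-probe baselines as simulate_cohort
    tet3_mask = probe_ids.isin(tet3_planted).astype(bool)
    mu = base_rng.normal(cfg.baseline_mu, cfg.baseline_sd, n_probes)
    lo, hi = cfg.sig_baseline_range
    mu[tet3_mask] = _logit2(base_rng.uniform(lo, hi, int(tet3_mask.sum())))
    beta0 = _expit2(mu)

    mask = probe_ids.isin(list(planted_ids)).astype(bool)
    delta = np.zeros(n_probes)
    delta[mask] = _delta_m_for_beta_shift(beta0[mask], effect)

    eps = rng.normal(0.0, cfg.noise_sd, (n_probes, n_cases))
    beta = _expit2(mu[:, None] + delta[:, None] + eps)
    ids = [f"{prefix}{i + 1:02d}" for i in range(n_cases)]
    lo_a, hi_a = cfg.age_range
    sheet = SampleSheet(pd.DataFrame({
        "group": "query",
        "age_years": np.round(rng.uniform(lo_a, hi_a, n_cases), 1),
        "sex": np.where(rng.random(n_cases) < cfg.sex_ratio, "F", "M"),
        "batch": "b2",
    }, index=pd.Index(ids, name="sample_id")))
    return BetaMatrix(pd.DataFrame(beta, index=probe_ids, columns=ids)), sheet


def simulate_mixture(ref: CellReference, proportions: np.ndarray,
                     noise_sd: float, seed: int) -> pd.DataFrame:
    """Beta-scale mixtures of reference profiles plus Gaussian beta noise,
    for deconvolution recovery studies.  ``proportions`` is samples x
    cell-types, rows on the simplex."""
    props = np.asarray(proportions, dtype=float)
    if props.ndim == 1:
        props = props[None, :]
    if not np.allclose(props.sum(axis=1), 1.0, atol=1e-8):
        raise ValidationError("mixture proportions must sum to 1")
    rng = np.random.default_rng(seed)
    mix = ref.ref_beta.to_numpy() @ props.T
    mix = np.clip(mix + rng.normal(0.0, noise_sd, mix.shape), 0.0, 1.0)
    cols = [f"mix{i + 1:02d}" for i in range(props.shape[0])]
    return pd.DataFrame(mix, index=ref.probe_ids, columns=cols)


def simulate_expression(dmr_genes: list[str], n_background: int,
                        enrichment: float, seed: int,
                        cell_types: tuple[str, ...] = ("excitatory_neurons",
                                                       "inhibitory_neurons"),
                        ) -> ExpressionMatrix:
    """Log-normal TPM per cell type; DMR-associated genes get a location
    shift of ``enrichment`` on the natural-log scale.  The expressed-cell
    proportion is a saturating monotone transform of TPM."""
    if enrichment < 0:
        raise ValidationError("enrichment must be >= 0")
    if n_background <= 0:
        raise ValidationError("n_background must be positive: "
                              "comparison undefined without background genes")
    rng = np.random.default_rng(seed)
    genes = list(dmr_genes) + [f"BGGENE{i:05d}" for i in range(n_background)]
    n = len(genes)
    base = rng.normal(1.0, 1.2, n)  # shared gene-level effect
    tpm = {}
    for ct in cell_types:
        log_tpm = base + rng.normal(0.0, 0.8, n)
        log_tpm[:len(dmr_genes)] += enrichment
        tpm[ct] = np.exp(log_tpm)
    tpm_df = pd.DataFrame(tpm, index=pd.Index(genes, name="gene_id"))
    prop = tpm_df / (tpm_df + 5.0)
    return ExpressionMatrix(tpm_df, prop)
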