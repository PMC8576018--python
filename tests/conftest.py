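import numpy as np
import pandas as pd
import pytest

from episig.containers import BetaMatrix, ProbeManifest, SampleSheet
from episig.simulate import SimulationConfig, _build_manifest, simulate_cohort


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(
        n_probes=2000, n_signature_probes=60, n_clusters=4, cluster_size=6,
        n_case_bi=4, n_case_mono=4, n_control_pool=16, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    manifest, _, _ = _build_manifest(small_cfg)
    beta, samples, truth, ref = simulate_cohort(small_cfg, manifest)
    return {"manifest": manifest, "beta": beta, "samples": samples,
            "truth": truth, "ref": ref}


def make_manifest(rows) -> ProbeManifest:
    """rows: (probe_id, chrom, pos, on_450k, snp, cross, genes)."""
    df = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "on_450k",
                                     "snp_flag", "cross_reactive_flag",
                                     "genes"]).set_index("probe_id")
    return ProbeManifest(df)


def make_samples(groups: dict[str, int], seed: int = 0,
                 sexes=None, ages=None) -> SampleSheet:
    prefix = {"case_biallelic": "bi", "case_monoallelic": "mono",
              "control": "ctl", "query": "qry"}
    rng = np.random.default_rng(seed)
    ids, grp = [], []
    for g, n in groups.items():
        for i in range(n):
            ids.append(f"{prefix[g]}{i}")
            grp.append(g)
    n = len(ids)
    return SampleSheet(pd.DataFrame({
        "group": grp,
        "age_years": ages if ages is not None else rng.uniform(5, 60, n).round(1),
        "sex": sexes if sexes is not None else
               np.where(rng.random(n) < 0.5, "F", "M"),
        "batch": "b1",
    }, index=pd.Index(ids, name="sample_id")))


def make_beta(values, probe_ids=None, sample_ids=None,
              detection_p=None) -> BetaMatrix:
    arr = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"cg{i:03d}" for i in range(arr.shape[0])]
    sample_ids = sample_ids or [f"s{i}" for i in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=probe_ids, columns=sample_ids)
    det = None
    if detection_p is not None:
        det = pd.DataFrame(np.asarray(detection_p, dtype=float),
                           index=probe_ids, columns=sample_ids)
    return BetaMatrix(df, det)
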