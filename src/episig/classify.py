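"""Supervised MVP scoring and unsupervised structure checks.

The methylation-variant-pathogenicity (MVP) score is the calibrated output
of a linear-kernel maximum-margin classifier trained on the signature-probe
beta values: 0 = control-like, 1 = matches the disorder's episignature.
Calibration is a Platt sigmoid fitted on the training decision values with
the usual regularised targets, so scoring is a deterministic pure function
of the features.  Unsupervised checks are classical (Torgerson) metric MDS
on pairwise Euclidean distances and Ward hierarchical clustering.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.optimize
import scipy.spatial.distance
from sklearn.svm import SVC

from .containers import BetaMatrix, SampleSheet, Signature, ValidationError

logger = logging.getLogger(__name__)

#: reporting bands for MVP scores (artifact convention, not a hard cutoff)
DEFAULT_BANDS = {"negative": 0.2, "positive": 0.5}


@dataclass
class PlattScaler:
    """Sigmoid p = 1/(1 + exp(a*f + b)) fitted by regularised ML."""

    a: float
    b: float

    @classmethod
    def fit(cls, decision: np.ndarray, y: np.ndarray) -> "PlattScaler":
        n_pos = int(y.sum())
        n_neg = len(y) - n_pos
        # Platt's regularised targets keep the fit away from saturation
        t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0),
                     1.0 / (n_neg + 2.0))

        def nll(params: np.ndarray) -> float:
            a, b = params
            z = a * decision + b
            # log(1+e^z) stable
            log1pez = np.logaddexp(0.0, z)
            return float(np.sum(t * log1pez + (1 - t) * (log1pez - z)))

        res = scipy.optimize.minimize(nll, x0=np.array([-1.0, 0.0]),
                                      method="Nelder-Mead",
                                      options={"xatol": 1e-10, "fatol": 1e-12,
                                               "maxiter": 2000})
        return cls(a=float(res.x[0]), b=float(res.x[1]))

    def transform(self, decision: np.ndarray) -> np.ndarray:
        z = self.a * np.asarray(decision) + self.b
        return 1.0 / (1.0 + np.exp(z))


@dataclass
class MVPModel:
    """Trained maximum-margin episignature classifier."""

    signature_probes: list[str]
    svm: SVC
    platt: PlattScaler
    classes: tuple[str, str]  # (negative label, positive label)
    training_scores: pd.Series = field(repr=False, default=None)
    metadata: dict = field(default_factory=dict)


@dataclass
class EmbeddingResult:
    """Two-dimensional MDS coordinates and/or a hierarchical-cluster tree."""

    coordinates: pd.DataFrame | None = None  # samples x (dim1, dim2)
    linkage: np.ndarray | None = None
    leaf_order: list[str] | None = None
    eigenvalues: np.ndarray | None = None


def _features(beta: BetaMatrix, probes: list[str]) -> np.ndarray:
    missing = [p for p in probes if p not in beta.beta.index]
    if missing:
        raise ValidationError(f"samples lack signature probes: {missing[:5]}"
                              f" ({len(missing)} total)")
    x = beta.beta.loc[probes].to_numpy(dtype=float).T  # samples x probes
    if np.isnan(x).any():
        raise ValidationError("missing beta values at signature probes")
    return x


def train_mvp(beta: BetaMatrix, samples: SampleSheet, signature: Signature,
              case_groups: tuple[str, ...] = ("case_biallelic",
                                              "case_monoallelic"),
              c: float = 1.0, seed: int = 0) -> MVPModel:
    """Train the binary MVP classifier on signature-probe betas.

    Linear kernel, inverse-frequency class weights (cases are typically
    heavily outnumbered), Platt sigmoid calibration on the training
    decision values.  Deterministic given the seed.
    """
    y = samples.table["group"].isin(case_groups).to_numpy().astype(int)
    if y.sum() < 2 or (len(y) - y.sum()) < 2:
        raise ValidationError("need >= 2 samples in each class")
    x = _features(beta.subset_samples(samples.sample_ids.tolist()),
                  signature.probe_ids)
    svm = SVC(kernel="linear", C=c, class_weight="balanced",
              random_state=seed)
    svm.fit(x, y)
    decision = svm.decision_function(x)
    platt = PlattScaler.fit(decision, y)
    scores = pd.Series(platt.transform(decision), index=samples.sample_ids,
                       name="mvp")
    logger.info("trained MVP model on %d cases vs %d controls, %d probes",
                int(y.sum()), int(len(y) - y.sum()), len(signature))
    return MVPModel(
        signature_probes=signature.probe_ids, svm=svm, platt=platt,
        classes=("control", "case"), training_scores=scores,
        metadata={"n_case": int(y.sum()), "n_control": int(len(y) - y.sum()),
                  "seed": seed, "C": c},
    )


def score_mvp(model: MVPModel, beta: BetaMatrix,
              bands: dict[str, float] | None = None) -> pd.DataFrame:
    """MVP scores in [0, 1] for every sample in ``beta``, with an
    interpretation band (< 0.2 negative, >= 0.5 positive, else
    intermediate by default)."""
    bands = bands or DEFAULT_BANDS
    x = _features(beta, model.signature_probes)
    scores = model.platt.transform(model.svm.decision_function(x))
    scores = np.clip(scores, 0.0, 1.0)
    band = np.where(scores < bands["negative"], "negative",
                    np.where(scores >= bands["positive"], "positive",
                             "intermediate"))
    return pd.DataFrame({"mvp": scores, "band": band},
                        index=beta.sample_ids)


def train_multiclass(beta: BetaMatrix, cohorts: dict[str, list[str]],
                     control_ids: list[str], signature: Signature,
                     train_frac: float = 0.75, seed: int = 0,
                     ) -> tuple[dict[str, MVPModel], pd.DataFrame]:
    """One-against-all multiclass MVP models with a stratified 75/25 split.

    ``cohorts`` maps syndrome name -> sample ids; controls are shared across
    all binary problems.  Per class, a binary model is trained (that class
    = positive, every other sample = negative) on the training split, and
    the held-out samples of every cohort are scored against every class.
    Returns (models per class, held-out scores: sample x class with a
    'cohort' column).
    """
    if not (0.0 < train_frac < 1.0):
        raise ValidationError("train_frac must be in (0, 1): an empty test "
                              "set makes evaluation undefined")
    rng = np.random.default_rng(seed)
    groups = dict(cohorts)
    groups["control"] = list(control_ids)
    train_ids: dict[str, list[str]] = {}
    test_ids: dict[str, list[str]] = {}
    for name, ids in groups.items():
        ids = list(ids)
        n_train = int(round(train_frac * len(ids)))
        if len(ids) < 4 or n_train == len(ids) or n_train == 0:
            raise ValidationError(
                f"cohort {name!r} too small for a {train_frac:.0%} split "
                f"({len(ids)} samples)")
        perm = rng.permutation(len(ids))
        train_ids[name] = [ids[i] for i in perm[:n_train]]
        test_ids[name] = [ids[i] for i in perm[n_train:]]

    all_train = [sid for ids in train_ids.values() for sid in ids]
    all_test = [(sid, name) for name, ids in test_ids.items() for sid in ids]
    x_train = _features(beta.subset_samples(all_train), signature.probe_ids)
    x_test = _features(beta.subset_samples([s for s, _ in all_test]),
                       signature.probe_ids)

    models: dict[str, MVPModel] = {}
    held_out = pd.DataFrame(index=pd.Index([s for s, _ in all_test],
                                           name="sample_id"))
    held_out["cohort"] = [c for _, c in all_test]
    for name in cohorts:  # one model per syndrome (controls are never 'positive')
        y = np.array([1 if sid in set(train_ids[name]) else 0
                      for sid in all_train])
        svm = SVC(kernel="linear", C=1.0, class_weight="balanced",
                  random_state=seed)
        svm.fit(x_train, y)
        platt = PlattScaler.fit(svm.decision_function(x_train), y)
        models[name] = MVPModel(
            signature_probes=signature.probe_ids, svm=svm, platt=platt,
            classes=("rest", name),
            training_scores=pd.Series(platt.transform(
                svm.decision_function(x_train)), index=all_train),
            metadata={"class": name, "seed": seed,
                      "train_frac": train_frac},
        )
        held_out[name] = platt.transform(svm.decision_function(x_test))
    return models, held_out


def mds_embed(beta: BetaMatrix, probes: list[str],
              n_components: int = 2) -> EmbeddingResult:
    """Classical (Torgerson) metric MDS on pairwise Euclidean distances of
    the signature-probe beta vectors.

    Deterministic: eigen-decomposition of the double-centred squared
    distance matrix; each axis's sign is fixed by forcing the
    largest-magnitude coordinate positive.
    """
    if len(beta.sample_ids) < 3:
        raise ValidationError("MDS needs >= 3 samples")
    x = _features(beta, list(probes))
    d = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(x, metric="euclidean"))
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:n_components]
    lam = np.clip(evals[order], 0.0, None)
    lam[lam < lam.max() * 1e-12] = 0.0  # null directions carry no geometry
    coords = evecs[:, order] * np.sqrt(lam)
    for k in range(coords.shape[1]):
        i_max = int(np.argmax(np.abs(coords[:, k])))
        if coords[i_max, k] < 0:
            coords[:, k] = -coords[:, k]
    cols = [f"dim{i + 1}" for i in range(coords.shape[1])]
    return EmbeddingResult(
        coordinates=pd.DataFrame(coords, index=beta.sample_ids, columns=cols),
        eigenvalues=evals[order],
    )


def hcluster(beta: BetaMatrix, probes: list[str],
             linkage: str = "ward") -> EmbeddingResult:
    """Agglomerative clustering of samples on signature-probe betas
    (Euclidean distance, Ward linkage by default).  Returns the merge tree
    and the dendrogram leaf order; ``cut_clusters`` partitions it."""
    if len(beta.sample_ids) < 2:
        raise ValidationError("clustering needs >= 2 samples")
    x = _features(beta, list(probes))
    z = scipy.cluster.hierarchy.linkage(x, method=linkage,
                                        metric="euclidean")
    leaves = scipy.cluster.hierarchy.leaves_list(z)
    return EmbeddingResult(
        linkage=z,
        leaf_order=[beta.sample_ids[i] for i in leaves],
    )


def cut_clusters(result: EmbeddingResult, sample_ids: pd.Index,
                 k: int = 2) -> pd.Series:
    """Cut the hierarchical tree into k flat clusters (labels 1..k)."""
    labels = scipy.cluster.hierarchy.fcluster(result.linkage, t=k,
                                              criterion="maxclust")
    return pd.Series(labels, index=sample_ids, name="cluster")
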