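"""Core in-memory containers for methylation-array analysis.

Matrices are thin wrappers around :class:`pandas.DataFrame` (probes as rows,
samples as columns) so that all joins happen by key, never by position.
Coordinates are 1-based inclusive throughout (array-manifest convention);
only BED export converts to 0-based half-open.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

GROUPS = ("case_biallelic", "case_monoallelic", "control", "query")
CASE_GROUPS = ("case_biallelic", "case_monoallelic")
SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions, beta in [0, 1].

    Missing measurements are NaN; optional ``detection_p`` is aligned
    cell-for-cell with ``beta``.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.beta.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            r, c = np.argwhere(bad & ~np.isnan(vals))[0]
            raise ValidationError(
                f"beta value {vals[r, c]} outside [0, 1] at probe "
                f"{self.beta.index[r]!r}, sample {self.beta.columns[c]!r}"
            )
        if self.beta.index.has_duplicates:
            raise ValidationError("duplicate probe ids in beta matrix")
        if self.detection_p is not None and self.detection_p.shape != self.beta.shape:
            raise ValidationError("detection_p shape differs from beta shape")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.beta.shape

    def subset_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        det = None if self.detection_p is None else self.detection_p.loc[probe_ids]
        return BetaMatrix(self.beta.loc[probe_ids], det)

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        det = None if self.detection_p is None else self.detection_p[list(sample_ids)]
        return BetaMatrix(self.beta[list(sample_ids)], det)


@dataclass
class MValueMatrix:
    """Probes x samples M-values, log2-odds of methylation."""

    m: pd.DataFrame

    @property
    def probe_ids(self) -> pd.Index:
        return self.m.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.m.columns


@dataclass
class ProbeManifest:
    """Array probe bookkeeping: genomic position, platform and QC flags.

    ``table`` columns: chrom, pos (1-based), on_450k, snp_flag,
    cross_reactive_flag, genes (list of ``(symbol, region_class)`` tuples),
    indexed by probe_id.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids in manifest: {dups}")
        if (self.table["pos"] < 1).any():
            bad = self.table.index[self.table["pos"] < 1][0]
            raise ValidationError(f"probe {bad!r} has position < 1")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def positions(self, probe_ids: Sequence[str] | None = None) -> pd.DataFrame:
        t = self.table if probe_ids is None else self.table.loc[probe_ids]
        return t[["chrom", "pos"]]


@dataclass
class SampleSheet:
    """Per-sample metadata: group label, age, sex, batch."""

    table: pd.DataFrame  # indexed by sample_id: group, age_years, sex, batch

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate sample ids in sample sheet")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        bad_sex = set(self.table["sex"]) - {"F", "M"}
        if bad_sex:
            raise ValidationError(f"unknown sex codes: {sorted(bad_sex)}")
        if (self.table["age_years"] < 0).any():
            raise ValidationError("negative age in sample sheet")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def ids_in_group(self, *groups: str) -> list[str]:
        mask = self.table["group"].isin(groups)
        return self.table.index[mask].tolist()

    @property
    def case_ids(self) -> list[str]:
        return self.ids_in_group(*CASE_GROUPS)

    @property
    def control_ids(self) -> list[str]:
        return self.ids_in_group("control")

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        return SampleSheet(self.table.loc[list(sample_ids)])


@dataclass
class CellReference:
    """Reference beta profiles of purified cell populations (e.g. leukocytes)."""

    ref_beta: pd.DataFrame  # probes x cell types, beta in [0, 1]

    @property
    def probe_ids(self) -> pd.Index:
        return self.ref_beta.index

    @property
    def cell_types(self) -> pd.Index:
        return self.ref_beta.columns


@dataclass
class ExpressionMatrix:
    """Gene x cell-type expression (TPM) with an optional matrix giving the
    fraction of cells expressing each gene (>0 UMI)."""

    tpm: pd.DataFrame
    prop_expressed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.tpm.to_numpy() < 0).any():
            raise ValidationError("negative TPM")
        if self.prop_expressed is not None:
            p = self.prop_expressed.to_numpy()
            if ((p < 0) | (p > 1)).any():
                raise ValidationError("prop_expressed outside [0, 1]")

    @property
    def gene_ids(self) -> pd.Index:
        return self.tpm.index

    @property
    def cell_types(self) -> pd.Index:
        return self.tpm.columns


@dataclass
class Signature:
    """An episignature: the ordered probe list surviving the selection cascade.

    ``table`` is indexed by probe_id (ascending adjusted p) with columns
    direction ('hyper'/'hypo'), mean_beta_case, mean_beta_control, delta_beta,
    p_adj, auc.  ``provenance`` records thresholds, cohort sizes and the
    count surviving each cascade stage.
    """

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def probe_ids(self) -> list[str]:
        return self.table.index.tolist()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class DMRSet:
    """Differentially methylated regions with per-region statistics.

    ``table`` columns: chrom, start, end (1-based inclusive), n_cpgs_total,
    n_cpgs_significant, mean_delta_beta, fisher_chi2, fisher_df, combined_p,
    direction, genes (list of ``(symbol, region_class)``), tss_overlap.
    Rows sorted by combined_p ascending.
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)
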