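"""Readers and writers for the plain-text exchange formats.

Beta / detection-p / M matrices travel as TSV with probes as rows and a
header row of sample ids; sample sheets, manifests and statistics tables as
CSV.  DMRs are exported both as BED6 (0-based half-open) and as a CSV with
the full per-region statistics.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    BetaMatrix,
    CellReference,
    DMRSet,
    ExpressionMatrix,
    ProbeManifest,
    SampleSheet,
    ValidationError,
)

MANIFEST_COLUMNS = ["probe_id", "chrom", "pos", "on_450k",
                    "snp_flag", "cross_reactive_flag", "genes"]


def _read_matrix_tsv(path: str | Path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    out = {}
    for col in df.columns:
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna() & (raw.str.strip() != "")
        if bad.any():
            probe = raw.index[bad][0]
            raise ValidationError(
                f"non-numeric {what} cell {raw.loc[probe]!r} at probe "
                f"{probe!r}, sample {col!r}"
            )
        out[col] = num.astype(float)
    return pd.DataFrame(out, index=df.index)


def read_beta_matrix(path: str | Path,
                     detection_p_path: str | Path | None = None) -> BetaMatrix:
    """Read a beta-value TSV (probes x samples); empty cells become missing.

    Raises :class:`ValidationError` on non-numeric cells or beta outside
    [0, 1], naming the offending probe and sample.
    """
    beta = _read_matrix_tsv(path, "beta")
    det = None
    if detection_p_path is not None:
        det = _read_matrix_tsv(detection_p_path, "detection p")
        det = det.reindex(index=beta.index, columns=beta.columns)
    return BetaMatrix(beta, det)


def write_beta_matrix(bm: BetaMatrix, path: str | Path,
                      detection_p_path: str | Path | None = None) -> None:
    bm.beta.round(6).to_csv(path, sep="\t", index_label="probe_id", na_rep="")
    if detection_p_path is not None and bm.detection_p is not None:
        bm.detection_p.to_csv(detection_p_path, sep="\t",
                              index_label="probe_id", na_rep="")


def _parse_genes(field: str) -> list[tuple[str, str]]:
    if not isinstance(field, str) or field.strip() == "":
        return []
    out = []
    for pair in field.split(";"):
        sym, _, region = pair.partition(":")
        out.append((sym.strip(), region.strip() or "intergenic"))
    return out


def _format_genes(genes: Sequence[tuple[str, str]]) -> str:
    return ";".join(f"{s}:{r}" for s, r in genes)


def read_manifest(path: str | Path) -> ProbeManifest:
    """Read a probe manifest CSV (probe_id, chrom, pos, flags, genes)."""
    df = pd.read_csv(path, dtype={"probe_id": str, "chrom": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")
    df = df.set_index("probe_id")
    for col in ("on_450k", "snp_flag", "cross_reactive_flag"):
        df[col] = df[col].astype(int).astype(bool)
    df["pos"] = df["pos"].astype(int)
    df["genes"] = [_parse_genes(g) for g in df["genes"].fillna("")]
    return ProbeManifest(df)


def write_manifest(manifest: ProbeManifest, path: str | Path) -> None:
    df = manifest.table.copy()
    for col in ("on_450k", "snp_flag", "cross_reactive_flag"):
        df[col] = df[col].astype(int)
    df["genes"] = [_format_genes(g) for g in df["genes"]]
    df.to_csv(path, index_label="probe_id")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, dtype={"sample_id": str, "batch": str})
    df = df.set_index("sample_id")
    df["age_years"] = df["age_years"].astype(float)
    return SampleSheet(df)


def write_sample_sheet(samples: SampleSheet, path: str | Path) -> None:
    samples.table.to_csv(path, index_label="sample_id")


def read_cell_reference(path: str | Path) -> CellReference:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CellReference(df.astype(float))


def write_cell_reference(ref: CellReference, path: str | Path) -> None:
    ref.ref_beta.to_csv(path, sep="\t", index_label="probe_id")


def read_expression_matrix(path: str | Path,
                           prop_path: str | Path | None = None) -> ExpressionMatrix:
    tpm = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    prop = None
    if prop_path is not None:
        prop = pd.read_csv(prop_path, sep="\t", index_col=0).astype(float)
        prop = prop.reindex(index=tpm.index, columns=tpm.columns)
    return ExpressionMatrix(tpm, prop)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path,
                            prop_path: str | Path | None = None) -> None:
    expr.tpm.to_csv(path, sep="\t", index_label="gene_id")
    if prop_path is not None and expr.prop_expressed is not None:
        expr.prop_expressed.to_csv(prop_path, sep="\t", index_label="gene_id")


def restrict_to_platform(signature_probes: Sequence[str],
                         manifest: ProbeManifest,
                         platform: str = "EPIC") -> list[str]:
    """Restrict a probe list to those present on the target array platform.

    ``platform='K450'`` keeps only probes flagged ``on_450k`` (order
    preserved); ``'EPIC'`` is the identity.  Unknown probe ids raise.
    """
    unknown = [p for p in signature_probes if p not in manifest.table.index]
    if unknown:
        raise ValidationError(f"probes not in manifest: {unknown[:5]}")
    if platform == "EPIC":
        return list(signature_probes)
    if platform != "K450":
        raise ValueError(f"unknown platform {platform!r}")
    on450 = manifest.table["on_450k"]
    return [p for p in signature_probes if on450.loc[p]]


def write_dmr_bed(dmrs: DMRSet, path: str | Path) -> None:
    """Write DMRs as BED6: 0-based half-open, name = rank, score =
    min(1000, -10*log10(combined_p)) rounded."""
    lines = ["#chrom\tstart\tend\tname\tscore\tstrand"]
    for rank, (_, row) in enumerate(dmrs.table.iterrows(), start=1):
        p = max(float(row["combined_p"]), 1e-300)
        score = int(round(min(1000.0, -10.0 * math.log10(p)))) if p < 1 else 0
        lines.append(
            f"{row['chrom']}\t{int(row['start']) - 1}\t{int(row['end'])}"
            f"\tDMR_{rank}\t{score}\t."
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_dmr_csv(dmrs: DMRSet, path: str | Path) -> None:
    df = dmrs.table.copy()
    if "genes" in df.columns:
        df["genes"] = [_format_genes(g) if isinstance(g, list) else ""
                       for g in df["genes"]]
    df.to_csv(path, index=False)


def read_dmr_csv(path: str | Path) -> DMRSet:
    df = pd.read_csv(path)
    if "genes" in df.columns:
        df["genes"] = [_parse_genes(g) if isinstance(g, str) else []
                       for g in df["genes"]]
    return DMRSet(df)
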