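"""Readers and writers for the pipeline's plain-text formats.

Matrices are TSV with features in rows and a header row of sample ids;
regions are 6-column BED (0-based, half-open) with a 7th column giving the
region role (promoter or enhancer); gene sets are GMT.  Parsers validate
eagerly and report the offending line or cell in error messages.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .network import DrugSignature
from .stats import RankedGeneList

__all__ = [
    "read_matrix",
    "read_bed",
    "write_bed",
    "read_gmt",
    "write_gmt",
    "read_labels",
    "read_purity",
    "read_sites",
    "read_annotation",
    "read_survival",
    "read_drug_signatures",
]

BED_COLUMNS = ["chrom", "start", "end", "lncrna_id", "score", "strand", "role"]


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Numeric features x samples TSV with a header of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate feature id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        if vals.isna().any():
            row = df.index[vals.isna().argmax()]
            raise ValueError(f"{path}: missing value at row {row!r}, column {col!r}")
        df[col] = vals
    return df.astype(float)


def read_bed(path: str | Path) -> pd.DataFrame:
    """7-column BED: chrom start end name score strand role."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise ValueError(f"{path}:{lineno}: expected 7 tab-separated fields, got {len(parts)}")
            chrom, start, end, name, score, strand, role = parts[:7]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start_i >= end_i:
                raise ValueError(f"{path}:{lineno}: start {start_i} >= end {end_i}")
            if role not in ("promoter", "enhancer"):
                raise ValueError(f"{path}:{lineno}: unknown region role {role!r}")
            rows.append((chrom, start_i, end_i, name, score, strand, role))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def write_bed(regions: pd.DataFrame, path: str | Path) -> None:
    regions.loc[:, BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: name TAB description TAB member..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set {name!r}")
            sets[name] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sets:
            fh.write("\t".join([name, "na", *sets[name]]) + "\n")


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = df.iloc[:, 0].astype(str)
    bad = ~labels.isin(["tumor", "normal"])
    if bad.any():
        raise ValueError(f"{path}: unknown group label {labels[bad].iloc[0]!r}")
    return labels


def read_purity(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(float)


def read_sites(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str, "chrom": str})
    for col in ("site_id", "chrom", "pos"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if df["site_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate site ids")
    df["pos"] = df["pos"].astype(int)
    return df[["site_id", "chrom", "pos"]]


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    bad = ~df["group"].isin(["AT+", "AT-", "both", "unknown"])
    if bad.any():
        raise ValueError(f"{path}: unknown direction group {df['group'][bad].iloc[0]!r}")
    return df[["gene_id", "group"]]


def read_survival(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    df["time"] = df["time"].astype(float)
    if (df["time"] <= 0).any():
        raise ValueError(f"{path}: survival times must be positive")
    df["event"] = df["event"].astype(int)
    if not df["event"].isin([0, 1]).all():
        raise ValueError(f"{path}: event indicator must be 0/1")
    return df


def read_drug_signatures(path: str | Path) -> list[DrugSignature]:
    """Combined signature TSV with columns drug_id, gene_id, score."""
    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "gene_id": str})
    for col in ("drug_id", "gene_id", "score"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    sigs = []
    for drug, grp in df.groupby("drug_id", sort=True):
        if grp["gene_id"].duplicated().any():
            raise ValueError(f"{path}: duplicate gene in signature {drug!r}")
        scores = pd.Series(grp["score"].astype(float).to_numpy(), index=grp["gene_id"])
        sigs.append(DrugSignature(drug_id=str(drug), ranking=RankedGeneList.from_scores(scores)))
    return sigs
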