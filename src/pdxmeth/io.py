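"""Readers and writers for the standard text formats used across stages.

Matrices (beta values, detection p, bead counts) travel as TSV with the
probe id in the first column and one column per sample; annotation
manifests as TSV with 1-based positions; probe exports as BED (0-based,
half-open); read fixtures as SAM.  Missing values are forbidden everywhere.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from pdxmeth.fidelity import _KNOWN_FEATURES, _KNOWN_ISLAND

_CHROM_ORDER = {f"chr{i}": i for i in range(1, 23)} | {"chrX": 23, "chrY": 24}

ANNOTATION_COLUMNS = ("chrom", "pos", "feature", "island_relation")


def _read_matrix_tsv(path: str | Path, value_range: tuple[float, float] | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty matrix")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate probe id {dup!r}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            probe = df.index[(bad | df[col].isna()).to_numpy()][0]
            raise ValueError(f"{path}: non-numeric or missing value at probe {probe!r}, column {col!r}")
        df[col] = coerced
    if value_range is not None:
        lo, hi = value_range
        values = df.to_numpy()
        out = (values < lo) | (values > hi)
        if out.any():
            i, j = np.argwhere(out)[0]
            raise ValueError(
                f"{path}: value {values[i, j]!r} out of [{lo}, {hi}] at probe "
                f"{df.index[i]!r}, column {df.columns[j]!r}"
            )
    return df


def read_beta_tsv(path: str | Path) -> pd.DataFrame:
    """Read a probes x samples beta matrix; values must lie in [0, 1]."""
    return _read_matrix_tsv(path, (0.0, 1.0))


def read_detp_tsv(path: str | Path) -> pd.DataFrame:
    """Read a detection p-value matrix; values must lie in [0, 1]."""
    return _read_matrix_tsv(path, (0.0, 1.0))


def read_beads_tsv(path: str | Path) -> pd.DataFrame:
    """Read a bead-count matrix; values must be non-negative integers."""
    df = _read_matrix_tsv(path, (0.0, float("inf")))
    values = df.to_numpy()
    if not np.all(values == np.floor(values)):
        i, j = np.argwhere(values != np.floor(values))[0]
        raise ValueError(
            f"{path}: non-integer bead count at probe {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return df.astype(int)


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a probes x samples matrix as TSV (probe id first column)."""
    df.to_csv(path, sep="\t", index_label=df.index.name or "probe_id")


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    """Read a probe annotation manifest (1-based positions)."""
    # keep_default_na: the island relation 'None' is a real label, not missing
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False, na_values=[""])
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: annotation is missing column(s) {missing}")
    bad_chrom = sorted(set(df["chrom"]) - set(_CHROM_ORDER))
    if bad_chrom:
        raise ValueError(f"{path}: unknown chromosome(s) {bad_chrom}")
    bad_feat = sorted(set(df["feature"]) - set(_KNOWN_FEATURES))
    if bad_feat:
        raise ValueError(f"{path}: unknown feature label(s) {bad_feat}")
    bad_isl = sorted(set(df["island_relation"]) - set(_KNOWN_ISLAND))
    if bad_isl:
        raise ValueError(f"{path}: unknown island relation(s) {bad_isl}")
    return df


def write_annotation_tsv(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index_label=annotation.index.name or "probe_id")


def write_bed(
    probes: Sequence[str] | pd.Index,
    annotation: pd.DataFrame,
    path: str | Path,
    scores: Mapping[str, float] | None = None,
) -> None:
    """Export probes as BED records for genome-browser use.

    Manifest positions are 1-based; BED is 0-based half-open, so a probe at
    position ``pos`` covers ``[pos - 1, pos + 1)`` (the two bases of the
    CpG).  Records are sorted by chromosome then start.  ``scores`` maps
    probe id to a value in [0, 1] (e.g. |delta beta|), written as
    ``round(1000 * value)``.
    """
    probes = pd.Index(probes)
    missing = probes.difference(annotation.index)
    if len(missing):
        raise ValueError(f"probe {missing[0]!r} has no coordinates in the annotation")
    sub = annotation.loc[probes, ["chrom", "pos"]]
    rows = [
        (chrom, int(pos) - 1, int(pos) + 1, pid,
         int(round(1000 * scores[pid])) if scores is not None else 0)
        for pid, chrom, pos in zip(sub.index, sub["chrom"], sub["pos"])
    ]
    rows.sort(key=lambda r: (_CHROM_ORDER[r[0]], r[1]))
    with open(path, "w") as fh:
        for chrom, start, end, name, score in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file written by :func:`write_bed`."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score"],
    )
    if df.empty:
        raise ValueError(f"{path}: empty BED file")
    return df


def write_probe_list(probes: Sequence[str] | pd.Index, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f"{p}\n")


def read_probe_list(path: str | Path) -> pd.Index:
    with open(path) as fh:
        return pd.Index([line.strip() for line in fh if line.strip()], name="probe_id")
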