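"""Readers and writers for the tab-separated interchange formats.

All matrices are TSV: first column the feature id, header row of sample ids,
``NA`` (or an empty cell) for missing.  Output files carry ``#``-prefixed
comment headers recording the tool version and, when given, the seed and a
config hash, so every table is self-describing.

A reader for vast-tools-style inclusion tables is provided: per-event
metadata columns followed by repeated (PSI, quality) column pairs, where the
leading comma-separated field of the quality string is an ordinal coverage
grade (default order N < VLOW < LOW < OK < SOK).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ExonAnnotation,
    MatrixKind,
    OmicsMatrix,
    SampleTable,
    TargetMap,
)

__all__ = [
    "load_matrix",
    "write_matrix",
    "load_sample_table",
    "write_sample_table",
    "load_exon_annotation",
    "load_target_map",
    "write_target_map",
    "load_vast_inclusion_table",
    "load_gene_list",
    "DEFAULT_QUALITY_ORDER",
    "config_hash",
]

MISSING_TOKEN = "NA"

#: vast-tools coverage grades from worst to best.
DEFAULT_QUALITY_ORDER = ("N", "VLOW", "LOW", "OK", "SOK")


def _version() -> str:
    from . import __version__

    return __version__


def config_hash(config) -> str:
    """Short stable hash of a config mapping, for output provenance headers."""
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header_lines(seed=None, config=None, extra: dict | None = None) -> list[str]:
    meta = {"tool": "microsplice", "version": _version()}
    if seed is not None:
        meta["seed"] = seed
    if config is not None:
        meta["config_hash"] = config_hash(config)
    if extra:
        meta.update(extra)
    return [f"# {k}: {v}" for k, v in meta.items()]


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        comment="#",
        na_values=[MISSING_TOKEN, ""],
        keep_default_na=False,
        **kwargs,
    )


def load_matrix(path, kind: MatrixKind | str) -> OmicsMatrix:
    """Load a feature x sample TSV and validate it as ``kind``.

    Range violations (a beta of 1.2, a negative expression value, a missing
    cell in a non-PSI matrix) raise ``ValueError`` rather than being clamped.
    """
    frame = _read_tsv(path, index_col=0)
    non_numeric = frame.select_dtypes(exclude=[np.number]).columns
    if len(non_numeric):
        raise ValueError(f"non-numeric cells in column(s) {list(non_numeric)}")
    return OmicsMatrix(MatrixKind(kind), frame)


def write_matrix(matrix: OmicsMatrix, path, seed=None, config=None) -> None:
    path = Path(path)
    header = _header_lines(seed, config, {"kind": matrix.kind.value})
    with open(path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        frame = matrix.values.copy()
        frame.index.name = "feature_id"
        frame.to_csv(fh, sep="\t", na_rep=MISSING_TOKEN)


def load_sample_table(path) -> SampleTable:
    frame = _read_tsv(path, dtype={"sample_id": str})
    for col in ("sample_id", "tissue", "condition"):
        if col not in frame.columns:
            raise ValueError(f"sample table missing column {col!r}")
    return SampleTable(frame.set_index("sample_id"))


def write_sample_table(table: SampleTable, path, seed=None, config=None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(seed, config):
            fh.write(line + "\n")
        frame = table.frame.copy()
        frame.index.name = "sample_id"
        frame.to_csv(fh, sep="\t", na_rep=MISSING_TOKEN)


def load_exon_annotation(path) -> ExonAnnotation:
    frame = _read_tsv(path, index_col=0)
    return ExonAnnotation(frame)


def load_target_map(path) -> TargetMap:
    """Two-column TSV (sf_id, exon_id), one regulated exon per row."""
    frame = _read_tsv(path, header=0)
    sf_col, exon_col = frame.columns[:2]
    mapping: dict[str, set[str]] = {}
    for sf, exon in zip(frame[sf_col], frame[exon_col]):
        mapping.setdefault(str(sf), set()).add(str(exon))
    return TargetMap(mapping)


def write_target_map(targets: TargetMap, path, seed=None, config=None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(seed, config):
            fh.write(line + "\n")
        fh.write("sf_id\texon_id\n")
        for sf in sorted(targets.mapping):
            for exon in sorted(targets.mapping[sf]):
                fh.write(f"{sf}\t{exon}\n")


def load_gene_list(path) -> list[str]:
    """One id per line; ``#`` comments and blank lines ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def _quality_grade(cell: str) -> str:
    return str(cell).split(",")[0].strip()


def load_vast_inclusion_table(
    path,
    min_quality: str = "LOW",
    quality_order=DEFAULT_QUALITY_ORDER,
    metadata_columns: int = 3,
) -> tuple[OmicsMatrix, ExonAnnotation]:
    """Parse a vast-tools-style inclusion table into a PSI matrix.

    The first ``metadata_columns`` columns are event id, gene and event
    length; the remainder must come in (PSI, quality) pairs, one pair per
    sample.  A PSI cell whose paired quality grade ranks below
    ``min_quality`` in ``quality_order`` is set to missing.  Event lengths
    populate the returned :class:`ExonAnnotation`.
    """
    order = {g: i for i, g in enumerate(quality_order)}
    if min_quality not in order:
        raise ValueError(f"min_quality {min_quality!r} not in grade order {quality_order}")
    frame = _read_tsv(path, dtype=str)
    if frame.shape[1] < metadata_columns + 2:
        raise ValueError("inclusion table has no sample columns")
    sample_cols = list(frame.columns[metadata_columns:])
    if len(sample_cols) % 2:
        raise ValueError("odd number of sample columns: expected (PSI, quality) pairs")
    event_col, gene_col, length_col = frame.columns[:metadata_columns]
    events = frame[event_col].astype(str)
    if events.duplicated().any():
        raise ValueError("duplicate event ids")

    psi = {}
    for psi_col, q_col in zip(sample_cols[0::2], sample_cols[1::2]):
        values = pd.to_numeric(frame[psi_col], errors="raise").astype(float).to_numpy()
        grades = frame[q_col].map(_quality_grade)
        unknown = sorted(set(grades) - set(order))
        if unknown:
            raise ValueError(f"unparsable quality grade(s) {unknown} in column {q_col!r}")
        low = grades.map(order).to_numpy() < order[min_quality]
        values = values.copy()
        values[low] = np.nan
        psi[psi_col] = values

    matrix = OmicsMatrix(MatrixKind.psi, pd.DataFrame(psi, index=events))
    annotation = ExonAnnotation(
        pd.DataFrame(
            {
                "gene_id": frame[gene_col].astype(str).to_numpy(),
                "length_nt": pd.to_numeric(frame[length_col]).astype(int).to_numpy(),
            },
            index=events,
        )
    )
    return matrix, annotation
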