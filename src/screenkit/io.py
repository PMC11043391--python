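"""Readers and writers for the pipeline's text formats.

Count matrices use the de-facto pooled-screen layout: tab-separated, one
row per guide, first column guide id, second column gene symbol, then one
column per sample with non-negative integer counts.  Gene sets use the
GMT dialect (name, description, members).  Per-cell tables and sample
sheets are plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .enrichment import GeneSetCollection
from .pooled import GuideCountMatrix

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "validate_sample_sheet",
    "read_gmt",
    "write_gmt",
    "read_cell_table",
    "write_cell_table",
]

ARMS = ("plasmid", "vehicle", "drug")


class ParseError(ValueError):
    """Raised for malformed input files, naming the offending line."""


def read_count_matrix(path: str | Path) -> GuideCountMatrix:
    """Read a guide x sample count matrix (guide, gene, sample columns)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3:
            raise ParseError(f"{path}:1: need guide, gene and >=1 sample column")
        samples = header[2:]
        guides, genes, rows = [], [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            guides.append(fields[0])
            genes.append(fields[1])
            vals = []
            for col, raw in zip(samples, fields[2:]):
                try:
                    v = int(raw)
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-integer count {raw!r} in sample {col}"
                    ) from None
                if v < 0:
                    raise ParseError(
                        f"{path}:{lineno}: negative count {v} in sample {col}"
                    )
                vals.append(v)
            rows.append(vals)
    counts = pd.DataFrame(rows, index=pd.Index(guides, name="guide"), columns=samples)
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate guide id {dup!r}")
    return GuideCountMatrix(
        counts=counts, guide_to_gene=pd.Series(genes, index=counts.index, name="gene")
    )


def write_count_matrix(matrix: GuideCountMatrix, path: str | Path) -> None:
    out = matrix.counts.copy()
    out.insert(0, "gene", matrix.guide_to_gene)
    out.index.name = "guide"
    out.to_csv(path, sep="\t")


def validate_sample_sheet(sheet: pd.DataFrame, matrix: GuideCountMatrix | None = None) -> None:
    """Enforce the sample-sheet contract (unique ids, valid arms, matrix match)."""
    required = {"sample_id", "cell_line", "arm", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample sheet")
    bad = set(sheet["arm"]) - set(ARMS)
    if bad:
        raise ValueError(f"unknown arm value(s) {sorted(bad)}; expected {ARMS}")
    if (sheet["replicate"].astype(int) < 1).any():
        raise ValueError("replicate must be a positive integer")
    if matrix is not None:
        sheet_ids = set(sheet["sample_id"])
        mat_ids = set(matrix.samples)
        if sheet_ids != mat_ids:
            raise ValueError(
                "sample sheet and count matrix disagree: "
                f"sheet-only {sorted(sheet_ids - mat_ids)}, "
                f"matrix-only {sorted(mat_ids - sheet_ids)}"
            )


def read_sample_sheet(path: str | Path, matrix: GuideCountMatrix | None = None) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    validate_sample_sheet(sheet, matrix)
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, members...)."""
    path = Path(path)
    sets: dict[str, frozenset] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT lines need >= 3 tab-separated fields"
                )
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                raise ParseError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read a per-cell CSV (synthetic-table schema)."""
    cells = pd.read_csv(path)
    required = {"plate", "well", "perturbation", "treatment", "area", "is_border"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cell table missing columns {sorted(missing)}")
    cells["is_border"] = cells["is_border"].astype(bool)
    return cells


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, index=False)
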