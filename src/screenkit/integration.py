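"""Cross-screen integration: recurrence counts and core resistance genes.

Hit tables from independent screens (cell line x drug x modality) are
combined by counting, per gene, the number of screens in which it was
called a hit.  Genes recurring in at least ``recurrence_min`` screens
(default 4 of 6) form the core resistance-gene set.  Knockout and
activation screens are counted symmetrically: a hit is a hit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pooled import ScreenHitTable

__all__ = ["count_recurrence", "recurrence_histogram"]


def count_recurrence(
    tables: list[ScreenHitTable],
    recurrence_min: int = 4,
) -> pd.DataFrame:
    """Per-gene recurrence over screens and the core flag.

    A gene absent from a screen's table counts as a non-hit there.
    Returns a DataFrame (gene, recurrence, core) covering the union of
    genes, sorted by descending recurrence then gene symbol.
    """
    if not tables:
        raise ValueError("need at least one hit table")
    ids = [t.screen_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate screen ids: {ids}")
    if recurrence_min < 1:
        raise ValueError("recurrence_min must be >= 1")

    counts: dict[str, int] = {}
    for t in tables:
        hits = t.table.loc[t.table["hit"].astype(bool), "gene"]
        for g in hits:
            counts[g] = counts.get(g, 0) + 1
        for g in t.table["gene"]:
            counts.setdefault(g, 0)

    out = pd.DataFrame(
        {"gene": list(counts), "recurrence": list(counts.values())}
    )
    out["core"] = out["recurrence"] >= recurrence_min
    out = out.sort_values(["recurrence", "gene"], ascending=[False, True], kind="stable")
    return out.reset_index(drop=True)


def recurrence_histogram(core: pd.DataFrame) -> dict[int, int]:
    """Gene counts per recurrence level (>= 1 only).

    The values sum to the number of genes that were a hit in at least one
    screen.
    """
    rec = core["recurrence"].to_numpy()
    rec = rec[rec >= 1]
    vals, cnts = np.unique(rec, return_counts=True)
    return {int(v): int(c) for v, c in zip(vals, cnts)}
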