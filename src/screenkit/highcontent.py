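"""Arrayed high-content screen scoring.

Per-cell tables (one row per segmented cell, with nuclear and cytoplasmic
mean intensities per channel) are quality-filtered, summarised per well,
normalised against non-targeting-control (NTC) anchors, and turned into
per-gene calls:

* pathway markers (pAKT, pERK, pS6) are expressed on a two-point scale
  where the NTC-vehicle mean maps to 0 and the NTC-drug mean to -100;
* the translocation channel (YAP1/WWTR1) is expressed as the Nuc:Cyt
  fold change over the treatment-matched NTC, with a hit called when the
  fold exceeds 1 + threshold (default >20% increase);
* rank-sum and Fisher exact machinery backs the per-cell and 2x2
  comparisons.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .enrichment import benjamini_hochberg  # noqa: F401  (re-used by callers)

__all__ = [
    "filter_cells",
    "nuc_cyt_ratio",
    "well_summaries",
    "TwoPointScale",
    "build_two_point_scale",
    "two_point_normalize",
    "call_yap_hits",
    "wilcoxon_rank_sum",
    "fisher_association",
    "score_arrayed_screen",
]

NTC = "NTC"


def filter_cells(cells: pd.DataFrame, min_cells_warn: int = 10) -> pd.DataFrame:
    """Remove border cells, then trim the area-extreme deciles per well.

    Cells flagged ``is_border`` are dropped first.  Within each (plate,
    well), the remaining cells are ranked by area (ties resolved by
    stable input order) and ``floor(n * 0.1)`` cells are removed from
    each end.
    """
    if cells.empty:
        warnings.warn("empty cell table", stacklevel=2)
        return cells.copy()
    kept = cells.loc[~cells["is_border"].astype(bool)]
    pieces = []
    for _, grp in kept.groupby(["plate", "well"], sort=False):
        n = len(grp)
        if n < min_cells_warn:
            warnings.warn(
                f"well {grp['well'].iloc[0]} has only {n} non-border cells", stacklevel=2
            )
        trim = int(n * 0.1)
        order = np.argsort(grp["area"].to_numpy(), kind="stable")
        keep_pos = np.sort(order[trim : n - trim]) if n - 2 * trim > 0 else order[:0]
        pieces.append(grp.iloc[keep_pos])
    if not pieces:
        return kept.iloc[:0]
    return pd.concat(pieces)


def nuc_cyt_ratio(cells: pd.DataFrame, channel: str) -> pd.Series:
    """Per-cell nuclear:cytoplasmic intensity ratio for one channel.

    Cells with zero cytoplasmic signal are returned as NaN (excluded, not
    an error).
    """
    nuc = cells[f"nuclear_mean_{channel}"].to_numpy(dtype=float)
    cyt = cells[f"cytoplasm_mean_{channel}"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(cyt > 0, nuc / cyt, np.nan)
    return pd.Series(ratio, index=cells.index, name=f"nuc_cyt_{channel}")


def well_summaries(
    cells: pd.DataFrame,
    channels: list[str],
    ratio_channel: str = "yap",
) -> pd.DataFrame:
    """Aggregate filtered cells into per-well medians.

    For each (plate, well) the summary holds the median per-cell
    intensity of every channel (mean of the nuclear and cytoplasmic
    compartment means), the median Nuc:Cyt ratio of the translocation
    channel, and the retained cell count.
    """
    if cells.empty:
        raise ValueError("no cells to summarise")
    work = cells.copy()
    for ch in channels:
        work[f"intensity_{ch}"] = (
            work[f"nuclear_mean_{ch}"] + work[f"cytoplasm_mean_{ch}"]
        ) / 2.0
    work["nuc_cyt"] = nuc_cyt_ratio(work, ratio_channel)
    agg = {f"intensity_{ch}": "median" for ch in channels}
    agg["nuc_cyt"] = "median"
    grouped = work.groupby(
        ["plate", "well", "perturbation", "treatment"], sort=False, dropna=False
    )
    out = grouped.agg(agg)
    out["n_cells_retained"] = grouped.size()
    out = out.reset_index().rename(columns={"nuc_cyt": "nuc_cyt_median"})
    return out


@dataclass(frozen=True)
class TwoPointScale:
    """Anchors of the two-point normalisation.

    ``ref_max`` (NTC vehicle mean) maps to 0; ``ref_min`` (NTC drug mean)
    maps to -100.
    """

    ref_max: float
    ref_min: float

    def __post_init__(self) -> None:
        if self.ref_max == self.ref_min:
            raise ValueError("degenerate assay window: ref_max == ref_min")


def build_two_point_scale(summaries: pd.DataFrame, value_col: str) -> TwoPointScale:
    """Two-point scale from the NTC wells of a summary table."""
    ntc = summaries.loc[summaries["perturbation"] == NTC]
    veh = ntc.loc[ntc["treatment"] == "vehicle", value_col]
    drg = ntc.loc[ntc["treatment"] == "drug", value_col]
    if veh.empty or drg.empty:
        raise ValueError("need at least one NTC vehicle and one NTC drug well")
    return TwoPointScale(ref_max=float(veh.mean()), ref_min=float(drg.mean()))


def two_point_normalize(values, scale: TwoPointScale) -> np.ndarray:
    """Affine rescale: ref_max -> 0, ref_min -> -100.

    normalised(x) = -100 * (ref_max - x) / (ref_max - ref_min); values
    above the vehicle anchor come out positive.
    """
    x = np.asarray(values, dtype=float)
    return -100.0 * (scale.ref_max - x) / (scale.ref_max - scale.ref_min)


def call_yap_hits(
    summaries: pd.DataFrame,
    threshold: float = 0.20,
    treatment: str = "drug",
    cells: pd.DataFrame | None = None,
    ratio_channel: str = "yap",
) -> pd.DataFrame:
    """Translocation hit calls: Nuc:Cyt fold change over the NTC wells.

    Per perturbation, the fold change is the mean (across replicate
    wells) of the well Nuc:Cyt medians divided by the mean of the NTC
    well medians under the same treatment; a hit requires a fold change
    strictly greater than ``1 + threshold``.  When the per-cell table is
    supplied, a two-sided rank-sum p comparing the perturbation's cell
    ratios against the NTC cells is attached.
    """
    sub = summaries.loc[summaries["treatment"] == treatment]
    ntc = sub.loc[sub["perturbation"] == NTC, "nuc_cyt_median"]
    if ntc.empty:
        raise ValueError(f"no NTC wells under treatment {treatment!r}")
    ntc_ref = float(ntc.mean())

    cell_ratios = None
    if cells is not None:
        sel = cells.loc[cells["treatment"] == treatment].copy()
        sel["ratio"] = nuc_cyt_ratio(sel, ratio_channel)
        cell_ratios = {
            pert: grp["ratio"].dropna().to_numpy()
            for pert, grp in sel.groupby("perturbation", sort=False)
        }

    rows = []
    for pert, grp in sub.groupby("perturbation", sort=False):
        fold = float(grp["nuc_cyt_median"].mean()) / ntc_ref
        p = np.nan
        if cell_ratios is not None and pert != NTC and pert in cell_ratios:
            p = wilcoxon_rank_sum(cell_ratios[pert], cell_ratios[NTC])
        rows.append((pert, fold, fold > 1.0 + threshold, p))
    return pd.DataFrame(
        rows, columns=["perturbation", "fold_change_over_ntc", "yap_hit", "wilcoxon_p"]
    )


def _rank_sum_exact(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments.

    Midranks are computed on the pooled sample, so ties are handled; the
    p-value is the fraction of C(n+m, n) assignments whose rank sum
    deviates from its mean at least as much as the observed one.
    """
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n = len(a)
    total = ranks.sum()
    mean_a = total * n / len(pooled)
    obs = abs(ranks[:n].sum() - mean_a)
    count = 0
    n_comb = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        n_comb += 1
        if abs(ranks[list(combo)].sum() - mean_a) >= obs - 1e-12:
            count += 1
    return count / n_comb


def wilcoxon_rank_sum(sample_a, sample_b) -> float:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum p-value.

    Exact enumeration over all group assignments when both samples have
    at most 8 observations; otherwise the normal approximation with tie
    correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if a.size <= 8 and b.size <= 8:
        return _rank_sum_exact(a, b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n, m = a.size, b.size
    N = n + m
    R = ranks[:n].sum()
    mu = n * (N + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (N * (N - 1))
    var = n * m / 12.0 * (N + 1 - tie_term)
    if var == 0:
        return 1.0
    z = (R - mu) / math.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def fisher_association(table) -> float:
    """Two-sided Fisher exact p for a 2x2 contingency table.

    All tables with the observed margins are enumerated through the
    hypergeometric distribution of the top-left cell; the p-value sums
    the probabilities of tables no more likely than the observed one.
    A table with a zero margin has a single attainable configuration and
    returns p = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table cells must be non-negative integers")
    t = t.astype(int)
    if t.sum() < 1:
        raise ValueError("grand total must be >= 1")
    a = t[0, 0]
    r1, r2 = t.sum(axis=1)
    c1 = t[:, 0].sum()
    N = t.sum()
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, N, c1, r1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    # summing the full support accumulates float error just below 1
    return 1.0 if p > 1.0 - 1e-12 else p


def score_arrayed_screen(
    cells: pd.DataFrame,
    channels: list[str] = ("yap", "pakt", "perk", "ps6"),
    ratio_channel: str = "yap",
    yap_hit_threshold: float = 0.20,
    preservation_floor: float = -50.0,
    hit_treatment: str = "drug",
) -> dict:
    """End-to-end scoring of an arrayed high-content screen.

    Pipeline: per-cell filtering -> well summaries -> per-marker two-point
    normalisation (NTC anchors) under drug -> per-gene Nuc:Cyt fold and
    translocation hit call -> Fisher 2x2 of translocation-hit status vs
    pathway preservation (normalised effect >= ``preservation_floor`` on
    pAKT or pERK).

    Returns a dict with ``report`` (per-gene DataFrame), ``fisher_p``,
    ``fisher_table`` and ``scales``.
    """
    filtered = filter_cells(cells)
    summaries = well_summaries(filtered, list(channels), ratio_channel)

    marker_channels = [c for c in channels if c != ratio_channel]
    scales = {
        ch: build_two_point_scale(summaries, f"intensity_{ch}") for ch in marker_channels
    }

    drug = summaries.loc[summaries["treatment"] == hit_treatment]
    effects = {}
    for ch in marker_channels:
        per_gene = drug.groupby("perturbation", sort=False)[f"intensity_{ch}"].mean()
        effects[ch] = pd.Series(
            two_point_normalize(per_gene.to_numpy(), scales[ch]), index=per_gene.index
        )

    yap = call_yap_hits(
        summaries,
        threshold=yap_hit_threshold,
        treatment=hit_treatment,
        cells=filtered,
        ratio_channel=ratio_channel,
    ).set_index("perturbation")

    report = pd.DataFrame(
        {"perturbation": yap.index}
    ).set_index("perturbation")
    for ch in marker_channels:
        report[f"effect_{ch}"] = effects[ch]
    report["nuc_cyt_fold"] = yap["fold_change_over_ntc"]
    report["yap_hit"] = yap["yap_hit"]
    report["wilcoxon_p"] = yap["wilcoxon_p"]

    genes = report.drop(index=NTC, errors="ignore")
    preserved = (
        (genes.get("effect_pakt", pd.Series(-100.0, index=genes.index)) >= preservation_floor)
        | (genes.get("effect_perk", pd.Series(-100.0, index=genes.index)) >= preservation_floor)
    )
    yap_hit = genes["yap_hit"].astype(bool)
    fisher_table = np.array(
        [
            [int((yap_hit & preserved).sum()), int((yap_hit & ~preserved).sum())],
            [int((~yap_hit & preserved).sum()), int((~yap_hit & ~preserved).sum())],
        ]
    )
    fisher_p = fisher_association(fisher_table)

    return {
        "report": report.reset_index(),
        "fisher_p": fisher_p,
        "fisher_table": fisher_table,
        "scales": scales,
        "summaries": summaries,
    }
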