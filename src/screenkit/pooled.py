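"""Pooled-screen statistics: guide-level NB enrichment tests and alpha-RRA.

A pooled resistance screen compares guide abundance between drug- and
vehicle-treated arms.  Per guide, counts are modelled as negative binomial
with variance ``mu + phi * mu**2``; the drug-arm count sum is tested
against the vehicle-derived expectation (upper tail for enrichment, lower
tail for depletion).  Genes are then scored with alpha-RRA: the guides of
a gene are located in the global p-value ranking, guides passing the
``alpha`` significance threshold are "selected", and the gene score rho is
the smallest Beta(j, k-j+1) order-statistic probability over selected
positions.  A permutation test that reassigns guides to genes (preserving
guides-per-gene) converts rho into a p-value.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .enrichment import benjamini_hochberg

__all__ = [
    "GuideCountMatrix",
    "ScreenHitTable",
    "size_factors",
    "guide_test",
    "rra_aggregate",
    "call_screen_hits",
]

#: floor for the method-of-moments dispersion estimate
_MIN_DISPERSION = 1e-8


@dataclass
class GuideCountMatrix:
    """Integer guide x sample count matrix plus the guide -> gene map.

    ``counts`` is indexed by guide id with one column per sample;
    ``guide_to_gene`` maps each guide id to exactly one gene symbol, in
    library order.
    """

    counts: pd.DataFrame
    guide_to_gene: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate guide ids: {dups[:5]}")
        if not self.counts.index.equals(self.guide_to_gene.index):
            raise ValueError("counts index and guide_to_gene index differ")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def guides(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> np.ndarray:
        return self.guide_to_gene.unique()


@dataclass
class ScreenHitTable:
    """Per-gene hit calls for one screen (cell line x drug x modality)."""

    screen_id: str
    table: pd.DataFrame = field(repr=False)  # gene, fold_change, p, hit

    def __post_init__(self) -> None:
        missing = {"gene", "fold_change", "p", "hit"} - set(self.table.columns)
        if missing:
            raise ValueError(f"hit table missing columns {sorted(missing)}")
        if self.table["gene"].duplicated().any():
            raise ValueError("one row per gene required")


def size_factors(matrix: GuideCountMatrix) -> pd.Series:
    """Median-of-ratios size factors against a geometric-mean reference.

    The pseudo-reference is the per-guide geometric mean over samples,
    computed on guides with all-positive counts; each sample's factor is
    the median ratio of its counts to the reference.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    if (counts.sum(axis=0) == 0).any():
        bad = [s for s, tot in zip(matrix.samples, counts.sum(axis=0)) if tot == 0]
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    pos = (counts > 0).all(axis=1)
    if not pos.any():
        raise ValueError("no guide has positive counts in every sample")
    sub = counts[pos]
    ref = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / ref[:, None], axis=0)
    return pd.Series(factors, index=matrix.samples, name="size_factor")


def _arm_samples(sheet: pd.DataFrame, arm: str) -> list[str]:
    sel = sheet.loc[sheet["arm"] == arm, "sample_id"].tolist()
    return sel


def _pooled_dispersion(norm_vehicle: np.ndarray) -> float:
    """Method-of-moments dispersion pooled across guides (vehicle arm).

    phi-hat = sum_g (s2_g - m_g) / sum_g m_g**2 on normalised counts,
    floored at a small positive value.  Requires >= 2 vehicle replicates;
    with a single replicate the floor is returned (Poisson-like test).
    """
    if norm_vehicle.shape[1] < 2:
        return _MIN_DISPERSION
    m = norm_vehicle.mean(axis=1)
    v = norm_vehicle.var(axis=1, ddof=1)
    keep = m > 0
    denom = float((m[keep] ** 2).sum())
    if denom == 0:
        return _MIN_DISPERSION
    phi = float((v[keep] - m[keep]).sum()) / denom
    return max(phi, _MIN_DISPERSION)


def _nb_tail_pvalues(obs_sum: np.ndarray, mean_sum: np.ndarray, phi_sum: float):
    """Upper/lower NB tail probabilities of the summed drug counts.

    The sum of r independent NB(mu, phi) draws is NB(r*mu, phi/r); the
    caller passes the dispersion of the sum.  p_enrich = P(X >= obs),
    p_deplete = P(X <= obs).
    """
    mean_sum = np.maximum(mean_sum, 1e-12)
    r = 1.0 / phi_sum
    p = r / (r + mean_sum)
    p_enrich = sps.nbinom.sf(obs_sum - 1, r, p)
    p_deplete = sps.nbinom.cdf(obs_sum, r, p)
    # clip into (0, 1]: a p-value of exactly 0 is an artefact of float underflow
    tiny = np.finfo(float).tiny
    return np.clip(p_enrich, tiny, 1.0), np.clip(p_deplete, tiny, 1.0)


def guide_test(
    matrix: GuideCountMatrix,
    sheet: pd.DataFrame,
    sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-guide NB enrichment/depletion test of drug vs vehicle.

    Parameters
    ----------
    matrix
        Guide count matrix covering all samples in the sheet.
    sheet
        Sample sheet with columns ``sample_id`` and ``arm`` (at least one
        ``vehicle`` and one ``drug`` sample).
    sizes
        Optional precomputed size factors; computed from ``matrix`` when
        omitted.

    Returns
    -------
    DataFrame indexed by guide with columns ``gene``, ``log2fc``,
    ``p_enrich``, ``p_deplete``, ``u_enrich``, ``u_deplete``.  log2fc uses
    a 0.5 pseudocount on the mean normalised counts; the normalised ranks
    ``u`` are mid-rank ties of ascending p within each direction, divided
    by the total number of guides.
    """
    vehicle = _arm_samples(sheet, "vehicle")
    drug = _arm_samples(sheet, "drug")
    if not vehicle or not drug:
        raise ValueError("need at least one vehicle and one drug sample")
    missing = set(vehicle + drug) - set(matrix.samples)
    if missing:
        raise ValueError(f"samples missing from count matrix: {sorted(missing)}")
    if sizes is None:
        sizes = size_factors(matrix)

    counts = matrix.counts
    norm = counts / sizes
    norm_v = norm[vehicle].to_numpy(dtype=float)
    norm_d = norm[drug].to_numpy(dtype=float)
    mu_v = norm_v.mean(axis=1)
    mu_d = norm_d.mean(axis=1)

    log2fc = np.log2((mu_d + 0.5) / (mu_v + 0.5))

    phi = _pooled_dispersion(norm_v)
    # expected raw drug-arm sum given the vehicle rate and drug depths
    drug_depth = float(sizes[drug].sum())
    mean_sum = mu_v * drug_depth
    obs_sum = counts[drug].sum(axis=1).to_numpy(dtype=float)
    p_enrich, p_deplete = _nb_tail_pvalues(obs_sum, mean_sum, phi / len(drug))

    n = len(counts)
    u_enrich = sps.rankdata(p_enrich, method="average") / n
    u_deplete = sps.rankdata(p_deplete, method="average") / n

    return pd.DataFrame(
        {
            "gene": matrix.guide_to_gene.to_numpy(),
            "log2fc": log2fc,
            "p_enrich": p_enrich,
            "p_deplete": p_deplete,
            "u_enrich": u_enrich,
            "u_deplete": u_deplete,
        },
        index=counts.index,
    )


def _rho_rows(u: np.ndarray, selected: np.ndarray) -> np.ndarray:
    """alpha-RRA rho for each row of a (B, k) matrix of guide ranks.

    Per row: sort u ascending; for selected positions j (1-based), take
    Beta(j, k-j+1).cdf(u_(j)); rho is the minimum, or 1 when no guide is
    selected.  Because selection is a threshold on the same ordering as u,
    selected guides occupy a prefix of the sorted row.
    """
    B, k = u.shape
    order = np.argsort(u, axis=1, kind="stable")
    u_sorted = np.take_along_axis(u, order, axis=1)
    sel_sorted = np.take_along_axis(selected, order, axis=1)
    j = np.arange(1, k + 1, dtype=float)
    beta_cdf = sps.beta.cdf(u_sorted, j[None, :], (k - j + 1)[None, :])
    beta_cdf = np.where(sel_sorted, beta_cdf, np.inf)
    rho = beta_cdf.min(axis=1)
    return np.where(np.isfinite(rho), rho, 1.0)


def _sample_assignments(rng: np.random.Generator, n: int, k: int, B: int) -> np.ndarray:
    """B random k-subsets of range(n), without replacement within a row."""
    if k > n:
        raise ValueError("gene has more guides than the universe")
    idx = rng.integers(0, n, size=(B, k))
    if k > 1:
        while True:
            srt = np.sort(idx, axis=1)
            bad = (np.diff(srt, axis=1) == 0).any(axis=1)
            if not bad.any():
                break
            idx[bad] = rng.integers(0, n, size=(int(bad.sum()), k))
    return idx


def rra_aggregate(
    guide_stats: pd.DataFrame,
    alpha: float = 0.05,
    n_permutations: int = 10_000,
    seed: int = 0,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Aggregate guide statistics into gene-level alpha-RRA scores.

    For each direction (enriched, depleted) the gene score rho is computed
    from the guides' normalised ranks; the permutation p-value compares
    rho against random reassignments of guides to genes that preserve the
    number of guides per gene: ``p_perm = (b + 1) / (B + 1)`` with ``b``
    the number of permuted scores ``rho* <= rho``.  Benjamini-Hochberg
    FDR is applied within each direction.

    Parameters
    ----------
    guide_stats
        Output of :func:`guide_test`.
    alpha
        Guide-level p threshold for selection into the gene score.
    n_permutations
        Number of random assignments B (shared across genes with the same
        guide count).
    seed
        Seed for the permutation draws.
    exhaustive
        Enumerate *all* guide-to-gene assignments instead of sampling;
        only feasible on small universes (useful for exact verification).

    Returns
    -------
    DataFrame with one row per (gene, direction): ``gene``, ``direction``,
    ``n_guides``, ``rho``, ``p_perm``, ``fdr``, ``gene_log2fc`` (median
    guide log2fc).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if guide_stats.empty:
        raise ValueError("no guide statistics supplied")

    n = len(guide_stats)
    genes = guide_stats["gene"].to_numpy()
    gene_order = pd.unique(genes)
    gene_log2fc = guide_stats.groupby("gene", sort=False)["log2fc"].median()

    rng = np.random.default_rng(seed)
    out_frames = []
    for direction, pcol, ucol in (
        ("enriched", "p_enrich", "u_enrich"),
        ("depleted", "p_deplete", "u_deplete"),
    ):
        u = guide_stats[ucol].to_numpy(dtype=float)
        sel = guide_stats[pcol].to_numpy(dtype=float) < alpha

        rho_obs = {}
        sizes = {}
        for gene in gene_order:
            mask = genes == gene
            k = int(mask.sum())
            sizes[gene] = k
            rho_obs[gene] = _rho_rows(u[mask][None, :], sel[mask][None, :])[0]

        # one shared null distribution per distinct guides-per-gene k
        null_by_k: dict[int, np.ndarray] = {}
        for k in sorted(set(sizes.values())):
            if exhaustive:
                combos = list(itertools.combinations(range(n), k))
                idx = np.asarray(combos, dtype=np.intp)
            else:
                idx = _sample_assignments(rng, n, k, n_permutations)
            null = _rho_rows(u[idx], sel[idx])
            null_by_k[k] = np.sort(null)

        rows = []
        for gene in gene_order:
            k = sizes[gene]
            null = null_by_k[k]
            B = len(null)
            b = int(np.searchsorted(null, rho_obs[gene], side="right"))
            p_perm = (b + 1) / (B + 1)
            rows.append((gene, direction, k, rho_obs[gene], p_perm))
        df = pd.DataFrame(rows, columns=["gene", "direction", "n_guides", "rho", "p_perm"])
        df["fdr"] = benjamini_hochberg(df["p_perm"].to_numpy())
        out_frames.append(df)

    out = pd.concat(out_frames, ignore_index=True)
    out["gene_log2fc"] = out["gene"].map(gene_log2fc)
    return out


def call_screen_hits(
    gene_stats: pd.DataFrame,
    fc_cutoff: float = 2.0,
    p_cutoff: float = 0.005,
    screen_id: str = "screen",
) -> ScreenHitTable:
    """Call resistance hits from gene-level statistics.

    A gene is a hit iff it is in the *enriched* direction, its linear fold
    change ``2**gene_log2fc`` is >= ``fc_cutoff``, and ``p_perm`` is
    < ``p_cutoff``.  All genes are retained with a boolean flag.
    """
    if fc_cutoff <= 0 or not 0 < p_cutoff < 1:
        raise ValueError("cutoffs must be positive (p in (0,1))")
    enr = gene_stats.loc[gene_stats["direction"] == "enriched"].copy()
    if enr.empty:
        raise ValueError("no enriched-direction statistics present")
    fc = np.power(2.0, enr["gene_log2fc"].to_numpy(dtype=float))
    hit = (fc >= fc_cutoff) & (enr["p_perm"].to_numpy() < p_cutoff)
    table = pd.DataFrame(
        {
            "gene": enr["gene"].to_numpy(),
            "fold_change": fc,
            "p": enr["p_perm"].to_numpy(),
            "fdr": enr["fdr"].to_numpy(),
            "hit": hit,
        }
    )
    return ScreenHitTable(screen_id=screen_id, table=table)
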