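"""Gene-set enrichment over DE lists, pre-ranked scores, signature scores.

Over-representation uses the upper-tail hypergeometric test of the
overlap between a differentially-expressed (DE) gene list and each gene
set, relative to an explicit background; transcription-factor (TF)
activity is the same test run on TF target sets.  A combined score
-ln(p) * odds_ratio summarises significance and effect size in one
number.  Pre-ranked enrichment follows the weighted Kolmogorov-Smirnov
running-sum formulation; per-cell signature ("module") scores subtract
expression-matched control genes drawn from average-expression bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GeneSetCollection",
    "hypergeometric_enrich",
    "combined_score",
    "benjamini_hochberg",
    "infer_tf_activity",
    "preranked_es",
    "module_score",
    "normalize_counts",
    "de_gene_list",
]


@dataclass
class GeneSetCollection:
    """Named, deduplicated gene sets (pathways or TF target sets)."""

    sets: dict[str, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for name, members in self.sets.items():
            members = frozenset(members)
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            clean[name] = members
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values, in input order.

    adjusted_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _odds_ratio(k: int, K: int, n: int, N: int) -> float:
    """Odds ratio of the overlap 2x2 table, Haldane 0.5 if any cell is 0."""
    a = k
    b = n - k
    c = K - k
    d = N - K - n + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def hypergeometric_enrich(
    query,
    sets: GeneSetCollection,
    background,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each set in the query.

    Sets are intersected with the background before testing; the query
    must be a subset of the background.  Returns one row per set with
    columns ``set``, ``k`` (overlap), ``K`` (set size in background),
    ``n`` (query size), ``N`` (background size), ``p``, ``fdr``,
    ``odds_ratio``, ``combined_score``.
    """
    background = set(background)
    query = set(query)
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    if not background:
        raise ValueError("background is empty")
    if not query:
        warnings.warn("empty query list: all enrichment p-values are 1", stacklevel=2)
    N = len(background)
    n = len(query)
    rows = []
    for name, members in sets:
        eff = members & background
        if not eff:
            continue
        K = len(eff)
        k = len(eff & query)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = 1.0 if k == 0 else float(sps.hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, np.finfo(float).tiny), 1.0)
        oddsr = _odds_ratio(k, K, n, N)
        rows.append((name, k, K, n, N, p, oddsr))
    out = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p", "odds_ratio"])
    out["fdr"] = benjamini_hochberg(out["p"].to_numpy()) if len(out) else []
    out["combined_score"] = [
        combined_score(p, o) for p, o in zip(out["p"], out["odds_ratio"])
    ]
    return out[["set", "k", "K", "n", "N", "p", "fdr", "odds_ratio", "combined_score"]]


def combined_score(p: float, odds_ratio: float) -> float:
    """Combined enrichment score -ln(p) * odds_ratio.

    Folds significance and association strength into one number: 0 when
    p = 1 regardless of the odds ratio, and growing both with smaller p
    and with stronger overlap.
    """
    if p <= 0:
        raise ValueError("p must be positive")
    return -np.log(p) * odds_ratio


def de_gene_list(
    stats: pd.DataFrame,
    p_cutoff: float = 0.01,
    fc_cutoff: float = 1.5,
) -> list[str]:
    """DE gene list from a (gene, log2fc, p) table.

    A gene passes with p < ``p_cutoff`` and linear |fold change| >=
    ``fc_cutoff`` (the fold-change boundary is inclusive).
    """
    fc = np.power(2.0, np.abs(stats["log2fc"].to_numpy(dtype=float)))
    keep = (stats["p"].to_numpy(dtype=float) < p_cutoff) & (fc >= fc_cutoff)
    return stats.loc[keep, "gene"].tolist()


def infer_tf_activity(
    de_genes,
    tf_sets: GeneSetCollection,
    background,
    p_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Transcription-factor activity from target-set over-representation.

    Each TF's target set is tested with :func:`hypergeometric_enrich`;
    TFs with p < ``p_cutoff`` are flagged significant.  ``activity`` is
    the combined score min-max scaled across the profile and then
    log2(1 + scaled) for display.
    """
    res = hypergeometric_enrich(de_genes, tf_sets, background)
    res = res.rename(columns={"set": "tf"})
    res["significant"] = res["p"] < p_cutoff
    cs = res["combined_score"].to_numpy(dtype=float)
    span = cs.max() - cs.min() if len(cs) else 0.0
    scaled = (cs - cs.min()) / span if span > 0 else np.zeros_like(cs)
    res["activity"] = np.log2(1.0 + scaled)
    return res


def preranked_es(
    ranked: pd.Series,
    gene_set,
    n_permutations: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> tuple[float, float]:
    """Weighted KS running-sum enrichment score on a pre-ranked gene list.

    ``ranked`` maps gene -> ranking score, ordered from most up- to most
    down-regulated.  Hits advance the running sum by |score|**weight
    (normalised), misses retreat by 1/(N - Nh); the enrichment score ES
    is the extremum of the running sum.  The p-value permutes gene labels
    and compares sign-matched permuted scores against ES.
    """
    genes = np.asarray(ranked.index)
    scores = ranked.to_numpy(dtype=float)
    in_set = np.isin(genes, list(gene_set))
    nh = int(in_set.sum())
    N = len(genes)
    if nh == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if nh == N:
        warnings.warn("gene set spans the entire ranked list; ES set to 0", stacklevel=2)
        return 0.0, 1.0

    def _es(hit_mask: np.ndarray) -> float:
        w = np.abs(scores) ** weight
        denom = w[hit_mask].sum()
        if denom == 0:  # all hit scores zero: fall back to unweighted steps
            p_hit = hit_mask / hit_mask.sum()
        else:
            p_hit = np.where(hit_mask, w, 0.0) / denom
        p_miss = np.where(hit_mask, 0.0, 1.0 / (N - nh))
        run = np.cumsum(p_hit - p_miss)
        return float(run[np.argmax(np.abs(run))])

    es = _es(in_set)
    rng = np.random.default_rng(seed)
    same_sign = 0
    as_extreme = 0
    for _ in range(n_permutations):
        perm = np.zeros(N, dtype=bool)
        perm[rng.choice(N, nh, replace=False)] = True
        es_p = _es(perm)
        if np.sign(es_p) == np.sign(es) or es_p == 0:
            same_sign += 1
            if abs(es_p) >= abs(es):
                as_extreme += 1
    p = (as_extreme + 1) / (same_sign + 1)
    return es, float(min(p, 1.0))


def normalize_counts(expr: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """Library-size normalise a gene x cell count matrix.

    Counts are divided by the per-cell total, multiplied by ``scale`` and
    log(1 + x)-transformed — the conventional single-cell normalisation
    the signature score expects.
    """
    totals = expr.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("every cell needs a positive total count")
    return np.log1p(expr / totals * scale)


def module_score(
    expr: pd.DataFrame,
    signature,
    n_bins: int = 24,
    n_controls: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell signature score against expression-matched controls.

    Genes are binned by average expression across cells (``n_bins``
    equal-count bins); for each signature gene, ``n_controls`` control
    genes are sampled (with replacement) from its bin.  The score is the
    per-cell mean over signature genes minus the mean over the pooled
    control draws.  ``expr`` must already be normalised
    (:func:`normalize_counts`).
    """
    signature = list(dict.fromkeys(signature))
    present = [g for g in signature if g in expr.index]
    dropped = set(signature) - set(present)
    if dropped:
        warnings.warn(f"signature genes absent from matrix: {sorted(dropped)}", stacklevel=2)
    if not present:
        raise ValueError("no signature gene present in the expression matrix")

    avg = expr.mean(axis=1)
    ranks = avg.rank(method="first")
    bins = pd.cut(ranks, bins=min(n_bins, len(avg)), labels=False).to_numpy()
    bin_of = dict(zip(expr.index, bins))
    genes_in_bin: dict[int, np.ndarray] = {
        b: expr.index.to_numpy()[bins == b] for b in np.unique(bins)
    }

    rng = np.random.default_rng(seed)
    controls = []
    for g in present:
        pool = genes_in_bin[bin_of[g]]
        controls.append(rng.choice(pool, size=n_controls, replace=True))
    control_genes = np.concatenate(controls)

    sig_mean = expr.loc[present].mean(axis=0)
    ctrl_mean = expr.loc[control_genes].mean(axis=0)
    score = sig_mean - ctrl_mean
    score.name = "module_score"
    return score
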