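"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates the corresponding real data source closely enough
to exercise the downstream statistics:

* pooled-screen counts — negative-binomial guide counts (variance
  mu + phi * mu**2) with a planted log2 enrichment on the guides of
  resistant genes under drug, and a configurable fraction of inefficient
  ("dropout") guides within resistant genes;
* per-cell high-content tables — lognormal areas and intensities, border
  flags, a planted nuclear:cytoplasmic fold per perturbation and a
  multiplicative drug effect per pathway channel;
* DE gene lists — Bernoulli gene membership with a boosted rate inside
  chosen active gene sets;
* IHC category distributions — multinomial draws over the four staining
  intensities, converted to percentages.

All generators are driven by an explicit seed; no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .pooled import GuideCountMatrix

__all__ = [
    "ScreenSimConfig",
    "ScreenTruth",
    "CellSimConfig",
    "simulate_pooled_screen",
    "simulate_cell_table",
    "simulate_de_lists",
    "simulate_ihc",
    "random_gene_sets",
    "default_plate_design",
]


# --------------------------------------------------------------------------
# pooled screen
# --------------------------------------------------------------------------

@dataclass
class ScreenSimConfig:
    """Generative parameters of a pooled resistance screen.

    Counts are NB with mean ``mu_g`` and variance ``mu_g + dispersion *
    mu_g**2``; per-guide means scatter lognormally around ``mean_depth``
    (sigma ``library_sigma``) to emulate uneven library representation.
    Guides of resistant genes gain ``resistant_log2fc`` under drug except
    for a ``dropout_fraction`` of inefficient guides with no effect.
    """

    n_genes: int = 1000
    guides_per_gene: int = 5
    n_resistant: int = 20
    resistant_log2fc: float = 2.0
    mean_depth: float = 300.0
    dispersion: float = 0.1
    n_replicates: int = 2
    dropout_fraction: float = 0.1
    library_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.guides_per_gene < 1 or self.n_replicates < 1:
            raise ValueError("n_genes, guides_per_gene, n_replicates must be >= 1")
        if self.n_resistant < 0 or self.n_resistant > self.n_genes:
            raise ValueError("need 0 <= n_resistant <= n_genes")
        if self.dispersion <= 0 or self.mean_depth <= 0:
            raise ValueError("dispersion and mean_depth must be positive")
        if not 0 <= self.dropout_fraction <= 1:
            raise ValueError("dropout_fraction must be a probability")


@dataclass
class ScreenTruth:
    """Planted ground truth: resistant genes and per-guide true log2FC."""

    resistant_genes: frozenset
    guide_log2fc: pd.Series = field(repr=False)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_pooled_screen(cfg: ScreenSimConfig):
    """Generate (GuideCountMatrix, sample sheet, ScreenTruth).

    Samples: one plasmid library sample, ``n_replicates`` vehicle and
    ``n_replicates`` drug samples.  Vehicle and plasmid counts are
    NB(mu_g, phi); drug counts are NB(mu_g * 2**delta_g, phi) where
    delta_g is the planted per-guide log2 fold change.
    """
    rng = np.random.default_rng(cfg.seed)
    width = len(str(cfg.n_genes))
    gene_names = np.array([f"G{i + 1:0{width}d}" for i in range(cfg.n_genes)])
    guides = np.array(
        [f"{g}_sg{j + 1}" for g in gene_names for j in range(cfg.guides_per_gene)]
    )
    guide_gene = np.repeat(gene_names, cfg.guides_per_gene)

    resistant = rng.choice(gene_names, size=cfg.n_resistant, replace=False)
    resistant_set = frozenset(resistant.tolist())
    is_resist = np.isin(guide_gene, resistant)
    dropout = rng.random(len(guides)) < cfg.dropout_fraction
    delta = np.where(is_resist & ~dropout, cfg.resistant_log2fc, 0.0)

    sigma = cfg.library_sigma
    mu = cfg.mean_depth * rng.lognormal(-(sigma**2) / 2, sigma, size=len(guides))

    cols = {}
    sheet_rows = []
    cols["plasmid_1"] = _nb_draw(rng, mu, cfg.dispersion)
    sheet_rows.append(("plasmid_1", "simulated", "plasmid", 1, None))
    for r in range(1, cfg.n_replicates + 1):
        cols[f"vehicle_{r}"] = _nb_draw(rng, mu, cfg.dispersion)
        sheet_rows.append((f"vehicle_{r}", "simulated", "vehicle", r, None))
    for r in range(1, cfg.n_replicates + 1):
        cols[f"drug_{r}"] = _nb_draw(rng, mu * np.power(2.0, delta), cfg.dispersion)
        sheet_rows.append((f"drug_{r}", "simulated", "drug", r, "osimertinib"))

    counts = pd.DataFrame(cols, index=pd.Index(guides, name="guide"))
    matrix = GuideCountMatrix(
        counts=counts, guide_to_gene=pd.Series(guide_gene, index=counts.index, name="gene")
    )
    sheet = pd.DataFrame(
        sheet_rows, columns=["sample_id", "cell_line", "arm", "replicate", "drug_name"]
    )
    truth = ScreenTruth(
        resistant_genes=resistant_set,
        guide_log2fc=pd.Series(delta, index=counts.index, name="true_log2fc"),
    )
    return matrix, sheet, truth


# --------------------------------------------------------------------------
# arrayed high-content screen
# --------------------------------------------------------------------------

@dataclass
class CellSimConfig:
    """Generative parameters of per-cell high-content tables.

    Cytoplasmic intensities are lognormal (median ``baseline_intensity``,
    coefficient of variation ``intensity_noise_cv``); the nuclear
    intensity of the translocation channel is the cell's cytoplasmic
    value times ``baseline_nuc_cyt`` times the perturbation's planted
    fold (times ``drug_nuc_cyt_fold`` under drug) times multiplicative
    noise.  Pathway-marker channels are scaled by ``drug_effect`` under
    drug.  Areas are lognormal; border cells occur with probability
    ``border_fraction``.
    """

    cells_per_well: int = 2000
    baseline_nuc_cyt: float = 0.8
    planted_fold: dict = field(default_factory=lambda: {"NTC": 1.0})
    intensity_noise_cv: float = 0.3
    border_fraction: float = 0.1
    area_log_mean: float = 6.2   # log um^2, median ~ 490 um^2
    area_log_sigma: float = 0.35
    baseline_intensity: float = 100.0
    drug_effect: dict = field(
        default_factory=lambda: {"pakt": 0.15, "perk": 0.10, "ps6": 0.20, "yap": 1.0}
    )
    drug_nuc_cyt_fold: float = 1.5
    channels: tuple = ("yap", "pakt", "perk", "ps6")
    ratio_channel: str = "yap"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_fold.get("NTC", 1.0) != 1.0:
            raise ValueError("the NTC planted fold must be 1 by construction")
        self.planted_fold.setdefault("NTC", 1.0)
        if self.cells_per_well < 1:
            raise ValueError("cells_per_well must be >= 1")
        if not 0 <= self.border_fraction <= 1:
            raise ValueError("border_fraction must be a probability")
        if self.intensity_noise_cv <= 0 or self.baseline_nuc_cyt <= 0:
            raise ValueError("noise CV and baseline nuc:cyt must be positive")


def default_plate_design(
    perturbations, treatments=("vehicle", "drug"), wells_per_condition: int = 1
) -> dict:
    """Map wells (A01, A02, ...) to (perturbation, treatment) pairs."""
    design = {}
    i = 0
    for pert in perturbations:
        for treat in treatments:
            for _ in range(wells_per_condition):
                row, col = divmod(i, 24)
                design[f"{chr(65 + row)}{col + 1:02d}"] = (pert, treat)
                i += 1
    return design


def simulate_cell_table(cfg: CellSimConfig, design: dict) -> pd.DataFrame:
    """Per-cell table for one plate, following the given well design.

    ``design`` maps well id -> (perturbation, treatment).  Every
    perturbation must have a planted fold in the config (NTC defaults to
    1).  Returns one row per cell with columns plate, well, perturbation,
    treatment, nuclear_mean_<ch>, cytoplasm_mean_<ch>, area, is_border.
    """
    rng = np.random.default_rng(cfg.seed)
    sigma = np.sqrt(np.log1p(cfg.intensity_noise_cv**2))
    frames = []
    for well, (pert, treat) in design.items():
        if pert not in cfg.planted_fold:
            raise ValueError(f"unknown perturbation label {pert!r} (no planted fold)")
        if treat not in ("vehicle", "drug"):
            raise ValueError(f"unknown treatment {treat!r}")
        n = cfg.cells_per_well
        row = {
            "plate": "plate1",
            "well": well,
            "perturbation": pert,
            "treatment": treat,
            "area": rng.lognormal(cfg.area_log_mean, cfg.area_log_sigma, n),
            "is_border": rng.random(n) < cfg.border_fraction,
        }
        for ch in cfg.channels:
            drug_mult = cfg.drug_effect.get(ch, 1.0) if treat == "drug" else 1.0
            cyt = cfg.baseline_intensity * drug_mult * rng.lognormal(0.0, sigma, n)
            if ch == cfg.ratio_channel:
                ratio = cfg.baseline_nuc_cyt * cfg.planted_fold[pert]
                if treat == "drug":
                    ratio = ratio * cfg.drug_nuc_cyt_fold
                nuc = cyt * ratio * rng.lognormal(0.0, sigma, n)
            else:
                nuc = cyt * rng.lognormal(0.0, sigma / 2, n)
            row[f"cytoplasm_mean_{ch}"] = cyt
            row[f"nuclear_mean_{ch}"] = nuc
        frames.append(pd.DataFrame(row))
    out = pd.concat(frames, ignore_index=True)
    cols = ["plate", "well", "perturbation", "treatment"]
    cols += [f"nuclear_mean_{ch}" for ch in cfg.channels]
    cols += [f"cytoplasm_mean_{ch}" for ch in cfg.channels]
    cols += ["area", "is_border"]
    return out[cols]


# --------------------------------------------------------------------------
# DE lists and IHC
# --------------------------------------------------------------------------

def random_gene_sets(
    background,
    n_sets: int,
    set_size: int,
    seed: int = 0,
    prefix: str = "SET",
) -> GeneSetCollection:
    """Random gene sets drawn without replacement from a background list."""
    rng = np.random.default_rng(seed)
    bg = np.asarray(list(background))
    if set_size > len(bg):
        raise ValueError("set_size exceeds background size")
    sets = {
        f"{prefix}{i + 1:03d}": frozenset(rng.choice(bg, set_size, replace=False).tolist())
        for i in range(n_sets)
    }
    return GeneSetCollection(sets)


def simulate_de_lists(
    n_genes: int,
    gene_sets: GeneSetCollection,
    active_sets,
    enrichment_factor: float = 1.0,
    seed: int = 0,
    base_rate: float = 0.2,
):
    """Simulated DE gene list over a synthetic background.

    Background genes are ``G00001..``; each gene enters the DE list with
    probability ``base_rate``, boosted to ``min(base_rate *
    enrichment_factor, 0.99)`` for members of any active set.  Returns
    (de_list, background).
    """
    if n_genes < 1:
        raise ValueError("empty background")
    active_sets = set(active_sets)
    unknown = active_sets - set(gene_sets.names())
    if unknown:
        raise ValueError(f"active sets not in the collection: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    background = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    active_members = set().union(*(gene_sets[s] for s in active_sets)) if active_sets else set()
    probs = np.where(
        np.isin(background, list(active_members)),
        min(base_rate * enrichment_factor, 0.99),
        base_rate,
    )
    de_mask = rng.random(n_genes) < probs
    de_list = [g for g, m in zip(background, de_mask) if m]
    return de_list, background


def simulate_ihc(
    probabilities,
    n_cells: int = 500,
    seed: int = 0,
    compartment: str = "nucleus",
):
    """Multinomial draw over the four intensity categories, as percentages."""
    from .ihc import IntensityDistribution

    p = np.asarray(probabilities, dtype=float)
    if p.shape != (4,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must be four non-negative values summing to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_cells, p)
    pct = counts / n_cells * 100.0
    return IntensityDistribution(compartment, *pct)
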