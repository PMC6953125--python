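"""Synthetic single-cell and bulk datasets with planted zonation structure.

The generators emulate the statistical shape of the data the zonation
pipeline consumes:

* a hepatocyte UMI count matrix over a 9-layer lobule axis (layer 1 most
  pericentral, layer 9 most periportal), where each cell carries a
  probabilistic layer membership and zonated genes have strictly monotone
  mean profiles across layers;
* a CCl4/olive-oil bulk RNA-seq time course (months 0/2/6/12, six
  replicates per group) in which pericentral genes are progressively
  downregulated and periportal genes transiently upregulated;
* noisy per-study pericentral/periportal gene lists for exercising the
  cross-study consensus rule.

Counts are negative binomial with variance mu + phi * mu**2 (a single
global dispersion phi); per-cell/per-sample sequencing depth varies by
log-normal size factors. All randomness flows from the single integer
seed in :class:`SimConfig` through one :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "TruthLabels",
    "ConfigError",
    "simulate_layered_cells",
    "simulate_bulk_timecourse",
    "simulate_study_sets",
    "DEFAULT_BULK_EFFECTS",
]


class ConfigError(ValueError):
    """Raised for invalid simulation parameters."""


#: month -> (pericentral logFC, periportal logFC) planted in ccl4 vs oil.
#: Pericentral downregulation grows in magnitude with month; periportal
#: upregulation is transient (months 2 and 6, gone by month 12).
DEFAULT_BULK_EFFECTS: dict[int, tuple[float, float]] = {
    2: (-1.5, 2.0),
    6: (-2.0, 1.5),
    12: (-3.0, 0.0),
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the planted-structure simulation.

    Parameters
    ----------
    n_genes
        Number of simulated genes.
    n_cells
        Number of single cells (default 1415, the size of the layered
        hepatocyte reference dataset).
    n_layers
        Number of lobule layers on the porto-central axis (default 9).
    frac_pericentral, frac_periportal
        Fractions of genes planted with decreasing / increasing layer
        profiles; the remainder are flat ("none").
    profile_amplitude
        Maximum log2 fold-range of a zonated gene's mean across layers.
    nb_dispersion
        Global negative-binomial dispersion phi, var = mu + phi * mu**2.
        Zero gives Poisson counts.
    dirichlet_concentration
        Sharpness of the per-cell layer-membership probabilities; the
        Dirichlet is centred on the true layer (see
        :func:`simulate_layered_cells`).
    depth_sigma
        Log-normal sigma of per-cell / per-sample size factors.
    base_mean
        Median per-cell mean count of a gene (gene baselines are
        log-normal around this).
    n_replicates
        Bulk replicates per (treatment, month) group (default 6 mice).
    bulk_effects
        Map month -> (pericentral logFC, periportal logFC) planted into
        the ccl4-vs-oil comparison.
    seed
        Integer seed for the single random generator.
    """

    n_genes: int = 2000
    n_cells: int = 1415
    n_layers: int = 9
    frac_pericentral: float = 0.05
    frac_periportal: float = 0.05
    profile_amplitude: float = 2.0
    nb_dispersion: float = 0.1
    dirichlet_concentration: float = 15.0
    depth_sigma: float = 0.3
    base_mean: float = 0.5
    n_replicates: int = 6
    bulk_effects: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BULK_EFFECTS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_cells < 1:
            raise ConfigError("n_genes and n_cells must be positive")
        if self.n_layers < 2:
            raise ConfigError("n_layers must be >= 2")
        if not (0.0 <= self.frac_pericentral <= 1.0 and 0.0 <= self.frac_periportal <= 1.0):
            raise ConfigError("gene fractions must lie in [0, 1]")
        if self.frac_pericentral + self.frac_periportal > 1.0 + 1e-12:
            raise ConfigError("frac_pericentral + frac_periportal must be <= 1")
        if self.profile_amplitude < 0:
            raise ConfigError("profile_amplitude must be >= 0")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if self.dirichlet_concentration <= 0:
            raise ConfigError("dirichlet_concentration must be > 0")
        if self.depth_sigma < 0:
            raise ConfigError("depth_sigma must be >= 0")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")
        if self.seed < 0:
            raise ConfigError("seed must be a non-negative integer")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class TruthLabels:
    """Ground truth of a simulation run.

    Attributes
    ----------
    gene_direction
        Series indexed by gene id with values 'pericentral' |
        'periportal' | 'none'.
    cell_layer
        Series indexed by cell id with the true 1-based layer, or None
        for bulk-only runs.
    bulk_logfc
        DataFrame gene x month of planted ccl4-vs-oil log2 fold changes,
        or None for single-cell-only runs.
    """

    gene_direction: pd.Series
    cell_layer: pd.Series | None = None
    bulk_logfc: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB counts with var = mu + phi mu^2 (Poisson when phi == 0)."""
    mu = np.asarray(mu, dtype=float)
    if phi == 0.0:
        return rng.poisson(mu)
    # gamma-Poisson mixture: shape 1/phi, scale phi*mu
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
    return rng.poisson(lam)


def _assign_directions(cfg: SimConfig) -> pd.Series:
    n_pc = int(round(cfg.frac_pericentral * cfg.n_genes))
    n_pp = int(round(cfg.frac_periportal * cfg.n_genes))
    if n_pc + n_pp > cfg.n_genes:
        n_pp = cfg.n_genes - n_pc
    directions = np.array(
        ["pericentral"] * n_pc
        + ["periportal"] * n_pp
        + ["none"] * (cfg.n_genes - n_pc - n_pp)
    )
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    return pd.Series(directions, index=pd.Index(genes, name="gene"), name="direction")


def _layer_profiles(cfg: SimConfig, directions: pd.Series) -> np.ndarray:
    """Genes x layers matrix of relative means, geometric in log2.

    Zonated genes step by amplitude/(L-1) log2 units per layer, centred so
    the profile has unit geometric mean; flat genes are all ones.
    """
    L = cfg.n_layers
    step = cfg.profile_amplitude / (L - 1)
    axis = np.arange(L) - (L - 1) / 2.0  # centred layer coordinate
    log2_prof = np.zeros((len(directions), L))
    sign = np.where(
        directions.to_numpy() == "periportal",
        1.0,
        np.where(directions.to_numpy() == "pericentral", -1.0, 0.0),
    )
    log2_prof += sign[:, None] * step * axis[None, :]
    return 2.0 ** log2_prof


def simulate_layered_cells(config: SimConfig) -> tuple["LayeredCellMatrix", TruthLabels]:
    """Simulate a layered single-cell UMI matrix with planted zonation.

    Each cell gets a true layer (uniform over layers) and a Dirichlet
    layer-membership row with concentration mass on that layer
    (``alpha = 0.3`` everywhere plus ``dirichlet_concentration`` on the
    true layer), so rows sum to one and the arg-max recovers the true
    layer with high probability. Pericentral genes have strictly
    decreasing, periportal strictly increasing mean profiles from layer
    1 to ``n_layers``; counts are NB around
    ``depth_factor * baseline * profile``.

    Returns the matrix together with :class:`TruthLabels`.
    """
    from .zonation import LayeredCellMatrix  # local import to avoid cycle

    cfg = config
    rng = np.random.default_rng(cfg.seed)
    directions = _assign_directions(cfg)
    genes = directions.index.to_numpy()
    cells = np.array([f"c{i:04d}" for i in range(cfg.n_cells)])

    true_layer = rng.integers(1, cfg.n_layers + 1, size=cfg.n_cells)
    alpha = np.full((cfg.n_cells, cfg.n_layers), 0.3)
    alpha[np.arange(cfg.n_cells), true_layer - 1] += cfg.dirichlet_concentration
    layer_probs = np.empty_like(alpha)
    for i in range(cfg.n_cells):
        layer_probs[i] = rng.dirichlet(alpha[i])

    baselines = cfg.base_mean * np.exp(rng.normal(0.0, 1.0, size=cfg.n_genes))
    depth = np.exp(rng.normal(0.0, cfg.depth_sigma, size=cfg.n_cells))
    profiles = _layer_profiles(cfg, directions)  # genes x layers

    mu = baselines[:, None] * profiles[:, true_layer - 1] * depth[None, :]
    counts = _nb_draw(rng, mu, cfg.nb_dispersion).astype(np.int64)

    matrix = LayeredCellMatrix(
        counts=counts,
        layer_probs=layer_probs,
        gene_ids=list(genes),
        cell_ids=list(cells),
    )
    truth = TruthLabels(
        gene_direction=directions,
        cell_layer=pd.Series(true_layer, index=pd.Index(cells, name="cell"), name="layer"),
    )
    return matrix, truth


def simulate_bulk_timecourse(
    config: SimConfig,
    pericentral_genes: list[str] | None = None,
    periportal_genes: list[str] | None = None,
) -> tuple["BulkExperiment", TruthLabels]:
    """Simulate the CCl4/oil bulk time course with planted fold changes.

    Groups: untreated month 0; oil months 2 and 12; ccl4 months 2, 6 and
    12 — each with ``n_replicates`` samples. Untreated and oil group
    means equal the gene baseline (no solvent effect is planted, so the
    month-6 oil imputation downstream is unbiased); ccl4 means multiply
    the baseline by ``2**logFC`` with the per-month planted logFC from
    ``config.bulk_effects`` applied to the supplied pericentral and
    periportal gene lists.

    When the gene lists are omitted they default to the genes labelled
    by the config's own fractions (same labelling as
    :func:`simulate_layered_cells`).
    """
    from .diffexp import BulkExperiment  # local import to avoid cycle

    cfg = config
    directions = _assign_directions(cfg)
    if pericentral_genes is None and periportal_genes is None:
        pericentral_genes = list(directions.index[directions == "pericentral"])
        periportal_genes = list(directions.index[directions == "periportal"])
    pericentral_genes = list(pericentral_genes or [])
    periportal_genes = list(periportal_genes or [])
    if set(pericentral_genes) & set(periportal_genes):
        raise ConfigError("pericentral and periportal gene lists overlap")
    unknown = (set(pericentral_genes) | set(periportal_genes)) - set(directions.index)
    if unknown:
        raise ConfigError(f"gene lists refer to unsimulated genes: {sorted(unknown)[:5]}")

    rng = np.random.default_rng(cfg.seed + 1)  # distinct stream from the sc draw
    genes = directions.index.to_numpy()
    n_genes = len(genes)

    groups = [("untreated", 0), ("oil", 2), ("oil", 12), ("ccl4", 2), ("ccl4", 6), ("ccl4", 12)]
    design_rows = []
    sample_ids = []
    for treatment, month in groups:
        for r in range(1, cfg.n_replicates + 1):
            sample_ids.append(f"{treatment}_m{month}_r{r}")
            design_rows.append({"sample": sample_ids[-1], "treatment": treatment,
                                "month": month, "replicate": r})
    design = pd.DataFrame(design_rows).set_index("sample")

    # bulk baselines: moderately expressed genes (log-normal around ~100 counts)
    baselines = 100.0 * np.exp(rng.normal(0.0, 1.0, size=n_genes))

    is_pc = np.isin(genes, pericentral_genes)
    is_pp = np.isin(genes, periportal_genes)
    months = sorted(cfg.bulk_effects)
    logfc = pd.DataFrame(0.0, index=directions.index, columns=months)
    for m in months:
        pc_fc, pp_fc = cfg.bulk_effects[m]
        logfc.loc[is_pc, m] = pc_fc
        logfc.loc[is_pp, m] = pp_fc

    depth = np.exp(rng.normal(0.0, cfg.depth_sigma, size=len(sample_ids)))
    counts = np.empty((n_genes, len(sample_ids)), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        treatment = design.loc[sid, "treatment"]
        month = int(design.loc[sid, "month"])
        mu = baselines.copy()
        if treatment == "ccl4" and month in cfg.bulk_effects:
            mu = mu * 2.0 ** logfc[month].to_numpy()
        counts[:, j] = _nb_draw(rng, mu * depth[j], cfg.nb_dispersion)

    experiment = BulkExperiment(
        counts=counts, design=design, gene_ids=list(genes), sample_ids=sample_ids
    )
    truth = TruthLabels(gene_direction=directions, bulk_logfc=logfc)
    return experiment, truth


def simulate_study_sets(
    truth: TruthLabels,
    sensitivity: float,
    fpr: float,
    n_studies: int,
    seed: int,
) -> list[tuple[set[str], set[str]]]:
    """Noisy per-study (pericentral, periportal) gene sets.

    Each study reports each truly zonated gene with probability
    ``sensitivity`` in its true direction, and each non-zonated gene
    with probability ``fpr`` in a random direction — a minimal model of
    independent studies with imperfect, partly discordant calls.
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= fpr <= 1.0):
        raise ConfigError("sensitivity and fpr must lie in [0, 1]")
    if n_studies < 1:
        raise ConfigError("n_studies must be >= 1")
    rng = np.random.default_rng(seed)
    direction = truth.gene_direction
    genes = direction.index.to_numpy()
    is_pc = (direction == "pericentral").to_numpy()
    is_pp = (direction == "periportal").to_numpy()
    is_none = ~(is_pc | is_pp)

    studies = []
    for _ in range(n_studies):
        keep = rng.random(len(genes))
        pc = set(genes[is_pc & (keep < sensitivity)])
        pp = set(genes[is_pp & (keep < sensitivity)])
        false_hit = is_none & (rng.random(len(genes)) < fpr)
        coin = rng.random(len(genes)) < 0.5
        pc |= set(genes[false_hit & coin])
        pp |= set(genes[false_hit & ~coin])
        studies.append((pc, pp))
    return studies
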