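"""Pericentral/periportal gene calling from layered single-cell data.

The porto-central axis of the liver lobule is discretised into ordered
layers (1 = most pericentral, L = most periportal). Given UMI counts and
a per-cell layer-membership probability matrix, the screen proceeds:

1. drop genes expressed (count >= 1) in fewer than ``min_cells`` cells;
2. normalise cells by median-of-ratios size factors;
3. assign each cell to its maximum-probability layer;
4. per gene, test for a monotone trend across the ordered layers with
   the Jonckheere-Terpstra (JT) statistic, exactly (convolution of
   Mann-Whitney null distributions) for small tie-free samples and via
   the tie-corrected normal approximation otherwise;
5. Benjamini-Hochberg across genes; significant increasing genes are
   periportal, decreasing genes pericentral.

Cross-study consensus sets keep genes called in the same direction by at
least ``min_studies`` independent studies, after harmonising gene
symbols through an alias table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "LayeredCellMatrix",
    "ZonationCall",
    "GeneSet",
    "filter_low_expression",
    "compute_size_factors",
    "normalize_cells",
    "assign_layers",
    "jt_statistic",
    "jt_null_distribution",
    "jt_test",
    "call_zonation",
    "map_aliases",
    "build_consensus",
]

PROB_ROW_TOL = 1e-6


@dataclass
class LayeredCellMatrix:
    """UMI counts plus probabilistic layer membership.

    Attributes
    ----------
    counts
        genes x cells matrix of non-negative integer UMI counts.
    layer_probs
        cells x L matrix; each row is a probability distribution over
        the L ordered lobule layers (sums to 1 within ``PROB_ROW_TOL``).
    gene_ids, cell_ids
        Row / column identifiers.
    """

    counts: np.ndarray
    layer_probs: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.layer_probs = np.asarray(self.layer_probs, dtype=float)
        ng, nc = self.counts.shape
        if len(self.gene_ids) != ng or len(self.cell_ids) != nc:
            raise ValueError("identifier lists do not match matrix dimensions")
        if self.layer_probs.shape[0] != nc:
            raise ValueError("layer_probs rows must match the cell count")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.layer_probs < -PROB_ROW_TOL) or np.any(self.layer_probs > 1 + PROB_ROW_TOL):
            raise ValueError("layer probabilities must lie in [0, 1]")
        sums = self.layer_probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > PROB_ROW_TOL):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"layer probability row for cell {self.cell_ids[bad]!r} sums to {sums[bad]:.6g}"
            )

    @property
    def n_layers(self) -> int:
        return self.layer_probs.shape[1]

    def subset_genes(self, keep: np.ndarray) -> "LayeredCellMatrix":
        keep = np.asarray(keep)
        genes = [g for g, k in zip(self.gene_ids, keep) if k] if keep.dtype == bool else [
            self.gene_ids[i] for i in keep
        ]
        return LayeredCellMatrix(
            counts=self.counts[keep],
            layer_probs=self.layer_probs,
            gene_ids=genes,
            cell_ids=list(self.cell_ids),
        )


@dataclass(frozen=True)
class ZonationCall:
    """Per-gene trend-test result."""

    gene_id: str
    U: float
    z: float
    p: float
    q: float
    direction: str  # 'pericentral' | 'periportal' | 'none'


@dataclass(frozen=True)
class GeneSet:
    """A named gene set with an optional zonation direction tag."""

    name: str
    members: frozenset[str]
    direction: str = "untagged"  # 'pericentral' | 'periportal' | 'untagged'

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if self.direction not in ("pericentral", "periportal", "untagged"):
            raise ValueError(f"unknown direction tag {self.direction!r}")

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# filtering and normalisation
# ---------------------------------------------------------------------------

def filter_low_expression(matrix: LayeredCellMatrix, min_cells: int = 15) -> LayeredCellMatrix:
    """Remove genes expressed (count >= 1) in fewer than ``min_cells`` cells."""
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    n_expressed = (matrix.counts >= 1).sum(axis=1)
    keep = n_expressed >= min_cells
    if not keep.any():
        logger.warning("expression filter removed all %d genes", len(keep))
    logger.info("expression filter: kept %d / %d genes", int(keep.sum()), len(keep))
    return matrix.subset_genes(keep)


def compute_size_factors(counts: np.ndarray, cell_ids: list[str] | None = None) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference profile is the per-gene geometric mean over cells,
    computed on genes with nonzero counts in every cell; each cell's
    factor is the median of its count ratios to that reference. When no
    gene is nonzero in all cells (very sparse matrices) total-count
    factors are used instead, with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        bad = int(np.argmax(totals == 0))
        name = cell_ids[bad] if cell_ids else f"column {bad}"
        raise ValueError(f"cell {name!r} has zero total count; cannot normalise")
    all_nonzero = np.all(counts > 0, axis=1)
    if all_nonzero.any():
        sub = counts[all_nonzero]
        ref = np.exp(np.mean(np.log(sub), axis=1))  # per-gene geometric mean
        factors = np.median(sub / ref[:, None], axis=0)
    else:
        logger.warning(
            "no gene is nonzero in all cells; falling back to total-count size factors"
        )
        factors = totals.astype(float)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def normalize_cells(matrix: LayeredCellMatrix) -> np.ndarray:
    """Depth-normalised expression: count / per-cell size factor."""
    factors = compute_size_factors(matrix.counts, matrix.cell_ids)
    return matrix.counts / factors[None, :]


def assign_layers(layer_probs: np.ndarray, tol: float = PROB_ROW_TOL) -> np.ndarray:
    """Maximum-probability layer per cell (1-based); ties -> lowest layer.

    Raises if any probability row does not sum to 1 within ``tol``.
    """
    probs = np.asarray(layer_probs, dtype=float)
    sums = probs.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > tol):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(f"probability row {bad} sums to {sums[bad]:.6g}, not 1")
    return probs.argmax(axis=1) + 1  # argmax returns the first maximum


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra trend test
# ---------------------------------------------------------------------------

def jt_statistic(groups: list[np.ndarray]) -> float:
    """JT statistic: concordant between-group pairs, ties counted 1/2.

    U = sum over ordered group pairs a < b of
    #{x_a < x_b} + 0.5 * #{x_a = x_b}.
    """
    U = 0.0
    sorted_groups = [np.sort(np.asarray(g, dtype=float)) for g in groups]
    for a in range(len(groups) - 1):
        ga = sorted_groups[a]
        for b in range(a + 1, len(groups)):
            gb = sorted_groups[b]
            lo = np.searchsorted(ga, gb, side="left")
            hi = np.searchsorted(ga, gb, side="right")
            U += lo.sum() + 0.5 * (hi - lo).sum()
    return float(U)


def _mann_whitney_null(m: int, n: int) -> np.ndarray:
    """Exact null pmf of the Mann-Whitney U statistic for sizes (m, n).

    Classic counting recurrence N(i, j, u) = N(i, j-1, u) + N(i-1, j, u-j)
    over support u = 0..m*n, returned as probabilities.
    """
    prev = [np.array([1.0]) for _ in range(n + 1)]  # i = 0 row
    for i in range(1, m + 1):
        cur = [np.array([1.0])]
        for j in range(1, n + 1):
            arr = np.zeros(i * j + 1)
            a = cur[j - 1]
            arr[: a.size] += a
            b = prev[j]
            arr[j : j + b.size] += b
            cur.append(arr)
        prev = cur
    pmf = prev[n]
    return pmf / pmf.sum()


def jt_null_distribution(group_sizes: list[int]) -> np.ndarray:
    """Exact tie-free null pmf of the JT statistic.

    Under the tie-free null the JT statistic decomposes into independent
    Mann-Whitney statistics U(n_1 + ... + n_{i-1}, n_i), whose null pmfs
    are convolved; support is 0 .. sum_{a<b} n_a n_b.
    """
    pmf = np.array([1.0])
    cum = group_sizes[0]
    for n_i in group_sizes[1:]:
        pmf = np.convolve(pmf, _mann_whitney_null(cum, n_i))
        cum += n_i
    return pmf


def _jt_moments(group_sizes: np.ndarray, tie_sizes: np.ndarray) -> tuple[float, float]:
    """Null mean and tie-corrected variance of the JT statistic."""
    n = group_sizes.astype(float)
    t = tie_sizes.astype(float)
    N = n.sum()
    mean = (N**2 - np.sum(n**2)) / 4.0
    term1 = (
        N * (N - 1) * (2 * N + 5)
        - np.sum(n * (n - 1) * (2 * n + 5))
        - np.sum(t * (t - 1) * (2 * t + 5))
    ) / 72.0
    term2 = (
        np.sum(n * (n - 1) * (n - 2)) * np.sum(t * (t - 1) * (t - 2))
    ) / (36.0 * N * (N - 1) * (N - 2))
    term3 = (np.sum(n * (n - 1)) * np.sum(t * (t - 1))) / (8.0 * N * (N - 1))
    return mean, term1 + term2 + term3


def jt_test(
    values: np.ndarray,
    groups: np.ndarray,
    mode: str = "auto",
    exact_cap: int = 20,
) -> tuple[float, float, float]:
    """Jonckheere-Terpstra trend test across ordered groups.

    Parameters
    ----------
    values
        Observations.
    groups
        Ordered group label per observation (sortable; the natural sort
        order of the labels defines the hypothesised trend direction).
    mode
        'exact' (full permutation null via convolution; tie-free data
        only — with ties it falls back to the asymptotic branch),
        'asymptotic' (tie-corrected normal approximation), or 'auto'
        (exact when total n <= ``exact_cap`` and the data are tie-free).

    Returns
    -------
    (U, z, p_two_sided)
        The statistic, its standardised value, and the two-sided p-value
        (exact: twice the smaller tail, capped at 1).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have the same length")
    labels = np.unique(groups)  # sorted -> defines the ordering
    if labels.size < 2:
        raise ValueError("jt_test requires at least 2 non-empty ordered groups")
    by_group = [values[groups == lab] for lab in labels]
    sizes = np.array([len(g) for g in by_group])
    N = int(sizes.sum())

    U = jt_statistic(by_group)
    _, tie_counts = np.unique(values, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))
    mean, var = _jt_moments(sizes, tie_counts)
    z = 0.0 if var <= 0 else (U - mean) / np.sqrt(var)

    if mode not in ("exact", "asymptotic", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (mode == "auto" and N <= exact_cap)
    if use_exact and has_ties:
        if mode == "exact":
            logger.debug("ties present; exact JT null undefined, using asymptotic branch")
        use_exact = False

    if use_exact:
        pmf = jt_null_distribution(list(sizes))
        u_int = int(round(U))
        lower = float(pmf[: u_int + 1].sum())
        upper = float(pmf[u_int:].sum())
        p = min(1.0, 2.0 * min(lower, upper))
    else:
        if var <= 0:
            p = 1.0
        else:
            p = 2.0 * stats.norm.sf(abs(z))
    return U, float(z), float(p)


def call_zonation(
    expression: np.ndarray,
    gene_ids: list[str],
    layers: np.ndarray,
    fdr_threshold: float = 0.001,
    mode: str = "asymptotic",
) -> pd.DataFrame:
    """Per-gene JT screen across ordered layers with BH correction.

    Parameters
    ----------
    expression
        genes x cells normalised expression.
    gene_ids
        Row identifiers.
    layers
        Per-cell 1-based layer assignment (from :func:`assign_layers`).
    fdr_threshold
        BH FDR below which a gene is called zonated.
    mode
        JT mode passed through; layered data with hundreds of cells per
        layer always lands in the asymptotic branch.

    Returns
    -------
    DataFrame indexed by gene with columns U, z, p, q, direction
    (periportal for significant increasing trends toward the last layer,
    pericentral for decreasing).
    """
    from statsmodels.stats.multitest import multipletests

    expression = np.asarray(expression, dtype=float)
    layers = np.asarray(layers)
    occupied = np.unique(layers)
    if occupied.size < 2:
        raise ValueError("call_zonation requires at least 2 occupied layers")
    if expression.shape[0] != len(gene_ids):
        raise ValueError("gene_ids must match the expression row count")

    order = np.argsort(layers, kind="stable")
    layers_sorted = layers[order]

    rows = []
    for gi, gene in enumerate(gene_ids):
        vals = expression[gi, order]
        U, z, p = jt_test(vals, layers_sorted, mode=mode)
        rows.append((gene, U, z, p))
    calls = pd.DataFrame(rows, columns=["gene", "U", "z", "p"]).set_index("gene")
    _, q, _, _ = multipletests(calls["p"].to_numpy(), method="fdr_bh")
    calls["q"] = q
    sig = calls["q"] <= fdr_threshold
    calls["direction"] = "none"
    calls.loc[sig & (calls["z"] > 0), "direction"] = "periportal"
    calls.loc[sig & (calls["z"] < 0), "direction"] = "pericentral"
    n_pc = int((calls["direction"] == "pericentral").sum())
    n_pp = int((calls["direction"] == "periportal").sum())
    logger.info("zonation calls at FDR<=%g: %d pericentral, %d periportal", fdr_threshold, n_pc, n_pp)
    return calls


def zonation_calls_as_records(calls: pd.DataFrame) -> list[ZonationCall]:
    """View a call table as a list of :class:`ZonationCall` records."""
    return [
        ZonationCall(gene_id=g, U=r.U, z=r.z, p=r.p, q=r.q, direction=r.direction)
        for g, r in calls.iterrows()
    ]


# ---------------------------------------------------------------------------
# alias harmonisation and cross-study consensus
# ---------------------------------------------------------------------------

def map_aliases(gene_set: GeneSet, aliases: dict[str, str]) -> GeneSet:
    """Replace outdated symbols via the alias table; duplicates collapse."""
    members = frozenset(aliases.get(g, g) for g in gene_set.members)
    return GeneSet(name=gene_set.name, members=members, direction=gene_set.direction)


def build_consensus(
    per_study_sets: list[tuple[GeneSet | set, GeneSet | set]],
    min_studies: int = 2,
) -> tuple[GeneSet, GeneSet]:
    """Genes called in the same direction by >= ``min_studies`` studies.

    Genes that would qualify in both directions are excluded from both
    consensus sets and logged (discordant cross-study evidence).
    """
    if min_studies < 1:
        raise ValueError("min_studies must be >= 1")
    if len(per_study_sets) < min_studies:
        raise ValueError(
            f"need at least min_studies={min_studies} studies, got {len(per_study_sets)}"
        )

    def _members(s) -> frozenset:
        return s.members if isinstance(s, GeneSet) else frozenset(s)

    pc_counts: dict[str, int] = {}
    pp_counts: dict[str, int] = {}
    for pc_set, pp_set in per_study_sets:
        for g in _members(pc_set):
            pc_counts[g] = pc_counts.get(g, 0) + 1
        for g in _members(pp_set):
            pp_counts[g] = pp_counts.get(g, 0) + 1
    pc = {g for g, c in pc_counts.items() if c >= min_studies}
    pp = {g for g, c in pp_counts.items() if c >= min_studies}
    conflicts = pc & pp
    if conflicts:
        logger.warning(
            "%d genes qualify for both directions and are excluded: %s",
            len(conflicts),
            sorted(conflicts)[:10],
        )
    return (
        GeneSet("consensus_pericentral", frozenset(pc - conflicts), "pericentral"),
        GeneSet("consensus_periportal", frozenset(pp - conflicts), "periportal"),
    )
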