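"""Set enrichment, over-representation, and activity scoring.

Quantifies periportalization of a ranked differential-expression
signature (genes ordered by moderated t, upregulated at the top):

* weighted Kolmogorov-Smirnov GSEA with a gene-set permutation null and
  leading-edge extraction — positive ES means the set concentrates
  among upregulated genes, negative among downregulated;
* over-representation analysis (one-sided Fisher exact test against a
  fixed background universe, default 20,000 genes);
* footprint pathway activity: weighted sum of the statistics of a
  pathway's most responsive genes, standardised against a
  gene-permutation null;
* regulon activity: signed sum of normal-quantile-transformed target
  ranks, scaled by sqrt(regulon size) — a rank-based normalized
  enrichment score for transcription-factor activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .zonation import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "EsProfile",
    "EnrichmentResult",
    "ORAResult",
    "rank_signature",
    "gsea_es",
    "gsea_test",
    "leading_edge",
    "ora_test",
    "footprint_scores",
    "regulon_activity",
    "periportalization_report",
]


@dataclass
class EsProfile:
    """Running-sum profile of one weighted-KS evaluation."""

    es: float
    running: np.ndarray  # length = signature size, value after each rank
    peak: int  # 0-based rank index at which |deviation| is maximal


@dataclass
class EnrichmentResult:
    """GSEA outcome for one gene set against one ranked signature."""

    name: str
    es: float
    nes: float
    p_perm: float
    n_perm: int
    leading_edge: list[str] = field(default_factory=list)


@dataclass
class ORAResult:
    """Fisher-exact over-representation outcome."""

    name: str
    overlap: int  # k
    query_n: int  # n
    set_n: int  # K
    background_n: int  # N
    odds_ratio: float
    p: float
    continuity: bool = False  # 0.5 added to the odds ratio's cells


def rank_signature(rows: pd.DataFrame | pd.Series, stat_col: str = "t") -> pd.Series:
    """Signature: genes sorted by statistic descending, ties by gene id."""
    if isinstance(rows, pd.Series):
        stat = rows.astype(float)
    else:
        stat = rows[stat_col].astype(float)
    if stat.index.has_duplicates:
        dupes = stat.index[stat.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate gene ids in signature: {dupes}")
    if not np.all(np.isfinite(stat.to_numpy())):
        raise ValueError("signature statistics must be finite")
    order = sorted(stat.index, key=lambda g: (-stat[g], g))
    out = stat.loc[order]
    out.index.name = "gene"
    return out


# ---------------------------------------------------------------------------
# weighted-KS GSEA
# ---------------------------------------------------------------------------

def _hit_positions(signature: pd.Series, members) -> np.ndarray:
    genes = signature.index
    mask = genes.isin(set(members))
    n_missing = len(set(members)) - int(mask.sum())
    if n_missing:
        logger.info("%d set members absent from the signature were dropped", n_missing)
    if not mask.any():
        raise ValueError("gene set has no overlap with the signature")
    return np.flatnonzero(mask)


def gsea_es(signature: pd.Series, gene_set: GeneSet | set, weight_exponent: float = 1.0
            ) -> EsProfile:
    """Weighted-KS running sum and enrichment score.

    Walking down the ranking, a set member ("hit") at rank i increments
    the running sum by |stat_i|^weight_exponent normalised over all hit
    weights; a non-member decrements by 1/(N - n_hits). ES is the
    running-sum value of maximal absolute deviation from zero.
    """
    members = gene_set.members if isinstance(gene_set, GeneSet) else gene_set
    pos = _hit_positions(signature, members)
    stat = signature.to_numpy(dtype=float)
    N = stat.size
    k = pos.size
    w = np.abs(stat[pos]) ** weight_exponent
    if w.sum() == 0:
        w = np.ones(k)  # all statistics zero: fall back to unweighted
    step = np.full(N, -1.0 / (N - k) if N > k else 0.0)
    step[pos] = w / w.sum()
    running = np.cumsum(step)
    peak = int(np.argmax(np.abs(running)))
    return EsProfile(es=float(running[peak]), running=running, peak=peak)


def _null_es(stat: np.ndarray, k: int, n_perm: int, weight_exponent: float,
             rng: np.random.Generator, chunk: int = 512) -> np.ndarray:
    """Null ES for random same-size gene sets, vectorised over permutations."""
    N = stat.size
    weights = np.abs(stat) ** weight_exponent
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # m random k-subsets of 0..N-1, rows sorted ascending
        pos = np.argpartition(rng.random((m, N)), k - 1, axis=1)[:, :k]
        pos.sort(axis=1)
        w = weights[pos]
        cumw = np.cumsum(w, axis=1)
        nr = cumw[:, -1:]
        zero_nr = nr[:, 0] == 0
        if np.any(zero_nr):  # all-zero weights: unweighted fallback, as observed path
            cumw[zero_nr] = np.arange(1, k + 1)[None, :]
            nr[zero_nr] = k
        miss = (pos - np.arange(k)[None, :]) / (N - k)
        at_hit = cumw / nr - miss
        before_hit = (cumw - w) / nr - miss
        es_pos = at_hit.max(axis=1)
        es_neg = before_hit.min(axis=1)
        out[done : done + m] = np.where(es_pos >= -es_neg, es_pos, es_neg)
        done += m
    return out


def gsea_test(
    signature: pd.Series,
    gene_set: GeneSet | set,
    n_perm: int = 100_000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> EnrichmentResult:
    """GSEA with a random-gene-set permutation null.

    p is one-tailed on the observed ES sign: (1 + b) / (1 + m) where b
    counts same-sign null ES at least as extreme and m counts the
    same-sign nulls, so a null p is uniform; NES is ES divided by the
    mean |null ES| of matching sign.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    members = gene_set.members if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    profile = gsea_es(signature, members, weight_exponent)
    pos = _hit_positions(signature, members)
    rng = np.random.default_rng(seed)
    null = _null_es(signature.to_numpy(dtype=float), pos.size, n_perm, weight_exponent, rng)

    es = profile.es
    same_sign = null >= 0 if es >= 0 else null < 0
    b = int(np.sum(same_sign & (np.abs(null) >= abs(es))))
    p = (1 + b) / (1 + int(same_sign.sum()))
    denom_pool = np.abs(null[same_sign])
    denom = float(denom_pool.mean()) if denom_pool.size else float(np.abs(null).mean())
    nes = es / denom if denom > 0 else 0.0
    name = gene_set.name if isinstance(gene_set, GeneSet) else "set"
    return EnrichmentResult(
        name=name,
        es=es,
        nes=float(nes),
        p_perm=float(p),
        n_perm=n_perm,
        leading_edge=leading_edge(signature, members, profile),
    )


def leading_edge(signature: pd.Series, gene_set: GeneSet | set, profile: EsProfile
                 ) -> list[str]:
    """Set members driving the enrichment.

    Positive ES: members at ranks up to and including the running-sum
    peak; negative ES: members at or after the peak; zero ES: empty.
    """
    members = gene_set.members if isinstance(gene_set, GeneSet) else gene_set
    if profile.es == 0:
        return []
    pos = _hit_positions(signature, members)
    if profile.es > 0:
        sel = pos[pos <= profile.peak]
    else:
        sel = pos[pos >= profile.peak]
    return [signature.index[i] for i in sel]


# ---------------------------------------------------------------------------
# over-representation analysis
# ---------------------------------------------------------------------------

def ora_test(query: GeneSet | set, gene_set: GeneSet | set, background_n: int = 20_000
             ) -> ORAResult:
    """One-sided Fisher exact test of set overlap against a background.

    The 2x2 table is (k, n-k; K-k, N-n-K+k) with k the overlap, n the
    query size, K the set size, N the background; the alternative is
    enrichment (greater). The odds ratio gets a 0.5 continuity
    correction only when a cell is zero (flagged).
    """
    q = query.members if isinstance(query, GeneSet) else frozenset(query)
    s = gene_set.members if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    k = len(q & s)
    n = len(q)
    K = len(s)
    N = background_n
    if N < len(q | s):
        raise ValueError("background_n smaller than the union of query and set")
    table = np.array([[k, n - k], [K - k, N - n - K + k]])
    if np.any(table < 0):
        raise ValueError("inconsistent 2x2 table (negative cell)")
    _, p = stats.fisher_exact(table, alternative="greater")
    continuity = bool(np.any(table == 0))
    t = table + 0.5 if continuity else table
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    name = gene_set.name if isinstance(gene_set, GeneSet) else "set"
    return ORAResult(
        name=name, overlap=k, query_n=n, set_n=K, background_n=N,
        odds_ratio=float(odds), p=float(p), continuity=continuity,
    )


# ---------------------------------------------------------------------------
# footprint pathway and regulon activity scores
# ---------------------------------------------------------------------------

def footprint_scores(
    statistics: pd.Series,
    model: dict[str, dict[str, float]],
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Footprint pathway activities from a gene-level statistic.

    Per pathway, raw = sum over model genes present in the signature of
    weight * statistic; z standardises raw against a null where the
    gene-to-statistic assignment is permuted (model weights applied to
    random statistic draws without replacement).
    """
    stat = statistics.astype(float)
    values = stat.to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for pathway, weights in model.items():
        present = [g for g in weights if g in stat.index]
        if not present:
            raise ValueError(f"pathway {pathway!r} has no genes in the signature")
        w = np.array([weights[g] for g in present])
        raw = float(w @ stat.loc[present].to_numpy())
        m = len(present)
        null = np.empty(n_perm)
        chunk = max(1, min(2048, n_perm))
        done = 0
        while done < n_perm:
            c = min(chunk, n_perm - done)
            idx = np.argpartition(rng.random((c, values.size)), m - 1, axis=1)[:, :m]
            null[done : done + c] = values[idx] @ w
            done += c
        sd = null.std()
        z = (raw - null.mean()) / sd if sd > 0 else 0.0
        rows.append((pathway, raw, float(z)))
    return pd.DataFrame(rows, columns=["pathway", "score", "z"]).set_index("pathway")


def regulon_activity(statistics: pd.Series, regulons: dict[str, dict[str, int]]
                     ) -> pd.Series:
    """Rank-based regulon (transcription factor) activity scores.

    Statistics are rank-transformed to standard-normal quantiles
    Phi^-1(rank / (N + 1)); a regulon's NES is the mode-signed sum of
    its targets' quantiles divided by sqrt(number of targets present),
    so positive activating targets among upregulated genes give
    positive activity.
    """
    stat = statistics.astype(float)
    ranks = stats.rankdata(stat.to_numpy())
    quantiles = pd.Series(
        stats.norm.ppf(ranks / (len(ranks) + 1.0)), index=stat.index
    )
    out = {}
    for tf, targets in regulons.items():
        present = [(g, s) for g, s in targets.items() if g in quantiles.index]
        if not present:
            raise ValueError(f"regulon {tf!r} has no targets in the signature")
        total = sum(s * quantiles[g] for g, s in present)
        out[tf] = total / np.sqrt(len(present))
    return pd.Series(out, name="nes").sort_values(ascending=False)


# ---------------------------------------------------------------------------
# the periportalization report
# ---------------------------------------------------------------------------

def periportalization_report(
    signatures_by_month: dict[int, pd.Series],
    pericentral: GeneSet,
    periportal: GeneSet,
    n_perm: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-month GSEA of the two consensus zonation sets.

    Positive NES: the set is enriched among upregulated genes; negative
    among downregulated. Fibrotic periportalization shows as negative
    pericentral and positive periportal enrichment. p-values are not
    adjusted across the two sets per signature.
    """
    if len(pericentral) == 0 or len(periportal) == 0:
        raise ValueError("consensus sets must be non-empty")
    rows = []
    for i, (month, sig) in enumerate(sorted(signatures_by_month.items())):
        for j, gs in enumerate((pericentral, periportal)):
            res = gsea_test(sig, gs, n_perm=n_perm, seed=seed + 1000 * i + j)
            rows.append(
                {
                    "month": month,
                    "set": gs.name,
                    "direction": gs.direction,
                    "es": res.es,
                    "nes": res.nes,
                    "p": res.p_perm,
                    "n_leading_edge": len(res.leading_edge),
                    "leading_edge": ";".join(res.leading_edge),
                }
            )
    return pd.DataFrame(rows)
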