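"""Moderated differential expression for the CCl4/oil bulk time course.

Per-month contrasts of ccl4 vs oil on TMM-normalised log2-CPM, with an
empirical-Bayes moderated t-statistic: per-gene residual variances are
shrunk toward a scaled-inverse-chi-squared prior fitted by moment
matching on log variances, and the contrast t gains the prior degrees
of freedom. The design has no oil group at month 6; its log expression
is imputed as the arithmetic mean of the month-2 and month-12 oil group
means, entering the contrast mean only — the imputed group contributes
no residual degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "BulkExperiment",
    "EBPrior",
    "ContrastFit",
    "normalize_bulk",
    "tmm_factors",
    "impute_oil_month6",
    "fit_contrasts",
    "estimate_eb_prior",
    "moderated_t",
    "bh_fdr",
    "select_de",
    "overlap_union",
    "run_diffexp",
]

VALID_TREATMENTS = {"untreated", "oil", "ccl4"}
VALID_MONTHS = {0, 2, 6, 12}


@dataclass
class BulkExperiment:
    """Bulk counts plus the treatment x month design.

    ``counts`` is genes x samples; ``design`` is indexed by sample id
    with columns treatment (untreated|oil|ccl4), month (0|2|6|12) and
    replicate.
    """

    counts: np.ndarray
    design: pd.DataFrame
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match identifier lists")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        missing = set(self.sample_ids) - set(self.design.index)
        if missing:
            raise ValueError(f"design table missing samples: {sorted(missing)[:5]}")
        bad_t = set(self.design["treatment"]) - VALID_TREATMENTS
        if bad_t:
            raise ValueError(f"unknown treatments {bad_t}")
        bad_m = set(int(m) for m in self.design["month"]) - VALID_MONTHS
        if bad_m:
            raise ValueError(f"unknown months {bad_m}")


@dataclass(frozen=True)
class EBPrior:
    """Scaled-inverse-chi-squared prior on gene variances.

    ``d0`` prior degrees of freedom (``np.inf`` means all gene
    variances are shrunk fully to ``s0_sq``); ``s0_sq`` prior variance.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be >= 0 (inf allowed)")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be > 0")


@dataclass
class ContrastFit:
    """Group-mean fit of the time course.

    ``logfc`` genes x months ccl4-vs-oil contrasts; ``s2`` pooled
    per-gene residual variance with ``df`` residual degrees of freedom
    (real groups only); ``stderr_unit[m]`` the per-gene-independent
    standard-error multiplier sqrt(sum c_i^2 / n_i) of month m's
    contrast; ``mean_expr`` average log2-CPM per gene.
    """

    logfc: pd.DataFrame
    s2: pd.Series
    df: int
    stderr_unit: dict[int, float]
    mean_expr: pd.Series


# ---------------------------------------------------------------------------
# TMM normalisation
# ---------------------------------------------------------------------------

def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              logratio_trim: float = 0.3, sum_trim: float = 0.05) -> float:
    """Trimmed weighted mean of M-values of one sample against the reference.

    30% two-sided trim on M, 5% on A; weights are inverse asymptotic
    (delta-method binomial) variances. Returns the log2 scale factor.
    """
    pos = (obs > 0) & (ref > 0)
    obs, ref = obs[pos].astype(float), ref[pos].astype(float)
    if obs.size == 0:
        return 0.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)

    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or np.sum(1.0 / w[keep]) == 0:
        return 0.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(f) if np.isfinite(f) else 0.0


def tmm_factors(counts: np.ndarray) -> np.ndarray:
    """TMM scale factors with geometric mean 1.

    Reference sample: the one whose upper-quartile of depth-scaled
    counts is closest to the mean upper quartile.
    """
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    if np.any(lib == 0):
        bad = int(np.argmax(lib == 0))
        raise ValueError(f"sample column {bad} has zero total count")
    uq = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    log_f = np.array([
        _tmm_pair(counts[:, j], counts[:, ref_idx], lib[j], lib[ref_idx])
        for j in range(counts.shape[1])
    ])
    factors = 2.0 ** log_f
    return factors / np.exp(np.mean(np.log(factors)))


def normalize_bulk(experiment: BulkExperiment) -> pd.DataFrame:
    """TMM-normalised log2-CPM with a 0.5 pseudocount on the CPM scale.

    log2(count / effective_library * 1e6 + 0.5); putting the pseudocount
    on the CPM scale makes the transform exactly invariant to pure
    sequencing-depth rescaling of a sample.
    """
    counts = experiment.counts.astype(float)
    lib = counts.sum(axis=0)
    factors = tmm_factors(counts)
    eff_lib = lib * factors
    logcpm = np.log2(counts / eff_lib[None, :] * 1e6 + 0.5)
    return pd.DataFrame(logcpm, index=pd.Index(experiment.gene_ids, name="gene"),
                        columns=experiment.sample_ids)


# ---------------------------------------------------------------------------
# contrast fitting with month-6 oil imputation
# ---------------------------------------------------------------------------

def impute_oil_month6(logexpr_oil_m2: pd.Series, logexpr_oil_m12: pd.Series) -> pd.Series:
    """Month-6 oil log expression as the mean of months 2 and 12.

    The imputed values stand in for a missing control group; they carry
    no replicate scatter, so downstream fits must not draw residual
    variance from them.
    """
    if not logexpr_oil_m2.index.equals(logexpr_oil_m12.index):
        raise ValueError("gene lists of the month-2 and month-12 oil means differ")
    out = (logexpr_oil_m2 + logexpr_oil_m12) / 2.0
    out.name = "oil_m6_imputed"
    return out


def fit_contrasts(
    logexpr: pd.DataFrame,
    design: pd.DataFrame,
    months: tuple[int, ...] = (2, 6, 12),
) -> ContrastFit:
    """OLS group-mean fit and ccl4-vs-oil contrasts per month.

    Residual variance is pooled over the real (treatment, month) groups
    with df = n_samples - n_groups. For a month with no oil group the
    oil mean is imputed via :func:`impute_oil_month6` and the contrast
    variance multiplier accounts for the halved weights on the two
    donor oil groups; the imputed group adds nothing to the residual
    pool.
    """
    design = design.loc[logexpr.columns]
    key = list(zip(design["treatment"], design["month"].astype(int)))
    group_labels = sorted(set(key))
    group_cols = {g: [s for s, k in zip(logexpr.columns, key) if k == g] for g in group_labels}
    for g, cols in group_cols.items():
        if len(cols) < 2:
            raise ValueError(f"group {g} has fewer than 2 replicates")

    means = pd.DataFrame({g: logexpr[cols].mean(axis=1) for g, cols in group_cols.items()})
    n_samples = logexpr.shape[1]
    n_groups = len(group_labels)
    df = n_samples - n_groups
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    rss = pd.Series(0.0, index=logexpr.index)
    for g, cols in group_cols.items():
        resid = logexpr[cols].sub(means[g], axis=0)
        rss += (resid**2).sum(axis=1)
    s2 = rss / df

    oil_months = {m for t, m in group_labels if t == "oil"}
    logfc = {}
    stderr_unit = {}
    for m in months:
        if ("ccl4", m) not in group_cols:
            raise ValueError(f"no ccl4 group at month {m}")
        n_c = len(group_cols[("ccl4", m)])
        if m in oil_months:
            logfc[m] = means[("ccl4", m)] - means[("oil", m)]
            n_o = len(group_cols[("oil", m)])
            stderr_unit[m] = float(np.sqrt(1.0 / n_c + 1.0 / n_o))
        else:
            donors = sorted(oil_months)
            if len(donors) != 2:
                raise ValueError(
                    f"month {m} oil imputation needs exactly 2 donor oil months, have {donors}"
                )
            m_lo, m_hi = donors
            oil_imp = impute_oil_month6(means[("oil", m_lo)], means[("oil", m_hi)])
            logfc[m] = means[("ccl4", m)] - oil_imp
            n_lo = len(group_cols[("oil", m_lo)])
            n_hi = len(group_cols[("oil", m_hi)])
            stderr_unit[m] = float(np.sqrt(1.0 / n_c + 0.25 / n_lo + 0.25 / n_hi))
            logger.info("month %d oil group imputed from months %d and %d", m, m_lo, m_hi)

    return ContrastFit(
        logfc=pd.DataFrame(logfc),
        s2=s2,
        df=df,
        stderr_unit=stderr_unit,
        mean_expr=logexpr.mean(axis=1),
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (trigamma is monotone decreasing)."""
    if x <= 0:
        raise ValueError("trigamma inverse requires a positive argument")
    lo, hi = 1e-8, 1e8
    tri = lambda y: special.polygamma(1, y) - x
    # expand the bracket if needed (trigamma(1e-8) ~ 1e16, trigamma(1e8) ~ 1e-8)
    while tri(lo) < 0:
        lo /= 10.0
    while tri(hi) > 0:
        hi *= 10.0
    return float(optimize.brentq(tri, lo, hi, xtol=1e-12, rtol=1e-14))


def estimate_eb_prior(s_sq: np.ndarray, df: float | np.ndarray) -> EBPrior:
    """Fit (d0, s0^2) by moment matching on log variances.

    Under the hierarchical model s^2 | sigma^2 ~ sigma^2 chi^2_df / df,
    sigma^-2 ~ chi^2_d0 / (d0 s0^2), the statistic
    e = log s^2 - digamma(df/2) + log(df/2) has
    E[e] = log s0^2 + digamma(d0/2) - log(d0/2) and
    Var[e] = trigamma(df/2) + trigamma(d0/2); matching the empirical
    mean and variance of e gives d0 via the trigamma inverse. When the
    empirical variance does not exceed the sampling term the dispersion
    of true variances is indistinguishable from zero and d0 = inf.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s_sq.shape)
    ok = np.isfinite(s_sq) & (s_sq > 0) & (df >= 1)
    if ok.sum() < 10:
        raise ValueError("need at least 10 genes with positive variance and df >= 1")
    s_sq, df = s_sq[ok], df[ok]
    e = np.log(s_sq) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    sampling = float(np.mean(special.polygamma(1, df / 2.0)))
    excess = e_var - sampling
    if e_var < 1e-15:
        # degenerate: observed variances literally identical
        return EBPrior(d0=np.inf, s0_sq=float(np.exp(np.mean(np.log(s_sq)))))
    if excess <= 0:
        return EBPrior(d0=np.inf, s0_sq=float(np.exp(e_mean)))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return EBPrior(d0=d0, s0_sq=s0_sq)


def moderated_t(
    logfc: np.ndarray,
    s_sq: np.ndarray,
    df: float,
    prior: EBPrior,
    stderr_unit: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t and two-sided p for one contrast.

    Posterior variance s~^2 = (d0 s0^2 + df s^2) / (d0 + df);
    t = logFC / (stderr_unit * s~); p from t with d0 + df degrees of
    freedom (standard normal in the d0 = inf limit). d0 = 0 recovers
    the ordinary t-statistic.
    """
    logfc = np.asarray(logfc, dtype=float)
    s_sq = np.asarray(s_sq, dtype=float)
    if np.isinf(prior.d0):
        s2_post = np.full_like(s_sq, prior.s0_sq)
        with np.errstate(divide="ignore"):
            t = logfc / (stderr_unit * np.sqrt(s2_post))
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        s2_post = (prior.d0 * prior.s0_sq + df * s_sq) / (prior.d0 + df)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = logfc / (stderr_unit * np.sqrt(s2_post))
        t = np.where(np.isnan(t), 0.0, t)
        p = 2.0 * stats.t.sf(np.abs(t), prior.d0 + df)
    return t, p


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def select_de(rows: pd.DataFrame, lfc_min: float = 1.5, fdr_max: float = 0.05
              ) -> tuple[set[str], set[str]]:
    """DE gene sets: up = logFC >= lfc_min & q <= fdr_max; down mirrored.

    Boundaries are inclusive.
    """
    sig = rows["q"] <= fdr_max
    up = set(rows.index[sig & (rows["logFC"] >= lfc_min)])
    down = set(rows.index[sig & (rows["logFC"] <= -lfc_min)])
    return up, down


def overlap_union(
    rows_by_month: dict[int, pd.DataFrame],
    zonation_set,
    lfc_min: float = 0.8,
    fdr_max: float = 0.2,
):
    """Union over months of (relaxed DE genes ∩ zonation set).

    Relaxed DE means abs(logFC) >= lfc_min and q <= fdr_max in either
    direction; the per-month intersections with the zonation set are
    unioned across months. Returns a :class:`~zonepipe.zonation.GeneSet`
    carrying the input set's direction tag.
    """
    from .zonation import GeneSet

    members = (
        zonation_set.members if isinstance(zonation_set, GeneSet) else frozenset(zonation_set)
    )
    universes = [frozenset(r.index) for r in rows_by_month.values()]
    if universes and any(u != universes[0] for u in universes[1:]):
        raise ValueError("months have different gene universes")
    out: set[str] = set()
    for month, rows in rows_by_month.items():
        up, down = select_de(rows, lfc_min=lfc_min, fdr_max=fdr_max)
        out |= (up | down) & members
    name = getattr(zonation_set, "name", "set") + "_overlap"
    direction = getattr(zonation_set, "direction", "untagged")
    return GeneSet(name=name, members=frozenset(out), direction=direction)


def run_diffexp(
    experiment: BulkExperiment,
    months: tuple[int, ...] = (2, 6, 12),
) -> tuple[dict[int, pd.DataFrame], EBPrior]:
    """Full bulk DE: normalise, fit, moderate, adjust.

    Returns per-month contrast tables (columns logFC, t, p, q,
    mean_expr, indexed by gene) and the fitted variance prior.
    """
    logexpr = normalize_bulk(experiment)
    fit = fit_contrasts(logexpr, experiment.design, months=months)
    prior = estimate_eb_prior(fit.s2.to_numpy(), fit.df)
    tables = {}
    for m in months:
        t, p = moderated_t(
            fit.logfc[m].to_numpy(), fit.s2.to_numpy(), fit.df, prior, fit.stderr_unit[m]
        )
        tables[m] = pd.DataFrame(
            {
                "logFC": fit.logfc[m],
                "t": t,
                "p": p,
                "q": bh_fdr(p),
                "mean_expr": fit.mean_expr,
            }
        )
    return tables, prior
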