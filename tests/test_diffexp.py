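"""TMM, imputation, contrast fits, EB moderation, FDR, DE selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from zonepipe import (
    BulkExperiment,
    EBPrior,
    SimConfig,
    bh_fdr,
    estimate_eb_prior,
    fit_contrasts,
    impute_oil_month6,
    moderated_t,
    normalize_bulk,
    overlap_union,
    run_diffexp,
    select_de,
    simulate_bulk_timecourse,
    tmm_factors,
)
from zonepipe.zonation import GeneSet


# ---------------------------------------------------------------------------
# TMM normalisation
# ---------------------------------------------------------------------------

def test_identical_samples_give_unit_factors():
    col = np.array([100, 50, 10, 200, 5])
    counts = np.tile(col[:, None], (1, 4))
    assert np.allclose(tmm_factors(counts), 1.0)


def test_depth_scaling_invariance():
    """Multiplying one sample's counts by 4 leaves its log2-CPM exactly
    unchanged at fixed scale factors (pseudocount on the CPM scale), and
    nearly unchanged through the full TMM fit, whose inverse-variance
    precision weights depend mildly on absolute depth."""
    rng = np.random.default_rng(2)
    base = rng.negative_binomial(5, 0.05, size=(500, 4)) + 1
    scaled = base.copy()
    scaled[:, 2] *= 4
    # exact invariance of the transform itself
    lib_a, lib_b = base.sum(axis=0), scaled.sum(axis=0)
    cpm_a = np.log2(base / lib_a[None, :] * 1e6 + 0.5)
    cpm_b = np.log2(scaled / lib_b[None, :] * 1e6 + 0.5)
    assert np.allclose(cpm_a[:, 2], cpm_b[:, 2], atol=1e-12)
    # near-invariance end to end
    design = pd.DataFrame(
        {"treatment": ["oil"] * 4, "month": [2] * 4, "replicate": range(1, 5)},
        index=[f"s{j}" for j in range(4)],
    )
    exp_a = BulkExperiment(base, design, [f"g{i}" for i in range(500)], list(design.index))
    exp_b = BulkExperiment(scaled, design, [f"g{i}" for i in range(500)], list(design.index))
    a = normalize_bulk(exp_a)
    b = normalize_bulk(exp_b)
    assert np.allclose(a["s2"], b["s2"], atol=0.05)


def test_tmm_factor_matches_stepwise_oracle():
    """Independent plain-python evaluation of the doubly trimmed weighted
    mean of M-values against the reference sample."""
    rng = np.random.default_rng(2)
    counts = rng.negative_binomial(5, 0.02, size=(300, 5)).astype(float) + 1
    factors = tmm_factors(counts)

    lib = counts.sum(axis=0)
    uq = [np.quantile(counts[:, j] / lib[j], 0.75) for j in range(5)]
    ref = int(np.argmin(np.abs(np.array(uq) - np.mean(uq))))
    j = 0 if ref != 0 else 1
    obs, refc = counts[:, j], counts[:, ref]
    m = np.log2((obs / lib[j]) / (refc / lib[ref]))
    a = 0.5 * np.log2((obs / lib[j]) * (refc / lib[ref]))
    w = (lib[j] - obs) / (lib[j] * obs) + (lib[ref] - refc) / (lib[ref] * refc)
    n = len(m)
    lo_m, hi_m = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
    lo_a, hi_a = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
    rm, ra = stats.rankdata(m), stats.rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    f_j = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    # compare ratios (the geometric-mean-1 rescale cancels); reference has f=1
    assert factors[j] / factors[ref] == pytest.approx(f_j, rel=1e-10)


def test_zero_total_sample_rejected():
    with pytest.raises(ValueError):
        tmm_factors(np.array([[1, 0], [2, 0]]))


# ---------------------------------------------------------------------------
# imputation and contrast fit
# ---------------------------------------------------------------------------

def test_impute_oil_month6_is_elementwise_mean():
    idx = pd.Index([f"g{i}" for i in range(100)])
    rng = np.random.default_rng(0)
    a = pd.Series(rng.normal(size=100), index=idx)
    b = pd.Series(rng.normal(size=100), index=idx)
    out = impute_oil_month6(a, b)
    assert np.allclose(out, (a.to_numpy() + b.to_numpy()) / 2)
    assert impute_oil_month6(pd.Series([2.0]), pd.Series([4.0])).iloc[0] == 3.0
    x = pd.Series([1.7, -2.0])
    assert impute_oil_month6(x, x).equals(x.rename("oil_m6_imputed"))
    with pytest.raises(ValueError):
        impute_oil_month6(pd.Series([1.0], index=["a"]), pd.Series([1.0], index=["b"]))


def _logexpr(toy_design, values_by_group, n_genes=1):
    data = {}
    for s in toy_design.index:
        g = (toy_design.loc[s, "treatment"], int(toy_design.loc[s, "month"]))
        r = int(toy_design.loc[s, "replicate"])
        data[s] = [values_by_group[g][r - 1] for _ in range(n_genes)]
    return pd.DataFrame(data, index=[f"g{i}" for i in range(n_genes)])


def test_constant_groups_give_exact_logfc_and_zero_variance(toy_design):
    vals = {("untreated", 0): [0, 0, 0], ("oil", 2): [1, 1, 1], ("oil", 12): [1, 1, 1],
            ("ccl4", 2): [3, 3, 3], ("ccl4", 6): [5, 5, 5], ("ccl4", 12): [2, 2, 2]}
    fit = fit_contrasts(_logexpr(toy_design, vals), toy_design)
    assert fit.logfc.loc["g0", 2] == 2.0
    assert fit.logfc.loc["g0", 6] == 4.0  # 5 - mean(1, 1)
    assert fit.logfc.loc["g0", 12] == 1.0
    assert fit.s2["g0"] == 0.0
    assert fit.df == 18 - 6  # imputed month-6 oil group contributes no df


def test_location_invariance_of_logfc(toy_design):
    rng = np.random.default_rng(8)
    groups = [("untreated", 0), ("oil", 2), ("oil", 12), ("ccl4", 2), ("ccl4", 6), ("ccl4", 12)]
    vals = {g: list(rng.normal(size=3)) for g in groups}
    shifted = {g: [v + 7.5 for v in vs] for g, vs in vals.items()}
    f0 = fit_contrasts(_logexpr(toy_design, vals), toy_design)
    f1 = fit_contrasts(_logexpr(toy_design, shifted), toy_design)
    assert np.allclose(f0.logfc, f1.logfc)
    assert np.allclose(f0.s2, f1.s2)


def test_fit_matches_group_mean_arithmetic(toy_design):
    rng = np.random.default_rng(9)
    logexpr = pd.DataFrame(rng.normal(size=(20, 18)), columns=toy_design.index,
                           index=[f"g{i}" for i in range(20)])
    fit = fit_contrasts(logexpr, toy_design)
    key = list(zip(toy_design["treatment"], toy_design["month"]))
    for gi in range(20):
        y = logexpr.iloc[gi]
        means = {}
        rss = 0.0
        for g in set(key):
            cols = [s for s, k in zip(toy_design.index, key) if k == g]
            means[g] = y[cols].mean()
            rss += ((y[cols] - means[g]) ** 2).sum()
        assert fit.logfc.iloc[gi][2] == pytest.approx(means[("ccl4", 2)] - means[("oil", 2)])
        oil6 = (means[("oil", 2)] + means[("oil", 12)]) / 2
        assert fit.logfc.iloc[gi][6] == pytest.approx(means[("ccl4", 6)] - oil6)
        assert fit.s2.iloc[gi] == pytest.approx(rss / 12)
    # contrast variance multipliers: 1/3+1/3 for matched, 1/3+2*(1/4)/3 for imputed
    assert fit.stderr_unit[2] == pytest.approx(np.sqrt(2 / 3))
    assert fit.stderr_unit[6] == pytest.approx(np.sqrt(1 / 3 + 0.5 / 3))


# ---------------------------------------------------------------------------
# empirical-Bayes prior and moderated t
# ---------------------------------------------------------------------------

def test_equal_variances_give_infinite_prior_df():
    prior = estimate_eb_prior(np.full(50, 2.5), df=4)
    assert np.isinf(prior.d0)
    assert prior.s0_sq == pytest.approx(2.5)


def test_eb_prior_recovery_from_scaled_inv_chisq():
    """Variances drawn with true d0 = 4, s0^2 = 1: the moment estimator
    recovers d0 in [2.5, 6] and s0^2 in [0.8, 1.25]."""
    rng = np.random.default_rng(9)
    d0, s0_sq, df = 4.0, 1.0, 10
    sigma2 = d0 * s0_sq / rng.chisquare(d0, size=5000)
    s2 = sigma2 * rng.chisquare(df, size=5000) / df
    prior = estimate_eb_prior(s2, df)
    assert 2.5 <= prior.d0 <= 6.0
    assert 0.8 <= prior.s0_sq <= 1.25


def test_eb_prior_matches_independent_moment_solution():
    """10-gene fixture: the (d0, s0^2) estimate solves the two moment
    equations, checked by an independent fsolve on the raw system."""
    rng = np.random.default_rng(42)
    s2 = rng.lognormal(0, 0.9, size=10)
    df = 6
    prior = estimate_eb_prior(s2, df)
    e = np.log(s2) - special.digamma(df / 2) + np.log(df / 2)

    def system(params):
        # model moments: Var[e] = trigamma(df/2) + trigamma(d0/2);
        # E[e] = E[log sigma^2] = log s0^2 + log(d0/2) - digamma(d0/2)
        d0, log_s0 = params
        return [
            (special.polygamma(1, d0 / 2) + special.polygamma(1, df / 2)) - np.var(e, ddof=1),
            (log_s0 + np.log(d0 / 2) - special.digamma(d0 / 2)) - e.mean(),
        ]

    d0_ref, log_s0_ref = optimize.fsolve(system, x0=[4.0, 0.0], xtol=1e-12)
    assert prior.d0 == pytest.approx(d0_ref, rel=1e-6)
    assert prior.s0_sq == pytest.approx(np.exp(log_s0_ref), rel=1e-6)


def test_moderated_t_reduces_to_ordinary_t_at_d0_zero():
    rng = np.random.default_rng(1)
    logfc = rng.normal(size=10)
    s2 = rng.lognormal(0, 0.5, size=10)
    df, unit = 8, np.sqrt(1 / 3)
    t_mod, p_mod = moderated_t(logfc, s2, df, EBPrior(d0=0.0, s0_sq=1.0), unit)
    t_ord = logfc / (unit * np.sqrt(s2))
    assert np.allclose(t_mod, t_ord)
    assert np.allclose(p_mod, 2 * stats.t.sf(np.abs(t_ord), df))


def test_moderated_t_equals_ordinary_t_under_homogeneous_variance():
    logfc = np.array([1.0, -2.0, 0.5])
    s0 = 0.7
    s2 = np.full(3, s0)
    t_mod, _ = moderated_t(logfc, s2, 8, EBPrior(d0=4.0, s0_sq=s0), 0.5)
    assert np.allclose(t_mod, logfc / (0.5 * np.sqrt(s0)))


def test_moderated_t_matches_posterior_variance_formula():
    rng = np.random.default_rng(3)
    logfc = rng.normal(size=10)
    s2 = rng.lognormal(0, 0.5, size=10)
    d0, s0_sq, df, unit = 4.0, 1.0, 6, 0.6
    t, p = moderated_t(logfc, s2, df, EBPrior(d0, s0_sq), unit)
    s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    assert np.allclose(t, logfc / (unit * np.sqrt(s2_post)))
    assert np.allclose(p, 2 * stats.t.sf(np.abs(t), d0 + df))


# ---------------------------------------------------------------------------
# FDR and DE selection
# ---------------------------------------------------------------------------

def test_bh_examples():
    assert bh_fdr([0.03])[0] == pytest.approx(0.03)
    assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)
    assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)


def test_bh_order_invariance_and_bounds():
    rng = np.random.default_rng(7)
    p = rng.uniform(size=40)
    perm = rng.permutation(40)
    q = bh_fdr(p)
    assert np.allclose(q[perm], bh_fdr(p[perm]))
    assert (q <= 1).all() and (q >= p - 1e-15).all()
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])


def test_select_de_boundaries_inclusive():
    rows = pd.DataFrame(
        {"logFC": [1.5, -1.5, 1.49, 0.0, 3.0], "q": [0.05, 0.05, 0.01, 1.0, 0.051]},
        index=["up_edge", "down_edge", "below_lfc", "null", "above_fdr"],
    )
    up, down = select_de(rows)
    assert up == {"up_edge"} and down == {"down_edge"}


def test_select_de_matches_manual_filter():
    rng = np.random.default_rng(12)
    rows = pd.DataFrame({"logFC": rng.normal(0, 2, 20), "q": rng.uniform(size=20)},
                        index=[f"g{i}" for i in range(20)])
    up, down = select_de(rows, lfc_min=1.0, fdr_max=0.3)
    for g in rows.index:
        lfc, q = rows.loc[g, "logFC"], rows.loc[g, "q"]
        assert (g in up) == (lfc >= 1.0 and q <= 0.3)
        assert (g in down) == (lfc <= -1.0 and q <= 0.3)


def test_overlap_union_set_algebra():
    def rows(de_genes, universe):
        return pd.DataFrame(
            {"logFC": [2.0 if g in de_genes else 0.0 for g in universe],
             "q": [0.01 if g in de_genes else 0.9 for g in universe]},
            index=universe,
        )

    universe = [f"g{i}" for i in range(8)]
    by_month = {2: rows({"g0", "g1"}, universe), 6: rows({"g2"}, universe),
                12: rows({"g3", "g7"}, universe)}
    zset = GeneSet("pc", frozenset({"g1", "g2", "g5"}), "pericentral")
    out = overlap_union(by_month, zset)
    manual = ({"g0", "g1"} & zset.members) | ({"g2"} & zset.members) | ({"g3", "g7"} & zset.members)
    assert out.members == frozenset(manual) == frozenset({"g1", "g2"})
    assert out.direction == "pericentral"
    empty = overlap_union({2: rows(set(), universe)}, zset)
    assert empty.members == frozenset()


# ---------------------------------------------------------------------------
# end-to-end recovery on synthetic bulk
# ---------------------------------------------------------------------------

def test_logfc_unbiased_with_delta_method_coverage(small_bulk):
    """Planted logFC recovered without bias; scatter consistent with the
    delta-method sd sqrt(2 (phi + 1/mu) / n) / ln 2 of an NB group-mean
    log-ratio (checked as ~90% coverage at 1.96 predicted sd)."""
    cfg, bulk, truth = small_bulk
    tables, _ = run_diffexp(bulk)
    sd_pred = np.sqrt(2 * (cfg.nb_dispersion + 1 / 50.0) / cfg.n_replicates) / np.log(2)
    for m in (2, 12):
        planted = truth.bulk_logfc.index[truth.bulk_logfc[m] != 0]
        err = tables[m].loc[planted, "logFC"] - truth.bulk_logfc.loc[planted, m]
        assert abs(err.mean()) < 3 * err.std(ddof=1) / np.sqrt(len(err)) + 0.05
        assert (err.abs() <= 1.96 * sd_pred).mean() >= 0.85


def test_empirical_fdr_controlled_on_planted_bulk():
    cfg = SimConfig(n_genes=2000, frac_pericentral=0.1, frac_periportal=0.1, seed=21)
    bulk, truth = simulate_bulk_timecourse(cfg)
    tables, _ = run_diffexp(bulk)
    for m in (2, 6, 12):
        sig = tables[m].index[tables[m]["q"] <= 0.05]
        assert len(sig) >= 20
        false = [g for g in sig if truth.bulk_logfc.loc[g, m] == 0]
        assert len(false) / len(sig) <= 0.10


def test_null_bulk_false_positive_rate():
    """With zero planted effects, <= 10% of >= 1000 genes reach q <= 0.05."""
    cfg = SimConfig(n_genes=1200, frac_pericentral=0.0, frac_periportal=0.0, seed=31)
    bulk, _ = simulate_bulk_timecourse(cfg)
    tables, _ = run_diffexp(bulk)
    for m in (2, 6, 12):
        assert (tables[m]["q"] <= 0.05).mean() <= 0.10
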