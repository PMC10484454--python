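import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sstats

from wormscore import (AssayDataset, anova_dunnett, anova_tukey, bh_adjust,
                       bleb_defect_tests, brood_size, ctcf, percent_lethality,
                       two_group_t, viability_summary)
from wormscore.stats import dunnett_from_groups


def _dataset(assay, col, groups):
    rows = []
    for g, vals in groups.items():
        for i, v in enumerate(vals):
            rows.append({"genotype": g, "animal_id": f"{g}{i}", col: v})
    df = pd.DataFrame(rows)
    if assay == "viability":
        df["unhatched"] = 0
    if assay == "migration":
        df["nuclei_total"] = 16
    return AssayDataset(assay, df)


# ------------------------------------------------------------- summaries

def test_brood_size_sums_daily_counts():
    assert brood_size([0, 0, 0]) == 0
    assert brood_size([50, 40, 10]) == 100
    with pytest.raises(ValueError):
        brood_size([10, -1])
    with pytest.raises(ValueError):
        brood_size([1, 2, 3, 4])


def test_percent_lethality_arithmetic_and_sterile_marker():
    assert percent_lethality(0, 100) == 0.0
    assert percent_lethality(100, 100) == 100.0
    assert percent_lethality(5, 50) == 10.0
    assert np.isnan(percent_lethality(0, 0))  # sterile: missing, never 0
    with pytest.raises(ValueError):
        percent_lethality(5, 4)


def test_viability_summary_excludes_sterile_from_lethality():
    df = pd.DataFrame({
        "genotype": ["v"] * 3, "animal_id": list("abc"),
        "brood_size": [0, 100, 50], "unhatched": [0, 10, 10],
    })
    s = viability_summary(AssayDataset("viability", df)).iloc[0]
    assert s["n_sterile"] == 1 and not s["all_sterile"]
    assert s["mean_brood"] == pytest.approx(50.0)
    assert s["mean_lethality_pct"] == pytest.approx((10.0 + 20.0) / 2)
    assert s["viable_offspring"] == 130


def test_ctcf_formula():
    assert ctcf(100, 10, 2) == 80
    assert ctcf(100, 10, 0) == 100
    assert ctcf(50, 10, 5) == 0
    assert ctcf(10, 10, 5) == -40  # negative preserved
    with pytest.raises(ValueError):
        ctcf(10, 0, 1)


# ------------------------------------------------------------- BH step-up

def _bh_bruteforce(p):
    """Independent O(m^2) step-up oracle: adj_(i) = min_{j>=i} m p_(j)/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        cands = [m * p[order[j - 1]] / j for j in range(rank_i, m + 1)]
        adj[idx] = min(min(cands), 1.0)
    return adj


def test_bh_examples():
    adj, rej = bh_adjust([0.04])
    assert adj[0] == pytest.approx(0.04) and rej[0]
    adj, rej = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(adj, 0.04) and rej.all()
    with pytest.raises(ValueError):
        bh_adjust([])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


def test_bh_matches_bruteforce_exactly_on_random_vectors():
    rng = np.random.default_rng(0)
    for _ in range(300):
        m = rng.integers(1, 25)
        p = rng.random(m)
        adj, _ = bh_adjust(p)
        assert np.array_equal(adj, _bh_bruteforce(p))


def test_bh_agrees_with_statsmodels():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(1)
    for _ in range(50):
        p = rng.random(rng.integers(1, 30))
        adj, rej = bh_adjust(p)
        _, sm_adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.allclose(adj, sm_adj, atol=1e-12)


@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
def test_bh_adjusted_monotone_and_never_below_raw(p):
    adj, _ = bh_adjust(p)
    assert (adj >= np.asarray(p) - 1e-15).all()
    order = np.argsort(p, kind="stable")
    assert (np.diff(adj[order]) >= -1e-15).all()


# ------------------------------------------------------- Dunnett / Tukey

def test_dunnett_single_comparison_equals_pooled_t():
    rng = np.random.default_rng(2)
    worst = 0.0
    for _ in range(50):
        a, b = rng.normal(0, 1, 15), rng.normal(0.4, 1, 12)
        ds = _dataset("swimming", "bbps", {"wt": np.abs(a), "v": np.abs(b)})
        res = anova_dunnett(ds, "bbps", "wt")[0]
        t = sstats.ttest_ind(ds.values("v", "bbps"), ds.values("wt", "bbps"),
                             equal_var=True)
        worst = max(worst, abs(res.p_adjusted - t.pvalue))
    assert worst < 1e-6


def test_tukey_single_pair_equals_pooled_t():
    rng = np.random.default_rng(3)
    worst = 0.0
    for _ in range(50):
        a, b = np.abs(rng.normal(1, 0.3, 14)), np.abs(rng.normal(1.3, 0.3, 14))
        ds = _dataset("swimming", "bbps", {"g1": a, "g2": b})
        res = anova_tukey(ds, "bbps")[0]
        t = sstats.ttest_ind(ds.values("g1", "bbps"), ds.values("g2", "bbps"),
                             equal_var=True)
        worst = max(worst, abs(res.p_adjusted - t.pvalue))
    assert worst < 1e-6


def test_dunnett_quadrature_agrees_with_monte_carlo_oracle():
    """Dunnett adjusted p via multivariate-t integration vs a 1e5-replicate
    Monte-Carlo of the null max-|t| distribution, within 0.005."""
    rng = np.random.default_rng(4)
    ns = [12, 10, 10, 10]  # control + 3 groups
    data = [rng.normal(0, 1, n) for n in ns]
    data[1] += 0.8
    ds = _dataset("fluorescence", "intensity",
                  {"wt": data[0], "a": data[1], "b": data[2], "c": data[3]})
    res = anova_dunnett(ds, "intensity", "wt")

    # MC oracle: null distribution of max_j |t_j| with pooled variance
    reps = 100_000
    rng2 = np.random.default_rng(5)
    draws = [rng2.normal(0, 1, (reps, n)) for n in ns]
    means = [d.mean(axis=1) for d in draws]
    ss = sum(((d - m[:, None]) ** 2).sum(axis=1) for d, m in zip(draws, means))
    s2 = ss / (sum(ns) - len(ns))
    tmax = np.max([np.abs(means[j] - means[0])
                   / np.sqrt(s2 * (1 / ns[j] + 1 / ns[0]))
                   for j in range(1, len(ns))], axis=0)
    for r in res:
        p_mc = float(np.mean(tmax >= abs(r.statistic)))
        assert abs(r.p_adjusted - p_mc) < 0.005


def test_dunnett_null_and_power_behaviour():
    # identically drawn groups: never significant, and typically far from it
    ps = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        ds = _dataset("fluorescence", "intensity",
                      {"wt": rng.normal(0, 1, 1000), "v": rng.normal(0, 1, 1000)})
        ps.append(anova_dunnett(ds, "intensity", "wt")[0].p_adjusted)
    assert np.median(ps) > 0.2

    hits = 0
    for seed in range(100):
        r = np.random.default_rng(seed)
        ds = _dataset("fluorescence", "intensity",
                      {"wt": r.normal(0, 1, 20), "v": r.normal(3, 1, 20)})
        hits += anova_dunnett(ds, "intensity", "wt")[0].p_adjusted <= 0.001
    assert hits >= 99


def test_dunnett_familywise_error_near_nominal():
    """Family-wise type-I error over 11 many-to-one null comparisons stays
    near the 5% Dunnett guarantee (Monte Carlo)."""
    reps, fwer = 400, 0
    for seed in range(reps):
        rng = np.random.default_rng(1000 + seed)
        groups = {f"v{j}": rng.normal(0, 1, 10) for j in range(11)}
        groups["wt"] = rng.normal(0, 1, 22)
        res = dunnett_from_groups(groups, "wt")
        fwer += any(r.p_adjusted <= 0.05 for r in res)
    assert 0.025 <= fwer / reps <= 0.08


def test_tukey_null_and_outlier_group():
    rng = np.random.default_rng(7)
    base = {f"g{j}": rng.normal(5, 1, 30) for j in range(4)}
    ds = _dataset("fluorescence", "intensity", base)
    assert all(r.p_adjusted > 0.05 for r in anova_tukey(ds, "intensity"))

    base["out"] = rng.normal(9, 1, 30)
    ds = _dataset("fluorescence", "intensity", base)
    for r in anova_tukey(ds, "intensity"):
        involves_out = "out" in r.comparison
        assert r.significant == involves_out


def test_corrections_never_reduce_p(panel_datasets):
    res = anova_dunnett(panel_datasets["viability"], "brood_size", "wild_type")
    res += anova_tukey(panel_datasets["migration"], "mislocalized")
    for r in res:
        assert r.p_adjusted >= r.p_raw - 1e-12
        assert r.significant == (r.p_adjusted <= r.alpha)


def test_summaries_invariant_to_record_order_and_relabeling(panel_datasets):
    ds = panel_datasets["viability"]
    shuffled = AssayDataset(
        "viability", ds.records.sample(frac=1, random_state=0))
    a = anova_dunnett(ds, "brood_size", "wild_type")
    b = anova_dunnett(shuffled, "brood_size", "wild_type")
    pa = {r.comparison: r.p_adjusted for r in a}
    pb = {r.comparison: r.p_adjusted for r in b}
    assert pa == pb

    # relabeling can reorder the groups seen by the multivariate-t
    # integration, so agreement is to numerical-integration accuracy
    renamed = ds.records.replace({"genotype": {"Y59C": "XYZ"}})
    c = anova_dunnett(AssayDataset("viability", renamed), "brood_size",
                      "wild_type")
    pc = {r.comparison: r.p_adjusted for r in c}
    assert pc["XYZ vs wild_type"] == pytest.approx(
        pa["Y59C vs wild_type"], abs=1e-3)


# ------------------------------------------------------------ t test

def test_t_test_identical_samples_degenerate():
    ds = _dataset("fluorescence", "intensity", {"a": [5.0] * 5, "b": [5.0] * 5})
    r = two_group_t(ds, "intensity", "a", "b")
    assert r.statistic == 0.0 and r.p_raw == 1.0


def test_t_test_type_one_error_calibrated():
    rng = np.random.default_rng(8)
    a = rng.normal(0, 1, (5000, 50))
    b = rng.normal(0, 1, (5000, 50))
    p = sstats.ttest_ind(a, b, axis=1, equal_var=True).pvalue
    # the pipeline's t test is exactly this scipy call; check calibration
    assert 0.04 <= np.mean(p <= 0.05) <= 0.06


def test_t_test_power_matches_noncentral_t_within_two_points():
    """Simulated power of the two-sample t (n=12 vs 10, 2 SD shift) matches
    the closed-form noncentral-t value."""
    n1, n2, delta = 12, 10, 2.0
    df = n1 + n2 - 2
    ncp = delta / np.sqrt(1 / n1 + 1 / n2)
    tcrit = sstats.t.ppf(0.975, df)
    power_exact = (1 - sstats.nct.cdf(tcrit, df, ncp)
                   + sstats.nct.cdf(-tcrit, df, ncp))
    rng = np.random.default_rng(9)
    a = rng.normal(delta, 1, (20_000, n1))
    b = rng.normal(0, 1, (20_000, n2))
    p = sstats.ttest_ind(a, b, axis=1, equal_var=True).pvalue
    assert abs(np.mean(p <= 0.05) - power_exact) < 0.02


# ------------------------------------------------------------ bleb tests

def test_bleb_control_vs_itself_not_significant():
    rng = np.random.default_rng(10)
    ds = _dataset("morphology", "blebs",
                  {"wt": rng.poisson(0.4, 20), "twin": rng.poisson(0.4, 20)})
    res = bleb_defect_tests(ds, "wt")
    assert not res[0].significant


def test_bleb_strong_effect_detected_after_bh():
    hits = 0
    for seed in range(200):
        rng = np.random.default_rng(seed)
        ds = _dataset("morphology", "blebs",
                      {"wt": rng.poisson(0.1, 20), "v": rng.poisson(3.0, 20)})
        hits += bleb_defect_tests(ds, "wt")[0].significant
    assert hits >= 198


def test_bleb_null_false_discovery_proportion_controlled():
    """12 null comparisons through BH: average false-discovery proportion
    stays at or below the 5% target."""
    fdps = []
    for seed in range(500):
        rng = np.random.default_rng(20_000 + seed)
        groups = {f"v{j}": rng.poisson(1.0, 20) for j in range(12)}
        groups["wt"] = rng.poisson(1.0, 20)
        res = bleb_defect_tests(_dataset("morphology", "blebs", groups), "wt")
        n_rej = sum(r.significant for r in res)
        fdps.append(1.0 if n_rej > 0 else 0.0)  # all rejections are false
    assert np.mean(fdps) <= 0.05 + 0.02
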