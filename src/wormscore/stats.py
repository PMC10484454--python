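"""Per-assay summaries and multiple-comparison statistics.

Covers the comparisons used across the assays: one-way ANOVA with Dunnett's
many-to-one correction (viability), Tukey's all-pairs correction (nuclear
migration), a 2x2 chi-squared test (swimming defect fractions; in
``motility``), Student's t (fluorescence), rank tests with
Benjamini-Hochberg adjustment (bleb counts), and the corrected total
nuclear fluorescence arithmetic.

The Benjamini-Hochberg step-up is implemented here directly (reverse
cumulative minimum of ``m * p_(j) / j``), so adjusted values match the
textbook definition to the last float.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .dataset import AssayDataset

__all__ = [
    "StatResult", "brood_size", "percent_lethality", "viability_summary",
    "anova_dunnett", "dunnett_from_groups", "anova_tukey", "bh_adjust",
    "ctcf", "two_group_t",
    "bleb_defect_tests", "group_summary",
]

#: base significance level for all "significant" calls
ALPHA = 0.05

#: internal rng seed for the multivariate-t integration in Dunnett p-values
#: (fixed so results are deterministic across runs)
_DUNNETT_RNG = 987654321


@dataclass
class StatResult:
    """One comparison's outcome.

    ``significant`` is always ``p_adjusted <= alpha``; corrections never
    reduce a p-value, so ``p_adjusted >= p_raw``.
    """

    comparison: str
    statistic: float
    p_raw: float
    p_adjusted: float
    method: str
    alpha: float = ALPHA
    note: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in (self.p_raw, self.p_adjusted):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p-value out of [0, 1]: {p}")
        if self.p_adjusted < self.p_raw - 1e-12:
            raise ValueError("adjusted p-value below raw p-value")

    @property
    def significant(self) -> bool:
        return self.p_adjusted <= self.alpha

    def to_row(self) -> dict:
        return {
            "comparison": self.comparison, "statistic": self.statistic,
            "p_raw": self.p_raw, "p_adjusted": self.p_adjusted,
            "method": self.method, "significant": self.significant,
            "note": self.note,
        }


# ---------------------------------------------------------------- summaries

def brood_size(per_day_egg_counts) -> int:
    """Total eggs over the (up to three) daily plate counts."""
    counts = list(per_day_egg_counts)
    if not 1 <= len(counts) <= 3:
        raise ValueError("expected 1-3 daily egg counts")
    if any(c < 0 for c in counts):
        raise ValueError("daily egg counts must be nonnegative")
    return int(sum(counts))


def percent_lethality(unhatched: int, total: int) -> float:
    """Percent of laid eggs that failed to hatch; NaN for a sterile mother.

    A mother that laid no eggs has no defined lethality — the value is
    missing (NaN), never coerced to 0.
    """
    if unhatched < 0 or total < 0 or unhatched > total:
        raise ValueError("need 0 <= unhatched <= total")
    if total == 0:
        return float("nan")
    return 100.0 * unhatched / total


def viability_summary(dataset: AssayDataset) -> pd.DataFrame:
    """Per-genotype brood/lethality summary used by the scoring rubric.

    Sterile mothers (brood 0) are kept in the brood-size mean but excluded
    from the lethality mean, which is undefined for them.
    """
    if dataset.assay != "viability":
        raise ValueError("viability_summary needs a viability dataset")
    rows = []
    for g in dataset.genotypes:
        grp = dataset.group(g)
        brood = grp["brood_size"].to_numpy(dtype=float)
        unhatched = grp["unhatched"].to_numpy(dtype=float)
        leth = np.array([percent_lethality(int(u), int(b))
                         for u, b in zip(unhatched, brood)])
        laid = brood.sum()
        rows.append({
            "genotype": g,
            "n_mothers": len(grp),
            "mean_brood": float(brood.mean()),
            "n_sterile": int((brood == 0).sum()),
            "all_sterile": bool((brood == 0).all()),
            "mean_lethality_pct": float(np.nanmean(leth)) if laid > 0 else float("nan"),
            "viable_offspring": int(laid - unhatched.sum()),
        })
    return pd.DataFrame(rows)


def group_summary(dataset: AssayDataset, value_column: str) -> pd.DataFrame:
    """Per-genotype mean and 95% CI (t-based), as shown in the figures."""
    rows = []
    for g in dataset.genotypes:
        v = dataset.values(g, value_column)
        m = float(v.mean()) if v.size else float("nan")
        if v.size >= 2 and v.std(ddof=1) > 0:
            half = sstats.t.ppf(0.975, v.size - 1) * v.std(ddof=1) / np.sqrt(v.size)
        else:
            half = 0.0
        rows.append({"genotype": g, "n": int(v.size), "mean": m,
                     "ci95_lo": m - half, "ci95_hi": m + half})
    return pd.DataFrame(rows)


# ------------------------------------------------- multiple comparisons

def _group_values(dataset: AssayDataset, value_column: str,
                  min_n: int = 2) -> dict[str, np.ndarray]:
    out = {}
    for g in dataset.genotypes:
        v = dataset.values(g, value_column)
        if v.size >= min_n:
            out[g] = v
    return out


def _pooled_t_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided pooled two-sample t statistic and p (the family-of-one
    limit of both Dunnett and Tukey)."""
    import warnings
    with warnings.catch_warnings():
        # an all-identical group (e.g. a fully sterile strain's broods) is a
        # legitimate input; scipy warns about the within-group moment only
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sstats.ttest_ind(a, b, equal_var=True)
    stat, p = float(res.statistic), float(res.pvalue)
    if np.isnan(stat) or np.isnan(p):
        # zero pooled variance: identical constants are a perfect null,
        # different constants a perfect separation
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    return stat, p


def dunnett_from_groups(groups: dict[str, np.ndarray], control_genotype: str,
                        alpha: float = ALPHA) -> list[StatResult]:
    """Dunnett many-to-one comparisons on pre-extracted value groups."""
    if control_genotype not in groups:
        raise ValueError(
            f"control genotype {control_genotype!r} missing or has <2 records")
    # sorted so the multivariate-t integration sees a record-order-independent
    # group sequence (its QMC estimate depends slightly on ordering)
    others = sorted(g for g in groups if g != control_genotype)
    if not others:
        raise ValueError("need at least one non-control genotype")
    control = groups[control_genotype]
    all_vals = np.concatenate([control] + [groups[g] for g in others])
    if np.ptp(all_vals) == 0:
        return [StatResult(f"{g} vs {control_genotype}", 0.0, 1.0, 1.0,
                           "dunnett", alpha, note="degenerate: zero variance")
                for g in others]

    raws = [_pooled_t_p(groups[g], control) for g in others]
    if len(others) == 1:
        stat, p = raws[0]
        adj = [p]
        stats_ = [stat]
    else:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sstats.dunnett(*[groups[g] for g in others], control=control,
                                 rng=_DUNNETT_RNG)
        adj = [float(np.clip(p, r[1], 1.0))  # family never helps a raw p
               for p, r in zip(res.pvalue, raws)]
        stats_ = [float(s) for s in res.statistic]
    out = []
    for g, (t_raw, p_raw), stat, p_adj in zip(others, raws, stats_, adj):
        mean_diff = float(groups[g].mean() - control.mean())
        out.append(StatResult(
            f"{g} vs {control_genotype}", stat, p_raw, p_adj, "dunnett",
            alpha, extra={"mean_diff": mean_diff}))
    return out


def anova_dunnett(dataset: AssayDataset, value_column: str,
                  control_genotype: str, alpha: float = ALPHA
                  ) -> list[StatResult]:
    """Many-to-one comparisons of every genotype against the control.

    Adjusted p-values come from the Dunnett max-|t| family (multivariate-t
    integration); with a single comparison the family collapses to the
    pooled two-sample t test, which is then computed exactly.
    """
    return dunnett_from_groups(_group_values(dataset, value_column),
                               control_genotype, alpha)


def anova_tukey(dataset: AssayDataset, value_column: str,
                alpha: float = ALPHA) -> list[StatResult]:
    """All-pairs comparisons with Tukey's studentized-range correction."""
    groups = _group_values(dataset, value_column)
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two genotypes with >= 2 records")
    all_vals = np.concatenate([groups[g] for g in names])
    pairs = [(i, j) for i in range(len(names)) for j in range(i + 1, len(names))]
    if np.ptp(all_vals) == 0:
        return [StatResult(f"{names[i]} vs {names[j]}", 0.0, 1.0, 1.0,
                           "tukey", alpha, note="degenerate: zero variance")
                for i, j in pairs]
    res = sstats.tukey_hsd(*[groups[g] for g in names])
    out = []
    for i, j in pairs:
        t_raw, p_raw = _pooled_t_p(groups[names[i]], groups[names[j]])
        p_adj = float(np.clip(res.pvalue[i, j], p_raw, 1.0))
        mean_diff = float(groups[names[i]].mean() - groups[names[j]].mean())
        out.append(StatResult(
            f"{names[i]} vs {names[j]}", float(res.statistic[i, j]),
            p_raw, p_adj, "tukey", alpha, extra={"mean_diff": mean_diff}))
    return out


def bh_adjust(p_values, fdr: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and rejection flags.

    ``adj_(i) = min_{j >= i} m * p_(j) / j`` (capped at 1) on the sorted
    p-values; reject where adjusted <= ``fdr``.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("bh_adjust needs at least one p-value")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj, adj <= fdr


def ctcf(integrated_density: float, area: float, background_mean: float) -> float:
    """Corrected total nuclear fluorescence.

    ``integrated_density - area * background_mean``; negative results are
    preserved (an ROI dimmer than its background is real information).
    """
    if area <= 0:
        raise ValueError("area must be positive")
    for v in (integrated_density, area, background_mean):
        if not np.isfinite(v):
            raise ValueError("ctcf inputs must be finite")
    return float(integrated_density - area * background_mean)


def two_group_t(dataset: AssayDataset, value_column: str, group_a: str,
                group_b: str, alpha: float = ALPHA) -> StatResult:
    """Two-sided Student's t test between two genotypes."""
    a = dataset.values(group_a, value_column)
    b = dataset.values(group_b, value_column)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 records")
    if np.ptp(np.concatenate([a, b])) == 0:
        return StatResult(f"{group_a} vs {group_b}", 0.0, 1.0, 1.0, "t_test",
                          alpha, note="degenerate: zero pooled variance")
    stat, p = _pooled_t_p(a, b)
    return StatResult(f"{group_a} vs {group_b}", stat, p, p, "t_test", alpha)


def bleb_defect_tests(dataset: AssayDataset, control_genotype: str,
                      fdr: float = 0.05) -> list[StatResult]:
    """Per-genotype bleb-count comparison vs control, BH-adjusted.

    The underlying two-group comparison is rank-based (Mann-Whitney U, no
    distributional assumption on the counts); raw p-values across all
    genotypes are adjusted together at the given false discovery rate.
    """
    if dataset.assay != "morphology":
        raise ValueError("bleb_defect_tests needs a morphology dataset")
    groups = _group_values(dataset, "blebs")
    if control_genotype not in groups:
        raise ValueError(f"control genotype {control_genotype!r} missing")
    others = [g for g in groups if g != control_genotype]
    control = groups[control_genotype]
    raws, stats_ = [], []
    for g in others:
        v = groups[g]
        if np.ptp(np.concatenate([v, control])) == 0:
            raws.append(1.0)
            stats_.append(0.0)
            continue
        res = sstats.mannwhitneyu(v, control, alternative="two-sided")
        raws.append(float(res.pvalue))
        stats_.append(float(res.statistic))
    adj, reject = bh_adjust(raws, fdr=fdr)
    return [
        StatResult(f"{g} vs {control_genotype}", s, pr, float(pa), "bh",
                   alpha=fdr,
                   extra={"mean_diff": float(groups[g].mean() - control.mean())})
        for g, s, pr, pa in zip(others, stats_, raws, adj)
    ]
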