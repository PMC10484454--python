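"""Pathogenicity score card for each lamin variant.

The rubric condenses the assays into a per-variant score:

* viability — 2 for homozygous inviable (every mother sterile, or eggs are
  laid but none hatch), 1 for significantly decreased viability (brood size
  reduced or embryonic lethality elevated vs control at Dunnett-adjusted
  p <= alpha), 0 otherwise;
* swimming — 2 when strictly more than 30% of animals swim at or below the
  1.1 BBPS defect threshold, else 0;
* migration — 1 when the mislocalized-nuclei count exceeds control at
  Tukey-adjusted p <= alpha, 0 otherwise, and missing (scored as 0, printed
  N/A) when the assay was not run for that strain.

The total is the sum of available components; a variant classifies
``severe_skeletal_and_cardiac`` when total >= 2 and ``mild_or_cardiac_only``
below that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .dataset import AssayDataset, normalize_genotype
from .motility import BBPS_THRESHOLD, defect_fraction, swim_defect_test
from .profiles import HUMAN_ALIASES
from .stats import (ALPHA, StatResult, anova_dunnett, anova_tukey,
                    dunnett_from_groups, viability_summary)

__all__ = ["VariantScoreCard", "viability_score", "swimming_score",
           "migration_score", "total_score", "score_variants",
           "SWIM_FRACTION_CUTOFF"]

#: strict lower bound on the defective-swimmer fraction for a swimming score of 2
SWIM_FRACTION_CUTOFF = 0.30

SEVERE = "severe_skeletal_and_cardiac"
MILD = "mild_or_cardiac_only"


@dataclass
class VariantScoreCard:
    """One row of the score table."""

    variant: str
    human_label: str | None
    viability_score: int
    swimming_score: int
    migration_score: int | None    # None when the assay was not run
    total: int = 0
    classification: str = MILD
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.viability_score not in (0, 1, 2):
            raise ValueError("viability_score must be 0, 1 or 2")
        if self.swimming_score not in (0, 2):
            raise ValueError("swimming_score must be 0 or 2")
        if self.migration_score not in (0, 1, None):
            raise ValueError("migration_score must be 0, 1 or missing")
        self.total = (self.viability_score + self.swimming_score
                      + (self.migration_score or 0))
        self.classification = SEVERE if self.total >= 2 else MILD

    def to_row(self) -> dict:
        return {
            "human_label": self.human_label or "NA",
            "worm_label": self.variant,
            "viability": self.viability_score,
            "swimming": self.swimming_score,
            "migration": "NA" if self.migration_score is None
                         else self.migration_score,
            "score": self.total,
            "classification": self.classification,
        }


def viability_score(summary_row: dict | pd.Series,
                    brood_result: StatResult | None,
                    lethality_result: StatResult | None = None,
                    alpha: float = ALPHA) -> int:
    """Score the viability component for one variant.

    ``summary_row`` is that variant's row of
    :func:`wormscore.stats.viability_summary`; the StatResults are its
    Dunnett comparisons against the control for mean brood and per-mother
    lethality (the latter may be absent, e.g. for an all-sterile strain).
    """
    if summary_row["all_sterile"] or summary_row["viable_offspring"] == 0:
        return 2
    if brood_result is None:
        raise ValueError("viability_score needs the brood Dunnett comparison")
    worse_brood = (brood_result.p_adjusted <= alpha
                   and brood_result.extra.get("mean_diff", 0.0) < 0)
    worse_leth = (lethality_result is not None
                  and lethality_result.p_adjusted <= alpha
                  and lethality_result.extra.get("mean_diff", 0.0) > 0)
    return 1 if (worse_brood or worse_leth) else 0


def swimming_score(fraction: float,
                   cutoff: float = SWIM_FRACTION_CUTOFF) -> int:
    """2 when the defective fraction strictly exceeds the cutoff, else 0."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    return 2 if fraction > cutoff else 0


def migration_score(tukey_result: StatResult | None,
                    data_available: bool = True,
                    alpha: float = ALPHA) -> int | None:
    """1 for a significant excess of mislocalized nuclei; None when the
    assay was not performed (propagates as N/A, contributing 0)."""
    if not data_available or tukey_result is None:
        return None
    worse = tukey_result.extra.get("mean_diff", 0.0) > 0
    return 1 if (tukey_result.p_adjusted <= alpha and worse) else 0


def total_score(variant: str, viability: int, swimming: int,
                migration: int | None, evidence: dict | None = None
                ) -> VariantScoreCard:
    """Assemble a score card; total and classification are derived."""
    return VariantScoreCard(
        variant=variant, human_label=HUMAN_ALIASES.get(variant),
        viability_score=viability, swimming_score=swimming,
        migration_score=migration, evidence=evidence or {})


def score_variants(datasets: dict[str, AssayDataset], control_genotype: str,
                   alpha: float = ALPHA,
                   bbps_threshold: float = BBPS_THRESHOLD,
                   swim_fraction_cutoff: float = SWIM_FRACTION_CUTOFF,
                   ) -> list[VariantScoreCard]:
    """Score every non-control genotype from the assay datasets.

    Requires ``viability`` and ``swimming`` datasets; ``migration`` is
    optional per strain (absent strains get an N/A migration component).
    Deterministic given the data and thresholds.
    """
    control = normalize_genotype(control_genotype)
    for needed in ("viability", "swimming"):
        if needed not in datasets:
            raise ValueError(f"score_variants requires a {needed!r} dataset")
    viab = datasets["viability"]
    swim = datasets["swimming"]
    if control not in viab.genotypes or control not in swim.genotypes:
        raise ValueError(f"control genotype {control!r} absent from the data")

    summary = viability_summary(viab).set_index("genotype")
    brood_res = {r.comparison.split(" vs ")[0]: r
                 for r in anova_dunnett(viab, "brood_size", control, alpha)}

    # lethality compares per-mother percent lethality among egg-laying mothers
    leth_records = viab.records.copy()
    leth_records = leth_records[leth_records["brood_size"] > 0]
    leth_records["lethality_pct"] = (100.0 * leth_records["unhatched"]
                                     / leth_records["brood_size"])
    leth_res: dict[str, StatResult] = {}
    leth_groups = {
        g: grp["lethality_pct"].to_numpy(dtype=float)
        for g, grp in leth_records.groupby("genotype", sort=False)
        if len(grp) >= 2
    }
    if control in leth_groups and len(leth_groups) > 1:
        leth_res = {r.comparison.split(" vs ")[0]: r
                    for r in dunnett_from_groups(leth_groups, control, alpha)}

    mig = datasets.get("migration")
    mig_res: dict[str, StatResult] = {}
    if mig is not None and control in mig.genotypes and len(mig.genotypes) > 1:
        for r in anova_tukey(mig, "mislocalized", alpha):
            a, b = r.comparison.split(" vs ")
            if b == control:
                mig_res[a] = r
            elif a == control:
                # orient the comparison as variant-minus-control
                r.extra["mean_diff"] = -r.extra.get("mean_diff", 0.0)
                mig_res[b] = r

    wt_bbps = swim.values(control, "bbps")
    cards = []
    variants = [g for g in dict.fromkeys(
        list(viab.genotypes) + list(swim.genotypes)) if g != control]
    for g in variants:
        if g not in summary.index or swim.group(g).empty:
            raise ValueError(f"variant {g!r} lacks viability or swimming data")
        row = summary.loc[g]
        v_score = viability_score(row, brood_res.get(g), leth_res.get(g), alpha)

        bbps = swim.values(g, "bbps")
        frac = defect_fraction(bbps, threshold=bbps_threshold)
        s_score = swimming_score(frac, cutoff=swim_fraction_cutoff)
        chi2 = swim_defect_test(bbps, wt_bbps, threshold=bbps_threshold,
                                comparison=f"{g} vs {control}", alpha=alpha)

        have_mig = mig is not None and not mig.group(g).empty
        m_score = migration_score(mig_res.get(g), data_available=have_mig,
                                  alpha=alpha)

        evidence = {
            "mean_brood": float(row["mean_brood"]),
            "mean_lethality_pct": float(row["mean_lethality_pct"]),
            "all_sterile": bool(row["all_sterile"]),
            "viable_offspring": int(row["viable_offspring"]),
            "brood_p_adj": brood_res[g].p_adjusted if g in brood_res else None,
            "lethality_p_adj": leth_res[g].p_adjusted if g in leth_res else None,
            "defect_fraction": frac,
            "swim_chi2_p": chi2.p_raw,
            "migration_p_adj": mig_res[g].p_adjusted if g in mig_res else None,
            "mean_mislocalized": (float(mig.values(g, "mislocalized").mean())
                                  if have_mig else None),
        }
        cards.append(total_score(g, v_score, s_score, m_score, evidence))
    return cards


def scorecards_to_frame(cards: list[VariantScoreCard]) -> pd.DataFrame:
    """Score-table DataFrame, one row per variant, stable column order."""
    return pd.DataFrame([c.to_row() for c in cards])
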