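"""Simulate -> analyze -> score orchestration and the run report."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from .dataset import AssayDataset
from .io import RunConfig, write_outputs
from .motility import swim_defect_test, defect_fraction
from .scoring import VariantScoreCard, score_variants, scorecards_to_frame
from .stats import (StatResult, anova_dunnett, anova_tukey, bleb_defect_tests,
                    group_summary, two_group_t, viability_summary)

__all__ = ["analyze_datasets", "run_pipeline", "render_report", "config_hash"]


def config_hash(config: RunConfig) -> str:
    from dataclasses import asdict
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def analyze_datasets(datasets: dict[str, AssayDataset], config: RunConfig
                     ) -> dict[str, list[StatResult]]:
    """Per-assay statistics against the control genotype.

    Missing assays are skipped (the caller decides whether that warrants a
    warning); a missing control is an error.
    """
    ctrl = config.control_genotype
    results: dict[str, list[StatResult]] = {}
    if "viability" in datasets:
        ds = datasets["viability"]
        if ctrl not in ds.genotypes:
            raise ValueError(f"control genotype {ctrl!r} absent from viability data")
        results["brood"] = anova_dunnett(ds, "brood_size", ctrl, config.alpha)
    if "swimming" in datasets:
        ds = datasets["swimming"]
        if ctrl not in ds.genotypes:
            raise ValueError(f"control genotype {ctrl!r} absent from swimming data")
        wt = ds.values(ctrl, "bbps")
        results["swimming"] = [
            swim_defect_test(ds.values(g, "bbps"), wt,
                             threshold=config.bbps_threshold,
                             comparison=f"{g} vs {ctrl}", alpha=config.alpha)
            for g in ds.genotypes if g != ctrl
        ]
    if "migration" in datasets and len(datasets["migration"].genotypes) > 1:
        results["migration"] = anova_tukey(datasets["migration"],
                                           "mislocalized", config.alpha)
    if "morphology" in datasets:
        results["morphology"] = bleb_defect_tests(datasets["morphology"], ctrl,
                                                  fdr=config.fdr)
    if "fluorescence" in datasets:
        ds = datasets["fluorescence"]
        results["fluorescence"] = [
            two_group_t(ds, "intensity", g, ctrl, config.alpha)
            for g in ds.genotypes if g != ctrl
        ]
    return results


def run_pipeline(datasets: dict[str, AssayDataset], config: RunConfig,
                 out_dir=None):
    """Analyze + score; optionally write all outputs under ``out_dir``."""
    results = analyze_datasets(datasets, config)
    cards = score_variants(
        datasets, config.control_genotype, alpha=config.alpha,
        bbps_threshold=config.bbps_threshold,
        swim_fraction_cutoff=config.swim_fraction_cutoff)
    if out_dir is not None:
        write_outputs(results, cards, out_dir)
    return results, cards


def _stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def render_report(datasets: dict[str, AssayDataset],
                  results: dict[str, list[StatResult]],
                  cards: list[VariantScoreCard], config: RunConfig) -> str:
    """Markdown run report: group summaries, starred comparisons, score table.

    Stars follow the usual convention *p<=0.05, **p<=0.01, ***p<=0.001 on
    the adjusted p-values.
    """
    lines = ["# wormscore run report", "",
             f"control genotype: {config.control_genotype}; "
             f"alpha {config.alpha}; FDR {config.fdr}; "
             f"BBPS threshold {config.bbps_threshold}; "
             f"swim fraction cutoff {config.swim_fraction_cutoff}",
             f"config hash: {config_hash(config)}; seed: {config.seed}", ""]

    value_cols = {"viability": "brood_size", "swimming": "bbps",
                  "migration": "mislocalized", "morphology": "blebs",
                  "fluorescence": "intensity"}
    for assay, ds in datasets.items():
        lines.append(f"## {assay} summary (mean, 95% CI)")
        summ = group_summary(ds, value_cols[assay])
        for _, r in summ.iterrows():
            lines.append(f"- {r['genotype']}: n={r['n']}, "
                         f"mean={r['mean']:.3f} "
                         f"[{r['ci95_lo']:.3f}, {r['ci95_hi']:.3f}]")
        if assay == "swimming":
            for g in ds.genotypes:
                frac = defect_fraction(ds.values(g, "bbps"),
                                       threshold=config.bbps_threshold)
                lines.append(f"  - {g}: defective fraction "
                             f"(<= {config.bbps_threshold} BBPS) = {frac:.2f}")
        lines.append("")

    for name, rs in results.items():
        lines.append(f"## {name} comparisons")
        for r in rs:
            lines.append(f"- {r.comparison}: stat={r.statistic:.3f}, "
                         f"p_adj={r.p_adjusted:.4g} {_stars(r.p_adjusted)} "
                         f"[{r.method}]")
        lines.append("")

    lines.append("## score table")
    table = scorecards_to_frame(cards)
    lines.append(table.to_string(index=False))
    lines.append("")
    return "\n".join(lines)
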