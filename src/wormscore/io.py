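"""File formats and run configuration.

Tidy per-animal CSVs are the native interchange format (one file per
assay). The per-figure workbook layout used for the published raw data —
one section per assay, one column per genotype, one value per animal per
cell, ragged columns allowed — is supported for both writing (the synthetic
fixture) and reading. Outputs (statistics tables, the score table, evidence
bundles) are written with fixed column order and formatting so identical
inputs give byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import ASSAY_SCHEMAS, AssayDataset, normalize_genotype
from .motility import BBPS_THRESHOLD
from .scoring import SWIM_FRACTION_CUTOFF, VariantScoreCard, scorecards_to_frame
from .stats import ALPHA

__all__ = [
    "RunConfig", "read_tidy_assays", "write_tidy_assays",
    "read_s1_workbook", "write_s1_workbook", "write_outputs",
]

#: canonical workbook section titles per assay (reader accepts overrides)
S1_SECTIONS: dict[str, str] = {
    "viability_brood": "Brood size",
    "viability_hatch": "Percent hatched",
    "swimming": "BBPS",
    "migration": "Mislocalized nuclei",
    "morphology": "Nuclear blebs",
    "fluorescence": "Fluorescence intensity",
}


@dataclass
class RunConfig:
    """Thresholds, identifiers and paths for one pipeline run."""

    control_genotype: str = "wild_type"
    alpha: float = ALPHA
    fdr: float = 0.05
    bbps_threshold: float = BBPS_THRESHOLD
    swim_fraction_cutoff: float = SWIM_FRACTION_CUTOFF
    seed: int = 0
    nuclei_per_animal: int = 16
    section_names: dict = field(default_factory=lambda: dict(S1_SECTIONS))
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.fdr < 1:
            raise ValueError("alpha and fdr must lie in (0, 1)")
        if self.bbps_threshold <= 0 or not 0 < self.swim_fraction_cutoff < 1:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


# ------------------------------------------------------------- tidy CSV

def write_tidy_assays(datasets: dict[str, AssayDataset], directory) -> list[Path]:
    """One ``<assay>.csv`` per dataset; deterministic formatting."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for assay in sorted(datasets):
        ds = datasets[assay]
        path = directory / f"{assay}.csv"
        cols = ["genotype", "animal_id", *ASSAY_SCHEMAS[ds.assay]]
        extra = [c for c in ds.records.columns if c not in cols]
        ds.records[cols + extra].to_csv(path, index=False, float_format="%.6g")
        written.append(path)
    return written


def read_tidy_assays(directory) -> dict[str, AssayDataset]:
    """Read every recognized ``<assay>.csv`` under ``directory``.

    Validation failures report the assay, column and row of the offending
    cell (see :class:`wormscore.dataset.SchemaError`).
    """
    directory = Path(directory)
    if not directory.exists():
        raise FileNotFoundError(directory)
    out = {}
    for assay in ASSAY_SCHEMAS:
        path = directory / f"{assay}.csv"
        if path.exists():
            df = pd.read_csv(path)
            out[assay] = AssayDataset(assay, df)
    if not out:
        raise FileNotFoundError(f"no assay CSVs found under {directory}")
    return out


# ----------------------------------------------------- workbook layout

def write_s1_workbook(datasets: dict[str, AssayDataset], path,
                      section_names: dict[str, str] | None = None) -> Path:
    """Write assays in the per-figure workbook layout (XLSX).

    One section per assay, a one-row gap between sections; within a
    section, one column per genotype with one value per animal. Viability
    is split into a brood-size section and a percent-hatched section
    (hatch cell blank for a sterile mother).
    """
    from openpyxl import Workbook

    names = dict(S1_SECTIONS)
    names.update(section_names or {})
    wb = Workbook()
    ws = wb.active
    ws.title = "data"
    row = 1

    def emit(title: str, columns: dict[str, list]) -> None:
        nonlocal row
        ws.cell(row=row, column=1, value=title)
        row += 1
        genos = list(columns)
        for j, g in enumerate(genos, start=1):
            ws.cell(row=row, column=j, value=g)
        depth = max((len(v) for v in columns.values()), default=0)
        for i in range(depth):
            for j, g in enumerate(genos, start=1):
                vals = columns[g]
                if i < len(vals) and vals[i] is not None:
                    ws.cell(row=row + 1 + i, column=j, value=vals[i])
        row += depth + 2  # blank row between sections

    if "viability" in datasets:
        ds = datasets["viability"]
        brood = {g: ds.group(g)["brood_size"].tolist() for g in ds.genotypes}
        hatch = {}
        for g in ds.genotypes:
            grp = ds.group(g)
            cells = []
            for b, u in zip(grp["brood_size"], grp["unhatched"]):
                cells.append(None if b == 0 else 100.0 * (b - u) / b)
            hatch[g] = cells
        emit(names["viability_brood"], brood)
        emit(names["viability_hatch"], hatch)
    for assay, col in (("swimming", "bbps"), ("migration", "mislocalized"),
                       ("morphology", "blebs"), ("fluorescence", "intensity")):
        if assay in datasets:
            ds = datasets[assay]
            emit(names[assay], {g: ds.group(g)[col].tolist()
                                for g in ds.genotypes})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    wb.save(path)
    return path


def _read_sections(path) -> dict[str, dict[str, list[float]]]:
    from openpyxl import load_workbook

    wb = load_workbook(path, read_only=True, data_only=True)
    ws = wb.worksheets[0]
    rows = [[c for c in r] for r in ws.iter_rows(values_only=True)]
    sections: dict[str, dict[str, list[float]]] = {}
    i = 0
    while i < len(rows):
        r = rows[i]
        nonempty = [v for v in r if v is not None]
        if len(nonempty) == 1 and isinstance(nonempty[0], str):
            title = str(nonempty[0]).strip()
            header = rows[i + 1] if i + 1 < len(rows) else []
            genos = [normalize_genotype(v) for v in header if v is not None]
            cols: dict[str, list[float]] = {g: [] for g in genos}
            j = i + 2
            while j < len(rows) and any(v is not None for v in rows[j]):
                for k, g in enumerate(genos):
                    v = rows[j][k] if k < len(rows[j]) else None
                    if v is not None:
                        cols[g].append(float(v))
                j += 1
            sections[title] = cols
            i = j
        else:
            i += 1
    return sections


def read_s1_workbook(path, section_names: dict[str, str] | None = None,
                     nuclei_per_animal: int = 16) -> dict[str, AssayDataset]:
    """Read a per-figure workbook into tidy assay datasets.

    Trailing blanks in a column are simply absent values (ragged columns
    are expected); a genotype column with no values at all is an error.
    Brood-size and percent-hatched sections are paired positionally per
    genotype to recover per-mother unhatched counts; mothers with brood 0
    carry an empty hatch cell.
    """
    names = dict(S1_SECTIONS)
    names.update(section_names or {})
    wanted = {v: k for k, v in names.items()}
    sections = _read_sections(path)
    unknown = set(sections) - set(wanted)
    if unknown:
        raise ValueError(f"unrecognized workbook section header(s): "
                         f"{sorted(unknown)}")
    by_key = {wanted[t]: cols for t, cols in sections.items()}
    for key, cols in by_key.items():
        for g, vals in cols.items():
            if not vals and key != "viability_hatch":
                raise ValueError(f"empty column {g!r} in section {names[key]!r}")

    out: dict[str, AssayDataset] = {}
    if "viability_brood" in by_key:
        brood_cols = by_key["viability_brood"]
        hatch_cols = by_key.get("viability_hatch", {})
        recs = []
        for g, broods in brood_cols.items():
            hatches = list(hatch_cols.get(g, []))
            hi = 0
            for i, b in enumerate(broods):
                b = int(round(b))
                if b == 0:
                    unh = 0
                else:
                    if hi >= len(hatches):
                        raise ValueError(
                            f"genotype {g!r}: fewer hatch values than "
                            f"egg-laying mothers")
                    unh = int(round(b * (1.0 - hatches[hi] / 100.0)))
                    hi += 1
                recs.append({"genotype": g, "animal_id": f"m{i + 1:03d}",
                             "brood_size": b, "unhatched": unh})
        out["viability"] = AssayDataset("viability", pd.DataFrame(recs))

    simple = {"swimming": "bbps", "migration": "mislocalized",
              "morphology": "blebs", "fluorescence": "intensity"}
    for key, col in simple.items():
        if key not in by_key:
            continue
        recs = []
        for g, vals in by_key[key].items():
            for i, v in enumerate(vals):
                recs.append({"genotype": g, "animal_id": f"a{i + 1:03d}",
                             col: v})
        df = pd.DataFrame(recs)
        if key in ("migration", "morphology"):
            df[col] = df[col].round().astype(int)
        if key == "migration":
            df["nuclei_total"] = nuclei_per_animal
        out[key] = AssayDataset(key, df)
    return out


# ------------------------------------------------------------- outputs

def write_outputs(results: dict[str, list], cards: list[VariantScoreCard],
                  directory) -> dict[str, Path]:
    """Write statistics tables, the score table and evidence bundles.

    ``results`` maps an assay/analysis name to a list of StatResults. The
    score table is TSV with the sentinel string ``NA`` for the missing
    migration component; all floats use fixed formatting so reruns on the
    same inputs are byte-identical.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in sorted(results):
        rows = [r.to_row() for r in results[name]]
        df = pd.DataFrame(rows, columns=["comparison", "statistic", "p_raw",
                                         "p_adjusted", "method", "significant",
                                         "note"])
        path = directory / f"stats_{name}.csv"
        df.to_csv(path, index=False, float_format="%.6g")
        written[f"stats_{name}"] = path

    table = scorecards_to_frame(cards)
    path = directory / "score_table.tsv"
    table.to_csv(path, sep="\t", index=False, na_rep="NA")
    written["score_table"] = path

    evidence = {c.variant: _jsonable(c.evidence) for c in cards}
    path = directory / "evidence.json"
    with open(path, "w") as fh:
        json.dump(evidence, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["evidence"] = path
    return written


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and obj != obj:
        return None
    return obj
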