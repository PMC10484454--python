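"""Synthetic per-animal assay data.

Each assay draws from its own deterministic random stream derived from
``(seed, assay tag, genotype)`` via CRC32, so adding or reordering assays
never perturbs another assay's draws and every dataset is reproducible
byte-for-byte from the global seed.

Generative models
-----------------
viability     brood ~ zero-inflated negative binomial (sterile mothers lay
              nothing); unhatched ~ Binomial(brood, lethality_prob)
swimming      BBPS ~ two-component normal mixture truncated at 0
              (impaired vs unimpaired swimmers)
migration     mislocalized nuclei ~ Binomial(nuclei_per_animal, mig_fail_prob)
morphology    blebs per animal side ~ Poisson(bleb_rate)
fluorescence  per-nucleus intensity ~ Normal(fluor_mean, fluor_sd)
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from .dataset import AssayDataset
from .profiles import (GenotypeProfile, MIGRATION_NOT_ASSAYED, PANEL_SAMPLE_SIZES,
                       PAPER_PANEL)

__all__ = [
    "assay_rng", "simulate_viability", "simulate_swimming", "simulate_migration",
    "simulate_blebs", "simulate_fluorescence", "simulate_panel",
]


def _tag(s: str) -> int:
    return zlib.crc32(s.encode("utf-8"))


def assay_rng(seed: int, assay: str, genotype: str) -> np.random.Generator:
    """Derived random stream for one (assay, genotype) pair."""
    return np.random.default_rng([int(seed) % (2**31), _tag(assay), _tag(genotype)])


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1:03d}" for i in range(n)]


def _check_n(n: int, what: str) -> None:
    if n < 1:
        raise ValueError(f"{what} must be >= 1, got {n}")


def simulate_viability(profile: GenotypeProfile, n_mothers: int,
                       seed: int) -> AssayDataset:
    """Per-mother total eggs and unhatched eggs over the 3-day window."""
    _check_n(n_mothers, "n_mothers")
    rng = assay_rng(seed, "viability", profile.name)
    sterile = rng.random(n_mothers) < profile.sterile_fraction
    k = profile.brood_dispersion
    mu = profile.brood_mean
    if mu > 0:
        brood = rng.negative_binomial(k, k / (k + mu), size=n_mothers)
    else:
        brood = np.zeros(n_mothers, dtype=int)
    brood = np.where(sterile, 0, brood)
    unhatched = rng.binomial(brood, profile.lethality_prob)
    df = pd.DataFrame({
        "genotype": profile.name,
        "animal_id": _ids("m", n_mothers),
        "brood_size": brood.astype(int),
        "unhatched": unhatched.astype(int),
    })
    return AssayDataset("viability", df, {"seed": int(seed)})


def _truncated_normal(rng: np.random.Generator, mu: np.ndarray,
                      sd: float) -> np.ndarray:
    """Draws from N(mu, sd) conditioned on being >= 0 (inverse-CDF)."""
    from scipy import stats
    u = rng.random(mu.shape)
    a = (0.0 - mu) / sd
    return stats.truncnorm.ppf(u, a, np.inf, loc=mu, scale=sd)


def simulate_swimming(profile: GenotypeProfile, n_animals: int,
                      seed: int, duration_s: float = 30.0) -> AssayDataset:
    """Per-animal BBPS from the impaired/unimpaired mixture."""
    _check_n(n_animals, "n_animals")
    rng = assay_rng(seed, "swimming", profile.name)
    impaired = rng.random(n_animals) < profile.impaired_fraction
    mu = np.where(impaired, profile.swim_mean_bad, profile.swim_mean_ok)
    bbps = _truncated_normal(rng, mu, profile.swim_sd)
    df = pd.DataFrame({
        "genotype": profile.name,
        "animal_id": _ids("w", n_animals),
        "bbps": bbps,
    })
    return AssayDataset("swimming", df,
                        {"seed": int(seed), "duration_s": duration_s})


def simulate_migration(profile: GenotypeProfile, n_animals: int,
                       seed: int) -> AssayDataset:
    """Per-animal counts of hyp7 nuclei stranded in the dorsal cord."""
    _check_n(n_animals, "n_animals")
    rng = assay_rng(seed, "migration", profile.name)
    counts = rng.binomial(profile.nuclei_per_animal, profile.mig_fail_prob,
                          size=n_animals)
    df = pd.DataFrame({
        "genotype": profile.name,
        "animal_id": _ids("a", n_animals),
        "mislocalized": counts.astype(int),
        "nuclei_total": profile.nuclei_per_animal,
    })
    return AssayDataset("migration", df, {"seed": int(seed)})


def simulate_blebs(profile: GenotypeProfile, n_animals: int,
                   seed: int) -> AssayDataset:
    """Per-animal nuclear-bleb counts (one lateral side)."""
    _check_n(n_animals, "n_animals")
    rng = assay_rng(seed, "morphology", profile.name)
    counts = rng.poisson(profile.bleb_rate, size=n_animals)
    df = pd.DataFrame({
        "genotype": profile.name,
        "animal_id": _ids("a", n_animals),
        "blebs": counts.astype(int),
    })
    return AssayDataset("morphology", df, {"seed": int(seed)})


def simulate_fluorescence(profile: GenotypeProfile, n_nuclei: int,
                          seed: int) -> AssayDataset:
    """Per-nucleus background-corrected envelope intensity (a.u.)."""
    _check_n(n_nuclei, "n_nuclei")
    rng = assay_rng(seed, "fluorescence", profile.name)
    vals = rng.normal(profile.fluor_mean, profile.fluor_sd, size=n_nuclei)
    df = pd.DataFrame({
        "genotype": profile.name,
        "animal_id": _ids("n", n_nuclei),
        "intensity": vals,
    })
    return AssayDataset("fluorescence", df, {"seed": int(seed)})


_SIMULATORS = {
    "viability": simulate_viability,
    "swimming": simulate_swimming,
    "migration": simulate_migration,
    "morphology": simulate_blebs,
    "fluorescence": simulate_fluorescence,
}


def _concat(datasets: list[AssayDataset]) -> AssayDataset:
    assay = datasets[0].assay
    df = pd.concat([d.records for d in datasets], ignore_index=True)
    meta = dict(datasets[0].metadata)
    return AssayDataset(assay, df, meta)


def simulate_panel(profiles: dict[str, GenotypeProfile] | None = None,
                   seed: int = 0,
                   sample_sizes: dict[str, dict[str, int]] | None = None,
                   skip_migration: tuple[str, ...] = MIGRATION_NOT_ASSAYED,
                   ) -> dict[str, AssayDataset]:
    """Simulate every assay for a panel of strains.

    Defaults to the twelve-variant panel plus the wild-type control at the
    published per-assay sample sizes. Returns one combined
    :class:`AssayDataset` per assay; strains in ``skip_migration`` are left
    out of the migration dataset (their score table cell prints N/A).
    """
    profiles = dict(PAPER_PANEL) if profiles is None else profiles
    sizes = PANEL_SAMPLE_SIZES if sample_sizes is None else sample_sizes
    out: dict[str, AssayDataset] = {}
    for assay, sim in _SIMULATORS.items():
        per_geno = []
        for name, prof in profiles.items():
            if assay == "migration" and name in skip_migration:
                continue
            n = sizes[assay].get(name, sizes[assay]["default"])
            per_geno.append(sim(prof, n, seed))
        out[assay] = _concat(per_geno)
    return out
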