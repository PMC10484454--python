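"""Generative phenotype profiles for lamin-variant strains.

A :class:`GenotypeProfile` holds the full parameter set the simulator needs
to emit one strain's data for every assay: brood counts (negative binomial,
zero-inflated by a sterile fraction), per-egg hatching failure, a
two-component body-bends-per-second mixture (impaired vs unimpaired
swimmers, truncated at 0), per-nucleus migration failure, bleb counts and
nuclear-envelope fluorescence.

Four generic templates (``wild_type``, ``severe``, ``cardiac_only``,
``benign_vus``) cover the clinical classes, and :data:`PAPER_PANEL` provides
per-variant profiles for the twelve LMN-1 missense strains, tuned to the
published summary magnitudes (wild-type swimmers average 1.86 BBPS, Y59C
1.1 BBPS, severe-class broods 30-40% of wild type, ~75% migration failure
for R204W, and so on).
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

from scipy import stats

CLINICAL_CLASSES = ("skeletal_and_cardiac", "cardiac_only", "vus", "wild_type")


@dataclass(frozen=True)
class GenotypeProfile:
    """Generative parameters for one strain, all assays.

    Units: ``brood_mean`` eggs/mother; ``swim_mean_*`` and ``swim_sd``
    bends/s; ``bleb_rate`` blebs per animal side; ``fluor_*`` arbitrary
    intensity units. Probabilities are per-egg (``lethality_prob``),
    per-mother (``sterile_fraction``), per-animal (``impaired_fraction``)
    or per-nucleus (``mig_fail_prob``).
    """

    name: str
    clinical_class: str
    brood_mean: float
    brood_dispersion: float
    lethality_prob: float
    sterile_fraction: float
    swim_mean_ok: float
    swim_mean_bad: float
    swim_sd: float
    impaired_fraction: float
    mig_fail_prob: float
    nuclei_per_animal: int
    bleb_rate: float
    fluor_mean: float
    fluor_sd: float

    def __post_init__(self) -> None:
        if self.clinical_class not in CLINICAL_CLASSES:
            raise ValueError(f"unknown clinical_class {self.clinical_class!r}")
        for p in ("lethality_prob", "sterile_fraction", "impaired_fraction",
                  "mig_fail_prob"):
            v = getattr(self, p)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{p} must be in [0, 1], got {v}")
        for p in ("brood_mean", "swim_mean_ok", "swim_mean_bad", "bleb_rate"):
            v = getattr(self, p)
            if not (v >= 0.0 and v == v and abs(v) != float("inf")):
                raise ValueError(f"{p} must be finite and >= 0, got {v}")
        for p in ("brood_dispersion", "swim_sd", "fluor_sd"):
            if not getattr(self, p) > 0:
                raise ValueError(f"{p} must be > 0")
        if self.nuclei_per_animal < 1:
            raise ValueError("nuclei_per_animal must be >= 1")
        if (self.clinical_class != "wild_type"
                and self.swim_mean_bad > self.swim_mean_ok):
            raise ValueError("swim_mean_bad must not exceed swim_mean_ok")

    # ---- analytic moments (used by moment-fidelity tests) ----

    def expected_brood(self) -> float:
        """Mean eggs/mother including sterile mothers."""
        return (1.0 - self.sterile_fraction) * self.brood_mean

    def _trunc_mean(self, mu: float, sd: float) -> float:
        a = (0.0 - mu) / sd
        return float(stats.truncnorm.mean(a, float("inf"), loc=mu, scale=sd))

    def expected_bbps(self) -> float:
        """Population mean BBPS of the impaired/unimpaired mixture."""
        w = self.impaired_fraction
        return (w * self._trunc_mean(self.swim_mean_bad, self.swim_sd)
                + (1.0 - w) * self._trunc_mean(self.swim_mean_ok, self.swim_sd))

    def expected_defect_fraction(self, threshold: float = 1.1) -> float:
        """P(BBPS <= threshold) under the mixture."""
        def p_le(mu: float) -> float:
            a = (0.0 - mu) / self.swim_sd
            return float(stats.truncnorm.cdf(threshold, a, float("inf"),
                                             loc=mu, scale=self.swim_sd))
        w = self.impaired_fraction
        return w * p_le(self.swim_mean_bad) + (1.0 - w) * p_le(self.swim_mean_ok)

    def expected_mislocalized(self) -> float:
        return self.mig_fail_prob * self.nuclei_per_animal

    def to_dict(self) -> dict:
        return asdict(self)


_TEMPLATES: dict[str, GenotypeProfile] = {
    # Healthy reference strain: large brood, ~1% embryonic lethality,
    # 1.86 BBPS swimmers, essentially no migration or morphology defects.
    "wild_type": GenotypeProfile(
        name="wild_type", clinical_class="wild_type",
        brood_mean=280.0, brood_dispersion=8.0,
        lethality_prob=0.010, sterile_fraction=0.0,
        swim_mean_ok=1.86, swim_mean_bad=0.40, swim_sd=0.35,
        impaired_fraction=0.0,
        mig_fail_prob=0.005, nuclei_per_animal=16,
        bleb_rate=0.3, fluor_mean=100.0, fluor_sd=15.0,
    ),
    # Skeletal+cardiac class: brood ~35% of wild type, elevated lethality,
    # most animals swim at or below the 1.1 BBPS defect threshold, and a
    # 20-35%-of-nuclei migration defect.
    "severe": GenotypeProfile(
        name="severe", clinical_class="skeletal_and_cardiac",
        brood_mean=98.0, brood_dispersion=6.0,
        lethality_prob=0.26, sterile_fraction=0.0,
        swim_mean_ok=1.86, swim_mean_bad=0.45, swim_sd=0.40,
        impaired_fraction=0.58,
        mig_fail_prob=0.27, nuclei_per_animal=16,
        bleb_rate=3.0, fluor_mean=100.0, fluor_sd=15.0,
    ),
    # Cardiac-only class: fitness and motility indistinguishable from wild
    # type; mild morphology signal only.
    "cardiac_only": GenotypeProfile(
        name="cardiac_only", clinical_class="cardiac_only",
        brood_mean=270.0, brood_dispersion=8.0,
        lethality_prob=0.012, sterile_fraction=0.0,
        swim_mean_ok=1.80, swim_mean_bad=0.40, swim_sd=0.35,
        impaired_fraction=0.02,
        mig_fail_prob=0.006, nuclei_per_animal=16,
        bleb_rate=0.9, fluor_mean=100.0, fluor_sd=15.0,
    ),
    # Benign variant of unknown significance: wild-type-like throughout.
    "benign_vus": GenotypeProfile(
        name="benign_vus", clinical_class="vus",
        brood_mean=278.0, brood_dispersion=8.0,
        lethality_prob=0.010, sterile_fraction=0.0,
        swim_mean_ok=1.84, swim_mean_bad=0.40, swim_sd=0.35,
        impaired_fraction=0.02,
        mig_fail_prob=0.006, nuclei_per_animal=16,
        bleb_rate=0.4, fluor_mean=100.0, fluor_sd=15.0,
    ),
}


def make_profile(template: str, overrides: dict | None = None) -> GenotypeProfile:
    """Build a :class:`GenotypeProfile` from a named template.

    Parameters
    ----------
    template
        ``wild_type``, ``severe``, ``cardiac_only`` or ``benign_vus``.
    overrides
        Partial map of GenotypeProfile field names to replacement values.
        Overrides are validated against the profile invariants.
    """
    if template not in _TEMPLATES:
        raise ValueError(
            f"unknown template {template!r}; expected one of {sorted(_TEMPLATES)}"
        )
    prof = _TEMPLATES[template]
    if overrides:
        unknown = set(overrides) - set(prof.to_dict())
        if unknown:
            raise ValueError(f"unknown profile fields in overrides: {sorted(unknown)}")
        prof = replace(prof, **overrides)  # __post_init__ re-validates
    return prof


def _variant(name, clin, **kw) -> GenotypeProfile:
    base = "wild_type" if clin == "wild_type" else (
        "severe" if clin == "skeletal_and_cardiac" else
        "cardiac_only" if clin == "cardiac_only" else "benign_vus")
    return make_profile(base, {"name": name, "clinical_class": clin, **kw})


#: Worm residue label -> homologous human LMNA residue label.
HUMAN_ALIASES: dict[str, str] = {
    "N53S": "N39S", "Y59C": "Y45C", "R64P": "R50P", "E358K": "E358K",
    "L535P": "L530P", "E96K": "E82K", "E175K": "E161K", "R204W": "R190W",
    "K284Q": "K270Q", "K331Q": "R331Q", "G407D": "S407D", "G528R": "G523R",
}

#: Per-variant generative profiles for the twelve-strain panel, in the
#: published table's row order. Magnitudes are tuned to the printed summary
#: statements; see docs/methods.md for each anchor.
PAPER_PANEL: dict[str, GenotypeProfile] = {
    "wild_type": make_profile("wild_type"),
    # laid some eggs, none viable; mild swim slowing; migration defect
    "N53S": _variant("N53S", "skeletal_and_cardiac",
                     brood_mean=60.0, brood_dispersion=5.0,
                     lethality_prob=1.0, sterile_fraction=0.05,
                     swim_mean_ok=1.70, impaired_fraction=0.08,
                     mig_fail_prob=0.27),
    # brood ~35% of WT, +25% lethality, 1.1 BBPS mean, migration defect
    "Y59C": _variant("Y59C", "skeletal_and_cardiac"),
    # like Y59C but normal migration
    "R64P": _variant("R64P", "skeletal_and_cardiac",
                     brood_mean=100.0, lethality_prob=0.28,
                     impaired_fraction=0.55, mig_fail_prob=0.010,
                     bleb_rate=1.2),
    # reduced brood (<40% of WT overall), some mothers lay few/no eggs
    "E358K": _variant("E358K", "skeletal_and_cardiac",
                      brood_mean=120.0, brood_dispersion=5.0,
                      lethality_prob=0.12, sterile_fraction=0.25,
                      swim_mean_ok=1.75, swim_sd=0.35,
                      impaired_fraction=0.05,
                      mig_fail_prob=0.010, bleb_rate=1.2),
    # sterile homozygotes; worst swimmers (<1 BBPS mean)
    "L535P": _variant("L535P", "skeletal_and_cardiac",
                      brood_mean=0.0, sterile_fraction=1.0,
                      lethality_prob=0.5,
                      swim_mean_ok=1.70, swim_mean_bad=0.35, swim_sd=0.35,
                      impaired_fraction=0.75,
                      mig_fail_prob=0.015),
    "E96K": _variant("E96K", "cardiac_only", brood_mean=270.0),
    "E175K": _variant("E175K", "cardiac_only",
                      brood_mean=275.0, swim_mean_ok=1.82),
    # separation-of-function: healthy fitness/motility, ~75% of nuclei
    # fail to migrate
    "R204W": _variant("R204W", "cardiac_only",
                      brood_mean=265.0, mig_fail_prob=0.75),
    "K284Q": _variant("K284Q", "vus", brood_mean=278.0, bleb_rate=0.8),
    # the one pathogenic VUS: swimming defect only
    "K331Q": _variant("K331Q", "vus",
                      brood_mean=272.0, lethality_prob=0.012,
                      swim_mean_ok=1.80, swim_mean_bad=0.50, swim_sd=0.40,
                      impaired_fraction=0.52, mig_fail_prob=0.008,
                      bleb_rate=0.8),
    "G407D": _variant("G407D", "vus",
                      brood_mean=280.0, swim_mean_ok=1.85,
                      impaired_fraction=0.01, mig_fail_prob=0.005,
                      bleb_rate=0.35),
    # migration assay not performed for this strain (N/A in the score table)
    "G528R": _variant("G528R", "vus",
                      brood_mean=276.0, swim_mean_ok=1.83),
}

#: Assay sample sizes of the published experiments (per genotype).
PANEL_SAMPLE_SIZES: dict[str, dict[str, int]] = {
    "viability": {"wild_type": 22, "default": 10},
    "swimming": {"wild_type": 100, "default": 40},
    "migration": {"default": 20},
    "morphology": {"default": 20},
    "fluorescence": {"default": 30},
}

#: Strains for which the migration assay is absent (score table prints N/A).
MIGRATION_NOT_ASSAYED = ("G528R",)
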