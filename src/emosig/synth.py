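"""Synthetic behavioral cohorts and spectral-count proteomes.

The generators emulate the two kinds of data the analysis consumes:

* a chronic-corticosterone mouse cohort run through a three-test
  behavioral battery (elevated plus maze, novelty-suppressed feeding,
  splash test), with group-level shifts planted in the anxio-depressive
  direction and the NSF latency right-censored at the 10-minute cap;
* label-free spectral-counting proteomics: integer count matrices drawn
  from a Poisson model in which abundance is proportional to the expected
  number of MS/MS spectra, with planted fold-changes for a subset of
  proteins, plus peptide-to-protein identification tables with
  controllable shared-peptide ambiguity for the grouping stage.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError

DEFAULT_GROUPS: tuple[str, ...] = (
    "Veh/Veh",
    "Cort/Veh",
    "Cort/Flx",
    "Cort/Flx-NR-ECS",
)

DEFAULT_SESSIONS: tuple[str, ...] = ("W5", "W10")

#: measure -> (test, baseline location, reference SD, sampling family)
#: Families: "gaussian" (clamped), "poisson" (counts), "lognormal"
#: (positive latencies, censored downstream).  Baselines are typical
#: values for adult C57BL/6 males in a 5-min EPM / 5-min splash test /
#: 10-min NSF session.
MEASURE_MODELS: dict[str, tuple[str, float, float, str]] = {
    "open_arm_time": ("EPM", 60.0, 20.0, "gaussian"),
    "open_arm_entries": ("EPM", 8.0, math.sqrt(8.0), "poisson"),
    "latency_to_feed": ("NSF", math.log(150.0), 0.5, "lognormal"),
    "grooming_duration": ("ST", 70.0, 15.0, "gaussian"),
}

#: physical clamping ranges (seconds within the test window, counts >= 0)
MEASURE_RANGES: dict[str, tuple[float, float]] = {
    "open_arm_time": (0.0, 300.0),
    "open_arm_entries": (0.0, math.inf),
    "grooming_duration": (0.0, 300.0),
}

#: Default planted shifts, in reference-SD units, keyed by
#: (group, measure) or (group, measure, session).  Signs follow the
#: anxio-depressive direction: chronic corticosterone raises NSF latency
#: and lowers open-arm activity and grooming; fluoxetine (last 5 weeks)
#: partially normalizes the phenotype by the second behavioral round, and
#: ECS in the non-responder arm normalizes it by the post-ECS round.
DEFAULT_GROUP_EFFECTS: dict[tuple, float] = {
    ("Cort/Veh", "open_arm_time"): -1.2,
    ("Cort/Veh", "open_arm_entries"): -1.2,
    ("Cort/Veh", "latency_to_feed"): 1.5,
    ("Cort/Veh", "grooming_duration"): -1.0,
    # Flx arm looks like Cort at the pre-treatment round ...
    ("Cort/Flx", "open_arm_time", "W5"): -1.2,
    ("Cort/Flx", "open_arm_entries", "W5"): -1.2,
    ("Cort/Flx", "latency_to_feed", "W5"): 1.5,
    ("Cort/Flx", "grooming_duration", "W5"): -1.0,
    # ... and mostly recovers after 4 weeks of fluoxetine.
    ("Cort/Flx", "open_arm_time", "W10"): -0.3,
    ("Cort/Flx", "open_arm_entries", "W10"): -0.3,
    ("Cort/Flx", "latency_to_feed", "W10"): 0.4,
    ("Cort/Flx", "grooming_duration", "W10"): -0.25,
    ("Cort/Flx-NR-ECS", "open_arm_time", "W5"): -1.2,
    ("Cort/Flx-NR-ECS", "open_arm_entries", "W5"): -1.2,
    ("Cort/Flx-NR-ECS", "latency_to_feed", "W5"): 1.5,
    ("Cort/Flx-NR-ECS", "grooming_duration", "W5"): -1.0,
    ("Cort/Flx-NR-ECS", "open_arm_time", "W10"): -0.2,
    ("Cort/Flx-NR-ECS", "open_arm_entries", "W10"): -0.2,
    ("Cort/Flx-NR-ECS", "latency_to_feed", "W10"): 0.3,
    ("Cort/Flx-NR-ECS", "grooming_duration", "W10"): -0.2,
}

#: Default arm sizes mirror the study design: a vehicle arm, a
#: corticosterone arm, a 25-mouse fluoxetine arm (later split into
#: responders and non-responders) and the non-responder/ECS arm.
DEFAULT_N_PER_GROUP: dict[str, int] = {
    "Veh/Veh": 10,
    "Cort/Veh": 10,
    "Cort/Flx": 25,
    "Cort/Flx-NR-ECS": 7,
}


@dataclass
class CohortConfig:
    """Configuration of a simulated behavioral cohort.

    ``group_effects`` maps ``(group, measure)`` — optionally
    ``(group, measure, session)`` for round-specific shifts — to a mean
    shift expressed in reference-SD units of that measure.  For the
    log-normally distributed NSF latency the shift acts on the log scale.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_GROUP)
    )
    group_effects: Mapping[tuple, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_EFFECTS)
    )
    sessions: Sequence[str] = DEFAULT_SESSIONS
    nsf_max_latency: float = 600.0
    measure_noise_sd: Mapping[str, float] = field(default_factory=dict)
    #: between-animal SD of a persistent susceptibility trait (in SD
    #: units, shared across sessions and measures); this is what makes
    #: some fluoxetine-arm animals responders and others not.
    animal_heterogeneity_sd: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_per_group, int):
            self.n_per_group = {g: self.n_per_group for g in DEFAULT_GROUPS}
        for group, n in self.n_per_group.items():
            if n < 2:
                raise SchemaError(f"n_per_group must be >= 2 (group {group!r}: {n})")
        if self.nsf_max_latency <= 0:
            raise SchemaError("nsf_max_latency must be positive")
        for m, sd in self.measure_noise_sd.items():
            if m not in MEASURE_MODELS:
                raise SchemaError(f"unknown measure in measure_noise_sd: {m!r}")
            if sd <= 0:
                raise SchemaError(f"noise SD must be positive (measure {m!r})")
        groups = set(self.n_per_group)
        for key in self.group_effects:
            if len(key) not in (2, 3):
                raise SchemaError(f"group_effects key must be (group, measure[, session]): {key!r}")
            if key[0] not in groups:
                raise SchemaError(f"group_effects refers to unknown group {key[0]!r}")
            if key[1] not in MEASURE_MODELS:
                raise SchemaError(f"group_effects refers to unknown measure {key[1]!r}")


def _effect_for(effects: Mapping[tuple, float], group: str, measure: str, session: str) -> float:
    if (group, measure, session) in effects:
        return effects[(group, measure, session)]
    return effects.get((group, measure), 0.0)


def simulate_behavior_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a long-format behavioral dataset with one row per
    animal x session x measure.

    Columns: ``animal, group, session, test, measure, value, censored``.
    Gaussian measures are clamped to their physical range, counts are
    Poisson, and the NSF latency is log-normal right-censored at
    ``nsf_max_latency`` with ``censored`` set on capped rows.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[tuple] = []
    for group in config.n_per_group:
        n = config.n_per_group[group]
        # persistent per-animal susceptibility, shared across sessions
        traits = rng.normal(0.0, config.animal_heterogeneity_sd, size=n)
        for i in range(n):
            animal = f"{group.replace('/', '-')}_{i + 1:02d}"
            for session in config.sessions:
                for measure, (test, loc, sd_ref, family) in MEASURE_MODELS.items():
                    shift = _effect_for(config.group_effects, group, measure, session)
                    noise_sd = config.measure_noise_sd.get(measure, sd_ref)
                    # the trait moves the animal along the anxio-depressive
                    # axis only where a group effect is planted
                    trait = traits[i] * (1.0 if shift != 0.0 else 0.0)
                    mu = loc + (shift + trait * np.sign(shift)) * sd_ref
                    censored = False
                    if family == "gaussian":
                        value = rng.normal(mu, noise_sd)
                        lo, hi = MEASURE_RANGES[measure]
                        value = float(min(max(value, lo), hi))
                    elif family == "poisson":
                        lam = max(mu, 0.1)
                        value = float(rng.poisson(lam))
                    elif family == "lognormal":
                        value = float(np.exp(rng.normal(mu, noise_sd)))
                        if value >= config.nsf_max_latency:
                            value = config.nsf_max_latency
                            censored = True
                    else:  # pragma: no cover - defensive
                        raise AssertionError(family)
                    rows.append((animal, group, session, test, measure, value, censored))
    return pd.DataFrame(
        rows,
        columns=["animal", "group", "session", "test", "measure", "value", "censored"],
    )


@dataclass
class ProteomeSimConfig:
    """Configuration of a simulated spectral-count experiment.

    Counts for protein *p* in sample *s* are Poisson with rate
    ``baseline_rate * library_factor[s] * effect(p, s)`` where the effect
    is ``fold_change`` (up) or ``1/fold_change`` (down) when *p* carries a
    planted effect and *s* belongs to an affected group, else 1.
    """

    n_proteins: int = 200
    n_samples_per_group: int = 3
    baseline_rate: float = 10.0
    frac_de: float = 0.165
    fold_change: float = 4.0
    #: fraction of DE proteins that are down-regulated in affected groups
    frac_down: float = 7.0 / 33.0
    #: per-sample sequencing-depth-like factor, drawn log-uniform
    library_size_variation: tuple[float, float] = (0.8, 1.25)
    groups: Sequence[str] = ("Cort/Veh", "Flx-NR", "Flx-NR-ECS")
    #: groups in which planted effects are expressed
    affected_groups: Sequence[str] = ("Flx-NR-ECS",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_samples_per_group < 1:
            raise SchemaError("n_proteins and n_samples_per_group must be positive")
        if not 0.0 <= self.frac_de <= 1.0:
            raise SchemaError("frac_de must be in [0, 1]")
        if not 0.0 <= self.frac_down <= 1.0:
            raise SchemaError("frac_down must be in [0, 1]")
        if self.baseline_rate <= 0 or self.fold_change <= 0:
            raise SchemaError("baseline_rate and fold_change must be positive")
        lo, hi = self.library_size_variation
        if not 0 < lo <= hi:
            raise SchemaError("library_size_variation must satisfy 0 < lo <= hi")
        unknown = set(self.affected_groups) - set(self.groups)
        if unknown:
            raise SchemaError(f"affected_groups not in groups: {sorted(unknown)}")


def simulate_spectral_counts(
    config: ProteomeSimConfig,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Return ``(counts, sample_groups, truth)``.

    ``counts`` is an integer proteins x samples DataFrame,
    ``sample_groups`` maps sample id -> group label, and ``truth`` marks
    per protein whether an effect was planted and its direction
    (``up`` / ``down`` / ``none``) together with the rate multiplier.
    """
    rng = np.random.default_rng(config.seed)
    proteins = [f"P{i:04d}" for i in range(config.n_proteins)]
    samples, labels = [], []
    for g in config.groups:
        for j in range(config.n_samples_per_group):
            samples.append(f"{g.replace('/', '-')}_s{j + 1}")
            labels.append(g)
    sample_groups = pd.Series(labels, index=samples, name="group")

    n_de = int(round(config.frac_de * config.n_proteins))
    n_down = int(round(config.frac_down * n_de))
    de_idx = rng.choice(config.n_proteins, size=n_de, replace=False)
    down_idx = set(de_idx[:n_down])
    direction = np.full(config.n_proteins, "none", dtype=object)
    multiplier = np.ones(config.n_proteins)
    for idx in de_idx:
        if idx in down_idx:
            direction[idx] = "down"
            multiplier[idx] = 1.0 / config.fold_change
        else:
            direction[idx] = "up"
            multiplier[idx] = config.fold_change

    lo, hi = config.library_size_variation
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(samples)))
    affected = np.array([g in set(config.affected_groups) for g in labels])

    rate = np.outer(np.full(config.n_proteins, config.baseline_rate), lib)
    rate[:, affected] *= multiplier[:, None]
    counts = rng.poisson(rate)

    counts_df = pd.DataFrame(counts, index=proteins, columns=samples)
    truth = pd.DataFrame(
        {
            "protein": proteins,
            "is_de": direction != "none",
            "direction": direction,
            "rate_multiplier": multiplier,
        }
    ).set_index("protein")
    return counts_df, sample_groups, truth


def simulate_psm_table(
    n_proteins: int,
    ambiguity_spec: Mapping[str, Sequence[str]] | None = None,
    seed: int = 0,
    n_samples: int = 3,
    peptides_per_protein: int = 3,
    mean_spectra: float = 5.0,
) -> pd.DataFrame:
    """Generate a long-format peptide identification table.

    ``ambiguity_spec`` maps peptide id -> list of protein accessions
    sharing that peptide, letting tests plant exact shared-peptide
    structure for the grouping stage.  Proteins not covered by the spec
    receive ``peptides_per_protein`` specific peptides each.  E-values
    are drawn log-uniform over [1e-6, 0.1] so both sides of the 0.01
    identification threshold occur.

    Columns: ``peptide, evalue, proteins`` (semicolon-joined),
    ``sample, spectra``.
    """
    rng = np.random.default_rng(seed)
    ambiguity_spec = dict(ambiguity_spec or {})
    accessions = [f"PROT{i:03d}" for i in range(n_proteins)]
    known = set(accessions)
    mapping: dict[str, tuple[str, ...]] = {}
    for pep, prots in ambiguity_spec.items():
        prots = tuple(dict.fromkeys(prots))
        if not prots:
            raise SchemaError(f"ambiguity_spec peptide {pep!r} maps to no protein")
        missing = set(prots) - known
        if missing:
            raise SchemaError(
                f"ambiguity_spec peptide {pep!r} maps to unknown proteins {sorted(missing)}"
            )
        if pep in mapping:
            raise SchemaError(f"duplicate peptide id in ambiguity_spec: {pep!r}")
        mapping[pep] = prots
    covered = {p for prots in mapping.values() for p in prots}
    for acc in accessions:
        if acc in covered:
            continue
        for k in range(peptides_per_protein):
            mapping[f"pep_{acc}_{k}"] = (acc,)

    samples = [f"s{j + 1}" for j in range(n_samples)]
    rows = []
    for pep in sorted(mapping):
        evalue = float(10 ** rng.uniform(-6, -1))
        for s in samples:
            spectra = int(rng.poisson(mean_spectra))
            rows.append((pep, evalue, ";".join(mapping[pep]), s, spectra))
    return pd.DataFrame(rows, columns=["peptide", "evalue", "proteins", "sample", "spectra"])
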