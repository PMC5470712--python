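"""Synthetic choice-set generator with known ground truth.

Generates datasets with exactly the statistical structure the inference
assumes: individual-level utility coefficients drawn from normal
population-level distributions per stage, covariate triples with
configurable marginals and within-set correlation (locations 50 m apart
share habitat, which appears here as correlation, not geometry), and
choices drawn from the same conditional-logit likelihood the fitting code
evaluates.

Coefficients act on the pooled z-score scale of the emitted dataset: all
locations are generated first, covariates are standardized by the pooled
mean/SD, and choices are then simulated from utilities on that scale.  The
ground truth recorded in :class:`SimTruth` is therefore directly comparable
to a fit run with ``scheme="zscore"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .choice_data import (
    ALL_COVARIATES,
    ChoiceSet,
    Dataset,
    Location,
)
from .dcm_core import DEFAULT_SPEC, ModelSpec, build_design, choice_probabilities


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# ---------------------------------------------------------------------------
# Covariate marginals
# ---------------------------------------------------------------------------

#: Default marginal distributions, shaped to the field protocol's natural
#: ranges (canopy 0-100%, understory board scores 0-1, stem densities up to
#: ~2000/ha, litter 0-10 cm, edge 10-400 m).  Presets, not field estimates.
DEFAULT_MARGINALS: dict[str, tuple] = {
    "litter_depth": ("truncnorm", 3.0, 1.5, 0.0, 10.0),
    "understory_density": ("beta", 2.0, 2.0, 0.0, 1.0),
    "sapling_density": ("gamma", 2.0, 250.0, 0.0, 2000.0),
    "pole_density": ("gamma", 2.0, 150.0, 0.0, 2000.0),
    "saw_density": ("gamma", 2.0, 75.0, 0.0, 1000.0),
    "canopy_cover": ("beta", 8.0, 2.0, 0.0, 100.0),
    "edge_distance": ("gamma", 2.0, 80.0, 10.0, 400.0),
}


def _marginal_ppf(spec: tuple, u: np.ndarray) -> np.ndarray:
    """Quantile transform of uniforms for one covariate marginal.

    ``spec`` is ``(family, a, b, lo, hi)``; results are clipped into
    [lo, hi] so every emitted location satisfies its validity range.
    """
    family, a, b, lo, hi = spec
    if family == "truncnorm":
        if b <= 0:
            raise ConfigError("truncnorm scale must be > 0")
        x = stats.truncnorm.ppf(u, (lo - a) / b, (hi - a) / b, loc=a, scale=b)
    elif family == "beta":
        if a <= 0 or b <= 0:
            raise ConfigError("beta shapes must be > 0")
        x = lo + (hi - lo) * stats.beta.ppf(u, a, b)
    elif family == "gamma":
        if a <= 0 or b <= 0:
            raise ConfigError("gamma shape/scale must be > 0")
        x = lo + stats.gamma.ppf(u, a, scale=b)
    elif family == "uniform":
        x = lo + (hi - lo) * u
    else:
        raise ConfigError(f"unknown marginal family {family!r}")
    return np.clip(x, lo, hi)


# ---------------------------------------------------------------------------
# Configuration and truth
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Study design and ground-truth parameters for one synthetic dataset.

    ``population_means`` / ``population_sds`` map each stage name to a
    P-vector (model order of ``spec.labels``) of the population mean and SD
    of the individual-level coefficients, on the pooled z-score scale of
    the emitted dataset.  ``sets_per_individual`` is either a fixed count
    or an inclusive ``(lo, hi)`` range sampled per individual.
    """

    stages: tuple[str, ...] = ("early_dependent", "late_dependent")
    n_individuals_per_stage: int = 30
    sets_per_individual: int | tuple[int, int] = (3, 8)
    population_means: Mapping[str, Sequence[float]] | None = None
    population_sds: Mapping[str, Sequence[float]] | None = None
    marginals: Mapping[str, tuple] = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    rho: float = 0.5
    independence_day: int = 20
    species: str = "synthetic"
    spec: ModelSpec = field(default_factory=lambda: DEFAULT_SPEC)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.sets_per_individual, int):
            if self.sets_per_individual < 1:
                raise ConfigError("sets_per_individual must be >= 1")
        else:
            lo, hi = self.sets_per_individual
            if lo < 1 or hi < lo:
                raise ConfigError("sets_per_individual range must satisfy 1 <= lo <= hi")
        if not 0.0 <= self.rho < 1.0:
            raise ConfigError("within-set correlation rho must lie in [0, 1)")
        if self.n_individuals_per_stage < 1:
            raise ConfigError("n_individuals_per_stage must be >= 1")
        P = self.spec.n_params
        if self.population_means is None:
            self.population_means = {s: np.zeros(P) for s in self.stages}
        if self.population_sds is None:
            self.population_sds = {s: np.full(P, 0.3) for s in self.stages}
        for s in self.stages:
            mu = np.asarray(self.population_means[s], dtype=float)
            sd = np.asarray(self.population_sds[s], dtype=float)
            if mu.shape != (P,) or sd.shape != (P,):
                raise ConfigError(f"stage {s!r}: mean/SD vectors must have length {P}")
            if np.any(sd < 0):
                raise ConfigError(f"stage {s!r}: population SDs must be >= 0")
        unknown = set(self.marginals) - set(ALL_COVARIATES)
        if unknown:
            raise ConfigError(f"marginals for unknown covariates {sorted(unknown)}")


@dataclass
class SimTruth:
    """Every latent quantity behind a synthetic dataset."""

    population_means: dict[str, list[float]]
    population_sds: dict[str, list[float]]
    individual_coefficients: dict[str, list[float]]  # "individual|stage" keys
    labels: tuple[str, ...]
    seed: int

    def coefficient(self, individual_id: str, stage: str) -> np.ndarray:
        return np.asarray(self.individual_coefficients[f"{individual_id}|{stage}"])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        d["labels"] = tuple(d["labels"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Sampling primitives
# ---------------------------------------------------------------------------


def simulate_covariates(cfg: SimConfig, rng: np.random.Generator) -> tuple[Location, Location, Location]:
    """Draw one within-set-correlated triple of locations.

    A Gaussian copula couples the three locations: for each covariate a
    shared set-level factor with loading sqrt(rho) plus independent noise
    gives equicorrelated normal scores, which the marginal quantile
    functions map onto the field scales.
    """
    raw = _raw_covariate_block(cfg, rng, n_sets=1)[0]
    locs = []
    for j in range(3):
        covs = {c: float(raw[j, k]) for k, c in enumerate(ALL_COVARIATES)}
        locs.append(Location(role="available", **covs))
    return tuple(locs)  # type: ignore[return-value]


def _raw_covariate_block(cfg: SimConfig, rng: np.random.Generator, n_sets: int) -> np.ndarray:
    """(n_sets, 3, 7) covariate draws on raw field scales."""
    out = np.empty((n_sets, 3, len(ALL_COVARIATES)))
    sq_rho = np.sqrt(cfg.rho)
    sq_com = np.sqrt(1.0 - cfg.rho)
    for k, c in enumerate(ALL_COVARIATES):
        shared = rng.standard_normal((n_sets, 1))
        noise = rng.standard_normal((n_sets, 3))
        z = sq_rho * shared + sq_com * noise
        u = stats.norm.cdf(z)
        # keep ppf away from exact 0/1
        u = np.clip(u, 1e-12, 1.0 - 1e-12)
        out[:, :, k] = _marginal_ppf(cfg.marginals[c], u)
    return out


def simulate_individual_coefficients(
    mu: np.ndarray, sd: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One individual's coefficient vector, componentwise Normal(mu, sd)."""
    mu = np.asarray(mu, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd < 0):
        raise ValueError("population SDs must be >= 0")
    return mu + sd * rng.standard_normal(mu.shape)


def simulate_choice(
    locations: Sequence[Location],
    beta: np.ndarray,
    rng: np.random.Generator,
    spec: ModelSpec = DEFAULT_SPEC,
) -> int:
    """Draw the used index with probability softmax(utility).

    Uses the same design construction and softmax as the inference code, so
    the generator's implied likelihood is the fitted likelihood by
    construction.
    """
    dummy = _DummySet(tuple(locations))
    p = choice_probabilities(build_design(dummy, spec), beta)
    return int(rng.choice(3, p=p))


class _DummySet:
    """Duck-typed stand-in so build_design can expand bare location triples."""

    def __init__(self, locations):
        self.locations = locations
        self.set_id = "<unsaved>"


# ---------------------------------------------------------------------------
# Full dataset generation
# ---------------------------------------------------------------------------


def _stage_days(stage: str, n: int, cfg: SimConfig, rng: np.random.Generator) -> list[int | None]:
    if stage == "nest":
        return [None] * n
    if stage == "early_dependent":
        return [int(d) for d in rng.integers(0, 8, n)]
    if stage == "late_dependent":
        return [int(d) for d in rng.integers(8, cfg.independence_day, n)]
    if stage == "independent":
        return [int(d) for d in rng.integers(cfg.independence_day, cfg.independence_day + 20, n)]
    raise ConfigError(f"unknown stage {stage!r}")


def generate_dataset(cfg: SimConfig) -> tuple[Dataset, SimTruth]:
    """Generate a full synthetic dataset plus its ground-truth ledger.

    Fully reproducible from ``cfg.seed``.  The emitted dataset carries
    covariates on raw field scales and passes every validation in
    :mod:`fledgechoice.choice_data`; the recorded coefficients act on the
    pooled z-score scale (see module docstring).
    """
    root = np.random.SeedSequence(cfg.seed)
    rng_cov, rng_beta, rng_choice, rng_misc = [
        np.random.default_rng(s) for s in root.spawn(4)
    ]
    P = cfg.spec.n_params

    # ---- plan individuals and their sets
    plan = []  # (individual_id, brood_id, stage, day)
    for stage in cfg.stages:
        for i in range(cfg.n_individuals_per_stage):
            ind = f"{stage[:4]}_{i:03d}"
            if isinstance(cfg.sets_per_individual, int):
                n_sets = cfg.sets_per_individual
            else:
                lo, hi = cfg.sets_per_individual
                n_sets = int(rng_misc.integers(lo, hi + 1))
            days = _stage_days(stage, n_sets, cfg, rng_misc)
            for day in days:
                plan.append((ind, f"brood_{ind}", stage, day))

    # ---- covariates for every set, then pooled standardization
    n_total = len(plan)
    raw = _raw_covariate_block(cfg, rng_cov, n_total)
    flat = raw.reshape(-1, len(ALL_COVARIATES))
    means = flat.mean(axis=0)
    sds = flat.std(axis=0, ddof=0)
    std = (raw - means) / sds

    # ---- individual coefficients
    truth_coef: dict[str, list[float]] = {}
    beta_of: dict[tuple[str, str], np.ndarray] = {}
    for stage in cfg.stages:
        mu = np.asarray(cfg.population_means[stage], dtype=float)
        sd = np.asarray(cfg.population_sds[stage], dtype=float)
        for i in range(cfg.n_individuals_per_stage):
            ind = f"{stage[:4]}_{i:03d}"
            b = simulate_individual_coefficients(mu, sd, rng_beta)
            beta_of[(ind, stage)] = b
            truth_coef[f"{ind}|{stage}"] = [float(x) for x in b]

    # ---- choices on the standardized scale; assemble ChoiceSets
    sets = []
    for s_idx, (ind, brood, stage, day) in enumerate(plan):
        beta = beta_of[(ind, stage)]
        std_locs = tuple(
            Location.__new__(Location) for _ in range(3)
        )
        for j, loc in enumerate(std_locs):
            for k, c in enumerate(ALL_COVARIATES):
                object.__setattr__(loc, c, float(std[s_idx, j, k]))
            object.__setattr__(loc, "role", "available")
        used = simulate_choice(std_locs, beta, rng_choice, cfg.spec)

        # emitted locations carry raw field-scale values; used position is
        # randomized so position never leaks into downstream code
        order = rng_choice.permutation(3)
        locs = []
        used_index = 0
        for new_j, old_j in enumerate(order):
            role = "used" if old_j == used else "available"
            if role == "used":
                used_index = new_j
            covs = {c: float(raw[s_idx, old_j, k]) for k, c in enumerate(ALL_COVARIATES)}
            locs.append(Location(role=role, **covs))
        sets.append(
            ChoiceSet(
                set_id=f"set_{s_idx:05d}",
                species=cfg.species,
                individual_id=ind,
                brood_id=brood,
                stage=stage,
                day_postfledge=day,
                locations=tuple(locs),  # type: ignore[arg-type]
                used_index=used_index,
            )
        )

    grouping = {s: i for i, s in enumerate(cfg.stages)}
    dataset = Dataset(sets=sets, species=cfg.species, stage_grouping=grouping)
    truth = SimTruth(
        population_means={s: [float(x) for x in np.asarray(cfg.population_means[s])] for s in cfg.stages},
        population_sds={s: [float(x) for x in np.asarray(cfg.population_sds[s])] for s in cfg.stages},
        individual_coefficients=truth_coef,
        labels=cfg.spec.labels,
        seed=cfg.seed,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# Study-shaped presets
# ---------------------------------------------------------------------------


def _vec(spec: ModelSpec, **entries: float) -> np.ndarray:
    """P-vector with named nonzero entries (model-order labels)."""
    v = np.zeros(spec.n_params)
    labels = list(spec.labels)
    for name, value in entries.items():
        key = name.replace("__x__", ":")
        v[labels.index(key)] = value
    return v


def flycatcher_preset(seed: int = 0) -> tuple[SimConfig, SimConfig]:
    """Nest + juvenile configs shaped like the flycatcher field study.

    Set counts mirror the field design (170 nest sets; three juvenile
    stages totalling ~420 sets across ~39 birds).  Nonzero population means
    follow the headline estimates of that study on the standardized scale
    (e.g. canopy-cover selection ratio 2.19 at the nest -> beta = ln 2.19);
    coefficients the study did not highlight are set to zero.  SDs default
    to 0.5, a moderate level of individual heterogeneity.
    """
    spec = DEFAULT_SPEC
    nest = SimConfig(
        stages=("nest",),
        n_individuals_per_stage=170,
        sets_per_individual=1,
        population_means={"nest": _vec(spec, canopy_cover=np.log(2.19),
                                       understory_density=np.log(0.79))},
        population_sds={"nest": np.zeros(spec.n_params)},
        species="flycatcher",
        seed=seed,
    )
    juvenile = SimConfig(
        stages=("early_dependent", "late_dependent", "independent"),
        n_individuals_per_stage=13,
        sets_per_individual=(6, 16),
        population_means={
            "early_dependent": _vec(spec, canopy_cover=np.log(1.37)),
            "late_dependent": _vec(spec, canopy_cover=np.log(1.6),
                                   understory_density__x__edge_distance=0.45),
            "independent": _vec(spec, canopy_cover=np.log(1.5),
                                understory_density=np.log(1.88)),
        },
        population_sds={s: np.full(spec.n_params, 0.5)
                        for s in ("early_dependent", "late_dependent", "independent")},
        species="flycatcher",
        seed=seed + 1,
    )
    return nest, juvenile


def ovenbird_preset(seed: int = 0) -> tuple[SimConfig, SimConfig]:
    """Nest + juvenile configs shaped like the ovenbird field study.

    53 nest sets; juveniles in two pooled model stages (early dependent vs
    late dependent & independent, the pooling the converging field model
    used), ~500 sets from ~42 birds.  Headline truth values: understory
    effect 0.25 early vs 1.16 late, understory-by-edge interaction -0.32
    early vs 0.41 late, late litter-depth ratio 0.82, nest understory
    ratio 1.37.
    """
    spec = DEFAULT_SPEC
    nest = SimConfig(
        stages=("nest",),
        n_individuals_per_stage=53,
        sets_per_individual=1,
        population_means={"nest": _vec(spec, understory_density=np.log(1.37),
                                       litter_depth=0.8)},
        population_sds={"nest": np.zeros(spec.n_params)},
        species="ovenbird",
        seed=seed,
    )
    juvenile = SimConfig(
        stages=("early_dependent", "late_dependent"),
        n_individuals_per_stage=21,
        sets_per_individual=(6, 18),
        population_means={
            "early_dependent": _vec(spec, understory_density=0.25,
                                    understory_density__x__edge_distance=-0.32),
            "late_dependent": _vec(spec, understory_density=1.16,
                                   understory_density__x__edge_distance=0.41,
                                   litter_depth=np.log(0.82),
                                   sapling_density=0.35),
        },
        population_sds={s: np.full(spec.n_params, 0.5)
                        for s in ("early_dependent", "late_dependent")},
        species="ovenbird",
        seed=seed + 1,
    )
    return nest, juvenile
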