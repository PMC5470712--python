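import numpy as np
import pandas as pd
import pytest

from fledgechoice.choice_data import (
    ALL_COVARIATES,
    ChoiceSet,
    Dataset,
    Location,
    standardize_covariates,
)
from fledgechoice.inference import MCMCSettings, fit_postfledging
from fledgechoice.synthetic_data import (
    SimConfig,
    _raw_covariate_block,
    generate_dataset,
    simulate_choice,
)


def make_location(role="available", rng=None, **overrides):
    """A valid location with plausible field values, optionally overridden."""
    rng = rng or np.random.default_rng(0)
    vals = {
        "litter_depth": float(rng.uniform(0.5, 6)),
        "understory_density": float(rng.uniform(0.05, 0.95)),
        "sapling_density": float(rng.uniform(50, 1200)),
        "pole_density": float(rng.uniform(20, 700)),
        "saw_density": float(rng.uniform(10, 350)),
        "canopy_cover": float(rng.uniform(30, 100)),
        "edge_distance": float(rng.uniform(10, 380)),
    }
    vals.update(overrides)
    return Location(role=role, **vals)


def make_choice_set(set_id="s0", species="synthetic", individual="i0",
                    brood=None, stage="nest", day=None, used_index=0, rng=None):
    locs = tuple(
        make_location(role="used" if j == used_index else "available", rng=rng)
        for j in range(3)
    )
    return ChoiceSet(
        set_id=set_id, species=species, individual_id=individual,
        brood_id=brood or individual, stage=stage, day_postfledge=day,
        locations=locs, used_index=used_index,
    )


def build_custom_dataset(individual_betas, sets_per_individual, stage="early_dependent",
                         species="synthetic", rho=0.5, seed=0):
    """Synthetic dataset with exact per-individual coefficient vectors.

    Mirrors the package generator's construction — covariates drawn raw,
    choices simulated on the pooled z-score scale — but with caller-fixed
    individual coefficients, for shrinkage/degeneracy experiments.
    Returns the raw-scale Dataset (standardize before fitting).
    """
    cfg = SimConfig(stages=(stage,), n_individuals_per_stage=1, rho=rho, seed=seed)
    rng = np.random.default_rng(seed)
    plan = [(ind, n) for ind, n in sets_per_individual.items()]
    n_total = sum(n for _, n in plan)
    raw = _raw_covariate_block(cfg, rng, n_total)
    flat = raw.reshape(-1, len(ALL_COVARIATES))
    means, sds = flat.mean(axis=0), flat.std(axis=0)
    std = (raw - means) / sds

    sets, s_idx = [], 0
    for ind, n in plan:
        beta = np.asarray(individual_betas[ind], dtype=float)
        for _ in range(n):
            std_locs = []
            for j in range(3):
                loc = object.__new__(Location)
                for k, c in enumerate(ALL_COVARIATES):
                    object.__setattr__(loc, c, float(std[s_idx, j, k]))
                object.__setattr__(loc, "role", "available")
                std_locs.append(loc)
            used = simulate_choice(std_locs, beta, rng)
            locs = tuple(
                Location(role="used" if j == used else "available",
                         **{c: float(raw[s_idx, j, k])
                            for k, c in enumerate(ALL_COVARIATES)})
                for j in range(3)
            )
            sets.append(ChoiceSet(
                set_id=f"s{s_idx:04d}", species=species, individual_id=ind,
                brood_id=f"b_{ind}", stage=stage, day_postfledge=3,
                locations=locs, used_index=used,
            ))
            s_idx += 1
    return Dataset(sets=sets, species=species)


@pytest.fixture(scope="session")
def two_stage_truth():
    """Moderate-effect population means for a 2-stage hierarchical preset."""
    return {
        "early_dependent": np.r_[0.3, -0.2, 0.1, 0.0, 0.0, 0.4, 0.1, np.zeros(6)],
        "late_dependent": np.r_[-0.1, 0.5, 0.0, 0.0, 0.2, 0.3, 0.0, np.zeros(6)],
    }


@pytest.fixture(scope="session")
def hier_fit(two_stage_truth):
    """One medium hierarchical fit shared by summary-level tests.

    20 individuals per stage x 8 sets keeps it quick; the fit itself is
    validated elsewhere, here it provides realistic labelled draws.
    """
    cfg = SimConfig(
        stages=("early_dependent", "late_dependent"),
        n_individuals_per_stage=20,
        sets_per_individual=8,
        population_means=two_stage_truth,
        seed=7,
    )
    import warnings

    dataset, truth = generate_dataset(cfg)
    std, _ = standardize_covariates(dataset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = fit_postfledging(
            std, settings=MCMCSettings(n_iterations=1500, seed=5))
    return {"draws": draws, "dataset": std, "truth": truth}


@pytest.fixture()
def canonical_frame():
    """A 3-set, 9-row canonical table built programmatically."""
    rng = np.random.default_rng(42)
    rows = []
    for i in range(3):
        used = int(rng.integers(3))
        for j in range(3):
            loc = make_location(role="used" if j == used else "available", rng=rng)
            row = {
                "set_id": f"set_{i}",
                "species": "flycatcher",
                "individual_id": f"ind_{i % 2}",
                "brood_id": f"brood_{i % 2}",
                "stage": "early_dependent",
                "day_postfledge": 4,
                "role": loc.role,
            }
            row.update(loc.covariates())
            rows.append(row)
    return pd.DataFrame(rows)
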