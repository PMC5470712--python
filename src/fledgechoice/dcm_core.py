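"""Design matrices, choice probabilities, and the conditional-logit likelihood.

Each location in a choice set receives a utility V = x'beta, a linear score
in the six vegetation covariates, distance to nonforest edge, and the six
vegetation-by-edge interactions (13 coefficients in the default model).  The
probability that the bird picks location j out of its three options is the
softmax of the utilities within the set; only within-set covariate
differences are identified, so there is no intercept.  All likelihood
evaluations go through a max-shifted log-sum-exp — raw utilities are never
exponentiated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .choice_data import (
    EDGE_COVARIATE,
    VEGETATION_COVARIATES,
    ChoiceSet,
    Dataset,
)


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the utility.

    The default — six vegetation mains, the edge main effect, and each
    vegetation covariate crossed with edge — yields 13 coefficients in a
    fixed, documented order: mains, edge, then interactions, each in
    :data:`~fledgechoice.choice_data.VEGETATION_COVARIATES` order.
    """

    main_covariates: tuple[str, ...] = VEGETATION_COVARIATES
    edge_term: bool = True
    interactions: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.main_covariates) - set(VEGETATION_COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates {sorted(unknown)}")
        if self.interactions and not self.edge_term:
            raise ValueError("interactions require the edge term")

    @property
    def labels(self) -> tuple[str, ...]:
        cols = list(self.main_covariates)
        if self.edge_term:
            cols.append(EDGE_COVARIATE)
        if self.interactions:
            cols.extend(f"{c}:{EDGE_COVARIATE}" for c in self.main_covariates)
        return tuple(cols)

    @property
    def n_params(self) -> int:
        return len(self.labels)


DEFAULT_SPEC = ModelSpec()


def build_design(cs: ChoiceSet, spec: ModelSpec = DEFAULT_SPEC) -> np.ndarray:
    """3 x P design matrix for one choice set; row j expands location j."""
    rows = []
    for loc in cs.locations:
        vals = [getattr(loc, c) for c in spec.main_covariates]
        for c in spec.main_covariates + ((EDGE_COVARIATE,) if spec.edge_term else ()):
            v = getattr(loc, c)
            if not np.isfinite(v):
                raise ValueError(f"covariate {c!r} is not finite in set {cs.set_id!r}")
        edge = getattr(loc, EDGE_COVARIATE)
        if spec.edge_term:
            vals.append(edge)
        if spec.interactions:
            vals.extend(getattr(loc, c) * edge for c in spec.main_covariates)
        rows.append(vals)
    return np.asarray(rows, dtype=float)


def stack_design(
    dataset: Dataset, spec: ModelSpec = DEFAULT_SPEC
) -> tuple[np.ndarray, np.ndarray]:
    """Stack all sets into (n_sets, 3, P) plus the used indices (n_sets,)."""
    if not dataset.sets:
        return (np.zeros((0, 3, spec.n_params)), np.zeros(0, dtype=int))
    X = np.stack([build_design(cs, spec) for cs in dataset.sets])
    used = np.array([cs.used_index for cs in dataset.sets], dtype=int)
    return X, used


def _check_utilities(V: np.ndarray) -> None:
    if not np.all(np.isfinite(V)):
        raise ValueError("non-finite utility encountered")


def choice_probabilities(D: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Softmax of the three utilities V = D @ beta; sums to 1 to 1e-12."""
    V = np.asarray(D, dtype=float) @ np.asarray(beta, dtype=float)
    _check_utilities(V)
    shifted = V - V.max()
    w = np.exp(shifted)
    return w / w.sum()


def set_loglik(D: np.ndarray, beta: np.ndarray, used_index: int) -> float:
    """Log-probability of the used alternative, via max-shifted log-sum-exp."""
    if used_index not in (0, 1, 2):
        raise ValueError("used_index must be in {0, 1, 2}")
    V = np.asarray(D, dtype=float) @ np.asarray(beta, dtype=float)
    _check_utilities(V)
    m = V.max()
    return float(V[used_index] - m - np.log(np.exp(V - m).sum()))


def loglik_per_set(V: np.ndarray, used: np.ndarray) -> np.ndarray:
    """Vectorized set log-likelihoods from a (n, 3) utility array."""
    m = V.max(axis=1)
    lse = m + np.log(np.exp(V - m[:, None]).sum(axis=1))
    return V[np.arange(V.shape[0]), used] - lse


def data_loglik(
    dataset: Dataset,
    coefficients: np.ndarray | Mapping[str, np.ndarray],
    spec: ModelSpec = DEFAULT_SPEC,
) -> float:
    """Sum of set log-likelihoods over all choice sets.

    ``coefficients`` is either one shared P-vector or a mapping from
    ``set_id`` to the coefficient vector governing that set (the individual
    level of the hierarchical model).
    """
    total = 0.0
    for cs in dataset.sets:
        if isinstance(coefficients, Mapping):
            try:
                beta = coefficients[cs.set_id]
            except KeyError:
                raise KeyError(f"no coefficient vector assigned to set {cs.set_id!r}")
        else:
            beta = coefficients
        total += set_loglik(build_design(cs, spec), beta, cs.used_index)
    return total
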