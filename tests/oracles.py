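"""Independent reference implementations used only to check the package.

Everything here is deliberately written without the package's numerics:
plain Python loops, ``math``/``numpy.longdouble`` arithmetic, direct
formula transcriptions.  These stay independent of the code paths they
validate.
"""

from __future__ import annotations

import math

import numpy as np

from fledgechoice.choice_data import EDGE_COVARIATE


def naive_set_loglik(locations, beta, used_index, main_covariates, edge_term, interactions):
    """Brute-force conditional-logit log-likelihood for one choice set.

    Builds each location's covariate expansion with plain loops and
    normalizes raw exponentiated utilities in extended precision.
    """
    utilities = []
    for loc in locations:
        row = [getattr(loc, c) for c in main_covariates]
        if edge_term:
            row.append(getattr(loc, EDGE_COVARIATE))
        if interactions:
            edge = getattr(loc, EDGE_COVARIATE)
            row.extend(getattr(loc, c) * edge for c in main_covariates)
        utilities.append(sum(np.longdouble(x) * np.longdouble(b)
                             for x, b in zip(row, beta)))
    exps = [np.exp(u) for u in utilities]
    total = exps[0] + exps[1] + exps[2]
    return float(np.log(exps[used_index] / total))


def naive_data_loglik(dataset, beta, main_covariates, edge_term=True, interactions=True):
    """Sum of naive per-set log-likelihoods under one shared coefficient vector."""
    return sum(
        naive_set_loglik(cs.locations, beta, cs.used_index,
                         main_covariates, edge_term, interactions)
        for cs in dataset.sets
    )


def estrella_r2_reference(loglik_hat: float, n: int, J: int) -> float:
    """Direct extended-precision transcription of the pseudo-R2 formula."""
    L0 = np.longdouble(n) * np.log(np.longdouble(1.0) / J)
    ratio = np.longdouble(loglik_hat) / L0
    exponent = -(np.longdouble(2.0) / n) * L0
    return float(1.0 - ratio ** exponent)


def grid_posterior_mean_sd(loglik_fn, prior_sd: float, lo: float, hi: float,
                           n_grid: int = 20001) -> tuple[float, float]:
    """Dense-grid posterior mean/SD for a 1-parameter model.

    ``loglik_fn`` maps a scalar coefficient to the data log-likelihood;
    the prior is Normal(0, prior_sd^2).  Trapezoidal integration on a
    uniform grid.
    """
    grid = np.linspace(lo, hi, n_grid)
    logpost = np.array([loglik_fn(b) for b in grid])
    logpost = logpost - 0.5 * (grid / prior_sd) ** 2
    logpost -= logpost.max()
    w = np.exp(logpost)
    Z = np.trapezoid(w, grid)
    mean = np.trapezoid(w * grid, grid) / Z
    var = np.trapezoid(w * (grid - mean) ** 2, grid) / Z
    return float(mean), float(math.sqrt(var))
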