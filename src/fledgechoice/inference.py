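"""Bayesian fitting of the nest-site and hierarchical postfledging models.

Two models share one conditional-logit likelihood:

* **Nest model** — all nest choice sets share a single coefficient vector
  beta with vague Normal(0, precision 0.01) priors (variance 100).
* **Postfledging model** — each individual-by-stage combination carries its
  own coefficient vector beta_{i,s}, drawn from stage-level normal
  population distributions, beta_{i,s,k} ~ Normal(mu_{s,k}, sigma_{s,k}).
  Hyperpriors: mu_{s,k} ~ Normal(0, precision 0.01); each precision
  tau_{s,k} = 1/sigma_{s,k}^2 ~ Gamma(1, 0.0001) (equivalently an
  inverse-gamma on the variance).  Individuals with few choice sets shrink
  toward the population mean.

The sampler is an adaptive random-walk Metropolis-within-Gibbs:
coefficient components are updated by componentwise random-walk proposals
(independent across individuals given the hyperparameters), while mu and
tau have conjugate Gibbs updates.  Two interweaved moves per stage and
component keep the hierarchy mobile where centered Gibbs samplers stall:
a joint location shift of mu and all its individual coefficients, and a
non-centered rescaling of sigma that drags the individual offsets with it
(the funnel-escaping move of interweaving/ASIS samplers).  Proposal
scales adapt toward a 0.44 componentwise acceptance rate during burn-in
only, so the post-burn-in chain is a valid fixed-kernel MCMC.  The inner
loops are compiled with numba.

Convergence is judged by the split-chain Gelman-Rubin statistic with the
conventional 1.1 threshold; non-convergence is a reported state, never an
exception.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from numba import njit

from .choice_data import Dataset, JUVENILE_STAGES
from .dcm_core import DEFAULT_SPEC, ModelSpec, stack_design


@dataclass(frozen=True)
class PriorSpec:
    """Priors for both models, in precision parameterization.

    ``fixed_effect_precision`` applies to nest coefficients and to the
    population-mean hyperparameters (default precision 0.01, i.e. variance
    100 — a vague prior).  ``tau_shape``/``tau_rate`` parameterize the
    Gamma prior on each precision hyperparameter tau = 1/sigma^2.
    """

    fixed_effect_mean: float = 0.0
    fixed_effect_precision: float = 0.01
    tau_shape: float = 1.0
    tau_rate: float = 1.0e-4

    def __post_init__(self) -> None:
        if self.fixed_effect_precision <= 0:
            raise ValueError("fixed_effect_precision must be > 0")
        if self.tau_shape <= 0 or self.tau_rate <= 0:
            raise ValueError("tau_shape and tau_rate must be > 0")


@dataclass(frozen=True)
class MCMCSettings:
    n_chains: int = 3
    n_iterations: int = 4000
    n_burnin: int | None = None  # default: half of n_iterations
    thin: int = 1
    seed: int = 0
    adapt_window: int = 50
    init_scale: float = 0.5  # SD of overdispersed chain initializations
    prior_only: bool = False

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        burn = self.burnin
        if not 0 <= burn < self.n_iterations:
            raise ValueError("burn-in must satisfy 0 <= burnin < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def burnin(self) -> int:
        return self.n_iterations // 2 if self.n_burnin is None else self.n_burnin


@dataclass
class PosteriorDraws:
    """chains x draws x parameters array with a labelled parameter registry.

    ``kinds`` maps each parameter name to one of ``beta`` (nest shared
    coefficients), ``mu`` / ``sigma`` (population-level hyperparameters),
    or ``beta_i`` (individual-level coefficients).
    """

    array: np.ndarray
    names: list[str]
    kinds: dict[str, str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.array.ndim != 3 or self.array.shape[2] != len(self.names):
            raise ValueError("array must be chains x draws x len(names)")
        if len(set(self.names)) != len(self.names):
            raise ValueError("parameter names must be unique")

    @property
    def n_chains(self) -> int:
        return self.array.shape[0]

    @property
    def n_draws(self) -> int:
        return self.array.shape[1]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def get(self, name: str) -> np.ndarray:
        """(chains, draws) array for one parameter."""
        return self.array[:, :, self.index(name)]

    def pooled(self, name: str) -> np.ndarray:
        """All post-burn-in draws of one parameter, chains concatenated."""
        return self.get(name).reshape(-1)

    def select(self, kind: str | None = None, prefix: str | None = None) -> list[str]:
        out = []
        for n in self.names:
            if kind is not None and self.kinds[n] != kind:
                continue
            if prefix is not None and not n.startswith(prefix):
                continue
            out.append(n)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format draws table (chain, draw, one column per parameter)."""
        frames = []
        for c in range(self.n_chains):
            df = pd.DataFrame(self.array[c], columns=self.names)
            df.insert(0, "draw", np.arange(self.n_draws))
            df.insert(0, "chain", c)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


@dataclass
class ConvergenceReport:
    rhat: dict[str, float]
    threshold: float = 1.1

    @property
    def all_converged(self) -> bool:
        return all(r <= self.threshold for r in self.rhat.values())

    @property
    def worst(self) -> tuple[str, float]:
        name = max(self.rhat, key=self.rhat.get)  # type: ignore[arg-type]
        return name, self.rhat[name]


def split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one parameter.

    Each chain is split in half, giving 2m sequences; Rhat is the usual
    sqrt of (weighted within+between variance) / (within variance).  The
    split variant also flags chains that are stationary but drifting.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (chains >= 2, draws) array")
    n = x.shape[1] // 2
    if n < 5:
        raise ValueError("need at least 10 retained draws per chain")
    halves = np.concatenate([x[:, :n], x[:, n: 2 * n]], axis=0)
    means = halves.mean(axis=1)
    variances = halves.var(axis=1, ddof=1)
    W = variances.mean()
    B = n * means.var(ddof=1)
    if W == 0.0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def gelman_rubin(draws: PosteriorDraws, threshold: float = 1.1) -> ConvergenceReport:
    """Split-chain Gelman-Rubin diagnostic for every monitored parameter."""
    if draws.n_chains < 2:
        raise ValueError("convergence diagnostics need >= 2 chains")
    rhat = {name: split_rhat(draws.get(name)) for name in draws.names}
    return ConvergenceReport(rhat=rhat, threshold=threshold)


# ---------------------------------------------------------------------------
# Core sampler (numba-compiled)
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _ll3(v0: float, v1: float, v2: float, used: int) -> float:
    """log softmax probability of the used alternative among three."""
    m = v0
    if v1 > m:
        m = v1
    if v2 > m:
        m = v2
    lse = m + np.log(np.exp(v0 - m) + np.exp(v1 - m) + np.exp(v2 - m))
    if used == 0:
        return v0 - lse
    if used == 1:
        return v1 - lse
    return v2 - lse


@njit(cache=True)
def _chain_core(
    X, used, block_of_set, stage_of_block, stage_of_set,
    hierarchical, prior_only,
    m0, p0, tau_shape, tau_rate,
    n_iterations, burnin, thin, adapt_window,
    beta, mu, tau,
    out_beta, out_mu, out_sigma,
    rng,
):
    n_sets = X.shape[0]
    P = X.shape[2]
    B = beta.shape[0]
    S = mu.shape[0]

    n_blocks_per_stage = np.zeros(S)
    for b in range(B):
        if hierarchical:
            n_blocks_per_stage[stage_of_block[b]] += 1.0

    # likelihood cache
    V = np.zeros((n_sets, 3))
    cur_ll = np.zeros(n_sets)
    for s in range(n_sets):
        b = block_of_set[s]
        for j in range(3):
            v = 0.0
            for p in range(P):
                v += X[s, j, p] * beta[b, p]
            V[s, j] = v
        cur_ll[s] = _ll3(V[s, 0], V[s, 1], V[s, 2], used[s])

    use_lik = (n_sets > 0) and (not prior_only)

    step = np.full((B, P), 0.2)
    acc = np.zeros((B, P))
    shift_step = np.full((S, P), 0.2)
    shift_acc = np.zeros((S, P))
    scale_step = np.full((S, P), 0.5)
    scale_acc = np.zeros((S, P))
    batch = 0

    new_ll = np.zeros(n_sets)
    delta_b = np.zeros(B)
    dll_b = np.zeros(B)
    accept_b = np.zeros(B, dtype=np.bool_)
    delta_s = np.zeros(S)
    dll_s = np.zeros(S)
    accept_s = np.zeros(S, dtype=np.bool_)
    dbeta = np.zeros(B)

    gamma_shape = tau_shape + 0.5 * n_blocks_per_stage  # fixed over iterations

    for it in range(n_iterations):
        # ---- componentwise random-walk update of every block's beta
        for k in range(P):
            for b in range(B):
                delta_b[b] = step[b, k] * rng.standard_normal()
                dll_b[b] = 0.0
            if use_lik:
                for s in range(n_sets):
                    b = block_of_set[s]
                    d = delta_b[b]
                    nl = _ll3(
                        V[s, 0] + X[s, 0, k] * d,
                        V[s, 1] + X[s, 1, k] * d,
                        V[s, 2] + X[s, 2, k] * d,
                        used[s],
                    )
                    new_ll[s] = nl
                    dll_b[b] += nl - cur_ll[s]
            for b in range(B):
                b_old = beta[b, k]
                b_new = b_old + delta_b[b]
                if hierarchical:
                    g = stage_of_block[b]
                    dp = -0.5 * tau[g, k] * (
                        (b_new - mu[g, k]) ** 2 - (b_old - mu[g, k]) ** 2
                    )
                else:
                    dp = -0.5 * p0 * ((b_new - m0) ** 2 - (b_old - m0) ** 2)
                if np.log(rng.random()) < dll_b[b] + dp:
                    accept_b[b] = True
                    beta[b, k] = b_new
                    acc[b, k] += 1.0
                else:
                    accept_b[b] = False
            if use_lik:
                for s in range(n_sets):
                    b = block_of_set[s]
                    if accept_b[b]:
                        d = delta_b[b]
                        V[s, 0] += X[s, 0, k] * d
                        V[s, 1] += X[s, 1, k] * d
                        V[s, 2] += X[s, 2, k] * d
                        cur_ll[s] = new_ll[s]

        if hierarchical:
            # ---- conjugate Gibbs updates of mu and tau
            for g in range(S):
                for k in range(P):
                    sum_b = 0.0
                    for b in range(B):
                        if stage_of_block[b] == g:
                            sum_b += beta[b, k]
                    prec = p0 + n_blocks_per_stage[g] * tau[g, k]
                    mean = (p0 * m0 + tau[g, k] * sum_b) / prec
                    mu[g, k] = mean + rng.standard_normal() / np.sqrt(prec)
            for g in range(S):
                for k in range(P):
                    ss = 0.0
                    for b in range(B):
                        if stage_of_block[b] == g:
                            ss += (beta[b, k] - mu[g, k]) ** 2
                    rate = tau_rate + 0.5 * ss
                    tau[g, k] = rng.gamma(gamma_shape[g], 1.0 / rate)

            # ---- interweaved moves per stage and component
            for k in range(P):
                # (a) joint location shift of mu and all its betas
                for g in range(S):
                    delta_s[g] = shift_step[g, k] * rng.standard_normal()
                    dll_s[g] = 0.0
                if use_lik:
                    for s in range(n_sets):
                        g = stage_of_set[s]
                        d = delta_s[g]
                        nl = _ll3(
                            V[s, 0] + X[s, 0, k] * d,
                            V[s, 1] + X[s, 1, k] * d,
                            V[s, 2] + X[s, 2, k] * d,
                            used[s],
                        )
                        new_ll[s] = nl
                        dll_s[g] += nl - cur_ll[s]
                for g in range(S):
                    mu_new = mu[g, k] + delta_s[g]
                    dp = -0.5 * p0 * ((mu_new - m0) ** 2 - (mu[g, k] - m0) ** 2)
                    if np.log(rng.random()) < dll_s[g] + dp:
                        accept_s[g] = True
                        mu[g, k] = mu_new
                        shift_acc[g, k] += 1.0
                    else:
                        accept_s[g] = False
                for b in range(B):
                    if accept_s[stage_of_block[b]]:
                        beta[b, k] += delta_s[stage_of_block[b]]
                if use_lik:
                    for s in range(n_sets):
                        g = stage_of_set[s]
                        if accept_s[g]:
                            d = delta_s[g]
                            V[s, 0] += X[s, 0, k] * d
                            V[s, 1] += X[s, 1, k] * d
                            V[s, 2] += X[s, 2, k] * d
                            cur_ll[s] = new_ll[s]

                # (c) wide non-centered sigma jump: fixed log-scale step to
                # cross the flat ridge the posterior has when individual
                # information is weak
                for g in range(S):
                    eps = 1.5 * rng.standard_normal()
                    delta_s[g] = np.exp(eps)
                    dll_s[g] = 0.0
                for b in range(B):
                    g = stage_of_block[b]
                    dbeta[b] = (delta_s[g] - 1.0) * (beta[b, k] - mu[g, k])
                if use_lik:
                    for s in range(n_sets):
                        b = block_of_set[s]
                        g = stage_of_set[s]
                        d = dbeta[b]
                        nl = _ll3(
                            V[s, 0] + X[s, 0, k] * d,
                            V[s, 1] + X[s, 1, k] * d,
                            V[s, 2] + X[s, 2, k] * d,
                            used[s],
                        )
                        new_ll[s] = nl
                        dll_s[g] += nl - cur_ll[s]
                for g in range(S):
                    fac = delta_s[g]
                    tau_new = tau[g, k] / (fac * fac)
                    dp = (tau_shape * (np.log(tau_new) - np.log(tau[g, k]))
                          - tau_rate * (tau_new - tau[g, k]))
                    if np.log(rng.random()) < dll_s[g] + dp:
                        accept_s[g] = True
                        tau[g, k] = tau_new
                    else:
                        accept_s[g] = False
                for b in range(B):
                    if accept_s[stage_of_block[b]]:
                        beta[b, k] += dbeta[b]
                if use_lik:
                    for s in range(n_sets):
                        g = stage_of_set[s]
                        if accept_s[g]:
                            d = dbeta[block_of_set[s]]
                            V[s, 0] += X[s, 0, k] * d
                            V[s, 1] += X[s, 1, k] * d
                            V[s, 2] += X[s, 2, k] * d
                            cur_ll[s] = new_ll[s]

                # (b) non-centered sigma rescaling (random walk on log sigma)
                for g in range(S):
                    eps = scale_step[g, k] * rng.standard_normal()
                    delta_s[g] = np.exp(eps)  # scale factor
                    dll_s[g] = 0.0
                for b in range(B):
                    g = stage_of_block[b]
                    dbeta[b] = (delta_s[g] - 1.0) * (beta[b, k] - mu[g, k])
                if use_lik:
                    for s in range(n_sets):
                        b = block_of_set[s]
                        g = stage_of_set[s]
                        d = dbeta[b]
                        nl = _ll3(
                            V[s, 0] + X[s, 0, k] * d,
                            V[s, 1] + X[s, 1, k] * d,
                            V[s, 2] + X[s, 2, k] * d,
                            used[s],
                        )
                        new_ll[s] = nl
                        dll_s[g] += nl - cur_ll[s]
                for g in range(S):
                    fac = delta_s[g]
                    tau_new = tau[g, k] / (fac * fac)
                    # prior density of log sigma: shape*log(tau) - rate*tau
                    dp = (tau_shape * (np.log(tau_new) - np.log(tau[g, k]))
                          - tau_rate * (tau_new - tau[g, k]))
                    if np.log(rng.random()) < dll_s[g] + dp:
                        accept_s[g] = True
                        tau[g, k] = tau_new
                        scale_acc[g, k] += 1.0
                    else:
                        accept_s[g] = False
                for b in range(B):
                    if accept_s[stage_of_block[b]]:
                        beta[b, k] += dbeta[b]
                if use_lik:
                    for s in range(n_sets):
                        g = stage_of_set[s]
                        if accept_s[g]:
                            d = dbeta[block_of_set[s]]
                            V[s, 0] += X[s, 0, k] * d
                            V[s, 1] += X[s, 1, k] * d
                            V[s, 2] += X[s, 2, k] * d
                            cur_ll[s] = new_ll[s]

        # ---- proposal-scale adaptation, burn-in only
        if it < burnin and (it + 1) % adapt_window == 0:
            batch += 1
            gain = 1.0 / np.sqrt(batch)
            if gain > 0.25:
                gain = 0.25
            for b in range(B):
                for k in range(P):
                    if acc[b, k] / adapt_window > 0.44:
                        step[b, k] *= np.exp(gain)
                    else:
                        step[b, k] *= np.exp(-gain)
                    acc[b, k] = 0.0
            if hierarchical:
                for g in range(S):
                    for k in range(P):
                        if shift_acc[g, k] / adapt_window > 0.44:
                            shift_step[g, k] *= np.exp(gain)
                        else:
                            shift_step[g, k] *= np.exp(-gain)
                        shift_acc[g, k] = 0.0
                        if scale_acc[g, k] / adapt_window > 0.44:
                            scale_step[g, k] *= np.exp(gain)
                        else:
                            scale_step[g, k] *= np.exp(-gain)
                        scale_acc[g, k] = 0.0

        # ---- storage
        if it >= burnin and (it - burnin) % thin == 0:
            j = (it - burnin) // thin
            for b in range(B):
                for k in range(P):
                    out_beta[j, b, k] = beta[b, k]
            if hierarchical:
                for g in range(S):
                    for k in range(P):
                        out_mu[j, g, k] = mu[g, k]
                        out_sigma[j, g, k] = 1.0 / np.sqrt(tau[g, k])


def _run_chain(
    X: np.ndarray,                # (n_sets, 3, P)
    used: np.ndarray,             # (n_sets,)
    block_of_set: np.ndarray,     # (n_sets,) int in [0, B)
    stage_of_block: np.ndarray,   # (B,) int in [0, S)
    hierarchical: bool,
    priors: PriorSpec,
    settings: MCMCSettings,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """One MCMC chain; returns stacked post-burn-in draws."""
    n_sets, _, P = X.shape
    B = stage_of_block.shape[0]
    S = int(stage_of_block.max()) + 1 if hierarchical else 1
    burnin, thin = settings.burnin, settings.thin
    n_store = (settings.n_iterations - burnin + thin - 1) // thin

    # overdispersed initialization
    beta = settings.init_scale * rng.standard_normal((B, P))
    mu = settings.init_scale * rng.standard_normal((S, P)) if hierarchical \
        else np.zeros((S, P))
    tau = np.ones((S, P))

    out_beta = np.empty((n_store, B, P))
    out_mu = np.empty((n_store, S, P))
    out_sigma = np.empty((n_store, S, P))

    _chain_core(
        np.ascontiguousarray(X, dtype=np.float64),
        np.ascontiguousarray(used, dtype=np.int64),
        np.ascontiguousarray(block_of_set, dtype=np.int64),
        np.ascontiguousarray(stage_of_block, dtype=np.int64),
        np.ascontiguousarray(stage_of_block[block_of_set] if n_sets else
                             np.zeros(0, dtype=np.int64), dtype=np.int64),
        hierarchical, settings.prior_only,
        priors.fixed_effect_mean, priors.fixed_effect_precision,
        priors.tau_shape, priors.tau_rate,
        settings.n_iterations, burnin, thin, settings.adapt_window,
        beta, mu, tau,
        out_beta, out_mu, out_sigma,
        rng,
    )
    out = {"beta": out_beta}
    if hierarchical:
        out["mu"] = out_mu
        out["sigma"] = out_sigma
    return out


def _finalize(
    chains: list[dict[str, np.ndarray]],
    names: list[str],
    kinds: dict[str, str],
    layout: list[tuple[str, int, int]],
    meta: dict,
) -> PosteriorDraws:
    """Assemble per-chain draw dicts into one labelled array."""
    mats = []
    for ch in chains:
        cols = [ch[group][:, b, k] for group, b, k in layout]
        mats.append(np.column_stack(cols))
    arr = np.stack(mats)
    draws = PosteriorDraws(array=arr, names=names, kinds=kinds, meta=meta)
    report = gelman_rubin(draws, threshold=meta.get("rhat_threshold", 1.1))
    draws.meta["rhat"] = report.rhat
    draws.meta["all_converged"] = report.all_converged
    if not report.all_converged:
        name, worst = report.worst
        warnings.warn(
            f"MCMC did not converge: Rhat={worst:.3f} for {name} "
            f"(threshold {report.threshold}); rerun with more iterations",
            stacklevel=2,
        )
    return draws


def fit_nest(
    dataset: Dataset,
    priors: PriorSpec = PriorSpec(),
    settings: MCMCSettings = MCMCSettings(),
    spec: ModelSpec = DEFAULT_SPEC,
) -> PosteriorDraws:
    """Posterior of the single shared coefficient vector for nest sets.

    All sets must have stage ``nest`` (an empty dataset is allowed and
    returns draws from the prior).  Coefficients carry independent
    Normal(mean 0, precision 0.01) priors.
    """
    if any(cs.stage != "nest" for cs in dataset.sets):
        raise ValueError("fit_nest expects only nest-stage choice sets")
    X, used = stack_design(dataset, spec)
    block = np.zeros(len(dataset.sets), dtype=int)
    stage_of_block = np.zeros(1, dtype=int)

    seeds = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    chains = [
        _run_chain(X, used, block, stage_of_block, False, priors, settings,
                   np.random.default_rng(s))
        for s in seeds
    ]
    names = list(spec.labels)
    kinds = {n: "beta" for n in names}
    layout = [("beta", 0, k) for k in range(spec.n_params)]
    meta = {
        "model": "nest",
        "species": dataset.species,
        "labels": spec.labels,
        "n_sets": len(dataset.sets),
        "settings": settings,
        "priors": priors,
    }
    return _finalize(chains, names, kinds, layout, meta)


def model_stage_names(grouping: Mapping[str, int]) -> list[str]:
    """Human-readable name per model-stage index, pooled labels joined by '+'."""
    by_index: dict[int, list[str]] = {}
    for label in sorted(grouping, key=lambda s: (grouping[s], JUVENILE_STAGES.index(s)
                                                 if s in JUVENILE_STAGES else -1)):
        by_index.setdefault(grouping[label], []).append(label)
    return ["+".join(by_index[i]) for i in sorted(by_index)]


def fit_postfledging(
    dataset: Dataset,
    grouping: Mapping[str, int] | None = None,
    priors: PriorSpec = PriorSpec(),
    settings: MCMCSettings = MCMCSettings(),
    spec: ModelSpec = DEFAULT_SPEC,
) -> PosteriorDraws:
    """Hierarchical posterior for juvenile choice sets.

    ``grouping`` maps stage labels to model-stage indices (defaults to the
    dataset's own grouping); mapping late_dependent and independent to the
    same index pools them under one population-level distribution.  Each
    individual-by-model-stage combination receives its own coefficient
    vector; all hyperparameters and individual vectors are monitored.
    """
    if not dataset.sets:
        raise ValueError("fit_postfledging needs at least one choice set")
    if any(cs.stage == "nest" for cs in dataset.sets):
        raise ValueError("fit_postfledging expects juvenile choice sets only")
    grouping = dict(grouping if grouping is not None else dataset.stage_grouping)
    for cs in dataset.sets:
        if cs.stage not in grouping:
            raise ValueError(f"stage {cs.stage!r} missing from grouping")
    # normalize model-stage indices to 0..S-1 preserving order
    used_indices = sorted({grouping[cs.stage] for cs in dataset.sets})
    if sorted(set(grouping.values())) != used_indices:
        raise ValueError("a configured model stage has zero choice sets")
    remap = {g: i for i, g in enumerate(used_indices)}
    grouping = {s: remap[g] for s, g in grouping.items()}
    stage_names = model_stage_names(grouping)

    blocks: dict[tuple[str, int], int] = {}
    block_of_set = np.empty(len(dataset.sets), dtype=int)
    for i, cs in enumerate(dataset.sets):
        key = (cs.individual_id, grouping[cs.stage])
        block_of_set[i] = blocks.setdefault(key, len(blocks))
    stage_of_block = np.empty(len(blocks), dtype=int)
    for (_, g), b in blocks.items():
        stage_of_block[b] = g

    X, used = stack_design(dataset, spec)
    seeds = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    chains = [
        _run_chain(X, used, block_of_set, stage_of_block, True, priors,
                   settings, np.random.default_rng(s))
        for s in seeds
    ]

    names: list[str] = []
    kinds: dict[str, str] = {}
    layout: list[tuple[str, int, int]] = []
    for g, sname in enumerate(stage_names):
        for k, lab in enumerate(spec.labels):
            names.append(f"mu[{sname}].{lab}")
            kinds[names[-1]] = "mu"
            layout.append(("mu", g, k))
    for g, sname in enumerate(stage_names):
        for k, lab in enumerate(spec.labels):
            names.append(f"sigma[{sname}].{lab}")
            kinds[names[-1]] = "sigma"
            layout.append(("sigma", g, k))
    for (ind, g), b in blocks.items():
        for k, lab in enumerate(spec.labels):
            names.append(f"beta[{ind}|{stage_names[g]}].{lab}")
            kinds[names[-1]] = "beta_i"
            layout.append(("beta", b, k))

    meta = {
        "model": "postfledging",
        "species": dataset.species,
        "labels": spec.labels,
        "stage_names": stage_names,
        "grouping": grouping,
        "blocks": {f"{ind}|{stage_names[g]}": b for (ind, g), b in blocks.items()},
        "n_sets": len(dataset.sets),
        "settings": settings,
        "priors": priors,
    }
    return _finalize(chains, names, kinds, layout, meta)
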