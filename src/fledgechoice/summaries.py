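"""Posterior summarization: coefficient tables, selection ratios,
Estrella's pseudo-R-squared, and relative-probability-of-use curves.

Summaries follow the reporting conventions of Bayesian discrete-choice
resource-selection analyses: for each coefficient the posterior mean, the
central 95% credible interval (CRI), and *f* — the proportion of the
posterior sharing the sign of the mean, a directional-confidence measure.
Selection ratios exp(beta) give the multiplicative change in relative
selection probability per one-unit covariate change; they are flagged
not-interpretable when the covariate's interaction with edge distance is
strongly supported (interaction f >= 0.90), since selection then depends
on more than one coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .choice_data import Dataset, EDGE_COVARIATE
from .dcm_core import DEFAULT_SPEC, ModelSpec, data_loglik
from .inference import PosteriorDraws

#: Interactions with f at or above this are "strongly supported" and make
#: the main effect's selection ratio not interpretable on its own.
INTERACTION_F_THRESHOLD = 0.90


@dataclass(frozen=True)
class CoefficientSummary:
    parameter: str
    mean: float
    cri_low: float
    cri_high: float
    f: float

    def __post_init__(self) -> None:
        if self.cri_low > self.cri_high:
            raise ValueError("CRI endpoints out of order")


@dataclass(frozen=True)
class SelectionRatio:
    covariate: str
    ratio: float
    ratio_cri: tuple[float, float]
    eligible: bool


@dataclass(frozen=True)
class FitStats:
    loglik_hat: float
    loglik_null: float
    n_sets: int
    estrella_r2: float


@dataclass(frozen=True)
class UseCurve:
    focal: str
    scenario: str  # none | near | far
    edge_value: float
    grid: np.ndarray
    mean: np.ndarray
    cri_low: np.ndarray
    cri_high: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.focal,
                "scenario": self.scenario,
                "x": self.grid,
                "mean": self.mean,
                "lo": self.cri_low,
                "hi": self.cri_high,
            }
        )


def _summary_from_draws(name: str, x: np.ndarray) -> CoefficientSummary:
    mean = float(x.mean())
    lo, hi = (float(q) for q in np.percentile(x, [2.5, 97.5]))
    sign = math.copysign(1.0, mean) if mean != 0 else 1.0
    # draws exactly at zero count as agreeing with the mean's sign
    f = float(np.mean(sign * x >= 0.0))
    return CoefficientSummary(parameter=name, mean=mean, cri_low=lo, cri_high=hi, f=f)


def summarize_coefficients(
    draws: PosteriorDraws, which: Sequence[str] | str | None = None
) -> list[CoefficientSummary]:
    """Posterior mean, 95% CRI and f for the selected parameters.

    ``which`` is a list of parameter names, a name prefix (string), or
    None for every monitored parameter.  Chains are pooled.
    """
    if which is None:
        names = list(draws.names)
    elif isinstance(which, str):
        names = [n for n in draws.names if n.startswith(which)]
    else:
        names = list(which)
        for n in names:
            if n not in draws.names:
                raise KeyError(f"unknown parameter {n!r}")
    if not names:
        raise ValueError("empty parameter selection")
    return [_summary_from_draws(n, draws.pooled(n)) for n in names]


def selection_ratio(summary: CoefficientSummary, interaction_f: float = 0.0) -> SelectionRatio:
    """exp-transform a main-effect summary into a selection ratio.

    ``interaction_f`` is the f of the covariate's edge interaction in the
    same stage; at or above 0.90 the ratio is computed but flagged
    ineligible for stand-alone interpretation.
    """
    return SelectionRatio(
        covariate=summary.parameter,
        ratio=float(np.exp(summary.mean)),
        ratio_cri=(float(np.exp(summary.cri_low)), float(np.exp(summary.cri_high))),
        eligible=bool(interaction_f < INTERACTION_F_THRESHOLD),
    )


def estrella_r2(loglik_hat: float, n_sets: int, n_alternatives: int = 3) -> float:
    """Estrella's pseudo-R-squared for a discrete-choice model.

    With null log-likelihood L0 = n ln(1/J) for J equally likely
    alternatives, R2 = 1 - (L/L0)^(-(2/n) L0); 0 when the model predicts
    at random (L = L0) and 1 at perfect prediction (L = 0).
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if loglik_hat > 0:
        raise ValueError("a log-likelihood cannot be positive")
    L0 = n_sets * math.log(1.0 / n_alternatives)
    if loglik_hat == 0.0:
        return 1.0
    return 1.0 - (loglik_hat / L0) ** (-(2.0 / n_sets) * L0)


def posterior_mean_coefficients(draws: PosteriorDraws) -> dict[str, np.ndarray]:
    """Posterior-mean coefficient vector per unit.

    Nest model: one entry ``"beta"``.  Hierarchical model: one entry per
    individual-by-stage block, keyed ``"ind|stage"`` as in
    ``draws.meta["blocks"]``.
    """
    labels = list(draws.meta["labels"])
    if draws.meta["model"] == "nest":
        return {"beta": np.array([draws.pooled(lab).mean() for lab in labels])}
    out = {}
    for key in draws.meta["blocks"]:
        out[key] = np.array(
            [draws.pooled(f"beta[{key}].{lab}").mean() for lab in labels]
        )
    return out


def fit_stats(
    draws: PosteriorDraws, dataset: Dataset, spec: ModelSpec = DEFAULT_SPEC
) -> FitStats:
    """Model-fit statistics with the likelihood at posterior means.

    For the hierarchical model the likelihood is evaluated at each
    individual's posterior-mean coefficient vector (the individual level of
    the model); for the nest model at the shared posterior mean.
    """
    means = posterior_mean_coefficients(draws)
    if draws.meta["model"] == "nest":
        ll = data_loglik(dataset, means["beta"], spec)
    else:
        grouping = draws.meta["grouping"]
        stage_names = draws.meta["stage_names"]
        per_set = {}
        for cs in dataset.sets:
            key = f"{cs.individual_id}|{stage_names[grouping[cs.stage]]}"
            per_set[cs.set_id] = means[key]
        ll = data_loglik(dataset, per_set, spec)
    n = len(dataset.sets)
    return FitStats(
        loglik_hat=ll,
        loglik_null=n * math.log(1.0 / 3.0),
        n_sets=n,
        estrella_r2=estrella_r2(ll, n),
    )


def _population_prefix(draws: PosteriorDraws, stage: str | None) -> str:
    """Prefix selecting the population-level coefficients of one stage."""
    if draws.meta["model"] == "nest":
        return ""
    if stage is None:
        stages = draws.meta["stage_names"]
        if len(stages) != 1:
            raise ValueError(f"stage required; model has stages {stages}")
        stage = stages[0]
    return f"mu[{stage}]."


def use_curve(
    draws: PosteriorDraws,
    focal: str,
    dataset: Dataset,
    scenario: str = "none",
    stage: str | None = None,
    spec: ModelSpec = DEFAULT_SPEC,
    n_grid: int = 50,
) -> UseCurve:
    """Relative probability of use over the observed range of one covariate.

    For each posterior draw, r(x) = exp(V(x) - V(x_bar)) with the focal
    covariate at x, every other covariate at its dataset mean, and edge
    distance fixed by the scenario: ``"none"`` uses the mean edge distance,
    ``"near"``/``"far"`` the 10th/90th percentile (the scenarios of
    interest when the focal-by-edge interaction is supported).  The curve
    is anchored at the all-covariates-at-mean point, so r(x_bar) = 1 with a
    zero-width band there; anchoring changes only the y-scale of the
    curve, never its shape.

    ``dataset`` must be on the same covariate scale the model was fitted
    on.
    """
    if focal not in spec.main_covariates:
        raise ValueError(f"{focal!r} is not a main-effect covariate of the model")
    frame = dataset.to_frame()
    x_vals = frame[focal].to_numpy(dtype=float)
    edge_vals = frame[EDGE_COVARIATE].to_numpy(dtype=float)
    if scenario == "none":
        edge = float(edge_vals.mean())
    elif scenario == "near":
        edge = float(np.percentile(edge_vals, 10))
    elif scenario == "far":
        edge = float(np.percentile(edge_vals, 90))
    else:
        raise ValueError("scenario must be 'none', 'near' or 'far'")

    prefix = _population_prefix(draws, stage)
    b_main = draws.pooled(f"{prefix}{focal}")
    if spec.interactions:
        b_int = draws.pooled(f"{prefix}{focal}:{EDGE_COVARIATE}")
    else:
        b_int = np.zeros_like(b_main)

    grid = np.linspace(x_vals.min(), x_vals.max(), n_grid)
    x_bar = float(x_vals.mean())
    # other covariates cancel in V(x) - V(x_bar)
    slope = b_main + b_int * edge                      # (draws,)
    log_r = np.outer(slope, grid - x_bar)              # (draws, grid)
    r = np.exp(log_r)
    return UseCurve(
        focal=focal,
        scenario=scenario,
        edge_value=edge,
        grid=grid,
        mean=r.mean(axis=0),
        cri_low=np.percentile(r, 2.5, axis=0),
        cri_high=np.percentile(r, 97.5, axis=0),
    )


def coefficient_table(draws: PosteriorDraws, spec: ModelSpec = DEFAULT_SPEC) -> pd.DataFrame:
    """One row per (stage, parameter): beta, CRI, f, and the selection
    ratio where the parameter is a main effect whose edge interaction is
    not strongly supported.

    For the nest model the single shared vector forms one stage ``nest``;
    for the hierarchical model rows summarize the population means mu.
    """
    if draws.meta["model"] == "nest":
        stages = ["nest"]
        prefixes = [""]
    else:
        stages = list(draws.meta["stage_names"])
        prefixes = [f"mu[{s}]." for s in stages]

    rows = []
    for stage, prefix in zip(stages, prefixes):
        summaries = {
            lab: _summary_from_draws(lab, draws.pooled(f"{prefix}{lab}"))
            for lab in spec.labels
        }
        for lab in spec.labels:
            s = summaries[lab]
            row = {
                "stage": stage,
                "parameter": lab,
                "mean": s.mean,
                "cri_low": s.cri_low,
                "cri_high": s.cri_high,
                "f": s.f,
                "ratio": np.nan,
                "ratio_low": np.nan,
                "ratio_high": np.nan,
                "ratio_eligible": False,
            }
            if lab in spec.main_covariates:
                int_lab = f"{lab}:{EDGE_COVARIATE}"
                int_f = summaries[int_lab].f if int_lab in summaries else 0.0
                sr = selection_ratio(s, interaction_f=int_f)
                row.update(
                    ratio=sr.ratio,
                    ratio_low=sr.ratio_cri[0],
                    ratio_high=sr.ratio_cri[1],
                    ratio_eligible=sr.eligible,
                )
            rows.append(row)
    return pd.DataFrame(rows)
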