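"""Bayesian discrimination of candidate metabolic objective functions.

Given observed storage fluxes with standard errors and each candidate
objective's predicted fluxes, the posterior probability share of
candidate ``k`` under equal priors is

    P(k | data) = L_k / sum_j L_j,
    log L_k = sum_i log N(y_i | m_ki, se_i^2),

i.e. independent Gaussian measurement errors with the observed SEs as
standard deviations.  Shares are computed in the log domain (log-sum-exp)
so that residuals of many tens of SEs neither overflow nor underflow.
The Gaussian likelihood is the simplest member of the Bayesian
model-discrimination family and is deliberately swappable; an SE floor
is available for sensitivity analysis of near-zero standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "ObservationSet",
    "ObjectivePrediction",
    "PosteriorShares",
    "posterior_shares",
    "shares_from_frame",
    "DiscriminationError",
]


class DiscriminationError(ValueError):
    pass


@dataclass(frozen=True)
class ObservationSet:
    ids: tuple[str, ...]
    observed: dict[str, float]
    standard_errors: dict[str, float]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise DiscriminationError("observable ids must be unique")
        for oid in self.ids:
            if not self.standard_errors.get(oid, 0.0) > 0:
                raise DiscriminationError(
                    f"observable {oid!r} needs a positive SE"
                )


@dataclass(frozen=True)
class ObjectivePrediction:
    name: str
    predicted: dict[str, float]


@dataclass
class PosteriorShares:
    shares: dict[str, float]
    log_likelihoods: dict[str, float]
    priors: dict[str, float]
    residual_z: dict[str, dict[str, float]] = field(default_factory=dict)

    def report(self) -> str:
        lines = ["candidate\tposterior_share\tlog_likelihood"]
        for name, share in self.shares.items():
            lines.append(f"{name}\t{share:.6g}\t{self.log_likelihoods[name]:.6g}")
        return "\n".join(lines) + "\n"


def posterior_shares(
    observations: ObservationSet,
    predictions: list[ObjectivePrediction],
    priors: dict[str, float] | None = None,
    se_floor: float = 0.0,
) -> PosteriorShares:
    """Posterior probability share of each candidate objective function."""
    if len(predictions) < 2:
        raise DiscriminationError("need at least two candidate objectives")
    names = [p.name for p in predictions]
    if len(set(names)) != len(names):
        raise DiscriminationError(f"duplicate candidate names in {names}")
    if priors is None:
        priors = {n: 1.0 / len(names) for n in names}
    missing_prior = [n for n in names if n not in priors]
    if missing_prior:
        raise DiscriminationError(f"no prior for candidates {missing_prior}")

    log_lik: dict[str, float] = {}
    residual_z: dict[str, dict[str, float]] = {}
    for pred in predictions:
        total = 0.0
        zrow = {}
        for oid in observations.ids:
            if oid not in pred.predicted:
                raise DiscriminationError(
                    f"candidate {pred.name!r} misses observable {oid!r}"
                )
            se = max(observations.standard_errors[oid], se_floor)
            z = (observations.observed[oid] - pred.predicted[oid]) / se
            total += norm.logpdf(observations.observed[oid],
                                 loc=pred.predicted[oid], scale=se)
            zrow[oid] = z
        log_lik[pred.name] = float(total)
        residual_z[pred.name] = zrow

    log_post = np.array([np.log(priors[n]) + log_lik[n] for n in names])
    log_norm = logsumexp(log_post)
    shares = {n: float(np.exp(lp - log_norm)) for n, lp in zip(names, log_post)}
    return PosteriorShares(
        shares=shares,
        log_likelihoods=log_lik,
        priors={n: priors[n] for n in names},
        residual_z=residual_z,
    )


def shares_from_frame(
    frame: pd.DataFrame, priors: dict[str, float] | None = None,
    se_floor: float = 0.0,
) -> PosteriorShares:
    """Discriminate from a table with columns ``observable``, ``observed``,
    ``se`` and one prediction column per candidate."""
    reserved = {"observable", "observed", "se"}
    candidates = [c for c in frame.columns if c not in reserved]
    if not candidates:
        raise DiscriminationError("table carries no candidate prediction columns")
    obs = ObservationSet(
        ids=tuple(str(o) for o in frame["observable"]),
        observed={str(r["observable"]): float(r["observed"])
                  for _, r in frame.iterrows()},
        standard_errors={str(r["observable"]): float(r["se"])
                         for _, r in frame.iterrows()},
    )
    preds = [
        ObjectivePrediction(
            name=c,
            predicted={str(r["observable"]): float(r[c])
                       for _, r in frame.iterrows()},
        )
        for c in candidates
    ]
    return posterior_shares(obs, preds, priors=priors, se_floor=se_floor)
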