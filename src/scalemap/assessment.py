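"""Model fit and predictive accuracy: deviance, DIC/pD, MSPE, comparison.

All quantities are computed per geographic level, mirroring the way
aggregated-data analyses report fit at the fine and coarse scales
separately.  DIC = Dbar + pD with pD = Dbar − D(eta_bar), the plug-in
deviance evaluated at the posterior mean of the linear predictor (the
predictor is linear in all parameters, so this equals the deviance at
the posterior-mean parameters).  MSPE draws one binomial replicate
dataset per retained posterior draw and averages the squared deviation
from the observed counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import MultiscaleData
from .geography import MultiscaleGeography
from .model import ModelSpec, ParameterState, binomial_loglik, _binom_loglik_terms
from .sampler import PosteriorSamples

__all__ = [
    "AssessmentReport",
    "deviance",
    "dic",
    "mspe",
    "assess",
    "compare_models",
    "eta_draws",
]

LEVEL_LABEL = {1: "fine", 2: "coarse"}


def deviance(
    state: ParameterState,
    data: MultiscaleData,
    geog: MultiscaleGeography,
    spec: ModelSpec,
    level: int,
) -> float:
    """−2 × binomial log likelihood at one level (normalizing constant included)."""
    return -2.0 * binomial_loglik(state, data, geog, level, spec)


def _deviance_from_eta(eta, data: MultiscaleData, level: int) -> float:
    ld = data.level(level)
    return -2.0 * float(np.sum(_binom_loglik_terms(ld.y, ld.n, eta)))


def dic(
    samples: PosteriorSamples,
    data: MultiscaleData,
    geog: MultiscaleGeography,
    spec: ModelSpec,
    level: int,
) -> tuple[float, float, float]:
    """Posterior mean deviance, effective parameters and DIC at one level.

    Returns ``(Dbar, pD, DIC)``.  Negative pD is a known pathology of the
    plug-in construction and is reported as-is (callers may flag it).
    """
    if samples.n_kept == 0:
        raise ValueError("empty retained sample")
    dbar = float(samples.deviance[level].mean())
    dhat = _deviance_from_eta(samples.eta_mean[level], data, level)
    pd_ = dbar - dhat
    return dbar, pd_, dbar + pd_


def eta_draws(samples: PosteriorSamples, data: MultiscaleData, geog, level: int) -> np.ndarray:
    """Reconstruct linear-predictor draws, shape (n_draws_pooled, n_units)."""
    lab = LEVEL_LABEL[level]
    ld = data.level(level)
    b0 = samples.pooled(f"beta0_{lab}")[:, None]
    b1 = samples.pooled(f"beta1_{lab}")[:, None]
    v = samples.pooled(f"v_{lab}")
    e = samples.pooled(f"eps_{lab}")
    eta = b0 + b1 * ld.x[None, :] + v + e
    if level == 1 and samples.spec.model_kind == "shared":
        eta = eta + samples.pooled("v_coarse")[:, geog.parent_index]
    return eta


def mspe(
    samples: PosteriorSamples,
    data: MultiscaleData,
    geog: MultiscaleGeography,
    spec: ModelSpec,
    level: int,
    rng: np.random.Generator | int | None = 0,
) -> float:
    """Posterior-predictive mean squared prediction error at one level.

    For each retained draw a replicate dataset y_rep ~ Binomial(n, p) is
    simulated and (y_rep − y)² averaged over draws and units.  Seeded and
    reproducible.
    """
    if samples.n_kept == 0:
        raise ValueError("empty retained sample")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ld = data.level(level)
    eta = eta_draws(samples, data, geog, level)
    total = 0.0
    count = 0
    for start in range(0, eta.shape[0], 2000):  # chunked to bound memory
        p = expit(eta[start : start + 2000])
        y_rep = rng.binomial(ld.n[None, :].astype(np.int64), p)
        total += float(np.sum((y_rep - ld.y[None, :]) ** 2))
        count += p.shape[0] * p.shape[1]
    return total / count


@dataclass
class AssessmentReport:
    """Per-level fit and prediction summary for one fitted model."""

    model_kind: str
    dbar: dict[int, float]
    pd: dict[int, float]
    dic: dict[int, float]
    mspe: dict[int, float]
    n_draws: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for level in (1, 2):
            rows.append(
                {
                    "model": self.model_kind,
                    "level": LEVEL_LABEL[level],
                    "Dbar": self.dbar[level],
                    "pD": self.pd[level],
                    "DIC": self.dic[level],
                    "MSPE": self.mspe[level],
                }
            )
        return pd.DataFrame(rows)


def assess(
    samples: PosteriorSamples,
    data: MultiscaleData,
    geog: MultiscaleGeography,
    spec: ModelSpec,
    mspe_seed: int = 0,
) -> AssessmentReport:
    """Compute Dbar, pD, DIC and MSPE at both levels for one fitted model."""
    dbar, pd_, dic_, ms = {}, {}, {}, {}
    for level in (1, 2):
        dbar[level], pd_[level], dic_[level] = dic(samples, data, geog, spec, level)
        ms[level] = mspe(samples, data, geog, spec, level, rng=mspe_seed)
    return AssessmentReport(
        model_kind=spec.model_kind,
        dbar=dbar,
        pd=pd_,
        dic=dic_,
        mspe=ms,
        n_draws=samples.n_chains * samples.n_kept,
    )


IMPROVEMENT_THRESHOLD = 3.0  # a DIC difference of 3–7 counts as an improvement


def compare_models(reports: list[AssessmentReport]) -> tuple[pd.DataFrame, dict]:
    """Side-by-side per-level comparison and a preferred-model call.

    Preference: lower DIC (and, as a tiebreaker of interpretation, lower
    MSPE); a DIC gap of at least 3 is flagged as an improvement.
    """
    if len(reports) < 2:
        raise ValueError("need at least two fitted models to compare")
    table = pd.concat([r.to_frame() for r in reports], ignore_index=True)
    call: dict = {"improvement": {}, "preferred": {}, "dic_difference": {}}
    for level in (1, 2):
        lab = LEVEL_LABEL[level]
        dics = {r.model_kind: r.dic[level] for r in reports}
        best = min(dics, key=dics.get)
        worst = max(dics, key=dics.get)
        diff = dics[worst] - dics[best]
        call["dic_difference"][lab] = diff
        call["improvement"][lab] = bool(diff >= IMPROVEMENT_THRESHOLD)
        call["preferred"][lab] = best if diff > 0 else None
    return table, call
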