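"""Probability model: binomial convolution predictors, ICAR prior, hyperpriors.

Two variants of a two-level disease-mapping model are defined.  Both give
each level k a logit-linear predictor

    eta_ik = beta0_k + beta1_k * x_ik + v_ik + eps_ik,

where v_k is spatially correlated heterogeneity (CH) with an intrinsic
conditional autoregressive (ICAR) prior on the level-k neighbourhood
graph, and eps_k is uncorrelated heterogeneity (UH), iid Normal(0,
sigma_eps_k^2).  Outcomes are y_ik ~ Binomial(n_ik, expit(eta_ik)).

The *independent* variant stops there: the two levels share no
parameters.  The *shared* variant adds the parent's coarse-level CH term
to every nested fine unit's predictor,

    eta_i1 = beta0_1 + beta1_1 * x_i1 + v_i1 + eps_i1 + v_{parent(i),2},

so the coarse spatial field is common to all fine units it contains.
This is the device that carries information across scales and
compensates for the smoothing ("scaling effect") induced when fine
counts are aggregated to the coarse level.

Hyperpriors: flat on intercepts, Normal(0, slope_prior_sd^2) on slopes
(vague but proper; default sd 1000), and Uniform(0, sd_prior_upper) on
every random-effect standard deviation (default upper bound 100).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping

import networkx as nx
import numpy as np
from scipy.special import gammaln

from .data import MultiscaleData
from .errors import DimensionError, IslandError
from .geography import MultiscaleGeography

__all__ = [
    "ModelSpec",
    "ParameterState",
    "linear_predictor",
    "icar_logpdf",
    "icar_full_conditional",
    "binomial_loglik",
    "log_posterior",
]

_KINDS = ("independent", "shared")


@dataclass(frozen=True)
class ModelSpec:
    """Which model variant to fit and its (fixed) prior settings."""

    model_kind: str = "independent"
    sd_prior_upper: float = 100.0
    slope_prior_sd: float = 1000.0
    link: str = "logit"

    def __post_init__(self) -> None:
        if self.model_kind not in _KINDS:
            raise ValueError(f"model_kind must be one of {_KINDS}, got {self.model_kind!r}")
        if self.sd_prior_upper <= 0 or self.slope_prior_sd <= 0:
            raise ValueError("prior scales must be positive")
        if self.link != "logit":
            raise ValueError("only the logit link is supported")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ParameterState:
    """One point in parameter space for either model variant."""

    beta0: np.ndarray  # intercepts, shape (2,): fine, coarse
    beta1: np.ndarray  # slopes per SD of standardized covariate, shape (2,)
    v1: np.ndarray  # fine-level CH, length n_fine
    v2: np.ndarray  # coarse-level CH, length n_coarse
    eps1: np.ndarray  # fine-level UH
    eps2: np.ndarray  # coarse-level UH
    sigma_v: np.ndarray  # CH standard deviations, shape (2,)
    sigma_eps: np.ndarray  # UH standard deviations, shape (2,)

    @classmethod
    def zeros(cls, geog: MultiscaleGeography, sigma: float = 1.0) -> "ParameterState":
        return cls(
            beta0=np.zeros(2),
            beta1=np.zeros(2),
            v1=np.zeros(geog.n_fine),
            v2=np.zeros(geog.n_coarse),
            eps1=np.zeros(geog.n_fine),
            eps2=np.zeros(geog.n_coarse),
            sigma_v=np.full(2, float(sigma)),
            sigma_eps=np.full(2, float(sigma)),
        )

    def v(self, level: int) -> np.ndarray:
        return self.v1 if level == 1 else self.v2

    def eps(self, level: int) -> np.ndarray:
        return self.eps1 if level == 1 else self.eps2

    def copy(self) -> "ParameterState":
        return ParameterState(
            beta0=self.beta0.copy(),
            beta1=self.beta1.copy(),
            v1=self.v1.copy(),
            v2=self.v2.copy(),
            eps1=self.eps1.copy(),
            eps2=self.eps2.copy(),
            sigma_v=self.sigma_v.copy(),
            sigma_eps=self.sigma_eps.copy(),
        )


def _check_dims(state: ParameterState, geog: MultiscaleGeography) -> None:
    for level, vec, name in (
        (1, state.v1, "v1"),
        (1, state.eps1, "eps1"),
        (2, state.v2, "v2"),
        (2, state.eps2, "eps2"),
    ):
        if len(vec) != geog.n_units(level):
            raise DimensionError(
                f"{name} has length {len(vec)}, level {level} expects {geog.n_units(level)}"
            )


def linear_predictor(
    state: ParameterState,
    data: MultiscaleData,
    geog: MultiscaleGeography,
    level: int,
    spec: ModelSpec,
) -> np.ndarray:
    """Per-unit log-odds eta at the given level (see module docstring)."""
    _check_dims(state, geog)
    k = level - 1
    ld = data.level(level)
    eta = state.beta0[k] + state.beta1[k] * ld.x + state.v(level) + state.eps(level)
    if level == 1 and spec.model_kind == "shared":
        eta = eta + state.v2[geog.parent_index]
    return eta


# ---------------------------------------------------------------------------
# ICAR prior


def _adjacency_arrays(adjacency: Mapping[str, set]) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Edge index arrays (i<j), degrees, and component count for a dict-of-sets graph."""
    order = {u: i for i, u in enumerate(adjacency)}
    ii, jj = [], []
    for a, nbrs in adjacency.items():
        for b in nbrs:
            if order[a] < order[b]:
                ii.append(order[a])
                jj.append(order[b])
    g = nx.Graph()
    g.add_nodes_from(order)
    g.add_edges_from((a, b) for a, nbrs in adjacency.items() for b in nbrs)
    deg = np.array([len(adjacency[u]) for u in adjacency], dtype=np.intp)
    return (
        np.asarray(ii, dtype=np.intp),
        np.asarray(jj, dtype=np.intp),
        deg,
        nx.number_connected_components(g),
    )


def icar_logpdf(v, adjacency: Mapping[str, set], sigma_v: float) -> float:
    """Log density of the intrinsic CAR field, up to an additive constant.

    The improper joint density on a graph with edge set E is

        -(1/(2 sigma^2)) * sum_{(i,j) in E} (v_i - v_j)^2  -  r * log sigma,

    where the sigma power r is the rank of the graph Laplacian, N minus
    the number of connected components.  Units with no neighbours
    (islands) are not part of any pairwise difference; they are given a
    proper Normal(0, sigma_v^2) instead, contributing their own quadratic
    term and one additional power of 1/sigma each.
    """
    sigma_v = float(sigma_v)
    if sigma_v <= 0:
        raise ValueError(f"sigma_v must be positive, got {sigma_v}")
    v = np.asarray(v, dtype=float)
    if len(v) != len(adjacency):
        raise DimensionError(f"v has length {len(v)}, adjacency has {len(adjacency)} units")
    ii, jj, deg, n_comp = _adjacency_arrays(adjacency)
    quad = float(np.sum((v[ii] - v[jj]) ** 2))
    islands = deg == 0
    quad += float(np.sum(v[islands] ** 2))
    rank = len(v) - n_comp + int(islands.sum())
    return -quad / (2.0 * sigma_v**2) - rank * np.log(sigma_v)


def icar_full_conditional(
    i: int, v, adjacency: Mapping[str, set], sigma_v: float
) -> tuple[float, float]:
    """Conditional mean and variance of v_i given its neighbours.

    The ICAR conditional is Normal with mean the average of the
    neighbours' values and variance sigma_v^2 / degree.  Requesting the
    conditional of an island is an error; islands carry a proper
    Normal(0, sigma_v^2) handled by the sampler directly.
    """
    if sigma_v <= 0:
        raise ValueError(f"sigma_v must be positive, got {sigma_v}")
    v = np.asarray(v, dtype=float)
    ids = list(adjacency)
    pos = {u: k for k, u in enumerate(ids)}
    nbrs = adjacency[ids[i]]
    if not nbrs:
        raise IslandError(f"unit {ids[i]!r} has no neighbours; its conditional is Normal(0, sigma_v^2)")
    idx = [pos[b] for b in nbrs]
    return float(v[idx].mean()), float(sigma_v**2 / len(idx))


# ---------------------------------------------------------------------------
# likelihood and posterior


def _binom_loglik_terms(y, n, eta):
    # stable form: y*eta - n*log(1+e^eta) + log C(n, y)
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    eta = np.asarray(eta, dtype=float)
    logc = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    return logc + y * eta - n * np.logaddexp(0.0, eta)


def binomial_loglik(
    state: ParameterState,
    data: MultiscaleData,
    geog: MultiscaleGeography,
    level: int,
    spec: ModelSpec,
) -> float:
    """Binomial log likelihood at one level, including the combinatorial constant."""
    ld = data.level(level)
    eta = linear_predictor(state, data, geog, level, spec)
    return float(np.sum(_binom_loglik_terms(ld.y, ld.n, eta)))


_LOG_2PI = float(np.log(2.0 * np.pi))


def log_posterior(
    state: ParameterState,
    data: MultiscaleData,
    geog: MultiscaleGeography,
    spec: ModelSpec,
) -> float:
    """Unnormalized log posterior density; -inf outside the prior support."""
    sds = np.concatenate([state.sigma_v, state.sigma_eps])
    if np.any(sds <= 0) or np.any(sds >= spec.sd_prior_upper):
        return -np.inf
    lp = 0.0
    for level in (1, 2):
        lp += binomial_loglik(state, data, geog, level, spec)
        k = level - 1
        lp += icar_logpdf(state.v(level), geog.adjacency(level), state.sigma_v[k])
        eps = state.eps(level)
        n = len(eps)
        lp += -0.5 * n * _LOG_2PI - n * np.log(state.sigma_eps[k]) - float(
            np.sum(eps**2)
        ) / (2.0 * state.sigma_eps[k] ** 2)
        lp += -0.5 * _LOG_2PI - np.log(spec.slope_prior_sd) - state.beta1[k] ** 2 / (
            2.0 * spec.slope_prior_sd**2
        )
        # flat intercepts and in-range uniform sd priors contribute 0
    return float(lp)
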