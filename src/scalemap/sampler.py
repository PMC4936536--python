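"""Metropolis-within-Gibbs sampling for the multiscale convolution models.

The update scheme per sweep:

* each CH value v_ik by single-site Metropolis with the proposal drawn
  from the ICAR full conditional itself (neighbour average, variance
  sigma_v^2/degree) and a binomial-likelihood Metropolis correction —
  prior and proposal cancel, so the acceptance ratio is the likelihood
  ratio alone.  This proposal is not scale-adapted: for an independence
  proposal the acceptance rate is not monotone in the scale, so tuning
  it toward a fixed target is ill-posed;
* each UH value eps_ik by single-site random-walk Metropolis;
* the (intercept, slope) pair of each level by a joint random walk;
* each standard deviation by a random walk on log sigma with rejection
  outside the Uniform(0, upper) prior support;
* recentring: the mean of each CH vector is subtracted and folded into
  the level's intercept (and, for the shared model, the coarse CH mean
  also into the fine intercept, since the coarse field enters the fine
  predictor).  The likelihood and the translation-invariant ICAR prior
  are unchanged, so the move is posterior-invariant on connected maps.

Because the likelihood pins the per-unit log-odds while their split
between fixed effects and the two heterogeneity fields is only weakly
identified, the basic scheme alone crawls along several ridge/funnel
directions.  Four families of auxiliary posterior-invariant MH moves
mix them directly: eta-preserving shifts trading the intercept or slope
against the UH vector; a slope-vs-CH shift along the covariate
direction; colour-classed per-site CH/UH trades; and interweaved
(non-centred) rescales of each random-effect vector jointly with its
standard deviation.  Every coarse-CH move carries the fine-level
likelihood correction in the shared model, where the coarse field
enters the fine predictor.

Sites that are conditionally independent given the rest are updated
simultaneously: the UH vectors in one vectorized block, the CH vectors
colour class by colour class of a greedy colouring of the neighbourhood
graph (no two units of one class are neighbours, and — for the coarse
field under the shared model — child sets are disjoint by construction).

Proposal scales adapt by Robbins–Monro during burn-in only (targets 0.44
for single-site updates, 0.234 for blocks) and are frozen afterwards, so
the retained chain is a genuine Markov chain.  Identical seeds give
bit-identical draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data import MultiscaleData
from .errors import InitializationError, SamplingError
from .geography import MultiscaleGeography
from .model import ModelSpec, ParameterState, log_posterior

__all__ = [
    "McmcConfig",
    "PosteriorSamples",
    "run_mcmc",
    "gelman_rubin",
    "posterior_summary",
]

SCALAR_NAMES = (
    "beta0_fine",
    "beta1_fine",
    "beta0_coarse",
    "beta1_coarse",
    "sigma_v_fine",
    "sigma_eps_fine",
    "sigma_v_coarse",
    "sigma_eps_coarse",
)
VECTOR_NAMES = ("v_fine", "eps_fine", "v_coarse", "eps_coarse")


@dataclass(frozen=True)
class McmcConfig:
    """Chain protocol; the defaults reproduce the reference analysis setup
    (3 chains of 30,000 sweeps, first 15,000 discarded, 45,000 retained)."""

    n_chains: int = 3
    n_iter: int = 30000
    burn_in: int = 15000
    thin: int = 1
    seed: int = 0
    adapt_target_single: float = 0.44
    adapt_target_block: float = 0.234
    adapt_window: int | None = None  # defaults to burn_in
    update_v: bool = True
    update_eps: bool = True
    update_sigma: bool = True

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not (0 <= self.burn_in <= self.n_iter):
            raise ValueError("need 0 <= burn_in <= n_iter")

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PosteriorSamples:
    """Retained MCMC draws, per-iteration deviances and provenance."""

    scalars: dict[str, np.ndarray]  # name -> (n_chains, n_kept)
    vectors: dict[str, np.ndarray]  # name -> (n_chains, n_kept, n_units)
    deviance: dict[int, np.ndarray]  # level -> (n_chains, n_kept)
    eta_mean: dict[int, np.ndarray]  # level -> (n_units,), pooled posterior mean
    acceptance: dict[str, float]
    config: McmcConfig
    spec: ModelSpec
    fine_ids: list[str]
    coarse_ids: list[str]

    @property
    def n_chains(self) -> int:
        return self.config.n_chains

    @property
    def n_kept(self) -> int:
        next(iter(self.scalars.values())) if self.scalars else None
        return self.scalars["beta0_fine"].shape[1]

    def unit_ids(self, name: str) -> list[str]:
        return self.fine_ids if name.endswith("_fine") else self.coarse_ids

    def parameter_names(self, expand: bool = False) -> list[str]:
        names = list(SCALAR_NAMES)
        if expand:
            for vn in VECTOR_NAMES:
                names += [f"{vn}[{u}]" for u in self.unit_ids(vn)]
        else:
            names += list(VECTOR_NAMES)
        return names

    def draws(self, name: str) -> np.ndarray:
        """Draws for one parameter, shape (n_chains, n_kept[, n_units])."""
        if name in self.scalars:
            return self.scalars[name]
        if name in self.vectors:
            return self.vectors[name]
        if "[" in name and name.endswith("]"):
            base, unit = name[:-1].split("[", 1)
            if base in self.vectors:
                try:
                    j = self.unit_ids(base).index(unit)
                except ValueError:
                    raise KeyError(f"unknown unit {unit!r} for parameter {base!r}") from None
                return self.vectors[base][:, :, j]
        raise KeyError(
            f"unknown parameter {name!r}; available: {', '.join(self.parameter_names())}"
        )

    def pooled(self, name: str) -> np.ndarray:
        """Draws pooled across chains: (n_chains*n_kept,) or (..., n_units)."""
        d = self.draws(name)
        return d.reshape(-1, *d.shape[2:])

    def to_frame(self) -> pd.DataFrame:
        """Long format (chain, iteration, parameter, value) for CSV export."""
        rows = []
        for name in SCALAR_NAMES:
            arr = self.scalars[name]
            for c in range(arr.shape[0]):
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "iteration": np.arange(arr.shape[1]),
                            "parameter": name,
                            "value": arr[c],
                        }
                    )
                )
        for vn in VECTOR_NAMES:
            arr = self.vectors[vn]
            ids = self.unit_ids(vn)
            for c in range(arr.shape[0]):
                for j, u in enumerate(ids):
                    rows.append(
                        pd.DataFrame(
                            {
                                "chain": c,
                                "iteration": np.arange(arr.shape[1]),
                                "parameter": f"{vn}[{u}]",
                                "value": arr[c, :, j],
                            }
                        )
                    )
        return pd.concat(rows, ignore_index=True)

    def save(self, path) -> None:
        """Compact cache (npz with a JSON metadata entry)."""
        meta = {
            "config": self.config.to_dict(),
            "spec": self.spec.to_dict(),
            "fine_ids": self.fine_ids,
            "coarse_ids": self.coarse_ids,
            "acceptance": self.acceptance,
        }
        arrays = {f"scalar__{k}": v for k, v in self.scalars.items()}
        arrays.update({f"vector__{k}": v for k, v in self.vectors.items()})
        arrays.update({f"deviance__{k}": v for k, v in self.deviance.items()})
        arrays.update({f"eta_mean__{k}": v for k, v in self.eta_mean.items()})
        np.savez_compressed(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            scalars, vectors, deviance, eta_mean = {}, {}, {}, {}
            for key in z.files:
                if key.startswith("scalar__"):
                    scalars[key[8:]] = z[key]
                elif key.startswith("vector__"):
                    vectors[key[8:]] = z[key]
                elif key.startswith("deviance__"):
                    deviance[int(key[10:])] = z[key]
                elif key.startswith("eta_mean__"):
                    eta_mean[int(key[10:])] = z[key]
        return cls(
            scalars=scalars,
            vectors=vectors,
            deviance=deviance,
            eta_mean=eta_mean,
            acceptance=meta["acceptance"],
            config=McmcConfig(**meta["config"]),
            spec=ModelSpec(**meta["spec"]),
            fine_ids=meta["fine_ids"],
            coarse_ids=meta["coarse_ids"],
        )


# ---------------------------------------------------------------------------
# precomputed per-level working arrays


class _LevelWork:
    def __init__(self, geog: MultiscaleGeography, level: int, y, n, x):
        self.y = np.asarray(y, dtype=float)
        self.n = np.asarray(n, dtype=float)
        self.x = np.asarray(x, dtype=float)
        self.N = geog.n_units(level)
        self.logc = float(
            np.sum(gammaln(self.n + 1) - gammaln(self.y + 1) - gammaln(self.n - self.y + 1))
        )
        self.ii, self.jj = geog.edge_index(level)
        deg = geog.degrees(level).astype(float)
        self.islands = np.flatnonzero(deg == 0)
        self.deg_eff = np.where(deg == 0, 1.0, deg)
        self.rank = self.N - geog.n_components(level) + len(self.islands)
        # sparse neighbour-sum operator as index lists (W @ v via bincount)
        src = np.concatenate([self.ii, self.jj])
        dst = np.concatenate([self.jj, self.ii])
        self._src, self._dst = src, dst
        # greedy colouring: classes of mutually non-adjacent units
        g = geog.graph(level)
        colouring = nx.coloring.greedy_color(g, strategy="largest_first")
        ids = geog.ids(level)
        ncol = (max(colouring.values()) + 1) if colouring else 1
        self.colors = [
            np.array([k for k, u in enumerate(ids) if colouring[u] == c], dtype=np.intp)
            for c in range(ncol)
        ]

    def nbr_sum(self, v: np.ndarray) -> np.ndarray:
        return np.bincount(self._dst, weights=v[self._src], minlength=self.N)

    def icar_quad(self, v: np.ndarray) -> float:
        q = float(np.sum((v[self.ii] - v[self.jj]) ** 2))
        if len(self.islands):
            q += float(np.sum(v[self.islands] ** 2))
        return q


def _ll(y, n, eta):
    return y * eta - n * np.logaddexp(0.0, eta)


# ---------------------------------------------------------------------------
# the sampler


def run_mcmc(
    data: MultiscaleData,
    geog: MultiscaleGeography,
    spec: ModelSpec,
    config: McmcConfig,
) -> PosteriorSamples:
    """Sample the posterior of the chosen model variant (see module docstring)."""
    shared = spec.model_kind == "shared"
    lw1 = _LevelWork(geog, 1, data.fine.y, data.fine.n, data.fine.x)
    lw2 = _LevelWork(geog, 2, data.coarse.y, data.coarse.n, data.coarse.x)
    parent = geog.parent_index
    n_kept = config.n_kept
    adapt_until = config.burn_in if config.adapt_window is None else min(
        config.adapt_window, config.burn_in
    )

    state0 = ParameterState.zeros(geog)
    if not np.isfinite(log_posterior(state0, data, geog, spec)):
        raise InitializationError("log posterior is not finite at the initial state")

    scalars = {k: np.empty((config.n_chains, n_kept)) for k in SCALAR_NAMES}
    vectors = {
        "v_fine": np.empty((config.n_chains, n_kept, lw1.N)),
        "eps_fine": np.empty((config.n_chains, n_kept, lw1.N)),
        "v_coarse": np.empty((config.n_chains, n_kept, lw2.N)),
        "eps_coarse": np.empty((config.n_chains, n_kept, lw2.N)),
    }
    deviance = {1: np.empty((config.n_chains, n_kept)), 2: np.empty((config.n_chains, n_kept))}
    eta_sum = {1: np.zeros(lw1.N), 2: np.zeros(lw2.N)}
    acc_tot: dict[str, list[float]] = {}

    chain_seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    for c in range(config.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        _run_chain(
            rng, c, lw1, lw2, parent, shared, spec, config, adapt_until,
            scalars, vectors, deviance, eta_sum, acc_tot,
        )

    total = max(config.n_chains * n_kept, 1)
    acceptance = {k: float(np.mean(v)) for k, v in acc_tot.items()}
    return PosteriorSamples(
        scalars=scalars,
        vectors=vectors,
        deviance=deviance,
        eta_mean={1: eta_sum[1] / total, 2: eta_sum[2] / total},
        acceptance=acceptance,
        config=config,
        spec=spec,
        fine_ids=list(geog.fine_ids),
        coarse_ids=list(geog.coarse_ids),
    )


def _run_chain(
    rng, chain, lw1, lw2, parent, shared, spec, config, adapt_until,
    scalars, vectors, deviance, eta_sum, acc_tot,
):
    upper = spec.sd_prior_upper
    slope_var = spec.slope_prior_sd**2
    t_single = config.adapt_target_single
    t_block = config.adapt_target_block

    # initial state: flat-start random effects, jittered fixed effects
    b0 = rng.normal(0.0, 1.0, size=2)
    b1 = rng.normal(0.0, 1.0, size=2)
    v = [np.zeros(lw1.N), np.zeros(lw2.N)]
    eps = [np.zeros(lw1.N), np.zeros(lw2.N)]
    sv = np.ones(2)
    se = np.ones(2)

    # adapted proposal scales (log)
    ls_e = [np.full(lw1.N, np.log(0.2)), np.full(lw2.N, np.log(0.2))]
    ls_b = [np.log(0.1), np.log(0.1)]
    ls_s = {"sv0": np.log(0.3), "sv1": np.log(0.3), "se0": np.log(0.3), "se1": np.log(0.3)}
    ls_iv = {"ivv0": np.log(0.3), "ivv1": np.log(0.3), "ive0": np.log(0.3), "ive1": np.log(0.3)}
    ls_sh = {f"sh_{w}{k}": np.log(0.1) for w in ("b0", "b1") for k in (0, 1)}
    ls_svsh = {"sv_sh0": np.log(0.1), "sv_sh1": np.log(0.1)}
    ls_tr = [np.full(lw1.N, np.log(0.1)), np.full(lw2.N, np.log(0.1))]

    lws = [lw1, lw2]
    eta = [None, None]
    ll = [None, None]

    def refresh_eta():
        for k in (0, 1):
            e = b0[k] + b1[k] * lws[k].x + v[k] + eps[k]
            if shared and k == 0:
                e = e + v[1][parent]
            eta[k] = e
            ll[k] = _ll(lws[k].y, lws[k].n, e)

    refresh_eta()
    acc_count: dict[str, float] = {}
    acc_n: dict[str, float] = {}

    def record_acc(name, rate, weight):
        acc_count[name] = acc_count.get(name, 0.0) + rate * weight
        acc_n[name] = acc_n.get(name, 0.0) + weight

    kept = 0
    for it in range(config.n_iter):
        adapting = it < adapt_until
        gamma = 4.0 / (it + 10.0) ** 0.6 if adapting else 0.0
        tracking = it >= config.burn_in

        # --- CH fields, colour class by colour class ----------------------
        if config.update_v:
            for k in (0, 1):
                lw = lws[k]
                for idx in lw.colors:
                    m = lw.nbr_sum(v[k])[idx] / lw.deg_eff[idx]
                    sd_prop = sv[k] / np.sqrt(lw.deg_eff[idx])
                    cur = v[k][idx]
                    prop = m + sd_prop * rng.standard_normal(len(idx))
                    if k == 0:
                        lnew = _ll(lw.y[idx], lw.n[idx], eta[0][idx] + (prop - cur))
                        dll = lnew - ll[0][idx]
                    else:
                        lnew = _ll(lw.y[idx], lw.n[idx], eta[1][idx] + (prop - cur))
                        dll = lnew - ll[1][idx]
                        if shared:
                            delta_all = np.zeros(lw2.N)
                            delta_all[idx] = prop - cur
                            eta1_new = eta[0] + delta_all[parent]
                            ll1_new = _ll(lw1.y, lw1.n, eta1_new)
                            dll = dll + np.bincount(
                                parent, weights=ll1_new - ll[0], minlength=lw2.N
                            )[idx]
                    # prior full conditional == proposal, so those terms
                    # cancel and the ratio is the likelihood ratio alone
                    log_acc = dll
                    accept = np.log(rng.random(len(idx))) < log_acc
                    if np.any(accept):
                        sel = idx[accept]
                        v[k][sel] = prop[accept]
                        if k == 0:
                            eta[0][sel] += prop[accept] - cur[accept]
                            ll[0][sel] = lnew[accept]
                        else:
                            eta[1][sel] += prop[accept] - cur[accept]
                            ll[1][sel] = lnew[accept]
                            if shared:
                                acc_delta = np.zeros(lw2.N)
                                acc_delta[sel] = prop[accept] - cur[accept]
                                unit_shift = acc_delta[parent]
                                moved = unit_shift != 0.0
                                eta[0][moved] += unit_shift[moved]
                                ll[0][moved] = ll1_new[moved]
                    if tracking:
                        record_acc(f"v_{'fine' if k == 0 else 'coarse'}", float(accept.mean()), len(idx))

        # --- UH fields, all sites simultaneously --------------------------
        if config.update_eps:
            for k in (0, 1):
                lw = lws[k]
                cur = eps[k]
                prop = cur + np.exp(ls_e[k]) * rng.standard_normal(lw.N)
                lnew = _ll(lw.y, lw.n, eta[k] + (prop - cur))
                log_acc = (lnew - ll[k]) - (prop**2 - cur**2) / (2.0 * se[k] ** 2)
                accept = np.log(rng.random(lw.N)) < log_acc
                if np.any(accept):
                    eta[k][accept] += prop[accept] - cur[accept]
                    ll[k][accept] = lnew[accept]
                    eps[k][accept] = prop[accept]
                if adapting:
                    ls_e[k] += gamma * (accept.astype(float) - t_single)
                if tracking:
                    record_acc(f"eps_{'fine' if k == 0 else 'coarse'}", float(accept.mean()), lw.N)

        # --- fixed effects, joint (intercept, slope) per level -------------
        for k in (0, 1):
            lw = lws[k]
            d0, d1 = np.exp(ls_b[k]) * rng.standard_normal(2)
            lnew = _ll(lw.y, lw.n, eta[k] + d0 + d1 * lw.x)
            dprior = -((b1[k] + d1) ** 2 - b1[k] ** 2) / (2.0 * slope_var)
            log_acc = float(np.sum(lnew - ll[k])) + dprior
            if np.log(rng.random()) < log_acc:
                b0[k] += d0
                b1[k] += d1
                eta[k] = eta[k] + d0 + d1 * lw.x
                ll[k] = lnew
                a = 1.0
            else:
                a = 0.0
            if adapting:
                ls_b[k] += gamma * (a - t_block)
            if tracking:
                record_acc(f"beta_{'fine' if k == 0 else 'coarse'}", a, 1.0)

        # --- standard deviations, random walk on log sigma ------------------
        if config.update_sigma:
            for k in (0, 1):
                tag = "fine" if k == 0 else "coarse"
                if config.update_v:
                    q = lws[k].icar_quad(v[k])
                    r = lws[k].rank
                    key = f"sv{k}"
                    new = sv[k] * np.exp(np.exp(ls_s[key]) * rng.standard_normal())
                    if new < upper:
                        la = (
                            -q / (2.0 * new**2)
                            - r * np.log(new)
                            + q / (2.0 * sv[k] ** 2)
                            + r * np.log(sv[k])
                            + np.log(new)
                            - np.log(sv[k])
                        )
                        a = 1.0 if np.log(rng.random()) < la else 0.0
                        if a:
                            sv[k] = new
                    else:
                        a = 0.0
                    if adapting:
                        ls_s[key] += gamma * (a - t_single)
                    if tracking:
                        record_acc(f"sigma_v_{tag}", a, 1.0)
                if config.update_eps:
                    q = float(np.sum(eps[k] ** 2))
                    nn = lws[k].N
                    key = f"se{k}"
                    new = se[k] * np.exp(np.exp(ls_s[key]) * rng.standard_normal())
                    if new < upper:
                        la = (
                            -q / (2.0 * new**2)
                            - nn * np.log(new)
                            + q / (2.0 * se[k] ** 2)
                            + nn * np.log(se[k])
                            + np.log(new)
                            - np.log(se[k])
                        )
                        a = 1.0 if np.log(rng.random()) < la else 0.0
                        if a:
                            se[k] = new
                    else:
                        a = 0.0
                    if adapting:
                        ls_s[key] += gamma * (a - t_single)
                    if tracking:
                        record_acc(f"sigma_eps_{tag}", a, 1.0)

        # --- eta-preserving shift moves ------------------------------------
        # With sharp likelihoods the per-unit eta is pinned while its split
        # between fixed effects and UH is not; trading the intercept (or
        # slope) against the UH vector leaves eta -- hence the likelihood --
        # unchanged and is accepted on the prior ratio alone.
        if config.update_eps:
            for k in (0, 1):
                tag = "fine" if k == 0 else "coarse"
                nn = lws[k].N
                for which in ("b0", "b1"):
                    key = f"sh_{which}{k}"
                    delta = np.exp(ls_sh[key]) * rng.standard_normal()
                    direction = np.ones(nn) if which == "b0" else lws[k].x
                    enew = eps[k] - delta * direction
                    la = -(float(np.sum(enew**2 - eps[k] ** 2))) / (2.0 * se[k] ** 2)
                    if which == "b1":
                        la += -((b1[k] + delta) ** 2 - b1[k] ** 2) / (2.0 * slope_var)
                    if np.log(rng.random()) < la:
                        a = 1.0
                        eps[k] = enew
                        if which == "b0":
                            b0[k] += delta
                        else:
                            b1[k] += delta
                    else:
                        a = 0.0
                    if adapting:
                        ls_sh[key] += gamma * (a - t_single)
                    if tracking:
                        record_acc(f"shift_{which}_{tag}", a, 1.0)

        # --- slope-vs-CH shift -----------------------------------------------
        # Trade the slope against the CH field along the covariate direction:
        # beta1 += delta, v -= delta*x leaves eta at the level unchanged;
        # acceptance is the ICAR prior ratio (plus, for the coarse field of
        # the shared model, the fine-level likelihood change it induces).
        if config.update_v:
            for k in (0, 1):
                tag = "fine" if k == 0 else "coarse"
                key = f"sv_sh{k}"
                delta = np.exp(ls_svsh[key]) * rng.standard_normal()
                vnew = v[k] - delta * lws[k].x
                la = -(lws[k].icar_quad(vnew) - lws[k].icar_quad(v[k])) / (2.0 * sv[k] ** 2)
                la += -((b1[k] + delta) ** 2 - b1[k] ** 2) / (2.0 * slope_var)
                shift1 = None
                if k == 1 and shared:
                    shift1 = -delta * lws[1].x[parent]
                    ll1_new = _ll(lw1.y, lw1.n, eta[0] + shift1)
                    la += float(np.sum(ll1_new - ll[0]))
                if np.log(rng.random()) < la:
                    a = 1.0
                    v[k] = vnew
                    b1[k] += delta
                    if shift1 is not None:
                        eta[0] = eta[0] + shift1
                        ll[0] = ll1_new
                else:
                    a = 0.0
                if adapting:
                    ls_svsh[key] += gamma * (a - t_single)
                if tracking:
                    record_acc(f"shift_b1v_{tag}", a, 1.0)

        # --- CH/UH trade ----------------------------------------------------
        # v_i += delta_i, eps_i -= delta_i keeps eta fixed; accepted on the
        # two prior ratios, colour class by colour class.  Mixes the split
        # between the spatial and exchangeable fields, which the likelihood
        # cannot identify unit by unit.
        if config.update_v and config.update_eps:
            for k in (0, 1):
                lw = lws[k]
                for idx in lw.colors:
                    m = lw.nbr_sum(v[k])[idx] / lw.deg_eff[idx]
                    delta = np.exp(ls_tr[k][idx]) * rng.standard_normal(len(idx))
                    vi = v[k][idx]
                    ei = eps[k][idx]
                    la = (
                        -(lw.deg_eff[idx] * ((vi + delta - m) ** 2 - (vi - m) ** 2))
                        / (2.0 * sv[k] ** 2)
                        - ((ei - delta) ** 2 - ei**2) / (2.0 * se[k] ** 2)
                    )
                    if k == 1 and shared:
                        # the coarse CH enters the fine predictor: the trade
                        # moves eta at the fine level and needs its likelihood
                        delta_all = np.zeros(lw2.N)
                        delta_all[idx] = delta
                        ll1_new = _ll(lw1.y, lw1.n, eta[0] + delta_all[parent])
                        la = la + np.bincount(
                            parent, weights=ll1_new - ll[0], minlength=lw2.N
                        )[idx]
                    accept = np.log(rng.random(len(idx))) < la
                    sel = idx[accept]
                    v[k][sel] += delta[accept]
                    eps[k][sel] -= delta[accept]
                    if k == 1 and shared and len(sel):
                        acc_delta = np.zeros(lw2.N)
                        acc_delta[sel] = delta[accept]
                        unit_shift = acc_delta[parent]
                        moved = unit_shift != 0.0
                        eta[0][moved] += unit_shift[moved]
                        ll[0][moved] = ll1_new[moved]
                    if adapting:
                        ls_tr[k][idx] += gamma * (accept.astype(float) - t_single)
                    if tracking:
                        record_acc(
                            f"trade_veps_{'fine' if k == 0 else 'coarse'}",
                            float(accept.mean()),
                            len(idx),
                        )

        # --- interweaved scale moves (non-centred sigma updates) -----------
        # Joint rescale of a random-effect vector with its sigma: in the
        # whitened (non-centred) coordinates the prior is free of sigma,
        # so the acceptance ratio is the likelihood ratio plus the log-RW
        # Jacobian.  Breaks the sigma/effect funnel that the centred
        # updates alone mix through very slowly.
        if config.update_sigma:
            for k in (0, 1):
                tag = "fine" if k == 0 else "coarse"
                if config.update_v:
                    key = f"ivv{k}"
                    delta = np.exp(ls_iv[key]) * rng.standard_normal()
                    new = sv[k] * np.exp(delta)
                    a = 0.0
                    if new < upper:
                        factor = new / sv[k]
                        vnew = v[k] * factor
                        lnew = _ll(lws[k].y, lws[k].n, eta[k] + (vnew - v[k]))
                        dll = float(np.sum(lnew - ll[k]))
                        if k == 1 and shared:
                            shift1 = (factor - 1.0) * v[1][parent]
                            ll1_new = _ll(lw1.y, lw1.n, eta[0] + shift1)
                            dll += float(np.sum(ll1_new - ll[0]))
                        if np.log(rng.random()) < dll + delta:
                            a = 1.0
                            eta[k] = eta[k] + (vnew - v[k])
                            ll[k] = lnew
                            if k == 1 and shared:
                                eta[0] = eta[0] + shift1
                                ll[0] = ll1_new
                            v[k] = vnew
                            sv[k] = new
                    if adapting:
                        ls_iv[key] += gamma * (a - t_single)
                    if tracking:
                        record_acc(f"scale_v_{tag}", a, 1.0)
                if config.update_eps:
                    key = f"ive{k}"
                    delta = np.exp(ls_iv[key]) * rng.standard_normal()
                    new = se[k] * np.exp(delta)
                    a = 0.0
                    if new < upper:
                        factor = new / se[k]
                        enew = eps[k] * factor
                        lnew = _ll(lws[k].y, lws[k].n, eta[k] + (enew - eps[k]))
                        dll = float(np.sum(lnew - ll[k]))
                        if np.log(rng.random()) < dll + delta:
                            a = 1.0
                            eta[k] = eta[k] + (enew - eps[k])
                            ll[k] = lnew
                            eps[k] = enew
                            se[k] = new
                    if adapting:
                        ls_iv[key] += gamma * (a - t_single)
                    if tracking:
                        record_acc(f"scale_eps_{tag}", a, 1.0)

        # --- recentring (posterior-invariant; eta unchanged) ---------------
        if config.update_v:
            m1 = float(v[0].mean())
            v[0] -= m1
            b0[0] += m1
            m2 = float(v[1].mean())
            v[1] -= m2
            b0[1] += m2
            if shared:
                b0[0] += m2

        if (it + 1) % 1000 == 0:
            refresh_eta()  # guard against floating drift in incremental eta

        s1 = float(np.sum(ll[0]))
        s2 = float(np.sum(ll[1]))
        if not (np.isfinite(s1) and np.isfinite(s2)):
            raise SamplingError(f"non-finite log likelihood at iteration {it} (chain {chain})")

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            scalars["beta0_fine"][chain, kept] = b0[0]
            scalars["beta1_fine"][chain, kept] = b1[0]
            scalars["beta0_coarse"][chain, kept] = b0[1]
            scalars["beta1_coarse"][chain, kept] = b1[1]
            scalars["sigma_v_fine"][chain, kept] = sv[0]
            scalars["sigma_eps_fine"][chain, kept] = se[0]
            scalars["sigma_v_coarse"][chain, kept] = sv[1]
            scalars["sigma_eps_coarse"][chain, kept] = se[1]
            vectors["v_fine"][chain, kept] = v[0]
            vectors["eps_fine"][chain, kept] = eps[0]
            vectors["v_coarse"][chain, kept] = v[1]
            vectors["eps_coarse"][chain, kept] = eps[1]
            deviance[1][chain, kept] = -2.0 * (s1 + lw1.logc)
            deviance[2][chain, kept] = -2.0 * (s2 + lw2.logc)
            eta_sum[1] += eta[0]
            eta_sum[2] += eta[1]
            kept += 1

    for name in acc_count:
        acc_tot.setdefault(name, []).append(acc_count[name] / max(acc_n[name], 1.0))


# ---------------------------------------------------------------------------
# diagnostics and summaries


def _rhat_array(draws: np.ndarray) -> float:
    """Classical potential scale reduction for draws of shape (chains, m)."""
    nchain, m = draws.shape
    means = draws.mean(axis=1)
    w = float(np.mean(draws.var(axis=1, ddof=1)))
    b_over_m = float(np.var(means, ddof=1))  # = B / m
    if w == 0.0:
        return 1.0 if b_over_m == 0.0 else np.inf
    return float(np.sqrt((m - 1) / m + b_over_m / w))


def gelman_rubin(
    samples: PosteriorSamples,
    params: Iterable[str] | None = None,
    split: bool = False,
) -> pd.Series:
    """Gelman–Rubin potential scale reduction factor R-hat per parameter.

    Computed from the retained draws across chains; values near 1
    indicate convergence.  With ``split=True`` each chain is halved
    first, which also makes the diagnostic available for a single chain.
    Degenerate separation (zero within-chain variance, distinct chains)
    yields ``inf``.
    """
    if samples.n_chains < 2 and not split:
        raise ValueError(
            "R-hat needs at least two chains; use split=True for the split-chain variant"
        )
    names = list(params) if params is not None else samples.parameter_names(expand=True)
    out = {}
    for name in names:
        d = samples.draws(name)
        if d.ndim != 2:
            raise KeyError(f"{name!r} is a vector; use component names like '{name}[unit]'")
        if split:
            m = d.shape[1] // 2
            if m < 5:
                raise ValueError("need at least 10 retained draws per chain")
            d = np.concatenate([d[:, :m], d[:, m : 2 * m]], axis=0)
        if d.shape[1] < 10:
            raise ValueError("need at least 10 retained draws per chain")
        out[name] = _rhat_array(d)
    return pd.Series(out, name="rhat")


def posterior_summary(
    samples: PosteriorSamples, params: Iterable[str] | None = None
) -> pd.DataFrame:
    """Pooled posterior mean, sd and equal-tailed 95% interval per parameter."""
    names = list(params) if params is not None else list(SCALAR_NAMES)
    if samples.n_kept == 0:
        raise ValueError("empty retained sample")
    rows = {}
    for name in names:
        d = samples.pooled(name)
        if d.ndim != 1:
            raise KeyError(f"{name!r} is a vector; use component names like '{name}[unit]'")
        lo, hi = np.percentile(d, [2.5, 97.5])
        rows[name] = {
            "mean": float(d.mean()),
            "sd": float(d.std(ddof=1)) if len(d) > 1 else 0.0,
            "2.5%": float(lo),
            "97.5%": float(hi),
        }
    return pd.DataFrame.from_dict(rows, orient="index")[["mean", "sd", "2.5%", "97.5%"]]
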