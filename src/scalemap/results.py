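"""The user-facing modelling surface: MultiscaleModel and MultiscaleResults.

    >>> geog = make_lattice_geography(12, 12, 4, 4)
    >>> data, _ = simulate_dataset(geog, SimulationTruth(seed=1))
    >>> model = MultiscaleModel(data, geog, kind="shared")
    >>> res = model.fit(n_iter=3000, burn_in=1500, seed=1)
    >>> print(res.summary())

A model object binds data, geography and the model variant; ``fit()``
runs the Metropolis-within-Gibbs sampler and returns a results object
carrying the posterior draws, convergence diagnostics, fit statistics
and reporting helpers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import assessment as _assessment
from . import reporting as _reporting
from .data import MultiscaleData
from .geography import MultiscaleGeography, validate_geography
from .model import ModelSpec
from .sampler import (
    SCALAR_NAMES,
    McmcConfig,
    PosteriorSamples,
    gelman_rubin,
    posterior_summary,
    run_mcmc,
)

__all__ = ["MultiscaleModel", "MultiscaleResults"]


class MultiscaleModel:
    """Two-level Bayesian convolution model for nested areal count data.

    Parameters
    ----------
    data : MultiscaleData
        Outcome counts, trials and (standardized) covariate per level.
    geography : MultiscaleGeography
        Unit labels, per-level adjacency and the nesting map.
    kind : {'independent', 'shared'}
        Whether the coarse spatial field also enters the fine-level
        predictor (the shared multiscale model) or the levels are fitted
        independently.
    """

    def __init__(
        self,
        data: MultiscaleData,
        geography: MultiscaleGeography,
        kind: str = "independent",
        sd_prior_upper: float = 100.0,
        slope_prior_sd: float = 1000.0,
        validate: bool = True,
    ):
        if validate:
            report = validate_geography(geography)
            if not report.ok:
                raise ValueError("invalid geography:\n" + "\n".join(report.violations))
        self.data = data
        self.geography = geography
        self.spec = ModelSpec(
            model_kind=kind,
            sd_prior_upper=sd_prior_upper,
            slope_prior_sd=slope_prior_sd,
        )

    @classmethod
    def from_frames(
        cls,
        fine: pd.DataFrame,
        geography: MultiscaleGeography,
        coarse: pd.DataFrame | None = None,
        kind: str = "independent",
        **kwargs,
    ) -> "MultiscaleModel":
        """Build from per-level (unit_id, y, n, x) frames; the coarse frame
        is aggregated from the fine one if omitted."""
        data = MultiscaleData.from_frames(geography, fine, coarse)
        return cls(data, geography, kind=kind, **kwargs)

    def fit(
        self,
        n_chains: int = 3,
        n_iter: int = 30000,
        burn_in: int = 15000,
        thin: int = 1,
        seed: int = 0,
        **config_kwargs,
    ) -> "MultiscaleResults":
        """Run the sampler and return a results object."""
        config = McmcConfig(
            n_chains=n_chains,
            n_iter=n_iter,
            burn_in=burn_in,
            thin=thin,
            seed=seed,
            **config_kwargs,
        )
        samples = run_mcmc(self.data, self.geography, self.spec, config)
        return MultiscaleResults(self, samples)


class MultiscaleResults:
    """Posterior draws plus diagnostics, assessment and reporting."""

    def __init__(self, model: MultiscaleModel, samples: PosteriorSamples):
        self.model = model
        self.samples = samples

    # -- basic posterior accessors -----------------------------------------

    @property
    def params(self) -> pd.Series:
        """Posterior means of the scalar parameters."""
        return pd.Series({k: float(self.samples.pooled(k).mean()) for k in SCALAR_NAMES})

    def posterior_summary(self, params=None) -> pd.DataFrame:
        return posterior_summary(self.samples, params)

    def rhat(self, params=None, split: bool = False) -> pd.Series:
        return gelman_rubin(self.samples, params, split=split)

    def converged(self, threshold: float = 1.1) -> bool:
        return bool((self.rhat() < threshold).all())

    # -- assessment ---------------------------------------------------------

    def dic(self, level: int) -> tuple[float, float, float]:
        """(Dbar, pD, DIC) at one level."""
        return _assessment.dic(self.samples, self.model.data, self.model.geography, self.model.spec, level)

    def mspe(self, level: int, seed: int = 0) -> float:
        return _assessment.mspe(
            self.samples, self.model.data, self.model.geography, self.model.spec, level, rng=seed
        )

    def assessment(self, mspe_seed: int = 0) -> _assessment.AssessmentReport:
        return _assessment.assess(
            self.samples, self.model.data, self.model.geography, self.model.spec, mspe_seed
        )

    # -- reporting ----------------------------------------------------------

    def odds_ratio(self, level: int) -> _reporting.OddsRatio:
        """Odds ratio per raw covariate unit, from the posterior-mean slope
        and the level's stored covariate SD."""
        lab = _assessment.LEVEL_LABEL[level]
        beta = float(self.samples.pooled(f"beta1_{lab}").mean())
        sd_x = self.model.data.level(level).x_sd
        return _reporting.odds_ratio_per_unit(beta, sd_x)

    def odds_ratio_table(self) -> pd.DataFrame:
        """Per-level odds ratio per raw unit: point arithmetic on the
        posterior-mean slope (headline) plus the draw-wise posterior mean
        and interval of exp(beta/sd) (the Bayesian-coherent companion)."""
        rows = []
        for level in (1, 2):
            lab = _assessment.LEVEL_LABEL[level]
            sd_x = self.model.data.level(level).x_sd
            orr = self.odds_ratio(level)
            draws = np.exp(self.samples.pooled(f"beta1_{lab}") / sd_x)
            lo, hi = np.percentile(draws, [2.5, 97.5])
            rows.append(
                {
                    "level": lab,
                    "sd_x": sd_x,
                    "transformed_estimate": round(orr.transformed_estimate, 3),
                    "odds_ratio": round(orr.odds_ratio, 3),
                    "pct_decrease": _reporting.percent_change(orr.odds_ratio),
                    "or_post_mean": round(float(draws.mean()), 3),
                    "or_2.5%": round(float(lo), 3),
                    "or_97.5%": round(float(hi), 3),
                }
            )
        return pd.DataFrame(rows)

    def risk_surface(self) -> pd.DataFrame:
        return _reporting.risk_surface(
            self.samples, self.model.data, self.model.geography, self.model.spec
        )

    # -- display ------------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary (2-decimal posterior table)."""
        spec = self.model.spec
        lines = [
            f"Multiscale convolution model ({spec.model_kind})",
            f"fine units: {self.model.geography.n_fine}   coarse units: {self.model.geography.n_coarse}",
            f"chains: {self.samples.n_chains}   retained draws: {self.samples.n_chains * self.samples.n_kept}",
            "",
            self.posterior_summary().round(2).to_string(),
            "",
        ]
        try:
            rh = self.rhat(params=SCALAR_NAMES)
            lines.append("max R-hat (scalars): %.3f" % float(rh.max()))
        except ValueError:
            pass
        for level, lab in ((1, "fine"), (2, "coarse")):
            dbar, pd_, dic_ = self.dic(level)
            lines.append(f"{lab}: Dbar={dbar:.2f}  pD={pd_:.2f}  DIC={dic_:.2f}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MultiscaleResults kind={self.model.spec.model_kind!r} "
            f"draws={self.samples.n_chains * self.samples.n_kept}>"
        )
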