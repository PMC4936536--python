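"""Effect-size back-transformation and per-unit risk surfaces.

Slopes are estimated per standard deviation of the standardized
covariate; for interpretation on the raw scale (here: per one thousand
dollars of median household income) the estimate is divided by the
covariate's sample SD and exponentiated, giving an odds ratio per raw
unit.  ``(1 − OR)·100`` is the percent decrease in the odds per raw
unit (negative values mean an increase).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .assessment import LEVEL_LABEL, eta_draws
from .data import MultiscaleData
from .geography import MultiscaleGeography
from .model import ModelSpec
from .sampler import PosteriorSamples

__all__ = ["OddsRatio", "odds_ratio_per_unit", "percent_change", "risk_surface", "roughness"]


@dataclass(frozen=True)
class OddsRatio:
    """Back-transformed effect of one raw covariate unit on the odds."""

    transformed_estimate: float  # slope per raw unit (log-odds scale)
    odds_ratio: float

    @property
    def rounded(self) -> tuple[float, float]:
        return round(self.transformed_estimate, 3), round(self.odds_ratio, 3)


def odds_ratio_per_unit(beta_std: float, sd_x: float) -> OddsRatio:
    """Odds ratio per one raw covariate unit from a standardized-scale slope.

    ``beta_std`` is the slope per SD of the standardized covariate and
    ``sd_x`` the covariate's sample SD on the raw scale; the odds ratio
    is exp(beta_std / sd_x).
    """
    if sd_x <= 0:
        raise ValueError(f"sd_x must be positive, got {sd_x}")
    transformed = beta_std / sd_x
    return OddsRatio(transformed_estimate=transformed, odds_ratio=float(np.exp(transformed)))


def percent_change(odds_ratio: float) -> float:
    """Percent decrease in the odds per raw unit: (1 − OR)·100, 1 decimal.

    Positive values are decreases; an OR above 1 yields a negative value
    (an increase).
    """
    if odds_ratio <= 0:
        raise ValueError(f"odds ratio must be positive, got {odds_ratio}")
    return round((1.0 - odds_ratio) * 100.0, 1)


def risk_surface(
    samples: PosteriorSamples,
    data: MultiscaleData,
    geog: MultiscaleGeography,
    spec: ModelSpec,
) -> pd.DataFrame:
    """Posterior mean outcome probability and 95% interval per unit and level.

    Columns: unit_id, level, post_mean_p, 2.5%, 97.5%.  The fine-level
    surface of the shared model is typically smoother than the
    independent model's on data generated with a shared coarse field —
    the coarse CH term smooths spatial variation (see :func:`roughness`).
    """
    rows = []
    for level in (1, 2):
        eta = eta_draws(samples, data, geog, level)
        p = expit(eta)
        lo, hi = np.percentile(p, [2.5, 97.5], axis=0)
        rows.append(
            pd.DataFrame(
                {
                    "unit_id": geog.ids(level),
                    "level": LEVEL_LABEL[level],
                    "post_mean_p": p.mean(axis=0),
                    "2.5%": lo,
                    "97.5%": hi,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def roughness(p_hat, geog: MultiscaleGeography, level: int = 1) -> float:
    """Spatial roughness of a per-unit surface: sum of squared neighbour gaps."""
    p_hat = np.asarray(p_hat, dtype=float)
    ii, jj = geog.edge_index(level)
    return float(np.sum((p_hat[ii] - p_hat[jj]) ** 2))
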