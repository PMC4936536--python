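"""Two-level outcome/trial/covariate data with aggregation consistency.

Each level carries binomial counts ``y`` out of ``n`` trials and a single
covariate supplied on its raw scale (for the motivating application,
median household income in thousands of dollars).  Covariates are
standardized per level — (x − mean) / sd with the sample sd (N−1) — and
the standardization record is kept so that effect estimates can be
back-transformed to the raw scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateCovariateError, DimensionError, MissingDataError
from .geography import MultiscaleGeography

__all__ = ["LevelData", "MultiscaleData", "standardize_covariate"]


def standardize_covariate(x_raw) -> tuple[np.ndarray, float, float]:
    """Center and scale a covariate; returns ``(x, mean, sd)`` with sd = sample sd.

    Raises :class:`DegenerateCovariateError` for constant input (sd = 0).
    """
    x_raw = np.asarray(x_raw, dtype=float)
    if x_raw.size < 2:
        raise DegenerateCovariateError("need at least two units to standardize a covariate")
    mean = float(x_raw.mean())
    sd = float(x_raw.std(ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateCovariateError("covariate is constant; standardization undefined")
    return (x_raw - mean) / sd, mean, sd


@dataclass
class LevelData:
    """Counts and covariate for one geographic level, in canonical unit order."""

    y: np.ndarray
    n: np.ndarray
    x_raw: np.ndarray
    x: np.ndarray
    x_mean: float
    x_sd: float

    @classmethod
    def from_raw(cls, y, n, x_raw) -> "LevelData":
        y = np.asarray(y, dtype=np.int64)
        n = np.asarray(n, dtype=np.int64)
        x_raw = np.asarray(x_raw, dtype=float)
        if not (len(y) == len(n) == len(x_raw)):
            raise DimensionError("y, n and x must have equal length")
        if np.any(y < 0) or np.any(y > n):
            bad = np.flatnonzero((y < 0) | (y > n))
            raise ValueError(f"need 0 <= y <= n; violated at positions {bad.tolist()}")
        x, mean, sd = standardize_covariate(x_raw)
        return cls(y=y, n=n, x_raw=x_raw, x=x, x_mean=mean, x_sd=sd)

    @property
    def n_units(self) -> int:
        return len(self.y)


@dataclass
class MultiscaleData:
    """Fine- and coarse-level :class:`LevelData` tied to one geography."""

    fine: LevelData
    coarse: LevelData

    def level(self, level: int) -> LevelData:
        if level == 1:
            return self.fine
        if level == 2:
            return self.coarse
        raise ValueError(f"level must be 1 or 2, got {level!r}")

    @classmethod
    def from_frames(
        cls,
        geog: MultiscaleGeography,
        fine: pd.DataFrame,
        coarse: pd.DataFrame | None = None,
    ) -> "MultiscaleData":
        """Build from per-level data frames with columns (unit_id, y, n, x).

        If the coarse frame is omitted it is produced by aggregation:
        outcome and trial counts are summed and the covariate averaged
        within each parent — the construction by which aggregated
        surveillance data arise.
        """
        fine_ld = _level_from_frame(fine, geog.fine_ids, "fine")
        if coarse is None:
            idx = pd.Index(geog.fine_ids)
            y2 = geog.aggregate(pd.Series(fine_ld.y, index=idx), "sum")
            n2 = geog.aggregate(pd.Series(fine_ld.n, index=idx), "sum")
            x2 = geog.aggregate(pd.Series(fine_ld.x_raw, index=idx), "mean")
            coarse_ld = LevelData.from_raw(
                y2.to_numpy().round().astype(np.int64),
                n2.to_numpy().round().astype(np.int64),
                x2.to_numpy(),
            )
        else:
            coarse_ld = _level_from_frame(coarse, geog.coarse_ids, "coarse")
        return cls(fine=fine_ld, coarse=coarse_ld)

    @classmethod
    def from_csv(cls, geog: MultiscaleGeography, fine_path, coarse_path=None) -> "MultiscaleData":
        fine = pd.read_csv(fine_path, comment="#")
        coarse = pd.read_csv(coarse_path, comment="#") if coarse_path else None
        return cls.from_frames(geog, fine, coarse)

    def to_frames(self, geog: MultiscaleGeography) -> tuple[pd.DataFrame, pd.DataFrame]:
        frames = []
        for level in (1, 2):
            ld = self.level(level)
            frames.append(
                pd.DataFrame(
                    {"unit_id": geog.ids(level), "y": ld.y, "n": ld.n, "x": ld.x_raw}
                )
            )
        return frames[0], frames[1]


def _level_from_frame(df: pd.DataFrame, ids, name: str) -> LevelData:
    required = {"unit_id", "y", "n", "x"}
    if not required.issubset(df.columns):
        raise MissingDataError(
            f"{name} data frame needs columns {sorted(required)}, has {list(df.columns)}"
        )
    df = df.set_index(df["unit_id"].astype(str))
    missing = [u for u in ids if u not in df.index]
    if missing:
        raise MissingDataError(f"{name} data missing unit(s): {', '.join(missing)}")
    df = df.loc[list(ids)]
    return LevelData.from_raw(df["y"].to_numpy(), df["n"].to_numpy(), df["x"].to_numpy())
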