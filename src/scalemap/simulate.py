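"""Synthetic nested geographies and datasets with the model's structure.

The generator emulates the structure of county-in-district surveillance
data: fine units on a lattice (or an irregular Georgia-scale preset)
nested into contiguous coarse blocks, a Normal covariate averaged upward,
spatially correlated (ICAR) plus exchangeable heterogeneity at each
level, binomial outcomes at the fine level — and, crucially, coarse
outcomes obtained by *summing the fine outcomes* rather than by an
independent coarse-level draw.  That mirrors how aggregated data arise
in practice: the coarse-level model is an approximating model for sums,
which is exactly the situation the shared multiscale model addresses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import LevelData, MultiscaleData
from .geography import MultiscaleGeography
from .model import ModelSpec, ParameterState, linear_predictor

__all__ = [
    "SimulationTruth",
    "make_lattice_geography",
    "make_georgia_like_geography",
    "sample_icar",
    "simulate_dataset",
]


# ---------------------------------------------------------------------------
# geographies


def make_lattice_geography(
    n_rows: int, n_cols: int, block_rows: int, block_cols: int
) -> MultiscaleGeography:
    """Rook-adjacency grid of fine units partitioned into rectangular blocks.

    Block dimensions must divide the grid dimensions.  Coarse units are
    the blocks; coarse adjacency is rook adjacency of the block grid,
    which coincides with "blocks sharing at least one cross-block fine
    edge" for a full rectangular partition.
    """
    if n_rows % block_rows or n_cols % block_cols:
        raise ValueError(
            f"block dims ({block_rows}x{block_cols}) must divide grid dims ({n_rows}x{n_cols})"
        )
    fine_ids = [f"c{r:02d}_{c:02d}" for r in range(n_rows) for c in range(n_cols)]
    fine_adj: dict[str, set[str]] = {u: set() for u in fine_ids}
    for r in range(n_rows):
        for c in range(n_cols):
            u = f"c{r:02d}_{c:02d}"
            if r + 1 < n_rows:
                fine_adj[u].add(f"c{r + 1:02d}_{c:02d}")
                fine_adj[f"c{r + 1:02d}_{c:02d}"].add(u)
            if c + 1 < n_cols:
                fine_adj[u].add(f"c{r:02d}_{c + 1:02d}")
                fine_adj[f"c{r:02d}_{c + 1:02d}"].add(u)
    br, bc = n_rows // block_rows, n_cols // block_cols
    coarse_ids = [f"d{r:02d}_{c:02d}" for r in range(br) for c in range(bc)]
    parent = {
        f"c{r:02d}_{c:02d}": f"d{r // block_rows:02d}_{c // block_cols:02d}"
        for r in range(n_rows)
        for c in range(n_cols)
    }
    coarse_adj: dict[str, set[str]] = {u: set() for u in coarse_ids}
    for r in range(br):
        for c in range(bc):
            u = f"d{r:02d}_{c:02d}"
            if r + 1 < br:
                coarse_adj[u].add(f"d{r + 1:02d}_{c:02d}")
                coarse_adj[f"d{r + 1:02d}_{c:02d}"].add(u)
            if c + 1 < bc:
                coarse_adj[u].add(f"d{r:02d}_{c + 1:02d}")
                coarse_adj[f"d{r:02d}_{c + 1:02d}"].add(u)
    return MultiscaleGeography(fine_ids, coarse_ids, parent, fine_adj, coarse_adj)


def induced_coarse_adjacency(geog: MultiscaleGeography) -> dict[str, set[str]]:
    """Coarse neighbour sets induced by cross-parent fine edges."""
    adj: dict[str, set[str]] = {c: set() for c in geog.coarse_ids}
    for a, nbrs in geog.fine_adjacency.items():
        for b in nbrs:
            pa, pb = geog.parent[a], geog.parent[b]
            if pa != pb:
                adj[pa].add(pb)
                adj[pb].add(pa)
    return adj


def make_georgia_like_geography() -> MultiscaleGeography:
    """Irregular planar geography at the Georgia scale: 159 fine units in 18 blocks.

    Built deterministically from a 12×14 grid with nine corner cells
    removed (159 cells), partitioned into 18 contiguous segments of a
    serpentine (boustrophedon) walk — 15 blocks of nine units and 3 of
    eight.  Coarse adjacency is induced from cross-block fine edges.
    """
    n_rows, n_cols = 12, 14
    removed = {(0, 0), (0, 1), (0, 13), (11, 0), (11, 12), (11, 13), (0, 12), (1, 13), (10, 13)}
    cells = [(r, c) for r in range(n_rows) for c in range(n_cols) if (r, c) not in removed]
    assert len(cells) == 159
    label = {rc: f"c{rc[0]:02d}_{rc[1]:02d}" for rc in cells}
    fine_adj: dict[str, set[str]] = {label[rc]: set() for rc in cells}
    cellset = set(cells)
    for r, c in cells:
        for rr, cc in ((r + 1, c), (r, c + 1)):
            if (rr, cc) in cellset:
                fine_adj[label[(r, c)]].add(label[(rr, cc)])
                fine_adj[label[(rr, cc)]].add(label[(r, c)])
    # serpentine order keeps consecutive cells adjacent, so each segment is
    # a connected block
    snake = []
    for r in range(n_rows):
        row = [rc for rc in cells if rc[0] == r]
        row.sort(key=lambda rc: rc[1], reverse=bool(r % 2))
        snake.extend(row)
    sizes = [9] * 15 + [8] * 3
    parent: dict[str, str] = {}
    pos = 0
    coarse_ids = []
    for b, size in enumerate(sizes):
        cid = f"d{b:02d}"
        coarse_ids.append(cid)
        for rc in snake[pos : pos + size]:
            parent[label[rc]] = cid
        pos += size
    fine_ids = [label[rc] for rc in snake]
    geog = MultiscaleGeography(fine_ids, coarse_ids, parent, fine_adj, {c: set() for c in coarse_ids})
    geog.coarse_adjacency = induced_coarse_adjacency(geog)
    return geog


# ---------------------------------------------------------------------------
# random fields


def sample_icar(adjacency, sigma_v: float, rng: np.random.Generator) -> np.ndarray:
    """Draw an intrinsic CAR field on a graph given as dict-of-neighbour-sets.

    Each connected component's draw comes from the degenerate Gaussian
    with precision (D − W)/sigma_v² restricted to the component's
    sum-to-zero subspace, constructed by eigendecomposition of the
    component Laplacian.  Islands are drawn Normal(0, sigma_v²) (the
    proper prior they carry in the model).  The output sums to zero
    within every multi-node component by construction.
    """
    if sigma_v <= 0:
        raise ValueError(f"sigma_v must be positive, got {sigma_v}")
    ids = list(adjacency)
    pos = {u: i for i, u in enumerate(ids)}
    n = len(ids)
    out = np.zeros(n)
    seen: set[str] = set()
    for start in ids:
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        stack = [start]
        while stack:
            u = stack.pop()
            for b in sorted(adjacency[u]):
                if b not in seen:
                    seen.add(b)
                    comp.append(b)
                    stack.append(b)
        idx = np.array([pos[u] for u in comp])
        if len(comp) == 1:
            out[idx[0]] = rng.normal(0.0, sigma_v)
            continue
        lap = np.zeros((len(comp), len(comp)))
        local = {u: k for k, u in enumerate(comp)}
        for u in comp:
            for b in adjacency[u]:
                lap[local[u], local[u]] += 1.0
                lap[local[u], local[b]] -= 1.0
        w, q = np.linalg.eigh(lap)
        keep = w > 1e-10  # drop the constant null direction
        z = rng.standard_normal(int(keep.sum()))
        draw = q[:, keep] @ (z * sigma_v / np.sqrt(w[keep]))
        out[idx] = draw - draw.mean()  # exact zero sum despite roundoff
    return out


# ---------------------------------------------------------------------------
# datasets


@dataclass
class SimulationTruth:
    """The generating parameter values and design of one synthetic study.

    Defaults follow the scale of the motivating Georgia low-birth-weight
    analysis: baseline risk around 10% (intercept −2.2 on the log-odds
    scale), a fine-level covariate effect of −0.1 per SD of income, and
    random-effect standard deviations of the order seen in convolution
    models of such data.  Covariates are in thousands of dollars.
    """

    beta0_fine: float = -2.2
    beta0_coarse: float = -2.2
    beta1_fine: float = -0.1
    beta1_coarse: float = -0.06
    sigma_v_fine: float = 0.1
    sigma_eps_fine: float = 0.1
    sigma_v_coarse: float = 0.3
    sigma_eps_coarse: float = 0.05
    model_kind: str = "shared"
    n_trials: int = 500
    x_mean: float = 40.0
    x_sd: float = 8.0
    x_gradient: float = 0.0  # per-column raw-scale trend across the lattice
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        return cls(**json.loads(text))


def simulate_dataset(
    geog: MultiscaleGeography,
    truth: SimulationTruth,
    rng: np.random.Generator | int | None = None,
) -> tuple[MultiscaleData, ParameterState]:
    """Simulate one aggregation-consistent dataset under the truth.

    Fine covariates are Normal(x_mean, x_sd) (plus an optional smooth
    column gradient on lattice geographies); coarse covariates are parent
    means.  Random effects are drawn from their priors at the truth's
    sigmas; fine outcomes are Binomial(n, expit(eta)); coarse outcomes
    and trials are parent *sums* of the fine ones.  Returns the dataset
    and the generating random-effect state (for recovery scoring).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(truth.seed if rng is None else rng)
    n1 = np.full(geog.n_fine, int(truth.n_trials), dtype=np.int64)
    x1_raw = rng.normal(truth.x_mean, truth.x_sd, size=geog.n_fine)
    if truth.x_gradient:
        x1_raw = x1_raw + truth.x_gradient * _column_coord(geog.fine_ids)

    v1 = sample_icar(geog.fine_adjacency, truth.sigma_v_fine, rng)
    v2 = sample_icar(geog.coarse_adjacency, truth.sigma_v_coarse, rng)
    e1 = rng.normal(0.0, truth.sigma_eps_fine, size=geog.n_fine)
    e2 = rng.normal(0.0, truth.sigma_eps_coarse, size=geog.n_coarse)

    fine_index = pd.Index(geog.fine_ids)
    x2_raw = geog.aggregate(pd.Series(x1_raw, index=fine_index), "mean").to_numpy()

    fine = LevelData.from_raw(np.zeros(geog.n_fine, dtype=np.int64), n1, x1_raw)
    coarse_n = geog.aggregate(pd.Series(n1, index=fine_index), "sum").to_numpy().astype(np.int64)
    coarse = LevelData.from_raw(np.zeros(geog.n_coarse, dtype=np.int64), coarse_n, x2_raw)
    data = MultiscaleData(fine=fine, coarse=coarse)

    state = ParameterState(
        beta0=np.array([truth.beta0_fine, truth.beta0_coarse]),
        beta1=np.array([truth.beta1_fine, truth.beta1_coarse]),
        v1=v1,
        v2=v2,
        eps1=e1,
        eps2=e2,
        sigma_v=np.array([truth.sigma_v_fine, truth.sigma_v_coarse]),
        sigma_eps=np.array([truth.sigma_eps_fine, truth.sigma_eps_coarse]),
    )
    spec = ModelSpec(model_kind=truth.model_kind)
    eta1 = linear_predictor(state, data, geog, 1, spec)
    y1 = rng.binomial(n1, expit(eta1))
    # coarse counts ARE sums of fine counts, as in aggregated surveillance data
    y2 = geog.aggregate(pd.Series(y1, index=fine_index), "sum").to_numpy().astype(np.int64)

    data.fine.y = y1.astype(np.int64)
    data.coarse.y = y2
    return data, state


def _column_coord(fine_ids) -> np.ndarray:
    cols = []
    for u in fine_ids:
        try:
            cols.append(float(u.rsplit("_", 1)[1]))
        except (IndexError, ValueError):
            cols.append(0.0)
    cols = np.asarray(cols)
    return cols - cols.mean()
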