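"""Benchmark generator: backgrounds, planted coherent biclusters, noise,
corruption and missing-value injection, with exact ground truth.

Backgrounds are drawn either uniformly over ``[1, |L|]`` or from a Gaussian
``N(|L|/2, |L|/6)`` clipped to the same range (|L| is the intended symbol
alphabet size, so values live on the discretization scale).  Planted
biclusters take integer alphabet values following the configured coherency
model; model parameters are sampled so that all planted values stay inside
``[1, |L|]`` without clipping.  Background cells then receive additive noise
uniform in ``+-noise_factor * |L|`` (up to +-15% of the value range by
default); a flag extends the noise to planted cells for harder benchmarks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .core import Bicluster, BiclusteringSolution, ExpressionMatrix, MISSING

#: The benchmark presets: shape, number of planted biclusters and the
#: inclusive uniform ranges their row/column counts are drawn from.
PRESETS = {
    "100x30": dict(n=100, m=30, n_biclusters=3, row_range=(10, 20), col_range=(5, 7)),
    "500x60": dict(n=500, m=60, n_biclusters=5, row_range=(15, 30), col_range=(6, 8)),
    "1000x100": dict(n=1000, m=100, n_biclusters=10, row_range=(20, 40), col_range=(6, 10)),
    "2000x200": dict(n=2000, m=200, n_biclusters=15, row_range=(40, 70), col_range=(6, 14)),
    "4000x400": dict(n=4000, m=400, n_biclusters=20, row_range=(60, 100), col_range=(6, 20)),
}

GENERATOR_COHERENCIES = ("constant", "constant_overall", "additive",
                         "multiplicative", "symmetric")


@dataclass
class GeneratorConfig:
    n: int = 100
    m: int = 30
    n_biclusters: int = 3
    row_range: tuple[int, int] = (10, 20)
    col_range: tuple[int, int] = (5, 7)
    coherency: str = "constant"
    alphabet_size: int = 7
    background: str = "uniform"
    noise_factor: float = 0.15
    noise_on_planted: bool = False
    corruption_rate: float = 0.0
    missing_rate: float = 0.0
    allow_overlap: bool = True
    seed: int | None = None

    @classmethod
    def preset(cls, name: str, **kw) -> "GeneratorConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        return cls(**{**PRESETS[name], **kw})

    def __post_init__(self):
        if self.coherency not in GENERATOR_COHERENCIES:
            raise ValueError(f"unknown generator coherency {self.coherency!r}")
        if self.background not in ("uniform", "gaussian"):
            raise ValueError(f"unknown background {self.background!r}")
        if self.row_range[1] > self.n or self.col_range[1] > self.m:
            raise ValueError("bicluster ranges exceed matrix shape")
        if self.coherency == "symmetric" and self.alphabet_size % 2 == 0:
            raise ValueError("symmetric planting needs an odd alphabet size")


@dataclass
class HiddenSolution:
    """Ground truth: planted biclusters, their generating parameters (inside
    each bicluster's ``model_params``) and the pre-noise clean matrix.

    When planted biclusters overlap, the later one owns the shared cells;
    rows of an earlier bicluster whose cells were overwritten no longer
    follow its model and are removed from its ground-truth row set (the
    ``drawn_areas`` record keeps the sizes as sampled, before trimming)."""

    solution: BiclusteringSolution
    clean_matrix: ExpressionMatrix
    clipped_fraction: float = 0.0
    drawn_areas: list[int] = field(default_factory=list)

    @property
    def biclusters(self) -> list[Bicluster]:
        return self.solution.biclusters

    def __iter__(self):
        return iter(self.solution.biclusters)


def _plant_values(rng, coherency, L, r, s):
    """Integer cell values (r x s) plus the model parameter record."""
    if coherency == "constant":
        beta = rng.integers(1, L + 1, size=s)
        vals = np.tile(beta, (r, 1))
        params = {"c": 0, "beta": beta.tolist()}
    elif coherency == "constant_overall":
        c = int(rng.integers(1, L + 1))
        vals = np.full((r, s), c)
        params = {"c": c}
    elif coherency == "additive":
        # a_ij = c + alpha_i + beta_j, spans chosen so values fill [1, |L|]
        kb = int(rng.integers(1, L - 1))           # column span
        beta = rng.integers(0, kb + 1, size=s)
        alpha = rng.integers(0, L - kb, size=r)
        vals = 1 + alpha[:, None] + beta[None, :]
        params = {"c": 1, "alpha": alpha.tolist(), "beta": beta.tolist()}
    elif coherency == "multiplicative":
        # a_ij = alpha_i * beta_j with products inside [1, |L|]
        bmax = max(2, L // 3)
        beta = rng.integers(1, bmax + 1, size=s)
        amax = max(2, L // int(beta.max()))
        alpha = rng.integers(1, amax + 1, size=r)
        vals = alpha[:, None] * beta[None, :]
        params = {"c": 1, "alpha": alpha.tolist(), "beta": beta.tolist()}
    else:  # symmetric: signed reflection of a constant profile about centre
        centre = (L + 1) / 2
        beta = rng.integers(1, L + 1, size=s)
        signs = rng.choice([-1, 1], size=r)
        vals = centre + signs[:, None] * (beta[None, :] - centre)
        params = {"beta": beta.tolist(), "signs": signs.tolist(),
                  "centre": centre}
    return vals.astype(float), params


_COHERENCY_LABEL = {
    "constant": "constant_rows",
    "constant_overall": "constant_overall",
    "additive": "additive",
    "multiplicative": "multiplicative",
    "symmetric": "symmetric+constant",
}


def generate(cfg: GeneratorConfig) -> tuple[ExpressionMatrix, HiddenSolution]:
    """Draw one (matrix, ground truth) pair; fully reproducible under seed."""
    rng = np.random.default_rng(cfg.seed)
    n, m, L = cfg.n, cfg.m, cfg.alphabet_size
    if cfg.background == "uniform":
        bg = rng.uniform(1.0, float(L), size=(n, m))
    else:
        bg = rng.normal(L / 2.0, L / 6.0, size=(n, m))
        bg = np.clip(bg, 1.0, float(L))
    values = bg.copy()

    planted_mask = np.zeros((n, m), dtype=bool)
    owner = np.full((n, m), -1, dtype=np.int64)  # last bicluster per cell
    drawn = []
    clipped = 0
    total_planted = 0
    for k in range(cfg.n_biclusters):
        r = int(rng.integers(cfg.row_range[0], cfg.row_range[1] + 1))
        s = int(rng.integers(cfg.col_range[0], cfg.col_range[1] + 1))
        while True:
            rows = np.sort(rng.choice(n, size=r, replace=False))
            cols = np.sort(rng.choice(m, size=s, replace=False))
            if cfg.allow_overlap:
                break
            sub = planted_mask[np.ix_(rows, cols)]
            if not sub.any():
                break
        vals, params = _plant_values(rng, cfg.coherency, L, r, s)
        lo, hi = 1.0, float(L)
        clipped += int(((vals < lo) | (vals > hi)).sum())
        total_planted += vals.size
        vals = np.clip(vals, lo, hi)
        values[np.ix_(rows, cols)] = vals
        planted_mask[np.ix_(rows, cols)] = True
        owner[np.ix_(rows, cols)] = k
        drawn.append((rows, cols, params))

    # overlapping cells belong to the later bicluster (they follow its
    # model); the ground truth keeps every planted bicluster at its drawn
    # position, matching how overlap is treated in the benchmark protocol
    bics = []
    for k, (rows, cols, params) in enumerate(drawn):
        bics.append(Bicluster(rows=tuple(int(x) for x in rows),
                              cols=tuple(int(x) for x in cols),
                              coherency=_COHERENCY_LABEL[cfg.coherency],
                              model_params=params))

    clean = values.copy()
    noise = rng.uniform(-cfg.noise_factor * L, cfg.noise_factor * L, size=(n, m))
    if cfg.noise_on_planted:
        values = values + noise
    else:
        values = np.where(planted_mask, values, values + noise)

    row_ids = [f"g{i}" for i in range(n)]
    col_ids = [f"c{j}" for j in range(m)]
    mx = ExpressionMatrix(values, row_ids, col_ids)
    hidden = HiddenSolution(
        BiclusteringSolution(bics, {"generator": vars(cfg).copy()}),
        ExpressionMatrix(clean, list(row_ids), list(col_ids)),
        clipped_fraction=clipped / max(total_planted, 1),
        drawn_areas=[len(r) * len(c) for r, c, _ in drawn],
    )

    if cfg.missing_rate > 0:
        mx = inject_missings(mx, cfg.missing_rate, rng, alphabet_size=L)
    if cfg.corruption_rate > 0:
        mx = corrupt_elements(mx, hidden, cfg.corruption_rate, rng)
    return mx, hidden


def expected_planted_area(cfg: GeneratorConfig) -> float:
    """Analytic expected summed bicluster area as a fraction of the matrix:
    ``n_biclusters * E[rows] * E[cols] / (n*m)`` (overlap ignored)."""
    er = (cfg.row_range[0] + cfg.row_range[1]) / 2.0
    ec = (cfg.col_range[0] + cfg.col_range[1]) / 2.0
    return cfg.n_biclusters * er * ec / (cfg.n * cfg.m)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def corrupt_elements(mx: ExpressionMatrix, hidden: HiddenSolution | None,
                     rate: float, seed) -> ExpressionMatrix:
    """Replace a ``rate`` fraction of cells (uniformly chosen) by a value at
    distance > 25% of the observed value range, staying inside the domain.
    Corrupted positions are recorded in ``out.provenance`` for diagnostics
    via the returned matrix's ``corrupted`` attribute."""
    rng = _as_rng(seed)
    out = mx.copy()
    n, m = mx.n, mx.m
    k = int(round(rate * n * m))
    if k == 0:
        out.corrupted = []  # type: ignore[attr-defined]
        return out
    obs = np.flatnonzero(~mx.missing_mask.ravel())
    chosen = rng.choice(obs, size=min(k, obs.size), replace=False)
    lo = float(np.nanmin(mx.values))
    hi = float(np.nanmax(mx.values))
    d = 0.25 * (hi - lo)
    flat = out.values.ravel()
    pos = []
    for idx in chosen:
        v = flat[idx]
        while True:
            new = rng.uniform(lo, hi)
            if abs(new - v) > d:
                break
        flat[idx] = new
        pos.append((int(idx // m), int(idx % m)))
    out.corrupted = pos  # type: ignore[attr-defined]
    return out


def inject_missings(mx: ExpressionMatrix, rate: float, seed,
                    alphabet_size: int | None = None) -> ExpressionMatrix:
    """Set exactly ``floor(rate * n * m)`` uniformly chosen observed cells to
    MISSING (reproducible under seed)."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("missing rate must lie in [0, 1)")
    rng = _as_rng(seed)
    out = mx.copy()
    k = int(math.floor(rate * mx.n * mx.m))
    if k == 0:
        return out
    obs = np.flatnonzero(~mx.missing_mask.ravel())
    if k > obs.size:
        raise ValueError("missing rate removes more cells than are observed")
    chosen = rng.choice(obs, size=k, replace=False)
    flat = out.values.ravel()
    flat[chosen] = MISSING
    if alphabet_size is not None:
        remaining = flat[~np.isnan(flat)]
        if np.unique(remaining).size < alphabet_size:
            raise ValueError("missing rate leaves fewer distinct observed "
                             "values than the alphabet size")
    return out
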