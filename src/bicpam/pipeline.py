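"""End-to-end orchestration: mapping -> (coherency-aware) mining -> closing.

Defaults are data-driven where the method itself gives no universal value:
the minimum pattern length and the support floor of the adaptive loop are
estimated from the database's own item-frequency profile so that the
expected number of chance patterns surviving the floor stays below a small
budget (see :func:`bicpam.mining.estimate_mining_defaults`).  The support
schedule starts at 25% of the rows and decays by 10% per rung; by default it
runs down to the estimated floor (favouring completeness of the solution),
with the covered-area target available as an early-stop for dense data.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np

from .closing import ClosingConfig, close_solution
from .coherency import make_merge_guard, make_row_trimmer, mine_coherent
from .core import BiclusteringSolution, ExpressionMatrix
from .mapping import (MappingConfig, assign_boundary_items, build_transactions,
                      discretize, handle_missing, normalize)
from .mining import MiningConfig, estimate_mining_defaults
from . import core

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full parameter record for one run.

    ``alphabets`` allows pooling solutions mined at several discretization
    granularities (e.g. ``[3, 5, 7]``); they are closed jointly after
    pooling.  ``coherency`` is ``constant`` or one of the aligned modes
    (``additive``, ``multiplicative``, ``symmetric[+base]``).
    """

    mapping: MappingConfig = field(default_factory=lambda: MappingConfig(
        boundary_multi_item=True, missing_strategy="delta_replace"))
    mining: MiningConfig = field(default_factory=lambda: MiningConfig(
        representation="closed", coverage_target=1.0))
    closing: ClosingConfig = field(default_factory=ClosingConfig)
    coherency: str = "constant"
    orientation: str = "rows"
    alphabets: list[int] | None = None
    lcm_delta: float = 0.1
    auto_tune: bool = True
    spurious_budget: float = 0.1
    seed: int | None = None

    def resolved_alphabets(self) -> list[int]:
        return list(self.alphabets) if self.alphabets else [self.mapping.alphabet_size]


def _provenance(cfg: RunConfig, stage_log: dict) -> dict:
    return {
        "mapping": vars(cfg.mapping).copy(),
        "mining": {k: v for k, v in vars(cfg.mining).items()},
        "closing": vars(cfg.closing).copy(),
        "coherency": cfg.coherency,
        "orientation": cfg.orientation,
        "alphabets": cfg.resolved_alphabets(),
        "lcm_delta": cfg.lcm_delta,
        "auto_tune": cfg.auto_tune,
        "seed": cfg.seed,
        "stages": stage_log,
    }


def run_bicpam(mx: ExpressionMatrix, cfg: RunConfig | None = None) -> BiclusteringSolution:
    """Run the full pipeline and return a validated solution.

    Deterministic: all stages are deterministic given the input matrix and
    configuration (the recorded ``seed`` only labels provenance; the
    generator, not the pipeline, consumes randomness).
    """
    cfg = cfg or RunConfig()
    if cfg.orientation == "columns":
        tmx = core.transpose(mx)
        inner = replace(cfg, orientation="rows")
        sol = run_bicpam(tmx, inner)
        flipped = [core.Bicluster(rows=b.cols, cols=b.rows, coherency=b.coherency,
                                  model_params=b.model_params)
                   for b in sol.biclusters]
        sol.biclusters = flipped
        sol.provenance["orientation"] = "columns"
        sol.validate(mx.n, mx.m)
        return sol

    stage_log: dict = {}
    pooled = []
    last_itemized = None
    last_db = None
    has_missing = bool(mx.missing_mask.any())
    for L in cfg.resolved_alphabets():
        t0 = time.perf_counter()
        mcfg = replace(cfg.mapping, alphabet_size=L)
        if cfg.coherency.startswith("symmetric"):
            mcfg = replace(mcfg, zero_centered=True, zero_mean=True)
            if mcfg.normalization_scope == "none":
                mcfg = replace(mcfg, normalization_scope="overall")
        normed = normalize(mx, mcfg.normalization_scope, mcfg.zero_mean)
        it = discretize(normed, mcfg)
        if mcfg.boundary_multi_item:
            it = assign_boundary_items(it, normed, mcfg.epsilon)
        if has_missing:
            it = handle_missing(it, normed, mcfg.missing_strategy,
                                (mcfg.delta_min_items, mcfg.delta_max_items))
        t_map = time.perf_counter() - t0

        n_alignments = 1 if cfg.coherency in (
            "constant", "constant_rows", "constant_overall") else it.m
        tune = None
        if cfg.auto_tune:
            budget = cfg.spurious_budget / n_alignments
            # scale coherency admits many more chance agreements (any
            # proportional row pair collides), so one more column is required
            cap = 5 if "multiplicative" in cfg.coherency else 4

            def tune(db, _budget=budget, _m=it.m, _cap=cap):
                return estimate_mining_defaults(db, _m, spurious_budget=_budget,
                                                max_min_cols=_cap)

        mine_log: list = []
        bics = mine_coherent(it, cfg.coherency, cfg.mining,
                             delta=cfg.lcm_delta, adaptive=True,
                             tune=tune, calibrate=cfg.auto_tune, log=mine_log)
        t_mine = time.perf_counter() - t0 - t_map
        cal = [e["calibrated_floors"] for e in mine_log if "calibrated_floors" in e]
        stage_log[f"alphabet_{L}"] = {
            "mapping_seconds": round(t_map, 3),
            "mining_seconds": round(t_mine, 3),
            "n_raw_biclusters": len(bics),
            "calibrated_floors": cal[0] if cal else None,
            "adaptive_log": [e for e in mine_log[-3:] if "theta" in e],
        }
        logger.info("alphabet %d: %d raw biclusters (map %.2fs, mine %.2fs)",
                    L, len(bics), t_map, t_mine)
        pooled.extend(bics)
        last_itemized = it
        last_db = build_transactions(it, "rows")

    def remine():
        kw = {}
        if cfg.auto_tune and last_db is not None:
            mc, _fl = estimate_mining_defaults(last_db, last_itemized.m,
                                               spurious_budget=cfg.spurious_budget)
            kw["min_cols"] = mc
        relaxed_cfg = replace(
            cfg.mining,
            theta=max(cfg.mining.support_floor,
                      int(np.floor(_last_theta(stage_log) *
                                   cfg.closing.extension_support_decay))),
            **kw)
        return mine_coherent(last_itemized, cfg.coherency, relaxed_cfg,
                             delta=cfg.lcm_delta, adaptive=False)

    guard = make_merge_guard(last_itemized, cfg.coherency,
                             tau_q=cfg.closing.merge_overlap,
                             delta=cfg.lcm_delta) if last_itemized is not None else None
    floor_dicts = [rec["calibrated_floors"] for rec in stage_log.values()
                   if rec.get("calibrated_floors")]
    min_support: dict | None = None
    if floor_dicts:
        min_support = {}
        for d in floor_dicts:  # across alphabets keep the loosest floor
            for c, f in d.items():
                min_support[c] = min(min_support.get(c, f), f)
    trimmer = make_row_trimmer(last_itemized, cfg.coherency,
                               h=cfg.closing.homogeneity_min,
                               delta=cfg.lcm_delta) if last_itemized is not None else None
    closed = close_solution(pooled, mx, cfg.closing,
                            itemized=last_itemized, remine=remine, guard=guard,
                            min_support=min_support, row_trim=trimmer)
    sol = BiclusteringSolution(closed, _provenance(cfg, stage_log))
    sol.validate(mx.n, mx.m)
    return sol


def _last_theta(stage_log: dict) -> int:
    for rec in reversed(list(stage_log.values())):
        if rec.get("adaptive_log"):
            return rec["adaptive_log"][-1]["theta"]
    return 2
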