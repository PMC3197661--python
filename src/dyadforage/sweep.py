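"""Random parameter generation and the 2^4 interference-cost factorial.

A sweep draws ``n_sets`` random parameter sets (six uniform draws each) and,
for every set, solves the game under all sixteen scenarios in which each of
the four interference costs D_dRsR, D_dFsR, D_dRsF, D_dFsF is either 0 or 1
state units.  The six draws are shared across a set's sixteen scenarios, so
cost effects are compared within parameter sets — this within-set pairing
is what makes the factorial ANOVA on the resulting table meaningful.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .params import COST_NAMES, derive_parameters
from .solver import ConvergenceError, solve_ess
from .stationary import stationary_distribution
from .summary import SummaryRecord, summarize_run

__all__ = ["SweepDesign", "build_design", "run_sweep", "SCENARIOS"]

logger = logging.getLogger(__name__)

#: the sixteen cost scenarios, in lexicographic order over COST_NAMES
SCENARIOS = tuple(itertools.product((0, 1), repeat=4))


@dataclasses.dataclass(frozen=True)
class SweepDesign:
    """The full run plan: one row per (parameter set x cost scenario)."""

    table: pd.DataFrame
    master_seed: int

    @property
    def n_sets(self) -> int:
        return self.table["set_id"].nunique()

    def __len__(self) -> int:
        return len(self.table)


def build_design(n_sets: int, master_seed: int) -> SweepDesign:
    """Draw ``n_sets`` parameter sets and cross them with the 16 scenarios.

    The six uniform(0, 1) draws r1..r6 are sampled once per set and shared
    by that set's sixteen scenario rows.  Each row receives its own
    deterministic substream seed derived from the master seed.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    ss = np.random.SeedSequence(master_seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    rows = []
    run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_sets * len(SCENARIOS))]
    run = 0
    for set_id in range(n_sets):
        draws = rng.uniform(size=6)
        for scenario in SCENARIOS:
            row = {"run_id": run, "set_id": set_id}
            row.update({f"r{i+1}": draws[i] for i in range(6)})
            row.update(dict(zip(COST_NAMES, scenario)))
            row["run_seed"] = run_seeds[run]
            rows.append(row)
            run += 1
    return SweepDesign(pd.DataFrame(rows), master_seed)


def _run_one(row: pd.Series, overrides: dict) -> SummaryRecord:
    draws = [row[f"r{i}"] for i in range(1, 7)]
    costs = {name: float(row[name]) for name in COST_NAMES}
    params = derive_parameters(*draws, **costs, **overrides)
    ess = solve_ess(params)
    dist = stationary_distribution(ess.policy, params)
    return summarize_run(ess, params, dist=dist,
                         set_id=int(row["set_id"]), seed=int(row["run_seed"]))


def run_sweep(
    design: SweepDesign,
    overrides: dict | None = None,
    out: str | Path | None = None,
) -> pd.DataFrame:
    """Execute every run of a design and collect the results table.

    ``overrides`` are fixed-field overrides applied to every parameter set
    (e.g. ``{"S": 20}`` for a desk-scale sweep).  Failed runs are recorded
    with ``failed=True`` and the error message, never aborting the sweep.
    When ``out`` is given, rows are appended to the CSV incrementally so an
    interrupted sweep can be inspected (and not silently lost).
    """
    overrides = dict(overrides or {})
    out_path = Path(out) if out is not None else None
    records = []
    t_start = time.time()
    for _, row in design.table.iterrows():
        t0 = time.time()
        try:
            rec = _run_one(row, overrides)
        except (ConvergenceError, ValueError) as exc:
            logger.warning("run %s failed: %s", row["run_id"], exc)
            rec = SummaryRecord(
                *([np.nan] * 15),
                **{name: float(row[name]) for name in COST_NAMES},
                set_id=int(row["set_id"]), seed=int(row["run_seed"]),
                failed=True, error=str(exc),
            )
        rec_dict = {"run_id": int(row["run_id"]),
                    **{f"r{i}": row[f"r{i}"] for i in range(1, 7)},
                    **rec.to_dict()}
        records.append(rec_dict)
        logger.info("run %s done in %.2fs", row["run_id"], time.time() - t0)
        if out_path is not None:
            pd.DataFrame([rec_dict]).to_csv(
                out_path, mode="a", header=not out_path.exists(), index=False,
                float_format="%.12g",
            )
    logger.info("sweep of %d runs finished in %.1fs", len(records), time.time() - t_start)
    return pd.DataFrame(records)
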