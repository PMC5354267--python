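"""Saturation analysis: accumulation of unique residue pairs over LC-MS runs.

Whether further acquisitions would keep adding identifications is read off the
mean cumulative-unique-pair curve over permuted run orders (100 permutations
by default; with seven runs or fewer all orders are enumerated exactly, which
removes Monte-Carlo noise entirely).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

EXHAUSTIVE_MAX_RUNS = 7


@dataclass
class RunAccumulation:
    run_ids: list
    mean_cumulative: np.ndarray
    std_cumulative: np.ndarray
    n_permutations: int
    seed: int | None
    exhaustive: bool

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rank": np.arange(1, len(self.mean_cumulative) + 1),
                             "mean_cumulative": self.mean_cumulative,
                             "std": self.std_cumulative})


def saturation_curve(pairs_by_run: Mapping, n_permutations: int = 100,
                     seed: int = 0) -> RunAccumulation:
    """Mean cumulative unique-pair counts per rank over run-order permutations.

    Every individual permutation's curve is non-decreasing and ends at the
    total unique-pair count, so the mean does too.
    """
    run_ids = sorted(pairs_by_run)
    if not run_ids:
        raise ValueError("need at least one run")
    sets = [frozenset(tuple(sorted(p)) for p in pairs_by_run[r]) for r in run_ids]
    k = len(sets)
    exhaustive = k <= EXHAUSTIVE_MAX_RUNS
    if exhaustive:
        orders = list(itertools.permutations(range(k)))
    else:
        rng = np.random.default_rng(seed)
        orders = [tuple(rng.permutation(k)) for _ in range(n_permutations)]
    curves = np.empty((len(orders), k), dtype=float)
    for o, order in enumerate(orders):
        seen: set = set()
        for rank, idx in enumerate(order):
            seen |= sets[idx]
            curves[o, rank] = len(seen)
    return RunAccumulation(run_ids, curves.mean(axis=0), curves.std(axis=0),
                           len(orders), None if exhaustive else seed, exhaustive)


def expected_curve_inclusion_exclusion(pairs_by_run: Mapping) -> np.ndarray:
    """Analytic E[|union of the first r sets|] under a uniformly random run
    order, by inclusion–exclusion over the pair universe: a pair present in m
    of the k runs is missing from the first r with probability
    C(k-m, r)/C(k, r)."""
    run_ids = sorted(pairs_by_run)
    sets = [frozenset(tuple(sorted(p)) for p in pairs_by_run[r]) for r in run_ids]
    k = len(sets)
    universe = set().union(*sets) if sets else set()
    out = np.zeros(k)
    for pair in universe:
        m = sum(1 for s in sets if pair in s)
        for r in range(1, k + 1):
            p_missing = (math.comb(k - m, r) / math.comb(k, r)) if k - m >= r else 0.0
            out[r - 1] += 1.0 - p_missing
    return out


def saturation_slope(curve: RunAccumulation, saturated_fraction: float = 0.01
                     ) -> dict:
    """Per-rank marginal gains (first differences of the mean curve) and a
    saturation flag: saturated when the final marginal gain falls below
    ``saturated_fraction`` of the total."""
    mean = curve.mean_cumulative
    gains = np.diff(mean)
    total = mean[-1]
    last_gain = float(gains[-1]) if gains.size else 0.0
    return {"gains": gains,
            "saturated": bool(total == 0 or last_gain < saturated_fraction * total),
            "final_total": float(total)}


def pairs_by_run_from_frame(df: pd.DataFrame) -> dict:
    """Group a residue-pair table (pos_a, pos_b, runs ';'-joined or run_id
    column) into per-run pair sets."""
    out: dict = {}
    if "run_id" in df.columns:
        for row in df.itertuples(index=False):
            out.setdefault(row.run_id, set()).add((row.pos_a, row.pos_b))
    elif "runs" in df.columns:
        for row in df.itertuples(index=False):
            for r in str(row.runs).split(";"):
                if r:
                    out.setdefault(r, set()).add((row.pos_a, row.pos_b))
    else:
        raise ValueError("need a run_id or runs column")
    return out
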