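"""Steady-state multistability census over random parameter sets.

For each sampled parameter set, steady states are sought by integration from
several random initial conditions (all species uniform on [0, 1]); the
converged states are deduplicated by a max-norm tolerance well above the
steady-state resolution, and a parameter set is called multistable when more
than one distinct state remains.  Parameter sets where no initial condition
converges are counted as having no steady state (such sets plausibly sit on
limit cycles, which this census does not classify).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import find_steady_state
from .screen import _record_rng, sample_one

__all__ = ["MultistabRecord", "run_multistab_census", "compare_parameter_distributions"]

#: two converged states closer than this (max-norm) are the same attractor;
#: 100x the steady-state resolution separates numerical jitter from
#: genuinely distinct states by two orders of magnitude
DEDUP_TOL = 1e-2


@dataclass
class MultistabRecord:
    index: int
    sampled_params: np.ndarray
    n_ic: int
    n_converged: int
    distinct_states: list = field(default_factory=list)

    @property
    def n_distinct(self) -> int:
        return len(self.distinct_states)


def dedup_states(states: list, tol: float = DEDUP_TOL) -> list:
    """Cluster converged states into distinct attractors (order-independent).

    States are sorted lexicographically before greedy clustering, so any
    permutation of the input yields the same representatives.
    """
    if not states:
        return []
    arr = np.array(states)
    order = np.lexsort(arr.T[::-1])
    distinct: list[np.ndarray] = []
    for idx in order:
        s = arr[idx]
        if all(np.max(np.abs(s - d)) >= tol for d in distinct):
            distinct.append(s)
    return distinct


def run_multistab_census(
    model,
    n_params: int = 5000,
    n_ic: int = 15,
    seed: int = 0,
    resolution: float = 1e-4,
    t_max: float = 1e6,
    dedup_tol: float = DEDUP_TOL,
    progress=None,
) -> tuple[list, dict]:
    """Census of steady-state multiplicity; returns (records, summary)."""
    if n_params < 1 or n_ic < 1:
        raise ValueError("n_params and n_ic must be >= 1")
    table = model.params
    records: list[MultistabRecord] = []
    for i in range(n_params):
        sampled = sample_one(table, _record_rng(seed, i, stream=2))
        pvec = table.vector_from_sampled(sampled)
        converged = []
        for k in range(n_ic):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(3, i, k))
            )
            x0 = rng.uniform(0.0, 1.0, model.n_species)
            ss = find_steady_state(
                model, x0, resolution=resolution, t_max=t_max, params=pvec
            )
            if ss.converged:
                converged.append(ss.state)
        records.append(
            MultistabRecord(i, sampled, n_ic, len(converged),
                            dedup_states(converged, dedup_tol))
        )
        if progress is not None:
            progress(i)
    n_any = sum(r.n_distinct >= 1 for r in records)
    n_multi = sum(r.n_distinct > 1 for r in records)
    summary = {
        "n_params": n_params,
        "n_ic": n_ic,
        "seed": seed,
        "with_steady_state": n_any,
        "multistable": n_multi,
        "frac_with_steady_state": n_any / n_params,
        "frac_multistable": n_multi / n_params,
    }
    return records, summary


def records_frame(records: list, table) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {"index": r.index, "n_ic": r.n_ic, "n_converged": r.n_converged,
             "n_distinct": r.n_distinct,
             **dict(zip(table.sampled_names, r.sampled_params))}
        )
    return pd.DataFrame(rows)


def compare_parameter_distributions(records: list, table) -> pd.DataFrame:
    """Median of each sampled parameter in monostable vs multistable sets.

    Returns per-parameter medians and the fold change median_multi /
    median_mono, sorted by decreasing |log fold change|.  Also the data
    source for scatter/histogram views of any parameter pair.
    """
    frame = records_frame(records, table)
    mono = frame[(frame["n_distinct"] == 1)]
    multi = frame[frame["n_distinct"] > 1]
    if not len(mono) or not len(multi):
        raise ValueError("need at least one monostable and one multistable set")
    rows = []
    for name in table.sampled_names:
        m1 = float(mono[name].median())
        m2 = float(multi[name].median())
        rows.append({"parameter": name, "median_mono": m1, "median_multi": m2,
                     "fold_change": m2 / m1})
    out = pd.DataFrame(rows)
    out["abs_log_fold"] = np.abs(np.log10(out["fold_change"]))
    out = out.sort_values("abs_log_fold", ascending=False).drop(columns="abs_log_fold")
    return out.reset_index(drop=True)
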