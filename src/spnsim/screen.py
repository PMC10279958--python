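"""Random-parameter robustness screen with the stripe-pattern score.

For each try, the 48 sampled parameters are drawn log-uniformly within their
registry ranges, the model is integrated from the preset initial condition
over the standard 1100-time-unit horizon, and the trajectory is scored
against the target stripe pattern.  A try is a hit when the integration
succeeded and the score is below 0.2 (at least five-fold on/off separation
for every scored mRNA).  Failed integrations count as tries, never as hits.

Per-record seeds are derived independently from (seed, index), so batches
are order-independent and resumable.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .dynamics import Trajectory, run_timecourse
from .params import ParameterTable
from .presets import ICPreset, PatternTarget, default_target

__all__ = [
    "sample_parameters",
    "pattern_score",
    "run_screen",
    "export_hit_profile",
    "HIT_THRESHOLD",
]

HIT_THRESHOLD = 0.2
#: numerical floor applied to both the on- and off-cell averages before the
#: ratio: far below any resolvable concentration, it clamps integrator
#: overshoot (tiny negatives) and makes a fully decayed (everything ~ 0)
#: trajectory score 1, never a spurious perfect stripe
SCORE_EPS = 1e-12


def _record_rng(seed: int, index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream, index)))


def sample_one(table: ParameterTable, rng: np.random.Generator) -> np.ndarray:
    """One 48-vector of sampled parameter values (registry order)."""
    out = np.empty(table.n_sampled)
    j = 0
    for row in table.rows:
        if not row.sampled:
            continue
        if row.scale == "log":
            lo, hi = math.log10(row.range_lo), math.log10(row.range_hi)
            out[j] = 10.0 ** rng.uniform(lo, hi)
        else:
            out[j] = rng.uniform(row.range_lo, row.range_hi)
        j += 1
    return out


def sample_parameters(
    table: ParameterTable, n: int, seed: int, stream: int = 1
) -> np.ndarray:
    """(n, 48) matrix of sampled parameter vectors, reproducible from seed."""
    for row in table.rows:
        if row.sampled and not (0 < row.range_lo < row.range_hi):
            raise ValueError(f"invalid range for {row.name}")
    return np.array([sample_one(table, _record_rng(seed, i, stream)) for i in range(n)])


def pattern_score(
    traj: Trajectory,
    target: PatternTarget | None = None,
    window: float = 200.0,
) -> float:
    """Stripe-pattern score: max over scored mRNAs of (max off) / (min on).

    Concentrations are time-averaged over the trailing ``window`` time units.
    0 is a perfect pattern; a uniform pattern scores 1; scores below 0.2
    demand at least five-fold separation for every scored species.  Failed
    trajectories score +inf.
    """
    if traj.status != "ok":
        return math.inf
    target = target if target is not None else default_target()
    t_end = traj.times[-1]
    mask = traj.times >= t_end - window
    mean_state = traj.states[mask].mean(axis=0)
    name_to_idx = {n: i for i, n in enumerate(traj.species_names)}
    score = 0.0
    for gene, on_cells in target.on.items():
        def cell_val(cell1: int) -> float:
            return mean_state[name_to_idx[f"{gene}_0_{cell1 - 1}"]]

        m_on = max(min(cell_val(c) for c in on_cells), SCORE_EPS)
        m_off = max(max(cell_val(c) for c in target.off[gene]), SCORE_EPS)
        score = max(score, m_off / m_on)
    return float(score)


def run_screen(
    model,
    preset: ICPreset,
    n_tries: int,
    seed: int,
    target: PatternTarget | None = None,
    t_end: float = 1100.0,
    dt_out: float = 5.0,
    window: float = 200.0,
    threshold: float = HIT_THRESHOLD,
    count_failures_as_tries: bool = True,
    start: int = 0,
    progress=None,
) -> tuple[pd.DataFrame, dict]:
    """Screen ``n_tries`` random parameter sets from one preset.

    Returns (records, summary).  ``start`` offsets the record indices so
    batches [0,n) and [n,2n) of the same seed compose into one larger screen.
    """
    table = model.params
    target = target if target is not None else default_target()
    x0 = preset.build(model)
    recs = []
    for i in range(start, start + n_tries):
        sampled = sample_one(table, _record_rng(seed, i, stream=1))
        pvec = table.vector_from_sampled(sampled)
        traj = run_timecourse(model, x0, t_end=t_end, dt_out=dt_out, params=pvec)
        score = pattern_score(traj, target, window)
        hit = traj.status == "ok" and score < threshold
        recs.append(
            {"index": i, "seed": seed, "score": score, "hit": hit,
             "status": traj.status,
             **dict(zip(table.sampled_names, sampled))}
        )
        if progress is not None:
            progress(i)
    records = pd.DataFrame(recs)
    if len(records):
        n_failed = int((records["status"] != "ok").sum())
        hits = int(records["hit"].sum())
    else:
        n_failed, hits = 0, 0
    tries = n_tries if count_failures_as_tries else n_tries - n_failed
    summary = {
        "preset": preset.name,
        "seed": seed,
        "tries": tries,
        "hits": hits,
        "failed": n_failed,
        "hit_rate": hits / tries if tries else 0.0,
        "tries_per_hit": tries / hits if hits else math.inf,
    }
    return records, summary


def export_hit_profile(
    records: pd.DataFrame,
    table: ParameterTable,
    include_half_lives: bool = False,
    include_cooperativities: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalized log-range positions of the hit parameter sets.

    Each hit value x maps to (log x - log lo) / (log hi - log lo) in [0, 1].
    Returns (positions, stats) where stats carries per-parameter mean and SD
    — the data behind a radar/spoke plot of the successful sets.  Half-lives
    and cooperativity exponents are omitted by default, as in the published
    representation.
    """
    hits = records[records["hit"]] if "hit" in records else records
    if not len(hits):
        raise ValueError("no hits to profile")
    cols, pos = [], {}
    for row in table.rows:
        if not row.sampled:
            continue
        if row.category == "half_life" and not include_half_lives:
            continue
        if row.category == "nu" and not include_cooperativities:
            continue
        lo, hi = math.log10(row.range_lo), math.log10(row.range_hi)
        pos[row.name] = (np.log10(hits[row.name].to_numpy()) - lo) / (hi - lo)
        cols.append(row.name)
    positions = pd.DataFrame(pos, columns=cols)
    stats = pd.DataFrame(
        {"parameter": cols,
         "mean": [positions[c].mean() for c in cols],
         "sd": [positions[c].std(ddof=0) for c in cols]}
    )
    return positions, stats
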