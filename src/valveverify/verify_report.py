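"""Simulation-vs-experiment comparison tables and summary errors.

Builds the per-condition verification table (one row per valve model and
dobutamine condition), computes symmetric percent errors, the per-group
mean error, and within-measurement-uncertainty flags.

The error metric is the symmetric percent difference
100 |sim - exp| / ((sim + exp)/2).  The denominator is configurable
(``exp``, ``sim`` or ``mean``) because the convention is ambiguous in
routine reporting; the symmetric (mean) denominator is the default.
Rounding to integer percent happens once, at the group-summary level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

CONDITIONS = ("d0", "d5", "d10", "d20")
VALVES = ("non-calcified", "calcified")

_COLUMNS = ["valve", "dobutamine", "cycle_time_s", "dp_mean_mmhg",
            "q_exp", "q_exp_unc", "q_sim", "q_sim_sd",
            "ava_exp", "ava_exp_lo", "ava_exp_hi",
            "ava_sim", "ava_sim_lo", "ava_sim_hi"]


@dataclass
class VerificationRow:
    valve: str
    dobutamine: str
    cycle_time: float
    dp_mean: float
    q_exp: float
    q_exp_unc: float
    q_sim: float | None
    q_sim_sd: float | None
    ava_exp: float | None = None
    ava_exp_range: tuple | None = None
    ava_sim: float | None = None
    ava_sim_range: tuple | None = None

    def __post_init__(self):
        if self.valve not in VALVES:
            raise ValueError(f"valve must be one of {VALVES}")
        if self.dobutamine not in CONDITIONS:
            raise ValueError(f"dobutamine must be one of {CONDITIONS}")
        for centre, rng in ((self.ava_exp, self.ava_exp_range), (self.ava_sim, self.ava_sim_range)):
            if centre is not None and rng is not None:
                if not rng[0] - 1e-9 <= centre <= rng[1] + 1e-9:
                    raise ValueError("range must contain its central value")


@dataclass
class ErrorSummary:
    group: str  # valve label
    metric: str  # 'q_mean' or 'ava'
    per_condition: dict  # condition -> percent error (unrounded)
    mean_percent: int = field(init=False)

    def __post_init__(self):
        self.mean_percent = int(round(float(np.mean(list(self.per_condition.values())))))


def symmetric_percent_error(sim: float, exp: float, denominator: str = "mean") -> float:
    """Percent difference between simulated and experimental values.

    denominator='mean' gives the symmetric form 100|sim-exp|/((sim+exp)/2);
    'exp' and 'sim' normalise by that single value instead.
    """
    if denominator == "mean":
        den = 0.5 * (sim + exp)
    elif denominator == "exp":
        den = exp
    elif denominator == "sim":
        den = sim
    else:
        raise ValueError("denominator must be 'mean', 'exp' or 'sim'")
    if den == 0:
        return 0.0 if sim == exp else float("inf")
    return 100.0 * abs(sim - exp) / den


def within_uncertainty(sim: float, exp: float, frac: float = 0.10) -> bool:
    """True iff the simulated value lies within frac of the experimental one."""
    return abs(sim - exp) <= frac * abs(exp)


def load_table1(path: str | Path | None = None) -> pd.DataFrame:
    """Load the packaged summary-table fixture (or a user file of the same layout)."""
    if path is None:
        ref = resources.files("valveverify") / "fixtures" / "table1.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    return df


def error_summary(rows: pd.DataFrame, valve: str, metric: str,
                  denominator: str = "mean") -> ErrorSummary:
    """Mean symmetric percent error across the four dobutamine conditions."""
    sub = rows[rows["valve"] == valve].set_index("dobutamine")
    missing = set(CONDITIONS) - set(sub.index)
    if missing:
        raise ValueError(f"missing conditions for {valve}: {sorted(missing)}")
    col_sim, col_exp = {"q_mean": ("q_sim", "q_exp"), "ava": ("ava_sim", "ava_exp")}[metric]
    per = {c: symmetric_percent_error(float(sub.loc[c, col_sim]), float(sub.loc[c, col_exp]),
                                      denominator)
           for c in CONDITIONS}
    return ErrorSummary(group=valve, metric=metric, per_condition=per)


def build_table(rows: list[VerificationRow]) -> pd.DataFrame:
    """Assemble verification rows into the canonical column layout."""
    recs = []
    for r in rows:
        er = r.ava_exp_range or (np.nan, np.nan)
        sr = r.ava_sim_range or (np.nan, np.nan)
        recs.append({"valve": r.valve, "dobutamine": r.dobutamine,
                     "cycle_time_s": r.cycle_time, "dp_mean_mmhg": r.dp_mean,
                     "q_exp": r.q_exp, "q_exp_unc": r.q_exp_unc,
                     "q_sim": np.nan if r.q_sim is None else r.q_sim,
                     "q_sim_sd": np.nan if r.q_sim_sd is None else r.q_sim_sd,
                     "ava_exp": np.nan if r.ava_exp is None else r.ava_exp,
                     "ava_exp_lo": er[0], "ava_exp_hi": er[1],
                     "ava_sim": np.nan if r.ava_sim is None else r.ava_sim,
                     "ava_sim_lo": sr[0], "ava_sim_hi": sr[1]})
    return pd.DataFrame.from_records(recs, columns=_COLUMNS)


def save_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def abstract_error_summaries(table: pd.DataFrame | None = None,
                             denominator: str = "mean") -> dict:
    """The four headline mean-error percentages from the summary table.

    Returns {(valve, metric): integer percent} for flow and AVA on both
    valve models.
    """
    df = load_table1() if table is None else table
    out = {}
    for valve in VALVES:
        for metric in ("q_mean", "ava"):
            out[(valve, metric)] = error_summary(df, valve, metric, denominator).mean_percent
    return out


def pipeline_verify(sim: dict, exp: dict, uncertainty_frac: float = 0.10,
                    denominator: str = "mean") -> pd.DataFrame:
    """Assemble a verification table from per-condition summary dicts.

    ``sim`` and ``exp`` map (valve, condition) to a dict with keys
    ``q_mean`` (and optionally ``q_sd``/``q_unc``, ``ava``, ``ava_range``,
    ``dp_mean``, ``cycle_time``).  Rows are emitted for every key of
    ``exp``; metrics absent on either side are left as NaN.  Adds per-row
    symmetric errors and within-uncertainty flags.
    """
    recs = []
    for key, e in exp.items():
        valve, cond = key
        s = sim.get(key, {})
        q_sim = s.get("q_mean")
        ava_sim = s.get("ava")
        rec = {"valve": valve, "dobutamine": cond,
               "cycle_time_s": e.get("cycle_time", np.nan),
               "dp_mean_mmhg": e.get("dp_mean", np.nan),
               "q_exp": e.get("q_mean", np.nan),
               "q_exp_unc": e.get("q_unc", uncertainty_frac * e.get("q_mean", np.nan)),
               "q_sim": np.nan if q_sim is None else q_sim,
               "q_sim_sd": s.get("q_sd", np.nan),
               "ava_exp": e.get("ava", np.nan),
               "ava_exp_lo": (e.get("ava_range") or (np.nan, np.nan))[0],
               "ava_exp_hi": (e.get("ava_range") or (np.nan, np.nan))[1],
               "ava_sim": np.nan if ava_sim is None else ava_sim,
               "ava_sim_lo": (s.get("ava_range") or (np.nan, np.nan))[0],
               "ava_sim_hi": (s.get("ava_range") or (np.nan, np.nan))[1]}
        if q_sim is not None and np.isfinite(rec["q_exp"]):
            rec["q_error_pct"] = symmetric_percent_error(q_sim, rec["q_exp"], denominator)
            rec["q_within_unc"] = within_uncertainty(q_sim, rec["q_exp"], uncertainty_frac)
        if ava_sim is not None and np.isfinite(rec["ava_exp"]):
            rec["ava_error_pct"] = symmetric_percent_error(ava_sim, rec["ava_exp"], denominator)
            rec["ava_within_unc"] = within_uncertainty(ava_sim, rec["ava_exp"], uncertainty_frac)
        recs.append(rec)
    return pd.DataFrame.from_records(recs)
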