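"""Doubling-time and fitness estimation from OD600 timecourses.

The doubling-time statistic is the spacing of threshold crossings on the
growth curve: with baseline density B, let t_k be the earliest time the
culture reaches B * 2^k; the doubling time is D = (t5 - t2) / 3, i.e. the
average time per doubling between the second and fifth doubling, a window
chosen to sit inside the exponential phase. Strain fitness is the
wild-type reference doubling time divided by the strain's, so wild type
has fitness 1 and slower strains fall below it. Strains at or below a
fitness cutoff (default 0.7, a growth-rate reduction of 30% or more) are
classified toxic.

Crossing times are located by log-linear interpolation between the two
samples bracketing each threshold, which is exact for exponential growth.
Strains that do not complete five doublings within the run are censored:
the same spacing statistic is applied to the last completed doubling
(D = (t4 - t2)/2 or t3 - t2), or, below three doublings, D is bounded
below by the remaining run time; censored strains carry an upper-bound
fitness and are flagged, never dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DoublingTime",
    "compute_doubling_time",
    "compute_fitness",
    "classify_toxic",
    "fitness_table",
    "read_growth_curves",
    "write_fitness_records",
]

BASELINE_POLICIES = ("first", "fixed", "min3")

OD_FLOOR = 1e-4


@dataclass(frozen=True)
class DoublingTime:
    """Doubling-time estimate with censoring state.

    ``censored`` is True when the curve never reached five doublings;
    ``minutes`` is then a lower bound (or NaN when not even two doublings
    were observed, in which case ``fully_censored`` is also True).
    """

    minutes: float
    censored: bool = False
    fully_censored: bool = False
    t2: float = math.nan
    t5: float = math.nan


def _crossing_time(times: np.ndarray, od: np.ndarray, threshold: float) -> float:
    """Earliest time OD reaches ``threshold``; first upward crossing wins.

    Log-linear interpolation between the bracketing samples (exact in log
    space for exponential growth). NaN when the curve never reaches it.
    """
    above = od >= threshold
    if not above.any():
        return math.nan
    i = int(np.argmax(above))
    if i == 0:
        return float(times[0])
    lo, hi = od[i - 1], od[i]
    if hi <= lo:  # flat or noisy step landing exactly on threshold
        return float(times[i])
    if lo <= 0:
        # cannot interpolate in log space; fall back to linear
        frac = (threshold - lo) / (hi - lo)
    else:
        frac = (math.log(threshold) - math.log(lo)) / (math.log(hi) - math.log(lo))
    return float(times[i - 1] + frac * (times[i] - times[i - 1]))


def compute_doubling_time(
    times: Sequence[float],
    od: Sequence[float],
    *,
    baseline_policy: str = "first",
    fixed_baseline: float = 0.1,
    smooth: bool = False,
) -> DoublingTime:
    """Estimate D = (t5 - t2) / 3 from one OD600 timecourse.

    Baseline policies: ``first`` (first OD reading, the inoculation
    density), ``fixed`` (use ``fixed_baseline``), ``min3`` (minimum of the
    first three readings, robust to a high first read). ``smooth`` applies
    a 3-point running median before crossing detection (off by default).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and od must be 1-D arrays of equal length")
    if len(t) < 4:
        raise ValueError(f"need at least 4 timepoints, got {len(t)}")
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    # negative ODs after blank correction are floored, not errors
    y = np.maximum(y, OD_FLOOR)
    if smooth and len(y) >= 3:
        sm = y.copy()
        sm[1:-1] = np.median(np.column_stack([y[:-2], y[1:-1], y[2:]]), axis=1)
        y = sm

    if baseline_policy == "first":
        baseline = y[0]
    elif baseline_policy == "fixed":
        baseline = fixed_baseline
    elif baseline_policy == "min3":
        baseline = float(np.min(y[:3]))
    else:
        raise ValueError(
            f"unknown baseline_policy {baseline_policy!r}; choose from {BASELINE_POLICIES}"
        )
    if baseline <= 0:
        raise ValueError("baseline OD must be positive")

    if int(np.sum(y > baseline)) < 2:
        # flat or declining culture: no growth to time
        return DoublingTime(math.nan, censored=True, fully_censored=True)

    t2 = _crossing_time(t, y, baseline * 4.0)
    t5 = _crossing_time(t, y, baseline * 32.0)
    if math.isnan(t2):
        return DoublingTime(math.nan, censored=True, fully_censored=True)
    if math.isnan(t5):
        # censored: apply the same average-spacing statistic to the last
        # completed doubling, D = (t_k - t2)/(k - 2) for k = 4 or 3; if not
        # even a third doubling completed, all we know is that one doubling
        # took longer than the remaining run, D >= t_end - t2
        for k in (4, 3):
            tk = _crossing_time(t, y, baseline * 2.0**k)
            if not math.isnan(tk):
                return DoublingTime((tk - t2) / (k - 2), censored=True, t2=t2)
        return DoublingTime(t[-1] - t2, censored=True, t2=t2)
    return DoublingTime((t5 - t2) / 3.0, t2=t2, t5=t5)


def compute_fitness(d_oe: float, d_wt_ref: float) -> float:
    """Wild-type-normalized fitness: D_wt / D_OE.

    ``d_wt_ref`` is the mean doubling time of the wild-type reference
    replicates. A censored (lower-bound) ``d_oe`` yields an upper-bound
    fitness; the caller carries the censoring flag.
    """
    if not d_oe > 0 or not d_wt_ref > 0:
        raise ValueError("doubling times must be positive")
    return d_wt_ref / d_oe


def classify_toxic(fitness: float, *, cutoff: float = 0.7, censored: bool = False,
                   fully_censored: bool = False) -> bool:
    """Toxic iff fitness <= cutoff (growth reduced by 30% or more).

    The boundary is toxic. Censored fitnesses are upper bounds, so a
    censored value at or below the cutoff is still toxic; a fully censored
    strain (fewer than two doublings in the whole run) is toxic a fortiori.
    """
    if fully_censored or (isinstance(fitness, float) and math.isnan(fitness)):
        return True
    return fitness <= cutoff


def fitness_table(
    curves: pd.DataFrame,
    *,
    wt_ids: Sequence[str] = ("WT",),
    cutoff: float = 0.7,
    baseline_policy: str = "first",
    fixed_baseline: float = 0.1,
    medium: str | None = "inducing",
    smooth: bool = False,
) -> pd.DataFrame:
    """Per-strain fitness from a long-format growth-curve table.

    ``curves`` columns: strain_id, replicate, time_min, od600 and
    optionally medium (filtered to ``medium`` when present). The wild-type
    reference doubling time is the mean over all replicates of the strains
    in ``wt_ids`` (pooled globally). Replicate fitnesses are averaged per
    strain (mean) with the dispersion reported.
    """
    df = curves
    if medium is not None and "medium" in df.columns:
        df = df[df["medium"] == medium]
    if df.empty:
        raise ValueError("no growth curves to analyze")

    per_rep = []
    for (strain, rep), grp in df.groupby(["strain_id", "replicate"], sort=True):
        grp = grp.sort_values("time_min")
        dt = compute_doubling_time(
            grp["time_min"].to_numpy(), grp["od600"].to_numpy(),
            baseline_policy=baseline_policy, fixed_baseline=fixed_baseline,
            smooth=smooth,
        )
        per_rep.append((strain, rep, dt))

    wt_ids = set(wt_ids)
    wt_ds = [dt.minutes for s, _, dt in per_rep
             if s in wt_ids and not dt.fully_censored]
    if not wt_ds:
        raise ValueError("no usable wild-type reference replicates")
    d_wt = float(np.mean(wt_ds))

    rows = []
    by_strain: dict[str, list[DoublingTime]] = {}
    for strain, _, dt in per_rep:
        by_strain.setdefault(strain, []).append(dt)
    for strain, dts in sorted(by_strain.items()):
        usable = [dt for dt in dts if not dt.fully_censored]
        fully = len(usable) == 0
        censored = fully or any(dt.censored for dt in usable)
        if fully:
            d_mean = math.nan
            fit_vals = []
        else:
            d_mean = float(np.mean([dt.minutes for dt in usable]))
            fit_vals = [compute_fitness(dt.minutes, d_wt) for dt in usable]
        fit = float(np.mean(fit_vals)) if fit_vals else math.nan
        sd = float(np.std(fit_vals, ddof=1)) if len(fit_vals) > 1 else math.nan
        rows.append({
            "strain_id": strain,
            "d_min": d_mean,
            "fitness": fit,
            "sd": sd,
            "n": len(usable),
            "censored": censored,
            "toxic": classify_toxic(fit, cutoff=cutoff, censored=censored,
                                    fully_censored=fully),
        })
    return pd.DataFrame(rows)


def read_growth_curves(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"strain_id", "replicate", "time_min", "od600"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"growth-curve table missing columns: {sorted(missing)}")
    return df


def write_fitness_records(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False)
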