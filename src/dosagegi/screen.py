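"""Primary colony-array screen processing.

The primary screen pins each TF OE strain in quadruplicate (2x2 blocks) on
1536-format arrays, once in the query-mutant background and once in a
wild-type control background. Sizes are made comparable by dividing each
plate by the median of its non-border, non-empty colonies (optionally
followed by a row/column median polish in log space to remove smooth
gradients), quadruplicates are collapsed by the median, and candidate
interactions are called from the mutant/control size ratio.

The ratio already approximates observed/expected fitness under the
multiplicative null: plate-median normalization divides out the query
single-mutant fitness from the mutant plate and the TF single fitness
cancels between plates, leaving 1 + gi/(fA*fB) for an interaction of
deviation gi. Candidates feed the spot-dilution confirmation stage; they
are screen leads, not confirmed interactions.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "normalize_plate",
    "collapse_quadruplicates",
    "call_candidates",
    "screen_query",
    "read_plates",
    "write_candidates",
]

PLATE_ROWS, PLATE_COLS = 32, 48

# calling defaults: a one-sided ratio drop of 35% catches a GI deviation of
# 0.4 even against near-wild-type singles (ratio 0.6) with margin for
# quadruplicate noise; positives are only expressible with headroom below
# the product null, which pushes their ratio past 1.5
DEFAULT_LOWER = 0.65
DEFAULT_UPPER = 1.5


def _plate_stats_mask(plate: pd.DataFrame) -> pd.Series:
    return (~plate["border_flag"]) & (plate["strain_id"] != "") \
        & plate["strain_id"].notna() & (plate["size"] > 0)


def normalize_plate(plate: pd.DataFrame, *, polish: bool = False,
                    tol: float = 1e-13, max_sweeps: int = 500) -> pd.DataFrame:
    """Scale a plate to median colony size 1 over non-border positions.

    Optional row/column median polish (log scale, iterated to convergence)
    removes smooth spatial gradients. Polish is off by default: the median
    rescaling already removes whole-plate effects, and because each array
    row holds a specific set of strains, a polish cannot distinguish a
    spatial artifact from genuine row-correlated strain composition —
    enable it only when a gradient is suspected. Border positions are
    excluded from every statistic but are rescaled alongside.
    Normalization is idempotent: renormalizing a normalized plate is an
    exact no-op without polish; the iterated polish can end in a median
    limit cycle, leaving renormalization a no-op only to ~1e-6.
    """
    required = {"plate", "row", "col", "strain_id", "size", "border_flag"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    out = plate.copy()
    mask = _plate_stats_mask(out)
    n_filled = int((out["strain_id"] != "").sum())
    if n_filled < 0.5 * len(out):
        raise ValueError("plate rejected: fewer than 50% non-empty positions")
    med = float(out.loc[mask, "size"].median()) if mask.any() else 0.0
    if not med > 0:
        raise ValueError("plate rejected: median colony size is zero")
    out["size"] = out["size"] / med

    if polish:
        sizes = out["size"].to_numpy(dtype=float).copy()
        rows = out["row"].to_numpy()
        cols = out["col"].to_numpy()
        stat = mask.to_numpy() & (sizes > 0)
        logs = np.where(sizes > 0, np.log(np.where(sizes > 0, sizes, 1.0)), np.nan)
        row_eff = np.zeros(PLATE_ROWS)
        col_eff = np.zeros(PLATE_COLS)
        for _ in range(max_sweeps):
            shift = 0.0
            resid = logs - row_eff[rows] - col_eff[cols]
            for r in range(PLATE_ROWS):
                sel = stat & (rows == r)
                if sel.any():
                    m = float(np.median(resid[sel]))
                    row_eff[r] += m
                    shift = max(shift, abs(m))
            resid = logs - row_eff[rows] - col_eff[cols]
            for c in range(PLATE_COLS):
                sel = stat & (cols == c)
                if sel.any():
                    m = float(np.median(resid[sel]))
                    col_eff[c] += m
                    shift = max(shift, abs(m))
            if shift < tol:
                break
        corr = np.exp(row_eff[rows] + col_eff[cols])
        sizes = np.where(sizes > 0, sizes / corr, sizes)
        out["size"] = sizes
        mask = _plate_stats_mask(out)
        med = float(out.loc[mask, "size"].median())
        if med > 0:
            out["size"] = out["size"] / med
    return out


def collapse_quadruplicates(plate: pd.DataFrame, *, cv_max: float = 0.5,
                            min_replicates: int = 2) -> pd.DataFrame:
    """Per-strain size estimate: median of the (up to 4) replicate colonies.

    Border controls and empty positions are skipped. A colony of size 0 is
    a dead colony — an observation, not missing data — so an all-dead
    quadruplicate collapses to size 0 (a maximal negative signal). Strains
    present at fewer than ``min_replicates`` positions are flagged
    ``missing``; a replicate coefficient of variation above ``cv_max`` is
    flagged ``high_cv`` (jackpot colonies).
    """
    body = plate[(~plate["border_flag"]) & (plate["strain_id"] != "")
                 & plate["strain_id"].notna()]
    rows = []
    for strain, grp in body.groupby("strain_id", sort=True):
        sizes = grp["size"].to_numpy(dtype=float)
        sizes = sizes[~np.isnan(sizes)]
        n = len(sizes)
        if n < min_replicates:
            rows.append({"strain_id": strain, "size": math.nan, "cv": math.nan,
                         "n": n, "flag": "missing"})
            continue
        med = float(np.median(sizes))
        mean = float(np.mean(sizes))
        if mean > 0:
            cv = float(np.std(sizes, ddof=1) / mean)
        else:
            cv = 0.0  # uniformly dead: no dispersion to flag
        rows.append({"strain_id": strain, "size": med, "cv": cv, "n": n,
                     "flag": "high_cv" if cv > cv_max else ""})
    return pd.DataFrame(rows, columns=["strain_id", "size", "cv", "n", "flag"])


def call_candidates(mutant_sizes: pd.DataFrame, control_sizes: pd.DataFrame,
                    *, lower: float = DEFAULT_LOWER,
                    upper: float = DEFAULT_UPPER) -> pd.DataFrame:
    """Candidate GIs from strain-matched mutant/control size ratios.

    Negative candidate when ratio <= ``lower``, positive when >= ``upper``
    (both boundaries inclusive); ordered by |log2 ratio| descending.
    Strains with zero/missing control size are skipped with a flag.
    """
    if not 0 <= lower <= upper:
        raise ValueError("need 0 <= lower <= upper")
    merged = mutant_sizes.merge(control_sizes, on="strain_id",
                                suffixes=("_mut", "_ctrl"))
    rows = []
    for _, r in merged.iterrows():
        mut, ctrl = r["size_mut"], r["size_ctrl"]
        if not (isinstance(ctrl, (int, float)) and ctrl > 0) or math.isnan(mut):
            rows.append({"strain_id": r["strain_id"], "ratio": math.nan,
                         "log2_ratio": math.nan, "call": "skipped"})
            continue
        ratio = mut / ctrl
        if ratio <= lower:
            call = "negative"
        elif ratio >= upper:
            call = "positive"
        else:
            call = "none"
        rows.append({"strain_id": r["strain_id"], "ratio": ratio,
                     "log2_ratio": math.log2(ratio) if ratio > 0 else -math.inf,
                     "call": call})
    out = pd.DataFrame(rows, columns=["strain_id", "ratio", "log2_ratio", "call"])
    order = out["log2_ratio"].abs().fillna(-1.0)
    return out.loc[order.sort_values(ascending=False, kind="stable").index] \
              .reset_index(drop=True)


def screen_query(mutant_plate: pd.DataFrame, control_plate: pd.DataFrame,
                 *, polish: bool = False, cv_max: float = 0.5,
                 lower: float = DEFAULT_LOWER, upper: float = DEFAULT_UPPER
                 ) -> pd.DataFrame:
    """Normalize, collapse, and call one query screen (mutant vs control)."""
    mut = collapse_quadruplicates(normalize_plate(mutant_plate, polish=polish),
                                  cv_max=cv_max)
    ctrl = collapse_quadruplicates(normalize_plate(control_plate, polish=polish),
                                   cv_max=cv_max)
    return call_candidates(mut, ctrl, lower=lower, upper=upper)


def read_plates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"strain_id": str})
    df["size"] = pd.to_numeric(df["size"])
    df["border_flag"] = df["border_flag"].astype(str).str.lower().isin(
        ("true", "1"))
    for col in ("row", "col"):
        df[col] = df[col].astype(int)
    return df


def write_candidates(candidates: pd.DataFrame, path: str | Path) -> None:
    candidates.to_csv(path, sep="\t", index=False)
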