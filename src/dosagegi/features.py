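"""Protein-feature associations with overexpression toxicity.

Toxic and nontoxic proteins (kinases and TFs separately) are compared on
total disordered-region length, conserved linear-motif count, and
high-throughput PPI count with the Wilcoxon/Mann-Whitney rank-sum test;
enrichment of known kinase substrates among SDL hits uses the upper-tail
hypergeometric test.

The rank-sum test uses midranks for ties. For small groups the null is
exact — the distribution of the rank sum over all C(n, n_a) labelings,
computed by integer dynamic programming over doubled midranks — otherwise
a normal approximation with tie and continuity corrections is used.
Two-sided P = min(1, 2*min(lower tail, upper tail)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "group_means",
    "rank_sum_test",
    "substrate_enrichment",
    "feature_report",
    "read_features",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = ("disorder_len", "n_motifs", "n_ppi")

EXACT_GROUP_LIMIT = 10
EXACT_ARRANGEMENT_LIMIT = 2_000_000


@dataclass(frozen=True)
class GroupSummary:
    """Toxic/nontoxic group means and extrema for one class x feature."""

    klass: str
    feature: str
    toxic_mean: float
    nontoxic_mean: float
    toxic_min: float
    toxic_max: float
    nontoxic_min: float
    nontoxic_max: float
    n_toxic: int
    n_nontoxic: int

    @property
    def defined(self) -> bool:
        return self.n_toxic > 0 and self.n_nontoxic > 0


def group_means(features: pd.DataFrame, klass: str, feature: str) -> GroupSummary:
    """Arithmetic group means with min/max error bars, as reported per class.

    Proteins with no annotated physical interaction are excluded from the
    PPI comparison (they may simply never have been assayed).
    """
    sub = features[features["klass"].isin([klass, "both"])] \
        if klass in ("kinase", "TF") else features[features["klass"] == klass]
    if feature == "n_ppi":
        sub = sub[sub["n_ppi"] > 0]
    tox = sub.loc[sub["toxic"], feature].to_numpy(dtype=float)
    non = sub.loc[~sub["toxic"], feature].to_numpy(dtype=float)

    def agg(v: np.ndarray) -> tuple[float, float, float]:
        if len(v) == 0:
            return math.nan, math.nan, math.nan
        return float(np.mean(v)), float(np.min(v)), float(np.max(v))

    tm, tmin, tmax = agg(tox)
    nm, nmin, nmax = agg(non)
    return GroupSummary(klass=klass, feature=feature, toxic_mean=tm,
                        nontoxic_mean=nm, toxic_min=tmin, toxic_max=tmax,
                        nontoxic_min=nmin, nontoxic_max=nmax,
                        n_toxic=len(tox), n_nontoxic=len(non))


def _exact_rank_sum_p(ranks2: np.ndarray, n_a: int, w2_obs: int) -> float:
    """Exact two-sided P for the group-A rank sum over all labelings.

    ``ranks2`` are midranks doubled to integers; DP table counts, for each
    chosen-group size k and doubled rank sum s, the number of index subsets
    achieving it.
    """
    total = int(ranks2.sum())
    # ways[k] maps doubled rank sum -> count, over subsets of size k
    ways: list[dict[int, int]] = [dict() for _ in range(n_a + 1)]
    ways[0][0] = 1
    for r in ranks2.tolist():
        for k in range(n_a, 0, -1):
            prev = ways[k - 1]
            if not prev:
                continue
            cur = ways[k]
            for s, c in prev.items():
                cur[s + r] = cur.get(s + r, 0) + c
    dist = ways[n_a]
    n_total = sum(dist.values())  # == C(n, n_a)
    lower = sum(c for s, c in dist.items() if s <= w2_obs)
    upper = sum(c for s, c in dist.items() if s >= w2_obs)
    p = 2.0 * min(lower, upper) / n_total
    return min(1.0, p)


def rank_sum_test(group_a: Sequence[float], group_b: Sequence[float],
                  *, mode: str = "auto", exact_limit: int = EXACT_GROUP_LIMIT
                  ) -> tuple[float, float]:
    """Wilcoxon/Mann-Whitney rank-sum test; returns (U of group A, two-sided P).

    ``mode``: 'exact' enumerates the null (midranks, ties allowed),
    'normal_approx' uses the tie-corrected normal approximation with
    continuity correction, 'auto' picks exact when min(n) <= exact_limit
    and the arrangement count is tractable.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)  # midranks
    w_a = float(ranks[:n_a].sum())
    u_a = w_a - n_a * (n_a + 1) / 2.0

    if np.all(combined == combined[0]):
        return u_a, 1.0

    if mode == "auto":
        mode = ("exact" if min(n_a, n_b) <= exact_limit
                and comb(n, min(n_a, n_b)) <= EXACT_ARRANGEMENT_LIMIT
                else "normal_approx")
    if mode == "exact":
        ranks2 = np.rint(ranks * 2).astype(np.int64)
        w2 = int(round(w_a * 2))
        return u_a, _exact_rank_sum_p(ranks2, n_a, w2)
    if mode != "normal_approx":
        raise ValueError(f"unknown mode {mode!r}")

    mu = n_a * n_b / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u_a, 1.0
    # continuity correction toward the mean
    z = (u_a - mu - 0.5 * np.sign(u_a - mu)) / math.sqrt(var)
    return u_a, min(1.0, 2.0 * float(sps.norm.sf(abs(z))))


def substrate_enrichment(hits: Iterable[str], known_substrates: Iterable[str],
                         background: Iterable[str]) -> tuple[float, float]:
    """Fold enrichment and upper-tail hypergeometric P of substrate overlap.

    fold = (|hits ∩ substrates| / |hits|) / (|substrates| / |background|);
    P = P(overlap >= observed) drawing |hits| genes from the background.
    """
    bg = set(background)
    h = set(hits)
    s = set(known_substrates)
    if not h or not bg:
        raise ValueError("hits and background must be non-empty")
    if not h <= bg:
        raise ValueError("hits must be a subset of the background")
    if not s <= bg:
        raise ValueError("known substrates must be a subset of the background")
    k = len(h & s)
    if not s:
        return math.nan, 1.0
    fold = (k / len(h)) / (len(s) / len(bg))
    p = float(sps.hypergeom.sf(k - 1, len(bg), len(s), len(h)))
    return fold, min(1.0, p)


def feature_report(features: pd.DataFrame, *, alpha: float = 0.05,
                   bh: bool = False, mode: str = "auto") -> pd.DataFrame:
    """Toxic-vs-nontoxic comparison per class x feature.

    One row per (klass, feature): group means/extrema, rank-sum U and P,
    and the rejection call at ``alpha`` (after Benjamini-Hochberg across
    the three features within each class when ``bh`` is set).
    """
    rows = []
    for klass in ("kinase", "TF"):
        for feature in FEATURE_COLUMNS:
            summ = group_means(features, klass, feature)
            if not summ.defined:
                rows.append({"klass": klass, "feature": feature,
                             "toxic_mean": summ.toxic_mean,
                             "nontoxic_mean": summ.nontoxic_mean,
                             "toxic_min": summ.toxic_min,
                             "toxic_max": summ.toxic_max,
                             "nontoxic_min": summ.nontoxic_min,
                             "nontoxic_max": summ.nontoxic_max,
                             "n_toxic": summ.n_toxic,
                             "n_nontoxic": summ.n_nontoxic,
                             "U": math.nan, "p": math.nan,
                             "flag": "empty_group"})
                continue
            sub = features[features["klass"].isin([klass, "both"])]
            if feature == "n_ppi":
                sub = sub[sub["n_ppi"] > 0]
            u, p = rank_sum_test(sub.loc[sub["toxic"], feature],
                                 sub.loc[~sub["toxic"], feature], mode=mode)
            rows.append({"klass": klass, "feature": feature,
                         "toxic_mean": summ.toxic_mean,
                         "nontoxic_mean": summ.nontoxic_mean,
                         "toxic_min": summ.toxic_min, "toxic_max": summ.toxic_max,
                         "nontoxic_min": summ.nontoxic_min,
                         "nontoxic_max": summ.nontoxic_max,
                         "n_toxic": summ.n_toxic, "n_nontoxic": summ.n_nontoxic,
                         "U": u, "p": p, "flag": ""})
    out = pd.DataFrame(rows)
    if bh:
        out["p_adj"] = math.nan
        for klass in ("kinase", "TF"):
            sel = (out["klass"] == klass) & out["p"].notna()
            p = out.loc[sel, "p"].to_numpy()
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank_i in range(m - 1, -1, -1):
                idx = order[rank_i]
                running = min(running, p[idx] * m / (rank_i + 1))
                adj[idx] = running
            out.loc[sel, "p_adj"] = adj
        out["significant"] = out["p_adj"] <= alpha
    else:
        out["significant"] = out["p"] <= alpha
    return out


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    required = {"gene", "klass", "disorder_len", "n_motifs", "n_ppi", "toxic"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    if df["gene"].duplicated().any():
        raise ValueError("gene identifiers must be unique")
    if df["toxic"].dtype == object:
        df["toxic"] = df["toxic"].astype(str).str.lower().isin(("true", "1"))
    return df
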