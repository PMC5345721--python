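"""Genetic-interaction scoring from serial spot-dilution assays.

A strain's semiquantitative fitness is the number of viable spots it shows
divided by the number shown by wild type (at most ``max_spots``, default 5).
Under the multiplicative null the double mutant's expected fitness is the
product of the two single-mutant fitnesses; the GI score is the observed
double-mutant fitness minus that expectation, and the Genetic Interaction
Strength is the score scaled by ``max_spots`` onto [-5, 5].

All scoring is exact rational arithmetic on spot counts (``fractions.
Fraction``); nothing is rounded. Both SDL designs (kinase loss-of-function
x TF overexpression) and DDL designs (cyclin OE x TF OE) use the same
arithmetic and differ only in the ``design`` label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SpotAssay",
    "GIRecord",
    "UnscorableAssayError",
    "spot_fitness",
    "expected_double_fitness",
    "gi_score",
    "gi_strength",
    "score_assay",
    "score_assay_table",
    "read_spot_assays",
    "write_gi_records",
    "records_to_frame",
]

SIGN_NEGATIVE = "negative"
SIGN_POSITIVE = "positive"
SIGN_NONE = "none"


class UnscorableAssayError(ValueError):
    """Raised when an assay cannot be scored (e.g. wild type shows no spots)."""


@dataclass(frozen=True)
class SpotAssay:
    """Spot counts for one strain quartet on one plate (one condition).

    ``a`` is the query single mutant (kinase LOF allele or cyclin OE),
    ``b`` the TF OE single, ``double`` the double mutant.
    """

    pair_id: str
    design: str  # "SDL" | "DDL"
    condition: str  # "inducing" | "control"
    wt_spots: int
    a_spots: int
    b_spots: int
    double_spots: int
    max_spots: int = 5

    def __post_init__(self) -> None:
        if self.max_spots < 1:
            raise ValueError(f"max_spots must be >= 1, got {self.max_spots}")
        for name in ("wt_spots", "a_spots", "b_spots", "double_spots"):
            v = getattr(self, name)
            if not (0 <= v <= self.max_spots):
                raise ValueError(
                    f"{name}={v} outside [0, max_spots={self.max_spots}] "
                    f"for pair {self.pair_id!r}"
                )
        if self.design not in ("SDL", "DDL"):
            raise ValueError(f"design must be 'SDL' or 'DDL', got {self.design!r}")


@dataclass
class GIRecord:
    """Scored genetic interaction for one query-allele x TF-OE pair."""

    pair_id: str
    query_id: str = ""
    tf_id: str = ""
    design: str = "SDL"
    allele_class: str = "LOF"  # LOF | analog-sensitive | OE
    f_a: Fraction = Fraction(1)
    f_b: Fraction = Fraction(1)
    f_expected: Fraction = Fraction(1)
    f_observed: Fraction = Fraction(1)
    gi_score: Fraction = Fraction(0)
    strength: Fraction = Fraction(0)
    sign: str = SIGN_NONE
    flags: tuple = field(default_factory=tuple)

    @property
    def scorable(self) -> bool:
        return "unscorable" not in self.flags and "uninterpretable" not in self.flags


def _as_fraction(x) -> Fraction:
    if isinstance(x, Rational):
        return Fraction(x)
    return Fraction(x).limit_denominator(10**9)


def spot_fitness(spots: int, wt_spots: int, *, clamp: bool = True) -> Fraction:
    """Fitness of a strain as viable spots relative to wild type.

    A strain spotting more dilutions than wild type (suppression beyond wt)
    is clamped to fitness 1 with a warning unless ``clamp=False``.
    """
    if wt_spots == 0:
        raise UnscorableAssayError("wild-type shows 0 viable spots; assay unscorable")
    if spots < 0:
        raise ValueError(f"negative spot count {spots}")
    f = Fraction(spots, wt_spots)
    if f > 1 and clamp:
        warnings.warn(
            f"spot count {spots} exceeds wild-type {wt_spots}; fitness clamped to 1",
            stacklevel=2,
        )
        return Fraction(1)
    return f


def expected_double_fitness(f_a, f_b) -> Fraction:
    """Multiplicative-null expectation: product of the single fitnesses."""
    fa, fb = _as_fraction(f_a), _as_fraction(f_b)
    for name, f in (("f_a", fa), ("f_b", fb)):
        if not 0 <= f <= 1:
            raise ValueError(f"{name}={float(f)} outside [0, 1]")
    return fa * fb


def gi_score(f_observed, f_expected) -> Fraction:
    """GI score: observed double-mutant fitness minus expected fitness."""
    fo, fe = _as_fraction(f_observed), _as_fraction(f_expected)
    for name, f in (("f_observed", fo), ("f_expected", fe)):
        if not 0 <= f <= 1:
            raise ValueError(f"{name}={float(f)} outside [0, 1]")
    return fo - fe


def gi_strength(score, max_spots: int = 5) -> Fraction:
    """Scale a GI score in [-1, 1] to Genetic Interaction Strength in [-5, 5]."""
    s = _as_fraction(score)
    if not -1 <= s <= 1:
        raise ValueError(f"gi score {float(s)} outside [-1, 1]")
    return s * max_spots


def score_assay(
    assay: SpotAssay,
    control: SpotAssay | None = None,
    *,
    sign_threshold=Fraction(1, 5),
    control_floor=Fraction(3, 5),
    clamp: bool = True,
    query_id: str = "",
    tf_id: str = "",
    allele_class: str = "LOF",
) -> GIRecord:
    """Score one inducing-condition assay against the multiplicative null.

    ``control`` is the matched noninducing plate: pairs whose double mutant
    is already sick without induction (control double fitness below
    ``control_floor``) are flagged ``uninterpretable`` and not signed.
    Sign is negative when score <= -sign_threshold, positive when
    >= +sign_threshold, else none.
    """
    thr = _as_fraction(sign_threshold)
    rec = GIRecord(
        pair_id=assay.pair_id,
        query_id=query_id,
        tf_id=tf_id,
        design=assay.design,
        allele_class=allele_class,
    )
    flags: list[str] = []

    if assay.wt_spots == 0:
        rec.flags = ("unscorable",)
        return rec

    if control is not None and control.wt_spots > 0:
        f_ctrl = spot_fitness(control.double_spots, control.wt_spots, clamp=clamp)
        if f_ctrl < _as_fraction(control_floor):
            flags.append("uninterpretable")

    rec.f_a = spot_fitness(assay.a_spots, assay.wt_spots, clamp=clamp)
    rec.f_b = spot_fitness(assay.b_spots, assay.wt_spots, clamp=clamp)
    rec.f_expected = expected_double_fitness(rec.f_a, rec.f_b)
    rec.f_observed = spot_fitness(assay.double_spots, assay.wt_spots, clamp=clamp)
    rec.gi_score = gi_score(rec.f_observed, rec.f_expected)
    rec.strength = gi_strength(rec.gi_score, assay.max_spots)

    if not flags:
        if rec.gi_score <= -thr:
            rec.sign = SIGN_NEGATIVE
        elif rec.gi_score >= thr:
            rec.sign = SIGN_POSITIVE
    rec.flags = tuple(flags)
    return rec


def score_assay_table(
    assays: pd.DataFrame,
    *,
    sign_threshold=Fraction(1, 5),
    control_floor=Fraction(3, 5),
    clamp: bool = True,
) -> list[GIRecord]:
    """Score a long-format assay table (one row per pair x condition).

    Expected columns: pair_id, design, condition, wt_spots, a_spots,
    b_spots, double_spots and optionally max_spots, query_id, tf_id,
    allele_class. Inducing rows are scored; control rows gate them.
    """
    records = []
    for pair_id, grp in assays.groupby("pair_id", sort=True):
        by_cond = {row["condition"]: row for _, row in grp.iterrows()}
        if "inducing" not in by_cond:
            continue
        ind = by_cond["inducing"]
        mk = lambda row: SpotAssay(
            pair_id=str(pair_id),
            design=row["design"],
            condition=row["condition"],
            wt_spots=int(row["wt_spots"]),
            a_spots=int(row["a_spots"]),
            b_spots=int(row["b_spots"]),
            double_spots=int(row["double_spots"]),
            max_spots=int(row.get("max_spots", 5)),
        )
        ctrl = mk(by_cond["control"]) if "control" in by_cond else None
        records.append(
            score_assay(
                mk(ind),
                ctrl,
                sign_threshold=sign_threshold,
                control_floor=control_floor,
                clamp=clamp,
                query_id=str(ind.get("query_id", "")),
                tf_id=str(ind.get("tf_id", "")),
                allele_class=str(ind.get("allele_class", "LOF")),
            )
        )
    return records


def records_to_frame(records: Iterable[GIRecord]) -> pd.DataFrame:
    """GIRecords as a table matching the published supplementary layout
    (per-pair score plus a 'Genetic Interaction Strength' column in -5..5)."""
    rows = [
        {
            "pair_id": r.pair_id,
            "query_id": r.query_id,
            "tf_id": r.tf_id,
            "design": r.design,
            "allele_class": r.allele_class,
            "f_a": float(r.f_a),
            "f_b": float(r.f_b),
            "f_expected": float(r.f_expected),
            "f_observed": float(r.f_observed),
            "gi_score": float(r.gi_score),
            "gi_strength": float(r.strength),
            "sign": r.sign,
            "flags": ";".join(r.flags),
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "pair_id", "query_id", "tf_id", "design", "allele_class",
            "f_a", "f_b", "f_expected", "f_observed",
            "gi_score", "gi_strength", "sign", "flags",
        ],
    )


def read_spot_assays(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"pair_id", "design", "condition", "wt_spots", "a_spots",
                "b_spots", "double_spots"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"spot assay table missing columns: {sorted(missing)}")
    return df


def write_gi_records(records: Sequence[GIRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)
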