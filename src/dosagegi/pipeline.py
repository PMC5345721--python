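"""End-to-end screen pipeline: simulate -> screen -> confirm -> network.

Mirrors the study workflow on synthetic data: colony-array screens per
query allele produce candidate pairs, candidates are re-tested in
spot-dilution assays, the spot scores are thresholded into confirmed
interactions, and the confirmed records are assembled into the bipartite
GI network. Returns the network together with the ground truth so
recall/precision of the planted interactions can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import networkx as nx
import pandas as pd

from . import network as net_mod
from . import screen as screen_mod
from .spots import GIRecord, score_assay
from .synthetic import (
    GroundTruth,
    SimConfig,
    simulate_ground_truth,
    simulate_screen_plate,
    simulate_spot_assay,
)

__all__ = ["PipelineResult", "run_pipeline", "planted_recall"]


@dataclass
class PipelineResult:
    """Everything the synthetic screen produced, truth included."""

    config: SimConfig
    truth: GroundTruth
    candidates: pd.DataFrame  # query_id, strain_id (tf), ratio, call
    records: list[GIRecord]  # spot-confirmation scores for candidates
    network: nx.MultiGraph

    def confirmed_pairs(self) -> set[tuple[str, str]]:
        return {(r.query_id, r.tf_id) for r in self.records
                if r.sign != "none" and r.scorable}


def run_pipeline(config: SimConfig, *,
                 sign_threshold: Fraction = Fraction(1, 5),
                 lower: float = screen_mod.DEFAULT_LOWER,
                 upper: float = screen_mod.DEFAULT_UPPER,
                 polish: bool = False) -> PipelineResult:
    """Run the full synthetic screen for every query allele."""
    truth = simulate_ground_truth(config)
    plate_rng = config.rng(53)  # shared stream across plates
    spot_rng = config.rng(37)

    cand_frames = []
    records: list[GIRecord] = []
    queries = truth.strains.loc[truth.strains["klass"] == "query", "strain_id"]
    for query_id in queries:
        mutant = simulate_screen_plate(config, truth, query_id,
                                       background="mutant", rng=plate_rng)
        control = simulate_screen_plate(config, truth, query_id,
                                        background="control", rng=plate_rng)
        calls = screen_mod.screen_query(mutant, control, polish=polish,
                                        lower=lower, upper=upper)
        calls = calls[calls["strain_id"] != "BORDER"].assign(query_id=query_id)
        cand_frames.append(calls)

        design = str(truth.pairs.loc[truth.pairs["query_id"] == query_id,
                                     "design"].iloc[0])
        hits = calls[calls["call"].isin(["negative", "positive"])]
        pair_truth = truth.pairs[truth.pairs["query_id"] == query_id] \
            .set_index("tf_id")["gi_effect"]
        # spot viability saturates at wild type: fitness above 1 reads as 5/5
        fa = min(truth.fitness_of(query_id), 1.0)
        for tf_id in hits["strain_id"]:
            fb = min(truth.fitness_of(tf_id), 1.0)
            gi = float(pair_truth.get(tf_id, 0.0))
            inducing, ctrl = simulate_spot_assay(
                fa, fb, gi, config, pair_id=f"{query_id}__{tf_id}",
                design=design, rng=spot_rng)
            records.append(score_assay(inducing, ctrl,
                                       sign_threshold=sign_threshold,
                                       query_id=query_id, tf_id=tf_id,
                                       allele_class="LOF" if design == "SDL"
                                       else "OE"))

    candidates = pd.concat(cand_frames, ignore_index=True) if cand_frames \
        else pd.DataFrame()
    g = net_mod.build_network(records)
    return PipelineResult(config=config, truth=truth, candidates=candidates,
                          records=records, network=g)


def planted_recall(result: PipelineResult, *, min_effect: float = 0.0) -> dict:
    """Recovery of planted interactions by the confirmed network.

    Recall is measured over planted pairs with |gi_effect| >= min_effect;
    precision over all confirmed pairs. Sign breakdown compares confirmed
    edge signs with the planted effect signs.
    """
    planted = result.truth.pairs[result.truth.pairs["gi_effect"] != 0.0]
    target = planted[planted["gi_effect"].abs() >= min_effect]
    planted_set = {(q, t): e for q, t, e in
                   zip(planted["query_id"], planted["tf_id"],
                       planted["gi_effect"])}
    target_set = set(zip(target["query_id"], target["tf_id"]))
    confirmed = result.confirmed_pairs()

    sign_of = {(r.query_id, r.tf_id): r.sign for r in result.records
               if r.sign != "none" and r.scorable}
    true_neg = sum(1 for p, s in sign_of.items()
                   if planted_set.get(p, 0.0) < 0 and s == "negative")
    true_pos = sum(1 for p, s in sign_of.items()
                   if planted_set.get(p, 0.0) > 0 and s == "positive")
    n_hit = len(confirmed & target_set)
    return {
        "n_planted": len(planted_set),
        "n_target": len(target_set),
        "n_confirmed": len(confirmed),
        "recall": n_hit / len(target_set) if target_set else float("nan"),
        "precision": (len(confirmed & set(planted_set)) / len(confirmed)
                      if confirmed else float("nan")),
        "confirmed_negative": sum(1 for s in sign_of.values()
                                  if s == "negative"),
        "confirmed_positive": sum(1 for s in sign_of.values()
                                  if s == "positive"),
        "true_sign_negative": true_neg,
        "true_sign_positive": true_pos,
    }
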