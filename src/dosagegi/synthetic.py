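"""Synthetic screen data with known ground truth.

Emulates the data streams of a yeast kinase/TF overexpression study so the
whole analysis chain is testable without wet-lab data:

* triplicate 24-h growth curves sampled every 15 min from an inoculation
  density of ~0.1, with ~40 wild-type reference replicates;
* spot-dilution assays with 5 scored spots from 15-fold serial dilutions;
* 1536-format quadruplicate colony arrays (32 x 48, 2x2 blocks);
* protein feature tables whose toxic/nontoxic group means are configurable
  (defaults follow the observed kinase/TF disorder, motif and PPI means);
* a ground-truth genetic-interaction map planted on query x TF pairs.

Growth follows a logistic law OD(t) = K*OD0*e^{rt} / (K + OD0*(e^{rt}-1))
with r = ln2 / (wt_doubling / fitness), so early growth is exponential —
the regime the downstream doubling-time statistic uses. The OD scale is
blank- and linearity-corrected culture density (saturating near the
carrying capacity, default 8 density units), not raw single-path OD.

Determinism: every generator derives its random stream from the config
seed plus a per-product tag, so one seed fixes every output byte.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .spots import SpotAssay

__all__ = [
    "SimConfig",
    "GroundTruth",
    "DEFAULT_FEATURE_MEANS",
    "simulate_ground_truth",
    "simulate_growth_curves",
    "simulate_spot_assay",
    "simulate_screen_plate",
    "simulate_feature_table",
    "write_dataset",
]

# Toxic/nontoxic group means per protein class for (disorder_len [aa],
# n_motifs [count], n_ppi [count]); defaults are the observed study means.
DEFAULT_FEATURE_MEANS: dict[str, dict[str, tuple[float, float, float]]] = {
    "kinase": {"toxic": (309.0, 4.4, 26.0), "nontoxic": (218.0, 2.8, 20.0)},
    "TF": {"toxic": (316.0, 1.6, 29.9), "nontoxic": (257.0, 2.4, 30.1)},
}

# plate geometry: 1536-format, quadruplicate 2x2 blocks
PLATE_ROWS, PLATE_COLS = 32, 48
BLOCK_ROWS, BLOCK_COLS = PLATE_ROWS // 2, PLATE_COLS // 2  # 16 x 24 blocks
BORDER_WIDTH = 2  # outer two rows/columns = outer block ring


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the generator.

    Defaults are the study's conditions: 129 kinase and 239 TF strains,
    triplicate growth curves over 24 h at 15-min sampling from density
    ~0.1 with a ~40-replicate wild-type reference, 5-spot dilution assays,
    and toxic fractions of 20% (kinases) / 26% (TFs).
    """

    seed: int = 0
    n_kinases: int = 129
    n_tfs: int = 239
    wt_replicates: int = 40
    strain_replicates: int = 3
    sampling_interval: float = 15.0  # minutes
    horizon: float = 1440.0  # minutes (24 h)
    od_start: float = 0.1
    od_noise_sd: float = 0.01
    wt_doubling: float = 80.0  # minutes, rich galactose medium
    carrying_capacity: float = 8.0  # corrected density units
    toxic_fraction_kinase: float = 0.20
    toxic_fraction_tf: float = 0.26
    # planted GI effects: per query x TF pair
    gi_rate: float = 0.05
    gi_negative_prob: float = 0.8
    gi_magnitudes: tuple[float, ...] = (0.4, 0.6, 0.8)
    n_sdl_queries: int = 4
    n_ddl_queries: int = 5
    # spot assays
    spot_count_max: int = 5
    spot_noise_prob: float = 0.0  # chance of a +/-1 miscount per strain
    # colony arrays
    colony_base_size: float = 400.0
    colony_noise_sd: float = 0.05  # lognormal sigma (log scale)
    plate_effect_sd: float = 0.10  # lognormal sigma of per-plate factor
    row_gradient: float = 0.0  # peak-to-trough multiplicative row trend
    col_gradient: float = 0.0
    # feature tables
    feature_group_means: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FEATURE_MEANS.items()}
    )
    disorder_shape: float = 3.0  # gamma shape for disorder lengths
    ppi_shape: float = 2.0  # gamma shape for PPI counts
    # substrate ground truth
    substrate_background_rate: float = 0.10
    substrate_hit_rate: float = 0.35

    def validate(self) -> None:
        for name in ("toxic_fraction_kinase", "toxic_fraction_tf", "gi_rate",
                     "gi_negative_prob", "spot_noise_prob",
                     "substrate_background_rate", "substrate_hit_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        for name in ("sampling_interval", "horizon", "wt_doubling",
                     "carrying_capacity", "colony_base_size"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not self.od_start > 0:
            raise ValueError("od_start must be > 0")
        if self.spot_count_max < 1:
            raise ValueError("spot_count_max must be >= 1")
        for m in self.gi_magnitudes:
            if not 0.0 < m <= 1.0:
                raise ValueError(f"gi magnitude {m} must be in (0, 1]")

    def rng(self, tag: int) -> np.random.Generator:
        """Stream for one simulated product; distinct tags are independent."""
        return np.random.default_rng([int(self.seed), int(tag)])


# per-product stream tags
_TAG_TRUTH, _TAG_GROWTH, _TAG_SPOTS, _TAG_PLATE, _TAG_FEATURES = 11, 23, 37, 53, 71


@dataclass
class GroundTruth:
    """True per-strain fitness and per-pair GI effects behind a simulation.

    ``strains``: strain_id, klass (kinase|TF|query), fitness, toxic.
    ``pairs``: query_id, tf_id, design (SDL|DDL), gi_effect (0 = null pair).
    ``substrates``: tf_id, kinase (query), tier (in_vitro|in_vivo|both).
    """

    strains: pd.DataFrame
    pairs: pd.DataFrame
    substrates: pd.DataFrame

    def fitness_of(self, strain_id: str) -> float:
        s = self.strains.loc[self.strains["strain_id"] == strain_id, "fitness"]
        if s.empty:
            raise KeyError(f"no ground-truth fitness for strain {strain_id!r}")
        return float(s.iloc[0])


def _draw_fitness(rng: np.random.Generator, n: int, toxic_fraction: float
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Bimodal single-mutant fitness: toxic ~ U(0.12, 0.7), nontoxic a
    tight mode just below/above wild type (truncated normal on (0.705, 1.1];
    OE strains rarely outgrow wild type by more than ~10%)."""
    toxic = rng.random(n) < toxic_fraction
    fit = np.empty(n)
    fit[toxic] = rng.uniform(0.12, 0.7, size=int(toxic.sum()))
    k = int((~toxic).sum())
    vals = rng.normal(0.97, 0.06, size=(k, 8))  # 8 tries is ample
    ok = (vals > 0.705) & (vals <= 1.1)
    first = np.argmax(ok, axis=1)
    fit[~toxic] = np.where(ok.any(axis=1), vals[np.arange(k), first], 0.98)
    return fit, toxic


def simulate_ground_truth(config: SimConfig) -> GroundTruth:
    """Draw per-strain fitness, planted GI effects, and substrate labels."""
    config.validate()
    rng = config.rng(_TAG_TRUTH)

    kin_fit, kin_tox = _draw_fitness(rng, config.n_kinases,
                                     config.toxic_fraction_kinase)
    tf_fit, tf_tox = _draw_fitness(rng, config.n_tfs, config.toxic_fraction_tf)
    strains = pd.DataFrame({
        "strain_id": ([f"KIN{i:03d}" for i in range(config.n_kinases)]
                      + [f"TF{i:03d}" for i in range(config.n_tfs)]),
        "klass": ["kinase"] * config.n_kinases + ["TF"] * config.n_tfs,
        "fitness": np.concatenate([kin_fit, tf_fit]),
        "toxic": np.concatenate([kin_tox, tf_tox]),
    })

    # query alleles grow like wild type (as alleles / benign deletions at
    # screening doses; cyclin OE singles modeled the same way)
    queries = ([(f"Q-SDL{i}", "SDL") for i in range(config.n_sdl_queries)]
               + [(f"Q-DDL{i}", "DDL") for i in range(config.n_ddl_queries)])
    qrows = pd.DataFrame({
        "strain_id": [q for q, _ in queries],
        "klass": "query",
        "fitness": 1.0,
        "toxic": False,
    })
    strains = pd.concat([strains, qrows], ignore_index=True)

    tf_ids = [f"TF{i:03d}" for i in range(config.n_tfs)]
    pair_rows = []
    for query_id, design in queries:
        has_gi = rng.random(config.n_tfs) < config.gi_rate
        signs = np.where(rng.random(config.n_tfs) < config.gi_negative_prob,
                         -1.0, 1.0)
        mags = rng.choice(config.gi_magnitudes, size=config.n_tfs)
        for j, tf_id in enumerate(tf_ids):
            effect = 0.0
            if has_gi[j]:
                e = signs[j] * mags[j]
                fb = tf_fit[j]
                # positive deviations are only expressible when the product
                # null leaves headroom below full viability; pairs without
                # it simply carry no positive interaction
                if e > 0 and fb + e > 1.0:
                    e = 0.0
                effect = float(e)
            pair_rows.append((query_id, tf_id, design, effect))
    pairs = pd.DataFrame(pair_rows,
                         columns=["query_id", "tf_id", "design", "gi_effect"])

    # substrate labels: negatively interacting TFs are enriched for
    # substrates of the SDL query kinase (the screen's discovery premise)
    sub_rows = []
    tiers = np.array(["in_vitro", "in_vivo", "both"])
    for query_id, design in queries:
        if design != "SDL":
            continue
        sub = pairs[(pairs["query_id"] == query_id)]
        for _, row in sub.iterrows():
            rate = (config.substrate_hit_rate if row["gi_effect"] < 0
                    else config.substrate_background_rate)
            if rng.random() < rate:
                sub_rows.append((row["tf_id"], query_id,
                                 tiers[rng.integers(len(tiers))]))
    substrates = pd.DataFrame(sub_rows, columns=["tf_id", "kinase", "tier"])
    return GroundTruth(strains=strains, pairs=pairs, substrates=substrates)


def logistic_od(t: np.ndarray, fitness: float, config: SimConfig) -> np.ndarray:
    """Noiseless logistic density at times ``t`` for a strain of given fitness."""
    if not fitness > 0:
        raise ValueError(f"fitness must be > 0, got {fitness}")
    r = np.log(2.0) / (config.wt_doubling / fitness)
    k, od0 = config.carrying_capacity, config.od_start
    e = np.exp(r * np.asarray(t, dtype=float))
    return k * od0 * e / (k + od0 * (e - 1.0))


def simulate_growth_curves(config: SimConfig, truth: GroundTruth,
                           *, include_queries: bool = False) -> pd.DataFrame:
    """Triplicate growth curves for every strain plus the wild-type pool.

    Long format: strain_id, replicate, time_min, od600, medium. Gaussian
    read noise (sd ``od_noise_sd``) floored at 0.
    """
    config.validate()
    if config.horizon < 5 * config.wt_doubling:
        warnings.warn(
            "horizon shorter than five wild-type doublings; wild-type curves "
            "will be censored", stacklevel=2)
    rng = config.rng(_TAG_GROWTH)
    t = np.arange(0.0, config.horizon + 0.5 * config.sampling_interval,
                  config.sampling_interval)

    strains = truth.strains
    if not include_queries:
        strains = strains[strains["klass"] != "query"]
    jobs = [("WT", rep, 1.0) for rep in range(1, config.wt_replicates + 1)]
    for _, row in strains.iterrows():
        for rep in range(1, config.strain_replicates + 1):
            jobs.append((row["strain_id"], rep, float(row["fitness"])))

    frames = []
    for strain_id, rep, fit in jobs:
        od = logistic_od(t, fit, config)
        if config.od_noise_sd > 0:
            od = od + rng.normal(0.0, config.od_noise_sd, size=od.shape)
        od = np.maximum(od, 0.0)
        frames.append(pd.DataFrame({
            "strain_id": strain_id, "replicate": rep, "time_min": t,
            "od600": od, "medium": "inducing",
        }))
    return pd.concat(frames, ignore_index=True)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def simulate_spot_assay(
    f_a: float, f_b: float, gi_effect: float, config: SimConfig,
    *, pair_id: str = "pair", design: str = "SDL",
    rng: np.random.Generator | None = None,
) -> tuple[SpotAssay, SpotAssay]:
    """Spot counts for one pair: (inducing assay, noninducing control).

    True double fitness is clamp(f_a*f_b + gi_effect, 0, 1); each strain's
    viable-spot count is round(spot_count_max * fitness) with an optional
    +/-1 miscount at probability ``spot_noise_prob``. The control plate is
    noninducing, so every strain shows full viability there.
    """
    config.validate()
    for name, f in (("f_a", f_a), ("f_b", f_b)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name}={f} outside [0, 1]")
    if rng is None:
        rng = config.rng(_TAG_SPOTS)
    m = config.spot_count_max
    f_double = float(np.clip(f_a * f_b + gi_effect, 0.0, 1.0))

    def spots(f: float) -> int:
        s = _round_half_up(m * f)
        if config.spot_noise_prob > 0 and rng.random() < config.spot_noise_prob:
            s += int(rng.choice([-1, 1]))
        return int(np.clip(s, 0, m))

    inducing = SpotAssay(pair_id=pair_id, design=design, condition="inducing",
                         wt_spots=m, a_spots=spots(f_a), b_spots=spots(f_b),
                         double_spots=spots(f_double), max_spots=m)
    control = SpotAssay(pair_id=pair_id, design=design, condition="control",
                        wt_spots=m, a_spots=m, b_spots=m, double_spots=m,
                        max_spots=m)
    return inducing, control


def _block_layout(n_strains: int) -> list[tuple[int, int, str | None, bool]]:
    """Assign strains to 2x2 blocks row-major inside the non-border region.

    Returns (block_row, block_col, strain_id_index_or_None, border) tuples;
    border blocks (outer ring) hold the wild-type border control.
    """
    interior = [(br, bc) for br in range(1, BLOCK_ROWS - 1)
                for bc in range(1, BLOCK_COLS - 1)]
    if n_strains > len(interior):
        raise ValueError(
            f"{n_strains} strains exceed the {len(interior)} non-border "
            f"quadruplicate blocks of a 1536 array")
    layout = []
    for br in range(BLOCK_ROWS):
        for bc in range(BLOCK_COLS):
            if br in (0, BLOCK_ROWS - 1) or bc in (0, BLOCK_COLS - 1):
                layout.append((br, bc, "BORDER", True))
    # unused interior blocks are padded with the control strain, as on a
    # real array; they are non-border but carry no TF
    for idx, (br, bc) in enumerate(interior):
        layout.append((br, bc, idx if idx < n_strains else "BORDER", False))
    return layout


def simulate_screen_plate(
    config: SimConfig, truth: GroundTruth, query_id: str,
    *, background: str = "mutant", plate_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """One 1536-format colony array for a query screen.

    ``background='mutant'`` crosses the query allele into the TF OE array,
    so each colony reports the double-mutant fitness clamp(fA*fB + gi);
    ``background='control'`` is the wild-type query cross reporting fB.
    Colony size = base * fitness * plate_effect * gradient * lognormal
    noise. Border positions (outer two rows/columns) carry a wild-type
    control and are flagged.
    """
    config.validate()
    if background not in ("mutant", "control"):
        raise ValueError("background must be 'mutant' or 'control'")
    if rng is None:
        rng = config.rng(_TAG_PLATE)
    if plate_id is None:
        plate_id = f"{query_id}-{background}"

    tf = truth.strains[truth.strains["klass"] == "TF"].reset_index(drop=True)
    tf_ids = tf["strain_id"].tolist()
    tf_fit = tf["fitness"].to_numpy()
    f_a = truth.fitness_of(query_id) if background == "mutant" else 1.0
    effects = {}
    if background == "mutant":
        sub = truth.pairs[truth.pairs["query_id"] == query_id]
        effects = dict(zip(sub["tf_id"], sub["gi_effect"]))

    plate_effect = float(np.exp(rng.normal(0.0, config.plate_effect_sd))) \
        if config.plate_effect_sd > 0 else 1.0

    def gradient(row: int, col: int) -> float:
        g = 1.0
        if config.row_gradient:
            g *= 1.0 + config.row_gradient * (row / (PLATE_ROWS - 1) - 0.5)
        if config.col_gradient:
            g *= 1.0 + config.col_gradient * (col / (PLATE_COLS - 1) - 0.5)
        return g

    rows = []
    for br, bc, ident, border in _block_layout(len(tf_ids)):
        if ident is None:
            strain, fit = None, 0.0
        elif ident == "BORDER":
            strain, fit = "BORDER", f_a  # wt array strain in query background
        else:
            strain = tf_ids[ident]
            fb = tf_fit[ident]
            fit = float(np.clip(f_a * fb + effects.get(strain, 0.0), 0.0, 1.0)) \
                if background == "mutant" else fb
        for pos, (dr, dc) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
            r, c = 2 * br + dr, 2 * bc + dc
            if strain is None:
                size = 0.0
            else:
                noise = float(np.exp(rng.normal(0.0, config.colony_noise_sd))) \
                    if config.colony_noise_sd > 0 else 1.0
                size = config.colony_base_size * fit * plate_effect \
                    * gradient(r, c) * noise
            rows.append((plate_id, r, c, strain if strain else "",
                         pos, size, border))
    return pd.DataFrame(rows, columns=["plate", "row", "col", "strain_id",
                                       "replicate_pos", "size", "border_flag"])


def simulate_feature_table(config: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Protein feature table: disorder length (gamma), conserved-motif count
    (Poisson), PPI count (gamma, rounded), with toxic/nontoxic group means
    from the config and labels from the ground truth."""
    config.validate()
    rng = config.rng(_TAG_FEATURES)
    rows = []
    strains = truth.strains[truth.strains["klass"].isin(["kinase", "TF"])]
    substrate_map: dict[str, list[str]] = {}
    for _, s in truth.substrates.iterrows():
        substrate_map.setdefault(s["tf_id"], []).append(
            f"{s['kinase']}:{s['tier']}")
    for klass in ("kinase", "TF"):
        grp_all = strains[strains["klass"] == klass]
        means = config.feature_group_means.get(klass)
        if means is None:
            raise ValueError(f"no feature group means configured for {klass!r}")
        for toxic_label, key in ((True, "toxic"), (False, "nontoxic")):
            grp = grp_all[grp_all["toxic"] == toxic_label]
            if grp.empty:
                warnings.warn(f"empty {key} {klass} group; no features emitted",
                              stacklevel=2)
                continue
            m_dis, m_motif, m_ppi = means[key]
            if min(m_dis, m_motif, m_ppi) <= 0:
                raise ValueError("feature group means must be positive")
            n = len(grp)
            dis = rng.gamma(config.disorder_shape,
                            m_dis / config.disorder_shape, size=n)
            motifs = rng.poisson(m_motif, size=n)
            ppi = np.floor(rng.gamma(config.ppi_shape,
                                     m_ppi / config.ppi_shape, size=n) + 0.5)
            for i, (_, s) in enumerate(grp.iterrows()):
                rows.append({
                    "gene": s["strain_id"], "klass": klass,
                    "disorder_len": float(dis[i]),
                    "n_motifs": int(motifs[i]), "n_ppi": int(ppi[i]),
                    "toxic": bool(toxic_label),
                    "substrate_of": ";".join(
                        substrate_map.get(s["strain_id"], [])),
                })
    return pd.DataFrame(rows, columns=["gene", "klass", "disorder_len",
                                       "n_motifs", "n_ppi", "toxic",
                                       "substrate_of"])


def write_dataset(config: SimConfig, outdir: str | Path) -> dict:
    """Simulate every product and write the TSVs plus a JSON manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth = simulate_ground_truth(config)

    curves = simulate_growth_curves(config, truth)
    curves.to_csv(out / "growth_curves.tsv", sep="\t", index=False)

    assay_rows = []
    rng = config.rng(_TAG_SPOTS)
    planted = truth.pairs[truth.pairs["gi_effect"] != 0.0]
    for _, row in planted.iterrows():
        fa = min(truth.fitness_of(row["query_id"]), 1.0)
        fb = min(truth.fitness_of(row["tf_id"]), 1.0)
        ind, ctrl = simulate_spot_assay(
            fa, fb, row["gi_effect"], config, rng=rng,
            pair_id=f"{row['query_id']}__{row['tf_id']}", design=row["design"])
        for a in (ind, ctrl):
            assay_rows.append({
                "pair_id": a.pair_id, "design": a.design,
                "condition": a.condition, "wt_spots": a.wt_spots,
                "a_spots": a.a_spots, "b_spots": a.b_spots,
                "double_spots": a.double_spots, "max_spots": a.max_spots,
                "query_id": row["query_id"], "tf_id": row["tf_id"],
            })
    pd.DataFrame(assay_rows).to_csv(out / "spot_assays.tsv", sep="\t",
                                    index=False)

    plate_rng = config.rng(_TAG_PLATE)
    plates = []
    queries = truth.strains[truth.strains["klass"] == "query"]["strain_id"]
    for query_id in queries:
        for background in ("mutant", "control"):
            plates.append(simulate_screen_plate(
                config, truth, query_id, background=background, rng=plate_rng))
    pd.concat(plates, ignore_index=True).to_csv(out / "screen_plates.tsv",
                                                sep="\t", index=False)

    simulate_feature_table(config, truth).to_csv(out / "features.tsv",
                                                 sep="\t", index=False)

    truth.strains.to_csv(out / "truth_strains.tsv", sep="\t", index=False)
    truth.pairs.to_csv(out / "truth_pairs.tsv", sep="\t", index=False)
    truth.substrates.to_csv(out / "truth_substrates.tsv", sep="\t", index=False)

    manifest = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in dataclasses.asdict(config).items()},
                "files": sorted(p.name for p in out.glob("*.tsv"))}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
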