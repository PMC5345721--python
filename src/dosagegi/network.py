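"""Signed bipartite genetic-interaction network assembly and export.

Confirmed GI records are assembled into a bipartite graph: query nodes
(kinase LOF alleles or cyclin OE alleles) on one side, TF OE alleles on
the other. Edges carry the screen design (SDL or DDL), the interaction
sign, and the Genetic Interaction Strength in [-5, 5]; nodes may carry
substrate-evidence tiers (in vitro / in vivo phosphorylation by the
interacting kinase). Gene identity is the node key; allele descriptors
are attributes.

The container is a :class:`networkx.MultiGraph` with the design as the
edge key, so the same pair may carry one SDL and one DDL edge but never
two of the same design. Same-design duplicates with equal sign are merged
(mean strength); opposite signs are conflicts and are excluded (or raise
in strict mode).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .spots import GIRecord, SIGN_NONE

__all__ = [
    "build_network",
    "network_summary",
    "shared_interactors",
    "export_network",
    "write_sif",
    "write_tsv",
    "read_tsv",
    "ConflictError",
]

QUERY_ROLES = {"SDL": "kinase_LOF", "DDL": "cyclin_OE"}
TF_ROLE = "TF_OE"


class ConflictError(ValueError):
    """Opposite-sign duplicate records for the same pair and design."""


def _record_fields(rec: GIRecord) -> tuple[str, str, str, str, float]:
    query = rec.query_id or rec.pair_id.split("__")[0]
    tf = rec.tf_id or (rec.pair_id.split("__")[1] if "__" in rec.pair_id else rec.pair_id)
    return query, tf, rec.design, rec.sign, float(rec.strength)


def build_network(records: Iterable[GIRecord], *, strict: bool = False,
                  evidence: pd.DataFrame | None = None) -> nx.MultiGraph:
    """Assemble confirmed GI records into the bipartite network.

    Records with sign ``none`` or quality flags are ignored (they are not
    confirmed interactions). ``evidence`` may carry columns (tf_id,
    kinase, tier) to annotate TF nodes with phosphorylation evidence.
    Conflicting duplicates are collected in ``graph.graph['conflicts']``
    and excluded; with ``strict`` they raise :class:`ConflictError`.
    A gene appearing on both sides of the bipartition is an error.
    """
    g = nx.MultiGraph()
    g.graph["conflicts"] = []
    pending: dict[tuple[str, str, str], list[tuple[str, float]]] = {}
    for rec in records:
        if rec.sign == SIGN_NONE or not rec.scorable:
            continue
        query, tf, design, sign, strength = _record_fields(rec)
        pending.setdefault((query, tf, design), []).append((sign, strength))

    queries = {q for q, _, _ in pending}
    tfs = {t for _, t, _ in pending}
    overlap = queries & tfs
    if overlap:
        raise ValueError(
            f"bipartiteness violated: {sorted(overlap)} appear as both query "
            "and TF")

    for (query, tf, design), entries in sorted(pending.items()):
        signs = {s for s, _ in entries}
        if len(signs) > 1:
            g.graph["conflicts"].append((query, tf, design))
            continue
        sign = entries[0][0]
        strength = sum(s for _, s in entries) / len(entries)
        g.add_node(query, role=QUERY_ROLES[design], bipartite=0)
        g.add_node(tf, role=TF_ROLE, bipartite=1)
        g.add_edge(query, tf, key=design, design=design, sign=sign,
                   strength=strength)
    if strict and g.graph["conflicts"]:
        raise ConflictError(f"conflicting duplicate records: "
                            f"{g.graph['conflicts']}")

    if evidence is not None:
        for _, row in evidence.iterrows():
            if row["tf_id"] in g:
                g.nodes[row["tf_id"]]["evidence"] = str(row["tier"])
    for node, data in g.nodes(data=True):
        data.setdefault("evidence", "none")
    return g


def network_summary(net: nx.MultiGraph) -> dict:
    """Edge counts by design and sign, node counts, degree distributions."""
    counts = {(d, s): 0 for d in ("SDL", "DDL")
              for s in ("negative", "positive")}
    tf_by_design: dict[str, set] = {"SDL": set(), "DDL": set()}
    query_by_design: dict[str, set] = {"SDL": set(), "DDL": set()}
    for u, v, data in net.edges(data=True):
        d, s = data["design"], data["sign"]
        counts[(d, s)] += 1
        tf, query = (u, v) if net.nodes[u]["role"] == TF_ROLE else (v, u)
        tf_by_design[d].add(tf)
        query_by_design[d].add(query)
    tfs = [n for n, d in net.nodes(data=True) if d["role"] == TF_ROLE]
    queries = [n for n, d in net.nodes(data=True) if d["role"] != TF_ROLE]
    return {
        "n_edges": net.number_of_edges(),
        "edges_by_design_sign": {f"{d}_{s}": c for (d, s), c in counts.items()},
        "n_tfs": len(tfs),
        "n_queries": len(queries),
        "tfs_by_design": {d: len(v) for d, v in tf_by_design.items()},
        "queries_by_design": {d: len(v) for d, v in query_by_design.items()},
        "tf_degree": {n: net.degree(n) for n in sorted(tfs)},
        "query_degree": {n: net.degree(n) for n in sorted(queries)},
        "n_conflicts": len(net.graph.get("conflicts", [])),
    }


def shared_interactors(net: nx.MultiGraph, design_a: str, design_b: str,
                       *, sources: Sequence[str] | None = None) -> set[str]:
    """TFs with at least one edge in each of two designs.

    ``sources`` optionally restricts each design's edges to the named
    query alleles (e.g. TFs with a DDL edge to CLB5/CLB2 and an SDL edge
    to the cognate CDK allele).
    """
    hits: dict[str, set[str]] = {design_a: set(), design_b: set()}
    src = set(sources) if sources is not None else None
    for u, v, data in net.edges(data=True):
        d = data["design"]
        if d not in hits:
            continue
        tf, query = (u, v) if net.nodes[u]["role"] == TF_ROLE else (v, u)
        if src is not None and query not in src:
            continue
        hits[d].add(tf)
    return hits[design_a] & hits[design_b]


def write_sif(net: nx.MultiGraph, path: str | Path) -> None:
    """SIF export; interaction type is '<design>-neg' or '<design>-pos'."""
    with open(path, "w") as fh:
        for u, v, data in sorted(net.edges(data=True)):
            tag = "neg" if data["sign"] == "negative" else "pos"
            query, tf = (u, v) if net.nodes[u]["role"] != TF_ROLE else (v, u)
            fh.write(f"{query}\t{data['design']}-{tag}\t{tf}\n")


def write_tsv(net: nx.MultiGraph, path: str | Path) -> None:
    rows = []
    for u, v, data in sorted(net.edges(data=True)):
        query, tf = (u, v) if net.nodes[u]["role"] != TF_ROLE else (v, u)
        rows.append({
            "query_id": query, "tf_id": tf, "design": data["design"],
            "sign": data["sign"], "strength": data["strength"],
            "query_evidence": net.nodes[query].get("evidence", "none"),
            "tf_evidence": net.nodes[tf].get("evidence", "none"),
        })
    pd.DataFrame(rows, columns=["query_id", "tf_id", "design", "sign",
                                "strength", "query_evidence", "tf_evidence"]
                 ).to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> nx.MultiGraph:
    """Rebuild a network from its TSV export (lossless round trip)."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        records.append(GIRecord(
            pair_id=f"{row['query_id']}__{row['tf_id']}",
            query_id=row["query_id"], tf_id=row["tf_id"],
            design=row["design"], sign=row["sign"],
            strength=row["strength"], gi_score=row["strength"] / 5,
        ))
    g = build_network(records)
    for _, row in df.iterrows():
        if row["tf_evidence"] != "none":
            g.nodes[row["tf_id"]]["evidence"] = row["tf_evidence"]
        if row["query_evidence"] != "none":
            g.nodes[row["query_id"]]["evidence"] = row["query_evidence"]
    return g


def export_network(net: nx.MultiGraph, path: str | Path, *,
                   format: str = "TSV") -> None:
    """Write the network as SIF, GraphML, or TSV."""
    fmt = format.upper()
    if fmt == "SIF":
        write_sif(net, path)
    elif fmt == "GRAPHML":
        g = net.copy()
        g.graph.pop("conflicts", None)  # GraphML attributes must be scalar
        nx.write_graphml(g, path)
    elif fmt == "TSV":
        write_tsv(net, path)
    else:
        raise ValueError(f"unknown network format {format!r}; "
                         "choose SIF, GraphML, or TSV")
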