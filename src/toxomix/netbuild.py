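"""Assembly of the aggregated heterogeneous molecular interaction network.

Three interaction sources are combined into one undirected, weighted graph:
KEGG-style metabolite-enzyme links, STRING-style scored gene-gene links and
mirTarBase-style miRNA-gene links. Source-specific filters (STRING combined
score > 0.7; miRNA links supported by at least two publications and two
non-high-throughput methods) are applied before edge costs are assigned
(0.1 for KEGG and mirTarBase; (1 - combined score) + 0.1 for STRING).
mRNA and protein features of the same gene collapse onto a single gene
node; parallel edges collapse to the minimum cost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .syndata import INTERACTION_COLUMNS, OmicsLayer

logger = logging.getLogger(__name__)

STRING_SCORE_MIN = 0.7  # strictly greater-than
MIRTARBASE_MIN_PUBLICATIONS = 2
MIRTARBASE_MIN_NONHTS = 2
BASE_EDGE_COST = 0.1

_TYPE_RULES = {
    "kegg": {("metabolite", "gene"), ("gene", "metabolite")},
    "string": {("gene", "gene")},
    "mirtarbase": {("mirna", "gene")},
}


@dataclass
class MultiLayerNetwork:
    """Typed molecular nodes with undirected, costed edges."""

    graph: nx.Graph

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def node_type(self, node: str) -> str:
        return self.graph.nodes[node]["layer"]

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def write_sif(self, path, attr_path=None) -> None:
        with open(path, "w") as fh:
            for a, b, data in self.graph.edges(data=True):
                fh.write(f"{a}\t{data.get('provenance', 'link')}\t{b}\n")
        if attr_path:
            rows = [
                {"source": a, "target": b, **{k: v for k, v in d.items()}}
                for a, b, d in self.graph.edges(data=True)
            ]
            pd.DataFrame(rows).to_csv(attr_path, sep="\t", index=False)


def _check_columns(records: pd.DataFrame) -> None:
    missing = [c for c in INTERACTION_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"interaction table lacks columns: {missing}")


def filter_interactions(records: pd.DataFrame) -> pd.DataFrame:
    """Source-specific confidence filters.

    STRING records kept iff combined score > 0.7; mirTarBase iff supported by
    >= 2 publications AND >= 2 non-high-throughput methods; KEGG kept
    unconditionally. Idempotent.
    """
    _check_columns(records)
    unknown = set(records["database"]) - set(_TYPE_RULES)
    if unknown:
        raise ValueError(f"unknown database tag(s): {sorted(unknown)}")
    is_string = records["database"] == "string"
    is_mtb = records["database"] == "mirtarbase"
    is_kegg = records["database"] == "kegg"
    keep = (
        (is_string & (records["combined_score"] > STRING_SCORE_MIN))
        | (
            is_mtb
            & (records["n_publications"] >= MIRTARBASE_MIN_PUBLICATIONS)
            & (records["n_nonhts_methods"] >= MIRTARBASE_MIN_NONHTS)
        )
        | is_kegg
    )
    out = records[keep].reset_index(drop=True)
    for db in ("kegg", "string", "mirtarbase"):
        n_in = int((records["database"] == db).sum())
        n_out = int((out["database"] == db).sum())
        logger.info("filter_interactions: %s kept %d / %d", db, n_out, n_in)
    return out


def assign_edge_weights(records: pd.DataFrame) -> MultiLayerNetwork:
    """Build the costed network from filtered records.

    KEGG/mirTarBase edges cost 0.1; STRING edges (1 - combined score) + 0.1.
    Self loops are dropped; parallel edges collapse to the minimum cost.
    """
    _check_columns(records)
    g = nx.Graph()
    for rec in records.itertuples(index=False):
        db = rec.database
        pair = (rec.source_type, rec.target_type)
        if pair not in _TYPE_RULES.get(db, set()):
            raise ValueError(f"type pair {pair} incompatible with database {db!r}")
        if rec.source_id == rec.target_id:
            continue
        if db == "string":
            score = float(rec.combined_score)
            if not (0 < score < 1):
                raise ValueError(f"STRING combined score outside (0,1): {score}")
            cost = (1.0 - score) + BASE_EDGE_COST
        else:
            cost = BASE_EDGE_COST
        a, b = rec.source_id, rec.target_id
        g.add_node(a, layer=rec.source_type)
        g.add_node(b, layer=rec.target_type)
        if g.has_edge(a, b):
            if cost < g[a][b]["cost"]:
                g[a][b]["cost"] = cost
                g[a][b]["provenance"] = db
        else:
            g.add_edge(a, b, cost=float(cost), provenance=db)
    return MultiLayerNetwork(graph=g)


def harmonize_ids(layers: list[OmicsLayer], network: MultiLayerNetwork) -> tuple[dict[str, str], list[str]]:
    """Map omics features onto network nodes.

    mRNA and protein features of the same gene map to the same gene node;
    metabolite and miRNA features map by their own node ids. Features without
    a resolvable node are returned in the unmapped list.
    """
    nodes = set(network.graph.nodes)
    mapping: dict[str, str] = {}
    unmapped: list[str] = []
    for ly in layers:
        for feat, row in ly.annotations.iterrows():
            node = row.get("node_id", "") or ""
            if node and node in nodes:
                if feat in mapping and mapping[feat] != node:
                    raise ValueError(f"conflicting node mapping for feature {feat}")
                mapping[feat] = node
            else:
                unmapped.append(feat)
    logger.info("harmonize_ids: mapped %d features, %d unmapped", len(mapping), len(unmapped))
    return mapping, unmapped
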