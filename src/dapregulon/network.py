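"""Merge per-TF regulons into one gene regulatory network and export it.

Nodes are TFs and target genes (a target gene that is itself an assayed TF
is typed TF); edges are TF -> gene with evidence summaries.  Exports cover
SIF, GraphML and an edge-list TSV, all Cytoscape-importable.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .regulon import Regulon


def build_network(regulons: list[Regulon],
                  tf_gene_map: dict[str, str] | None = None) -> nx.DiGraph:
    """Directed TF -> target-gene graph with union-of-evidence edge merging.

    ``tf_gene_map`` maps TF names to the locus tags encoding them, so that a
    target gene encoding an assayed TF is typed (and linked) as a TF node.
    """
    tf_gene_map = tf_gene_map or {}
    gene_to_tf = {g: tf for tf, g in tf_gene_map.items()}
    net = nx.DiGraph()
    for regulon in regulons:
        tf_node = regulon.tf
        net.add_node(tf_node, node_type="TF",
                     locus_tag=tf_gene_map.get(regulon.tf, regulon.tf))
        for edge in regulon.edges:
            for gene in edge.target_genes:
                target = gene_to_tf.get(gene, gene)
                if target not in net:
                    net.add_node(target,
                                 node_type="TF" if gene in gene_to_tf else "gene",
                                 locus_tag=gene)
                elif gene in gene_to_tf:
                    net.nodes[target]["node_type"] = "TF"
                evid = ",".join(sorted(edge.evidence.flags))
                sites = ";".join(
                    f"{s.location}:{s.end}:{s.strand}" for s in edge.evidence.sites)
                if net.has_edge(tf_node, target):
                    prev = net.edges[tf_node, target]
                    prev["evidence"] = ",".join(
                        sorted(set(prev["evidence"].split(",")) | set(evid.split(","))))
                    if sites:
                        prev["sites"] = ";".join(
                            sorted(set(filter(None, prev["sites"].split(";"))
                                       | set(sites.split(";")))))
                else:
                    net.add_edge(tf_node, target, evidence=evid,
                                 operon=edge.target_operon, sites=sites)
    return net


def detect_autoregulation(network: nx.DiGraph) -> list[str]:
    """TFs that target their own gene (self-edges after TF-node collapsing)."""
    return sorted(n for n in network.nodes
                  if network.nodes[n].get("node_type") == "TF"
                  and network.has_edge(n, n))


def detect_hierarchy(network: nx.DiGraph) -> list[tuple[str, str]]:
    """TF -> TF edges excluding self-edges (regulatory cascades)."""
    out = []
    for u, v in network.edges:
        if u == v:
            continue
        if network.nodes[u].get("node_type") == "TF" and \
           network.nodes[v].get("node_type") == "TF":
            out.append((u, v))
    return sorted(out)


def shared_targets(network: nx.DiGraph, min_regulators: int = 2) -> list[str]:
    """Target nodes regulated by at least ``min_regulators`` distinct TFs."""
    if min_regulators < 2:
        raise ValueError("min_regulators must be >= 2")
    out = []
    for n in network.nodes:
        regulators = {u for u, _ in network.in_edges(n)
                      if network.nodes[u].get("node_type") == "TF" and u != n}
        auto = network.has_edge(n, n)
        if len(regulators) + (1 if auto else 0) >= min_regulators:
            out.append(n)
    return sorted(out)


def annotate_site_overlaps(network: nx.DiGraph, min_overlap: int = 1) -> int:
    """Mark pairs of edges from different TFs whose binding-site intervals
    intersect by at least ``min_overlap`` bp; returns the number of overlaps."""
    intervals = []
    for u, v, data in network.edges(data=True):
        for token in filter(None, (data.get("sites") or "").split(";")):
            start, end, _ = token.split(":")
            intervals.append((u, v, int(start), int(end)))
    n_overlap = 0
    for i, (u1, v1, a1, b1) in enumerate(intervals):
        for u2, v2, a2, b2 in intervals[i + 1:]:
            if u1 == u2:
                continue
            if min(b1, b2) - max(a1, a2) >= min_overlap:
                d1 = network.edges[u1, v1]
                d2 = network.edges[u2, v2]
                d1["site_overlap_with"] = ",".join(sorted(
                    set(filter(None, d1.get("site_overlap_with", "").split(","))) | {u2}))
                d2["site_overlap_with"] = ",".join(sorted(
                    set(filter(None, d2.get("site_overlap_with", "").split(","))) | {u1}))
                n_overlap += 1
    return n_overlap


# ----------------------------------------------------------------------
# Export / import
# ----------------------------------------------------------------------


def write_sif(network: nx.DiGraph, path: str | Path,
              relation: str = "regulates") -> None:
    with open(path, "w") as fh:
        for u, v in sorted(network.edges):
            fh.write(f"{u}\t{relation}\t{v}\n")
        for n in sorted(network.nodes):
            if network.degree(n) == 0:
                fh.write(f"{n}\n")


def read_sif(path: str | Path) -> nx.DiGraph:
    net = nx.DiGraph()
    for line in Path(path).read_text().splitlines():
        parts = line.split("\t")
        if len(parts) >= 3:
            net.add_edge(parts[0], parts[2])
        elif len(parts) == 1 and parts[0]:
            net.add_node(parts[0])
    return net


def write_graphml(network: nx.DiGraph, path: str | Path) -> None:
    nx.write_graphml(network, str(path))


def read_graphml(path: str | Path) -> nx.DiGraph:
    return nx.read_graphml(str(path))


def edges_to_table(network: nx.DiGraph) -> pd.DataFrame:
    rows = [{"tf": u, "target": v, **data} for u, v, data in
            sorted(network.edges(data=True))]
    return pd.DataFrame(rows)


def nodes_to_table(network: nx.DiGraph) -> pd.DataFrame:
    rows = [{"node": n, "type": d.get("node_type", "gene"),
             "locus_tag": d.get("locus_tag", n)}
            for n, d in sorted(network.nodes(data=True))]
    return pd.DataFrame(rows)
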