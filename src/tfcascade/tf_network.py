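"""Directed, root-centred transcription-factor regulatory network.

The root TF (e.g. VDR) points at every primary-target TF
(``root_primary`` edges).  An early-responding TF points at another TF
(``predicted_binding`` edge) when its decayed TF-gene score at the target
TF's gene locus exceeds a threshold; only early TFs emit binding edges.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ROOT_PRIMARY",
    "PREDICTED_BINDING",
    "build_tf_network",
    "export_network",
    "read_network_tsv",
    "to_dot",
]

ROOT_PRIMARY = "root_primary"
PREDICTED_BINDING = "predicted_binding"


def build_tf_network(
    primary_tfs_with_timing: Mapping[str, str],
    score_matrix: pd.DataFrame,
    tf_gene_ids: Mapping[str, str],
    edge_threshold: float | Mapping[str, float],
    root: str = "VDR",
    half_width: int | None = None,
) -> nx.DiGraph:
    """Build the directed TF network.

    Parameters
    ----------
    primary_tfs_with_timing:
        mapping TF name -> ``early`` / ``late`` for every primary-target TF.
    score_matrix:
        genes x TF-motifs decayed score matrix (one condition); rows must
        contain the TF genes, columns the early-TF motifs where they exist.
    tf_gene_ids:
        mapping TF name -> gene_id of the gene coding for that TF.
    edge_threshold:
        absolute score threshold, or a per-TF mapping (e.g. the calibrated
        random-sequence thresholds).
    """
    graph = nx.DiGraph(root=root)
    if half_width is not None:
        graph.graph["half_width"] = half_width
    graph.add_node(root, timing="root", is_root=True)
    for tf, timing in primary_tfs_with_timing.items():
        if timing not in ("early", "late"):
            raise ValueError(f"timing for {tf} must be early/late, got {timing!r}")
        if tf == root:
            raise ValueError("the root TF cannot also be a primary-target node")
        graph.add_node(tf, timing=timing, is_root=False)
        graph.add_edge(root, tf, evidence=ROOT_PRIMARY)
    early_tfs = [tf for tf, t in primary_tfs_with_timing.items() if t == "early"]
    for source in early_tfs:
        if source not in score_matrix.columns:
            logger.warning(
                "early TF %s has no motif column in the score matrix; "
                "no outgoing binding edges", source,
            )
            continue
        threshold = (
            edge_threshold[source]
            if isinstance(edge_threshold, Mapping)
            else float(edge_threshold)
        )
        for target in primary_tfs_with_timing:
            if target == source:
                continue
            gene = tf_gene_ids.get(target)
            if gene is None or gene not in score_matrix.index:
                logger.warning(
                    "no gene row for TF %s in the score matrix; skipped", target
                )
                continue
            score = float(score_matrix.at[gene, source])
            if score > threshold:
                graph.add_edge(
                    source, target,
                    evidence=PREDICTED_BINDING, affinity_score=score,
                )
    return graph


def export_network(
    network: nx.DiGraph, prefix: str | Path, fmt: str = "tsv"
) -> list[Path]:
    """Write the network; returns the paths written.

    ``tsv`` writes ``<prefix>.edges.tsv`` (source, target, evidence,
    affinity_score) and ``<prefix>.nodes.tsv`` (tf_name, timing, is_root)
    and round-trips losslessly through :func:`read_network_tsv`.
    ``graphml`` and ``dot`` write single files.
    """
    prefix = Path(prefix)
    if fmt == "tsv":
        edges_path = prefix.with_suffix(".edges.tsv")
        nodes_path = prefix.with_suffix(".nodes.tsv")
        with open(nodes_path, "w") as fh:
            fh.write("tf_name\ttiming\tis_root\n")
            for node in sorted(network.nodes):
                data = network.nodes[node]
                fh.write(
                    f"{node}\t{data.get('timing', '')}\t"
                    f"{int(bool(data.get('is_root', False)))}\n"
                )
        with open(edges_path, "w") as fh:
            fh.write("source\ttarget\tevidence\taffinity_score\n")
            for u, v, data in sorted(network.edges(data=True)):
                score = data.get("affinity_score")
                fh.write(
                    f"{u}\t{v}\t{data['evidence']}\t"
                    f"{'' if score is None else repr(score)}\n"
                )
        return [edges_path, nodes_path]
    if fmt == "graphml":
        path = prefix.with_suffix(".graphml")
        nx.write_graphml(network, path)
        return [path]
    if fmt == "dot":
        path = prefix.with_suffix(".dot")
        path.write_text(to_dot(network))
        return [path]
    raise ValueError(f"unknown network format {fmt!r}")


def read_network_tsv(prefix: str | Path) -> nx.DiGraph:
    """Read a network written by :func:`export_network` in tsv format."""
    prefix = Path(prefix)
    graph = nx.DiGraph()
    nodes = pd.read_csv(prefix.with_suffix(".nodes.tsv"), sep="\t")
    for _, row in nodes.iterrows():
        graph.add_node(
            row["tf_name"], timing=row["timing"], is_root=bool(row["is_root"])
        )
        if row["is_root"]:
            graph.graph["root"] = row["tf_name"]
    edges = pd.read_csv(prefix.with_suffix(".edges.tsv"), sep="\t")
    for _, row in edges.iterrows():
        attrs = {"evidence": row["evidence"]}
        if pd.notna(row["affinity_score"]):
            attrs["affinity_score"] = float(row["affinity_score"])
        graph.add_edge(row["source"], row["target"], **attrs)
    return graph


def to_dot(network: nx.DiGraph) -> str:
    """Render the network in DOT syntax (plain digraph, quoted names)."""
    lines = ["digraph tf_network {"]
    for node in sorted(network.nodes):
        data = network.nodes[node]
        attrs = f'timing="{data.get("timing", "")}"'
        if data.get("is_root"):
            attrs += ', shape="doublecircle"'
        lines.append(f'    "{node}" [{attrs}];')
    for u, v, data in sorted(network.edges(data=True)):
        attrs = f'evidence="{data["evidence"]}"'
        if "affinity_score" in data:
            attrs += f', weight="{data["affinity_score"]:.6g}"'
        lines.append(f'    "{u}" -> "{v}" [{attrs}];')
    lines.append("}")
    return "\n".join(lines) + "\n"
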