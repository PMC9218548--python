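"""DEG-DEmiR regulatory network: the two-stage filter cascade.

Consensus target pairs are (1) filtered for a significant negative Pearson
correlation (r < 0, P < 0.05) between log-scale expression of the gene and
the miRNA across all analyzed samples, and (2) kept as edges only if, at at
least one developmental stage, both members are significantly DE with
opposite log2 fold-change signs. Correlation P-values are deliberately left
uncorrected across pairs, reproducing the raw 0.05 cut of the emulated
analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class RegulatoryEdge:
    mirna: str
    gene: str
    r: float
    p: float
    active_stages: list  # stages where both members are DE with opposite signs
    stage_lfc: dict  # stage -> (gene log2FC, miRNA log2FC)


def pearson_r_p(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-sided t-test p-value (n-2 df).

    r = +-1 gives P = 0. Zero variance in either vector is undefined and
    raises ``ValueError`` (callers drop the pair with a logged reason).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 for a correlation test")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = math.sqrt(float(xd @ xd))
    sy = math.sqrt(float(yd @ yd))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance")
    r = float(xd @ yd) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(min(1.0, p))


def correlation_filter(
    pairs,
    gene_expr: pd.DataFrame,
    mir_expr: pd.DataFrame,
    samples=None,
    p_threshold: float = 0.05,
) -> dict:
    """Retain pairs with r < 0 and P < ``p_threshold``.

    ``gene_expr``/``mir_expr`` are log2(normalized count + 1) matrices;
    ``samples`` defaults to the samples shared by both matrices (all
    analyzed libraries, pooling stages and forms).
    """
    if samples is None:
        samples = [s for s in gene_expr.columns if s in set(mir_expr.columns)]
    samples = list(samples)
    kept: dict = {}
    for mid, gid in sorted(pairs):
        if gid not in gene_expr.index or mid not in mir_expr.index:
            logger.warning("pair (%s, %s): feature missing from matrix", mid, gid)
            continue
        try:
            r, p = pearson_r_p(
                mir_expr.loc[mid, samples].to_numpy(),
                gene_expr.loc[gid, samples].to_numpy(),
            )
        except ValueError as exc:
            logger.info("pair (%s, %s) dropped: %s", mid, gid, exc)
            continue
        if r < 0 and p < p_threshold:
            kept[(mid, gid)] = (r, p)
    return kept


def stage_sign_filter(
    validated: dict,
    gene_de: dict,
    mir_de: dict,
    padj_threshold: float = 0.05,
) -> list[RegulatoryEdge]:
    """Emit edges active at >= 1 stage.

    ``gene_de``/``mir_de`` map stage -> list of DE results. An edge is
    active at a stage iff gene and miRNA are both significant
    (padj < threshold) there and their log2FC signs are opposite.
    """
    stages = list(gene_de)
    gtab = {
        st: {r.feature: r for r in results} for st, results in gene_de.items()
    }
    mtab = {st: {r.feature: r for r in mir_de[st]} for st in mir_de}
    edges: list[RegulatoryEdge] = []
    for (mid, gid), (r, p) in sorted(validated.items()):
        active = []
        lfcs = {}
        for st in stages:
            g = gtab[st].get(gid)
            m = mtab.get(st, {}).get(mid)
            if g is None or m is None:
                continue
            if g.padj < padj_threshold and m.padj < padj_threshold:
                if g.log2fc * m.log2fc < 0:
                    active.append(st)
                    lfcs[st] = (g.log2fc, m.log2fc)
        if active:
            edges.append(
                RegulatoryEdge(mirna=mid, gene=gid, r=r, p=p,
                               active_stages=active, stage_lfc=lfcs)
            )
    return edges


def mirna_direction(edge: RegulatoryEdge) -> str:
    """Cluster label from the miRNA's fold-change sign at its active stages."""
    signs = {np.sign(edge.stage_lfc[st][1]) for st in edge.active_stages}
    if signs == {1.0}:
        return "up-in-WS"
    if signs == {-1.0}:
        return "up-in-DS"
    return "mixed"


def network_stats(edges, gene_de: dict, mir_de: dict, padj_threshold: float = 0.05) -> dict:
    """Per-stage regulation coverage, node degrees and hub miRNAs."""
    from .diffexpr import call_deg

    per_stage = {}
    for st in gene_de:
        degs = call_deg(gene_de[st], padj_threshold)
        demirs = call_deg(mir_de[st], padj_threshold)
        regulated = {e.gene for e in edges if st in e.active_stages}
        regulating = {e.mirna for e in edges if st in e.active_stages}
        per_stage[st] = {
            "n_degs": len(degs),
            "n_demirs": len(demirs),
            "fraction_degs_regulated": len(regulated & degs) / len(degs) if degs else 0.0,
            "fraction_demirs_regulating": len(regulating & demirs) / len(demirs) if demirs else 0.0,
        }
    mir_degree: dict = {}
    gene_degree: dict = {}
    for e in edges:
        mir_degree[e.mirna] = mir_degree.get(e.mirna, 0) + 1
        gene_degree[e.gene] = gene_degree.get(e.gene, 0) + 1
    hubs = sorted(mir_degree.items(), key=lambda kv: (-kv[1], kv[0]))[:10]
    clusters = {e.mirna: mirna_direction(e) for e in edges}
    return {
        "n_edges": len(edges),
        "per_stage": per_stage,
        "mirna_degree": mir_degree,
        "gene_degree": gene_degree,
        "hub_mirnas": hubs,
        "mirna_cluster": clusters,
    }


def recovery_metrics(edges, truth, gene_de: dict, mir_de: dict,
                     padj_threshold: float = 0.05) -> dict:
    """Precision/recall/F1 of recovered edges against the planted pairs.

    Recall's denominator is the set of planted pairs whose gene and miRNA
    are each DE-called (padj < threshold) at >= 1 stage; with no predicted
    edges, precision is reported as 1 by convention and flagged.
    """
    from .diffexpr import call_deg

    called_genes = set()
    called_mirs = set()
    for st in gene_de:
        called_genes |= call_deg(gene_de[st], padj_threshold)
    for st in mir_de:
        called_mirs |= call_deg(mir_de[st], padj_threshold)
    planted = truth.regulatory_pairs
    recoverable = {
        (m, g) for m, g in planted if g in called_genes and m in called_mirs
    }
    predicted = {(e.mirna, e.gene) for e in edges}
    tp = predicted & planted
    precision = len(tp) / len(predicted) if predicted else 1.0
    recall = len(tp & recoverable) / len(recoverable) if recoverable else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return {
        "n_planted": len(planted),
        "n_recoverable": len(recoverable),
        "n_predicted": len(predicted),
        "n_true_positive": len(tp),
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "empty_prediction": not predicted,
    }


def edges_to_frame(edges) -> pd.DataFrame:
    rows = []
    for e in sorted(edges, key=lambda e: (e.mirna, e.gene)):
        rows.append(
            {
                "miRNA": e.mirna,
                "gene": e.gene,
                "r": e.r,
                "P": e.p,
                "stages": ",".join(e.active_stages),
                "gene_log2FC": ";".join(
                    f"{st}:{e.stage_lfc[st][0]:.4f}" for st in e.active_stages
                ),
                "miRNA_log2FC": ";".join(
                    f"{st}:{e.stage_lfc[st][1]:.4f}" for st in e.active_stages
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["miRNA", "gene", "r", "P", "stages", "gene_log2FC", "miRNA_log2FC"]
    )


def to_graphml(edges, path) -> nx.Graph:
    """Bipartite graph with node attributes (kind, direction cluster, degree)."""
    g = nx.Graph()
    for e in edges:
        g.add_node(e.mirna, kind="miRNA", cluster=mirna_direction(e))
        g.add_node(e.gene, kind="gene")
        g.add_edge(e.mirna, e.gene, r=e.r, P=e.p, stages=",".join(e.active_stages))
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree(node)
    nx.write_graphml(g, path)
    return g
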