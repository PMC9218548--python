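"""End-to-end orchestration: simulate -> DE -> splicing -> targets -> network.

A :class:`RunConfig` captures every threshold of the filter cascade plus the
generator settings; a run is a pure function of the config (seed included),
and every output file name embeds a short hash of the config so edited
thresholds produce distinguishable artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, io, network, sets, splicing, targets
from .design import STAGES, default_design
from .matrix import ExpressionMatrix
from .simulate import GeneratorConfig, generate_truth, simulate_counts, simulate_junctions

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    seed: int = 0
    n_replicates: int = 4
    dropped: tuple = ("DS_rep2_P15",)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    # DE thresholds
    de_padj: float = 0.05
    de_lfc: float = 0.0  # network DEG definition: padj only by default
    # splicing thresholds
    splice_fdr: float = 0.05
    min_junction_sum: int = 20
    junction_mode: str = "sum"
    psi_band: tuple = (0.1, 0.9)
    # target-prediction thresholds
    min_seed_class: str = "7mer-A1"
    min_duplex_score: float = 80.0
    max_ddg: float = -10.0
    flank: int = 17
    # network thresholds
    correlation_p: float = 0.05

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "generator" in d and isinstance(d["generator"], dict):
            gknown = set(GeneratorConfig.__dataclass_fields__)
            gunknown = set(d["generator"]) - gknown
            if gunknown:
                raise ValueError(f"unknown generator keys: {sorted(gunknown)}")
            d["generator"] = GeneratorConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["generator"].items()
            })
        for key in ("dropped", "psi_band"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:8]

    def thresholds(self) -> targets.ConsensusThresholds:
        return targets.ConsensusThresholds(
            min_seed_class=self.min_seed_class,
            min_duplex_score=self.min_duplex_score,
            max_ddg=self.max_ddg,
            flank=self.flank,
        )


def _pooled_de_features(de_tables: dict, padj: float, lfc: float) -> set:
    out: set = set()
    for results in de_tables.values():
        out |= diffexpr.call_deg(results, padj, lfc)
    return out


def analyze(
    config: RunConfig,
    gene_matrix: ExpressionMatrix,
    mir_matrix: ExpressionMatrix,
    events,
    utrs: dict,
    matures: dict,
    eyespot: dict | None = None,
    truth=None,
) -> dict:
    """Run DE, splicing, targets and network on in-memory inputs.

    Returns a dict of intermediate objects plus a JSON-ready ``summary``.
    """
    stages = [st for st in STAGES if st in set(gene_matrix.meta["stage"])]

    logger.info("differential expression: %d genes, %d miRNAs, %d stages",
                len(gene_matrix.features), len(mir_matrix.features), len(stages))
    gene_de = {st: diffexpr.nb_wald_test(gene_matrix, st) for st in stages}
    mir_de = {st: diffexpr.nb_wald_test(mir_matrix, st) for st in stages}

    # splicing: census over all analyzed samples, DS test per stage
    samples = gene_matrix.samples
    norm_means = diffexpr.normalized_counts(gene_matrix).mean(axis=1).to_dict()
    surviving = splicing.census_filter(
        events, samples, config.min_junction_sum, config.junction_mode,
        tuple(config.psi_band),
    )
    census = splicing.event_census(events=surviving, samples=samples,
                                   gene_norm_means=norm_means)
    splice_results = {}
    dsg_tables = {}
    for st in stages:
        meta = gene_matrix.meta
        ws = [s for s in samples if meta.loc[s, "stage"] == st and meta.loc[s, "form"] == "WS"]
        ds = [s for s in samples if meta.loc[s, "stage"] == st and meta.loc[s, "form"] == "DS"]
        res = splicing.diff_splicing(
            events, ws, ds, stage=st,
            min_junction_sum=config.min_junction_sum, mode=config.junction_mode,
        )
        splice_results[st] = res
        dsg_tables[st] = splicing.summarize_dsg(res, config.splice_fdr)

    # pooled DEGs/DEmiRs define the target-prediction universe
    degs = _pooled_de_features(gene_de, config.de_padj, config.de_lfc)
    demirs = _pooled_de_features(mir_de, config.de_padj, config.de_lfc)
    deg_utrs = {}
    for g in sorted(degs):
        if g in utrs:
            deg_utrs[g] = utrs[g]
        else:
            logger.warning("DEG %s has no 3'UTR sequence; excluded", g)
    demir_seqs = {m: matures[m] for m in sorted(demirs) if m in matures}
    logger.info("target prediction: %d DEG UTRs x %d DEmiRs", len(deg_utrs), len(demir_seqs))
    consensus = targets.consensus_targets(demir_seqs, deg_utrs, config.thresholds())

    gene_expr = diffexpr.log_expression(gene_matrix)
    mir_expr = diffexpr.log_expression(mir_matrix)
    validated = network.correlation_filter(
        consensus.pairs, gene_expr, mir_expr, p_threshold=config.correlation_p
    )
    edges = network.stage_sign_filter(validated, gene_de, mir_de, config.de_padj)
    stats = network.network_stats(edges, gene_de, mir_de, config.de_padj)

    # set-overlap summaries
    venn = {}
    for st in stages:
        st_degs = diffexpr.call_deg(gene_de[st], config.de_padj, config.de_lfc)
        st_dsgs = set(dsg_tables[st]["gene"])
        venn[st] = overlap = sets.overlap_counts(st_degs, st_dsgs)
        logger.info("stage %s: DEG-only %d, DSG-only %d, both %d", st, *overlap)
    eyespot_summary = None
    if eyespot:
        gl = sets.GeneList("eyespot", set(eyespot), dict(eyespot))
        crosstab = sets.eyespot_crosstab(gl, gene_de, config.de_padj)
        frac = {}
        for st in stages:
            st_degs = diffexpr.call_deg(gene_de[st], config.de_padj, config.de_lfc)
            st_dsgs = set(dsg_tables[st]["gene"])
            frac[st] = sets.overlap_fraction_de_ds(
                st_degs & gl.members, st_dsgs & gl.members
            )
        eyespot_summary = {"crosstab": crosstab, "fraction_de_and_ds": frac}

    summary = {
        "stages": stages,
        "n_genes": len(gene_matrix.features),
        "n_mirnas": len(mir_matrix.features),
        "n_samples": len(samples),
        "deg_per_stage": {
            st: len(diffexpr.call_deg(gene_de[st], config.de_padj, config.de_lfc))
            for st in stages
        },
        "demir_per_stage": {
            st: len(diffexpr.call_deg(mir_de[st], config.de_padj, config.de_lfc))
            for st in stages
        },
        "n_deg_pooled": len(degs),
        "n_demir_pooled": len(demirs),
        "dsg_per_stage": {st: int(len(dsg_tables[st])) for st in stages},
        "event_census": {k: v for k, v in census.items() if k != "per_library"},
        "venn_deg_dsg": {st: list(venn[st]) for st in stages},
        "n_consensus_pairs": len(consensus.pairs),
        "n_validated_pairs": len(validated),
        "n_edges": len(edges),
        "network": {
            "per_stage": stats["per_stage"],
            "hub_mirnas": stats["hub_mirnas"][:5],
        },
    }
    if eyespot_summary:
        summary["eyespot"] = eyespot_summary
    recovery = None
    if truth is not None:
        recovery = network.recovery_metrics(edges, truth, gene_de, mir_de, config.de_padj)
        summary["recovery"] = recovery

    return {
        "gene_de": gene_de,
        "mir_de": mir_de,
        "splice_results": splice_results,
        "dsg_tables": dsg_tables,
        "census": census,
        "consensus": consensus,
        "validated": validated,
        "edges": edges,
        "network_stats": stats,
        "recovery": recovery,
        "summary": summary,
    }


def run_pipeline(config: RunConfig, outdir, write_dataset: bool = False) -> dict:
    """Synthetic-mode run: generate, analyze, and write all result tables.

    Returns a manifest of output paths plus the summary dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = config.hash()
    log_path = outdir / f"run_{tag}.log"
    handler = logging.FileHandler(log_path)
    logging.getLogger("wingnet").addHandler(handler)
    try:
        design = default_design(config.n_replicates, tuple(config.dropped))
        truth = generate_truth(config.generator, config.seed)
        genes, mirnas = simulate_counts(truth, design)
        events = simulate_junctions(truth, design)
        if write_dataset:
            io.write_dataset(truth, (genes, mirnas), events, outdir / "dataset")
        matures = {m.id: m.mature for m in truth.mirnas}
        res = analyze(
            config, genes, mirnas, events, truth.utrs, matures,
            eyespot=truth.eyespot, truth=truth,
        )
    finally:
        logging.getLogger("wingnet").removeHandler(handler)
        handler.close()

    manifest = {"config_hash": tag, "log": str(log_path)}
    de_frames = []
    for kind, tables in (("gene", res["gene_de"]), ("miRNA", res["mir_de"])):
        for st, results in tables.items():
            df = diffexpr.results_to_frame(results)
            df.insert(0, "kind", kind)
            de_frames.append(df)
    path = outdir / f"de_results_{tag}.tsv"
    pd.concat(de_frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    manifest["de_results"] = str(path)

    splice_frames = [
        splicing.results_to_frame(r) for r in res["splice_results"].values()
    ]
    path = outdir / f"splice_results_{tag}.tsv"
    pd.concat(splice_frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    manifest["splice_results"] = str(path)

    path = outdir / f"edges_{tag}.tsv"
    network.edges_to_frame(res["edges"]).to_csv(path, sep="\t", index=False)
    manifest["edges"] = str(path)
    path = outdir / f"network_{tag}.graphml"
    network.to_graphml(res["edges"], path)
    manifest["graphml"] = str(path)

    path = outdir / f"summary_{tag}.json"
    path.write_text(json.dumps(res["summary"], indent=1, sort_keys=True))
    manifest["summary_json"] = str(path)
    manifest["summary"] = res["summary"]
    path = outdir / f"manifest_{tag}.json"
    path.write_text(json.dumps({k: v for k, v in manifest.items() if k != "summary"},
                               indent=1, sort_keys=True))
    manifest["manifest_json"] = str(path)
    return manifest


def write_report(manifest: dict, path=None) -> str:
    """Human-readable report mirroring the study's summary tables."""
    s = manifest["summary"] if "summary" in manifest else manifest
    lines = ["wingnet run report", "=" * 18, ""]
    lines.append(f"samples analyzed: {s['n_samples']}  "
                 f"genes: {s['n_genes']}  miRNAs: {s['n_mirnas']}")
    lines.append("")
    lines.append("stage    DEGs  DEmiRs  DSGs   Venn(DEG-only/DSG-only/both)")
    for st in s["stages"]:
        venn = s["venn_deg_dsg"][st]
        lines.append(
            f"{st:<8} {s['deg_per_stage'][st]:>4}  {s['demir_per_stage'][st]:>6}"
            f"  {s['dsg_per_stage'][st]:>4}   {venn[0]}/{venn[1]}/{venn[2]}"
        )
    lines.append("")
    census = s["event_census"]
    lines.append(f"splicing census: {census['n_events']} surviving events in "
                 f"{census['n_genes_with_events']} genes")
    by_type = census["by_type"]
    lines.append("  " + "  ".join(f"{t}:{by_type[t]}" for t in sorted(by_type)))
    if "fraction_expressed_genes_with_event" in census:
        lines.append(
            "  fraction of expressed genes with >= 1 event: "
            f"{census['fraction_expressed_genes_with_event']:.3f}"
        )
    lines.append("")
    lines.append(
        f"filter cascade: consensus {s['n_consensus_pairs']} -> "
        f"validated {s['n_validated_pairs']} -> edges {s['n_edges']}"
    )
    for st in s["stages"]:
        ps = s["network"]["per_stage"][st]
        lines.append(
            f"  {st:<6} {100 * ps['fraction_degs_regulated']:5.1f}% of DEGs regulated "
            f"by {100 * ps['fraction_demirs_regulating']:5.1f}% of DEmiRs"
        )
    if s["network"]["hub_mirnas"]:
        hubs = ", ".join(f"{m} ({d})" for m, d in s["network"]["hub_mirnas"])
        lines.append(f"  hub miRNAs: {hubs}")
    if "eyespot" in s:
        lines.append("")
        lines.append("eyespot cross-tabulation (up/down in eyespot vs WS-up/DS-up):")
        for st in s["stages"]:
            tab = s["eyespot"]["crosstab"][st]
            lines.append(
                f"  {st:<6} up&WS {tab['eyespot_up_ws_up']:>3}  up&DS {tab['eyespot_up_ds_up']:>3}"
                f"  down&WS {tab['eyespot_down_ws_up']:>3}  down&DS {tab['eyespot_down_ds_up']:>3}"
            )
    if "recovery" in s:
        r = s["recovery"]
        lines.append("")
        lines.append(
            f"planted-truth recovery: precision {r['precision']:.3f} "
            f"recall {r['recall']:.3f} F1 {r['f1']:.3f} "
            f"({r['n_true_positive']}/{r['n_recoverable']} recoverable pairs)"
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
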