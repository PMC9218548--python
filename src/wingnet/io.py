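"""Readers and writers for the dataset's on-disk formats.

All text formats: FASTA (3'UTRs as DNA, mature miRNAs as RNA), a minimal
GFF3 (1-based inclusive coordinates, + strand, one contig per gene), TSV
count matrices (features as rows, header row of sample ids), TSV sample
metadata, a tidy junction TSV, and the planted-truth JSON. ``read_dataset``
reproduces objects equal to what ``write_dataset`` received.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matrix import ExpressionMatrix
from .simulate import PlantedTruth
from .splicing import events_to_frame, frame_to_events

GFF_HEADER = "##gff-version 3"


def write_fasta(path, records: dict) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_counts(path, counts: pd.DataFrame) -> None:
    counts.rename_axis("feature").to_csv(path, sep="\t")


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return df


def write_metadata(path, meta: pd.DataFrame) -> None:
    meta.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_gff3(path, truth: PlantedTruth) -> None:
    """One contig per gene; gene body spans the contig, three_prime_UTR at
    the recorded offset. Coordinates 1-based inclusive, + strand only."""
    lines = [GFF_HEADER]
    start = truth.utr_start
    for gid in sorted(truth.contigs):
        contig = truth.contigs[gid]
        utr_len = len(truth.utrs[gid])
        lines.append(
            "\t".join(
                [gid, "wingnet", "gene", "1", str(len(contig)), ".", "+", ".",
                 f"ID={gid}"]
            )
        )
        lines.append(
            "\t".join(
                [gid, "wingnet", "three_prime_UTR", str(start + 1),
                 str(start + utr_len), ".", "+", ".",
                 f"ID={gid}.utr3;Parent={gid}"]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3_utrs(path) -> dict:
    """gene id -> (start, end) of its 3'UTR, 1-based inclusive."""
    out = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        fields = line.split("\t")
        if fields[2] != "three_prime_UTR":
            continue
        out[fields[0]] = (int(fields[3]), int(fields[4]))
    return out


def extract_utr(contig: str, start: int, end: int) -> str:
    """Substring at 1-based inclusive GFF3 coordinates."""
    return contig[start - 1 : end]


def write_dataset(truth: PlantedTruth, matrices, events, outdir) -> dict:
    """Write the full dataset; returns a manifest of paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, mirnas = matrices
    manifest = {
        "utr_fasta": outdir / "utrs.fa",
        "contig_fasta": outdir / "contigs.fa",
        "mature_fasta": outdir / "matures.fa",
        "gff3": outdir / "genes.gff3",
        "gene_counts": outdir / "gene_counts.tsv",
        "mirna_counts": outdir / "mirna_counts.tsv",
        "metadata": outdir / "samples.tsv",
        "junctions": outdir / "junctions.tsv",
        "truth": outdir / "truth.json",
        "eyespot": outdir / "eyespot_genes.tsv",
    }
    write_fasta(manifest["utr_fasta"], truth.utrs)
    write_fasta(manifest["contig_fasta"], truth.contigs)
    write_fasta(manifest["mature_fasta"], {m.id: m.mature for m in truth.mirnas})
    write_gff3(manifest["gff3"], truth)
    write_counts(manifest["gene_counts"], genes.counts)
    write_counts(manifest["mirna_counts"], mirnas.counts)
    write_metadata(manifest["metadata"], genes.meta)
    events_to_frame(events, genes.samples).to_csv(manifest["junctions"], sep="\t", index=False)
    manifest["truth"].write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))
    pd.DataFrame(
        sorted(truth.eyespot.items()), columns=["gene", "direction"]
    ).to_csv(manifest["eyespot"], sep="\t", index=False)
    return {k: str(v) for k, v in manifest.items()}


def read_dataset(outdir) -> dict:
    """Read everything back; inverse of :func:`write_dataset`."""
    outdir = Path(outdir)
    truth = PlantedTruth.from_dict(json.loads((outdir / "truth.json").read_text()))
    meta = read_metadata(outdir / "samples.tsv")
    genes = ExpressionMatrix(read_counts(outdir / "gene_counts.tsv"), meta, "gene")
    mirnas = ExpressionMatrix(read_counts(outdir / "mirna_counts.tsv"), meta, "miRNA")
    events = frame_to_events(pd.read_csv(outdir / "junctions.tsv", sep="\t"))
    eyespot_df = pd.read_csv(outdir / "eyespot_genes.tsv", sep="\t")
    return {
        "truth": truth,
        "genes": genes,
        "mirnas": mirnas,
        "events": events,
        "utrs": read_fasta(outdir / "utrs.fa"),
        "contigs": read_fasta(outdir / "contigs.fa"),
        "matures": read_fasta(outdir / "matures.fa"),
        "gff_utrs": read_gff3_utrs(outdir / "genes.gff3"),
        "eyespot": dict(zip(eyespot_df["gene"], eyespot_df["direction"])),
    }
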