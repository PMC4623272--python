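"""Reading and writing the pipeline's file formats.

FASTA via Biopython; tables are plain TSV.  Traces carry their
sequencing-project id as a ``project=<ID>`` token on the FASTA header.
Interval tracks are BED (0-based half-open); locus reports use 1-based
inclusive coordinates.
"""

from __future__ import annotations

import os

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .polymorph import TraceRead


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: dict[str, str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


def read_traces(path) -> list[TraceRead]:
    traces = []
    for rec in SeqIO.parse(str(path), "fasta"):
        project = ""
        for token in rec.description.split():
            if token.startswith("project="):
                project = token.split("=", 1)[1]
        traces.append(TraceRead(rec.id, str(rec.seq).upper(), project))
    return traces


def write_traces(path, traces: list[TraceRead]) -> None:
    SeqIO.write(
        (
            SeqRecord(
                Seq(t.sequence), id=t.trace_id, description=f"project={t.project_id}"
            )
            for t in traces
        ),
        str(path),
        "fasta",
    )


def write_bed(path, intervals) -> None:
    """Intervals: (chrom, start, end[, name]) tuples, 0-based half-open."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2]), *parts[3:4]))
    return out


def write_dataset(dataset, outdir) -> None:
    """Write every artifact of a synthetic dataset to a directory."""
    os.makedirs(outdir, exist_ok=True)
    join = lambda name: os.path.join(outdir, name)
    write_fasta(join("genome.fa"), dataset.chromosomes)
    write_fasta(join("contigs.fa"), dataset.contigs)
    write_fasta(join("consensus.fa"), {"ERE1_synth_consensus": dataset.consensus})
    with open(join("placement.tsv"), "w") as fh:
        fh.write("#contig\tchrom\toffset\torientation\n")
        for row in dataset.placement:
            fh.write("\t".join(str(x) for x in row) + "\n")
    write_bed(join("repeats.bed"), dataset.repeats)
    dataset.genes.to_csv(join("genes.tsv"), sep="\t", index=False)
    dataset.truth_table.to_csv(join("truth.tsv"), sep="\t", index=False)
    write_traces(join("traces.fa"), dataset.traces)
    dataset.genotypes.to_csv(join("genotypes.tsv"), sep="\t")
    dataset.genotype_meta.to_csv(join("individuals.tsv"), sep="\t", index=False)
    with open(join("tree.nwk"), "w") as fh:
        fh.write(dataset.tree + "\n")
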